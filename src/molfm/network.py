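"""SE(3)-equivariant graph denoiser.

The denoiser maps a noisy molecular state g_t (positions, partially masked
categorical tokens) at time t to a predicted clean endpoint: final
coordinates X̂₁ plus logits over atom types, charges, and bond orders.

Architecture: per-node scalar features (rotation-invariant), per-node
geometric vector features (rotation-equivariant, order 1), and per-directed-
edge scalar features flow through a stack of Molecule Update Blocks, each a
node feature update (message-passing with geometric-vector-perceptron
chains), a node position update, and an edge feature update. The GVP
primitive is extended with cross-product channels whose scalar triple
products are pseudo-scalars, making the network sensitive to reflections
(SE(3), not E(3)) — stereoisomers get different outputs.

A residual self-conditioning module lets the network optionally consume its
own previous endpoint prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import ad
from .flows import DenoiserOutput
from .molgraph import InterpolantState, MoleculeGraph, Vocabulary, pair_indices


@dataclass
class NetworkConfig:
    """Feature widths and depths of the denoiser.

    The full-scale default lands in the single-digit-millions parameter
    regime; ``toy()`` is the desk-scale configuration used in tests.
    """

    n_blocks: int = 5
    scalar_dim: int = 280
    vector_dim: int = 16
    edge_dim: int = 160
    rbf_count: int = 16
    rbf_max: float = 10.0

    def __post_init__(self):
        for name in ("n_blocks", "scalar_dim", "vector_dim", "edge_dim", "rbf_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def toy(cls) -> "NetworkConfig":
        return cls(n_blocks=4, scalar_dim=64, vector_dim=8, edge_dim=32,
                   rbf_count=16, rbf_max=10.0)


# ---------------------------------------------------------------------------
# batched graph container
# ---------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """Several molecules packed into one disjoint fully-connected graph."""

    coords: np.ndarray          # (Ntot, 3)
    atom_types: np.ndarray      # (Ntot,)
    charges: np.ndarray         # (Ntot,)
    bond_orders: np.ndarray     # (Ptot,) per unordered pair, molecule-blocked
    node_mol: np.ndarray        # (Ntot,) molecule id per node
    pair_mol: np.ndarray        # (Ptot,) molecule id per pair
    edge_src: np.ndarray        # (Etot,) directed edges (both directions)
    edge_dst: np.ndarray        # (Etot,)
    edge_pair: np.ndarray       # (Etot,) undirected pair id of each directed edge
    node_slices: list[slice]    # per-molecule node ranges
    pair_slices: list[slice]    # per-molecule pair ranges
    times: np.ndarray           # (n_mols,) flow time per molecule

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.bond_orders.shape[0]

    @property
    def n_mols(self) -> int:
        return len(self.node_slices)

    @classmethod
    def from_graphs(cls, graphs: list[MoleculeGraph],
                    times: np.ndarray | float) -> "GraphBatch":
        coords, ats, chs, bos = [], [], [], []
        node_mol, pair_mol = [], []
        esrc, edst, epair = [], [], []
        node_slices, pair_slices = [], []
        n_off = p_off = 0
        for m, g in enumerate(graphs):
            n = g.n_atoms
            coords.append(g.coords)
            ats.append(g.atom_types)
            chs.append(g.charges)
            bos.append(g.bond_orders)
            node_mol.append(np.full(n, m))
            npairs = n * (n - 1) // 2
            pair_mol.append(np.full(npairs, m))
            iu, ju = pair_indices(n)
            pid = np.arange(npairs) + p_off
            esrc.extend([iu + n_off, ju + n_off])
            edst.extend([ju + n_off, iu + n_off])
            epair.extend([pid, pid])
            node_slices.append(slice(n_off, n_off + n))
            pair_slices.append(slice(p_off, p_off + npairs))
            n_off += n
            p_off += npairs
        t = np.asarray(times, dtype=np.float64)
        if t.ndim == 0:
            t = np.full(len(graphs), float(t))
        return cls(
            coords=np.concatenate(coords, axis=0),
            atom_types=np.concatenate(ats),
            charges=np.concatenate(chs),
            bond_orders=np.concatenate(bos) if bos else np.zeros(0, dtype=np.int64),
            node_mol=np.concatenate(node_mol),
            pair_mol=np.concatenate(pair_mol) if pair_mol else np.zeros(0, dtype=np.int64),
            edge_src=np.concatenate(esrc) if esrc else np.zeros(0, dtype=np.int64),
            edge_dst=np.concatenate(edst) if edst else np.zeros(0, dtype=np.int64),
            edge_pair=np.concatenate(epair) if epair else np.zeros(0, dtype=np.int64),
            node_slices=node_slices,
            pair_slices=pair_slices,
            times=t,
        )

    @classmethod
    def from_state(cls, state: InterpolantState) -> "GraphBatch":
        return cls.from_graphs([state.graph], state.time)


def _one_hot(idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(idx), n))
    out[np.arange(len(idx)), np.asarray(idx, dtype=np.int64)] = 1.0
    return out


def time_features(t: np.ndarray) -> np.ndarray:
    """Fourier embedding of flow time: t plus 4 sin/cos pairs."""
    t = np.asarray(t, dtype=np.float64).reshape(-1, 1)
    freqs = np.array([1.0, 2.0, 4.0, 8.0]) * np.pi
    return np.concatenate([t, np.sin(t * freqs), np.cos(t * freqs)], axis=1)


TIME_DIM = 9


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class Linear(ad.Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / np.sqrt(d_in)
        self.W = ad.Tensor(rng.standard_normal((d_in, d_out)) * scale,
                           requires_grad=True)
        self.b = ad.Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x):
        return ad.linear(x, self.W, self.b)


class MLP(ad.Module):
    """Feed-forward stack with SiLU between layers (none after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = ad.silu(x)
        return x


class LayerNorm(ad.Module):
    def __init__(self, dim: int):
        self.gamma = ad.Tensor(np.ones(dim), requires_grad=True)
        self.beta = ad.Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x):
        return ad.layer_norm(x, self.gamma, self.beta)


class GVP(ad.Module):
    """Geometric vector perceptron with cross-product channels.

    Scalar outputs are invariant under proper rotations; vector outputs are
    equivariant. Cross-product channels contribute scalar triple products
    (pseudo-scalars) to the invariant pathway, so outputs differ between a
    chiral input and its mirror image.
    """

    def __init__(self, s_in: int, v_in: int, s_out: int, v_out: int,
                 rng: np.random.Generator, scalar_act=ad.silu,
                 gate_act=ad.sigmoid, zero_init_vout: bool = False):
        self.s_out_dim = s_out
        self.v_out_dim = v_out
        self.scalar_act = scalar_act
        self.gate_act = gate_act
        h = max(v_in, v_out, 1)
        c = h  # cross-product channels
        sv = 1.0 / np.sqrt(v_in)
        self.Wh = ad.Tensor(rng.standard_normal((h, v_in)) * sv, requires_grad=True)
        self.Wa = ad.Tensor(rng.standard_normal((c, v_in)) * sv, requires_grad=True)
        self.Wb = ad.Tensor(rng.standard_normal((c, v_in)) * sv, requires_grad=True)
        self.Wd = ad.Tensor(rng.standard_normal((c, v_in)) * sv, requires_grad=True)
        s_hid = s_out if s_out > 0 else max(v_out, 1)
        self.scalar_lin = Linear(s_in + h + c, s_hid, rng)
        if v_out > 0:
            self.Wmu = ad.Tensor(
                np.zeros((v_out, h + c)) if zero_init_vout
                else rng.standard_normal((v_out, h + c)) / np.sqrt(h + c),
                requires_grad=True)
            self.gate_lin = Linear(s_hid, v_out, rng)

    def __call__(self, s, V):
        Vh = ad.vec_linear(self.Wh, V)
        Vx = ad.cross(ad.vec_linear(self.Wa, V), ad.vec_linear(self.Wb, V))
        triple = ad.dot_last(ad.vec_linear(self.Wd, V), Vx)  # pseudo-scalars
        s_m = self.scalar_lin(ad.concat([s, ad.vnorm(Vh), triple], axis=-1))
        s_out = self.scalar_act(s_m) if self.s_out_dim > 0 else None
        v_out = None
        if self.v_out_dim > 0:
            Vmu = ad.vec_linear(self.Wmu, ad.concat([Vh, Vx], axis=1))
            gate = self.gate_act(self.gate_lin(s_m))
            v_out = ad.mul(Vmu, ad.reshape(gate, (-1, self.v_out_dim, 1)))
        return s_out, v_out


class GVPChain(ad.Module):
    def __init__(self, dims: list[tuple[int, int]], rng: np.random.Generator,
                 zero_init_last: bool = False, last_gate_identity: bool = False):
        self.gvps = []
        for k, ((si, vi), (so, vo)) in enumerate(zip(dims[:-1], dims[1:])):
            last = k == len(dims) - 2
            self.gvps.append(GVP(
                si, vi, so, vo, rng,
                scalar_act=(lambda x: x) if last else ad.silu,
                gate_act=(lambda x: x) if (last and last_gate_identity) else ad.sigmoid,
                zero_init_vout=zero_init_last and last,
            ))

    def __call__(self, s, V):
        for gvp in self.gvps:
            s, V = gvp(s, V)
        return s, V


def vec_rms_norm(V, eps: float = 1e-6):
    """Normalize vector channels by their per-node RMS norm (equivariant).

    Keeps vector-feature magnitudes O(1) across blocks; the direction
    content is untouched, so rotation equivariance is preserved.
    """
    norms = ad.vnorm(V)                       # (N, C)
    rms = ad.power(ad.add(ad.tmean(ad.mul(norms, norms), axis=1, keepdims=True),
                          eps), -0.5)
    return ad.mul(V, ad.reshape(rms, (-1, 1, 1)))


def rbf_embed(d, count: int, d_max: float):
    """Gaussian radial basis of distances; width = center spacing."""
    centers = np.linspace(0.0, d_max, count)
    width = centers[1] - centers[0]
    if isinstance(d, ad.Tensor):
        z = ad.mul(ad.add(ad.reshape(d, (-1, 1)), -centers), 1.0 / width)
        return ad.exp(ad.mul(ad.mul(z, z), -0.5))
    z = (np.reshape(d, (-1, 1)) - centers) / width
    return np.exp(-0.5 * z * z)


# ---------------------------------------------------------------------------
# the denoiser
# ---------------------------------------------------------------------------

class MoleculeUpdateBlock(ad.Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        S, V, E, R = cfg.scalar_dim, cfg.vector_dim, cfg.edge_dim, cfg.rbf_count
        self.cfg = cfg
        # NFU: message chain ψ_M on (sender, receiver, edge, rbf | node vectors,
        # the edge direction, and each endpoint's centroid-relative position —
        # the latter give the cross-product channels independent directions
        # from the first block on)
        self.psi_m = GVPChain([(2 * S + E + R, 2 * V + 3), (S, V), (S, V), (S, V)], rng)
        # node update chain ψ_U on (node, aggregated message)
        self.psi_u = GVPChain([(2 * S, 2 * V), (S, V), (S, V), (S, V)], rng)
        self.node_ln = LayerNorm(S)
        # NPU: ψ_x emits a single position-update vector, identity final gate
        self.psi_x = GVPChain([(S, V), (S, V), (S, V), (0, 1)], rng,
                              zero_init_last=True, last_gate_identity=True)
        # EFU: shallow MLP φ_e on (edge, endpoint scalars, rbf of new distance)
        self.phi_e = MLP([E + 2 * S + R, E, E], rng)
        self.edge_ln = LayerNorm(E)

    def node_feature_update(self, s, v, e, pos, batch: GraphBatch):
        cfg = self.cfg
        src, dst = batch.edge_src, batch.edge_dst
        rel = ad.add(ad.gather(pos, src), ad.mul(ad.gather(pos, dst), -1.0))
        dist = ad.vnorm(rel)
        rbf = rbf_embed(dist, cfg.rbf_count, cfg.rbf_max)
        # unit direction vector; the distance magnitude enters through the RBF
        unit = ad.mul(rel, ad.power(ad.add(ad.reshape(dist, (-1, 1)), 1e-6), -1.0))
        # centroid-relative positions: translation-invariant, equivariant
        centroid = ad.segment_mean(pos, batch.node_mol, batch.n_mols)
        pos_rel = ad.add(pos, ad.mul(ad.gather(centroid, batch.node_mol), -1.0))
        ms_in = ad.concat([ad.gather(s, src), ad.gather(s, dst), e, rbf], axis=-1)
        mv_in = ad.concat([ad.gather(v, src), ad.gather(v, dst),
                           ad.reshape(unit, (-1, 1, 3)),
                           ad.reshape(ad.gather(pos_rel, src), (-1, 1, 3)),
                           ad.reshape(ad.gather(pos_rel, dst), (-1, 1, 3))], axis=1)
        m_s, m_v = self.psi_m(ms_in, mv_in)
        agg_s = ad.segment_mean(m_s, dst, batch.n_nodes)
        agg_v = ad.segment_mean(m_v, dst, batch.n_nodes)
        u_s, u_v = self.psi_u(ad.concat([s, agg_s], axis=-1),
                              ad.concat([v, agg_v], axis=1))
        s = self.node_ln(ad.add(s, u_s))
        v = vec_rms_norm(ad.add(v, u_v))
        return s, v

    def node_position_update(self, s, v, pos):
        _, delta = self.psi_x(s, v)
        return ad.add(pos, ad.reshape(delta, (-1, 3)))

    def edge_feature_update(self, e, s, pos, batch: GraphBatch):
        cfg = self.cfg
        rel = ad.add(ad.gather(pos, batch.edge_src),
                     ad.mul(ad.gather(pos, batch.edge_dst), -1.0))
        rbf = rbf_embed(ad.vnorm(rel), cfg.rbf_count, cfg.rbf_max)
        upd = self.phi_e(ad.concat(
            [e, ad.gather(s, batch.edge_src), ad.gather(s, batch.edge_dst), rbf],
            axis=-1))
        return self.edge_ln(ad.add(e, upd))

    def __call__(self, s, v, e, pos, batch: GraphBatch):
        s, v = self.node_feature_update(s, v, e, pos, batch)
        pos = self.node_position_update(s, v, pos)
        e = self.edge_feature_update(e, s, pos, batch)
        return s, v, e, pos


class SelfConditioningResidual(ad.Module):
    """Residual embeddings of the previous endpoint prediction.

    Produces increments quantifying the difference between g_t and the
    previous ĝ₁: the displacement X̂₁ − x_t seeds equivariant vector
    channels, previous categorical probabilities feed the invariant node and
    edge channels. With no previous prediction the increments are exactly
    zero (the module is skipped).
    """

    def __init__(self, cfg: NetworkConfig, vocab: Vocabulary,
                 rng: np.random.Generator):
        S, V, E, R = cfg.scalar_dim, cfg.vector_dim, cfg.edge_dim, cfg.rbf_count
        self.cfg = cfg
        d_in = vocab.n_atom_types + vocab.n_charges + R
        self.node_mlp = MLP([d_in, S, S], rng)
        self.vec_w = ad.Tensor(rng.standard_normal((V, 1)), requires_grad=True)
        self.edge_lin = Linear(vocab.n_bond_orders, E, rng)

    def __call__(self, batch: GraphBatch, prev: DenoiserOutput):
        cfg = self.cfg
        disp = ad.to_numpy(prev.pred_coords) - batch.coords  # constant input
        node_in = np.concatenate(
            [prev.atom_probs(), prev.charge_probs(),
             rbf_embed(np.linalg.norm(disp, axis=-1), cfg.rbf_count, cfg.rbf_max)],
            axis=-1)
        ds = self.node_mlp(ad.Tensor(node_in))
        dv = ad.vec_linear(self.vec_w, ad.Tensor(disp[:, None, :]))
        de = self.edge_lin(ad.Tensor(prev.bond_probs()[batch.edge_pair]))
        return ds, dv, de


class Denoiser(ad.Module):
    """Endpoint-predicting denoiser over batched molecular graphs."""

    def __init__(self, cfg: NetworkConfig, vocab: Vocabulary, seed: int = 0):
        rng = np.random.default_rng(seed)
        S, V, E = cfg.scalar_dim, cfg.vector_dim, cfg.edge_dim
        self.cfg = cfg
        self.vocab = vocab
        d_node = vocab.n_atom_types + vocab.n_charges + TIME_DIM
        self.node_embed = MLP([d_node, S, S], rng)
        self.edge_embed = Linear(vocab.n_bond_orders, E, rng)
        self.self_cond = SelfConditioningResidual(cfg, vocab, rng)
        self.blocks = [MoleculeUpdateBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.atom_head = MLP([S, S, vocab.n_atom_types], rng)
        self.charge_head = MLP([S, S, vocab.n_charges], rng)
        self.bond_head = MLP([E, E, vocab.n_bond_orders], rng)

    # -- forward -------------------------------------------------------------
    def forward_batch(self, batch: GraphBatch,
                      prev: DenoiserOutput | None = None) -> DenoiserOutput:
        vocab, cfg = self.vocab, self.cfg
        if (batch.atom_types.max(initial=0) >= vocab.n_atom_types
                or batch.charges.max(initial=0) >= vocab.n_charges
                or batch.bond_orders.max(initial=0) >= vocab.n_bond_orders):
            raise ValueError("token index outside the model vocabulary")
        t_node = batch.times[batch.node_mol]
        node_in = np.concatenate(
            [_one_hot(batch.atom_types, vocab.n_atom_types),
             _one_hot(batch.charges, vocab.n_charges),
             time_features(t_node)], axis=-1)
        s = self.node_embed(ad.Tensor(node_in))
        e = self.edge_embed(ad.Tensor(
            _one_hot(batch.bond_orders, vocab.n_bond_orders)[batch.edge_pair]))
        v = ad.Tensor(np.zeros((batch.n_nodes, cfg.vector_dim, 3)))
        pos = ad.Tensor(batch.coords)
        if prev is not None:
            ds, dv, de = self.self_cond(batch, prev)
            s, v, e = ad.add(s, ds), ad.add(v, dv), ad.add(e, de)
        for block in self.blocks:
            s, v, e, pos = block(s, v, e, pos, batch)
        atom_logits = self.atom_head(s)
        charge_logits = self.charge_head(s)
        bond_dir = self.bond_head(e)
        # one bond order per unordered pair: average the two directions
        bond_logits = ad.segment_mean(bond_dir, batch.edge_pair, batch.n_pairs)
        return DenoiserOutput(pred_coords=pos, atom_logits=atom_logits,
                              charge_logits=charge_logits, bond_logits=bond_logits)

    def forward(self, state: InterpolantState,
                prev: DenoiserOutput | None = None) -> DenoiserOutput:
        """Single-molecule convenience wrapper (returns NumPy fields)."""
        with ad.no_grad():
            out = self.forward_batch(GraphBatch.from_state(state), prev)
        return detach_output(out)

    __call__ = forward_batch


def detach_output(out: DenoiserOutput) -> DenoiserOutput:
    return DenoiserOutput(
        pred_coords=ad.to_numpy(out.pred_coords),
        atom_logits=ad.to_numpy(out.atom_logits),
        charge_logits=ad.to_numpy(out.charge_logits),
        bond_logits=ad.to_numpy(out.bond_logits),
    )


def split_output(out: DenoiserOutput, batch: GraphBatch) -> list[DenoiserOutput]:
    """Per-molecule views of a batched output (keeps the autodiff tape)."""
    outs = []
    for ns, ps in zip(batch.node_slices, batch.pair_slices):
        outs.append(DenoiserOutput(
            pred_coords=out.pred_coords[ns],
            atom_logits=out.atom_logits[ns],
            charge_logits=out.charge_logits[ns],
            bond_logits=out.bond_logits[ps],
        ))
    return outs


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: Denoiser, extra: dict | None = None,
                    optimizer_state: dict | None = None) -> None:
    """Weights + config + vocabulary in one .npz archive."""
    meta = {"network": asdict(model.cfg), "vocabulary": model.vocab.to_dict(),
            "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    if optimizer_state is not None:
        arrays["opt/t"] = np.array(optimizer_state["t"])
        for k, v in optimizer_state["m"].items():
            arrays[f"opt/m/{k}"] = v
        for k, v in optimizer_state["v"].items():
            arrays[f"opt/v/{k}"] = v
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[Denoiser, dict, dict | None]:
    """Rebuild a Denoiser (plus extra metadata and optimizer state)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = NetworkConfig(**meta["network"])
        vocab = Vocabulary.from_dict(meta["vocabulary"])
        model = Denoiser(cfg, vocab, seed=0)
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
        model.load_state_dict(state)
        opt_state = None
        if "opt/t" in data.files:
            opt_state = {
                "t": int(data["opt/t"]),
                "m": {k[len("opt/m/"):]: data[k] for k in data.files
                      if k.startswith("opt/m/")},
                "v": {k[len("opt/v/"):]: data[k] for k in data.files
                      if k.startswith("opt/v/")},
            }
    return model, meta.get("extra", {}), opt_state
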