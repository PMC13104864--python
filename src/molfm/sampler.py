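"""Joint inference: Euler integration of coordinates + CTMC token sampling.

Starting from a centered Gaussian point cloud and all-MASK tokens, the
sampler alternates denoiser calls with, per step, a coordinate Euler update
``x ← x + Δt·(X̂₁ − x)/(1−t)`` and an independent categorical transition for
every atom-type/charge/bond token. The previous step's prediction is fed
back as the self-conditioning input. At the final step coordinates land on
X̂₁ exactly (the limit of the Euler step) and any residual MASK resolves to
the denoiser argmax, so outputs are always mask-free; atoms predicted FAKE
are stripped together with their incident pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig, strip_fake_atoms
from .coupling import sample_prior
from .flows import DenoiserOutput, discrete_transition_probs, step_discrete
from .molgraph import DatasetStats, InterpolantState, MoleculeGraph, Vocabulary
from .network import Denoiser, GraphBatch, detach_output, split_output
from . import ad


@dataclass
class SamplerConfig:
    """Inference settings: 250 evenly spaced Euler steps by default."""

    n_steps: int = 250
    eta: float = 0.0
    seed: int = 0
    keep_trajectory: bool = False

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


@dataclass
class TrajectoryRecord:
    """Per-step snapshots of one molecule's generation trajectory."""

    times: list[float] = field(default_factory=list)
    states: list[InterpolantState] = field(default_factory=list)
    outputs: list[DenoiserOutput] = field(default_factory=list)

    def append(self, t: float, state: InterpolantState, out: DenoiserOutput):
        if self.times and t <= self.times[-1]:
            raise ValueError("trajectory times must be strictly increasing")
        self.times.append(t)
        self.states.append(state)
        self.outputs.append(out)


def init_graphs(n_molecules: int, size_source: DatasetStats,
                vocab: Vocabulary, rng: np.random.Generator,
                augment: AugmentConfig | None = None) -> list[MoleculeGraph]:
    """All-MASK graphs with prior coordinates and a fake-atom slot allowance."""
    graphs = []
    for _ in range(n_molecules):
        n_real = size_source.sample_size(rng)
        n_fake = 0
        if augment is not None and augment.p_fake > 0:
            n_fake = int(rng.integers(0, int(np.ceil(augment.p_fake * n_real)) + 1))
        n = n_real + n_fake
        graphs.append(MoleculeGraph(
            coords=sample_prior(n, rng),
            atom_types=np.full(n, vocab.atom_mask_index, dtype=np.int64),
            charges=np.full(n, vocab.charge_mask_index, dtype=np.int64),
            bond_orders=np.full(n * (n - 1) // 2, vocab.bond_mask_index,
                                dtype=np.int64),
        ))
    return graphs


def sample_from_initial(model: Denoiser, graphs: list[MoleculeGraph],
                        cfg: SamplerConfig, rng: np.random.Generator
                        ) -> tuple[list[MoleculeGraph], list[TrajectoryRecord]]:
    """Integrate the joint flow from given initial (all-MASK, prior) graphs."""
    vocab = model.vocab
    graphs = [g.copy() for g in graphs]
    n_steps = cfg.n_steps
    dt = 1.0 / n_steps
    trajs = [TrajectoryRecord() for _ in graphs] if cfg.keep_trajectory else []
    prev: DenoiserOutput | None = None
    for k in range(n_steps):
        t = k / n_steps
        last = k == n_steps - 1
        batch = GraphBatch.from_graphs(graphs, t)
        with ad.no_grad():
            out = detach_output(model.forward_batch(batch, prev))
        per_mol = split_output(out, batch)
        if cfg.keep_trajectory:
            for traj, g, o in zip(trajs, graphs, per_mol):
                traj.append(t, InterpolantState(g.copy(), t), o)
        for g, o in zip(graphs, per_mol):
            if last:
                g.coords = np.asarray(o.pred_coords, dtype=np.float64)
            else:
                g.coords = g.coords + dt * (o.pred_coords - g.coords) / (1.0 - t)
            for tokens, probs, mask_idx in (
                    (g.atom_types, o.atom_probs(), vocab.atom_mask_index),
                    (g.charges, o.charge_probs(), vocab.charge_mask_index),
                    (g.bond_orders, o.bond_probs(), vocab.bond_mask_index)):
                if len(tokens) == 0:
                    continue
                rates = discrete_transition_probs(probs, tokens, t, dt,
                                                  eta=cfg.eta, mask_index=mask_idx)
                tokens[:] = step_discrete(tokens, rates, rng)
                if last:  # terminal guard: resolve stragglers by argmax
                    still = tokens == mask_idx
                    if np.any(still):
                        p = probs[still].copy()
                        p[:, mask_idx] = -np.inf
                        tokens[still] = np.argmax(p, axis=1)
        prev = out
    return graphs, trajs


def sample_molecules(model: Denoiser, n_molecules: int, size_source: DatasetStats,
                     cfg: SamplerConfig | None = None,
                     augment: AugmentConfig | None = None
                     ) -> tuple[list[MoleculeGraph], list[TrajectoryRecord]]:
    """Generate molecules; returns mask-free, FAKE-stripped graphs.

    Sizes are drawn from the training size histogram; extra candidate slots
    are added with the training-time fake-atom rule so the atom counts the
    network sees match training. Trajectories are recorded only when
    ``cfg.keep_trajectory`` (their per-step masks include the slots later
    stripped as FAKE).
    """
    cfg = cfg or SamplerConfig()
    vocab = model.vocab
    rng = np.random.default_rng(cfg.seed)
    graphs = init_graphs(n_molecules, size_source, vocab, rng, augment)
    raw, trajs = sample_from_initial(model, graphs, cfg, rng)
    final = [strip_fake_atoms(g, g.atom_types == vocab.fake_index) for g in raw]
    return final, trajs


def x1_movement(traj: TrajectoryRecord,
                real_mask: np.ndarray | None = None) -> np.ndarray:
    """Mean per-atom displacement of X̂₁ between consecutive steps.

    Returns an array of length ``n_steps − 1``; ``real_mask`` restricts the
    average to real (non-FAKE) atoms.
    """
    if len(traj.outputs) < 2:
        raise ValueError("x1_movement needs a trajectory with >= 2 steps")
    preds = [np.asarray(o.pred_coords, dtype=np.float64) for o in traj.outputs]
    if real_mask is None:
        real_mask = np.ones(preds[0].shape[0], dtype=bool)
    real_mask = np.asarray(real_mask, dtype=bool)
    out = np.empty(len(preds) - 1)
    for k in range(len(preds) - 1):
        disp = np.linalg.norm(preds[k + 1] - preds[k], axis=1)
        out[k] = disp[real_mask].mean()
    return out
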