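"""Training loop: coupling, path sampling, augmentation, loss, optimization.

One training step, per molecule: center the conformer, pad with fake atoms,
draw t ~ U[0, 1), couple the coordinate prior to the (fake-augmented)
target, sample the multi-modal conditional path with geometry distortion,
run the denoiser (with the two-pass self-conditioning branch on a random
fraction of steps, first pass gradient-free), and minimize the weighted sum
of per-modality endpoint losses with Adam under cosine learning-rate decay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import ad
from .augment import AugmentConfig, add_fake_atoms, self_conditioning_schedule
from .coupling import make_coupling
from .flows import LossConfig, multimodal_sample_path
from .molgraph import MoleculeGraph, Vocabulary, center_coords
from .network import (Denoiser, GraphBatch, NetworkConfig, detach_output,
                      load_checkpoint, save_checkpoint)


@dataclass
class TrainConfig:
    """All training hyperparameters (the single source for a run)."""

    batch_size: int = 10
    learning_rate: float = 1e-3
    n_steps: int = 1000
    seed: int = 0
    cosine_decay: bool = True
    min_lr_factor: float = 0.1
    log_every: int = 50
    checkpoint_every: int | None = None
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig.toy)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def _as_conformer_groups(dataset) -> list[list[MoleculeGraph]]:
    """Normalize a dataset to molecule-wise conformer groups."""
    groups = []
    for entry in dataset:
        if isinstance(entry, MoleculeGraph):
            groups.append([entry])
        else:
            groups.append(list(entry))
    return groups


def prepare_example(g1: MoleculeGraph, augment: AugmentConfig,
                    vocab: Vocabulary, rng: np.random.Generator):
    """Build (fake-augmented target, interpolant state) for one molecule."""
    g1 = center_coords(g1)
    g1_aug, fake_mask = add_fake_atoms(g1, augment, rng, vocab)
    g1_aug = center_coords(g1_aug)
    t = float(rng.uniform(0.0, 1.0))
    pair = make_coupling(g1_aug.coords, rng)
    state = multimodal_sample_path(g1_aug, pair, t, rng, vocab, augment)
    return g1_aug, state, fake_mask


def training_step(batch: list[MoleculeGraph], model: Denoiser,
                  loss_cfg: LossConfig, augment: AugmentConfig,
                  rng: np.random.Generator,
                  counters: dict | None = None) -> tuple[ad.Tensor, dict]:
    """Loss (autodiff scalar) and per-modality breakdown for one batch."""
    if not batch:
        raise ValueError("training batch is empty")
    vocab = model.vocab
    targets, states = [], []
    for g1 in batch:
        g1_aug, state, _ = prepare_example(g1, augment, vocab, rng)
        targets.append(g1_aug)
        states.append(state)
    graph_batch = GraphBatch.from_graphs([s.graph for s in states],
                                         np.array([s.time for s in states]))

    prev = None
    if self_conditioning_schedule(augment, rng):
        with ad.no_grad():  # first pass: no gradient tracking
            prev = detach_output(model.forward_batch(graph_batch))
        if counters is not None:
            counters["forward_passes"] = counters.get("forward_passes", 0) + 1
    out = model.forward_batch(graph_batch, prev)
    if counters is not None:
        counters["forward_passes"] = counters.get("forward_passes", 0) + 1

    total, breakdown = _batched_loss(out, targets, states, graph_batch,
                                     loss_cfg, vocab)
    if not np.isfinite(float(total.data)):
        raise RuntimeError(f"non-finite training loss; breakdown: {breakdown}")
    return total, breakdown


def _batched_loss(out, targets, states, graph_batch: GraphBatch,
                  cfg: LossConfig, vocab: Vocabulary):
    """Batch-mean of per-molecule losses in a handful of fused tape ops.

    Algebraically identical to averaging ``total_loss`` over the batch
    (each molecule weighted equally within each modality), but builds four
    weighted-sum nodes instead of four small subgraphs per molecule.
    """
    from .flows import time_weight

    B = len(targets)
    times = np.array([st.time for st in states])
    n_nodes = graph_batch.n_nodes

    # coordinates: Σ_m w(t_m)/B · mean squared error of molecule m
    x1 = np.concatenate([g.coords for g in targets], axis=0)
    coord_w = np.empty(n_nodes)
    for m, ns in enumerate(graph_batch.node_slices):
        n_m = ns.stop - ns.start
        coord_w[ns] = time_weight(times[m], cfg.w_clamp) / (3.0 * n_m * B)
    diff = ad.add(out.pred_coords, -x1)
    coord_term = ad.tsum(ad.mul(ad.mul(diff, diff), coord_w[:, None]))

    def ce_term(logits, final, current, mask_index, slices):
        is_masked = (current == mask_index).astype(np.float64)
        w = np.zeros(len(current))
        for sl in slices:
            n_masked = is_masked[sl].sum()
            if n_masked > 0:
                w[sl] = is_masked[sl] / (n_masked * B)
        if w.sum() == 0:
            return ad.Tensor(0.0)
        picked = ad.gather_cols(ad.log_softmax(logits), final)
        return ad.tsum(ad.mul(picked, -w))

    at_term = ce_term(out.atom_logits,
                      np.concatenate([g.atom_types for g in targets]),
                      graph_batch.atom_types, vocab.atom_mask_index,
                      graph_batch.node_slices)
    ch_term = ce_term(out.charge_logits,
                      np.concatenate([g.charges for g in targets]),
                      graph_batch.charges, vocab.charge_mask_index,
                      graph_batch.node_slices)
    bo_term = ce_term(out.bond_logits,
                      np.concatenate([g.bond_orders for g in targets]),
                      graph_batch.bond_orders, vocab.bond_mask_index,
                      graph_batch.pair_slices)

    breakdown = {"coords": float(coord_term.data),
                 "atom_types": float(at_term.data),
                 "charges": float(ch_term.data),
                 "bonds": float(bo_term.data)}
    total = ad.add(ad.add(ad.mul(coord_term, cfg.weight_coords),
                          ad.mul(at_term, cfg.weight_atom_types)),
                   ad.add(ad.mul(ch_term, cfg.weight_charges),
                          ad.mul(bo_term, cfg.weight_bonds)))
    return total, breakdown


def fit(dataset, config: TrainConfig, vocab: Vocabulary | None = None,
        checkpoint_path=None, resume_from=None, verbose: bool = False):
    """Train a denoiser on a dataset of molecules (or conformer groups).

    Deterministic given ``config.seed``. Returns ``(model, log)`` where the
    log is a list of per-step records; when ``checkpoint_path`` is set, the
    final model (with config and vocabulary embedded) is saved there.
    """
    groups = _as_conformer_groups(dataset)
    if not groups:
        raise ValueError("training dataset is empty")
    vocab = vocab or Vocabulary()
    rng = np.random.default_rng(config.seed)
    start_step = 0
    if resume_from is not None:
        model, extra, opt_state = load_checkpoint(resume_from)
        opt = ad.Adam(model.parameters(), lr=config.learning_rate)
        if opt_state is not None:
            opt.load_state_dict(opt_state)
        start_step = int(extra.get("step", 0))
        # replay the RNG to the resume point for a reproducible continuation
        rng = np.random.default_rng(config.seed)
        for _ in range(start_step):
            _skip_step_rng(rng, groups, config, vocab)
    else:
        model = Denoiser(config.network, vocab, seed=config.seed)
        opt = ad.Adam(model.parameters(), lr=config.learning_rate)

    log: list[dict] = []
    counters: dict = {}
    for step in range(start_step, config.n_steps):
        if config.cosine_decay:
            frac = step / max(config.n_steps - 1, 1)
            opt.lr = config.learning_rate * (
                config.min_lr_factor
                + (1 - config.min_lr_factor) * 0.5 * (1 + np.cos(np.pi * frac)))
        idx = rng.choice(len(groups), size=min(config.batch_size, len(groups)),
                         replace=len(groups) < config.batch_size)
        batch = [groups[i][rng.integers(len(groups[i]))] for i in idx]
        model.zero_grad()
        loss, breakdown = training_step(batch, model, config.loss,
                                        config.augment, rng, counters)
        loss.backward()
        opt.step()
        record = {"step": step, "loss": float(loss.data), **breakdown}
        if step % config.log_every == 0 or step == config.n_steps - 1:
            log.append(record)
            if verbose:
                print(json.dumps(record))
        if (config.checkpoint_every and checkpoint_path
                and (step + 1) % config.checkpoint_every == 0):
            save_checkpoint(checkpoint_path, model,
                            extra={"step": step + 1, "counters": counters},
                            optimizer_state=opt.state_dict())
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model,
                        extra={"step": config.n_steps, "counters": counters},
                        optimizer_state=opt.state_dict())
    return model, log


def _skip_step_rng(rng: np.random.Generator, groups, config: TrainConfig,
                   vocab: Vocabulary) -> None:
    """Advance one step's RNG draws without touching the model.

    Every random draw in a training step (data order, fakes, t, coupling
    prior, path masks, distortion, self-conditioning branch) is independent
    of network weights, so replaying them restores the exact stream and a
    resumed run continues the uninterrupted trajectory bit-for-bit.
    """
    idx = rng.choice(len(groups), size=min(config.batch_size, len(groups)),
                     replace=len(groups) < config.batch_size)
    batch = [groups[i][rng.integers(len(groups[i]))] for i in idx]
    for g1 in batch:
        prepare_example(g1, config.augment, vocab, rng)
    self_conditioning_schedule(config.augment, rng)
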