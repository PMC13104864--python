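"""Training-time self-correction features.

Three cheap augmentations teach the denoiser to detect and repair
off-distribution states during sampling:

* **fake atoms** — pad the target molecule with atoms of a dedicated FAKE
  type placed as Gaussian offsets from randomly chosen real anchor atoms;
  the model learns to recognise and discard superfluous atoms.
* **geometry distortion** — past a time threshold, displace a Bernoulli
  subset of atoms on top of the interpolant so the model sees (and learns
  to fix) corrupted geometry.
* **self-conditioning** — on a fraction of steps, run a gradient-free first
  pass and feed its prediction back as an extra input before the loss pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molgraph import MoleculeGraph, Vocabulary, pair_indices


@dataclass
class AugmentConfig:
    """Hyperparameters of the three self-correction features.

    Defaults: fake-atom budget fraction 0.3 with 1.0 Å anchor offsets;
    distortion probability 0.7 past t = 0.25 with 0.5 Å displacements;
    self-conditioning on half the training steps.
    """

    p_fake: float = 0.3
    sigma_fake: float = 1.0
    p_distort: float = 0.7
    t_distort: float = 0.25
    sigma_distort: float = 0.5
    self_cond_rate: float = 0.5

    def __post_init__(self):
        for name in ("p_fake", "p_distort", "self_cond_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sigma_fake < 0 or self.sigma_distort < 0:
            raise ValueError("sigmas must be >= 0")
        if not 0.0 <= self.t_distort <= 1.0:
            raise ValueError("t_distort outside [0, 1]")


def add_fake_atoms(g1: MoleculeGraph, cfg: AugmentConfig, rng: np.random.Generator,
                   vocab: Vocabulary | None = None, n_fake: int | None = None,
                   return_anchors: bool = False):
    """Append fake atoms to a target molecule.

    The count is drawn uniformly from {0, …, ⌈p_fake·N⌉} unless ``n_fake``
    is forced. Each fake atom sits at a uniformly chosen real anchor plus an
    isotropic Gaussian offset (per-axis std ``sigma_fake``), has atom type
    FAKE, charge 0, and NONE bonds to everything. Returns the augmented
    graph and a boolean mask flagging the fakes (plus the anchor indices
    when ``return_anchors`` is set).
    """
    vocab = vocab or Vocabulary()
    if g1.has_fake(vocab):
        raise ValueError("molecule already contains FAKE atoms")
    n = g1.n_atoms
    if n_fake is None:
        upper = int(np.ceil(cfg.p_fake * n))
        n_fake = int(rng.integers(0, upper + 1))
    if n_fake == 0:
        empty = np.zeros(0, dtype=np.int64)
        return ((g1.copy(), np.zeros(n, dtype=bool), empty) if return_anchors
                else (g1.copy(), np.zeros(n, dtype=bool)))

    anchors = rng.integers(0, n, size=n_fake)
    offsets = rng.standard_normal((n_fake, 3)) * cfg.sigma_fake
    coords = np.vstack([g1.coords, g1.coords[anchors] + offsets])
    atom_types = np.concatenate(
        [g1.atom_types, np.full(n_fake, vocab.fake_index, dtype=np.int64)])
    charges = np.concatenate(
        [g1.charges, np.full(n_fake, vocab.charge_index(0), dtype=np.int64)])

    m = n + n_fake
    dense = np.zeros((m, m), dtype=np.int64)
    iu, ju = pair_indices(n)
    dense[iu, ju] = g1.bond_orders  # fake rows/cols stay NONE
    iu2, ju2 = pair_indices(m)
    bonds = dense[iu2, ju2]

    fake_mask = np.zeros(m, dtype=bool)
    fake_mask[n:] = True
    graph = MoleculeGraph(coords, atom_types, charges, bonds)
    return (graph, fake_mask, anchors) if return_anchors else (graph, fake_mask)


def strip_fake_atoms(g: MoleculeGraph, fake_mask: np.ndarray) -> MoleculeGraph:
    """Remove flagged atoms (and their pairs), recovering the real subgraph."""
    keep = ~np.asarray(fake_mask, dtype=bool)
    idx = np.where(keep)[0]
    dense = g.bond_matrix()[np.ix_(idx, idx)]
    iu, ju = pair_indices(len(idx))
    return MoleculeGraph(g.coords[idx], g.atom_types[idx], g.charges[idx],
                         dense[iu, ju])


def distort_coords(xt: np.ndarray, t: float, cfg: AugmentConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-displace a Bernoulli subset of atoms when t exceeds the onset.

    At ``t ≤ t_distort`` coordinates pass through untouched. Otherwise each
    atom is flagged independently with probability ``p_distort``; flagged
    atoms receive an isotropic displacement with per-axis std
    ``sigma_distort``. Returns (coords, flag mask).
    """
    xt = np.asarray(xt, dtype=np.float64)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"time {t} outside [0, 1]")
    n = xt.shape[0]
    if t <= cfg.t_distort:
        return xt.copy(), np.zeros(n, dtype=bool)
    flagged = rng.random(n) < cfg.p_distort
    out = xt.copy()
    out[flagged] += rng.standard_normal((int(flagged.sum()), 3)) * cfg.sigma_distort
    return out, flagged


def self_conditioning_schedule(cfg: AugmentConfig, rng: np.random.Generator) -> bool:
    """Whether this training step runs the two-pass self-conditioning branch."""
    return bool(rng.random() < cfg.self_cond_rate)
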