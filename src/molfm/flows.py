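"""Conditional probability paths, transition kernels, and losses.

Coordinates follow a deterministic linear interpolant
``x_t = (1−t)·x₀ + t·x₁`` trained with an endpoint (X̂₁) regression loss
weighted by ``w(t) = min((1−t)⁻², w_clamp)``.

Categorical modalities follow masking discrete flow matching: each token
starts as MASK and is revealed along the conditional path
``p_t(a) = t·δ(a₁, a) + (1−t)·δ(M, a)``. Sampling simulates the CTMC whose
per-step transition kernel, for a masked token, jumps to category j with
probability ``Δt·(1+ηt)/(1−t)·p̂(j)`` and, for an unmasked token, remasks
with probability ``ηΔt``. The denoiser is trained with cross-entropy on
masked tokens only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ad
from .augment import AugmentConfig, distort_coords
from .molgraph import InterpolantState, MoleculeGraph, Vocabulary
from .coupling import CouplingPair


@dataclass
class LossConfig:
    """Per-modality loss weights and the clamp on the coordinate weighting."""

    weight_coords: float = 1.0
    weight_atom_types: float = 1.0
    weight_charges: float = 1.0
    weight_bonds: float = 1.0
    w_clamp: float = 100.0

    def __post_init__(self):
        weights = (self.weight_coords, self.weight_atom_types,
                   self.weight_charges, self.weight_bonds)
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("weights must be non-negative with at least one > 0")
        if self.w_clamp < 1:
            raise ValueError("w_clamp must be >= 1")


@dataclass
class DiscreteRates:
    """One Euler step's categorical transition probabilities per token."""

    probs: np.ndarray  # (n_tokens, n_categories), rows sum to 1

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if np.any(self.probs < -1e-12):
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")


@dataclass
class DenoiserOutput:
    """Predicted endpoint: coordinates plus per-token category logits."""

    pred_coords: np.ndarray          # (N, 3)
    atom_logits: np.ndarray          # (N, n_atom_types)
    charge_logits: np.ndarray        # (N, n_charges)
    bond_logits: np.ndarray          # (n_pairs, n_bond_orders)

    def atom_probs(self) -> np.ndarray:
        return ad.softmax_np(ad.to_numpy(self.atom_logits))

    def charge_probs(self) -> np.ndarray:
        return ad.softmax_np(ad.to_numpy(self.charge_logits))

    def bond_probs(self) -> np.ndarray:
        return ad.softmax_np(ad.to_numpy(self.bond_logits))


# ---------------------------------------------------------------------------
# continuous modality
# ---------------------------------------------------------------------------

def interpolate_coords(x0: np.ndarray, x1: np.ndarray, t: float) -> np.ndarray:
    """Linear interpolant ``(1−t)·x0 + t·x1``."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"time {t} outside [0, 1]")
    return (1.0 - t) * np.asarray(x0) + t * np.asarray(x1)


def time_weight(t: float, w_clamp: float = 100.0) -> float:
    """Clamped endpoint-loss weighting ``min((1−t)⁻², w_clamp)``."""
    if t >= 1.0:
        return w_clamp
    return min((1.0 - t) ** -2, w_clamp)


def endpoint_coord_loss(pred, x1, t: float, cfg: LossConfig | None = None):
    """``w(t) ×`` mean squared coordinate error (autodiff-aware)."""
    cfg = cfg or LossConfig()
    w = time_weight(t, cfg.w_clamp)
    if isinstance(pred, ad.Tensor):
        diff = pred - ad.Tensor(np.asarray(x1, dtype=np.float64))
        return ad.mul(ad.tmean(ad.mul(diff, diff)), w)
    diff = np.asarray(pred) - np.asarray(x1)
    return w * float(np.mean(diff * diff))


# ---------------------------------------------------------------------------
# discrete modality
# ---------------------------------------------------------------------------

def sample_discrete_path(final_tokens: np.ndarray, t: float, rng: np.random.Generator,
                         mask_index: int) -> np.ndarray:
    """Conditional-path sample: each token is final with probability t, else MASK."""
    final_tokens = np.asarray(final_tokens, dtype=np.int64)
    if np.any(final_tokens == mask_index):
        raise ValueError("final tokens must not contain MASK")
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"time {t} outside [0, 1]")
    revealed = rng.random(final_tokens.shape) < t
    out = np.full_like(final_tokens, mask_index)
    out[revealed] = final_tokens[revealed]
    return out


def masked_ce_loss(logits, final_tokens: np.ndarray, current_tokens: np.ndarray,
                   mask_index: int):
    """Mean cross-entropy of final tokens, restricted to currently-MASK tokens."""
    final_tokens = np.asarray(final_tokens, dtype=np.int64)
    current_tokens = np.asarray(current_tokens, dtype=np.int64)
    is_masked = (current_tokens == mask_index).astype(np.float64)
    if isinstance(logits, ad.Tensor):
        return ad.masked_cross_entropy(logits, final_tokens, is_masked)
    if is_masked.sum() == 0:
        return 0.0
    logp = np.log(ad.softmax_np(np.asarray(logits, dtype=np.float64)) + 1e-300)
    rows = np.arange(len(final_tokens))
    ce = -logp[rows, final_tokens]
    return float((ce * is_masked).sum() / is_masked.sum())


def discrete_transition_probs(denoiser_probs: np.ndarray, current_tokens: np.ndarray,
                              t: float, dt: float, eta: float = 0.0,
                              mask_index: int | None = None) -> DiscreteRates:
    """Per-token categorical kernel for one Euler step of the masking CTMC.

    Masked token: jump to category j with probability
    ``dt·(1+ηt)/(1−t)·p̂(j)`` (rows clamped and renormalized near t→1);
    unmasked token: remask with probability ``ηΔt``, else stay.
    """
    if not 0.0 <= t < 1.0:
        raise ValueError("t must lie in [0, 1)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if eta < 0:
        raise ValueError("eta must be non-negative")
    probs = np.asarray(denoiser_probs, dtype=np.float64)
    current = np.asarray(current_tokens, dtype=np.int64)
    n_tokens, n_cat = probs.shape
    if mask_index is None:
        mask_index = n_cat - 1
    out = np.zeros((n_tokens, n_cat))
    masked = current == mask_index

    # masked rows: off-diagonal mass dt·(1+ηt)/(1−t)·p̂(j)
    rate = dt * (1.0 + eta * t) / (1.0 - t)
    jump = rate * probs[masked]
    jump[:, mask_index] = 0.0
    total = jump.sum(axis=1, keepdims=True)
    over = total[:, 0] > 1.0
    if np.any(over):  # late-time guard: unmask with certainty
        jump[over] /= total[over]
        total[over] = 1.0
    out[masked] = jump
    out[masked, mask_index] = 1.0 - total[:, 0]

    # unmasked rows: remask with probability ηΔt
    remask = min(eta * dt, 1.0)
    um = ~masked
    out[um, mask_index] = remask
    out[um, current[um]] += 1.0 - remask
    return DiscreteRates(out)


def step_discrete(current_tokens: np.ndarray, rates: DiscreteRates,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample each token independently from its categorical transition row."""
    probs = rates.probs
    cdf = np.cumsum(probs, axis=1)
    u = rng.random((probs.shape[0], 1))
    return np.argmax(u < cdf, axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# multi-modal composition
# ---------------------------------------------------------------------------

def multimodal_sample_path(g1: MoleculeGraph, pair: CouplingPair, t: float,
                           rng: np.random.Generator, vocab: Vocabulary,
                           augment: "AugmentConfig | None" = None) -> InterpolantState:
    """Sample g_t: interpolated (optionally distorted) coords, masked tokens.

    Modalities are conditionally independent given (g₀, g₁): coordinates via
    the linear interpolant, each categorical modality via its own masking
    path draw.
    """
    # draw tokens before distorting coordinates so the distortion config can
    # never perturb the categorical draws of a shared seeded stream
    atom_types = sample_discrete_path(g1.atom_types, t, rng, vocab.atom_mask_index)
    charges = sample_discrete_path(g1.charges, t, rng, vocab.charge_mask_index)
    bonds = sample_discrete_path(g1.bond_orders, t, rng, vocab.bond_mask_index)
    coords = interpolate_coords(pair.x0, pair.x1, t)
    if augment is not None:
        coords, _ = distort_coords(coords, t, augment, rng)
    graph = MoleculeGraph(coords=coords, atom_types=atom_types,
                          charges=charges, bond_orders=bonds)
    return InterpolantState(graph=graph, time=t)


def total_loss(out: DenoiserOutput, g1: MoleculeGraph, state: InterpolantState,
               cfg: LossConfig, vocab: Vocabulary):
    """Weighted sum of per-modality losses, with a per-modality breakdown.

    Works on plain arrays (evaluation) or autodiff tensors (training).
    """
    gt = state.graph
    parts = {
        "coords": endpoint_coord_loss(out.pred_coords, g1.coords, state.time, cfg),
        "atom_types": masked_ce_loss(out.atom_logits, g1.atom_types,
                                     gt.atom_types, vocab.atom_mask_index),
        "charges": masked_ce_loss(out.charge_logits, g1.charges,
                                  gt.charges, vocab.charge_mask_index),
        "bonds": masked_ce_loss(out.bond_logits, g1.bond_orders,
                                gt.bond_orders, vocab.bond_mask_index),
    }
    weights = {"coords": cfg.weight_coords, "atom_types": cfg.weight_atom_types,
               "charges": cfg.weight_charges, "bonds": cfg.weight_bonds}
    terms = [ad.mul(parts[k], weights[k]) if isinstance(parts[k], ad.Tensor)
             else weights[k] * parts[k] for k in parts]
    if any(isinstance(x, ad.Tensor) for x in terms):
        total = terms[0]
        for term in terms[1:]:
            total = ad.add(total, term)
    else:
        total = float(sum(terms))
    return total, parts
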