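"""Equivariant coupling between the coordinate prior and target positions.

The coordinate flow transports a centered standard Gaussian point cloud to
the target conformer along straight lines. Straight-line paths are shortest
when the endpoints are matched well, so the conditioning pair (X₀, X₁) is
built by drawing the prior and then alternating a rigid-body (proper
rotation only) alignment with a squared-distance-minimizing atom assignment
until the assignment stabilizes. Reflections are excluded: the model is
SE(3)-equivariant and must distinguish stereoisomers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation


@dataclass
class CouplingPair:
    """Aligned endpoints of one conditional coordinate path."""

    x0: np.ndarray  # (N, 3) prior coordinates after alignment/permutation
    x1: np.ndarray  # (N, 3) target coordinates
    cost: float     # total squared distance between paired atoms

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=np.float64)
        self.x1 = np.asarray(self.x1, dtype=np.float64)
        if self.x0.shape != self.x1.shape:
            raise ValueError("x0 and x1 must have equal shapes")
        if self.cost < 0:
            raise ValueError("cost must be non-negative")


def sample_prior(n: int, rng: np.random.Generator) -> np.ndarray:
    """Centered i.i.d. standard-normal coordinates for ``n`` atoms."""
    if n < 1:
        raise ValueError("atom count must be >= 1")
    x = rng.standard_normal((n, 3))
    return x - x.mean(axis=0)


def kabsch_align(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation of ``moving`` onto ``fixed`` (both centered).

    Returns ``(R, moving @ R)`` where ``R`` (det +1) minimizes the residual
    squared distance over rotations; reflections are never applied.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("inputs must be matching (N, 3) arrays")
    # align_vectors finds R minimizing ||fixed - R·moving||², det(R) = +1
    import warnings
    with warnings.catch_warnings():
        # degenerate point sets (single atom, collinear) have non-unique optima
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(fixed, moving)
    R = rot.as_matrix().T  # row-vector convention: aligned = moving @ R
    return R, moving @ R


def assign_atoms(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Permutation π minimizing Σᵢ ‖x0[π(i)] − x1[i]‖² (exact, Hungarian)."""
    x0 = np.asarray(x0, dtype=np.float64)
    x1 = np.asarray(x1, dtype=np.float64)
    if x0.shape != x1.shape:
        raise ValueError("equal atom counts required")
    # cost[i, j] = ||x1_i - x0_j||²
    diff = x1[:, None, :] - x0[None, :, :]
    cost = np.einsum("ijk,ijk->ij", diff, diff)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=np.int64)
    perm[rows] = cols
    return perm


def coupling_cost(x0: np.ndarray, x1: np.ndarray) -> float:
    d = x0 - x1
    return float(np.sum(d * d))


def make_coupling(x1: np.ndarray, rng: np.random.Generator,
                  max_rounds: int = 10) -> CouplingPair:
    """Draw the prior and couple it to ``x1`` (centered).

    Alternates proper-rotation alignment and optimal assignment until the
    assignment is a fixed point (at most ``max_rounds`` rounds). Each round
    solves its subproblem exactly, so the paired cost never increases.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x0 = sample_prior(x1.shape[0], rng)
    for _ in range(max_rounds):
        _, x0 = kabsch_align(x0, x1)
        perm = assign_atoms(x0, x1)
        x0 = x0[perm]
        if np.array_equal(perm, np.arange(len(perm))):
            break
    return CouplingPair(x0=x0, x1=x1, cost=coupling_cost(x0, x1))
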