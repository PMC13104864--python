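"""Molecule-quality metrics for generated samples.

The suite runs on molecules alone (SDF or in-memory graphs, no model
required): RDKit-sanitization validity, functional-group deviation against
a training reference (sum over alert groups of the absolute difference in
instances-per-molecule), the out-of-distribution ring-system rate against a
reference ring catalog, optional physical-plausibility and semi-empirical
relaxation wrappers, subset-based confidence intervals, and the linear
additive-effects analysis of endpoint-movement trajectories.
"""

from __future__ import annotations

import shutil
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem

from .molgraph import Vocabulary, to_rdkit


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_rdkit(mols, vocab: Vocabulary) -> list[Chem.Mol | None]:
    """Convert graphs to sanitized RDKit mols; None marks invalid entries."""
    out = []
    for m in mols:
        if isinstance(m, Chem.Mol):
            try:
                Chem.SanitizeMol(m)
                out.append(m)
            except Exception:
                out.append(None)
            continue
        try:
            out.append(to_rdkit(m, vocab, sanitize=True))
        except Exception:
            out.append(None)
    return out


def load_alert_smarts(source="default") -> dict[str, str]:
    """Load a named alert set bundled with the package, or a user file.

    The bundled ``default`` set is a curated list of classic structural
    alerts / reactive functional groups. User files may be
    ``SMARTS<whitespace>name`` lines (``#`` comments) or rd_filters-style
    CSV (``rule_id,smarts,max,description``).
    """
    if source == "default":
        text = (resources.files("molfm") / "data" / "alerts_default.smarts"
                ).read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "," in line and "\t" not in line:  # rd_filters CSV
            parts = line.split(",")
            if len(parts) >= 4 and parts[1]:
                out[parts[3].strip() or parts[0]] = parts[1].strip()
        else:
            parts = line.split(None, 1)
            smarts = parts[0]
            name = parts[1].strip() if len(parts) > 1 else smarts
            out[name] = smarts
    return out


def _compile_smarts(smarts_sets: dict[str, str]) -> dict[str, Chem.Mol]:
    patterns = {}
    for name, sm in smarts_sets.items():
        patt = Chem.MolFromSmarts(sm)
        if patt is None:
            raise ValueError(f"unparsable SMARTS pattern {sm!r} for group {name!r}")
        patterns[name] = patt
    return patterns


# ---------------------------------------------------------------------------
# validity
# ---------------------------------------------------------------------------

def validity_rate(mols, vocab: Vocabulary | None = None
                  ) -> tuple[float, np.ndarray]:
    """Percent of molecules passing RDKit sanitization, plus per-mol flags."""
    if not mols:
        raise ValueError("validity_rate requires a non-empty list")
    vocab = vocab or Vocabulary()
    rd = _as_rdkit(mols, vocab)
    flags = np.array([m is not None for m in rd], dtype=bool)
    return 100.0 * flags.mean(), flags


# ---------------------------------------------------------------------------
# functional-group deviation
# ---------------------------------------------------------------------------

@dataclass
class FunctionalGroupReport:
    """Per-group instance frequencies and their summed absolute deviation."""

    generated_freqs: dict[str, float]
    reference_freqs: dict[str, float]

    @property
    def deviation(self) -> float:
        return float(sum(abs(self.reference_freqs.get(k, 0.0)
                             - self.generated_freqs.get(k, 0.0))
                         for k in set(self.reference_freqs)
                         | set(self.generated_freqs)))


def fg_frequencies(mols, smarts_sets: dict[str, str],
                   vocab: Vocabulary | None = None) -> dict[str, float]:
    """Instances of each group per molecule (may exceed 1)."""
    vocab = vocab or Vocabulary()
    patterns = _compile_smarts(smarts_sets)
    rd = _as_rdkit(mols, vocab)
    n = len(rd)
    freqs = {}
    for name, patt in patterns.items():
        count = sum(len(m.GetSubstructMatches(patt)) for m in rd if m is not None)
        freqs[name] = count / n
    return freqs


def fg_deviation(generated, reference_freqs: dict[str, float],
                 smarts_sets: dict[str, str],
                 vocab: Vocabulary | None = None) -> FunctionalGroupReport:
    """Sum over groups of |reference − generated| instance frequency."""
    gen = fg_frequencies(generated, smarts_sets, vocab)
    return FunctionalGroupReport(generated_freqs=gen,
                                 reference_freqs=dict(reference_freqs))


# ---------------------------------------------------------------------------
# ring systems
# ---------------------------------------------------------------------------

def ring_system_keys(mol: Chem.Mol) -> list[str]:
    """Canonical keys of the ring systems in a molecule.

    A ring system is a connected component of fused rings (rings sharing an
    atom) extended by exocyclic atoms attached through a double bond; its
    key is the canonical SMILES of that atom subset. Hydrogens are made
    implicit first so explicit-H and implicit-H inputs give identical keys.
    """
    mol = Chem.RemoveHs(mol)
    ri = mol.GetRingInfo()
    rings = [set(r) for r in ri.AtomRings()]
    if not rings:
        return []
    # merge rings sharing atoms into fused systems
    systems: list[set[int]] = []
    for ring in rings:
        merged = ring
        rest = []
        for sys_ in systems:
            if sys_ & merged:
                merged = merged | sys_
            else:
                rest.append(sys_)
        systems = rest + [merged]
    keys = []
    for sys_ in systems:
        atoms = set(sys_)
        for bond in mol.GetBonds():
            if bond.GetBondType() == Chem.BondType.DOUBLE:
                a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
                if a in sys_ and b not in sys_:
                    atoms.add(b)
                elif b in sys_ and a not in sys_:
                    atoms.add(a)
        keys.append(Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms),
                                             canonical=True))
    return keys


def ring_reference_from_smiles(smiles_list) -> set[str]:
    """Build a ring-system reference key set from molecule SMILES."""
    keys: set[str] = set()
    for sm in smiles_list:
        mol = Chem.MolFromSmiles(sm)
        if mol is None:
            raise ValueError(f"unparsable SMILES in ring reference: {sm!r}")
        keys.update(ring_system_keys(mol))
    return keys


def load_ring_reference(source="toy") -> set[str]:
    """Load the bundled toy ring reference, or a user file of SMILES lines."""
    if source == "toy":
        text = (resources.files("molfm") / "data" / "toy_ring_reference.txt"
                ).read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    smiles = [ln.strip() for ln in text.splitlines()
              if ln.strip() and not ln.startswith("#")]
    return ring_reference_from_smiles(smiles)


def ood_ring_rate(generated, ring_reference: set[str],
                  vocab: Vocabulary | None = None,
                  per_ring_system: bool = False) -> tuple[float, list[str]]:
    """Rate of generated ring systems absent from the reference catalog.

    Default denominator: occurrences per molecule; ``per_ring_system``
    switches to occurrences per extracted ring system.
    """
    vocab = vocab or Vocabulary()
    rd = _as_rdkit(generated, vocab)
    novel: list[str] = []
    n_systems = 0
    for m in rd:
        if m is None:
            continue
        for key in ring_system_keys(m):
            n_systems += 1
            if key not in ring_reference:
                novel.append(key)
    denom = n_systems if per_ring_system else len(rd)
    rate = len(novel) / denom if denom else 0.0
    return rate, novel


# ---------------------------------------------------------------------------
# optional wrappers
# ---------------------------------------------------------------------------

def pb_validity(mols, vocab: Vocabulary | None = None) -> float | None:
    """Percent passing the PoseBusters physical-plausibility battery.

    Returns None (with a warning) when the posebusters package is absent;
    per-molecule tool failures count as failing the battery.
    """
    vocab = vocab or Vocabulary()
    try:
        from posebusters import PoseBusters  # optional dependency
    except ImportError:
        warnings.warn("posebusters is not installed; PB-validity omitted",
                      stacklevel=2)
        return None
    rd = _as_rdkit(mols, vocab)
    flags = []
    buster = PoseBusters(config="mol")
    for m in rd:
        if m is None:
            flags.append(False)
            continue
        try:
            df = buster.bust([m], None, None)
            flags.append(bool(df.all(axis=1).iloc[0]))
        except Exception:
            flags.append(False)
    return 100.0 * float(np.mean(flags))


def relax_metrics(mols, vocab: Vocabulary | None = None
                  ) -> tuple[float, float] | None:
    """Median energy drop and RMSD under GFN2-xTB minimization.

    Requires the ``xtb`` binary; returns None (with a warning) when absent.
    """
    if shutil.which("xtb") is None:
        warnings.warn("xtb binary not found; relaxation metrics omitted",
                      stacklevel=2)
        return None
    import subprocess
    import tempfile
    from pathlib import Path

    vocab = vocab or Vocabulary()
    rd = _as_rdkit(mols, vocab)
    d_es, rmsds = [], []
    for m in rd:
        if m is None:
            continue
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "mol.sdf"
            Chem.SDWriter(str(inp)).write(m)
            try:
                subprocess.run(["xtb", str(inp), "--opt", "--gfn", "2"],
                               cwd=tmp, capture_output=True, check=True)
                opt = Chem.SDMolSupplier(str(Path(tmp) / "xtbopt.sdf"),
                                         removeHs=False)[0]
                e0 = float(m.GetProp("xtb_energy")) if m.HasProp("xtb_energy") else np.nan
                e1 = float(opt.GetProp("total energy / Eh"))
                d_es.append((e0 - e1) * 627.509)  # Hartree → kcal/mol
                from rdkit.Chem import AllChem
                rmsds.append(AllChem.GetBestRMS(m, opt))
            except Exception:
                continue
    if not d_es:
        return None
    return float(np.median(d_es)), float(np.median(rmsds))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def subset_ci(values, k_subsets: int = 5, statistic=np.mean,
              rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Mean and normal-approximation 95% CI half-width over random subsets.

    Values are shuffled, split into ``k_subsets`` groups, the statistic is
    computed per group, and the half-width is 1.96·sd/√k with the sample
    (ddof=1) standard deviation of the subset statistics.
    """
    values = np.asarray(values, dtype=np.float64)
    if len(values) < k_subsets:
        raise ValueError(f"need at least {k_subsets} values for {k_subsets} subsets")
    rng = rng or np.random.default_rng()
    perm = rng.permutation(len(values))
    stats = np.array([statistic(chunk)
                      for chunk in np.array_split(values[perm], k_subsets)])
    mean = float(stats.mean())
    half = float(1.96 * stats.std(ddof=1) / np.sqrt(k_subsets))
    return mean, half


def subset_stats_ci(stats: np.ndarray) -> tuple[float, float]:
    """CI from precomputed per-subset statistics (closed form of subset_ci)."""
    stats = np.asarray(stats, dtype=np.float64)
    return float(stats.mean()), float(1.96 * stats.std(ddof=1) / np.sqrt(len(stats)))


# ---------------------------------------------------------------------------
# additive-effects analysis of endpoint movement
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("self_conditioning", "fake_atoms", "distortion")


@dataclass
class AdditiveEffects:
    """Per-time OLS coefficients of movement on binary feature indicators."""

    times: np.ndarray
    intercept: np.ndarray                    # (T,)
    coefficients: dict[str, np.ndarray]      # feature → (T,)
    relative_effects: dict[str, np.ndarray]  # coefficient / no-feature baseline


def additive_effects(runs: list[tuple[tuple[bool, bool, bool], np.ndarray]],
                     times: np.ndarray | None = None) -> AdditiveEffects:
    """Fit movement(t) ≈ b₀(t) + Σ_f b_f(t)·1[feature f on], per time step.

    ``runs`` pairs each movement trajectory with its (self-conditioning,
    fake-atoms, distortion) flags. Features constant across all runs are
    dropped (coefficient reported as NaN); a rank-deficient design over the
    varying features raises an error listing the missing combinations. The
    relative effect of a feature is its coefficient divided by the fitted
    baseline with that feature off (others at their observed mean).
    """
    if len({flags for flags, _ in runs}) < 2:
        raise ValueError("need at least 2 distinct feature combinations")
    Y = np.stack([np.asarray(mv, dtype=np.float64) for _, mv in runs])
    F = np.array([[float(b) for b in flags] for flags, _ in runs])
    n_runs, T = Y.shape
    varying = [j for j in range(3) if len(np.unique(F[:, j])) > 1]
    X = np.column_stack([np.ones(n_runs)] + [F[:, j] for j in varying])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        seen = {flags for flags, _ in runs}
        missing = [c for c in _needed_combos(varying) if c not in seen]
        raise ValueError(
            f"rank-deficient feature design; missing combinations: {missing}")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    intercept = beta[0]
    coefficients = {name: np.full(T, np.nan) for name in FEATURE_NAMES}
    relative = {name: np.full(T, np.nan) for name in FEATURE_NAMES}
    mean_flags = F.mean(axis=0)
    for pos, j in enumerate(varying):
        b = beta[1 + pos]
        baseline = intercept.copy()
        for pos2, j2 in enumerate(varying):
            if j2 != j:
                baseline = baseline + beta[1 + pos2] * mean_flags[j2]
        coefficients[FEATURE_NAMES[j]] = b
        with np.errstate(divide="ignore", invalid="ignore"):
            relative[FEATURE_NAMES[j]] = b / baseline
    if times is None:
        times = np.arange(T, dtype=np.float64)
    return AdditiveEffects(times=np.asarray(times), intercept=intercept,
                           coefficients=coefficients, relative_effects=relative)


def _needed_combos(varying):
    from itertools import product
    combos = []
    for bits in product([False, True], repeat=len(varying)):
        base = [False, False, False]
        for j, b in zip(varying, bits):
            base[j] = b
        combos.append(tuple(base))
    return combos


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Batch-level quality summary with optional plausibility fields."""

    percent_valid: float
    fg_deviation: float
    ood_ring_rate: float
    percent_pb_valid: float | None = None
    median_delta_e_relax: float | None = None
    median_rmsd: float | None = None
    subset_means: dict[str, float] = field(default_factory=dict)
    subset_ci_half_widths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.percent_valid <= 100.0:
            raise ValueError("percentages must lie in [0, 100]")

    def to_dict(self) -> dict:
        out = {"percent_valid": self.percent_valid,
               "fg_deviation": self.fg_deviation,
               "ood_ring_rate": self.ood_ring_rate,
               "subset_means": self.subset_means,
               "subset_ci_half_widths": self.subset_ci_half_widths}
        for key in ("percent_pb_valid", "median_delta_e_relax", "median_rmsd"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out


def evaluate(mols, reference_freqs: dict[str, float], ring_reference: set[str],
             smarts_sets: dict[str, str] | None = None,
             vocab: Vocabulary | None = None, k_subsets: int = 5,
             with_posebusters: bool = False, with_xtb: bool = False,
             seed: int = 0) -> MetricsReport:
    """Full metric suite on a batch of molecules (graphs or RDKit mols)."""
    vocab = vocab or Vocabulary()
    smarts_sets = smarts_sets or load_alert_smarts()
    pct_valid, flags = validity_rate(mols, vocab)
    report = fg_deviation(mols, reference_freqs, smarts_sets, vocab)
    rate, _ = ood_ring_rate(mols, ring_reference, vocab)
    subset_means, subset_hw = {}, {}
    if len(mols) >= k_subsets:
        rng = np.random.default_rng(seed)
        m, h = subset_ci(flags.astype(float) * 100.0, k_subsets, np.mean, rng)
        subset_means["percent_valid"], subset_hw["percent_valid"] = m, h
    pb = pb_validity(mols, vocab) if with_posebusters else None
    relax = relax_metrics(mols, vocab) if with_xtb else None
    return MetricsReport(
        percent_valid=pct_valid,
        fg_deviation=report.deviation,
        ood_ring_rate=rate,
        percent_pb_valid=pb,
        median_delta_e_relax=relax[0] if relax else None,
        median_rmsd=relax[1] if relax else None,
        subset_means=subset_means,
        subset_ci_half_widths=subset_hw,
    )
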