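"""Domain types and SDF I/O for 3D molecular graphs.

A molecule is a fully-connected graph ``g = (X, A, C, E)``: Cartesian
coordinates in Å, categorical atom types, formal charges, and a bond order
for every unordered atom pair (most pairs are NONE). Aromatic systems are
kekulized on read so the bond vocabulary has no aromatic category. Two
auxiliary categories exist: a MASK token (the prior state of the discrete
flows, always the last index of each modality) and a FAKE atom type (padding
atoms the generator may introduce and later strip).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem

MASK_TOKEN = "<MASK>"
FAKE_TOKEN = "<FAKE>"
BOND_NAMES = ("NONE", "SINGLE", "DOUBLE", "TRIPLE")

_RD_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}
_BOND_IDX = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
}


class VocabularyError(ValueError):
    """An atom type or charge falls outside the configured vocabulary."""


class ContractError(ValueError):
    """A precondition on graph content (e.g. mask-free) was violated."""


@dataclass(frozen=True)
class Vocabulary:
    """Category sets for the three discrete modalities.

    ``elements`` and ``charge_values`` are the *chemical* categories; the
    full per-modality lists append FAKE (atom types only) and MASK (always
    last). Bond orders are fixed: NONE, SINGLE, DOUBLE, TRIPLE, MASK —
    NONE is a real category (index 0), not a mask.
    """

    elements: tuple[str, ...] = ("H", "C", "N", "O", "F")
    charge_values: tuple[int, ...] = (-2, -1, 0, 1, 2, 3)

    # -- full category lists -------------------------------------------------
    @property
    def atom_types(self) -> tuple[str, ...]:
        return self.elements + (FAKE_TOKEN, MASK_TOKEN)

    @property
    def charges(self) -> tuple:
        return self.charge_values + (MASK_TOKEN,)

    @property
    def bond_orders(self) -> tuple[str, ...]:
        return BOND_NAMES + (MASK_TOKEN,)

    # -- special indices -----------------------------------------------------
    @property
    def fake_index(self) -> int:
        return len(self.elements)

    @property
    def atom_mask_index(self) -> int:
        return len(self.elements) + 1

    @property
    def charge_mask_index(self) -> int:
        return len(self.charge_values)

    @property
    def bond_mask_index(self) -> int:
        return len(BOND_NAMES)

    @property
    def n_atom_types(self) -> int:
        return len(self.elements) + 2

    @property
    def n_charges(self) -> int:
        return len(self.charge_values) + 1

    @property
    def n_bond_orders(self) -> int:
        return len(BOND_NAMES) + 1

    def element_index(self, symbol: str) -> int:
        try:
            return self.elements.index(symbol)
        except ValueError:
            raise VocabularyError(
                f"element {symbol!r} is not in the vocabulary {self.elements}"
            ) from None

    def charge_index(self, charge: int) -> int:
        try:
            return self.charge_values.index(charge)
        except ValueError:
            raise VocabularyError(
                f"formal charge {charge:+d} is not in the vocabulary "
                f"{self.charge_values}"
            ) from None

    def to_dict(self) -> dict:
        return {"elements": list(self.elements),
                "charge_values": [int(c) for c in self.charge_values]}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls(elements=tuple(d["elements"]),
                   charge_values=tuple(int(c) for c in d["charge_values"]))

    @classmethod
    def from_molecules(cls, mols) -> "Vocabulary":
        """Scan RDKit molecules for the element/charge sets they use."""
        elems: set[str] = set()
        charges: set[int] = set()
        for m in mols:
            for a in m.GetAtoms():
                elems.add(a.GetSymbol())
                charges.add(a.GetFormalCharge())
        order = {s: i for i, s in enumerate(
            ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"])}
        return cls(elements=tuple(sorted(elems, key=lambda s: order.get(s, 99))),
                   charge_values=tuple(sorted(charges)))


def pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Unordered-pair (i < j) index arrays in condensed (pdist) order."""
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju


def pair_index(i: int, j: int, n: int) -> int:
    """Condensed index of the unordered pair {i, j} in an n-atom graph."""
    if i == j:
        raise ValueError("no self-pairs")
    if i > j:
        i, j = j, i
    return n * i - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class MoleculeGraph:
    """One molecule: coordinates + categorical modalities.

    ``bond_orders`` holds one category index per unordered pair i<j in
    condensed order (length N(N−1)/2).
    """

    coords: np.ndarray
    atom_types: np.ndarray
    charges: np.ndarray
    bond_orders: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.atom_types = np.asarray(self.atom_types, dtype=np.int64)
        self.charges = np.asarray(self.charges, dtype=np.int64)
        self.bond_orders = np.asarray(self.bond_orders, dtype=np.int64)
        n = self.coords.shape[0]
        if self.atom_types.shape != (n,) or self.charges.shape != (n,):
            raise ValueError("per-atom field length mismatch")
        if self.bond_orders.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"bond_orders must cover the {n * (n - 1) // 2} unordered pairs")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(self.coords.copy(), self.atom_types.copy(),
                             self.charges.copy(), self.bond_orders.copy())

    def bond_matrix(self) -> np.ndarray:
        """Dense symmetric (N, N) bond-order matrix; diagonal 0 (NONE)."""
        n = self.n_atoms
        mat = np.zeros((n, n), dtype=np.int64)
        iu, ju = pair_indices(n)
        mat[iu, ju] = self.bond_orders
        mat[ju, iu] = self.bond_orders
        return mat

    def has_mask(self, vocab: Vocabulary) -> bool:
        return (np.any(self.atom_types == vocab.atom_mask_index)
                or np.any(self.charges == vocab.charge_mask_index)
                or np.any(self.bond_orders == vocab.bond_mask_index))

    def has_fake(self, vocab: Vocabulary) -> bool:
        return bool(np.any(self.atom_types == vocab.fake_index))

    def __eq__(self, other) -> bool:
        if not isinstance(other, MoleculeGraph):
            return NotImplemented
        return (np.array_equal(self.atom_types, other.atom_types)
                and np.array_equal(self.charges, other.charges)
                and np.array_equal(self.bond_orders, other.bond_orders)
                and np.allclose(self.coords, other.coords, atol=1e-12))


@dataclass
class InterpolantState:
    """A partially generated molecule at flow time ``t`` ∈ [0, 1]."""

    graph: MoleculeGraph
    time: float

    def __post_init__(self):
        if not 0.0 <= self.time <= 1.0:
            raise ValueError(f"time {self.time} outside [0, 1]")


# ---------------------------------------------------------------------------
# RDKit conversion
# ---------------------------------------------------------------------------

def from_rdkit(mol: Chem.Mol, vocab: Vocabulary, conf_id: int = 0) -> MoleculeGraph:
    """Convert a sanitized, kekulized RDKit mol with a 3D conformer."""
    n = mol.GetNumAtoms()
    conf = mol.GetConformer(conf_id)
    coords = np.array(conf.GetPositions(), dtype=np.float64)
    atom_types = np.array([vocab.element_index(a.GetSymbol())
                           for a in mol.GetAtoms()], dtype=np.int64)
    charges = np.array([vocab.charge_index(a.GetFormalCharge())
                        for a in mol.GetAtoms()], dtype=np.int64)
    bonds = np.zeros(n * (n - 1) // 2, dtype=np.int64)
    for b in mol.GetBonds():
        bt = b.GetBondType()
        if bt not in _BOND_IDX:
            raise ContractError(f"unsupported bond type {bt} (kekulization failed?)")
        bonds[pair_index(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), n)] = _BOND_IDX[bt]
    return MoleculeGraph(coords, atom_types, charges, bonds)


def to_rdkit(graph: MoleculeGraph, vocab: Vocabulary,
             sanitize: bool = True) -> Chem.Mol:
    """Build an RDKit mol (with conformer) from a mask-free, fake-free graph."""
    if graph.has_mask(vocab):
        raise ContractError("graph contains MASK tokens; cannot build a molecule")
    if graph.has_fake(vocab):
        raise ContractError("graph contains FAKE atoms; strip them first")
    rw = Chem.RWMol()
    for t, c in zip(graph.atom_types, graph.charges):
        atom = Chem.Atom(vocab.atom_types[t])
        atom.SetFormalCharge(int(vocab.charges[c]))
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    n = graph.n_atoms
    iu, ju = pair_indices(n)
    for i, j, o in zip(iu, ju, graph.bond_orders):
        if o != 0:
            rw.AddBond(int(i), int(j), _RD_BOND[int(o)])
    mol = rw.GetMol()
    conf = Chem.Conformer(n)
    for i, (x, y, z) in enumerate(graph.coords):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    mol.AddConformer(conf)
    if sanitize:
        Chem.SanitizeMol(mol)
    return mol


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_sdf(path, vocab: Vocabulary | None = None) -> list[MoleculeGraph]:
    """Read an SDF file into MoleculeGraphs (kekulized, explicit hydrogens).

    Unparsable records are collected and reported as a single warning;
    elements or charges outside the vocabulary raise :class:`VocabularyError`.
    """
    vocab = vocab or Vocabulary()
    import os
    if os.path.getsize(path) == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    graphs: list[MoleculeGraph] = []
    failures: list[tuple[int, str]] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            failures.append((idx, "unparsable record"))
            continue
        try:
            Chem.SanitizeMol(mol)
            Chem.Kekulize(mol, clearAromaticFlags=True)
            if mol.GetNumConformers() == 0:
                raise ValueError("record has no 3D coordinates")
            graphs.append(from_rdkit(mol, vocab))
        except VocabularyError:
            raise
        except Exception as exc:  # per-record parse/sanitize failure
            failures.append((idx, str(exc)))
    if failures:
        detail = "; ".join(f"record {i}: {msg}" for i, msg in failures[:10])
        warnings.warn(f"{len(failures)} SDF record(s) skipped ({detail})",
                      stacklevel=2)
    return graphs


def write_sdf(mols: list[MoleculeGraph], path, vocab: Vocabulary | None = None) -> None:
    """Write mask-free, fake-free graphs as a kekulized V2000 SDF.

    Graphs that fail sanitization (e.g. invalid generated molecules) are
    still written, with only a property-cache update — an SDF of generated
    samples must not silently drop the failures it is meant to expose.
    """
    vocab = vocab or Vocabulary()
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for g in mols:
            try:
                mol = to_rdkit(g, vocab, sanitize=True)
            except ContractError:
                raise
            except Exception:
                mol = to_rdkit(g, vocab, sanitize=False)
                mol.UpdatePropertyCache(strict=False)
                Chem.FastFindRings(mol)
            writer.write(mol)
    finally:
        writer.close()


def center_coords(mol: MoleculeGraph) -> MoleculeGraph:
    """Translate so coordinates have zero mean per axis."""
    if mol.n_atoms < 1:
        raise ValueError("empty molecule")
    return replace(mol, coords=mol.coords - mol.coords.mean(axis=0))


@dataclass
class DatasetStats:
    """Size histogram and per-modality marginal frequencies of a dataset."""

    size_hist: dict[int, int]
    atom_type_freqs: np.ndarray
    charge_freqs: np.ndarray
    bond_order_freqs: np.ndarray
    n_molecules: int = 0

    def sample_size(self, rng: np.random.Generator) -> int:
        sizes = np.array(sorted(self.size_hist))
        counts = np.array([self.size_hist[s] for s in sizes], dtype=np.float64)
        return int(rng.choice(sizes, p=counts / counts.sum()))


def dataset_stats(mols: list[MoleculeGraph],
                  vocab: Vocabulary | None = None) -> DatasetStats:
    """Histogram over molecule sizes plus marginal category frequencies."""
    if not mols:
        raise ValueError("dataset_stats requires a non-empty molecule list")
    vocab = vocab or Vocabulary()
    size_hist: dict[int, int] = {}
    at = np.zeros(vocab.n_atom_types)
    ch = np.zeros(vocab.n_charges)
    bo = np.zeros(vocab.n_bond_orders)
    for g in mols:
        size_hist[g.n_atoms] = size_hist.get(g.n_atoms, 0) + 1
        at += np.bincount(g.atom_types, minlength=vocab.n_atom_types)
        ch += np.bincount(g.charges, minlength=vocab.n_charges)
        bo += np.bincount(g.bond_orders, minlength=vocab.n_bond_orders)
    return DatasetStats(size_hist=size_hist,
                        atom_type_freqs=at / at.sum(),
                        charge_freqs=ch / ch.sum(),
                        bond_order_freqs=bo / bo.sum(),
                        n_molecules=len(mols))
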