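"""Synthetic fixture molecules: small valid organics over {H, C, N, O, F}.

A catalog of ~30 small kekulizable structures (4–20 atoms with explicit
hydrogens, including rings, charged species, a chiral center, and one
deliberately rare alert group) is embedded into 3D with RDKit's distance
geometry (ETKDG, seeded) and a force-field cleanup, so every stage of the
pipeline — I/O, coupling, training, sampling, metrics — is testable with no
download. An optional processing path handles a user-downloaded copy of a
large training archive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem

from .metrics import fg_frequencies, load_alert_smarts, ring_system_keys
from .molgraph import MoleculeGraph, Vocabulary, from_rdkit, write_sdf

# ~30 structures over {H,C,N,O,F}: acyclic + rings, all three bond orders,
# charges in {-1, 0, +1}, one chiral center (alanine), and one rare alert
# group (the single epoxide) to exercise skewed functional-group frequencies.
DEFAULT_CATALOG: tuple[str, ...] = (
    "C",                 # methane
    "N",                 # ammonia
    "C#C",               # ethyne (triple bond)
    "C=O",               # formaldehyde
    "CF",                # fluoromethane
    "CO",                # methanol
    "C=C",               # ethene
    "CN",                # methylamine
    "CC",                # ethane
    "CC#N",              # acetonitrile
    "CCO",               # ethanol
    "CC=O",              # acetaldehyde
    "C1CO1",             # ethylene oxide — the rare alert group
    "CC(N)=O",           # acetamide
    "CC(=O)O",           # acetic acid
    "CC(=O)[O-]",        # acetate (charge −1)
    "C[NH3+]",           # methylammonium (charge +1)
    "FC(F)F",            # fluoroform
    "C1CC1",             # cyclopropane
    "CC(C)=O",           # acetone
    "c1ccoc1",           # furan
    "c1cc[nH]c1",        # pyrrole
    "C1COC1",            # oxetane
    "c1ccncc1",          # pyridine
    "c1ccccc1",          # benzene (kekulization exercise)
    "CNC(C)=O",          # N-methylacetamide
    "C1CCC1",            # cyclobutane
    "N[C@@H](C)C(=O)O",  # L-alanine (chiral center)
    "Oc1ccccc1",         # phenol
    "OCC(O)CO",          # glycerol
    "C1CCNC1",           # pyrrolidine
    "CCOC(C)=O",         # ethyl acetate
)

# the ten smallest, structurally simplest entries: the desk-scale training set
TRAIN_CATALOG: tuple[str, ...] = (
    "C", "N", "C#C", "C=O", "CF", "CO", "C=C", "CN", "CC", "CC=O",
)


@dataclass
class ToyDatasetConfig:
    """Catalog + embedding settings for fixture generation."""

    smiles_catalog: tuple[str, ...] = DEFAULT_CATALOG
    n_conformers_per_molecule: int = 1
    seed: int = 0


def embed_smiles(smiles: str, seed: int, n_conformers: int = 1) -> Chem.Mol:
    """Explicit-H, kekulized 3D structure(s) via seeded distance geometry."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"catalog entry {smiles!r} does not parse")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    for k in range(n_conformers):
        params.randomSeed = seed + 1000 * k + 1
        params.clearConfs = k == 0
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise ValueError(f"3D embedding failed for catalog entry {smiles!r}")
    for conf in mol.GetConformers():
        AllChem.MMFFOptimizeMolecule(mol, confId=conf.GetId(), maxIters=500)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


@dataclass
class FixtureSet:
    """Fixtures plus the companion references computed from them."""

    graphs: list[MoleculeGraph]
    conformer_groups: list[list[MoleculeGraph]]
    fg_reference: dict[str, float]
    ring_reference: set[str]
    vocab: Vocabulary = field(default_factory=Vocabulary)


def generate_fixtures(cfg: ToyDatasetConfig | None = None,
                      vocab: Vocabulary | None = None) -> FixtureSet:
    """Embed the catalog and build companion FG / ring references.

    Deterministic under ``cfg.seed``. The functional-group reference holds
    the alert-group frequencies of the fixture set itself; the ring
    reference holds the canonical keys of every fixture ring system.
    """
    cfg = cfg or ToyDatasetConfig()
    vocab = vocab or Vocabulary()
    graphs: list[MoleculeGraph] = []
    groups: list[list[MoleculeGraph]] = []
    ring_ref: set[str] = set()
    for i, smiles in enumerate(cfg.smiles_catalog):
        mol = embed_smiles(smiles, cfg.seed + 10_000 * i,
                           cfg.n_conformers_per_molecule)
        confs = [from_rdkit(mol, vocab, conf_id=c.GetId())
                 for c in mol.GetConformers()]
        graphs.append(confs[0])
        groups.append(confs)
        ring_ref.update(ring_system_keys(mol))
    fg_ref = fg_frequencies(graphs, load_alert_smarts(), vocab)
    return FixtureSet(graphs=graphs, conformer_groups=groups,
                      fg_reference=fg_ref, ring_reference=ring_ref, vocab=vocab)


def write_fixture_files(out_dir, cfg: ToyDatasetConfig | None = None) -> dict:
    """Write fixtures.sdf plus companion reference files; returns the paths."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fx = generate_fixtures(cfg)
    paths = {
        "sdf": out_dir / "fixtures.sdf",
        "fg_reference": out_dir / "fg_reference.json",
        "ring_reference": out_dir / "ring_reference.txt",
    }
    write_sdf(fx.graphs, paths["sdf"], fx.vocab)
    paths["fg_reference"].write_text(json.dumps(fx.fg_reference, indent=1))
    paths["ring_reference"].write_text(
        "# canonical ring-system keys of the fixture set\n"
        + "\n".join(sorted(fx.ring_reference)) + "\n")
    return paths


def process_geom_drugs(raw_path, splits=("train", "val", "test"),
                       vocab: Vocabulary | None = None) -> dict:
    """Process a user-downloaded large-scale training archive.

    Expects ``raw_path`` to contain one SDF per split (``<split>.sdf``) with
    explicit hydrogens and one record per conformer, grouped by molecule
    title. Returns per-split conformer groups and counts (unique molecules,
    conformers, mean conformers per molecule).
    """
    raw_path = Path(raw_path)
    if not raw_path.exists():
        raise FileNotFoundError(
            f"{raw_path} not found. Download the GEOM-Drugs archive "
            "(Zenodo DOI 10.5281/zenodo.19150583) and extract per-split SDF "
            "files named <split>.sdf before processing.")
    vocab = vocab or Vocabulary(
        elements=("H", "B", "C", "N", "O", "F", "Al", "Si", "P", "S", "Cl",
                  "As", "Br", "I", "Hg", "Bi"),
        charge_values=(-2, -1, 0, 1, 2, 3))
    out: dict[str, dict] = {}
    for split in splits:
        sdf = raw_path / f"{split}.sdf"
        if not sdf.exists():
            raise FileNotFoundError(
                f"missing split file {sdf} (expected <split>.sdf inside the "
                "extracted archive; Zenodo DOI 10.5281/zenodo.19150583)")
        supplier = Chem.SDMolSupplier(str(sdf), removeHs=False, sanitize=False)
        groups: dict[str, list[MoleculeGraph]] = {}
        for idx, mol in enumerate(supplier):
            if mol is None:
                continue
            try:
                Chem.SanitizeMol(mol)
                Chem.Kekulize(mol, clearAromaticFlags=True)
                name = mol.GetProp("_Name") if mol.HasProp("_Name") else str(idx)
                groups.setdefault(name, []).append(from_rdkit(mol, vocab))
            except Exception:
                continue
        n_mol = len(groups)
        n_conf = sum(len(g) for g in groups.values())
        out[split] = {
            "conformer_groups": list(groups.values()),
            "n_molecules": n_mol,
            "n_conformers": n_conf,
            "mean_conformers_per_molecule": n_conf / n_mol if n_mol else 0.0,
        }
    return out
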