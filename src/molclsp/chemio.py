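"""Molecular input/output, synthetic fixture generation and scaffold splitting.

Every molecule is carried as a :class:`MoleculeRecord` whose atom indexing
convention is fixed package-wide: atoms are numbered in the order RDKit
parses ``record.smiles``.  Conformers read from SDF are permuted into that
order, so the 1D token alignment, the 2D graph and the 3D coordinates all
index the same heavy atoms.  Hydrogens are never graph nodes: SDF blocks
with explicit H are stripped to the heavy-atom skeleton (coordinates
included) so the atom count n is identical across modalities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import ConfigurationError, InputError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Conformer",
    "MoleculeRecord",
    "DatasetSplit",
    "read_smiles_table",
    "read_sdf",
    "write_sdf",
    "generate_fixture_set",
    "scaffold_split",
    "bemis_murcko_scaffold",
]


@dataclass
class Conformer:
    """A single 3D conformation: heavy-atom coordinates in Ångström."""

    coords: np.ndarray  # (n, 3) float64

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or self.coords.shape[0] < 1:
            raise InputError(f"conformer coordinates must be (n>=1, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("conformer contains non-finite coordinates")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass
class MoleculeRecord:
    id: str
    smiles: str
    labels: dict[str, float] | None = None
    conformer: Conformer | None = None
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def mol(self) -> Chem.Mol:
        """Parsed RDKit molecule (cached); atom order defines the package-wide
        atom indexing for this record."""
        if self._mol is None:
            m = Chem.MolFromSmiles(self.smiles)
            if m is None or m.GetNumAtoms() == 0:
                raise InputError(f"record {self.id!r}: unparseable SMILES {self.smiles!r}")
            self._mol = m
        return self._mol

    @property
    def n_atoms(self) -> int:
        return self.mol().GetNumAtoms()

    def validate(self) -> None:
        n = self.n_atoms
        if self.conformer is not None and self.conformer.n != n:
            raise InputError(
                f"record {self.id!r}: conformer has {self.conformer.n} atoms, SMILES has {n}"
            )


@dataclass
class DatasetSplit:
    train: list[str]
    valid: list[str]
    test: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"train": self.train, "valid": self.valid, "test": self.test}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        d = json.loads(Path(path).read_text())
        return cls(train=d["train"], valid=d["valid"], test=d["test"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_smiles_table(
    path: str | Path,
    smiles_column: str = "smiles",
    label_columns: list[str] | None = None,
    id_column: str | None = None,
) -> list[MoleculeRecord]:
    """Read a CSV of SMILES (+ optional task labels) into records.

    Rows whose SMILES does not parse are skipped with a warning that lists
    their row numbers.  Duplicate SMILES stay distinct records.
    """
    df = pd.read_csv(path)
    label_columns = label_columns or []
    for col in [smiles_column, *label_columns]:
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} not in {path} (has {list(df.columns)})")
    records: list[MoleculeRecord] = []
    bad_rows: list[int] = []
    for i, row in df.iterrows():
        smi = str(row[smiles_column])
        if Chem.MolFromSmiles(smi) is None:
            bad_rows.append(int(i))
            continue
        labels = None
        if label_columns:
            labels = {c: float(row[c]) for c in label_columns if pd.notna(row[c])}
        rid = str(row[id_column]) if id_column else f"row{i}"
        records.append(MoleculeRecord(id=rid, smiles=smi, labels=labels))
    if bad_rows:
        warnings.warn(f"skipped {len(bad_rows)} unparseable SMILES rows: {bad_rows}")
    if not records:
        raise InputError(f"no valid SMILES rows in {path}")
    return records


def _canonical_record(mol: Chem.Mol, rid: str, labels=None) -> MoleculeRecord:
    """Canonicalize `mol` (with an optional conformer) into a record whose
    conformer rows follow the atom order of the canonical SMILES."""
    smiles = Chem.MolToSmiles(mol)
    order = json.loads(mol.GetProp("_smilesAtomOutputOrder"))
    conf = None
    if mol.GetNumConformers():
        coords = mol.GetConformer().GetPositions()[np.asarray(order)]
        conf = Conformer(coords=coords)
    rec = MoleculeRecord(id=rid, smiles=smiles, labels=labels, conformer=conf)
    rec.validate()
    return rec


def read_sdf(path: str | Path) -> list[MoleculeRecord]:
    """Read a V2000/V3000 SDF; each record carries the block's 3D coordinates.

    Explicit hydrogens are stripped (heavy atoms keep their coordinates) and
    the coordinates are permuted to canonical-SMILES atom order, the indexing
    every other module uses.  Malformed blocks are skipped with a warning.
    """
    if Path(path).stat().st_size == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    records, bad = [], 0
    for i, mol in enumerate(supplier):
        if mol is None or mol.GetNumAtoms() == 0:
            bad += 1
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i}"
        records.append(_canonical_record(mol, name))
    if bad:
        warnings.warn(f"skipped {bad} malformed SDF block(s) in {path}")
    return records


def write_sdf(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write records (requires conformers) as a V2000 SDF."""
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.Mol(rec.mol())
            if rec.conformer is None:
                raise InputError(f"record {rec.id!r} has no conformer to write")
            conf = Chem.Conformer(mol.GetNumAtoms())
            for a in range(mol.GetNumAtoms()):
                x, y, z = rec.conformer.coords[a]
                conf.SetAtomPosition(a, (float(x), float(y), float(z)))
            mol.AddConformer(conf, assignId=True)
            mol.SetProp("_Name", rec.id)
            writer.write(mol)
    finally:
        writer.close()


def write_smiles_table(records: list[MoleculeRecord], path: str | Path) -> None:
    label_keys = sorted({k for r in records if r.labels for k in r.labels})
    rows = []
    for r in records:
        row = {"id": r.id, "smiles": r.smiles}
        for k in label_keys:
            row[k] = (r.labels or {}).get(k, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

# Small drug-like fragments spanning 3-20 heavy atoms: alkanes/branched
# alkanes, alcohols, ethers, amines, carbonyl compounds, halogenated species
# and (hetero)aromatics.  Together they exercise rings, branches, charge-free
# heteroatoms, all common bond orders and both halogen classes.
_FIXTURE_TEMPLATES: tuple[str, ...] = (
    "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCCC", "CCCCCCCCCC",
    "CC(C)C", "CC(C)(C)C", "CCC(C)CC",
    "CCO", "CCCO", "OCCO", "CC(C)O",
    "CCOC", "CCOCC", "COCCOC",
    "CCN", "CCNC", "CN(C)C", "NCCN", "CCCN",
    "CC(=O)C", "CC(=O)OC", "CCOC(C)=O", "CC(=O)N", "CCNC(C)=O", "OC(=O)CC",
    "C=CC", "C=CCC", "CC=CC",
    "CCCl", "CCBr", "CCCF", "ClCCCl", "FC(F)CF", "CC(Cl)C", "BrCCCBr",
    "CCCCCl", "FCCCF", "ClCC(C)C",
    "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1", "Nc1ccccc1",
    "COc1ccccc1", "c1ccncc1", "Cc1ccncc1", "CC(=O)c1ccccc1", "OC(=O)c1ccccc1",
    "c1ccc2ccccc2c1", "Cc1ccc(C)cc1",
    "Clc1ccccc1", "Fc1ccccc1", "Brc1ccccc1", "Clc1ccc(Cl)cc1",
    "Fc1ccc(C)cc1", "ClCc1ccccc1", "Fc1ccc(O)cc1",
)

_HALOGENS = {"F", "Cl", "Br", "I"}


def _embed_conformer(smiles: str, seed: int) -> np.ndarray:
    """Deterministic heavy-atom 3D coordinates for a SMILES (ETKDG with a
    fixed seed; planar 2D fallback if distance-geometry embedding fails)."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    ok = AllChem.EmbedMolecule(mol, params)
    if ok != 0:  # rare for these templates; idealized flat geometry instead
        mol = Chem.MolFromSmiles(smiles)
        AllChem.Compute2DCoords(mol)
        return mol.GetConformer().GetPositions().astype(np.float64)
    heavy = Chem.RemoveHs(mol)
    return heavy.GetConformer().GetPositions().astype(np.float64)


def generate_fixture_set(n_molecules: int, seed: int) -> list[MoleculeRecord]:
    """Deterministic set of small valid molecules with 3D conformers.

    Each record carries two labels: ``halogen`` (1.0 if the molecule contains
    F/Cl/Br/I, else 0.0) and ``mw`` (molecular weight, g/mol) so the same
    fixtures serve classification and regression exercises.
    """
    if n_molecules < 0:
        raise InputError("n_molecules must be >= 0")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(_FIXTURE_TEMPLATES), size=n_molecules)
    records = []
    for i, t in enumerate(picks):
        template = _FIXTURE_TEMPLATES[t]
        mol = Chem.MolFromSmiles(template)
        smiles = Chem.MolToSmiles(mol)
        coords = _embed_conformer(smiles, seed=(seed * 100003 + i) % (2**31 - 1))
        has_halogen = float(any(a.GetSymbol() in _HALOGENS for a in mol.GetAtoms()))
        labels = {"halogen": has_halogen, "mw": float(Descriptors.MolWt(mol))}
        rec = MoleculeRecord(
            id=f"fix{i:04d}", smiles=smiles, labels=labels, conformer=Conformer(coords)
        )
        rec.validate()
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# scaffold splitting
# ---------------------------------------------------------------------------

def bemis_murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko framework of the canonical SMILES; acyclic molecules
    (empty framework) are grouped by their own canonical SMILES so every
    molecule belongs to exactly one well-defined group."""
    canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(smiles=canonical)
    return scaffold if scaffold else canonical


def scaffold_split(
    records: list[MoleculeRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    shuffle_seed: int | None = None,
) -> DatasetSplit:
    """Leakage-free train/valid/test split by Bemis-Murcko scaffold.

    Scaffold groups are assigned whole, largest group first, each to the part
    currently furthest below its target count — so no scaffold ever straddles
    two parts.  Ties between equal-sized groups are broken by scaffold string
    (or by seeded order when `shuffle_seed` is given).
    """
    if not records:
        raise InputError("cannot split an empty record list")
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must be positive and sum to 1, got {fractions}")

    groups: dict[str, list[str]] = {}
    for rec in records:
        groups.setdefault(bemis_murcko_scaffold(rec.smiles), []).append(rec.id)

    keys = sorted(groups)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        keys = [keys[i] for i in rng.permutation(len(keys))]
    # stable sort: largest first, ties keep the (possibly seeded) key order
    keys.sort(key=lambda k: -len(groups[k]))

    total = len(records)
    targets = [f * total for f in fractions]
    parts: list[list[str]] = [[], [], []]
    for k in keys:
        deficits = [targets[j] - len(parts[j]) for j in range(3)]
        j = int(np.argmax(deficits))  # ties -> earlier part (train first)
        parts[j].extend(groups[k])

    if len(groups) == 1:
        warnings.warn("all molecules share one scaffold; entire set assigned to a single part")
    if not parts[1] or not parts[2]:
        warnings.warn("scaffold grouping left an empty validation or test part")
    return DatasetSplit(train=parts[0], valid=parts[1], test=parts[2])
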