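"""Reading, standardising and cleaning compound tables, and fingerprint I/O.

Compounds arrive as SMILES strings in delimited tables. Before any
fingerprinting they are standardised (isotopes stripped, salts removed,
charges neutralised where possible) and the table is cleaned: unparseable
records, genuine multi-fragment mixtures and duplicate structures are
dropped. All randomness (which duplicate survives) flows from one explicit
seed so cleaning is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

REGRESSION = "regression"
CLASSIFICATION = "binary-classification"


@dataclass(frozen=True)
class CompoundRecord:
    """One standardised compound: unique id, canonical SMILES, optional label."""

    id: str
    smiles: str
    label: Optional[float] = None


@dataclass
class DatasetTable:
    """An ordered, duplicate-free collection of standardised compounds."""

    records: list[CompoundRecord]
    task_type: str = REGRESSION
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.task_type not in (REGRESSION, CLASSIFICATION):
            raise ValueError(f"unknown task_type: {self.task_type!r}")
        if self.task_type == CLASSIFICATION:
            for r in self.records:
                if r.label is not None and r.label not in (0.0, 1.0):
                    raise ValueError(
                        f"classification label must be 0/1, got {r.label!r} for {r.id}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def labels(self) -> np.ndarray:
        return np.asarray([r.label for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "label": [r.label for r in self.records],
            }
        )


class EmptyDatasetError(ValueError):
    """Raised when cleaning rejects every input record."""


_UNCHARGER = rdMolStandardize.Uncharger()


def _n_organic_fragments(mol: Chem.Mol) -> int:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return sum(1 for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms()))


def standardize_and_desalt(raw_smiles: str) -> Optional[str]:
    """Standardise one SMILES string; return canonical parent SMILES or None.

    Pinned behaviour: parse; strip isotope annotations; structural cleanup
    (normalisation, metal disconnection, reionisation); if at most one
    organic (carbon-containing) fragment is present, keep the largest
    organic fragment and neutralise it. A string with two or more organic
    fragments is a genuine mixture and is returned multi-fragment so that
    dataset cleaning can reject it. Unparseable input returns None.
    """
    if not raw_smiles or not isinstance(raw_smiles, str):
        return None
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        return None
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    try:
        mol = rdMolStandardize.Cleanup(mol)
        if mol is None:
            return None
        if _n_organic_fragments(mol) <= 1:
            mol = rdMolStandardize.FragmentParent(mol)
            mol = _UNCHARGER.uncharge(mol)
    except Exception:  # rdkit raises on pathological valence states
        return None
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(mol)


def clean_dataset(
    records: Sequence[tuple[str, str, Optional[float]]],
    seed: int,
    task_type: str = REGRESSION,
    provenance: str = "",
) -> DatasetTable:
    """Standardise raw (id, smiles, label) triples into a clean DatasetTable.

    Rejects unparseable SMILES and records that remain multi-fragment after
    standardisation. Among records sharing a canonical SMILES exactly one
    survives, chosen uniformly at random under ``seed``; the labels of the
    dropped duplicates are discarded. The surviving record count is
    invariant to the seed.
    """
    if not records:
        raise EmptyDatasetError("no input records")
    standardised: list[CompoundRecord] = []
    for rid, smi, label in records:
        canon = standardize_and_desalt(smi)
        if canon is None:
            logger.info("dropped %s: unparseable or unstandardisable SMILES %r", rid, smi)
            continue
        if "." in canon:
            logger.info("dropped %s: multi-fragment after standardisation (%s)", rid, canon)
            continue
        standardised.append(CompoundRecord(str(rid), canon, label))
    if not standardised:
        raise EmptyDatasetError("all records rejected during cleaning")

    rng = np.random.default_rng(seed)
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in standardised:
        if rec.smiles not in groups:
            groups[rec.smiles] = []
            order.append(rec.smiles)
        groups[rec.smiles].append(rec)
    kept: list[CompoundRecord] = []
    for smi in order:
        group = groups[smi]
        if len(group) == 1:
            kept.append(group[0])
        else:
            survivor = group[int(rng.integers(len(group)))]
            for rec in group:
                if rec is not survivor:
                    logger.info("dropped %s: duplicate of %s", rec.id, survivor.id)
            kept.append(survivor)
    ids = [r.id for r in kept]
    if len(set(ids)) != len(ids):
        raise ValueError("record ids are not unique after cleaning")
    return DatasetTable(kept, task_type=task_type, provenance=provenance)


def read_table(
    path: str | Path,
    smiles_col: str = "smiles",
    label_col: Optional[str] = "label",
    id_col: Optional[str] = None,
    task_type: str = REGRESSION,
    sep: str = ",",
) -> list[tuple[str, str, Optional[float]]]:
    """Read raw (id, smiles, label) triples from a delimited table."""
    df = pd.read_csv(path, sep=sep)
    if smiles_col not in df.columns:
        raise KeyError(f"column {smiles_col!r} not in {list(df.columns)}")
    ids = (
        df[id_col].astype(str)
        if id_col and id_col in df.columns
        else pd.Series([str(i) for i in range(len(df))])
    )
    if label_col and label_col in df.columns:
        labels = pd.to_numeric(df[label_col], errors="coerce")
    else:
        labels = pd.Series([np.nan] * len(df))
    out: list[tuple[str, str, Optional[float]]] = []
    for rid, smi, lab in zip(ids, df[smiles_col].astype(str), labels):
        out.append((rid, smi, None if pd.isna(lab) else float(lab)))
    return out


def read_sdf(path: str | Path, label_prop: Optional[str] = None) -> list[tuple[str, str, Optional[float]]]:
    """Read raw triples from an SDF file, mapping mol blocks to SMILES."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    out: list[tuple[str, str, Optional[float]]] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        label = None
        if label_prop and mol.HasProp(label_prop):
            try:
                label = float(mol.GetProp(label_prop))
            except ValueError:
                label = None
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else str(i)
        out.append((name, Chem.MolToSmiles(mol), label))
    return out


def write_dataset(table: DatasetTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_fingerprints(
    matrix: np.ndarray, path: str | Path, format: str = "dense"
) -> None:
    """Write a binary fingerprint matrix as delimited text.

    ``dense``: one row per compound, header of bit indices. ``sparse``:
    coordinate triples (row, column, 1) under a header line recording the
    shape, so the round-trip is lossless including all-zero rows.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError("fingerprint matrix must be 2-D with rows of equal length")
    n, length = matrix.shape
    path = Path(path)
    if format == "dense":
        header = ",".join(f"bit_{j}" for j in range(length))
        np.savetxt(path, matrix, fmt="%d", delimiter=",", header=header, comments="")
    elif format == "sparse":
        rows, cols = np.nonzero(matrix)
        with open(path, "w") as fh:
            fh.write(f"# n={n} L={length}\n")
            fh.write("row,col,value\n")
            for r, c in zip(rows, cols):
                fh.write(f"{r},{c},1\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_fingerprints(path: str | Path, format: str = "dense") -> np.ndarray:
    path = Path(path)
    if format == "dense":
        return np.loadtxt(path, dtype=np.uint8, delimiter=",", skiprows=1, ndmin=2)
    if format == "sparse":
        with open(path) as fh:
            header = fh.readline().strip()
        parts = dict(tok.split("=") for tok in header.lstrip("# ").split())
        n, length = int(parts["n"]), int(parts["L"])
        mat = np.zeros((n, length), dtype=np.uint8)
        coo = pd.read_csv(path, skiprows=1)
        if len(coo):
            mat[coo["row"].to_numpy(), coo["col"].to_numpy()] = 1
        return mat
    raise ValueError(f"unknown format {format!r}")
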