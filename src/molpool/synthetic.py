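"""Seeded generator of small synthetic molecule libraries.

Molecules are composed by chaining SMILES fragments from a vetted grammar:
every non-terminal fragment starts and ends on an atom with spare valence,
so any concatenation of fragments is itself a valid SMILES string and no
rejection loop is needed. A small pool of common backbone fragments is
sampled often and a larger pool of rare decorated fragments is sampled
seldom, which together with the combinatorial diversity of fragment
junctions reproduces the heavy-tailed substructure-frequency distribution
of real chemical datasets (most circular substructures occur in only one or
a few compounds).

Labels are planted on top of a generated library as a weighted sum of
fragment presences plus Gaussian noise (regression) or its thresholded sign
(classification), so the supervised selectors have a recoverable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import CLASSIFICATION, REGRESSION, CompoundRecord, DatasetTable

#: frequent backbone pieces
COMMON_FRAGMENTS: tuple[str, ...] = (
    "CC",
    "CCO",
    "CCN",
    "CC(=O)",
    "CC(C)",
    "CCOC",
    "c1ccccc1",
    "C1CCCCC1",
)

#: infrequent decorated pieces (no fluorine: that element is reserved for
#: planted fragments so a planted substructure's support is exact)
RARE_FRAGMENTS: tuple[str, ...] = (
    "C(Cl)C",
    "C(Br)C",
    "C(I)C",
    "C(C#N)C",
    "C(Cl)(Cl)C",
    "C(Br)(Br)C",
    "C(Cl)C(Cl)C",
    "C(O)C(O)C",
    "C(C(=O)O)C",
    "C(=S)NC",
    "C(SC)C",
    "C#CC",
    "C=CC",
    "C=C(C)C",
    "c1ccncc1",
    "c1cccnc1C",
    "c1ccsc1",
    "c1ccoc1",
    "c1cc[nH]c1",
    "C1CCNCC1",
    "C1CCOCC1",
    "C1CCSCC1",
    "C1CC1",
    "C1CCC1",
    "C1CCCC1",
    "N1CCNCC1",
    "C(=O)N(C)C",
    "C(N)C(=O)C",
)

#: default planted fragment; the only fluorine source in any default grammar,
#: so the radius-0 fluorine identifier's support equals the planted support
DEFAULT_PLANTED_FRAGMENT = "C(F)(F)C"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic library.

    ``p_rare`` is the per-slot probability of drawing from the rare pool;
    ``planted_fragment``/``p_planted`` optionally insert a marker fragment
    into a random subset of compounds (the hook the label rule attaches to).
    """

    n_compounds: int = 100
    seed: int = 0
    common_fragments: tuple[str, ...] = COMMON_FRAGMENTS
    rare_fragments: tuple[str, ...] = RARE_FRAGMENTS
    p_rare: float = 0.35
    min_fragments: int = 2
    max_fragments: int = 5
    planted_fragment: Optional[str] = None
    p_planted: float = 0.5

    def __post_init__(self) -> None:
        if self.n_compounds < 4:
            raise ValueError("n_compounds must be >= 4")
        if not self.common_fragments:
            raise ValueError("grammar needs at least one common fragment")
        if not 0.0 <= self.p_rare <= 1.0:
            raise ValueError("p_rare must be in [0, 1]")
        if self.min_fragments < 1 or self.max_fragments < self.min_fragments:
            raise ValueError("invalid fragment chain length range")


def _compose(rng: np.random.Generator, spec: FixtureSpec) -> str:
    length = int(rng.integers(spec.min_fragments, spec.max_fragments + 1))
    parts = []
    for _ in range(length):
        if spec.rare_fragments and rng.random() < spec.p_rare:
            parts.append(spec.rare_fragments[int(rng.integers(len(spec.rare_fragments)))])
        else:
            parts.append(spec.common_fragments[int(rng.integers(len(spec.common_fragments)))])
    if spec.planted_fragment and rng.random() < spec.p_planted:
        slot = int(rng.integers(len(parts) + 1))
        parts.insert(slot, spec.planted_fragment)
    return "".join(parts)


def generate_library(spec: FixtureSpec) -> DatasetTable:
    """Compose a library of valid molecules by seeded fragment chaining."""
    rng = np.random.default_rng(spec.seed)
    records: list[CompoundRecord] = []
    for i in range(spec.n_compounds):
        smi = _compose(rng, spec)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(
                f"grammar produced an invalid SMILES {smi!r}; vet the fragment list"
            )
        records.append(CompoundRecord(id=f"syn{i}", smiles=Chem.MolToSmiles(mol)))
    if not records:
        raise ValueError("grammar produced no valid molecules")
    return DatasetTable(records, task_type=REGRESSION, provenance="synthetic")


def fragment_presence(table: DatasetTable, fragment_smiles: str) -> np.ndarray:
    """Binary vector: does each compound contain the fragment as a subgraph."""
    query = Chem.MolFromSmiles(fragment_smiles)
    if query is None:
        raise ValueError(f"invalid fragment SMILES {fragment_smiles!r}")
    out = np.zeros(len(table), dtype=int)
    for i, rec in enumerate(table.records):
        mol = Chem.MolFromSmiles(rec.smiles)
        out[i] = int(mol.HasSubstructMatch(query))
    return out


def plant_labels(
    table: DatasetTable,
    weights: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    task_type: str = REGRESSION,
) -> DatasetTable:
    """Attach labels driven by planted fragment presences.

    Regression: label = sum_f w_f * presence_f + Gaussian noise.
    Classification: the thresholded sign of the same quantity (> 0 -> 1).
    """
    rng = np.random.default_rng(seed)
    raw = np.zeros(len(table), dtype=float)
    for frag, w in weights.items():
        raw += float(w) * fragment_presence(table, frag)
    if noise_sd > 0:
        raw += rng.normal(0.0, noise_sd, size=len(table))
    if task_type == CLASSIFICATION:
        labels = (raw > 0).astype(float)
    elif task_type == REGRESSION:
        labels = raw
    else:
        raise ValueError(f"unknown task_type {task_type!r}")
    records = [
        CompoundRecord(id=r.id, smiles=r.smiles, label=float(lab))
        for r, lab in zip(table.records, labels)
    ]
    return DatasetTable(records, task_type=task_type, provenance=table.provenance)


def planted_library(
    n_compounds: int,
    seed: int,
    planted_fragment: str = DEFAULT_PLANTED_FRAGMENT,
    p_planted: float = 0.5,
    weight: float = 1.0,
    noise_sd: float = 0.0,
    task_type: str = CLASSIFICATION,
    **spec_kwargs,
) -> DatasetTable:
    """Library with one planted fragment and labels driven by its presence."""
    spec = FixtureSpec(
        n_compounds=n_compounds,
        seed=seed,
        planted_fragment=planted_fragment,
        p_planted=p_planted,
        **spec_kwargs,
    )
    table = generate_library(spec)
    return plant_labels(
        table,
        {planted_fragment: weight},
        noise_sd=noise_sd,
        seed=seed + 1,
        task_type=task_type,
    )
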