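"""Circular-substructure enumeration and training vocabularies.

A compound is mapped to the set of hashed 32-bit integer identifiers of all
circular atom environments up to a maximal diameter D (Morgan/ECFP scheme).
Identifiers are taken directly from RDKit's sparse Morgan generator and are
treated as opaque: the pooling operators only need identity and an arbitrary
total order on them. Per-compound multiplicities are discarded (binary
fingerprints only); the atom-environment trace behind each identifier is
kept on demand because the filtering selector must reconstruct environment
subgraphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import CompoundRecord, DatasetTable

STANDARD = "standard"
PHARMACOPHORIC = "pharmacophoric"


@dataclass(frozen=True)
class EnumerationConfig:
    """Hyperparameters of substructure enumeration.

    ``max_diameter`` is the maximal environment diameter D (an even
    non-negative integer; the radius is D/2). ``invariants`` selects the
    standard atomic invariants (ECFP) or the six binary pharmacophoric
    invariants (FCFP). ``use_chirality`` appends the tetrahedral R/S
    chirality invariant.
    """

    max_diameter: int = 4
    invariants: str = STANDARD
    use_chirality: bool = True

    def __post_init__(self) -> None:
        if self.max_diameter < 0 or self.max_diameter % 2 != 0:
            raise ValueError(f"max_diameter must be even and >= 0, got {self.max_diameter}")
        if self.invariants not in (STANDARD, PHARMACOPHORIC):
            raise ValueError(f"invariants must be standard|pharmacophoric, got {self.invariants!r}")

    @property
    def radius(self) -> int:
        return self.max_diameter // 2

    def to_dict(self) -> dict:
        return {
            "max_diameter": self.max_diameter,
            "invariants": self.invariants,
            "use_chirality": self.use_chirality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnumerationConfig":
        return cls(**d)


@dataclass
class CompoundTrace:
    """Enumeration of one compound with its identifier -> environment map.

    ``environments`` maps each identifier to the tuples (atom_index, radius)
    of the atom environments that hashed to it within this molecule.
    """

    mol: Chem.Mol
    identifiers: frozenset[int]
    environments: dict[int, tuple[tuple[int, int], ...]]


@dataclass
class FrequencyTable:
    """Training vocabulary: identifier -> number of training compounds containing it."""

    n: int
    entries: dict[int, int]
    config: EnumerationConfig

    @property
    def m_t(self) -> int:
        return len(self.entries)

    def __post_init__(self) -> None:
        for ident, count in self.entries.items():
            if not 1 <= count <= self.n:
                raise ValueError(f"count {count} for identifier {ident} outside [1, {self.n}]")


def _generator(config: EnumerationConfig) -> rdFingerprintGenerator.FingerprintGenerator64:
    kwargs = dict(radius=config.radius, includeChirality=config.use_chirality)
    if config.invariants == PHARMACOPHORIC:
        kwargs["atomInvariantsGenerator"] = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
    return rdFingerprintGenerator.GetMorganGenerator(**kwargs)


def _mol_from(compound: CompoundRecord | Chem.Mol | str) -> Chem.Mol:
    if isinstance(compound, Chem.Mol):
        return compound
    smiles = compound.smiles if isinstance(compound, CompoundRecord) else compound
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol


def enumerate_with_trace(
    compound: CompoundRecord | Chem.Mol | str, config: EnumerationConfig
) -> CompoundTrace:
    """Enumerate circular substructures keeping the atom-environment trace."""
    mol = _mol_from(compound)
    gen = _generator(config)
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    fp = gen.GetSparseCountFingerprint(mol, additionalOutput=out)
    info = {int(k): tuple(v) for k, v in out.GetBitInfoMap().items()}
    identifiers = frozenset(int(k) for k in fp.GetNonzeroElements())
    return CompoundTrace(mol=mol, identifiers=identifiers, environments=info)


def enumerate_substructures(
    compound: CompoundRecord | Chem.Mol | str, config: EnumerationConfig
) -> frozenset[int]:
    """Map a compound to its set of circular-substructure identifiers."""
    return enumerate_with_trace(compound, config).identifiers


def enumerate_dataset(
    table: DatasetTable, config: EnumerationConfig, with_trace: bool = False
) -> list[CompoundTrace] | list[frozenset[int]]:
    traces = [enumerate_with_trace(rec, config) for rec in table.records]
    return traces if with_trace else [t.identifiers for t in traces]


def build_frequency_table(
    training: DatasetTable | list[frozenset[int]],
    config: EnumerationConfig,
) -> FrequencyTable:
    """Count, for every training substructure, the compounds containing it.

    Presence counts, not multiplicities: a substructure occurring twice in
    one compound contributes one.
    """
    if isinstance(training, DatasetTable):
        sets = enumerate_dataset(training, config)
    else:
        sets = list(training)
    if not sets:
        raise ValueError("empty training set")
    counts: dict[int, int] = {}
    for identifiers in sets:
        for ident in identifiers:
            counts[ident] = counts.get(ident, 0) + 1
    return FrequencyTable(n=len(sets), entries=counts, config=config)


def supports(sets: list[frozenset[int]]) -> dict[int, frozenset[int]]:
    """Map each identifier to the set of compound indices containing it."""
    supp: dict[int, set[int]] = {}
    for i, identifiers in enumerate(sets):
        for ident in identifiers:
            supp.setdefault(ident, set()).add(i)
    return {ident: frozenset(v) for ident, v in supp.items()}


def environment_subgraph(mol: Chem.Mol, atom_index: int, radius: int) -> Chem.Mol:
    """Extract the circular environment of an atom as a molecular subgraph.

    Bonds within ``radius`` of the root atom are included together with
    their endpoint atoms, so boundary bonds (and the atoms they attach) are
    part of the subgraph. A radius-0 environment is the root atom alone.
    """
    if radius == 0:
        rw = Chem.RWMol()
        rw.AddAtom(Chem.Atom(mol.GetAtomWithIdx(atom_index).GetAtomicNum()))
        return rw.GetMol()
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_index)
    if not bond_ids:
        # isolated atom or radius beyond molecule extent: fall back to root atom
        return environment_subgraph(mol, atom_index, 0)
    sub = Chem.PathToSubmol(mol, bond_ids)
    sub.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(sub)
    return sub


def representative_environment(
    traces: list[CompoundTrace], identifier: int
) -> Optional[tuple[Chem.Mol, int]]:
    """First available environment subgraph for an identifier.

    Returns (subgraph, radius) from the first compound whose trace contains
    the identifier, or None if no trace does.
    """
    for trace in traces:
        envs = trace.environments.get(identifier)
        if envs:
            atom_index, radius = envs[0]
            return environment_subgraph(trace.mol, atom_index, radius), radius
    return None
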