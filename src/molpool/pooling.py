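"""Substructure-pooling operators.

A pooling operator maps a compound's set of circular-substructure
identifiers to a fixed-length binary fingerprint. Four operators are
provided:

* **hash-based folding** — the classical default: identifiers are compressed
  onto {0, ..., L-1} by a fixed hash (identifier mod L); distinct
  substructures may collide on one bit. Needs no calibration data.
* **Sort & Slice** — unsupervised: training substructures are ranked by the
  number of training compounds containing them (ties by ascending
  identifier value) and the top L become one bit each. Collision-free.
* **filtering** — supervised: singleton substructures, then redundant
  non-closed substructures (same support, environment containing a smaller
  same-support environment) are removed at random, and the remainder is
  trimmed to the L features most dependent on the (binarised) label under a
  Pearson chi-squared test.
* **mutual-information maximisation (MIM)** — supervised: substructures
  sharing an identical support set are deduplicated at random, then the L
  features with the highest plug-in mutual information with the binarised
  label are kept.

All calibrated operators store their state in a :class:`PoolerCalibration`
which serialises to plain JSON so the substructure owning every bit can be
audited. At transform time, substructures never seen in training map to the
zero vector for the selection-based operators, while folding hashes them
like any other identifier — an intentional asymmetry.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .enumeration import (
    CompoundTrace,
    FrequencyTable,
    environment_subgraph,
    representative_environment,
    supports as compute_supports,
)
from .infotheory import chi2_pvalue, mutual_information

logger = logging.getLogger(__name__)

FOLDED = "folded"
SORT_SLICE = "sort_slice"
FILTERED = "filtered"
MIM = "mim"


class DegenerateLabelError(ValueError):
    """Raised when a constant (binarised) label makes the chi-squared order undefined."""


@dataclass
class PoolerCalibration:
    """Fitted state of one pooling operator.

    For ``folded`` only the length and the hash spec matter. For the
    selection-based methods, ``identifiers[i]`` owns fingerprint position
    ``i``; the list has no duplicates and length min(L, m_T) — shorter lists
    are zero-padded at transform time.
    """

    method: str
    L: int
    identifiers: list[int] = field(default_factory=list)
    hash_spec: str = "mod"

    def __post_init__(self) -> None:
        if self.method not in (FOLDED, SORT_SLICE, FILTERED, MIM):
            raise ValueError(f"unknown pooling method {self.method!r}")
        if self.L < 1:
            raise ValueError("fingerprint length L must be >= 1")
        if len(set(self.identifiers)) != len(self.identifiers):
            raise ValueError("calibration identifier list contains duplicates")
        if len(self.identifiers) > self.L:
            raise ValueError("calibration identifier list longer than L")

    def position_of(self, identifier: int) -> Optional[int]:
        try:
            return self.identifiers.index(identifier)
        except ValueError:
            return None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "method": self.method,
            "L": self.L,
            "identifiers": self.identifiers,
            "hash_spec": self.hash_spec,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PoolerCalibration":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            method=d["method"],
            L=int(d["L"]),
            identifiers=[int(i) for i in d["identifiers"]],
            hash_spec=d.get("hash_spec", "mod"),
        )


# ---------------------------------------------------------------------------
# hash-based folding


def hash_fold(substructures: frozenset[int] | set[int], L: int) -> np.ndarray:
    """Fold a set of identifiers onto L bits via identifier mod L (0-indexed)."""
    if L < 1:
        raise ValueError("fingerprint length L must be >= 1")
    bits = np.zeros(L, dtype=np.uint8)
    for ident in substructures:
        bits[ident % L] = 1
    return bits


def calibrate_folded(L: int) -> PoolerCalibration:
    return PoolerCalibration(method=FOLDED, L=L)


# ---------------------------------------------------------------------------
# Sort & Slice


def sort_slice_order(freq: FrequencyTable) -> list[int]:
    """All training identifiers ranked by descending support count.

    Ties at equal count are broken by ascending identifier value, so the
    smaller identifier gets the earlier rank.
    """
    return sorted(freq.entries, key=lambda j: (-freq.entries[j], j))


def calibrate_sort_slice(freq: FrequencyTable, L: int) -> PoolerCalibration:
    """Keep the min(L, m_T) most frequent training substructures, in rank order."""
    if L < 1:
        raise ValueError("fingerprint length L must be >= 1")
    if not freq.entries:
        raise ValueError("empty frequency table")
    ordered = sort_slice_order(freq)[: min(L, freq.m_t)]
    return PoolerCalibration(method=SORT_SLICE, L=L, identifiers=ordered)


# ---------------------------------------------------------------------------
# shared transform for the selection-based operators


def transform_selected(
    cal: PoolerCalibration, substructures: frozenset[int] | set[int]
) -> np.ndarray:
    """One-hot presence vector over the calibrated identifier list, zero-padded to L."""
    if cal.method not in (SORT_SLICE, FILTERED, MIM):
        raise ValueError(f"transform_selected needs a selection-based calibration, got {cal.method}")
    bits = np.zeros(cal.L, dtype=np.uint8)
    for pos, ident in enumerate(cal.identifiers):
        if ident in substructures:
            bits[pos] = 1
    return bits


def transform(cal: PoolerCalibration, substructures: frozenset[int] | set[int]) -> np.ndarray:
    if cal.method == FOLDED:
        return hash_fold(substructures, cal.L)
    return transform_selected(cal, substructures)


def fingerprint_matrix(
    cal: PoolerCalibration, substructure_sets: Sequence[frozenset[int] | set[int]]
) -> np.ndarray:
    return np.vstack([transform(cal, s) for s in substructure_sets]).astype(np.uint8)


# ---------------------------------------------------------------------------
# label handling for the supervised selectors


def binarize_labels(labels: np.ndarray) -> np.ndarray:
    """Binarise continuous labels at the median: <= median -> 0, > median -> 1.

    Already-binary labels pass through unchanged.
    """
    labels = np.asarray(labels, dtype=float)
    values = set(np.unique(labels))
    if values <= {0.0, 1.0}:
        return labels.astype(int)
    med = float(np.median(labels))
    return (labels > med).astype(int)


def _feature_column(support: frozenset[int], n: int) -> np.ndarray:
    col = np.zeros(n, dtype=int)
    col[list(support)] = 1
    return col


# ---------------------------------------------------------------------------
# filtering


def _is_proper_subgraph(smaller: Chem.Mol, larger: Chem.Mol) -> bool:
    """True if ``smaller`` matches a strictly smaller subgraph of ``larger``."""
    if (
        smaller.GetNumAtoms() > larger.GetNumAtoms()
        or smaller.GetNumBonds() > larger.GetNumBonds()
    ):
        return False
    if (
        smaller.GetNumAtoms() == larger.GetNumAtoms()
        and smaller.GetNumBonds() == larger.GetNumBonds()
    ):
        return False
    return larger.HasSubstructMatch(smaller)


def _non_closed_members(
    group: list[int],
    traces: list[CompoundTrace],
    support: frozenset[int],
) -> set[int]:
    """Identifiers in a same-support group whose environment properly contains
    another group member's environment.

    The representative environments are reconstructed in one shared compound
    (the first of the common support) so the radius shortcut applies: a
    smaller-radius environment rooted at the same atom is always a proper
    subgraph of the larger-radius one.
    """
    ref = min(support)
    trace = traces[ref]
    envs: dict[int, tuple[Chem.Mol, int, int]] = {}
    for ident in group:
        occ = trace.environments.get(ident)
        if occ:
            atom_index, radius = occ[0]
            envs[ident] = (environment_subgraph(trace.mol, atom_index, radius), radius, atom_index)
        else:
            rep = representative_environment(traces, ident)
            if rep is not None:
                envs[ident] = (rep[0], rep[1], -1)
    non_closed: set[int] = set()
    for j in group:
        if j not in envs:
            continue
        env_j, r_j, atom_j = envs[j]
        for jt in group:
            if jt == j or jt not in envs:
                continue
            env_t, r_t, atom_t = envs[jt]
            if atom_j >= 0 and atom_j == atom_t and r_t < r_j:
                non_closed.add(j)  # same root, smaller radius: nested by construction
                break
            if _is_proper_subgraph(env_t, env_j):
                non_closed.add(j)
                break
    return non_closed


def calibrate_filtered(
    freq: FrequencyTable,
    traces: list[CompoundTrace],
    labels: np.ndarray,
    L: int,
    seed: int,
) -> PoolerCalibration:
    """Supervised substructure selection: singleton removal, redundancy
    (non-closed) removal, then chi-squared trimming to L features.

    Continuous labels are binarised at their median first. Random removals
    in the first two steps consume a dedicated seeded generator, so a fixed
    seed reproduces the selection exactly. If L >= m_T the whole vocabulary
    is kept and fingerprints are zero-padded.
    """
    if L < 1:
        raise ValueError("fingerprint length L must be >= 1")
    if len(traces) != len(labels):
        raise ValueError("traces and labels have different lengths")
    y = binarize_labels(np.asarray(labels, dtype=float))
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("constant label after binarisation: chi-squared order undefined")

    sets = [t.identifiers for t in traces]
    supp = compute_supports(sets)
    selected = set(freq.entries)
    rng = np.random.default_rng(seed)

    # Step 1: drop substructures occurring in a single training compound.
    singletons = sorted(j for j in selected if len(supp[j]) == 1)
    while singletons and len(selected) > L:
        pick = int(rng.integers(len(singletons)))
        selected.discard(singletons.pop(pick))

    # Step 2: drop redundant non-closed substructures.
    while len(selected) > L:
        by_support: dict[frozenset[int], list[int]] = {}
        for j in selected:
            by_support.setdefault(supp[j], []).append(j)
        candidates: list[int] = []
        for support, group in by_support.items():
            if len(group) >= 2:
                candidates.extend(_non_closed_members(sorted(group), traces, support))
        if not candidates:
            break
        candidates.sort()
        selected.discard(candidates[int(rng.integers(len(candidates)))])

    # Step 3: trim by chi-squared dependence on the label; larger p removed
    # first, ties removing the smaller identifier first.
    if len(selected) > L:
        n = len(traces)
        pvals = {j: chi2_pvalue(_feature_column(supp[j], n), y) for j in selected}
        doomed = sorted(selected, key=lambda j: (-pvals[j], j))
        for j in doomed[: len(selected) - L]:
            selected.discard(j)

    n = len(traces)
    pvals = {j: chi2_pvalue(_feature_column(supp[j], n), y) for j in selected}
    ordered = sorted(selected, key=lambda j: (pvals[j], j))
    return PoolerCalibration(method=FILTERED, L=L, identifiers=ordered)


# ---------------------------------------------------------------------------
# mutual-information maximisation


def calibrate_mim(
    freq: FrequencyTable,
    supports: dict[int, frozenset[int]],
    labels: np.ndarray,
    L: int,
    seed: int,
) -> PoolerCalibration:
    """Supervised selection by plug-in mutual information with the label.

    Substructures sharing an identical support set are first deduplicated
    (a random member of a random duplicated pair is removed) and the L
    features with the highest mutual information survive, ties removing the
    smaller identifier first. A degenerate label makes every MI zero; the
    order then falls back to identifier ties and a warning is logged.
    """
    if L < 1:
        raise ValueError("fingerprint length L must be >= 1")
    y = binarize_labels(np.asarray(labels, dtype=float))
    n = len(y)
    if len(np.unique(y)) < 2:
        warnings.warn(
            "constant label after binarisation: mutual information is zero for "
            "all features; selection falls back to identifier order",
            stacklevel=2,
        )

    selected = set(freq.entries)
    rng = np.random.default_rng(seed)

    # Step 1: deduplicate identical support sets.
    while len(selected) > L:
        by_support: dict[frozenset[int], list[int]] = {}
        for j in selected:
            by_support.setdefault(supports[j], []).append(j)
        dup_groups = sorted(
            (sorted(g) for g in by_support.values() if len(g) >= 2),
            key=lambda g: g[0],
        )
        if not dup_groups:
            break
        group = dup_groups[int(rng.integers(len(dup_groups)))]
        pair = rng.choice(len(group), size=2, replace=False)
        selected.discard(group[int(pair[int(rng.integers(2))])])

    # Step 2: keep the L features with highest mutual information.
    if len(selected) > L:
        mi = {j: mutual_information(_feature_column(supports[j], n), y) for j in selected}
        doomed = sorted(selected, key=lambda j: (mi[j], j))
        for j in doomed[: len(selected) - L]:
            selected.discard(j)

    mi = {j: mutual_information(_feature_column(supports[j], n), y) for j in selected}
    ordered = sorted(selected, key=lambda j: (-mi[j], j))
    return PoolerCalibration(method=MIM, L=L, identifiers=ordered)
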