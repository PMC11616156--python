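"""Plug-in information estimators and vocabulary frequency statistics.

Entropy and mutual information are computed in bits from empirical cell
frequencies with the convention 0*log(0) = 0 and no bias correction. The
chi-squared p-value is the upper tail of a Pearson test on the 2x2
contingency table of (binary label x feature presence) with one degree of
freedom and no continuity correction; degenerate margins carry no signal
and get p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .enumeration import FrequencyTable


def _entropy_from_probs(probs: np.ndarray) -> float:
    probs = probs[probs > 0]
    return float(-(probs * np.log2(probs)).sum())


def shannon_entropy(col: np.ndarray) -> float:
    """Empirical Shannon entropy (bits) of a binary column."""
    col = np.asarray(col)
    if col.size == 0:
        raise ValueError("empty column")
    p = float(np.mean(col))
    return _entropy_from_probs(np.array([p, 1.0 - p]))


def contingency_2x2(col: np.ndarray, labels: np.ndarray) -> np.ndarray:
    col = np.asarray(col).astype(int)
    labels = np.asarray(labels).astype(int)
    if col.shape != labels.shape:
        raise ValueError("feature column and labels have different lengths")
    table = np.zeros((2, 2), dtype=float)
    for a in (0, 1):
        for b in (0, 1):
            table[a, b] = np.sum((labels == a) & (col == b))
    return table


def mutual_information(col: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two binary vectors.

    I = H(labels) + H(col) - H(joint), each term from empirical frequencies.
    """
    table = contingency_2x2(col, labels)
    n = table.sum()
    joint = table.ravel() / n
    h_joint = _entropy_from_probs(joint)
    h_label = _entropy_from_probs(table.sum(axis=1) / n)
    h_col = _entropy_from_probs(table.sum(axis=0) / n)
    return max(0.0, h_label + h_col - h_joint)


def chi2_pvalue(col: np.ndarray, labels: np.ndarray) -> float:
    """Pearson chi-squared independence p-value on the 2x2 table (df = 1)."""
    table = contingency_2x2(col, labels)
    n = table.sum()
    row = table.sum(axis=1)
    colsum = table.sum(axis=0)
    if np.any(row == 0) or np.any(colsum == 0):
        return 1.0
    expected = np.outer(row, colsum) / n
    stat = float(((table - expected) ** 2 / expected).sum())
    return float(_chi2_dist.sf(stat, df=1))


@dataclass(frozen=True)
class FrequencySummary:
    """Frequency-distribution statistics of a training vocabulary.

    Percentages are over the m_T unique training substructures; the nested
    support thresholds 1 <= 10 <= 100 make the first three non-decreasing.
    "Fewer/more than half" use strict inequalities against n/2; the
    high-frequency count uses support >= 0.9 n.
    """

    m_t: int
    pct_support_1: float
    pct_support_le10: float
    pct_support_le100: float
    pct_support_lt_half: float
    n_gt_half: int
    n_ge_90pct: int


def frequency_stats(freq: FrequencyTable) -> FrequencySummary:
    counts = np.asarray(list(freq.entries.values()), dtype=float)
    if counts.size == 0:
        raise ValueError("empty frequency table")
    m_t = counts.size
    n = freq.n
    pct = lambda mask: 100.0 * float(np.sum(mask)) / m_t  # noqa: E731
    return FrequencySummary(
        m_t=int(m_t),
        pct_support_1=pct(counts == 1),
        pct_support_le10=pct(counts <= 10),
        pct_support_le100=pct(counts <= 100),
        pct_support_lt_half=pct(counts < n / 2),
        n_gt_half=int(np.sum(counts > n / 2)),
        n_ge_90pct=int(np.sum(counts >= 0.9 * n)),
    )
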