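import numpy as np
import pytest

from molpool import (
    CompoundRecord,
    DatasetTable,
    EnumerationConfig,
    FrequencyTable,
    build_frequency_table,
    calibrate_filtered,
    calibrate_folded,
    calibrate_mim,
    calibrate_sort_slice,
    fingerprint_matrix,
    hash_fold,
    transform,
    transform_selected,
)
from molpool.enumeration import enumerate_dataset, supports
from molpool.pooling import DegenerateLabelError, PoolerCalibration, sort_slice_order

from conftest import marker_table


def freq_of(entries: dict, n: int) -> FrequencyTable:
    return FrequencyTable(n=n, entries=entries, config=EnumerationConfig())


# ---------------------------------------------------------------------------
# hash-based folding


def test_hash_fold_examples():
    assert not hash_fold(frozenset(), 8).any()
    fp = hash_fold({5, 1029}, 1024)
    assert fp[5] == 1 and fp.sum() == 1  # 1029 mod 1024 = 5: a collision
    assert hash_fold(set(range(16)), 16).all()


def test_hash_fold_popcount_vs_residue_oracle():
    rng = np.random.default_rng(42)
    for _ in range(50):
        ids = set(rng.integers(0, 2**32, size=rng.integers(1, 40)).tolist())
        L = int(rng.choice([8, 16, 64, 1024]))
        fp = hash_fold(ids, L)
        residues = {i % L for i in ids}  # brute-force oracle
        assert fp.sum() == len(residues) <= len(ids)
        assert set(np.flatnonzero(fp)) == residues


# ---------------------------------------------------------------------------
# Sort & Slice


def test_sort_slice_order_and_tiebreak():
    freq = freq_of({100: 3, 5: 1, 7: 1}, n=3)
    cal = calibrate_sort_slice(freq, 2)
    assert cal.identifiers == [100, 5]  # tie at count 1 broken by ascending id


def test_sort_slice_keeps_all_when_L_large():
    freq = freq_of({1: 2, 2: 1, 3: 3}, n=3)
    cal = calibrate_sort_slice(freq, 10)
    assert cal.identifiers == [3, 1, 2]
    fp = transform_selected(cal, {1, 2, 3})
    assert fp.tolist() == [1, 1, 1] + [0] * 7  # zero-padding branch


def test_sort_slice_padding_single_entry():
    cal = calibrate_sort_slice(freq_of({77: 5}, n=5), 4)
    assert cal.identifiers == [77]
    assert transform_selected(cal, {77}).tolist() == [1, 0, 0, 0]


def test_sort_slice_frequency_monotonic_and_collision_free(library100):
    _, sets, freq = library100
    cal = calibrate_sort_slice(freq, 256)
    counts = [freq.entries[j] for j in cal.identifiers]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert len(set(cal.identifiers)) == len(cal.identifiers)  # injective position map


def test_sort_slice_limit_equivalence(library100):
    # with L >= m_T the fingerprint is a relabelling of the identifier set
    _, sets, freq = library100
    cal = calibrate_sort_slice(freq, freq.m_t + 10)
    for s in sets[::10]:
        fp = transform_selected(cal, s)
        assert fp.sum() == len(s)
        assert {cal.identifiers[i] for i in np.flatnonzero(fp)} == set(s)


def test_transform_selected_ignores_unlisted():
    cal = PoolerCalibration(method="sort_slice", L=2, identifiers=[10, 20])
    assert transform_selected(cal, {10, 99}).tolist() == [1, 0]
    assert transform_selected(cal, set()).tolist() == [0, 0]


def test_all_methods_emit_length_L_binary(library100):
    table, sets, freq = library100
    config = freq.config
    traces = enumerate_dataset(table, config, with_trace=True)
    labels = np.arange(len(table)) % 2  # arbitrary non-degenerate labels
    supp = supports(sets)
    L = 50
    cals = [
        calibrate_folded(L),
        calibrate_sort_slice(freq, L),
        calibrate_filtered(freq, traces, labels, L, seed=0),
        calibrate_mim(freq, supp, labels, L, seed=0),
    ]
    for cal in cals:
        X = fingerprint_matrix(cal, sets)
        assert X.shape == (len(sets), L)
        assert set(np.unique(X)) <= {0, 1}


# ---------------------------------------------------------------------------
# filtering


def duplicated_cf_fixture(n_copies=2):
    # two copies of CCF: every identifier has support {0, 1}; the three
    # radius-1 environments each properly contain a radius-0 atom
    config = EnumerationConfig(max_diameter=2, use_chirality=False)
    table = DatasetTable(
        [CompoundRecord(f"c{i}", "CCF", float(i % 2)) for i in range(n_copies)]
    )
    traces = enumerate_dataset(table, config, with_trace=True)
    freq = build_frequency_table([t.identifiers for t in traces], config)
    return table, traces, freq


def radius_of(traces, ident):
    for t in traces:
        if ident in t.environments:
            return t.environments[ident][0][1]
    raise KeyError(ident)


def test_filtered_step1_removes_singleton():
    config = EnumerationConfig(max_diameter=0, use_chirality=False)
    table = DatasetTable(
        [
            CompoundRecord("a", "CCO", 1.0),
            CompoundRecord("b", "CCO", 0.0),
            CompoundRecord("c", "CCN", 1.0),
            CompoundRecord("d", "CCN", 0.0),
            CompoundRecord("e", "CCS", 1.0),  # sulfur identifier occurs once
        ]
    )
    traces = enumerate_dataset(table, config, with_trace=True)
    freq = build_frequency_table([t.identifiers for t in traces], config)
    supp = supports([t.identifiers for t in traces])
    singles = {j for j, s in supp.items() if len(s) == 1}
    assert singles  # the fixture does plant singleton substructures
    cal = calibrate_filtered(freq, traces, table.labels(), freq.m_t - len(singles), seed=0)
    assert set(cal.identifiers).isdisjoint(singles)


def test_filtered_step2_removes_non_closed():
    table, traces, freq = duplicated_cf_fixture()
    assert freq.m_t == 6
    cal = calibrate_filtered(freq, traces, table.labels(), 3, seed=5)
    assert sorted(radius_of(traces, j) for j in cal.identifiers) == [0, 0, 0]


def test_filtered_step2_partial_removal_is_one_of_the_larger():
    table, traces, freq = duplicated_cf_fixture()
    cal = calibrate_filtered(freq, traces, table.labels(), 5, seed=1)
    radii = sorted(radius_of(traces, j) for j in cal.identifiers)
    assert radii == [0, 0, 0, 1, 1]  # exactly one radius-1 environment removed


def test_filtered_step3_keeps_label_separating_feature():
    labels = [1, 1, 1, 0, 0, 0]
    presence = np.array(
        [[1, 1], [1, 1], [1, 0], [0, 1], [0, 0], [0, 0]]
    )  # chlorine column equals the label; bromine column does not
    table = marker_table(presence, ["C(Cl)C", "C(Br)C"], labels=labels)
    config = EnumerationConfig(max_diameter=2, use_chirality=False)
    traces = enumerate_dataset(table, config, with_trace=True)
    freq = build_frequency_table([t.identifiers for t in traces], config)
    cal = calibrate_filtered(freq, traces, table.labels(), 1, seed=0)
    supp = supports([t.identifiers for t in traces])
    col = np.zeros(len(table), dtype=int)
    col[list(supp[cal.identifiers[0]])] = 1
    assert col.tolist() == labels


def test_filtered_degenerate_label_errors():
    table, traces, freq = duplicated_cf_fixture()
    with pytest.raises(DegenerateLabelError):
        calibrate_filtered(freq, traces, np.zeros(len(table)), 2, seed=0)


def test_filtered_median_binarisation_of_continuous_labels():
    labels = [1, 1, 1, 0, 0, 0]
    presence = np.array([[1, 1], [1, 1], [1, 0], [0, 1], [0, 0], [0, 0]])
    table = marker_table(
        presence, ["C(Cl)C", "C(Br)C"], labels=[3.2, 2.9, 2.7, 1.1, 0.4, 0.9]
    )
    config = EnumerationConfig(max_diameter=2, use_chirality=False)
    traces = enumerate_dataset(table, config, with_trace=True)
    freq = build_frequency_table([t.identifiers for t in traces], config)
    cal = calibrate_filtered(freq, traces, table.labels(), 1, seed=0)
    supp = supports([t.identifiers for t in traces])
    col = np.zeros(len(table), dtype=int)
    col[list(supp[cal.identifiers[0]])] = 1
    assert col.tolist() == labels


# ---------------------------------------------------------------------------
# mutual-information maximisation


def test_mim_prefers_label_identical_feature():
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    freq = freq_of({5: 4, 9: 8}, n=8)
    supp = {5: frozenset({0, 1, 2, 3}), 9: frozenset(range(8))}
    cal = calibrate_mim(freq, supp, labels, 1, seed=0)
    assert cal.identifiers == [5]  # 1 bit of mutual information vs 0


def test_mim_step1_removes_exactly_one_of_equal_supports():
    labels = np.array([1, 0, 1, 0])
    freq = freq_of({5: 2, 6: 2, 7: 2}, n=4)
    supp = {5: frozenset({0, 1}), 6: frozenset({0, 1}), 7: frozenset({2, 3})}
    cal = calibrate_mim(freq, supp, labels, 2, seed=3)
    assert 7 in cal.identifiers
    assert len(set(cal.identifiers) & {5, 6}) == 1


def test_mim_top2_match_brute_force():
    import math

    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    supp = {
        11: frozenset({0, 1, 2, 3}),
        12: frozenset({0, 1, 2, 4}),
        13: frozenset({0, 1, 4, 5}),
    }
    freq = freq_of({j: len(s) for j, s in supp.items()}, n=8)

    def plug_in_mi(support):  # independent exhaustive oracle
        n = 8
        counts = {(a, b): 0 for a in (0, 1) for b in (0, 1)}
        for i in range(n):
            counts[(int(labels[i]), int(i in support))] += 1
        mi = 0.0
        for (a, b), c in counts.items():
            if c == 0:
                continue
            pa = sum(v for (x, _), v in counts.items() if x == a) / n
            pb = sum(v for (_, y), v in counts.items() if y == b) / n
            mi += (c / n) * math.log2((c / n) / (pa * pb))
        return mi

    expected = sorted(supp, key=lambda j: -plug_in_mi(supp[j]))[:2]
    cal = calibrate_mim(freq, supp, labels, 2, seed=0)
    assert set(cal.identifiers) == set(expected)


def test_mim_degenerate_label_warns_but_proceeds():
    freq = freq_of({5: 1, 6: 2}, n=3)
    supp = {5: frozenset({0}), 6: frozenset({0, 1})}
    with pytest.warns(UserWarning):
        cal = calibrate_mim(freq, supp, np.ones(3), 1, seed=0)
    assert len(cal.identifiers) == 1


# ---------------------------------------------------------------------------
# reproducibility and serialisation


def test_supervised_calibrations_reproducible(library100):
    table, sets, freq = library100
    traces = enumerate_dataset(table, freq.config, with_trace=True)
    labels = np.arange(len(table)) % 2
    supp = supports(sets)
    a = calibrate_filtered(freq, traces, labels, 40, seed=7)
    b = calibrate_filtered(freq, traces, labels, 40, seed=7)
    assert a.identifiers == b.identifiers
    c = calibrate_mim(freq, supp, labels, 40, seed=7)
    d = calibrate_mim(freq, supp, labels, 40, seed=7)
    assert c.identifiers == d.identifiers


def test_calibration_json_roundtrip(tmp_path, library100):
    _, _, freq = library100
    cal = calibrate_sort_slice(freq, 32)
    path = tmp_path / "cal.json"
    cal.to_json(path)
    loaded = PoolerCalibration.from_json(path)
    assert loaded.method == cal.method and loaded.L == cal.L
    assert loaded.identifiers == cal.identifiers


def test_transform_dispatch_folded_vs_selected():
    folded = calibrate_folded(8)
    assert transform(folded, {3, 11}).tolist() == hash_fold({3, 11}, 8).tolist()
    sel = PoolerCalibration(method="mim", L=3, identifiers=[3, 11])
    assert transform(sel, {3, 11}).tolist() == [1, 1, 0]
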