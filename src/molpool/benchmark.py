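"""Scaled-down benchmarking harness for pooling-method comparison.

Repeated two-fold cross-validation (default three seeds) over a grid of
enumeration settings (diameter, invariants), fingerprint lengths and pooling
methods, with random, stratified or Bemis-Murcko scaffold splits. Models are
scikit-learn random forests (default) or multilayer perceptrons (optional,
heavier). Pooler calibration happens strictly on the training fold, so test
compounds never influence which substructures own fingerprint bits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import average_precision_score, mean_absolute_error, roc_auc_score
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .chem_io import CLASSIFICATION, REGRESSION, DatasetTable
from .enumeration import (
    CompoundTrace,
    EnumerationConfig,
    build_frequency_table,
    enumerate_dataset,
    supports as compute_supports,
)
from . import pooling

RANDOM = "random"
STRATIFIED = "stratified"
SCAFFOLD = "scaffold"

MAE = "MAE"
AUROC = "AUROC"
AUPRC = "AUPRC"


@dataclass
class SplitPlan:
    """Fold assignments for repeated k-fold cross-validation.

    ``assignments[(seed, fold)]`` is the sorted list of record indices in
    that fold; for each seed the folds partition the dataset.
    """

    scheme: str
    n_folds: int
    seeds: list[int]
    assignments: dict[tuple[int, int], list[int]]

    def train_test(self, seed: int, test_fold: int) -> tuple[list[int], list[int]]:
        test = self.assignments[(seed, test_fold)]
        train: list[int] = []
        for f in range(self.n_folds):
            if f != test_fold:
                train.extend(self.assignments[(seed, f)])
        return sorted(train), sorted(test)


def bemis_murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES; acyclic molecules share the empty scaffold."""
    try:
        return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles) or ""
    except Exception:
        return ""


def make_split(
    table: DatasetTable,
    scheme: str = RANDOM,
    seeds: Sequence[int] = (0, 1, 2),
    n_folds: int = 2,
) -> SplitPlan:
    """Build per-seed fold assignments under one of three schemes.

    random: seeded shuffle dealt round-robin into folds. stratified:
    per-class seeded shuffle dealt round-robin, keeping fold class rates
    within one compound of the global rate. scaffold: compounds grouped by
    Bemis-Murcko scaffold, groups ordered by descending size (ties shuffled
    under the seed) and greedily assigned to the currently smallest fold, so
    no scaffold crosses folds.
    """
    n = len(table)
    assignments: dict[tuple[int, int], list[int]] = {}
    for seed in seeds:
        rng = np.random.default_rng(seed)
        folds: list[list[int]] = [[] for _ in range(n_folds)]
        if scheme == RANDOM:
            order = rng.permutation(n)
            for pos, idx in enumerate(order):
                folds[pos % n_folds].append(int(idx))
        elif scheme == STRATIFIED:
            labels = table.labels()
            for cls in np.unique(labels):
                members = np.flatnonzero(labels == cls)
                members = members[rng.permutation(len(members))]
                sizes = [len(f) for f in folds]
                start = int(np.argmin(sizes))
                for pos, idx in enumerate(members):
                    folds[(start + pos) % n_folds].append(int(idx))
        elif scheme == SCAFFOLD:
            groups: dict[str, list[int]] = {}
            for i, rec in enumerate(table.records):
                groups.setdefault(bemis_murcko_scaffold(rec.smiles), []).append(i)
            keys = sorted(groups)
            rng.shuffle(keys)
            keys.sort(key=lambda k: -len(groups[k]))  # stable: ties stay shuffled
            for key in keys:
                smallest = int(np.argmin([len(f) for f in folds]))
                folds[smallest].extend(groups[key])
        else:
            raise ValueError(f"unknown split scheme {scheme!r}")
        for f in range(n_folds):
            assignments[(seed, f)] = sorted(folds[f])
    return SplitPlan(scheme=scheme, n_folds=n_folds, seeds=list(seeds), assignments=assignments)


@dataclass(frozen=True)
class ModelSpec:
    """A model family bound to a task.

    ``random-forest``: scikit-learn defaults, except regression feature
    subsampling uses the square-root rule. ``multilayer-perceptron``: five
    hidden layers of 512 rectified units, adam with initial step 1e-3,
    weight-decay 0.1, batch 64, up to 250 epochs (optional; much heavier
    than the forest).
    """

    family: str = "random-forest"
    task: str = REGRESSION
    n_jobs: int = 1

    def build(self, seed: int):
        if self.family == "random-forest":
            if self.task == REGRESSION:
                return RandomForestRegressor(max_features="sqrt", random_state=seed, n_jobs=self.n_jobs)
            return RandomForestClassifier(random_state=seed, n_jobs=self.n_jobs)
        if self.family == "multilayer-perceptron":
            kwargs = dict(
                hidden_layer_sizes=(512,) * 5,
                activation="relu",
                solver="adam",
                learning_rate_init=1e-3,
                alpha=0.1,
                batch_size=64,
                max_iter=250,
                random_state=seed,
            )
            return MLPRegressor(**kwargs) if self.task == REGRESSION else MLPClassifier(**kwargs)
        raise ValueError(f"unknown model family {self.family!r}")


def compute_metric(predictions: np.ndarray, truth: np.ndarray, metric: str) -> float:
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth have different lengths")
    if metric == MAE:
        return float(mean_absolute_error(truth, predictions))
    if metric in (AUROC, AUPRC):
        if len(np.unique(truth)) < 2:
            raise ValueError(f"{metric} undefined for single-class truth")
        fn = roc_auc_score if metric == AUROC else average_precision_score
        return float(fn(truth, predictions))
    raise ValueError(f"unknown metric {metric!r}")


def default_metric(task: str, imbalanced: bool = False) -> str:
    if task == REGRESSION:
        return MAE
    return AUPRC if imbalanced else AUROC


def calibrate_pooler(
    method: str,
    L: int,
    freq,
    traces: list[CompoundTrace],
    labels: np.ndarray,
    seed: int,
) -> pooling.PoolerCalibration:
    if method == pooling.FOLDED:
        return pooling.calibrate_folded(L)
    if method == pooling.SORT_SLICE:
        return pooling.calibrate_sort_slice(freq, L)
    if method == pooling.FILTERED:
        return pooling.calibrate_filtered(freq, traces, labels, L, seed)
    if method == pooling.MIM:
        supp = compute_supports([t.identifiers for t in traces])
        return pooling.calibrate_mim(freq, supp, labels, L, seed)
    raise ValueError(f"unknown pooling method {method!r}")


def calibration_digest(cal: pooling.PoolerCalibration) -> str:
    """Stable hash of a calibration's state, for leakage assertions."""
    return hashlib.sha256(cal.to_json().encode()).hexdigest()


@dataclass
class MetricResult:
    metric: str
    per_run: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_run))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_run, ddof=1)) if len(self.per_run) > 1 else 0.0


def run_grid(
    table: DatasetTable,
    diameters: Sequence[int] = (4,),
    invariants: Sequence[str] = ("standard",),
    lengths: Sequence[int] = (1024,),
    methods: Sequence[str] = (pooling.FOLDED, pooling.SORT_SLICE),
    models: Sequence[ModelSpec] = (),
    scheme: str = RANDOM,
    seeds: Sequence[int] = (0, 1, 2),
    n_folds: int = 2,
    use_chirality: bool = True,
    metric: Optional[str] = None,
    dataset_name: str = "dataset",
) -> pd.DataFrame:
    """Cross-validated evaluation of every grid cell; returns a tidy frame.

    Columns: dataset, scheme, model, method, D, invariants, L, seed, fold,
    metric, value. Calibration is performed on the training fold only.
    Classification folds lacking both classes are flagged invalid (value NaN).
    """
    if not models:
        models = (ModelSpec(task=table.task_type),)
    metric = metric or default_metric(table.task_type)
    labels = table.labels()
    split = make_split(table, scheme=scheme, seeds=seeds, n_folds=n_folds)
    rows = []
    for D, inv in product(diameters, invariants):
        config = EnumerationConfig(max_diameter=D, invariants=inv, use_chirality=use_chirality)
        traces = enumerate_dataset(table, config, with_trace=True)
        for seed in seeds:
            for fold in range(n_folds):
                train_idx, test_idx = split.train_test(seed, fold)
                train_traces = [traces[i] for i in train_idx]
                freq = build_frequency_table([t.identifiers for t in train_traces], config)
                y_train, y_test = labels[train_idx], labels[test_idx]
                for L, method, model in product(lengths, methods, models):
                    cal = calibrate_pooler(method, L, freq, train_traces, y_train, seed)
                    X_train = pooling.fingerprint_matrix(cal, [t.identifiers for t in train_traces])
                    X_test = pooling.fingerprint_matrix(cal, [traces[i].identifiers for i in test_idx])
                    est = model.build(seed)
                    value = np.nan
                    if metric == MAE:
                        est.fit(X_train, y_train)
                        value = compute_metric(est.predict(X_test), y_test, metric)
                    else:
                        if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
                            value = np.nan  # invalid run: fold with a single class
                        else:
                            est.fit(X_train, y_train.astype(int))
                            scores = est.predict_proba(X_test)[:, 1]
                            value = compute_metric(scores, y_test, metric)
                    rows.append(
                        {
                            "dataset": dataset_name,
                            "scheme": scheme,
                            "model": model.family,
                            "method": method,
                            "D": D,
                            "invariants": inv,
                            "L": L,
                            "seed": seed,
                            "fold": fold,
                            "metric": metric,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)


def summarise(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the metric over the seed x fold runs of each grid cell."""
    keys = ["dataset", "scheme", "model", "method", "D", "invariants", "L", "metric"]
    g = results.groupby(keys)["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_runs="count").reset_index()
    return out
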