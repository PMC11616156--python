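# molpool

Substructure pooling for extended-connectivity fingerprints (ECFPs): a
library and CLI for turning molecules into fixed-length binary fingerprints
via **hash-based folding**, **Sort & Slice**, **filtering**, or
**mutual-information maximisation**, with information-theoretic diagnostics
and a cross-validated benchmarking harness for molecular property
prediction.

## The problem

The ECFP algorithm maps a molecule M to a *set* of hashed 32-bit integer
identifiers, φ(M) = {J₁, …, J_k} ⊆ {1, …, 2³²}, one per circular atom
environment up to a maximal diameter D. Machine-learning models need a
fixed-length vector, so this set must be *pooled* into F ∈ {0,1}^L — a set
function Ψ: P(𝔍) → ℝ^L. The default everywhere is hash-based folding,
F_i = 1 iff ∃J: h(J) = i, which inevitably produces **bit collisions** once
L is smaller than the number m_T of substructures seen in training —
degrading both interpretability and predictive performance.

molpool implements the pooling alternatives built on substructure
*selection*, all collision-free by construction:

- **Sort & Slice** (unsupervised): rank training substructures by the
  number of training compounds containing them, c(J) = |supp_T(J)| (ties by
  ascending identifier), keep the top L, one bit each. Because real
  chemical vocabularies are heavy-tailed — most substructures occur in one
  or a few compounds, almost all in fewer than half — ranking by frequency
  coincides with ranking binary feature columns by Shannon entropy, so the
  slice keeps essentially the most informative features.
- **Filtering** (supervised): drop singleton-support substructures, then
  redundant *non-closed* substructures (same support as a smaller
  substructure whose environment graph they properly contain), then trim to
  the L features with the strongest χ² dependence on the (median-binarised)
  label.
- **Mutual-information maximisation** (supervised): deduplicate identical
  support sets, then keep the L features with the highest plug-in mutual
  information with the label.

## Worked example

Everything runs on seeded synthetic libraries (no downloads): molecules are
composed from a fragment grammar, with a label planted on a marker
substructure plus noise.

```python
from molpool import (EnumerationConfig, build_frequency_table, calibrate_sort_slice,
                     fingerprint_matrix, frequency_stats, planted_library)
from molpool.benchmark import ModelSpec, run_grid, summarise
from molpool.enumeration import enumerate_dataset

table = planted_library(200, seed=42, weight=2.0, noise_sd=0.3, task_type="regression")
config = EnumerationConfig()          # D=4, standard invariants, chirality on
sets = enumerate_dataset(table, config)
freq = build_frequency_table(sets, config)
stats = frequency_stats(freq)
print(f"vocabulary: m_T = {freq.m_t} substructures over n = {freq.n} compounds")
print(f"{stats.pct_support_1:.1f}% occur in a single compound; "
      f"{stats.n_gt_half} occur in more than half")

cal = calibrate_sort_slice(freq, L=128)
X = fingerprint_matrix(cal, sets)
print(f"fingerprints: {X.shape}, densest bit set in {X[:, 0].sum()} compounds")

results = run_grid(table, lengths=[128], methods=["folded", "sort_slice"],
                   models=[ModelSpec(task="regression")], seeds=[0, 1, 2])
print(summarise(results)[["method", "mean", "sd"]].to_string(index=False))
```

Output:

```
vocabulary: m_T = 1512 substructures over n = 200 compounds
58.9% occur in a single compound; 4 occur in more than half
fingerprints: (200, 128), densest bit set in 187 compounds
    method     mean       sd
    folded 0.629793 0.042972
sort_slice 0.336413 0.023132
```

The vocabulary is heavy-tailed (59 % singletons), and at L = 128 ≪ m_T the
folded fingerprint suffers heavy bit collisions: the random-forest mean
absolute error nearly halves when folding is replaced by Sort & Slice
(0.63 → 0.34, averaged over two-fold cross-validation with three seeds).
Position i of a Sort & Slice fingerprint always means "contains the i-th
most frequent training substructure" — the calibration JSON records which.

The same workflow is available from the shell:

```bash
molpool synth --n 200 --planted 'C(F)(F)C:2.0' --noise 0.3 --seed 42 --out synth.csv
molpool clean --in synth.csv --id-col id --seed 0 --out clean.csv
molpool enumerate --in clean.csv --diameter 4 --out vocab.json
molpool stats --vocab vocab.json --out summary.json
molpool featurise --train clean.csv --method sort_slice --length 128 --out-prefix fp
molpool benchmark --in clean.csv --methods folded,sort_slice --lengths 128 --out results.csv
```

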