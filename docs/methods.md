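# Methods

## Setting

A training set T = {M₁, …, M_n} of standardised single-fragment compounds is
enumerated into per-compound sets of circular-substructure identifiers
φ(M) ⊆ {1, …, 2³²} (Morgan/ECFP scheme). The union of these sets is the
training vocabulary 𝔍_T with cardinality m_T; the support count
c(J) ∈ {1, …, n} of a substructure is the number of training compounds
containing it (presence, not multiplicity — the package produces binary
fingerprints only). A pooling operator Ψ maps any identifier set to a
length-L binary vector; the four operators differ in how bit positions are
assigned.

## Standardisation contract

`standardize_and_desalt` pins one documented behaviour: parse, strip
isotope annotations, RDKit structural cleanup (normalisation, metal
disconnection, reionisation); when at most one organic (carbon-containing)
fragment is present, take the largest-organic-fragment parent and
neutralise it with the uncharger. A string with two or more organic
fragments is a genuine mixture: it is returned multi-fragment and
`clean_dataset` rejects it, while a salt or an inorganic co-fragment is
stripped and the parent survives. Duplicates are detected on the canonical
SMILES of the standardised structure; exactly one member of each duplicate
group survives, chosen uniformly at random from a single explicit seed, and
the labels of the dropped duplicates are discarded rather than averaged.
Cleaning is idempotent, and the surviving record count does not depend on
the seed. Stereo annotations are preserved (chirality is an enumeration
invariant downstream); tautomer canonicalisation is out of scope.

## Enumeration

Identifiers are RDKit's native sparse 32-bit Morgan identifiers, used
directly — the pooling operators only require identity and an arbitrary
total order, so re-hashing would add nothing. The configuration is the
maximal diameter D ∈ {0, 2, 4, …} (radius D/2), the invariant set (standard
atomic invariants, or the six binary pharmacophoric invariants of the
functional-connectivity variant) and a tetrahedral-chirality flag. The
default D = 4, standard invariants, chirality on. RDKit deduplicates
environments that cover the same bond set within one molecule, so e.g. a
two-atom molecule yields three identifiers, not four. The per-compound
trace (identifier → (root atom, radius)) is retained on demand because the
filtering selector reconstructs environment subgraphs from it.

## Pooling operators

**Hash-based folding.** Bit i is set iff some identifier J satisfies
h(J) = i. The hash is pinned to `J mod L` (0-indexed); any fixed choice is
equivalent in principle since the scheme treats h as arbitrary, and the
modulus matches common fingerprint-folding practice. Folding needs no
training data; identifiers unseen in training are hashed like any other —
this asymmetry with the selection operators is intentional.

**Sort & Slice.** Training substructures are ordered by descending support
count; ties are broken by ascending identifier value, so the smaller
identifier gets the earlier rank (the direction is arbitrary in principle;
this package pins ascending and tests it). The first min(L, m_T)
substructures each own one bit in rank order; when L > m_T the fingerprint
is zero-padded. Because positions map one-to-one to identifiers the
fingerprint is collision-free, and for a training compound with L ≥ m_T its
popcount equals its substructure count exactly.

A frequency interpretation backs the method: the entropy of a binary
feature column with support c is H(c/n), which is strictly increasing for
c ≤ n/2. On vocabularies where every support is at most n/2 — nearly true
for any realistic library, and exactly true for the heavy tail — the
frequency order therefore *is* the entropy order, which the test suite
asserts exactly on generated vocabularies.

**Filtering.** Labels are binarised at the median when continuous
(≤ median → 0, > median → 1; the tie side is a documented choice). Starting
from the full vocabulary: (1) substructures with singleton support are
removed in uniformly random order; (2) *non-closed* substructures — those
sharing their exact support with another remaining substructure whose
environment graph is isomorphic to a proper subgraph of their own — are
removed in uniformly random order; (3) the remainder is trimmed to L by the
χ² independence order, removing larger p-values first and, at ties, smaller
identifiers first. Each step stops early if the list reaches L. The
environment graphs include boundary bonds and their endpoint atoms (the
subgraph spanned by all bonds within the radius); a radius-0 environment is
the bare root atom. A same-root smaller radius is used as a fast sufficient
condition for the subgraph test before general substructure matching.
Because subgraph containment is transitive within a same-support group, the
surviving closed set after step 2 is independent of the random removal
order whenever the step runs to completion. A constant binarised label
leaves the χ² order undefined and raises a degenerate-label error.

**Mutual-information maximisation.** Step 1 repeatedly picks a random pair
of substructures with identical support sets and removes one member
uniformly at random, until supports are pairwise distinct (or L is
reached). Step 2 keeps the L features with the highest plug-in mutual
information with the binarised label, removing smaller values first and, at
ties, smaller identifiers first. A constant label makes all MI zero; the
calibration proceeds on the identifier fallback order with a warning.

Both supervised selectors consume a dedicated seeded generator, so a fixed
seed reproduces the selected list exactly. All calibrations serialise to
plain JSON (method, L, ordered identifier list), making every bit auditable.

## Information estimators

Entropy and mutual information are plug-in estimates in bits
(0·log 0 = 0, no bias correction — deliberately, matching the selection
schemes' definitions). The χ² p-value is the upper tail of the Pearson
statistic on the 2×2 table of (binarised label × feature presence) with one
degree of freedom and no continuity correction; a degenerate margin
(constant feature or label) carries no signal and is assigned p = 1.
Frequency-distribution statistics use strict inequalities for "fewer/more
than half" (< n/2, > n/2) and ≥ 0.9 n for the high-frequency count; with an
even n a support of exactly n/2 counts as neither.

## Synthetic libraries

The generator composes molecules by seeded chaining of 2–5 SMILES fragments
from a vetted grammar in which every non-terminal fragment begins and ends
on an atom with spare valence — any concatenation is therefore a valid
SMILES and no rejection loop is needed. Eight common backbone fragments are
drawn with probability 0.65 per slot and twenty-eight rare decorated
fragments with probability 0.35; junction environments between fragments
are combinatorially diverse, so the resulting vocabularies are heavy-tailed
(typically 50–60 % singleton substructures at n = 100–400, with only a
handful of substructures in more than half of the compounds) — emulating
the frequency profile of real chemical datasets. What the generator does
*not* emulate: drug-likeness, realistic property distributions, scaffold
composition, or activity cliffs; passing tests on these libraries validate
the operators' contracts and relative behaviour, not absolute performance
on real assay data.

Labels are planted as a weighted sum of fragment presences plus Gaussian
noise, or its thresholded sign for classification. The default planted
fragment (a CF₂ unit) is the only fluorine source in the default grammar,
so the radius-0 fluorine identifier's support coincides exactly with the
planted presence column — giving the supervised selectors a recoverable
target whose recovery the tests check exactly, at L = 1, across seeds.

## Benchmarking harness

Two-fold cross-validation repeated with three seeds (six runs per cell) over
a grid of diameters, invariants, lengths and pooling methods. Splits:
`random` deals a seeded shuffle round-robin; `stratified` deals each class
separately, keeping per-fold positive counts within one compound of exact
balance (classification only; regression uses plain random); `scaffold`
groups compounds by Bemis–Murcko scaffold SMILES (acyclic molecules share
the empty scaffold), orders groups by descending size with seeded shuffling
among equal sizes, and greedily assigns each group to the currently
smallest fold — scaffolds never cross folds. Pooler calibration uses the
training fold only; the test suite asserts that deleting the held-out
compounds leaves the calibration digest unchanged.

The default model is a scikit-learn random forest with library defaults,
except regression feature subsampling uses the square-root rule. An
optional multilayer perceptron (five hidden layers of 512 rectified units,
adam, initial step 10⁻³, weight-decay 0.1, batch 64, up to 250 epochs) is
provided through scikit-learn; it omits batch normalisation, dropout and
per-epoch learning-rate decay, which that implementation does not expose,
and is far heavier than the forest — the forest is the desk-scale default.
Metrics: MAE for regression, AUROC for balanced classification, AUPRC
(average precision) for imbalanced classification; classification folds
lacking both classes are flagged invalid rather than scored.

## Problem sizes and numerical choices

The shipped evaluations use synthetic libraries of 60–400 compounds and
128-bit fingerprints against vocabularies of 1,500–2,500 substructures
(m_T/L > 10), sizes at which the collision disadvantage of folding is
clearly expressed while a full run stays in the seconds-to-minutes range;
the directional comparison (Sort & Slice MAE ≤ folded MAE) is asserted on
means over the six cross-validation runs, not per run. Ties everywhere are
broken deterministically by identifier value; all stochastic steps
(duplicate survival, random removals, splits, forests) flow from explicit
integer seeds.

## Known limitations

- Count/multiset fingerprints are not produced; the set formalism is
  binary-only by design.
- Trainable pooling over learned substructure embeddings and conditional
  mutual-information selection are out of scope.
- Intra-molecular identifier hash collisions (two environments, one
  identifier) are not resolved; identifiers are treated as opaque.
- The standardiser does not canonicalise tautomers or enumerate stereo
  centres, and its mixture rule (two organic fragments ⇒ reject) is a
  deliberate simplification of full salt/solvent dictionaries.
- The filtering selector's environment-isomorphism test uses default
  substructure-matching semantics; exotic query features (dative bonds,
  polymer monomers) are untested.
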