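# Methods

This note records the modeling decisions behind `pdsubtypes`, the default
parameter values and their rationale, what the synthetic generator does
and does not emulate, and the known limitations.

## Onset labels

EOPD = 0 for 21 < AO < 50; LOPD = 1 for AO > 50. Patients with AO = 50
sit exactly on the class boundary and patients with AO ≤ 21 fall under
juvenile PD, a clinically distinct entity; both groups are excluded, and
`assign_onset_labels` reports their ids. LOPD is the positive class
throughout (it is the majority class in the cohorts this design targets),
so precision/recall in `tree.evaluate` are reported for LOPD.

## Preprocessing (`pdsubtypes.preprocess`)

- **Missingness cut (15%)**: features missing in more than 15% of
  patients are dropped rather than imputed — beyond that level a single
  normative fill dominates the column.
- **AO blocklist**: age of onset, assessment age and PD duration are
  removed before modeling because the label is a deterministic function
  of AO; leaving them in would let the tree re-derive the label.
- **Collinearity (|r| ≥ 0.999)**: of an (almost) identical pair, the
  later column in table order is dropped. The near-1 threshold removes
  only true duplicates (e.g. the same item recorded twice after
  harmonization); milder correlation is left for the tree to arbitrate.
- **Imputation**: normative values (median for numeric, mode for
  categorical, mode ties to the smallest value) fitted on training data
  only and applied to train and test; the external cohort is imputed with
  its *own* normative values, since in deployment the external site never
  sees the training data. Chosen over model-based imputation for
  interpretability: a filled value is a defensible "typical" value.
- **Split**: seeded 80/20 patient split, train size `floor(0.8 n)`.
- **Oversampling**: the minority class is resampled with replacement up
  to the majority count. Duplicated rows keep their patient id, so every
  downstream statistic that matters (subtype membership, class
  composition, criterion 1) is computed over *unique* patients and is
  insensitive to the duplication. With 197 majority / 107 minority
  patients this implies an expected 84.1% duplication load per minority
  patient, and a 10-unique-patient leaf floor corresponds to ~18.4
  (enforced: 19) oversampled rows.

## The tree (`pdsubtypes.tree`)

A from-scratch binary CART with the Gini impurity criterion
(1 − Σ p²). At each node every feature and every midpoint between
consecutive distinct sorted values is scored by the count-weighted
impurity decrease; the best split must *strictly* decrease impurity and
leave ≥ `min_samples_leaf` rows on both sides. Ties break
deterministically: lowest feature index, then smallest threshold — so a
fitted tree is a pure function of (data, hyperparameters). A leaf
majority tie is labeled late onset (the dataset majority class) and
logged. Feature importances are normalized totals of
(node-fraction × impurity decrease) over internal nodes.

The tree is implemented here, not delegated to scikit-learn, because the
subtyping step needs per-leaf artifacts a generic tree does not expose:
unique-patient class counts, deterministic left-to-right leaf order, and
exact root-to-leaf condition paths for rule extraction. scikit-learn's
`DecisionTreeClassifier` appears only as an independent oracle in the
test suite (note it accepts zero-gain splits, so deep trees can
legitimately differ; agreement is exact when every node has a unique
positive-gain optimum).

Hyperparameters are selected by 10-fold cross-validated grid search over
`min_samples_leaf ∈ {10, 12, 14, 16, 18, 20}` × `max_depth ∈ {4, 8, 12,
16, 20}`. Folds partition unique patients; by default each fold's
training portion is oversampled *after* the split so oversampling
duplicates never leak into validation folds (`oversample_before_cv=True`
reproduces the alternative, leak-prone ordering). `min_samples_leaf`
candidates below 10 are rejected: a leaf smaller than 10 unique patients
could never survive Criterion 1, so searching there wastes budget on
unanalyzable trees.

## Subtyping (`pdsubtypes.subtyping`)

Each leaf is a candidate subtype: the conjunction of its path conditions,
simplified to the tightest lower/upper bound per feature. Composition is
measured over unique patients. Gini ≤ 0.4 marks a skewed
(early/late) candidate — 0.4 corresponds to roughly a 70/30 majority —
and Gini > 0.4 a mixed one.

Filtering criteria:

1. **Size**: ≥ 10 unique training patients (enough to characterize).
2. **External match**: matches ≥ ⌈5% of the external same-onset class⌉;
   mixed candidates are measured against the whole external cohort.
3. **Precision**: own-class external matches over all external matches
   must *exceed* the external class prior — i.e. the rule must enrich its
   claimed class beyond chance. Mixed candidates make no class claim and
   are exempt.

Note on the mixed base: criterion 2 for mixed candidates uses the labeled
external table the pipeline actually holds; patients excluded by the AO
rules (boundary/juvenile/missing AO) are not part of it. If the intended
base is the full pre-exclusion cohort, pass its size through
`criteria2_from_counts` / `filter_from_counts` directly.

## Harmonization (`pdsubtypes.harmonize`)

Rules learned in one cohort's vocabulary transfer to another through a
TSV feature map of exact renames and derived features (expressions like
`A minus B`, `Product of A and B`). Derived entries are one-way; missing
inputs propagate as missing. Duplicate source rows are rejected by
default (`on_duplicate="first"` keeps the first and warns — the packaged
80-row example map intentionally contains one duplicated item, mirroring
its published source). Matching is exact and case-sensitive after
whitespace trimming, as clinical data dictionaries use exact codes.

## Characterization (`pdsubtypes.characterize`)

Per-subtype demographic summaries (sample s.d., n−1; PD duration as the
difference of mean assessment and onset ages), binary check-sheet
positive ratios (denominator = subtype size, missing counts as
non-positive, features with ≥ 30% cohort-wide missingness excluded), the
distinguishable-feature screen (|subtype mean − cohort mean| > 0.1; a
feature distinguishes the subtype *set* when flagged for ≥ 50% of
subtypes), and comparison with external clustering labels: clusters with
< 10 patients are merged into one group, agreement is the unadjusted 1971
Rand index (pair-counting form), and overlaps of ≥ 10 patients are
tabulated. Clustering algorithms themselves are out of scope; labels are
ingested from a two-column CSV.

## Synthetic cohorts (`pdsubtypes.synthetic`)

The generator emulates the *shape* of the motivating clinical data, not
its correlation structure:

- 65 MDS-UPDRS-style ordinal items (0–4) drawn from a truncated geometric
  distribution (q = 0.45) concentrated on Normal/Slight, plus a Hoehn &
  Yahr stage peaked at 2, a GDS-15-like score, two binary dyskinesia
  items and gender;
- onset ages from class-conditional truncated normals — N(42.6, 10.5) on
  [22, 49] for early, N(58, 10.5) on [51, 95] for late, rounded to whole
  years — with a 2:1 late:early mix; assessment age = onset + a
  truncated-normal disease duration;
- independent per-cell missingness at per-feature rates;
- a paired validation cohort from the same recipe with an optional
  demographic shift (default +5 years, applied before rounding);
- optional planted subtypes: a conjunction of conditions, a prevalence, an
  onset skew (fraction late) and an adherence; planted members' feature
  values are redrawn conditional on the rule, and membership is recorded
  for recovery scoring (`pipeline.planted_recovery`, best Jaccard overlap
  per planted set).

Not emulated: inter-item correlation beyond the planted rules, site
effects, longitudinal structure, informative missingness, and mutation
carrier status. Features are sampled independently, so background
patients can match a planted rule by chance; common (low-threshold)
planted conditions therefore blur into the background.

All randomness flows through `numpy.random.SeedSequence.spawn`
substreams, so one integer seed fixes both cohorts byte-for-byte and
adding a stage never perturbs the other stages' draws.

## Known limitations

- **Leaf fragmentation under noisy planting.** If a planted subtype's
  onset skew is only partially class-aligned (e.g. 5% of its members in
  the opposite class), its leaf stays impure and CART keeps splitting it
  on noise features; recovery at Jaccard ≥ 0.8 then becomes seed-
  dependent (observed ~5/10 seeds). With fully class-aligned planting
  (skew 0 or 1, adherence 1, rare severe-level conditions) the planted
  leaves are pure and recovery is robust (10/10 seeds at n = 1500, grid
  {10, 20} × {4, 8}); that configuration is what the recovery test in
  `tests/test_acceptance.py` pins down. Generator defaults keep the
  noisier, more realistic skews (0.05/0.95).
- Accuracy on synthetic default cohorts is modest (~0.6): by design most
  features carry no onset signal, and the onset-age distributions of the
  planted classes overlap.
- The CART is exhaustive over midpoints and O(features × n log n) per
  node — fine at clinical scale (hundreds to thousands of patients), not
  tuned for large n.
- Problem sizes used in tests (n = 300–1500 per cohort, reduced CV grids)
  are this package's choice for fast, deterministic verification; the
  full grid at clinical scale runs in minutes.
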