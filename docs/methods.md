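# Methods

## Problem and scope

`phenoclass` implements an end-to-end workflow for building binary
classifiers of antiproliferative compound activity on prostate-cancer
cell lines (PC-3, DU-145 style phenotypic screens): assay-aware data
curation, two activity-threshold labelling schemes, molecular-descriptor
computation and decorrelation, a multi-algorithm benchmarking harness
with a fixed split/calibration protocol, two external-validation
designs, and a biological-target association filter. A synthetic-data
generator reproduces the statistical structure of curated screening
datasets so that every stage is testable offline and at any size.

## Curation model

A raw export has one row per measurement: compound, cell line, assay
protocol (assay type and incubation time), potency type, relation,
value and units. The curation pipeline applies, in order:

1. **Protocol filter** — keep MTT or SRB colorimetric viability assays
   at 48 h or 72 h incubation. These protocols correlate well with each
   other while excluding heterogeneous readouts; the cross-protocol
   overlap report (shared-compound counts and Pearson r of per-protocol
   mean pActivities) quantifies this on any given dataset. A regex
   pre-tagger is provided for exports that carry the protocol only in a
   free-text assay description; structured columns always win.
2. **Standard filter** — keep exact potencies (`relation == "="`) in nM
   as IC50 or GI50. Censored values (">", "<") are uninformative for
   regression-to-label conversion and are dropped.
3. **pActivity conversion** — pActivity = 9 − log10(value in nM), i.e.
   the negative decadic log of the molar concentration (10 µM ↔ 5.0).
4. **Duplicate resolution** — measurements are pooled per compound per
   cell line across protocols and potency types. Groups whose pActivity
   range is ≤ 1 log unit (compared with a 1e−9 tolerance so the boundary
   is inclusive) collapse to the arithmetic mean; wider groups are
   discarded as irreproducible. IC50 and GI50 are pooled *before*
   resolution: both measure 50% response in the same cell system and the
   range rule already rejects discordant pairs.
5. **Molecular-weight window** — keep compounds with average MW in
   [100, 600] Da (inclusive bounds), computed from the SMILES with
   RDKit. Unparseable structures are dropped with a warning, never
   imputed.

The protocol and standard filters commute and are idempotent, which the
test suite asserts; the fixed order above is therefore a presentation
choice, not a numerical one.

## Threshold labelling

Compounds are ranked by descending pActivity (most potent first; ties
broken by compound id for reproducibility).

**FIX p** labels the top p% active (p ∈ [40, 60] in the standard
configurations). The base count is round-half-up of p%·n; all compounds
tied at the boundary potency are absorbed into the active class so that
equal potencies never receive different labels. Class counts can
therefore deviate slightly from the exact percentage; the deviation is
logged.

**GAP g** excludes g% of the compounds around the median rank
(g ∈ {5, 10, 15, 20}) and labels the remaining upper half active. The
total excluded count is round-half-up of g%·n, split evenly across the
median cut with an odd leftover taken from the more potent side. The
rationale: compounds near the threshold are the ones whose labels are
most sensitive to assay noise, and removing them both cleans the
training signal and widens the potency separation between classes.

Each labelled dataset reports diagnostics: the least-potent active and
most-potent inactive in µM, their ratio (the **closest ratio**,
min-inactive µM / max-active µM, ≥ 1 under monotone labels and exactly
1.00 for FIX on dense data), and the mean ± sd Tanimoto similarity
between the classes on Morgan fingerprints of radius 2 (ECFP4
equivalent, 2048 bits). Cross-class similarity uses full pair
enumeration up to 10⁶ pairs and a seeded subsample beyond that.

## Descriptors and decorrelation

The descriptor block is a fixed, versioned list of 123 RDKit
physicochemical/topological descriptors, shipped as
`data/descriptor_manifest.json` (the non-fragment-count descriptors of
the pinned toolkit, excluding one overflow-prone information index and
one composite drug-likeness score). Pinning the list keeps the feature
space stable across toolkit upgrades. Rare non-finite descriptor values
(a few descriptors are undefined for certain molecules) are imputed with
the column median so the matrix is dense.

Redundancy is removed greedily: scanning descriptors in manifest order,
a descriptor is dropped when its absolute Pearson correlation with any
already-retained descriptor exceeds the threshold t (0.95 / 0.85 / 0.75
in the standard configurations; 1.0 disables filtering). Zero-variance
columns are removed first (their correlation is undefined). Greedy
keep-first is order-dependent by construction; the order is fixed and
documented, and the invariant that every retained pair satisfies
|r| ≤ t is verified by brute force in the tests. Absolute correlation is
used: a strongly anti-correlated pair is as redundant as a correlated
one.

No global feature standardisation is applied. Scale-sensitive learners
(LR, KNN, SVM) run inside a pipeline whose standard scaler is fit on the
training split only, avoiding leakage into validation and test.

## Evaluation metrics

Ten quantities are computed literally from the confusion counts
(active = positive class):

accuracy, precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = harmonic mean of precision and recall,
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
TNR = TN/(TN+FP), FPR = FP/(TN+FP), FNR = FN/(TP+FN), TPR = TP/(TP+FN),
plus rank-based ROC AUC (Mann–Whitney; ties ½), computed on calibrated
probabilities.

A zero denominator yields *undefined* (`None`), propagated to report
files as a missing cell — never silently 0. Report files round half away
from zero to 2 decimals; full precision is retained internally. The
implementation is checked against an independent oracle (reconstructed
label vectors scored by scikit-learn) on 1000 random confusion matrices.

## Benchmarking protocol

Each labelled dataset is split into four stratified folds (per-fold
class proportions within one compound of the global proportions). The
twelve iterations are the twelve ordered (validation, test) assignments
among the four folds — the exhaustive set, making the scheme seed-free
given the fold partition and realising a 50:25:25 train/validation/test
ratio in every iteration.

Within an iteration: hyper-parameters are tuned on the two training
folds by grid search with internal fivefold stratified CV scored by F1;
the best configuration is refit on the full training split; the fitted
model's scores are calibrated on the validation fold with a Platt
sigmoid (isotonic optional) — the model itself is frozen, only the
monotone score→probability map is learned; class predictions use a 0.5
threshold on the calibrated probability. Calibration on a single-class
validation split is skipped with a warning and raw scores are used.

Ten algorithms are registered (LR, LDA, KNN, CART, NB, SVM, AB, GBM,
RF, ET — scikit-learn implementations) with config-overridable default
grids: LR C ∈ {0.01, 0.1, 1, 10}; KNN k ∈ {3, 5, 7, 11, 15}; CART depth
∈ {none, 4, 8, 16}; SVM (RBF) C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01,
0.001}; AB estimators ∈ {50, 100, 200}; GBM learning rate ∈ {0.05,
0.1}; RF/ET trees ∈ {100, 300, 500}, depth ∈ {none, 8, 16}; LDA/NB no
grid. One master seed expands deterministically (SHA-256 of the context
tuple) into per-iteration and per-search seeds, so results are
bit-reproducible given (seed, dataset, grid).

## External validation

**Assay holdout** removes every compound of one assay document
(≥ 30 labelled compounds required) as the external test set; the
remainder splits 75:25 (stratified, seeded) into train and validation;
tune → calibrate → evaluate as above (default algorithm RF). Test
disjointness from train and validation is asserted structurally.

**Combined cell lines** pools the single-line compounds of two curated
datasets into one training corpus and uses the dual-activity compounds
(present in both lines) as the test set, each carrying one label per
line. Cross-line compound identity is the canonical SMILES with a
compound-id fallback (`identity="id"` switches to id matching, needed
for corpora where structures are not unique keys, e.g. the synthetic
library). Each line's full dataset is labelled with the chosen method;
under GAP labelling, gap-excluded single-line compounds are omitted from
training and each line's gap-excluded test compounds are omitted from
that line's scoring, so per-line scored counts plus gap-excluded counts
reconcile to the overlap size. The default feature threshold is
PCC ≤ 0.95, configurable (0.85 is an equally defensible choice and both
are runnable).

## Target association filter

Compound–target records are kept when they are exact (`=`) IC50 values
in nM at ≤ 1000 nM (inclusive), from binding assays on human targets;
non-IC50 potency types (Ki, Kd) are dropped and counted. Promiscuous
binders are excluded by id list. A pair qualifies if *any* of its
records qualifies; frequency counts then collapse to distinct active
compounds per target, binned as 1, 2–9 and ≥ 10. Disease association is
a flag against a provided accession list (built, in the original
workflow, from UniProt reviewed entries matching "prostate cancer" +
human plus TTD disease-keyword targets, deduplicated); live database
querying is out of scope.

## Synthetic-data generator

The generator emulates the statistical shape of the curated screening
data; its defaults are the study conditions:

- **pActivity** — truncated normal on [3.5, 9.0], mean 5.1, sd 0.5.
  The sd is set so the distribution satisfies the contract that ≥ 85 %
  of values fall in [4.5, 6.5] (analytically 88.3 % at sd 0.5; the
  window is asymmetric about the mean, so larger spreads violate the
  contract). Verified empirically in the tests at n = 10⁴.
- **Repeat records** — a configurable fraction of compounds (default
  0.2) receives 2–3 records with N(0, 0.15) log-unit noise under
  independently sampled protocols and document ids, then back-converted
  to nM, exercising the duplicate-resolution rule. The discard rate
  under heavy noise matches a direct simulation of the range
  distribution.
- **Paired cell lines** — shared compounds draw bivariate-normal
  pActivities through a Gaussian copula with truncated-normal margins at
  correlation 0.93 (default). `gen_study_scale_datasets` fixes the
  published scale: 4353 + 2393 compounds, 587 shared, per-line means
  5.12 / 5.16.
- **Features** — block-correlated Gaussians (default 5 blocks,
  within-block r ≈ 0.9). Class signal is a mean shift of each block's
  first feature, either by label (`labels=`) or along a continuous
  covariate (`signal_values=`), tuning recovery from null to separable.
- **Structures** — sampled with replacement from a shipped library of
  135 real, RDKit-validated drug-like SMILES (all MW 100–600 Da), so
  descriptor and fingerprint code paths run on genuine chemistry.

What the generator does **not** emulate: real structure–activity
relationships (features are Gaussian, not descriptor-derived from the
sampled structures), assay-specific batch effects, chemical-series
clustering, and the long right tail of potency distributions. Passing
tests therefore demonstrate that the machinery is correct and that the
protocols behave as designed under controlled conditions — not that any
particular accuracy will be achieved on real screening data.

## Problem sizes used in the checks

The statistical acceptance checks use deliberately small problems:
null recovery uses 20 seeds × 160 compounds × 3 fast algorithms
(single-point grids) and asserts mean test MCC within ±0.05 of 0;
signal recovery uses 240 strongly separated compounds and asserts
RF/KNN/SVM test MCC > 0.9; the GAP-vs-FIX comparison uses 20 seeds ×
300 compounds whose observed potencies are a latent signal plus
N(0, 0.3) noise, features driven by the latent value, scored with LDA —
label noise then concentrates at the class boundary and excluding the
intermediate band (GAP 20) yields higher mean validation MCC than the
single-threshold split (FIX 50). These sizes are the package's own
choice: large enough for stable means, small enough to iterate on.

## Known limitations

- Exact reproduction of published class counts under FIX labelling is
  not guaranteed: boundary-tie structure in the real data is not
  recoverable from the printed tables, and the tie-absorption rule can
  differ by a few compounds.
- The greedy decorrelation order makes retained-descriptor identities
  (not the pairwise-compliance guarantee) dependent on the manifest
  order.
- Calibration uses the validation split once; no repeated-calibration
  variance estimate is provided.
- Chemical standardisation is limited to SMILES parsing and MW — no
  salt stripping or tautomer canonicalisation.
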