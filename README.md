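# phenoclass

Binary classification of antiproliferative compound activity on
prostate-cancer cell lines (PC-3 / DU-145 style phenotypic screens),
from raw assay exports to externally validated models.

Phenotypic screening data aggregated from the literature is noisy and
heterogeneous: the same compound is measured under different assay
protocols, potency types and incubation times, and the active/inactive
boundary is an arbitrary cut through a distribution concentrated around
10 µM. `phenoclass` is for cheminformaticians who want to build such
classifiers reproducibly: it curates the records, labels them with
either a fixed-percentile threshold (**FIX p**) or an
intermediate-exclusion threshold (**GAP g**), computes and decorrelates
a pinned block of 123 RDKit descriptors, benchmarks ten scikit-learn
algorithms under a fixed protocol, and validates the winners on held-out
assay documents and across cell lines.

## The core procedure

- **Curation.** Keep MTT/SRB viability assays at 48/72 h; exact (`=`)
  IC50/GI50 potencies in nM; convert to pActivity = −log₁₀(molar
  concentration) = 9 − log₁₀(nM); collapse repeat measurements whose
  range is ≤ 1 log unit to their mean and discard wider groups; keep
  compounds with MW ∈ [100, 600] Da.
- **Labelling.** Rank by descending potency. FIX p: top p% active.
  GAP g: exclude g% around the median rank, upper half active. Each
  dataset reports the *closest ratio* — potency of the most-potent
  inactive over the least-potent active, the class separation at the
  threshold — and the cross-class ECFP4 Tanimoto similarity.
- **Evaluation.** Four stratified folds; twelve iterations = all ordered
  (validation, test) fold pairs (50:25:25). Per iteration: fivefold grid
  search on F1 → Platt calibration on the validation fold → scores on
  all splits. Metrics: accuracy, precision, recall, F1, MCC, ROC AUC,
  TNR/FPR/FNR/TPR, computed literally from confusion counts with zero
  denominators reported as undefined, never as 0.
- **External validation.** Leave-one-assay-document-out (all compounds
  from one publication form the test set), and a combined two-cell-line
  model tested on the dual-activity compounds with one label per line.

See `docs/methods.md` for the full model description, parameter
defaults and design rationale.

## Worked example

```python
from phenoclass import curate, label_gap, compute_descriptors, decorrelate
from phenoclass.simulate import GeneratorConfig, gen_activity_records

records = gen_activity_records(
    GeneratorConfig(n_compounds=300, duplicate_rate=0.4,
                    duplicate_noise_sd=0.4, seed=42), cell_line="PC3")
entries = curate(records, cell_line="PC3")
print(len(records), "->", len(entries))          # 495 -> 284

ds = label_gap(entries, 20)
print(ds.n_active, ds.n_inactive, ds.n_excluded) # 113 114 57
print(round(ds.closest_ratio, 2))                # 1.93

fm = decorrelate(compute_descriptors(
    [e.smiles for e in ds.entries],
    [e.compound_id for e in ds.entries]), 0.95)
print(fm.n_descriptors)                          # 100
```

495 raw measurements curate down to 284 compounds (the rest were
measured only under unsupported protocols or had repeat potencies
spanning more than one log unit). GAP 20 excludes the 57 compounds of
intermediate potency; the least-potent active and most-potent inactive
then differ 1.93-fold in micromolar potency. Of the 123 descriptors, 100
survive decorrelation at |r| ≤ 0.95 on this dataset.

The `examples/` directory holds one short script per capability
(curation and protocol overlap, threshold labelling, descriptor
filtering, benchmarking, assay holdout, combined cell lines, target
annotation); each prints the numbers it computes with a note on what
they mean. A thin CLI wraps the same functions:

```bash
phenoclass simulate --n-compounds 400 --out raw.csv
phenoclass curate --in raw.csv --cell-line PC3 --out curated.csv
phenoclass label --method gap --pct 20 --in curated.csv --out labelled.csv
phenoclass featurize --in labelled.csv --pcc 0.95 --out features.csv
phenoclass benchmark --features features.csv --labels labelled.csv --out results/
phenoclass run --config config.yaml --out run/       # full pipeline + manifest
```

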