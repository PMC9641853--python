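"""External validation protocols: assay holdout and combined cell lines.

Two designs probe how the classifiers generalise beyond a random split:

* **Leave-one-assay-document-out** — all compounds reported by one
  publication's assay form the external test set; the remainder is split
  75:25 (stratified) into training and validation, a model is tuned,
  calibrated and then scored on the held-out document.  This mimics
  prospective use on a new study's chemistry.
* **Combined cell lines** — compounds with activity on both cell lines
  form the test set (each carrying one label per line); all single-line
  compounds are pooled into one training corpus.  A single model's test
  predictions are scored twice, once against each line's labels.  Under
  GAP labelling, test compounds falling in a line's excluded
  intermediate zone are omitted from that line's scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.model_selection import train_test_split

from .benchmark import (AlgorithmSpec, CalibratedModel, calibrate,
                        default_algorithms, derive_seed, tune)
from .curation import CompoundEntry
from .features import FeatureMatrix
from .labelling import ACTIVE, INACTIVE, LabelledDataset, label_fixed, label_gap
from .metrics import ConfusionMatrix, MetricReport, confusion, score_predictions

logger = logging.getLogger(__name__)

DEFAULT_MIN_RECORDS = 30


@dataclass
class HoldoutResult:
    """Scores of one model on one held-out assay document."""

    document_id: str
    n_compounds: int
    n_active: int
    n_inactive: int
    confusion: ConfusionMatrix
    report: MetricReport
    algorithm: str = "RF"

    def to_row(self) -> dict:
        r = self.report.rounded()
        return {"document_id": self.document_id, "n_compounds": self.n_compounds,
                "n_active": self.n_active, "n_inactive": self.n_inactive,
                "accuracy": r["accuracy"], "tn": self.confusion.tn,
                "fp": self.confusion.fp, "fn": self.confusion.fn,
                "tp": self.confusion.tp, "tnr": r["tnr"], "fpr": r["fpr"],
                "fnr": r["fnr"], "tpr": r["tpr"]}


def _xy(dataset: LabelledDataset, features: FeatureMatrix, ids: Sequence[str]):
    label_of = {e.compound_id: l for e, l in zip(dataset.entries, dataset.labels)}
    sub = features.subset(list(ids))
    y = np.array([1 if label_of[c] == ACTIVE else 0 for c in ids])
    return sub.values, y


def assay_holdout(
    dataset: LabelledDataset,
    features: FeatureMatrix,
    documents: Mapping[str, str],
    document_id: str,
    min_records: int = DEFAULT_MIN_RECORDS,
    algorithm: AlgorithmSpec | None = None,
    seed: int = 0,
    calibration: str = "sigmoid",
) -> HoldoutResult:
    """Hold out every compound of one assay document and score on it.

    ``documents`` maps compound_id → document_id.  The document must
    contribute at least ``min_records`` labelled compounds.  The
    remaining compounds are split 75:25 (stratified, seeded) into train
    and validation; the model is tuned on train, calibrated on
    validation, and evaluated on the held-out document.
    """
    if algorithm is None:
        algorithm = default_algorithms()["RF"]
    all_ids = [e.compound_id for e in dataset.entries]
    test_ids = [c for c in all_ids if documents.get(c) == document_id]
    if len(test_ids) < min_records:
        raise ValueError(
            f"document {document_id} has {len(test_ids)} labelled compounds, "
            f"fewer than the required {min_records}")
    rest = [c for c in all_ids if c not in set(test_ids)]
    _, y_rest = _xy(dataset, features, rest)
    train_ids, val_ids = train_test_split(
        rest, test_size=0.25, stratify=y_rest,
        random_state=derive_seed(seed, "holdout", document_id))
    assert not set(test_ids) & (set(train_ids) | set(val_ids))

    X_tr, y_tr = _xy(dataset, features, train_ids)
    X_val, y_val = _xy(dataset, features, val_ids)
    X_te, y_te = _xy(dataset, features, test_ids)
    model, _ = tune(algorithm, X_tr, y_tr,
                    seed=derive_seed(seed, "tune", document_id))
    cal = calibrate(model, X_val, y_val, method=calibration)
    prob = cal.predict_proba(X_te)
    pred = np.where(prob >= 0.5, ACTIVE, INACTIVE)
    truth = np.where(y_te == 1, ACTIVE, INACTIVE)
    cm = confusion(truth, pred)
    return HoldoutResult(
        document_id=document_id, n_compounds=len(test_ids),
        n_active=int(y_te.sum()), n_inactive=int(len(y_te) - y_te.sum()),
        confusion=cm, report=score_predictions(truth, pred, prob),
        algorithm=algorithm.name)


def eligible_documents(dataset: LabelledDataset, documents: Mapping[str, str],
                       min_records: int = DEFAULT_MIN_RECORDS) -> list[str]:
    """Documents with at least ``min_records`` labelled compounds."""
    counts: dict[str, int] = {}
    for e in dataset.entries:
        doc = documents.get(e.compound_id)
        if doc is not None:
            counts[doc] = counts.get(doc, 0) + 1
    return sorted(d for d, n in counts.items() if n >= min_records)


@dataclass
class CombinedDatasetPlan:
    """Partition for the combined two-cell-line model.

    ``test_pairs`` holds (entry_on_line_a, entry_on_line_b) for every
    compound with activity on both lines; ``train_val_a``/``train_val_b``
    the single-line compounds of each line.
    """

    train_val_a: list[CompoundEntry]
    train_val_b: list[CompoundEntry]
    test_pairs: list[tuple[CompoundEntry, CompoundEntry]]

    @property
    def n_train_val(self) -> int:
        return len(self.train_val_a) + len(self.train_val_b)

    @property
    def n_test(self) -> int:
        return len(self.test_pairs)


def _structure_key(entry: CompoundEntry) -> str:
    mol = Chem.MolFromSmiles(entry.smiles)
    return Chem.MolToSmiles(mol) if mol is not None else f"id:{entry.compound_id}"


def build_combined(
    entries_a: Sequence[CompoundEntry],
    entries_b: Sequence[CompoundEntry],
    identity: str = "structure",
) -> CombinedDatasetPlan:
    """Split two curated cell-line datasets into combined train and dual test.

    Compound identity across lines is the canonical SMILES by default
    (compound-id fallback for unparseable structures); ``identity="id"``
    matches on compound ids instead, for corpora where the structure is
    not a unique key.  A mismatch between id-based and structure-based
    overlap is logged.  Compounds present in both lines become the
    dual-label test set; all others form the pooled train/validation
    corpus.  An empty overlap yields an empty test set with a warning.
    """
    if identity not in {"structure", "id"}:
        raise ValueError(f"identity must be 'structure' or 'id', got {identity!r}")
    key = (_structure_key if identity == "structure"
           else lambda e: e.compound_id)
    a_by_key = {}
    for e in entries_a:
        a_by_key.setdefault(key(e), e)
    b_by_key = {}
    for e in entries_b:
        b_by_key.setdefault(key(e), e)
    shared_keys = sorted(set(a_by_key) & set(b_by_key),
                         key=lambda k: a_by_key[k].compound_id)

    id_shared = {e.compound_id for e in entries_a} & {e.compound_id for e in entries_b}
    if len(id_shared) != len(shared_keys):
        logger.info("build_combined: structure-key overlap (%d) differs from "
                    "compound-id overlap (%d)", len(shared_keys), len(id_shared))
    if not shared_keys:
        logger.warning("build_combined: no shared compounds — empty test set")

    test_a_ids = {a_by_key[k].compound_id for k in shared_keys}
    test_b_ids = {b_by_key[k].compound_id for k in shared_keys}
    return CombinedDatasetPlan(
        train_val_a=[e for e in entries_a if e.compound_id not in test_a_ids],
        train_val_b=[e for e in entries_b if e.compound_id not in test_b_ids],
        test_pairs=[(a_by_key[k], b_by_key[k]) for k in shared_keys],
    )


def _label_line(entries: Sequence[CompoundEntry], method: str,
                pct: float) -> LabelledDataset:
    if method.upper() == "GAP":
        return label_gap(list(entries), pct)
    if method.upper() == "FIX":
        return label_fixed(list(entries), pct)
    raise ValueError(f"unknown labelling method {method!r}")


def evaluate_combined(
    plan: CombinedDatasetPlan,
    features: FeatureMatrix,
    algorithms: dict[str, AlgorithmSpec] | None = None,
    method: str = "GAP",
    pct: float = 20.0,
    seed: int = 0,
    calibration: str = "sigmoid",
) -> pd.DataFrame:
    """Train on the pooled single-line corpus, score per-line on the dual test.

    Each cell line's full dataset (single-line plus its half of the test
    pairs) is labelled with the requested method; single-line compounds
    keep their line's label in the pooled corpus (GAP-excluded singles
    are omitted from training), and each test compound receives one label
    per line.  For every algorithm one model is tuned on a stratified
    75:25 train/validation split of the corpus, calibrated on the
    validation part, and its test predictions are scored against each
    line's labels — skipping, per line, test compounds that fall in that
    line's excluded gap zone.  Returns one row per (algorithm, line).
    """
    if algorithms is None:
        reg = default_algorithms()
        algorithms = {k: reg[k] for k in ("SVM", "RF", "KNN")}
    if not plan.test_pairs:
        raise ValueError("plan has an empty test set")

    full_a = list(plan.train_val_a) + [p[0] for p in plan.test_pairs]
    full_b = list(plan.train_val_b) + [p[1] for p in plan.test_pairs]
    lab_a = _label_line(full_a, method, pct)
    lab_b = _label_line(full_b, method, pct)

    def line_labels(lab: LabelledDataset) -> dict[str, str]:
        return {e.compound_id: l for e, l in zip(lab.entries, lab.labels)}

    labels_a, labels_b = line_labels(lab_a), line_labels(lab_b)

    corpus_ids, corpus_y = [], []
    for e in plan.train_val_a:
        if e.compound_id in labels_a:           # not gap-excluded
            corpus_ids.append(e.compound_id)
            corpus_y.append(1 if labels_a[e.compound_id] == ACTIVE else 0)
    for e in plan.train_val_b:
        if e.compound_id in labels_b:
            corpus_ids.append(e.compound_id)
            corpus_y.append(1 if labels_b[e.compound_id] == ACTIVE else 0)
    corpus_y = np.array(corpus_y)

    train_ids, val_ids, y_tr, y_val = train_test_split(
        corpus_ids, corpus_y, test_size=0.25, stratify=corpus_y,
        random_state=derive_seed(seed, "combined-split", method, pct))
    X_tr = features.subset(train_ids).values
    X_val = features.subset(val_ids).values

    rows = []
    for name, spec in algorithms.items():
        model, _ = tune(spec, X_tr, y_tr,
                        seed=derive_seed(seed, "combined-tune", name, method, pct))
        cal = calibrate(model, X_val, y_val, method=calibration)
        for labels, pick in ((labels_a, 0), (labels_b, 1)):
            line = plan.test_pairs[0][pick].cell_line
            scored = [p for p in plan.test_pairs
                      if p[pick].compound_id in labels]
            ids = [p[pick].compound_id for p in scored]
            truth = [labels[c] for c in ids]
            prob = cal.predict_proba(features.subset(ids).values)
            pred = np.where(prob >= 0.5, ACTIVE, INACTIVE)
            report = score_predictions(truth, pred, prob)
            r = report.rounded()
            rows.append({
                "cell_line": line, "algorithm": name,
                "method": f"{method.upper()} {pct:g}",
                "n_compounds": len(ids),
                "n_active": sum(1 for t in truth if t == ACTIVE),
                "n_inactive": sum(1 for t in truth if t == INACTIVE),
                "n_gap_excluded": plan.n_test - len(ids),
                **{k: r[k] for k in ("accuracy", "precision", "recall", "f1",
                                     "mcc", "roc_auc", "tnr", "fpr", "fnr", "tpr")},
            })
    return pd.DataFrame(rows)
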