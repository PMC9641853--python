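"""Compound–target association filtering and prostate-cancer annotation.

Potency records linking compounds to biological targets are filtered to
high-confidence direct measurements: exact (``=``) IC50 values in nM of
at most 1000 nM (1 µM, inclusive), from binding assays on human targets.
Promiscuous binders (e.g. staurosporine) can be excluded by id.  The
surviving targets are flagged against a provided list of prostate-cancer
-associated accession ids, and per-target counts of distinct active
compounds are summarised into frequency bins (1, 2–9, ≥10 compounds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

POTENCY_MAX_NM = 1000.0
FREQUENCY_BINS = ("1", "2-9", ">=10")


@dataclass(frozen=True)
class TargetAssociation:
    """One compound–target potency record."""

    compound_id: str
    target_id: str
    potency_nM: float
    standard_type: str = "IC50"
    standard_relation: str = "="
    standard_units: str = "nM"
    assay_class: str = "binding"       # binding | functional | other
    organism: str = "human"
    uniprot_id: str | None = None
    pca_associated: bool = False


def filter_target_records(
    records: Iterable[TargetAssociation],
    exclusion_list: Iterable[str] = (),
) -> list[TargetAssociation]:
    """Keep exact nM IC50 binding records on human targets at ≤ 1000 nM.

    ``exclusion_list`` removes promiscuous compounds by id.  Multiple
    records per compound–target pair are kept individually here — any
    qualifying record keeps the pair (downstream counts collapse
    duplicates to distinct compounds).  Non-IC50 potency types (Ki, Kd…)
    are dropped and counted in the log.
    """
    excluded = set(exclusion_list)
    kept: list[TargetAssociation] = []
    n_type = 0
    for r in records:
        if r.compound_id in excluded:
            continue
        if r.standard_type.upper() != "IC50":
            n_type += 1
            continue
        if (r.standard_relation == "=" and r.standard_units == "nM"
                and r.assay_class == "binding"
                and r.organism.lower() == "human"
                and 0 < r.potency_nM <= POTENCY_MAX_NM):
            kept.append(r)
    if n_type:
        logger.info("filter_target_records: dropped %d non-IC50 record(s)", n_type)
    return kept


def annotate_pca(
    associations: Iterable[TargetAssociation],
    pca_target_list: Iterable[str],
    target_to_uniprot: Mapping[str, str] | None = None,
) -> list[TargetAssociation]:
    """Flag associations whose target maps to a prostate-cancer accession.

    ``pca_target_list`` holds UniProt accession ids; ``target_to_uniprot``
    maps target ids to accessions (records already carrying a uniprot_id
    need no mapping).  Unmapped targets are flagged False with a warning.
    """
    accessions = set(pca_target_list)
    mapping = dict(target_to_uniprot or {})
    out = []
    unmapped: set[str] = set()
    for r in associations:
        acc = r.uniprot_id or mapping.get(r.target_id)
        if acc is None:
            unmapped.add(r.target_id)
        out.append(replace(r, uniprot_id=acc,
                           pca_associated=acc is not None and acc in accessions))
    if unmapped:
        logger.warning("annotate_pca: %d target(s) without a UniProt mapping: %s",
                       len(unmapped), sorted(unmapped)[:10])
    return out


def target_frequency(
    associations: Iterable[TargetAssociation],
    active_compound_ids: Iterable[str],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Distinct-active-compound counts per target, plus binned frequencies.

    Counts consider only compounds in ``active_compound_ids`` and collapse
    duplicate records per compound–target pair.  The second return value
    gives the relative frequency of targets with 1, 2–9 and ≥10 associated
    active compounds.
    """
    actives = set(active_compound_ids)
    pairs = {(r.target_id, r.compound_id)
             for r in associations if r.compound_id in actives}
    counts: dict[str, int] = {}
    for target, _ in pairs:
        counts[target] = counts.get(target, 0) + 1
    table = pd.DataFrame(sorted(counts.items()),
                         columns=["target_id", "n_active_compounds"])
    n_targets = len(counts)
    bins = {b: 0 for b in FREQUENCY_BINS}
    for n in counts.values():
        if n == 1:
            bins["1"] += 1
        elif n < 10:
            bins["2-9"] += 1
        else:
            bins[">=10"] += 1
    freq = {b: (bins[b] / n_targets if n_targets else float("nan"))
            for b in FREQUENCY_BINS}
    return table, freq


def read_association_table(path: str | Path) -> list[TargetAssociation]:
    """Load a compound–target CSV (columns as in :class:`TargetAssociation`)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"compound_id", "target_id", "potency_nM"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"missing column(s): {sorted(missing)}")
    out = []
    for row in df.to_dict("records"):
        try:
            potency = float(row["potency_nM"])
        except ValueError:
            continue
        out.append(TargetAssociation(
            compound_id=row["compound_id"], target_id=row["target_id"],
            potency_nM=potency,
            standard_type=row.get("standard_type", "IC50") or "IC50",
            standard_relation=row.get("standard_relation", "=") or "=",
            standard_units=row.get("standard_units", "nM") or "nM",
            assay_class=row.get("assay_class", "binding") or "binding",
            organism=row.get("organism", "human") or "human",
            uniprot_id=row.get("uniprot_id") or None,
        ))
    return out


def read_id_list(path: str | Path) -> list[str]:
    """One id per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
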