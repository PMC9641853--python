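"""Curation of raw cell-based antiproliferative activity tables.

Raw ChEMBL-style exports contain one row per activity measurement (a
compound tested on a cell line under a given assay protocol).  This module
turns such tables into one consensus entry per compound per cell line:

1. keep only colorimetric viability protocols (MTT or SRB) with 48 h or
   72 h incubation;
2. keep only exact potencies (``standard_relation == "="``) reported in nM
   as IC50 or GI50;
3. convert potencies to pActivity, the negative base-10 logarithm of the
   molar concentration (10 µM ↔ pActivity 5);
4. collapse repeated measurements of a compound: groups whose pActivity
   range is ≤ 1 log unit are averaged, wider groups are discarded as
   irreproducible;
5. keep only compounds with average molecular weight between 100 and
   600 Da (computed from the SMILES with RDKit).

A cross-protocol overlap report (shared-compound counts and Pearson
correlations between protocols) quantifies how consistent the retained
protocols are with each other.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _Desc
from rdkit import RDLogger as _RDLogger
from scipy import stats as _stats

_RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

VALID_ASSAY_TYPES = frozenset({"MTT", "SRB"})
VALID_INCUBATIONS_H = frozenset({48, 72})
VALID_STANDARD_TYPES = frozenset({"IC50", "GI50"})
MW_MIN, MW_MAX = 100.0, 600.0
#: pActivity ranges up to and including this value are averaged; wider
#: groups are discarded.  Compared with a small tolerance so that a range
#: of exactly 1.0 survives floating-point noise.
DUPLICATE_RANGE_MAX = 1.0
_RANGE_TOL = 1e-9

_CELL_LINE_ALIASES = {
    "PC3": "PC3", "PC-3": "PC3",
    "DU145": "DU145", "DU-145": "DU145",
}

DEFAULT_SCHEMA: dict[str, str] = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "assay_id": "assay_id",
    "document_id": "document_id",
    "cell_line": "cell_line",
    "assay_type": "assay_type",
    "incubation_h": "incubation_h",
    "standard_type": "standard_type",
    "standard_relation": "standard_relation",
    "standard_value": "standard_value",
    "standard_units": "standard_units",
}


class SchemaError(KeyError):
    """A required column is missing from the input table."""


@dataclass(frozen=True)
class ActivityRecord:
    """One raw assay measurement of one compound on one cell line."""

    compound_id: str
    smiles: str
    assay_id: str
    document_id: str
    cell_line: str
    assay_type: str            # "MTT" | "SRB" | anything else
    incubation_h: int
    standard_type: str         # e.g. "IC50", "GI50"
    standard_relation: str     # e.g. "=", ">", "<"
    standard_value: float      # potency in standard_units
    standard_units: str        # expected "nM"
    pactivity: float | None = None


@dataclass(frozen=True)
class CompoundEntry:
    """One curated compound on one cell line with consensus pActivity."""

    compound_id: str
    smiles: str
    cell_line: str
    pactivity: float
    mw: float | None = None
    n_source_records: int = 1


@dataclass
class ProtocolOverlapReport:
    """Shared-compound counts and Pearson r between assay protocols.

    ``protocols`` orders the (assay_type, incubation_h) pairs; ``counts``
    is the symmetric matrix of compounds measured under both protocols and
    ``pearson`` the matching matrix of correlations between per-protocol
    mean pActivities (NaN where fewer than 2 shared compounds).
    """

    protocols: list[tuple[str, int]]
    counts: np.ndarray
    pearson: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{a} {h} h" for a, h in self.protocols]
        cells = []
        for i in range(len(labels)):
            row = {}
            for j, lab in enumerate(labels):
                r = self.pearson[i, j]
                rtxt = "/" if np.isnan(r) else f"{r:.2f}"
                row[lab] = f"{int(self.counts[i, j])} ({rtxt})"
            cells.append(row)
        return pd.DataFrame(cells, index=labels)


def normalize_cell_line(value: str) -> str:
    key = str(value).strip().upper()
    return _CELL_LINE_ALIASES.get(key, key)


_DESC_TIME = re.compile(r"\b(24|48|72)\s*h(?:ours?|rs?)?\b", re.IGNORECASE)
_DESC_ASSAY = re.compile(r"\b(MTT|SRB)\b", re.IGNORECASE)


def tag_protocol_from_description(description: str) -> tuple[str | None, int | None]:
    """Extract (assay_type, incubation_h) from a free-text assay description.

    Convenience pre-tagger for raw exports that carry the protocol only in
    the assay description field; structured columns take precedence when
    present.  Returns ``None`` for a field that cannot be recognised.
    """
    a = _DESC_ASSAY.search(description or "")
    t = _DESC_TIME.search(description or "")
    return (a.group(1).upper() if a else None, int(t.group(1)) if t else None)


def read_activity_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[ActivityRecord]:
    """Parse a CSV/TSV activity table into :class:`ActivityRecord` rows.

    ``schema`` maps canonical field names to the file's column names
    (defaults to identity).  Rows whose ``standard_value`` or
    ``incubation_h`` cannot be parsed as numbers are dropped and counted in
    the log; everything else is kept verbatim for the downstream filters to
    judge.
    """
    path = Path(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[ActivityRecord] = []
    n_dropped = 0
    for row in df.to_dict("records"):
        r = {k: row[v] for k, v in colmap.items()}
        try:
            value = float(r["standard_value"])
            incubation = int(float(r["incubation_h"]))
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        records.append(ActivityRecord(
            compound_id=str(r["compound_id"]),
            smiles=str(r["smiles"]),
            assay_id=str(r["assay_id"]),
            document_id=str(r["document_id"]),
            cell_line=normalize_cell_line(r["cell_line"]),
            assay_type=str(r["assay_type"]).strip().upper(),
            incubation_h=incubation,
            standard_type=str(r["standard_type"]).strip().upper(),
            standard_relation=str(r["standard_relation"]).strip(),
            standard_value=value,
            standard_units=str(r["standard_units"]).strip(),
        ))
    if n_dropped:
        logger.warning("read_activity_table: dropped %d unparseable row(s) from %s",
                       n_dropped, path)
    read_activity_table.last_drop_count = n_dropped  # type: ignore[attr-defined]
    return records


def filter_protocol(records: Iterable[ActivityRecord]) -> list[ActivityRecord]:
    """Keep MTT/SRB measurements with 48 h or 72 h incubation."""
    return [r for r in records
            if r.assay_type in VALID_ASSAY_TYPES
            and r.incubation_h in VALID_INCUBATIONS_H]


def filter_standard(records: Iterable[ActivityRecord]) -> list[ActivityRecord]:
    """Keep exact (``=``) IC50/GI50 potencies reported in nM."""
    return [r for r in records
            if r.standard_relation == "="
            and r.standard_units == "nM"
            and r.standard_type in VALID_STANDARD_TYPES]


def to_pactivity(value_nM: float) -> float:
    """Convert a potency in nM to pActivity = −log10(molar concentration).

    10 000 nM (10 µM) ↦ 5.0; 1 nM ↦ 9.0.
    """
    if not value_nM > 0:
        raise ValueError(f"potency must be positive, got {value_nM!r} nM")
    return 9.0 - math.log10(value_nM)


def pactivity_to_uM(pactivity: float) -> float:
    """Inverse view of :func:`to_pactivity` on the micromolar scale."""
    return 10.0 ** (6.0 - pactivity)


def annotate_pactivity(records: Iterable[ActivityRecord]) -> list[ActivityRecord]:
    """Attach pActivity to every record (assumes nM units already enforced)."""
    return [replace(r, pactivity=to_pactivity(r.standard_value)) for r in records]


def mol_weight(smiles: str) -> float | None:
    """Average molecular weight (Da) from SMILES, or None if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return _Desc.MolWt(mol)


def resolve_duplicates(records: Iterable[ActivityRecord]) -> list[CompoundEntry]:
    """Collapse repeated measurements into one consensus entry per compound.

    Records are grouped per (compound_id, cell_line), pooling all retained
    protocols and both IC50/GI50 potency types.  A group whose pActivity
    range is ≤ 1 log unit collapses to the arithmetic-mean pActivity; a
    wider group is discarded entirely as internally inconsistent.
    """
    groups: dict[tuple[str, str], list[ActivityRecord]] = {}
    for r in records:
        if r.pactivity is None:
            raise ValueError("resolve_duplicates requires pActivity-annotated records")
        groups.setdefault((r.compound_id, r.cell_line), []).append(r)

    entries: list[CompoundEntry] = []
    n_discarded = 0
    for (cid, line), grp in groups.items():
        pvals = [r.pactivity for r in grp]
        if max(pvals) - min(pvals) > DUPLICATE_RANGE_MAX + _RANGE_TOL:
            n_discarded += 1
            continue
        entries.append(CompoundEntry(
            compound_id=cid,
            smiles=grp[0].smiles,
            cell_line=line,
            pactivity=float(np.mean(pvals)),
            n_source_records=len(grp),
        ))
    if n_discarded:
        logger.info("resolve_duplicates: discarded %d compound group(s) with "
                    "pActivity range > %.1f", n_discarded, DUPLICATE_RANGE_MAX)
    return entries


def filter_mw(entries: Iterable[CompoundEntry]) -> list[CompoundEntry]:
    """Keep compounds with 100 ≤ MW ≤ 600 Da (inclusive bounds).

    MW is computed from the SMILES when not already present; entries whose
    structure cannot be parsed are dropped with a logged warning.
    """
    kept: list[CompoundEntry] = []
    for e in entries:
        mw = e.mw if e.mw is not None else mol_weight(e.smiles)
        if mw is None:
            logger.warning("filter_mw: dropping %s — unparseable SMILES %r",
                           e.compound_id, e.smiles)
            continue
        if MW_MIN <= mw <= MW_MAX:
            kept.append(replace(e, mw=mw))
    return kept


def protocol_overlap(records: Iterable[ActivityRecord]) -> ProtocolOverlapReport:
    """Cross-protocol shared-compound counts and pActivity correlations.

    For every (assay_type, incubation_h) pair the per-compound mean
    pActivity is formed; each off-diagonal cell then reports how many
    compounds were measured under both protocols and the Pearson r of
    their protocol means (NaN when fewer than 2 shared compounds).
    Diagonal cells carry the protocol's own compound count with r = 1.
    """
    per_protocol: dict[tuple[str, int], dict[str, list[float]]] = {}
    for r in records:
        if r.pactivity is None:
            raise ValueError("protocol_overlap requires pActivity-annotated records")
        per_protocol.setdefault((r.assay_type, r.incubation_h), {}) \
            .setdefault(r.compound_id, []).append(r.pactivity)

    protocols = sorted(per_protocol)
    means = {p: {c: float(np.mean(v)) for c, v in d.items()}
             for p, d in per_protocol.items()}
    k = len(protocols)
    counts = np.zeros((k, k), dtype=int)
    pearson = np.full((k, k), np.nan)
    for i, pi in enumerate(protocols):
        counts[i, i] = len(means[pi])
        pearson[i, i] = 1.0
        for j in range(i + 1, k):
            pj = protocols[j]
            shared = sorted(set(means[pi]) & set(means[pj]))
            counts[i, j] = counts[j, i] = len(shared)
            if len(shared) >= 2:
                x = [means[pi][c] for c in shared]
                y = [means[pj][c] for c in shared]
                if np.std(x) > 0 and np.std(y) > 0:
                    r_val = float(_stats.pearsonr(x, y).statistic)
                    pearson[i, j] = pearson[j, i] = r_val
    return ProtocolOverlapReport(protocols=protocols, counts=counts, pearson=pearson)


def curate(
    records: Iterable[ActivityRecord],
    cell_line: str | None = None,
) -> list[CompoundEntry]:
    """Full curation pipeline: protocol → standard → pActivity → duplicates → MW."""
    recs = list(records)
    if cell_line is not None:
        target = normalize_cell_line(cell_line)
        recs = [r for r in recs if r.cell_line == target]
    recs = filter_protocol(recs)
    recs = filter_standard(recs)
    recs = annotate_pactivity(recs)
    entries = resolve_duplicates(recs)
    return filter_mw(entries)


def entries_to_frame(entries: Sequence[CompoundEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"compound_id": e.compound_id, "smiles": e.smiles,
          "cell_line": e.cell_line, "pActivity": e.pactivity,
          "mw": e.mw, "n_source_records": e.n_source_records}
         for e in entries]
    )


def frame_to_entries(df: pd.DataFrame) -> list[CompoundEntry]:
    return [CompoundEntry(
        compound_id=str(r["compound_id"]), smiles=str(r["smiles"]),
        cell_line=normalize_cell_line(r["cell_line"]),
        pactivity=float(r["pActivity"]),
        mw=float(r["mw"]) if "mw" in df.columns and pd.notna(r["mw"]) else None,
        n_source_records=int(r.get("n_source_records", 1)),
    ) for _, r in df.iterrows()]


def summarize_curated(
    pc3: Sequence[CompoundEntry],
    du145: Sequence[CompoundEntry],
) -> dict[str, float]:
    """Headline statistics of a curated dataset pair.

    Returns compound counts and mean pActivity per cell line, the number
    of compounds with activity on both lines, and the Pearson correlation
    of the shared compounds' pActivities.
    """
    p_map = {e.compound_id: e.pactivity for e in pc3}
    d_map = {e.compound_id: e.pactivity for e in du145}
    shared = sorted(set(p_map) & set(d_map))
    if len(shared) >= 2:
        r = float(_stats.pearsonr([p_map[c] for c in shared],
                                  [d_map[c] for c in shared]).statistic)
    else:
        r = float("nan")
    return {
        "n_pc3": len(pc3),
        "n_du145": len(du145),
        "mean_pactivity_pc3": float(np.mean([e.pactivity for e in pc3])) if pc3 else float("nan"),
        "mean_pactivity_du145": float(np.mean([e.pactivity for e in du145])) if du145 else float("nan"),
        "n_shared": len(shared),
        "pearson_r_shared": r,
    }
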