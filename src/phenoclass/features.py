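"""Molecular descriptor block and Pearson-correlation feature filtering.

The descriptor block is a fixed, versioned list of 123 physicochemical
and topological RDKit descriptors, pinned in ``data/descriptor_manifest
.json`` so the feature space is stable across toolkit upgrades.
Redundancy among descriptors is removed with a greedy Pearson filter:
scanning the descriptors in manifest order, a descriptor is dropped when
its absolute correlation with any already-retained descriptor exceeds the
threshold (0.95 / 0.85 / 0.75 in the standard configurations; 1.0 means
no filtering).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _Desc

logger = logging.getLogger(__name__)


def load_descriptor_manifest() -> list[str]:
    """Names of the pinned descriptor block, in canonical order."""
    with resources.files("phenoclass.data").joinpath(
            "descriptor_manifest.json").open() as fh:
        manifest = json.load(fh)
    return list(manifest["descriptors"])


@dataclass
class FeatureMatrix:
    """Dense compounds × descriptors matrix with aligned name lists."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    pcc_threshold: float = 1.0   # 1.0 = unfiltered

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise ValueError("values shape does not match id/name lists")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, "compound_id", self.compound_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pcc_threshold: float = 1.0) -> "FeatureMatrix":
        names = [c for c in df.columns if c != "compound_id"]
        return cls(compound_ids=[str(c) for c in df["compound_id"]],
                   descriptor_names=names,
                   values=df[names].to_numpy(dtype=float),
                   pcc_threshold=pcc_threshold)

    def subset(self, compound_ids: list[str]) -> "FeatureMatrix":
        index = {c: i for i, c in enumerate(self.compound_ids)}
        rows = [index[c] for c in compound_ids]
        return FeatureMatrix(list(compound_ids), list(self.descriptor_names),
                             self.values[rows], self.pcc_threshold)


def compute_descriptors(
    smiles: list[str],
    compound_ids: list[str] | None = None,
) -> FeatureMatrix:
    """Compute the pinned 123-descriptor block for a list of structures.

    Unparseable SMILES drop their compound with a warning.  Descriptor
    values that come back non-finite (a few descriptors are undefined for
    certain molecules) are imputed with the column median so the matrix
    is dense; fully-failed columns fall back to 0.  Constant columns are
    flagged in the log but kept — the decorrelation step removes them.
    """
    names = load_descriptor_manifest()
    funcs = dict(_Desc._descList)
    missing = [n for n in names if n not in funcs]
    if missing:
        raise RuntimeError(f"descriptor manifest not satisfied by this RDKit: {missing}")
    if compound_ids is None:
        compound_ids = [f"C{i}" for i in range(len(smiles))]

    kept_ids: list[str] = []
    rows: list[list[float]] = []
    for cid, s in zip(compound_ids, smiles):
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            logger.warning("compute_descriptors: dropping %s — unparseable SMILES %r",
                           cid, s)
            continue
        rows.append([float(funcs[n](mol)) for n in names])
        kept_ids.append(cid)
    values = np.asarray(rows, dtype=float)
    if values.size:
        bad = ~np.isfinite(values)
        if bad.any():
            for j in np.where(bad.any(axis=0))[0]:
                col = values[:, j]
                finite = col[np.isfinite(col)]
                col[~np.isfinite(col)] = np.median(finite) if finite.size else 0.0
            logger.info("compute_descriptors: imputed %d non-finite value(s)",
                        int(bad.sum()))
        const = np.where(values.std(axis=0) == 0)[0]
        if const.size:
            logger.info("compute_descriptors: %d constant column(s): %s",
                        const.size, [names[j] for j in const[:10]])
    return FeatureMatrix(kept_ids, names, values)


def decorrelate(m: FeatureMatrix, t: float) -> FeatureMatrix:
    """Greedy Pearson filter at threshold ``t`` (keep-first in manifest order).

    Zero-variance columns are removed first (their correlation is
    undefined); then descriptors are scanned in canonical order and one is
    dropped whenever |r| with any already-retained descriptor exceeds
    ``t``.  ``t = 1.0`` is the no-filter sentinel and returns the input
    unchanged.  The result therefore always retains the first
    variable descriptor, and every retained pair satisfies |r| ≤ t.
    """
    if not 0 < t <= 1:
        raise ValueError(f"PCC threshold must be in (0, 1], got {t}")
    if t == 1.0:
        return FeatureMatrix(list(m.compound_ids), list(m.descriptor_names),
                             m.values.copy(), 1.0)
    if m.n_compounds < 2:
        raise ValueError("decorrelate requires at least 2 compounds")

    std = m.values.std(axis=0)
    variable = [j for j in range(m.n_descriptors) if std[j] > 0]
    if len(variable) < m.n_descriptors:
        logger.info("decorrelate: dropping %d constant column(s)",
                    m.n_descriptors - len(variable))
    sub = m.values[:, variable]
    corr = np.corrcoef(sub, rowvar=False)
    corr = np.atleast_2d(corr)

    kept: list[int] = []
    for j in range(len(variable)):
        if all(abs(corr[j, k]) <= t for k in kept):
            kept.append(j)
    cols = [variable[j] for j in kept]
    return FeatureMatrix(
        list(m.compound_ids),
        [m.descriptor_names[j] for j in cols],
        m.values[:, cols].copy(),
        pcc_threshold=t,
    )
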