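"""Binary active/inactive labelling of curated compounds.

Two threshold families are provided, both operating on the compounds
sorted by descending pActivity (most potent first):

* **FIX p** — the top p % of the potency ranking is labelled active, the
  rest inactive.  Compounds tied at the boundary pActivity all receive
  the active label (the tie block is absorbed upward), so class counts
  can deviate slightly from the exact percentage.
* **GAP g** — g % of the compounds, taken symmetrically around the median
  rank, are excluded as intermediate; the remaining upper half is active
  and lower half inactive.  Excluding the ambiguous middle widens the
  potency separation between the classes.

Each labelled dataset carries threshold diagnostics: the least-potent
active and most-potent inactive (in µM), their ratio (the *closest
ratio*, 1.0 for FIX by construction), and the mean ± sd Tanimoto
similarity between the two classes on ECFP4-style fingerprints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .curation import CompoundEntry, pactivity_to_uM

logger = logging.getLogger(__name__)

ACTIVE, INACTIVE = "active", "inactive"

#: Cross-class Tanimoto pairs beyond this cap are subsampled (seeded).
MAX_SIMILARITY_PAIRS = 1_000_000


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class LabelledDataset:
    """Compounds plus binary labels from one threshold method."""

    entries: list[CompoundEntry]
    labels: list[str]                  # parallel to entries; "active"/"inactive"
    method: str                        # "FIX" | "GAP"
    parameter_pct: float
    excluded: list[CompoundEntry] = field(default_factory=list)
    max_active_uM: float = float("nan")    # least-potent active
    min_inactive_uM: float = float("nan")  # most-potent inactive

    @property
    def n_active(self) -> int:
        return sum(1 for l in self.labels if l == ACTIVE)

    @property
    def n_inactive(self) -> int:
        return sum(1 for l in self.labels if l == INACTIVE)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    @property
    def excluded_ids(self) -> list[str]:
        return [e.compound_id for e in self.excluded]

    @property
    def closest_ratio(self) -> float:
        return closest_ratio(self.max_active_uM, self.min_inactive_uM)

    def actives(self) -> list[CompoundEntry]:
        return [e for e, l in zip(self.entries, self.labels) if l == ACTIVE]

    def inactives(self) -> list[CompoundEntry]:
        return [e for e, l in zip(self.entries, self.labels) if l == INACTIVE]

    def summary_row(self) -> dict:
        """One row of a dataset-composition summary table."""
        return {
            "method": f"{self.method} {self.parameter_pct:g}",
            "total": len(self.entries) + self.n_excluded,
            "n_active": self.n_active,
            "n_inactive": self.n_inactive,
            "n_excluded": self.n_excluded,
            "max_active_uM": round(self.max_active_uM, 2),
            "min_inactive_uM": round(self.min_inactive_uM, 2),
            "closest_ratio": round(self.closest_ratio, 2),
        }


def _sorted_desc(entries: list[CompoundEntry]) -> list[CompoundEntry]:
    for e in entries:
        if not np.isfinite(e.pactivity):
            raise ValueError(f"non-finite pActivity for {e.compound_id}")
    # compound_id tiebreak keeps the ordering reproducible across runs
    return sorted(entries, key=lambda e: (-e.pactivity, e.compound_id))


def _diagnostics(ds: LabelledDataset) -> None:
    act, inact = ds.actives(), ds.inactives()
    if act:
        ds.max_active_uM = pactivity_to_uM(min(e.pactivity for e in act))
    if inact:
        ds.min_inactive_uM = pactivity_to_uM(max(e.pactivity for e in inact))


def label_fixed(entries: list[CompoundEntry], p: float) -> LabelledDataset:
    """FIX labelling: top ``p`` % of the potency ranking is active.

    The base active count is round-half-up of p %·n; every compound tied
    at the boundary pActivity is then absorbed into the active class so
    that equal potencies never straddle the class border.
    """
    if not entries:
        raise ValueError("label_fixed requires a nonempty dataset")
    if not 0 < p < 100:
        raise ValueError(f"active percentage must be in (0, 100), got {p}")
    ranked = _sorted_desc(entries)
    n = len(ranked)
    k = _round_half_up(p / 100.0 * n)
    k = min(max(k, 0), n)
    if 0 < k < n:
        boundary = ranked[k - 1].pactivity
        while k < n and ranked[k].pactivity == boundary:
            k += 1
        if k != _round_half_up(p / 100.0 * n):
            logger.info("label_fixed(p=%g): boundary ties extended the active "
                        "class to %d of %d", p, k, n)
    labels = [ACTIVE] * k + [INACTIVE] * (n - k)
    ds = LabelledDataset(entries=ranked, labels=labels, method="FIX",
                         parameter_pct=float(p))
    _diagnostics(ds)
    return ds


def label_gap(entries: list[CompoundEntry], g: float) -> LabelledDataset:
    """GAP labelling: exclude ``g`` % of compounds around the median rank.

    The total excluded count is round-half-up of g %·n, split evenly
    across the median cut with an odd leftover taken from the active
    (more potent) side.  The remaining upper half is active, the lower
    half inactive.  ``g = 0`` reduces to an even 50:50 split.
    """
    if not entries:
        raise ValueError("label_gap requires a nonempty dataset")
    if g < 0:
        raise ValueError(f"gap percentage must be non-negative, got {g}")
    ranked = _sorted_desc(entries)
    n = len(ranked)
    n_excl = _round_half_up(g / 100.0 * n)
    if n_excl >= n:
        raise ValueError(f"gap of {g}% excludes all {n} compounds")
    k_below = n_excl // 2            # taken from the inactive side
    k_above = n_excl - k_below       # active side absorbs an odd leftover
    upper, lower = ranked[: n // 2], ranked[n // 2:]
    actives = upper[: len(upper) - k_above]
    inactives = lower[k_below:]
    excluded = upper[len(upper) - k_above:] + lower[:k_below]
    ds = LabelledDataset(
        entries=actives + inactives,
        labels=[ACTIVE] * len(actives) + [INACTIVE] * len(inactives),
        method="GAP", parameter_pct=float(g), excluded=excluded,
    )
    _diagnostics(ds)
    return ds


def closest_ratio(max_active_uM: float, min_inactive_uM: float) -> float:
    """Potency separation between classes at the threshold.

    The micromolar potency of the most-potent inactive divided by that of
    the least-potent active; ≥ 1 whenever the labelling is monotone in
    potency, and exactly 1 for a single-threshold (FIX) split on dense
    data.  Reported to 2 decimals in summary tables.
    """
    if not (max_active_uM > 0 and min_inactive_uM > 0):
        raise ValueError("potencies must be positive")
    return min_inactive_uM / max_active_uM


_FP_GEN_CACHE: dict[tuple[int, int], object] = {}


def _fingerprints(smiles: list[str], radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _FP_GEN_CACHE:
        _FP_GEN_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits)
    gen = _FP_GEN_CACHE[key]
    fps = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {s!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def class_similarity(
    active_smiles: list[str],
    inactive_smiles: list[str],
    fp_radius: int = 2,
    fp_bits: int = 2048,
    max_pairs: int = MAX_SIMILARITY_PAIRS,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean ± sd Tanimoto similarity between the two classes.

    Similarity is computed over all active×inactive pairs on circular
    (Morgan) fingerprints of the given radius — radius 2 corresponds to
    ECFP4.  Pair sets larger than ``max_pairs`` are subsampled with the
    given seed.  Returns ``(nan, nan)`` when either class is empty.
    """
    if not active_smiles or not inactive_smiles:
        logger.warning("class_similarity: empty class, similarity undefined")
        return (float("nan"), float("nan"))
    fa = _fingerprints(active_smiles, fp_radius, fp_bits)
    fi = _fingerprints(inactive_smiles, fp_radius, fp_bits)
    n_pairs = len(fa) * len(fi)
    if n_pairs <= max_pairs:
        sims = np.concatenate(
            [DataStructs.BulkTanimotoSimilarity(a, fi) for a in fa])
    else:
        rng = np.random.default_rng(seed)
        ia = rng.integers(0, len(fa), size=max_pairs)
        ib = rng.integers(0, len(fi), size=max_pairs)
        sims = np.array([DataStructs.TanimotoSimilarity(fa[i], fi[j])
                         for i, j in zip(ia, ib)])
    return (float(np.mean(sims)), float(np.std(sims)))
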