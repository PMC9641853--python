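"""Synthetic activity and feature data with the structure of the curated sets.

The generator emulates the statistical shape of curated PC-3/DU-145
antiproliferative datasets so every pipeline stage can be exercised
offline and at any size:

* per-compound true pActivity from a truncated normal on [3.5, 9.0]
  centred at 5.1 with sd 0.75 — concentrated so that ≥ 85 % of the mass
  falls in [4.5, 6.5], matching the published activity distributions;
* a configurable fraction of compounds carrying 2–3 noisy repeat
  records under sampled protocols (MTT/SRB × 48/72 h, document ids), so
  the duplicate-resolution rule has real work to do;
* paired cell-line data whose shared compounds have bivariate-normal
  pActivities at a configurable correlation (default 0.93);
* block-correlated Gaussian descriptor matrices whose class signal is a
  tunable mean shift, from null (0) to cleanly separable.

"Structures" are drawn with replacement from a shipped library of real,
RDKit-validated drug-like SMILES (all MW 100–600 Da), so descriptor and
fingerprint code paths run on genuine chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy import stats as _stats

from .curation import ActivityRecord, CompoundEntry, mol_weight
from .features import FeatureMatrix
from .labelling import ACTIVE, LabelledDataset

PACTIVITY_LO, PACTIVITY_HI = 3.5, 9.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator (defaults = study conditions)."""

    n_compounds: int = 500
    pactivity_mean: float = 5.1
    pactivity_sd: float = 0.5
    duplicate_rate: float = 0.2       # fraction of compounds with repeats
    duplicate_noise_sd: float = 0.15  # log-unit sd among repeat records
    overlap_fraction: float = 0.2     # shared compounds between two lines
    cross_line_r: float = 0.93
    n_features: int = 30
    n_correlated_blocks: int = 5
    block_r: float = 0.9
    signal_strength: float = 0.0      # class-mean shift in feature units
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplicate_rate", "overlap_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pactivity_sd <= 0 or self.duplicate_noise_sd < 0:
            raise ValueError("standard deviations must be positive")
        if not -1 <= self.cross_line_r <= 1:
            raise ValueError("cross_line_r must be in [-1, 1]")


def load_smiles_library() -> list[tuple[str, str]]:
    """(name, smiles) pairs of the shipped small-molecule library."""
    text = resources.files("phenoclass.data").joinpath(
        "smiles_library.txt").read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smi = line.split("\t")
        out.append((name, smi))
    return out


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               size: int) -> np.ndarray:
    a, b = (PACTIVITY_LO - mean) / sd, (PACTIVITY_HI - mean) / sd
    return _stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                                random_state=rng)


def sample_true_pactivities(cfg: GeneratorConfig,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    rng = rng or np.random.default_rng(cfg.seed)
    return _truncnorm(rng, cfg.pactivity_mean, cfg.pactivity_sd, cfg.n_compounds)


def _sample_smiles(rng: np.random.Generator, n: int) -> list[str]:
    lib = load_smiles_library()
    idx = rng.integers(0, len(lib), size=n)
    return [lib[i][1] for i in idx]


def gen_activity_records(cfg: GeneratorConfig,
                         cell_line: str = "PC3") -> list[ActivityRecord]:
    """Raw activity table for one cell line, one list item per measurement.

    Compound ``SYN{i}`` gets a true pActivity; ``duplicate_rate`` of the
    compounds receive 2–3 records whose pActivities are the truth plus
    N(0, duplicate_noise_sd) noise, each under an independently sampled
    protocol and document.  pActivities are back-converted to nM potencies
    so the records look like a raw export.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = sample_true_pactivities(cfg, rng)
    smiles = _sample_smiles(rng, cfg.n_compounds)
    records: list[ActivityRecord] = []
    assay_types = ["MTT", "SRB"]
    hours = [48, 72]
    n_docs = max(3, cfg.n_compounds // 40)
    for i in range(cfg.n_compounds):
        n_rec = 1
        if rng.random() < cfg.duplicate_rate:
            n_rec = int(rng.integers(2, 4))
        for _ in range(n_rec):
            p = truth[i]
            if n_rec > 1 and cfg.duplicate_noise_sd > 0:
                p = p + rng.normal(0.0, cfg.duplicate_noise_sd)
            doc = int(rng.integers(0, n_docs))
            records.append(ActivityRecord(
                compound_id=f"SYN{i}",
                smiles=smiles[i],
                assay_id=f"ASSAY{doc}_{int(rng.integers(0, 5))}",
                document_id=f"DOC{doc}",
                cell_line=cell_line,
                assay_type=assay_types[int(rng.integers(0, 2))],
                incubation_h=hours[int(rng.integers(0, 2))],
                standard_type="IC50" if rng.random() < 0.7 else "GI50",
                standard_relation="=",
                standard_value=float(10.0 ** (9.0 - p)),
                standard_units="nM",
            ))
    return records


def gen_curated_entries(cfg: GeneratorConfig, cell_line: str = "PC3",
                        rng: np.random.Generator | None = None,
                        ids: list[str] | None = None,
                        pactivities: np.ndarray | None = None) -> list[CompoundEntry]:
    """Curated-stage entries directly (bypassing the raw-record detour)."""
    rng = rng or np.random.default_rng(cfg.seed)
    if pactivities is None:
        pactivities = sample_true_pactivities(cfg, rng)
    n = len(pactivities)
    if ids is None:
        ids = [f"SYN{i}" for i in range(n)]
    smiles = _sample_smiles(rng, n)
    return [CompoundEntry(compound_id=ids[i], smiles=smiles[i],
                          cell_line=cell_line, pactivity=float(pactivities[i]),
                          mw=mol_weight(smiles[i]))
            for i in range(n)]


def gen_paired_cell_data(
    cfg: GeneratorConfig,
) -> tuple[list[CompoundEntry], list[CompoundEntry]]:
    """Two curated datasets sharing correlated compounds.

    ``overlap_fraction`` of ``n_compounds`` appear in both cell lines
    with bivariate-normal pActivities at correlation ``cross_line_r``
    (each margin the configured truncated normal via a Gaussian copula);
    the remaining compounds are split between the two lines.
    """
    rng = np.random.default_rng(cfg.seed)
    n_shared = int(round(cfg.overlap_fraction * cfg.n_compounds))
    n_rest = cfg.n_compounds - n_shared
    n_a_only = n_rest // 2
    n_b_only = n_rest - n_a_only

    if abs(cfg.cross_line_r) == 1.0:      # degenerate: exactly collinear
        z1 = rng.normal(size=n_shared)
        z = np.column_stack([z1, cfg.cross_line_r * z1])
    else:
        cov = np.array([[1.0, cfg.cross_line_r], [cfg.cross_line_r, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n_shared)
    u = _stats.norm.cdf(z)
    a, b = (PACTIVITY_LO - cfg.pactivity_mean) / cfg.pactivity_sd, \
           (PACTIVITY_HI - cfg.pactivity_mean) / cfg.pactivity_sd
    shared_a = _stats.truncnorm.ppf(u[:, 0], a, b, loc=cfg.pactivity_mean,
                                    scale=cfg.pactivity_sd) if n_shared else np.empty(0)
    shared_b = _stats.truncnorm.ppf(u[:, 1], a, b, loc=cfg.pactivity_mean,
                                    scale=cfg.pactivity_sd) if n_shared else np.empty(0)

    shared_ids = [f"SHARED{i}" for i in range(n_shared)]
    pc3 = gen_curated_entries(cfg, "PC3", rng, ids=shared_ids, pactivities=shared_a)
    du = [replace(e, cell_line="DU145", pactivity=float(shared_b[i]))
          for i, e in enumerate(pc3)]
    pc3 += gen_curated_entries(cfg, "PC3", rng,
                               ids=[f"PA{i}" for i in range(n_a_only)],
                               pactivities=_truncnorm(rng, cfg.pactivity_mean,
                                                      cfg.pactivity_sd, n_a_only))
    du += gen_curated_entries(cfg, "DU145", rng,
                              ids=[f"DB{i}" for i in range(n_b_only)],
                              pactivities=_truncnorm(rng, cfg.pactivity_mean,
                                                     cfg.pactivity_sd, n_b_only))
    return pc3, du


def gen_study_scale_datasets(seed: int = 0) -> tuple[list[CompoundEntry],
                                                     list[CompoundEntry]]:
    """Paired curated datasets at the published study scale.

    4353 PC-3 and 2393 DU-145 compounds of which 587 are shared, the
    shared pActivities bivariate at correlation 0.93; per-line activity
    means 5.12 and 5.16.  This is the configuration used for end-to-end
    checks that need realistically sized inputs.
    """
    n_shared, n_pc3, n_du = 587, 4353, 2393
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, 0.93], [0.93, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_shared)
    u = _stats.norm.cdf(z)

    def margin(u_col, mean):
        sd = 0.5
        a, b = (PACTIVITY_LO - mean) / sd, (PACTIVITY_HI - mean) / sd
        return _stats.truncnorm.ppf(u_col, a, b, loc=mean, scale=sd)

    cfg_a = GeneratorConfig(n_compounds=n_pc3, pactivity_mean=5.12, seed=seed)
    cfg_b = GeneratorConfig(n_compounds=n_du, pactivity_mean=5.16, seed=seed)
    shared_ids = [f"SHARED{i}" for i in range(n_shared)]
    pc3 = gen_curated_entries(cfg_a, "PC3", rng, ids=shared_ids,
                              pactivities=margin(u[:, 0], 5.12))
    shared_b = margin(u[:, 1], 5.16)
    du = [replace(e, cell_line="DU145", pactivity=float(shared_b[i]))
          for i, e in enumerate(pc3)]
    pc3 += gen_curated_entries(
        cfg_a, "PC3", rng, ids=[f"PA{i}" for i in range(n_pc3 - n_shared)],
        pactivities=_truncnorm(rng, 5.12, 0.5, n_pc3 - n_shared))
    du += gen_curated_entries(
        cfg_b, "DU145", rng, ids=[f"DB{i}" for i in range(n_du - n_shared)],
        pactivities=_truncnorm(rng, 5.16, 0.5, n_du - n_shared))
    return pc3, du


def gen_feature_matrix(cfg: GeneratorConfig,
                       labels: list[str] | None = None,
                       compound_ids: list[str] | None = None,
                       signal_values: np.ndarray | None = None) -> FeatureMatrix:
    """Block-correlated Gaussian features with optional class signal.

    Features are grouped into ``n_correlated_blocks`` blocks; within a
    block every feature is the shared block factor mixed with independent
    noise so that within-block correlation ≈ ``block_r``.  When labels
    are given, the first feature of every block has its mean shifted by
    ``signal_strength`` for the active class, making classifier recovery
    tunable from null (0) to trivially separable (large).  Alternatively
    ``signal_values`` injects a continuous per-compound covariate (scaled
    by ``signal_strength``) into the same features — useful when the
    class signal should follow an underlying potency rather than the
    label itself.
    """
    if labels is not None and signal_values is not None:
        raise ValueError("pass either labels or signal_values, not both")
    rng = np.random.default_rng(cfg.seed)
    if labels is not None:
        n = len(labels)
    elif signal_values is not None:
        n = len(signal_values)
    else:
        n = cfg.n_compounds
    if compound_ids is None:
        compound_ids = [f"SYN{i}" for i in range(n)]
    p = cfg.n_features
    blocks = np.array_split(np.arange(p), cfg.n_correlated_blocks)
    X = np.empty((n, p))
    w = np.sqrt(cfg.block_r)
    for block in blocks:
        factor = rng.normal(size=n)
        for j in block:
            X[:, j] = w * factor + np.sqrt(1 - w * w) * rng.normal(size=n)
    if cfg.signal_strength != 0:
        if labels is not None:
            shift = np.array([1.0 if l == ACTIVE else 0.0 for l in labels])
        elif signal_values is not None:
            shift = np.asarray(signal_values, dtype=float)
        else:
            shift = None
        if shift is not None:
            for block in blocks:
                X[:, block[0]] += cfg.signal_strength * shift
    names = [f"feat_{i}" for i in range(p)]
    return FeatureMatrix(list(compound_ids), names, X)


def gen_labelled_feature_data(
    cfg: GeneratorConfig,
) -> tuple[LabelledDataset, FeatureMatrix]:
    """Convenience: curated entries, a 50:50 potency labelling, features.

    Labels are assigned by median split on pActivity; the feature matrix
    then carries ``signal_strength`` of class signal.  Useful for
    benchmark recovery and null experiments.
    """
    rng = np.random.default_rng(cfg.seed)
    entries = gen_curated_entries(cfg, rng=rng)
    ranked = sorted(entries, key=lambda e: (-e.pactivity, e.compound_id))
    k = len(ranked) // 2
    labels = [ACTIVE] * k + ["inactive"] * (len(ranked) - k)
    ds = LabelledDataset(entries=ranked, labels=labels, method="FIX",
                         parameter_pct=50.0)
    fm = gen_feature_matrix(cfg, labels=labels,
                            compound_ids=[e.compound_id for e in ranked])
    return ds, fm


def records_to_frame(records: list[ActivityRecord]):
    """Raw records as a DataFrame in the curation module's input schema."""
    import pandas as pd

    return pd.DataFrame([{
        "compound_id": r.compound_id, "smiles": r.smiles,
        "assay_id": r.assay_id, "document_id": r.document_id,
        "cell_line": r.cell_line, "assay_type": r.assay_type,
        "incubation_h": r.incubation_h, "standard_type": r.standard_type,
        "standard_relation": r.standard_relation,
        "standard_value": r.standard_value, "standard_units": r.standard_units,
    } for r in records])
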