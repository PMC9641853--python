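"""End-to-end pipeline driver with configuration and run manifests.

One flat YAML config describes a full run: where the raw activity table
comes from (a file, or the synthetic generator), the labelling method,
the descriptor-correlation threshold, and which algorithms to benchmark.
Every run writes its outputs next to a ``manifest.json`` capturing the
config snapshot, package version, master seed, input digests and
per-stage row counts — identical manifests imply bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .benchmark import default_algorithms, run_benchmark
from .curation import (curate, entries_to_frame, read_activity_table)
from .features import FeatureMatrix, compute_descriptors, decorrelate
from .labelling import LabelledDataset, class_similarity, label_fixed, label_gap
from .simulate import GeneratorConfig, gen_activity_records, records_to_frame

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cell_line": "PC3",
    "input": None,                  # path to raw CSV; None -> simulate
    "simulate": {"n_compounds": 400},
    "label": {"method": "GAP", "pct": 20},
    "features": {"pcc": 0.95},
    "benchmark": {"algorithms": ["RF", "SVM", "KNN"], "grids": {}},
    "similarity": {"enabled": False},   # class Tc diagnostics (slower)
}

_ALLOWED_KEYS = set(DEFAULT_CONFIG)


class ConfigError(ValueError):
    pass


def load_config(path_or_dict) -> dict:
    """Merge a YAML file (or dict) over the defaults and validate it."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    unknown = set(user) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))   # deep copy
    for k, v in user.items():
        if isinstance(cfg.get(k), dict) and isinstance(v, dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    method = str(cfg["label"]["method"]).upper()
    if method not in {"FIX", "GAP"}:
        raise ConfigError(f"label.method must be FIX or GAP, got {method!r}")
    if not 0 < float(cfg["features"]["pcc"]) <= 1:
        raise ConfigError("features.pcc must be in (0, 1]")
    bad = [a for a in cfg["benchmark"]["algorithms"]
           if a not in default_algorithms()]
    if bad:
        raise ConfigError(f"unknown algorithm(s): {bad}")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record written alongside every pipeline run."""

    config: dict
    package_version: str
    master_seed: int
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1, default=str))


def run_pipeline(config, out_dir: str | Path) -> RunManifest:
    """Execute curate → label → featurize → benchmark per the config.

    Writes ``curated.csv``, ``labelled.csv``, ``label_summary.csv``,
    ``features.csv``, ``benchmark_results.csv``,
    ``benchmark_summary.csv`` and ``manifest.json`` into ``out_dir``.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, package_version=__version__,
                           master_seed=seed)

    # --- input stage -----------------------------------------------------
    if cfg["input"]:
        path = Path(cfg["input"])
        records = read_activity_table(path)
        manifest.input_digests[str(path)] = _digest(path)
    else:
        gen = GeneratorConfig(seed=seed, **cfg["simulate"])
        records = gen_activity_records(gen, cell_line=cfg["cell_line"])
        records_to_frame(records).to_csv(out / "simulated_records.csv",
                                         index=False)
    manifest.stage_counts["raw_records"] = len(records)

    # --- curation --------------------------------------------------------
    entries = curate(records, cell_line=cfg["cell_line"])
    manifest.stage_counts["curated_compounds"] = len(entries)
    entries_to_frame(entries).to_csv(out / "curated.csv", index=False)
    if not entries:
        raise RuntimeError("curation produced an empty dataset "
                           f"({len(records)} raw records)")

    # --- labelling -------------------------------------------------------
    method = cfg["label"]["method"].upper()
    pct = float(cfg["label"]["pct"])
    labelled = (label_gap if method == "GAP" else label_fixed)(entries, pct)
    manifest.stage_counts.update(
        n_active=labelled.n_active, n_inactive=labelled.n_inactive,
        n_excluded=labelled.n_excluded)
    df = entries_to_frame(labelled.entries)
    df["label"] = labelled.labels
    df.to_csv(out / "labelled.csv", index=False)
    row = labelled.summary_row()
    if cfg["similarity"]["enabled"]:
        mean_tc, sd_tc = class_similarity(
            [e.smiles for e in labelled.actives()],
            [e.smiles for e in labelled.inactives()], seed=seed)
        row["tc_mean"], row["tc_sd"] = round(mean_tc, 3), round(sd_tc, 3)
    pd.DataFrame([row]).to_csv(out / "label_summary.csv", index=False)

    # --- features --------------------------------------------------------
    fm = compute_descriptors([e.smiles for e in labelled.entries],
                             [e.compound_id for e in labelled.entries])
    fm = decorrelate(fm, float(cfg["features"]["pcc"]))
    manifest.stage_counts["n_descriptors"] = fm.n_descriptors
    fm.to_frame().to_csv(out / "features.csv", index=False)
    (out / "feature_manifest.json").write_text(
        json.dumps({"pcc_threshold": fm.pcc_threshold,
                    "descriptors": fm.descriptor_names}, indent=1))

    # --- benchmark -------------------------------------------------------
    registry = default_algorithms(cfg["benchmark"].get("grids") or None)
    algos = {a: registry[a] for a in cfg["benchmark"]["algorithms"]}
    results, summary = run_benchmark(
        {f"{method} {pct:g}": labelled}, {f"PCC {cfg['features']['pcc']}": fm},
        algorithms=algos, seed=seed)
    results.to_csv(out / "benchmark_results.csv", index=False)
    summary.to_csv(out / "benchmark_summary.csv", index=False)
    manifest.stage_counts["benchmark_rows"] = len(results)

    manifest.write(out / "manifest.json")
    return manifest
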