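"""File-based pipeline: simulate -> fc -> efficiency -> complexity -> effects
-> rank -> pca, every stage resumable and communicating only through TSV files.

Output layout under ``out_dir``::

    partition.tsv            roi_id, network, hierarchy
    manifest.tsv             subject, state, class, file
    timeseries/*.tsv         frames x ROIs, header row of ROI ids
    metrics_fc.tsv           subject, state, class, metric, level, contrast, value
    metrics_eff.tsv          (same schema)
    metrics_cplx.tsv         (same schema)
    effects.tsv              state, class, metric, level, contrast, n, d, se_d, t, p, p_fdr, ...
    rank_table.tsv           per analysis-metric pair state ranks
    composite_rank.tsv       state, class, mean_rank
    tau.tsv                  metric, analysis, tau
    pca_scores.tsv           state, PC1, PC2, explained fractions
    pca_loadings_*.tsv       7 x 7 PC1 loading maps per metric
    run_metadata.json        config echo, seed, package versions, stage timings
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import recording_metrics
from .config import RunConfig
from .effects import build_effect_table
from .ordering import (
    build_feature_matrix,
    pca_uncentered,
    pc1_loading_matrices,
    rank_agreement,
    rank_states,
)
from .partition import NetworkPartition
from .simulate import CohortDataset, Recording, TimeSeriesMatrix, simulate_cohort

log = logging.getLogger("intseg")

STAGES = ("simulate", "fc", "efficiency", "complexity", "effects", "rank", "pca")

_METRIC_FILES = {
    "fc": ("FC", "metrics_fc.tsv"),
    "efficiency": ("EFF", "metrics_eff.tsv"),
    "complexity": ("CPLX", "metrics_cplx.tsv"),
}


class StageError(RuntimeError):
    """A stage failure, tagged with the stage name and offending input."""


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def write_timeseries(ts: TimeSeriesMatrix, path: Path) -> None:
    frame = pd.DataFrame(ts.values, columns=list(ts.roi_ids))
    _write_tsv(frame, path)


def read_timeseries(path: Path, frame_interval: float = 2.0) -> TimeSeriesMatrix:
    frame = pd.read_csv(path, sep="\t")
    return TimeSeriesMatrix(frame.to_numpy(dtype=float), tuple(frame.columns), frame_interval)


def load_cohort(manifest_path: Path, partition_path: Path) -> CohortDataset:
    """Rebuild a cohort from its manifest + partition + time-series files."""
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"subject", "state", "class", "file"}
    if not required.issubset(manifest.columns):
        raise StageError(f"manifest must have columns {sorted(required)}")
    partition = NetworkPartition.from_frame(pd.read_csv(partition_path, sep="\t"))
    root = manifest_path.parent
    recordings = []
    for row in manifest.to_dict("records"):
        fpath = Path(row["file"])
        if not fpath.is_absolute():
            fpath = root / fpath
        series = read_timeseries(fpath)
        if series.roi_ids != partition.roi_ids:
            raise StageError(f"{fpath}: ROI columns do not match the partition")
        recordings.append(
            Recording(str(row["subject"]), str(row["state"]), str(row["class"]), series)
        )
    dataset = CohortDataset(None, partition, tuple(recordings))
    _check_pairing(dataset)
    return dataset


def _check_pairing(dataset: CohortDataset) -> None:
    for rec in dataset.recordings:
        if rec.state_class != "baseline":
            dataset.baseline_of(rec.subject)


def stage_simulate(cfg: RunConfig) -> None:
    if cfg.simulation is None:
        raise StageError("stage simulate: config uses external data")
    dataset = simulate_cohort(cfg.simulation)
    out = cfg.out_dir
    _write_tsv(dataset.partition.to_frame(), out / "partition.tsv")
    manifest = dataset.manifest()
    files = []
    for rec in dataset.recordings:
        rel = Path("timeseries") / f"{rec.subject}__{rec.state}.tsv"
        write_timeseries(rec.series, out / rel)
        files.append(str(rel))
    manifest["file"] = files
    _write_tsv(manifest, out / "manifest.tsv")


def _load_for_metrics(cfg: RunConfig) -> CohortDataset:
    if cfg.external is not None:
        return load_cohort(cfg.external.manifest, cfg.external.partition)
    return load_cohort(cfg.out_dir / "manifest.tsv", cfg.out_dir / "partition.tsv")


def _stage_metric(cfg: RunConfig, stage: str) -> None:
    metric, filename = _METRIC_FILES[stage]
    dataset = _load_for_metrics(cfg)
    table = recording_metrics(
        dataset,
        metrics=(metric,),
        width=cfg.metrics.window_width,
        n_null=cfg.metrics.n_null,
        seed=cfg.seed,
        fc_convention=cfg.metrics.fc_convention,
    )
    _write_tsv(table, cfg.out_dir / filename)


def stage_effects(cfg: RunConfig) -> None:
    parts = []
    for stage, (_, filename) in _METRIC_FILES.items():
        path = cfg.out_dir / filename
        if not path.is_file():
            raise StageError(f"stage effects: missing input {path} (run '{stage}' first)")
        parts.append(pd.read_csv(path, sep="\t"))
    results = pd.concat(parts, ignore_index=True)
    table = build_effect_table(results, fdr_family=cfg.metrics.fdr_family)
    _write_tsv(table, cfg.out_dir / "effects.tsv")


def _load_effects(cfg: RunConfig) -> pd.DataFrame:
    path = cfg.out_dir / "effects.tsv"
    if not path.is_file():
        raise StageError(f"missing input {path} (run 'effects' first)")
    return pd.read_csv(path, sep="\t")


def stage_rank(cfg: RunConfig) -> None:
    effects = _load_effects(cfg)
    rank_table = rank_states(effects)
    flat = rank_table.ranks.copy()
    flat.columns = [f"{m}|{a}" for m, a in flat.columns]
    _write_tsv(flat, cfg.out_dir / "rank_table.tsv", index=True)
    classes = effects.drop_duplicates("state").set_index("state")["class"]
    comp = rank_table.composite.rename("mean_rank").to_frame()
    comp.insert(0, "class", classes.reindex(comp.index))
    _write_tsv(comp.reset_index(), cfg.out_dir / "composite_rank.tsv")
    tau = rank_agreement(rank_table).reset_index()
    _write_tsv(tau, cfg.out_dir / "tau.tsv")


def stage_pca(cfg: RunConfig) -> None:
    effects = _load_effects(cfg)
    features = build_feature_matrix(effects)
    pca = pca_uncentered(features)
    scores = pca.scores[["PC1", "PC2"]].copy()
    scores["explained_PC1"] = pca.explained[0]
    scores["explained_PC2"] = pca.explained[1]
    _write_tsv(scores.reset_index(), cfg.out_dir / "pca_scores.tsv")
    from .partition import NETWORKS

    for metric, mat in pc1_loading_matrices(pca).items():
        frame = pd.DataFrame(
            mat, index=pd.Index(NETWORKS, name="network"), columns=NETWORKS
        )
        _write_tsv(frame.reset_index(), cfg.out_dir / f"pca_loadings_{metric}.tsv")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fc": lambda cfg: _stage_metric(cfg, "fc"),
    "efficiency": lambda cfg: _stage_metric(cfg, "efficiency"),
    "complexity": lambda cfg: _stage_metric(cfg, "complexity"),
    "effects": stage_effects,
    "rank": stage_rank,
    "pca": stage_pca,
}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the requested stages in canonical order; returns the output dir."""
    if stages is None:
        stages = [s for s in STAGES if not (s == "simulate" and cfg.external is not None)]
    unknown = sorted(set(stages) - set(STAGES))
    if unknown:
        raise StageError(f"unknown stage(s): {unknown}")
    ordered = [s for s in STAGES if s in stages]
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}
    for stage in ordered:
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            raise StageError(f"stage {stage} failed: {exc}") from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.2fs", stage, timings[stage])
    _write_metadata(cfg, ordered, timings)
    return cfg.out_dir


def _write_metadata(cfg: RunConfig, stages: list[str], timings: dict) -> None:
    import scipy

    from . import __version__

    sim = None
    if cfg.simulation is not None:
        sim = {
            k: (list(v) if isinstance(v, tuple) and k == "network_sizes" else v)
            for k, v in {
                "n_rois": cfg.simulation.n_rois,
                "network_sizes": cfg.simulation.network_sizes,
                "n_frames": cfg.simulation.n_frames,
                "n_subjects_per_state": cfg.simulation.n_subjects_per_state,
                "w_base": cfg.simulation.w_base,
                "b_base": cfg.simulation.b_base,
                "subject_sd": cfg.simulation.subject_sd,
                "states": [s.name for s in cfg.simulation.states],
            }.items()
        }
    meta = {
        "seed": cfg.seed,
        "stages": stages,
        "timings_s": timings,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "versions": {
            "intseg": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "simulation": sim,
        "metrics": {
            "window_width": cfg.metrics.window_width,
            "n_null": cfg.metrics.n_null,
            "fdr_family": cfg.metrics.fdr_family,
            "fc_convention": cfg.metrics.fc_convention,
        },
    }
    (cfg.out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
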