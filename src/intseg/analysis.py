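"""In-memory end-to-end analysis of a cohort: recordings -> effect table -> ordering.

These helpers chain the metric modules without touching the filesystem; the
file-based pipeline stages in :mod:`intseg.pipeline` are thin wrappers around
them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .complexity import complexity_levels
from .connectivity import compute_fc, summarize_levels
from .effects import build_effect_table
from .ordering import (
    PCAResult,
    RankTable,
    build_feature_matrix,
    pca_uncentered,
    rank_agreement,
    rank_states,
)
from .simulate import CohortDataset, _stream
from .topology import efficiency_levels


def recording_metrics(
    dataset: CohortDataset,
    metrics: tuple[str, ...] = ("FC", "EFF", "CPLX"),
    width: int = 5,
    n_null: int = 100,
    seed: int = 0,
    fc_convention: str = "block",
) -> pd.DataFrame:
    """Long-format per-recording metric table.

    Columns: subject, state, class, metric, level, contrast, value.  The
    efficiency null model draws from a per-recording RNG stream derived from
    ``seed`` and the recording identity, so results are independent of
    iteration order.
    """
    rows: list[dict] = []
    partition = dataset.partition
    for rec in dataset.recordings:
        fc = compute_fc(rec.series)
        summaries = {}
        if "FC" in metrics:
            summaries["FC"] = summarize_levels(fc, partition, fc_convention)
        if "EFF" in metrics:
            rng = _stream(seed, "efficiency_null", rec.subject, rec.state)
            summaries["EFF"] = efficiency_levels(fc, partition, n_null=n_null, rng=rng)
        if "CPLX" in metrics:
            summaries["CPLX"] = complexity_levels(rec.series, partition, width)
        for metric, summary in summaries.items():
            for row in summary.to_rows():
                rows.append(
                    {
                        "subject": rec.subject,
                        "state": rec.state,
                        "class": rec.state_class,
                        "metric": metric,
                        **row,
                    }
                )
    return pd.DataFrame(rows)


def analyze_cohort(
    dataset: CohortDataset,
    width: int = 5,
    n_null: int = 100,
    seed: int = 0,
    fc_convention: str = "block",
    fdr_family: str = "metric_level",
) -> dict:
    """Run the full chain and return every intermediate product.

    Returns a dict with keys ``results`` (long per-recording table),
    ``effects`` (effect-size table), ``rank_table``, ``composite``, ``tau``,
    ``features`` (84 x 9), and ``pca``.
    """
    results = recording_metrics(
        dataset, width=width, n_null=n_null, seed=seed, fc_convention=fc_convention
    )
    effects = build_effect_table(results, fdr_family=fdr_family)
    rank_table: RankTable = rank_states(effects)
    tau = rank_agreement(rank_table)
    features = build_feature_matrix(effects)
    pca: PCAResult = pca_uncentered(features)
    return {
        "results": results,
        "effects": effects,
        "rank_table": rank_table,
        "composite": rank_table.composite,
        "tau": tau,
        "features": features,
        "pca": pca,
    }
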