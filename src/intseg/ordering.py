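"""Rank aggregation of states across analyses and uncentered PCA ordering.

For each of the 27 analysis x metric pairs (3 metrics x 9 global/hierarchy
analyses), the nine states are ranked by their signed Cohen's d (rank 1 = most
negative, rank 9 = most positive; ties get average ranks).  The composite rank
is each state's mean rank over all 27 pairs, and Kendall's tau-b measures how
well each individual pair agrees with the composite.

The network-level effect sizes form an 84 x 9 feature matrix (3 metrics x 28
upper-triangular network-pair entries), decomposed by *uncentered* PCA: the
matrix is not mean-centered because d = 0 means "no effect" and is a meaningful
origin.  Explained variance is therefore the squared singular value as a
fraction of the total sum of squares.  Each component's sign is fixed by making
its largest-magnitude loading positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, rankdata

from .partition import NETWORKS

METRICS: tuple[str, ...] = ("FC", "EFF", "CPLX")

#: the nine global/hierarchy analyses entering the rank aggregation
RANK_ANALYSES: tuple[tuple[str, str], ...] = (
    ("global", "whole_brain"),
    ("global", "within_network"),
    ("global", "between_network"),
    ("hierarchy", "U-U"),
    ("hierarchy", "A-A"),
    ("hierarchy", "T-T"),
    ("hierarchy", "U-A"),
    ("hierarchy", "U-T"),
    ("hierarchy", "A-T"),
)

#: canonical network-pair feature order (upper triangle, diagonal included)
NETWORK_PAIRS: tuple[str, ...] = tuple(
    f"{NETWORKS[i]}-{NETWORKS[j]}"
    for i in range(len(NETWORKS))
    for j in range(i, len(NETWORKS))
)


@dataclass(frozen=True)
class RankTable:
    """Per-pair state ranks (states x 27 columns) and the composite mean rank."""

    ranks: pd.DataFrame
    composite: pd.Series


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame          # states x components
    loadings: pd.DataFrame        # features x components
    singular_values: np.ndarray
    explained: np.ndarray         # fraction of total sum of squares


def rank_states(effect_table: pd.DataFrame) -> RankTable:
    """Rank the states by signed d within each of the 27 analysis-metric pairs."""
    states = list(dict.fromkeys(effect_table["state"]))
    indexed = effect_table.set_index(["metric", "level", "contrast", "state"])["d"]
    cols = {}
    for metric in METRICS:
        for level, contrast in RANK_ANALYSES:
            try:
                d = indexed.loc[
                    [(metric, level, contrast, s) for s in states]
                ].to_numpy()
            except KeyError:
                raise ValueError(
                    f"effect table is missing states for {metric}/{level}/{contrast}"
                ) from None
            if np.any(~np.isfinite(d)):
                raise ValueError(
                    f"undefined effect sizes in {metric}/{level}/{contrast}"
                )
            cols[(metric, f"{level}:{contrast}")] = rankdata(d, method="average")
    ranks = pd.DataFrame(cols, index=pd.Index(states, name="state"))
    ranks.columns = pd.MultiIndex.from_tuples(ranks.columns, names=["metric", "analysis"])
    return RankTable(ranks, ranks.mean(axis=1).rename("mean_rank"))


def composite_rank(rank_table: RankTable | pd.DataFrame) -> pd.Series:
    """Per-state arithmetic mean of its ranks over all analysis-metric pairs."""
    ranks = rank_table.ranks if isinstance(rank_table, RankTable) else rank_table
    if ranks.isna().any().any():
        raise ValueError("rank table is incomplete")
    return ranks.mean(axis=1).rename("mean_rank")


def rank_agreement(rank_table: RankTable) -> pd.Series:
    """Kendall's tau-b between each pair's ranking and the composite ranking."""
    comp = rank_table.composite.to_numpy()
    taus = {}
    for col in rank_table.ranks.columns:
        r = rank_table.ranks[col].to_numpy()
        if np.unique(r).size == 1 or np.unique(comp).size == 1:
            taus[col] = float("nan")  # undefined for constant rankings
        else:
            taus[col] = float(kendalltau(r, comp).statistic)
    out = pd.Series(taus, name="tau")
    out.index.names = ["metric", "analysis"]
    return out


def build_feature_matrix(effect_table: pd.DataFrame) -> pd.DataFrame:
    """84 x 9 matrix of network-level d values (features x states).

    Feature order is metric-major (FC, EFF, CPLX), then the 28 network pairs in
    canonical upper-triangular order, diagonal included.
    """
    states = list(dict.fromkeys(effect_table["state"]))
    net = effect_table[effect_table["level"] == "network"]
    lookup = net.set_index(["metric", "contrast", "state"])["d"]
    rows = []
    index = []
    for metric in METRICS:
        for pair in NETWORK_PAIRS:
            try:
                vals = lookup.loc[[(metric, pair, s) for s in states]].to_numpy()
            except KeyError:
                raise ValueError(
                    f"missing network-level effect for {metric}/{pair}"
                ) from None
            rows.append(vals)
            index.append(f"{metric}:{pair}")
    return pd.DataFrame(rows, index=pd.Index(index, name="feature"), columns=states)


def pca_uncentered(features: pd.DataFrame | np.ndarray) -> PCAResult:
    """Uncentered PCA of the features x states matrix.

    The nine states are the observations; the raw matrix is decomposed by SVD
    without centering or scaling.  Scores are the state projections U * S;
    loadings are the orthonormal feature weights.
    """
    if isinstance(features, pd.DataFrame):
        x = features.to_numpy(dtype=float)
        state_names = list(features.columns)
        feature_names = list(features.index)
    else:
        x = np.asarray(features, dtype=float)
        state_names = [f"state_{j}" for j in range(x.shape[1])]
        feature_names = [f"f_{i}" for i in range(x.shape[0])]
    if not np.any(x):
        raise ValueError("all-zero feature matrix")
    obs = x.T  # states x features
    u, s, vt = np.linalg.svd(obs, full_matrices=False)
    loadings = vt.T
    scores = u * s
    for c in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, c])), c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    explained = s**2 / np.sum(s**2)
    comp_names = [f"PC{c + 1}" for c in range(s.size)]
    return PCAResult(
        pd.DataFrame(scores, index=pd.Index(state_names, name="state"), columns=comp_names),
        pd.DataFrame(loadings, index=pd.Index(feature_names, name="feature"), columns=comp_names),
        s,
        explained,
    )


def pc1_loading_matrices(pca: PCAResult) -> dict[str, np.ndarray]:
    """Reorganize PC1 loadings into three 7 x 7 upper-triangular network maps."""
    pc1 = pca.loadings["PC1"]
    if len(pc1) != len(METRICS) * len(NETWORK_PAIRS):
        raise ValueError(
            f"expected {len(METRICS) * len(NETWORK_PAIRS)} features, got {len(pc1)}"
        )
    out = {}
    for metric in METRICS:
        mat = np.full((7, 7), np.nan)
        for i in range(7):
            for j in range(i, 7):
                mat[i, j] = pc1[f"{metric}:{NETWORKS[i]}-{NETWORKS[j]}"]
        out[metric] = mat
    return out
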