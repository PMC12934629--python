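"""Pearson functional connectivity and its global / hierarchy / network averages.

A recording's functional connectivity (FC) matrix holds the Pearson correlation
between every pair of ROI time series.  Three nested summaries are derived from
it: the whole-brain average over all unique ROI pairs, within- and
between-network averages (segregation vs integration indices), the six
hierarchy-level block averages (unimodal/attention/transmodal, limbic
excluded), and the full 7 x 7 network-level block matrix.

Raw correlations are averaged directly (no Fisher transform) and negative
values are retained; non-negativity is enforced only by the graph-efficiency
analysis, never here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .partition import (
    HIERARCHIES,
    HIERARCHY_ABBREV,
    HIERARCHY_CONTRASTS,
    NETWORKS,
    NetworkPartition,
)
from .simulate import TimeSeriesMatrix

GLOBAL_CONTRASTS: tuple[str, ...] = ("whole_brain", "within_network", "between_network")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix."""

    values: np.ndarray
    roi_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != len(self.roi_ids):
            raise ValueError("matrix size must match roi_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class LevelSummary:
    """One metric's values at the three spatial levels.

    ``global_`` keys: whole_brain, within_network, between_network.
    ``hierarchy`` keys: U-U, A-A, T-T, U-A, U-T, A-T.
    ``network`` is the symmetric 7 x 7 block matrix in canonical network order
    (diagonal = within-network values).
    """

    global_: dict[str, float]
    hierarchy: dict[str, float]
    network: np.ndarray

    def network_value(self, net_a: str, net_b: str) -> float:
        i, j = NETWORKS.index(net_a), NETWORKS.index(net_b)
        return float(self.network[i, j])

    def to_rows(self) -> list[dict]:
        rows = [
            {"level": "global", "contrast": k, "value": v} for k, v in self.global_.items()
        ]
        rows += [
            {"level": "hierarchy", "contrast": k, "value": v}
            for k, v in self.hierarchy.items()
        ]
        for i, a in enumerate(NETWORKS):
            for j in range(i, len(NETWORKS)):
                rows.append(
                    {
                        "level": "network",
                        "contrast": f"{a}-{NETWORKS[j]}",
                        "value": float(self.network[i, j]),
                    }
                )
        return rows


def compute_fc(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation between all ROI pairs, diagonal forced to 1."""
    x = ts.values
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.roi_ids[i] for i in dead[:5]]
        raise ValueError(f"zero-variance ROI time series: {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, ts.roi_ids)


def mean_block(
    fc: ConnectivityMatrix | np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    exclude_self: bool = True,
) -> float:
    """Mean correlation over unordered ROI pairs (i in rows, j in cols).

    Each unordered pair is counted once; self-pairs (i == j) are dropped when
    ``exclude_self`` (the default, matching the "excluding self-connections"
    convention for every averaged block).
    """
    v = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc)
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("mean_block requires nonempty ROI sets")
    same = rows.size == cols.size and np.array_equal(np.sort(rows), np.sort(cols))
    if same:
        sub = v[np.ix_(rows, rows)]
        if exclude_self:
            if rows.size < 2:
                raise ValueError("within-set average needs >= 2 ROIs")
            iu = np.triu_indices(rows.size, k=1)
            return float(sub[iu].mean())
        iu = np.triu_indices(rows.size, k=0)
        return float(sub[iu].mean())
    if np.intersect1d(rows, cols).size:
        # overlapping, non-identical sets: enumerate unordered pairs explicitly
        pairs = {
            (min(i, j), max(i, j))
            for i in rows
            for j in cols
            if (i != j or not exclude_self)
        }
        if not pairs:
            raise ValueError("no eligible ROI pairs in block")
        return float(np.mean([v[i, j] for i, j in pairs]))
    return float(v[np.ix_(rows, cols)].mean())


def summarize_levels(
    fc: ConnectivityMatrix,
    partition: NetworkPartition,
    convention: str = "block",
) -> LevelSummary:
    """Global, hierarchy, and network-level FC averages.

    ``convention`` controls the global within/between-network values:
    ``"block"`` (default) averages the 7 within-network and 21 between-network
    block means with equal weight, matching the efficiency and complexity
    aggregation; ``"pooled"`` averages the underlying ROI pairs directly.
    """
    if tuple(fc.roi_ids) != tuple(partition.roi_ids):
        raise ValueError("partition ROIs do not match connectivity matrix ROIs")
    if convention not in ("block", "pooled"):
        raise ValueError(f"unknown pooling convention {convention!r}")
    v = fc.values
    n = v.shape[0]
    net_idx = {net: partition.network_indices(net) for net in NETWORKS}

    network = np.empty((7, 7))
    for i, a in enumerate(NETWORKS):
        for j in range(i, 7):
            network[i, j] = network[j, i] = mean_block(v, net_idx[a], net_idx[NETWORKS[j]])

    iu = np.triu_indices(n, k=1)
    whole = float(v[iu].mean())
    if convention == "block":
        within = float(np.diagonal(network).mean())
        between = float(network[np.triu_indices(7, k=1)].mean())
    else:
        labels = np.asarray(partition.networks)
        same = labels[iu[0]] == labels[iu[1]]
        within = float(v[iu][same].mean())
        between = float(v[iu][~same].mean())

    hier_idx = {h: partition.hierarchy_indices(h) for h in HIERARCHIES}
    hierarchy = {}
    for ha, hb in HIERARCHY_CONTRASTS:
        key = f"{HIERARCHY_ABBREV[ha]}-{HIERARCHY_ABBREV[hb]}"
        hierarchy[key] = mean_block(v, hier_idx[ha], hier_idx[hb])

    return LevelSummary(
        {"whole_brain": whole, "within_network": within, "between_network": between},
        hierarchy,
        network,
    )
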