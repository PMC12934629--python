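"""Weighted global efficiency with log weight-to-distance transform and
weight-shuffled null normalization.

Positive correlation weights w become path lengths -log(w) (strong coupling =
short distance); non-positive weights are removed and weights >= 1 are clipped
just below 1.  Efficiency is the mean inverse shortest-path length over the
selected node pairs, with unreachable pairs contributing 0.  Every reported
efficiency is normalized by the mean efficiency of surrogate graphs whose edge
weights are randomly permuted (weight distribution preserved, degree sequence
not), isolating topology from overall coupling strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import floyd_warshall

try:  # compiled kernel; scipy path used when numba is unavailable
    from numba import njit

    @njit(cache=True)
    def _fw_kernel(d: np.ndarray) -> None:  # pragma: no cover - thin kernel
        n = d.shape[0]
        for k in range(n):
            for i in range(n):
                dik = d[i, k]
                if dik == np.inf:
                    continue
                for j in range(n):
                    alt = dik + d[k, j]
                    if alt < d[i, j]:
                        d[i, j] = alt

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

from .connectivity import ConnectivityMatrix, LevelSummary
from .partition import (
    HIERARCHIES,
    HIERARCHY_ABBREV,
    HIERARCHY_CONTRASTS,
    NETWORKS,
    NetworkPartition,
)

_CLIP = 1.0 - 1e-10


@dataclass(frozen=True)
class EfficiencyResult:
    """Raw, null, and normalized efficiency for one node specification."""

    eg: float
    eg_rand: float
    eg_norm: float
    n_null: int
    node_spec: str

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.eg_norm)


def weights_to_distances(fc: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Logarithmic weight-to-distance transform.

    Weights in (0, 1) map to length -log(w); weights <= 0 are removed
    (length +inf); weights >= 1 are clipped to 1 - 1e-10 first.  Diagonal 0.
    """
    w = np.asarray(fc.values if isinstance(fc, ConnectivityMatrix) else fc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(w > 0, -np.log(np.minimum(w, _CLIP)), np.inf)
    np.fill_diagonal(dist, 0.0)
    return dist


def shortest_paths(dist: np.ndarray) -> np.ndarray:
    """All-pairs shortest path closure (Floyd-Warshall); +inf stays unreachable."""
    out = np.array(dist, dtype=float)
    np.fill_diagonal(out, 0.0)
    if _HAVE_NUMBA:
        _fw_kernel(out)
        return out
    adj = out.copy()
    adj[~np.isfinite(adj)] = 0.0  # csgraph convention: 0 = absent edge
    return floyd_warshall(adj, directed=False)


def global_efficiency(spl: np.ndarray, pair_mask: np.ndarray | None = None) -> float:
    """Mean of 1/d(i, j) over the masked ordered node pairs (1/inf = 0).

    The default mask is all ordered pairs i != j, giving
    Eg = (1 / (N (N - 1))) * sum of inverse shortest path lengths.
    """
    n = spl.shape[0]
    if pair_mask is None:
        pair_mask = ~np.eye(n, dtype=bool)
    if not pair_mask.any():
        raise ValueError("empty pair mask")
    # off-diagonal d = 0 cannot occur: the w >= 1 clip keeps all lengths > 0
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(spl) & (spl > 0), 1.0 / spl, 0.0)
    return float(inv[pair_mask].mean())


def shuffle_weights(
    fc: ConnectivityMatrix | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute the off-diagonal weights as a multiset, preserving symmetry."""
    w = np.array(fc.values if isinstance(fc, ConnectivityMatrix) else fc, dtype=float)
    iu = np.triu_indices(w.shape[0], k=1)
    vals = w[iu]
    shuffled = vals[rng.permutation(vals.size)]
    out = np.zeros_like(w)
    out[iu] = shuffled
    out = out + out.T
    np.fill_diagonal(out, np.diag(w))
    return out


def _masked_efficiency(weights: np.ndarray, pair_mask: np.ndarray | None) -> float:
    return global_efficiency(shortest_paths(weights_to_distances(weights)), pair_mask)


def normalized_efficiency(
    fc: ConnectivityMatrix | np.ndarray,
    set1: np.ndarray | None = None,
    set2: np.ndarray | None = None,
    n_null: int = 100,
    rng: np.random.Generator | None = None,
) -> EfficiencyResult:
    """Null-normalized efficiency for a whole-brain, within-set, or between-set spec.

    Within-set (``set1`` only): efficiency of the set's submatrix over all its
    node pairs.  Between-set (``set1`` and ``set2``): the joint submatrix is
    built, shortest paths may relay through either set, but only cross-set
    pairs enter the average (within-set pairs are excluded from numerator and
    denominator).  The null shuffles the submatrix weights before the distance
    transform; ``eg_rand`` is the mean over ``n_null`` realizations.
    """
    if rng is None:
        rng = np.random.default_rng()
    w = np.asarray(fc.values if isinstance(fc, ConnectivityMatrix) else fc, dtype=float)
    if set1 is None and set2 is not None:
        raise ValueError("between-set spec requires set1 and set2")
    if set1 is None:
        sub = w
        mask = None
        spec = "whole"
    elif set2 is None:
        set1 = np.asarray(set1, dtype=int)
        if set1.size < 2:
            raise ValueError("within-set efficiency needs >= 2 nodes")
        sub = w[np.ix_(set1, set1)]
        mask = None
        spec = f"within[{set1.size}]"
    else:
        set1 = np.asarray(set1, dtype=int)
        set2 = np.asarray(set2, dtype=int)
        if np.intersect1d(set1, set2).size:
            raise ValueError("between-set spec requires disjoint sets")
        nodes = np.concatenate([set1, set2])
        sub = w[np.ix_(nodes, nodes)]
        mask = np.zeros((nodes.size, nodes.size), dtype=bool)
        mask[: set1.size, set1.size :] = True
        mask[set1.size :, : set1.size] = True
        spec = f"between[{set1.size},{set2.size}]"
    eg = _masked_efficiency(sub, mask)
    nulls = np.empty(n_null)
    for k in range(n_null):
        nulls[k] = _masked_efficiency(shuffle_weights(sub, rng), mask)
    eg_rand = float(nulls.mean())
    eg_norm = eg / eg_rand if eg_rand > 0 else float("nan")
    return EfficiencyResult(eg, eg_rand, eg_norm, n_null, spec)


def efficiency_levels(
    fc: ConnectivityMatrix,
    partition: NetworkPartition,
    n_null: int = 100,
    rng: np.random.Generator | None = None,
) -> LevelSummary:
    """Normalized efficiency at all three spatial levels.

    Whole brain, the 6 hierarchy specs (3 within, 3 between), and the 28
    network specs (7 within, 21 between); the global within/between values are
    the unweighted means of the 7 and 21 normalized network values.
    """
    if rng is None:
        rng = np.random.default_rng()
    if tuple(fc.roi_ids) != tuple(partition.roi_ids):
        raise ValueError("partition ROIs do not match connectivity matrix ROIs")

    whole = normalized_efficiency(fc, n_null=n_null, rng=rng).eg_norm

    net_idx = {net: partition.network_indices(net) for net in NETWORKS}
    network = np.empty((7, 7))
    for i, a in enumerate(NETWORKS):
        network[i, i] = normalized_efficiency(
            fc, net_idx[a], n_null=n_null, rng=rng
        ).eg_norm
        for j in range(i + 1, 7):
            r = normalized_efficiency(
                fc, net_idx[a], net_idx[NETWORKS[j]], n_null=n_null, rng=rng
            )
            network[i, j] = network[j, i] = r.eg_norm

    hier_idx = {h: partition.hierarchy_indices(h) for h in HIERARCHIES}
    hierarchy = {}
    for ha, hb in HIERARCHY_CONTRASTS:
        key = f"{HIERARCHY_ABBREV[ha]}-{HIERARCHY_ABBREV[hb]}"
        if ha == hb:
            res = normalized_efficiency(fc, hier_idx[ha], n_null=n_null, rng=rng)
        else:
            res = normalized_efficiency(
                fc, hier_idx[ha], hier_idx[hb], n_null=n_null, rng=rng
            )
        hierarchy[key] = res.eg_norm

    return LevelSummary(
        {
            "whole_brain": whole,
            "within_network": float(np.diagonal(network).mean()),
            "between_network": float(network[np.triu_indices(7, k=1)].mean()),
        },
        hierarchy,
        network,
    )
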