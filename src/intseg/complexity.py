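"""Interaction complexity: SVD entropy of windowed cross-product matrices.

The recording is cut into non-overlapping windows of ``width`` frames
(default 5; the trailing remainder is dropped).  For each window and a pair of
ROI sets, the interaction matrix M = X1' X2 is formed from the windowed series,
mean-centered by its scalar global mean, and decomposed by SVD.  Complexity is
the entropy of the normalized singular-value spectrum, scaled to [0, 1] by
log2 K with K = min(n1, n2):

    C = -(1 / log2 K) * sum_k p_k log2 p_k,   p_k = s_k / sum_j s_j

Low C means a few interaction modes dominate (low-dimensional coupling);
high C means many comparable modes.  Per-recording complexity is the mean of C
over windows.  Because a window holds only ``width`` frames, at most
``width`` (+1 after centering) singular values are nonzero; zeros contribute 0
to the entropy but K still sets the normalization scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import LevelSummary
from .partition import (
    HIERARCHIES,
    HIERARCHY_ABBREV,
    HIERARCHY_CONTRASTS,
    NETWORKS,
    NetworkPartition,
)
from .simulate import TimeSeriesMatrix

DEFAULT_WIDTH = 5


@dataclass(frozen=True)
class WindowSpec:
    """Non-overlapping consecutive windows; remainder frames are dropped."""

    width: int = DEFAULT_WIDTH

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError("window width must be >= 2")


@dataclass(frozen=True)
class ComplexityResult:
    """Per-window complexity values and their mean for one (set1, set2) pair."""

    per_window: tuple[float, ...]
    c_mean: float
    node_spec: str
    n_skipped: int = 0


def make_windows(n_frames: int, spec: WindowSpec | int = DEFAULT_WIDTH) -> list[range]:
    """floor(n_frames / width) disjoint consecutive frame ranges."""
    width = spec.width if isinstance(spec, WindowSpec) else int(spec)
    if width < 2:
        raise ValueError("window width must be >= 2")
    if n_frames < width:
        raise ValueError(f"n_frames={n_frames} shorter than window width {width}")
    return [range(k * width, (k + 1) * width) for k in range(n_frames // width)]


def interaction_matrix(
    x1_window: np.ndarray, x2_window: np.ndarray, center: bool = True
) -> np.ndarray:
    """M = X1' X2 over one window, optionally centered by its global mean."""
    x1 = np.asarray(x1_window, dtype=float)
    x2 = np.asarray(x2_window, dtype=float)
    if x1.shape[0] != x2.shape[0]:
        raise ValueError("windows must cover the same frames")
    m = x1.T @ x2
    if center:
        m = m - m.mean()
    return m


def singular_entropy(m: np.ndarray) -> float:
    """Normalized entropy of the singular-value spectrum of M.

    Returns NaN for an all-zero matrix (undefined complexity; callers skip the
    window).  Requires K = min(n1, n2) >= 2.
    """
    m = np.asarray(m, dtype=float)
    k = min(m.shape)
    if k < 2:
        raise ValueError("complexity needs K = min(n1, n2) >= 2")
    s = np.linalg.svd(m, compute_uv=False)
    total = s.sum()
    if total <= 0:
        return float("nan")
    p = s / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum() / np.log2(k))


def _windowed_entropies(
    x: np.ndarray, set1: np.ndarray, set2: np.ndarray, width: int
) -> np.ndarray:
    """Batched per-window C for one set pair (NaN marks all-zero windows)."""
    n_win = x.shape[0] // width
    xw = x[: n_win * width].reshape(n_win, width, x.shape[1])
    a = xw[:, :, set1]
    b = xw[:, :, set2]
    m = np.matmul(a.transpose(0, 2, 1), b)
    m -= m.mean(axis=(1, 2), keepdims=True)
    s = np.linalg.svd(m, compute_uv=False)  # (n_win, min(n1, n2))
    totals = s.sum(axis=1)
    k = min(set1.size, set2.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = s / totals[:, None]
        terms = np.where(p > 0, p * np.log2(p), 0.0)
        c = -terms.sum(axis=1) / np.log2(k)
    c[totals <= 0] = np.nan
    return c


def interaction_complexity(
    ts: TimeSeriesMatrix | np.ndarray,
    set1: np.ndarray,
    set2: np.ndarray | None = None,
    spec: WindowSpec | int = DEFAULT_WIDTH,
) -> ComplexityResult:
    """Window-averaged interaction complexity for one (set1, set2) pair.

    ``set2 = None`` means self-interaction (set2 = set1, symmetric square M).
    All-zero windows yield undefined C and are skipped; zero valid windows is
    an error.
    """
    x = ts.values if isinstance(ts, TimeSeriesMatrix) else np.asarray(ts, dtype=float)
    width = spec.width if isinstance(spec, WindowSpec) else int(spec)
    make_windows(x.shape[0], width)  # validates frame count
    set1 = np.asarray(set1, dtype=int)
    set2 = set1 if set2 is None else np.asarray(set2, dtype=int)
    if set1.size < 2 or set2.size < 2:
        raise ValueError("both ROI sets need >= 2 members")
    c = _windowed_entropies(x, set1, set2, width)
    valid = np.isfinite(c)
    if not valid.any():
        raise ValueError("no valid windows: every interaction matrix was zero")
    label = (
        f"self[{set1.size}]"
        if np.array_equal(set1, set2)
        else f"cross[{set1.size},{set2.size}]"
    )
    return ComplexityResult(
        tuple(float(v) for v in c),
        float(c[valid].mean()),
        label,
        int((~valid).sum()),
    )


def complexity_levels(
    ts: TimeSeriesMatrix,
    partition: NetworkPartition,
    spec: WindowSpec | int = DEFAULT_WIDTH,
) -> LevelSummary:
    """Interaction complexity at all three spatial levels.

    Whole brain (set1 = set2 = all ROIs), the 6 hierarchy pairs, and the 28
    network pairs; global within/between values are unweighted means of the 7
    within-network and 21 between-network complexities.
    """
    if tuple(ts.roi_ids) != tuple(partition.roi_ids):
        raise ValueError("partition ROIs do not match time-series ROIs")
    all_rois = np.arange(partition.n_rois)
    whole = interaction_complexity(ts, all_rois, spec=spec).c_mean

    net_idx = {net: partition.network_indices(net) for net in NETWORKS}
    network = np.empty((7, 7))
    for i, a in enumerate(NETWORKS):
        network[i, i] = interaction_complexity(ts, net_idx[a], spec=spec).c_mean
        for j in range(i + 1, 7):
            c = interaction_complexity(
                ts, net_idx[a], net_idx[NETWORKS[j]], spec=spec
            ).c_mean
            network[i, j] = network[j, i] = c

    hier_idx = {h: partition.hierarchy_indices(h) for h in HIERARCHIES}
    hierarchy = {}
    for ha, hb in HIERARCHY_CONTRASTS:
        key = f"{HIERARCHY_ABBREV[ha]}-{HIERARCHY_ABBREV[hb]}"
        s2 = None if ha == hb else hier_idx[hb]
        hierarchy[key] = interaction_complexity(ts, hier_idx[ha], s2, spec=spec).c_mean

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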