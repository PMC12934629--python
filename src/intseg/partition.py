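"""Cortical network partition: ROIs -> seven canonical networks -> three hierarchy tiers.

Every level-wise average in the pipeline (global, hierarchy, network) is driven
by a :class:`NetworkPartition`, which assigns each parcellated ROI to exactly one
of the seven canonical resting-state networks (visual, somatomotor, dorsal
attention, ventral attention, limbic, frontoparietal, default mode) and groups
six of them into the unimodal / attention / transmodal cortical hierarchy.  The
limbic network carries no hierarchy label and is excluded from hierarchy-level
quantities only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NETWORKS: tuple[str, ...] = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")

#: hierarchy tier of each network; LIM is deliberately absent
HIERARCHY_OF_NETWORK: dict[str, str] = {
    "VIS": "unimodal",
    "SMN": "unimodal",
    "DAN": "attention",
    "VAN": "attention",
    "FPN": "transmodal",
    "DMN": "transmodal",
}

HIERARCHIES: tuple[str, ...] = ("unimodal", "attention", "transmodal")

#: short labels used in output tables (U-U, U-A, ...)
HIERARCHY_ABBREV: dict[str, str] = {
    "unimodal": "U",
    "attention": "A",
    "transmodal": "T",
}

#: the six hierarchy analyses, in reporting order
HIERARCHY_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("unimodal", "unimodal"),
    ("attention", "attention"),
    ("transmodal", "transmodal"),
    ("unimodal", "attention"),
    ("unimodal", "transmodal"),
    ("attention", "transmodal"),
)


class PartitionError(ValueError):
    """Raised for inconsistent partition specifications."""


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of ROIs to networks and hierarchy tiers.

    Parameters
    ----------
    roi_ids
        Ordered ROI labels, matching the column order of every time-series
        and connectivity matrix the partition is applied to.
    networks
        Network label per ROI, aligned with ``roi_ids``.
    """

    roi_ids: tuple[str, ...]
    networks: tuple[str, ...]
    _index: dict[str, np.ndarray] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(self.roi_ids) != len(self.networks):
            raise PartitionError("roi_ids and networks must have equal length")
        bad = sorted(set(self.networks) - set(NETWORKS))
        if bad:
            raise PartitionError(f"unknown network labels: {bad}")
        arr = np.asarray(self.networks)
        index = {net: np.flatnonzero(arr == net) for net in NETWORKS}
        for net, idx in index.items():
            if idx.size == 1:
                raise PartitionError(
                    f"network {net} has a single ROI; block averages need >= 2"
                )
        object.__setattr__(self, "_index", index)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def network_of(self, roi_id: str) -> str:
        return self.networks[self.roi_ids.index(roi_id)]

    def hierarchy_of(self, network: str) -> str | None:
        return HIERARCHY_OF_NETWORK.get(network)

    def network_indices(self, network: str) -> np.ndarray:
        """Column indices of the ROIs belonging to ``network``."""
        if network not in NETWORKS:
            raise PartitionError(f"unknown network {network!r}")
        return self._index[network]

    def hierarchy_indices(self, hierarchy: str) -> np.ndarray:
        """Column indices of all ROIs in a hierarchy tier (LIM never included)."""
        if hierarchy not in HIERARCHIES:
            raise PartitionError(f"unknown hierarchy {hierarchy!r}")
        nets = [n for n, h in HIERARCHY_OF_NETWORK.items() if h == hierarchy]
        return np.sort(np.concatenate([self._index[n] for n in nets]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "network": self.networks,
                "hierarchy": [HIERARCHY_OF_NETWORK.get(n, "none") for n in self.networks],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NetworkPartition":
        return cls(tuple(frame["roi_id"].astype(str)), tuple(frame["network"]))


def make_partition(n_rois: int, network_sizes: list[int] | None = None) -> NetworkPartition:
    """Build a partition of ``n_rois`` into contiguous network blocks.

    Blocks are assigned in the canonical order VIS, SMN, DAN, VAN, LIM, FPN,
    DMN.  When ``network_sizes`` is omitted, the ROIs are split as evenly as
    possible across the seven networks.
    """
    if network_sizes is None:
        base, extra = divmod(n_rois, len(NETWORKS))
        network_sizes = [base + (1 if i < extra else 0) for i in range(len(NETWORKS))]
    if len(network_sizes) != len(NETWORKS):
        raise PartitionError(
            f"expected {len(NETWORKS)} network sizes, got {len(network_sizes)}"
        )
    if any(s < 2 for s in network_sizes):
        raise PartitionError("every network needs at least 2 ROIs")
    if sum(network_sizes) != n_rois:
        raise PartitionError(
            f"network sizes sum to {sum(network_sizes)}, expected n_rois={n_rois}"
        )
    width = len(str(n_rois))
    roi_ids = tuple(f"ROI_{i:0{width}d}" for i in range(n_rois))
    networks: list[str] = []
    for net, size in zip(NETWORKS, network_sizes):
        networks.extend([net] * size)
    return NetworkPartition(roi_ids, tuple(networks))
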