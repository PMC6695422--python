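"""Functionally defined white-matter tracts (fWMT), fascicle fingerprints,
and pairwise ROI connections with the Dice statistic.

A streamline belongs to an ROI's fWMT when one of its endpoints falls in the
ROI mask (endpoint mode, the default; ``any_point`` mode is available for
sensitivity checks).  Two ROIs' connection strength is the Dice coefficient

    DC = 2 |A ∩ B| / (|A| + |B|)

over their streamline connection sets A and B: 1 means every streamline
reaching one ROI also reaches the other, 0 means the sets are disjoint.
An empirical chance level is the mean DC between network ROIs and
off-network control ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import numpy as np

from .io_formats import TractSet, VoxelGrid, world_to_voxel

__all__ = [
    "ConnectivityFingerprint",
    "PairwiseConnection",
    "connects_to",
    "connects_to_many",
    "extract_fwmt",
    "connectivity_fingerprint",
    "pairwise_connection",
    "chance_dc",
    "exclude_multi_roi",
]


@dataclass
class ConnectivityFingerprint:
    """Percentage of an ROI's fWMT carried by each fascicle."""

    roi_name: str
    weights: Dict[str, float]
    n_fwmt: int
    defined: bool = True


@dataclass
class PairwiseConnection:
    """Connection sets of two ROIs and their Dice coefficient.

    ``dc`` is NaN (``defined=False``) when neither ROI is contacted by any
    streamline; an undefined DC is reported as missing, never as 0.
    """

    roi_a: str
    roi_b: str
    count_a: int
    count_b: int
    count_both: int
    dc: float
    defined: bool
    member_ids: np.ndarray
    fascicle_composition: Dict[str, float] = field(default_factory=dict)


def _mask_lookup(mask: VoxelGrid):
    if mask.kind != "mask":
        raise ValueError("connectivity masks must be binary")
    shape = np.asarray(mask.data.shape)

    def inside(points: np.ndarray) -> np.ndarray:
        idx = world_to_voxel(points, mask)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        hit = np.zeros(len(idx), dtype=bool)
        if ok.any():
            sel = idx[ok]
            hit[ok] = mask.data[sel[:, 0], sel[:, 1], sel[:, 2]] > 0
        return hit

    return inside


def connects_to(streamline: np.ndarray, mask: VoxelGrid,
                mode: str = "endpoint") -> bool:
    """True when a streamline touches the mask (endpoints only by default)."""
    return bool(connects_to_many([np.asarray(streamline)], mask, mode)[0])


def connects_to_many(streamlines: Sequence[np.ndarray] | TractSet,
                     mask: VoxelGrid, mode: str = "endpoint") -> np.ndarray:
    """Vectorized :func:`connects_to` over a bundle → boolean array."""
    if isinstance(streamlines, TractSet):
        streamlines = streamlines.streamlines
    inside = _mask_lookup(mask)
    if mode == "endpoint":
        if not streamlines:
            return np.zeros(0, dtype=bool)
        ends = np.concatenate([[s[0], s[-1]] for s in streamlines])
        hits = inside(ends).reshape(-1, 2)
        return hits.any(axis=1)
    if mode == "any_point":
        return np.array([inside(s).any() for s in streamlines], dtype=bool)
    raise ValueError(f"unknown intersection mode: {mode!r}")


def extract_fwmt(tracts: TractSet, mask: VoxelGrid,
                 mode: str = "endpoint") -> TractSet:
    """The subset of streamlines whose endpoint reaches the ROI mask."""
    hit = connects_to_many(tracts, mask, mode)
    if not hit.any():
        warnings.warn("no streamlines connect to the ROI mask", stacklevel=2)
    return tracts.subset(hit)


def connectivity_fingerprint(fwmt: TractSet, roi_name: str,
                             label_set: Iterable[str]) -> ConnectivityFingerprint:
    """Percentage of the fWMT associated with each fascicle label.

    With an empty fWMT the fingerprint is flagged undefined (all-zero
    weights) rather than propagating NaNs.
    """
    labels = list(label_set)
    n = len(fwmt)
    if n == 0:
        return ConnectivityFingerprint(roi_name, {f: 0.0 for f in labels}, 0,
                                       defined=False)
    weights = {
        f: 100.0 * float(np.sum(fwmt.fascicle == f)) / n for f in labels
    }
    return ConnectivityFingerprint(roi_name, weights, n, defined=True)


def _fascicle_composition(tracts: TractSet, member: np.ndarray) -> Dict[str, float]:
    members = tracts.fascicle[member]
    if members.size == 0:
        return {}
    labels, counts = np.unique(members.astype(str), return_counts=True)
    return {l: 100.0 * c / members.size for l, c in zip(labels, counts)}


def pairwise_connection(tracts: TractSet, mask_a: VoxelGrid, mask_b: VoxelGrid,
                        names: Tuple[str, str] = ("a", "b"),
                        mode: str = "endpoint") -> PairwiseConnection:
    """Connection sets A, B, A∩B of two ROIs and DC = 2|A∩B| / (|A| + |B|)."""
    hit_a = connects_to_many(tracts, mask_a, mode)
    hit_b = connects_to_many(tracts, mask_b, mode)
    both = hit_a & hit_b
    count_a, count_b, count_both = int(hit_a.sum()), int(hit_b.sum()), int(both.sum())
    if count_a + count_b == 0:
        dc, defined = float("nan"), False
    else:
        dc, defined = 2.0 * count_both / (count_a + count_b), True
    return PairwiseConnection(
        roi_a=names[0], roi_b=names[1],
        count_a=count_a, count_b=count_b, count_both=count_both,
        dc=dc, defined=defined,
        member_ids=tracts.ids[both],
        fascicle_composition=_fascicle_composition(tracts, both),
    )


def chance_dc(tracts: TractSet, network_masks: Mapping[str, VoxelGrid],
              control_masks: Mapping[str, VoxelGrid],
              exclusions: Set[Tuple[str, str]] | None = None,
              mode: str = "endpoint") -> float:
    """Empirical chance DC: mean DC of (network ROI, control ROI) pairs.

    ``exclusions`` lists ``(network_name, control_name)`` pairs to skip
    (e.g. ROIs anatomically adjacent to a control region).  Undefined DCs
    are skipped; if every pair is undefined an error is raised.
    """
    if not control_masks:
        raise ValueError("at least one control mask is required")
    exclusions = exclusions or set()
    dcs = []
    for net_name, net_mask in network_masks.items():
        for ctl_name, ctl_mask in control_masks.items():
            if (net_name, ctl_name) in exclusions:
                continue
            conn = pairwise_connection(tracts, net_mask, ctl_mask,
                                       names=(net_name, ctl_name), mode=mode)
            if conn.defined:
                dcs.append(conn.dc)
    if not dcs:
        raise ValueError("all network-control pairs have undefined DC")
    return float(np.mean(dcs))


def exclude_multi_roi(tracts: TractSet, masks: Mapping[str, VoxelGrid],
                      k: int, mode: str = "endpoint") -> TractSet:
    """Drop streamlines that connect to ``k`` or more of the given masks."""
    if k > len(masks):
        raise ValueError("k exceeds the number of masks")
    hits = np.zeros(len(tracts), dtype=int)
    for mask in masks.values():
        hits += connects_to_many(tracts, mask, mode).astype(int)
    return tracts.subset(hits < k)
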