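"""Bundle orientation, 100-node resampling, outlier cleaning, core tracts
and within/between-network distance statistics.

The node convention is anterior-first: after :func:`orient_bundle`, node 0
sits at the end whose start-to-end vector agrees with the anchor direction
(default +y, i.e. posterior-to-anterior becomes increasing y), so "the node
five steps more posterior" of node ``i`` is node ``i + lag`` counted toward
the far end.  All coordinates stay in mm world space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import TractSet

__all__ = [
    "ResampledBundle",
    "CoreTract",
    "DistanceComparison",
    "orient_bundle",
    "resample_streamline",
    "resample_bundle",
    "core_tract",
    "clean_outliers",
    "distance_to_core",
    "within_between_distances",
]


@dataclass
class ResampledBundle:
    """``(n_streamlines, n_nodes, 3)`` equal-arc-length node coordinates."""

    coords: np.ndarray
    source_ids: np.ndarray
    node_order: str = "anterior_first"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_streamlines, n_nodes, 3)")
        self.source_ids = np.asarray(self.source_ids)
        if self.source_ids.shape[0] != self.coords.shape[0]:
            raise ValueError("one source id per streamline required")

    @property
    def n_streamlines(self) -> int:
        return self.coords.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[1]

    def subset(self, index) -> "ResampledBundle":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ResampledBundle(self.coords[index], self.source_ids[index],
                               self.node_order)


@dataclass
class CoreTract:
    """Per-node mean coordinates and coordinate SDs of a bundle."""

    mean_coords: np.ndarray  # (n_nodes, 3)
    sd_coords: np.ndarray    # (n_nodes, 3)


@dataclass
class DistanceComparison:
    """Distances of every streamline to its own vs the other network's core."""

    within: np.ndarray          # (n_a + n_b, n_nodes)
    between: np.ndarray         # (n_a + n_b, n_nodes)
    within_streamline_means: np.ndarray
    between_streamline_means: np.ndarray
    mean_within: float
    mean_between: float
    group: np.ndarray           # "a"/"b" per row


# ---------------------------------------------------------------------------
# orientation and resampling
# ---------------------------------------------------------------------------

def orient_bundle(tracts: TractSet, anchor="first") -> TractSet:
    """Flip streamlines so all start-to-end vectors agree with an anchor.

    ``anchor`` is a 3-vector (e.g. ``(0, 1, 0)`` for anterior-first under
    RAS+) or ``"first"`` to use the first streamline's own direction.
    Idempotent.
    """
    if len(tracts) == 0:
        return tracts
    if isinstance(anchor, str):
        if anchor != "first":
            raise ValueError(f"unknown anchor {anchor!r}")
        ref = tracts.streamlines[0][-1] - tracts.streamlines[0][0]
    else:
        ref = np.asarray(anchor, dtype=float)
    norm = np.linalg.norm(ref)
    if norm == 0:
        raise ValueError("anchor direction has zero length")
    ref = ref / norm
    flipped = []
    for s in tracts.streamlines:
        d = s[-1] - s[0]
        flipped.append(s[::-1].copy() if d @ ref < 0 else s)
    return TractSet(flipped, fascicle=tracts.fascicle, network=tracts.network,
                    ids=tracts.ids, validate=False)


def resample_streamline(points: np.ndarray, n_nodes: int = 100) -> np.ndarray:
    """Resample a polyline to ``n_nodes`` points at equal arc length.

    Endpoints are preserved exactly; interior nodes are linear interpolation
    along the piecewise-linear path.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        raise ValueError("zero-length streamline cannot be resampled")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n_nodes)
    out = np.empty((n_nodes, 3))
    for axis in range(3):
        out[:, axis] = np.interp(targets, s, pts[:, axis])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def resample_bundle(tracts: TractSet | Sequence[np.ndarray],
                    n_nodes: int = 100) -> ResampledBundle:
    """Resample every streamline of a (pre-oriented) bundle to node space."""
    if isinstance(tracts, TractSet):
        streamlines = tracts.streamlines
        ids = tracts.ids
    else:
        streamlines = list(tracts)
        ids = np.arange(len(streamlines))
    if not streamlines:
        raise ValueError("cannot resample an empty bundle")
    coords = np.stack([resample_streamline(s, n_nodes) for s in streamlines])
    return ResampledBundle(coords=coords, source_ids=np.asarray(ids))


# ---------------------------------------------------------------------------
# core tract, cleaning, distances
# ---------------------------------------------------------------------------

def core_tract(bundle: ResampledBundle) -> CoreTract:
    """The per-node mean (and SD) streamline of a bundle."""
    if bundle.n_streamlines < 1:
        raise ValueError("core tract of an empty bundle is undefined")
    mean = bundle.coords.mean(axis=0)
    sd = bundle.coords.std(axis=0, ddof=1) if bundle.n_streamlines > 1 \
        else np.zeros_like(mean)
    return CoreTract(mean_coords=mean, sd_coords=sd)


def distance_to_core(bundle: ResampledBundle, core: CoreTract) -> np.ndarray:
    """Euclidean mm distance of every node of every streamline to the core."""
    if bundle.n_nodes != core.mean_coords.shape[0]:
        raise ValueError("bundle and core have different node counts")
    return np.linalg.norm(bundle.coords - core.mean_coords[None], axis=2)


def clean_outliers(bundle: ResampledBundle, n_sd: float = 4.0,
                   max_iter: int = 5):
    """Iteratively remove streamlines far from the bundle core.

    A streamline's representative distance is its mean node distance to the
    current core; streamlines whose representative distance exceeds
    ``mean + n_sd * SD`` of that distribution are dropped, the core is
    recomputed, and the procedure repeats to a fixpoint (or ``max_iter``).

    Returns ``(cleaned_bundle, removed_source_ids)``.
    """
    if bundle.n_streamlines < 3:
        raise ValueError("cleaning needs at least 3 streamlines")
    keep = np.ones(bundle.n_streamlines, dtype=bool)
    for _ in range(max_iter):
        current = bundle.subset(keep)
        rep = distance_to_core(current, core_tract(current)).mean(axis=1)
        threshold = rep.mean() + n_sd * rep.std(ddof=1)
        bad = rep > threshold
        if not bad.any():
            break
        keep[np.flatnonzero(keep)[bad]] = False
        if keep.sum() == 0:
            raise ValueError("cleaning removed every streamline")
    removed = bundle.source_ids[~keep]
    return bundle.subset(keep), removed


def _loo_distances(bundle: ResampledBundle) -> np.ndarray:
    """Distance of each streamline to the core of the *other* streamlines.

    Using the leave-one-out core for within-network distances removes the
    O(1/n) shrinkage a streamline induces on its own bundle mean; without it
    the within-vs-between comparison is biased toward "segregated" even for
    perfectly intertwined lanes.
    """
    n = bundle.n_streamlines
    total = bundle.coords.sum(axis=0)  # (n_nodes, 3)
    loo_means = (total[None] - bundle.coords) / (n - 1)
    return np.linalg.norm(bundle.coords - loo_means, axis=2)


def within_between_distances(bundle_a: ResampledBundle,
                             bundle_b: ResampledBundle) -> DistanceComparison:
    """Distance of each streamline to its own core vs the other bundle's core.

    Rows are the streamlines of ``bundle_a`` followed by ``bundle_b``;
    segregated lanes show ``mean_within < mean_between``, intertwined lanes
    show no difference.  Within-network distances are taken to the
    leave-one-out core (see :func:`_loo_distances`) so the comparison is
    unbiased under the intertwined null; between-network distances use the
    other bundle's full core.  Group-level inference across replicates is
    done by the stats layer (:func:`tractlanes.qprofile_stats.paired_t`).
    """
    if bundle_a.n_streamlines < 2 or bundle_b.n_streamlines < 2:
        raise ValueError("both bundles need at least 2 streamlines")
    if bundle_a.n_nodes != bundle_b.n_nodes:
        raise ValueError("bundles must share the node count")
    core_a = core_tract(bundle_a)
    core_b = core_tract(bundle_b)
    within = np.concatenate([_loo_distances(bundle_a),
                             _loo_distances(bundle_b)])
    between = np.concatenate([distance_to_core(bundle_a, core_b),
                              distance_to_core(bundle_b, core_a)])
    group = np.array(["a"] * bundle_a.n_streamlines
                     + ["b"] * bundle_b.n_streamlines, dtype=object)
    return DistanceComparison(
        within=within,
        between=between,
        within_streamline_means=within.mean(axis=1),
        between_streamline_means=between.mean(axis=1),
        mean_within=float(within.mean()),
        mean_between=float(between.mean()),
        group=group,
    )
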