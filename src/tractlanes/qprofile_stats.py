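"""Quantitative-map sampling along tracts, node profiles, and the
statistical comparisons used throughout the pipeline.

Scalar maps (T1 in seconds, MTV, or any co-registered quantitative volume)
are sampled at every node of a resampled bundle by trilinear interpolation
in world space; per-node means across streamlines form a tract profile.
Group comparisons are paired t-tests across replicates (replicates stand in
for subjects), with Bonferroni adjustment for per-node tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates

from .io_formats import VoxelGrid
from .tractometry import ResampledBundle

__all__ = [
    "NodeProfile",
    "ProfileComparison",
    "TTestResult",
    "sample_scalar",
    "tract_profile",
    "compare_profiles",
    "paired_t",
    "bonferroni",
]


@dataclass
class TTestResult:
    """Paired t statistic with explicit degenerate-case flagging.

    ``degenerate`` marks a zero-variance difference distribution: ``t`` is 0
    (all differences zero) or signed infinity (constant nonzero difference),
    never a silent NaN.
    """

    t: float
    df: int
    p: float
    degenerate: bool = False


@dataclass
class NodeProfile:
    """Per-node summary of a scalar map sampled along a bundle."""

    node_values: np.ndarray        # (n_nodes,) mean across streamlines
    node_sem: np.ndarray
    streamline_means: np.ndarray   # (n_streamlines,)
    n_missing: int
    map_name: str = ""
    units: str = ""

    @property
    def n_nodes(self) -> int:
        return self.node_values.shape[0]

    @property
    def tract_mean(self) -> float:
        return float(np.mean(self.streamline_means))


@dataclass
class ProfileComparison:
    """Group comparison of two sets of paired replicate profiles."""

    mean_a: float
    mean_b: float
    test: TTestResult
    node_diff: np.ndarray          # per-node mean(a) - mean(b)
    node_p: np.ndarray
    bonferroni_threshold: float
    significant_nodes: np.ndarray  # boolean
    pooled_a: np.ndarray           # replicate-node means, both groups
    pooled_b: np.ndarray


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_scalar(volume: VoxelGrid, points: np.ndarray,
                  interp: str = "trilinear") -> np.ndarray:
    """Sample a scalar map at mm world points; out-of-grid points give NaN.

    ``trilinear`` (default) interpolates between voxel centres and is exact
    at voxel centres; ``nearest`` uses the voxel-membership convention
    (round half away from zero).
    """
    if volume.kind != "scalar":
        raise ValueError("sampling requires a scalar-kind volume")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("sample points must be finite")
    idx = pts @ volume.inv_affine[:3, :3].T + volume.inv_affine[:3, 3]
    shape = np.asarray(volume.data.shape)
    if interp == "trilinear":
        valid = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
        values = map_coordinates(volume.data, idx.T, order=1, mode="nearest")
    elif interp == "nearest":
        vox = (np.sign(idx) * np.floor(np.abs(idx) + 0.5)).astype(int)
        valid = np.all((vox >= 0) & (vox < shape), axis=1)
        values = np.zeros(len(pts))
        sel = vox[valid]
        values[valid] = volume.data[sel[:, 0], sel[:, 1], sel[:, 2]]
    else:
        raise ValueError(f"unknown interpolation scheme: {interp!r}")
    values = values.astype(float)
    values[~valid] = np.nan
    if not valid.any():
        raise ValueError("every sample point lies outside the grid")
    return values


def tract_profile(bundle: ResampledBundle, volume: VoxelGrid,
                  interp: str = "trilinear", map_name: str = "") -> NodeProfile:
    """Sample the map at every node of every streamline and summarize.

    Missing (out-of-grid) samples are excluded from means and counted;
    more than 50% missing raises an error.
    """
    n, m = bundle.n_streamlines, bundle.n_nodes
    samples = sample_scalar(volume, bundle.coords.reshape(-1, 3),
                            interp=interp).reshape(n, m)
    n_missing = int(np.isnan(samples).sum())
    if n_missing > 0.5 * samples.size:
        raise ValueError(
            f"{n_missing}/{samples.size} samples fall outside the map"
        )
    node_values = np.nanmean(samples, axis=0)
    counts = np.sum(~np.isnan(samples), axis=0)
    node_sem = np.nanstd(samples, axis=0, ddof=1) / np.sqrt(np.maximum(counts, 1))
    streamline_means = np.nanmean(samples, axis=1)
    return NodeProfile(
        node_values=node_values, node_sem=node_sem,
        streamline_means=streamline_means, n_missing=n_missing,
        map_name=map_name, units=volume.units,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def paired_t(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Two-sided paired t-test; zero-variance differences are flagged."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return TTestResult(t=0.0, df=n - 1, p=1.0, degenerate=True)
        t = float(np.sign(d.mean()) * np.inf)
        return TTestResult(t=t, df=n - 1, p=0.0, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), df=n - 1, p=float(p))


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance threshold: ``alpha / m``."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def compare_profiles(profiles_a: Sequence[NodeProfile],
                     profiles_b: Sequence[NodeProfile],
                     alpha: float = 0.05) -> ProfileComparison:
    """Compare two groups of paired replicate profiles.

    The primary test is a paired t-test on tract-average values across
    replicates; per-node paired tests use replicate-level node means
    (avoiding streamline-level pseudo-replication) against the
    Bonferroni-adjusted threshold ``alpha / n_nodes``.
    """
    if len(profiles_a) != len(profiles_b) or len(profiles_a) < 2:
        raise ValueError("paired replicate profiles required (n >= 2 each)")
    n_nodes = profiles_a[0].n_nodes
    if any(p.n_nodes != n_nodes for p in list(profiles_a) + list(profiles_b)):
        raise ValueError("all profiles must share the node count")
    means_a = np.array([p.tract_mean for p in profiles_a])
    means_b = np.array([p.tract_mean for p in profiles_b])
    test = paired_t(means_a, means_b)
    nodes_a = np.stack([p.node_values for p in profiles_a])  # (R, n_nodes)
    nodes_b = np.stack([p.node_values for p in profiles_b])
    node_diff = (nodes_a - nodes_b).mean(axis=0)
    node_p = np.array([
        paired_t(nodes_a[:, k], nodes_b[:, k]).p for k in range(n_nodes)
    ])
    threshold = bonferroni(alpha, n_nodes)
    return ProfileComparison(
        mean_a=float(means_a.mean()), mean_b=float(means_b.mean()),
        test=test, node_diff=node_diff, node_p=node_p,
        bonferroni_threshold=threshold,
        significant_nodes=node_p < threshold,
        pooled_a=nodes_a.ravel(), pooled_b=nodes_b.ravel(),
    )
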