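"""Synthetic streamline phantoms with known ground truth.

The generator emulates the geometry the lane analysis assumes: a single
fascicle-like arched bundle (think left SLF) carrying two labelled
sub-bundles — "reading" and "math" — whose centrelines are either parallel
but offset along +z (segregated lanes, the math lane superior) or co-located
(``separation_d = 0``, intertwined).  Each sub-bundle terminates in a pair of
spherical grey-white-matter-interface (GWMI) endpoint masks, an off-bundle
control ROI is provided for empirical chance levels, and a co-registered
scalar map (T1-like, seconds) carries sub-bundle-specific baselines plus
voxel noise.  Gross outlier streamlines are injected to give the 4-SD
cleaning step real work.

Every stage downstream (endpoint filtering, Dice overlap, core-tract
distances, node-wise classification, scalar profiling) is tested against the
spec of this generator, so everything here is deterministic in ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import TractSet, VoxelGrid, world_to_voxel

__all__ = [
    "PhantomSpec",
    "PhantomSet",
    "make_centerline",
    "jitter_bundle",
    "build_sphere_mask",
    "generate_phantom",
]

# mask names follow the reading (IFG–SMGr) and math (PCS–SMGm) pairs of the
# frontoparietal lane analysis; purely nominal here
READING_MASKS = ("IFG", "SMGr")
MATH_MASKS = ("PCS", "SMGm")


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative configuration; the ground truth for every test.

    Units are mm and seconds throughout.  Defaults give a 120 mm cube at
    1 mm isotropic resolution with two 100-streamline sub-bundles, 2 mm
    Gaussian cross-sectional scatter, an 8 mm superior offset of the math
    lane, plausible 3T T1 baselines, and five gross outliers.
    """

    grid_shape: Tuple[int, int, int] = (120, 120, 120)
    voxel_size: float = 1.0
    n_per_bundle: int = 100
    separation_d: float = 8.0
    jitter_sigma: float = 2.0
    curvature: float = 10.0
    n_points: int = 100
    scalar_values: Dict[str, float] = field(
        default_factory=lambda: {"reading": 0.95, "math": 1.05, "background": 1.50}
    )
    scalar_noise_sd: float = 0.02
    n_outliers: int = 5
    outlier_offset: float = 50.0
    endpoint_radius: float = 5.0
    control_roi_center: Tuple[float, float, float] = (30.0, 60.0, 25.0)
    control_roi_radius: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation_d < 0:
            raise ValueError("separation_d must be >= 0")
        if self.jitter_sigma <= 0:
            raise ValueError("jitter_sigma must be > 0")
        if self.n_per_bundle < 2:
            raise ValueError("n_per_bundle must be >= 2")

    # centreline termini: the bundle runs along +y through the grid centre,
    # arched in +z, with enough margin for endpoint masks
    def reading_termini(self) -> Tuple[np.ndarray, np.ndarray]:
        nx, ny, nz = self.grid_shape
        vs = self.voxel_size
        x = 0.5 * nx * vs
        z = 0.42 * nz * vs
        y0, y1 = 0.17 * ny * vs, 0.83 * ny * vs
        return np.array([x, y0, z]), np.array([x, y1, z])

    def math_termini(self) -> Tuple[np.ndarray, np.ndarray]:
        a, b = self.reading_termini()
        off = np.array([0.0, 0.0, self.separation_d])
        return a + off, b + off


@dataclass
class PhantomSet:
    """Generated phantom: tracts with truth labels, masks, map, and the spec."""

    tracts: TractSet
    gwmi_masks: Dict[str, VoxelGrid]
    scalar_map: VoxelGrid | None
    truth: PhantomSpec


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def make_centerline(start, end, curvature: float, n_points: int) -> np.ndarray:
    """Planar circular arc from ``start`` to ``end`` with sagitta ``curvature``.

    The arc bulges along +z (or +y when the chord is z-aligned); points are
    equally spaced in arc length.  ``curvature = 0`` degenerates to a straight
    segment.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    chord = end - start
    length = np.linalg.norm(chord)
    if length == 0:
        raise ValueError("start and end coincide")
    t = np.linspace(0.0, 1.0, n_points)
    if curvature == 0:
        return start + t[:, None] * chord
    u = chord / length
    w = np.array([0.0, 0.0, 1.0])
    if abs(u @ w) > 0.9:  # chord nearly z-aligned: bulge along +y instead
        w = np.array([0.0, 1.0, 0.0])
    w = w - (w @ u) * u
    w /= np.linalg.norm(w)
    h = float(curvature)
    # circle of radius R through both termini with sagitta h at mid-chord
    R = (length**2 / 4.0 + h**2) / (2.0 * h)
    center = start + 0.5 * chord - (R - h) * w
    half_angle = np.arcsin(min(1.0, (length / 2.0) / R))
    angles = (2 * t - 1) * half_angle  # uniform angle == uniform arc length
    along = np.sin(angles)[:, None] * (R * u)
    upward = np.cos(angles)[:, None] * (R * w)
    return center + along + upward


def _gp_cholesky(n_points: int, length_scale_frac: float = 0.25) -> np.ndarray:
    """Cholesky factor of a unit-variance squared-exponential kernel on [0,1]."""
    t = np.linspace(0.0, 1.0, n_points)
    d = t[:, None] - t[None, :]
    K = np.exp(-0.5 * (d / length_scale_frac) ** 2)
    K[np.diag_indices_from(K)] += 1e-8
    return np.linalg.cholesky(K)


def _smooth_offsets(n: int, n_points: int, sigma: float,
                    rng: np.random.Generator) -> np.ndarray:
    """(n, n_points, 3) smooth Gaussian offset fields, marginal SD ``sigma``."""
    L = _gp_cholesky(n_points)
    z = rng.standard_normal((n_points, n * 3))
    offsets = (L @ z).T.reshape(n, 3, n_points).transpose(0, 2, 1)
    return sigma * offsets


def jitter_bundle(centerline: np.ndarray, n: int, sigma: float,
                  seed: int, fascicle: str = "SLF",
                  network: str = "unassigned") -> TractSet:
    """``n`` smooth random perturbations of a centreline.

    Offsets are draws of a smooth Gaussian process along arc length whose
    per-node marginal SD is exactly ``sigma`` per axis, so cross-sections are
    isotropic 3D Gaussian scatter while individual streamlines stay smooth.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    centerline = np.asarray(centerline, dtype=float)
    rng = np.random.default_rng(seed)
    offsets = _smooth_offsets(n, centerline.shape[0], sigma, rng)
    streamlines = [centerline + offsets[k] for k in range(n)]
    return TractSet(streamlines, fascicle=[fascicle] * n, network=[network] * n,
                    validate=False)


def build_sphere_mask(grid: VoxelGrid, center, radius: float) -> VoxelGrid:
    """Binary mask of voxels whose centre lies within ``radius`` mm of ``center``."""
    center = np.asarray(center, dtype=float)
    cidx = (grid.inv_affine[:3, :3] @ center + grid.inv_affine[:3, 3])
    shape = np.asarray(grid.data.shape)
    if np.any(cidx < -0.5) or np.any(cidx > shape - 0.5):
        raise ValueError("sphere center lies outside the grid")
    # only visit the bounding box of the sphere
    vox_extent = radius / np.abs(np.diag(grid.affine)[:3]).min() + 1
    lo = np.maximum(0, np.floor(cidx - vox_extent).astype(int))
    hi = np.minimum(shape, np.ceil(cidx + vox_extent).astype(int) + 1)
    data = np.zeros(grid.data.shape, dtype=np.uint8)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)],
                             indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = grid.voxel_centers_world(idx)
    inside = np.linalg.norm(centers - center, axis=1) <= radius
    data[idx[inside, 0], idx[inside, 1], idx[inside, 2]] = 1
    return VoxelGrid(data=data, affine=grid.affine, kind="mask")


# ---------------------------------------------------------------------------
# full phantom
# ---------------------------------------------------------------------------

def _template_grid(spec: PhantomSpec) -> VoxelGrid:
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    return VoxelGrid(np.zeros(spec.grid_shape, dtype=np.uint8), affine, kind="mask")


def _scalar_map(spec: PhantomSpec, clouds: Dict[str, np.ndarray],
                rng: np.random.Generator) -> VoxelGrid:
    """Baseline field + iid voxel noise.

    A voxel takes the baseline of the nearest sub-bundle streamline cloud if
    that cloud passes within ``2 * jitter_sigma`` of its centre; background
    elsewhere.  Cloud (not centreline) distance keeps every sampled tract node
    inside its own bundle's region, which the profile recovery bounds assume.
    """
    grid = _template_grid(spec)
    data = np.full(spec.grid_shape, spec.scalar_values["background"], dtype=float)
    band = 2.0 * spec.jitter_sigma
    points = np.concatenate(list(clouds.values()))
    lo_w = points.min(axis=0) - band
    hi_w = points.max(axis=0) + band
    shape = np.asarray(spec.grid_shape)
    lo = np.maximum(0, np.floor(lo_w / spec.voxel_size).astype(int))
    hi = np.minimum(shape, np.ceil(hi_w / spec.voxel_size).astype(int) + 1)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)],
                             indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = grid.voxel_centers_world(idx)
    names = list(clouds)
    dists = np.stack(
        [cKDTree(clouds[name]).query(centers, workers=1)[0] for name in names],
        axis=1,
    )
    nearest = np.argmin(dists, axis=1)
    in_band = dists[np.arange(len(idx)), nearest] <= band
    for b, name in enumerate(names):
        sel = in_band & (nearest == b)
        data[idx[sel, 0], idx[sel, 1], idx[sel, 2]] = spec.scalar_values[name]
    data += rng.normal(0.0, spec.scalar_noise_sd, size=data.shape)
    return VoxelGrid(data=data, affine=grid.affine, kind="scalar", units="s")


def generate_phantom(spec: PhantomSpec,
                     include_scalar_map: bool = True) -> PhantomSet:
    """Generate the full phantom described by ``spec``.

    Streamline order is reading sub-bundle, math sub-bundle, outliers.
    Sub-bundle streamlines are drawn by rejection: a draw whose endpoints do
    not both land in the designated GWMI masks is redrawn, so the endpoint
    guarantee holds exactly while node cross-sections keep their isotropic
    Gaussian scatter.  Outliers are jittered copies of the reading centreline
    displaced by ``outlier_offset`` mm laterally (in the x–z plane, so they
    stay on-grid); they carry the reading lane's fascicle label but network
    label ``"outlier"`` and are excluded from the endpoint guarantee.
    Deterministic in ``spec.seed``.
    """
    # local import: fwmt depends on io_formats only, no cycle at runtime
    from .fwmt import connects_to_many

    rng = np.random.default_rng(spec.seed)
    grid = _template_grid(spec)

    r0, r1 = spec.reading_termini()
    m0, m1 = spec.math_termini()
    extent = np.asarray(spec.grid_shape) * spec.voxel_size
    for name, c in (("IFG", r0), ("SMGr", r1), ("PCS", m0), ("SMGm", m1)):
        if np.any(c - spec.endpoint_radius < 0) or np.any(c + spec.endpoint_radius > extent):
            raise ValueError(f"endpoint mask {name!r} exceeds the grid")

    masks = {
        "IFG": build_sphere_mask(grid, r0, spec.endpoint_radius),
        "SMGr": build_sphere_mask(grid, r1, spec.endpoint_radius),
        "PCS": build_sphere_mask(grid, m0, spec.endpoint_radius),
        "SMGm": build_sphere_mask(grid, m1, spec.endpoint_radius),
        "control": build_sphere_mask(grid, spec.control_roi_center,
                                     spec.control_roi_radius),
    }

    center_r = make_centerline(r0, r1, spec.curvature, spec.n_points)
    center_m = make_centerline(m0, m1, spec.curvature, spec.n_points)

    def draw(centerline: np.ndarray, n: int) -> np.ndarray:
        offsets = _smooth_offsets(n, spec.n_points, spec.jitter_sigma, rng)
        return centerline[None] + offsets

    def bundle(centerline: np.ndarray, mask_start: VoxelGrid,
               mask_end: VoxelGrid, n: int) -> np.ndarray:
        """Draw n streamlines whose endpoints land in both masks (rejection)."""
        out = draw(centerline, n)
        for _ in range(200):
            ok = (connects_to_many(list(out), mask_start)
                  & connects_to_many(list(out), mask_end))
            if ok.all():
                return out
            out[~ok] = draw(centerline, int((~ok).sum()))
        raise RuntimeError(
            "endpoint rejection sampling did not converge; "
            "endpoint_radius is too small for jitter_sigma"
        )

    reading = bundle(center_r, masks["IFG"], masks["SMGr"], spec.n_per_bundle)
    math = bundle(center_m, masks["PCS"], masks["SMGm"], spec.n_per_bundle)

    outliers = []
    if spec.n_outliers > 0:
        base = draw(center_r, spec.n_outliers)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_outliers)
        # lateral displacement only (x-z plane): keeps outliers inside the grid
        disp = spec.outlier_offset * np.stack(
            [np.cos(theta), np.zeros_like(theta), np.sin(theta)], axis=1
        )
        outliers = [base[k] + disp[k] for k in range(spec.n_outliers)]

    streamlines = (
        [reading[k] for k in range(spec.n_per_bundle)]
        + [math[k] for k in range(spec.n_per_bundle)]
        + outliers
    )
    network = (["reading"] * spec.n_per_bundle + ["math"] * spec.n_per_bundle
               + ["outlier"] * spec.n_outliers)
    fascicle = ["SLF"] * len(streamlines)
    tracts = TractSet(streamlines, fascicle=fascicle, network=network,
                      validate=False)

    scalar_map = None
    if include_scalar_map:
        clouds = {
            "reading": reading.reshape(-1, 3),
            "math": math.reshape(-1, 3),
        }
        scalar_map = _scalar_map(spec, clouds, rng)

    return PhantomSet(tracts=tracts, gwmi_masks=masks, scalar_map=scalar_map,
                      truth=spec)
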