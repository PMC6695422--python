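"""Streamline, mask and table I/O with a single internal geometry convention.

Everything downstream assumes:

* streamline coordinates are in RAS+ world millimetres,
* voxel indices are 0-based, and
* a world point lies in voxel ``v`` iff mapping it through the inverse affine
  and rounding half-away-from-zero to the nearest integer index gives ``v``
  (voxel-centre convention).

TRK's voxel-corner/voxel-offset conventions are resolved by nibabel on load,
so TRK and TCK files describing the same geometry produce identical internal
coordinates.  Per-streamline labels travel in a CSV sidecar
(``<tractogram>.labels.csv``) because TCK has no native per-streamline fields.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Streamline",
    "TractSet",
    "VoxelGrid",
    "world_to_voxel",
    "read_streamlines",
    "write_streamlines",
    "read_volume",
    "write_volume",
    "write_table",
    "sidecar_path",
]

#: fascicle vocabulary used when no explicit label set is supplied (the 13
#: major fascicles segmented by automated fibre quantification; "SLF" etc.)
DEFAULT_FASCICLES = (
    "ATR", "CGC", "CGH", "CST", "FMA", "FMI", "IFOF",
    "ILF", "SLF", "AF", "pAF", "VOF", "UF",
)

UNLABELED = "unlabeled"


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Streamline:
    """An ordered 3D polyline in mm world space (RAS+)."""

    points: np.ndarray  # (n, 3) float
    id: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("streamline needs an (n>=2, 3) point array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("streamline contains non-finite coordinates")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("streamline has coincident consecutive points")
        object.__setattr__(self, "points", pts)


class TractSet:
    """A collection of streamlines with per-streamline categorical labels.

    Parameters
    ----------
    streamlines :
        Sequence of ``(n_i, 3)`` float arrays, mm world coordinates.
    fascicle :
        Per-streamline fascicle label (e.g. ``"SLF"``).
    network :
        Optional per-streamline network label (e.g. ``"math"``, ``"reading"``,
        ``"outlier"``); defaults to ``"unassigned"``.
    ids :
        Opaque integer identifiers; default ``0..n-1``.
    """

    def __init__(
        self,
        streamlines: Sequence[np.ndarray],
        fascicle: Sequence[str] | None = None,
        network: Sequence[str] | None = None,
        ids: Sequence[int] | None = None,
        label_set: Iterable[str] | None = None,
        validate: bool = True,
    ) -> None:
        self.streamlines = [np.ascontiguousarray(s, dtype=float) for s in streamlines]
        n = len(self.streamlines)
        self.fascicle = np.asarray(
            fascicle if fascicle is not None else [UNLABELED] * n, dtype=object
        )
        self.network = np.asarray(
            network if network is not None else ["unassigned"] * n, dtype=object
        )
        self.ids = np.asarray(ids if ids is not None else np.arange(n), dtype=int)
        for name, arr in (("fascicle", self.fascicle),
                          ("network", self.network), ("ids", self.ids)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} needs exactly one entry per streamline")
        if validate:
            for s in self.streamlines:
                Streamline(s)
            if label_set is not None:
                unknown = set(self.fascicle) - set(label_set) - {UNLABELED}
                if unknown:
                    raise ValueError(f"unknown fascicle labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def subset(self, index) -> "TractSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return TractSet(
            [self.streamlines[i] for i in index],
            fascicle=self.fascicle[index],
            network=self.network[index],
            ids=self.ids[index],
            validate=False,
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "TractSet":
        """Rigidly transform every streamline (used in invariance checks)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return TractSet(
            [s @ R.T + t for s in self.streamlines],
            fascicle=self.fascicle, network=self.network, ids=self.ids,
            validate=False,
        )


@dataclass
class VoxelGrid:
    """A 3D volume plus its voxel-to-world affine.

    ``kind`` is ``"mask"`` (data restricted to {0, 1}) or ``"scalar"``.
    ``units`` is the physical unit of scalar values ("" for masks,
    e.g. "s" for T1 maps).
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str = "mask"
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be 3D with positive extents")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.kind == "mask":
            bad = np.setdiff1d(np.unique(self.data), [0, 1])
            if bad.size:
                raise ValueError(f"mask contains non-binary values: {bad.tolist()}")
            self.data = self.data.astype(np.uint8)
        elif self.kind == "scalar":
            self.data = self.data.astype(float)
        else:
            raise ValueError(f"unknown volume kind: {self.kind!r}")

    @property
    def inv_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def voxel_centers_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round is half-to-even; the internal convention is half-away-from-zero
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def world_to_voxel(points: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Map mm world points to integer voxel indices (may lie outside the grid)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = pts @ grid.inv_affine[:3, :3].T + grid.inv_affine[:3, 3]
    return _round_half_away(idx).astype(int)


# ---------------------------------------------------------------------------
# tractogram I/O
# ---------------------------------------------------------------------------

def sidecar_path(path: os.PathLike | str) -> Path:
    return Path(str(path) + ".labels.csv")


def _resolve_format(path: Path, format_hint: str) -> str:
    if format_hint in ("trk", "tck"):
        return format_hint
    if format_hint != "auto":
        raise ValueError(f"unsupported tractogram format: {format_hint!r}")
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("trk", "tck"):
        return suffix
    raise ValueError(f"cannot infer tractogram format from {path.name!r}")


def read_streamlines(
    path: os.PathLike | str,
    format_hint: str = "auto",
    label_set: Iterable[str] | None = None,
) -> TractSet:
    """Load a TRK/TCK tractogram into world-mm coordinates.

    A ``<path>.labels.csv`` sidecar (columns ``id, fascicle, network``), if
    present, supplies per-streamline labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format_hint)
    try:
        tfile = nib.streamlines.load(str(path), lazy_load=False)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"malformed {fmt} file {path.name}: {exc}") from exc
    # nibabel returns streamlines already transformed to RAS+ mm
    streamlines = [np.asarray(s, dtype=float) for s in tfile.tractogram.streamlines]
    n = len(streamlines)
    fascicle = network = ids = None
    sidecar = sidecar_path(path)
    if sidecar.exists():
        table = pd.read_csv(sidecar)
        if len(table) != n:
            raise ValueError(
                f"label sidecar has {len(table)} rows for {n} streamlines"
            )
        ids = table["id"].to_numpy()
        fascicle = table["fascicle"].astype(str).to_numpy()
        if "network" in table:
            network = table["network"].astype(str).to_numpy()
    return TractSet(streamlines, fascicle=fascicle, network=network, ids=ids,
                    label_set=label_set)


def write_streamlines(
    tracts: TractSet,
    path: os.PathLike | str,
    format: str = "auto",
    reference: VoxelGrid | None = None,
) -> None:
    """Write a TractSet as TRK or TCK plus a label sidecar CSV.

    ``reference`` fills the TRK header (grid dimensions / voxel sizes); it is
    optional because coordinates are stored resolvable to world mm either way.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in tracts.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if fmt == "trk":
        header = nib.streamlines.TrkFile.create_empty_header()
        if reference is not None:
            header["voxel_to_rasmm"] = reference.affine.astype(np.float32)
            header["voxel_sizes"] = np.abs(
                np.linalg.norm(reference.affine[:3, :3], axis=0)
            ).astype(np.float32)
            header["dimensions"] = np.asarray(reference.data.shape, dtype=np.int16)
        fobj = nib.streamlines.TrkFile(tractogram, header=header)
    else:
        fobj = nib.streamlines.TckFile(tractogram)
    try:
        fobj.save(str(path))
    except OSError as exc:
        raise OSError(f"cannot write tractogram to {path}: {exc}") from exc
    write_table(
        pd.DataFrame(
            {"id": tracts.ids, "fascicle": tracts.fascicle, "network": tracts.network}
        ),
        sidecar_path(path),
    )


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def read_volume(path: os.PathLike | str, kind: str = "scalar",
                units: str = "") -> VoxelGrid:
    """Load a NIfTI-1 volume; ``kind="mask"`` enforces binary data."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return VoxelGrid(data=data, affine=np.asarray(img.affine), kind=kind, units=units)


def write_volume(grid: VoxelGrid, path: os.PathLike | str) -> None:
    dtype = np.uint8 if grid.kind == "mask" else np.float32
    img = nib.Nifti1Image(grid.data.astype(dtype), grid.affine)
    nib.save(img, str(path))


def write_table(rows, path: os.PathLike | str) -> None:
    """Write tabular results as CSV with a header row and stable column order."""
    if isinstance(rows, pd.DataFrame):
        table = rows
    else:
        rows = list(rows)
        if rows:
            schema = tuple(rows[0].keys())
            for r in rows:
                if tuple(r.keys()) != schema:
                    raise ValueError("rows do not share a common schema")
        table = pd.DataFrame(rows)
    table.to_csv(path, index=False)
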