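"""Volumetric and streamline I/O plus the in-memory containers used package-wide.

The central objects are:

* :class:`Volume` — a 3D grid with a world-from-voxel affine (NIfTI-1 on disk).
* :class:`VoxelIndex` — the deterministic (lexicographic) enumeration of the
  nonzero voxels of a mask; it fixes the column order of every feature matrix.
* :class:`SkeletonDataset` — a subjects x voxels matrix of skeletonized FA
  values bound to a :class:`VoxelIndex`.
* :class:`Tractogram` — streamlines as point sequences in world millimetres.

World/voxel conventions: voxel coordinates are 0-based; world coordinates
follow the image affine (RAS assumed, not enforced). A world point belongs to
the voxel whose centre is nearest, i.e. round-half-away-from-zero after
applying the inverse affine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import (
    DataError,
    DegenerateInputError,
    DimensionError,
    FormatError,
    GeometryError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "VoxelIndex",
    "SkeletonDataset",
    "Tractogram",
    "load_volume",
    "save_volume",
    "extract_matrix",
    "project_map",
    "read_streamlines",
    "write_streamlines",
    "world_to_voxel",
    "voxel_to_world",
    "read_score_table",
]

#: tolerance on FA values nominally bounded by [0, 1]
FA_TOL = 1e-6


@dataclass(frozen=True)
class Volume:
    """A 3D image grid together with its world-from-voxel affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3:
            raise DimensionError(f"expected a 3D grid, got ndim={data.ndim}")
        if affine.shape != (4, 4):
            raise DimensionError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the affine's linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def same_geometry(self, other: "Volume", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass(frozen=True)
class VoxelIndex:
    """Ordered enumeration of the in-mask voxels of a reference grid.

    ``coords`` is an (n, 3) int array in lexicographic order; it defines the
    column order of all feature matrices referring to the same mask.
    """

    coords: np.ndarray
    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.intp).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @classmethod
    def from_mask(cls, mask: Volume) -> "VoxelIndex":
        if not mask.is_binary():
            raise DataError("mask must be binary (values in {0, 1})")
        coords = np.argwhere(mask.data > 0)  # argwhere is lexicographic
        if coords.size == 0:
            raise DegenerateInputError("mask is empty")
        return cls(coords=coords, shape=mask.shape, affine=mask.affine)

    def __len__(self) -> int:
        return int(self.coords.shape[0])

    def as_tuple_index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.coords[:, 0], self.coords[:, 1], self.coords[:, 2])


@dataclass(frozen=True)
class SkeletonDataset:
    """Subjects x voxels FA feature matrix bound to a voxel index."""

    features: np.ndarray
    subject_ids: tuple
    voxel_index: VoxelIndex

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=float)
        if features.ndim != 2:
            raise DimensionError("features must be 2D (subjects x voxels)")
        if features.shape[1] != len(self.voxel_index):
            raise DimensionError(
                f"feature columns ({features.shape[1]}) != voxel index length "
                f"({len(self.voxel_index)})"
            )
        if len(self.subject_ids) != features.shape[0]:
            raise DimensionError("subject_ids length != number of rows")
        if not np.isfinite(features).all():
            raise DataError("features contain non-finite values")
        out_of_range = (features < -FA_TOL) | (features > 1 + FA_TOL)
        if out_of_range.any():
            logger.warning(
                "clipping %d FA values outside [0, 1]", int(out_of_range.sum())
            )
            features = np.clip(features, 0.0, 1.0)
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class Tractogram:
    """Streamlines as point sequences in world (mm) coordinates."""

    streamlines: tuple
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        cleaned = []
        for i, s in enumerate(self.streamlines):
            arr = np.asarray(s, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise DimensionError(f"streamline {i} is not an (n, 3) array")
            if arr.shape[0] < 2:
                raise DimensionError(f"streamline {i} has fewer than 2 points")
            if not np.isfinite(arr).all():
                raise DataError(f"streamline {i} has non-finite coordinates")
            cleaned.append(arr)
        object.__setattr__(self, "streamlines", tuple(cleaned))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    def __len__(self) -> int:
        return len(self.streamlines)


# ---------------------------------------------------------------------------
# volume I/O


def load_volume(path: str | Path) -> Volume:
    """Load a 3D NIfTI-1 image (optionally gzipped) as a :class:`Volume`.

    Integer-typed images keep their exact labels; floating images are read
    as float64.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI image at {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D image, got shape {img.shape}"
        )
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    return Volume(data=data, affine=np.asarray(img.affine))


def save_volume(volume: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` to NIfTI-1; integer grids stay integer."""
    data = volume.data
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    nib.save(nib.Nifti1Image(data, volume.affine), str(path))


def extract_matrix(
    volumes: Sequence[Volume],
    mask: Volume,
    subject_ids: Sequence | None = None,
) -> SkeletonDataset:
    """Stack per-subject volumes into a subjects x voxels matrix at mask voxels.

    Row ``i`` holds subject ``i``'s values at the mask voxels in
    :class:`VoxelIndex` (lexicographic) order.
    """
    if not volumes:
        raise DegenerateInputError("no volumes given")
    index = VoxelIndex.from_mask(mask)
    for i, v in enumerate(volumes):
        if not v.same_geometry(mask):
            raise GeometryError(
                f"volume {i} geometry (shape {v.shape}) does not match mask"
            )
    idx = index.as_tuple_index()
    features = np.stack([np.asarray(v.data, dtype=float)[idx] for v in volumes])
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(len(volumes))]
    return SkeletonDataset(
        features=features, subject_ids=tuple(subject_ids), voxel_index=index
    )


def project_map(
    values: np.ndarray, voxel_index: VoxelIndex, fill: float = 0.0
) -> Volume:
    """Render per-voxel scalars back into a volume; ``fill`` elsewhere."""
    values = np.asarray(values)
    if values.shape != (len(voxel_index),):
        raise DimensionError(
            f"got {values.shape[0] if values.ndim == 1 else values.shape} "
            f"values for {len(voxel_index)} indexed voxels"
        )
    fill_is_int = float(fill) == int(fill) if np.isfinite(fill) else False
    dtype = values.dtype if np.issubdtype(values.dtype, np.integer) and fill_is_int else float
    grid = np.full(voxel_index.shape, fill, dtype=dtype)
    grid[voxel_index.as_tuple_index()] = values
    return Volume(data=grid, affine=voxel_index.affine)


# ---------------------------------------------------------------------------
# world <-> voxel


def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world (mm) points to 0-based voxel indices.

    Rounds half away from zero after applying the inverse affine, i.e. each
    point is attributed to the voxel whose centre is nearest.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    continuous = points @ inv[:3, :3].T + inv[:3, 3]
    return np.sign(continuous) * np.floor(np.abs(continuous) + 0.5)


def voxel_to_world(voxels: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices to the world (mm) coordinates of their centres."""
    voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
    affine = np.asarray(affine, dtype=float)
    return voxels @ affine[:3, :3].T + affine[:3, 3]


# ---------------------------------------------------------------------------
# streamline I/O


def read_streamlines(path: str | Path) -> Tractogram:
    """Read a TCK or TRK file; streamlines are returned in world mm (RAS+)."""
    path = Path(path)
    try:
        tfile = nib.streamlines.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read streamline file {path}: {exc}") from exc
    sl = [np.asarray(s, dtype=float) for s in tfile.streamlines]
    affine = np.eye(4)
    header = getattr(tfile, "header", {}) or {}
    vox2ras = header.get("voxel_to_rasmm")
    if vox2ras is not None and np.isfinite(np.asarray(vox2ras, float)).all():
        affine = np.asarray(vox2ras, dtype=float)
    if not sl:
        return Tractogram(streamlines=(), affine=affine)
    return Tractogram(streamlines=tuple(sl), affine=affine)


def write_streamlines(
    tractogram: Tractogram,
    path: str | Path,
    reference: Volume | None = None,
) -> None:
    """Write streamlines to TCK or TRK (chosen by extension).

    TRK stores grid metadata in its header, so a ``reference`` volume is
    required for ``.trk`` output.
    """
    path = Path(path)
    nib_tg = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".tck"):
        nib.streamlines.save(nib_tg, str(path))
    elif suffix.endswith(".trk"):
        if reference is None:
            raise FormatError("TRK output requires a reference volume")
        header = {
            "voxel_to_rasmm": reference.affine.astype(np.float32),
            "voxel_sizes": np.sqrt(
                (reference.affine[:3, :3] ** 2).sum(axis=0)
            ).astype(np.float32),
            "dimensions": np.asarray(reference.shape, dtype=np.uint16),
        }
        nib.streamlines.save(nib_tg, str(path), header=header)
    else:
        raise FormatError(f"unsupported streamline format: {path.name}")


# ---------------------------------------------------------------------------
# tabular I/O


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated subject table (subject_id, score, covariates)."""
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns or "score" not in df.columns:
        raise FormatError(
            f"{path}: expected a header with at least 'subject_id' and 'score'"
        )
    if df["score"].isna().any():
        raise DataError(f"{path}: missing scores")
    return df
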