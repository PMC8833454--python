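"""Streamline-based structural disconnection relative to a damage map.

Given a tractogram, a parcellation (e.g. an 84-region Desikan-Killiany-style
labelling) and a binary statistical map, this module counts, per unordered
region pair, how many streamlines connect the pair at all (``total``) and how
many of those pass through the map (``crossing``), and derives proportions
and per-region totals. The absolute crossing count is the primary statistic;
proportions are always reported alongside, since proportions alone would
overstate complete disconnection of faintly connected pairs.

A streamline "crosses" the map iff at least one of its points maps to a mask
voxel under nearest-voxel-centre lookup. Endpoints falling on background are
snapped to the nearest labelled voxel within a search radius (default 3 mm);
streamlines with an unassignable endpoint go to an explicit unassigned bucket
rather than being silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DataError, ParameterError
from .io import Tractogram, Volume, world_to_voxel

__all__ = [
    "DisconnectionMatrix",
    "streamlines_crossing_mask",
    "assign_endpoints",
    "build_disconnection_matrix",
    "report_edges",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class DisconnectionMatrix:
    """Symmetric region-pair streamline counts and derived proportions."""

    labels: np.ndarray
    total_counts: np.ndarray
    crossing_counts: np.ndarray
    proportion: np.ndarray
    region_total_crossing: np.ndarray
    region_proportion: np.ndarray
    n_unassigned: int
    n_unassigned_crossing: int

    def __post_init__(self) -> None:
        r = len(self.labels)
        for name in ("total_counts", "crossing_counts", "proportion"):
            m = getattr(self, name)
            if m.shape != (r, r):
                raise ParameterError(f"{name} must be {r}x{r}")
        if (self.crossing_counts > self.total_counts).any():
            raise DataError("crossing counts exceed totals")

    def region_table(self) -> pd.DataFrame:
        """Per-region disconnection totals, strongest first."""
        df = pd.DataFrame(
            {
                "region": self.labels,
                "n_disconnections": self.region_total_crossing,
                "fibre_damage_pct": 100.0 * self.region_proportion,
            }
        )
        return df.sort_values(
            ["n_disconnections", "region"], ascending=[False, True]
        ).reset_index(drop=True)


def _points_to_voxels(
    points: np.ndarray, volume: Volume
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest voxel of each world point plus an in-grid validity mask."""
    vox = world_to_voxel(points, volume.affine).astype(int)
    shape = np.asarray(volume.shape)
    ok = ((vox >= 0) & (vox < shape)).all(axis=1)
    return vox, ok


def streamlines_crossing_mask(tractogram: Tractogram, mask: Volume) -> set[int]:
    """Indices of streamlines with at least one point in a mask voxel."""
    if not mask.is_binary():
        raise DataError("crossing mask must be binary")
    crossing: set[int] = set()
    data = mask.data > 0
    for i, line in enumerate(tractogram.streamlines):
        vox, ok = _points_to_voxels(line, mask)
        if ok.any() and data[tuple(vox[ok].T)].any():
            crossing.add(i)
    return crossing


def assign_endpoints(
    tractogram: Tractogram,
    parcellation: Volume,
    search_radius_mm: float = 3.0,
) -> np.ndarray:
    """Unordered region pair per streamline, or (-1, -1) when unassignable.

    Each endpoint takes the parcel label at its nearest voxel; endpoints on
    background are snapped to the nearest labelled voxel within
    ``search_radius_mm`` (Euclidean distance in mm, voxel spacing from the
    affine). Pairs are stored with the smaller label first.
    """
    if search_radius_mm < 0:
        raise ParameterError("search_radius_mm must be non-negative")
    labels_grid = np.asarray(parcellation.data)
    if not np.issubdtype(labels_grid.dtype, np.integer):
        raise DataError("parcellation must be integer-labelled")
    spacing = np.sqrt((parcellation.affine[:3, :3] ** 2).sum(axis=0))
    distances, nearest = ndimage.distance_transform_edt(
        labels_grid == 0, sampling=spacing, return_indices=True
    )

    def label_at(point: np.ndarray) -> int:
        vox, ok = _points_to_voxels(point[None, :], parcellation)
        if not ok[0]:
            return UNASSIGNED
        vox = tuple(vox[0])
        lab = int(labels_grid[vox])
        if lab > 0:
            return lab
        if distances[vox] <= search_radius_mm:
            snapped = tuple(nearest[(slice(None),) + vox])
            return int(labels_grid[snapped])
        return UNASSIGNED

    pairs = np.empty((len(tractogram), 2), dtype=int)
    for i, line in enumerate(tractogram.streamlines):
        a = label_at(line[0])
        b = label_at(line[-1])
        if a == UNASSIGNED or b == UNASSIGNED:
            pairs[i] = (UNASSIGNED, UNASSIGNED)
        else:
            pairs[i] = (min(a, b), max(a, b))
    return pairs


def build_disconnection_matrix(
    tractogram: Tractogram,
    crossing: set[int],
    assignments: np.ndarray,
    labels: np.ndarray | None = None,
) -> DisconnectionMatrix:
    """Aggregate endpoint assignments and mask crossings into region-pair counts.

    Intra-region streamlines (both endpoints in one parcel) are kept and
    count once toward that region's totals. ``labels`` fixes the matrix
    ordering; by default the sorted set of assigned labels is used.
    """
    assignments = np.asarray(assignments, dtype=int).reshape(-1, 2)
    if len(assignments) != len(tractogram):
        raise ParameterError("one assignment per streamline required")
    assigned = assignments[:, 0] != UNASSIGNED
    if labels is None:
        labels = np.unique(assignments[assigned])
    labels = np.asarray(sorted(int(l) for l in labels))
    pos = {lab: i for i, lab in enumerate(labels)}
    r = len(labels)
    total = np.zeros((r, r), dtype=int)
    cross = np.zeros((r, r), dtype=int)
    n_unassigned = int((~assigned).sum())
    n_unassigned_crossing = sum(1 for i in crossing if not assigned[i])
    for i, (a, b) in enumerate(assignments):
        if not assigned[i] or a not in pos or b not in pos:
            continue
        ia, ib = pos[a], pos[b]
        total[ia, ib] += 1
        if ia != ib:
            total[ib, ia] += 1
        if i in crossing:
            cross[ia, ib] += 1
            if ia != ib:
                cross[ib, ia] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        proportion = np.where(total > 0, cross / np.maximum(total, 1), 0.0)
    region_cross = cross.sum(axis=1)
    region_total_all = total.sum(axis=1)
    region_prop = np.where(
        region_total_all > 0, region_cross / np.maximum(region_total_all, 1), 0.0
    )
    return DisconnectionMatrix(
        labels=labels,
        total_counts=total,
        crossing_counts=cross,
        proportion=proportion,
        region_total_crossing=region_cross,
        region_proportion=region_prop,
        n_unassigned=n_unassigned,
        n_unassigned_crossing=n_unassigned_crossing,
    )


def report_edges(matrix: DisconnectionMatrix, min_count: int = 0) -> pd.DataFrame:
    """Unordered region pairs with ``crossing >= min_count``, strongest first.

    Ordering is deterministic: crossing count descending, then the label pair
    lexicographically.
    """
    rows = []
    r = len(matrix.labels)
    for i in range(r):
        for j in range(i, r):
            total = matrix.total_counts[i, j]
            crossing = matrix.crossing_counts[i, j]
            if total == 0 or crossing < min_count:
                continue
            rows.append(
                {
                    "region_a": int(matrix.labels[i]),
                    "region_b": int(matrix.labels[j]),
                    "crossing": int(crossing),
                    "total": int(total),
                    "proportion": float(matrix.proportion[i, j]),
                }
            )
    df = pd.DataFrame(
        rows, columns=["region_a", "region_b", "crossing", "total", "proportion"]
    )
    if df.empty:
        return df
    return df.sort_values(
        ["crossing", "region_a", "region_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
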