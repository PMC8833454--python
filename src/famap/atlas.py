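"""Overlap of a significance map with probabilistic white-matter tract maps.

Probabilistic tract maps (values in [0, 1], one per named tract, grouped into
association / projection / commissural categories) are binarized at an
inclusive probability cutoff (default P >= 0.4), intersected with the
significant-voxel mask, and the overlapping volume in mm^3 is reported per
tract. Tracts with less than a floor volume of overlap (default 20 mm^3) are
omitted from the report.

No atlas is bundled; maps are user-supplied NIfTI files declared in a
manifest TSV (tract_name, category, path).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, GeometryError, ParameterError
from .io import Volume, load_volume

__all__ = ["TractAtlas", "binarize_map", "overlap_report"]


@dataclass(frozen=True)
class TractAtlas:
    """Named probabilistic tract maps with per-tract categories."""

    maps: dict
    categories: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.maps:
            raise ParameterError("atlas has no maps")
        ref = next(iter(self.maps.values()))
        for name, vol in self.maps.items():
            if not vol.same_geometry(ref):
                raise GeometryError(f"tract map {name!r} geometry differs")
            if vol.data.min() < 0 or vol.data.max() > 1 + 1e-6:
                raise DataError(f"tract map {name!r} is not probabilistic")
        object.__setattr__(
            self,
            "categories",
            {name: self.categories.get(name, "unspecified") for name in self.maps},
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return next(iter(self.maps.values())).voxel_volume_mm3

    @classmethod
    def from_manifest(cls, manifest_path: str | Path) -> "TractAtlas":
        """Load maps listed in a TSV manifest (tract_name, category, path)."""
        manifest_path = Path(manifest_path)
        table = pd.read_csv(manifest_path, sep="\t")
        required = {"tract_name", "category", "path"}
        if not required.issubset(table.columns):
            raise DataError(f"manifest must have columns {sorted(required)}")
        maps = {}
        categories = {}
        for _, row in table.iterrows():
            path = Path(row["path"])
            if not path.is_absolute():
                path = manifest_path.parent / path
            maps[row["tract_name"]] = load_volume(path)
            categories[row["tract_name"]] = row["category"]
        return cls(maps=maps, categories=categories)


def binarize_map(prob_map: Volume, threshold: float = 0.4) -> Volume:
    """Threshold a probabilistic map: voxel = 1 iff probability >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError("threshold must lie in [0, 1]")
    return Volume(
        (np.asarray(prob_map.data) >= threshold).astype(np.int16), prob_map.affine
    )


def overlap_report(
    sig_mask: Volume,
    atlas: TractAtlas,
    min_volume_mm3: float = 20.0,
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Per-tract overlap volume between the significance mask and the atlas.

    Overlap is the voxel count of (sig AND binarized tract) times the voxel
    volume from the affine. Rows under ``min_volume_mm3`` are omitted; output
    is sorted by category then tract name.
    """
    if not sig_mask.is_binary():
        raise DataError("significance mask must be binary")
    rows = []
    sig = sig_mask.data > 0
    for name, prob in atlas.maps.items():
        if not prob.same_geometry(sig_mask):
            raise GeometryError(f"tract map {name!r} geometry differs from mask")
        tract = binarize_map(prob, threshold).data > 0
        overlap = float((sig & tract).sum()) * atlas.voxel_volume_mm3
        if overlap < min_volume_mm3:
            continue
        rows.append(
            {
                "tract": name,
                "category": atlas.categories[name],
                "overlap_mm3": overlap,
            }
        )
    df = pd.DataFrame(rows, columns=["tract", "category", "overlap_mm3"])
    if df.empty:
        return df
    return df.sort_values(["category", "tract"]).reset_index(drop=True)
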