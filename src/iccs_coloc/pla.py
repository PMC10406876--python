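"""Puncta counting in confocal z-stacks.

Threshold, 3D connected-component labeling, size filter.  Touching
puncta are counted as one component (no watershed splitting); this is a
known bias at high spot density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import DegenerateInputError, ValidationError

_CONNECTIVITY_3D = {6: 1, 18: 2, 26: 3}


@dataclass
class SpotStack:
    """A (z, y, x) intensity stack with physical voxel size in nm."""

    voxels: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (200.0, 40.0, 40.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError("voxels must be 3D (z, y, x)")
        if self.voxels.shape[0] < 1:
            raise ValidationError("need at least one z-plane")
        arr = np.asarray(self.voxels, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValidationError("intensities must be finite and >= 0")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValidationError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SpotCountResult:
    count: int
    centroids: list[tuple[float, float, float]]
    volumes_vox: list[int]
    threshold_used: float

    def __post_init__(self) -> None:
        if not (self.count == len(self.centroids) == len(self.volumes_vox)):
            raise ValidationError("count must equal number of centroids and volumes")


def count_spots(
    stack: SpotStack,
    threshold: float | str = "otsu",
    min_size_vox: int = 4,
    connectivity: int = 26,
    roi: np.ndarray | None = None,
) -> SpotCountResult:
    """Count bright puncta in a z-stack.

    Binarize ``voxels > threshold`` (optionally restricted to a 2D ROI
    applied to every plane), label components at 6/18/26 connectivity,
    discard components below ``min_size_vox``, and return results sorted
    by descending volume (ties broken by centroid for determinism).
    """
    if min_size_vox <= 0:
        raise ValidationError("min_size_vox must be positive")
    if connectivity not in _CONNECTIVITY_3D:
        raise ValidationError("connectivity must be one of 6, 18, 26")
    vox = np.asarray(stack.voxels, dtype=float)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != vox.shape[1:]:
            raise ValidationError("roi shape must match (y, x) plane shape")
        region = vox[:, roi]
    else:
        region = vox
    if threshold == "otsu":
        if np.ptp(region) == 0:
            raise DegenerateInputError("constant stack: Otsu threshold undefined")
        thr = float(threshold_otsu(region.ravel()))
    else:
        thr = float(threshold)
    binary = vox > thr
    if roi is not None:
        binary &= roi[None, :, :]
    labels = label(binary, connectivity=_CONNECTIVITY_3D[connectivity])
    spots = []
    for prop in regionprops(labels):
        if prop.area >= min_size_vox:
            spots.append((int(prop.area), tuple(float(c) for c in prop.centroid)))
    spots.sort(key=lambda s: (-s[0], s[1]))
    return SpotCountResult(
        count=len(spots),
        centroids=[c for _, c in spots],
        volumes_vox=[v for v, _ in spots],
        threshold_used=thr,
    )


def summarize_counts(
    results: list[SpotCountResult],
    labels: list[str],
) -> pd.DataFrame:
    """Tidy per-cell count table: columns (group, cell_id, count).

    ``cell_id`` numbers cells within each group in input order.
    """
    if len(results) != len(labels):
        raise ValidationError(
            f"results ({len(results)}) and labels ({len(labels)}) length mismatch"
        )
    rows = []
    seen: dict[str, int] = {}
    for res, grp in zip(results, labels):
        idx = seen.get(grp, 0)
        seen[grp] = idx + 1
        rows.append({"group": grp, "cell_id": idx, "count": res.count})
    df = pd.DataFrame(rows, columns=["group", "cell_id", "count"])
    return df.sort_values(["group", "cell_id"], kind="stable").reset_index(drop=True)
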