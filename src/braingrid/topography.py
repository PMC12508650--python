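"""Per-patient tumour topography and group-level infiltration mapping.

Quantities computed here:

* ``occupancy_profile`` — which of the 48 grid voxels a tumour infiltrates
  and with how much volume; the number of infiltrated grid voxels is the
  invasiveness metric used downstream.
* ``occurrence_map`` — the occurrence-weighted frequency map of a patient
  group: at each template voxel, the percentage of the group's tumours
  overlapping it.
* ``bundle_infiltration`` — overlap summaries between a group frequency map
  and a white-matter bundle mask (AF, SLF2-3, IFOF, CST, FAT, Ci, per side).
* ``laterality`` / ``volume_ml`` — hemispheric dominance call and volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, GeometryError
from .grid import BrainGrid, GridVoxelLabel

logger = logging.getLogger(__name__)

__all__ = [
    "TumourMask",
    "OccupancyProfile",
    "FrequencyMap",
    "BundleProfile",
    "LateralityCall",
    "occupancy_profile",
    "occurrence_map",
    "minmax_frequency",
    "bundle_infiltration",
    "laterality",
    "volume_ml",
]

BUNDLE_NAMES = ("AF", "SLF2-3", "IFOF", "CST", "FAT", "Ci")


@dataclass
class TumourMask:
    """A binary lesion segmentation in template space."""

    data: np.ndarray
    affine: np.ndarray
    patient_id: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"mask for {self.patient_id} must be 3D, got {self.data.ndim}D")
        uniq = np.unique(self.data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise GeometryError(f"mask for {self.patient_id} is not binary")
        self.data = self.data.astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class OccupancyProfile:
    """Grid voxels infiltrated by one tumour, with per-cell overlap volume."""

    patient_id: str
    overlap_mm3: dict[GridVoxelLabel, float]
    total_volume_mm3: float

    @property
    def labels(self) -> frozenset[GridVoxelLabel]:
        return frozenset(self.overlap_mm3)

    @property
    def bg_voxel_count(self) -> int:
        return len(self.overlap_mm3)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": self.patient_id, "label": lab.name, "overlap_mm3": vol}
            for lab, vol in sorted(self.overlap_mm3.items())
        ]
        return pd.DataFrame(rows, columns=["patient_id", "label", "overlap_mm3"])


@dataclass
class FrequencyMap:
    """Occurrence-weighted infiltration map for one molecular subgroup."""

    group: str
    n: int
    data: np.ndarray  # voxelwise percent of patients infiltrating, 0..100
    affine: np.ndarray
    cell_table: pd.DataFrame  # columns: label, n_infiltrated, percent


@dataclass
class BundleProfile:
    """Group-level infiltration summary of one white-matter bundle."""

    bundle: str
    covered_fraction: float  # fraction of bundle voxels with frequency > 0
    mean_frequency: float  # mean group frequency over bundle voxels, percent
    max_frequency: float
    per_patient_infiltrated: list[bool] = field(default_factory=list)


@dataclass
class LateralityCall:
    left_fraction: float
    call: str  # 'L' | 'R' | 'B'


def _check_geometry(mask: TumourMask, grid: BrainGrid) -> None:
    geom = grid.geometry
    if mask.data.shape != geom.shape or not np.allclose(mask.affine, geom.affine, atol=1e-4):
        raise GeometryError(
            f"mask {mask.patient_id} not on the template lattice; resample first "
            "(see braingrid.io.resample_mask_to)"
        )


def occupancy_profile(
    mask: TumourMask, grid: BrainGrid, min_overlap_mm3: float = 0.0
) -> OccupancyProfile:
    """Grid-voxel occupancy of one tumour.

    A grid voxel counts as infiltrated when the tumour's overlap volume with
    it exceeds ``min_overlap_mm3`` (default 0: any shared voxel counts).
    Per-cell overlap volumes always sum to the total tumour volume regardless
    of the threshold applied to the reported label set.
    """
    if mask.n_voxels == 0:
        raise EmptyInputError(f"mask {mask.patient_id} is empty")
    _check_geometry(mask, grid)
    codes = grid.rasterize()
    vv = grid.geometry.voxel_volume_mm3
    counts = np.bincount(codes[mask.data], minlength=49)
    overlap = {
        GridVoxelLabel.from_code(c): float(counts[c] * vv)
        for c in range(1, 49)
        if counts[c] > 0 and counts[c] * vv > min_overlap_mm3
    }
    if not overlap:
        # threshold swallowed everything; keep the largest cell so the
        # profile is never silently empty for a nonempty tumour
        c = int(np.argmax(counts[1:]) + 1)
        logger.warning(
            "min_overlap_mm3=%.1f removed all cells for %s; reporting the largest",
            min_overlap_mm3,
            mask.patient_id,
        )
        overlap = {GridVoxelLabel.from_code(c): float(counts[c] * vv)}
    return OccupancyProfile(
        patient_id=mask.patient_id,
        overlap_mm3=overlap,
        total_volume_mm3=float(mask.n_voxels * vv),
    )


def occurrence_map(masks: list[TumourMask], grid: BrainGrid, group: str = "all") -> FrequencyMap:
    """Occurrence-weighted frequency map of a group of tumours.

    Voxel value = 100 x (number of tumours overlapping the voxel) / n, so all
    values are multiples of 100/n and the minimum nonzero frequency of a group
    of n patients is exactly 100/n.
    """
    if not masks:
        raise EmptyInputError("occurrence_map requires at least one mask")
    for m in masks:
        _check_geometry(m, grid)
    n = len(masks)
    counts = np.zeros(grid.geometry.shape, dtype=np.int32)
    for m in masks:
        counts += m.data
    data = counts.astype(float) * (100.0 / n)

    codes = grid.rasterize()
    cell_counts = {c: 0 for c in range(1, 49)}
    for m in masks:
        present = np.unique(codes[m.data])
        for c in present:
            cell_counts[int(c)] += 1
    rows = [
        {
            "label": GridVoxelLabel.from_code(c).name,
            "n_infiltrated": cell_counts[c],
            "percent": 100.0 * cell_counts[c] / n,
        }
        for c in range(1, 49)
    ]
    table = pd.DataFrame(rows)
    return FrequencyMap(group=group, n=n, data=data, affine=grid.geometry.affine, cell_table=table)


def minmax_frequency(fmap: FrequencyMap) -> tuple[float, float]:
    """(min nonzero frequency, max frequency) of a map, in percent."""
    positive = fmap.data[fmap.data > 0]
    if positive.size == 0:
        raise EmptyInputError("frequency map has no infiltrated voxel")
    return float(positive.min()), float(fmap.data.max())


def bundle_infiltration(fmap: FrequencyMap, bundle_mask: np.ndarray, name: str) -> BundleProfile:
    """Summarize how much of a white-matter bundle the group map infiltrates."""
    bundle = np.asarray(bundle_mask).astype(bool)
    if bundle.shape != fmap.data.shape:
        raise GeometryError(f"bundle {name} shape {bundle.shape} != map shape {fmap.data.shape}")
    nb = int(bundle.sum())
    if nb == 0:
        raise EmptyInputError(f"bundle mask {name} is empty")
    vals = fmap.data[bundle]
    return BundleProfile(
        bundle=name,
        covered_fraction=float((vals > 0).mean()),
        mean_frequency=float(vals.mean()),
        max_frequency=float(vals.max()),
    )


def laterality(
    mask: TumourMask, bilateral_threshold: float = 0.05
) -> LateralityCall:
    """Hemispheric dominance of a tumour from voxel centres' world x.

    Voxels at x < 0 count as left; the midline (x = 0) counts as right,
    consistent with the grid's half-open sagittal convention.  The call is
    'B' (bilateral) when the minority hemisphere holds at least
    ``bilateral_threshold`` of the tumour volume.
    """
    if mask.n_voxels == 0:
        raise EmptyInputError(f"mask {mask.patient_id} is empty")
    idx = np.argwhere(mask.data).astype(float)
    world_x = (
        idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    )[:, 0]
    left = float((world_x < 0).mean())
    minority = min(left, 1.0 - left)
    if minority >= bilateral_threshold:
        call = "B"
    else:
        call = "L" if left >= 0.5 else "R"
    return LateralityCall(left_fraction=left, call=call)


def volume_ml(mask: TumourMask) -> float:
    """Tumour volume in millilitres (nonzero voxels x voxel volume)."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


def cohort_summary(
    masks: list[TumourMask], grid: BrainGrid, min_overlap_mm3: float = 0.0,
    bilateral_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-patient summary: invasiveness, volume and laterality."""
    rows = []
    for m in masks:
        prof = occupancy_profile(m, grid, min_overlap_mm3)
        lat = laterality(m, bilateral_threshold)
        rows.append(
            {
                "patient_id": m.patient_id,
                "bg_voxel_count": prof.bg_voxel_count,
                "volume_ml": volume_ml(m),
                "laterality": lat.call,
            }
        )
    return pd.DataFrame(rows)
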