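"""The Brain-Grid: an orthogonal sub-lobar partition of template brain space.

Three axial, two coronal and three sagittal planes (world mm, e.g. MNI space)
cut the template bounding box into ``4 x 3 x 4 = 48`` labelled grid voxels.
Labels follow the ``A{a}C{c}S{s}`` convention: axial slabs A1..A4 numbered
inferior to superior, coronal slabs C1..C3 anterior to posterior, sagittal
slabs S1..S4 left to right.  The middle sagittal plane is pinned to the
midline (x = 0) so S1/S2 lie in the left hemisphere and S3/S4 in the right.

Slab intervals are half-open: a point exactly on a cutting plane belongs to
the higher-index slab.  In particular a point on the midline has s-index 3.

The partition is defined in *world* coordinates; any affine (including the
MNI152 radiological-storage convention with a negative x step) is supported
because voxel centres are mapped through the affine before classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from nibabel.affines import apply_affine

from .errors import GridConfigurationError, OutOfBoundsError

__all__ = [
    "PlaneSet",
    "GridVoxelLabel",
    "TemplateGeometry",
    "BrainGrid",
    "build_grid",
    "label_of",
    "rasterize_grid",
    "mni152_2mm_geometry",
    "default_plane_set",
    "ALL_LABEL_NAMES",
]


@dataclass(frozen=True)
class PlaneSet:
    """World-mm coordinates of the 8 cutting planes.

    ``axial_mm``: 3 z-coordinates, ``coronal_mm``: 2 y-coordinates,
    ``sagittal_mm``: 3 x-coordinates with the middle one pinned to 0.
    All sequences strictly increasing.
    """

    axial_mm: tuple[float, float, float]
    coronal_mm: tuple[float, float]
    sagittal_mm: tuple[float, float, float]

    def __post_init__(self):
        ax = tuple(float(v) for v in self.axial_mm)
        co = tuple(float(v) for v in self.coronal_mm)
        sa = tuple(float(v) for v in self.sagittal_mm)
        object.__setattr__(self, "axial_mm", ax)
        object.__setattr__(self, "coronal_mm", co)
        object.__setattr__(self, "sagittal_mm", sa)
        if len(ax) != 3 or len(co) != 2 or len(sa) != 3:
            raise GridConfigurationError(
                "plane counts must be 3 axial / 2 coronal / 3 sagittal"
            )
        for name, seq in (("axial", ax), ("coronal", co), ("sagittal", sa)):
            if not all(np.isfinite(seq)):
                raise GridConfigurationError(f"{name} planes must be finite")
            if not all(a < b for a, b in zip(seq, seq[1:])):
                raise GridConfigurationError(f"{name} planes must be strictly increasing")
        if sa[1] != 0.0:
            raise GridConfigurationError("middle sagittal plane must sit on the midline x=0")


@dataclass(frozen=True, order=True)
class GridVoxelLabel:
    """One of the 48 sub-lobar grid voxels, identified by slab indices."""

    a_index: int  # 1..4, inferior -> superior
    c_index: int  # 1..3, anterior -> posterior
    s_index: int  # 1..4, left -> right

    def __post_init__(self):
        if not (1 <= self.a_index <= 4 and 1 <= self.c_index <= 3 and 1 <= self.s_index <= 4):
            raise GridConfigurationError(f"slab indices out of range: {self}")

    @property
    def hemisphere(self) -> str:
        """'L' for S1/S2 (x < 0), 'R' for S3/S4."""
        return "L" if self.s_index <= 2 else "R"

    @property
    def name(self) -> str:
        return f"A{self.a_index}C{self.c_index}S{self.s_index}"

    @property
    def code(self) -> int:
        """Integer code 1..48 used in rasterized label volumes."""
        return (self.a_index - 1) * 12 + (self.c_index - 1) * 4 + self.s_index

    @classmethod
    def from_name(cls, name: str) -> "GridVoxelLabel":
        if len(name) != 6 or name[0] != "A" or name[2] != "C" or name[4] != "S":
            raise GridConfigurationError(f"malformed grid voxel name {name!r}")
        return cls(int(name[1]), int(name[3]), int(name[5]))

    @classmethod
    def from_code(cls, code: int) -> "GridVoxelLabel":
        if not 1 <= code <= 48:
            raise GridConfigurationError(f"grid voxel code out of range: {code}")
        z = code - 1
        return cls(z // 12 + 1, (z % 12) // 4 + 1, z % 4 + 1)

    def mirrored(self) -> "GridVoxelLabel":
        """The label of the cell reflected through the midline."""
        return GridVoxelLabel(self.a_index, self.c_index, 5 - self.s_index)


ALL_LABEL_NAMES: tuple[str, ...] = tuple(
    GridVoxelLabel.from_code(c).name for c in range(1, 49)
)


@dataclass(frozen=True)
class TemplateGeometry:
    """Shape and voxel-to-world affine of the reference template."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GridConfigurationError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GridConfigurationError("affine is singular")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world coordinates over voxel centres, per axis."""
        nx, ny, nz = self.shape
        corners = np.array(
            [[i, j, k] for i in (0, nx - 1) for j in (0, ny - 1) for k in (0, nz - 1)],
            dtype=float,
        )
        world = apply_affine(self.affine, corners)
        return world.min(axis=0), world.max(axis=0)

    def voxel_centres_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (*shape, 3)."""
        ii, jj, kk = np.meshgrid(
            *[np.arange(n) for n in self.shape], indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).astype(float)
        return apply_affine(self.affine, idx)


def mni152_2mm_geometry() -> TemplateGeometry:
    """Geometry of the standard 2 mm MNI152 template (91 x 109 x 91)."""
    affine = np.array(
        [
            [-2.0, 0.0, 0.0, 90.0],
            [0.0, 2.0, 0.0, -126.0],
            [0.0, 0.0, 2.0, -72.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return TemplateGeometry((91, 109, 91), affine)


def default_plane_set() -> PlaneSet:
    """Package default cutting planes on the MNI 2 mm template.

    These are documented *defaults* producing anatomically plausible sub-lobar
    slabs (inferior/temporal, insular, supra-insular and high-convexity axial
    slabs; prefrontal, central and retro-central coronal slabs; lateral and
    para-midline sagittal slabs).  They are a package choice, not published
    anatomical landmarks, and should be overridden via configuration when a
    specific landmark set is required.
    """
    return PlaneSet(axial_mm=(-24.0, 4.0, 32.0), coronal_mm=(-38.0, 10.0), sagittal_mm=(-26.0, 0.0, 26.0))


class BrainGrid:
    """A rasterizable 48-cell partition of the template bounding box."""

    def __init__(self, planes: PlaneSet, geometry: TemplateGeometry):
        self.planes = planes
        self.geometry = geometry
        lo, hi = geometry.world_bounds()
        self._lo, self._hi = lo, hi
        for name, coords, axis in (
            ("axial", planes.axial_mm, 2),
            ("coronal", planes.coronal_mm, 1),
            ("sagittal", planes.sagittal_mm, 0),
        ):
            for c in coords:
                if not (lo[axis] < c < hi[axis]):
                    raise GridConfigurationError(
                        f"{name} plane at {c} mm lies outside the template "
                        f"bounding box [{lo[axis]}, {hi[axis]}]"
                    )
        self._label_volume: np.ndarray | None = None

    # -- classification ----------------------------------------------------

    def _indices_for(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized slab indices for an (n, 3) array of world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        # boundary points belong to the higher-index slab
        a = 1 + np.searchsorted(self.planes.axial_mm, z, side="right")
        s = 1 + np.searchsorted(self.planes.sagittal_mm, x, side="right")
        # c increases anterior -> posterior (decreasing y): count planes >= y
        c = 1 + (len(self.planes.coronal_mm) - np.searchsorted(self.planes.coronal_mm, y, side="left"))
        return a.astype(np.int64), c.astype(np.int64), s.astype(np.int64)

    def label_of(self, point) -> GridVoxelLabel:
        """Grid voxel containing a world-mm point; raises outside the box."""
        p = np.asarray(point, dtype=float)
        if p.shape != (3,):
            raise OutOfBoundsError("point must be a 3-vector of world mm")
        if np.any(p < self._lo - 1e-9) or np.any(p > self._hi + 1e-9):
            raise OutOfBoundsError(f"point {p.tolist()} outside template bounding box")
        a, c, s = self._indices_for(p[None, :])
        return GridVoxelLabel(int(a[0]), int(c[0]), int(s[0]))

    def rasterize(self) -> np.ndarray:
        """Integer label volume on the template lattice (codes 1..48)."""
        if self._label_volume is None:
            world = self.geometry.voxel_centres_world().reshape(-1, 3)
            a, c, s = self._indices_for(world)
            codes = (a - 1) * 12 + (c - 1) * 4 + s
            self._label_volume = codes.reshape(self.geometry.shape).astype(np.int16)
        return self._label_volume

    # -- bookkeeping -------------------------------------------------------

    @property
    def labels(self) -> tuple[GridVoxelLabel, ...]:
        return tuple(GridVoxelLabel.from_code(c) for c in range(1, 49))

    @property
    def cells(self) -> dict[GridVoxelLabel, tuple[tuple[float, float], ...]]:
        """World-space axis-aligned boxes per label: ((x0,x1),(y0,y1),(z0,z1)).

        Box edges follow the half-open slab convention; outermost edges are
        the template bounding box.
        """
        xa = (self._lo[0], *self.planes.sagittal_mm, self._hi[0])
        yb = (self._lo[1], *self.planes.coronal_mm, self._hi[1])
        za = (self._lo[2], *self.planes.axial_mm, self._hi[2])
        out = {}
        for lab in self.labels:
            s, c, a = lab.s_index, lab.c_index, lab.a_index
            xbox = (xa[s - 1], xa[s])
            # c=1 is the most anterior slab (largest y)
            ybox = (yb[3 - c], yb[4 - c])
            zbox = (za[a - 1], za[a])
            out[lab] = (xbox, ybox, zbox)
        return out

    def cell_centroid(self, label: GridVoxelLabel) -> np.ndarray:
        """World-mm centroid of a cell's bounding box."""
        (x0, x1), (y0, y1), (z0, z1) = self.cells[label]
        return np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0, (z0 + z1) / 2.0])

    def code_table(self) -> pd.DataFrame:
        """Code <-> label mapping emitted alongside rasterized volumes."""
        rows = [
            {
                "code": lab.code,
                "label": lab.name,
                "a_index": lab.a_index,
                "c_index": lab.c_index,
                "s_index": lab.s_index,
                "hemisphere": lab.hemisphere,
            }
            for lab in self.labels
        ]
        return pd.DataFrame(rows)


def build_grid(planes: PlaneSet, geometry: TemplateGeometry) -> BrainGrid:
    """Construct the 48-cell Brain-Grid for a plane set on a template."""
    return BrainGrid(planes, geometry)


def label_of(point, grid: BrainGrid) -> GridVoxelLabel:
    return grid.label_of(point)


def rasterize_grid(grid: BrainGrid) -> np.ndarray:
    return grid.rasterize()
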