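"""Grids, voxel images, VOI masks, mask algebra and inter-grid resampling.

All geometry lives in a fixed right-handed patient coordinate frame.
Positions are physical millimetres; ``origin`` is the position of the
*center* of voxel index (0, 0, 0); indices are 0-based.  No orientation
metadata beyond origin/spacing is carried: every grid is axis-aligned in
the same frame, which makes the exact fractional-overlap resampling below
separable per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Grid",
    "VoxelImage",
    "VOIMask",
    "FuzzyMask",
    "CompartmentSet",
    "mask_algebra",
    "resample_mask",
    "integrate_image",
    "mask_statistics",
]


@dataclass(frozen=True)
class Grid:
    """A regular axis-aligned 3-D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts ``(nx, ny, nz)``; every entry >= 1.
    spacing : tuple of float
        Voxel edge lengths ``(sx, sy, sz)`` in mm; every entry > 0.
    origin : tuple of float
        Position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("Grid is three-dimensional: shape/spacing/origin need 3 entries")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0 mm, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- derived geometry ---------------------------------------------------
    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 * 1e-3

    @property
    def voxel_volume_m3(self) -> float:
        return self.voxel_volume_mm3 * 1e-9

    @property
    def diagonal_mm(self) -> float:
        """Voxel space diagonal sqrt(sx^2 + sy^2 + sz^2) in mm."""
        return float(np.linalg.norm(self.spacing))

    def centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def extent_mm(self) -> tuple[tuple[float, float], ...]:
        """Outer (edge-to-edge) physical extent per axis, in mm."""
        return tuple(
            (self.origin[a] - self.spacing[a] / 2,
             self.origin[a] + self.spacing[a] * (self.shape[a] - 0.5))
            for a in range(3)
        )

    def index_of(self, point_mm) -> np.ndarray:
        """Continuous (fractional) voxel index of a physical point."""
        p = np.asarray(point_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def position_of(self, index) -> np.ndarray:
        """Physical position (mm) of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def contains_point(self, point_mm) -> bool:
        idx = self.index_of(point_mm)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.asarray(self.shape) - 0.5))

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _require_same_grid(a, b, what: str) -> None:
    if not a.grid.same_geometry(b.grid):
        raise ValueError(
            f"{what}: grids differ "
            f"(shape {a.grid.shape} spacing {a.grid.spacing} origin {a.grid.origin} vs "
            f"shape {b.grid.shape} spacing {b.grid.spacing} origin {b.grid.origin})"
        )


@dataclass
class VoxelImage:
    """A scalar field on a :class:`Grid` — activity (Bq/voxel) or dose (Gy)."""

    grid: Grid
    values: np.ndarray
    quantity: str = "activity"  # "activity" | "dose"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel values must be finite")
        if self.quantity == "activity" and np.any(self.values < 0):
            raise ValueError("activity values must be >= 0")

    def total(self) -> float:
        return float(self.values.sum())

    def scaled(self, factor: float) -> "VoxelImage":
        return VoxelImage(self.grid, self.values * factor, self.quantity)


@dataclass
class VOIMask:
    """Binary voxel membership for one volume of interest."""

    grid: Grid
    membership: np.ndarray
    label: str = "voi"

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership).astype(bool)
        if self.membership.shape != self.grid.shape:
            raise ValueError(
                f"membership shape {self.membership.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_ml

    def center_of_mass_mm(self) -> np.ndarray:
        if self.is_empty:
            raise ValueError(f"mask '{self.label}' is empty: center of mass undefined")
        idx = np.argwhere(self.membership)
        return self.grid.position_of(idx.mean(axis=0))


@dataclass
class FuzzyMask:
    """Fractional voxel membership in [0, 1] (e.g. a resampled or shifted VOI)."""

    grid: Grid
    weights: np.ndarray
    label: str = "voi"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.grid.shape:
            raise ValueError(
                f"weights shape {self.weights.shape} does not match grid {self.grid.shape}"
            )
        # tolerate tiny numeric overshoot from resampling arithmetic
        if self.weights.min() < -1e-9 or self.weights.max() > 1 + 1e-9:
            raise ValueError("fuzzy weights must lie in [0, 1]")
        np.clip(self.weights, 0.0, 1.0, out=self.weights)

    @property
    def volume_ml(self) -> float:
        return float(self.weights.sum()) * self.grid.voxel_volume_ml

    def threshold(self, level: float = 0.5) -> VOIMask:
        if not 0.0 < level < 1.0:
            raise ValueError("threshold level must lie in (0, 1)")
        return VOIMask(self.grid, self.weights >= level, self.label)


# ---------------------------------------------------------------------------
# mask algebra
# ---------------------------------------------------------------------------

_SET_OPS = {
    "union": np.logical_or,
    "intersection": np.logical_and,
    "difference": lambda a, b: np.logical_and(a, np.logical_not(b)),
}


def mask_algebra(a: VOIMask, b: VOIMask, op: str) -> VOIMask:
    """Voxelwise set operation on two masks sharing one grid."""
    if op not in _SET_OPS:
        raise ValueError(f"unknown op {op!r}; expected one of {sorted(_SET_OPS)}")
    _require_same_grid(a, b, f"mask_algebra({op})")
    out = _SET_OPS[op](a.membership, b.membership)
    return VOIMask(a.grid, out, f"({a.label} {op} {b.label})")


# ---------------------------------------------------------------------------
# resampling: exact separable fractional-volume overlap
# ---------------------------------------------------------------------------

def _overlap_matrix(src: Grid, dst: Grid, axis: int) -> np.ndarray:
    """Pairwise 1-D overlap lengths (mm) between source and target voxels."""
    cs, ct = src.centers(axis), dst.centers(axis)
    hs, ht = src.spacing[axis], dst.spacing[axis]
    lo = np.maximum(cs[:, None] - hs / 2, ct[None, :] - ht / 2)
    hi = np.minimum(cs[:, None] + hs / 2, ct[None, :] + ht / 2)
    return np.clip(hi - lo, 0.0, None)


def _separable_transfer(values: np.ndarray, src: Grid, dst: Grid, norm: str) -> np.ndarray:
    """Contract a source field with per-axis overlap matrices.

    norm="target": result is the fraction of each target voxel covered
    (volume-weighted average) — used for masks.
    norm="source": result redistributes source voxel content by the fraction
    of the source voxel inside each target voxel — conserves the total sum
    within the overlap region, used for activity integration.
    """
    out = np.asarray(values, dtype=float)
    for axis in range(3):
        m = _overlap_matrix(src, dst, axis)
        m = m / (dst.spacing[axis] if norm == "target" else src.spacing[axis])
        # contracted axis is always axis 0 after the previous tensordot rotated it away
        out = np.tensordot(out, m, axes=([0], [0]))
    return out


def resample_mask(mask: VOIMask | FuzzyMask, target: Grid, mode: str = "fractional") -> FuzzyMask:
    """Resample a mask onto another grid.

    ``fractional`` returns, per target voxel, the exact fraction of its
    volume covered by the source mask (axis-separable overlap integral);
    ``nearest`` looks the target voxel center up in the source grid.
    """
    values = mask.weights if isinstance(mask, FuzzyMask) else mask.membership.astype(float)
    src = mask.grid
    if mode == "fractional":
        w = _separable_transfer(values, src, target, norm="target")
        w = np.clip(w, 0.0, 1.0)
    elif mode == "nearest":
        idx, ok = [], []
        for a in range(3):
            ix = np.rint((target.centers(a) - src.origin[a]) / src.spacing[a]).astype(int)
            ok.append((ix >= 0) & (ix < src.shape[a]))
            idx.append(np.clip(ix, 0, src.shape[a] - 1))
        w = values[np.ix_(idx[0], idx[1], idx[2])].astype(float)
        w[~(ok[0][:, None, None] & ok[1][None, :, None] & ok[2][None, None, :])] = 0.0
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    if w.sum() == 0 and not (isinstance(mask, VOIMask) and mask.is_empty):
        warnings.warn(
            f"resample_mask: '{mask.label}' has no spatial overlap with the target grid",
            stacklevel=2,
        )
    return FuzzyMask(target, w, mask.label, provenance=f"resampled[{mode}]")


def integrate_image(image: VoxelImage, target: Grid) -> VoxelImage:
    """Integrate a per-voxel activity field into coarser target voxels.

    Each source voxel's content is split among target voxels by exact
    fractional volume overlap, so the total is conserved wherever the
    target grid covers the source grid.
    """
    vals = _separable_transfer(image.values, image.grid, target, norm="source")
    np.clip(vals, 0.0, None, out=vals)
    return VoxelImage(target, vals, image.quantity)


def mask_statistics(mask: VOIMask) -> dict:
    """Volume (ml), center of mass (mm) and index bounding box of a mask."""
    stats: dict = {"volume_ml": mask.volume_ml}
    if mask.is_empty:
        stats.update(center_of_mass_mm=None, bounding_box=None, empty=True)
        return stats
    idx = np.argwhere(mask.membership)
    stats["center_of_mass_mm"] = mask.center_of_mass_mm()
    stats["bounding_box"] = tuple(
        (int(idx[:, a].min()), int(idx[:, a].max())) for a in range(3)
    )
    stats["empty"] = False
    return stats


# ---------------------------------------------------------------------------
# liver compartments
# ---------------------------------------------------------------------------

@dataclass
class CompartmentSet:
    """Liver, liver-perfusion territories (LPTs) and tumors on one grid.

    Tumor masks are clipped to the liver; each tumor is assigned to the LPT
    containing the larger fraction of its voxels.  Non-tumoral volumes (NTVs)
    are derived by exact set difference, so no voxel is counted both as
    tumor and NTV.
    """

    liver: VOIMask
    lpts: list[VOIMask]
    tumors: list[VOIMask]
    tumor_lpt: list[int] = field(default_factory=list)

    @classmethod
    def assemble(cls, liver: VOIMask, lpts: list[VOIMask], tumors: list[VOIMask],
                 warn_uncovered: bool = True) -> "CompartmentSet":
        for m in [*lpts, *tumors]:
            _require_same_grid(liver, m, "CompartmentSet")
        clipped = [mask_algebra(t, liver, "intersection") for t in tumors]
        clipped = [VOIMask(liver.grid, c.membership, t.label) for c, t in zip(clipped, tumors)]
        assignment = []
        for t in clipped:
            overlaps = [np.logical_and(t.membership, l.membership).sum() for l in lpts]
            if t.is_empty or max(overlaps, default=0) == 0:
                raise ValueError(f"tumor '{t.label}' lies outside the liver/LPTs")
            assignment.append(int(np.argmax(overlaps)))
        if warn_uncovered and lpts:
            union = np.zeros(liver.grid.shape, dtype=bool)
            for l in lpts:
                union |= l.membership
            uncovered = liver.membership & ~union
            n = int(uncovered.sum())
            if n:
                warnings.warn(
                    f"{n * liver.grid.voxel_volume_ml:.1f} ml of liver is covered by no LPT; "
                    "kept in total-liver reports, excluded from per-LPT reports",
                    stacklevel=2,
                )
        return cls(liver, list(lpts), clipped, assignment)

    @property
    def grid(self) -> Grid:
        return self.liver.grid

    def tumor_union(self) -> VOIMask:
        out = np.zeros(self.grid.shape, dtype=bool)
        for t in self.tumors:
            out |= t.membership
        return VOIMask(self.grid, out, "tumors")

    def ntv_total(self) -> VOIMask:
        m = mask_algebra(self.liver, self.tumor_union(), "difference")
        m.label = "ntv-total"
        return m

    def ntv_of(self, lpt_index: int) -> VOIMask:
        lpt = self.lpts[lpt_index]
        tum = np.zeros(self.grid.shape, dtype=bool)
        for t, k in zip(self.tumors, self.tumor_lpt):
            if k == lpt_index:
                tum |= t.membership
        m = VOIMask(self.grid, lpt.membership & ~tum, f"ntv-{lpt.label}")
        return m

    def resampled_to(self, target: Grid, threshold: float = 0.5) -> "CompartmentSet":
        """Fractionally resample every mask onto another grid and binarize."""
        if self.grid.same_geometry(target):
            return self
        liver = resample_mask(self.liver, target).threshold(threshold)
        lpts = [resample_mask(m, target).threshold(threshold) for m in self.lpts]
        tumors = [resample_mask(m, target).threshold(threshold) for m in self.tumors]
        return CompartmentSet.assemble(liver, lpts, tumors, warn_uncovered=False)

    def lpt_volume_ratio(self, lpt_index: int) -> float:
        """LPT-to-whole-liver volume ratio, in [0, 1]."""
        if self.liver.is_empty:
            raise ValueError("liver mask is empty")
        return self.lpts[lpt_index].volume_ml / self.liver.volume_ml
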