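"""Digital-liver phantoms with known ground truth.

The phantom emulates the data a SIRT dosimetry study works from: binary
VOIs on a fine 1 mm "CBCT-like" grid (liver, perfusion territories,
tumors), a pre-treatment activity map on a coarse SPECT-like grid and a
post-treatment map on a PET-like grid.  Both maps start from the same
piecewise-constant fine-grid concentration field (background in normal
parenchyma, tnr x background inside each tumor); the post-treatment field
additionally multiplies each tumor by a *discrepancy factor* emulating
MAA-vs-microsphere mismatch (catheter repositioning, flow changes), and
both fields are renormalized per territory to the administered activity.
Imaging is emulated by an isotropic Gaussian blur on the fine grid
followed by exact integration into the coarse voxels, with optional
multiplicative Gaussian noise.  Tumor masks handed to the analysis are
displaced by a known residual misalignment relative to activity space, so
registration error is a controlled input rather than a simulation step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .dosimetry import DoseKernel
from .volumes import CompartmentSet, Grid, VOIMask, VoxelImage, integrate_image

__all__ = ["TumorSpec", "PhantomSpec", "Phantom", "PhantomTruth", "build_phantom",
           "regenerate_truth"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class TumorSpec:
    """One spherical tumor: geometry, uptake and controlled imperfections."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    tnr: float = 3.0                 # tumor-to-normal activity concentration ratio
    discrepancy: float = 1.0         # post-treatment concentration multiplier
    misalignment_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str | None = None

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("tumor radius must be positive")
        if self.tnr < 0 or self.discrepancy < 0:
            raise ValueError("tnr and discrepancy factor must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a phantom; identical spec + seed => identical phantom.

    Defaults describe a realistic treatment: a ~1740 ml ellipsoidal liver
    split by a sagittal plane into two perfusion territories, one tumor per
    territory (>= 5 ml each), ~1.5 GBq total administered activity, and
    effective imaging resolutions of 12 mm (SPECT-like) and 6 mm (PET-like)
    FWHM.
    """

    seed: int = 0
    liver_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    liver_semiaxes_mm: tuple[float, float, float] = (95.0, 70.0, 62.5)
    lpt_plane_x_mm: float = 15.0
    tumors: tuple[TumorSpec, ...] = (
        TumorSpec(center_mm=(-40.0, 10.0, 5.0), radius_mm=20.0),
        TumorSpec(center_mm=(45.0, -15.0, -8.0), radius_mm=14.0),
    )
    background_bq_per_ml: float = 1.0
    administered_gbq: tuple[float, ...] = (0.9, 0.6)
    pre_fwhm_mm: float = 12.0
    post_fwhm_mm: float = 6.0
    noise_sd: float = 0.0            # relative sd of multiplicative Gaussian noise
    fine_spacing_mm: float = 1.0
    pre_spacing_mm: tuple[float, float, float] = (4.8, 4.8, 4.8)
    post_spacing_mm: tuple[float, float, float] = (3.13, 3.13, 2.78)
    margin_mm: float = 36.0          # fine-grid margin around the liver (>= 3 x FWHM)
    min_tumor_ml: float = 5.0        # inclusion rule; set to 0 to disable

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.liver_semiaxes_mm):
            raise ValueError("liver semi-axes must be positive")
        if self.pre_fwhm_mm < 0 or self.post_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("fwhm and noise sd must be >= 0")
        if len(self.administered_gbq) != 2:
            raise ValueError("administered_gbq needs one entry per LPT (two LPTs)")


@dataclass
class PhantomTruth:
    """Ground truth, recomputable deterministically (noise-free) from the spec."""

    fine_activity_pre: VoxelImage
    fine_activity_post: VoxelImage
    mean_dose_pre: dict[str, float]
    mean_dose_post: dict[str, float]
    tumor_misalignment_mm: list[np.ndarray]
    tumor_discrepancy: list[float]
    lpt_energy_j: list[float]
    voi_doses_pre: dict[str, np.ndarray]
    voi_doses_post: dict[str, np.ndarray]


@dataclass
class Phantom:
    spec: PhantomSpec
    compartments: CompartmentSet      # masks as "observed" (tumors misaligned)
    true_compartments: CompartmentSet  # masks at their true position
    pre: VoxelImage                   # SPECT-like coarse activity map
    post: VoxelImage                  # PET-like coarse activity map
    truth: PhantomTruth


# ---------------------------------------------------------------------------

def _fine_grid(spec: PhantomSpec) -> Grid:
    half = np.asarray(spec.liver_semiaxes_mm) + spec.margin_mm
    h = spec.fine_spacing_mm
    shape = tuple(int(np.ceil(2 * e / h)) for e in half)
    origin = tuple(
        c - (n - 1) * h / 2.0 for c, n in zip(spec.liver_center_mm, shape)
    )
    return Grid(shape, (h, h, h), origin)


def _coarse_grid(fine: Grid, spacing: tuple[float, float, float]) -> Grid:
    ext = fine.extent_mm()
    shape = tuple(int(np.ceil((hi - lo) / s)) for (lo, hi), s in zip(ext, spacing))
    center = [(lo + hi) / 2.0 for lo, hi in ext]
    origin = tuple(c - (n - 1) * s / 2.0 for c, n, s in zip(center, shape, spacing))
    return Grid(shape, spacing, origin)


def _ellipsoid_mask(grid: Grid, center, semiaxes, label: str) -> VOIMask:
    x, y, z = (grid.centers(a) for a in range(3))
    cx, cy, cz = center
    ax, ay, az = semiaxes
    r2 = ((x[:, None, None] - cx) / ax) ** 2 \
        + ((y[None, :, None] - cy) / ay) ** 2 \
        + ((z[None, None, :] - cz) / az) ** 2
    return VOIMask(grid, r2 <= 1.0, label)


def _sphere_mask(grid: Grid, center, radius: float, label: str) -> VOIMask:
    return _ellipsoid_mask(grid, center, (radius, radius, radius), label)


def _validate_tumors(spec: PhantomSpec, grid: Grid, liver: VOIMask,
                     tumor_masks: list[VOIMask]) -> None:
    taken = np.zeros(grid.shape, dtype=bool)
    for t, m in zip(spec.tumors, tumor_masks):
        if np.any(m.membership & ~liver.membership):
            raise ValueError(f"tumor '{m.label}' extends outside the liver")
        if np.any(m.membership & taken):
            raise ValueError(f"tumor '{m.label}' overlaps another tumor")
        taken |= m.membership
        if spec.min_tumor_ml > 0 and m.volume_ml < spec.min_tumor_ml:
            raise ValueError(
                f"tumor '{m.label}' is {m.volume_ml:.2f} ml < minimum "
                f"{spec.min_tumor_ml} ml (inclusion rule)"
            )


def _fine_activity(spec: PhantomSpec, grid: Grid, liver: VOIMask,
                   lpts: list[VOIMask], tumor_masks: list[VOIMask],
                   session: str) -> VoxelImage:
    """Piecewise-constant per-voxel activity, renormalized per LPT (Bq)."""
    conc = np.where(liver.membership, spec.background_bq_per_ml, 0.0)
    for t, m in zip(spec.tumors, tumor_masks):
        factor = t.tnr if session == "pre" else t.tnr * t.discrepancy
        conc[m.membership] = spec.background_bq_per_ml * factor
    act = conc * grid.voxel_volume_ml
    for lpt, a_gbq in zip(lpts, spec.administered_gbq):
        s = act[lpt.membership].sum()
        if s <= 0:
            raise ValueError(f"LPT '{lpt.label}' contains no activity")
        act[lpt.membership] *= a_gbq * 1e9 / s
    return VoxelImage(grid, act, "activity")


def _blur_and_sample(fine: VoxelImage, fwhm_mm: float, coarse: Grid) -> VoxelImage:
    if fwhm_mm > 0:
        sigma_vox = [fwhm_mm * _FWHM_TO_SIGMA / s for s in fine.grid.spacing]
        blurred = ndimage.gaussian_filter(fine.values, sigma_vox, mode="constant")
        fine = VoxelImage(fine.grid, blurred, "activity")
    return integrate_image(fine, coarse)


def _voi_table(comp: CompartmentSet) -> dict[str, VOIMask]:
    vois: dict[str, VOIMask] = {"liver": comp.liver, "ntv-total": comp.ntv_total()}
    for i, lpt in enumerate(comp.lpts):
        vois[f"lpt-{i}"] = lpt
        vois[f"ntv-lpt-{i}"] = comp.ntv_of(i)
    for i, t in enumerate(comp.tumors):
        vois[f"tumor-{i}"] = t
    return vois


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Generate masks, coarse activity maps and ground truth from a spec."""
    grid = _fine_grid(spec)
    liver = _ellipsoid_mask(grid, spec.liver_center_mm, spec.liver_semiaxes_mm, "liver")
    x = grid.centers(0)
    left = x[:, None, None] < spec.lpt_plane_x_mm
    lpts = [
        VOIMask(grid, liver.membership & np.broadcast_to(left, grid.shape), "lpt-0"),
        VOIMask(grid, liver.membership & np.broadcast_to(~left, grid.shape), "lpt-1"),
    ]
    true_tumors = [
        _sphere_mask(grid, t.center_mm, t.radius_mm, t.label or f"tumor-{i}")
        for i, t in enumerate(spec.tumors)
    ]
    _validate_tumors(spec, grid, liver, true_tumors)
    observed_tumors = [
        _sphere_mask(grid, tuple(np.asarray(t.center_mm) + np.asarray(t.misalignment_mm)),
                     t.radius_mm, m.label)
        for t, m in zip(spec.tumors, true_tumors)
    ]
    true_comp = CompartmentSet.assemble(liver, lpts, true_tumors, warn_uncovered=False)
    observed_comp = CompartmentSet.assemble(liver, lpts, observed_tumors, warn_uncovered=False)

    act_pre = _fine_activity(spec, grid, liver, lpts, true_tumors, "pre")
    act_post = _fine_activity(spec, grid, liver, lpts, true_tumors, "post")

    # ground-truth doses from the noiseless, unblurred fine-grid fields
    kernel = DoseKernel()
    s_fine = kernel.s_value(grid)
    vois = _voi_table(true_comp)
    voi_doses_pre = {k: act_pre.values[v.membership] * s_fine for k, v in vois.items()}
    voi_doses_post = {k: act_post.values[v.membership] * s_fine for k, v in vois.items()}
    truth = PhantomTruth(
        fine_activity_pre=act_pre,
        fine_activity_post=act_post,
        mean_dose_pre={k: float(d.mean()) for k, d in voi_doses_pre.items()},
        mean_dose_post={k: float(d.mean()) for k, d in voi_doses_post.items()},
        tumor_misalignment_mm=[np.asarray(t.misalignment_mm, float) for t in spec.tumors],
        tumor_discrepancy=[t.discrepancy for t in spec.tumors],
        lpt_energy_j=[a * 1e9 * kernel.e_ave_j * kernel.t_half_s / np.log(2.0)
                      for a in spec.administered_gbq],
        voi_doses_pre=voi_doses_pre,
        voi_doses_post=voi_doses_post,
    )

    pre_grid = _coarse_grid(grid, spec.pre_spacing_mm)
    post_grid = _coarse_grid(grid, spec.post_spacing_mm)
    pre = _blur_and_sample(act_pre, spec.pre_fwhm_mm, pre_grid)
    post = _blur_and_sample(act_post, spec.post_fwhm_mm, post_grid)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        for img in (pre, post):
            img.values *= 1.0 + spec.noise_sd * rng.standard_normal(img.values.shape)
            np.clip(img.values, 0.0, None, out=img.values)

    return Phantom(spec, observed_comp, true_comp, pre, post, truth)


def regenerate_truth(spec: PhantomSpec) -> PhantomTruth:
    """Recompute the deterministic (noise-free) ground truth for a spec."""
    return build_phantom(replace(spec, noise_sd=0.0)).truth
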