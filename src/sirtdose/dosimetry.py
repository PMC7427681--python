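"""Local-deposition voxel dosimetry and activity prescription for 90Y SIRT.

The local deposition model assumes every decay's energy is absorbed in the
voxel where the decay occurs and that there is no biological clearance, so
the absorbed dose in a voxel is the cumulated activity times a single
conversion factor

    S [Gy/Bq] = (T_half / ln 2) * E_ave / (rho * vox_vol)

with the 90Y physical half-life T_half, the mean energy released per decay
E_ave, the tissue density rho and the voxel volume vox_vol.  Integrating
the same constants over a whole compartment of mass M gives the familiar
dose-per-activity factor of ~49.87 Gy.kg/GBq used in MIRD-style and
partition-model activity prescription.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volumes import Grid, VOIMask, VoxelImage

__all__ = [
    "Y90_HALF_LIFE_S",
    "Y90_MEAN_ENERGY_J",
    "LIVER_DENSITY_KG_M3",
    "CLINICAL_GY_KG_PER_GBQ",
    "DoseKernel",
    "compute_svalue",
    "normalize_pre",
    "normalize_post",
    "dose_map",
    "PlanningSpec",
    "prescribe_mird",
    "prescribe_partition",
    "lung_cap",
]

#: physical half-life of 90Y, seconds (64.1 h)
Y90_HALF_LIFE_S = 64.1 * 3600.0
#: mean energy released per 90Y decay, joule
Y90_MEAN_ENERGY_J = 1.498e-13
#: liver soft-tissue density, kg/m^3
LIVER_DENSITY_KG_M3 = 1.04e3
#: rounded clinical dose-per-activity factor, Gy.kg/GBq, as used on
#: prescription sheets (the kernel-derived value is 49.871)
CLINICAL_GY_KG_PER_GBQ = 49.87


@dataclass(frozen=True)
class DoseKernel:
    """Physical constants of the local deposition model."""

    t_half_s: float = Y90_HALF_LIFE_S
    e_ave_j: float = Y90_MEAN_ENERGY_J
    rho_kg_m3: float = LIVER_DENSITY_KG_M3

    def __post_init__(self) -> None:
        if self.t_half_s <= 0 or self.e_ave_j <= 0 or self.rho_kg_m3 <= 0:
            raise ValueError("kernel constants must all be positive")

    @property
    def gy_kg_per_gbq(self) -> float:
        """Whole-compartment dose-per-activity factor (Gy.kg/GBq)."""
        return self.t_half_s / math.log(2.0) * self.e_ave_j * 1e9

    def s_value(self, grid: Grid) -> float:
        """Voxel self-irradiation factor S (Gy per Bq of administered activity)."""
        vox_vol = grid.voxel_volume_m3
        if vox_vol <= 0:
            raise ValueError("voxel volume must be positive")
        return self.t_half_s / math.log(2.0) * self.e_ave_j / (self.rho_kg_m3 * vox_vol)


def compute_svalue(grid: Grid, kernel: DoseKernel | None = None) -> float:
    """S value (Gy/Bq) for a grid's voxel size under the local deposition model."""
    return (kernel or DoseKernel()).s_value(grid)


# ---------------------------------------------------------------------------
# activity-map normalization
# ---------------------------------------------------------------------------

def normalize_pre(image: VoxelImage, lpts: list[VOIMask], prescribed_gbq) -> VoxelImage:
    """Normalize a pre-treatment (MAA-SPECT-like) map to per-LPT prescriptions.

    The raw map is treated as a relative uptake surrogate: within each liver
    perfusion territory voxel values are rescaled so that the territory sum
    equals its prescribed activity (GBq -> Bq).  Voxels outside every LPT are
    zeroed, reflecting injection exclusively into the planned territories.
    """
    prescribed = list(np.atleast_1d(np.asarray(prescribed_gbq, dtype=float)))
    if len(prescribed) != len(lpts):
        raise ValueError(f"{len(lpts)} LPTs but {len(prescribed)} prescriptions")
    out = np.zeros_like(image.values)
    for lpt, act_gbq in zip(lpts, prescribed):
        if not lpt.grid.same_geometry(image.grid):
            raise ValueError(f"LPT '{lpt.label}' is not on the activity grid")
        total = image.values[lpt.membership].sum()
        if total <= 0:
            raise ValueError(
                f"LPT '{lpt.label}' has zero summed counts: fractional uptake undefined"
            )
        out[lpt.membership] = image.values[lpt.membership] * (act_gbq * 1e9 / total)
    return VoxelImage(image.grid, out, "activity")


def normalize_post(image: VoxelImage, liver: VOIMask, administered_gbq: float) -> VoxelImage:
    """Normalize a post-treatment (90Y-PET-like) map to the administered activity.

    A single global scale makes the liver-mask sum equal the administered
    activity, i.e. all administered 90Y is assumed to have ended up in the
    liver (lung shunt fraction of 0%).  Signal outside the liver is scaled
    by the same factor, not zeroed.
    """
    if not liver.grid.same_geometry(image.grid):
        raise ValueError("liver mask is not on the activity grid")
    total = image.values[liver.membership].sum()
    if administered_gbq == 0:
        return VoxelImage(image.grid, np.zeros_like(image.values), "activity")
    if total <= 0:
        raise ValueError("liver mask contains zero summed signal")
    return image.scaled(administered_gbq * 1e9 / total)


def dose_map(activity: VoxelImage, s_gy_per_bq: float) -> VoxelImage:
    """Voxelwise dose (Gy) = activity (Bq) x S, under local deposition."""
    if activity.quantity != "activity":
        raise ValueError(f"expected an activity image, got quantity={activity.quantity!r}")
    if s_gy_per_bq <= 0:
        raise ValueError("S value must be positive")
    return VoxelImage(activity.grid, activity.values * s_gy_per_bq, "dose")


# ---------------------------------------------------------------------------
# activity prescription
# ---------------------------------------------------------------------------

@dataclass
class PlanningSpec:
    """Inputs for MIRD-style or partition-model activity prescription.

    Masses in kg, doses in Gy, activities in GBq; ``tnr`` is the
    tumor-to-normal activity concentration ratio measured on the
    pre-treatment study; ``lsf`` the planar lung shunt fraction.
    """

    model: str = "mird"  # "mird" | "partition"
    target_lpt_dose_gy: float | None = None
    target_tumor_dose_gy: float | None = None
    max_ntv_dose_gy: float | None = None
    lpt_mass_kg: float | None = None
    ntv_mass_kg: float | None = None
    tumor_mass_kg: float | None = None
    tnr: float | None = None
    lsf: float = 0.0
    lung_mass_kg: float = 1.0
    lung_limit_gy: float = 30.0
    conversion_gy_kg_per_gbq: float = CLINICAL_GY_KG_PER_GBQ

    def __post_init__(self) -> None:
        if not 0.0 <= self.lsf < 1.0:
            raise ValueError("lung shunt fraction must lie in [0, 1)")


def prescribe_mird(spec: PlanningSpec) -> float:
    """Non-compartmental (whole-LPT) prescription: A = D_target * M / CF (GBq)."""
    if spec.target_lpt_dose_gy is None or spec.lpt_mass_kg is None:
        raise ValueError("MIRD prescription needs target_lpt_dose_gy and lpt_mass_kg")
    if spec.target_lpt_dose_gy < 0 or spec.lpt_mass_kg <= 0:
        raise ValueError("target dose must be >= 0 and LPT mass > 0")
    return spec.target_lpt_dose_gy * spec.lpt_mass_kg / spec.conversion_gy_kg_per_gbq


def prescribe_partition(spec: PlanningSpec) -> dict:
    """Compartmental partition-model prescription.

    With concentration ratio r (tnr), tumor and normal-tissue doses obey
    D_T = r * D_N; the activity splits as A_N = D_N*M_N/CF and
    A_T = r*D_N*M_T/CF.  When both a tumor-dose target and an NTV ceiling
    are given, the binding (smaller-activity) constraint is applied.
    """
    if spec.ntv_mass_kg is None or spec.tumor_mass_kg is None or spec.tnr is None:
        raise ValueError("partition prescription needs ntv_mass_kg, tumor_mass_kg and tnr")
    if spec.ntv_mass_kg <= 0 or spec.tumor_mass_kg <= 0:
        raise ValueError("compartment masses must be positive")
    if spec.target_tumor_dose_gy is None and spec.max_ntv_dose_gy is None:
        raise ValueError("give target_tumor_dose_gy and/or max_ntv_dose_gy")
    r = spec.tnr
    candidates = []
    if spec.max_ntv_dose_gy is not None:
        candidates.append(spec.max_ntv_dose_gy)
    if spec.target_tumor_dose_gy is not None:
        if r <= 0:
            raise ValueError("tumor-dose criterion unreachable with tnr = 0")
        candidates.append(spec.target_tumor_dose_gy / r)
    d_n = min(candidates)  # binding constraint = smaller activity
    cf = spec.conversion_gy_kg_per_gbq
    a_n = d_n * spec.ntv_mass_kg / cf
    a_t = r * d_n * spec.tumor_mass_kg / cf
    return {
        "activity_gbq": a_n + a_t,
        "ntv_activity_gbq": a_n,
        "tumor_activity_gbq": a_t,
        "predicted_ntv_dose_gy": d_n,
        "predicted_tumor_dose_gy": r * d_n,
    }


def lung_cap(activity_gbq: float, lsf: float, lung_mass_kg: float = 1.0,
             limit_gy: float = 30.0,
             conversion: float = CLINICAL_GY_KG_PER_GBQ) -> dict:
    """Lung-dose check: dose = CF*A*LSF/M_lung; activity capped to the limit."""
    if not 0.0 <= lsf < 1.0:
        raise ValueError("lung shunt fraction must lie in [0, 1)")
    lung_dose = conversion * activity_gbq * lsf / lung_mass_kg
    if lsf == 0.0:
        return {"lung_dose_gy": 0.0, "capped_activity_gbq": activity_gbq, "capped": False}
    a_max = limit_gy * lung_mass_kg / (conversion * lsf)
    capped = activity_gbq > a_max
    return {
        "lung_dose_gy": lung_dose,
        "capped_activity_gbq": min(activity_gbq, a_max),
        "capped": capped,
    }
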