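"""Cumulative dose-volume histograms and their clinical summary parameters.

For a VOI with N voxels of dose d_i (uniform voxel mass, single tissue
density):

* mean dose   — arithmetic mean of the voxel doses;
* Vd (%)      — percentage of the VOI volume receiving at least d Gy;
* Dn (Gy)     — the n-th percentile dose, i.e. the largest dose D such
  that at least n% of the volume receives >= D.  Dn is evaluated on the
  sorted raw voxel doses (no interpolation; ties take the lower dose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import CompartmentSet, Grid, VOIMask, VoxelImage, resample_mask

__all__ = ["DVHResult", "compute_dvh", "compartment_report",
           "TUMOR_DN", "TUMOR_VD", "NTV_DN", "NTV_VD", "LPT_DN", "LPT_VD"]

# clinically conventional report sets
TUMOR_DN = (50.0, 70.0)
TUMOR_VD = (70.0, 100.0)
NTV_DN = (30.0, 50.0)
NTV_VD = (40.0, 50.0)
LPT_DN = (30.0, 50.0)
LPT_VD = (30.0, 50.0)


@dataclass
class DVHResult:
    label: str
    volume_ml: float
    mean_gy: float
    dose_grid_gy: np.ndarray       # curve support, fixed resolution
    cum_volume_pct: np.ndarray     # % of VOI volume receiving >= dose
    d_pct: dict[float, float]      # n (%) -> Dn (Gy)
    v_gy: dict[float, float]       # d (Gy) -> Vd (%)

    def to_row(self) -> dict:
        row = {"voi": self.label, "volume_ml": self.volume_ml, "mean_gy": self.mean_gy}
        row.update({f"D{n:g}_gy": v for n, v in self.d_pct.items()})
        row.update({f"V{d:g}_pct": v for d, v in self.v_gy.items()})
        return row


def _dn(doses_desc: np.ndarray, n_pct: float) -> float:
    """Largest dose received by at least n% of the voxels (lower tie rule)."""
    n_vox = doses_desc.size
    k = max(1, math.ceil(n_pct * n_vox / 100.0 - 1e-12))
    if k > n_vox:
        k = n_vox
    return float(doses_desc[k - 1])


def _vd(doses: np.ndarray, d_gy: float) -> float:
    return 100.0 * float(np.count_nonzero(doses >= d_gy)) / doses.size


def compute_dvh(dose: VoxelImage, mask: VOIMask,
                dn_list=NTV_DN, vd_list=NTV_VD,
                curve_resolution_gy: float = 0.5) -> DVHResult:
    """Cumulative DVH with mean, Dn and Vd summaries for one VOI."""
    if dose.quantity != "dose":
        raise ValueError("compute_dvh expects a dose image")
    if not mask.grid.same_geometry(dose.grid):
        raise ValueError(f"mask '{mask.label}' is not on the dose grid")
    if mask.is_empty:
        raise ValueError(f"mask '{mask.label}' is empty")
    doses = dose.values[mask.membership]
    desc = np.sort(doses)[::-1]
    top = max(doses.max(), curve_resolution_gy)
    grid_gy = np.arange(0.0, top + 2 * curve_resolution_gy, curve_resolution_gy)
    cum = np.array([_vd(doses, g) for g in grid_gy])
    return DVHResult(
        label=mask.label,
        volume_ml=mask.volume_ml,
        mean_gy=float(doses.mean()),
        dose_grid_gy=grid_gy,
        cum_volume_pct=cum,
        d_pct={float(n): _dn(desc, float(n)) for n in dn_list},
        v_gy={float(d): _vd(doses, float(d)) for d in vd_list},
    )


def _on_dose_grid(mask: VOIMask, grid: Grid, threshold: float) -> VOIMask:
    if mask.grid.same_geometry(grid):
        return mask
    return resample_mask(mask, grid, mode="fractional").threshold(threshold)


def compartment_report(dose: VoxelImage, comp: CompartmentSet,
                       tumor_dn=TUMOR_DN, tumor_vd=TUMOR_VD,
                       ntv_dn=NTV_DN, ntv_vd=NTV_VD,
                       lpt_dn=LPT_DN, lpt_vd=LPT_VD,
                       threshold: float = 0.5) -> tuple[pd.DataFrame, list[DVHResult]]:
    """Per-compartment DVH table: tumors, per-LPT NTV/total, whole-liver NTV/total.

    Masks defined on a different (finer) grid are fractionally resampled to
    the dose grid and binarized at ``threshold``; NTV rows exclude every
    tumor voxel exactly (set difference on the dose grid).
    """
    grid = dose.grid
    liver = _on_dose_grid(comp.liver, grid, threshold)
    lpts = [_on_dose_grid(m, grid, threshold) for m in comp.lpts]
    tumors = [_on_dose_grid(m, grid, threshold) for m in comp.tumors]

    tumor_union = np.zeros(grid.shape, dtype=bool)
    for t in tumors:
        tumor_union |= t.membership

    results: list[DVHResult] = []

    def add(mask: VOIMask, kind: str, dn, vd):
        if mask.is_empty:
            return
        r = compute_dvh(dose, mask, dn, vd)
        r.kind = kind  # type: ignore[attr-defined]
        results.append(r)

    for i, t in enumerate(tumors):
        add(t, "tumor", tumor_dn, tumor_vd)
    for i, (lpt, raw) in enumerate(zip(lpts, comp.lpts)):
        ntv = VOIMask(grid, lpt.membership & ~tumor_union, f"ntv-{raw.label}")
        add(ntv, "ntv-lpt", ntv_dn, ntv_vd)
        add(lpt, "lpt", lpt_dn, lpt_vd)
    ntv_total = VOIMask(grid, liver.membership & ~tumor_union, "ntv-total")
    add(ntv_total, "ntv-total", ntv_dn, ntv_vd)
    add(liver, "liver", lpt_dn, lpt_vd)

    rows = []
    for r in results:
        row = r.to_row()
        row["kind"] = getattr(r, "kind", "")
        rows.append(row)
    return pd.DataFrame(rows), results
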