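"""Tumor-VOI propagation and relocation on activity maps.

After a tumor contour drawn on anatomical imaging is propagated to the
SPECT/PET frame, a small residual misalignment between the mask and the
activity distribution can remain.  The relocation step shifts the mask
rigidly to maximize the activity it captures, while a cubic penalty on the
translation magnitude and a hard constraint — the initial center must stay
inside the shifted VOI — keep the move local:

    cost(s) = -(U(s) - U(0)) / U(0) + beta * (||s|| / (5 d))^3   if C_init in T_new
              +inf                                               otherwise

where U(s) is the activity captured by the shifted VOI, d the activity
voxel diagonal (mm) and beta a dimensionless penalty weight.

The mask keeps its native resolution: when it lives on a finer grid than
the activity map, the coarse activity is first redistributed onto the mask
grid by exact fractional-volume overlap, so U(s) is the integral of the
piecewise-constant activity density over the translated VOI.  Sub-voxel
shifts use trilinear (fractional) mask weights, making U continuous in s;
the minimization is a derivative-free direction-set (Powell) search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .volumes import FuzzyMask, Grid, VOIMask, VoxelImage, integrate_image, resample_mask

__all__ = ["AlignmentProblem", "AlignmentResult", "propagate_by_center",
           "alignment_cost", "optimize_location", "INFEASIBLE_COST"]

#: large finite sentinel standing in for +inf so line searches stay stable
INFEASIBLE_COST = 1e6


@dataclass
class AlignmentProblem:
    """A tumor mask, the activity map it should lock onto, and the parameters.

    The mask may live on the activity grid or on a finer mask grid; the
    activity is brought to the mask grid internally.  ``c_init_mm``
    defaults to the mask's center of mass (the optional expert seed point
    overrides it).
    """

    tumor: VOIMask | FuzzyMask
    activity: VoxelImage
    c_init_mm: np.ndarray | None = None
    beta: float = 1.0
    max_shift_mm: float = 15.0
    fuzzy_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.max_shift_mm <= 0:
            raise ValueError("max_shift_mm must be positive")
        grid = self.tumor.grid
        weights = (self.tumor.weights if isinstance(self.tumor, FuzzyMask)
                   else self.tumor.membership.astype(float))
        if grid.same_geometry(self.activity.grid):
            act = self.activity.values
        else:
            act = integrate_image(self.activity, grid).values
        # penalty scale: diagonal of the *activity* voxels (SPECT/PET voxel size)
        self.diagonal_mm = self.activity.grid.diagonal_mm

        if self.c_init_mm is None:
            if weights.sum() > 0:
                self.c_init_mm = grid.position_of(ndimage.center_of_mass(weights))
            else:
                self.c_init_mm = grid.position_of((np.asarray(grid.shape) - 1) / 2.0)
        self.c_init_mm = np.asarray(self.c_init_mm, dtype=float)
        if not grid.contains_point(self.c_init_mm):
            raise ValueError("initial center lies outside the mask grid")

        # crop to the mask bounding box + shift margin: evaluations stay cheap
        # and nothing outside can ever contribute to the uptake sum
        if weights.sum() > 0:
            idx = np.argwhere(weights > 0)
            pad = np.ceil(self.max_shift_mm / np.asarray(grid.spacing)).astype(int) + 2
            lo = np.maximum(idx.min(axis=0) - pad, 0)
            hi = np.minimum(idx.max(axis=0) + pad + 1, grid.shape)
        else:
            lo, hi = np.zeros(3, dtype=int), np.asarray(grid.shape)
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        self.weights0 = np.ascontiguousarray(weights[sl])
        self._act = np.ascontiguousarray(act[sl])
        self.grid = Grid(self.weights0.shape, grid.spacing,
                         tuple(grid.position_of(lo)))

    @property
    def initial_uptake(self) -> float:
        return float((self.weights0 * self._act).sum())


@dataclass
class AlignmentResult:
    shift_mm: np.ndarray
    cost: float
    fuzzy: FuzzyMask
    final: VOIMask
    status: str                     # "converged" | "boundary" | "degenerate"
    n_evaluations: int = 0


def _shifted_weights(problem: AlignmentProblem, shift_mm) -> np.ndarray:
    """Trilinearly shifted fractional VOI weights (continuous in the shift)."""
    shift_vox = np.asarray(shift_mm, dtype=float) / np.asarray(problem.grid.spacing)
    if np.all(shift_vox == 0):
        return problem.weights0
    return ndimage.shift(problem.weights0, shift_vox, order=1,
                         mode="constant", cval=0.0, prefilter=False)


def _center_inside(problem: AlignmentProblem, w: np.ndarray) -> bool:
    idx = problem.grid.index_of(problem.c_init_mm)
    val = ndimage.map_coordinates(w, idx[:, None], order=1, mode="constant", cval=0.0)
    return bool(val[0] >= problem.fuzzy_threshold)


def alignment_cost(problem: AlignmentProblem, shift_mm) -> float:
    """Evaluate the relocation cost for a candidate translation (mm).

    Returns :data:`INFEASIBLE_COST` where the initial center leaves the
    shifted VOI (the +inf branch).
    """
    u0 = problem.initial_uptake
    if u0 <= 0:
        raise ValueError("zero initial uptake: degenerate alignment problem")
    shift_mm = np.asarray(shift_mm, dtype=float)
    w = _shifted_weights(problem, shift_mm)
    if not _center_inside(problem, w):
        return INFEASIBLE_COST
    uptake = float((w * problem._act).sum())
    penalty = problem.beta * (np.linalg.norm(shift_mm) / (5.0 * problem.diagonal_mm)) ** 3
    return -(uptake - u0) / u0 + penalty


def optimize_location(problem: AlignmentProblem) -> AlignmentResult:
    """Direction-set (Powell) minimization of the relocation cost.

    Starts at zero shift, translation only; deterministic for fixed inputs.
    A degenerate problem (no initial uptake) returns the zero shift with
    status ``"degenerate"``.
    """

    def result_at(shift, cost, status, n_eval=0):
        w = _shifted_weights(problem, shift)
        full = np.zeros(problem.tumor.grid.shape)
        lo = np.rint(problem.tumor.grid.index_of(
            problem.grid.position_of((0, 0, 0)))).astype(int)
        sl = tuple(slice(a, a + n) for a, n in zip(lo, problem.grid.shape))
        full[sl] = np.clip(w, 0.0, 1.0)
        fuzzy = FuzzyMask(problem.tumor.grid, full, problem.tumor.label, "aligned")
        return AlignmentResult(np.asarray(shift, float), float(cost), fuzzy,
                               fuzzy.threshold(problem.fuzzy_threshold), status, n_eval)

    if problem.initial_uptake <= 0:
        warnings.warn("zero uptake under the initial VOI; returning zero shift",
                      stacklevel=2)
        return result_at(np.zeros(3), 0.0, "degenerate")

    n_eval = 0

    def fun(s):
        nonlocal n_eval
        n_eval += 1
        return alignment_cost(problem, s)

    m = problem.max_shift_mm
    res = optimize.minimize(
        fun, x0=np.zeros(3), method="Powell",
        bounds=[(-m, m)] * 3,
        options={"xtol": 0.1, "ftol": 1e-6, "maxiter": 200},
    )
    shift = np.asarray(res.x, dtype=float)
    cost = float(res.fun)
    if cost > 0.0:  # the minimizer can never beat the feasible start at zero shift
        shift, cost = np.zeros(3), 0.0
    status = "boundary" if np.any(np.isclose(np.abs(shift), m, atol=0.1)) else "converged"
    return result_at(shift, cost, status, n_eval)


def propagate_by_center(tumor_fine: VOIMask, displacement_mm, target: Grid,
                        threshold: float = 0.5) -> VOIMask:
    """Rigidly propagate a fine-grid tumor mask onto an activity grid.

    The mask is translated by the mass-center displacement (mm) reported by
    the registration, fractionally resampled onto the target grid and
    thresholded.
    """
    disp = np.asarray(displacement_mm, dtype=float)
    moved_grid = Grid(tumor_fine.grid.shape, tumor_fine.grid.spacing,
                      tuple(np.asarray(tumor_fine.grid.origin) + disp))
    moved = VOIMask(moved_grid, tumor_fine.membership, tumor_fine.label)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # a fully off-grid shift becomes an error below
        fuzzy = resample_mask(moved, target, mode="fractional")
    out = fuzzy.threshold(threshold)
    if out.is_empty and not tumor_fine.is_empty:
        raise ValueError(
            f"displacement {disp} moves tumor '{tumor_fine.label}' outside the target grid"
        )
    return out
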