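# Methods

## Dose model

All dosimetry uses the local energy deposition model: the energy of every
decay is absorbed in the voxel where the decay occurs, there is no
biological clearance, and the full physical decay of ⁹⁰Y is integrated.
The voxel dose is then `D_i = A_i · S` with

```
S [Gy/Bq] = (T_half / ln 2) · E_ave / (rho · vox_vol)
```

Constants (module defaults, `DoseKernel`):

| constant | value | units | meaning |
|---|---|---|---|
| `t_half_s` | 64.1 × 3600 | s | ⁹⁰Y physical half-life |
| `e_ave_j` | 1.498 × 10⁻¹³ | J | mean energy released per decay |
| `rho_kg_m3` | 1.04 × 10³ | kg/m³ | liver soft-tissue density |

The same constants give the whole-compartment factor
`(T_half/ln2)·E_ave·10⁹ = 49.871 Gy·kg/GBq`; prescription functions use
the rounded clinical value 49.87 by default, matching prescription-sheet
practice. The ⁹⁹ᵐTc half-life never enters: the pre-treatment map is a
*relative* surrogate for the microsphere distribution and is normalized
before dose conversion, so ⁹⁰Y decay applies to both sessions.

Activity normalization conventions:

* **Pre-treatment (SPECT-like):** voxels outside every perfusion
  territory are zeroed (activity is injected exclusively into the planned
  territories) and each territory is rescaled so its sum equals the
  prescribed activity. Per-territory mean doses are therefore invariant
  to any global calibration of the raw map.
* **Post-treatment (PET-like):** one global scale makes the liver-mask
  sum equal the administered activity (lung shunt fraction treated as
  0%); signal outside the liver is scaled, not zeroed. The sum is taken
  over the liver mask, not the field of view, so out-of-liver
  reconstruction signal does not dilute the liver dose.

## Geometry and resampling

All grids are axis-aligned in one fixed right-handed frame; positions are
physical millimetres, the origin is the center of voxel (0,0,0), indices
are 0-based. No orientation metadata is carried — a single convention
avoids silent axis flips, and NIfTI I/O only accepts diagonal affines.

Mask transfer between grids uses exact separable fractional-volume
overlap: the weight of a target voxel is the exact fraction of its volume
covered by the source mask (product of per-axis interval overlaps). This
conserves mask volume to floating precision whenever the target grid
covers the source, and the same operator with source-side normalization
redistributes activity between grids with exact sum conservation
("integration" of a fine activity field into coarse imaging voxels).
Fuzzy masks are binarized at 0.5 by default (configurable); the rasterized
boundary is the only approximation.

Tumors straddling a territory boundary are assigned to the territory
containing the larger voxel fraction. Liver voxels covered by no
territory stay in whole-liver reports, are excluded from per-territory
reports, and trigger a warning with the uncovered volume.

## Digital-liver phantom

The generator emulates the data objects of a SIRT dosimetry study, with
ground truth known by construction:

* Ellipsoidal liver, default semi-axes (95, 70, 62.5) mm ≈ 1740 ml
  (a typical treated liver), split into two perfusion territories by a
  sagittal plane (default x = 15 mm).
* Spherical tumors, default one per territory with radii 20 and 14 mm
  (≈ 33 and 11 ml); a 5 ml minimum volume is enforced by default,
  mirroring the usual analysis inclusion rule. Tumor-to-normal activity
  concentration ratio (tnr) defaults to 3, a typical hypervascular value.
* Administered activity defaults to 0.9 + 0.6 GBq ≈ 1.5 GBq total, a
  typical two-territory treatment.
* The fine ("CBCT-like") grid is 1 mm isotropic; the pre-treatment grid
  is 4.8 mm isotropic (SPECT), the post-treatment grid 3.13×3.13×2.78 mm
  (PET/MR, the most common post-treatment modality; the 2.73×2.73×2.79 mm
  PET/CT grid is available as an option).
* Imaging is emulated by an isotropic Gaussian PSF applied on the fine
  grid — default FWHM 12 mm (pre) and 6 mm (post), plausible *effective*
  system-plus-reconstruction resolutions — followed by exact integration
  into the coarse voxels. Optional multiplicative Gaussian noise
  (relative sd, seeded) is off by default so tests are deterministic.
* Controlled imperfections: each tumor carries a **discrepancy factor**
  multiplying its concentration in the post-treatment field only
  (emulating MAA-vs-microsphere mismatch from catheter repositioning or
  flow change; both fields are renormalized per territory so the
  administered activity is preserved), and a **misalignment vector**
  displacing its mask relative to activity space (emulating residual
  registration error, so registration itself need not be simulated).

Ground truth (per-VOI voxel doses, mean doses, territory energies, applied
shifts and discrepancies) is computed from the noiseless, unblurred
fine-grid fields and is reproducible bit-for-bit from the spec and seed.

What the phantom does **not** model: projection-domain physics
(attenuation, scatter, Poisson sinogram noise, reconstruction artifacts),
extrahepatic uptake and lung shunt, irregular tumor shapes, necrotic
cores, intra-tumor heterogeneity, and breathing-related deformation.
Passing tests on this phantom therefore validates the numerical chain —
geometry, normalization, dose conversion, relocation, DVH and statistics —
not the clinical fidelity of SPECT/PET quantification.

A consequence of the asymmetric default resolutions worth knowing: with
discrepancy 1 and no misalignment, pre- and post-derived *tumor* mean
doses still differ by ~10% for a 30 ml tumor, because the 12 mm PSF
spills more tumor signal into surrounding tissue than the 6 mm PSF. With
matched PSFs the residual grid-sampling difference is ≈ 2% for tumors
≥ 20 ml. Normal-tissue means, which average over much larger volumes, are
insensitive to this.

## VOI relocation

The relocation cost for a rigid translation `s` of the tumor VOI is

```
cost(s) = −(U(s) − U(0))/U(0) + β · (‖s‖ / (5 d))³     if C_init ∈ T_new
          +∞                                            otherwise
```

with `U(s)` the activity captured by the shifted VOI, `d` the diagonal of
the activity voxel (mm) and `C_init` the initial center (mask center of
mass, or an expert-supplied seed point overriding it).

Numerical choices:

* The mask keeps its native resolution. When it lives on a finer grid
  than the activity map, the coarse activity is first redistributed onto
  the mask grid by exact fractional overlap; `U(s)` is then the integral
  of this piecewise-constant activity density over the translated VOI.
  Evaluating `U` directly with coarse-voxel mask weights biases the
  optimum by up to half an activity voxel; the fine-grid formulation
  reduces the recovery error on phantoms from ≈ 2.4 mm to ≈ 0.9 mm.
* Sub-voxel shifts use trilinear interpolation of the fractional mask
  weights, making `U` continuous in `s`.
* The infeasible region returns a large finite sentinel (10⁶) instead of
  `inf` so Powell line searches remain stable.
* Optimizer: `scipy.optimize.minimize(method="Powell")` from `s = 0`,
  translation only, bounds ±`max_shift_mm` (default 15 mm), `xtol`
  0.1 mm, at most 200 iterations; deterministic. A result with positive
  cost is replaced by the feasible start (zero shift, cost 0).
* `β` defaults to 1.0 and is exposed; the penalty is dimensionless and
  reaches 0.008 at a 2-voxel shift, so the uptake term dominates for the
  local corrections the step is meant for. The fuzzy VOI is thresholded
  at 0.5 to produce the final binary mask.
* Degenerate problems (zero initial uptake) return a zero shift with
  status `"degenerate"` and a warning.

## DVH conventions

Uniform voxel mass within a VOI (single tissue density), so volume
fractions equal voxel-count fractions. `Vd` is the percentage of VOI
voxels with dose ≥ d. `Dn` is evaluated on the raw sorted voxel doses
with no interpolation: the largest dose received by at least n% of the
voxels, taking the lower dose at ties (so `D50` is the volume-weighted
median). The stored cumulative curve uses 0.5 Gy steps and is only for
reporting/plotting; summaries never come from the binned curve. Default
report sets follow clinical practice: D50/D70 and V70/V100 for tumors,
D30/D50 and V40/V50 for normal tissue, D30/D50 and V30/V50 for whole
territories. Non-tumoral volumes exclude tumor voxels by exact set
difference on the dose grid.

## Agreement statistics

* **Passing–Bablok:** slope = shifted median of pairwise slopes
  (undefined pairs skipped, slopes of −1 discarded, median index offset
  by the count of slopes < −1); intercept = median(y − b·x); 95% CIs by
  the classical rank-based formula (not bootstrap).
* **Bland–Altman:** differences y − x; limits mean ± 1.96·sd (sample sd);
  CI of the mean via the t distribution, CI of each limit with standard
  error sd·√(3/n).
* **Pearson:** r graded weak/moderate/strong at 0.3/0.5/0.7.
* **Wilcoxon:** paired signed-rank on y − x, zeros dropped. For n ≤ 25
  the two-sided p is exact, computed by subset-sum convolution of the
  (possibly tied, average-rank) rank distribution — valid with ties,
  unlike textbook exact tables; beyond 25, normal approximation with
  continuity correction.
* **Ratios:** quartiles of y/x with the type-7 (linear interpolation)
  convention; units with non-positive x are excluded with a warning.
* **Fixed-dose criteria:** tumors classified at 70 Gy with a 100 Gy
  refinement, normal tissue at 50 Gy with a 40 Gy refinement; a value
  exactly at a cut goes to the upper bin (one convention, documented,
  applied everywhere). The four-region counts are exactly recoverable by
  collapsing the 3×3 joint histogram.
* **Planned-vs-calculated:** signed relative differences with the
  clinical sign convention — negative means under-dosed normal tissue and
  over-dosed tumor respectively.

## Problem sizes used in the test suite

Unit and acceptance tests run on reduced phantoms (liver semi-axes
(45, 35, 30) mm ≈ 200 ml, 2 mm fine grid) — small enough to iterate on
while keeping every grid ratio (fine : SPECT : PET) and every physical
constant identical to the defaults. Alignment recovery is validated over
20 seeded phantoms with shifts of 2–8 mm and tnr 3–6; the optimizer is
cross-checked against an exhaustive 0.5 mm shift lattice on a 15³ grid;
Passing–Bablok confidence intervals are checked for ≥ 90% coverage of a
known generating slope over 200 simulated cohorts.

## Known limitations

* Local deposition ignores the ~2.5 mm ⁹⁰Y beta range; doses near VOI
  boundaries are sharper than a dose-point-kernel or Monte-Carlo model
  would give.
* Translation-only relocation: no rotation, scaling or deformation, and
  tumors are optimized independently (two adjacent tumors could in
  principle lock onto the same uptake spot).
* The phantom's partial-volume behaviour at mask boundaries (coarse
  voxels half-inside a VOI) slightly dilutes boundary-heavy compartments'
  mean doses; medians are robust to it.
* Lung dosimetry is a scalar cap from the planar lung-shunt fraction with
  a default 1 kg lung mass — an assumption, not an imaging result.
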