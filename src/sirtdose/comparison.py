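"""Method-comparison statistics for paired predicted vs. measured dose parameters.

Implements the agreement layer used to compare pre-treatment (predicted)
and post-treatment (measured) dosimetry across tumors / territories /
patients: Passing–Bablok regression with rank-based 95% confidence
intervals, Bland–Altman limits of agreement, Pearson correlation with the
conventional 0.3/0.5/0.7 strength grading, the paired Wilcoxon signed-rank
test, ratio quartiles, fixed-dose-criteria classification (70/100 Gy for
tumors, 40/50 Gy for normal tissue) and signed planned-vs-calculated
relative differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedSeries",
    "passing_bablok",
    "bland_altman",
    "correlate",
    "paired_wilcoxon",
    "ratio_summary",
    "classify_criteria",
    "planned_vs_calculated",
    "agreement_report",
    "TUMOR_THRESHOLDS",
    "NTV_THRESHOLDS",
]

# (main decision threshold, refinement threshold) in Gy
TUMOR_THRESHOLDS = (70.0, 100.0)
NTV_THRESHOLDS = (50.0, 40.0)


@dataclass
class PairedSeries:
    """Paired predicted (x) and measured (y) values of one dose parameter."""

    x: np.ndarray
    y: np.ndarray
    labels: list[str] = field(default_factory=list)
    parameter: str = ""
    units: str = "Gy"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("paired values must be finite")
        if not self.labels:
            self.labels = [f"unit-{i}" for i in range(self.x.size)]

    @property
    def n(self) -> int:
        return self.x.size


# ---------------------------------------------------------------------------
# Passing–Bablok
# ---------------------------------------------------------------------------

def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(x.size, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    ok = dx != 0
    return dy[ok] / dx[ok]


def passing_bablok(s: PairedSeries, alpha: float = 0.05) -> dict:
    """Passing–Bablok regression: shifted-median pairwise slope + rank CIs.

    The slope is the median of all pairwise slopes (y_j-y_i)/(x_j-x_i),
    i<j, after discarding slopes equal to -1 and shifting the median index
    by K = #(slopes < -1); the intercept is median(y - slope*x).  CIs use
    the classical rank-based formula.  Pairs with x_i = x_j are skipped.
    """
    if s.n < 3:
        raise ValueError("Passing–Bablok needs at least 3 pairs")
    if np.all(s.x == s.x[0]):
        raise ValueError("all x values identical: slope undefined")
    slopes = _pairwise_slopes(s.x, s.y)
    slopes = slopes[slopes != -1.0]
    if slopes.size == 0:
        raise ValueError("no valid pairwise slopes")
    slopes = np.sort(slopes)
    n_slopes = slopes.size
    k_off = int(np.count_nonzero(slopes < -1.0))

    def shifted_median(offset: int) -> float:
        if n_slopes % 2:
            idx = (n_slopes + 1) // 2 + offset  # 1-based
            return float(slopes[np.clip(idx - 1, 0, n_slopes - 1)])
        i1 = np.clip(n_slopes // 2 + offset - 1, 0, n_slopes - 1)
        i2 = np.clip(n_slopes // 2 + 1 + offset - 1, 0, n_slopes - 1)
        return float(0.5 * (slopes[i1] + slopes[i2]))

    slope = shifted_median(k_off)
    n = s.n
    z = stats.norm.ppf(1 - alpha / 2)
    c = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((n_slopes - c) / 2.0))
    m2 = n_slopes - m1 + 1
    lo = float(slopes[np.clip(m1 + k_off - 1, 0, n_slopes - 1)])
    hi = float(slopes[np.clip(m2 + k_off - 1, 0, n_slopes - 1)])
    intercept = float(np.median(s.y - slope * s.x))
    return {
        "slope": slope,
        "intercept": intercept,
        "slope_ci": (lo, hi),
        "intercept_ci": (float(np.median(s.y - hi * s.x)),
                         float(np.median(s.y - lo * s.x))),
        "n": n,
    }


def bland_altman(s: PairedSeries, alpha: float = 0.05) -> dict:
    """Bland–Altman agreement: mean difference and 95% limits of agreement.

    Differences d = y - x; limits are mean(d) +/- 1.96 sd(d) (sample sd);
    the mean's CI uses the t distribution, each limit's CI the standard
    error sd*sqrt(3/n).
    """
    if s.n < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs")
    d = s.y - s.x
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = mean - 1.96 * sd, mean + 1.96 * sd
    t = stats.t.ppf(1 - alpha / 2, n - 1)
    se_mean = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(3.0 / n)
    return {
        "mean_diff": mean,
        "sd_diff": sd,
        "loa_low": loa_low,
        "loa_high": loa_high,
        "mean_ci": (mean - t * se_mean, mean + t * se_mean),
        "loa_low_ci": (loa_low - t * se_loa, loa_low + t * se_loa),
        "loa_high_ci": (loa_high - t * se_loa, loa_high + t * se_loa),
        "n": n,
    }


def correlate(s: PairedSeries) -> dict:
    """Pearson correlation with 0.3/0.5/0.7 strength grading."""
    if s.n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.ptp(s.x) == 0 or np.ptp(s.y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(s.x, s.y)
    if r > 0.7:
        grade = "strong"
    elif r > 0.5:
        grade = "moderate"
    elif r > 0.3:
        grade = "weak"
    else:
        grade = "negligible"
    return {"r": float(r), "p": float(p), "grade": grade, "n": s.n}


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    """Ranks of |d| with average ranks at ties."""
    return stats.rankdata(np.abs(d), method="average")


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p over all 2^n sign assignments.

    Tied absolute differences get average ranks; doubling makes every rank
    an integer, so the null distribution of W+ is built by polynomial
    (subset-sum) convolution rather than explicit enumeration.  The
    distribution is symmetric about its mean, so the two-sided p is the
    null mass at least as far from the mean as the observed statistic.
    """
    ranks = _signed_ranks(d)
    w_obs = float(ranks[d > 0].sum())
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    sums = np.arange(total + 1)
    mu = total / 2.0
    dev = abs(2.0 * w_obs - mu)
    p = float(counts[np.abs(sums - mu) >= dev - 1e-9].sum())
    return w_obs, min(p, 1.0)


def paired_wilcoxon(s: PairedSeries) -> dict:
    """Paired Wilcoxon signed-rank test on y - x (zeros dropped).

    Exact two-sided p for n <= 25 non-zero differences (valid with tied
    ranks); normal approximation with continuity correction beyond.  The
    statistic reported is W+, the positive-rank sum.
    """
    d = s.y - s.x
    nz = d[d != 0]
    if nz.size == 0:
        return {"statistic": 0.0, "p": 1.0, "n": 0, "degenerate": True}
    if nz.size < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    if nz.size <= 25:
        w_plus, p = _exact_signed_rank_p(nz)
    else:
        res = stats.wilcoxon(nz, correction=True, method="approx",
                             alternative="two-sided")
        w_plus = float(_signed_ranks(nz)[nz > 0].sum())
        p = float(res.pvalue)
    return {"statistic": w_plus, "p": p, "n": int(nz.size), "degenerate": False}


def ratio_summary(s: PairedSeries) -> dict:
    """Quartiles of measured/predicted ratios (type-7 linear interpolation)."""
    ok = s.x > 0
    if not np.all(ok):
        warnings.warn(f"{int((~ok).sum())} unit(s) with non-positive predicted value "
                      "excluded from ratio summary", stacklevel=2)
    ratios = s.y[ok] / s.x[ok]
    if ratios.size == 0:
        raise ValueError("no units with positive predicted values")
    q1, med, q3 = np.quantile(ratios, [0.25, 0.5, 0.75])
    return {"q1": float(q1), "median": float(med), "q3": float(q3),
            "n": int(ratios.size)}


# ---------------------------------------------------------------------------
# fixed-dose-criteria classification
# ---------------------------------------------------------------------------

def _bin_index(value: float, cuts: tuple[float, float]) -> int:
    """0: below both cuts, 1: between, 2: at/above the upper cut (boundary up)."""
    lo, hi = sorted(cuts)
    if value >= hi:
        return 2
    if value >= lo:
        return 1
    return 0


@dataclass
class CriteriaClassification:
    compartment: str
    main_threshold_gy: float
    bins_gy: tuple[float, float]
    categories: list[str]
    region_counts: dict[str, int]
    joint_histogram: np.ndarray     # rows: predicted bin, cols: measured bin

    def collapse_to_regions(self) -> dict[str, int]:
        """Recover the four 70 Gy (or 50 Gy) regions from the 3x3 histogram."""
        h = self.joint_histogram
        split = 1 if self.main_threshold_gy == min(self.bins_gy) else 2
        # predicted/measured >= main threshold <=> bin index >= split
        return {
            "concordant_above": int(h[split:, split:].sum()),
            "concordant_below": int(h[:split, :split].sum()),
            "measured_only_above": int(h[:split, split:].sum()),
            "predicted_only_above": int(h[split:, :split].sum()),
        }


def classify_criteria(s: PairedSeries, compartment: str) -> CriteriaClassification:
    """Classify units against fixed clinical dose criteria.

    Tumors: 70 Gy response threshold with a 100 Gy high-probability
    refinement (bins [0,70), [70,100), [100,inf)).  Normal tissue: 50 Gy
    safety threshold with a 40 Gy cirrhotic-liver refinement (bins [0,40),
    [40,50), [50,inf)).  A dose exactly at a cut goes to the upper bin.

    Categories (per unit): ``concordant_above``/``concordant_below`` when
    both maps agree about the main threshold; ``measured_only_above`` when
    the outcome was better than predicted; ``predicted_only_above`` when
    the prediction was falsely favorable (tumor) or falsely alarming (NTV
    reading: predicted risk that did not materialize).
    """
    if compartment == "tumor":
        main, other = TUMOR_THRESHOLDS
    elif compartment == "ntv":
        main, other = NTV_THRESHOLDS
    else:
        raise ValueError("compartment must be 'tumor' or 'ntv'")
    bins = (min(main, other), max(main, other))
    hist = np.zeros((3, 3), dtype=int)
    categories = []
    for xp, ym in zip(s.x, s.y):
        hist[_bin_index(xp, bins), _bin_index(ym, bins)] += 1
        pa, ma = xp >= main, ym >= main
        if pa and ma:
            categories.append("concordant_above")
        elif not pa and not ma:
            categories.append("concordant_below")
        elif ma:
            categories.append("measured_only_above")
        else:
            categories.append("predicted_only_above")
    counts = {c: categories.count(c) for c in
              ("concordant_above", "concordant_below",
               "measured_only_above", "predicted_only_above")}
    return CriteriaClassification(compartment, main, bins, categories, counts, hist)


def planned_vs_calculated(planned_gy: float, calculated_gy: float,
                          compartment: str) -> float:
    """Signed relative difference (%) between calculated and planned dose.

    The sign convention makes negative values clinically unfavorable on
    both sides: for NTV, negative means the parenchyma received *less*
    than planned (100*(calc-planned)/planned); for tumors, negative means
    the tumor received *more* than planned (100*(planned-calc)/planned),
    i.e. negative tumor values flag doses above plan.
    """
    if planned_gy <= 0:
        raise ValueError("planned dose must be positive")
    if compartment == "ntv":
        return 100.0 * (calculated_gy - planned_gy) / planned_gy
    if compartment == "tumor":
        return 100.0 * (planned_gy - calculated_gy) / planned_gy
    raise ValueError("compartment must be 'tumor' or 'ntv'")


def agreement_report(s: PairedSeries) -> dict:
    """Full agreement bundle for one paired dose parameter."""
    report = {
        "parameter": s.parameter,
        "units": s.units,
        "n": s.n,
        "pb": passing_bablok(s),
        "ba": bland_altman(s),
        "pearson": correlate(s),
        "ratio": ratio_summary(s),
    }
    try:
        report["wilcoxon"] = paired_wilcoxon(s)
    except ValueError as exc:
        report["wilcoxon"] = {"error": str(exc)}
    return report
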