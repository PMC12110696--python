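"""Clinical-validation statistics for method comparison, precision and agreement.

Covers the statistics a laboratory runs when validating an AI-assisted MRD
method against a manual reference: Deming (errors-in-variables) regression
with jackknife standard errors and group comparison, binary concordance with
exact Clopper–Pearson intervals, a noninferiority test on accuracy, a sample
size calculator for the quantitative comparison, repeatability /
within-laboratory variance components with chi-square upper verification
limits, Langton-style accordance / concordance / concordance odds ratio for
qualitative replicate agreement, tests of equal rater sensitivities and
specificities, and the LLOQ coefficient-of-variation check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from flowmrd.synthcyto import RaterTable

__all__ = [
    "DemingFit",
    "ConfusionCounts",
    "PrecisionResult",
    "AgreementStats",
    "Metric",
    "deming_fit",
    "compare_deming",
    "binary_concordance",
    "noninferiority_accuracy_test",
    "sample_size_quantitative",
    "precision_components",
    "verification_limit",
    "accordance_concordance",
    "equal_rates_test",
    "lloq_cv",
]


# ---------------------------------------------------------------------------
# Deming regression

@dataclass(frozen=True)
class DemingFit:
    """Errors-in-variables straight-line fit between two measurement methods."""

    slope: float
    intercept: float
    r: float
    se_slope: float
    se_intercept: float
    n: int
    lam: float


def _deming_coeffs(x: np.ndarray, y: np.ndarray, lam: float
                   ) -> tuple[float, float]:
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    syy = np.sum((y - ybar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    if sxy == 0:
        raise ValueError("degenerate fit: zero covariance between methods")
    disc = (syy - lam * sxx) ** 2 + 4 * lam * sxy**2
    slope = (syy - lam * sxx + math.sqrt(disc)) / (2 * sxy)
    return slope, ybar - slope * xbar


def deming_fit(x: Sequence[float], y: Sequence[float],
               lam: float = 1.0) -> DemingFit:
    """Deming regression of test method ``y`` on reference method ``x``.

    ``lam`` is the ratio of the y-error variance to the x-error variance
    (1 = orthogonal regression). Standard errors are delete-1 jackknife.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if lam <= 0:
        raise ValueError("lambda must be positive")

    slope, intercept = _deming_coeffs(x, y, lam)

    slopes = np.empty(n)
    intercepts = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        slopes[i], intercepts[i] = _deming_coeffs(x[mask], y[mask], lam)
        mask[i] = True
    fac = (n - 1) / n
    se_slope = math.sqrt(fac * np.sum((slopes - slopes.mean()) ** 2))
    se_intercept = math.sqrt(fac * np.sum((intercepts - intercepts.mean()) ** 2))

    r = float(np.corrcoef(x, y)[0, 1])
    return DemingFit(slope=slope, intercept=intercept, r=r,
                     se_slope=se_slope, se_intercept=se_intercept,
                     n=n, lam=lam)


def compare_deming(fit_a: DemingFit, fit_b: DemingFit
                   ) -> dict[str, float]:
    """Two-sided z-tests for equality of slopes and intercepts of two fits."""
    out = {}
    for name, a, b, se_a, se_b in (
        ("slope", fit_a.slope, fit_b.slope, fit_a.se_slope, fit_b.se_slope),
        ("intercept", fit_a.intercept, fit_b.intercept,
         fit_a.se_intercept, fit_b.se_intercept),
    ):
        pooled = math.hypot(se_a, se_b)
        if pooled == 0:
            if a == b:
                out[f"p_{name}"] = 1.0
                continue
            raise ValueError(f"zero pooled SE for {name}")
        z = (a - b) / pooled
        out[f"p_{name}"] = float(2 * stats.norm.sf(abs(z)))
    return out


# ---------------------------------------------------------------------------
# binary concordance

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class Metric:
    """Proportion with numerator/denominator and exact Clopper–Pearson CI."""

    value: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    @property
    def percent(self) -> float:
        return 100.0 * self.value


def clopper_pearson(x: int, n: int, alpha: float = 0.05
                    ) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval."""
    if n == 0:
        raise ValueError("n must be positive")
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _metric(x: int, n: int, alpha: float) -> Metric | None:
    if n == 0:
        return None
    low, high = clopper_pearson(x, n, alpha)
    return Metric(value=x / n, ci_low=low, ci_high=high,
                  numerator=x, denominator=n)


def binary_concordance(counts: ConfusionCounts, alpha: float = 0.05
                       ) -> dict[str, Metric | None]:
    """Accuracy, sensitivity, specificity, PPV, NPV with exact intervals.

    Ratios with an empty denominator are reported as ``None`` (absent), not 0.
    """
    if counts.total == 0:
        return {m: None for m in
                ("accuracy", "sensitivity", "specificity", "ppv", "npv")}
    return {
        "accuracy": _metric(counts.tp + counts.tn, counts.total, alpha),
        "sensitivity": _metric(counts.tp, counts.tp + counts.fn, alpha),
        "specificity": _metric(counts.tn, counts.tn + counts.fp, alpha),
        "ppv": _metric(counts.tp, counts.tp + counts.fp, alpha),
        "npv": _metric(counts.tn, counts.tn + counts.fn, alpha),
    }


def noninferiority_accuracy_test(observed_correct: int, n: int,
                                 p0: float = 0.975, alpha: float = 0.05
                                 ) -> dict[str, object]:
    """Exact one-sided binomial check that accuracy is not below ``p0``.

    The p-value is the lower-tail probability P(X <= observed | n, p0); the
    method passes when the observed proportion reaches p0 outright or the
    exact test fails to show it significantly below p0.
    """
    if observed_correct > n:
        raise ValueError("observed_correct exceeds n")
    p_value = float(stats.binom.cdf(observed_correct, n, p0))
    phat = observed_correct / n
    passed = phat >= p0 or p_value > alpha
    return {"pass": passed, "p_value": p_value, "observed": phat, "p0": p0}


def sample_size_quantitative(r_expected: float = 0.95,
                             slope_tol: float = 0.05,
                             alpha: float = 0.05,
                             beta: float = 0.20) -> dict[str, object]:
    """Sample size for detecting a Deming slope deviation of ``slope_tol``.

    Uses the large-sample approximation for the slope's standard error in an
    errors-in-variables fit, se(b) ≈ sqrt((1/r² − 1)/(n − 2)), inverted for
    the n at which a one-sided level-alpha test of |slope − 1| ≥ slope_tol
    has power 1 − beta:

        n = 2 + (1/r² − 1) · ((z_{1−α} + z_{1−β}) / slope_tol)²
    """
    if not 0 < r_expected < 1:
        raise ValueError("r_expected must be in (0, 1)")
    if slope_tol <= 0:
        raise ValueError("slope_tol must be positive")
    z_a = stats.norm.ppf(1 - alpha)
    z_b = stats.norm.ppf(1 - beta)
    raw = 2 + (1 / r_expected**2 - 1) * ((z_a + z_b) / slope_tol) ** 2
    n = max(3, math.ceil(raw))
    return {
        "n": n,
        "formula": "n = 2 + (1/r^2 - 1) * ((z_{1-alpha} + z_{1-beta}) / slope_tol)^2",
        "inputs": {"r_expected": r_expected, "slope_tol": slope_tol,
                   "alpha": alpha, "beta": beta},
    }


# ---------------------------------------------------------------------------
# precision

@dataclass(frozen=True)
class PrecisionResult:
    mean: float
    sd_repeatability: float
    sd_within_lab: float
    cv_repeatability: float
    cv_within_lab: float
    df_repeatability: int
    df_within_lab: int
    uvl_repeatability: float | None = None
    uvl_within_lab: float | None = None
    pass_repeatability: bool | None = None
    pass_within_lab: bool | None = None


def verification_limit(claimed_sd: float, df: int,
                       alpha: float = 0.05) -> float:
    """Upper verification limit for an observed SD against a claimed SD.

    One-sided chi-square bound: an observed SD exceeding
    claimed_sd * sqrt(chi2_{1-alpha, df} / df) is inconsistent with the
    claimed precision at level alpha.
    """
    if claimed_sd <= 0:
        raise ValueError("claimed_sd must be positive")
    if df < 1:
        raise ValueError("df must be >= 1")
    return claimed_sd * math.sqrt(stats.chi2.ppf(1 - alpha, df) / df)


def precision_components(
    values: pd.DataFrame,
    claimed_sd_repeatability: float | None = None,
    claimed_sd_within_lab: float | None = None,
    alpha: float = 0.05,
) -> PrecisionResult:
    """Repeatability and within-laboratory precision from a crossed design.

    ``values`` needs columns ``operator``, ``instrument``, ``value``; each
    operator x instrument combination is one run cell. Repeatability variance
    is the pooled within-cell variance; the within-laboratory variance adds
    the between-cell component estimated by the ANOVA method of moments
    (negative estimates truncated at zero). CVs are relative to the grand
    mean. When claimed SDs are given, chi-square upper verification limits
    and pass flags are attached.
    """
    required = {"operator", "instrument", "value"}
    if not required <= set(values.columns):
        raise ValueError(f"need columns {sorted(required)}")
    groups = values.groupby(["operator", "instrument"])["value"]
    sizes = groups.size()
    if len(sizes) < 2:
        raise ValueError("need at least 2 design cells")
    if sizes.nunique() != 1:
        raise ValueError("unbalanced design")
    n_rep = int(sizes.iloc[0])
    if n_rep < 2:
        raise ValueError("need at least 2 replicates per cell")
    n_cells = len(sizes)

    cell_means = groups.mean()
    cell_vars = groups.var(ddof=1)
    grand_mean = float(values["value"].mean())
    if grand_mean == 0:
        raise ValueError("grand mean is zero; CV undefined")

    var_rep = float(cell_vars.mean())
    var_between = max(0.0, float(cell_means.var(ddof=1)) - var_rep / n_rep)
    var_wl = var_rep + var_between

    sd_rep = math.sqrt(var_rep)
    sd_wl = math.sqrt(var_wl)
    df_rep = n_cells * (n_rep - 1)
    df_wl = n_cells * n_rep - 1

    uvl_rep = uvl_wl = p_rep = p_wl = None
    if claimed_sd_repeatability is not None:
        uvl_rep = verification_limit(claimed_sd_repeatability, df_rep, alpha)
        p_rep = sd_rep <= uvl_rep
    if claimed_sd_within_lab is not None:
        uvl_wl = verification_limit(claimed_sd_within_lab, df_wl, alpha)
        p_wl = sd_wl <= uvl_wl

    return PrecisionResult(
        mean=grand_mean,
        sd_repeatability=sd_rep,
        sd_within_lab=sd_wl,
        cv_repeatability=100.0 * sd_rep / grand_mean,
        cv_within_lab=100.0 * sd_wl / grand_mean,
        df_repeatability=df_rep,
        df_within_lab=df_wl,
        uvl_repeatability=uvl_rep,
        uvl_within_lab=uvl_wl,
        pass_repeatability=p_rep,
        pass_within_lab=p_wl,
    )


# ---------------------------------------------------------------------------
# qualitative agreement (Langton accordance / concordance)

@dataclass(frozen=True)
class AgreementStats:
    accordance: float
    concordance: float
    cor: float  # concordance odds ratio


def _sample_accordance(calls: np.ndarray) -> float:
    """Probability two same-rater replicates of one sample agree."""
    m = calls.shape[0]
    accs = []
    for k in range(calls.shape[1]):
        x = int(calls[:, k].sum())
        accs.append((x * (x - 1) + (m - x) * (m - x - 1)) / (m * (m - 1)))
    return float(np.mean(accs))


def _sample_concordance(calls: np.ndarray) -> float:
    """Probability two different-rater replicates of one sample agree."""
    m, n_r = calls.shape
    cons = []
    for i in range(n_r):
        for j in range(i + 1, n_r):
            xi, xj = int(calls[:, i].sum()), int(calls[:, j].sum())
            cons.append((xi * xj + (m - xi) * (m - xj)) / (m * m))
    return float(np.mean(cons))


def _odds_ratio(acc: float, con: float) -> float:
    if math.isclose(acc, con):
        return 1.0
    if con in (0.0, 1.0) or acc in (0.0, 1.0):
        return math.inf if acc > con else 0.0
    return (acc / (1 - acc)) / (con / (1 - con))


def accordance_concordance(table: RaterTable
                           ) -> tuple[pd.DataFrame, dict[bool, AgreementStats]]:
    """Langton accordance, concordance and concordance odds ratio.

    Accordance is the chance that two replicate results from the *same* rater
    agree; concordance the chance that results from *different* raters agree.
    Returns a per-sample table and study-level values averaged over samples
    within each truth class (positive / negative).
    """
    if table.calls.shape[1] < 2:
        raise ValueError("need >= 2 replicates per rater")
    rows = []
    for i in range(table.calls.shape[0]):
        acc = _sample_accordance(table.calls[i])
        con = _sample_concordance(table.calls[i])
        rows.append({"sample": i, "truth": bool(table.truth[i]),
                     "accordance": acc, "concordance": con,
                     "cor": _odds_ratio(acc, con)})
    per_sample = pd.DataFrame(rows)
    by_class = {}
    for truth_val, grp in per_sample.groupby("truth"):
        acc = float(grp["accordance"].mean())
        con = float(grp["concordance"].mean())
        by_class[bool(truth_val)] = AgreementStats(
            accordance=acc, concordance=con, cor=_odds_ratio(acc, con))
    return per_sample, by_class


# ---------------------------------------------------------------------------
# equal rates across raters

def _chi2_stat(correct: np.ndarray, totals: np.ndarray) -> float:
    """Pearson chi-square for homogeneity of R binomial proportions."""
    p = correct.sum() / totals.sum()
    if p in (0.0, 1.0):
        return 0.0
    expected_c = totals * p
    expected_w = totals * (1 - p)
    wrong = totals - correct
    return float(np.sum((correct - expected_c) ** 2 / expected_c
                        + (wrong - expected_w) ** 2 / expected_w))


def _rates_p_value(correct: np.ndarray, totals: np.ndarray,
                   n_mc: int, rng: np.random.Generator) -> dict[str, object]:
    stat = _chi2_stat(correct, totals)
    n_r = len(correct)
    p = correct.sum() / totals.sum()
    expected = np.concatenate([totals * p, totals * (1 - p)])
    if (expected >= 5).all():
        pval = float(stats.chi2.sf(stat, n_r - 1))
        method = "chi2"
    else:
        # permutation null: reassign pooled correct/wrong outcomes to raters
        # with per-rater totals fixed (multivariate hypergeometric)
        pool = np.repeat([1, 0], [int(correct.sum()),
                                  int(totals.sum() - correct.sum())])
        bounds = np.cumsum(totals).astype(int)
        starts = bounds - totals.astype(int)
        hits = 0
        for _ in range(n_mc):
            rng.shuffle(pool)
            perm_correct = np.array([
                pool[a:b].sum() for a, b in zip(starts, bounds)])
            if _chi2_stat(perm_correct, totals) >= stat - 1e-12:
                hits += 1
        pval = (hits + 1) / (n_mc + 1)
        method = "monte-carlo"
    return {"p_value": pval, "statistic": stat, "method": method,
            "correct": correct.tolist(), "totals": totals.tolist()}


def equal_rates_test(table: RaterTable, n_mc: int = 10_000,
                     seed: int = 0) -> dict[str, dict[str, object]]:
    """Tests of equal sensitivities, specificities and accuracies across raters.

    For each quantity, per-rater correct/incorrect counts (restricted to
    true-positive samples for sensitivity, true-negative for specificity)
    enter a chi-square homogeneity test; when any expected cell is below 5
    the p-value is computed by Monte-Carlo permutation of rater assignments.
    """
    n_raters = table.calls.shape[2]
    if n_raters < 2:
        raise ValueError("need >= 2 raters")
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, object]] = {}
    masks = {
        "sensitivity": table.truth,
        "specificity": ~table.truth,
        "accuracy": np.ones_like(table.truth, dtype=bool),
    }
    for name, mask in masks.items():
        if not mask.any():
            continue
        sub = table.calls[mask]           # samples x reps x raters
        truth = table.truth[mask]
        correct = (sub == truth[:, None, None]).sum(axis=(0, 1))
        totals = np.full(n_raters, sub.shape[0] * sub.shape[1])
        out[name] = _rates_p_value(correct.astype(float),
                                   totals.astype(float), n_mc, rng)
    return out


# ---------------------------------------------------------------------------
# LLOQ

def lloq_cv(replicates: Sequence[float],
            threshold: float = 30.0) -> dict[str, object]:
    """Intra-assay CV of an LLOQ replicate set; pass iff CV < threshold (%)."""
    vals = np.asarray(replicates, dtype=float)
    if len(vals) < 2:
        raise ValueError("need >= 2 replicate values")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("mean must be positive for a CV")
    cv = 100.0 * vals.std(ddof=1) / mean
    return {"cv": float(cv), "pass": bool(cv < threshold),
            "mean": float(mean), "threshold": threshold}
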