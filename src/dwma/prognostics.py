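"""Prognostic evaluation statistics for DWMA cohort analyses.

Covers the statistics used when evaluating DWMA as an early biomarker of
motor impairment: global brain abnormality (Kidokoro) categories, severe
DWMA dichotomization at a pre-specified percentile, 2x2 prognostic test
properties (sensitivity, specificity, likelihood ratios) with exact
Clopper-Pearson and log-method confidence intervals, Fisher's exact test,
Cohen's kappa for intra-rater agreement, OLS and logistic regression
(through statsmodels), and bias-corrected bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)


class PrognosticsError(ValueError):
    """Raised for invalid statistical inputs."""


# ---------------------------------------------------------------------------
# categorical coding
# ---------------------------------------------------------------------------

GLOBAL_CATEGORIES = ("normal", "mild", "moderate", "severe")


def classify_global_abnormality(score: int) -> str:
    """Kidokoro global abnormality category from the total score.

    0-3 normal, 4-7 mild, 8-11 moderate, >= 12 severe.
    """
    score = int(score)
    if score < 0:
        raise PrognosticsError("global abnormality score must be >= 0")
    if score <= 3:
        return "normal"
    if score <= 7:
        return "mild"
    if score <= 11:
        return "moderate"
    return "severe"


def dichotomize_severe(ndwma_values, percentile: float = 90.0) -> np.ndarray:
    """Severe-DWMA flags: strictly above the given percentile (default 90th).

    The percentile uses linear interpolation between order statistics; the
    strict inequality means that with all values equal nothing is flagged.
    """
    values = np.asarray(ndwma_values, dtype=float)
    if values.size == 0:
        raise PrognosticsError("cannot dichotomize an empty list")
    cut = np.percentile(values, percentile)
    return values > cut


# ---------------------------------------------------------------------------
# 2x2 prognostic test properties
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    """2x2 counts: predictor positive/negative x outcome present/absent."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fn, self.fp, self.tn):
            if v < 0:
                raise PrognosticsError("contingency counts must be >= 0")
        if self.total == 0:
            raise PrognosticsError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, predicted, outcome) -> "ContingencyTable":
        predicted = np.asarray(predicted, dtype=bool)
        outcome = np.asarray(outcome, dtype=bool)
        return cls(
            tp=int(np.sum(predicted & outcome)),
            fn=int(np.sum(~predicted & outcome)),
            fp=int(np.sum(predicted & ~outcome)),
            tn=int(np.sum(~predicted & ~outcome)),
        )


def exact_binomial_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a binomial proportion.

    lo = BetaQuantile(a/2; x, n-x+1) (0 when x=0),
    hi = BetaQuantile(1-a/2; x+1, n-x) (1 when x=n).
    """
    if n <= 0 or not 0 <= x <= n:
        raise PrognosticsError(f"invalid binomial counts x={x}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lo, hi


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p (probability-mass rule).

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table
    (within numerical slack).
    """
    _, p = stats.fisher_exact(
        [[table.tp, table.fn], [table.fp, table.tn]], alternative="two-sided"
    )
    return float(min(p, 1.0))


def _lr_log_ci(lr, num_x, num_n, den_x, den_n, level):
    """Log-method CI for a likelihood ratio from its two binomial counts."""
    if lr == 0 or not np.isfinite(lr) or 0 in (num_x, den_x):
        return (float("nan"), float("nan"))
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(
        (1.0 - num_x / num_n) / num_x + (1.0 - den_x / den_n) / den_x
    )
    return float(lr * np.exp(-z * se)), float(lr * np.exp(z * se))


@dataclass
class PrognosticProperties:
    """Sensitivity/specificity/likelihood ratios with 95% CIs, plus Fisher p."""

    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    lr_pos: float
    lr_pos_ci: tuple
    lr_neg: float
    lr_neg_ci: tuple
    fisher_p: float


def prognostic_properties(
    table: ContingencyTable, level: float = 0.95
) -> PrognosticProperties:
    """Diagnostic test properties of a 2x2 predictor-outcome table.

    LR+ = sens/(1-spec); LR- = (1-sens)/spec. Proportions get exact
    Clopper-Pearson intervals; likelihood ratios the standard log-method
    interval. A perfect specificity makes LR+ infinite (one-sided CI).
    """
    n_pos = table.tp + table.fn
    n_neg = table.fp + table.tn
    if n_pos == 0 or n_neg == 0:
        raise PrognosticsError(
            "need at least one outcome-positive and one outcome-negative subject"
        )
    sens = table.tp / n_pos
    spec = table.tn / n_neg
    sens_ci = exact_binomial_ci(table.tp, n_pos, level)
    spec_ci = exact_binomial_ci(table.tn, n_neg, level)

    if spec < 1.0:
        lr_pos = sens / (1.0 - spec)
        lr_pos_ci = _lr_log_ci(lr_pos, table.tp, n_pos, table.fp, n_neg, level)
    else:
        lr_pos = float("inf")
        lr_pos_ci = (float(sens / (1.0 - spec_ci[0])) if spec_ci[0] < 1 else float("inf"),
                     float("inf"))
    if spec > 0.0:
        lr_neg = (1.0 - sens) / spec
        lr_neg_ci = _lr_log_ci(lr_neg, table.fn, n_pos, table.tn, n_neg, level)
    else:
        lr_neg = float("inf")
        lr_neg_ci = (float("nan"), float("nan"))

    return PrognosticProperties(
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        lr_pos=lr_pos,
        lr_pos_ci=lr_pos_ci,
        lr_neg=lr_neg,
        lr_neg_ci=lr_neg_ci,
        fisher_p=fisher_exact(table),
    )


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


@dataclass
class KappaResult:
    """Cohen's kappa with its observed and chance-expected agreement."""

    p_o: float
    p_e: float
    kappa: float


def cohen_kappa(p_o: float, p_e: float) -> KappaResult:
    """Kappa from observed and expected agreement: (p_o - p_e)/(1 - p_e)."""
    if not 0.0 <= p_e < 1.0:
        raise PrognosticsError("expected agreement must lie in [0, 1)")
    return KappaResult(p_o=p_o, p_e=p_e, kappa=(p_o - p_e) / (1.0 - p_e))


def cohen_kappa_from_table(confusion) -> KappaResult:
    """Kappa from a square confusion matrix (rater 1 x rater 2 counts)."""
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise PrognosticsError("confusion matrix must be square")
    total = m.sum()
    if total <= 0:
        raise PrognosticsError("confusion matrix is empty")
    p_o = np.trace(m) / total
    p_e = float(np.sum(m.sum(axis=0) * m.sum(axis=1)) / total**2)
    return cohen_kappa(float(p_o), p_e)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Fitted coefficients with Wald CIs; ORs populated for logistic fits."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    n: int
    r2: float | None = None
    r2_adj: float | None = None
    odds_ratios: np.ndarray | None = None
    or_ci_low: np.ndarray | None = None
    or_ci_high: np.ndarray | None = None

    def coefficient(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])

    def standard_error(self, name: str) -> float:
        return float(self.se[self.names.index(name)])


def _as_design(X, names):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


def ols_fit(X, y, names=None, add_intercept: bool = True) -> RegressionResult:
    """Ordinary least squares with classical SEs and t-based 95% CIs."""
    X, names = _as_design(X, names)
    y = np.asarray(y, dtype=float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
        names = ["intercept"] + names
    if X.shape[0] <= X.shape[1]:
        raise PrognosticsError("need more observations than parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PrognosticsError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return RegressionResult(
        names=names,
        coef=np.asarray(res.params),
        se=np.asarray(res.bse),
        ci_low=np.asarray(ci)[:, 0],
        ci_high=np.asarray(ci)[:, 1],
        pvalues=np.asarray(res.pvalues),
        n=int(res.nobs),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
    )


def logistic_fit(X, y, names=None, add_intercept: bool = True) -> RegressionResult:
    """Logistic regression (Newton MLE) reporting odds ratios with Wald CIs."""
    X, names = _as_design(X, names)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise PrognosticsError("outcome must include both classes")
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
        names = ["intercept"] + names
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(method="newton", maxiter=50, tol=1e-8, disp=False)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        raise PrognosticsError(
            "logistic fit failed (possible complete separation); "
            "consider exact logistic methods"
        ) from exc
    ci = np.asarray(res.conf_int(alpha=0.05))
    return RegressionResult(
        names=names,
        coef=np.asarray(res.params),
        se=np.asarray(res.bse),
        ci_low=ci[:, 0],
        ci_high=ci[:, 1],
        pvalues=np.asarray(res.pvalues),
        n=int(res.nobs),
        odds_ratios=np.exp(np.asarray(res.params)),
        or_ci_low=np.exp(ci[:, 0]),
        or_ci_high=np.exp(ci[:, 1]),
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_bca_ci(
    sample,
    statistic,
    B: int = 10000,
    level: float = 0.95,
    seed: int | None = None,
    method: str = "bc",
) -> tuple[float, float]:
    """Bias-corrected (BC, default) or BCa bootstrap percentile interval.

    ``statistic`` maps a 1D (or row-resampled 2D) sample to a scalar. The
    bias correction z0 comes from the fraction of bootstrap replicates below
    the point estimate; BCa adds jackknife acceleration. Deterministic for a
    fixed seed.
    """
    sample = np.asarray(sample)
    n = sample.shape[0]
    if n < 10:
        raise PrognosticsError("bootstrap needs a sample of at least 10")
    if B < 1000:
        raise PrognosticsError("use at least 1000 bootstrap resamples")
    if method not in ("bc", "bca"):
        raise PrognosticsError("method must be 'bc' or 'bca'")
    rng = np.random.default_rng(seed)
    theta = float(statistic(sample))
    boot = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        boot[b] = statistic(sample[idx])

    if np.ptp(boot) == 0:
        warnings.warn("degenerate bootstrap statistic; returning point interval")
        return float(boot[0]), float(boot[0])

    prop = ((boot < theta).sum() + 0.5 * (boot == theta).sum()) / B
    prop = min(max(prop, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = stats.norm.ppf(prop)

    accel = 0.0
    if method == "bca":
        jack = np.array(
            [statistic(np.delete(sample, i, axis=0)) for i in range(n)]
        )
        d = jack.mean() - jack
        denom = 6.0 * (np.sum(d**2) ** 1.5)
        if denom > 0:
            accel = np.sum(d**3) / denom

    alpha = 1.0 - level
    out = []
    for a in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = stats.norm.ppf(a)
        adj = z0 + (z0 + z) / (1.0 - accel * (z0 + z))
        out.append(float(np.percentile(boot, 100.0 * stats.norm.cdf(adj))))
    return out[0], out[1]
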