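"""Two-sample MR estimators and study-style reporting arithmetic.

Implements the Wald ratio, inverse-variance weighted (IVW) estimation with
the fixed/multiplicative-random-effects model-selection rule (random
effects once there are more than three variants, floored at the
fixed-effects SE), simple and weighted median estimators with parametric
bootstrap SEs, MR-Egger regression with its intercept test for directional
pleiotropy, odds-ratio scaling per 10 mmHg decrease in the exposure, the
propagation-of-error test for a difference between two MR estimates, and
Bonferroni significance classification with a nominal band.

All estimators treat instruments as uncorrelated (they are clumped
upstream); IVW and Egger accept an optional LD correlation matrix for a
generalized weighted fit, off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet, orient_positive

#: 97.5% normal quantile used for every 95% CI
Z95 = 1.959964


@dataclass
class MRResult:
    """One estimator's causal-effect estimate.

    ``beta`` is log-odds of the outcome per +1 exposure unit (mmHg);
    ``or_scaled`` is the odds ratio per ``scale_factor`` exposure units
    (default -10: per 10 mmHg *decrease*).
    """

    method: str
    n_snps: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_scaled: float
    or_ci_low: float
    or_ci_high: float
    scale_factor: float = -10.0
    q_stat: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None


@dataclass
class DifferenceResult:
    """Propagation-of-error difference between two MR estimates (per +1 mmHg)."""

    beta_diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    pval: float


@dataclass
class SignificanceCall:
    pval: float
    threshold: float
    category: str  # significant | nominal | none


def _two_sided_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def scale_or(beta: float, se: float, factor: float = -10.0
             ) -> tuple[float, float, float]:
    """Rescale a log-odds-per-unit estimate to an odds ratio per ``factor`` units.

    Returns (or, ci_low, ci_high) with the CI ordered ascending regardless
    of the sign of ``factor``.
    """
    if se < 0:
        raise ValueError("se must be >= 0")
    or_point = float(np.exp(factor * beta))
    lo = float(np.exp(factor * beta - Z95 * abs(factor) * se))
    hi = float(np.exp(factor * beta + Z95 * abs(factor) * se))
    return or_point, lo, hi


def _finish(method: str, n_snps: int, beta: float, se: float,
            scale_factor: float, **extra) -> MRResult:
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    or_point, or_lo, or_hi = scale_or(beta, se, scale_factor)
    return MRResult(method=method, n_snps=n_snps, beta=beta, se=se,
                    ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
                    pval=_two_sided_p(z) if np.isfinite(z) else 0.0,
                    or_scaled=or_point, or_ci_low=or_lo, or_ci_high=or_hi,
                    scale_factor=scale_factor, **extra)


def wald_ratio(beta_y: float, se_y: float, beta_x: float,
               scale_factor: float = -10.0) -> MRResult:
    """Single-instrument ratio estimate beta_y/beta_x with first-order SE
    |se_y/beta_x| (exposure uncertainty ignored)."""
    if beta_x == 0:
        raise ValueError("beta_x must be nonzero for a Wald ratio")
    beta = beta_y / beta_x
    se = abs(se_y / beta_x)
    return _finish("wald", 1, beta, se, scale_factor)


def ivw(h: HarmonizedSet, scale_factor: float = -10.0,
        mre_min_snps: int = 4, ld: np.ndarray | None = None) -> MRResult:
    """Inverse-variance weighted estimate (weighted regression through the origin).

    With more than three variants (``n_snps >= mre_min_snps``) a
    multiplicative random-effects SE is used: the fixed-effects SE scaled by
    max(1, sqrt(Q/(n-1))); otherwise fixed effects.  A single instrument
    reduces to the Wald ratio.  Passing ``ld`` (correlation matrix in SNP
    order) switches to the generalized fit accounting for correlated
    instruments.
    """
    n = h.n_snps
    if n == 0:
        raise ValueError("empty instrument set")
    if n == 1:
        return wald_ratio(float(h.beta_y[0]), float(h.se_y[0]),
                          float(h.beta_x[0]), scale_factor)
    bx, by, sy = h.beta_x, h.beta_y, h.se_y
    if ld is not None:
        omega = ld * np.outer(sy, sy)
        oi = np.linalg.solve(omega, np.column_stack([bx, by]))
        denom = float(bx @ oi[:, 0])
        beta = float(bx @ oi[:, 1]) / denom
        se_fixed = denom ** -0.5
        resid = by - beta * bx
        q = float(resid @ np.linalg.solve(omega, resid))
    else:
        w = 1.0 / sy ** 2
        denom = float(np.sum(w * bx ** 2))
        beta = float(np.sum(w * bx * by)) / denom
        se_fixed = denom ** -0.5
        q = float(np.sum(w * (by - beta * bx) ** 2))
    if n >= mre_min_snps:
        se = se_fixed * max(1.0, np.sqrt(q / (n - 1)))
        method = "ivw_mre"
    else:
        se = se_fixed
        method = "ivw_fixed"
    return _finish(method, n, beta, se, scale_factor, q_stat=q)


def _bootstrap_se(h: HarmonizedSet, point_fn, n_boot: int,
                  seed: int | None) -> float:
    """Parametric bootstrap SD of a ratio-median estimator: resample
    (beta_x_j, beta_y_j) from normals at their SEs and recompute."""
    rng = np.random.default_rng(seed)
    n = h.n_snps
    bx = h.beta_x + h.se_x * rng.standard_normal((n_boot, n))
    by = h.beta_y + h.se_y * rng.standard_normal((n_boot, n))
    est = np.array([point_fn(bx[i], by[i], h.se_y) for i in range(n_boot)])
    return float(est.std(ddof=1))


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    # cumulative weight at each ratio, measured at the centre of its mass
    p = np.cumsum(w) - 0.5 * w
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    k = int(np.searchsorted(p, 0.5) - 1)
    return float(r[k] + (r[k + 1] - r[k]) * (0.5 - p[k]) / (p[k + 1] - p[k]))


def simple_median(h: HarmonizedSet, n_boot: int = 5000,
                  seed: int | None = 0,
                  scale_factor: float = -10.0) -> MRResult:
    """Median of the per-SNP Wald ratios; SE by parametric bootstrap."""
    if h.n_snps < 3:
        raise ValueError("insufficient instruments (need >= 3)")
    beta = float(np.median(h.ratios()))
    se = _bootstrap_se(
        h, lambda bx, by, sy: np.median(by / bx), n_boot, seed)
    return _finish("simple_median", h.n_snps, beta, se, scale_factor)


def weighted_median(h: HarmonizedSet, n_boot: int = 5000,
                    seed: int | None = 0,
                    scale_factor: float = -10.0) -> MRResult:
    """50th weighted percentile of ordered Wald ratios, weights beta_x^2/se_y^2
    (inverse variance of each ratio, first order); bootstrap SE."""
    if h.n_snps < 3:
        raise ValueError("insufficient instruments (need >= 3)")

    def point(bx, by, sy):
        return _weighted_median_point(by / bx, bx ** 2 / sy ** 2)

    beta = point(h.beta_x, h.beta_y, h.se_y)
    se = _bootstrap_se(h, point, n_boot, seed)
    return _finish("weighted_median", h.n_snps, beta, se, scale_factor)


def mr_egger(h: HarmonizedSet, scale_factor: float = -10.0,
             intercept_reference: str = "normal") -> MRResult:
    """MR-Egger: weighted least squares of beta_y on beta_x with intercept.

    Inputs are first oriented so every beta_x > 0 (the intercept is defined
    relative to the exposure-raising allele).  Both SEs carry the
    multiplicative residual-dispersion inflation max(1, sqrt(Q/(n-2))).
    A nonzero intercept indicates directional pleiotropy.
    """
    if h.n_snps < 3:
        raise ValueError("insufficient instruments (need >= 3)")
    h = orient_positive(h)
    x, y, w = h.beta_x, h.beta_y, 1.0 / h.se_y ** 2
    if np.ptp(x) == 0:
        raise ValueError("collinear design: all beta_x equal")
    # closed-form weighted normal equations
    sw, swx, swx2 = w.sum(), (w * x).sum(), (w * x ** 2).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    det = sw * swx2 - swx ** 2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swx2 * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    q = float((w * resid ** 2).sum())
    phi = q / (h.n_snps - 2)
    infl = max(1.0, np.sqrt(phi))
    se_slope = np.sqrt(sw / det) * infl
    se_int = np.sqrt(swx2 / det) * infl
    if intercept_reference == "t":
        p_int = float(2 * stats.t.sf(abs(intercept / se_int), h.n_snps - 2))
    else:
        p_int = _two_sided_p(intercept / se_int)
    return _finish("egger", h.n_snps, float(slope), float(se_slope),
                   scale_factor, q_stat=q,
                   egger_intercept=float(intercept),
                   egger_intercept_se=float(se_int),
                   egger_intercept_p=p_int)


def recover_p_from_ci(estimate: float, ci_low: float, ci_high: float,
                      scale: str = "identity") -> float:
    """Back out the two-sided p-value implied by an estimate and its 95% CI.

    ``scale="log"`` treats the three inputs as an OR with CI (the Wald
    interval is symmetric on the log scale); ``"identity"`` treats them as a
    beta with CI.
    """
    if not ci_low < ci_high:
        raise ValueError("require ci_low < ci_high")
    if scale == "log":
        if min(estimate, ci_low, ci_high) <= 0:
            raise ValueError("log scale requires positive estimate and CI")
        t = np.log
    elif scale == "identity":
        def t(v):
            return v
    else:
        raise ValueError(f"unknown scale {scale!r}")
    se = (t(ci_high) - t(ci_low)) / (2 * Z95)
    return _two_sided_p(t(estimate) / se)


def difference_test(beta_drug: float, se_drug: float,
                    beta_ref: float, se_ref: float) -> DifferenceResult:
    """Propagation-of-error z-test for a difference between two independent MR
    estimates (drug-target vs general exposure-lowering), per +1 mmHg."""
    if se_drug <= 0 or se_ref <= 0:
        raise ValueError("standard errors must be positive")
    beta_diff = beta_drug - beta_ref
    se_diff = float(np.sqrt(se_drug ** 2 + se_ref ** 2))
    return DifferenceResult(
        beta_diff=beta_diff, se_diff=se_diff,
        ci_low=beta_diff - Z95 * se_diff, ci_high=beta_diff + Z95 * se_diff,
        pval=_two_sided_p(beta_diff / se_diff))


def bonferroni_classify(pval: float, n_tests: int) -> SignificanceCall:
    """Classify a p-value against 0.05/n_tests, with a nominal band up to 0.05."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = 0.05 / n_tests
    if pval < threshold:
        category = "significant"
    elif pval < 0.05:
        category = "nominal"
    else:
        category = "none"
    return SignificanceCall(pval=pval, threshold=threshold, category=category)
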