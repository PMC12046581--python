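"""Enumeration-based colocalization of two traits over a region.

Each SNP's evidence of association with a trait is summarized by a
Wakefield approximate Bayes factor; under the one-causal-variant-per-trait
assumption the posterior mass of the five hypotheses

    H0 no association, H1 trait-1 only, H2 trait-2 only,
    H3 two distinct causal variants, H4 one shared causal variant

is an enumeration over SNP configurations with per-SNP priors p1, p2 and
p12.  All sums are done in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    n_snps: int
    pp: dict[str, float]  # keys H0..H4
    priors: tuple[float, float, float]  # (p1, p2, p12)

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]

    @property
    def pp_h3(self) -> float:
        return self.pp["H3"]


#: reference defaults for the per-SNP effect-size prior SD
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.2


def log_abf(beta, se, prior_sd: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor for one (or a vector of) SNP(s).

    With V = se^2, W = prior_sd^2, r = W/(V+W), z = beta/se:
    log ABF = 0.5*(log(1-r) + r z^2).  Positive when the data favour
    association over the point null.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se ** 2
    w = prior_sd ** 2
    r = w / (v + w)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z ** 2)


def coloc_pp(labf1, labf2, p1: float = 1e-4, p2: float = 1e-4,
             p12: float = 1e-5) -> ColocResult:
    """Posterior hypothesis probabilities from per-SNP log ABFs of two traits.

    Vectors must be SNP-aligned.  Unnormalized masses: L0 = 1,
    L1 = p1*S1, L2 = p2*S2, L3 = p1*p2*(S1*S2 - S12), L4 = p12*S12 where
    S1, S2, S12 are sums of exp(labf1), exp(labf2), exp(labf1+labf2);
    evaluated with log-sum-exp throughout.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.ndim != 1:
        raise ValueError("labf vectors must be 1-D and the same length")
    m = len(labf1)
    if m < 1:
        raise ValueError("need at least one SNP")

    ls1 = float(logsumexp(labf1))
    ls2 = float(logsumexp(labf2))
    ls12 = float(logsumexp(labf1 + labf2))

    l0 = 0.0
    l1 = np.log(p1) + ls1
    l2 = np.log(p2) + ls2
    l4 = np.log(p12) + ls12
    # S1*S2 - S12 = sum over ordered pairs (i != j); for m = 1 it is exactly 0
    if m == 1:
        l3 = -np.inf
    else:
        # stable log(exp(a) - exp(b)) with a = ls1+ls2 >= b = ls12
        a, b = ls1 + ls2, ls12
        diff = -np.expm1(b - a)  # 1 - exp(b-a) >= 0
        l3 = np.log(p1) + np.log(p2) + (a + np.log(diff) if diff > 0 else -np.inf)

    logs = np.array([l0, l1, l2, l3, l4])
    denom = logsumexp(logs)
    pp = np.exp(logs - denom)
    return ColocResult(n_snps=m,
                       pp={f"H{i}": float(pp[i]) for i in range(5)},
                       priors=(p1, p2, p12))


def coloc_from_tables(beta1, se1, beta2, se2,
                      prior_sd1: float = PRIOR_SD_QUANTITATIVE,
                      prior_sd2: float = PRIOR_SD_BINARY,
                      p1: float = 1e-4, p2: float = 1e-4,
                      p12: float = 1e-5) -> ColocResult:
    """Convenience wrapper: ABFs from aligned effect/SE vectors, then enumeration."""
    return coloc_pp(log_abf(beta1, se1, prior_sd1),
                    log_abf(beta2, se2, prior_sd2), p1=p1, p2=p2, p12=p12)
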