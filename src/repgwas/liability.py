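"""Analytic liability-threshold transformations for binary traits.

A binary phenotype is modelled as y = 1 iff the Gaussian liability
``y_u = g_dose * beta_u + u`` exceeds a threshold tau, with ``u`` the non-QTL
liability (variance sigma_u^2) and tau expressed relative to the mean
liability of common-allele homozygotes.  These functions map the underlying
additive effect and threshold to what a linear (0/1-response) GWAS is
expected to estimate: the penetrance per genotype, the least-squares slope of
penetrance on dosage under Hardy-Weinberg weights, and the first-order
observed-scale genetic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .errors import DataError

__all__ = [
    "ThresholdModel",
    "penetrance",
    "expected_observed_slope",
    "solve_allele_freq",
    "expected_observed_genetic_variance",
    "expected_table",
]


@dataclass(frozen=True)
class ThresholdModel:
    """Liability-scale parameters of a single bi-allelic QTL.

    beta_u: additive liability effect per non-reference allele;
    tau: threshold relative to the common-homozygote liability mean;
    sigma_u2: non-QTL liability variance; p: non-reference allele frequency
    (Hardy-Weinberg proportions assumed).
    """

    beta_u: float
    tau: float
    sigma_u2: float
    p: float = None

    def __post_init__(self):
        if self.sigma_u2 <= 0:
            raise DataError("sigma_u2 must be positive")
        if self.p is not None and not (0.0 < self.p < 1.0):
            raise DataError("allele frequency must lie in (0, 1)")

    def _hwe_weights(self):
        p = self.p
        return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


def penetrance(model: ThresholdModel, genotype) -> np.ndarray | float:
    """P(y = 1 | dosage) = Phi((dosage * beta_u - tau) / sqrt(sigma_u2))."""
    g = np.asarray(genotype, dtype=float)
    val = stats.norm.cdf((g * model.beta_u - model.tau) / np.sqrt(model.sigma_u2))
    return float(val) if val.ndim == 0 else val


def population_fraction_ones(model: ThresholdModel) -> float:
    """HWE-weighted mean penetrance."""
    if model.p is None:
        raise DataError("model has no allele frequency")
    return float(model._hwe_weights() @ penetrance(model, [0, 1, 2]))


def expected_observed_slope(model: ThresholdModel) -> float:
    """Expected 0/1-scale regression slope of the trait on dosage.

    ``Cov(E[y|g], g) / Var(g)`` with g ~ Binomial(2, p): the estimand of the
    linear scan applied to a thresholded liability.
    """
    if model.p is None:
        raise DataError("model has no allele frequency")
    w = model._hwe_weights()
    g = np.array([0.0, 1.0, 2.0])
    pi = penetrance(model, g)
    mean_g = 2.0 * model.p
    var_g = 2.0 * model.p * (1.0 - model.p)
    cov = float(w @ (pi * (g - mean_g)))
    return cov / var_g


def solve_allele_freq(model: ThresholdModel, fraction_ones: float) -> float:
    """Invert the population fraction of ones for the allele frequency.

    The fraction is monotone in p between penetrance(0) and penetrance(2)
    (direction set by the sign of beta_u); solved by bracketing to 1e-10.
    """
    pi = penetrance(model, [0.0, 1.0, 2.0])
    lo, hi = min(pi[0], pi[2]), max(pi[0], pi[2])
    if not (lo < fraction_ones < hi):
        raise DataError(
            f"fraction {fraction_ones} outside attainable range ({lo:.4g}, {hi:.4g})"
        )

    def f(p):
        return population_fraction_ones(replace(model, p=p)) - fraction_ones

    return float(optimize.brentq(f, 1e-12, 1.0 - 1e-12, xtol=1e-10))


def expected_observed_genetic_variance(
    sigma_g2: float, sigma_u2: float, tau: float = 0.0
) -> float:
    """First-order observed-scale polygenic variance of a thresholded trait.

    ``phi(tau / sqrt(sigma_u2))^2 * sigma_g2 / sigma_u2`` — the liability->
    observed transform at the threshold (phi the standard normal density).
    """
    if sigma_g2 < 0 or sigma_u2 < sigma_g2 or sigma_u2 <= 0:
        raise DataError("need sigma_u2 >= sigma_g2 >= 0 and sigma_u2 > 0")
    dens = stats.norm.pdf(tau / np.sqrt(sigma_u2))
    return float(dens * dens * sigma_g2 / sigma_u2)


def expected_table(beta_u, sigma_u2, taus, fractions) -> "pd.DataFrame":
    """Expected observed-scale estimates for (tau, population fraction) pairs."""
    import pandas as pd

    rows = []
    for tau, frac in zip(taus, fractions):
        base = ThresholdModel(beta_u=beta_u, tau=tau, sigma_u2=sigma_u2)
        p = solve_allele_freq(base, frac)
        slope = expected_observed_slope(replace(base, p=p))
        rows.append(
            {"tau": tau, "fraction_ones": frac, "allele_freq": p,
             "expected_slope": slope}
        )
    return pd.DataFrame(rows)
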