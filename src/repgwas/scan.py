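"""Stage 2: rotated generalized least squares single-SNP association scan.

With V0 the marginal covariance fitted by the SNP-free model, each SNP is
tested in

    y = X beta + x_snp beta_snp + e,   e ~ N(0, V0 sigma^2),

by whitening with the eigendecomposition V0 = Gamma Lambda Gamma'
(premultiplying by Lambda^{-1/2} Gamma') and solving ordinary least squares;
the Wald statistic beta_snp_hat / SE is referred to the standard normal.  Two
algebraically identical code paths are provided: an explicit
rotation-plus-QR path (the reference algorithm, with the fixed-effect block
residualized once and reused across SNPs) and a Woodbury path that forms the
same V0^-1 inner products through the low-rank structure of V0 without ever
materializing an N x N matrix — the default for large N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .genotypes import GenotypeMatrix
from .null_model import NullFit, build_design

logger = logging.getLogger(__name__)

__all__ = [
    "RotationOperator",
    "ScanResult",
    "make_rotation",
    "scan",
    "inflation_lambda",
    "wald_p",
    "bonferroni_threshold",
]

_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...
_EIGEN_FLOOR_REL = 1e-8


@dataclass
class RotationOperator:
    """Whitening operator Lambda^{-1/2} Gamma' from V0 = Gamma Lambda Gamma'."""

    gamma: np.ndarray  # N x N orthonormal eigenvector matrix
    lam: np.ndarray  # N eigenvalues, all > 0 after flooring

    def whiten(self, v: np.ndarray) -> np.ndarray:
        """Apply Lambda^{-1/2} Gamma' to an observation-level vector or matrix."""
        out = self.gamma.T @ v
        scale = 1.0 / np.sqrt(self.lam)
        return out * (scale[:, None] if out.ndim == 2 else scale)


def make_rotation(null_fit: NullFit) -> RotationOperator:
    """Eigendecompose the fitted V0 and return the whitening operator.

    Eigenvalues below ``1e-8 * max`` are floored there before inversion; a
    non-positive eigenvalue after flooring is an error.
    """
    V0 = null_fit.v0_matrix()
    lam, gamma = np.linalg.eigh(V0)
    floor = _EIGEN_FLOOR_REL * lam.max()
    lam = np.maximum(lam, floor)
    if lam.min() <= 0:
        raise DataError("V0 has a non-positive eigenvalue after flooring")
    return RotationOperator(gamma=gamma, lam=lam)


@dataclass
class ScanResult:
    """Per-SNP effect estimates and Wald tests, plus scan-level metadata."""

    table: pd.DataFrame  # snp_id chrom pos maf n_used beta se z p flag
    lambda_gc: float
    components: object
    n: int
    N: int
    method: str

    def __len__(self):
        return len(self.table)

    def neglog10p(self) -> np.ndarray:
        return -np.log10(self.table["p"].to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        c = self.components
        with open(path, "w") as fh:
            fh.write(
                f"# repgwas scan: n={self.n} N={self.N} "
                f"sigma_g2={c.sigma_g2:.6g} sigma_p2={c.sigma_p2:.6g} "
                f"sigma_e2={c.sigma_e2:.6g} lambda={self.lambda_gc:.4f}\n"
            )
            self.table.to_csv(fh, sep="\t", index=False)


def wald_p(statistic) -> np.ndarray | float:
    """Two-sided standard-normal tail probability, clipped into (0, 1]."""
    z = np.asarray(statistic, dtype=float)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return float(p) if np.isscalar(statistic) or p.ndim == 0 else p


def inflation_lambda(p_values, method: str = "median") -> float:
    """Genomic-control inflation factor from a vector of scan p-values.

    ``median``: ratio of the median implied 1-df chi-square statistic to its
    null expectation (0.4549...).  ``regression``: zero-intercept regression
    of the ordered observed statistics on their null quantiles.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 10:
        raise DataError(f"need >=10 finite p-values to estimate lambda, got {len(p)}")
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    if method == "median":
        return float(np.median(chi2) / _CHI2_MEDIAN)
    if method == "regression":
        obs = np.sort(chi2)
        exp = stats.chi2.ppf((np.arange(1, len(p) + 1) - 0.5) / len(p), df=1)
        return float(np.sum(exp * obs) / np.sum(exp * exp))
    raise ValueError(f"unknown lambda method {method!r}")


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise p-value cutoff; offered as a helper, not applied by scan."""
    return alpha / n_tests


def _check_pheno_matches(pheno, null_fit, trait, id_col):
    y = pheno[trait].to_numpy(dtype=float)
    if len(y) != null_fit.N or not np.allclose(y, null_fit.y):
        raise DataError("phenotype table does not match the one used for the null fit")
    ids = pheno[id_col].to_numpy(dtype=object)
    pos = {v: k for k, v in enumerate(null_fit.individual_ids)}
    offenders = sorted({i for i in ids if i not in pos})
    if offenders:
        raise DataError(f"phenotype ids unknown to the null fit: {offenders[:5]}")
    idx = np.array([pos[i] for i in ids])
    if not np.array_equal(idx, null_fit.ind_index):
        raise DataError("phenotype rows are ordered differently than in the null fit")


def scan(
    pheno: pd.DataFrame,
    genotypes: GenotypeMatrix,
    null_fit: NullFit,
    covariates=None,
    trait: str = "value",
    id_col: str = "id",
    method: str = "auto",
    lambda_method: str = "median",
    snp_subset=None,
) -> ScanResult:
    """Test every SNP by rotated GLS against the fitted V0.

    Missing dosages are mean-imputed (2 p-hat per SNP); SNPs with zero dosage
    variance after imputation are flagged ``monomorphic`` and excluded from
    the inflation factor.  ``snp_subset`` restricts the scan to the given
    column indices (results keep SNP metadata).
    """
    covariates = list(covariates if covariates is not None else null_fit.covariates)
    if covariates != null_fit.covariates:
        raise DataError("scan covariates must match the null-model covariates")
    _check_pheno_matches(pheno, null_fit, trait, id_col)
    X, _ = build_design(pheno, covariates)
    if not np.allclose(X, null_fit.X):
        raise DataError("fixed-effect design differs from the null fit")
    gm = genotypes.subset_individuals(null_fit.individual_ids)
    if snp_subset is not None:
        gm = gm.subset_snps(np.asarray(snp_subset))
    Xdos = gm.imputed()  # n x m, mean-imputed
    maf = gm.maf
    n_used = (~np.isnan(gm.dosages)).sum(axis=0)
    y = null_fit.y
    N, q = X.shape
    m = Xdos.shape[1]
    if method == "auto":
        method = "rotation" if N <= 600 else "woodbury"

    if method == "rotation":
        rot = make_rotation(null_fit)
        ystar = rot.whiten(y)
        Xstar = rot.whiten(X)
        from .null_model import incidence_matrix

        Z = incidence_matrix(null_fit.ind_index, null_fit.n)
        Sstar = rot.whiten(Z @ Xdos)
        Q, _ = np.linalg.qr(Xstar)
        yr = ystar - Q @ (Q.T @ ystar)
        Sr = Sstar - Q @ (Q.T @ Sstar)
        ctil = np.einsum("ij,ij->j", Sr, Sr)
        dtil = Sr.T @ yr
        base_rss = float(yr @ yr)
    elif method == "woodbury":
        from scipy.linalg import cho_factor, cho_solve

        # all V0^-1 products via V0^-1 = (I - Z T~ Z') / sigma_e^2
        se2 = null_fit.components.sigma_e2
        t_tilde = null_fit.t_tilde
        d = null_fit.counts.astype(float)
        K = null_fit.ztv0inv_z()
        ZtX = np.vstack(
            [np.bincount(null_fit.ind_index, weights=X[:, j], minlength=null_fit.n)
             for j in range(q)]
        ).T
        Zty = np.bincount(null_fit.ind_index, weights=y, minlength=null_fit.n)
        ZWX = (ZtX - d[:, None] * (t_tilde @ ZtX)) / se2
        ZWy = (Zty - d * (t_tilde @ Zty)) / se2
        XWX = (X.T @ X - ZtX.T @ t_tilde @ ZtX) / se2
        XWy = (X.T @ y - ZtX.T @ (t_tilde @ Zty)) / se2
        yWy = (float(y @ y) - float(Zty @ t_tilde @ Zty)) / se2
        sWs = np.einsum("nm,nm->m", Xdos, K @ Xdos)
        SWX = Xdos.T @ ZWX  # m x q   (ZWX = Z'V0^-1 X)
        sWy = Xdos.T @ ZWy
        cf = cho_factor((XWX + XWX.T) / 2.0)
        CiXWy = cho_solve(cf, XWy)
        CiA = cho_solve(cf, SWX.T)  # q x m
        ctil = sWs - np.einsum("mq,qm->m", SWX, CiA)
        dtil = sWy - SWX @ CiXWy
        base_rss = yWy - float(XWy @ CiXWy)
    else:
        raise ValueError(f"unknown scan method {method!r}")

    flagged = ctil <= 1e-10 * max(1.0, float(np.nanmax(np.abs(ctil))))
    ctil_safe = np.where(flagged, np.nan, ctil)
    beta = dtil / ctil_safe
    rss = base_rss - dtil**2 / ctil_safe
    dof = N - q - 1
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / ctil_safe)
    z = beta / se
    p = np.where(np.isnan(z), np.nan, wald_p(np.nan_to_num(z)))

    if (~flagged).sum() >= 10:
        lam = inflation_lambda(p[~flagged], method=lambda_method)
    else:  # single-SNP / tiny scans: lambda is not estimable
        lam = float("nan")
    table = pd.DataFrame(
        {
            "snp_id": gm.snp_ids,
            "chrom": gm.snp_meta["chrom"].to_numpy(),
            "pos": gm.snp_meta["pos"].to_numpy(),
            "maf": maf,
            "n_used": n_used,
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "flag": np.where(flagged, "monomorphic", ""),
        }
    )
    logger.info("scan: %d SNPs, method=%s, lambda=%.3f", m, method, lam)
    return ScanResult(
        table=table,
        lambda_gc=lam,
        components=null_fit.components,
        n=null_fit.n,
        N=N,
        method=method,
    )
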