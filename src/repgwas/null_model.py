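"""Stage 1: REML fit of the SNP-free repeated-measures mixed model.

The model for N observations on n individuals is

    y = X beta + Z g + Z p + eps,
    g ~ N(0, sigma_g^2 G),  p ~ N(0, sigma_p^2 I_n),  eps ~ N(0, sigma_e^2 I_N),

with Z the 0/1 incidence matrix mapping observations to individuals and G the
genomic relationship matrix.  The marginal covariance is

    V = Z G Z' sigma_g^2 + Z Z' sigma_p^2 + I_N sigma_e^2.

Variance components are estimated by REML, profiling sigma_e^2 out in closed
form and optimizing the two variance ratios gamma_g = sigma_g^2/sigma_e^2 and
gamma_p = sigma_p^2/sigma_e^2 on the log scale.  All linear algebra exploits
the low-rank structure V = Z A Z' + sigma_e^2 I (A = sigma_g^2 G +
sigma_p^2 I), so each criterion evaluation costs O(n^3) — or O(n) once the
GRM eigendecomposition is cached, when every individual has the same number
of observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .errors import ConvergenceError, DataError
from .genotypes import RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "NullFit",
    "build_design",
    "build_V",
    "incidence_matrix",
    "reml_loglik",
    "fit_null",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_LOG_GAMMA_LO, _LOG_GAMMA_HI = -13.8, 9.2  # gamma in ~[1e-6, 1e4]


@dataclass
class VarianceComponents:
    """Estimated (or assumed) variance components of the repeated-measures model."""

    sigma_g2: float
    sigma_p2: float
    sigma_e2: float
    boundary: tuple = ()  # names of components floored at the lower bound

    def __post_init__(self):
        for name in ("sigma_g2", "sigma_p2", "sigma_e2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DataError(f"{name}={v!r} is not a finite non-negative value")

    @property
    def total(self) -> float:
        return self.sigma_g2 + self.sigma_p2 + self.sigma_e2


def incidence_matrix(ind_index: np.ndarray, n: int) -> np.ndarray:
    """Dense N x n incidence matrix Z from the obs -> individual index."""
    Z = np.zeros((len(ind_index), n))
    Z[np.arange(len(ind_index)), ind_index] = 1.0
    return Z


def build_design(pheno: pd.DataFrame, covariates=None):
    """Fixed-effect design matrix: intercept plus the named covariate columns.

    Numeric columns enter as-is; object/categorical columns are dummy-coded
    with the first level as reference.  Raises on rank deficiency, naming the
    collinear columns.
    """
    covariates = list(covariates or [])
    cols = [pd.Series(1.0, index=pheno.index, name="(intercept)")]
    for c in covariates:
        if c not in pheno.columns:
            raise DataError(f"covariate column {c!r} not in phenotype table")
        s = pheno[c]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype("category"), prefix=c, drop_first=True)
            cols.extend(dummies[c].astype(float) for c in dummies.columns)
    X = pd.concat(cols, axis=1)
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name offending columns: those whose removal restores full rank
        bad = []
        for j in range(1, mat.shape[1]):
            sub = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(mat):
                bad.append(X.columns[j])
        raise DataError(f"fixed-effect design is rank deficient; collinear: {bad}")
    return mat, list(X.columns)


def build_V(Z: np.ndarray, G: np.ndarray, components: VarianceComponents) -> np.ndarray:
    """Dense marginal covariance V = ZGZ' sigma_g^2 + ZZ' sigma_p^2 + I sigma_e^2."""
    Z = np.asarray(Z, dtype=float)
    G = np.asarray(G, dtype=float)
    if Z.ndim != 2 or G.shape != (Z.shape[1], Z.shape[1]):
        raise DataError(
            f"dimension mismatch: Z is {Z.shape}, G is {G.shape}"
        )
    N = Z.shape[0]
    V = (
        components.sigma_g2 * (Z @ G @ Z.T)
        + components.sigma_p2 * (Z @ Z.T)
        + components.sigma_e2 * np.eye(N)
    )
    return (V + V.T) / 2.0


def reml_loglik(components: VarianceComponents, y, X, Z, G) -> float:
    """Restricted log-likelihood of the mixed model at the given components.

    Dense O(N^3) evaluation:
    ``-0.5 [ log|V| + log|X'V^-1 X| + y'Py + (N-q) log 2 pi ]`` with P the
    REML projection matrix.  Used as the reference criterion; ``fit_null``
    maximizes an algebraically identical profiled form.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = build_V(Z, G, components)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        raise DataError("V is singular or indefinite at these components")
    Vi_y = linalg.solve(V, y, assume_a="pos")
    Vi_X = linalg.solve(V, X, assume_a="pos")
    XtViX = X.T @ Vi_X
    sign2, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        raise DataError("X'V^-1X is singular: rank-deficient fixed design")
    beta = linalg.solve(XtViX, X.T @ Vi_y, assume_a="pos")
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    q = X.shape[1]
    return -0.5 * (logdetV + logdetXtViX + yPy + (len(y) - q) * _LOG2PI)


# ---------------------------------------------------------------------------
# internal profiled REML machinery


class _RemlWorkspace:
    """Sufficient statistics and per-evaluation kernels for profiled REML."""

    def __init__(self, y, X, ind_index, counts, G, include_pe):
        self.y = y
        self.X = X
        self.N, self.q = X.shape
        self.n = len(counts)
        self.counts = counts.astype(float)
        self.G = G
        self.include_pe = include_pe
        self.yty = float(y @ y)
        self.Zty = np.bincount(ind_index, weights=y, minlength=self.n)
        self.ZtX = np.vstack(
            [np.bincount(ind_index, weights=X[:, j], minlength=self.n)
             for j in range(self.q)]
        ).T
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.balanced = bool(np.all(counts == counts[0]))
        self._grm_eigh = None

    def set_grm_eigh(self, eigh):
        wG, U = eigh
        self._grm_eigh = (wG, U, U.T @ self.Zty, U.T @ self.ZtX)

    def kernels(self, gamma_g, gamma_p):
        """Return (yHy, XHX, XHy, logdetH) for H = Z A Z' + I, A = gG + pI."""
        if self.balanced and self._grm_eigh is not None:
            wG, U, ty, tX = self._grm_eigh
            r = self.counts[0]
            alpha = gamma_g * wG + gamma_p
            denom = 1.0 + r * alpha
            if np.any(denom <= 0):
                return None
            t = alpha / denom
            yHy = self.yty - float((t * ty) @ ty)
            XHX = self.XtX - tX.T @ (t[:, None] * tX)
            XHy = self.Xty - tX.T @ (t * ty)
            logdetH = float(np.sum(np.log(denom)))
            return yHy, XHX, XHy, logdetH
        A = gamma_g * self.G + gamma_p * np.eye(self.n)
        M = np.eye(self.n) + A * self.counts[None, :]  # I + A D
        sign, logdetH = np.linalg.slogdet(M)
        if sign <= 0:
            return None
        T = linalg.solve(M, A)  # (I + A D)^-1 A, symmetric in exact arithmetic
        T = (T + T.T) / 2.0
        yHy = self.yty - float(self.Zty @ T @ self.Zty)
        XHX = self.XtX - self.ZtX.T @ T @ self.ZtX
        XHy = self.Xty - self.ZtX.T @ (T @ self.Zty)
        return yHy, XHX, XHy, float(logdetH)

    def neg_profiled(self, log_gammas):
        gamma_g = float(np.exp(log_gammas[0]))
        gamma_p = float(np.exp(log_gammas[1])) if self.include_pe else 0.0
        k = self.kernels(gamma_g, gamma_p)
        if k is None:
            return np.inf
        yHy, XHX, XHy, logdetH = k
        sign, logdetXHX = np.linalg.slogdet(XHX)
        if sign <= 0:
            return np.inf
        try:
            beta = linalg.solve(XHX, XHy, assume_a="pos")
        except linalg.LinAlgError:
            return np.inf
        rss = yHy - float(XHy @ beta)
        if rss <= 0:
            return np.inf
        nq = self.N - self.q
        sigma2 = rss / nq
        ll = -0.5 * (nq * (np.log(sigma2) + 1.0 + _LOG2PI) + logdetH + logdetXHX)
        return -ll

    def solution(self, log_gammas):
        """GLS estimates and variance components at the given ratios."""
        gamma_g = float(np.exp(log_gammas[0]))
        gamma_p = float(np.exp(log_gammas[1])) if self.include_pe else 0.0
        yHy, XHX, XHy, _ = self.kernels(gamma_g, gamma_p)
        beta = linalg.solve(XHX, XHy, assume_a="pos")
        rss = yHy - float(XHy @ beta)
        sigma_e2 = rss / (self.N - self.q)
        return gamma_g, gamma_p, sigma_e2, beta


@dataclass
class NullFit:
    """Result of the stage-1 (SNP-free) REML fit.

    Stores the estimated variance components, GLS fixed effects and a
    structured factorization of the fitted marginal covariance V0 that the
    scan stage whitens against.  The full eigendecomposition of V0 is
    available lazily through :meth:`v0_eigenvalues` / ``scan.make_rotation``;
    only the n non-trivial eigenpairs are ever materialized here (the
    remaining N - n eigenvalues all equal sigma_e^2).
    """

    components: VarianceComponents
    beta_fixed: pd.Series
    loglik_reml: float
    n: int
    N: int
    individual_ids: np.ndarray
    ind_index: np.ndarray  # obs -> position in individual_ids
    counts: np.ndarray
    y: np.ndarray
    X: np.ndarray
    fixed_names: list
    covariates: list
    grm: RelationshipMatrix
    t_tilde: np.ndarray = field(repr=False)  # (I + B D)^-1 B, B = A/sigma_e^2
    trace: list = field(default_factory=list, repr=False)
    _eigen_cache: tuple = field(default=None, repr=False)

    # -- V0 in structured form --------------------------------------------
    def _a_matrix(self) -> np.ndarray:
        c = self.components
        return c.sigma_g2 * self.grm.values + c.sigma_p2 * np.eye(self.n)

    def v0_nontrivial_eigen(self):
        """Eigenpairs (theta_j, u_j) of D^(1/2) A D^(1/2); V0 eigenvalues are
        sigma_e^2 + theta_j on Z D^(-1/2) u_j, and sigma_e^2 off col(Z)."""
        if self._eigen_cache is None:
            d = np.sqrt(self.counts.astype(float))
            S = self._a_matrix() * d[:, None] * d[None, :]
            theta, U = np.linalg.eigh((S + S.T) / 2.0)
            self._eigen_cache = (theta, U)
        return self._eigen_cache

    def v0_eigenvalues(self) -> np.ndarray:
        """All N eigenvalues of V0, descending."""
        theta, _ = self.v0_nontrivial_eigen()
        se2 = self.components.sigma_e2
        vals = np.concatenate([se2 + theta, np.full(self.N - self.n, se2)])
        return np.sort(vals)[::-1]

    def v0_matrix(self) -> np.ndarray:
        """Dense V0 (use only for small N)."""
        Z = incidence_matrix(self.ind_index, self.n)
        return build_V(Z, self.grm.values, self.components)

    # -- V0^-1 products through the Woodbury identity ----------------------
    def v0inv_quad(self, Ua: np.ndarray, Ub: np.ndarray, Za: np.ndarray, Zb: np.ndarray):
        """a' V0^-1 b given raw inner products Ua = a'b and Z-collapsed a, b."""
        se2 = self.components.sigma_e2
        return (Ua - Za @ self.t_tilde @ Zb) / se2

    def ztv0inv_z(self) -> np.ndarray:
        """K = Z' V0^-1 Z (n x n)."""
        d = self.counts.astype(float)
        se2 = self.components.sigma_e2
        K = (np.diag(d) - d[:, None] * self.t_tilde * d[None, :]) / se2
        return (K + K.T) / 2.0

    def ztv0inv_obs(self, v: np.ndarray) -> np.ndarray:
        """Z' V0^-1 v for an observation-level vector/matrix v."""
        Zv = np.vstack(
            [np.bincount(self.ind_index, weights=col, minlength=self.n)
             for col in np.atleast_2d(v.T)]
        ).T
        d = self.counts.astype(float)
        se2 = self.components.sigma_e2
        out = (Zv - d[:, None] * (self.t_tilde @ Zv)) / se2
        return out[:, 0] if v.ndim == 1 else out

    def obs_v0inv_obs(self, a: np.ndarray, b: np.ndarray) -> float:
        """a' V0^-1 b for observation-level vectors."""
        Za = np.bincount(self.ind_index, weights=a, minlength=self.n)
        Zb = np.bincount(self.ind_index, weights=b, minlength=self.n)
        se2 = self.components.sigma_e2
        return float((a @ b - Za @ self.t_tilde @ Zb) / se2)


def _prepare_pheno(pheno, grm, trait, id_col):
    if trait not in pheno.columns or id_col not in pheno.columns:
        raise DataError(f"phenotype table needs columns {id_col!r} and {trait!r}")
    y = pheno[trait].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite trait values in phenotype table")
    obs_ids = pheno[id_col].to_numpy(dtype=object)
    known = set(grm.individual_ids)
    offenders = sorted({i for i in obs_ids if i not in known})
    if offenders:
        raise DataError(
            f"{len(offenders)} phenotype id(s) missing from the relationship "
            f"matrix, e.g. {offenders[:5]}"
        )
    present = set(obs_ids)
    ids = np.array([i for i in grm.individual_ids if i in present], dtype=object)
    sub = grm if len(ids) == grm.n else grm.subset(ids)
    pos = {v: k for k, v in enumerate(ids)}
    ind_index = np.array([pos[i] for i in obs_ids])
    counts = np.bincount(ind_index, minlength=len(ids))
    return y, obs_ids, ids, sub, ind_index, counts


def fit_null(
    pheno: pd.DataFrame,
    grm: RelationshipMatrix,
    covariates=None,
    trait: str = "value",
    id_col: str = "id",
    include_permanent_env: bool = True,
    max_iter: int = 200,
) -> NullFit:
    """Fit the SNP-free mixed model by REML and package V0 for the scan.

    Parameters
    ----------
    pheno
        Long-format observation table; one row per measurement, with columns
        ``id_col`` and ``trait`` plus any covariates.
    grm
        Genomic relationship matrix covering every phenotyped individual.
    covariates
        Fixed-effect column names (year, age, sex, ...); an intercept is
        always included.
    include_permanent_env
        If False, drop the permanent-environment component (two-component
        model G + residual, as used for the individual-averages baseline).
    """
    y, _, ids, grm_sub, ind_index, counts = _prepare_pheno(pheno, grm, trait, id_col)
    n, N = len(ids), len(y)
    if n < 2:
        raise DataError("need at least two individuals")
    X, names = build_design(pheno, covariates)
    if include_permanent_env and counts.max() == 1:
        warnings.warn(
            "every individual has a single observation: sigma_p2 is not "
            "separately identifiable (only variance sums are identified)",
            UserWarning,
            stacklevel=2,
        )

    ws = _RemlWorkspace(y, X, ind_index, counts, grm_sub.values, include_permanent_env)
    if ws.balanced:
        ws.set_grm_eigh(grm_sub.eigh())

    trace = []

    def objective(params):
        f = ws.neg_profiled(params)
        trace.append((np.array(params), f))
        return f

    starts = [(0.0, 0.0), (-2.0, 1.0), (1.0, -2.0)]
    best = None
    for s in starts:
        res = optimize.minimize(
            objective,
            np.asarray(s),
            method="L-BFGS-B",
            bounds=[(_LOG_GAMMA_LO, _LOG_GAMMA_HI)] * 2,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(
            "REML optimization failed from all starts", trace=trace
        )

    gamma_g, gamma_p, sigma_e2, beta = ws.solution(best.x)
    floor = np.exp(_LOG_GAMMA_LO) * 2.0
    boundary = []
    sigma_g2 = gamma_g * sigma_e2
    sigma_p2 = gamma_p * sigma_e2 if include_permanent_env else 0.0
    if gamma_g < floor:
        sigma_g2, gamma_g = 0.0, 0.0
        boundary.append("sigma_g2")
    if include_permanent_env and gamma_p < floor:
        sigma_p2, gamma_p = 0.0, 0.0
        boundary.append("sigma_p2")
    comp = VarianceComponents(sigma_g2, sigma_p2, sigma_e2, boundary=tuple(boundary))

    # T~ = (I + B D)^-1 B at the optimum, B = A / sigma_e2
    B = gamma_g * grm_sub.values + gamma_p * np.eye(n)
    M = np.eye(n) + B * counts.astype(float)[None, :]
    t_tilde = linalg.solve(M, B)
    t_tilde = (t_tilde + t_tilde.T) / 2.0

    fit = NullFit(
        components=comp,
        beta_fixed=pd.Series(beta, index=names),
        loglik_reml=-float(best.fun),
        n=n,
        N=N,
        individual_ids=ids,
        ind_index=ind_index,
        counts=counts,
        y=y,
        X=X,
        fixed_names=names,
        covariates=list(covariates or []),
        grm=grm_sub,
        t_tilde=t_tilde,
        trace=trace,
    )
    logger.info(
        "null fit: n=%d N=%d sigma_g2=%.4g sigma_p2=%.4g sigma_e2=%.4g logL=%.4f",
        n, N, comp.sigma_g2, comp.sigma_p2, comp.sigma_e2, fit.loglik_reml,
    )
    return fit
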