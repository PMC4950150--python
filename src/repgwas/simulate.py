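"""Phenotype simulator: Gaussian and threshold-binary traits on given genotypes.

Emulates a long-term wild-population study: each individual carries a
polygenic effect g (multivariate normal with covariance sigma_g^2 G), a
permanent-environment effect p, and per-observation residuals e; QTL effects
enter additively through the dosage at chosen SNPs; between-year variation is
added as an i.i.d. normal effect shared by all observations from the same
year.  Binary traits threshold the Gaussian liability at a cut-off anchored
at the mean liability of common-allele homozygotes, so tau = 0 yields a 50/50
split for those individuals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .genotypes import GenotypeMatrix, RelationshipMatrix, allele_freq, compute_grm
from .null_model import VarianceComponents

__all__ = [
    "QTLSpec",
    "DesignSpec",
    "SimTruth",
    "make_design",
    "simulate_gaussian",
    "simulate_binary",
    "sample_qtl",
]


@dataclass
class QTLSpec:
    """Causal SNP positions (column indices into the genotype matrix) and
    their additive allele-substitution effects on the trait/liability scale."""

    snp_indices: tuple
    effects: tuple

    def __post_init__(self):
        self.snp_indices = tuple(int(i) for i in np.atleast_1d(self.snp_indices))
        self.effects = tuple(float(b) for b in np.atleast_1d(self.effects))
        if len(self.snp_indices) != len(self.effects):
            raise DataError("QTL indices and effects differ in length")
        if len(set(self.snp_indices)) != len(self.snp_indices):
            raise DataError("duplicate QTL indices")
        if not all(np.isfinite(self.effects)):
            raise DataError("non-finite QTL effect")

    @classmethod
    def none(cls):
        return cls((), ())


def sample_qtl(gm: GenotypeMatrix, n_qtl: int, effect: float, rng,
               min_maf: float = 0.0) -> QTLSpec:
    """Sample QTL positions uniformly among SNPs (optionally MAF-restricted)."""
    eligible = np.flatnonzero(gm.maf >= min_maf)
    if len(eligible) < n_qtl:
        raise DataError(f"only {len(eligible)} SNPs with MAF >= {min_maf}")
    idx = rng.choice(eligible, size=n_qtl, replace=False)
    return QTLSpec(tuple(idx), (effect,) * n_qtl)


@dataclass
class DesignSpec:
    """Repeat structure of the observations.

    ``balanced`` gives exactly ``obs_per_individual`` records each;
    ``unbalanced`` draws per-individual counts from Poisson(``mean_obs``)
    (mean 2, variance 2 at the default), dropping individuals that draw 0.
    Each observation is assigned one of ``n_years`` year labels uniformly,
    without repeating a year within an individual when possible.
    """

    mode: str = "balanced"
    obs_per_individual: int = 2
    mean_obs: float = 2.0
    n_years: int = 10

    def __post_init__(self):
        if self.mode not in ("balanced", "unbalanced"):
            raise DataError(f"unknown design mode {self.mode!r}")
        if self.n_years < 1:
            raise DataError("need n_years >= 1")
        if self.mode == "balanced" and self.obs_per_individual < 1:
            raise DataError("need >=1 observation per individual")


@dataclass
class SimTruth:
    """Realized random draws kept for recovery tests."""

    qtl: QTLSpec
    components: VarianceComponents
    g: np.ndarray
    p: np.ndarray
    year_effects: np.ndarray
    year_variance: float
    seed: object
    individual_ids: np.ndarray
    liabilities: np.ndarray = None
    tau: float = None

    def to_json(self, path) -> None:
        payload = {
            "qtl_indices": list(self.qtl.snp_indices),
            "qtl_effects": list(self.qtl.effects),
            "components": {
                "sigma_g2": self.components.sigma_g2,
                "sigma_p2": self.components.sigma_p2,
                "sigma_e2": self.components.sigma_e2,
            },
            "year_variance": self.year_variance,
            "seed": self.seed,
            "tau": self.tau,
            "individual_ids": list(map(str, self.individual_ids)),
            "g": list(map(float, self.g)),
            "p": list(map(float, self.p)),
            "year_effects": list(map(float, self.year_effects)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def make_design(individual_ids, design: DesignSpec, seed=None) -> pd.DataFrame:
    """Draw the observation-level (id, year) design for one replicate."""
    rng = np.random.default_rng(seed)
    ids = np.asarray(individual_ids, dtype=object)
    if design.mode == "balanced":
        counts = np.full(len(ids), design.obs_per_individual)
    else:
        counts = rng.poisson(design.mean_obs, size=len(ids))
    rows_id, rows_year = [], []
    for i, c in zip(ids, counts):
        if c == 0:
            continue
        # years without within-individual repetition while possible
        if c <= design.n_years:
            years = rng.choice(design.n_years, size=c, replace=False)
        else:
            years = np.concatenate(
                [rng.permutation(design.n_years),
                 rng.choice(design.n_years, size=c - design.n_years, replace=True)]
            )
        rows_id.extend([i] * c)
        rows_year.extend(int(t) for t in years)
    if not rows_id:
        raise DataError("design draw produced zero observations")
    return pd.DataFrame(
        {"id": rows_id, "year": [f"y{t:02d}" for t in rows_year]}
    )


def _polygenic_factor(grm: RelationshipMatrix) -> np.ndarray:
    """Matrix L with L L' = G, eigenvalues clipped at 0 (warn if repaired)."""
    w, u = grm.eigh()
    if w.min() < -1e-8 * max(1.0, w.max()):
        warnings.warn(
            "relationship matrix is not PSD; negative eigenvalues clipped at 0",
            UserWarning,
            stacklevel=3,
        )
    return u * np.sqrt(np.clip(w, 0.0, None))


def _simulate_liability(gm, qtl, components, design, year_variance, rng, grm):
    if grm is None:
        grm = compute_grm(gm)
    ids = gm.individual_ids
    pheno = make_design(ids, design, seed=rng)
    pos = {v: k for k, v in enumerate(ids)}
    ind = np.array([pos[i] for i in pheno["id"]])
    year_idx = pheno["year"].str.slice(1).astype(int).to_numpy()

    n = len(ids)
    g = _polygenic_factor(grm) @ rng.standard_normal(n) * np.sqrt(components.sigma_g2)
    p = rng.standard_normal(n) * np.sqrt(components.sigma_p2)
    year_eff = rng.standard_normal(design.n_years) * np.sqrt(year_variance)
    e = rng.standard_normal(len(pheno)) * np.sqrt(components.sigma_e2)

    dose = gm.imputed()
    qtl_ind = np.zeros(n)
    for j, b in zip(qtl.snp_indices, qtl.effects):
        qtl_ind += dose[:, j] * b
    y = qtl_ind[ind] + g[ind] + p[ind] + year_eff[year_idx] + e
    truth = SimTruth(
        qtl=qtl,
        components=components,
        g=g,
        p=p,
        year_effects=year_eff,
        year_variance=float(year_variance),
        seed=None,
        individual_ids=ids,
    )
    return pheno, y, truth


def simulate_gaussian(
    gm: GenotypeMatrix,
    qtl: QTLSpec,
    components: VarianceComponents,
    design: DesignSpec,
    year_variance: float = 0.0,
    seed=None,
    grm: RelationshipMatrix = None,
):
    """Simulate a Gaussian repeated-measures trait.

    ``value = sum_qtl x beta + g + p + year + e``; deterministic per seed.
    ``grm`` may be supplied to reuse a precomputed relationship matrix (it is
    otherwise computed from ``gm``).
    Returns ``(PhenotypeTable DataFrame with columns id/value/year, SimTruth)``.
    """
    rng = np.random.default_rng(seed)
    pheno, y, truth = _simulate_liability(
        gm, qtl, components, design, year_variance, rng, grm
    )
    pheno = pheno.assign(value=y)[["id", "value", "year"]]
    truth.seed = seed if isinstance(seed, (int, type(None))) else None
    return pheno, truth


def _common_homozygote_offset(gm: GenotypeMatrix, qtl: QTLSpec) -> float:
    """Liability mean of individuals homozygous for the common allele at all QTLs."""
    freq = allele_freq(gm)
    off = 0.0
    for j, b in zip(qtl.snp_indices, qtl.effects):
        common_dose = 0.0 if freq[j] <= 0.5 else 2.0
        off += common_dose * b
    return off


def simulate_binary(
    gm: GenotypeMatrix,
    qtl: QTLSpec,
    components: VarianceComponents,
    design: DesignSpec,
    tau: float = 0.0,
    year_variance: float = 0.0,
    seed=None,
    grm: RelationshipMatrix = None,
):
    """Simulate a binary trait by thresholding the Gaussian liability.

    ``y = 1`` iff the liability exceeds ``tau`` expressed relative to the mean
    liability of common-allele homozygotes (so ``tau = 0`` gives those
    individuals a 50/50 split).  The realized liabilities are kept in
    ``SimTruth.liabilities``.
    """
    rng = np.random.default_rng(seed)
    pheno, yu, truth = _simulate_liability(
        gm, qtl, components, design, year_variance, rng, grm
    )
    cut = tau + _common_homozygote_offset(gm, qtl)
    y = (yu > cut).astype(float)
    pheno = pheno.assign(value=y)[["id", "value", "year"]]
    truth.liabilities = yu
    truth.tau = float(tau)
    truth.seed = seed if isinstance(seed, (int, type(None))) else None
    return pheno, truth
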