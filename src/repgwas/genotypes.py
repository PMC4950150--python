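"""Genotype containers, file readers, QC filters and the genomic relationship matrix.

Dosages count non-reference alleles (0, 1, 2) and are stored as floats with
``NaN`` marking missing calls, which keeps per-SNP vector arithmetic simple.
The genomic relationship matrix follows VanRaden's method 1: columns centered
by twice the sample allele frequency, cross-product scaled by
``2 * sum_k p_k (1 - p_k)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, EmptyGenotypeError

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "QCReport",
    "read_vcf",
    "read_dosage_table",
    "write_dosage_table",
    "allele_freq",
    "hwe_test",
    "qc_filter",
    "compute_grm",
    "simulate_genotypes",
    "read_grm",
    "write_grm",
]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosages
        ``(n, m)`` float array; entries in ``{0, 1, 2}`` or ``NaN`` (missing).
    individual_ids
        Length-``n`` unique labels, one per row.
    snp_meta
        Length-``m`` frame with columns ``id``, ``chrom``, ``pos``, ``ref``,
        ``alt``; defaults are synthesized when omitted.
    """

    dosages: np.ndarray
    individual_ids: np.ndarray
    snp_meta: pd.DataFrame = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-d individuals x SNPs array")
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise DataError(
                f"{len(self.individual_ids)} individual ids for {n} dosage rows"
            )
        if len(set(self.individual_ids)) != n:
            raise DataError("individual ids are not unique")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise DataError(
                f"non-{{0,1,2,missing}} dosage {self.dosages[i, j]!r} at "
                f"individual {self.individual_ids[i]!r}, SNP column {j}"
            )
        if self.snp_meta is None:
            self.snp_meta = pd.DataFrame(
                {
                    "id": [f"snp{k}" for k in range(m)],
                    "chrom": "0",
                    "pos": np.arange(1, m + 1),
                    "ref": "A",
                    "alt": "B",
                }
            )
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        if len(self.snp_meta) != m:
            raise DataError(f"{len(self.snp_meta)} SNP records for {m} columns")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["id"].to_numpy()

    @property
    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency (NaN for all-missing SNPs)."""
        freq = allele_freq(self)
        return np.minimum(freq, 1.0 - freq)

    def subset_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.individual_ids,
            self.snp_meta.iloc[index].reset_index(drop=True),
        )

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        pos = {v: k for k, v in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise DataError(f"ids not in genotype matrix: {missing[:10]}")
        rows = np.array([pos[i] for i in ids])
        return GenotypeMatrix(self.dosages[rows], np.asarray(ids, dtype=object), self.snp_meta)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean ``2 p_hat``."""
        X = self.dosages.copy()
        freq = allele_freq(self)
        nan = np.isnan(X)
        X[nan] = np.broadcast_to(2.0 * freq, X.shape)[nan]
        return X


@dataclass
class RelationshipMatrix:
    """Symmetric n x n genomic relationship matrix with matching row/col ids."""

    values: np.ndarray
    individual_ids: np.ndarray
    _eigh_cache: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise DataError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("relationship matrix is not symmetric (tol 1e-10)")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def eigh(self):
        """Cached eigendecomposition (ascending eigenvalues)."""
        if self._eigh_cache is None:
            w, u = np.linalg.eigh(self.values)
            self._eigh_cache = (w, u)
        return self._eigh_cache

    def subset(self, ids) -> "RelationshipMatrix":
        pos = {v: k for k, v in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise DataError(f"ids not in relationship matrix: {missing[:10]}")
        rows = np.array([pos[i] for i in ids])
        return RelationshipMatrix(
            self.values[np.ix_(rows, rows)], np.asarray(ids, dtype=object)
        )


@dataclass
class QCReport:
    """Counts of SNPs removed by each quality-control rule (overlaps allowed)."""

    n_input_snps: int
    n_passed: int
    n_failed_call_rate: int
    n_failed_maf: int
    n_failed_hwe: int
    min_call_rate: float
    min_maf: float
    min_hwe_p: float

    def __str__(self):
        return (
            f"QC: {self.n_passed}/{self.n_input_snps} SNPs kept "
            f"(call rate<{self.min_call_rate}: {self.n_failed_call_rate}, "
            f"MAF<{self.min_maf}: {self.n_failed_maf}, "
            f"HWE p<={self.min_hwe_p}: {self.n_failed_hwe})"
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF (plain or bgzipped) into a dosage matrix.

    Bi-allelic sites only; multi-allelic records are skipped with a warning.
    Missing genotypes become NaN dosages.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except OSError as exc:  # pragma: no cover - cyvcf2 error text varies
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    samples = np.asarray(vcf.samples, dtype=object)
    rows, meta = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown/missing, 3 hom-alt
        gt = np.array(var.gt_types, dtype=float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dos)
        meta.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    vcf.close()
    if n_multi:
        logger.warning("skipped %d multi-allelic site(s) in %s", n_multi, path)
    if not rows:
        raise EmptyGenotypeError(f"no usable bi-allelic sites in {path}")
    return GenotypeMatrix(np.array(rows).T, samples, pd.DataFrame(meta))


def read_dosage_table(path, missing: str = "NA") -> GenotypeMatrix:
    """Read a TSV dosage matrix: first column individual id, header of SNP ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected an id column plus >=1 SNP column")
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    snp_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    dos = np.full(raw.shape, np.nan)
    for j in range(raw.shape[1]):
        for i in range(raw.shape[0]):
            cell = raw[i, j]
            if pd.isna(cell) or str(cell).strip() == missing:
                continue
            try:
                v = float(cell)
            except ValueError:
                v = -1.0
            if v not in (0.0, 1.0, 2.0):
                raise DataError(
                    f"{path}: invalid dosage {cell!r} at row {ids[i]!r}, "
                    f"column {snp_ids[j]!r}"
                )
            dos[i, j] = v
    meta = pd.DataFrame(
        {"id": snp_ids, "chrom": "0", "pos": np.arange(1, len(snp_ids) + 1),
         "ref": "A", "alt": "B"}
    )
    return GenotypeMatrix(dos, ids, meta)


def write_dosage_table(gm: GenotypeMatrix, path, missing: str = "NA") -> None:
    """Write the TSV format read by :func:`read_dosage_table`."""
    df = pd.DataFrame(gm.dosages, columns=gm.snp_ids)
    df = df.map(lambda v: missing if np.isnan(v) else str(int(v)))
    df.insert(0, "id", gm.individual_ids)
    df.to_csv(path, sep="\t", index=False)


def write_grm(grm: RelationshipMatrix, path) -> None:
    pd.DataFrame(grm.values, index=grm.individual_ids, columns=grm.individual_ids).to_csv(
        path, sep="\t", index_label="id"
    )


def read_grm(path) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(df.to_numpy(dtype=float), np.asarray(df.columns, dtype=object))


# ---------------------------------------------------------------------------
# allele frequency / HWE / QC


def allele_freq(gm: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of the non-reference allele, ignoring missing calls.

    SNPs with no non-missing call get NaN (they are removed by any call-rate
    filter anyway).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nansum(gm.dosages, axis=0) / (
            2.0 * np.sum(~np.isnan(gm.dosages), axis=0)
        )


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Expected genotype counts come from the observed allele frequency.
    Monomorphic SNPs return p = 1 by convention.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any() or counts.sum() <= 0:
        raise DataError("HWE test needs non-negative counts with positive total")
    n = counts.sum()
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
    statistic = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(statistic, df=1))


def _hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    out = np.empty(gm.n_snps)
    d = gm.dosages
    for j in range(gm.n_snps):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
    return out


def qc_filter(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.01,
    min_hwe_p: float = 0.001,
):
    """Apply the standard marker QC: call rate, MAF and HWE thresholds.

    A SNP is kept iff call_rate >= ``min_call_rate`` AND maf >= ``min_maf``
    AND HWE p > ``min_hwe_p``.  Returns ``(filtered GenotypeMatrix, QCReport)``.
    """
    cr = gm.call_rate
    maf = gm.maf
    hwe = _hwe_pvalues(gm)
    fail_cr = cr < min_call_rate
    fail_maf = ~(maf >= min_maf)  # NaN maf (all missing) counts as failure
    fail_hwe = ~(hwe > min_hwe_p)
    keep = ~(fail_cr | fail_maf | fail_hwe)
    report = QCReport(
        n_input_snps=gm.n_snps,
        n_passed=int(keep.sum()),
        n_failed_call_rate=int(fail_cr.sum()),
        n_failed_maf=int(fail_maf.sum()),
        n_failed_hwe=int(fail_hwe.sum()),
        min_call_rate=min_call_rate,
        min_maf=min_maf,
        min_hwe_p=min_hwe_p,
    )
    if not keep.any():
        raise EmptyGenotypeError(f"all SNPs removed by QC ({report})")
    return gm.subset_snps(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# GRM


def compute_grm(gm: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    ``G = W W' / (2 sum_k p_k (1 - p_k))`` with ``W`` the dosage matrix
    mean-imputed per SNP and column-centered by ``2 p_k``; allele frequencies
    are estimated from the sample itself.
    """
    freq = allele_freq(gm)
    usable = ~np.isnan(freq)
    denom = 2.0 * np.nansum(freq[usable] * (1.0 - freq[usable]))
    if denom <= 0:
        raise DataError("GRM denominator is zero: all SNPs monomorphic or missing")
    W = gm.imputed()[:, usable] - 2.0 * freq[usable]
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(G, gm.individual_ids)


# ---------------------------------------------------------------------------
# synthetic genotypes


def simulate_genotypes(
    n_families: int = 0,
    sibs_per_family: int = 2,
    n_unrelated: int = 0,
    n_snps: int = 1000,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed=None,
) -> GenotypeMatrix:
    """Simulate 0/1/2 genotypes for full-sib families plus unrelated individuals.

    Per SNP the non-reference allele frequency is drawn Uniform(maf_low,
    maf_high).  Founders are drawn from Hardy-Weinberg proportions; each
    family's sibs descend from two (latent) founder parents by Mendelian
    transmission, giving sib-pair GRM entries near 0.5 — the family structure
    stands in for a wild pedigreed population.  Deterministic per seed.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise DataError("need 0 < maf_low <= maf_high <= 0.5")
    n_total = n_families * sibs_per_family + n_unrelated
    if n_total <= 0 or n_snps <= 0:
        raise DataError("need a positive number of individuals and SNPs")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=n_snps)

    blocks, ids = [], []
    if n_families:
        mothers = rng.binomial(2, p, size=(n_families, n_snps)).astype(float)
        fathers = rng.binomial(2, p, size=(n_families, n_snps)).astype(float)
        for s in range(sibs_per_family):
            sib = rng.binomial(1, mothers / 2.0) + rng.binomial(1, fathers / 2.0)
            blocks.append(sib.astype(float))
        # interleave so family members are adjacent
        fam = np.stack(blocks, axis=1).reshape(n_families * sibs_per_family, n_snps)
        blocks = [fam]
        ids += [
            f"F{f:04d}_S{s + 1}"
            for f in range(n_families)
            for s in range(sibs_per_family)
        ]
    if n_unrelated:
        blocks.append(rng.binomial(2, p, size=(n_unrelated, n_snps)).astype(float))
        ids += [f"U{k:05d}" for k in range(n_unrelated)]
    dos = np.vstack(blocks)
    return GenotypeMatrix(dos, np.asarray(ids, dtype=object))
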