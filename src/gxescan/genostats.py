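"""Genotype-level statistics: MAF, LD r-squared, locus binning, PCA.

Genotypes are minor-allele dosages in {0, 1, 2} with ``NaN`` for missing.
LD is measured as the squared Pearson correlation of unphased genotype
dosages (the composite-LD estimate of the allelic r^2), which is invariant
to swapping the minor/major coding of either SNP.  PCA standardizes each
SNP EIGENSTRAT-style, centering at twice the allele frequency and scaling
by the binomial standard deviation sqrt(2 p (1 - p)), which is the usual
preparation when the components are destined for population-stratification
adjustment in a regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SnpMeta",
    "MafResult",
    "LDMatrix",
    "PCResult",
    "compute_maf",
    "ld_r2",
    "ld_matrix",
    "bin_adjacent_loci",
    "pca_genotypes",
]


@dataclass
class SnpMeta:
    """Per-SNP metadata: 1-based position, allele labels, in-sample MAF."""

    snp_id: str
    chromosome: str
    position: int
    minor_allele: str
    major_allele: str
    maf: float

    def __post_init__(self):
        if self.position <= 0:
            raise ValueError("position must be a positive 1-based coordinate")
        if not 0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")


@dataclass
class MafResult:
    maf: float
    minor_allele: str
    major_allele: str
    genotype: np.ndarray  # dosages re-oriented to count the minor allele
    flipped: bool  # True when the coded allele was the major one
    monomorphic: bool


@dataclass
class LDMatrix:
    """Symmetric matrix of pairwise dosage r^2 (NaN where undefined)."""

    snp_ids: list
    r2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids)


@dataclass
class PCResult:
    eigenvectors: np.ndarray  # subjects x k, unit-norm subject loadings
    eigenvalues: np.ndarray  # k sample variances along each component
    variance_fraction: np.ndarray  # fraction of total standardized variance
    n_snps_used: int = field(default=0)


def compute_maf(genotype, coded_allele: str = "B", other_allele: str = "A") -> MafResult:
    """Minor-allele frequency with re-orientation of the coded allele.

    ``genotype`` counts copies of ``coded_allele`` (0/1/2, NaN missing).
    When the coded allele turns out to be the in-sample major allele, the
    dosages are flipped (g -> 2 - g) so the returned dosages always count
    the minor allele.  A frequency tie at 0.5 is broken toward the
    lexicographically smaller allele label.
    """
    g = np.asarray(genotype, dtype=float)
    obs = ~np.isnan(g)
    if not obs.any():
        raise ValueError("all genotypes missing: MAF undefined")
    bad = obs & ~np.isin(g, (0.0, 1.0, 2.0))
    if bad.any():
        raise ValueError("genotype dosages must be 0, 1, 2 or missing")
    freq = g[obs].sum() / (2.0 * obs.sum())  # frequency of the coded allele
    if freq > 0.5 or (freq == 0.5 and other_allele < coded_allele):
        flipped = True
        maf = 1.0 - freq
        minor, major = other_allele, coded_allele
        g = 2.0 - g
    else:
        flipped = False
        maf = freq
        minor, major = coded_allele, other_allele
    return MafResult(
        maf=float(maf),
        minor_allele=minor,
        major_allele=major,
        genotype=g,
        flipped=flipped,
        monomorphic=bool(maf == 0.0),
    )


def ld_r2(geno_a, geno_b) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Missing values are handled pairwise-complete.  Returns NaN when either
    vector is constant over the complete pairs (allelic correlation
    undefined).
    """
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        return float("nan")
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def ld_matrix(genotypes, snp_ids=None) -> LDMatrix:
    """All-pairs dosage r^2 for a subjects x SNPs matrix."""
    G = np.asarray(genotypes, dtype=float)
    m = G.shape[1]
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(m)]
    r2 = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r2[i, j] = r2[j, i] = ld_r2(G[:, i], G[:, j])
        if np.nanvar(G[:, i]) == 0.0:
            r2[i, i] = float("nan")
    return LDMatrix(snp_ids=list(snp_ids), r2=r2)


def bin_adjacent_loci(genotypes, chromosomes, positions, threshold: float = 0.2):
    """Greedy adjacent-locus binning at an r^2 threshold.

    SNPs must be sorted by chromosome then position.  Scanning left to
    right, a SNP joins the current locus when its dosage r^2 with the
    locus's *index SNP* (the first SNP of the locus) is at least
    ``threshold``; otherwise it opens a new locus and becomes its index.  A
    chromosome change always opens a new locus.  Returns 1-based contiguous
    locus ids, one per SNP.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    G = np.asarray(genotypes, dtype=float)
    chrom = np.asarray(chromosomes, dtype=object)
    pos = np.asarray(positions, dtype=int)
    m = G.shape[1]
    if chrom.size != m or pos.size != m:
        raise ValueError("chromosomes/positions must match the SNP count")
    # sortedness: within each contiguous chromosome run positions increase,
    # and no chromosome appears in two separate runs
    runs = []
    for j in range(m):
        if j == 0 or chrom[j] != chrom[j - 1]:
            runs.append(chrom[j])
        elif pos[j] < pos[j - 1]:
            raise ValueError("SNPs must be sorted by chromosome and position")
    if len(runs) != len(set(runs)):
        raise ValueError("SNPs must be sorted by chromosome and position")

    locus = np.empty(m, dtype=int)
    current = 0
    anchor = -1
    for j in range(m):
        new = j == 0 or chrom[j] != chrom[j - 1]
        if not new:
            r2 = ld_r2(G[:, anchor], G[:, j])
            new = not (np.isfinite(r2) and r2 >= threshold)
        if new:
            current += 1
            anchor = j
        locus[j] = current
    return locus


def pca_genotypes(genotypes, k: int) -> PCResult:
    """Top-k principal components of the standardized genotype matrix.

    Missing dosages are mean-imputed per SNP.  Each SNP column is centered
    at its mean (2 p-hat) and scaled by sqrt(2 p (1 - p)); monomorphic
    columns carry no information and are dropped before the decomposition.
    ``variance_fraction`` is measured against the total variance of the
    standardized matrix, so the fractions over all min(n, p) components
    would sum to 1.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2 or G.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 SNPs")
    n, m = G.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k={k} must lie in [1, min(n_subjects, n_snps)={min(n, m)}]")
    X = G.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])
    p_hat = col_mean / 2.0
    sd = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 polymorphic SNPs")
    X = (X[:, keep] - col_mean[keep]) / sd[keep]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    kk = min(k, s.size)
    return PCResult(
        eigenvectors=U[:, :kk],
        eigenvalues=(s[:kk] ** 2) / (n - 1),
        variance_fraction=(s[:kk] ** 2) / total,
        n_snps_used=int(keep.sum()),
    )
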