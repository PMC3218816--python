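"""Genotype-stratified intervention odds ratios and interaction models.

All estimators here are *case-only*: because intervention assignment is
randomized (hence independent of genotype in the source population), the
odds of active assignment among cases at genotype g, relative to the known
randomization odds q/(1-q), estimates the intervention odds ratio on
disease at that genotype:

    OR_g = (n_active,g / n_control,g) / (q / (1 - q)).

A 2-df likelihood-ratio test compares the offset-logistic model with free
genotype-level effects (indicators for one and two minor alleles) against
the intercept-only offset model; genotype levels absent from the data
reduce the degrees of freedom.  Joint models regress assignment on several
SNP dosages together to judge whether nearby SNPs carry independent
interaction information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import xlogy

__all__ = [
    "GenotypeStratifiedOR",
    "JointInteractionModelResult",
    "genotype_stratified_or",
    "lrt_2df_interaction",
    "multi_snp_case_only",
    "subset_filter",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class GenotypeStratifiedOR:
    component: str
    snp_id: str
    counts: np.ndarray  # 3 x 2 array: rows genotype 0/1/2, cols (active, control)
    or_by_genotype: np.ndarray  # 3 ORs (NaN where undefined)
    ci95_by_genotype: np.ndarray  # 3 x 2 (lo, hi)
    lrt_2df_p: float
    lrt_df: int
    n_cases: int
    continuity_corrected: np.ndarray = field(default=None)  # bool per genotype

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": self.component,
            "snp_id": self.snp_id,
            "genotype": [0, 1, 2],
            "n_active": self.counts[:, 0],
            "n_control": self.counts[:, 1],
            "or": self.or_by_genotype,
            "ci_lo": self.ci95_by_genotype[:, 0],
            "ci_hi": self.ci95_by_genotype[:, 1],
            "continuity_corrected": self.continuity_corrected,
            "lrt_p": self.lrt_2df_p,
            "lrt_df": self.lrt_df,
        })


@dataclass
class JointInteractionModelResult:
    component: str
    snp_ids: list
    coefficients: np.ndarray  # per-SNP interaction log-ORs
    per_snp_p: np.ndarray  # Wald p-values
    intercept: float
    n_cases: int


def _counts_by_genotype(genotype, assignment) -> np.ndarray:
    g = np.asarray(genotype)
    a = np.asarray(assignment)
    counts = np.zeros((3, 2), dtype=float)
    for lev in (0, 1, 2):
        sel = g == lev
        counts[lev, 0] = np.sum(a[sel] == 1)
        counts[lev, 1] = np.sum(a[sel] == 0)
    return counts


def genotype_stratified_or(genotype=None, assignment=None, q: float = 0.5,
                           counts=None, component: str = "", snp_id: str = "",
                           with_lrt: bool = True) -> GenotypeStratifiedOR:
    """Case-only intervention OR at zero, one, and two minor alleles.

    Supply either case-level ``genotype`` (0/1/2) + ``assignment``
    (1 active / 0 control) vectors, or a precomputed 3x2 ``counts`` table
    (rows genotype, columns active/control).  Wald 95% CIs are computed on
    the log scale with standard error sqrt(1/n_active + 1/n_control).  A
    single zero cell triggers the Haldane-Anscombe +0.5 correction of both
    cells at that genotype (flagged); a genotype with both cells zero gets
    a missing OR.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if counts is None:
        if genotype is None or assignment is None:
            raise ValueError("need genotype+assignment or counts")
        counts = _counts_by_genotype(genotype, assignment)
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 2) or (counts < 0).any():
        raise ValueError("counts must be a nonnegative 3x2 table")
    rand_odds = q / (1.0 - q)
    ors = np.full(3, np.nan)
    cis = np.full((3, 2), np.nan)
    corrected = np.zeros(3, dtype=bool)
    for lev in range(3):
        na, nc = counts[lev]
        if na == 0 and nc == 0:
            continue
        if na == 0 or nc == 0:
            na, nc = na + 0.5, nc + 0.5
            corrected[lev] = True
        log_or = np.log(na / nc) - np.log(rand_odds)
        se = np.sqrt(1.0 / na + 1.0 / nc)
        ors[lev] = np.exp(log_or)
        cis[lev] = np.exp([log_or - _Z95 * se, log_or + _Z95 * se])
    if with_lrt:
        lrt_p, lrt_df = lrt_2df_interaction(counts=counts, q=q, return_df=True)
    else:
        lrt_p, lrt_df = float("nan"), 0
    return GenotypeStratifiedOR(
        component=component, snp_id=snp_id, counts=counts,
        or_by_genotype=ors, ci95_by_genotype=cis,
        lrt_2df_p=lrt_p, lrt_df=lrt_df,
        n_cases=int(counts.sum()), continuity_corrected=corrected,
    )


def lrt_2df_interaction(genotype=None, assignment=None, q: float = 0.5,
                        counts=None, return_df: bool = False):
    """Likelihood-ratio test of genotype-dependent intervention effect.

    Compares the case-only offset-logistic model with per-genotype-level
    indicators (plus a free intercept) against the intercept-only offset
    model.  With the intercept free the level-indicator model is saturated
    in genotype levels, so both maximized likelihoods have closed form
    (per-level and overall assignment fractions) and the constant offset
    log(q/(1-q)) cancels from the ratio.  df = (number of genotype levels
    present) - 1; a single level present is degenerate (p = NaN, df = 0).
    """
    if counts is None:
        counts = _counts_by_genotype(genotype, assignment)
    counts = np.asarray(counts, dtype=float)
    present = counts.sum(axis=1) > 0
    df = int(present.sum()) - 1
    if df < 1:
        return (float("nan"), 0) if return_df else float("nan")
    na = counts[present, 0]
    nc = counts[present, 1]
    tot = na + nc
    p_lev = na / tot
    p_all = na.sum() / tot.sum()
    ll_full = float(np.sum(xlogy(na, p_lev) + xlogy(nc, 1.0 - p_lev)))
    ll_null = float(np.sum(xlogy(na, p_all) + xlogy(nc, 1.0 - p_all)))
    lrt = max(2.0 * (ll_full - ll_null), 0.0)
    p = float(stats.chi2.sf(lrt, df=df))
    return (p, df) if return_df else p


def multi_snp_case_only(genotypes, assignment, q: float, snp_ids=None,
                        component: str = "") -> JointInteractionModelResult:
    """Joint case-only interaction model over several SNPs.

    One offset-logistic fit of assignment on all SNP dosages together;
    per-SNP Wald p-values judge each SNP's interaction conditional on the
    others.  A perfectly collinear SNP pair among the cases is rejected
    with an error naming the pair.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    a = np.asarray(assignment, dtype=float)
    n, k = G.shape
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            if G[:, i].std() > 0 and G[:, j].std() > 0:
                r = np.corrcoef(G[:, i], G[:, j])[0, 1]
                if abs(r) >= 1.0 - 1e-12:
                    raise ValueError(
                        f"collinear SNP pair among cases: {snp_ids[i]}, {snp_ids[j]}"
                    )
    X = sm.add_constant(G, has_constant="add")
    offset = np.full(n, np.log(q / (1.0 - q)))
    model = sm.GLM(a, X, family=sm.families.Binomial(), offset=offset)
    fit = model.fit()
    coefs = np.asarray(fit.params)[1:]
    pvals = np.asarray(fit.pvalues)[1:]
    return JointInteractionModelResult(
        component=component, snp_ids=list(snp_ids),
        coefficients=coefs, per_snp_p=pvals,
        intercept=float(fit.params[0]), n_cases=n,
    )


def subset_filter(pheno: pd.DataFrame, predicate, pair_col: str = "pair_id",
                  keep_cases: bool = False) -> pd.DataFrame:
    """Restrict a matched case-control table to subjects passing a predicate.

    ``predicate`` is either a callable over row Series or a
    ``(column, allowed_values)`` tuple.  Matched-pair integrity is
    preserved: a pair is kept only when both members pass.  With
    ``keep_cases=True`` (for case-only analyses) every passing *case* is
    retained even when its control fails.
    """
    if callable(predicate):
        mask = pheno.apply(predicate, axis=1).astype(bool)
    else:
        col, allowed = predicate
        if col not in pheno.columns:
            raise KeyError(f"predicate column not in table: {col}")
        if pheno[col].isna().any():
            raise ValueError(f"predicate column has missing values: {col}")
        allowed = {allowed} if np.isscalar(allowed) else set(allowed)
        mask = pheno[col].isin(allowed)
    if pair_col not in pheno.columns:
        return pheno.loc[mask].copy()
    ok_pairs = set(
        pid for pid, grp in pheno.groupby(pair_col, dropna=True)
        if mask.loc[grp.index].all()
    )
    keep = pheno[pair_col].isin(ok_pairs)
    if keep_cases:
        keep |= mask & pheno["case"].astype(bool)
    else:
        keep &= mask | pheno[pair_col].isin(ok_pairs)
    return pheno.loc[keep].copy()
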