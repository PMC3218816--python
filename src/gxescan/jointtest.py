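"""Five-component combined main-effect + interaction test.

For each SNP the scan assembles five score statistics:

* ``MAIN`` — score test for the genotype coefficient in a logistic
  regression of case (1) vs control (0) status on minor-allele dosage plus
  confounders (log risk score, prior hormone use, log BMI, matching
  variables, top principal components), evaluated at the covariates-only
  null fit.
* ``E_ALONE, E_PLUS_P, DMQ, CAD`` — case-only score tests for dependence of
  the intervention odds ratio on genotype: among the cases belonging to
  each trial component, logistic regression of active (1) vs placebo/usual
  diet (0) assignment on dosage, with the linear predictor offset by
  log q/(1-q) where q is the known randomization fraction.  A free
  intercept is retained alongside the offset so that an intervention main
  effect (which shifts P(active | case) away from q) does not masquerade as
  interaction; the offset then merely centers the intercept.

Because randomization makes assignment independent of genotype, the main
effect statistic is asymptotically independent of each case-only statistic,
and the two hormone-trial statistics are independent outright (their trials
enroll disjoint women: post-hysterectomy vs with uterus).  The covariance
matrix therefore carries structural zeros in those cells, while the
remaining case-only pairs — whose case sets overlap — get an empirical
sandwich cross term summed over shared subjects.  The combined statistic is
the quadratic form U' V^- U referred to a chi-square whose degrees of
freedom equal the rank of V over the non-degenerate components (five when
all components are informative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

COMPONENT_ORDER = ("MAIN", "E_ALONE", "E_PLUS_P", "DMQ", "CAD")
CASE_ONLY_COMPONENTS = ("E_ALONE", "E_PLUS_P", "DMQ", "CAD")

__all__ = [
    "COMPONENT_ORDER",
    "CASE_ONLY_COMPONENTS",
    "ComponentScore",
    "CombinedTestResult",
    "main_effect_score_test",
    "case_only_score_test",
    "assemble_covariance",
    "combined_chi2_test",
    "joint_test_snp",
    "joint_test_scan",
]


@dataclass
class ComponentScore:
    component: str
    U: float
    V: float
    n_used: int
    contributions: pd.Series  # per-subject score contributions, id-indexed
    p: float
    degenerate: bool = False
    message: str = ""

    @property
    def chi2(self) -> float:
        return self.U**2 / self.V if self.V > 0 else float("nan")


@dataclass
class CombinedTestResult:
    snp_id: str
    U_vec: np.ndarray
    V_mat: np.ndarray
    chi2: float
    df: int
    p: float
    components_used: dict = field(default_factory=dict)
    missing: bool = False


def _degenerate(component: str, n: int, msg: str) -> ComponentScore:
    return ComponentScore(
        component=component,
        U=0.0,
        V=0.0,
        n_used=n,
        contributions=pd.Series(dtype=float),
        p=float("nan"),
        degenerate=True,
        message=msg,
    )


def _irls_null_fit(y: np.ndarray, X: np.ndarray, offset: float = 0.0,
                   max_iter: int = 50, tol: float = 1e-10):
    """Covariates-only logistic ML fit by iteratively reweighted LS.

    Returns fitted probabilities, or None when the fit diverges
    (quasi-separation drives fitted probabilities to 0/1).
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        if np.max(np.abs(eta)) > 25:  # fitted probs at machine 0/1
            return None
        XtW = X.T * w
        try:
            delta = np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            return None
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            eta = X @ beta + offset
            return 1.0 / (1.0 + np.exp(-eta))
    warnings.warn("null logistic fit did not converge", RuntimeWarning)
    return 1.0 / (1.0 + np.exp(-(X @ beta + offset)))


def main_effect_score_test(case_status, genotype, covariates=None,
                           subject_ids=None) -> ComponentScore:
    """Score test for genotype in case/control logistic regression.

    The null model (intercept + covariates, genotype excluded) is fit by
    maximum likelihood; the genotype score U = sum g_i (y_i - p_i) is
    paired with the expected (Fisher) information of the *efficient* score,
    i.e. the variance of the genotype residualized on the covariates under
    the null weights.  Per-subject contributions use the same efficient
    score residual so cross-component covariances are estimable.
    """
    y = np.asarray(case_status, dtype=float)
    g = np.asarray(genotype, dtype=float)
    n = y.size
    if subject_ids is None:
        subject_ids = np.arange(n)
    ids = pd.Index(subject_ids)
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    if g.std() == 0:
        return _degenerate("MAIN", n, "monomorphic genotype")
    if y.min() == y.max():
        return _degenerate("MAIN", n, "single outcome class")

    mu = _irls_null_fit(y, X)
    if mu is None:
        return _degenerate("MAIN", n, "null fit failed (separation)")
    w = mu * (1.0 - mu)
    # efficient score: residualize genotype on covariates under null weights
    XtWX = (X.T * w) @ X
    coef = np.linalg.solve(XtWX, (X.T * w) @ g)
    g_res = g - X @ coef
    contrib = g_res * (y - mu)
    U = float(contrib.sum())
    V = float((g_res**2 * w).sum())
    if V <= 0:
        return _degenerate("MAIN", n, "zero information")
    p = float(stats.chi2.sf(U**2 / V, df=1))
    return ComponentScore("MAIN", U, V, n, pd.Series(contrib, index=ids), p)


def case_only_score_test(assignment, genotype, q: float, component: str = "CAD",
                         subject_ids=None) -> ComponentScore:
    """Case-only score test of intervention-by-genotype interaction.

    Model among cases in the component: logit P(active) =
    log(q/(1-q)) + alpha + beta * dosage, alpha free.  The score for
    beta = 0 with alpha profiled at its null MLE reduces to the trend
    statistic U = sum (g_i - gbar)(a_i - abar) with expected information
    V = abar (1-abar) sum (g_i - gbar)^2; the constant offset is absorbed
    by alpha and cancels from the statistic.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    a = np.asarray(assignment, dtype=float)
    g = np.asarray(genotype, dtype=float)
    if a.shape != g.shape:
        raise ValueError("assignment and genotype must have equal length")
    n = a.size
    if subject_ids is None:
        subject_ids = np.arange(n)
    ids = pd.Index(subject_ids)
    if n == 0:
        return _degenerate(component, 0, "no cases in component")
    if g.min() == g.max():
        return _degenerate(component, n, "monomorphic genotype among cases")
    abar = a.mean()
    if abar in (0.0, 1.0):
        return _degenerate(component, n, "all cases in one arm")
    g_res = g - g.mean()
    contrib = g_res * (a - abar)
    U = float(contrib.sum())
    V = float(abar * (1.0 - abar) * (g_res**2).sum())
    p = float(stats.chi2.sf(U**2 / V, df=1))
    return ComponentScore(component, U, V, n, pd.Series(contrib, index=ids), p)


def assemble_covariance(scores: dict, structural_zero_main: bool = True) -> np.ndarray:
    """Assemble the 5x5 component covariance matrix.

    Diagonal: component score variances (expected information).  Structural
    zeros: (MAIN, case-only) cells — the main-effect statistic is
    asymptotically independent of every case-only statistic because
    randomization makes assignment independent of genotype (disable with
    ``structural_zero_main=False`` to use the empirical cross term) — and
    the (E_ALONE, E_PLUS_P) cell, which is zero outright since the two
    hormone trials enroll disjoint women.  Every remaining case-only pair
    gets the empirical sandwich term: the sum over subjects in both
    components of the product of their per-subject score contributions.
    """
    for comp in COMPONENT_ORDER:
        if comp not in scores:
            raise ValueError(f"missing component score: {comp}")
    main = scores["MAIN"]
    if not main.degenerate:
        universe = set(main.contributions.index)
        for comp in CASE_ONLY_COMPONENTS:
            s = scores[comp]
            if not s.degenerate and not set(s.contributions.index) <= universe:
                raise ValueError(
                    f"subject ids of component {comp} are not a subset of the "
                    "main-effect subject universe"
                )
    k = len(COMPONENT_ORDER)
    V = np.zeros((k, k))
    for i, ci in enumerate(COMPONENT_ORDER):
        V[i, i] = scores[ci].V
    for i, ci in enumerate(COMPONENT_ORDER):
        for j in range(i + 1, k):
            cj = COMPONENT_ORDER[j]
            si, sj = scores[ci], scores[cj]
            if si.degenerate or sj.degenerate:
                continue
            if {ci, cj} == {"E_ALONE", "E_PLUS_P"}:
                continue  # disjoint trials: exactly zero
            if "MAIN" in (ci, cj) and structural_zero_main:
                continue  # randomization independence: structural zero
            shared = si.contributions.index.intersection(sj.contributions.index)
            if len(shared):
                V[i, j] = float(
                    (si.contributions.loc[shared] * sj.contributions.loc[shared]).sum()
                )
            V[j, i] = V[i, j]
    return V


def combined_chi2_test(U_vec, V_mat, degenerate=None, snp_id: str = "") -> CombinedTestResult:
    """Quadratic-form chi-square over the non-degenerate components.

    chi2 = U' V^- U with the Moore-Penrose pseudo-inverse restricted to the
    informative components; df is the rank of that restriction (5 when all
    five components are valid and V is full rank).
    """
    U = np.asarray(U_vec, dtype=float)
    V = np.asarray(V_mat, dtype=float)
    k = U.size
    if V.shape != (k, k):
        raise ValueError("V_mat shape must match U_vec")
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("V_mat must be symmetric")
    if degenerate is None:
        degenerate = [V[i, i] <= 0 for i in range(k)]
    use = ~np.asarray(degenerate, dtype=bool)
    used = {c: bool(u) for c, u in zip(COMPONENT_ORDER[:k], use)}
    if not use.any():
        return CombinedTestResult(snp_id, U, V, float("nan"), 0, float("nan"),
                                  used, missing=True)
    Ur = U[use]
    Vr = V[np.ix_(use, use)]
    rcond = 1e-10
    Vinv = np.linalg.pinv(Vr, rcond=rcond, hermitian=True)
    chi2 = float(Ur @ Vinv @ Ur)
    chi2 = max(chi2, 0.0)
    df = int(np.linalg.matrix_rank(Vr, tol=rcond * np.abs(np.linalg.eigvalsh(Vr)).max(),
                                   hermitian=True))
    p = float(stats.chi2.sf(chi2, df=df)) if df > 0 else float("nan")
    return CombinedTestResult(snp_id, U, V, chi2, df, p, used, missing=df == 0)


def joint_test_snp(pheno: pd.DataFrame, genotype, q_by_component: dict,
                   covariate_cols=None, snp_id: str = "",
                   structural_zero_main: bool = True):
    """Run all five components and the combined test for one SNP.

    ``pheno`` must carry, per subject (index = subject id): ``case``
    (bool/0-1), one membership column ``in_<COMPONENT>`` and one arm column
    ``active_<COMPONENT>`` (1 active / 0 control, NA outside the component)
    for each case-only component, plus any covariate columns named in
    ``covariate_cols`` for the main-effect null model.  ``genotype`` is the
    dosage vector aligned with ``pheno``'s rows.

    Returns ``(CombinedTestResult, dict of ComponentScore)``.
    """
    g = np.asarray(genotype, dtype=float)
    if g.size != len(pheno):
        raise ValueError("genotype length must match phenotype table")
    obs = ~np.isnan(g)
    if not obs.all():  # complete-case per SNP
        pheno = pheno.loc[obs]
        g = g[obs]
    y = pheno["case"].to_numpy(dtype=float)
    cov = pheno[list(covariate_cols)].to_numpy(dtype=float) if covariate_cols else None
    scores = {
        "MAIN": main_effect_score_test(y, g, cov, subject_ids=pheno.index)
    }
    case_mask = y == 1
    for comp in CASE_ONLY_COMPONENTS:
        member = pheno[f"in_{comp}"].fillna(False).to_numpy(dtype=bool)
        sel = case_mask & member
        if sel.sum() == 0:
            scores[comp] = _degenerate(comp, 0, "no cases in component")
            continue
        arm = pheno.loc[sel, f"active_{comp}"].to_numpy(dtype=float)
        scores[comp] = case_only_score_test(
            arm, g[sel], q=q_by_component[comp], component=comp,
            subject_ids=pheno.index[sel],
        )
    V = assemble_covariance(scores, structural_zero_main=structural_zero_main)
    U = np.array([scores[c].U for c in COMPONENT_ORDER])
    degen = [scores[c].degenerate for c in COMPONENT_ORDER]
    result = combined_chi2_test(U, V, degenerate=degen, snp_id=snp_id)
    return result, scores


def joint_test_scan(pheno: pd.DataFrame, genotypes, snp_ids, q_by_component: dict,
                    covariate_cols=None, structural_zero_main: bool = True) -> pd.DataFrame:
    """Per-SNP scan; returns one row per SNP with component and combined p."""
    G = np.asarray(genotypes, dtype=float)
    rows = []
    for j, sid in enumerate(snp_ids):
        res, sc = joint_test_snp(
            pheno, G[:, j], q_by_component, covariate_cols,
            snp_id=str(sid), structural_zero_main=structural_zero_main,
        )
        rows.append({
            "snp_id": str(sid),
            "U_main": sc["MAIN"].U,
            "p_main": sc["MAIN"].p,
            "p_Ealone": sc["E_ALONE"].p,
            "p_EP": sc["E_PLUS_P"].p,
            "p_DMQ": sc["DMQ"].p,
            "p_CaD": sc["CAD"].p,
            "chi2": res.chi2,
            "df": res.df,
            "p_combined": res.p,
        })
    return pd.DataFrame(rows)
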