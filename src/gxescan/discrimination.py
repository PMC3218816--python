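"""Case-control discrimination: nested risk models, AUC, bootstrap test.

Three nested logistic models are compared in-sample:

* M0 — confounders + the four intervention assignment indicators;
* M1 — M0 + per-SNP genotype indicators for one and two minor alleles;
* M2 — M1 + genotype-indicator x assignment interaction products.

AUC is the Mann-Whitney probability of concordance (ties count 1/2): the
probability that a random case's fitted risk exceeds a random control's.
The interaction terms' contribution is judged by a bootstrap that
resamples matched case-control *pairs* with replacement (matching induces
within-pair dependence, so pairs — not subjects — are the exchangeable
unit), refits both models per replicate, and refers the observed delta-AUC
to a two-sided normal approximation with the bootstrap standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DiscriminationResult",
    "FittedRiskModel",
    "auc",
    "fit_nested_risk_models",
    "bootstrap_auc_test",
]


@dataclass
class FittedRiskModel:
    label: str
    columns: list
    params: np.ndarray
    fitted: np.ndarray  # per-subject fitted probabilities
    loglik: float
    ridged: bool = False  # separation fallback used

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = np.clip(X @ self.params, -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class DiscriminationResult:
    model_label: str
    reference_label: str
    auc: float
    ci95: tuple
    auc_reference: float
    ci95_reference: tuple
    delta_auc_vs_reference: float
    bootstrap_p: float
    n_boot: int
    seed: int
    low_n_boot_warning: bool = False
    delta_boot: np.ndarray = field(default=None, repr=False)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with tie correction (tied pairs count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)  # average ranks implement the 1/2-tie rule
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _ridge_irls(y, X, alpha: float = 1e-2, max_iter: int = 100) -> np.ndarray:
    """L2-penalized logistic fit; the intercept is not penalized."""
    n, p = X.shape
    pen = alpha * np.eye(p)
    pen[0, 0] = 0.0
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        XtW = X.T * w
        step = np.linalg.solve(XtW @ X + pen, X.T @ (y - mu) - pen @ beta)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _fit_logistic(y, X, label, columns, ridge_alpha: float = 1e-2) -> FittedRiskModel:
    model = sm.GLM(y, X, family=sm.families.Binomial())
    ridged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = model.fit(maxiter=200)
        params = np.asarray(fit.params)
        eta = X @ params
        if not np.isfinite(params).all() or np.abs(eta).max() > 25:
            raise RuntimeError("separation")
    except Exception:
        # quasi-separation: ridge-stabilized refit (penalized IRLS), flagged
        params = _ridge_irls(y, X, alpha=ridge_alpha)
        ridged = True
    eta = np.clip(X @ params, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    ll = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    return FittedRiskModel(label, list(columns), params, mu, ll, ridged)


def _design_matrices(data: pd.DataFrame, snp_cols, assignment_cols, confounder_cols):
    """Build the M0/M1/M2 design matrices (shared column bookkeeping)."""
    n = len(data)
    cols0 = ["const"] + list(confounder_cols) + list(assignment_cols)
    X0 = np.column_stack(
        [np.ones(n)]
        + [data[c].to_numpy(dtype=float) for c in confounder_cols]
        + [data[c].fillna(0).to_numpy(dtype=float) for c in assignment_cols]
    )
    snp_ind_cols, snp_ind = [], []
    for s in snp_cols:
        g = data[s].to_numpy(dtype=float)
        snp_ind_cols += [f"{s}=1", f"{s}=2"]
        snp_ind += [(g == 1).astype(float), (g == 2).astype(float)]
    X1 = np.column_stack([X0] + snp_ind) if snp_ind else X0
    cols1 = cols0 + snp_ind_cols
    inter_cols, inter = [], []
    for a in assignment_cols:
        arm = data[a].fillna(0).to_numpy(dtype=float)
        for name, ind in zip(snp_ind_cols, snp_ind):
            inter_cols.append(f"{name}x{a}")
            inter.append(ind * arm)
    X2 = np.column_stack([X1] + inter) if inter else X1
    cols2 = cols1 + inter_cols
    return (X0, cols0), (X1, cols1), (X2, cols2)


def fit_nested_risk_models(data: pd.DataFrame, snp_cols, assignment_cols,
                           confounder_cols=()) -> dict:
    """Fit the nested logistic models M0 ⊂ M1 ⊂ M2.

    ``data`` needs a ``case`` column, the listed confounders, one 0/1
    assignment column per intervention (NA outside the component, treated
    as 0 = no active assignment), and the SNP dosage columns.  Returns
    ``{"M0": FittedRiskModel, "M1": ..., "M2": ...}``.
    """
    y = data["case"].to_numpy(dtype=float)
    (X0, c0), (X1, c1), (X2, c2) = _design_matrices(
        data, snp_cols, assignment_cols, confounder_cols
    )
    return {
        "M0": _fit_logistic(y, X0, "M0", c0),
        "M1": _fit_logistic(y, X1, "M1", c1),
        "M2": _fit_logistic(y, X2, "M2", c2),
    }


def bootstrap_auc_test(data: pd.DataFrame, snp_cols, assignment_cols,
                       confounder_cols=(), model_pair=("M2", "M1"),
                       n_boot: int = 1000, seed: int = 0,
                       pair_col: str = "pair_id") -> DiscriminationResult:
    """Bootstrap comparison of two nested risk models' in-sample AUC.

    Matched case-control pairs are resampled with replacement ``n_boot``
    times; both models are refit on each replicate and their AUCs
    recomputed.  p is the two-sided normal-approximation test of
    delta-AUC = 0 using the bootstrap standard error of the delta; each
    model's 95% CI comes from bootstrap percentiles.
    """
    rng = np.random.default_rng(seed)
    low_warn = n_boot < 100
    if low_warn:
        warnings.warn("n_boot < 100: bootstrap p is unreliable", RuntimeWarning)
    y = data["case"].to_numpy(dtype=float)

    def fit_and_auc(df):
        models = fit_nested_risk_models(df, snp_cols, assignment_cols, confounder_cols)
        yy = df["case"].to_numpy(dtype=float)
        return {k: auc(m.fitted, yy) for k, m in models.items()}

    full = fit_and_auc(data)
    label, ref = model_pair
    delta_obs = full[label] - full[ref]

    if pair_col in data.columns:
        groups = [grp.index.to_numpy() for _, grp in data.groupby(pair_col)]
    else:  # unmatched data: subjects are the resampling unit
        groups = [np.array([i]) for i in data.index]
    n_g = len(groups)
    aucs = {label: np.empty(n_boot), ref: np.empty(n_boot)}
    for b in range(n_boot):
        pick = rng.integers(0, n_g, size=n_g)
        idx = np.concatenate([groups[i] for i in pick])
        rep = data.loc[idx]
        try:
            a = fit_and_auc(rep)
        except ValueError:  # a replicate lost one class entirely
            a = full
        aucs[label][b] = a[label]
        aucs[ref][b] = a[ref]
    delta = aucs[label] - aucs[ref]
    se = float(delta.std(ddof=1))
    if se == 0.0:
        p = 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(delta_obs) / se))
    ci = tuple(np.percentile(aucs[label], [2.5, 97.5]))
    ci_ref = tuple(np.percentile(aucs[ref], [2.5, 97.5]))
    return DiscriminationResult(
        model_label=label, reference_label=ref,
        auc=full[label], ci95=ci,
        auc_reference=full[ref], ci95_reference=ci_ref,
        delta_auc_vs_reference=delta_obs, bootstrap_p=p,
        n_boot=n_boot, seed=seed, low_n_boot_warning=low_warn,
        delta_boot=delta,
    )
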