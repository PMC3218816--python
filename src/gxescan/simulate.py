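"""Synthetic partial-factorial randomized-trial cohort generator.

Emulates the structure of a large postmenopausal prevention trial cohort:
up to four overlapping randomized components — estrogen-alone (E_ALONE,
post-hysterectomy women), estrogen-plus-progestin (E_PLUS_P, women with a
uterus; the two hormone trials are therefore non-overlapping), low-fat
dietary modification (DM, with interaction analyses focused on the DMQ
subset whose baseline percent energy from fat is in the upper quartile),
and calcium/vitamin D (CAD, randomized at the one-year anniversary among
women still event-free) — plus LD-blocked genotypes with ancestry-linked
allele-frequency structure, a discrete-time logistic hazard outcome model,
and greedy risk-set matched 1:1 case-control selection.

The outcome model is a per-year logistic hazard: intervention, genotype,
and covariate effects enter as log odds ratios, and genotype-by-
intervention interaction is expressed by letting a component's
intervention log-OR depend on the minor-allele count of a chosen SNP
(a triple of ORs at 0/1/2 copies, the scale on which genotype-stratified
intervention ORs are reported downstream).

Genotypes come from per-block Gaussian-copula haplotypes: a latent AR(1)
Gaussian process per haplotype is thresholded at the allele frequency,
with the latent correlation calibrated (bivariate-normal inversion) so the
*allelic* correlation between adjacent SNPs hits the configured target;
two independent haplotypes per subject give Hardy-Weinberg genotypes.

All randomness flows from one master seed through named substreams
(`numpy` SeedSequence spawning), so each stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtri

from .genostats import SnpMeta, compute_maf

__all__ = [
    "TrialComponentSpec",
    "SimulationConfig",
    "CaseControlPair",
    "GenotypeMatrix",
    "default_component_specs",
    "simulate_genotypes",
    "simulate_cohort",
    "select_matched_case_control",
    "case_control_frame",
    "simulate_case_only_sample",
    "simulate_null_case_control",
]

COMPONENTS = ("E_ALONE", "E_PLUS_P", "DM", "CAD")

_ELIGIBILITY = {
    "E_ALONE": lambda df: df["hysterectomy"].to_numpy(dtype=bool),
    "E_PLUS_P": lambda df: ~df["hysterectomy"].to_numpy(dtype=bool),
    "DM": lambda df: np.ones(len(df), dtype=bool),
    "CAD": lambda df: np.ones(len(df), dtype=bool),
}


@dataclass
class TrialComponentSpec:
    """One randomized comparison within the partial factorial design."""

    name: str
    q: float  # active-assignment fraction
    enrollment_time: float = 0.0  # years from baseline (CAD: 1)
    participation: float = 1.0  # fraction of eligible women who enroll
    eligibility_rule: callable = None  # DataFrame -> boolean mask

    def __post_init__(self):
        if self.name not in COMPONENTS:
            raise ValueError(f"unknown component {self.name!r}")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if not 0 < self.participation <= 1:
            raise ValueError("participation must lie in (0, 1]")
        if self.eligibility_rule is None:
            self.eligibility_rule = _ELIGIBILITY[self.name]


def default_component_specs() -> list:
    """The four components at trial-like assignment and enrollment rates.

    Assignment fractions: 0.5 for the hormone and CaD components, 0.4 for
    DM.  Participation rates are set so the expected component sizes in a
    68,132-woman cohort match the published enrollment (10,739 E-alone,
    16,608 E+P, 48,835 DM, 36,282 CaD) given ~40% hysterectomy prevalence
    among hormone-trial participants.
    """
    return [
        TrialComponentSpec("E_ALONE", q=0.5, enrollment_time=0.0, participation=0.402),
        TrialComponentSpec("E_PLUS_P", q=0.5, enrollment_time=0.0, participation=0.402),
        TrialComponentSpec("DM", q=0.4, enrollment_time=0.0, participation=0.717),
        TrialComponentSpec("CAD", q=0.5, enrollment_time=1.0, participation=0.54),
    ]


def _default_blocks() -> list:
    # 4,988 SNPs in 3,224 LD blocks: 1,764 two-SNP blocks + 1,460 singletons
    return [2] * 1764 + [1] * 1460


@dataclass
class SimulationConfig:
    n_subjects: int = 68132
    seed: int = 0
    ld_block_sizes: list = field(default_factory=_default_blocks)
    within_block_adjacent_r: float = 0.9  # target allelic correlation
    ancestry_groups: list = field(default_factory=lambda: [
        ("european", 0.86, 0.0),
        ("african_american", 0.07, 0.15),
        ("hispanic", 0.04, -0.10),
        ("asian_pacific", 0.03, 0.10),
    ])
    maf_range: tuple = (0.05, 0.5)
    baseline_hazard: float = 0.004  # per-year event probability
    or_per_allele: dict = field(default_factory=dict)  # snp_id -> main OR
    interaction_or_by_genotype: dict = field(default_factory=dict)
    # ^ (snp_id, component) -> (OR at 0, 1, 2 minor alleles); replaces the
    #   component's main intervention OR for carriers of each genotype
    intervention_main_or: dict = field(default_factory=lambda: {
        "E_ALONE": 0.80, "E_PLUS_P": 1.25, "DM": 0.91, "CAD": 0.98,
    })
    covariate_effects: dict = field(default_factory=lambda: {
        "log_risk_score": 0.35, "log_bmi": 0.60,
    })
    component_specs: list = field(default_factory=default_component_specs)
    followup_years: int = 8
    dmq_quartile: float = 0.25
    receptor_positive_prob: dict = field(default_factory=lambda: {
        "ER": 0.75, "PR": 0.65,
    })
    hysterectomy_prevalence: float = 0.40

    @property
    def n_snps(self) -> int:
        return int(sum(self.ld_block_sizes))

    def validate(self) -> None:
        props = [p for _, p, _ in self.ancestry_groups]
        if abs(sum(props) - 1.0) > 1e-9 or any(p <= 0 for p in props):
            raise ValueError("ancestry proportions must be positive and sum to 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a subinterval of (0, 0.5]")
        if not 0 <= self.within_block_adjacent_r < 1:
            raise ValueError("within_block_adjacent_r must lie in [0, 1)")
        if not 0 < self.baseline_hazard < 1:
            raise ValueError("baseline_hazard must lie in (0, 1)")
        for or_val in self.or_per_allele.values():
            if or_val <= 0:
                raise ValueError("odds ratios must be positive")
        for triple in self.interaction_or_by_genotype.values():
            if len(triple) != 3 or any(v <= 0 for v in triple):
                raise ValueError("interaction OR triples must be 3 positive values")
        for or_val in self.intervention_main_or.values():
            if or_val <= 0:
                raise ValueError("odds ratios must be positive")
        names = [s.name for s in self.component_specs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate component specs")
        if not 0 < self.dmq_quartile <= 1:
            raise ValueError("dmq_quartile must lie in (0, 1]")


@dataclass(frozen=True)
class CaseControlPair:
    case_id: int
    control_id: int
    matching_factors: dict


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosages with per-SNP metadata."""

    dosages: np.ndarray  # float, NaN = missing
    snps: list  # list[SnpMeta], file/simulation order
    sample_ids: np.ndarray

    @property
    def snp_ids(self) -> list:
        return [s.snp_id for s in self.snps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids,
                            columns=self.snp_ids)


# ---------------------------------------------------------------------------
# genotype generation

_BVN_CACHE: dict = {}


def _latent_rho(p1: float, p2: float, target_r: float) -> float:
    """Latent Gaussian correlation giving allelic correlation ``target_r``.

    For thresholded Gaussians with allele frequencies p1, p2 the binary
    correlation is (Phi2(z1, z2; rho) - p1 p2) / sqrt(p1 q1 p2 q2); invert
    by bisection.  Cached on rounded (p1, p2, target).
    """
    if target_r == 0.0:
        return 0.0
    key = (round(p1, 4), round(p2, 4), round(target_r, 4))
    if key in _BVN_CACHE:
        return _BVN_CACHE[key]
    z1, z2 = ndtri(p1), ndtri(p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def gap(rho):
        cdf = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        ).cdf([z1, z2])
        return (cdf - p1 * p2) / denom - target_r

    hi = 0.999999
    if gap(hi) < 0:  # target exceeds the attainable binary correlation
        rho = hi
    else:
        rho = brentq(gap, -0.999999, hi, xtol=1e-8)
    _BVN_CACHE[key] = rho
    return rho


def _snp_positions(block_sizes):
    """Spread blocks over chromosomes 1..22 with wide inter-block gaps."""
    chroms, positions = [], []
    n_blocks = len(block_sizes)
    per_chrom = int(np.ceil(n_blocks / 22))
    b = 0
    for c in range(1, 23):
        pos = 1_000_000
        for _ in range(per_chrom):
            if b >= n_blocks:
                break
            for k in range(block_sizes[b]):
                chroms.append(str(c))
                positions.append(pos)
                pos += 5_000
            pos += 2_000_000  # recombination gap between blocks
            b += 1
    return chroms, positions


def simulate_genotypes(config: SimulationConfig, ancestry_labels,
                       rng=None) -> GenotypeMatrix:
    """Gaussian-copula haplotype genotypes in LD blocks.

    Ancestry-linked structure: each ancestry group's coded-allele frequency
    is the base frequency plus its configured shift (clipped to
    [0.01, 0.99]).  Dosages are re-oriented afterwards so they count the
    in-sample minor allele, and per-SNP metadata records the realized MAF.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = np.asarray(ancestry_labels)
    n = labels.size
    group_names = [g[0] for g in config.ancestry_groups]
    shifts = {g[0]: g[2] for g in config.ancestry_groups}
    group_idx = np.array([group_names.index(l) for l in labels])
    shift_vec = np.array([shifts[g] for g in group_names])

    lo, hi = config.maf_range
    # one base frequency per LD block (tightly linked SNPs share similar
    # allele frequencies; equal marginals also make any allelic correlation
    # target in [0, 1) attainable by the copula), with small per-SNP jitter
    base_freq = np.empty(config.n_snps)
    col0 = 0
    for size in config.ld_block_sizes:
        block_p = rng.uniform(lo, hi)
        jitter = rng.uniform(0.95, 1.05, size=size) if size > 1 else 1.0
        base_freq[col0:col0 + size] = np.clip(block_p * jitter, 0.01, 0.99)
        col0 += size
    # per-group coded-allele frequency, clipped away from fixation
    freqs = np.clip(base_freq[None, :] + shift_vec[:, None], 0.01, 0.99)
    thresholds = ndtri(freqs)  # latent threshold per (group, snp)

    target = config.within_block_adjacent_r
    dosage = np.empty((n, config.n_snps), dtype=float)
    col = 0
    for size in config.ld_block_sizes:
        z = np.empty((2 * n, size))
        z[:, 0] = rng.standard_normal(2 * n)
        for j in range(1, size):
            rho = _latent_rho(base_freq[col + j - 1], base_freq[col + j], target)
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(2 * n)
        thr = thresholds[group_idx][:, col:col + size]  # n x size
        h1 = (z[:n] < thr).astype(np.int8)
        h2 = (z[n:] < thr).astype(np.int8)
        dosage[:, col:col + size] = h1 + h2
        col += size

    chroms, positions = _snp_positions(config.ld_block_sizes)
    bases = ("A", "C", "G", "T")
    snps = []
    for j in range(config.n_snps):
        a_coded, a_other = rng.choice(4, size=2, replace=False)
        res = compute_maf(dosage[:, j], coded_allele=bases[a_coded],
                          other_allele=bases[a_other])
        dosage[:, j] = res.genotype
        snps.append(SnpMeta(
            snp_id=f"snp{j + 1:05d}", chromosome=chroms[j], position=positions[j],
            minor_allele=res.minor_allele, major_allele=res.major_allele,
            maf=res.maf,
        ))
    return GenotypeMatrix(dosages=dosage, snps=snps,
                          sample_ids=np.arange(n))


# ---------------------------------------------------------------------------
# cohort simulation

_PRIOR_USE_LEVELS = ("none", "<5", "5-10", ">=10")


def _component_log_or(config: SimulationConfig, comp: str,
                      geno: GenotypeMatrix) -> np.ndarray:
    """Per-subject intervention log-OR for one component.

    A configured (snp, component) OR triple replaces the component's main
    intervention OR for every subject, indexed by that subject's
    minor-allele count; multiple triples for one component multiply.
    """
    triples = [(sid, t) for (sid, c), t in config.interaction_or_by_genotype.items()
               if c == comp]
    n = geno.dosages.shape[0]
    if not triples:
        return np.full(n, np.log(config.intervention_main_or.get(comp, 1.0)))
    lor = np.zeros(n)
    ids = geno.snp_ids
    for sid, triple in triples:
        if sid not in ids:
            raise ValueError(f"interaction SNP {sid!r} not in genotype matrix")
        g = geno.dosages[:, ids.index(sid)].astype(int)
        lor += np.log(np.asarray(triple, dtype=float))[g]
    return lor


def simulate_cohort(config: SimulationConfig):
    """Generate the full cohort: covariates, memberships, genotypes, outcomes.

    Returns ``(cohort, genotypes)`` where ``cohort`` is a DataFrame indexed
    by subject id with covariates, per-component membership flags
    (``in_<NAME>``), arm indicators (``active_<NAME>``, NaN outside the
    component), the DMQ subset flag (``in_DMQ``), case status,
    ``event_time`` (event year, or follow-up end for censored subjects),
    and tumor receptor labels for cases.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_geno, rng_memb, rng_out, rng_rec = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    n = config.n_subjects

    # baseline covariates
    props = np.array([p for _, p, _ in config.ancestry_groups])
    groups = [g[0] for g in config.ancestry_groups]
    ethnicity = rng_cov.choice(groups, size=n, p=props)
    age = rng_cov.integers(50, 80, size=n).astype(float)
    hysterectomy = rng_cov.random(n) < config.hysterectomy_prevalence
    bmi = np.exp(rng_cov.normal(np.log(27.0), 0.17, size=n))
    risk_score = np.exp(rng_cov.normal(np.log(0.015), 0.5, size=n))
    pct_energy_fat = np.clip(rng_cov.normal(35.0, 6.5, size=n), 15.0, 60.0)
    prior_e = rng_cov.choice(_PRIOR_USE_LEVELS, size=n, p=[0.6, 0.2, 0.1, 0.1])
    prior_ep = rng_cov.choice(_PRIOR_USE_LEVELS, size=n, p=[0.7, 0.17, 0.08, 0.05])

    cohort = pd.DataFrame({
        "age": age, "ethnicity": ethnicity, "hysterectomy": hysterectomy,
        "bmi": bmi, "risk_score": risk_score, "pct_energy_fat": pct_energy_fat,
        "prior_e_years": prior_e, "prior_ep_years": prior_ep,
    })
    cohort.index.name = "subject_id"

    genotypes = simulate_genotypes(config, ethnicity, rng=rng_geno)

    specs = {s.name: s for s in config.component_specs}
    # baseline components (enrollment_time 0): membership + arm now
    for name, spec in specs.items():
        cohort[f"in_{name}"] = False
        cohort[f"active_{name}"] = np.nan
        if spec.enrollment_time == 0:
            eligible = spec.eligibility_rule(cohort)
            member = eligible & (rng_memb.random(n) < spec.participation)
            cohort.loc[member, f"in_{name}"] = True
            cohort.loc[member, f"active_{name}"] = (
                rng_memb.random(int(member.sum())) < spec.q
            ).astype(float)
    both = cohort.get("in_E_ALONE", pd.Series(False, index=cohort.index)) & \
        cohort.get("in_E_PLUS_P", pd.Series(False, index=cohort.index))
    if both.any():
        raise RuntimeError("hormone-trial memberships must be mutually exclusive")

    # time-constant part of the yearly hazard
    eta0 = np.full(n, logit(config.baseline_hazard))
    eff = config.covariate_effects
    if eff.get("log_risk_score"):
        lr = np.log(risk_score)
        eta0 += eff["log_risk_score"] * (lr - lr.mean())
    if eff.get("log_bmi"):
        lb = np.log(bmi)
        eta0 += eff["log_bmi"] * (lb - lb.mean())
    for sid, or_val in config.or_per_allele.items():
        if sid not in genotypes.snp_ids:
            raise ValueError(f"main-effect SNP {sid!r} not in genotype matrix")
        eta0 += np.log(or_val) * genotypes.dosages[:, genotypes.snp_ids.index(sid)]

    comp_lor = {name: _component_log_or(config, name, genotypes)
                for name in specs}

    case = np.zeros(n, dtype=bool)
    event_time = np.full(n, float(config.followup_years))
    at_risk = np.ones(n, dtype=bool)
    for t in range(1, int(config.followup_years) + 1):
        # late-enrolling components randomize among still-event-free women
        for name, spec in specs.items():
            if spec.enrollment_time == t - 1 and spec.enrollment_time > 0:
                eligible = spec.eligibility_rule(cohort) & at_risk
                member = eligible & (rng_memb.random(n) < spec.participation)
                cohort.loc[member, f"in_{name}"] = True
                cohort.loc[member, f"active_{name}"] = (
                    rng_memb.random(int(member.sum())) < spec.q
                ).astype(float)
        eta = eta0.copy()
        for name, spec in specs.items():
            if t < spec.enrollment_time + 1:
                continue
            active = (cohort[f"in_{name}"].to_numpy()
                      & (cohort[f"active_{name}"].to_numpy() == 1.0))
            eta[active] += comp_lor[name][active]
        hazard = expit(eta)
        events = at_risk & (rng_out.random(n) < hazard)
        case[events] = True
        event_time[events] = float(t)
        at_risk &= ~events

    cohort["case"] = case
    cohort["event_time"] = event_time

    # DMQ: DM participants in the top baseline-fat quartile
    cohort["in_DMQ"] = False
    if "DM" in specs:
        dm_idx = cohort.index[cohort["in_DM"]]
        k = int(round(config.dmq_quartile * len(dm_idx)))
        fat = cohort.loc[dm_idx, "pct_energy_fat"]
        top = fat.sort_values(ascending=False, kind="mergesort").index[:k]
        cohort.loc[top, "in_DMQ"] = True

    # tumor receptor status for cases, independent of genotype
    er = np.full(n, None, dtype=object)
    pr = np.full(n, None, dtype=object)
    n_cases = int(case.sum())
    er[case] = np.where(rng_rec.random(n_cases) < config.receptor_positive_prob["ER"],
                        "ER+", "ER-")
    pr[case] = np.where(rng_rec.random(n_cases) < config.receptor_positive_prob["PR"],
                        "PR+", "PR-")
    cohort["er_status"] = er
    cohort["pr_status"] = pr
    return cohort, genotypes


# ---------------------------------------------------------------------------
# matched case-control selection

DEFAULT_MATCH_FACTORS = ("ethnicity", "hysterectomy",
                         "in_E_ALONE", "in_E_PLUS_P", "in_DM", "in_CAD")


def select_matched_case_control(cohort: pd.DataFrame,
                                factors=DEFAULT_MATCH_FACTORS,
                                age_caliper: float = 2.0):
    """Greedy risk-set 1:1 matching of controls to cases.

    Cases are processed in event-time order; each receives the unused
    subject with exactly matching categorical factors, event-free at the
    case's event time (non-case with censoring time >= t, or a later case
    with event time > t), and nearest in age within the caliper.  Cases
    with no eligible control are flagged unmatched rather than failing.

    Returns ``(pairs, unmatched_case_ids)``.
    """
    cases = cohort.index[cohort["case"].astype(bool)]
    if len(cases) == 0:
        raise ValueError("cohort contains no cases")
    order = cohort.loc[cases].sort_values(["event_time"], kind="mergesort").index
    key_cols = list(factors)
    keys = cohort[key_cols].astype(object).apply(tuple, axis=1)
    pool: dict = {}
    for sid, key in keys.items():
        pool.setdefault(key, []).append(sid)
    used = set()
    age_v = cohort["age"]
    case_v = cohort["case"].astype(bool)
    time_v = cohort["event_time"]
    pairs, unmatched = [], []
    for cid in order:
        t = time_v[cid]
        best, best_gap = None, None
        for sid in pool.get(keys[cid], ()):
            if sid == cid or sid in used or sid == cid:
                continue
            if case_v[sid]:
                if time_v[sid] <= t:
                    continue
            elif time_v[sid] < t:
                continue
            gap = abs(age_v[sid] - age_v[cid])
            if gap > age_caliper:
                continue
            if best is None or gap < best_gap or (gap == best_gap and sid < best):
                best, best_gap = sid, gap
        if best is None:
            unmatched.append(cid)
            continue
        used.add(best)
        used.add(cid)
        pairs.append(CaseControlPair(
            case_id=cid, control_id=best,
            matching_factors=dict(zip(key_cols, keys[cid])),
        ))
    return pairs, unmatched


def case_control_frame(cohort: pd.DataFrame, pairs) -> pd.DataFrame:
    """Phenotype table for the matched sample (one row per subject).

    Adds ``pair_id`` plus the derived covariates used by the main-effect
    null model: log risk score, log BMI, and prior-hormone-use indicator
    columns.
    """
    rows = []
    for k, p in enumerate(pairs):
        rows.append((p.case_id, k))
        rows.append((p.control_id, k))
    ids = [r[0] for r in rows]
    out = cohort.loc[ids].copy()
    out["pair_id"] = [r[1] for r in rows]
    out["log_risk_score"] = np.log(out["risk_score"])
    out["log_bmi"] = np.log(out["bmi"])
    for col in ("prior_e_years", "prior_ep_years"):
        for lev in _PRIOR_USE_LEVELS[1:]:
            out[f"{col}_{lev}"] = (out[col] == lev).astype(float)
    return out


# ---------------------------------------------------------------------------
# direct case-control-level samplers (large-sample shortcuts)


def simulate_case_only_sample(n_cases: int, q: float, or_by_genotype=(1.0, 1.0, 1.0),
                              maf: float = 0.3, seed: int = 0):
    """Draw (genotype, assignment) for cases of one trial component.

    Among cases at genotype g the odds of active assignment are
    (q/(1-q)) * OR_g — the exact induced distribution in the cohort model
    when the component's intervention OR at genotype g is OR_g.  This is
    the large-sample shortcut for parameter-recovery studies of the
    case-only estimators.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    triple = np.asarray(or_by_genotype, dtype=float)
    if triple.shape != (3,) or (triple <= 0).any():
        raise ValueError("or_by_genotype must be 3 positive ORs")
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, maf, size=n_cases)
    p_active = expit(logit(q) + np.log(triple)[g])
    a = (rng.random(n_cases) < p_active).astype(int)
    return g, a


def simulate_null_case_control(n_pairs: int, q_by_component=None,
                               case_arm_or=None, maf: float = 0.3,
                               membership_rates=None, n_covariates: int = 2,
                               seed: int = 0):
    """Matched case-control sample under the genotype-null hypothesis.

    Generates the nested case-control sample directly at the case-control
    level: genotype ~ Binomial(2, maf) independently of everything (no
    main effect, no interaction), component memberships drawn per case at
    trial-like rates (hormone membership split by hysterectomy so E_ALONE
    and E_PLUS_P never co-occur; DMQ as a fat-quartile subset of DM) and
    copied to the matched control, and *intervention main effects present*:
    among cases of component c, P(active) = expit(logit(q_c) + log
    case_arm_or[c]), the distribution a nonzero intervention main effect
    induces in cases.  Noise covariates are independent standard normals.

    Returns ``(pheno, genotype)`` ready for :func:`gxescan.jointtest.joint_test_snp`.
    """
    if q_by_component is None:
        q_by_component = {"E_ALONE": 0.5, "E_PLUS_P": 0.5, "DMQ": 0.4, "CAD": 0.5}
    if case_arm_or is None:
        case_arm_or = {"E_ALONE": 0.80, "E_PLUS_P": 1.25, "DMQ": 0.80, "CAD": 0.98}
    if membership_rates is None:
        # case counts per component relative to 2,166 total cases
        membership_rates = {"hormone": 0.33, "E_ALONE_frac": 0.34,
                            "DM": 0.80, "fat_quartile": 0.25, "CAD": 0.48}
    rng = np.random.default_rng(seed)
    n = 2 * n_pairs
    case = np.zeros(n, dtype=bool)
    case[:n_pairs] = True
    pair_id = np.concatenate([np.arange(n_pairs), np.arange(n_pairs)])

    hormone = rng.random(n_pairs) < membership_rates["hormone"]
    hyst = rng.random(n_pairs) < membership_rates["E_ALONE_frac"]
    in_ea = hormone & hyst
    in_ep = hormone & ~hyst
    in_dm = rng.random(n_pairs) < membership_rates["DM"]
    in_dmq = in_dm & (rng.random(n_pairs) < membership_rates["fat_quartile"])
    in_cad = rng.random(n_pairs) < membership_rates["CAD"]
    member = {"E_ALONE": in_ea, "E_PLUS_P": in_ep, "DMQ": in_dmq, "CAD": in_cad}

    pheno = pd.DataFrame(index=pd.RangeIndex(n, name="subject_id"))
    pheno["case"] = case.astype(int)
    pheno["pair_id"] = pair_id
    for comp in ("E_ALONE", "E_PLUS_P", "DMQ", "CAD"):
        m = np.concatenate([member[comp], member[comp]])  # control matches case
        pheno[f"in_{comp}"] = m
        arm = np.full(n, np.nan)
        q = q_by_component[comp]
        # cases: randomization odds tilted by the intervention main effect
        p_case = expit(logit(q) + np.log(case_arm_or[comp]))
        arm_case = (rng.random(n_pairs) < p_case).astype(float)
        arm_ctrl = (rng.random(n_pairs) < q).astype(float)
        arm[:n_pairs] = np.where(member[comp], arm_case, np.nan)
        arm[n_pairs:] = np.where(member[comp], arm_ctrl, np.nan)
        pheno[f"active_{comp}"] = arm
    for k in range(n_covariates):
        pheno[f"x{k + 1}"] = rng.standard_normal(n)
    genotype = rng.binomial(2, maf, size=n).astype(float)
    return pheno, genotype
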