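import numpy as np
import pandas as pd
import pytest

from gxescan.genostats import ld_r2, pca_genotypes
from gxescan.simulate import (SimulationConfig, TrialComponentSpec,
                              select_matched_case_control, simulate_case_only_sample,
                              simulate_cohort, simulate_genotypes,
                              simulate_null_case_control)


class TestConfigValidation:
    def test_bad_proportions_rejected(self):
        cfg = SimulationConfig(ancestry_groups=[("a", 0.6, 0.0), ("b", 0.6, 0.1)])
        with pytest.raises(ValueError):
            cfg.validate()

    def test_bad_or_rejected(self):
        cfg = SimulationConfig(or_per_allele={"snp00001": -1.0})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_bad_maf_range_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.6)).validate()

    def test_bad_q_rejected(self):
        with pytest.raises(ValueError):
            TrialComponentSpec("DM", q=1.0)

    def test_default_snp_count_matches_block_sum(self):
        cfg = SimulationConfig()
        assert cfg.n_snps == sum(cfg.ld_block_sizes) == 4988
        assert len(cfg.ld_block_sizes) == 3224  # one LD bin per block


class TestCohort:
    def test_hormone_trials_mutually_exclusive(self, small_cohort):
        _, cohort, _ = small_cohort
        assert not (cohort.in_E_ALONE & cohort.in_E_PLUS_P).any()
        # eligibility respected
        assert cohort.loc[cohort.in_E_ALONE, "hysterectomy"].all()
        assert not cohort.loc[cohort.in_E_PLUS_P, "hysterectomy"].any()

    def test_arms_only_for_members(self, small_cohort):
        _, cohort, _ = small_cohort
        for comp in ("E_ALONE", "E_PLUS_P", "DM", "CAD"):
            assert cohort.loc[~cohort[f"in_{comp}"], f"active_{comp}"].isna().all()
            assert cohort.loc[cohort[f"in_{comp}"], f"active_{comp}"].notna().all()

    def test_assignment_fraction_converges_to_q(self, small_cohort):
        cfg, cohort, _ = small_cohort
        for spec in cfg.component_specs:
            arms = cohort.loc[cohort[f"in_{spec.name}"], f"active_{spec.name}"]
            se = np.sqrt(spec.q * (1 - spec.q) / len(arms))
            assert arms.mean() == pytest.approx(spec.q, abs=4 * se)

    def test_null_case_fraction_binomial(self):
        """With all ORs at 1 and no covariate effects, the case fraction
        follows 1 - (1 - h)^T within 3 binomial SDs."""
        h, T, n = 0.01, 8, 20_000
        cfg = SimulationConfig(
            n_subjects=n, seed=5, ld_block_sizes=[1] * 4, baseline_hazard=h,
            covariate_effects={}, followup_years=T,
            intervention_main_or={c: 1.0 for c in ("E_ALONE", "E_PLUS_P", "DM", "CAD")},
        )
        cohort, _ = simulate_cohort(cfg)
        expect = 1 - (1 - h) ** T
        sd = np.sqrt(expect * (1 - expect) / n)
        assert cohort.case.mean() == pytest.approx(expect, abs=3 * sd)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_subjects=600, seed=42, ld_block_sizes=[2, 2, 1],
                               baseline_hazard=0.02)
        c1, g1 = simulate_cohort(cfg)
        c2, g2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)

    def test_cad_membership_requires_surviving_year_one(self, small_cohort):
        _, cohort, _ = small_cohort
        assert (cohort.loc[cohort.in_CAD, "event_time"] > 1).all()

    def test_dmq_subset_is_top_fat_quartile_of_dm(self, small_cohort):
        cfg, cohort, _ = small_cohort
        n_dm = int(cohort.in_DM.sum())
        assert abs(cohort.in_DMQ.sum() - cfg.dmq_quartile * n_dm) <= 1
        assert cohort.loc[cohort.in_DMQ, "in_DM"].all()
        dmq_min = cohort.loc[cohort.in_DMQ, "pct_energy_fat"].min()
        other = cohort.loc[cohort.in_DM & ~cohort.in_DMQ, "pct_energy_fat"]
        assert (other <= dmq_min).all()

    def test_receptor_status_only_for_cases(self, small_cohort):
        _, cohort, _ = small_cohort
        assert cohort.loc[cohort.case, "er_status"].isin(["ER+", "ER-"]).all()
        assert cohort.loc[~cohort.case, "er_status"].isna().all()

    def test_randomization_independent_of_genotype(self):
        """Arm-genotype correlation is 0 within Monte-Carlo error — the
        property that validates every case-only statistic."""
        cors = []
        for seed in range(6):
            cfg = SimulationConfig(n_subjects=3000, seed=seed,
                                   ld_block_sizes=[2, 2], baseline_hazard=0.02)
            cohort, geno = simulate_cohort(cfg)
            dm = cohort.in_DM.to_numpy()
            arm = cohort.loc[dm, "active_DM"].to_numpy(float)
            for j in range(4):
                cors.append(np.corrcoef(arm, geno.dosages[dm, j])[0, 1])
        cors = np.array(cors)
        assert abs(cors.mean()) < 2 / np.sqrt(len(cors) * 1200)
        assert np.abs(cors).max() < 0.1

    def test_interaction_triple_shapes_case_only_arm_odds(self):
        """A configured OR triple reproduces itself in the cohort's cases:
        among E_ALONE cases at genotype g, odds(active)/rand-odds ~= OR_g."""
        triple = (0.4, 1.0, 1.0)
        cfg = SimulationConfig(
            n_subjects=30_000, seed=17, ld_block_sizes=[1, 1],
            baseline_hazard=0.03, maf_range=(0.4, 0.5),
            interaction_or_by_genotype={("snp00001", "E_ALONE"): triple},
        )
        cohort, geno = simulate_cohort(cfg)
        sel = (cohort.case & cohort.in_E_ALONE).to_numpy()
        g = geno.dosages[sel, 0]
        a = cohort.loc[sel, "active_E_ALONE"].to_numpy(float)
        odds = [a[g == k].mean() / (1 - a[g == k].mean()) for k in (0, 1)]
        or0 = odds[0] / 1.0  # q = 0.5: randomization odds 1
        or1 = odds[1] / 1.0
        assert or0 < 0.75  # strong protective shift at genotype 0
        assert or1 == pytest.approx(1.0, abs=0.35)


class TestGenotypes:
    def test_zero_target_correlation(self):
        cfg = SimulationConfig(n_subjects=4000, seed=2, ld_block_sizes=[4],
                               within_block_adjacent_r=0.0)
        geno = simulate_genotypes(cfg, ["european"] * 4000,
                                  rng=np.random.default_rng(2))
        for j in range(3):
            r2 = ld_r2(geno.dosages[:, j], geno.dosages[:, j + 1])
            assert r2 < 0.01

    def test_calibrated_adjacent_r2(self):
        """Target allelic correlation 0.9 yields adjacent r^2 near 0.81."""
        cfg = SimulationConfig(n_subjects=10_000, seed=3, ld_block_sizes=[5],
                               within_block_adjacent_r=0.9)
        geno = simulate_genotypes(cfg, ["european"] * 10_000,
                                  rng=np.random.default_rng(3))
        r2s = [ld_r2(geno.dosages[:, j], geno.dosages[:, j + 1]) for j in range(4)]
        np.testing.assert_allclose(r2s, 0.81, atol=0.05)

    def test_between_block_independence(self):
        cfg = SimulationConfig(n_subjects=6000, seed=4, ld_block_sizes=[2, 2],
                               within_block_adjacent_r=0.9)
        geno = simulate_genotypes(cfg, ["european"] * 6000,
                                  rng=np.random.default_rng(4))
        assert ld_r2(geno.dosages[:, 1], geno.dosages[:, 2]) < 0.01

    def test_dosages_count_minor_allele(self, small_cohort):
        _, _, geno = small_cohort
        for j, snp in enumerate(geno.snps):
            col = geno.dosages[:, j]
            assert set(np.unique(col)) <= {0.0, 1.0, 2.0}
            assert col.mean() / 2 == pytest.approx(snp.maf, abs=1e-12)
            assert snp.maf <= 0.5

    def test_ancestry_shift_separates_on_first_pc(self):
        """A 0.2 allele-frequency shift between two groups dominates PC1."""
        n = 3000
        labels = ["g1"] * (n // 2) + ["g2"] * (n // 2)
        cfg = SimulationConfig(
            n_subjects=n, seed=6, ld_block_sizes=[1] * 100,
            within_block_adjacent_r=0.0, maf_range=(0.2, 0.4),
            ancestry_groups=[("g1", 0.5, 0.0), ("g2", 0.5, 0.2)],
        )
        geno = simulate_genotypes(cfg, labels, rng=np.random.default_rng(6))
        pcs = pca_genotypes(geno.dosages, k=2)
        grp = np.array([0] * (n // 2) + [1] * (n // 2), float)
        r = abs(np.corrcoef(pcs.eigenvectors[:, 0], grp)[0, 1])
        assert r > 0.9


class TestMatching:
    @staticmethod
    def _base_row(**kw):
        row = dict(age=60.0, ethnicity="european", hysterectomy=False,
                   bmi=27.0, risk_score=0.015, pct_energy_fat=35.0,
                   prior_e_years="none", prior_ep_years="none",
                   in_E_ALONE=False, in_E_PLUS_P=False, in_DM=False,
                   in_CAD=False, in_DMQ=False,
                   active_E_ALONE=np.nan, active_E_PLUS_P=np.nan,
                   active_DM=np.nan, active_CAD=np.nan,
                   case=False, event_time=8.0)
        row.update(kw)
        return row

    def test_clone_pool_fully_matched(self):
        rows = []
        for i, age in enumerate((55, 62, 71)):
            rows.append(self._base_row(age=age, case=True, event_time=3.0))
            rows.append(self._base_row(age=age))  # exact clone, event-free
        cohort = pd.DataFrame(rows)
        pairs, unmatched = select_matched_case_control(cohort)
        assert len(pairs) == 3 and not unmatched
        for p in pairs:
            assert cohort.loc[p.case_id, "age"] == cohort.loc[p.control_id, "age"]

    def test_risk_set_violation_unmatched(self):
        cohort = pd.DataFrame([
            self._base_row(case=True, event_time=5.0),
            self._base_row(case=False, event_time=3.0),  # left risk set earlier
        ])
        pairs, unmatched = select_matched_case_control(cohort)
        assert not pairs and unmatched == [0]

    def test_later_case_can_serve_as_control(self):
        cohort = pd.DataFrame([
            self._base_row(case=True, event_time=2.0),
            self._base_row(case=True, event_time=6.0),
        ])
        pairs, unmatched = select_matched_case_control(cohort)
        assert len(pairs) == 1
        assert pairs[0].case_id == 0 and pairs[0].control_id == 1
        assert unmatched == [1]  # its only candidate is used up

    def test_greedy_nearest_age_hand_example(self):
        """3 cases, 5 controls: greedy event-time order, nearest age."""
        cohort = pd.DataFrame([
            self._base_row(age=60, case=True, event_time=2.0),  # id 0
            self._base_row(age=70, case=True, event_time=4.0),  # id 1
            self._base_row(age=64, case=True, event_time=1.0),  # id 2
            self._base_row(age=61),  # id 3
            self._base_row(age=65),  # id 4
            self._base_row(age=69),  # id 5
            self._base_row(age=71),  # id 6
            self._base_row(age=52),  # id 7
        ])
        pairs, unmatched = select_matched_case_control(cohort, age_caliper=2.0)
        got = {p.case_id: p.control_id for p in pairs}
        # hand enumeration: case 2 (t=1) first -> nearest age 64 is 65 (id 4);
        # case 0 (t=2) -> 61 (id 3); case 1 (t=4) -> 71 and 69 tie at gap 1,
        # smaller id wins (id 5)
        assert got == {2: 4, 0: 3, 1: 5}
        assert not unmatched

    def test_empty_case_set_rejected(self):
        cohort = pd.DataFrame([self._base_row()])
        with pytest.raises(ValueError):
            select_matched_case_control(cohort)

    def test_factor_exact_match_enforced(self, small_cohort):
        _, cohort, _ = small_cohort
        pairs, _ = select_matched_case_control(cohort)
        for p in pairs[:50]:
            for f in ("ethnicity", "hysterectomy", "in_E_ALONE", "in_DM"):
                assert cohort.loc[p.case_id, f] == cohort.loc[p.control_id, f]
            assert abs(cohort.loc[p.case_id, "age"]
                       - cohort.loc[p.control_id, "age"]) <= 2.0
            assert (cohort.loc[p.control_id, "event_time"]
                    >= cohort.loc[p.case_id, "event_time"])


class TestDirectSamplers:
    def test_case_only_sampler_null_is_binomial_q(self):
        g, a = simulate_case_only_sample(20_000, q=0.4, seed=1)
        assert a.mean() == pytest.approx(0.4, abs=0.01)
        assert g.mean() / 2 == pytest.approx(0.3, abs=0.01)

    def test_null_case_control_structure(self):
        pheno, g = simulate_null_case_control(500, seed=2)
        assert len(pheno) == 1000
        assert pheno.case.sum() == 500
        assert not (pheno.in_E_ALONE & pheno.in_E_PLUS_P).any()
        assert pheno.loc[~pheno.in_CAD, "active_CAD"].isna().all()
        assert pheno.loc[pheno.in_DMQ, "in_DMQ"].all()
        # membership matched within pair
        wide = pheno.groupby("pair_id")["in_DMQ"].nunique()
        assert (wide == 1).all()

    def test_intervention_main_effect_shifts_case_arms_only(self):
        pheno, _ = simulate_null_case_control(20_000, seed=3,
                                              case_arm_or={"E_ALONE": 0.5,
                                                           "E_PLUS_P": 1.0,
                                                           "DMQ": 1.0, "CAD": 1.0})
        cases = pheno[(pheno.case == 1) & pheno.in_E_ALONE]
        ctrls = pheno[(pheno.case == 0) & pheno.in_E_ALONE]
        expected = 1 / (1 + np.exp(-(np.log(0.5))))  # expit(logit(.5)+log .5)
        assert cases.active_E_ALONE.mean() == pytest.approx(expected, abs=0.02)
        assert ctrls.active_E_ALONE.mean() == pytest.approx(0.5, abs=0.02)
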