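import numpy as np
import pytest

from gxescan.simulate import (SimulationConfig, case_control_frame,
                              select_matched_case_control, simulate_cohort)

Q_DEFAULT = {"E_ALONE": 0.5, "E_PLUS_P": 0.5, "DMQ": 0.4, "CAD": 0.5}


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with elevated hazard so the matched sample is usable."""
    cfg = SimulationConfig(
        n_subjects=4000, seed=11, ld_block_sizes=[3] * 8 + [1] * 6,
        baseline_hazard=0.02,
    )
    cohort, geno = simulate_cohort(cfg)
    return cfg, cohort, geno


@pytest.fixture(scope="session")
def matched_sample(small_cohort):
    """Matched case-control frame + aligned dosage matrix."""
    _, cohort, geno = small_cohort
    pairs, _ = select_matched_case_control(cohort)
    cc = case_control_frame(cohort, pairs)
    cc["active_DMQ"] = cc["active_DM"]
    pos = {s: i for i, s in enumerate(geno.sample_ids)}
    dosages = geno.dosages[[pos[s] for s in cc.index]]
    return cc, dosages, geno.snp_ids


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
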