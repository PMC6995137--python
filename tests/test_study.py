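"""Synthetic before/after study: generator marginals and parameter recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from graftce.model import DecisionTreeModel
from graftce.study import (
    StudyConfig,
    end_to_end,
    estimate_cost_lognormal,
    estimate_regraft_beta,
    estimate_rr_lognormal,
    estimate_spec_set,
    estimate_utility_beta,
    generate_study,
)

BIG = replace(StudyConfig(), n_before=10_000, n_after=10_000, seed=0)


@pytest.fixture(scope="module")
def big_study():
    return generate_study(BIG)


class TestGenerator:
    def test_reproducible_from_seed(self):
        a = generate_study(StudyConfig(seed=3))
        b = generate_study(StudyConfig(seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_default_sizes_match_study_design(self):
        records = generate_study(StudyConfig(seed=0))
        assert (records["period"] == "before").sum() == 131
        assert (records["period"] == "after").sum() == 90

    def test_regraft_rates_converge_to_config(self, big_study):
        for period, p in [("before", BIG.p_regraft_before), ("after", BIG.p_regraft_after)]:
            rate = big_study.loc[big_study["period"] == period, "regraft"].mean()
            assert rate == pytest.approx(p, abs=0.01)

    def test_utilities_only_in_prospective_period(self, big_study):
        before = big_study[big_study["period"] == "before"]
        assert before["u_baseline"].isna().all() and before["u_day28"].isna().all()
        after = big_study[big_study["period"] == "after"]
        completion = after["u_day28"].notna().mean()
        assert completion == pytest.approx(BIG.utility_completion_rate, abs=0.02)

    def test_zero_completion_rate_gives_no_utilities(self):
        cfg = replace(StudyConfig(seed=0), utility_completion_rate=0.0)
        records = generate_study(cfg)
        assert records["u_baseline"].isna().all() and records["u_day28"].isna().all()

    def test_cost_marginals_kolmogorov_smirnov(self, big_study):
        costs = big_study.loc[big_study["regraft"] == 0, "inpatient_cost"]
        sample = costs.sample(10_000, random_state=0)
        ks = stats.kstest(
            np.log(sample), "norm", args=(BIG.cost_logmean_no, BIG.cost_logsd_no)
        )
        assert ks.pvalue > 0.01

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(p_regraft_after=1.5)
        with pytest.raises(ValueError):
            StudyConfig(n_after=0)


class TestEstimators:
    def test_regraft_beta_conjugate_arithmetic(self):
        records = pd.DataFrame({"period": ["after"] * 90, "regraft": [1] * 4 + [0] * 86})
        spec = estimate_regraft_beta(records, "after")
        assert (spec.shape_a, spec.shape_b) == (4.5, 86.5)
        assert spec.mean() == pytest.approx(4.5 / 91, rel=1e-12)

    def test_zero_events_never_degenerate(self):
        records = pd.DataFrame({"period": ["after"] * 50, "regraft": [0] * 50})
        spec = estimate_regraft_beta(records, "after")
        assert spec.mean() == pytest.approx(0.5 / 51, rel=1e-12)

    def test_regraft_beta_empty_period_raises(self):
        records = pd.DataFrame({"period": ["after"], "regraft": [0]})
        with pytest.raises(ValueError, match="no records"):
            estimate_regraft_beta(records, "before")

    def test_rr_delta_method_arithmetic(self):
        records = pd.DataFrame(
            {
                "period": ["after"] * 90 + ["before"] * 131,
                "regraft": [1] * 4 + [0] * 86 + [1] * 10 + [0] * 121,
            }
        )
        spec = estimate_rr_lognormal(records)
        assert np.exp(spec.shape_a) == pytest.approx((4 / 90) / (10 / 131), rel=1e-12)
        assert np.exp(spec.shape_a) == pytest.approx(0.582, abs=1e-3)
        assert spec.shape_b == pytest.approx(np.sqrt(1 / 4 - 1 / 90 + 1 / 10 - 1 / 131), rel=1e-12)
        assert spec.shape_b == pytest.approx(0.576, abs=1e-3)

    def test_equal_rates_give_zero_meanlog(self):
        records = pd.DataFrame(
            {"period": ["after"] * 40 + ["before"] * 40, "regraft": ([1] * 4 + [0] * 36) * 2}
        )
        assert estimate_rr_lognormal(records).shape_a == 0.0

    def test_rr_zero_events_advises_continuity_correction(self):
        records = pd.DataFrame(
            {"period": ["after"] * 20 + ["before"] * 20, "regraft": [0] * 20 + [1] * 5 + [0] * 15}
        )
        with pytest.raises(ValueError, match="continuity"):
            estimate_rr_lognormal(records)

    def test_cost_lognormal_recovery(self, big_study):
        re = estimate_cost_lognormal(big_study, "regraft")
        no = estimate_cost_lognormal(big_study, "no_regraft")
        assert re.shape_a == pytest.approx(BIG.cost_logmean_regraft, abs=0.05)
        assert no.shape_a == pytest.approx(BIG.cost_logmean_no, abs=0.01)
        assert re.shape_b == pytest.approx(BIG.cost_logsd_regraft, abs=0.05)

    def test_cost_identical_values_give_zero_sdlog(self):
        records = pd.DataFrame(
            {"period": ["after"] * 3, "regraft": [1, 1, 1], "inpatient_cost": [5000.0] * 3}
        )
        assert estimate_cost_lognormal(records, "regraft").shape_b == 0.0

    def test_cost_small_stratum_raises(self):
        records = pd.DataFrame(
            {"period": ["after"], "regraft": [1], "inpatient_cost": [5000.0]}
        )
        with pytest.raises(ValueError, match=">= 2"):
            estimate_cost_lognormal(records, "regraft")

    def test_utility_moment_recovery(self, big_study):
        spec = estimate_utility_beta(big_study, "no_regraft_d28")
        assert spec.mean() == pytest.approx(2.26 / (2.26 + 2.19), abs=0.02)
        base = estimate_utility_beta(big_study, "baseline")
        assert base.mean() == pytest.approx(0.77 / 2.18, abs=0.02)

    def test_utility_boundary_values_nudged_with_warning(self):
        records = pd.DataFrame(
            {
                "period": ["after"] * 4,
                "regraft": [0] * 4,
                "u_baseline": [0.0, 1.0, 0.5, 0.4],
                "u_day28": [np.nan] * 4,
            }
        )
        with pytest.warns(UserWarning, match="nudged"):
            spec = estimate_utility_beta(records, "baseline")
        assert spec.family == "beta"

    def test_utility_infeasible_variance_raises(self):
        records = pd.DataFrame(
            {
                "period": ["after"] * 4,
                "regraft": [0] * 4,
                "u_baseline": [0.01, 0.99, 0.01, 0.99],
                "u_day28": [np.nan] * 4,
            }
        )
        with pytest.raises(ValueError, match="infeasible"):
            estimate_utility_beta(records, "baseline")


class TestEndToEnd:
    def test_recovery_propagates_to_base_case_inb(self, big_study, base_results):
        """Generating at base-case truth with n=10,000 per period and
        re-estimating recovers the relative risk, cost scales, and the
        propagated incremental net benefit of the fixture analysis."""
        specs = estimate_spec_set(big_study)
        rr = specs["rr"]
        assert 0.52 < rr.median() < 0.63
        assert specs["c_regraft"].shape_a == pytest.approx(9.81, abs=0.01)
        assert specs["c_no_regraft"].shape_a == pytest.approx(9.20, abs=0.01)

        recovered = DecisionTreeModel(specs).fit(50_000, seed=1)
        inb_fixture = base_results.summary()["inb"]["mean"]
        inb_recovered = recovered.summary()["inb"]["mean"]
        assert inb_recovered == pytest.approx(inb_fixture, abs=60.0)

    def test_null_truth_gives_null_inb(self):
        cfg = replace(
            BIG, p_regraft_before=BIG.p_regraft_after, c_intervention=0.0, seed=0
        )
        out = end_to_end(cfg, n_iter=20_000, seed=1)
        inb = out["summary"]["inb"]["mean"]
        # truth RR=1 and free intervention: INB centred on 0 (estimation noise only)
        assert abs(inb) < 60.0

    def test_tiny_study_runs_with_instability_warning(self):
        cfg = replace(
            StudyConfig(),
            n_before=25,
            n_after=25,
            p_regraft_before=0.3,
            p_regraft_after=0.3,
            utility_completion_rate=1.0,
            seed=4,
        )
        with pytest.warns(UserWarning, match="unstable"):
            out = end_to_end(cfg, n_iter=2_000, seed=1)
        assert len(out["summary"].table) == 9
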