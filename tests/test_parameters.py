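"""Parameter distributions: construction, summaries, joint sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftce.parameters import (
    REQUIRED_PARAMETERS,
    Z975,
    ParameterSpec,
    ParameterSpecSet,
    lognormal_from_median_ci,
    summarize,
)


class TestLognormalFromMedianCI:
    @pytest.mark.parametrize(
        "median, lo, hi, meanlog, sdlog",
        [
            # relative risk of re-graft as published: median 0.574, 95% CI (0.52, 0.63)
            (0.574, 0.52, 0.63, math.log(0.574), (math.log(0.63) - math.log(0.52)) / (2 * Z975)),
            (1.0, 1.0, 1.0, 0.0, 0.0),
            # a no-bias / high-uncertainty bias factor
            (1.00, 0.47, 1.88, 0.0, (math.log(1.88) - math.log(0.47)) / (2 * Z975)),
        ],
    )
    def test_closed_form_inversion(self, median, lo, hi, meanlog, sdlog):
        spec = lognormal_from_median_ci(median, lo, hi, name="x")
        assert spec.family == "lognormal"
        assert spec.shape_a == pytest.approx(meanlog, abs=1e-12)
        assert spec.shape_b == pytest.approx(sdlog, abs=1e-12)
        # frozen values of the closed form
        if median == 0.574:
            assert spec.shape_a == pytest.approx(-0.5551, abs=5e-4)
            assert spec.shape_b == pytest.approx(0.04896, abs=5e-4)
        if lo == 0.47:
            assert spec.shape_b == pytest.approx(0.35366, abs=5e-4)

    @pytest.mark.parametrize(
        "median, lo, hi",
        [(0.5, 0.6, 0.7), (0.5, 0.4, 0.45), (-1.0, 0.1, 0.2), (0.5, 0.0, 1.0)],
    )
    def test_invalid_inputs_raise(self, median, lo, hi):
        with pytest.raises(ValueError):
            lognormal_from_median_ci(median, lo, hi)

    @given(
        median=st.floats(0.05, 20),
        ratio_lo=st.floats(0.2, 1.0),
        ratio_hi=st.floats(1.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_percentiles(self, median, ratio_lo, ratio_hi):
        """Analytic percentiles of the built spec match the symmetrised interval."""
        lo, hi = median * ratio_lo, median * ratio_hi
        spec = lognormal_from_median_ci(median, lo, hi, name="x")
        _, q_lo, q_hi = summarize(spec)
        sym_half = 0.5 * (math.log(hi) - math.log(lo))
        assert q_lo == pytest.approx(median * math.exp(-sym_half), rel=1e-6)
        assert q_hi == pytest.approx(median * math.exp(sym_half), rel=1e-6)
        assert spec.median() == pytest.approx(median, rel=1e-9)


class TestSummarize:
    def test_lognormal_cost_summary(self):
        # oracle: closed-form lognormal moments/quantiles
        spec = ParameterSpec("c", "lognormal", shape_a=9.81, shape_b=0.35)
        mean, lo, hi = summarize(spec)
        assert mean == pytest.approx(math.exp(9.81 + 0.35**2 / 2), rel=1e-9)
        assert lo == pytest.approx(math.exp(9.81 - Z975 * 0.35), rel=1e-6)
        assert hi == pytest.approx(math.exp(9.81 + Z975 * 0.35), rel=1e-6)
        # within ~1% of the published rounded summary 19,321 (9092, 36,251)
        assert mean == pytest.approx(19_321, rel=0.01)
        assert lo == pytest.approx(9_092, rel=0.01)
        assert hi == pytest.approx(36_251, rel=0.01)

    def test_beta_mean(self):
        mean, lo, hi = summarize(ParameterSpec("p", "beta", shape_a=4.96, shape_b=125.04))
        assert mean == pytest.approx(4.96 / 130.0, rel=1e-12)
        assert mean == pytest.approx(0.038, abs=5e-4)
        assert 0 < lo < mean < hi < 1

    def test_point_mass(self):
        assert summarize(ParameterSpec("c", "point", value=115)) == (115, 115, 115)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="beta", shape_a=-1, shape_b=2),
            dict(family="beta", shape_a=1),
            dict(family="lognormal", shape_a=0.0, shape_b=-0.1),
            dict(family="point"),
            dict(family="gamma", shape_a=1, shape_b=1),
        ],
    )
    def test_invalid_specs_raise(self, kwargs):
        with pytest.raises(ValueError):
            ParameterSpec(name="x", **kwargs)


class TestSpecSet:
    def test_requires_all_eight_parameters(self, base_config):
        specs = list(base_config.parameters.values())
        with pytest.raises(ValueError, match="missing required"):
            ParameterSpecSet(specs[:-1])

    def test_rejects_duplicates(self, base_config):
        specs = list(base_config.parameters.values())
        with pytest.raises(ValueError, match="duplicate"):
            ParameterSpecSet(specs + [specs[0]])

    def test_fixture_has_canonical_names(self, base_config):
        assert set(REQUIRED_PARAMETERS) <= set(base_config.parameters.names)


class TestSampling:
    def test_same_seed_reproduces_bit_identically(self, base_config):
        d1 = base_config.parameters.sample(500, seed=0)
        d2 = base_config.parameters.sample(500, seed=0)
        assert d1.values.equals(d2.values)

    def test_adding_a_parameter_leaves_other_columns_unchanged(self, base_config):
        extra = ParameterSpec("bias", "lognormal", shape_a=0.0, shape_b=0.3)
        d1 = base_config.parameters.sample(500, seed=0)
        d2 = base_config.parameters.add(extra).sample(500, seed=0)
        for name in d1.names:
            np.testing.assert_array_equal(d1[name], d2[name])

    def test_point_masses_sample_constant(self):
        specs = ParameterSpecSet(
            [ParameterSpec("a", "point", value=2.0), ParameterSpec("b", "point", value=3.0)],
            require_complete=False,
        )
        draws = specs.sample(100, seed=0)
        assert np.all(draws["a"] == 2.0) and np.all(draws["b"] == 3.0)

    def test_support_bounds_over_full_draw_matrix(self, base_config):
        draws = base_config.parameters.sample(20_000, seed=0)
        for name, spec in base_config.parameters.items():
            x = draws[name]
            if spec.family == "beta":
                assert np.all((x >= 0) & (x <= 1))
            elif spec.family == "lognormal":
                assert np.all(x > 0)

    def test_sample_quantiles_match_analytic_within_one_percent(self, base_config):
        draws = base_config.parameters.sample(100_000, seed=0)
        qs = [0.1, 0.25, 0.5, 0.75, 0.9]
        for name, spec in base_config.parameters.items():
            if spec.is_point():
                continue
            sample_q = np.quantile(draws[name], qs)
            analytic_q = spec.quantile(qs)
            np.testing.assert_allclose(sample_q, analytic_q, rtol=0.01)

    def test_sample_means_within_three_mc_standard_errors(self, base_config):
        n = 50_000
        draws = base_config.parameters.sample(n, seed=0)
        for name, spec in base_config.parameters.items():
            x = draws[name]
            if spec.is_point():
                assert np.all(x == spec.mean())
                continue
            se = x.std() / np.sqrt(n)
            assert abs(x.mean() - spec.mean()) < 3 * se + 1e-12

    def test_invalid_n_iter(self, base_config):
        with pytest.raises(ValueError):
            base_config.parameters.sample(0, seed=0)
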