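import math

import numpy as np
import pytest
from scipy import stats

from glmsim.distributions import (
    ConfigurationError,
    DistributionSpec,
    PRESETS,
    analytic_moments,
    empirical_moments,
    outlier_tendency,
    preset,
    rin_transform,
    sample_distribution,
    sample_matrix,
    spec_from_config,
)


class TestSpecValidation:
    def test_missing_required_parameter_named(self):
        with pytest.raises(ConfigurationError, match="shape_gamma"):
            DistributionSpec("gamma", scale_gamma=10.0)

    def test_extraneous_parameter_named(self):
        with pytest.raises(ConfigurationError, match="df_student"):
            DistributionSpec("gaussian", mean_gauss=0, sd_gauss=1, df_student=4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="gaussian", mean_gauss=0.0, sd_gauss=-1.0),
            dict(family="binomial", binom_p=1.5),
            dict(family="gamma", shape_gamma=0.0, scale_gamma=1.0),
            dict(family="nosuch"),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            DistributionSpec(**kwargs)


class TestSampling:
    def test_bit_reproducible_and_seed_sensitive(self):
        a = sample_distribution(preset("D9"), 1000, seed=7)
        b = sample_distribution(preset("D9"), 1000, seed=7)
        c = sample_distribution(preset("D9"), 1000, seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize(
        "pid,support",
        [
            ("D1", {0.0, 1.0}),
            ("D2", {0.0, 1.0, 2.0, 3.0, 4.0, 5.0}),
            ("D6", {1.0, 2.0, 3.0}),
            ("D8", {0.0, 1.0}),
        ],
    )
    def test_discrete_support(self, pid, support):
        x = sample_distribution(preset(pid), 5000, seed=1)
        assert set(np.unique(x)) <= support

    @pytest.mark.parametrize("pid", ["D2", "D3"])
    def test_zero_inflation_fraction(self, pid):
        # observed zero fraction within the 99.9% binomial band of 0.5
        n = 40_000
        x = sample_distribution(preset(pid), n, seed=3)
        frac = np.mean(x == 0.0)
        half_width = stats.norm.ppf(0.9995) * math.sqrt(0.25 / n)
        assert abs(frac - 0.5) < half_width

    def test_gaussian_standard_moments(self):
        x = sample_distribution(preset("D0"), 1_000_000, seed=0)
        assert abs(x.mean()) < 0.005
        assert abs(x.var() - 1.0) < 0.01


class TestAnalyticMoments:
    @pytest.mark.parametrize(
        "pid,mean,var,skew,kurt",
        [
            ("D0", 0.0, 1.0, 0.0, 3.0),
            ("D1", 0.5, 0.25, 0.0, 1.0),
            ("D7", 10.0, 110.0, 2.0024, 9.0092),
            ("D8", 0.9, 0.09, -2.6667, 8.1111),
            ("D9", 10.0, 1000.0, 6.3246, 63.0),
        ],
    )
    def test_closed_forms(self, pid, mean, var, skew, kurt):
        m = analytic_moments(preset(pid))
        assert m.source == "analytic"
        assert m.mean == pytest.approx(mean, abs=1e-9)
        assert m.variance == pytest.approx(var, abs=1e-9)
        assert m.skewness == pytest.approx(skew, abs=5e-4)
        assert m.kurtosis == pytest.approx(kurt, abs=5e-4)

    def test_heavy_tailed_t_flags_infinite_kurtosis(self):
        m = analytic_moments(preset("D5"))
        assert (m.mean, m.variance, m.skewness) == (0.0, 2.0, 0.0)
        assert m.kurtosis == math.inf

    def test_half_normal(self):
        m = analytic_moments(preset("D4"))
        assert m.mean == pytest.approx(math.sqrt(2 / math.pi))
        assert m.variance == pytest.approx(1 - 2 / math.pi)
        assert m.skewness == pytest.approx(0.9953, abs=1e-4)
        assert m.kurtosis == pytest.approx(3.8692, abs=1e-4)

    def test_categorized_family_falls_back_to_empirical(self):
        m = analytic_moments(preset("D2"), fallback_n=50_000)
        assert m.source == "empirical"
        assert "no closed form" in m.note

    def test_pearson_inequality(self):
        for pid in PRESETS:
            m = analytic_moments(preset(pid), fallback_n=50_000)
            if m.defined and np.isfinite(m.kurtosis):
                assert m.kurtosis >= 1.0 + m.skewness**2 - 1e-9


class TestEmpiricalMoments:
    def test_matches_direct_loop_computation(self, rng):
        x = rng.gamma(0.4, 3.0, size=200)
        m = empirical_moments(x)
        mean = sum(x) / len(x)
        m2 = sum((v - mean) ** 2 for v in x) / len(x)
        m3 = sum((v - mean) ** 3 for v in x) / len(x)
        m4 = sum((v - mean) ** 4 for v in x) / len(x)
        assert m.mean == pytest.approx(mean, abs=1e-12)
        assert m.variance == pytest.approx(m2, abs=1e-12)
        assert m.skewness == pytest.approx(m3 / m2**1.5, abs=1e-12)
        assert m.kurtosis == pytest.approx(m4 / m2**2, abs=1e-12)

    def test_constant_vector_flagged(self):
        m = empirical_moments(np.ones(10))
        assert m.variance == 0.0
        assert m.skewness is None and m.kurtosis is None
        assert "zero variance" in m.note

    @pytest.mark.parametrize("pid", ["D0", "D1", "D4", "D7", "D8", "D9"])
    def test_large_sample_matches_analytic(self, pid):
        """Empirical moments of 10^6 draws agree with the closed forms within
        5 Monte-Carlo standard errors (block estimate of the SE)."""
        n, blocks = 1_000_000, 20
        x = sample_matrix(preset(pid), n, np.random.default_rng(42))
        ana = analytic_moments(preset(pid))
        full = empirical_moments(x)
        parts = [empirical_moments(b) for b in x.reshape(blocks, -1)]
        for attr in ("mean", "variance", "skewness", "kurtosis"):
            target = getattr(ana, attr)
            if target is None or not np.isfinite(target):
                continue
            vals = np.array([getattr(p, attr) for p in parts])
            se = vals.std(ddof=1) / math.sqrt(blocks)
            assert abs(getattr(full, attr) - target) < 5 * se + 1e-9, attr


class TestRinTransform:
    def test_three_distinct_values_closed_form(self):
        out = rin_transform(np.array([10.0, -3.0, 4.0]))
        expected = stats.norm.ppf([5 / 6, 1 / 6, 3 / 6])
        assert out == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_mean_zero(self, rng):
        x = rng.gamma(0.1, 100.0, size=500)
        out = rin_transform(x)
        assert np.all(np.diff(out[np.argsort(x)]) >= 0)
        assert abs(out.mean()) < 1e-10

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            rin_transform(np.full(10, 3.0))

    @pytest.mark.parametrize("pid", ["D0", "D4", "D5", "D9"])
    def test_normalizes_continuous_shapes(self, pid):
        # rankit scores of any continuous sample are near-Gaussian
        x = sample_distribution(preset(pid), 2000, seed=11)
        m = empirical_moments(rin_transform(x))
        assert abs(m.skewness) < 0.1
        assert abs(m.kurtosis - 3.0) < 0.3

    def test_discrete_mass_is_not_normalized(self):
        # a Bernoulli marginal keeps its two-point shape under average ranks
        x = sample_distribution(preset("D8"), 2000, seed=5)
        m = empirical_moments(rin_transform(x))
        assert abs(m.skewness) > 1.0


class TestOutlierTendency:
    def test_extreme_skew_dominates_and_thin_tails_score_low(self):
        scores = {
            pid: outlier_tendency(preset(pid), reps=4000, seed=2).proportion
            for pid in PRESETS
        }
        assert max(scores, key=scores.get) == "D9"
        for pid in ("D1", "D2", "D3", "D8"):
            assert scores[pid] < scores["D0"]

    def test_degenerate_spec_all_replicates_dropped(self):
        res = outlier_tendency(
            DistributionSpec("binomial", binom_p=0.0), reps=200, seed=0
        )
        assert res.all_dropped
        assert res.n_dropped == 200
        assert math.isnan(res.proportion)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            outlier_tendency(preset("D0"), reps=10, seed=0)


class TestConfigLoading:
    def test_dotted_table_arguments(self):
        spec = spec_from_config(
            {"DistributionY": "Gamma", "ShapeY.gamma": 0.1, "ScaleY.gamma": 100}
        )
        assert spec.family == "gamma"
        assert spec.shape_gamma == 0.1 and spec.scale_gamma == 100.0

    def test_binomial_zero_level_maps_to_success_probability(self):
        spec = spec_from_config(
            {"DistributionY": "Binomial", "zeroLevelY.zero": 0.9}
        )
        assert spec.binom_p == 0.9
        assert analytic_moments(spec).skewness == pytest.approx(-2.6667, abs=1e-4)

    def test_role_suffix_respected(self):
        spec = spec_from_config(
            {"DistributionX": "StudentsT", "DFX.student": 4}, role="X"
        )
        assert spec.family == "students_t" and spec.df_student == 4.0

    def test_snake_case_alias(self):
        spec = spec_from_config({"family": "gamma", "shape_gamma": 1, "scale_gamma": 10})
        assert spec == DistributionSpec("gamma", shape_gamma=1.0, scale_gamma=10.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            spec_from_config({"DistributionY": "Gamma", "ShapeY.gamma": 1,
                              "ScaleY.gamma": 1, "bogus": 3})

    def test_preset_reference(self):
        assert spec_from_config({"preset": "D7"}) == preset("D7")
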