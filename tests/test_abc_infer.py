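import numpy as np
import pandas as pd
import pytest

from mupscent.abc_infer import (
    AbcConfig,
    STAT_COLUMNS,
    SelectionABC,
    inverse_tangent_transform,
    neutrality_biased_fit,
    posterior_summary,
    regression_adjust,
    rejection,
    tangent_transform,
)
from mupscent.errors import MupscentError, ValidationError


def synthetic_table(rng, n=500, noise=0.02):
    """A fast stand-in for the simulator: statistics linear in (s, N)."""
    s = rng.uniform(0.0, 0.1, n)
    N = rng.uniform(100, 1100, n)
    frame = pd.DataFrame({"seed": np.arange(n), "N": N, "s": s})
    frame["s_ns"] = 5 + 40 * s + noise * rng.standard_normal(n)
    frame["s_s"] = 10 + 0.01 * N + noise * rng.standard_normal(n)
    frame["mean_freq_ns"] = 0.02 + 0.3 * s + noise * rng.standard_normal(n)
    frame["mean_freq_s"] = 0.03 + noise * rng.standard_normal(n)
    return frame


class TestTangentTransform:
    def test_midpoint_maps_to_zero(self):
        assert tangent_transform(0.05, 0.0, 0.1) == pytest.approx(0.0, abs=1e-12)

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=1e-6, max_value=0.1 - 1e-6))
    @settings(deadline=None, derandomize=True)
    def test_round_trip_property(self, theta):
        back = inverse_tangent_transform(tangent_transform(theta, 0, 0.1), 0, 0.1)
        assert back == pytest.approx(theta, abs=1e-10)

    def test_round_trip(self, rng):
        theta = rng.uniform(0.0, 0.1, 1000)
        back = inverse_tangent_transform(tangent_transform(theta, 0, 0.1), 0, 0.1)
        np.testing.assert_allclose(back, theta, atol=1e-10)

    def test_strictly_increasing(self):
        grid = np.linspace(0.001, 0.099, 200)
        assert np.all(np.diff(tangent_transform(grid, 0, 0.1)) > 0)

    def test_boundary_nudged_not_rejected(self):
        assert np.isfinite(tangent_transform(0.0, 0.0, 0.1))
        assert np.isfinite(tangent_transform(0.1, 0.0, 0.1))

    def test_outside_support_rejected(self):
        with pytest.raises(ValidationError):
            tangent_transform(0.2, 0.0, 0.1)


class TestRejection:
    def test_full_tolerance_accepts_all(self, rng):
        tab = synthetic_table(rng, n=100)
        res = rejection(tab, tab[STAT_COLUMNS].iloc[0], tolerance=1.0)
        assert len(res.indices) == 100

    def test_accepted_count_is_ceiling(self, rng):
        tab = synthetic_table(rng, n=10_000)
        res = rejection(tab, tab[STAT_COLUMNS].mean(), tolerance=0.02)
        assert len(res.indices) == 200

    def test_exact_match_has_zero_distance_max_weight(self, rng):
        tab = synthetic_table(rng, n=200)
        res = rejection(tab, tab[STAT_COLUMNS].iloc[7], tolerance=0.1)
        assert res.indices[0] == 7
        assert res.distances[0] == 0.0
        assert res.weights[0] == res.weights.max()

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            rejection(pd.DataFrame(columns=STAT_COLUMNS), np.zeros(4), 0.1)


class TestRegressionAdjust:
    def test_constant_summaries_fall_back_unadjusted(self, rng):
        theta = rng.uniform(0, 1, 30)
        X = np.ones((30, 2))
        with pytest.warns(UserWarning, match="singular"):
            out = regression_adjust(theta, X, np.ones(2), np.ones(30) / 30)
        np.testing.assert_allclose(out, theta)

    def test_exact_linear_model_collapses_to_truth(self, rng):
        theta = rng.uniform(0, 1, 50)
        X = np.column_stack([2.0 * theta + 1.0, np.zeros(50) + rng.standard_normal(50)])
        observed = np.array([1.5, 0.0])  # corresponds to theta = 0.25
        out = regression_adjust(theta, X, observed, np.ones(50) / 50)
        np.testing.assert_allclose(out, 0.25, atol=1e-8)

    def test_weighted_mean_invariant_at_mean_observation(self, rng):
        theta = rng.uniform(0, 1, 60)
        X = rng.standard_normal((60, 3))
        w = rng.uniform(0.1, 1.0, 60)
        w = w / w.sum()
        obs = (X * w[:, None]).sum(axis=0)  # weighted mean summaries
        out = regression_adjust(theta, X, obs, w)
        assert np.sum(out * w) == pytest.approx(np.sum(theta * w))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            regression_adjust(np.ones(3), np.ones((3, 4)), np.ones(4), np.ones(3))


class TestPosteriorSummary:
    def test_uniform_draws_recover_central_interval(self, rng):
        draws = rng.uniform(0.0, 0.1, 20_000)
        post = posterior_summary(draws, support=(0.0, 0.1))
        lo, hi = post.equal_tailed
        assert lo == pytest.approx(0.0025, abs=0.001)
        assert hi == pytest.approx(0.0975, abs=0.001)

    def test_degenerate_draws(self):
        post = posterior_summary(np.full(20, 0.03), support=(0.0, 0.1))
        assert post.map_estimate == 0.03
        assert post.equal_tailed == (0.03, 0.03)
        assert post.excludes_zero

    def test_concentrated_positive_mass_excludes_zero(self, rng):
        draws = np.clip(rng.normal(0.08, 0.005, 2000), 0, 0.1)
        post = posterior_summary(draws, support=(0.0, 0.1))
        assert post.excludes_zero
        assert post.map_estimate == pytest.approx(0.08, abs=0.01)

    def test_mass_at_lower_bound_includes_zero(self, rng):
        draws = np.clip(np.abs(rng.normal(0.0, 0.01, 2000)), 0, 0.1)
        post = posterior_summary(draws, support=(0.0, 0.1))
        assert not post.excludes_zero

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValidationError):
            posterior_summary(np.ones(5))


class TestSelectionABCModel:
    def test_fit_recovers_parameter_on_linear_stand_in(self, rng):
        tab = synthetic_table(rng, n=4000, noise=0.05)
        s_true, n_true = 0.07, 600.0
        observed = np.array(
            [5 + 40 * s_true, 10 + 0.01 * n_true, 0.02 + 0.3 * s_true, 0.03]
        )
        res = SelectionABC(tab, observed, AbcConfig(n_sims=4000, tolerance=0.05)).fit()
        assert res.posterior_s.mean == pytest.approx(s_true, abs=0.01)
        lo, hi = res.conf_int("s")
        assert lo < s_true < hi
        assert "MAP" in res.summary()

    def test_draws_lie_in_prior_support(self, rng):
        tab = synthetic_table(rng, n=1000)
        res = SelectionABC(tab, tab[STAT_COLUMNS].median(), AbcConfig(
            n_sims=1000, tolerance=0.1)).fit()
        s = res.adjusted_draws["s"]
        assert (s >= 0.0).all() and (s <= 0.1).all()
        N = res.adjusted_draws["N"]
        assert (N >= 100).all() and (N <= 1100).all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            SelectionABC(pd.DataFrame({"s": [1]}), np.zeros(4))

    def test_neutral_table_empty_reduces_to_standard_fit(self, rng):
        tab = synthetic_table(rng, n=800)
        obs = tab[STAT_COLUMNS].median()
        cfg = AbcConfig(n_sims=800, tolerance=0.05)
        standard = SelectionABC(tab, obs, cfg).fit()
        combined = neutrality_biased_fit(tab, tab.iloc[0:0], obs, cfg)
        assert combined.map_s == pytest.approx(standard.map_s)

    def test_neutral_pooling_shifts_posterior_toward_zero(self, rng):
        """When the statistics carry no information about s, the standard
        posterior tracks the uniform prior mean (~0.05) while pooling a
        same-size neutral table pulls half the prior mass to s = 0."""

        def noise_table(n, s_values):
            frame = pd.DataFrame({"seed": np.arange(n), "s": s_values,
                                  "N": rng.uniform(100, 1100, n)})
            for col in STAT_COLUMNS:
                frame[col] = rng.standard_normal(n)
            return frame

        tab = noise_table(2000, rng.uniform(0.0, 0.1, 2000))
        neutral = noise_table(2000, np.zeros(2000))
        obs = np.zeros(4)
        cfg = AbcConfig(n_sims=2000, tolerance=0.1)
        standard = SelectionABC(tab, obs, cfg).fit()
        biased = neutrality_biased_fit(tab, neutral, obs, cfg)
        assert biased.posterior_s.mean < standard.posterior_s.mean - 0.01
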