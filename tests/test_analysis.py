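"""Map extraction, synthetic maps, goodness-of-fit and order metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import retinotopy as rt
from conftest import small_state


def make_estimate(x, mean_sc, population=None):
    n = len(x)
    return rt.MapEstimate(pd.DataFrame({
        "rgc_index": np.arange(n), "x": np.asarray(x, dtype=float),
        "mean_sc": np.asarray(mean_sc, dtype=float),
        "total_terminals": 16,
        "population": ["wt"] * n if population is None else list(population),
    }))


class StubFit:
    """Duck-typed regression fit with a known curve and constant stderr."""

    def __init__(self, curve, se=0.05, lo=0.0, hi=1.0):
        self.curve, self.se, self.lo, self.hi = curve, se, lo, hi

    def __call__(self, x):
        return self.curve(np.asarray(x, dtype=float))

    def stderr(self, x):
        return np.full(np.atleast_1d(x).shape, self.se)

    def in_support(self, x):
        x = np.asarray(x, dtype=float)
        return (x >= self.lo) & (x <= self.hi)


class TestWeightedMeanPositions:
    def test_single_cell_gives_that_position(self):
        state = small_state(counts=[[0, 16, 0]])
        est = rt.weighted_mean_positions(state, np.array([0.1, 0.25, 0.9]))
        assert est.mean_sc[0] == pytest.approx(0.25)

    def test_symmetric_split_averages(self):
        state = small_state(counts=[[8, 0, 8]])
        est = rt.weighted_mean_positions(state, np.array([0.25, 0.5, 0.75]))
        assert est.mean_sc[0] == pytest.approx(0.5)

    def test_hand_weighted_average(self):
        state = small_state(counts=[[1, 2, 1]])
        est = rt.weighted_mean_positions(state, np.array([0.1, 0.2, 0.3]))
        assert est.mean_sc[0] == pytest.approx(0.2)

    def test_zero_terminal_rgc_rejected(self):
        state = small_state(counts=[[1, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError):
            rt.weighted_mean_positions(state, np.array([0.1, 0.2, 0.3]))


class TestSyntheticMaps:
    def test_noiseless_identity_lies_on_diagonal(self):
        m = rt.synth_experimental_map(lambda x: x, noise_sd=0.0,
                                      n_points=50, seed=0)
        assert m.df["y"].to_numpy() == pytest.approx(m.df["x"].to_numpy())

    def test_double_map_offset_separates_labelled_clouds(self):
        m = rt.synth_experimental_map(lambda x: 0.5 + 0.3 * x, noise_sd=0.0,
                                      n_points=40, double_map_offset=0.2,
                                      seed=1)
        df = m.df
        ki = df[df["population"] == "ki"]
        wt = df[df["population"] == "wt"]
        assert len(ki) == 20 and len(wt) == 20
        # knock-in points displaced rostrally by the offset at every x
        assert (0.5 + 0.3 * ki["x"] - ki["y"]).to_numpy() == \
            pytest.approx(np.full(20, 0.2))
        assert (wt["y"] - 0.3 * wt["x"]).to_numpy() == \
            pytest.approx(np.full(20, 0.5))

    def test_reproducible_under_seed(self):
        a = rt.synth_experimental_map(lambda x: x, 0.05, 30, seed=9)
        b = rt.synth_experimental_map(lambda x: x, 0.05, 30, seed=9)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_round_trip_through_delimited_text(self, tmp_path):
        m = rt.synth_experimental_map(lambda x: x, 0.05, 25, seed=3)
        path = tmp_path / "map.tsv"
        m.write(path)
        again = rt.ExperimentalMap.read(path)
        assert again.df["x"].to_numpy() == pytest.approx(
            m.df["x"].to_numpy())

    def test_pipeline_recovers_identity_truth(self):
        m = rt.synth_experimental_map(lambda x: x, 0.05, 200, seed=21)
        fit = rt.fit_experimental_map(m)["wt"]
        deciles = np.arange(0.1, 0.95, 0.1)
        fitted = np.atleast_1d(fit(deciles))
        se = np.atleast_1d(fit.stderr(deciles))
        assert np.all(np.abs(fitted - deciles) < 2 * se)


class TestGoodnessOfFit:
    def test_perfect_agreement_scores_zero(self):
        x = np.linspace(0.1, 0.9, 20)
        est = make_estimate(x, 0.2 + 0.5 * x)
        score = rt.goodness_of_fit(est, StubFit(lambda v: 0.2 + 0.5 * v))
        assert score.g == 0.0
        assert score.n_rgc_used == 20

    def test_doubling_deviation_quadruples_score(self):
        x = np.linspace(0.1, 0.9, 15)
        fit = StubFit(lambda v: v)
        g1 = rt.goodness_of_fit(make_estimate(x, x + 0.02), fit).g
        g2 = rt.goodness_of_fit(make_estimate(x, x + 0.04), fit).g
        assert g2 == pytest.approx(4 * g1)

    def test_constant_offset_closed_form(self):
        x = np.linspace(0.2, 0.8, 25)
        delta, sigma = 0.06, 0.03
        est = make_estimate(x, x + delta)
        score = rt.goodness_of_fit(est, StubFit(lambda v: v, se=sigma))
        assert score.g == pytest.approx((delta / sigma) ** 2)

    def test_stderr_floor_guards_tiny_errors(self):
        x = np.linspace(0.1, 0.9, 10)
        est = make_estimate(x, x + 0.001)
        score = rt.goodness_of_fit(est, StubFit(lambda v: v, se=0.0),
                                   stderr_floor=1e-3)
        assert np.isfinite(score.g)
        assert score.g == pytest.approx(1.0)

    def test_extrapolating_rgcs_excluded(self):
        x = np.linspace(0, 1, 21)
        est = make_estimate(x, x)
        score = rt.goodness_of_fit(est, StubFit(lambda v: v, lo=0.25, hi=0.75))
        assert score.n_rgc_used == len(x[(x >= 0.25) & (x <= 0.75)])

    @given(st.integers(0, 100))
    def test_invariant_to_reordering_and_duplication(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 0.9, 12)
        est = make_estimate(x, x + rng.normal(0, 0.05, 12))
        fit = StubFit(lambda v: v)
        g = rt.goodness_of_fit(est, fit).g
        shuffled = rt.MapEstimate(
            est.df.sample(frac=1, random_state=0).reset_index(drop=True))
        doubled = rt.MapEstimate(
            pd.concat([est.df, est.df], ignore_index=True))
        assert rt.goodness_of_fit(shuffled, fit).g == pytest.approx(g)
        assert rt.goodness_of_fit(doubled, fit).g == pytest.approx(g)


class TestDoubleMapScoring:
    def test_both_populations_perfect_scores_zero(self):
        x = np.linspace(0.1, 0.9, 20)
        pop = ["ki", "wt"] * 10
        y = np.where(np.array(pop) == "ki", x - 0.2, x)
        est = make_estimate(x, y, population=pop)
        fits = {"ki": StubFit(lambda v: v - 0.2), "wt": StubFit(lambda v: v)}
        assert rt.split_and_score_double_map(est, fits).g == 0.0

    def test_overall_is_mean_of_population_scores(self):
        x = np.linspace(0.1, 0.9, 20)
        pop = ["ki", "wt"] * 10
        y = np.where(np.array(pop) == "ki", x + 0.06, x)
        est = make_estimate(x, y, population=pop)
        fits = {"ki": StubFit(lambda v: v, se=0.03),
                "wt": StubFit(lambda v: v, se=0.03)}
        score = rt.split_and_score_double_map(est, fits)
        assert score.components["ki"] == pytest.approx(4.0)
        assert score.components["wt"] == pytest.approx(0.0)
        assert score.g == pytest.approx(2.0)

    def test_single_population_reduces_to_plain_score(self):
        x = np.linspace(0.1, 0.9, 15)
        est = make_estimate(x, x + 0.03)
        fit = StubFit(lambda v: v)
        assert rt.split_and_score_double_map(est, {"wt": fit}).g == \
            pytest.approx(rt.goodness_of_fit(est, fit).g)

    def test_missing_population_fit_rejected(self):
        x = np.linspace(0.1, 0.9, 10)
        est = make_estimate(x, x, population=["ki", "wt"] * 5)
        with pytest.raises(ValueError):
            rt.split_and_score_double_map(est, {"wt": StubFit(lambda v: v)})


class TestOrderMetrics:
    def test_identity_map_is_perfectly_ordered(self):
        x = np.linspace(0.05, 0.95, 30)
        m = rt.order_metrics(make_estimate(x, x))
        assert m["rank_correlation"] == pytest.approx(1.0)
        assert m["rms_from_identity"] == 0.0
        assert m["mean_signed_shift"] == 0.0

    def test_reflected_map_anticorrelates(self):
        x = np.linspace(0.05, 0.95, 30)
        m = rt.order_metrics(make_estimate(x, 1 - x))
        assert m["rank_correlation"] == pytest.approx(-1.0)

    def test_rostral_half_occupancy(self):
        x = np.linspace(0.05, 0.95, 10)
        density = np.array([3, 4, 2, 1, 0, 0, 0, 0, 0, 0])
        m = rt.order_metrics(make_estimate(x, x / 2), density=density)
        assert m["occupied_fraction"] == pytest.approx(0.4)
        assert m["occupied_extent"] == pytest.approx(0.4)
        assert m["rostral_contiguous_fraction"] == pytest.approx(0.4)

    def test_gap_limits_rostral_contiguous_span(self):
        x = np.linspace(0.05, 0.95, 10)
        density = np.array([3, 4, 0, 1, 0, 0, 0, 0, 0, 2])
        m = rt.order_metrics(make_estimate(x, x / 2), density=density)
        assert m["rostral_contiguous_fraction"] == pytest.approx(0.2)
        assert m["occupied_extent"] == pytest.approx(1.0)

    def test_dii_injection_selects_radius(self):
        x = np.linspace(0.05, 0.95, 19)
        est = make_estimate(x, x)
        picked = rt.dii_injection(est, centre=0.5, radius=0.1)
        assert np.all(np.abs(picked["x"] - 0.5) <= 0.1)
        assert len(picked) > 0
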