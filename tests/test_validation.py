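import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from grasstox.validation import (
    FitMetrics,
    IntervalSeries,
    compute_MOI,
    effect_ratio,
    fresh_to_dry,
    metrics_report,
    percentile_band,
    welch_t_test,
    welch_table,
)


def series(bounds, source="modeled"):
    lo, hi = zip(*bounds)
    return IntervalSeries((2, 4, 6), tuple(lo), tuple(hi), source)


class TestFreshToDry:
    def test_static_factor_scales_linearly(self):
        assert fresh_to_dry(10.0, 0.2) == pytest.approx(2.0)
        assert fresh_to_dry(0.0, 0.2) == 0.0
        # static: the weekly ratio of conversions equals the mass ratio
        assert fresh_to_dry(30.0, 0.2) / fresh_to_dry(10.0, 0.2) == pytest.approx(3.0)

    @pytest.mark.parametrize("factor", [0.0, 1.0, -0.1, 1.5])
    def test_factor_outside_unit_interval_rejected(self, factor):
        with pytest.raises(ValueError):
            fresh_to_dry(1.0, factor)


class TestComputeMOI:
    def test_identical_envelopes_give_perfect_fit(self):
        m = series([(1, 5), (2, 8), (3, 9)])
        o = series([(1, 5), (2, 8), (3, 9)], "observed")
        fm = compute_MOI(m, o)
        assert fm.adequacy == pytest.approx(1.0)
        assert fm.reliability == pytest.approx(1.0)

    def test_disjoint_envelopes_give_zero_overlap(self):
        m = series([(0, 1), (0, 1), (0, 1)])
        o = series([(2, 3), (5, 9), (1.5, 2)], "observed")
        fm = compute_MOI(m, o)
        assert fm.I == 0.0
        assert fm.adequacy == 0.0 and fm.reliability == 0.0

    def test_nested_intervals_hand_computed(self):
        """Modeled [0,10] against observed [2,6] every week:
        M=30, O=12, I=12 -> adequacy 1, reliability 0.4."""
        m = series([(0, 10)] * 3)
        o = series([(2, 6)] * 3, "observed")
        fm = compute_MOI(m, o)
        assert (fm.M, fm.O, fm.I) == (30.0, 12.0, 12.0)
        assert fm.adequacy == pytest.approx(1.0)
        assert fm.reliability == pytest.approx(0.4)

    def test_mismatched_weeks_rejected(self):
        m = series([(0, 1)] * 3)
        o = IntervalSeries((1, 2, 3), (0, 0, 0), (1, 1, 1), "observed")
        with pytest.raises(ValueError):
            compute_MOI(m, o)

    @settings(derandomize=True, max_examples=80)
    @given(
        vals=st.lists(
            st.tuples(*[st.floats(0, 100) for _ in range(4)]),
            min_size=3, max_size=3,
        )
    )
    def test_symmetry_and_overlap_bound(self, vals):
        """Swapping the roles of the two envelopes swaps adequacy and
        reliability, and the intersection never exceeds either area."""
        mb = [tuple(sorted(v[:2])) for v in vals]
        ob = [tuple(sorted(v[2:])) for v in vals]
        m, o = series(mb), series(ob, "observed")
        fm = compute_MOI(m, o)
        sw = compute_MOI(series(ob), series(mb, "observed"))
        assert fm.I <= min(fm.M, fm.O) + 1e-9
        if fm.O > 0 and fm.M > 0:
            assert fm.adequacy == pytest.approx(sw.reliability)
            assert fm.reliability == pytest.approx(sw.adequacy)


class TestPercentileBand:
    def test_constant_values_give_zero_width(self):
        band = percentile_band({2: [5.0, 5.0, 5.0]}, "modeled")
        assert band.lower == band.upper == (5.0,)

    def test_normal_sample_matches_quantile_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20000)
        band = percentile_band({2: x}, "modeled")
        assert band.lower[0] == pytest.approx(-1.96, abs=0.06)
        assert band.upper[0] == pytest.approx(1.96, abs=0.06)

    def test_observed_band_is_the_exact_min_max(self):
        vals = [3.0, 9.0, 4.0, 8.5, 2.5, 7.0, 6.0, 5.0]
        band = percentile_band({4: vals}, "observed")
        assert band.lower == (2.5,) and band.upper == (9.0,)

    def test_empty_week_rejected(self):
        with pytest.raises(ValueError):
            percentile_band({2: []}, "observed")


class TestEffectRatio:
    def test_identical_arms_give_unit_ratio(self):
        vals = {2: [1.0, 2.0], 4: [3.0, 4.0], 6: [5.0]}
        r = effect_ratio(vals, vals)
        assert np.allclose(r.values, 1.0)

    def test_constant_suppression_gives_declining_ratio(self, pmap):
        """A 50% gain reduction from week 0 drives the treatment/control
        mass ratio below 1, monotonically down over the weeks."""
        from grasstox.engine import Grid, run_simulation
        from grasstox.experiments import init_monoculture

        ctrl = run_simulation(
            init_monoculture(pmap["B. erectus"], Grid(7, 7, 75, 90)), 6
        )
        treat = run_simulation(
            init_monoculture(pmap["B. erectus"], Grid(7, 7, 75, 90)), 6,
            {"B. erectus": [0.5] * 7},
        )
        t = {w: treat[treat["week"] == w]["shoot_mass_mg"].to_numpy()
             for w in (2, 4, 6)}
        c = {w: ctrl[ctrl["week"] == w]["shoot_mass_mg"].to_numpy()
             for w in (2, 4, 6)}
        r = effect_ratio(t, c)
        assert (r < 1).all()
        assert (np.diff(r.values) <= 1e-12).all()

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            effect_ratio({2: [1.0]}, {2: [0.0]})


class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """Welch statistic by hand: equal variances s^2 = 0.2/3, mean
        difference -1.0 -> t = -1 / sqrt(2 * 0.2/12) = -5.4772."""
        a = (2.1, 2.5, 2.3, 2.7)
        b = (3.1, 3.5, 3.3, 3.7)
        t, p = welch_t_test(a, b)
        assert t == pytest.approx(-5.477226, abs=1e-5)
        assert p == pytest.approx(
            float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        )
        assert p < 0.01

    def test_scale_invariance(self):
        a = np.array([2.1, 2.5, 2.3, 2.7])
        b = np.array([3.1, 3.5, 3.3, 3.9])
        t1, _ = welch_t_test(a, b)
        t2, _ = welch_t_test(10 * a, 10 * b)
        assert t1 == pytest.approx(t2)

    def test_zero_variance_in_both_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


def _records(entries):
    return pd.DataFrame(
        entries,
        columns=["herbicide", "rate", "week", "species", "shoot_mass_mg"],
    )


class TestMetricsReport:
    def _synthetic_tables(self):
        rng = np.random.default_rng(5)
        mod, obs = [], []
        for sp, mu in (("a", 10.0), ("b", 40.0)):
            for rate in (1.0, 2.0):
                for w in (2, 4, 6):
                    mod += [("H", rate, w, sp, mu * w + x)
                            for x in rng.normal(0, 2.0, 40)]
                    obs += [("H", rate, w, sp, mu * w + x)
                            for x in rng.normal(0, 2.0, 6)]
        return _records(mod), _records(obs)

    def test_all_row_is_the_mean_of_species_rows(self):
        mod, obs = self._synthetic_tables()
        for mode in ("area", "weekly"):
            rep = metrics_report(mod, obs, mode=mode)
            sp_rows = rep[rep["species"] != "All"]
            all_row = rep[rep["species"] == "All"].iloc[0]
            assert all_row["adequacy"] == pytest.approx(sp_rows["adequacy"].mean())
            assert all_row["reliability"] == pytest.approx(
                sp_rows["reliability"].mean()
            )

    def test_self_comparison_is_fully_reliable(self):
        """Comparing a dataset against itself: the modeled percentile band
        sits inside its own min-max envelope, so reliability is exactly 1
        and adequacy equals the (near-unit) percentile-trim ratio."""
        mod, _ = self._synthetic_tables()
        for mode in ("area", "weekly"):
            rep = metrics_report(mod, mod, mode=mode)
            assert np.allclose(rep["reliability"], 1.0)
            assert ((rep["adequacy"] > 0.7) & (rep["adequacy"] <= 1.0)).all()

    def test_report_shape(self):
        mod, obs = self._synthetic_tables()
        rep = metrics_report(mod, obs)
        assert list(rep.columns) == ["species", "herbicide", "adequacy",
                                     "reliability"]
        assert len(rep) == 3  # two species + All


class TestWelchTable:
    def test_flags_a_clear_difference_and_passes_a_match(self):
        rng = np.random.default_rng(1)
        base = [("H", 0.0, 2, "a", 10 + x) for x in rng.normal(0, 0.5, 20)]
        shifted = [("H", 0.0, 2, "a", 30 + x) for x in rng.normal(0, 0.5, 8)]
        same = [("H", 0.0, 2, "a", 10 + x) for x in rng.normal(0, 0.5, 8)]
        tab_diff = welch_table(_records(base), _records(shifted))
        tab_same = welch_table(_records(base), _records(same))
        assert bool(tab_diff["significant"].iloc[0])
        assert not bool(tab_same["significant"].iloc[0])
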