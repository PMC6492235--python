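"""ΔT, rate extrema, decay/power-law fits, identity-through-time."""

import math

import numpy as np
import pandas as pd
import pytest

from rcclock.analysis import (
    DecayFit,
    NoSolutionError,
    PowerLawFit,
    RateSeries,
    compute_delta_t,
    delta_t_from_means,
    expected_identity,
    extract_rate_series,
    fit_exponential_decay,
    fit_power_law,
    load_reference_node_ages,
    nu_extrema,
    rate_ratio_and_waiting_times,
    recompute_reference_delta_t,
    time_to_identity,
)
from rcclock.substitution import poisson_model
from rcclock.timetree import CladeResolutionError


class TestDeltaT:
    def test_published_scan_rows(self):
        """Recomputing ΔT from the printed mean ages matches the print."""
        cat38 = delta_t_from_means(3.44, 0.21, 2.27, 0.24)
        assert round(cat38.mean, 2) == pytest.approx(1.17)
        lg32 = delta_t_from_means(3.19, 0.08, 2.51, 0.13)
        assert round(lg32.mean, 2) == pytest.approx(0.68)

    def test_identical_nodes_give_zero_symmetric_range(self):
        dt = delta_t_from_means(3.0, 0.2, 3.0, 0.2)
        assert dt.mean == 0.0
        assert dt.range_low == pytest.approx(-dt.range_high)

    def test_antisymmetry(self):
        fwd = delta_t_from_means(3.44, 0.21, 2.27, 0.24)
        rev = delta_t_from_means(2.27, 0.24, 3.44, 0.21)
        assert rev.mean == pytest.approx(-fwd.mean)
        assert rev.range_low == pytest.approx(-fwd.range_high)
        assert rev.range_high == pytest.approx(-fwd.range_low)

    def test_reference_table_regression(self):
        """Every internally consistent published row recomputes to ±0.01 Ga.

        Rows flagged as misprinted in the source are checked to be
        genuinely inconsistent, so the exclusion cannot hide a real
        failure of the recomputation.
        """
        df = recompute_reference_delta_t()
        consistent = df[df.note != "inconsistent_in_print"]
        assert len(consistent) >= 20
        err = (consistent.delta_t_recomputed - consistent.delta_t_printed).abs()
        assert (err <= 0.01 + 1e-9).all(), consistent[err > 0.01]
        flagged = df[df.note == "inconsistent_in_print"]
        assert len(flagged) == 2
        assert (
            (flagged.delta_t_recomputed - flagged.delta_t_printed).abs() > 0.01
        ).all()
        transposed = df[df.note == "transposed_in_print"]
        assert len(transposed) == 1
        assert abs(
            transposed.range_high_recomputed.iloc[0]
            - transposed.range_high_printed.iloc[0]
        ) <= 0.01 + 1e-9

    def test_clade_resolution_on_summary(self, quartet_tree):
        rows = []
        for node in quartet_tree.nodes:
            rows.append({
                "node": f"n{node.index}",
                "age_mean": node.age or 0.0, "age_sd": 0.1,
                "rate_mean": 0.2, "rate_sd": 0.02,
            })
        summary = pd.DataFrame(rows)
        dt = compute_delta_t(summary, quartet_tree, ("A", "B", "C", "D"), ("A", "B"))
        assert dt.mean == pytest.approx(2.0 - 1.0)
        with pytest.raises(CladeResolutionError):
            compute_delta_t(summary, quartet_tree, "nonexistent_label", ("A", "B"))


class TestRateSeriesAndExtrema:
    def _summary(self, quartet_tree, rates):
        rows = []
        for node in quartet_tree.nodes:
            rows.append({
                "node": f"n{node.index}", "key": f"k{node.index}",
                "label": node.label or (node.name or ""),
                "age_mean": node.age or 0.0, "age_sd": 0.05,
                "rate_mean": rates.get(node.index, 0.2), "rate_sd": 0.02,
            })
        return pd.DataFrame(rows)

    def test_subset_selection(self, quartet_tree):
        summary = self._summary(quartet_tree, {})
        series = extract_rate_series(summary, quartet_tree, ("A", "B"))
        assert len(series.data) == 1  # the AB ancestor (tips excluded)
        both = extract_rate_series(
            summary, quartet_tree, [("A", "B"), ("C", "D")]
        )
        assert len(both.data) == 2

    def test_empty_subset_rejected(self, quartet_tree):
        summary = self._summary(quartet_tree, {})
        with pytest.raises(ValueError, match="empty rate series|selects no nodes"):
            extract_rate_series(
                summary[summary.node == "none"], quartet_tree, None
            )

    def test_nu_extrema_two_point_baseline(self, quartet_tree):
        ab = quartet_tree.mrca(["A", "B"]).index
        a = quartet_tree.mrca(["A"]).index
        b = quartet_tree.mrca(["B"]).index
        summary = self._summary(quartet_tree, {ab: 5.0, a: 0.10, b: 0.14})
        out = nu_extrema(
            summary, quartet_tree, max_node=("A", "B", "C", "D"),
            baseline_subset=[("A",), ("B",)],
        )
        assert out["nu_min"] == pytest.approx(0.12)
        out_single = nu_extrema(
            summary, quartet_tree, max_node=("A", "B"), baseline_subset=[("A",)]
        )
        assert out_single["nu_min"] == pytest.approx(0.10)
        assert out_single["nu_max"] == pytest.approx(5.0)


class TestWaitingTimes:
    def test_slow_psii_rate_waits_eight_billion_years(self):
        out = rate_ratio_and_waiting_times(0.12, 0.12)
        assert round(out["waiting_time_a_ga"]) == 8

    def test_neurotoxin_versus_psii(self):
        out = rate_ratio_and_waiting_times(17.0, 0.12)
        assert round(out["ratio"] / 10) * 10 == 140
        assert round(out["waiting_time_a_ma"] / 10) * 10 == 60

    def test_equal_rates_unit_ratio(self):
        assert rate_ratio_and_waiting_times(0.5, 0.5)["ratio"] == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rate_ratio_and_waiting_times(0.0, 0.1)


class TestExponentialDecay:
    def _series(self, ages, rates):
        return RateSeries(
            data=pd.DataFrame({
                "node": [f"n{i}" for i in range(len(ages))],
                "age_mean": ages, "age_sd": 0.0,
                "rate_mean": rates, "rate_sd": 0.0,
            })
        )

    def test_noiseless_recovery(self):
        ages = np.linspace(3.5, 0.2, 8)
        rates = 0.12 + 4.91 * np.exp(-(3.5 - ages) / 0.5)
        fit = fit_exponential_decay(self._series(ages, rates), root_age=3.5)
        assert fit.y_inf == pytest.approx(0.12, abs=1e-6)
        assert fit.amplitude == pytest.approx(4.91, abs=1e-6)
        assert fit.tau == pytest.approx(0.5, abs=1e-6)

    def test_noisy_recovery_within_fifteen_percent(self):
        rng = np.random.default_rng(21)
        ages = np.linspace(3.5, 0.1, 24)
        rates = 0.12 + 4.91 * np.exp(-(3.5 - ages) / 0.5)
        rates = np.clip(rates + rng.normal(0, 0.05, rates.size), 1e-3, None)
        fit = fit_exponential_decay(self._series(ages, rates), root_age=3.5)
        assert fit.amplitude == pytest.approx(4.91, rel=0.15)
        assert fit.tau == pytest.approx(0.5, rel=0.15)

    def test_constant_series_flagged_degenerate(self):
        fit = fit_exponential_decay(
            self._series(np.linspace(3.0, 0.5, 6), np.full(6, 0.12))
        )
        assert fit.degenerate
        assert fit.y_inf == pytest.approx(0.12)

    def test_time_rescaling_equivariance(self):
        """Fitting in Ma instead of Ga rescales tau by 1000 and nothing else."""
        ages = np.linspace(3.5, 0.2, 10)
        rng = np.random.default_rng(3)
        rates = 0.12 + 4.91 * np.exp(-(3.5 - ages) / 0.5) + rng.normal(0, 0.02, 10)
        fit_ga = fit_exponential_decay((ages, rates), root_age=3.5)
        fit_ma = fit_exponential_decay((ages * 1000, rates), root_age=3500)
        assert fit_ma.tau == pytest.approx(fit_ga.tau * 1000, rel=1e-4)
        assert fit_ma.y_inf == pytest.approx(fit_ga.y_inf, rel=1e-4)
        assert fit_ma.amplitude == pytest.approx(fit_ga.amplitude, rel=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_decay((np.array([1.0, 2.0]), np.array([1.0, 2.0])))


class TestPowerLaw:
    def test_exact_recovery(self):
        pts = [(dt, 5.0 * dt**-1.0) for dt in (0.1, 0.5, 1.0, 2.0)]
        fit = fit_power_law(pts)
        assert fit.a == pytest.approx(5.0, abs=1e-9)
        assert fit.b == pytest.approx(-1.0, abs=1e-12)

    def test_predict_monotone_decreasing_for_negative_exponent(self):
        fit = PowerLawFit(a=5.0, b=-1.3)
        xs = np.linspace(0.05, 3.0, 50)
        ys = [fit.predict(x) for x in xs]
        assert all(a > b for a, b in zip(ys, ys[1:]))

    def test_noisy_loglog_slope(self):
        rng = np.random.default_rng(14)
        dts = np.exp(rng.uniform(np.log(0.05), np.log(2.0), 30))
        nus = 5.0 * dts**-1.2 * np.exp(rng.normal(0, 0.05, 30))
        fit = fit_power_law(list(zip(dts, nus)))
        b_oracle = np.polyfit(np.log(dts), np.log(nus), 1)[0]
        assert fit.b == pytest.approx(b_oracle, abs=1e-12)
        assert abs(fit.b - (-1.2)) < 0.1

    def test_scale_equivariance_of_prediction(self):
        """Rescaling the ΔT axis leaves predicted rates at matching points."""
        pts = [(dt, 4.0 * dt**-0.8) for dt in (0.2, 0.6, 1.5)]
        fit = fit_power_law(pts)
        scaled = fit_power_law([(dt * 1000, nu) for dt, nu in pts])
        assert scaled.predict(500.0) == pytest.approx(fit.predict(0.5), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)])


class TestTimeToIdentity:
    def test_zero_time_at_full_identity(self):
        assert time_to_identity(5.0, poisson_model(), 100.0) == 0.0

    def test_poisson_closed_form_inversion(self):
        """Constant rate 5.03: 50% identity at (19/40)ln(0.95/0.45)/5.03 Ga."""
        t = time_to_identity(5.03, poisson_model(), 50.0)
        expected = (19 / 40) * math.log(0.95 / 0.45) / 5.03
        assert t == pytest.approx(expected, abs=1e-9)
        assert t == pytest.approx(0.0706, abs=2e-4)

    def test_decaying_rate_reaches_target_sooner_than_its_floor(self):
        fit = DecayFit(y_inf=0.12, amplitude=4.91, tau=0.5, rss=0.0)
        t_decay = time_to_identity(fit, poisson_model(), 50.0)
        t_floor = time_to_identity(0.12, poisson_model(), 50.0)
        assert t_decay <= t_floor

    def test_monotone_in_rate_and_target(self):
        m = poisson_model()
        assert time_to_identity(1.0, m, 50.0) > time_to_identity(2.0, m, 50.0)
        assert time_to_identity(1.0, m, 40.0) > time_to_identity(1.0, m, 60.0)

    def test_target_below_equilibrium_rejected(self):
        with pytest.raises(NoSolutionError):
            time_to_identity(1.0, poisson_model(), 4.0)  # equilibrium is 5%

    def test_expected_identity_closed_form(self):
        d = 0.3
        closed = 100 * (1 / 20 + (19 / 20) * math.exp(-(40 / 19) * d))
        assert expected_identity(poisson_model(), d) == pytest.approx(closed)


class TestReferenceTable:
    def test_fixture_loads_with_both_profiles(self):
        df = load_reference_node_ages()
        assert set(df.table) == {"scan", "sd"}
        assert set(df.model) == {"cat_gtr_g", "lg_g"}
        assert len(df) == 22


class TestRootPriorScan:
    def test_scan_layout_and_determinism(self):
        """One row per root prior, ΔT consistent with the anchor ages."""
        from rcclock.analysis import scan_root_priors
        from rcclock.mcmc import McmcConfig
        from rcclock.priors import ClockModel
        from rcclock.simulate import SimulationConfig, simulate_dataset
        from rcclock.substitution import poisson_model

        tree, aln, _ = simulate_dataset(
            SimulationConfig(seed=8, n_tips=6, n_sites=40)
        )
        tips = tree.tip_names
        table = scan_root_priors(
            aln, tree, poisson_model(), ClockModel(sigma2=0.1, root_rate=0.25),
            [3.2, 3.8], 0.05, [],
            McmcConfig(iterations=60, burn_in=20, thinning=2, seed=4),
            tuple(tips), tuple(tips[:2]),
        )
        assert list(table.root_prior_ga) == [3.2, 3.8]
        assert np.isfinite(table.delta_t).all()
        assert np.allclose(table.delta_t, table.a_mean - table.b_mean)
        assert table.root_mean.iloc[1] > table.root_mean.iloc[0]
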