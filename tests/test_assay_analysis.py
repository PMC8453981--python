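"""Initial rates, coupling ratios, fold-changes, censoring and the report."""

from dataclasses import replace

import numpy as np
import pytest

from capab.assay_analysis import (
    Censored,
    condition_summary,
    coupling_ratio,
    endpoint_conversion,
    estimate_initial_rate,
    fold_change,
    slope_from_specific_activity,
    specific_activity_from_slope,
)
from capab.assay_sim import (
    AssayCondition,
    TimeCourse,
    analytic_initial_rates,
    add_measurement_noise,
    panel_conditions,
    simulate_timecourse,
)


def make_timecourse(times, adp=None, aca=None, cap0=2.0, atp0=2.0, **cond_kwargs):
    """Hand-built time course; unspecified analytes follow mass balance."""
    times = np.asarray(times, dtype=float)
    adp = np.zeros_like(times) if adp is None else np.asarray(adp, dtype=float)
    aca = np.zeros_like(times) if aca is None else np.asarray(aca, dtype=float)
    cond = AssayCondition(cap0=cap0, atp0=atp0, hco3=50.0, t_end=float(times[-1]), **cond_kwargs)
    return TimeCourse(
        condition=cond,
        times=times,
        concentrations={"ADP": adp, "ATP": atp0 - adp, "ACA": aca, "Cap": cap0 - aca},
    )


class TestInitialRate:
    def test_exact_line_recovers_reported_specific_activity(self):
        """0.02295 mM/min in 2 mL with 0.09 mg enzyme is 0.51 U/mg."""
        t = np.arange(0, 18, 2.0)
        tc = make_timecourse(t, adp=0.02295 * t, enzyme_conc=0.045, volume=2.0)
        est = estimate_initial_rate(tc, "ADP")
        assert est.slope == pytest.approx(0.02295)
        assert est.specific_activity == pytest.approx(0.51)
        assert est.n_points >= 3

    def test_flat_curve_gives_zero_rate(self):
        tc = make_timecourse(np.arange(0, 20, 2.0))
        est = estimate_initial_rate(tc, "ACA")
        assert est.slope == 0.0
        assert est.specific_activity == 0.0

    def test_window_truncates_at_max_conversion(self):
        t = np.arange(0, 42, 2.0)
        tc = make_timecourse(t, adp=np.minimum(0.05 * t, 2.0))
        est = estimate_initial_rate(tc, "ADP", max_conversion=0.2)
        # 20% of 2 mM ATP is consumed at t = 8 min
        assert est.window_end <= 8.0

    def test_too_few_points_raises_window_error(self):
        t = np.array([0.0, 2.0, 4.0])
        tc = make_timecourse(t, adp=np.array([0.0, 1.0, 1.9]))
        with pytest.raises(ValueError, match="window"):
            estimate_initial_rate(tc, "ADP")

    def test_noiseless_simulator_recovery_within_one_percent(
        self, entry1_noiseless, params
    ):
        truth = analytic_initial_rates(entry1_noiseless.condition, params)
        for analyte in ("ADP", "ACA"):
            est = estimate_initial_rate(entry1_noiseless, analyte)
            assert est.specific_activity == pytest.approx(truth[analyte], rel=0.01)

    def test_unit_conversion_round_trip(self):
        slope = 0.02295
        act = specific_activity_from_slope(slope, 2.0, 0.09)
        assert slope_from_specific_activity(act, 2.0, 0.09) == pytest.approx(slope)


class TestCouplingRatio:
    def test_reported_worked_example(self):
        """1.68 mM ADP over 1.4 mM ACA gives the reported 1.2 ratio."""
        t = np.array([0.0, 60.0])
        tc = make_timecourse(t, adp=np.array([0.0, 1.68]), aca=np.array([0.0, 1.4]))
        assert coupling_ratio(tc) == pytest.approx(1.2)

    def test_perfect_coupling_is_unity(self, params):
        p = replace(params, v_unc_max=0.0)
        tc = simulate_timecourse(panel_conditions()[0], p)
        for t_ref in (20.0, 60.0, 120.0):
            assert coupling_ratio(tc, t_ref) == pytest.approx(1.0, abs=1e-9)

    def test_rate_form_matches_reference_rates(self):
        t = np.arange(0, 18, 2.0)
        tc = make_timecourse(t, adp=0.51 * 0.045 * t, aca=0.39 * 0.045 * t)
        assert coupling_ratio(tc, method="rate") == pytest.approx(0.51 / 0.39, rel=1e-6)

    def test_no_product_is_censored_not_division_error(self):
        t = np.arange(0, 20, 2.0)
        tc = make_timecourse(t, adp=0.01 * t)
        result = coupling_ratio(tc)
        assert isinstance(result, Censored)
        assert result.direction == ">"

    def test_monotone_in_uncoupled_rate(self, params):
        cond = panel_conditions()[0]
        ratios = []
        for v_unc in (0.0, 0.2, 0.5544, 1.0):
            tc = simulate_timecourse(cond, replace(params, v_unc_max=v_unc))
            ratios.append(coupling_ratio(tc, t_ref=40.0))
        assert ratios == sorted(ratios)


class TestFoldChange:
    def test_bicarbonate_removal_reference_rates(self):
        assert fold_change(0.51, 0.008) == pytest.approx(63.75)
        assert fold_change(0.51, 0.008) >= 60

    def test_identity(self):
        assert fold_change(0.37, 0.37) == pytest.approx(1.0)

    def test_intermediate_bicarbonate_reference_rates(self):
        assert fold_change(0.167, 0.021) == pytest.approx(7.952, abs=1e-3)

    def test_zero_denominator_censored_with_lod(self):
        result = fold_change(0.51, 0.0, detection_limit=0.004)
        assert isinstance(result, Censored)
        assert result.direction == ">"
        assert result.bound == pytest.approx(127.5)

    def test_zero_denominator_without_lod_rejected(self):
        with pytest.raises(ValueError, match="detection_limit"):
            fold_change(0.51, 0.0)


class TestEndpointConversion:
    def test_complete_conversion(self):
        t = np.array([0.0, 60.0])
        tc = make_timecourse(t, aca=np.array([0.0, 2.0]))
        assert endpoint_conversion(tc) == pytest.approx(100.0)

    def test_trace_conversion(self):
        t = np.array([0.0, 60.0])
        tc = make_timecourse(t, aca=np.array([0.0, 0.008]))
        assert endpoint_conversion(tc) == pytest.approx(0.4)

    def test_below_lod_is_censored_at_known_bound(self):
        t = np.array([0.0, 60.0])
        tc = make_timecourse(t, aca=np.array([0.0, 1e-4]))
        result = endpoint_conversion(tc, lod=3e-4)
        assert isinstance(result, Censored)
        assert str(result) == "<0.015"

    def test_never_reports_numeric_below_threshold(self):
        t = np.array([0.0, 60.0])
        for aca_end in (0.0, 1e-5, 2.9e-4, 3.1e-4, 0.01):
            tc = make_timecourse(t, aca=np.array([0.0, aca_end]))
            result = endpoint_conversion(tc, lod=3e-4)
            if isinstance(result, float):
                assert result >= 100 * 3e-4 / 2.0

    def test_no_substrate_rejected(self):
        t = np.array([0.0, 60.0])
        tc = make_timecourse(t, cap0=0.0)
        with pytest.raises(ValueError):
            endpoint_conversion(tc)


class TestConditionSummary:
    def test_noiseless_panel_report_structure(self, noiseless_panel):
        report = condition_summary(noiseless_panel)
        frame = report.to_frame()
        assert len(frame) == 7
        # conditions without caprolactam report a dash for the ACA rate
        no_cap = frame[frame["label"].isin(["entry2", "entry5", "entry7"])]
        assert (no_cap["rate_aca_u_mg"] == "—").all()

    def test_uncoupled_fraction_from_reference_rates(self, noiseless_panel):
        report = condition_summary(noiseless_panel)
        # entry1 (with caprolactam) pairs with entry2 (without) at 50 mM HCO3;
        # the generator is calibrated to 0.44/0.51 = 0.86
        assert report.row("entry1").uncoupled_fraction == pytest.approx(
            0.44 / 0.51, rel=0.02
        )

    def test_noisy_panel_rates_close_to_truth(self, params):
        from capab.assay_sim import generate_condition_panel

        panel = generate_condition_panel(params, seed=5)
        report = condition_summary(panel)
        truth = analytic_initial_rates(panel[0].condition, params)["ADP"]
        assert report.row("entry1").rate_adp.specific_activity == pytest.approx(
            truth, rel=0.15
        )

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            condition_summary([])

    def test_unmatched_pairing_names_offenders(self, noiseless_panel):
        with pytest.raises(ValueError, match="nonexistent"):
            condition_summary(noiseless_panel, pairing={"entry1": "nonexistent"})
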