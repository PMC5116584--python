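"""Curve simulation, slope estimation, and the RRR quantification pipeline."""

import io
from dataclasses import replace

import numpy as np
import pytest

from rcalogic import (
    FluorescenceCurve,
    KineticParams,
    catalogue_design,
    estimate_rate,
    evaluate_truth_table,
    quantify_curves,
    quantify_experiment,
    simulate_curve,
)
from rcalogic.kinetics import (
    DegenerateExperiment,
    curves_from_frame,
    curves_to_frame,
)

NOISELESS = KineticParams(noise_sd=0.0)


class TestSimulateCurve:
    def test_active_template_is_exact_line_without_noise_or_lag(self, registry):
        params = replace(NOISELESS, lag_min=0.0)
        system = catalogue_design("ALL", registry)
        curve = simulate_curve(system, {"IPTG": 0, "D-Gal": 0}, params)
        expected = params.baseline_rfu + params.k_full * curve.times
        np.testing.assert_allclose(curve.values, expected)

    def test_metj_leak_leaves_residual_slope(self, registry):
        """With both anti-inducers in, the NAND design's MetJ template leaks
        at 15% of the full rate while the TrpR template is silent."""
        system = catalogue_design("NAND", registry)
        curve = simulate_curve(system, {"SAM": 1, "L-Trp": 1}, NOISELESS)
        est = estimate_rate(curve)
        assert est.slope == pytest.approx(0.15 * NOISELESS.k_full)

    def test_polymerase_limited_parallel_templates(self, registry):
        """One active template and two active templates give the same rate:
        the enzyme, not the template pool, is limiting."""
        system = catalogue_design("OR", registry)
        one = simulate_curve(system, {"IPTG": 1, "D-Gal": 0}, NOISELESS)
        both = simulate_curve(system, {"IPTG": 1, "D-Gal": 1}, NOISELESS)
        assert estimate_rate(one).slope == pytest.approx(NOISELESS.k_full)
        assert estimate_rate(both).slope == pytest.approx(NOISELESS.k_full)

    def test_plateau_clips_signal(self, registry):
        params = replace(NOISELESS, plateau_rfu=300.0)
        system = catalogue_design("ALL", registry)
        curve = simulate_curve(system, {"IPTG": 0, "D-Gal": 0}, params)
        assert curve.values.max() == 300.0

    def test_seeded_noise_is_reproducible(self, registry):
        system = catalogue_design("AND", registry)
        params = KineticParams(seed=11)
        c1 = simulate_curve(system, {"IPTG": 1, "D-Gal": 1}, params)
        c2 = simulate_curve(system, {"IPTG": 1, "D-Gal": 1}, params)
        np.testing.assert_array_equal(c1.values, c2.values)


class TestEstimateRate:
    def test_noise_free_line_recovered_exactly(self):
        t = np.arange(0, 15.5, 0.5)
        curve = FluorescenceCurve("line", t, 40.0 + 7.0 * t)
        est = estimate_rate(curve)
        assert est.slope == pytest.approx(7.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_lag_points_excluded_from_window(self):
        """For a flat-then-linear curve the chosen window sits past the lag."""
        t = np.arange(0, 15.5, 0.5)
        lag = 3.0
        curve = FluorescenceCurve(
            "lagged", t, 40.0 + 9.0 * np.clip(t - lag, 0.0, None)
        )
        est = estimate_rate(curve)
        assert est.slope == pytest.approx(9.0)
        assert t[est.window[0]] >= lag

    def test_flat_curve_gives_zero_slope(self):
        t = np.arange(0, 15.5, 0.5)
        est = estimate_rate(FluorescenceCurve("flat", t, np.full_like(t, 50.0)))
        assert est.slope == pytest.approx(0.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_noisy_line_within_ten_percent(self):
        """Seeded noisy lines (k=5, sd=0.5, 31 points) against the
        post-lag least-squares oracle."""
        t = np.arange(0, 15.5, 0.5)
        for seed in range(25):
            rng = np.random.default_rng(seed)
            y = 40.0 + 5.0 * t + rng.normal(0, 0.5, t.shape)
            est = estimate_rate(FluorescenceCurve("noisy", t, y))
            oracle = np.polyfit(t, y, 1)[0]
            assert abs(est.slope - 5.0) / 5.0 < 0.10
            assert abs(est.slope - oracle) < 0.5

    def test_estimator_consistency_as_noise_vanishes(self):
        t = np.arange(0, 15.5, 0.5)
        errors = []
        for sd in (0.2, 0.02, 0.002):
            errs = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                y = 40.0 + 5.0 * t + rng.normal(0, sd, t.shape)
                errs.append(abs(estimate_rate(FluorescenceCurve("c", t, y)).slope - 5.0))
            errors.append(np.mean(errs))
            assert errors[-1] <= 2 * sd
        assert errors[0] > errors[-1]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            estimate_rate(
                FluorescenceCurve("short", np.arange(5.0), np.arange(5.0))
            )


class TestQuantifyExperiment:
    @pytest.mark.parametrize("gate", ["AND", "OR", "NONE", "XNOR", "THREE_INPUT"])
    def test_noise_free_quantification_equals_boolean_layer(self, registry, gate):
        system = catalogue_design(gate, registry)
        report = quantify_experiment(system, NOISELESS)
        assert report.truth_table.outputs == evaluate_truth_table(system).outputs

    def test_none_gate_normalizes_against_control(self, registry):
        """All-off gates read RRR against the repressor-free control, so
        every condition scores 0 while the control pins RRR = 1."""
        report = quantify_experiment(catalogue_design("NONE", registry), NOISELESS)
        assert report.truth_table.outputs == (0, 0, 0, 0)
        assert report.control.rrr == pytest.approx(1.0)
        assert all(r.rrr < 0.5 for r in report.results)

    def test_leak_never_crosses_threshold_noise_free(self, registry):
        report = quantify_experiment(catalogue_design("NAND", registry), NOISELESS)
        off_rows = [
            r
            for r, bit in enumerate(report.truth_table.outputs)
            if evaluate_truth_table(catalogue_design("NAND", registry)).outputs[r] == 0
        ]
        for row in off_rows:
            assert report.results[row].rrr <= 0.15 + 1e-9

    def test_rrr_bounded_zero_one_with_noise(self, registry):
        for seed in (0, 1, 2):
            report = quantify_experiment(
                catalogue_design("XOR", registry), KineticParams(seed=seed)
            )
            for r in (*report.results, report.control):
                assert 0.0 <= r.rrr <= 1.0

    def test_default_noise_recovers_printed_table(self, registry):
        system = catalogue_design("ANDN", registry)
        want = evaluate_truth_table(system).outputs
        hits = sum(
            quantify_experiment(system, KineticParams(seed=s)).truth_table.outputs
            == want
            for s in range(50)
        )
        assert hits >= 49

    def test_degenerate_without_positive_rate(self, registry):
        params = replace(NOISELESS, enzyme_capacity=0.0)
        with pytest.raises(DegenerateExperiment):
            quantify_experiment(catalogue_design("AND", registry), params)

    def test_report_frame_has_all_conditions(self, registry):
        report = quantify_experiment(catalogue_design("AND", registry), NOISELESS)
        frame = report.to_frame()
        assert list(frame["condition"]) == ["00", "01", "10", "11", "control"]


class TestCurveIO:
    def test_tidy_csv_round_trip(self, registry, tmp_path):
        from rcalogic.kinetics import read_curves_csv, write_curves_csv

        system = catalogue_design("OR", registry)
        params = KineticParams(seed=3)
        rng = np.random.default_rng(3)
        curves = [
            simulate_curve(system, {"IPTG": a, "D-Gal": b}, params, rng)
            for a in (0, 1)
            for b in (0, 1)
        ]
        path = tmp_path / "curves.csv"
        write_curves_csv(curves, path)
        back = read_curves_csv(path)
        assert [c.label for c in back] == [c.label for c in curves]
        for a, b in zip(back, curves):
            np.testing.assert_allclose(a.values, b.values)

    def test_quantify_imported_curves(self):
        t = np.arange(0, 15.5, 0.5)
        curves = [
            FluorescenceCurve("00", t, 40 + 1.0 * t),
            FluorescenceCurve("11", t, 40 + 80.0 * t),
        ]
        results = quantify_curves(curves)
        assert [r.output_bit for r in results] == [0, 1]

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing columns"):
            curves_from_frame(pd.DataFrame({"condition": [], "rfu": []}))
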