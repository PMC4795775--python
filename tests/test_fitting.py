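"""f statistic, model fitting, nested-model selection."""

import numpy as np
import pytest

from isopop.fitting import (
    FitOptions,
    classify,
    f_from_residuals,
    f_statistic,
    fit_both,
    fit_model,
    infer_report,
)
from isopop.model import BiochemParams, PopulationModel, PopulationState
from isopop.synthetic import NoiseModel, simulate_measurement


class TestFStatistic:
    def test_identical_inputs_give_zero(self, mm, one_state_5050):
        p = mm.predict(one_state_5050)
        assert f_statistic(p, p) == 0.0

    def test_hand_computed_omission_example(self):
        r = np.array([0.3, -0.2, 0.1, 0.05, -0.05])
        expected = np.sqrt(0.1**2 + 0.05**2 + 0.05**2)
        assert f_from_residuals(r, omit_outliers=True) == pytest.approx(expected)

    def test_scaling_homogeneity_without_omission(self):
        r = np.array([0.2, -0.1, 0.05, 0.3])
        f = f_from_residuals(r, omit_outliers=False)
        assert f_from_residuals(3.0 * r, omit_outliers=False) == pytest.approx(3.0 * f)

    def test_omission_needs_three_residuals(self):
        with pytest.raises(ValueError):
            f_from_residuals(np.array([0.1, -0.1]), omit_outliers=True)


class TestClassify:
    def _result_with_f(self, mm, f, n_states):
        from isopop.fitting import FitResult

        model = PopulationModel.one_state(PopulationState(0.5))
        if n_states == 2:
            model = PopulationModel.two_state(
                0.5, PopulationState(1.0), PopulationState(0.0)
            )
        return FitResult(model, f, {}, 5 if n_states == 1 else 11, [f])

    @pytest.mark.parametrize(
        "ratio,expected", [(0.21, 2), (0.19, 1), (0.20, 1)]
    )
    def test_threshold_rule_is_strict(self, mm, ratio, expected):
        one = self._result_with_f(mm, 1.0, 1)
        two = self._result_with_f(mm, 10 ** (-ratio), 2)
        sel = classify(one, two, FitOptions(threshold=0.2))
        assert sel.chosen == expected
        assert sel.log10_f_ratio == pytest.approx(ratio)

    def test_zero_f_two_uses_floor(self, mm):
        one = self._result_with_f(mm, 1e-3, 1)
        two = self._result_with_f(mm, 0.0, 2)
        sel = classify(one, two)
        assert np.isfinite(sel.log10_f_ratio)
        assert sel.chosen == 2


class TestRoundTrips:
    def test_one_state_noise_free_recovery(self, mm, fast_options, reference_biochem):
        truth = PopulationModel.one_state(PopulationState(0.3, reference_biochem))
        meas = mm.predict(truth, "rt1")
        fit = fit_model(meas, 1, fast_options, mm)
        assert fit.f < 1e-6
        assert fit.model.states[0][1].usage12c == pytest.approx(0.3, abs=1e-3)
        assert fit.n_free_parameters == 5

    def test_two_state_noise_free_recovery(self, mm, fast_options, reference_biochem):
        truth = PopulationModel.two_state(
            0.3,
            PopulationState(1.0, reference_biochem),
            PopulationState(0.0, reference_biochem),
        )
        meas = mm.predict(truth, "rt2")
        fit = fit_model(meas, 2, fast_options, mm)
        (w_a, s_a), (w_b, s_b) = fit.model.states
        assert w_a == pytest.approx(0.3, abs=1e-2)
        assert s_a.usage12c == pytest.approx(1.0, abs=1e-2)
        assert s_b.usage12c == pytest.approx(0.0, abs=1e-2)
        assert fit.n_free_parameters == 11

    def test_result_in_canonical_order(self, mm, fast_options, reference_biochem):
        truth = PopulationModel.two_state(
            0.5,
            PopulationState(0.9, reference_biochem),
            PopulationState(0.1, reference_biochem),
        )
        fit = fit_model(mm.predict(truth, "c"), 2, fast_options, mm)
        assert fit.model.states[0][1].usage12c >= fit.model.states[1][1].usage12c

    def test_deterministic_given_seed(self, mm, reference_biochem):
        meas = simulate_measurement(
            PopulationModel.one_state(PopulationState(0.6, reference_biochem)),
            NoiseModel(sd=0.005),
            mm,
            seed=5,
        )
        opts = FitOptions(multistart=3, seed=42)
        f1 = fit_model(meas, 1, opts, mm)
        f2 = fit_model(meas, 1, opts, mm)
        assert f1.f == f2.f
        assert f1.model.states[0][1].as_vector() == pytest.approx(
            f2.model.states[0][1].as_vector()
        )


class TestNestedOrdering:
    def test_f_two_never_exceeds_f_one(self, mm, reference_biochem):
        """Nested models with seeded two-state fits: f_two <= f_one."""
        rng = np.random.default_rng(3)
        opts = FitOptions(multistart=2, seed=7)
        for i in range(3):
            u = rng.uniform(0, 1)
            meas = simulate_measurement(
                PopulationModel.one_state(PopulationState(u, reference_biochem)),
                NoiseModel(sd=0.01),
                mm,
                seed=100 + i,
            )
            sel = fit_both(meas, opts, mm)
            assert sel.two_state.f <= sel.one_state.f + 1e-12


class TestInferReport:
    def test_replicates_yield_rows_with_uniform_schema(
        self, mm, fast_options, reference_biochem
    ):
        model = PopulationModel.one_state(PopulationState(0.5, reference_biochem))
        samples = [
            simulate_measurement(
                model, NoiseModel(sd=0.003), mm, sample_id="s", replicate=str(r), seed=r
            )
            for r in range(3)
        ]
        report = infer_report(samples, fast_options, mm)
        assert len(report) == 3
        assert (report["error"] == "").all()
        assert set(report["sample"]) == {"s"}

    def test_pure_light_sample_called_one_state(self, mm, fast_options, reference_biochem):
        meas = simulate_measurement(
            PopulationModel.one_state(PopulationState(1.0, reference_biochem)),
            NoiseModel(sd=0.003),
            mm,
            sample_id="pure12C",
            seed=2,
        )
        report = infer_report([meas], fast_options, mm)
        row = report.iloc[0]
        assert row["chosen_states"] == 1
        assert row["usage_a"] > 0.99

    def test_failures_recorded_not_raised(self, mm, fast_options):
        from isopop.measurement import SampleMeasurement

        bad = SampleMeasurement("broken", {"Ala_m57": np.array([1.0, 0.0])})
        report = infer_report([bad], fast_options, mm)
        assert len(report) == 1
        assert report.iloc[0]["error"] != ""


class TestOmissionModes:
    def test_fragment_edge_omission_drops_edge_channels(self, mm, one_state_5050):
        from isopop.measurement import SampleMeasurement

        pred = mm.predict(one_state_5050)
        meas = pred.copy()
        # perturb the first channel of two fragments: the edge-dropping
        # rule removes both, the global-extremes rule only the largest one
        for fid in ("Leu_m57", "Val_m57"):
            meas.mids[fid] = meas.mids[fid].copy()
            meas.mids[fid][0] += 0.05
        f_edges = f_statistic(meas, pred, omission_mode="fragment_edges")
        f_extremes = f_statistic(meas, pred, omission_mode="extremes")
        assert f_edges == pytest.approx(0.0, abs=1e-12)
        assert f_extremes == pytest.approx(0.05, abs=1e-9)

    def test_fit_accepts_edge_omission_mode(self, mm, reference_biochem):
        truth = PopulationModel.one_state(PopulationState(0.4, reference_biochem))
        meas = mm.predict(truth, "edge")
        opts = FitOptions(multistart=2, seed=1, omission_mode="fragment_edges")
        fit = fit_model(meas, 1, opts, mm)
        assert fit.model.states[0][1].usage12c == pytest.approx(0.4, abs=1e-3)

    def test_unknown_omission_mode_rejected(self):
        with pytest.raises(ValueError):
            FitOptions(omission_mode="median")
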