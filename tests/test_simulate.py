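"""Signal and study generator: shapes, ranges, determinism, DGP faithfulness."""

import numpy as np
import pandas as pd
import pytest

import actiflux as af
from actiflux.kinds import ActivityKind
from actiflux.simulate import (
    DEFAULT_SIGNAL_PARAMS,
    TABLE_ORIENTATIONS,
    AffectDGPParams,
    SignalParams,
)


class TestSignalModel:
    def test_zero_noise_posture_is_constant_gravity(self):
        p = SignalParams(np.array([0.0, 1.0, 0.0]), noise_sd=0.0)
        tr = af.simulate_activity_trace(ActivityKind.standing, 2.5, params=p)
        assert tr.n_samples == 75
        assert np.allclose(tr.samples, [0.0, 1.0, 0.0])

    def test_gait_sinusoid_variance_matches_closed_form(self):
        # brute-force check: sample variance of a sinusoid over whole
        # cycles equals a^2/2
        a, f = 0.8, 3.0
        t = np.arange(60 * 30) / 30.0
        brute = np.var(a * np.sin(2 * np.pi * f * t))
        p = SignalParams(np.array([0.0, 1.0, 0.0]), gait_frequency=f,
                         gait_amplitude=a, noise_sd=0.0)
        tr = af.simulate_activity_trace(ActivityKind.running, 60, params=p)
        assert brute == pytest.approx(a**2 / 2, abs=1e-12)
        assert tr.samples[:, 1].var() == pytest.approx(0.32, abs=1e-6)

    def test_device_at_rest_is_still(self):
        p = SignalParams(TABLE_ORIENTATIONS[2], noise_sd=0.002,
                         table_position_index=2)
        tr = af.simulate_activity_trace(ActivityKind.non_wear, 10, params=p, seed=4)
        assert np.abs(np.diff(tr.samples, axis=0)).std() < 0.01
        assert np.allclose(tr.samples.mean(axis=0), TABLE_ORIENTATIONS[2], atol=0.01)

    def test_samples_within_device_range(self):
        p = SignalParams(np.array([0.0, 1.0, 0.0]), gait_frequency=3.0,
                         gait_amplitude=5.9, noise_sd=1.0)
        tr = af.simulate_activity_trace(ActivityKind.running, 30, params=p, seed=0)
        assert tr.samples.min() >= -6.0 and tr.samples.max() <= 6.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            af.simulate_activity_trace(ActivityKind.standing, -5)
        with pytest.raises(ValueError):
            SignalParams(np.array([1.0, 1.0, 0.0]))  # not unit norm
        with pytest.raises(ValueError):
            SignalParams(np.array([0.0, 1.0, 0.0]), gait_frequency=0.0,
                         gait_amplitude=0.3)


class TestReferenceSession:
    def test_protocol_of_seven_60s_blocks(self):
        trace, epochs = af.simulate_reference_session("c1", seed=0)
        assert trace.duration_s == 420.0
        assert len(epochs) == 168
        # epoch boundaries never straddle activities: each 60 s block is
        # exactly 24 epochs of one label
        assert (np.bincount(epochs.labels, minlength=7) == 24).all()

    def test_same_seed_bit_identical(self):
        t1, e1 = af.simulate_reference_session("c1", seed=9)
        t2, e2 = af.simulate_reference_session("c1", seed=9)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(e1.labels, e2.labels)

    def test_bad_protocols_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            af.simulate_reference_session(
                "c1", protocol=[(k, 60.0) for k in list(ActivityKind)[:6]]
            )
        with pytest.raises(ValueError, match="multiple"):
            af.simulate_reference_session(
                "c1",
                protocol=[(k, 60.0) for k in list(ActivityKind)[:6]]
                + [(ActivityKind.non_wear, 61.0)],
            )


class TestAffectDGP:
    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            AffectDGPParams(var_sigma3=-0.1).validate()
        with pytest.raises(ValueError):
            af.simulate_study(2, 2, dgp=AffectDGPParams(var_sigma0=-1.0))

    def test_deterministic_dgp_reproduces_fixed_effects(self):
        # all variances zero: the latent day mean is exactly
        # g00 + g10*t + g20*PA_i (+ g30*(PA_ti - PA_i), here g30=0)
        dgp = AffectDGPParams(
            gamma00=3.0, gamma10=0.1, gamma20=2.0, gamma30=0.0,
            var_sigma0=0, var_sigma1=0, var_sigma3=0, var_epsilon=0,
            cov_sigma0_sigma1=0,
        )
        panel, _ = af.simulate_affect_panel(dgp, 5, 4, seed=1)
        pa_i = panel.groupby("child_id")["pa"].transform("mean")
        expected = 3.0 + 0.1 * panel["day"] + 2.0 * pa_i
        assert np.allclose(panel["affect"], expected)

    def test_person_intercept_variance_matches_dgp(self):
        # continuous (pre-discretization) generator faithfulness
        dgp = AffectDGPParams(var_sigma0=0.5)
        _, effects = af.simulate_affect_panel(dgp, 800, 5, seed=3)
        assert effects["sigma0"].var(ddof=1) == pytest.approx(0.5, rel=0.10)


@pytest.fixture(scope="module")
def study():
    return af.simulate_study(3, 4, seed=5)


class TestStudySimulation:
    def test_occasion_and_item_counts(self, study):
        resp = study.affect_responses
        # 3 children x 4 days x 4 occasions x 12 items
        assert len(resp) == 3 * 4 * 4 * 12
        assert resp["response"].between(1, 5).all()

    def test_diary_reports_previous_night(self, study):
        rep = study.sleep_reports
        assert set(rep.columns) == {"child_id", "date", "bed_time", "wake_time"}
        # wake time is on the report's date; bed time is before it
        assert (pd.to_datetime(rep["wake_time"]).dt.date == pd.to_datetime(rep["date"]).dt.date).all()
        assert (pd.to_datetime(rep["bed_time"]) < pd.to_datetime(rep["wake_time"])).all()

    def test_trace_regeneration_is_deterministic(self, study):
        child, date = list(study.schedules)[0]
        t1 = study.trace(child, date)
        t2 = study.trace(child, date)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.abs(t1.samples).max() <= 6.0

    def test_schedule_matches_trace_length(self, study):
        child, date = list(study.schedules)[2]
        sched = study.schedule(child, date)
        tr = study.trace(child, date)
        pad = study.margin_epochs * 75
        assert tr.n_samples == len(sched) * 75 + 2 * pad

    def test_truth_table_pa_in_range(self, study):
        truth = study.day_truth
        assert truth["pa_fraction_true"].between(0, 1).all()
        assert truth["vigorous_share_true"].between(0, 1).all()
        assert len(truth) == 12
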