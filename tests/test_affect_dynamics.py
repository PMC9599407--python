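"""Emotion-intensity recurrence, threshold estimation and activation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisiswarn import (
    ConfigurationError,
    DynamicsConfig,
    EmotionState,
    PersonalityProfile,
    ValidationError,
    activate,
    decay,
    personality_influence,
    run_dynamics,
    step,
    threshold_estimate,
)
from crisiswarn.affect_dynamics import Thresholds, clip_to_valence

unit = st.floats(0.0, 1.0, allow_nan=False)


def state_of(**kwargs) -> EmotionState:
    order = ("dis", "ang", "sur", "fea", "joy", "sad")
    vec = np.zeros(6)
    for name, value in kwargs.items():
        vec[order.index(name)] = value
    return EmotionState(1, vec)


class TestEmotionState:
    def test_valence_ranges_enforced(self):
        with pytest.raises(ValidationError):
            state_of(joy=-0.1)
        with pytest.raises(ValidationError):
            state_of(fea=0.2)
        with pytest.raises(ValidationError):
            state_of(sad=-1.5)

    def test_six_components_required(self):
        with pytest.raises(ValidationError):
            EmotionState(1, np.zeros(5))


class TestDecay:
    def test_zero_lambda_is_identity(self):
        s = state_of(joy=0.8, fea=-0.3)
        assert np.array_equal(decay(s, 0.0).intensities, s.intensities)

    def test_exponential_attenuation(self):
        # Oracle: 0.8 * e^{-0.5} evaluated independently.
        s = decay(state_of(joy=0.8), 0.5)
        assert s.intensities[4] == pytest.approx(0.8 * math.exp(-0.5), abs=1e-12)
        assert s.intensities[4] == pytest.approx(0.485224, abs=1e-6)

    def test_repeated_decay_vanishes_without_sign_flip(self):
        s = state_of(joy=1.0, sad=-1.0)
        for _ in range(1000):
            s = decay(s, 1.0)
        assert 0 <= s.intensities[4] < 1e-300
        assert -1e-300 < s.intensities[5] <= 0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            decay(state_of(), -0.1)

    @given(lam1=st.floats(0, 3), lam2=st.floats(0, 3))
    @settings(max_examples=40, deadline=None)
    def test_larger_lambda_never_increases_magnitude(self, lam1, lam2):
        lo, hi = sorted([lam1, lam2])
        s = state_of(joy=0.9, fea=-0.7)
        assert np.all(
            np.abs(decay(s, hi).intensities) <= np.abs(decay(s, lo).intensities)
        )


class TestThresholdEstimate:
    def test_balanced_personality_splits_evenly(self):
        th = threshold_estimate(PersonalityProfile(0.5, 0, 0, 0.5, 0))
        assert th.xi == 0.0
        assert th.omega_neg == pytest.approx(0.5)
        assert th.omega_pos == pytest.approx(0.5)

    def test_open_profile_thresholds(self, open_profile):
        # (arctan 0.8 + pi/2) / pi, checked on a calculator.
        th = threshold_estimate(open_profile)
        assert th.xi == pytest.approx(0.8)
        assert th.omega_neg == pytest.approx(0.7147767, abs=1e-6)
        assert th.omega_pos == pytest.approx(0.2852233, abs=1e-6)

    def test_neurotic_profile_thresholds(self, neurotic_profile):
        th = threshold_estimate(neurotic_profile)
        assert th.xi == pytest.approx(-0.2)
        assert th.omega_neg == pytest.approx(0.4371670, abs=1e-6)
        assert th.omega_pos == pytest.approx(0.5628330, abs=1e-6)

    @given(traits=st.lists(unit, min_size=5, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_thresholds_sum_to_one_and_lie_in_unit_interval(self, traits):
        th = threshold_estimate(PersonalityProfile.from_sequence(traits))
        assert th.omega_pos + th.omega_neg == pytest.approx(1.0, abs=1e-12)
        assert 0 < th.omega_pos < 1 and 0 < th.omega_neg < 1

    def test_monotone_in_xi_across_reachable_range(self):
        # xi = c + e - n spans [-1, 2]; build a profile ladder along it and
        # check omega_neg is strictly increasing and matches the arctan
        # transfer evaluated independently.
        def profile_for(x: float) -> PersonalityProfile:
            if x < 0:
                return PersonalityProfile(0, 0, 0, 0, -x)
            if x <= 1:
                return PersonalityProfile(0, x, 0, 0, 0)
            return PersonalityProfile(0, 1, x - 1, 0, 0)

        xis = np.linspace(-1, 2, 61)
        omegas = []
        for x in xis:
            th = threshold_estimate(profile_for(float(x)))
            assert th.omega_neg == pytest.approx(
                (math.atan(x) + math.pi / 2) / math.pi, abs=1e-12
            )
            omegas.append(th.omega_neg)
        assert all(b > a for a, b in zip(omegas, omegas[1:]))
        assert omegas[0] < 0.5 < omegas[-1]


class TestStep:
    CFG = DynamicsConfig(lambda_=0.5, gain=0.1)

    def test_all_zero_is_fixed_point(self):
        s = step(EmotionState.zero(), np.zeros(6), np.zeros(6), self.CFG)
        assert np.array_equal(s.intensities, np.zeros(6))
        assert s.t == 2

    def test_single_impulse_passes_through(self):
        stim = np.array([0, 0, 0, 0, 0.7, 0.0])
        s = step(EmotionState.zero(), stim, np.zeros(6), self.CFG)
        assert s.intensities[4] == pytest.approx(0.7)

    def test_positive_overflow_clips_to_one(self):
        stim = np.array([0, 0, 0, 0, 0.7, 0.0])
        phi = np.array([0, 0, 0, 0, 0.1, 0.0])
        s = step(
            state_of(joy=0.9), stim, phi, DynamicsConfig(lambda_=0.0, gain=0.1)
        )
        assert s.intensities[4] == pytest.approx(1.0)  # 0.9 + 0.7 + 0.1 clipped

    def test_no_cross_valence_leakage(self):
        # A strong negative stimulus on joy cannot push it below zero, and a
        # strong positive stimulus on fear cannot push it above zero.
        stim = np.array([0, 0, 0, 0.9, -0.9, 0.0])
        s = step(state_of(joy=0.2, fea=-0.3), stim, np.zeros(6), self.CFG)
        assert s.intensities[4] == 0.0
        assert s.intensities[3] == 0.0

    def test_component_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            step(EmotionState.zero(), np.zeros(5), np.zeros(6), self.CFG)


class TestActivate:
    TH = Thresholds(xi=0.8, omega_pos=0.2852233, omega_neg=0.7147767)

    def test_zero_state_expresses_nothing(self):
        act = activate(EmotionState.zero(), self.TH)
        assert not any(act.expressed)
        assert np.array_equal(act.values, np.zeros(6))

    def test_positive_expression_at_threshold(self):
        act = activate(state_of(joy=0.30), self.TH)
        assert act.expressed[4]
        assert act.values[4] == pytest.approx(0.30)

    def test_negative_below_threshold_not_expressed(self):
        act = activate(state_of(fea=-0.40), Thresholds(-0.2, 0.5628330, 0.4371670))
        assert not act.expressed[3]
        assert act.values[3] == 0.0

    def test_negative_magnitude_comparison(self):
        act = activate(state_of(fea=-0.45), Thresholds(-0.2, 0.5628330, 0.4371670))
        assert act.expressed[3]
        assert act.values[3] == pytest.approx(-0.45)


class TestRunDynamics:
    def test_quiet_run_stays_zero(self):
        p = PersonalityProfile(0, 0, 0, 0, 0)
        out = run_dynamics(p, {}, DynamicsConfig(gain=0.0), horizon=5)
        assert len(out) == 5
        for state, act in out:
            assert np.array_equal(state.intensities, np.zeros(6))
            assert not any(act.expressed)

    def test_single_impulse_decays_geometrically(self):
        # Closed form: after an impulse of 0.7 at day 3 with gain 0, the joy
        # intensity is 0.7 * e^{-lambda (t - 3)} for t >= 3.
        p = PersonalityProfile(0, 0, 0, 0, 0)
        lam = 0.5
        stim = np.array([0, 0, 0, 0, 0.7, 0.0])
        out = run_dynamics(
            p, {3: stim}, DynamicsConfig(lambda_=lam, gain=0.0), horizon=10
        )
        for state, _ in out:
            t = state.t
            expected = 0.7 * math.exp(-lam * (t - 3)) if t >= 3 else 0.0
            assert state.intensities[4] == pytest.approx(expected, abs=1e-12)

    def test_constant_bias_matches_affine_closed_form(self, rng):
        # Oracle: with constant phi and no stimulus the pre-clip recurrence
        # is affine, I_t = phi (1 - q^t) / (1 - q) with q = e^{-lambda};
        # parameters are drawn so no component ever clips.
        p = PersonalityProfile(0.8, 0.2, 0.6, 0.4, 0.0)
        for _ in range(50):
            lam = rng.uniform(0.3, 1.5)
            gain = rng.uniform(0.0, 0.1)
            cfg = DynamicsConfig(lambda_=lam, gain=gain)
            phi = personality_influence(p, gain=gain)
            q = math.exp(-lam)
            out = run_dynamics(p, {}, cfg, horizon=12)
            for state, _ in out:
                expected = phi * (1 - q ** state.t) / (1 - q)
                assert np.allclose(state.intensities, expected, atol=1e-9)

    def test_converges_to_fixed_point(self):
        # Long-run limit of the affine recurrence: phi / (1 - e^{-lambda}).
        p = PersonalityProfile(0.8, 0.2, 0.6, 0.4, 0.0)
        cfg = DynamicsConfig(lambda_=0.5, gain=0.1)
        phi = personality_influence(p, gain=0.1)
        out = run_dynamics(p, {}, cfg, horizon=80)
        limit = clip_to_valence(phi / (1 - math.exp(-0.5)))
        assert np.allclose(out[-1][0].intensities, limit, atol=1e-12)

    def test_sustained_mode_repeats_stimulus(self):
        p = PersonalityProfile(0, 0, 0, 0, 0)
        stim = np.array([0, 0, 0, 0, 0.2, 0.0])
        cfg = DynamicsConfig(lambda_=0.0, gain=0.0,
                             stimulus_mode="sustained", sustain_steps=3)
        out = run_dynamics(p, {2: stim}, cfg, horizon=6)
        joys = [s.intensities[4] for s, _ in out]
        assert joys == pytest.approx([0.0, 0.2, 0.4, 0.6, 0.6, 0.6])

    def test_schedule_day_outside_horizon_rejected(self):
        p = PersonalityProfile(0, 0, 0, 0, 0)
        with pytest.raises(ValidationError, match="outside"):
            run_dynamics(p, {11: np.zeros(6)}, DynamicsConfig(), horizon=10)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_intensities_stay_in_valence_ranges(self, seed):
        # Clamping invariant under arbitrary random stimulus schedules.
        gen = np.random.default_rng(seed)
        p = PersonalityProfile.from_sequence(gen.uniform(0, 1, 5))
        schedule = {
            int(day): gen.uniform(-1, 1, 6)
            for day in gen.integers(1, 16, size=6)
        }
        out = run_dynamics(
            p, schedule, DynamicsConfig(lambda_=0.5, gain=0.1), horizon=15
        )
        for state, _ in out:
            arr = state.intensities
            assert np.all(arr[[2, 4]] >= 0) and np.all(arr[[2, 4]] <= 1)
            assert np.all(arr[[0, 1, 3, 5]] <= 0) and np.all(arr[[0, 1, 3, 5]] >= -1)
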