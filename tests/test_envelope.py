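import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from envtacs import (
    Envelope,
    StimulationCondition,
    Waveform,
    all_conditions,
    analytic_envelope,
    condition_current,
    delay_envelope,
    extract_envelope,
    make_condition_current,
    phase_shift_envelope,
)
from envtacs.envelope import ENV_TACS_LATENCIES_MS, ENV_TACS_PHASES_DEG


class TestConditionBattery:
    def test_sixteen_conditions(self):
        conds = all_conditions()
        assert len(conds) == 16
        kinds = [c.kind for c in conds]
        assert kinds.count("env_tacs") == 12
        for k in ("sham", "dc_plus", "dc_minus", "unrelated_env"):
            assert kinds.count(k) == 1

    def test_labels_unique(self):
        labels = [c.label for c in all_conditions()]
        assert len(set(labels)) == 16

    def test_env_tacs_requires_phase_and_latency(self):
        with pytest.raises(ValueError):
            StimulationCondition("env_tacs")
        with pytest.raises(ValueError):
            StimulationCondition("env_tacs", phase_deg=45.0, latency_ms=100.0)
        with pytest.raises(ValueError):
            StimulationCondition("sham", phase_deg=0.0)
        with pytest.raises(ValueError):
            StimulationCondition("nonsense")


class TestExtractEnvelope:
    def test_recovers_slow_modulation(self):
        rate = 1000.0
        t = np.arange(int(8 * rate)) / rate
        modulation = 1.0 + 0.5 * np.cos(2 * np.pi * 2.0 * t)
        audio = Waveform(samples=modulation * np.sin(2 * np.pi * 150.0 * t), rate=rate)
        env = extract_envelope(audio)
        assert env.is_raw and np.all(env.samples >= 0)
        # compare away from the edges, where the FIR transient lives
        core = slice(int(rate), int(7 * rate))
        assert np.max(np.abs(env.samples[core] - modulation[core])) < 0.05

    def test_too_short_audio_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            extract_envelope(Waveform(samples=np.ones(100), rate=1000.0))

    def test_cutoff_above_nyquist_rejected(self):
        audio = Waveform(samples=np.random.default_rng(0).standard_normal(4000), rate=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            extract_envelope(audio, cutoff_hz=60.0)


class TestPhaseShift:
    def test_zero_shift_is_mean_removal_only(self, speech_env):
        out = phase_shift_envelope(speech_env, 0.0)
        expected = speech_env.samples - speech_env.samples.mean()
        np.testing.assert_allclose(out.samples, expected, atol=1e-12)

    def test_180_is_exact_negation(self, speech_env):
        y0 = speech_env.samples - speech_env.samples.mean()
        out = phase_shift_envelope(speech_env, 180.0)
        np.testing.assert_allclose(out.samples, -y0, atol=1e-9)

    def test_360_is_identity(self, speech_env):
        a = phase_shift_envelope(speech_env, 360.0)
        b = phase_shift_envelope(speech_env, 0.0)
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-12)

    def test_composition(self, speech_env):
        one = phase_shift_envelope(phase_shift_envelope(speech_env, 50.0), 70.0)
        both = phase_shift_envelope(speech_env, 120.0)
        assert np.max(np.abs(one.samples - both.samples)) < 1e-9

    @settings(max_examples=20, derandomize=True)
    @given(
        a=st.floats(min_value=0.0, max_value=360.0),
        b=st.floats(min_value=0.0, max_value=360.0),
    )
    def test_composition_property(self, a, b):
        # odd length: an even-length signal has a lone Nyquist bin, which a
        # real rotation can only attenuate (by cos phi), breaking exact
        # composition for broadband inputs; band-limited envelopes are immune
        env = Envelope(
            samples=np.random.default_rng(1).standard_normal(511), rate=64.0
        )
        one = phase_shift_envelope(phase_shift_envelope(env, a), b)
        both = phase_shift_envelope(env, a + b)
        assert np.max(np.abs(one.samples - both.samples)) < 1e-9

    def test_amplitude_spectrum_preserved(self, speech_env):
        before = np.abs(np.fft.rfft(speech_env.samples - speech_env.samples.mean()))
        after = np.abs(np.fft.rfft(phase_shift_envelope(speech_env, 73.0).samples))
        # every in-band magnitude is preserved (pure rotation); the atol floor
        # covers out-of-band bins that are zero up to roundoff
        np.testing.assert_allclose(
            after[1:], before[1:], rtol=1e-9, atol=1e-12 * before.max()
        )

    def test_cosine_advances_by_phi(self, grid_cosine_env):
        t = grid_cosine_env.times_s
        for phi in (30.0, 90.0, 245.0):
            out = phase_shift_envelope(grid_cosine_env, phi)
            expected = np.cos(2 * np.pi * 2.0 * t + np.deg2rad(phi))
            np.testing.assert_allclose(out.samples, expected, atol=1e-9)

    def test_analytic_real_part_is_zero_mean_input(self, speech_env):
        z = analytic_envelope(speech_env)
        np.testing.assert_allclose(
            z.samples.real, speech_env.samples - speech_env.samples.mean(), atol=1e-12
        )

    def test_hilbert_orthogonality_unpadded(self, speech_env):
        z = analytic_envelope(speech_env, pad=0)
        dot = float(z.samples.real @ z.samples.imag)
        norm = float(z.samples.real @ z.samples.real)
        assert abs(dot) / norm < 1e-12


class TestDelay:
    def test_integer_sample_delay(self, speech_env):
        out = delay_envelope(speech_env, 250.0)  # 25 samples at 100 Hz
        np.testing.assert_array_equal(out.samples[25:], speech_env.samples[:-25])
        assert np.all(out.samples[:25] == 0.0)

    def test_negative_delay_advances(self, speech_env):
        out = delay_envelope(speech_env, -100.0)
        np.testing.assert_array_equal(out.samples[:-10], speech_env.samples[10:])
        assert np.all(out.samples[-10:] == 0.0)

    def test_nearest_sample_quantisation(self, speech_env):
        # 62.5 ms at 100 Hz is 6.25 samples; it must round to 6
        out = delay_envelope(speech_env, 62.5)
        np.testing.assert_array_equal(out.samples[6:], speech_env.samples[:-6])

    def test_overlong_delay_rejected(self, speech_env):
        with pytest.raises(ValueError, match="exceeds"):
            delay_envelope(speech_env, 40_000.0)


class TestConditioning:
    def test_endpoints_and_peak_exact(self, speech_env):
        cur = condition_current(speech_env, max_abs_mA=0.9)
        assert cur.samples[0] == 0.0 and cur.samples[-1] == 0.0
        assert np.max(np.abs(cur.samples)) == pytest.approx(0.9, abs=0.0)

    def test_mean_near_zero(self, speech_env):
        cur = condition_current(speech_env, max_abs_mA=1.0)
        assert abs(np.mean(cur.samples)) < 0.05

    def test_constant_envelope_conditions_to_zero(self):
        env = Envelope(samples=np.full(1000, 3.0), rate=100.0)
        cur = condition_current(env, max_abs_mA=1.0)
        assert cur.is_zero and np.all(cur.samples == 0.0)

    def test_overlong_ramp_rejected(self, speech_env):
        with pytest.raises(ValueError, match="fit"):
            condition_current(speech_env, max_abs_mA=1.0, ramp_ms=20_000.0)


class TestMakeConditionCurrent:
    @pytest.fixture()
    def unrelated(self, speech_env):
        from envtacs import gen_speech_like_envelope

        return gen_speech_like_envelope(
            speech_env.duration_s, rate=speech_env.rate, seed=99
        )

    def test_env_tacs_is_shift_then_delay_then_condition(self, speech_env, unrelated):
        cond = StimulationCondition("env_tacs", phase_deg=120.0, latency_ms=250.0)
        got = make_condition_current(speech_env, unrelated, cond, max_abs_mA=0.9)
        manual = condition_current(
            delay_envelope(phase_shift_envelope(speech_env, 120.0), 250.0), 0.9
        )
        np.testing.assert_allclose(got.samples, manual.samples, atol=1e-12)

    @pytest.mark.parametrize("kind,sign", [("dc_plus", 1.0), ("dc_minus", -1.0)])
    def test_dc_plateau(self, speech_env, unrelated, kind, sign):
        cur = make_condition_current(
            speech_env, unrelated, StimulationCondition(kind), max_abs_mA=0.9
        )
        mid = cur.samples[cur.n // 2]
        assert mid == pytest.approx(sign * 0.9, abs=1e-12)
        assert cur.samples[0] == 0.0 and cur.samples[-1] == 0.0

    def test_sham_confined_to_burst(self, speech_env, unrelated):
        cur = make_condition_current(
            speech_env, unrelated, StimulationCondition("sham"), max_abs_mA=0.9
        )
        n_burst = int(round(0.5 * speech_env.rate))
        assert np.all(cur.samples[n_burst:] == 0.0)
        assert np.max(np.abs(cur.samples[:n_burst])) == pytest.approx(0.9)

    def test_unrelated_requires_second_envelope(self, speech_env):
        with pytest.raises(ValueError, match="unrelated"):
            make_condition_current(
                speech_env, None, StimulationCondition("unrelated_env"), max_abs_mA=0.9
            )

    def test_all_sixteen_conditions_build(self, speech_env, unrelated):
        for cond in all_conditions():
            cur = make_condition_current(speech_env, unrelated, cond, max_abs_mA=0.9)
            assert cur.samples[0] == 0.0 and cur.samples[-1] == 0.0
            assert np.max(np.abs(cur.samples)) <= 0.9 * (1 + 1e-12)


def test_phase_and_latency_grids():
    assert ENV_TACS_PHASES_DEG == (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)
    assert ENV_TACS_LATENCIES_MS == (100.0, 250.0)
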