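"""Demodulation, reference calibration and phasor/lifetime conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flits import (
    InstrumentConfig,
    NoiseSpec,
    PhaseStack,
    background_correct,
    demodulate,
    intensity_mask,
    lifetimes_to_phasor,
    phasor_to_lifetimes,
    reference_calibrate,
)
from flits.phasor import PhasorImage, RawPhasorImage
from flits.simulate import (
    simulate_mono_stack,
    simulate_reference_stack,
    simulate_two_state_stack,
)


def make_sinusoid_stack(config, amplitude=100.0, m=0.5, phase=0.6, shape=(4, 4)):
    theta = config.phase_steps
    frames = amplitude * (1.0 + m * np.cos(theta - phase))
    return PhaseStack(frames=np.broadcast_to(frames[:, None, None],
                                             (config.n_phase_steps, *shape)).copy(),
                      config=config)


class TestDemodulate:
    def test_recovers_sinusoid_parameters_exactly(self, config):
        raw = demodulate(make_sinusoid_stack(config))
        assert raw.dc[0, 0] == pytest.approx(100.0, abs=1e-10)
        assert raw.ac_amplitude[0, 0] / raw.dc[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert raw.raw_phase[0, 0] == pytest.approx(0.6, abs=1e-12)

    def test_constant_frames_have_zero_ac(self, config):
        frames = np.full((config.n_phase_steps, 3, 3), 42.0)
        raw = demodulate(PhaseStack(frames=frames, config=config))
        assert raw.dc[0, 0] == pytest.approx(42.0)
        assert raw.ac_amplitude[0, 0] == pytest.approx(0.0, abs=1e-12)
        # zero modulation pixels are flagged invalid downstream
        ph = reference_calibrate(raw, demodulate(simulate_reference_stack(config, shape=(3, 3))))
        assert not ph.valid_mask.any()

    def test_three_phase_steps_match_twelve(self):
        c12 = InstrumentConfig(n_phase_steps=12)
        c3 = InstrumentConfig(n_phase_steps=3)
        r12 = demodulate(make_sinusoid_stack(c12))
        r3 = demodulate(make_sinusoid_stack(c3))
        assert r3.dc[0, 0] == pytest.approx(r12.dc[0, 0], abs=1e-10)
        assert r3.ac_amplitude[0, 0] == pytest.approx(r12.ac_amplitude[0, 0], abs=1e-10)
        assert r3.raw_phase[0, 0] == pytest.approx(r12.raw_phase[0, 0], abs=1e-12)

    def test_fewer_than_three_steps_rejected(self):
        with pytest.raises(ValueError):
            InstrumentConfig(n_phase_steps=2)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(m=st.floats(0.05, 0.95), phase=st.floats(-3.0, 3.0),
           amplitude=st.floats(10.0, 1e4))
    def test_equals_least_squares_oracle(self, m, phase, amplitude):
        """DFT demodulation equals a brute-force a + b cos + c sin fit."""
        config = InstrumentConfig()
        stack = make_sinusoid_stack(config, amplitude=amplitude, m=m,
                                    phase=phase, shape=(1, 1))
        raw = demodulate(stack)
        theta = config.phase_steps
        design = np.column_stack([np.ones_like(theta), np.cos(theta), np.sin(theta)])
        a, b, c = np.linalg.lstsq(design, stack.frames[:, 0, 0], rcond=None)[0]
        assert raw.dc[0, 0] == pytest.approx(a, rel=1e-9)
        assert raw.ac_amplitude[0, 0] == pytest.approx(math.hypot(b, c), rel=1e-9)
        expected_phase = math.atan2(c, b)
        diff = (raw.raw_phase[0, 0] - expected_phase + math.pi) % (2 * math.pi) - math.pi
        assert diff == pytest.approx(0.0, abs=1e-9)


class TestReferenceCalibration:
    def test_self_calibration_recovers_reference_lifetime(self, config):
        raw = demodulate(simulate_reference_stack(config))
        lt = phasor_to_lifetimes(reference_calibrate(raw, raw, 4.05))
        np.testing.assert_allclose(lt.tau_phi, 4.05, rtol=1e-12)
        np.testing.assert_allclose(lt.tau_mod, 4.05, rtol=1e-12)

    def test_erythrosin_b_short_lifetime_reference(self, config):
        raw = demodulate(simulate_mono_stack(0.086, config))
        lt = phasor_to_lifetimes(reference_calibrate(raw, raw, 0.086))
        np.testing.assert_allclose(lt.tau_phi, 0.086, rtol=1e-10)
        np.testing.assert_allclose(lt.tau_mod, 0.086, rtol=1e-10)

    def test_apo_state_lifetimes(self, config, in_vitro_model):
        stack = simulate_two_state_stack(in_vitro_model, config, fraction_bound=0.0)
        ref = simulate_reference_stack(config)
        lt = phasor_to_lifetimes(reference_calibrate(demodulate(stack), demodulate(ref)))
        np.testing.assert_allclose(lt.tau_phi, 1.40, rtol=1e-9)
        np.testing.assert_allclose(lt.tau_mod, 1.80, rtol=1e-9)

    def test_instrument_offsets_cancel_exactly(self, config, in_situ_model):
        """A shared phase offset and modulation scaling leave (G,S) unchanged."""
        stack = simulate_two_state_stack(in_situ_model, config, fraction_bound=0.4)
        ref = simulate_reference_stack(config)
        raw_s, raw_r = demodulate(stack), demodulate(ref)
        baseline = reference_calibrate(raw_s, raw_r)

        def perturb(raw, dphi=0.37, scale=0.81):
            return RawPhasorImage(dc=raw.dc, ac_amplitude=raw.ac_amplitude * scale,
                                  raw_phase=raw.raw_phase + dphi, config=raw.config)

        shifted = reference_calibrate(perturb(raw_s), perturb(raw_r))
        np.testing.assert_allclose(shifted.g, baseline.g, atol=1e-10)
        np.testing.assert_allclose(shifted.s, baseline.s, atol=1e-10)

    def test_config_mismatch_rejected(self, config):
        other = InstrumentConfig(frequency_mhz=80.0)
        raw_a = demodulate(simulate_reference_stack(config))
        raw_b = demodulate(simulate_mono_stack(4.05, other))
        with pytest.raises(ValueError):
            reference_calibrate(raw_a, raw_b)

    def test_mixture_phase_lifetime_below_modulation_lifetime(self, config, in_situ_model):
        """tau_phi <= tau_mod pixel-wise for two-component mixtures."""
        ref = demodulate(simulate_reference_stack(config))
        for f in (0.2, 0.5, 0.8):
            stack = simulate_two_state_stack(in_situ_model, config, fraction_bound=f)
            lt = phasor_to_lifetimes(reference_calibrate(demodulate(stack), ref))
            assert np.all(lt.tau_phi[lt.valid_mask] <= lt.tau_mod[lt.valid_mask] + 1e-9)


class TestBackgroundCorrection:
    def test_uniform_background_removed_exactly(self, config):
        signal = simulate_mono_stack(2.5, config, amplitude=800.0)
        bg = simulate_mono_stack(0.5, config, amplitude=200.0)
        mixed_frames = signal.frames + bg.frames
        mixed = PhaseStack(frames=mixed_frames, config=config)
        # a region of pure background: append columns of bg only
        pure_bg = PhaseStack(frames=bg.frames, config=config)
        combined = PhaseStack(
            frames=np.concatenate([mixed.frames, pure_bg.frames], axis=2), config=config
        )
        mask = np.zeros(combined.shape, dtype=bool)
        mask[:, mixed.shape[1]:] = True
        corrected = background_correct(demodulate(combined), mask)
        ref = demodulate(simulate_reference_stack(config, shape=combined.shape))
        ph_corr = reference_calibrate(corrected, ref)
        ph_signal = reference_calibrate(
            demodulate(PhaseStack(
                frames=np.concatenate([signal.frames, np.zeros_like(bg.frames)], axis=2),
                config=config)),
            ref,
        )
        region = ~mask
        np.testing.assert_allclose(ph_corr.g[region], ph_signal.g[region], atol=1e-10)
        np.testing.assert_allclose(ph_corr.s[region], ph_signal.s[region], atol=1e-10)

    def test_zero_count_background_region_is_identity(self, config):
        signal = simulate_mono_stack(2.5, config, shape=(4, 8))
        frames = signal.frames.copy()
        frames[:, :, 4:] = 0.0
        stack = PhaseStack(frames=frames, config=config)
        raw = demodulate(stack)
        mask = np.zeros(stack.shape, dtype=bool)
        mask[:, 4:] = True
        corrected = background_correct(raw, mask)
        np.testing.assert_allclose(corrected.dc, raw.dc, atol=1e-12)
        np.testing.assert_allclose(corrected.ac_amplitude, raw.ac_amplitude, atol=1e-12)

    def test_oversubtracted_pixels_flagged_invalid(self, config):
        signal = simulate_mono_stack(2.5, config, shape=(4, 8), amplitude=100.0)
        frames = signal.frames.copy()
        frames[:, :, :2] = 0.0  # darker than the "background" region
        stack = PhaseStack(frames=frames, config=config)
        mask = np.zeros(stack.shape, dtype=bool)
        mask[:, 2:] = True
        corrected = background_correct(demodulate(stack), mask)
        ref = demodulate(simulate_reference_stack(config, shape=stack.shape))
        ph = reference_calibrate(corrected, ref)
        assert not ph.valid_mask[:, :2].any()

    def test_empty_mask_rejected(self, config):
        raw = demodulate(simulate_mono_stack(2.5, config))
        with pytest.raises(ValueError):
            background_correct(raw, np.zeros(raw.dc.shape, dtype=bool))


class TestPhasorLifetimeConversion:
    def test_zero_lifetime_is_unit_phasor(self):
        g, s = lifetimes_to_phasor(0.0, 0.0, 75.1)
        assert (g, s) == pytest.approx((1.0, 0.0))

    def test_omega_tau_one_gives_half_half(self, config):
        tau = 1.0 / config.omega_per_ns
        g, s = lifetimes_to_phasor(tau, tau, config.frequency_mhz)
        assert (g, s) == pytest.approx((0.5, 0.5))

    @pytest.mark.parametrize("tau_phi, tau_mod, expected", [
        (1.40, 1.80, (0.636, 0.420)),
        (2.78, 3.01, (0.349, 0.458)),
    ])
    def test_state_phasor_coordinates(self, tau_phi, tau_mod, expected):
        g, s = lifetimes_to_phasor(tau_phi, tau_mod, 75.1)
        assert (g, s) == pytest.approx(expected, abs=5e-4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(tau_phi=st.floats(0.01, 20.0), tau_mod=st.floats(0.01, 20.0))
    def test_round_trip_identity(self, tau_phi, tau_mod):
        config = InstrumentConfig()
        g, s = lifetimes_to_phasor(tau_phi, tau_mod, config.frequency_mhz)
        ph = PhasorImage(g=np.array([[g]]), s=np.array([[s]]),
                         intensity=np.ones((1, 1)), valid_mask=np.ones((1, 1), bool),
                         config=config)
        lt = phasor_to_lifetimes(ph)
        assert lt.tau_phi[0, 0] == pytest.approx(tau_phi, rel=1e-9)
        assert lt.tau_mod[0, 0] == pytest.approx(tau_mod, rel=1e-9)

    def test_unphysical_phasors_flagged_not_raised(self, config):
        ph = PhasorImage(g=np.array([[1.2, -0.5]]), s=np.array([[0.0, -0.1]]),
                         intensity=np.ones((1, 2)), valid_mask=np.ones((1, 2), bool),
                         config=config)
        lt = phasor_to_lifetimes(ph)
        assert not lt.valid_mask.any()
        assert np.isnan(lt.tau_phi).all()


class TestSemicircle:
    @pytest.mark.parametrize("tau", [0.086, 0.5, 1.4, 2.78, 4.05, 10.0])
    def test_mono_exponential_on_universal_semicircle(self, config, tau):
        raw = demodulate(simulate_mono_stack(tau, config, shape=(2, 2)))
        ref = demodulate(simulate_reference_stack(config, shape=(2, 2)))
        ph = reference_calibrate(raw, ref)
        radius_sq = (ph.g - 0.5) ** 2 + ph.s**2
        np.testing.assert_allclose(radius_sq, 0.25, atol=1e-12)


class TestIntensityMask:
    def test_strict_inequality(self):
        img = np.array([999.0, 1000.0, 1001.0])
        np.testing.assert_array_equal(intensity_mask(img, 1000.0),
                                      [False, False, True])

    def test_threshold_zero_passes_positive(self):
        assert intensity_mask(np.array([0.1, 5.0]), 0.0).all()

    def test_all_at_threshold_empty(self):
        assert not intensity_mask(np.full(5, 200.0), 200.0).any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            intensity_mask(np.ones(3), -1.0)


class TestReproducibility:
    def test_noise_free_output_bit_identical(self, config):
        a = simulate_mono_stack(2.0, config, noise=NoiseSpec(kind="none", seed=1))
        b = simulate_mono_stack(2.0, config, noise=NoiseSpec(kind="none", seed=99))
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_seeded_poisson_reproducible(self, config):
        a = simulate_mono_stack(2.0, config, noise=NoiseSpec(kind="poisson", seed=5))
        b = simulate_mono_stack(2.0, config, noise=NoiseSpec(kind="poisson", seed=5))
        c = simulate_mono_stack(2.0, config, noise=NoiseSpec(kind="poisson", seed=6))
        np.testing.assert_array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)
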