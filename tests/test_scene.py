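"""Phase objects, diffuser statistics and the multi-mode forward model."""

import math

import numpy as np
import pytest

from vortexdiff.optics import BeamSpec, PropagationGeometry, make_gaussian, propagate
from vortexdiff.pipeline import arm_modes
from vortexdiff.scene import (
    AcquisitionStack,
    acquire_stack,
    autocorrelation_width,
    downsample_stack,
    forward_image,
    image_to_phase,
    make_diffuser,
)

PITCH = 10e-6
WL = 632.8e-9


class TestImageToPhase:
    def test_endpoints_and_midpoint(self):
        img = np.array([[0, 128], [255, 64]], dtype=np.uint8)
        pm = image_to_phase(img, PITCH)
        assert pm.phase[0, 0] == 0.0
        assert pm.phase[0, 1] == pytest.approx(math.pi)
        assert pm.phase[1, 0] == pytest.approx(2 * math.pi * 255 / 256)

    def test_monotone_ramp_preserved(self):
        ramp = np.arange(256, dtype=np.uint8).reshape(16, 16)
        pm = image_to_phase(ramp, PITCH)
        assert np.all(np.diff(pm.phase.ravel()) > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            image_to_phase(np.zeros((4, 4, 3)), PITCH)  # not grayscale
        with pytest.raises(ValueError):
            image_to_phase(np.full((4, 4), 300), PITCH)


class TestDiffuser:
    def test_seed_determinism(self):
        a = make_diffuser(25e-6, 2 * math.pi, 64, PITCH, seed=5)
        b = make_diffuser(25e-6, 2 * math.pi, 64, PITCH, seed=5)
        assert np.array_equal(a.phase, b.phase)
        c = make_diffuser(25e-6, 2 * math.pi, 64, PITCH, seed=6)
        assert not np.array_equal(a.phase, c.phase)

    def test_zero_strength_is_transparent_window(self):
        d = make_diffuser(25e-6, 0.0, 64, PITCH, seed=1)
        assert np.all(d.phase == 0.0)

    def test_autocorrelation_width_matches_request(self):
        d = make_diffuser(15e-6, 2 * math.pi, 512, 6.45e-6, seed=2)
        assert autocorrelation_width(d) == pytest.approx(15e-6, rel=0.2)

    def test_unresolvable_correlation_length_rejected(self):
        with pytest.raises(ValueError, match="2 x pitch"):
            make_diffuser(1.5 * PITCH, 1.0, 64, PITCH, seed=0)


class TestForwardModel:
    def test_flat_object_flat_diffuser_is_free_propagation(self, tiny_scene):
        sc = tiny_scene
        beam = BeamSpec(waist_w0=sc.waist_w0, power=sc.power, wavelength=WL)
        obj = image_to_phase(np.zeros((sc.grid_side, sc.grid_side), dtype=np.uint8), sc.pitch)
        flat = make_diffuser(sc.correlation_length, 0.0, sc.grid_side, sc.pitch, seed=0)
        img = forward_image(beam, obj, flat, sc.z_leg)
        ref = make_gaussian(beam, sc.grid_side, sc.pitch)
        ref = propagate(ref, PropagationGeometry(2 * sc.z_leg))
        assert np.allclose(img, ref.intensity() * sc.pitch**2, rtol=1e-6, atol=1e-12 * img.max())

    def test_detected_power_bounded_by_input(self, tiny_scene):
        sc = tiny_scene
        beam = BeamSpec(waist_w0=sc.waist_w0, power=sc.power, wavelength=WL)
        obj = image_to_phase(np.random.default_rng(0).integers(0, 256, (sc.grid_side,) * 2), sc.pitch)
        diff = make_diffuser(sc.correlation_length, 2 * math.pi, sc.grid_side, sc.pitch, seed=3)
        img = forward_image(beam, obj, diff, sc.z_leg)
        assert np.all(img >= 0)
        assert img.sum() <= sc.power * (1 + 1e-6)

    def test_larger_waist_lowers_peak_intensity(self, tiny_scene):
        sc = tiny_scene
        obj = image_to_phase(np.zeros((sc.grid_side,) * 2, dtype=np.uint8), sc.pitch)
        flat = make_diffuser(sc.correlation_length, 0.0, sc.grid_side, sc.pitch, seed=0)
        peaks = []
        for w0 in (sc.waist_w0, 2 * sc.waist_w0):
            beam = BeamSpec(waist_w0=w0, power=sc.power, wavelength=WL)
            peaks.append(forward_image(beam, obj, flat, sc.z_leg).max())
        assert peaks[1] < peaks[0]

    def test_diffuser_strength_monotonically_degrades_image(self, tiny_scene):
        """Stronger phase screens decorrelate the detector image from the
        diffuser-free acquisition (averaged over seeds)."""
        sc = tiny_scene
        beam = BeamSpec(waist_w0=sc.waist_w0, power=sc.power, wavelength=WL)
        img8 = np.random.default_rng(1).integers(0, 256, (sc.grid_side,) * 2)
        obj = image_to_phase(img8, sc.pitch)
        flat = make_diffuser(sc.correlation_length, 0.0, sc.grid_side, sc.pitch, seed=0)
        clean = forward_image(beam, obj, flat, sc.z_leg).ravel()
        mean_corr = []
        for std in (0.5, 1.5, 4.0):
            cs = []
            for seed in range(10):
                d = make_diffuser(sc.correlation_length, std, sc.grid_side, sc.pitch, seed=seed)
                img = forward_image(beam, obj, d, sc.z_leg).ravel()
                cs.append(np.corrcoef(img, clean)[0, 1])
            mean_corr.append(np.mean(cs))
        assert mean_corr[0] > mean_corr[1] > mean_corr[2]


class TestAcquisitionStack:
    def test_stack_shape_and_channel_order(self, tiny_scene, tiny_corpus):
        sc = tiny_scene
        from vortexdiff.digits import upscale_to_object

        obj = upscale_to_object(tiny_corpus[0], sc.grid_side)
        diff = make_diffuser(sc.correlation_length, sc.phase_std, sc.grid_side, sc.pitch, seed=1)
        modes = arm_modes("vortex", sc)
        stack = acquire_stack(modes, obj, diff, sc.z_leg, sc.pitch)
        assert stack.channels.shape == (sc.grid_side, sc.grid_side, 3)
        assert [m.l for m in stack.channel_modes] == [0, 2, 4]
        assert np.all(stack.channels >= 0)
        assert np.array_equal(stack.ground_truth, obj)

    def test_requires_exactly_three_modes(self, tiny_scene):
        sc = tiny_scene
        diff = make_diffuser(sc.correlation_length, sc.phase_std, sc.grid_side, sc.pitch, seed=1)
        modes = arm_modes("vortex", sc)[:2]
        with pytest.raises(ValueError, match="3"):
            acquire_stack(modes, np.zeros((sc.grid_side,) * 2), diff, sc.z_leg, sc.pitch)

    def test_channel1_shared_between_arms(self, tiny_scene, tiny_corpus):
        """The l = 0 LG mode IS the smallest Gaussian: channel 1 coincides."""
        sc = tiny_scene
        from vortexdiff.digits import upscale_to_object

        obj = upscale_to_object(tiny_corpus[3], sc.grid_side)
        diff = make_diffuser(sc.correlation_length, sc.phase_std, sc.grid_side, sc.pitch, seed=1)
        sv = acquire_stack(arm_modes("vortex", sc), obj, diff, sc.z_leg, sc.pitch)
        sg = acquire_stack(arm_modes("gaussian", sc), obj, diff, sc.z_leg, sc.pitch)
        assert np.allclose(sv.channels[..., 0], sg.channels[..., 0])
        assert not np.allclose(sv.channels[..., 1], sg.channels[..., 1])


class TestDownsample:
    def _stack(self, channels):
        modes = [BeamSpec(waist_w0=1e-3)] * 3
        return AcquisitionStack(channels, modes, np.zeros((4, 4)))

    def test_block_mean(self):
        c = np.zeros((4, 4, 3))
        c[0, 1, 0] = 4.0  # block (0,0): values 0,4,0,0 -> mean 1
        out = downsample_stack(self._stack(c)).downsampled
        assert out.shape == (2, 2, 3)
        assert out[0, 0, 0] == 1.0

    def test_constant_preserved_and_sum_quartered(self):
        c = np.full((8, 8, 3), 3.7)
        out = downsample_stack(self._stack(c)).downsampled
        assert np.allclose(out, 3.7)
        r = np.random.default_rng(0).random((8, 8, 3))
        out = downsample_stack(self._stack(r)).downsampled
        assert out.sum() * 4 == pytest.approx(r.sum(), rel=1e-12)

    def test_odd_size_rejected(self):
        modes = [BeamSpec(waist_w0=1e-3)] * 3
        stack = AcquisitionStack(np.zeros((6, 6, 3)), modes, np.zeros((6, 6)))
        stack.channels = np.zeros((5, 5, 3))
        with pytest.raises(ValueError):
            downsample_stack(stack)
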