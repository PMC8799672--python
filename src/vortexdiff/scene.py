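"""Imaging scene: phase objects, random-phase diffuser screens, and the
multi-mode forward model producing 3-channel detector acquisitions.

The forward model is a two-leg split-step chain: the illumination mode picks
up the object's phase, propagates a leg z to the diffuser, picks up the
diffuser's phase, propagates a second leg z to the detector, where intensity
is recorded.  One acquisition per illumination mode fills one channel of the
detector stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .optics import (
    BeamFamily,
    BeamSpec,
    ComplexField,
    PropagationGeometry,
    apply_phase,
    make_gaussian,
    make_lg,
    propagate,
)

__all__ = [
    "PhaseMask",
    "DiffuserScreen",
    "AcquisitionStack",
    "image_to_phase",
    "make_diffuser",
    "autocorrelation_width",
    "forward_image",
    "acquire_stack",
    "downsample_stack",
]

TWO_PI = 2.0 * math.pi


@dataclass
class PhaseMask:
    """Thin phase element: radians wrapped to [0, 2pi) on a square grid."""

    phase: np.ndarray
    pitch: float

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float) % TWO_PI
        if self.phase.ndim != 2 or self.phase.shape[0] != self.phase.shape[1]:
            raise ValueError("phase mask grid must be square")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def side(self) -> int:
        return self.phase.shape[0]


def image_to_phase(image: np.ndarray, pitch: float) -> PhaseMask:
    """Map an 8-bit grayscale image linearly onto object phase in [0, 2pi):
    phase = pixel / 256 * 2pi, so 0 -> 0 rad, 128 -> pi, and 255 -> 2pi*255/256
    (keeping the map injective instead of wrapping 255 back onto 0)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("phase objects must be 2-D grayscale images")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return PhaseMask(image.astype(float) * (TWO_PI / 256.0), pitch)


@dataclass
class DiffuserScreen:
    """Seeded Gaussian-correlated random phase screen standing in for a
    ground-glass diffuser.

    ``phase`` holds the wrapped screen applied to fields; ``phase_raw`` keeps
    the unwrapped Gaussian field (std = phase_std) whose autocorrelation 1/e
    half-width defines ``correlation_length``.
    """

    phase: np.ndarray
    phase_raw: np.ndarray
    correlation_length: float
    phase_std: float
    pitch: float
    seed: int
    grit_label: str = "220"

    @property
    def side(self) -> int:
        return self.phase.shape[0]


def make_diffuser(
    correlation_length: float,
    phase_std: float,
    grid_side: int,
    pitch: float,
    seed: int,
    grit_label: str = "220",
) -> DiffuserScreen:
    """Generate a random phase screen: white Gaussian noise smoothed by a
    Gaussian kernel, rescaled to the requested phase standard deviation and
    wrapped to [0, 2pi).

    The smoothing sigma is correlation_length / 2 so that the screen's
    autocorrelation, itself Gaussian, falls to 1/e at a lag of exactly
    ``correlation_length``.  phase_std = 2pi gives fully developed scattering;
    phase_std = 0 returns a transparent window.  Deterministic under seed.
    """
    if correlation_length < 2.0 * pitch:
        raise ValueError(
            f"correlation_length {correlation_length:.3g} m is below 2 x pitch "
            f"({2*pitch:.3g} m): speckle would be unresolvable on this grid"
        )
    if phase_std < 0:
        raise ValueError("phase_std must be non-negative")
    rng = np.random.default_rng(seed)
    if phase_std == 0.0:
        raw = np.zeros((grid_side, grid_side))
    else:
        white = rng.standard_normal((grid_side, grid_side))
        sigma_px = (correlation_length / 2.0) / pitch
        smooth = gaussian_filter(white, sigma=sigma_px, mode="wrap")
        raw = smooth * (phase_std / smooth.std())
    return DiffuserScreen(
        phase=raw % TWO_PI,
        phase_raw=raw,
        correlation_length=correlation_length,
        phase_std=phase_std,
        pitch=pitch,
        seed=seed,
        grit_label=grit_label,
    )


def autocorrelation_width(screen: DiffuserScreen) -> float:
    """Empirical 1/e half-width (m) of the unwrapped screen's autocorrelation,
    measured along the lag axes via FFT (Wiener-Khinchin)."""
    x = screen.phase_raw - screen.phase_raw.mean()
    spec = np.abs(np.fft.fft2(x)) ** 2
    ac = np.fft.ifft2(spec).real
    ac /= ac[0, 0]
    profile = 0.5 * (ac[0, :] + ac[:, 0])  # average the two lag axes
    half = len(profile) // 2
    profile = profile[:half]
    target = 1.0 / math.e
    below = np.nonzero(profile < target)[0]
    if len(below) == 0:
        raise ValueError("autocorrelation never decays to 1/e on this grid")
    i = below[0]
    # linear interpolation between samples i-1 and i
    f = (profile[i - 1] - target) / (profile[i - 1] - profile[i])
    return (i - 1 + f) * screen.pitch


@dataclass
class AcquisitionStack:
    """3-channel detector intensity stack, one channel per illumination mode,
    paired with its ground-truth object image."""

    channels: np.ndarray  # (H, W, 3), non-negative intensities
    channel_modes: Sequence[BeamSpec]
    ground_truth: np.ndarray
    downsampled: np.ndarray | None = None

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[2] != 3:
            raise ValueError("acquisition stack must be (H, W, 3)")
        if len(self.channel_modes) != 3:
            raise ValueError("exactly 3 channel modes required")
        if np.any(self.channels < 0):
            raise ValueError("intensities must be non-negative")


def _make_beam(spec: BeamSpec, grid_side: int, pitch: float, min_capture: float) -> ComplexField:
    if spec.family is BeamFamily.gaussian:
        return make_gaussian(spec, grid_side, pitch, min_capture)
    return make_lg(spec, grid_side, pitch, min_capture)


def forward_image(
    beam: BeamSpec,
    obj: PhaseMask,
    diffuser: DiffuserScreen,
    z_leg: float,
    min_capture: float = 0.98,
) -> np.ndarray:
    """One-mode acquisition: |P_z[ exp(i P_scat) . P_z[ exp(i A_obj) . U_in ] ]|^2

    where U_in is the illumination mode, A_obj the object phase, P_scat the
    diffuser phase and P_z a free-space leg of length z_leg.  With a flat
    object and flat diffuser this reduces to the freely propagated beam
    intensity."""
    if z_leg <= 0:
        raise ValueError("z_leg must be positive")
    if obj.side != diffuser.side:
        raise ValueError("object and diffuser grids must match")
    geom = PropagationGeometry(z_leg)
    u = _make_beam(beam, obj.side, obj.pitch, min_capture)
    u = apply_phase(u, obj)
    u = propagate(u, geom)
    u = apply_phase(u, diffuser)
    u = propagate(u, geom)
    return u.intensity() * u.pitch**2  # per-pixel power so sums compare to watts


def acquire_stack(
    modes: Sequence[BeamSpec],
    object_image: np.ndarray,
    diffuser: DiffuserScreen,
    z_leg: float,
    pitch: float,
    min_capture: float = 0.98,
) -> AcquisitionStack:
    """Scan the object with the three illumination modes and assemble the
    (H, W, 3) detector stack; channel k holds the scan of modes[k] (l = 0 in
    channel 1, l = 2 in channel 2, l = 4 in channel 3 for the vortex arm)."""
    if len(modes) != 3:
        raise ValueError(f"exactly 3 illumination modes required, got {len(modes)}")
    obj = image_to_phase(object_image, pitch)
    chans = [forward_image(m, obj, diffuser, z_leg, min_capture) for m in modes]
    return AcquisitionStack(
        channels=np.stack(chans, axis=-1),
        channel_modes=list(modes),
        ground_truth=np.asarray(object_image),
    )


def downsample_stack(stack: AcquisitionStack) -> AcquisitionStack:
    """Fill the stack's half-resolution version by averaging 2x2 pixel blocks
    in every channel (the detector-to-network downsampling step); the summed
    intensity is exactly preserved up to the factor 4."""
    h, w, _ = stack.channels.shape
    if h % 2 or w % 2:
        raise ValueError("downsampling requires even image sides")
    c = stack.channels
    down = c.reshape(h // 2, 2, w // 2, 2, 3).mean(axis=(1, 3))
    stack.downsampled = down
    return stack
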