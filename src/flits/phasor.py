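"""Demodulation and phasor analysis of homodyne FD-FLIM phase stacks.

A phase stack is a set of K images of one field of view, acquired at
uniformly spaced detector phase steps theta_k = 2*pi*k/K.  At each pixel
the single-harmonic signal is

    I_k = A * (1 + m * cos(theta_k - phi)) + offset

and demodulation recovers (A, m, phi) by the first-harmonic DFT, which on
a uniform phase grid is the exact least-squares estimator.  Reference
calibration against a fluorophore with a known mono-exponential lifetime
removes the instrument's phase offset and modulation depth, giving
calibrated phasor coordinates

    G = M cos(Phi),   S = M sin(Phi)

from which phase and modulation lifetimes follow as

    tau_phi = tan(Phi) / omega,   tau_mod = sqrt(1/M^2 - 1) / omega.

Mono-exponential decays land on the universal semicircle
(G - 1/2)^2 + S^2 = 1/4; mixtures of two decays land on the chord between
the component phasors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .instrument import InstrumentConfig

__all__ = [
    "PhaseStack",
    "RawPhasorImage",
    "PhasorImage",
    "LifetimeImage",
    "demodulate",
    "reference_calibrate",
    "background_correct",
    "phasor_to_lifetimes",
    "lifetimes_to_phasor",
    "intensity_mask",
    "tau_to_phase_modulation",
]

# validity thresholds for calibrated pixels (configurable per call)
DEFAULT_MAX_MODULATION = 1.05
DEFAULT_MIN_PHASE = -0.05


@dataclass
class PhaseStack:
    """Raw modulated image sequence: axis 0 is the phase-step index."""

    frames: np.ndarray
    config: InstrumentConfig

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D array (phase_step, row, col)")
        if self.frames.shape[0] != self.config.n_phase_steps:
            raise ValueError(
                f"stack has {self.frames.shape[0]} frames but config expects "
                f"{self.config.n_phase_steps} phase steps"
            )
        if np.any(self.frames < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass
class RawPhasorImage:
    """Pre-calibration per-pixel decomposition of a phase stack.

    ``raw_phase`` follows the convention that a frame set
    A*(1 + m*cos(theta_k - phi)) demodulates to raw_phase = phi; the
    complex fundamental is then ``ac_amplitude * exp(-1j * raw_phase)``.
    """

    dc: np.ndarray
    ac_amplitude: np.ndarray
    raw_phase: np.ndarray
    config: InstrumentConfig

    @property
    def fundamental(self) -> np.ndarray:
        """Complex first-harmonic coefficient c = (2/K) sum_k I_k e^{-i theta_k}."""
        return self.ac_amplitude * np.exp(-1j * self.raw_phase)

    @classmethod
    def from_fundamental(cls, dc, c, config) -> "RawPhasorImage":
        return cls(dc=np.asarray(dc, dtype=float), ac_amplitude=np.abs(c),
                   raw_phase=-np.angle(c), config=config)


@dataclass
class PhasorImage:
    """Calibrated per-pixel phasor coordinates plus steady-state intensity."""

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    valid_mask: np.ndarray
    config: InstrumentConfig

    def mean_phasor(self, extra_mask=None) -> tuple[float, float]:
        """Mean (G, S) over valid pixels, optionally intersected with a mask."""
        m = self.valid_mask if extra_mask is None else (self.valid_mask & extra_mask)
        if not np.any(m):
            raise ValueError("no valid pixels to average")
        return float(np.mean(self.g[m])), float(np.mean(self.s[m]))


@dataclass
class LifetimeImage:
    """Per-pixel phase and modulation lifetimes (ns); NaN on invalid pixels."""

    tau_phi: np.ndarray
    tau_mod: np.ndarray
    intensity: np.ndarray
    valid_mask: np.ndarray
    config: InstrumentConfig


def tau_to_phase_modulation(tau_phi_ns, tau_mod_ns, omega_per_ns: float):
    """Forward single-decay relations Phi = atan(w*tau_phi), M = 1/sqrt(1+(w*tau_mod)^2)."""
    phi = np.arctan(omega_per_ns * np.asarray(tau_phi_ns, dtype=float))
    mod = 1.0 / np.sqrt(1.0 + (omega_per_ns * np.asarray(tau_mod_ns, dtype=float)) ** 2)
    return phi, mod


def demodulate(stack: PhaseStack) -> RawPhasorImage:
    """First-harmonic DFT demodulation of a phase stack.

    Per pixel: dc = mean_k I_k, complex fundamental
    c = (2/K) sum_k I_k exp(-i theta_k), ac_amplitude = |c| and
    raw_phase = -arg(c), so a noise-free sinusoid
    A*(1 + m*cos(theta_k - phi)) returns (A, A*m, phi) exactly.
    """
    theta = stack.config.phase_steps
    frames = stack.frames
    k = frames.shape[0]
    dc = frames.mean(axis=0)
    c = (2.0 / k) * np.tensordot(np.exp(-1j * theta), frames, axes=([0], [0]))
    return RawPhasorImage(dc=dc, ac_amplitude=np.abs(c), raw_phase=-np.angle(c),
                          config=stack.config)


def _trimmed_mean(values: np.ndarray, trim: float = 0.05) -> float:
    """Mean with ``trim`` of each tail removed; robust to dead/hot pixels."""
    return float(stats.trim_mean(values.ravel(), proportiontocut=trim))


def reference_calibrate(
    sample: RawPhasorImage,
    reference: RawPhasorImage,
    tau_ref_ns: float | None = None,
    max_modulation: float = DEFAULT_MAX_MODULATION,
    min_phase: float = DEFAULT_MIN_PHASE,
) -> PhasorImage:
    """Calibrate a demodulated sample against a reference fluorophore stack.

    The reference has a known mono-exponential lifetime ``tau_ref_ns``
    (default: the config's reference lifetime).  The instrument phase
    offset and modulation depth are estimated from the spatial trimmed
    mean (5% per tail) of the reference image and divided/subtracted out:

        Phi = raw_phase - (mean raw_phase_ref - atan(w tau_ref))
        M   = (ac/dc) / (mean (ac/dc)_ref / M(tau_ref))

    Pixels with dc <= 0, ac = 0, M > ``max_modulation`` or
    Phi outside [``min_phase``, pi/2] are flagged invalid (NaN).
    """
    if sample.config != reference.config:
        raise ValueError("sample and reference stacks have different instrument configs")
    if tau_ref_ns is None:
        tau_ref_ns = sample.config.reference_lifetime_ns
    omega = sample.config.omega_per_ns

    ref_ok = reference.dc > 0
    if not np.any(ref_ok):
        raise ValueError("reference image has no positive-intensity pixels")
    ref_moddepth = _trimmed_mean(reference.ac_amplitude[ref_ok] / reference.dc[ref_ok])
    if ref_moddepth <= 0:
        raise ValueError("reference stack has zero modulation")
    ref_phase = _trimmed_mean(reference.raw_phase[ref_ok])

    phi_true, mod_true = tau_to_phase_modulation(tau_ref_ns, tau_ref_ns, omega)
    instrument_phase = ref_phase - phi_true
    instrument_mod = ref_moddepth / mod_true

    with np.errstate(divide="ignore", invalid="ignore"):
        moddepth = np.where(sample.dc > 0, sample.ac_amplitude / sample.dc, np.nan)
    phi = sample.raw_phase - instrument_phase
    mod = moddepth / instrument_mod

    valid = (
        (sample.dc > 0)
        & (sample.ac_amplitude > 0)
        & (mod <= max_modulation)
        & (phi >= min_phase)
        & (phi <= math.pi / 2)
    )
    g = np.where(valid, mod * np.cos(phi), np.nan)
    s = np.where(valid, mod * np.sin(phi), np.nan)
    return PhasorImage(g=g, s=s, intensity=sample.dc.copy(), valid_mask=valid,
                       config=sample.config)


def background_correct(sample: RawPhasorImage, background_mask: np.ndarray) -> RawPhasorImage:
    """Subtract a background region's contribution before normalisation.

    The mean DC level and mean complex fundamental over the (manually
    indicated) background region are subtracted pixel-wise.  Subtraction
    happens on the linear (dc, complex-fundamental) decomposition, where
    the DFT is additive; pixels driven to dc <= 0 are flagged invalid by
    the subsequent calibration step.
    """
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != sample.dc.shape:
        raise ValueError("background mask shape does not match image")
    if not np.any(background_mask):
        raise ValueError("background mask selects no pixels")
    bg_dc = float(sample.dc[background_mask].mean())
    bg_c = complex(sample.fundamental[background_mask].mean())
    return RawPhasorImage.from_fundamental(
        dc=sample.dc - bg_dc, c=sample.fundamental - bg_c, config=sample.config
    )


def phasor_to_lifetimes(ph: PhasorImage) -> LifetimeImage:
    """Convert calibrated phasors to phase and modulation lifetime images.

    A pixel with M > 1 or Phi < 0 has no physical single-decay solution
    and is flagged invalid rather than raising (noise routinely pushes
    background pixels outside the physical region).
    """
    omega = ph.config.omega_per_ns
    phi = np.arctan2(ph.s, ph.g)
    mod = np.hypot(ph.g, ph.s)
    ok = ph.valid_mask & (phi >= 0) & (phi < math.pi / 2) & (mod > 0) & (mod <= 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau_phi = np.where(ok, np.tan(phi) / omega, np.nan)
        tau_mod = np.where(ok, np.sqrt(np.maximum(1.0 / mod**2 - 1.0, 0.0)) / omega, np.nan)
    return LifetimeImage(tau_phi=tau_phi, tau_mod=tau_mod, intensity=ph.intensity,
                         valid_mask=ok, config=ph.config)


def lifetimes_to_phasor(tau_phi_ns, tau_mod_ns, frequency_mhz: float):
    """Phasor coordinates (G, S) of given phase/modulation lifetimes."""
    if frequency_mhz <= 0:
        raise ValueError("frequency must be positive")
    omega = 2.0 * math.pi * frequency_mhz * 1e-3
    phi, mod = tau_to_phase_modulation(tau_phi_ns, tau_mod_ns, omega)
    return mod * np.cos(phi), mod * np.sin(phi)


def intensity_mask(intensity: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of pixels with intensity strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    return np.asarray(intensity) > threshold
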