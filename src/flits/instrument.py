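"""Instrument description and noise plumbing for homodyne FD-FLIM.

A frequency-domain FLIM acquisition records K images of the same field,
one per detector phase step, while excitation and detector gain are both
modulated at a common radio frequency.  Everything downstream (demodulation,
reference calibration, phasor math) only needs the modulation frequency,
the phase-step grid and the combined modulation depth, which live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["InstrumentConfig", "NoiseSpec"]


@dataclass(frozen=True)
class InstrumentConfig:
    """Homodyne FD-FLIM acquisition parameters.

    Parameters
    ----------
    frequency_mhz : float
        Modulation frequency in MHz.  The default, 75.1 MHz, is a typical
        image-intensifier setup frequency for cyan fluorescent proteins.
    n_phase_steps : int
        Number K of uniformly spaced detector phase steps per stack
        (theta_k = 2*pi*k/K).  K >= 3 is required to separate DC, cosine
        and sine components of the single-harmonic signal.
    excitation_modulation_depth, detection_modulation_depth : float
        Modulation depths of the source and the detector gain, each in
        (0, 1].  Only their product enters the forward model and it is
        removed exactly by reference calibration.
    reference_name : str
        Label of the reference fluorophore used for calibration.
    reference_lifetime_ns : float
        Known mono-exponential lifetime of the reference, in ns
        (Alexa488: 4.05 ns; Erythrosin B: 0.086 ns).
    """

    frequency_mhz: float = 75.1
    n_phase_steps: int = 12
    excitation_modulation_depth: float = 1.0
    detection_modulation_depth: float = 0.9
    reference_name: str = "Alexa488"
    reference_lifetime_ns: float = 4.05

    def __post_init__(self) -> None:
        if self.frequency_mhz <= 0:
            raise ValueError("modulation frequency must be positive")
        if self.n_phase_steps < 3:
            raise ValueError("need at least 3 phase steps (K >= 3)")
        for depth in (self.excitation_modulation_depth, self.detection_modulation_depth):
            if not 0.0 < depth <= 1.0:
                raise ValueError("modulation depths must lie in (0, 1]")
        if self.reference_lifetime_ns <= 0:
            raise ValueError("reference lifetime must be positive")

    @property
    def omega_per_ns(self) -> float:
        """Angular modulation frequency in rad/ns (derived, never stored)."""
        return 2.0 * math.pi * self.frequency_mhz * 1e-3

    @property
    def phase_steps(self) -> np.ndarray:
        """Detector phase grid theta_k = 2*pi*k/K, k = 0..K-1."""
        return 2.0 * math.pi * np.arange(self.n_phase_steps) / self.n_phase_steps

    @property
    def modulation_product(self) -> float:
        """Combined instrument modulation depth m_ex * m_det."""
        return self.excitation_modulation_depth * self.detection_modulation_depth


@dataclass(frozen=True)
class NoiseSpec:
    """Noise applied to synthetic data.

    ``kind`` is one of ``"none"`` (bit-reproducible output, seed ignored),
    ``"poisson"`` (shot noise on counts) or ``"gaussian"`` (additive,
    standard deviation ``gaussian_sd`` in the units of the quantity it is
    applied to: counts for image stacks, response units for tables).
    """

    kind: str = "none"
    gaussian_sd: float = 0.0
    seed: int = 0

    _KINDS = ("none", "poisson", "gaussian")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {self._KINDS}")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, mean: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Draw noisy values around ``mean`` according to the spec.

        Poisson noise clips negative means to zero (a negative expected
        count is not physical and only arises for pathological offsets).
        """
        mean = np.asarray(mean, dtype=float)
        if self.kind == "none":
            return mean.copy()
        if rng is None:
            rng = self.rng()
        if self.kind == "poisson":
            return rng.poisson(np.clip(mean, 0.0, None)).astype(float)
        return mean + rng.normal(0.0, self.gaussian_sd, size=mean.shape)
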