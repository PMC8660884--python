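"""Two-state phasor unmixing and conversion to absolute calcium concentration.

The core inference of the pipeline: a calibrated phasor of a pixel that
contains a mixture of the calcium-free and calcium-bound sensor states
lies on the straight chord between the two state phasors ("anchors").
Orthogonal projection onto that chord gives the line fraction

    a = (dG*dG_max + dS*dS_max) / (dG_max^2 + dS_max^2),
    dG = G - G_min, dS = S - S_min

which is the *intensity* fraction of the bound state.  Correcting for the
two states' brightness ratio R gives the molecular bound fraction

    F = a / (R * (1 - a) + a)

and the in situ Hill calibration converts F (or a directly, using the
a-parameterised calibration) into the free-calcium concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .hill import HillParams
from .phasor import (
    PhaseStack,
    PhasorImage,
    background_correct,
    demodulate,
    intensity_mask,
    reference_calibrate,
)

__all__ = [
    "TwoStateAnchors",
    "SessionCorrection",
    "ConcentrationMap",
    "line_fraction",
    "fraction_bound",
    "line_fraction_from_F",
    "estimate_session_correction",
    "apply_session_correction",
    "concentration_from_fraction",
    "quantify_stack",
    "roi_trace",
]

# F is clamped into [CLAMP_EPS, 1 - CLAMP_EPS] before Hill inversion;
# clamped pixels are excluded from the in-range mask.
CLAMP_EPS = 1e-4


@dataclass(frozen=True)
class TwoStateAnchors:
    """Apo and saturated phasor endpoints plus the brightness ratio R.

    The modulation frequency is stored so calibrations cannot be mixed
    across frequencies.
    """

    g_min: float
    s_min: float
    g_max: float
    s_max: float
    intensity_ratio_R: float
    frequency_mhz: float

    def __post_init__(self) -> None:
        if self.chord_length_sq == 0:
            raise ValueError("anchors coincide: chord is undefined")
        if self.intensity_ratio_R <= 0:
            raise ValueError("intensity ratio R must be positive")
        if self.frequency_mhz <= 0:
            raise ValueError("frequency must be positive")

    @property
    def chord_length_sq(self) -> float:
        return (self.g_max - self.g_min) ** 2 + (self.s_max - self.s_min) ** 2

    @classmethod
    def from_model(cls, model, config) -> "TwoStateAnchors":
        """Anchors implied by a ground-truth sensor model at a config's frequency."""
        from .phasor import lifetimes_to_phasor

        g0, s0 = lifetimes_to_phasor(model.tau_phi_apo, model.tau_mod_apo, config.frequency_mhz)
        g1, s1 = lifetimes_to_phasor(model.tau_phi_sat, model.tau_mod_sat, config.frequency_mhz)
        return cls(g_min=float(g0), s_min=float(s0), g_max=float(g1), s_max=float(s1),
                   intensity_ratio_R=model.intensity_ratio_R,
                   frequency_mhz=config.frequency_mhz)

    def to_dict(self) -> dict:
        return {
            "g_min": self.g_min, "s_min": self.s_min,
            "g_max": self.g_max, "s_max": self.s_max,
            "intensity_ratio_R": self.intensity_ratio_R,
            "frequency_mhz": self.frequency_mhz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoStateAnchors":
        return cls(**d)


@dataclass(frozen=True)
class SessionCorrection:
    """Daily-variance correction: additive in phase, divisive in modulation."""

    phase_offset: float = 0.0
    modulation_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.modulation_factor <= 0:
            raise ValueError("modulation factor must be positive")

    @property
    def is_identity(self) -> bool:
        return self.phase_offset == 0.0 and self.modulation_factor == 1.0


@dataclass
class ConcentrationMap:
    """Per-pixel calcium concentration with intermediate quantities."""

    ca_nM: np.ndarray
    fraction_bound: np.ndarray
    line_fraction: np.ndarray
    intensity: np.ndarray
    valid_mask: np.ndarray
    in_range_mask: np.ndarray


def line_fraction(g, s, anchors: TwoStateAnchors):
    """Project phasor(s) onto the apo->saturated chord.

    Returns the projection coefficient a (0 at the apo anchor, 1 at the
    saturated anchor).  Off-chord points project orthogonally; values
    outside [0, 1] are returned as-is so callers can flag them.
    """
    dg = np.asarray(g, dtype=float) - anchors.g_min
    ds = np.asarray(s, dtype=float) - anchors.s_min
    dg_max = anchors.g_max - anchors.g_min
    ds_max = anchors.s_max - anchors.s_min
    return (dg * dg_max + ds * ds_max) / anchors.chord_length_sq


def fraction_bound(a, r_ratio: float):
    """Molecular bound fraction F from intensity line fraction a."""
    if r_ratio <= 0:
        raise ValueError("intensity ratio R must be positive")
    a = np.asarray(a, dtype=float)
    return a / (r_ratio * (1.0 - a) + a)


def line_fraction_from_F(f, r_ratio: float):
    """Inverse of :func:`fraction_bound`: a = R*F / (1 + (R-1)*F)."""
    if r_ratio <= 0:
        raise ValueError("intensity ratio R must be positive")
    f = np.asarray(f, dtype=float)
    return r_ratio * f / (1.0 + (r_ratio - 1.0) * f)


def _polar(g, s):
    return np.arctan2(s, g), np.hypot(g, s)


def estimate_session_correction(control, anchors: TwoStateAnchors) -> SessionCorrection:
    """Estimate the daily-variance correction from a saturated-state control.

    ``control`` is either a (g, s) pair or a :class:`PhasorImage` of a
    field driven to the calcium-saturated state (e.g. ionomycin plus
    calcium); for an image the valid-pixel mean phasor is used.  The
    correction forces the control onto the calibration's saturated anchor:
    phase offset = Phi_control - Phi_anchor, modulation factor =
    M_control / M_anchor.
    """
    if isinstance(control, PhasorImage):
        g_c, s_c = control.mean_phasor()
    else:
        g_c, s_c = float(control[0]), float(control[1])
    phi_c, mod_c = _polar(g_c, s_c)
    if mod_c <= 0:
        raise ValueError("control phasor has nonpositive modulation")
    phi_a, mod_a = _polar(anchors.g_max, anchors.s_max)
    return SessionCorrection(phase_offset=float(phi_c - phi_a),
                             modulation_factor=float(mod_c / mod_a))


def apply_session_correction(phasor, correction: SessionCorrection):
    """Apply a session correction to a phasor image or (g, s) pair.

    Subtracts the phase offset from each pixel's Phi and divides each
    pixel's M by the modulation factor.
    """
    if isinstance(phasor, PhasorImage):
        phi, mod = _polar(phasor.g, phasor.s)
        phi = phi - correction.phase_offset
        mod = mod / correction.modulation_factor
        return replace(phasor, g=mod * np.cos(phi), s=mod * np.sin(phi))
    g, s = phasor
    phi, mod = _polar(np.asarray(g, float), np.asarray(s, float))
    phi = phi - correction.phase_offset
    mod = mod / correction.modulation_factor
    return mod * np.cos(phi), mod * np.sin(phi)


def concentration_from_fraction(
    x,
    calibration: HillParams,
    mode: str = "F",
    clamp: bool = True,
    clamp_eps: float = CLAMP_EPS,
):
    """Invert the Hill calibration to a free-calcium concentration (nM).

    ``x`` is the corrected bound fraction (mode "F") or the raw line
    fraction (mode "a"); the calibration must be parameterised on the
    matching quantity.  Values outside (fmin, fmax) carry no concentration
    information; with ``clamp=True`` (default) they are clamped to
    fmin/fmax plus/minus ``clamp_eps`` of the span and excluded from the
    returned in-range mask, with ``clamp=False`` they become NaN.

    Returns ``(ca_nM, in_range_mask)``.
    """
    if mode not in ("F", "a"):
        raise ValueError("mode must be 'F' or 'a'")
    if calibration.fmax <= calibration.fmin:
        raise ValueError("calibration must have fmax > fmin")
    x = np.asarray(x, dtype=float)
    span = calibration.fmax - calibration.fmin
    lo = calibration.fmin + clamp_eps * span
    hi = calibration.fmax - clamp_eps * span
    in_range = (x > lo) & (x < hi)
    if clamp:
        x_used = np.clip(x, lo, hi)
    else:
        x_used = np.where(in_range, x, np.nan)
    ca = calibration.inverse(x_used)
    return ca, in_range & np.isfinite(ca)


def quantify_stack(
    sample: PhaseStack,
    reference: PhaseStack,
    anchors: TwoStateAnchors,
    calibration: HillParams,
    mode: str = "F",
    session_correction: SessionCorrection | None = None,
    session_control=None,
    background_mask: np.ndarray | None = None,
    intensity_threshold: float | None = None,
    tau_ref_ns: float | None = None,
) -> ConcentrationMap:
    """Full pipeline from a raw phase stack to a calcium concentration map.

    Composes demodulation, optional background correction, reference
    calibration, optional session correction, chord projection, intensity
    correction and Hill inversion.  ``session_control`` may be a control
    :class:`PhaseStack` of the saturated state (processed identically to
    the sample) from which the session correction is estimated; an explicit
    ``session_correction`` takes precedence.

    Raises ``ValueError`` if the anchors' frequency does not match the
    stack's instrument config.
    """
    if sample.config != reference.config:
        raise ValueError("quantify: sample and reference configs differ")
    if not math.isclose(anchors.frequency_mhz, sample.config.frequency_mhz):
        raise ValueError(
            "quantify: anchors were derived at "
            f"{anchors.frequency_mhz} MHz but the stack was recorded at "
            f"{sample.config.frequency_mhz} MHz"
        )

    raw = demodulate(sample)
    raw_ref = demodulate(reference)
    if background_mask is not None:
        raw = background_correct(raw, background_mask)
    ph = reference_calibrate(raw, raw_ref, tau_ref_ns=tau_ref_ns)

    if session_correction is None and session_control is not None:
        ctrl_ph = reference_calibrate(demodulate(session_control), raw_ref,
                                      tau_ref_ns=tau_ref_ns)
        session_correction = estimate_session_correction(ctrl_ph, anchors)
    if session_correction is not None and not session_correction.is_identity:
        ph = apply_session_correction(ph, session_correction)

    valid = ph.valid_mask.copy()
    if intensity_threshold is not None:
        valid &= intensity_mask(ph.intensity, intensity_threshold)

    a = line_fraction(ph.g, ph.s, anchors)
    f = fraction_bound(np.clip(a, 0.0, 1.0), anchors.intensity_ratio_R)
    x = f if mode == "F" else np.clip(a, 0.0, 1.0)
    ca, in_range = concentration_from_fraction(x, calibration, mode=mode)
    ca = np.where(valid, ca, np.nan)
    return ConcentrationMap(
        ca_nM=ca, fraction_bound=np.where(valid, f, np.nan),
        line_fraction=np.where(valid, a, np.nan), intensity=ph.intensity,
        valid_mask=valid, in_range_mask=in_range & valid,
    )


def roi_trace(
    maps: list[ConcentrationMap],
    roi_labels: np.ndarray,
    timestamps_s=None,
    n_baseline_frames: int = 3,
) -> pd.DataFrame:
    """Per-ROI time traces of concentration, intensity and fold-change.

    ``roi_labels`` is a label image (0 = outside any ROI).  For each ROI
    and timepoint the mean concentration and mean intensity over valid
    pixels are reported, plus the intensity fold-change F/F0 where F0 is
    the ROI's mean intensity over the first ``n_baseline_frames`` frames.

    Returns a DataFrame (time_s, roi_id, ca_nM, intensity, fold_change).
    If no ROI contains any valid pixel in any frame the trace is empty and
    flagged via ``df.attrs["empty"] = True``.
    """
    roi_labels = np.asarray(roi_labels)
    roi_ids = [int(r) for r in np.unique(roi_labels) if r != 0]
    if not roi_ids:
        raise ValueError("roi_trace: label image contains no ROI")
    if timestamps_s is None:
        timestamps_s = np.arange(len(maps), dtype=float)
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    if timestamps_s.size != len(maps):
        raise ValueError("one timestamp per map is required")

    rows = []
    for roi in roi_ids:
        sel = roi_labels == roi
        ca_t, int_t = [], []
        for cmap in maps:
            ok = sel & cmap.valid_mask
            ca_t.append(float(np.nanmean(cmap.ca_nM[ok])) if np.any(ok) else np.nan)
            int_t.append(float(np.mean(cmap.intensity[ok])) if np.any(ok) else np.nan)
        int_t = np.asarray(int_t)
        head = int_t[: min(n_baseline_frames, len(int_t))]
        baseline = np.nan if np.all(np.isnan(head)) else np.nanmean(head)
        fold = int_t / baseline if baseline and np.isfinite(baseline) else np.full_like(int_t, np.nan)
        for t, ca, inten, fc in zip(timestamps_s, ca_t, int_t, fold):
            rows.append({"time_s": t, "roi_id": roi, "ca_nM": ca,
                         "intensity": inten, "fold_change": fc})
    df = pd.DataFrame(rows, columns=["time_s", "roi_id", "ca_nM", "intensity", "fold_change"])
    df = df.dropna(subset=["ca_nM", "intensity"], how="all").reset_index(drop=True)
    df.attrs["empty"] = df.empty
    return df
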