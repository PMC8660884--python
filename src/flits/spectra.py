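"""Relative quantum yield and extinction-coefficient math.

Relative quantum yield (QY) is determined from a dilution series: the
integrated emission I_em of each dilution is proportional to its
absorbance at the excitation wavelength (A440), and the through-origin
slope s of I_em versus A440 compares directly between a sample and a
reference fluorophore measured under identical settings:

    QY_sample = QY_reference * s_sample / s_reference

The extinction coefficient at 440 nm follows from alkali denaturation:
NaOH converts the folded chromophore into a free species with a known
extinction of 46 mM^-1 cm^-1 at 462 nm, so the Beer-Lambert chromophore
concentration drops out and

    eps440 = 46 * A440_native / A462_denatured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectralRecord",
    "QYResult",
    "quantum_yield",
    "through_origin_slope",
    "extinction_coefficient",
]

#: Accepted absorbance window for QY-eligible dilutions (inner-filter-safe).
A440_WINDOW = (0.002, 0.02)

#: Free denatured cyan chromophore extinction at 462 nm (mM^-1 cm^-1).
EPS_DENATURED_462 = 46.0


@dataclass(frozen=True)
class SpectralRecord:
    """One dilution's absorbance and emission spectra with derived scalars.

    ``a440`` is the offset-corrected absorbance at 440 nm (the offset is
    the mean absorbance over 631-650 nm, a region with no chromophore
    absorption); ``i_em`` is the emission integrated 450-650 nm by the
    trapezoid rule on the native wavelength grid.
    """

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    emission_wavelength_nm: np.ndarray
    emission: np.ndarray
    a440: float
    i_em: float

    @classmethod
    def from_raw(
        cls,
        wavelength_nm,
        absorbance,
        emission_wavelength_nm,
        emission,
        detector_correction=None,
    ) -> "SpectralRecord":
        """Build a record from raw spectra, applying the standard corrections.

        ``detector_correction``: optional per-wavelength sensitivity curve
        (callable on the emission grid) by which the emission is divided;
        identity when omitted.
        """
        wl = np.asarray(wavelength_nm, dtype=float)
        ab = np.asarray(absorbance, dtype=float)
        ewl = np.asarray(emission_wavelength_nm, dtype=float)
        em = np.asarray(emission, dtype=float)
        if wl.shape != ab.shape or ewl.shape != em.shape:
            raise ValueError("wavelength and spectrum arrays must match in shape")
        if detector_correction is not None:
            em = em / np.asarray(detector_correction(ewl), dtype=float)

        tail = (wl >= 631.0) & (wl <= 650.0)
        offset = float(ab[tail].mean()) if np.any(tail) else 0.0
        ab = ab - offset
        a440 = float(np.interp(440.0, wl, ab))
        band = (ewl >= 450.0) & (ewl <= 650.0)
        if band.sum() < 2:
            raise ValueError("emission grid does not cover the 450-650 nm band")
        i_em = float(np.trapezoid(em[band], ewl[band]))
        return cls(wavelength_nm=wl, absorbance=ab, emission_wavelength_nm=ewl,
                   emission=em, a440=a440, i_em=i_em)


def through_origin_slope(x, y) -> float:
    """Least-squares slope of y on x with the line forced through the origin.

    Closed form sum(x*y) / sum(x^2); raises on a rank-deficient design
    (all x identical gives a fit indistinguishable from a free offset).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 and x.size > 1:
        raise ValueError("rank-deficient design: all abscissae identical")
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValueError("cannot fit a slope through all-zero abscissae")
    return float(np.sum(x * y) / denom)


@dataclass(frozen=True)
class QYResult:
    """Relative quantum yield with the two underlying slopes."""

    qy: float
    slope_sample: float
    slope_reference: float
    qy_reference: float

    def summary(self) -> str:
        return (
            "Relative quantum yield\n"
            f"  reference QY : {self.qy_reference:.3g}\n"
            f"  slope sample : {self.slope_sample:.6g}\n"
            f"  slope ref    : {self.slope_reference:.6g}\n"
            f"  QY           : {self.qy:.4g}"
        )


def quantum_yield(
    sample_records: list[SpectralRecord],
    reference_records: list[SpectralRecord],
    qy_reference: float = 0.93,
    enforce_window: bool = True,
) -> QYResult:
    """Relative QY from matched sample and reference dilution series.

    Each series needs >= 3 records spanning distinct A440 values inside
    the accepted window.  The slope of integrated emission on A440 is
    fitted through the origin per series and the QY is the reference QY
    scaled by the slope ratio.
    """
    for name, records in (("sample", sample_records), ("reference", reference_records)):
        if len(records) < 3:
            raise ValueError(f"{name} series needs at least 3 records")
        if enforce_window:
            lo, hi = A440_WINDOW
            bad = [r.a440 for r in records if not lo < r.a440 < hi]
            if bad:
                raise ValueError(
                    f"{name} series has records outside the A440 window "
                    f"({lo}, {hi}): {bad}"
                )
    s_s = through_origin_slope([r.a440 for r in sample_records],
                               [r.i_em for r in sample_records])
    s_r = through_origin_slope([r.a440 for r in reference_records],
                               [r.i_em for r in reference_records])
    return QYResult(qy=qy_reference * s_s / s_r, slope_sample=s_s,
                    slope_reference=s_r, qy_reference=qy_reference)


def extinction_coefficient(
    a440_native: float,
    a462_denatured: float,
    eps_denatured: float = EPS_DENATURED_462,
    path_cm: float = 1.0,
) -> float:
    """Extinction coefficient at 440 nm via alkali denaturation (mM^-1 cm^-1).

    The chromophore concentration from the denatured spectrum is
    c = A462 / (eps_denatured * path); the native extinction is then
    A440_native / (c * path), so the path length cancels.
    """
    if a462_denatured <= 0:
        raise ValueError("denatured absorbance must be positive")
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    return eps_denatured * a440_native / a462_denatured
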