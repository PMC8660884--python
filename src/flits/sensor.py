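"""Ground-truth description of a two-state lifetime calcium biosensor.

A :class:`SensorModel` packages everything the synthetic-data generators
need about a sensor: the phase and modulation lifetimes of the calcium-free
(apo) and calcium-bound (saturated) conformations, the bound/unbound
brightness ratio R, the Hill binding curve that maps free calcium to
molecular occupancy F, the pH response models of both states, and the
spectroscopic constants (quantum yields, extinction coefficients, band
positions).

Two presets are packaged for the turquoise lifetime sensor characterised
in this package's documentation:

``"in_situ"``
    Parameters measured in permeabilised cells: R = 3.02 (from the
    intensity fold-change on saturation), Kd = 265 nM, n = 1.63.
``"in_vitro"``
    Parameters measured on purified protein: R = 3.51 (intensity ratio at
    pH 7.0), Kd = 372 nM for the lifetime/phasor readout, and a separate
    intensity-mode titration curve with Kd = 360 nM, n = 1.51.

Both presets share the state lifetimes (apo 1.40/1.80 ns, saturated
2.78/3.01 ns phase/modulation at 75.1 MHz), the pH models (apo one-site
pKa 4.36 [n 0.86]; saturated two-site pKa 4.71 [0.70] and 5.91 [3.58]),
quantum yields 0.25/0.75 and extinction coefficients 30.6/33.7 mM^-1 cm^-1
at 440 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .hill import HillParams
from .ph import OneSitePH, TwoSitePH

__all__ = ["SensorModel", "default_sensor_model", "REFERENCE_QY_MTURQUOISE2", "PRESETS"]

#: Quantum yield of the mTurquoise2 reference fluorophore.
REFERENCE_QY_MTURQUOISE2 = 0.93


@dataclass(frozen=True)
class SensorModel:
    """Ground-truth parameter set of a two-state lifetime sensor.

    Lifetimes are in ns, concentrations in nM, extinction coefficients in
    mM^-1 cm^-1.  ``binding`` maps free calcium to the molecular bound
    fraction F (so its fmin/fmax are pinned to 0/1); ``intensity_binding``,
    when present, is the empirical Hill curve of the *intensity* titration,
    which real sensors may report with a slightly different apparent Kd.
    """

    name: str
    tau_phi_apo: float
    tau_mod_apo: float
    tau_phi_sat: float
    tau_mod_sat: float
    intensity_ratio_R: float
    binding: HillParams
    ph_model_apo: OneSitePH
    ph_model_sat: TwoSitePH
    qy_apo: float
    qy_sat: float
    eps440_apo: float
    eps440_sat: float
    intensity_binding: HillParams | None = None
    lambda_abs_apo_nm: float = 442.0
    lambda_em_apo_nm: float = 489.0
    lambda_abs_sat_nm: float = 439.0
    lambda_em_sat_nm: float = 481.0

    def __post_init__(self) -> None:
        for tau in (self.tau_phi_apo, self.tau_mod_apo, self.tau_phi_sat, self.tau_mod_sat):
            if tau <= 0:
                raise ValueError("all lifetimes must be positive")
        if self.intensity_ratio_R <= 0:
            raise ValueError("intensity ratio R must be positive")
        if not (self.binding.fmin == 0.0 and self.binding.fmax == 1.0):
            raise ValueError("binding curve must map occupancy F with fmin=0, fmax=1")
        for qy in (self.qy_apo, self.qy_sat):
            if not 0.0 < qy <= 1.0:
                raise ValueError("quantum yields must lie in (0, 1]")

    def fraction_bound_at(self, free_ca_nM) -> "float":
        """Molecular occupancy F at a free-calcium concentration (nM)."""
        return self.binding(free_ca_nM)

    def relative_intensity(self, fraction_bound) -> "float":
        """Total brightness relative to the pure apo state: (1-F) + R*F."""
        return (1.0 - fraction_bound) + self.intensity_ratio_R * fraction_bound

    def titration_curve(self) -> HillParams:
        """Hill curve of the intensity titration.

        Returns ``intensity_binding`` when the preset carries a separate
        empirical intensity calibration, otherwise the curve implied by
        the binding model and R (fmin = 1, fmax = R, same Kd and n).
        """
        if self.intensity_binding is not None:
            return self.intensity_binding
        return HillParams(fmin=1.0, fmax=self.intensity_ratio_R,
                          kd=self.binding.kd, n=self.binding.n)


def _shared_kwargs() -> dict:
    return dict(
        tau_phi_apo=1.40, tau_mod_apo=1.80,
        tau_phi_sat=2.78, tau_mod_sat=3.01,
        ph_model_apo=OneSitePH(fmin=0.0, fmax=1.0, pka=4.36, n=0.86),
        ph_model_sat=TwoSitePH(fmin=0.0, fmed=1.4, fmax=3.51,
                               pka1=4.71, n1=0.70, pka2=5.91, n2=3.58),
        qy_apo=0.25, qy_sat=0.75,
        eps440_apo=30.6, eps440_sat=33.7,
    )


PRESETS = ("in_situ", "in_vitro")


def default_sensor_model(preset: str = "in_situ") -> SensorModel:
    """Packaged ground-truth sensor model.

    Parameters
    ----------
    preset : {"in_situ", "in_vitro"}
        Which calibration context the binding parameters come from (see
        module docstring).

    Raises
    ------
    ValueError
        If the preset name is unknown.
    """
    if preset == "in_situ":
        return SensorModel(
            name="Tq-Ca-FLITS (in situ)",
            intensity_ratio_R=3.02,
            binding=HillParams(fmin=0.0, fmax=1.0, kd=265.0, n=1.63),
            **_shared_kwargs(),
        )
    if preset == "in_vitro":
        return SensorModel(
            name="Tq-Ca-FLITS (in vitro)",
            intensity_ratio_R=3.51,
            binding=HillParams(fmin=0.0, fmax=1.0, kd=372.0, n=1.51),
            intensity_binding=HillParams(fmin=1.0, fmax=3.51, kd=360.0, n=1.51),
            **_shared_kwargs(),
        )
    raise ValueError(f"unknown sensor preset {preset!r}; expected one of {PRESETS}")
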