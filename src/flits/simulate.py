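"""Synthetic-data generators for every input the analysis pipeline consumes.

The generators produce homodyne phase stacks, in situ calibration time
series, plate-reader titration and pH tables, dilution-series spectra and
screening plate records from a ground-truth :class:`~flits.sensor.SensorModel`,
so that every downstream stage has a known-answer test surface.

Forward model of a phase stack (single harmonic, K uniform phase steps):

    I_k = A * (1 + m_ex*m_det * |r| * cos(theta_k - arg r)) + offset

where r is the complex response: M(tau) e^{i Phi(tau)} for a single decay,
or the intensity-weighted sum of the two state responses for a mixture.
With noise kind ``"none"`` all outputs are bit-reproducible; with a seed,
stochastic outputs are reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import CalibrationDataset
from .hill import HillParams
from .instrument import InstrumentConfig, NoiseSpec
from .phasor import PhaseStack, tau_to_phase_modulation
from .plates import PlateRecord
from .sensor import REFERENCE_QY_MTURQUOISE2, SensorModel
from .spectra import SpectralRecord

__all__ = [
    "simulate_mono_stack",
    "simulate_reference_stack",
    "simulate_two_state_stack",
    "two_state_response",
    "equilibrium_phasor",
    "simulate_calibration_experiment",
    "simulate_titration_table",
    "simulate_ph_series",
    "simulate_spectra_set",
    "simulate_reference_spectra",
    "simulate_mg_table",
    "simulate_plate_record",
]

_NO_NOISE = NoiseSpec()


def simulate_mono_stack(
    tau_ns: float,
    config: InstrumentConfig,
    shape: tuple[int, int] = (64, 64),
    amplitude: float = 1000.0,
    offset_background: float = 0.0,
    noise: NoiseSpec = _NO_NOISE,
) -> PhaseStack:
    """Phase stack of a uniform field with a single mono-exponential decay.

    The same ``tau_ns`` drives both the phase shift and the demodulation,
    as it must for a mono-exponential emitter.  ``amplitude`` is the mean
    DC count level, ``offset_background`` an unmodulated additive floor.
    """
    if tau_ns < 0:
        raise ValueError("lifetime must be nonnegative")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    omega = config.omega_per_ns
    phi, mod = tau_to_phase_modulation(tau_ns, tau_ns, omega)
    theta = config.phase_steps
    profile = 1.0 + config.modulation_product * mod * np.cos(theta - phi)
    mean = amplitude * profile[:, None, None] * np.ones((1, *shape)) + offset_background
    frames = np.clip(noise.apply(mean), 0.0, None)
    return PhaseStack(frames=frames, config=config)


def simulate_reference_stack(
    config: InstrumentConfig,
    shape: tuple[int, int] = (64, 64),
    amplitude: float = 1000.0,
    noise: NoiseSpec = _NO_NOISE,
) -> PhaseStack:
    """Stack of the configured reference fluorophore (default Alexa488, 4.05 ns)."""
    return simulate_mono_stack(config.reference_lifetime_ns, config, shape=shape,
                               amplitude=amplitude, noise=noise)


def _resolve_fraction(model: SensorModel, free_ca_nM, fraction_bound) -> float:
    if (free_ca_nM is None) == (fraction_bound is None):
        raise ValueError("supply exactly one of free_ca_nM or fraction_bound")
    if fraction_bound is None:
        if free_ca_nM < 0:
            raise ValueError("free calcium concentration must be nonnegative")
        fraction_bound = float(model.fraction_bound_at(free_ca_nM))
    f = float(fraction_bound)
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction bound must lie in [0, 1]")
    return f


def two_state_response(model: SensorModel, config: InstrumentConfig, fraction_bound: float):
    """Complex fundamental response of a two-state mixture.

    The phasor of a mixture is the *intensity*-weighted sum of the state
    phasors: with occupancy F and brightness ratio R, the bound state's
    intensity weight is a = R*F / (1 + (R-1)*F), and

        r = a * M_sat e^{i Phi_sat} + (1 - a) * M_apo e^{i Phi_apo}.

    Returns ``(r, a, relative_intensity)`` where relative intensity is
    (1-F) + R*F, the total brightness relative to the pure apo state.
    """
    omega = config.omega_per_ns
    phi_apo, mod_apo = tau_to_phase_modulation(model.tau_phi_apo, model.tau_mod_apo, omega)
    phi_sat, mod_sat = tau_to_phase_modulation(model.tau_phi_sat, model.tau_mod_sat, omega)
    r_ratio = model.intensity_ratio_R
    a = r_ratio * fraction_bound / (1.0 + (r_ratio - 1.0) * fraction_bound)
    r = a * mod_sat * np.exp(1j * phi_sat) + (1.0 - a) * mod_apo * np.exp(1j * phi_apo)
    return r, a, model.relative_intensity(fraction_bound)


def equilibrium_phasor(
    model: SensorModel,
    config: InstrumentConfig,
    free_ca_nM: float | None = None,
    fraction_bound: float | None = None,
) -> tuple[float, float, float]:
    """Exact calibrated (G, S) and relative intensity of an equilibrium mixture."""
    f = _resolve_fraction(model, free_ca_nM, fraction_bound)
    r, _, rel = two_state_response(model, config, f)
    return float(r.real), float(r.imag), float(rel)


def simulate_two_state_stack(
    model: SensorModel,
    config: InstrumentConfig,
    free_ca_nM: float | None = None,
    fraction_bound: float | None = None,
    shape: tuple[int, int] = (64, 64),
    amplitude: float = 1000.0,
    offset_background: float = 0.0,
    noise: NoiseSpec = _NO_NOISE,
) -> PhaseStack:
    """Phase stack of a uniform field of sensor at a given calcium level.

    Exactly one of ``free_ca_nM`` / ``fraction_bound`` must be given.
    ``amplitude`` is the DC count level of the pure apo state; the total
    brightness scales as (1-F) + R*F.
    """
    f = _resolve_fraction(model, free_ca_nM, fraction_bound)
    r, _, rel = two_state_response(model, config, f)
    theta = config.phase_steps
    profile = 1.0 + config.modulation_product * np.abs(r) * np.cos(theta - np.angle(r))
    mean = amplitude * rel * profile[:, None, None] * np.ones((1, *shape)) + offset_background
    frames = np.clip(noise.apply(mean), 0.0, None)
    return PhaseStack(frames=frames, config=config)


# ----------------------------------------------------------------------
# calibration experiment


def default_concentration_ladder() -> np.ndarray:
    """0 plus 10 log-spaced free-calcium concentrations, 17 nM to 39 uM.

    Emulates an 11-step EGTA-buffered calcium ladder spanning zero to a
    saturating concentration.
    """
    return np.concatenate([[0.0], np.geomspace(17.0, 39_000.0, 10)])


def simulate_calibration_experiment(
    concentrations_nM=None,
    model: SensorModel | None = None,
    config: InstrumentConfig | None = None,
    replicates: int = 1,
    frames_per_conc: int = 40,
    frame_interval_s: float = 20.0,
    digitonin_frame_index: int = 3,
    equilibration_rate_per_s: float = 0.02,
    resting_ca_nM: float = 100.0,
    amplitude: float = 1000.0,
    noise: NoiseSpec = _NO_NOISE,
) -> CalibrationDataset:
    """In situ calibration time series: one view per buffer concentration.

    Each series holds the view-average calibrated phasor every
    ``frame_interval_s`` seconds.  Before the digitonin frame the view
    sits at the resting phasor (``resting_ca_nM``); afterwards it relaxes
    single-exponentially (rate ``equilibration_rate_per_s``) to the
    equilibrium two-state phasor of the buffer concentration, emulating
    membrane permeabilisation and calcium equilibration.  Gaussian noise
    is applied to the phasor coordinates (sd in phasor units) and Poisson
    noise to the intensity channel.
    """
    if model is None:
        raise ValueError("a sensor model is required")
    if config is None:
        config = InstrumentConfig()
    if concentrations_nM is None:
        concentrations_nM = default_concentration_ladder()
    concentrations_nM = np.asarray(concentrations_nM, dtype=float)
    if concentrations_nM.size < 2:
        raise ValueError("need at least 2 concentrations (a floor and a saturating one)")
    if digitonin_frame_index >= frames_per_conc:
        raise ValueError("digitonin frame must fall inside the series")

    g_rest, s_rest, rel_rest = equilibrium_phasor(model, config, free_ca_nM=resting_ca_nM)
    times = np.arange(frames_per_conc) * frame_interval_s
    t_dig = digitonin_frame_index * frame_interval_s
    rng = noise.rng()

    rows = []
    for conc in concentrations_nM:
        g_eq, s_eq, rel_eq = equilibrium_phasor(model, config, free_ca_nM=conc)
        for rep in range(replicates):
            dt = np.clip(times - t_dig, 0.0, None)
            if np.isinf(equilibration_rate_per_s):
                decay = np.where(times < t_dig, 1.0, 0.0)
            else:
                decay = np.where(times < t_dig, 1.0, np.exp(-equilibration_rate_per_s * dt))
            g = g_eq + (g_rest - g_eq) * decay
            s = s_eq + (s_rest - s_eq) * decay
            inten = amplitude * (rel_eq + (rel_rest - rel_eq) * decay)
            if noise.kind == "gaussian":
                g = g + rng.normal(0.0, noise.gaussian_sd, size=g.shape)
                s = s + rng.normal(0.0, noise.gaussian_sd, size=s.shape)
            elif noise.kind == "poisson":
                inten = rng.poisson(np.clip(inten, 0.0, None)).astype(float)
            rows.append(pd.DataFrame({
                "conc_nM": conc, "replicate": rep, "time_s": times,
                "g": g, "s": s, "intensity": inten, "digitonin_time_s": t_dig,
            }))
    df = pd.concat(rows, ignore_index=True)
    return CalibrationDataset(df=df, frequency_mhz=config.frequency_mhz,
                              frame_interval_s=frame_interval_s)


# ----------------------------------------------------------------------
# plate tables


def simulate_titration_table(
    model: SensorModel,
    concentrations_nM=None,
    replicates: int = 3,
    noise: NoiseSpec = _NO_NOISE,
    scale: float = 1000.0,
) -> pd.DataFrame:
    """Intensity titration table (columns conc_nM, replicate, intensity).

    Intensities follow the model's intensity-mode Hill curve times an
    arbitrary plate scale; zero concentration maps exactly to fmin.
    """
    if concentrations_nM is None:
        concentrations_nM = default_concentration_ladder()
    conc = np.asarray(concentrations_nM, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    curve = model.titration_curve()
    rng = noise.rng()
    rows = []
    for rep in range(replicates):
        intensity = noise.apply(scale * curve(conc), rng)
        rows.append(pd.DataFrame({"conc_nM": conc, "replicate": rep, "intensity": intensity}))
    return pd.concat(rows, ignore_index=True)


def _state_attr(model: SensorModel, state: str, apo, sat):
    if state == "apo":
        return apo
    if state == "sat":
        return sat
    raise ValueError(f"unknown state {state!r}; expected 'apo' or 'sat'")


def simulate_ph_series(
    state: str,
    model: SensorModel,
    ph_values=None,
    replicates: int = 3,
    noise: NoiseSpec = _NO_NOISE,
    scale: float = 1.0,
) -> pd.DataFrame:
    """pH response table (columns pH, replicate, intensity) for one state."""
    if ph_values is None:
        ph_values = np.linspace(2.8, 10.0, 20)
    ph_values = np.asarray(ph_values, dtype=float)
    if np.any((ph_values < 2.0) | (ph_values > 11.0)):
        raise ValueError("pH values must lie within 2-11")
    ph_model = _state_attr(model, state, model.ph_model_apo, model.ph_model_sat)
    rng = noise.rng()
    rows = []
    for rep in range(replicates):
        intensity = noise.apply(scale * ph_model(ph_values), rng)
        rows.append(pd.DataFrame({"pH": ph_values, "replicate": rep, "intensity": intensity}))
    return pd.concat(rows, ignore_index=True)


# ----------------------------------------------------------------------
# spectra

_ABS_GRID = np.arange(380.0, 651.0)
_EM_GRID = np.arange(450.0, 651.0)


def _make_record(lambda_abs, lambda_em, a440_target, slope, rng, noise) -> SpectralRecord:
    abs_shape = np.exp(-((_ABS_GRID - lambda_abs) ** 2) / (2.0 * 28.0**2))
    absorbance = a440_target / np.exp(-((440.0 - lambda_abs) ** 2) / (2.0 * 28.0**2)) * abs_shape
    absorbance = absorbance + 0.0015  # flat baseline, removed by offset correction
    em_shape = np.exp(-((_EM_GRID - lambda_em) ** 2) / (2.0 * 18.0**2))
    em_shape = em_shape / np.trapezoid(em_shape, _EM_GRID)
    emission = slope * a440_target * em_shape
    emission = noise.apply(emission, rng)
    return SpectralRecord.from_raw(_ABS_GRID, absorbance, _EM_GRID, emission)


def simulate_spectra_set(
    state: str,
    model: SensorModel,
    n_dilutions: int = 3,
    replicates: int = 3,
    noise: NoiseSpec = _NO_NOISE,
    emission_per_absorbance: float = 5.0e4,
) -> list[SpectralRecord]:
    """Dilution-series spectra of one sensor state for relative-QY work.

    Absorbance peaks are placed so A440 spans 0.004-0.016 (inside the
    accepted 0.002 < A440 < 0.02 window) and integrated emission is
    proportional to A440 with slope
    ``emission_per_absorbance * QY_state / QY_mTurquoise2``.
    """
    qy = _state_attr(model, state, model.qy_apo, model.qy_sat)
    lam_abs = _state_attr(model, state, model.lambda_abs_apo_nm, model.lambda_abs_sat_nm)
    lam_em = _state_attr(model, state, model.lambda_em_apo_nm, model.lambda_em_sat_nm)
    slope = emission_per_absorbance * qy / REFERENCE_QY_MTURQUOISE2
    targets = np.geomspace(0.004, 0.016, n_dilutions)
    rng = noise.rng()
    return [
        _make_record(lam_abs, lam_em, a440, slope, rng, noise)
        for a440 in targets
        for _ in range(replicates)
    ]


def simulate_reference_spectra(
    n_dilutions: int = 3,
    replicates: int = 3,
    noise: NoiseSpec = _NO_NOISE,
    emission_per_absorbance: float = 5.0e4,
) -> list[SpectralRecord]:
    """Matching mTurquoise2 reference dilution series (QY 0.93)."""
    targets = np.geomspace(0.004, 0.016, n_dilutions)
    rng = noise.rng()
    return [
        _make_record(434.0, 474.0, a440, emission_per_absorbance, rng, noise)
        for a440 in targets
        for _ in range(replicates)
    ]


# ----------------------------------------------------------------------
# magnesium and screening plates


def simulate_mg_table(
    mg_levels_mM=(0.0, 0.9, 1.8, 3.7, 9.3, 18.7),
    intensity_ratio_R: float = 3.51,
    replicates: int = 3,
    free_state_mg_response=None,
    noise: NoiseSpec = _NO_NOISE,
    scale: float = 1000.0,
) -> pd.DataFrame:
    """Paired bound/free intensities across a free-magnesium ladder.

    By default the free-state brightness is magnesium independent (as for
    a Mg-insensitive sensor, giving a flat dynamic-range curve).  Passing
    ``free_state_mg_response`` (a callable mg_mM -> relative brightness)
    emulates a Mg-sensitive sensor whose free state brightens at low
    magnesium, depressing the ratio there.
    """
    mg = np.asarray(mg_levels_mM, dtype=float)
    free_rel = np.ones_like(mg) if free_state_mg_response is None else \
        np.asarray(free_state_mg_response(mg), dtype=float)
    rng = noise.rng()
    rows = []
    for rep in range(replicates):
        free = noise.apply(scale * free_rel, rng)
        bound = noise.apply(scale * intensity_ratio_R * np.ones_like(mg), rng)
        rows.append(pd.DataFrame({"mg_mM": mg, "replicate": rep,
                                  "state": "free", "intensity": free}))
        rows.append(pd.DataFrame({"mg_mM": mg, "replicate": rep,
                                  "state": "bound", "intensity": bound}))
    return pd.concat(rows, ignore_index=True)


def simulate_plate_record(
    model: SensorModel,
    well_id: str = "A1",
    n_reads: int = 8,
    addition_read: int = 3,
    background: float = 50.0,
    eb_reference: float = 20_000.0,
    signal_scale: float = 2000.0,
    noise: NoiseSpec = _NO_NOISE,
) -> PlateRecord:
    """Screening-well intensity series for a responsive sensor.

    The well starts calcium free and is saturated at ``addition_read``
    (e.g. CaCl2 added to periplasmic extract), so the background- and
    EB-normalised fold-change approaches the sensor's intensity ratio R.
    """
    series = np.full(n_reads, background + signal_scale)
    series[addition_read:] = background + signal_scale * model.intensity_ratio_R
    series = noise.apply(series)
    return PlateRecord(well_id=well_id, raw=series, eb_reference=eb_reference,
                       background=background)
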