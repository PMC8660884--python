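# flits

Frequency-domain FLIM phasor analysis and calibration for two-state
fluorescence-lifetime biosensors.

## The problem

Genetically encoded calcium indicators with an intensity readout are hard
to quantify: intensity depends on probe concentration, bleaching, cell
shape and instrument. A sensor whose calcium-bound and calcium-free
conformations have *different fluorescence lifetimes* sidesteps all of
that — lifetime is an absolute, instrument-independent parameter. On a
frequency-domain FLIM microscope each pixel yields a phasor

    G = M cos(Φ),  S = M sin(Φ),   Φ = atan(ω τ_φ),  M = 1/√(1 + (ω τ_M)²)

and a pixel containing a mixture of the two sensor states falls on the
straight chord between the pure-state phasors. Projecting onto that chord
gives the line fraction *a* (the bound state's *intensity* fraction),
which the brightness ratio *R* converts into the molecular bound fraction

    F = a / (R(1 − a) + a)

and a Hill calibration F(L) = L^n / (K_d^n + L^n) converts into the
absolute free-calcium concentration. `flits` implements this pipeline end
to end — homodyne demodulation, reference calibration against a
fluorophore of known mono-exponential lifetime, background and
session-drift correction, chord projection, concentration maps and ROI
traces — together with the sensor-characterisation math around it:
Hill fits of titrations, one- and two-site Henderson–Hasselbalch pH
models, relative quantum yield from dilution-series spectra, extinction
coefficients via alkali denaturation, and screening-plate normalisation.

A synthetic-data module (`flits.simulate`) generates every input the
pipeline consumes — phase stacks, calibration time series, titration, pH
and magnesium tables, spectra, plate records — from a packaged
ground-truth sensor model, so each stage has a known-answer test surface
without any experimental data.

## Worked example

Simulate an in situ calibration of the packaged turquoise sensor model,
fit it, then quantify an image of cells at 80 nM free calcium:

```python
import numpy as np
from flits import InstrumentConfig, calibrate_in_situ, quantify_stack
from flits.quantify import TwoStateAnchors
from flits.sensor import default_sensor_model
from flits.simulate import (
    simulate_calibration_experiment, simulate_reference_stack,
    simulate_two_state_stack,
)

model = default_sensor_model("in_situ")
config = InstrumentConfig()          # 75.1 MHz, 12 phase steps, Alexa488 ref

dataset = simulate_calibration_experiment(model=model)
result = calibrate_in_situ(dataset, r_ratio=model.intensity_ratio_R)
print(result.summary())

stack = simulate_two_state_stack(model, config, free_ca_nM=80.0)
ref = simulate_reference_stack(config)
cmap = quantify_stack(stack, ref, result.anchors, result.hill_on_F)
print(f"mean [Ca2+] = {np.nanmean(cmap.ca_nM):.1f} nM")
```

prints

```
In situ calibration
  intensity ratio R : 3.02
  apo anchor        : (0.6359, 0.4201)
  saturated anchor  : (0.3491, 0.4578)
  Kd (on F)         : 265 nM  [n = 1.63]
  Kd (on a)         : 134.5 nM  [n = 1.63]
mean [Ca2+] = 80.0 nM
```

The apo/saturated anchors are the phasors of the calcium-free and
calcium-bound states (phase/modulation lifetimes 1.40/1.80 ns and
2.78/3.01 ns at 75.1 MHz); the fit on the corrected bound fraction F
recovers the ground-truth K_d of 265 nM with Hill coefficient 1.63, and
the fit on the raw line fraction *a* has the same coefficient with its
midpoint shifted by R^(−1/n) — either form converts pixels to
concentrations, and the 80 nM image round-trips exactly.

The same objects are available from a shell: `flits simulate ...`,
`flits calibrate`, `flits lifetimes`, `flits quantify`, `flits qy`,
`flits fit-ph` — see `flits --help`.

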