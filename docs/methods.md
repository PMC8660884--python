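# Methods

## Forward model of homodyne FD-FLIM

A frequency-domain FLIM acquisition is modelled as single-harmonic
homodyne detection: the excitation and the detector gain are modulated at
a common angular frequency ω = 2πf (default f = 75.1 MHz) and K images
are recorded at uniform detector phase steps θ_k = 2πk/K (default
K = 12). The per-pixel frame means are

    I_k = A · (1 + m_ex m_det · |r| · cos(θ_k − arg r)) + offset

where r is the complex fundamental response of the emitter. For a
mono-exponential decay of lifetime τ, r = M e^{iΦ} with Φ = atan(ωτ) and
M = 1/√(1+(ωτ)²); for a two-state sensor mixture r is the
intensity-weighted sum of the state responses (below). The model carries
no optical PSF, photobleaching, multi-frequency content or
camera-specific artifacts; noise is optional Poisson shot noise on frame
counts (or additive Gaussian for plate-reader tables).

K and the modulation frequency of an intensifier-based setup are
acquisition settings rather than sensor properties; the defaults (12
steps, 75.1 MHz, combined modulation depth m_ex·m_det = 0.9) are typical
for image-intensifier instruments and are configurable. The combined
modulation depth is removed exactly by reference calibration, so its
value never reaches calibrated results (this is tested).

## Demodulation and calibration

Demodulation uses the first-harmonic DFT: dc = mean_k I_k and
c = (2/K) Σ_k I_k e^{−iθ_k}. On a uniform phase grid this equals the
linear least-squares fit of a + b cosθ + c sinθ at every pixel (tested
against that oracle) and is exact for a single harmonic at any K ≥ 3.

Reference calibration estimates the instrument phase offset and
modulation depth from a stack of a fluorophore with known
mono-exponential lifetime (defaults: Alexa488, 4.05 ns; Erythrosin B,
0.086 ns, selectable). The spatial statistic is a 5%-per-tail trimmed
mean, robust to dead or hot pixels. Background correction subtracts a
manually indicated region's mean dc and mean complex fundamental from
every pixel *before* normalisation — on the linear decomposition the DFT
is additive, so a spatially uniform background is removed exactly;
whether commercial FLIM packages subtract before or after normalisation
is not documented, and this choice is recorded here as the package's
interpretation.

Pixels with dc ≤ 0, zero AC amplitude, M > 1.05 or Φ outside
[−0.05, π/2] are flagged invalid and propagated as NaN rather than
raising; the thresholds are arguments of `reference_calibrate`.

## Two-state unmixing and concentration conversion

With occupancy F and bound/unbound brightness ratio R, the bound state
contributes the intensity fraction a = RF/(1+(R−1)F), so a mixture's
phasor is p = a·p_sat + (1−a)·p_apo and all mixtures lie on the
apo–saturated chord. The analysis inverts this: orthogonal projection
onto the chord gives a, the R-correction gives F, and the Hill
calibration's inverse gives the concentration. Algebraically the map
free-Ca → a is itself a Hill curve with the same coefficient n and
midpoint K_d·R^(−1/n), which is why the a-parameterised calibration
(no R correction at quantification time) gives identical concentrations;
both identities are tested.

Fractions outside (0, 1) carry no concentration information (the paperless
detection logic: beyond-anchor phasors arise from noise). The default
policy clamps the fraction to fmin/fmax ± 10⁻⁴ of the span, excludes the
pixel from the in-range mask, and never raises on images; clamping can be
disabled to get NaN instead.

Session (daily-variance) correction forces the measured saturated-state
control onto the calibration's saturated anchor: the phase offset is
added, the modulation factor divided, estimated from the control's
valid-pixel mean phasor (not per pixel, which would destroy the signal).

ROI traces report per-ROI mean concentration and intensity per timepoint
plus the intensity fold-change F/F₀ with F₀ the mean of the first three
frames (configurable).

## Hill fits

Every titration-shaped response is fitted with
f(L) = fmin + (fmax−fmin)/((K_d/L)^n + 1), evaluated as f(0) = fmin at
zero ligand (the (K_d/L)^n form is singular there). The fit is bounded
trust-region least squares; initialisation uses K_d⁰ = geometric mean of
the positive concentrations, n⁰ = 1 and the data extremes for
fmin⁰/fmax⁰; bounds are K_d ∈ [min positive L/100, max L·100] and
n ∈ [0.1, 10]. Noise-free synthetic data are recovered to at least six
significant digits, and the fit is invariant to concentration-unit
rescaling up to the units of K_d. Standard errors come from the
Gauss–Newton covariance at the solution.

## In situ calibration

Each buffer concentration's time series is averaged over the window
t ≥ digitonin time + 6 min (the transient after permeabilisation decays
below 0.1% by then at the packaged equilibration rate). Anchors are the
replicate-mean equilibrium phasors at the extreme concentrations; a
total-least-squares chord fit was considered and rejected as the default
because the extremes are exactly the physically meaningful endpoints when
the ladder spans zero to saturation.

The detection range uses the replicate spread of F at the extremes:
the 95% band is the Student-t quantile at n−1 degrees of freedom times
the *sample standard deviation* (a tolerance-band reading, not a
standard-error band — the band describes where a single future
measurement is distinguishable from the extreme, which is the quantity
that limits per-pixel detection). F_low = mean₀ + band, F_high =
mean_sat − band, both mapped through the Hill inverse. Zero-variance
(noise-free) replicates collapse the range onto the clamp limits and are
flagged degenerate rather than reported as a real range.

## pH models

One-site: f = fmin + (fmax−fmin)/(1+10^{n(pKa−pH)}); two-site adds a
second transition with an intermediate plateau fmed and ordering
constraint pKa₁ < pKa₂. The two-site fit multi-starts over 20
deterministic (pKa₁, pKa₂) grid pairs to avoid label switching and local
minima; fmin may go negative, mirroring the common fit restriction when
the acid baseline is indistinguishable from background.

The sensor's intensity dynamic range as a function of pH is the ratio of
the saturated-state model over the apo-state model. For the packaged
parameter set this ratio is ≈3.5 at pH 7 and deviates <5% from its mean
over pH 6.3–9.0; at exactly pH 6.2 the steep second transition
(pKa₂ = 5.91, n₂ = 3.58) is still ~8% below its plateau, so "insensitive
above pH 6.2" holds from the next measured buffer step onwards, not at
the boundary itself.

## Spectroscopy

Relative quantum yield: per dilution record, the absorbance spectrum is
offset-corrected by subtracting its 631–650 nm mean, A440 is read off,
and the emission is integrated 450–650 nm by the trapezoid rule on the
native grid (an optional user-supplied detector sensitivity curve divides
the emission first; identity by default). The through-origin slope
s = ΣA·I/ΣA² of integrated emission on A440 is computed per series and
QY = QY_ref · s_sample/s_ref with mTurquoise2 (QY 0.93) as reference.
Records must have 0.002 < A440 < 0.02 (inner-filter-safe window).

Extinction coefficient: alkali denaturation converts the chromophore to a
free species with ε(462 nm) = 46 mM⁻¹cm⁻¹, so
ε440 = 46 · A440_native / A462_denatured; the path length cancels.

Plate screening: well series are normalised as (I − background)/I_EB
(Erythrosin B bridge well) and the fold-change is max/first-read;
duplicate wells are averaged after normalisation. Magnesium sensitivity
is the per-level ratio mean(bound)/mean(free) with the SD propagated from
the per-state sample SDs.

## The synthetic-data generator

The generator is first-class, tested code and defines the study
conditions:

* packaged sensor model: apo/sat phase lifetimes 1.40/2.78 ns, modulation
  lifetimes 1.80/3.01 ns; binding K_d = 265 nM (n = 1.63, R = 3.02) for
  the in situ preset and K_d = 372 nM (lifetime mode) with a separate
  intensity titration curve (K_d = 360 nM, n = 1.51, fmax/fmin = 3.51)
  for the in vitro preset. The in vitro lifetime-mode Hill coefficient is
  not separately characterised and reuses the intensity value 1.51.
* pH models: apo one-site (pKa 4.36, n 0.86); saturated two-site
  (4.71 [0.70], 5.91 [3.58]) with plateau levels fmin 0 / fmed 1.4 /
  fmax 3.51 chosen (they are not independently characterised) so the
  sat/apo ratio is ~3.5 and stable above pH 6.2.
* quantum yields 0.25/0.75; extinction 30.6/33.7 mM⁻¹cm⁻¹ at 440 nm;
  absorbance/emission bands 442/489 nm (apo) and 439/481 nm (sat),
  Gaussian shapes (widths 28/18 nm) — band *positions and areas* are what
  the QY math consumes; real vibronic structure is not emulated.
* calibration ladder: 0 plus 10 log-spaced concentrations from 17 nM to
  39 µM (an 11-step ladder spanning zero to saturation; the exact
  commercial buffer-kit steps are not published, so the ladder is a
  documented choice). Frames every 20 s, digitonin at frame 3, resting
  level 100 nM, single-exponential equilibration at 0.02 s⁻¹.

What passing tests show — and do not show — about real data: the
generator produces exactly the single-harmonic, two-state,
spatially uniform world the estimators assume, so the recovery tests
validate the *math* (estimators, projections, fits, inversions) and the
pipeline's composition, not robustness to autofluorescence, multi-
exponential backgrounds, detector nonlinearity, motion or segmentation
error. Poisson-noise tests bound statistical, not systematic, error.

## Problem sizes and numerics

Image tests use 64×64 stacks (4×4 to 24×24 where many replicates are
needed); stochastic suites use 100–200 seeded replicates; these sizes
make the whole suite run in well under a minute while leaving the
recovery criteria far from their tolerances. All optimisers run with
tight tolerances (1e−14) so noise-free recoveries are limited by machine
precision, not stopping rules. Noise kind "none" bypasses the RNG
entirely, making noise-free outputs bit-identical across runs and seeds.

## Known limitations

* Single modulation frequency and first harmonic only; no TCSPC,
  multi-frequency global fitting or multi-harmonic phasors.
* Two states exactly; three-component mixtures are outside the chord
  model and will silently project onto it.
* No automatic segmentation or cell tracking; ROIs are supplied as label
  images.
* The detection-range convention (t·SD band) is one of several defensible
  readings of a "95% CI" on replicate extremes; it is isolated in
  `detection_range` and easy to swap.
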