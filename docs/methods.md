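# Methods

`plimox` implements the analysis chain of a dual-channel retinal imaging
experiment: phosphorescence-lifetime scanning-laser ophthalmoscopy (PLIM-SLO)
for absolute intravascular oxygen tension, and a minimal visible-light
spectral-domain OCT (VIS-OCT) reconstruction path. Because the measurements
the chain was designed for come from live animals, every stage is exercised
on synthetic inputs whose ground truth is known exactly; the generators are
first-class, tested code.

## Phosphorescence decay model and fitting

Each raster pixel records a 10 µs pulsed-excitation plateau followed by a
phosphorescence decay captured for the remainder of a 200 µs dwell. The decay
model, measured from pulse end, is

    I(t) = I0 · exp(−k t) + offset,

fitted by unweighted nonlinear least squares (trust-region reflective,
`scipy.optimize.curve_fit`) over the post-pulse samples. The free offset
absorbs the PMT baseline and, in simultaneous mode, the CW steady-state term,
so the rate estimate is insensitive to either. The initializer is a
log-linear regression on baseline-subtracted samples, with the baseline taken
as the mean of the last 5 % of the window; a trace whose baseline-subtracted
values are non-positive in more than half the window is declared unfittable
(no decay). Failures propagate as NaN/no-data, never as zero rates.

Numerical choices:

- **Guard interval** (default 2 µs after pulse end): the instrument response
  around the pulse edge is not modelled, so the first samples after the pulse
  are excluded from fits. Configurable.
- **Rate bounds** k ∈ (0, f_s/2]: a decay faster than half the sampling rate
  is not resolvable at that digitizer setting.
- **Intensity floor** in map fitting (default 2× the median per-pixel tail
  baseline): pixels with essentially no phosphorescence are skipped rather
  than fitted to noise.
- The per-pixel maps apply a 3×3 moving average to the traces *before*
  fitting; edge pixels use the shrunken neighbourhood (no padding), which
  preserves constants at the border instead of biasing edges toward zero.

The independent oracle for the fitter (used only in tests) is a brute-force
grid search over k in which the amplitude and offset are solved exactly by
linear least squares per candidate rate — same objective, no shared code.

## Oxygen calibration

Lifetime converts to oxygen tension through the probe's published
Stern-Volmer-like calibration

    pO2(τ, T) = (P10 + β·T)·τ^p − (P20 + γ·T),

with p = −1.265777, P10 = 3.06907×10⁻⁴ mmHg·s^−p,
β = −4.6205×10⁻⁶ mmHg·s^−p·°C⁻¹, P20 = 114.4061 mmHg,
γ = −1.60147 mmHg·°C⁻¹. The form is analytically invertible; the trace
simulator uses the inverse to inject a decay rate for a chosen ground-truth
pO2, which makes forward/inverse consistency (mutual inverses to 1×10⁻¹⁰
relative over pO2 ∈ [0, 160] mmHg, T ∈ [30, 40] °C) a structural requirement
rather than a nicety. Negative computed pO2 — possible under noise for
near-anoxic blood — is flagged with a warning but not clipped; clipping is
offered only at map export. Temperature is a per-acquisition scalar (body
temperature is servo-controlled to ~36.7 °C in the experiment this models).

Note that at 36.7 °C the calibration's zero-oxygen lifetime is ≈37.1 µs,
i.e. the slowest physiological rate is ≈26.9×10³ s⁻¹; rates below that are
outside the invertible physiological range at that temperature.

## Synthetic phantom and depth sectioning

The phantom emulates a ~0.5 mm field about the optic nerve head: two major
superficial arterioles, a central deeper venule, and a capillary bed at
depth, each vessel a constant-radius tube along a polyline with a class,
depth, and a ground-truth pO2 drawn from per-class ranges (defaults:
arterioles 60–90 mmHg, venules 20–45 mmHg, capillaries 35–60 mmHg; arteriole
and venule ranges are disjoint so the class ordering is guaranteed).
Capillaries are smooth random walks from an arteriole point to a venule
point, placed deep (40–70 µm) like the deep capillary plexus.

Depth sectioning — the tunable-lens focal scan plus collection pinhole — is
reduced to a single-parameter Gaussian weight
w(z) = exp(−(z − z_f)²/2σ²), σ default 15 µm. The real axial response is
aberration-dominated and unquantified, so any parametric form is a stand-in;
the Gaussian keeps one interpretable knob and the right qualitative
behaviour (vessels fade symmetrically as the focus moves off their plexus).
Where tubes overlap, the vessel nearest the focal plane owns the pixel so
each pixel has one truth value; real images instead see a haze of the
out-of-focus vessel.

## Trace simulation

Noiseless decays follow I_C·exp(−(k + k_OCT)t) + I_SS + I_PMT with
I_C = gain × sectioning weight. During simultaneous imaging the CW OCT beam
pumps the probe continuously; its steady-state emission is modelled as
I_SS = I_C·k_OCT/(k + k_OCT) × scale, the standard CW triplet steady state
with the scale configurable. Nothing downstream depends on this form because
the fit's offset is free. Default noise is Gaussian with variance
a + b·mean (a = 1×10⁻⁵, b = 2×10⁻⁴ on a unit-amplitude signal), a shot-like
model matched to a photon-rich PMT signal; a scaled-Poisson-plus-readout
option exists. The digitizer rate is not a measured quantity here; the
5 MHz default gives 1000 samples per dwell, ≥10 per lifetime at the fastest
physiological decays. With/without-CW pairs share one standard-normal noise
stream so the pair differs only through the signal model.

Features of real data the simulator does *not* emulate: motion, probe
concentration variation and leakage, eye aberrations, PMT saturation and
afterpulsing, scattering background from out-of-focus vessels. Passing tests
therefore demonstrate correctness of the estimators under the stated model,
not robustness to every in-vivo artefact.

## CW background-rate correction

The CW beam adds a constant k_OCT to every fitted rate. The correction is
estimated empirically: vessels are fitted with and without the CW source and
k_simul is regressed on k_native by ordinary least squares with a free slope
(unity is the theoretical slope, and leaving it free makes the fit an actual
check of that expectation). The intercept is k_corr, subtracted from
simultaneous-mode rates before oxygen conversion; rates not exceeding k_corr
become no-data. k_corr is illumination-specific — a tag travels with the fit
and applying it under a different tag warns.

## Dissociation analysis

Saturation follows the Hill curve sO2 = pO2^n/(pO2^n + p50^n) with C57BL/6
mouse defaults n = 2.59, p50 = 40.2 mmHg. Measured pO2 is first multiplied
by the Kelman environmental factor
f = 10^[−0.024(T−37) + 0.40(pH−7.40) − 0.06(log10 pCO2 − log10 40)], which
separates exactly into a temperature part f_T (measurable) and a pH/pCO2
part (not measurable noninvasively in the retina). The latter is fitted as a
single scalar by bounded least squares over (0.5, 2.0) against an
oxygen-challenge series of (systemic sO2, f_T-corrected arterial pO2) pairs.
Venous values reuse the arteriole-derived combined factor. Oxygen content is
cO2 = 1.36 mL O2/g Hb × 15 g/dL × sO2 + 0.0031 mL O2/dL/mmHg × pO2; the
three coefficients are standard physiology values, config-exposed and
recorded in output provenance. Extraction fractions are arteriovenous
differences over the arterial value, for sO2 and cO2.

The probe-dose utility computes blood concentration as
C = V·C₀/(m·v_blood + V), diluting the bolus into the estimated blood volume
plus the injected volume itself.

## VIS-OCT path

The spectrometer is modelled as uniform in wavenumber over 500.07–635.36 nm
(2048 pixels default, configurable), so reconstruction is background
subtraction, multiplication by a *given* dispersion-compensation phase,
optional apodization (default none), and a forward FFT; the positive-depth
half-space is kept, and the forward transform is chosen so the peak at
positive depth carries the +2nkz phase, giving adjacent-A-line Doppler
shifts the conventional sign Δφ = 4πnΔz/λ_c (n_medium default 1.35). Axial
pitch is π/(N·δk·n) ≈ 0.87 µm with the defaults. Flattening detects the
surface per A-line as the first axially-median-smoothed sample above a
configurable fraction (default 0.5) of the column maximum and circularly
shifts columns to the median surface row. B-scan stacks average magnitudes;
the 10→1 A-line merge for simultaneous protocols averages complex values by
default (phase-preserving) with a magnitude option. Dispersion-phase
*estimation* and sub-band spectroscopic oximetry are out of scope.

## Problem sizes

Tests run phantoms at 32–64 px grids and single-vessel scenes rather than
the instrument's 256×256 raster — the estimators are per-pixel, so grid size
changes coverage, not behaviour — and the kcorr validation uses 34 vessels
of 25 averaged traces each, matching the vessel-level averaging convention.
`scripts/acceptance.py` recomputes the standard-state Kelman pH/pCO2 factor
and the 34-pair background-rate regression intercept from scratch at each
invocation.

## Known limitations

- The Gaussian sectioning weight and the CW steady-state scale are
  conventions, not measurements; both are config-exposed.
- The segmentation stand-in (Otsu + connected components) is deliberately
  minimal; real analyses should supply vessel masks.
- Single-exponential fitting only: no multi-exponential or phasor analysis,
  no excitation-pulse deconvolution.
- The Kelman factor is calibrated to human hemoglobin; applying it to mouse
  blood inherits that approximation.
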