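# Methods

## The measurement model

A focused TEM00 laser beam has a very nearly Gaussian transverse intensity
profile. When an opaque straight edge at position *x* occludes part of the
beam, the transmitted power is the integral of a 2-D Gaussian over a
half-plane, which reduces to

T(x) = ½ erfc(√2 (x − x₀)/w),

where *w* is the 1/e² intensity radius and x₀ the beam centre. Two
consequences drive everything in this package:

* the 50% transmission point locates the beam centre on the edge, and
* the distance between the 10% and 90% transmission points is
  √2·erfinv(0.8)·w = 1.2816·w, so the 1/e² **diameter** is 1.561× the 10–90
  width (2/1.28155 = 1.5606, quoted as 1.561 to four significant figures).

The per-axis caustic is the free-divergence hyperbola
w(z)² = w₀² + θ²(z−z₀)². We deliberately do not tie θ to w₀: aberrated
beams have a larger waist than their divergence implies. The
diffraction-limited relations θ = λ/(nπw₀) and, at full aperture,
θ = arcsin(NA/n) serve as the reference the measurement is compared against.
The arcsin form (not the paraxial NA/n) is used for the half-angle;
at NA 1.3 in oil the two differ by several percent and only the arcsin form
reproduces the standard theoretical-waist values. The wavenumber in the
paraxial-validity metric kw₀/√2 is the in-medium k = 2πn/λ for the same
reason. Lengths are nanometres inside `beam_optics` and micrometres in the
trace/caustic layer; conversions happen only at module boundaries.

## Per-trace radius estimation (`trace_analysis`)

**Normalization.** The 2%/98% intensity quantiles bracket the trace range
robustly (isolated spikes cannot stretch it). The baseline and plateau
*levels* mapped to 0 and 1 are the medians of the samples within a quarter
of that range of each bracket. This matters: the tail quantiles themselves
sit ~2σ into the noise distribution, and using them directly inflates every
10–90 width by ~4% at the 1% noise level typical of laser intensity noise —
a bias larger than everything else in the error budget. Cluster medians are
unbiased under symmetric noise. The scheme assumes the flat regions dominate
the slope regions, which holds for the intended scene (edge width ≪ hole
width); traces whose plateau is a small fraction of the record can retain a
residual percent-level bias. Normalized values are clipped to [−0.05, 1.05]
so the error-function fit still sees genuine overshoot. A trace whose
plateau–baseline span is below 10× the robust noise floor (1.4826·median
|Δy|/√2) is rejected as degenerate.

**Clip crossings.** Crossing *detection* runs on a 5-sample moving mean and
rejects traces where a level is crossed at more than one distinct place
(crossings within 10 samples of each other count as one, keeping the first
in scan direction). The crossing *position* is then refined on the raw
samples with a short local least-squares quadratic centred on the bracketing
pair, window ≈ 10% of the rough 10–90 width (clamped to 2–25 samples).
Plain two-point interpolation between raw bracketing samples is exact on
noiseless data but has σ ≈ 0.03·w per crossing at 1% noise — and can
extrapolate arbitrarily far when the raw pair does not actually bracket the
level. The local quadratic removes the curvature bias a straight-line fit
would add at the 10% and 90% levels and averages the noise down to
≈ 0.01·w per crossing; on noiseless data it passes through the exact
samples (residual bias < 0.3% of w at the default sampling). When fewer
than five points are available the estimator degenerates to clamped linear
interpolation.

**Two estimators.** `clip` (default) uses only the two crossings and the
1.561 factor — the bench-standard recipe, insensitive to the curve shape
away from the clip levels. `erf_fit` least-squares fits
B + A·½erfc(±√2(x−x₀)/w) as a shape-sensitive cross-check; its residual is
rms-normalized by the fitted amplitude. A fit is flagged when that residual
exceeds 0.01 (a sharp-edge Gaussian trace should fit to within the noise)
**or** when the fitted 10–90 width exceeds half the scanned window: a
straight ramp is fit deceptively well (rms ≈ 0.003) by the linear core of a
much wider erf, so the residual alone cannot reject non-edge input.

**Hole traces.** A trace across a whole hole contains a rising and a falling
edge. It is split at the midpoint between the two 50% crossings and both
edges are analyzed; their radii are averaged. The same 50% midpoints drive
the time-to-distance calibration: scale = hole width / midpoint separation.
The 50% point (not the 10/90 midpoint) defines edge position because it is
symmetric in the edge profile and has the steepest slope, hence the best
noise immunity.

## Caustic fitting (`propagation_analysis`)

* **Waist**: mean of the three smallest radii; their standard deviation is
  reported as the waist uncertainty, so it reflects the z-plane spacing as
  well as the noise (with the default 9 planes over ±5 z_R the "three
  smallest" span ±1.25 z_R and the quoted scatter is conservative). The
  waist position starts from the w-weighted centroid of those planes. A
  minimum at the end of the scanned range triggers an extrapolation warning.
* **Divergence, trig route**: θ = mean of arctan(w/|z−z₀|) over planes at
  least 5 Rayleigh ranges out, where the hyperbola is within 2% of its
  asymptote. Anchoring the triangle at the waist position keeps the residual
  bias at ~+2% there; the finite-difference slope (w_far − w₀)/Δz
  undershoots by ~18% at 5 z_R and is not offered.
* **Divergence, hyperbola route** (default): least squares of
  w₀² + θ²(z−z₀)² − w² with residuals weighted by 1/(2w), which to first
  order equals fitting w itself. Unweighted squared-radius residuals let the
  far-field planes dominate and roughly double the waist error at realistic
  noise. Bounds keep w₀ ≤ 1.001× the smallest measured radius and
  θ ∈ (0, π/2). Initialisation comes from the near-focus waist and the trig
  divergence (or a coarse slope when no plane qualifies as far field).
  Three exact points are interpolated exactly (three unknowns).
* **Axes**: ellipticity = smaller/larger waist (≤ 1, invariant under axis
  relabeling); astigmatism = |z₀(0°) − z₀(90°)|. The report compares each
  axis against the full-NA theoretical waist and nominal NA, and evaluates
  kw₀/√2 at both the measured and the theoretical waist — callers choose
  which of the two is the relevant paraxial check for their question.

## The simulator (`synthetic_data`)

The scene is a square hole (default 40 μm, the standard TEM-grid pitch)
between opaque bars (default 20 μm, about half a grid period on either side
of the hole as one would frame it at high zoom). The transmission of a beam
of radius w across the hole is the difference of two error functions; the
reflected light simply never reaches the transmission detector. Each trace
is emitted in the time domain (default 2048 samples, 10 Hz line rate, 80 μm
span) with the true μm/s scale recorded in the manifest. Defaults encode the
study conditions: 1% multiplicative Gaussian intensity noise (laser noise;
shot and detector noise are not modelled), z-series of 9 planes spanning ±5
Rayleigh ranges of the smaller-waist axis, scan angles restricted to 0°/90°
(oblique angles would mix the axes and are rejected). A non-ideal knife edge
is modelled as a box-convolution of the profile with width `edge_grade`,
evaluated in closed form from the erf antiderivative — the simplest
one-parameter blur; it can only widen the apparent edge, so graded edges
bias the radius upward (≈ +0.8% at a grade of 0.2·w). Per-trace RNG streams
are spawned from one seed, so a series is bit-reproducible while traces stay
independent.

What passing the synthetic round trips does **not** show: performance under
edge diffraction ringing, electromagnetic edge–field interaction at high NA,
finite collection aperture, vectorial (non-paraxial) focal fields, or
non-Gaussian pupil profiles. None of these are simulated; the paraxial
metric in the report is the built-in caveat for the high-NA regime.

## Numerical choices and degenerate inputs

* Clip factor constant 1.561 (4 s.f.) is the user-overridable default;
  internally exact erfinv expressions are used where the inverse relation is
  needed, so round-trip tests close to 3×10⁻⁴.
* Crossings: ties broken by the first crossing in scan direction; refinement
  quadratic falls back to clamped linear interpolation when its discriminant
  is negative or its roots leave the window.
* Degenerate inputs raise typed errors: constant/noise-buried traces
  (`DegenerateTraceError`), missing or repeated level crossings
  (`AmbiguousEdgeError`), calibration scenes without two opposite edges
  (`CalibrationError`), non-convergent erf fits (`EdgeFitError`, carrying
  the clip-method initial estimate), series with no far-field plane
  (`InsufficientRangeError`, naming the required |z−z₀|).
* CLI exit codes: 0 success, 1 analysis failure, 2 usage/input error;
  per-trace failures in a series are logged, skipped and counted in
  `report.quality`.

## Problem sizes

The test suite and the acceptance script run the full synthetic pipeline at
the study conditions (2048-sample traces, 9-plane series, 20 replicates for
the recovery statistics); the whole suite completes in well under a minute
on one core. The clip-factor oracle integrates the 2-D Gaussian by adaptive
quadrature inside a root finder (~20 transmission evaluations).

## Known limitations

* The clip method's accuracy degrades when the beam radius approaches a
  quarter of the hole width (edge overlap depresses the plateau); the
  simulator warns in that regime.
* Only 0°/90° scan angles are supported; a beam whose principal axes are
  rotated relative to the scan axes will read as less elliptic than it is.
* The waist uncertainty convention (s.d. of the three smallest radii) mixes
  plane-spacing and noise contributions; with coarse z sampling it
  overstates the statistical error of the fitted waist.
* Time-domain calibration assumes a constant scan velocity across the line;
  galvanometer turnaround nonlinearity is not modelled or corrected.
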