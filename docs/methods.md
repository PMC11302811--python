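# Methods

## Measurement model

A picket-fence test delivers `n_segments` (default 8) adjacent step-and-shoot
segments of 20 mm pitch, each 100 MU, with a nominal abutment gap `W`
carved symmetrically at every internal boundary.  All positions are
isocenter-plane millimetres on a single axis along leaf motion; the portal
imager (1024 × 1024 pixels, 0.4 mm pitch at the panel, source-to-detector
160 cm over source-to-axis 100 cm) samples that plane at 0.25 mm.  Raw
images are 16-bit inverted ("delivered signal = 65535 − stored"); every
field image is divided by a 26 × 26 cm² open field from the same session
(`I_norm = ΔI_raw / ΔI_open`), which cancels the session output factor and
panel response.

Per (strip, leaf pair) the central 5 of the pair's 20 projected rows are
averaged — the outer rows carry interleaf-leakage ridges — and resampled to
a uniform 0.01 mm grid by cubic B-spline interpolation.  On the valley of
that profile three features are measured:

* **FWHM** — per side, the half level is (side peak + valley)/2; the
  boundary is the first fine-grid sample at or above that level walking
  outward from the valley (no sub-sample root-finding: the grid already
  bounds quantization at 0.005 mm).  FWHM = right boundary − left boundary.
* **valley area** — summed deficit below the flanking peak values, sample
  by sample, the valley sample counted once on the left side
  (unitless × samples).
* **valley depth** — the valley value itself.

Calibration fits `W_Abu = Σ c_k W_F^k` (quintic) through the 13 calibration
fields (`W` = 2 … 14 mm).  Features are averaged over sessions (default 8)
before fitting — the *nominal* feature — and likewise the log-derived
actual widths.  Scheme A fits one curve per strip from pair-averaged
features and log widths; Scheme B one curve per (strip, pair) against the
planned widths; Scheme C one per (strip, pair) against the log widths.
Abscissae are centered and scaled to [−1, 1] before the least-squares
solve (a raw quintic design matrix is ill-conditioned); the transform is
stored with the coefficients, so the raw-coefficient form is recovered
exactly.  Estimation is direct polynomial evaluation, restricted to the
fitted feature range ± 10% of its span.  The valley position splits the
estimated width into the two leaf edges (`P_peak ∓ W/2`), and per-leaf
errors are taken against the log-derived actual edges.  The integration
method keeps, per leaf, the feature method with the smallest absolute
error; its error is therefore exactly the per-leaf minimum.

Delivery logs hold one record per 40 ms (272 per 100 MU segment) with every
leaf of both banks; beam-off transition records are flagged and excluded.
The actual per-segment leaf position is the mean over beam-on records; the
abutment at strip `s` is bounded by segment `s`'s bank-B leaf (left) and
segment `s+1`'s bank-A leaf (right), so the actual width is the difference
of those two record-averaged edges.

## The synthetic linac

The simulator exists to exercise the full calibration/validation loop; it
emulates the features of real portal data that the method actually touches
and nothing else.

**Edge kernel.**  Each collimated edge follows a three-component response:
a Gaussian core (`penumbra_sigma`, default 0.7 mm — focal-spot and panel
blur), a uniform ramp of full width 8 mm at weight 0.4 (the gradual
transmission change through the rounded leaf end), and a broad Gaussian
glare tail (weight 0.05, sigma 8 mm — long-range optical spread in the
panel).  All three have closed forms, so images are rendered to machine
precision.  The ramp is what gives the FWHM-versus-width curve its
characteristic two-regime shape: below the ramp width the valley keeps
filling in as the gap narrows and FWHM responds sub-linearly; above it the
curve runs at unit slope.  A recorded sweep (`scripts/tune_penumbra.py`)
fixes the defaults so the two-segment piecewise-linear elbow of the
noiseless FWHM curve falls at 8.0 mm; a single-Gaussian penumbra cannot put
the elbow there (it saturates near 5.6 mm for any sigma).  The glare tail
keeps the valley-depth feature strictly monotone out to 14 mm (slope at
12 mm ≈ 2% of its 2 mm value) — without it the feature hits the
transmission floor near 9 mm and its calibration curve becomes
non-invertible even noiselessly.

**Stochastic layers.**  Per-record leaf error = persistent per-leaf bias
(mean −0.033 mm, SD 0.020 mm, drawn once per machine) + per-delivery offset
(SD 0.010 mm) + per-record jitter (SD 0.060 mm), for a marginal per-record
SD of ≈ 0.064 mm.  The marginal mean and SD are the machine-log statistics
the model is built to reproduce; the implied mean absolute per-record error
is ≈ 0.058 mm (a folded normal cannot match an arbitrary absolute mean
independently of its signed moments).  The persistent bias is what makes
log-anchored calibration (Scheme C) outperform planned-width calibration
(Scheme B); per-pair response factors (SD 2%, fixed per machine) are what
penalize strip-averaged calibration (Scheme A).  Session output factors
(SD 2%) multiply all images of a session and cancel under open-field
normalization; pixel noise is multiplicative Gaussian (SD 1%) — Poisson
statistics are not modelled, a ratio image does not need them.  Images are
rendered at the per-segment *realized mean* leaf positions of the generated
log, so image and log agree exactly in the noiseless limit.

**Deliberate errors.**  Validation plans displace leaves via the plan
(`single_bank`: each signed magnitude ±0.6, ±0.8, ±1.2, ±1.8, ±2.4 mm on a
unique pair, one bank; `both_bank`: each magnitude on two consecutive
adjacent pairs, both leaves together, i.e. a rigid gap translation).  The
two-bank composition is a design choice: displacing both leaves outward by
2.4 mm would close 5 mm gaps to 0.2 mm and push 11 mm gaps beyond the
calibrated range, so the translation reading is the one consistent with the
validation design.  Displacements are real leaf moves recorded by the log;
an `epid_only_errors` mode applies them to the image alone for testing
leaf-versus-log disagreement detection.

**What passing tests do not show.**  The simulator has no tongue-and-groove
structure (the modelled MLC design has none), no panel sag or dead pixels,
no gantry/collimator rotation, no spectral changes, and its noise is
stationary.  Synthetic results therefore validate the *algorithms* —
feature extraction, calibration, inversion, integration — not the physics
of any particular machine; absolute error levels on real data depend on the
real penumbra and jitter.

## Numerical choices

* Valley detection: most prominent local minimum (`scipy.signal.find_peaks`,
  prominence ≥ 0.06 ≈ 10% of an ideal 2 mm strip's depth), ties broken
  toward the window center; the valley position is then recentered on the
  midpoint of the near-flat bottom (within 10⁻³ of the minimum), which
  matters only for wide, saturated gaps.  Side peaks are the highest sample
  on each side, which remains correct when the search window cuts a
  shoulder before it turns over.
* Search window: nominal half-gap + 3·sigma + half the ramp width + 2 mm,
  capped at half the segment pitch + 2 mm so it never spans two abutments.
* Profile grid: 0.01 mm; `positions = x₀ + 0.01·k` exactly, so the uniform
  step survives floating point to < 10⁻⁹ mm.
* Breakpoint estimation (for the curve-shape check): continuous two-segment
  linear model, knot found by bounded scalar minimization of the SSE with
  the two slopes solved linearly at each knot.
* Quintic fits with a saturating feature leave systematic residuals: on
  noiseless synthetic data the FWHM curve inverts to ≤ 0.02 mm, the valley
  area to ≈ 0.05 mm and the valley depth to ≈ 0.1–0.3 mm at
  poorly-conditioned widths.  This is a property of the published fitting
  procedure, not of the implementation, and is the reason the integration
  method exists; it is also why the per-method accuracy ordering
  (integration < FWHM < valley area < valley depth) emerges.
* In this simulator the valley-area calibration curve turns mildly
  sublinear above ≈ 10 mm (the flanking peaks sink once segments narrow
  below the ramp width) and the valley-value curve's apparent elbow sits
  near 7.5 mm; machine data can place these differently.
* Degenerate inputs fail loudly: plans whose displacements close a gap are
  rejected ("degenerate abutment"); flat profiles report "no abutment
  detected"; features beyond the calibrated range raise instead of
  extrapolating silently; per-pair analysis failures degrade to an explicit
  failure list, never silent omission.

## Problem sizes

The shipped study pipeline (`picketqa.replication`) runs a desk-scale
rendition of the design: 24 leaf pairs (the two-adjacent-pair pattern
occupies 20), one analyzed strip for the error ensemble, a panel window
cropped to the analyzed band, 8 calibration sessions × 13 widths, and a
10-machine validation ensemble.  These sizes are configurable
(`ReplicationConfig`); defaults for physics parameters are the full-scale
values throughout.

## Tolerances and action levels

The QA report applies a 0.1 mm action level and a 0.2 mm investigation
level per leaf — the same threshold pair used to summarize log-file jitter
exceedance rates.
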