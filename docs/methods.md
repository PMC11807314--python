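# Methods

## The preprocessing model

A Fluorescent Timer reporter couples transcriptional activity to a
two-state chromophore: blue fluorescence appears with translation and
converts irreversibly to red with first-order kinetics. Per cell, the raw
measurement is a pair (blue, red) of fluorescence values in arbitrary
instrument units, contaminated by autofluorescence and scaled by
detector-specific gains. The pipeline estimates, per run, how large that
background is and how wide it spreads, using a Timer-negative control, and
expresses every cell's Timer signal relative to it.

The run order is fixed and shared by all samples:

1. thresholds from the negative control,
2. gate the negative control with those thresholds,
3. normalization statistics from the gated cells,
4. transform every sample (and the control itself) with the same
   thresholds and statistics.

Using one set of statistics for the whole batch is what makes angles
comparable across samples; a per-sample normalization would re-introduce
exactly the acquisition variability the method removes.

### Thresholding conventions

Quantile thresholds use linear interpolation between order statistics (the
common statistical-software default). The default q = 0.975 is a
conventional 2.5% tail-exceedance gate on autofluorescence — configurable,
and a manual mode accepts explicit raw-unit values for operators who set
gates by eye. The same two thresholds serve both purposes — gating the
negative control and defining Timer positivity — but with opposite
boundary conventions: control gating is inclusive (≤) and positivity is
strict (>), so a cell exactly at threshold is always background. A gated
control smaller than 10 cells is a hard error; extrema and MADs of a
handful of cells are noise.

### Log and normalization conventions

Fluorescence is log10-transformed with a floor (default 1 raw unit)
applied first, making the transform total on exports containing zeros or
negatives; the count of floored values is logged since a large count
signals a mis-scaled export. Per channel the location is the *maximum* of
the log gated-negative values (the top of the background) and the scale is
either the n−1 sample SD or the median absolute deviation times 1.4826
(the literal consistency constant; with it, MAD estimates the same σ as SD
under normality, and the two methods are interchangeable to sampling
error). MAD is the default because a few contaminating Timer-positive
cells in the control would inflate an SD but barely move a MAD. A zero
scale (degenerate control) is a hard error.

Normalized values are (log − location)/scale, *unclamped* in the output
tables so below-background structure remains visible for QC.

### Trigonometric transform

Before the polar transform, normalized values are clamped at zero: the
angle is meant to order cells by maturation state, and "how far below
background" a channel sits carries no such information. Clamping also
guarantees the arccos argument lies in [0, 1], hence θ ∈ [0, 90]° exactly.
A cell at the origin (both channels at/below background) has no direction;
its angle is missing rather than an arbitrary 0, and cells that are not
Timer-positive carry missing angle and intensity so they cannot leak into
angle statistics. Intensity satisfies I² = B̃² + R̃² to floating-point
accuracy.

The "non-normalized" comparison mode centres the log values on the control
maximum without dividing by the scale. This is one consistent definition
of a non-normalized angle (raw-scale angles would be dominated by the
log-decade structure of cytometry data); it isolates precisely the effect
of the per-channel scale division.

### Gain invariance and bias direction

Two properties summarize why normalization matters, and both are tested
end-to-end on files, not in-memory shortcuts:

- **Invariance:** multiplying the blue channel of *every* file (control
  included) by k > 0 and rerunning with normalization reproduces each
  cell's normalized values, angle and intensity to 1e−9. The quantile
  threshold scales by exactly k, the same cells are gated, the log values
  and the location both shift by log10 k, and SD/MAD are shift-invariant.
  The property holds exactly only while the log floor never binds, which
  the generator's defaults ensure for k ≥ 0.1 (see below).
- **Bias monotonicity:** with normalization off and k applied to the
  samples only, every cell with red signal above background has its angle
  non-increasing in k — inflating blue drags the apparent maturation state
  down. This is the distortion the normalization removes.

## The synthetic generator

The generator emulates a stimulation time course read by a Timer reporter.
It is a fixture with physics, not a model of any particular experiment.

**Kinetics.** Per cell, amounts follow the minimal two-compartment linear
model

    dB/dt = p − (m + d)B,   dR/dt = mB − dR,   B(0) = R(0) = 0

with maturation rate m = ln2 / 4 h (the one experimentally anchored
parameter), shared degradation d = ln2 / 24 h (a typical fluorescent-
protein half-life; `inf` disables it), and production p = 1000
molecules/h. Closed forms are implemented with expm1 and explicit d → 0
limits; tests verify them against a high-order numerical ODE integration
(relative error < 1e−6) and the d = 0 mass balance B + R = p·t. For a
pulse (bolus, p = 0) the immature fraction is exp(−mt) regardless of d,
which the half-time fit exploits: an OLS line through ln(B/(B+R)) vs t
recovers m, and ln2/m the half-time.

**Measurement.** Signal = amount × channel gain × lognormal noise
(CV 0.3); every cell, Timer-on or not, additionally receives additive
lognormal autofluorescence, 10^N(μ, σ²) with μ = 2.0 log10 units and
σ = 0.2 per channel. These defaults put the background median at ~100 raw
units on a 10^5-unit scale — a realistic autofluorescence level — and keep
essentially all raw values above 10 units, so the log floor (1 unit) never
binds even after a 0.1× gain distortion. Gains default to equal
(unbiased); bias experiments set them apart or use the blue-multiplier
helper. Within a timepoint, per-cell onset ages are uniform on
[0, elapsed], modelling continuous stimulation; the Timer-on fraction
defaults to 0.8. A forward-scatter channel with a mild Timer-on size shift
is included so size summaries are exercised.

**What it does not emulate:** spectral spillover/compensation, detector
saturation, pulse-shape artefacts, doublets, cell death, or any specific
biology of reporter regulation. Passing tests therefore demonstrate the
correctness and invariances of the *computation*, not performance on any
real dataset.

**Determinism.** All draws use numpy's PCG64; each file in a time course
gets its own generator seeded from (base seed, file index), so datasets
are byte-identical across reruns and insensitive to generation order.

## Numerical and design choices

- Quantiles: `numpy.quantile` linear interpolation; positively homogeneous,
  which the invariance property relies on.
- Angle at the axes is exact in IEEE arithmetic (arccos(1) = 0,
  degrees(arccos(0)) = 90.0); no special-casing needed.
- Output tables print floats at 6 significant digits; angle in degrees.
  Plot-data CSVs are written at full precision because they must reproduce
  the source values exactly (read them back with
  `float_precision="round_trip"`).
- Sample ids are file stems; duplicate stems across directories are a hard
  error rather than silently disambiguated.
- `common_variables` is stored sorted so a manifest does not depend on
  file enumeration order.
- MFI is the arithmetic mean of raw values over all cells (geometric mean
  and positive-only means are choices a user can make downstream; the
  summary exposes the arithmetic default with a geometric option).
- Problem sizes in the test suite are deliberately modest (hundreds to a
  few thousand cells per sample, a 33-file end-to-end fixture at 500
  cells/sample); every property checked is size-independent, and the
  gain-invariance suite uses ~10k cells total.

## Known limitations

- Normalization anchors on the control *maximum*, an extreme order
  statistic; with very small gated controls it is noisy, hence the
  10-cell floor. A high quantile would be more robust but changes the
  semantics of "top of background".
- Cells with extremely high expression are normalized by background
  statistics alone; no saturation correction is attempted.
- Forward-scatter-based size correction is deliberately out of scope, as
  are compensation/unmixing and any downstream analytics of the
  angle-intensity distribution.
- The interactive exploration workflow is replaced by the scripted
  `sweep` command; there is no GUI.
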