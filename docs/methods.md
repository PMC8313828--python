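# Methods

## Recording model and windows

A recording is a per-ROI fluorescence series at a fixed frame period
(default 4 s). The shipped protocol preset uses a 50-frame baseline,
stimulus additions at frames 50/100/150 and ionomycin at frame 200.
Total length is an acquisition choice, not part of the protocol; the
preset's 215 frames (860 s ≈ 14 min) leaves a 15-frame control window.

Frames are 0-based and windows half-open, so baseline [0,50), event
windows [50,100), [100,150), [150,200) and control [200, n_frames)
partition the recording exactly. Because stimuli are added without
washout, a response during the decay of an earlier transient is
attributed to the window it occurs in — a declared convention, since
nothing in the assay pins a response to its eliciting stimulus.

## Normalization and responder rule

Traces are divided by the mean of the whole baseline window rather than
the single first frame; a one-frame divisor makes the entire analysis
hostage to one noisy sample. (A single-frame baseline can be had by
setting `baseline_frames=1` in a custom schedule.) The responder
criterion is a window maximum ≥ 1.2-fold over baseline, boundary
inclusive. Thresholding is monotone: raising the fold can only demote
responders, never promote them.

Cells that fail the criterion in the control window are invalid —
interpreted as dead, unloaded or mis-segmented ROIs — and are excluded
from every percentage denominator; `n_excluded` is always reported
alongside `n_valid`.

## Spikes and dominant peaks

"Spike" has no unique quantitative definition in this assay; the
package's convention is the simplest one consistent with visual
transient counting: a strict local maximum (value greater than both
immediate neighbours, neighbours inside the window) at or above the
responder threshold, with accepted spikes at least `min_separation`
frames apart (default 2, i.e. only the strictness constraint); when two
candidates conflict the larger wins and ties keep the earlier. The
dominant peak is the plain window maximum in fold units. Both are
exposed per event plus for the baseline window, so culture-level means
cover baseline + events 1–3. By default per-event means average over
all valid cells; `responders_only=True` restricts to that event's
responders.

## Synthetic-data generator

The generator emulates the statistical structure the classifier
assumes, not the biophysics:

* Per-cell category codes drawn from `pattern_probs` over the 8 codes.
* Each responding window gets 1–3 transients (uniform count): an
  instantaneous rise of (fold − 1) over baseline, fold uniform in
  `peak_fold_range` (default 1.5–3.0), then exponential decay with
  1/e time `decay_frames` (default 8 frames = 32 s). Decay kinetics are
  free parameters of the generator — chosen as plausible for somatic
  Fluo-4 transients — not claims about any particular dataset.
* The first transient lands one frame after stimulus addition; extra
  transients land at uniformly random frames, ≥ 3 frames apart, and no
  later than a guard margin before the window end. The guard is
  ceil(τ·ln((fold_max−1)/0.05)), which caps the decay tail carried into
  the next window at 0.05 fold, so a silent window stays below the 1.2
  threshold by construction.
* Valid cells get an ionomycin transient (default 4-fold) at the
  control frame; invalid cells (probability `invalid_fraction`,
  default 5%) are flat noise throughout.
* Per-frame i.i.d. Gaussian noise (default SD 2 on a baseline of 100,
  i.e. 2% of baseline) added to the raw trace and truncated to stay
  positive.

With zero noise the classifier provably recovers every generated code,
validity flag and spike count — the construction keeps silent windows
below threshold and makes each transient a strict, separated local
maximum. With the default 2% noise, codes are still recovered
essentially always (the threshold sits 10 noise SDs above baseline and
≥ 15 below the smallest peak), but *spike counts* are no longer exact:
noise riding a slowly-decaying suprathreshold tail creates spurious
strict local maxima. This mirrors real data, where spike counts depend
on the detection convention; tests therefore assert exact spike
recovery only at zero noise.

What the generator does not model: photobleaching drift, oscillatory
(sinusoidal) calcium waves, cell-to-cell signal propagation, spatial
structure, or amplitude differences between stimulus types. Passing
tests show the *analysis* is correct under the stated assumptions, not
that the assumptions hold for any given microscope dataset.

Determinism: all randomness flows from one `numpy` generator seeded by
`SimulationConfig.seed`; identical config + schedule give byte-identical
CSV serializations.

## Culture statistics

Category percentages are over valid cells and sum to 100 by
construction. The multi-event statistic is the union {110, 011, 101,
111}. Fold ratios are plain quotients a/b; the comparative difference
is (fold − 1) × 100 — the only reading that makes a 3.57-fold gap equal
a 257% difference, recorded here as a derived convention. The
between-culture test is a Pearson chi-square (no continuity correction,
no exact-test fallback) on the 2 × k table of category counts, with
zero-total categories dropped and dof = k − 1; expected counts below 5
raise a warning rather than switching tests, so the reported statistic
is always the same statistic.

## Griess assay

The standard curve is ordinary least squares of absorbance on
concentration with a free intercept (the blank is a fitted point, not
subtracted first — whether the original protocol forced the line
through the blank is unknowable from the assay description, and a free
intercept is the safer default). Quality control compares the Pearson r
against a floor of 0.989, the lower edge of what a good standard run
achieves; breaching it warns but does not block. With exactly two
standards the line is the exact connector and the slope standard error
is reported as 0. Unknowns are inverted as (A − intercept)/slope, with
below-blank (negative) concentrations returned as-is for the caller to
flag.

Time courses report, per DIV, mean(treated) − mean(control) with SEM
propagated as √(SEM_t² + SEM_c²) — an independent-arms assumption,
since well pairing is not part of the plate layout. When an
`experiment` column is present, wells are averaged within experiment
first and SEMs taken across experiment means; single-well or
single-experiment arms report SEM 0 with n = 1 so the degenerate case
is visible rather than NaN.

## Morphometry

`object_stats` reports n, arithmetic mean and sample SD (n − 1
denominator) per measure; n = 1 reports SD 0 with a `single` flag. The
nuclear area factor is implemented as NAF = area × roundness — the
standard composite used in nuclear-morphometry work; the defining
methodology is external to this package's assay chain, so the formula
is a configurable convention, and NAF ≤ area always. Pixel↔μm
calibration is a scalar the caller applies; lengths and pixel areas are
never cross-compared.

## Numerical and design notes

* Trace CSVs round-trip at full float64 precision: writing uses
  shortest-repr formatting and reading parses with numpy's correctly
  rounded parser (`pandas.to_numeric`'s fast path is not, and loses the
  last ulp).
* NaN or non-positive raw fluorescence rejects a file; nothing is
  imputed.
* The chi-square on identical count vectors returns exactly 0 with
  p = 1; comparisons are symmetric in culture order.
* Problem sizes in the test suite (2,000-cell noiseless recovery,
  5,000-cell distributional recovery, the exhaustive 3^12 spike-oracle
  sweep, 200-seed curve-fit coverage) were chosen to make each
  statistical assertion sharp — 3-standard-error bands at these n are
  tight enough to catch real defects — while keeping the default suite
  quick to run.
* The 200-seed slope-recovery check allows the miss count a correct
  fit implies: the slope z-score is Student-t with n − 2 dof, so
  misses at 3 SE occur at rate 2·sf_t(3) ≈ 1.3%, and the bound is that
  binomial mean plus three binomial SDs.

## Known limitations

* No ROI segmentation from pixel data; inputs are per-ROI traces or
  pre-measured object tables.
* No calcium-concentration calibration: Fluo-4 is non-ratiometric, so
  outputs stay in fold units.
* The spike definition has no prominence or width criterion; densely
  overlapping transients are undercounted by design.
* The chi-square p-value is asymptotic; sparse categories warn but are
  not re-tested exactly.
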