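# Methods

This note documents the models, conventions, and numerical choices behind
`rampscope`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmarks do and do not show.

## Maze model and path convention

The maze is parameterized by arm lengths (80 cm horizontal, 40 cm vertical),
ramp base length *b* (48 cm), base angle θ, and the ramp's offset along the
horizontal arm (default: centered, 16 cm).  Derived quantities follow
triangle geometry: apex height (*b*/2)·tan θ, slope surface length
(*b*/2)/cos θ.  The *linearized path* replaces the ramp base with its two
slope surfaces, because that is the distance the animal actually walks; at
45° the horizontal walked path is ≈99.9 cm and the full path ≈139.9 cm.

The path origin sits at the outer end of the horizontal arm, so "right"
trials (reward at the horizontal end) run toward path 0.  Spatial bins are
1-based in this fixed frame: bins 1–90 tile the horizontal walked path
(slopes included), bins 91–130 the vertical arm.  The published description
divides the maze into 130 one-centimeter bins (90 + 40) although the walked
horizontal path at 45° is ≈100 cm; we keep the printed bin counts as
defaults and let the bin width follow from the geometry (≈1.11 cm per
horizontal bin at 45°) rather than asserting a specific 90-bins-on-100-cm
mapping, which the source leaves unspecified.  Windows w1–w8 are contiguous
path segments numbered along right-trial travel: w1/w2 halve the vertical
arm, w3/w4 the corner-side flat stretch, w5/w6 are the two slope surfaces,
w7/w8 halve the outer flat stretch.  The w-geometry is fixed in space;
direction only swaps which slope window means uphill (`window_roles`).

## Behavioral thresholds

Two speed thresholds coexist deliberately.  Locomotion onset (trial-start
marker) defaults to 30 cm/s; quiescence defaults to 0.5 cm/s.  The source
conventions for these two numbers use different units (m/s vs m/min), and a
30-cm/s onset exceeds the 16.7 cm/s mean running speed, so sessions whose
speeds never reach it need a lower onset (the synthetic-session helper uses
30% of the configured mean speed).  Both are independent config keys; no
silent reinterpretation is attempted.  The reward zone is the final 1 cm of
each arm (food wells sit 1 cm from the ends); reward consumption occupies
`reward_duration_s` (1 s) after arrival, and quiescence is scored from the
end of consumption to the next trial start, at sub-threshold speed.  Flat
walking is scored only on the vertical arm, keeping it clear of ramp
approach and departure; moving frames on the horizontal flat segments fall
into "other", as do turning and consumption frames.

## Synthetic-data generator

The generator's defaults encode the study conditions: 30-Hz frames,
16.7 cm/s (10 m/min) mean running speed, alternating left/right trials
separated by 3-s pauses at the wells.  Speed varies by a smooth
multiplicative jitter (15% SD, 0.3-s smoothing) and by slope factors
0.65 (climbing) / 0.85 (descending) relative to level speed — chosen so the
average uphill phase lasts ≈3.1 s, consistent with uphill walking being
reported slower and longer than downhill and with the 2-s phase-specific
criterion being two-thirds of the average uphill duration.  Turn-back
(incomplete) trials are off by default; when enabled, the turn point is
uniform before the apex.

Neuron classes cover the tuning taxonomy: uphill, downhill, both, flat,
quiescent, four phase-change types (0.5-s bursts at transitions), reward,
speed-coupled, and a Purkinje-like class (quiescence-active, striped
footprint).  Rates are `base_event_rate` (0.3 events/s) times the class
gain (default 5) inside the preferred condition; spiking is
inhomogeneous-Poisson per frame.  Fluorescence follows a linear
double-exponential kernel A·(1 − e^(−t/τᵣ))·e^(−t/τ_d) with τᵣ = 0.1 s,
τ_d = 1.0 s (GCaMP6s-like; the source reports no kernel constants) plus
white Gaussian noise; the kernel's closed-form peak time τᵣ·ln(1 + τ_d/τᵣ)
anchors the timing tests.  Movies are background + Σ footprint·trace +
pixel noise, with small isotropic Gaussian footprints for interneurons
(≈6 µm at the 1.3 µm/px default) and elongated Gaussians for Purkinje
dendrites, on a background with smooth structure and dark meandering vessel
shadows (the vessel mask is returned for QC tests).

What the generator does *not* emulate: photobleaching, motion artifacts
(motion correction is out of scope), overlapping/merging cells, neuropil
contamination, nonlinear indicator saturation, and step-cycle-locked
activity.  Passing tests therefore demonstrate correctness of the analysis
chain under the stated generative model — not robustness to every artifact
of real one-photon data.

## ΔF/F₀ and PCA-ICA

F₀ is the per-pixel mean over the whole session; pixels with F₀ ≤ 10⁻⁹ are
masked invalid.  PCA keeps 1.5× the requested number of ICs by default;
ICA (FastICA, cube nonlinearity — the skewness-seeking contrast) runs on
the joint spatiotemporal representation in which each principal component
contributes its spatial map (weight µ = 0.5) and temporal score (1 − µ),
each part scaled to unit RMS.  Component sign is fixed so temporal skewness
is ≥ 0, components are ordered by decreasing skewness, and the whole
decomposition is deterministic for a fixed seed.  Degenerate covariance
(zero-variance principal axes) raises with the offending dimension named.

Automated QC replaces visual inspection: reject temporal skewness < 1;
reject filters whose half-max support overlaps the vessel mask by > 50%;
classify by support geometry (equivalent diameter within 3–12 µm and
elongation ≤ 3 → MLI; larger or more elongated → PC).  Every decision is
appended to the component's `qc_log`.

## Event detection

The derivative is the least-squares slope over a 200-ms moving window
(6 frames at 30 Hz), not a two-point difference — materially more robust at
realistic noise.  Baseline fluctuation is the robust SD (1.4826 × MAD) over
supplied baseline frames (quiescent phase in pipeline use; the whole trace
as a fallback, which inflates the gates when transients are dense — supply
quiescent frames whenever phases exist).  A candidate rise runs from an
upward to the next downward zero-crossing of the derivative and must exceed
5× the baseline derivative SD within the rise; the event is kept if its
peak exceeds the baseline median by 3× the baseline trace SD.  Because the
centered slope window shifts zero-crossings by about half a window, the
*reported* rise start/end are refined inside the candidate: the start is
the last frame at or below baseline median + 2 SD before the peak (falling
back to the last pre-peak minimum when the rise sits on a previous tail),
and the end is the peak frame.  This removes the ±3-frame bias without
changing which rises are detected.  Events cannot overlap by construction,
and raising the amplitude gate can only remove events.  Event "intensity"
is the peak ΔF/F₀ above the baseline median (the quantity the detector
gates on); duration is rise start to peak.

## Tuning classification

Per-trial phase activity uses the Ca²⁺ event rate by default (events whose
rise starts fall in the phase ÷ phase time; a trace-mean option exists).
The still baseline is the last 2 s of quiescent frames before each trial
start.  Significance is a paired t-test across trials (trials are the
natural pairing unit; Welch unpaired is available), raw p < 0.05 with no
multiplicity correction by default.  Uphill requires significance against
baseline *and* downhill plus strict maximality across maze locations;
downhill and flat are symmetric (flat must beat both ramp phases), and
quiescent neurons must beat every movement phase.  Exact ties and
insufficient trials (< 5) fall to "other" with a logged reason.

Phase-shape analysis thresholds the trial-averaged peri-peak trace (10-s
window).  The activation threshold is the trace's 10th percentile (its
baseline level) + 1 SD.  A pure "SD as threshold" rule presumes near-zero
baseline activity; a mean + 1·SD rule can never flag activations filling
more than ~half the window (exactly the both-slopes response, which spans
~55% of a 10-s window).  The baseline-plus-SD default reduces to the former
when baseline activity is ≈0 and stays valid otherwise; both alternatives
remain as config options.  Spans ≥ 2 s are phase-specific (uphill if the
activation ends by the peak, downhill if it starts there, both if it
straddles, with a 0.25-s edge tolerance); spans < 1 s are phase-change,
assigned by the alignment in which they occur (peak, pre/post uphill start,
post downhill end; "close" means within 0.5 s).

Bin maps are occupancy-weighted means per direction; the difference map is
right − left, defined only where both directions visited a bin; sorting is
by difference-map peak location with ties (and all-missing maps) broken by
neuron id, so identical inputs always give identical orders.  Incline
profiles compare per-trial activity across 15°/30°/45° sessions with Welch
t-tests (sessions are different trials, so pairing is not assumed):
monotone means with a significant extreme-pair difference → increasing or
decreasing; no significant pair → similar; otherwise other.

## Decoding

Features are per-neuron min-max scaled over the session (constant traces
become zeros, warned); frames outside complete trials are dropped.  Raw
labels keep four classes (uphill/downhill/flat/others); evaluation
collapses flat into others, and both labelings are reported.  The split is
a random shuffle of trial ids into halves differing by at most one trial.
The classifier is a linear one-vs-rest SVM; the C grid
{0.01, 0.1, 1, 10} is searched by 10-fold *trial-grouped* cross-validation
(grouping prevents within-trial leakage; an RBF kernel with a gamma grid is
available).  The null circularly time-shifts the test-set feature matrix by
a uniform random offset per shuffle — this preserves the calcium signal's
autocorrelation and is therefore more conservative than frame permutation,
which is available as an option.  Empirical p-values are add-one smoothed.

## Statistics

The outlier rule flags |x − median| > 3 × 1.4826·MAD and is applied exactly
once per group before analysis (the rule is not idempotent under
re-computation of the median, so the pipeline never re-runs it on filtered
output).  One-way ANOVA uses the classical F; two-way ANOVA fits an OLS
model with interaction (type-II table) and reports the factor of interest,
with factors taken explicitly from the caller.  Pairwise follow-ups are
paired or Welch t-tests with Bonferroni adjustment min(1, m·p).

## Benchmark problem sizes

The validation suite and `scripts/acceptance.py` use: 200 planted
transients over an 11-min trace at peak-amplitude/noise 8 for the event
detector; eight disjoint sources in a 2000-frame 64×64 movie for PCA-ICA
(plus a 500-frame pure-noise control); 200 neurons × 30 trials for
classification; and 24-trial, 60-neuron sessions with 100-shuffle nulls for
decoding.  These sizes give stable statistics in about a minute of compute;
the shuffle count is configurable up to the conventional 1000.

## Known limitations

- PCA-ICA assumes sparse, positively skewed, spatially compact sources;
  heavily overlapping cells or dense activity degrade demixing (successor
  methods based on constrained matrix factorization handle those regimes).
- The event detector's whole-trace baseline fallback inflates gates at high
  event rates; quiescent frames should be supplied whenever available.
- The trial segmenter assumes well-to-well excursions; grooming bouts or
  mid-maze reversals are handled only as incomplete trials.
- Incline comparisons assume one session per angle with stable cell
  identity across sessions; no registration across days is provided.
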