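# Methods

This note documents the models, defaults and design choices behind each
stage of `wormcal`, what the synthetic generators do and do not emulate,
and the known limitations.

## Synthetic worm videos

The video generator renders a single partially immobilised worm: a
non-self-intersecting open tube of half-width 12 px around a midline that
undulates slowly (one sinusoidal wavelength along the body, temporal period
8 s, amplitude 15 px). Free-swimming coiled postures are deliberately not
simulated — the imaging assay records worms confined in a droplet. Defaults
are 10 fps for 20 s, a 300 px worm in a 128×400 16-bit frame; frame rate,
bit depth and magnification are not constrained by the assay description,
so these are stated configuration choices, not inferences.

Fluorescence structure:

* background `F_bg` = 100 AU; body interior 0.45·`F0`; muscle band — an
  annulus of width 5 px just inside the contour, where the body-wall
  muscle lies under the cuticle — at `F0` = 400 AU;
* Ca²⁺ transients at Poisson times (default 0.25 events/s), each a bump on
  the band, Gaussian in perimeter position (σ = 3% of perimeter) with peak
  amplitude `A·F0` (default `A` = 0.8 ΔF/F₀) and exponential temporal decay
  (τ = 1 s, instantaneous rise). A caffeine event, when scripted, is the
  same kinetics applied band-wide with a slower decay (3 s);
* additive Gaussian noise, default σ = 20 AU = 5% of `F0`. Poisson shot
  noise exists as an option but is off by default so fixed seeds are
  bit-reproducible. Photobleaching multiplies worm fluorescence by
  `exp(-bleach_rate·t)`; the default is 0 (a clean canonical video —
  bleaching and the matching per-row exponential detrend are exercised as
  options), and background does not bleach.

Ground truth (event times, perimeter positions, amplitudes, per-frame
analytic contours, scalar truths of the other modalities) is written as a
JSON manifest next to each dataset so recovery is machine-checkable.

What the generator does **not** emulate: pharyngeal pumping, egg-laying
artifacts, realistic texture, motion blur, multi-worm scenes, spatially
correlated noise, and indicator nonlinearity. Passing recovery tests
therefore demonstrate correctness of the measurement chain under the
stated image model, not robustness to every property of real microscopy.

## Segmentation and perimeter registration

The edge-detection contract is fixed (frame → mask → ordered perimeter);
the operator is configurable and defaults to Gaussian smoothing (σ = 1 px),
Otsu threshold, morphological closing (disk radius 2), largest connected
component, hole filling. Polarity is canonicalised before thresholding
(the image is reflected when the majority class is bright), which makes
the operator exactly symmetric under contrast inversion. Background
subtraction is exposed as a flag and off by default.

Contours are traced sub-pixel by marching squares at the 0.5 level,
lightly smoothed (periodic Gaussian) so arc length tracks the smooth
boundary rather than the rasterisation staircase, and resampled to
P = 200 equal-arc-length points — at default geometry ≥ 2 samples per
muscle-band bump. Coordinates are (row, col), 0-based, pixel centres at
integers; traversal is counter-clockwise (positive signed area with
x = col, y = row). Head and tail are not identified; registration is a
pure cyclic-shift search (FFT cross-correlation) minimising the sum of
squared point distances to the previous frame, with orientation flips
corrected by the sign of the signed area. `align_to_reference` applies the
same search against an arbitrary reference contour, which is how detected
event positions are mapped onto ground-truth perimeter fractions.

## Kymograph and transient detection

Kymograph entry (p, t) is the mean of `band_width` = 3 samples at 1 px
spacing along the inward normal at perimeter point p, starting 1 px inside
the contour (the inset keeps sub-pixel contour error from blending in
background). ΔF/F₀ uses a per-row baseline, by default the 10th percentile
of the row's time series — robust while events occupy < 90% of frames,
standard practice for this indicator; median/mean are alternatives, and an
exponential bleach detrend can be applied first.

Detection thresholds each row at median + 4 robust SD (1.4826·MAD), with
an absolute floor of 0.05 ΔF/F₀ — events below ~5% are not scorable with
this indicator, and on near-noiseless data the MAD alone would chase
sampling ripple. Candidates are closed along time (single-sample dropouts
bridged), merged by 8-connectivity, and fragments split by residual
registration jitter are re-merged when within 5% of the perimeter and
0.2 s of each other. Events shorter than 0.3 s are discarded. These
defaults were set on synthetic null recordings (no-event videos at the
default noise level yield < 1 false event per 20-s recording).

The per-recording summary is the arithmetic mean of event peaks — reading
"average of the peak signal" as averaging over events; the recording-wide
maximum is computed alongside for the other possible reading. An empty
event set returns 0 with an explicit flag rather than an error.

The caffeine readout averages ΔF/F₀ over the perimeter per frame, takes
the pre-addition mean as baseline, and calls a worm a responder when the
peak within a 10-s post-addition window exceeds baseline by 3 robust SD of
the baseline (floored at 0.05 ΔF/F₀ so a flat bright background — the
store-depleted phenotype — is not a trivial responder). Latency is the
first threshold crossing.

## Leak kinetics

Phases: baseline [0, t_ATP), uptake from t_ATP, plateau onset at the first
time where the windowed slope stays below 1% of the peak uptake slope for
≥ 10 s (`settle`), leak from t_Tg. On a noiseless exponential this
tolerance puts the plateau at t_ATP + ln(100)/k_up, which is what the
generator records as truth. `F_b` is the baseline mean; (k_up, plateau)
come from a least-squares exponential fit; the leak is fit as a line —
the assay reports a monotone rise with no stated functional form — with
the model-free endpoint change reported alongside. The normalised leak
s_leak/(F_b − plateau) is invariant to affine rescaling of the
fluorescence axis (gain/offset), making wells and instruments comparable.

## Behaviour

Curl percentage is computed per worm and then averaged (primary), with the
pooled-count percentage reported alongside, since the two readings differ
under heterogeneous bend counts. A worm with zero bends has an undefined
curl percentage and is flagged; curls > bends is flagged as a scoring slip
but not fatal. Automated curl detection from video is out of scope — the
events are scored upstream (or generated).

## Survival

The curve is the product-limit estimator with censored records leaving the
risk set on their day. "Average survival" is reported as the arithmetic
mean of uncensored lifespans (primary), with median and restricted mean
(area under the curve) alongside, since the term is ambiguous.
Gehan–Breslow–Wilcoxon is implemented as the n_j-weighted log-rank — the
meaning the term carries in common statistics packages — with statistic
(Σ w_j(o_j − e_j))² / Σ w_j² v_j referred to χ²(1), ties handled as
simultaneous deaths with standard risk-set bookkeeping. The permutation
method enumerates all label assignments exactly whenever there are no more
than `n_perm` of them, and samples otherwise. Gehan's pairwise-score U is
provided as a cross-check; without censoring it equals the weighted
numerator up to sign. The synthetic lifespan default is Weibull with
shape 4, scale 20 d (mean ≈ 18 d, a realistic wild-type cohort); days are
rounded **up** (death is scored on the day it is observed), which adds
about half a day to cohort means.

## Densitometry statistics

Band ratios are analysed on the ratio scale (as they are plotted), with a
log option. Replicates are analysed individually rather than averaged
before testing (the degrees of freedom question is otherwise ambiguous).
The t test is the pooled-variance Student t; two identical zero-variance
samples return p = 1 by convention. One-way ANOVA refuses two groups and
directs the caller to the t test (the t² = F identity makes them
equivalent); the all-constant degenerate case returns F = 0, p = 1.
Tukey–Kramer uses studentized-range tail probabilities evaluated by
numerical integration (no lookup tables) and honours unequal group sizes.
Two-way ANOVA uses type-II sums of squares, tolerating mild imbalance; an
empty cell is an error.

## Conservation

Global alignment is a three-state Gotoh dynamic program under BLOSUM62
with gap open 10 and extend 0.5 (the EMBOSS-needle defaults; identity and
similarity shift with these, so they are explicit). A gap of length g
costs open + (g−1)·extend. Tie-breaking is deterministic: diagonal, then
up, then left. The DP table is bounded (`max_cells`, default 4·10⁶) and
long pairs raise with guidance instead of exhausting memory. "~40%
homology" between the worm and human channel is interpreted as
alignment-based similarity; both percent identity and percent similarity
are reported (per alignment column, plus identity over the shorter
sequence) so either reading can be checked. The assay deposits no
accessions, so canonical UniProt entries are pinned in
`scripts/fetch_sequences.py` (human RyR1 P21817 and FKBP1A P62942 are
well-established; the worm entries should be verified against WormBase
before use), and the fetched FASTAs live under `data/sequences/` — they
are not redistributed with the package.

## Configuration and reproducibility

One JSON config mirrors every default above in per-stage sections; unknown
keys are rejected by name and configs round-trip exactly. JSON is used as
the canonical format because the standard library can read but not write
TOML, and round-tripping is part of the contract. All randomness flows
from a single global seed; fixed seeds give bit-identical videos, tables
and reports.

## Problem sizes in the test suite

Unit tests run on a reduced worm (150 px, 4-s recordings) with the same
model; the acceptance checks use the full-size study conditions — twenty
20-s videos at 5% noise for transient recovery, 100 noisy traces for leak
recovery, 2000 null replicates at n = 50/group for test calibration —
sizes at which the Monte-Carlo error of each check is comfortably below
its tolerance.

## Known limitations

* The perimeter parameterisation is shift-registered, not anatomically
  anchored; event positions are comparable within a recording but map to
  ground truth only up to the registration alignment.
* Amplitude recovery has small opposing biases (frame-rate discretisation
  of the instantaneous rise underestimates; baseline percentile under
  noise and peak selection overestimate) that roughly cancel at default
  settings; at very low frame rates or high noise the balance shifts.
* The leak fit assumes a single-exponential uptake and linear leak;
  saturating leaks bias the slope downward toward the window mean.
* The aligner is quadratic in time and memory; full-length RyR pairs
  (~5000 aa) require raising `max_cells` and patience, and the pairwise
  alignment of multidomain proteins compresses domain-level variation
  into single global percentages.
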