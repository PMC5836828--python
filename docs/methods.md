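# Methods

## The comet model and its measurement

A comet is treated as one-dimensional in x, the electrophoresis axis: all
head/tail geometry is defined on the per-column integrated intensity
profile of the comet's own pixels. The head center (CPH) is the profile
peak (leftmost on ties). The head radius `r` is the distance from the CPH
to the first column to its right whose profile value falls below
HT × peak; the profile end if no column does. The tail runs from the
head's right end (CPH + r) to the last strictly positive column; tail
columns are the half-open interval (CPH + r, tail end]. Columns left of
the head count toward total DNA but never toward the tail. With intensity
as mass: DNA is the profile sum, TDNA the tail fraction, the extent moment
TDNA × tail length, the Olive moment TDNA × (CMT − CPH) with CMT the
intensity-weighted mean tail column, and the moment of inertia the
DNA-normalized intensity-weighted squared column distance of the tail from
the CPH. Moments are stored as fraction × pixels, so a comet with
TDNA 74.84% and a 35 px tail has extent moment 26.19.

**Head threshold default.** HT is a user parameter; the package defaults
to 0.5 — the head ends at the profile's half-maximum. Much smaller values
are unusable as defaults: on any comet whose head/tail junction survives
binarization (i.e. whose mask is connected), the junction columns
integrate to far more than a few percent of the peak, so a low cut never
triggers until deep inside the tail and the measured head swallows it;
TDNA then saturates near 0.1 and stops tracking true damage. With
HT = 0.5 the measured TDNA of the synthetic sweep comets is monotone in
the generative damage fraction across 0–0.9. One consequence: a pure
Gaussian disc has a nonzero "tail" (the sub-half-max fringe right of
CPH + r, ~6% of mass); callers wanting literal zero should test
`tail_length` rather than TDNA.

A negative tail distance (CMT left of CPH) is preserved and flagged,
never clipped. Degenerate comets (zero DNA) are emitted with a
`degenerate` flag rather than dropped.

**Background subtraction.** The ambient pedestal is not DNA: before any
intensity measurement the pipeline subtracts the median of sub-threshold
pixels from the smoothed image (clipped at zero). Without this, the
pedestal inflates large faint tails relative to compact heads and biases
TDNA upward by ~0.05 at the synthetic noise level.

## Stage parameters

| parameter | default | units | role |
|---|---|---|---|
| smoothing_method / window | median, 5 | px | impulse-noise suppression before thresholding; window 1 disables |
| histogram_bins | 256 | — | matches 8-bit input |
| histogram_smooth_window | 5 | bins | moving average before the valley search; raw histograms are too jagged for "first valley" to be well defined |
| threshold_method | valley | — | first strict local minimum after the first local maximum of the smoothed counts, leftmost of plateau; falls back to Otsu when no valley exists |
| head_threshold (HT) | 0.5 | fraction of peak | head extent (above) |
| small_fragment_fraction | 0.001 | of image pixels | components strictly smaller are merged into the nearest large component (ties: larger, then lower label), or deleted when none exists |
| wavelet_level | 2 | — | Haar decomposition depth for relief smoothing; level 1 equals 2×2 block averaging, which makes the step testable in closed form |
| seed_prominence_h | 1.5 | distance units | regional maxima of the smoothed relief shallower than h are suppressed (grayscale reconstruction) before watershed seeding |
| horizontal_overlap_min | 0.5 | of the smaller span | column-range overlap above which 8-adjacent chunks stacked in y are re-merged |
| fourier_roundness_min | 0.70 | of spectrum sum | minimum share of the ±1 contour frequencies (DC excluded from both sums; ≥, not >) |
| area_ratio_min | 0.03 | of parent mask | minimum chunk area |
| centroid_match_radius_px | 15 | px | detection scoring radius |
| tail_direction | +x | — | −x mirrors the image before measurement |

Foreground is strictly greater than the threshold, keeping the background
peak bin in the background. Borders are handled by replicate padding in
the smoothing filter, so image size is preserved for labeling.

## Overlap correction

Per candidate component: Euclidean distance transform (the frame outside
the image counts as background, so border pixels get distance 1) → Haar
smoothing → h-maxima suppression → watershed → horizontal merging →
validity. The watershed is implemented directly with fully specified
tie-breaking so it can be checked against a brute-force flooding oracle:
basins grow from the regional-maximum plateaus (numbered in raster order)
one altitude level at a time; within a level each pixel takes the label of
the geodesically nearest labeled pixel through the level set, ties to the
smallest label. The h-maxima step is load-bearing: the distance ridge of
an elongated tail is nominally flat, and contour jitter that survives the
wavelet would otherwise seed one basin per ripple and shred the tail.
h = 1.5 px suppresses those ripples while preserving the saddle between
two genuinely distinct heads, whose prominence is set by head geometry
(several px). Invalid chunks are merged into their largest valid
8-adjacent neighbor — preserving DNA totals — or dropped when no valid
neighbor exists; a chunk must additionally clear the absolute
small-fragment cutoff, so debris absorbed during filtering cannot be
re-emitted as a comet. If no chunk at all passes validity the component is
kept whole: it was already a retained candidate.

The contour spectrum traces the outer boundary by clockwise Moore-neighbor
tracing from the topmost-then-leftmost pixel (Jacob's stopping criterion),
resamples it to 64 points by arc length, and takes DFT amplitudes of
col + i·row with DC discarded. DC carries only the centroid, so "the two
lowest frequencies" are the ±1 pair.

## Classification

Crops are resized (bilinear) to 50×50; the 25×50 left half captures the
apoptotic nucleus, which always sits left. HOG geometry — 9 unsigned
orientation bins, 8×8-pixel cells, 2×2-cell blocks at 1-cell stride, L2
block normalization — is the unique standard configuration giving exactly
900 features on 50×50 (6×6 cells) and 360 on 25×50. The box-ratio (bbox
width/height) separates the horizontally long necrosis type. Classifiers:
a cascade of three pairwise linear SVMs (normal-vs-necrosis first, the
winner then meets apoptosis — the aggregation order follows the pair
listing, the topology being otherwise unspecified), a single softmax layer
(multinomial logistic regression), AdaBoost with 200 depth-1 trees, and a
CART capped at depth 10. Scores are averages over stratified 10-fold
cross-validation, fully seeded.

## The synthetic generator

Each comet is an isotropic Gaussian head of peak (1 − damage) × head_peak
plus a tail band starting one head-sigma right of the center and carrying
the `damage` fraction of total mass: exponential x-decay over the tail
length with a gentle scale (1.5–3× the length), and a sharp-edged
super-Gaussian (power 4) vertical cross-section. The band-like tail is
what keeps scene histograms bimodal — a dominant background peak, a
sparse mid-range, and comet-intensity modes — which is the structural
premise of valley thresholding; soft Gaussian halos with steep decay fill
the mid-range and erase the valley. Archetypes: *normal* (peak 180–220,
damage ≤ 0.08, short tail), *necrosis* (peak 160–200, damage 0.35–0.6,
tail ≥ 3.2 sigma), *apoptosis* (peak 65–72 — at most 40% of the necrosis
default — damage 0.7–0.85, wide diffuse band; its mass and hence its
detected centroid are tail-dominated, as in heavily damaged cells whose
head is nearly gone). Noise: additive Gaussian background (mean 10,
s.d. 3) plus signal-dependent jitter (s.d. 0.5·√intensity), clipped to
0–255. Debris are sub-fragment-cutoff Gaussian speckles so the filtering
stage is exercised.

Scenes place comets away from the border (the border filter would delete
true comets, which the ground truth still counts) with clearance between
non-overlapping comets; ⌈overlap_rate × n⌉ pairs are displaced 0.65–0.95
of the partner's length along +x with small y jitter — overlap chains run
along the electrophoresis axis — and pair adjacency is verified on the
rendered masks, with retries. Ground truth per comet: the noiseless
render's mask above an intensity floor of 5 (a ~2σ camera detection
limit), its intensity-weighted centroid, and a record computed from the
noiseless render by the same profile equations the pipeline uses.

The damage-sweep comet used for parameter recovery fixes the geometry
(σ = 6, saturating 420 peak so the rendered head clips at 255, vertical
half-width 4.5) and elongates the tail with damage (length 380 × damage,
decay 1200) at roughly constant band brightness — migrated DNA spreads
further, not denser. This keeps the head column the profile maximum and
the head/tail gap below the half-max cut across damage 0–0.9, the regime
where measured TDNA tracks the generative fraction one-to-one.

**What the generator does not emulate:** optical PSF blur, uneven
illumination, agarose texture, saturated blooming, ragged real tail
margins, or biological shape variability. Passing tests therefore
demonstrate algorithmic correctness and internal consistency of the
pipeline under its own stated model — not accuracy on real micrographs,
whose detection scores and classifier accuracies will be lower.

## Evaluation choices

Centroid matching is greedy in order of increasing distance, one-to-one,
accepting pairs within the radius. Greedy is deterministic and attains the
maximum matching at realistic comet spacing (~100 px); in adversarial
dense packings it can be one pair short of optimal, which is accepted.
Undefined precision/recall (zero denominators) are reported as 0 with an
explicit flag so batch averages stay computable. The equivalent-confidence
computation uses normal quantiles by default (interval width ∝ z/√n, so
conf_sub = 2Φ(z_conf·√(n_sub/n_full)) − 1; 95% at 50 comets ↔ 92.4% at
41); a Student-t reading is available via `use_t=True`. Both readings are
provided because the two conventions genuinely differ and neither is
canonical for this use.

## Problem sizes

The bundled studies use 512×512 scenes with 15–25 comets (ten scenes for
the detection study), 200 single-comet renders for parameter recovery, and
60 comets per class for classifier demonstrations — sizes at which every
result in the test suite and acceptance script reproduces in well under a
minute each on one CPU, while exercising all failure modes the larger
images would (overlaps, debris, faint objects).

## Known limitations

- Deeply overlapping comets whose merged mask has a single distance
  maximum cannot be split; they surface as one detection between two
  truths. This bounds the synthetic detection F1 at roughly its observed
  0.90–0.94.
- The first-valley threshold adapts to the faintest object mode present;
  scenes whose faintest comets sit just above the valley lose their
  fringes, and region-based recall is accordingly modest even when
  centroid-based detection is high.
- Horizontal merging deliberately sacrifices genuinely vertically
  overlapping comets (rare under electrophoresis geometry) to repair
  horizontally divided single cells.
- The classifier accuracies reported by the examples reflect cleanly
  separable synthetic archetypes; they are demonstrations of the feature
  pipeline, not performance claims.
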