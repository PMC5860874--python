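# Methods

This note documents the models, defaults, and design choices behind
`flygroom`, and what the synthetic validation does and does not show.

## Analysis clock

Videos are native 10 Hz; analysis runs on every second frame (5 Hz),
which is fast enough to resolve grooming leg movements while halving
the work. Feature vector *i* describes the pair of analyzed frames
(*i*, *i*+1) and carries the later frame's index.

## Background model

The reference frame is one randomly chosen *template* frame with every
dark moving object erased: for each of seven randomly chosen *contrast*
frames, any template pixel darker than the contrast pixel by more than
C0 = 10 gray levels is replaced by the (brighter) contrast value. The
result is, up to C0, the per-pixel maximum over the eight frames, and
contains no fly as long as the fly moved at least once between the
template and some contrast frame at each of its pixels. Seven contrast
frames make a coincidental full overlap unlikely. Backgrounds are
regenerated every 1000 s (`background_interval_s`) so slow scene
changes (food level, debris) do not accumulate.

Two stabilizing choices are this package's own:

* **Background denoising.** The finished background is smoothed with a
  3×3 median filter (`denoise=True` in `build_backgrounds`). The
  background is a single sensor frame, so its pixel noise is *frozen*
  for the whole 1000 s interval; without smoothing, any fly pixel whose
  contrast to the background happens to sit near C0 flickers in and out
  of the silhouette on every frame, which a resting fly manifests as
  spurious periphery movement.
* **Hysteresis foreground.** The pipeline's working mask seeds at
  `diff > C0` and extends each seeded component down to `diff > C0/2`
  (`extract_foreground_hysteresis`). The strict mask
  (`extract_foreground`, exactly `background − frame > C0`) remains the
  primitive and equals the hysteresis mask on noise-free input; the
  hysteresis variant only stops marginal silhouette pixels of lightly
  pigmented flies from toggling frame to frame. Both knobs exist
  because the appearance-robustness benchmark shifts the periphery to
  within 15 gray levels of the background, where the strict mask alone
  is unstable.

A fly immobile for longer than one refresh interval is absorbed into
the background and not detected; such gaps inherit the last detected
observation (`hold_last_position`), so the fly is treated as stationary
where it was last seen. A fly never detected anywhere is excluded with
an error.

## Segmentation and features

Foreground components use 8-connectivity; components smaller than
C1 = 25 px are erased (a component of exactly 25 px is kept). The
largest component inside each tube ROI is the fly; size ties go to the
first component in raster order. The body splits at the per-frame
median gray value: strictly darker pixels are core, strictly lighter
are periphery, and median-valued pixels fill the core up to
ceil(area/2) in pixel-index order, so the parts differ by at most one
pixel. The median is recomputed every analyzed frame (illumination can
drift); a per-interval median would also be defensible and is trivial
to add at the call site.

PM and CM are the sizes of the symmetric difference of the part's pixel
sets between consecutive analyzed frames — a one-sided count would
weigh appearing and disappearing pixels asymmetrically. Parts
correspond across frames by label (core to core, periphery to
periphery). CD is the absolute centroid displacement projected on the
tube's long axis; motion across the narrow tube is ignored, and
displacements below 0.5 px (sensor noise) are zeroed, with exactly
0.5 px retained. Features are normalized by SP = √area with PM and CM
square-rooted first so all three axes share the dimension of length;
the un-rooted alternative (PM/SP) is available via
`normalize_features(..., sqrt_areas=False)` but is not the default
because it makes the axes dimensionally inhomogeneous.

## Classifier

k-nearest neighbors in (nPM, nCM, nCD) space, Euclidean distance,
k = 10, neighbor search through a k-d tree
(`sklearn.neighbors.KDTree`); query results are identical to exhaustive
search, with exact distance ties resolved toward the lower training
index. Votes are majority; vote ties go to the nearest neighbor's label
if it is among the tied classes, then to the fixed class order
grooming < locomotion < rest. The axes are already commensurate by
construction, so no re-standardization is applied. Ten-fold stratified
cross-validation over k = 1…50 is available to re-examine the k = 10
default.

**Pruning.** A raw grooming frame keeps its label iff it lies inside at
least one contiguous 15-frame window containing ≥ 12 raw grooming
labels (window slid one frame at a time); failing grooming frames are
relabeled *locomotion*, and non-grooming labels never change. A stream
shorter than the window is treated as a single window of its own
length. The filter is idempotent and monotone in the minimum count;
both properties and equivalence to brute-force window enumeration are
tested.

**Training data.** No annotated corpus ships with the package.
`synthetic_training_set` renders scripted videos, extracts features
with the standard pipeline, labels each frame pair from the script, and
drops pairs that straddle a bout boundary (their features mix two
behaviors, as a human annotator would skip them). User-labeled CSVs
(`nPM, nCM, nCD, label`) import through `flygroom.io.read_training_set`.

## Ethogram

Sleep is quiescence ≥ 5 min (boundary inclusive); shorter rest is
"short rest". Feeding is proximity to the food coordinate within one
body length lasting strictly more than 3 s; body length is estimated as
the median per-frame fly extent along the tube axis (robust, and the
choice of estimator is otherwise free). Per-frame precedence is
sleep > feeding > classifier label, and feeding replaces only
locomotion and short-rest frames: walking to the food is what the
classifier sees, while grooming near food is still grooming and sleep
is defined purely by quiescence length. Binned series normalize the
final partial bin by its own frame count; lights annotation is LD 12:12
by default with DD supported.

## Rhythm analysis

**Periodogram.** Standard Lomb-Scargle power divided by the series
variance, so white-noise power is Exp(1)-distributed. The frequency
grid spans periods 1–48 h with spacing 1/(span × 16) — 16-fold
oversampling resolves circadian periods to well under half an hour on
multi-day series. The significance threshold is the extreme-value
formula `Power = −ln(1 − (1 − p)^{1/N})` with N the estimated number of
*independent* frequencies, for which the Horne & Baliunas (1986)
empirical formula `N ≈ −6.362 + 1.193 n + 0.00098 n²` (n = number of
samples) is used. Using the oversampled grid size for N would overstate
the threshold by 1–2 power units, because neighboring grid powers are
strongly correlated; the calibration is verified against a Monte-Carlo
null (2000 white-noise series) in the test suite, which agrees with the
analytic threshold to within ~0.25 power units. Dominant-period
extraction takes the argmax over a circadian band (16–32 h by default);
power ties report the lower period.

**Two-peak activity model.** Daily activity is modeled as two periodic
peaks (morning and evening) with plateau heights H_M, H_E and widths
T_M, T_E; outside its plateau each peak decays as
`exp(−b_decay · Δt_since_end)` and rises as
`exp(−b_rise · Δt_until_start)`, the two tails being summed; the
evening plateau is offset half a period from the morning one, and the
shared period T_0 is a free parameter. This continuous
piecewise-exponential template is this package's own fixed
parameterization of the morning/evening-peak picture (negative rates
describe tails that grow away from the peak). Fitting is bounded
least squares (`scipy.optimize.least_squares`, trf), deterministic
given the initial guess; the default init is a generic circadian guess
(T_0 = 24 h, 3 h plateaus, rates 0.3 h⁻¹, heights from the data scale).
Fits whose total peak height is negligible against the data scale are
flagged `degenerate`. Rate parameters are only identifiable when the
tails are visible but not collinear: very steep rates leave too few
bins on a tail, while very shallow ones make the evening-decay and
morning-rise tails overlap through the night. The recovery tests use
rates of 0.5–0.7 h⁻¹ on 8 days of 30-min bins, where all nine
parameters are well determined.

**Shuffling.** Randomized grooming is a uniform permutation of the
grooming bins; modified locomotion (or wake) is
`companion + grooming − randomized grooming`, with permutations redrawn
(up to 1000 times) until the modified series lies in [0, 1], so
wakefulness remains a valid fraction. The subtraction is grouped as
`companion + (grooming − randomized)` so the identity permutation is an
exact no-op and the conservation identity holds to one rounding per
bin. A fixed permutation can be supplied for testing.

**Correlations.** Pearson r by the standard product-moment definition;
significance by re-pairing x with permutations of y (100,000 resamples
by default) and a two-tailed empirical p with a +1 continuity
correction, so p is never exactly zero and has resolution
1/(n_resamples + 1).

## Synthetic data: what it emulates, and what it does not

The renderer draws an elliptical two-tone fly (inner half of pixels at
the core gray, outer half at the periphery gray; defaults 40/90 on a
120 background, area 300 px, Gaussian sensor noise sd 2) inside a tube
ROI (64×420 px by default, food coordinate at the left end). Behavior
is rendered faithfully at the feature level:

* rest/short rest/sleep — identical fly pixels frame to frame;
* grooming — each frame, a random 10–40% of periphery pixels are
  re-drawn at adjacent free positions (core static; centroid shift
  ≤ ~0.2 px, safely under the 0.5 px CD floor), reproducing the
  PM ≫ CM, CD ≈ 0 signature without modeling limbs;
* locomotion — whole-body translation of 1 px per native frame along
  the tube (≥ 2 px per analyzed pair), bouncing at the tube ends;
* feeding — stationary with the centroid parked within one body length
  of the food coordinate; a feeding bout begins with an instantaneous
  relocation there (the script generator does not track position), so
  the single frame pair at the bout start is not behavior-faithful.

Bout scripts alternate behaviors drawn with fixed weights; bout lengths
are exponential around per-behavior means (grooming 13.8 s and
locomotion 26.4 s — the field-typical ~0.23 and ~0.44 min event means —
feeding 10 s, short rest 45 s, sleep 20 min), floored at one analyzed
frame pair, with sleep shifted to ≥ 5 min and short rest truncated
below 5 min. The exponential is a stand-in: only means and maxima of
real bout lengths are well established, and nothing here is an
inference about fly biology. An optional two-peak daily profile
modulates the choice weights of the active behaviors to emulate
circadian structure.

Consequences for interpretation: the synthetic benchmark shows that the
pipeline recovers the *feature-level* signatures it was designed
around, with clean class geometry — rest at the origin, locomotion at
high nCD, grooming at high nPM and near-zero nCD. Real flies produce
broader, overlapping clusters (partial-body locomotion, slow drifts,
stretching), so the ≈99% synthetic precision/recall is an upper bound
on, not an estimate of, real-video performance; conversely the
benchmark does exercise the full chain (background refresh,
segmentation noise, gap filling, pruning) under appearance shifts of
±30% area and ±15 gray levels with the classifier trained only on the
default appearance.

## Problem sizes

Default validation sizes, chosen to exercise the pipeline at realistic
scale: training fixture of three 2-min videos (~1800 labeled frame
pairs); benchmarks of ten 10-min videos per appearance (~30,000
evaluated frame pairs each); spectral calibration over 2000 white-noise
series of 4 days at 30-min bins; model-recovery fits on 8-day series.

## Known limitations

* One fly per ROI; no identity tracking, occlusion, or multi-fly logic.
* The renderer does not model limb kinematics, photorealistic texture,
  food depletion, or condensation; background drift is available only
  as a uniform brightening.
* Grooming subtypes (head vs. wing) are out of scope; the classifier is
  three-class by design.
* AVI I/O requires an ffmpeg-capable imageio backend; the package's own
  video interchange format is a numbered PNG sequence (plus in-memory
  arrays).
* The analytic spectral threshold assumes approximately independent
  Gaussian bins under the null; heavy-tailed or strongly autocorrelated
  noise would need the permutation route instead.
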