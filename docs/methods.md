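# Methods

This note documents the models, statistical procedures and numerical choices
behind `v4domains`, and what the synthetic-data generator does and does not
emulate.

## Response model and windows

The elementary measurement is the trial-locked fractional fluorescence
change ΔF/F0. Per trial, F0 is the mean fluorescence over frames whose
midpoints fall 0–0.5 s before stimulus onset and F the mean 0.5–1.25 s
after onset; ΔF/F0 = (F − F0)/F0, averaged over a stimulus's successful
repeats for mean maps. Window membership uses the half-open interval
[t0, t1) on frame midpoints, which is unambiguous at 8 frames/s where 0.5 s
is exactly a frame boundary: the pre-window covers 4 frames and the
post-window 6. Pixels whose F0 falls below 10⁻⁶ of the frame median are
masked (NaN) for that trial rather than clamped; masked pixels propagate as
explicit missing values.

Motion correction estimates one integer (dy, dx) per frame as the argmax of
the mean-subtracted 2-D cross-correlation with a template; constant
(zero-variance) frames tie-break to (0, 0), and frames whose estimated
shift exceeds a configurable bound (default 10 px) are flagged and excluded
from response extraction. Subpixel refinement is deliberately absent: the
synthetic jitter is integer-valued and the statistical stages are
insensitive to sub-pixel residuals at these soma sizes.

## Widefield domain detection

Trials are grouped into three categories (curves, corners, bars). Per
pixel, the target category's per-trial ΔF/F0 values are compared with each
of the other two by two-sample t-tests; the pixel's p-value is the **larger**
of the two when the target's mean exceeds both other means and 1 otherwise —
a one-sided selection rule that only credits pixels where the target is
strongest against *both* alternatives. Zero-variance pixels get p = 1.

The p-map is corrected by Benjamini–Hochberg: raw q_i = p_i · N / rank(p_i)
followed by the step-up monotonization, thresholded at q = 0.01. Surviving
connected components (8-connected) are screened by a max-cluster-size
permutation test: each permutation relabels all trials into the three
categories with counts preserved, recomputes the pixel p-map, thresholds at
uncorrected α = 0.01 and records the largest component. The cluster-size
threshold is the order statistic at ceil((1 − tail)·n_perm) of the null
(top 5% at the publication scale of 60,000 permutations, i.e. 3,000 null
entries above it); observed clusters must strictly exceed it, which treats
ties conservatively. By default observed clusters are defined on the FDR
mask; a flag moves them to the same uncorrected-α mask the permutations
use, which makes the screened statistic exactly exchangeable with its null
(used by the calibration tests). Permutations can run on block-mean
downsampled responses (default off in the library, 2–4× in pipeline
configs) with sizes rescaled by the square of the factor; this is an
efficiency device, not part of the statistical definition. Gaussian
smoothing (σ = 10 px at the publication scale) is applied to display maps
only — never to the per-trial responses entering statistics.

## ROI segmentation

Somata are detected on band-passed (difference-of-Gaussians, σ = 2 and
5 px) per-stimulus ΔF maps, binarized at mean + 3 SD of the filtered
pixel distribution (a median/MAD variant is available for fields with
bright artifacts), 8-connected components larger than 25 px kept, and
components whose maximum raw ΔF/F0 is below 0.3 dropped. The roundness
criterion C = P²/(4πS) < 1.1 is applied last with P estimated by the
4-direction Crofton formula; a naive boundary-pixel count overestimates P
for small discrete disks and would reject genuine somata. Calibration on
rasterized disks gives C within [0.94, 1.01] for radii ≥ 5 px (the r = 5
disk dips to ≈ 0.94; larger radii sit within ±5% of 1). ROIs detected on
different stimulus maps are merged when their centroids are closer than one
soma diameter (8 px default); the merge radius is a free parameter recorded
in config. Responsiveness is a two-group one-way ANOVA of pre- versus
post-window ROI fluorescence over all trials (algebraically a t-test,
F = t²); it is reported per ROI but not used as a filter.

## Selectivity indices

All indices are contrasts (a − b)/(a + b) on maximal family responses with
a, b ≥ 0: CVSI (curve vs. the joint best of bars and corners), CNSI
(corner vs. bars and curves), CVCNI (curve vs. corner), CVPII (curve vs.
Π-shape), CRI (concentric vs. radial gratings). The maximal response is the
maximum of mean-over-repeats responses within the family (ties to the
lowest stimulus id); the optimal stimulus is frozen from the means *before*
any repeat-level test, avoiding selection bias inside the test. Negative
mean responses, possible under noise, are floored at 0 before the contrast;
an index whose two maxima are both 0 is undefined and reported as NaN,
never as 0. The headline CRI uses the maximum over the three spatial
frequencies per grating class; per-SF CRI values are emitted alongside.
Index significance is a one-way ANOVA across the per-repeat responses at
the two optimal stimuli. Orientation tuning combines a pre/post
responsiveness ANOVA with an ANOVA across the 8 orientations of the optimal
curve/corner form, the latter Bonferroni-multiplied by 14 (6 corner + 8
curve forms) and capped at 1; a neuron counts as tuned when both pass 0.05.

## Spatial statistics

Pairs are formed within one imaging field only. The pairwise tuning
correlation is the Pearson correlation of the two neurons' mean responses
to all bar, curve and corner stimuli (Π-shapes and gratings excluded);
|ΔCVSI|, |ΔCNSI| and |ΔCVCNI| are absolute index differences. Profiles bin
distance every 100 μm, half-open [k·100, (k+1)·100), reporting mean ± SE;
empty bins are marked, never interpolated. Per-bin significance shuffles the
statistic-to-distance assignment (the distance multiset is invariant)
n_shuffle times and flags a bin when its observed mean lies strictly beyond
the k-th smallest or k-th largest shuffled bin mean, k = ceil(0.001 ·
n_shuffle) — at the publication scale of 100,000 shuffles, beyond the top
or bottom 100 (two-sided p < 0.001). Bins with fewer than 2 pairs are
marked untested.

## Population analysis

The response matrix R (forms × neurons) takes each neuron's maximum
mean response over a form's 8 orientations; the single-cell contour
protocol yields 20 forms (2 bars, 8 curves, 6 corners, 4 Π-shapes). Rows
are not standardized (raw responses; z-scoring is available behind a flag
in the caller's hands simply by transforming R). K-means uses squared
Euclidean distance with uniform random point seeding, best-of-restarts by
within-cluster sum (10,000 restarts and 10,000 iterations at the
publication scale), and the cluster count maximizing the Calinski–Harabasz
criterion over candidates (2–8 for forms, 2–10 for neurons; ties prefer the
smaller k). Classical MDS double-centers the squared dissimilarities
D = 1 − corrcoef(RP_i, RP_j), eigendecomposes, truncates negative
eigenvalues to zero for coordinates (1 − correlation is generally
non-Euclidean; the negative eigenvalue mass is recorded), and reports the
normalized stress Σ(D − D′)²/ΣD².

## Synthetic-data generator

The generator defines the study conditions for every test:

- **Layout** — non-overlapping circular curve- and corner-preferring
  domains placed by seeded rejection sampling on the imaging canvas
  (default 160×160 px at 1.7 μm/px; domain radius 30 px ≈ 50 μm at
  default, 80 px ≈ 136 μm in the clustered statistics fields, matching a
  domain transition scale of ~300 μm).
- **Neurons** — uniform positions; class from the containing mask (with a
  configurable impurity rate), unselective ("none") outside. Tuning is
  `peak_dff × class_gain × orientation_gain`: class gain 1 for the
  preferred family and `class_bias` (default 0.25) otherwise; orientation
  gain a von Mises bump exp(κ(cosΔ − 1)), κ = 2 by default, period 180° for
  bars and Cartesian gratings, 360° otherwise, none for concentric/radial
  gratings. Curve-preferring neurons treat Π-shapes as non-preferred
  (smoothness selectivity) and concentric gratings as preferred-like;
  corner-preferring neurons treat Π-shapes and radial gratings as
  preferred-like. Unselective neurons keep orientation tuning so any single
  stimulus map shows a sparse subset of responders, as in real fields.
  A pure curve-preferring neuron with bias b therefore has CVCNI =
  (1 − b)/(1 + b), the closed form the tests exploit.
- **Movies** — 2 s trials (1 s blank, 1 s stimulus) at 8 fps; somata are
  Gaussian disks truncated at the soma radius, summing where they overlap,
  on a constant background (default 20 fluorescence units vs. 100 at soma
  peak). Evoked transients follow a difference-of-exponentials kernel
  (0.1 s rise, 0.6 s decay, GCaMP-like) normalized so its mean over the
  post-window frames is 1, making the extracted windowed ΔF/F0 equal the
  planted amplitude exactly in the noise-free, zero-background case. The
  transient is truncated at the end of the response window; no analysis
  window looks past that point, and truncation keeps the next trial's
  baseline window clean. Background fluorescence attenuates pixel ΔF/F0 by
  B/(bg + B) — uniformly per neuron, so all contrast indices are unchanged.
  Per-trial log-normal gain noise, Gaussian pixel noise and per-frame
  integer motion jitter are optional; all randomness flows from one seed.
- **Two populations per pipeline run** — a sparse single-cell field (100
  neurons, soma radius 4 px by default, ~10–20% pixel coverage) for
  segmentation and indices, and a dense field (600 neurons, radius 3 px)
  whose overlapping somata produce the quasi-continuous signal of low-power
  widefield imaging, used for domain detection. This mirrors the
  two-objective design of the recordings.

What the generator does **not** emulate: neuropil contamination, indicator
nonlinearity and saturation, vasculature and occlusion, non-rigid motion,
bleaching, eye-position jitter, and correlated (shared) trial-to-trial
variability. Passing tests therefore demonstrate the correctness and
calibration of the analysis chain under its stated assumptions, not
robustness to those artifacts.

## Problem sizes and reduced scales

The publication-scale permutation counts (60,000 cluster permutations,
100,000 pair shuffles, 10,000 K-means restarts) are defaults in
`PipelineConfig` and reachable with `--full-scale`. Demos and the test
suite run reduced but statistically meaningful scales — hundreds of
permutations, thousands of shuffles, tens of restarts — on fields of
96–160 px and 60–500 neurons, chosen so a complete end-to-end run finishes
in minutes on one CPU while every threshold (q, α, tail fractions, size and
roundness criteria) keeps its published value. Calibration tests use
binomial envelopes appropriate to their reduced replication counts.

## Known limitations

- Cluster-size thresholds from downsampled permutations are rescaled by the
  square of the downsampling factor — an area approximation adequate for
  screening but not an exact equivariance.
- ROI merging across stimulus maps by centroid distance can fuse genuinely
  adjacent somata in dense fields; detected counts undershoot planted
  counts there.
- The widefield false-positive calibration is exact only in the
  uncorrected-mask mode; with the default FDR-mask observation the test is
  doubly protected and conservative.
- The pairwise-distance loop is quadratic in neuron count; fields beyond a
  few thousand neurons would need a vectorized or binned implementation.
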