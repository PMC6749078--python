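# Methods

This note records the model, the conventions the implementation commits
to where the method as usually described leaves room, and what the
synthetic generator does and does not emulate.

## Pipeline model and assumptions

The input is a region-by-time BOLD matrix per subject per session,
assumed already denoised (band-pass filtering, nuisance regression and
any global-signal decision happen upstream; this package never touches
voxel data). Head motion is handled by deletion: volumes with framewise
displacement above `fd_threshold_mm` (default 0.3 mm) are removed, not
interpolated — interpolation would invent data — and windows are defined
on the concatenated post-censoring series. A subject retaining fewer than
`min_volumes` (default 200) volumes is excluded.

Windowed connectivity uses a rectangular window of `window_length_s`
(default 60 s; at TR 2.5 s that is 24 volumes, within the 50–60 s range
where windowed correlation estimates stabilize), stepped by
`window_step_volumes` (default 1). The number of windows over T usable
volumes is `floor((T − width)/step) + 1`. Correlations are Fisher
z-transformed with |r| clamped at 1 − 1e−7 so degenerate windows stay
finite. Proportional thresholding keeps exactly `round(density · N(N−1)/2)`
off-diagonal edges (default density 0.40), ranked by **signed** weight —
the analysis targets positive connectivity, so a weak positive edge
outranks a strong negative one; ties at the cut are broken by (row,
column) order with a warning. `group_positive_mask` (one-sided one-sample
t-tests with Benjamini–Hochberg FDR over edges) is provided as guidance
for choosing the density on real cohorts, where such masks typically land
near 0.4.

Eigenvector centrality is the leading eigenvector of the thresholded
window, computed after zeroing any surviving negative weights: the
Perron–Frobenius guarantee of a nonnegative, unique leading eigenvector
holds only for nonnegative matrices. Solver: dense symmetric
eigendecomposition up to 256 nodes, power iteration (tol 1e−10, cap
10 000 iterations) beyond; a degenerate leading eigenvalue raises rather
than returning an arbitrary vector. Disconnected windows use the
full-matrix eigenvector (mass concentrates on the dominant component) and
log the isolated nodes. Per-window vectors are z-normalized with the
sample SD (divisor n − 1); a constant vector becomes an all-zero row and
is flagged.

## Clustering conventions

Correlation distance `1 − Pearson(u, v)` over z-scored centrality vectors
is, after per-vector centering and norm scaling, half a squared Euclidean
distance; because the pipeline's samples are row-standardized, Lloyd
iterations with plain arithmetic-mean centroid updates descend
monotonically, and the implementation asserts this at every iteration
(1e−9 slack for float noise). Centroids are **not** re-normalized after
averaging — the simplest convention consistent with "a metastate pattern
is the mean of its members". k-means++ seeding uses the correlation
distance in the role of the squared distance. The group stage runs 10
random restarts and keeps the lowest inertia; ties in nearest-center
assignment go to the lowest state index. An empty cluster is re-seeded at
the sample farthest from its assigned center at the group stage, but at
the per-subject refinement stage the center is **kept** where the group
put it: a subject who never visits a state must not have that state's
center drift onto another state's windows, which would scramble the
subject-to-group state correspondence (this failure mode is reproduced in
the test suite).

The number of states is chosen by the elbow of the best-inertia curve,
operationalized as the k maximizing the second-order difference of the
curve over the scanned range (default 2..10); the mean-silhouette curve
(correlation metric) is reported alongside as a secondary diagnostic.
Cluster-validity indices differ across the literature and the elbow is
the rule this package commits to; both curves are saved so a user can
apply another rule. Cross-session (or cross-model) state correspondence
is the Hungarian assignment minimizing summed center correlation
distance.

## Dynamics and reliability conventions

Dwell time is the per-state window count (× TR for seconds); transition
"time" is a count of consecutive-window switches, with self-transitions
excluded, so the off-diagonal total equals the number of label changes.
The ICC is the pooled-moment formula

    ICC = Σᵢ (x₁ᵢ − x̄)(x₂ᵢ − x̄) / ((n − 1) s_x²)

with x̄ the mean of all 2n observations and s_x² their sum of squares
divided by **2(n − 1)**. This divisor is a deliberate convention: it makes
a perfectly reproduced feature score exactly 1 (with divisor 2n − 1 the
duplicated case would exceed 1), anchoring the "1 = completely trusted"
reading. As printed, this is a Pearson-type consistency coefficient, not
a variance-components ICC(2,1)/ICC(3,1); it is reported raw — negative
values are possible and are not clamped — with the conventional 0.4/0.75
cutoffs applied to the raw value. ICC of dwell features uses window
counts; the TR multiplication is a common scale shared by both sessions
and the coefficient is invariant to it (asserted in tests). Features that
are constant across all subjects and sessions have no estimable
reliability and are reported as NA, not zero-filled. Bartlett and
Kolmogorov–Smirnov p-values ride along as heteroscedasticity/normality
diagnostics.

## Hubs and rich club

A hub is a region strictly above mean + `hub_sd_multiplier` × sample SD
(default 1) of its source pattern; the rule is affine-invariant. The
packaged reference hub lists (five metastates plus a structural list,
AAL-90 names) ship as a JSON fixture; intrinsic-subnetwork membership
tables are deliberately **not** invented — `overlap_rate` accepts any
user-supplied region set.

Rich-club analysis ranks nodes by weighted degree (strength), descending,
ties by label; the rank-r club is the top-r nodes. Φw(r) divides the
club's total edge weight by the sum of the equally many strongest weights
anywhere in the network, so Φ ∈ [0, 1] and Φ is undefined (NA) when the
club has no edges; the grid spans ranks 1..N−2. The null model rewires
topology by Maslov–Sneppen double edge swaps (10 × edge-count attempts,
degree sequence exactly preserved) and then reassigns the original weight
multiset to the surviving edges uniformly at random: degree sequence and
weight distribution are preserved exactly, strength sequence is not —
the standard "equal size, similar connectivity distribution" null.
Normalization divides by the null mean over `n_null` draws (default
1000); ranks where Φ is undefined in more than half the nulls are NA.

## Synthetic generator

The generator's defaults are the study conditions the package is sized
for: 23 subjects, two sessions, 5 states, 90 regions, 227 windows per
session at TR 2.5 s. (A protocol of 260 acquired volumes minus 10
dummy volumes, with a 24-volume window at step 1, gives
floor((250 − 24)/1) + 1 = 227 windows by the count formula; reports of
232 windows for this protocol do not satisfy the formula, and the
formula is what this package implements.) Remaining free knobs were fixed
once at field-plausible values: mean dwell 10 windows (25 s, consistent
with state durations of tens of seconds in windowed-correlation studies),
snr 5 (clearly separated but non-trivial states), retest ρ 0.8 (most
dwell reliabilities then land above the 0.4 cutoff, the regime the method
is designed to detect).

State sequences come from a Markov chain with geometric dwell; a
per-subject-state Gaussian latent modulates both entry propensity
(softmax weight exp(0.6 g)) and mean dwell (lognormal factor
exp(0.5 g − 0.125), mean-calibrated so the average dwell stays at
`mean_dwell`). Session II reuses session I's latent at weight ρ plus
fresh noise at weight √(1 − ρ²), which is what makes dwell/transition
reliability controllable and monotone in ρ. Centrality series are
zero-mean unit-SD hub templates (hubs at a common positive value,
non-hubs at a common negative value) plus N(0, 1/snr) noise, re-z-scored;
at snr → ∞ hub detection on a template returns exactly the planted set.
BOLD-like series are per-window latent-factor draws (hub loading 0.9,
background 0.25, noise SD 0.6) concatenated in width-volume blocks, so
windowing at the generator's width re-exposes the planted states.

What the generator does **not** emulate: hemodynamic autocorrelation and
its effect on window overlap, realistic fMRI noise spectra (scanner
drift, physiological cycles), motion artifacts, spatially structured
region covariance beyond the single shared factor, and non-geometric
dwell distributions. Passing recovery tests therefore demonstrates the
estimator chain is correct and well-calibrated under its own model, not
that real resting-state data contain k recoverable centrality states.

## Numerical and scale choices

Matrices are written as TSV at 10 significant digits (round-trip exact at
that precision); models as JSON. All randomness flows from explicit seeds
through `numpy` `SeedSequence` substreams (component-keyed by CRC32 so
streams are process-stable), making every fit and every generated dataset
bit-reproducible; the pipeline run is byte-identical given (inputs,
config, seed). Tests and the acceptance script run planted-recovery
problems at a few hundred to a few thousand windows and 20–90 regions —
sizes at which every assertion completes in seconds while all planted
structure is well above its recovery threshold. The group-level FDR mask
simulation uses 8-node networks and 200 replicates for the same reason.

## Known limitations

* Only the printed-formula ICC is implemented; variance-components ICCs
  and bootstrap CIs are out of scope.
* Rich-club ranking uses strength; binary-degree ranking is not offered.
* Tapered/DCC/wavelet alternatives to the rectangular sliding window are
  out of scope, as is any voxel-level preprocessing.
* The elbow rule is one defensible operationalization among several; on
  shallow inertia curves (single-blob data) its argmax is weakly
  determined, which is why the silhouette curve is always reported
  alongside.
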