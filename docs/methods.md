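# Methods

This note documents the models and procedures implemented in `resuskit`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.

## Data model

An *episode* is one newborn-resuscitation case: a list of timed annotation
records (activity name, start, stop, duration, in milliseconds from
recording start), optionally a time of birth (ToB) on the same clock, and
optional labels. An *activity profile* fixes the ordered list of `H`
activity channels for a dataset and thereby the code assignment; two
profiles are built in (a 6-activity SUS-style list and a 7-activity
Haydom-style list), with per-profile alias tables because annotation labels
are free text. Annotation times are treated as relative to recording start;
the ToB is carried out-of-band (in the label/metadata CSV) and used as the
time origin where a birth-aligned axis is wanted.

The duration column of an annotation file is validated (±1 ms against
stop − start, absorbing rounding in source files) but never trusted;
start/stop are authoritative.

## Periodic encoding

Activity `c_i` (1-based index in profile order, `i ≤ 16`) receives the code
`G_e(i) = 2^i − 1`. Episode `j` becomes an `H × N` integer matrix: entry
`(i, n)` is `G_e(i)` iff some record of `c_i` overlaps the half-open
second-bin `[(n−1)·1000, n·1000)` ms after the origin, else 0. Fusion sums
over activities: `x_j(n) = Σ_i G_j(i, n)`.

Key properties, all covered by tests:

- **Superincreasing codes.** `G_e(i) > Σ_{k<i} G_e(k)`, so all `2^H` subset
  sums are pairwise distinct (verified by brute-force enumeration for
  `H ≤ 10`). The largest allowed value for `H = 7` is
  `1+3+7+15+31+63+127 = 247`.
- **Exact decoding.** Greedy descent over `i = H..1` inverts any allowed
  value to its unique activity set; per-second decoding of a fused vector
  recovers exactly the activities active in that second.
- **Presence semantics.** Any overlap with a second-bin marks the whole
  bin (no minimum-overlap rule; this is the conservative choice that never
  drops an activity present in a second and reproduces the worked example
  for integer-second inputs). Overlapping records of the *same* activity
  collapse to a single code — otherwise fused values would leave the
  allowed set and uniqueness would break.
- **Fixed horizon.** `N = 720` s (the first 12 minutes) by default:
  episodes are truncated beyond it and zero-padded below it, giving fixed
  length vectors; the horizon is configurable.

All encoding arithmetic is integer; floats enter only at the autoencoder
boundary and in the projection back onto allowed values (nearest allowed
value, ties broken toward the smaller one).

## Timeline and aggregated views

The timeline view renders one episode as per-activity lanes of merged,
clipped intervals on a seconds-post-birth axis (ToB at second 0) and
derives per-activity onsets (e.g. ventilation onset relative to birth, the
quantity checked against the "golden minute" guideline). Requesting a
ToB-aligned view without a ToB is a configuration error directing the
caller to recording-origin encoding.

The aggregated view maps a whole dataset onto a 2-D grid: one point per
(episode, distinct nonzero fused value observed in that episode) — a
denser per-second variant is available behind a flag — with the category
axis enumerating the distinct fused values observed dataset-wide, sorted
ascending, and labelled by "+"-joined activity acronyms obtained by
decoding each value. Raw fused values are deliberately *not* normalized or
standardized; color encodes the value itself. Any true k-nearest-neighbor
graph overlay is out of scope: the view's information content is the
(episode, combination, value) triple set.

## Synthetic datasets

Real annotated resuscitation datasets are private, so the generator
produces structurally equivalent data: per episode, each activity draws
presence (Bernoulli), a bout count (1 + Poisson), a first-bout onset
(normal, clipped at 0), lognormal bout durations and exponential
inter-bout gaps; bouts are clipped to the horizon and written through the
same file writer the parser reads (bouts shorter than 0.5 s are dropped).
Distribution choices are the package's own, picked to be simple to invert
for oracle tests while matching the order of magnitude of published
per-activity bout counts and durations (several ~7 s stimulation bouts per
episode, a few ~25 s ventilation bouts, rare chest compression).

Outcome classes (normal / death / NICU admission, plus a binary NICU
protocol for SUS-style data) differ only in *timing and presence* patterns
— later ventilation onset, longer bouts and chest compression for adverse
outcomes — never in amplitude, because the encoding records presence only.
The generator returns exact per-episode bout bookkeeping so tests can
verify summaries and round trips against ground truth, and derives the
ventilation-presence label from the generated records, keeping it
consistent with the encoded data by construction.

What the generator does **not** emulate: annotation noise (missed or
mistimed annotations by human annotators), correlated activity sequences
driven by clinical state, inter-hospital protocol differences beyond the
activity lists, and class imbalance as extreme as real mortality rates.
Passing tests therefore demonstrate the correctness of the machinery and
the *mechanism* of the separability contrast, not clinical performance on
real data.

## Neighborhood component analysis

NCA is implemented from scratch (`resuskit.nca`). Given `D × M` inputs and
labels, it learns `A ∈ R^{2×D}` maximizing the expected number of points
softly assigned to a neighbor of their own class:

    P_jk = exp(−‖w_j − w_k‖²) / Σ_{l≠j} exp(−‖w_j − w_l‖²),  w = A x,
    f(A) = Σ_j Σ_{k: y_k = y_j, k≠j} P_jk,      0 ≤ f ≤ M,  P_jj = 0.

Numerical choices:

- Inputs are mean-centered per feature before optimization (no variance
  scaling).
- Row-wise log-sum-exp stabilization so the largest within-row exponent is
  0 — essential on raw fused data, where squared distances reach 10^5 and
  every exponential underflows.
- The analytic gradient `2 A Σ_{jz} (p_j P_jz − P_jz·[same]) d_jz d_jzᵀ` is
  evaluated through a graph-Laplacian identity as `2 (A X) L Xᵀ`, costing
  `O(M²d + MDd)` per iteration instead of `O(M²D)`; it matches central
  finite differences to 1e−5 on random instances.
- Maximization by Polak–Ribière conjugate gradients with automatic
  restarts and a backtracking Armijo line search; the accepted-step
  objective trace is non-decreasing by construction. Initialization is a
  seeded Gaussian with std `1/√D`; stopping at relative objective change
  < 1e−7 or `max_iter` (500 default, 300 in the pipeline).

The embedding dimensionality is 2 (the visualization target); scikit-learn's
`NeighborhoodComponentsAnalysis` maximizes the same objective and serves as
an independent cross-check in the test suite, never as the implementation.

## Sparse autoencoder and AE-NCA

The autoencoder is shallow — input `N`, bottleneck `d`, output `N` — with
the saturated-linear transfer `a(u) = min(1, max(0, u))` on encoder and
decoder outputs. Reference hyperparameters: 4000 epochs, L2 coefficient
1e−4, KL-sparsity coefficient 0.01 with target mean activation 0.05,
bottleneck 360 for the 7-activity profile and 500 for the sparser
6-activity profile (≈ half the input dimensionality, enlarged for sparsity),
training seeds 0 (outcome task) and 42 (ventilation task). The sparsity
penalty applies to the hidden layer only. A per-feature weighting hook for
the reconstruction error exists but defaults to uniform.

Design decisions that required care:

- **Input scaling is per-feature min–max** into [0, 1] (the activation's
  range). A single global scale (dividing by the maximum allowed value,
  247) makes the numerically small codes require ~0.2% absolute precision
  and concentrates residual errors exactly on them; per-feature scaling
  equalizes the precision demanded of small and large codes and is what
  standard autoencoder tooling with range-limited transfer functions does.
  Constant features (e.g. all-zero trailing seconds) carry zero range and
  are reconstructed exactly by the inverse affine map.
- **Optimizer: full-batch L-BFGS** for exactly `epochs` iterations
  (deterministic given the seeded initialization). Reaching
  lossless-after-projection needs every entry reconstructed to under half
  a code gap; a first-order method at a fixed learning rate cannot get
  there within the epoch budget on this loss surface, while quasi-Newton
  batch methods (the family used by the standard tooling for this model
  class) can. Plain and momentum gradient descent remain available as
  `optimizer="gd"` / `"momentum"`, where the `lr` and `momentum`
  parameters apply.
- **Boundary-recovery subgradient.** The clipping activation has zero
  derivative outside (0, 1); taken literally this permanently freezes any
  output unit whose pre-activation leaves the interval (observed: ~36% of
  entries stuck wrong). The backward pass therefore takes the boundary
  subgradient as 1 exactly when the loss gradient points back into the
  linear region. The true loss is still flat on such plateaus, so when the
  L-BFGS line search stalls there, training spends a slice of the epoch
  budget on momentum-GD steps (which cross plateaus) and then resumes
  L-BFGS with fresh curvature memory.
- Weights initialize from a seeded Gaussian (std `1/√fan-in`), encoder
  biases at 0.1 (all hidden units start in the linear region), decoder
  bias at the scaled data mean.

After training, the reconstruction is rescaled to code units and projected
entrywise onto the allowed-value lattice; the *lossless fraction* is the
share of entries where the projection equals the input. At the reference
settings on the 100-episode synthetic set this fraction is exactly 1.0 —
the bottleneck removes only redundancy.

**AE-NCA vs NCA.** The pipeline runs both routes under the labeling
protocol (outcome: binary NICU or multi-class normal/death/NICU/stillborn;
ventilation presence: binary, derivable from the encoding itself when no
label table provides it). NCA fitted directly on the centered fused matrix
barely moves: squared pairwise distances of raw code vectors are so large
that all soft-neighbor probabilities collapse onto single nearest
neighbors and gradients vanish — the embedding stays essentially random.
On the autoencoder's latent codes (entries in [0, 1]) the same NCA
separates the outcome classes. Separability is quantified by the
silhouette score (plus a within/between-class distance ratio and the final
NCA objective); the metric choice is this package's own, made to turn a
visual clustering claim into a testable number. With fewer than two
classes the metrics report null with a reason. The autoencoder is
retrained per label task with that task's seed.

## Problem sizes and determinism

The reference checks use: the deterministic 10-second worked example
(exact, integer arithmetic); 50 synthetic episodes × 720 s for the decode
round trip; a 100-episode, 720-second Haydom-like set with bottleneck 360
and 4000 epochs for the lossless-reconstruction check; and ten
seed-replicates of the 100-episode set with a 400-epoch autoencoder for
the separability contrast (the latent space needs to be useful, not
lossless, for clustering, and the contrast is insensitive to the remaining
epochs). Unit tests use smaller instances of the same generators. Every
stochastic component (generator, initializations) is driven by explicit
integer seeds; repeated runs are bit-identical within one platform's
floating-point environment.

## Known limitations

- Sub-second resolution is out of scope; the encoding is per-second
  presence, without intensity or weighting.
- The aggregated view reproduces the information content of the published
  dataset-level scatter; the nearest-neighbor-graph machinery cited as its
  inspiration is under-specified as a visualization recipe and is not
  reimplemented.
- One published symbol (an "orthogonal learnable metric distance" Q) never
  appears in any equation of the source description and is left
  unimplemented.
- Silhouette on a 2-D *training* embedding measures how well the learned
  map separates the episodes it was fitted on — the published claim is
  visual, not generalization performance; no held-out evaluation is
  implied.
- Mortality risk prediction and automated activity recognition from video
  are explicitly out of scope.
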