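# Methods

`fcx` implements a complete analysis chain for dual-task
modality-compatibility experiments: behavioral scoring, task-state
functional connectivity (FC), network-level comparisons, and an edge-level
brain–behavior stability selection. This note documents the models, the
defaults and their units, the numerical choices, and what the synthetic
cohort generator does and does not emulate.

## Behavioral scoring

Trials come from sensorimotor choice tasks in four stimulus–response
modality pairs — visual–manual (VM), auditory–vocal (AV), visual–vocal
(VV), auditory–manual (AM) — performed as single tasks and as two dual-task
pairings: *modality-compatible* (VM+AV) and *modality-incompatible*
(VV+AM).

**Exclusion rules** operate per run before any scoring:

* a single-task block with more than five wrong-response-modality trials
  invalidates its run;
* a single-task or localizer run with more than 30% errors (omissions
  count as errors) is invalid;
* dual-task runs apply the 30% rule to congruent trials only (both stimuli
  mapped to the same response side), because overall dual-task error rates
  are legitimately high. By default the congruent error rate is averaged
  across the subject's two dual runs before comparison with 30%; a
  `within-run` mode evaluates each run separately (the averaging scope is
  genuinely ambiguous; both are implemented, `across-runs` is the default).
* A participant is excluded when one dual-task run, more than one localizer
  run, or more than three single-task runs are invalid. Runs containing
  both single- and dual-task trials are treated as localizer runs; the
  localizer criterion uses the plain 30% rule with no congruency carve-out.

**Balanced integration score (BIS).** Per subject × task-type × pairing
cell, mean RT is computed over correct trials with an observed response and
accuracy over all trials (omissions = errors). Single-task cells use easy
blocks only and average the pairing's two component tasks. BIS =
z(accuracy) − z(mean RT), so larger is better; z-standardization uses
sample statistics (ddof = 1) over the pooled set of all cells, separately
for RT and accuracy. The pooling choice follows the usual BIS
recommendation and is the reason BIS is invariant to affine rescaling of RT
units. A zero-variance pool standardizes to all-zero z-scores (logged)
rather than dividing by zero. The dual-task cost of a pairing is
BIS(single) − BIS(dual); the behavioral modality-compatibility effect is
cost(incompatible) − cost(compatible), tested with a paired t and a JZS
Bayes factor. The behavioral difference score used by the edge selection
is the dual-task BIS difference (incompatible − compatible), i.e. positive
= relatively better incompatible performance.

## Functional connectivity

A run enters the analysis only if mean framewise displacement (FD) is
below 0.2 mm, fewer than 20% of frames exceed 0.25 mm, and no frame
exceeds 5 mm.

**Nuisance regression.** The confound set is global signal, CSF, white
matter, three translations, three rotations and FD. Each confound enters
with a four-term expansion: raw value, backward-difference temporal
derivative (first frame 0), square, and squared derivative (the
Satterthwaite-style expansion). Whether FD receives the full expansion is
switchable (`expand_fd`, default on). Rank-deficient designs are solved
through the pseudo-inverse, which is equivalent to dropping collinear
columns, with a warning; residuals are exactly orthogonal to the design
span, making the regression an idempotent projection.

**Task regression.** Mean task-evoked activity is removed per region with
a finite-impulse-response basis — one indicator regressor per post-onset
lag 0..K−1 per condition label, K = 8 frames by default (with a 2 s frame
spacing this covers a canonical hemodynamic response). This prevents
stimulus-locked transients from inflating inter-region correlations while
leaving genuine region–region interactions in place.

**FC matrices.** Edges are Fisher-z transformed Pearson correlations,
`z = arctanh(r)`. Correlations of exactly ±1 are clipped to 1 − 1e−7
before the transform and flagged. Zero-variance regions produce missing
(NaN) edges that propagate pairwise-completely through every downstream
statistic; nothing is imputed. Condition matrices average runs
element-wise in z space; single-task FCs are computed per component task
first and only then averaged across a pairing's two components where a
per-pairing single-task matrix is needed.

## Network statistics

Regions carry one of the seven canonical functional-network labels
(visual, somatomotor, dorsal-attention, ventral-attention, limbic,
control, default). For each network N, `within:N` collects the edges among
N's regions and `between:N` pools all edges with exactly one endpoint in N,
giving 7 + 7 subsets; every edge lies in exactly one within subset or
exactly two between subsets. An all-pairs between-network mode (21
combinations) exists but pooled-per-network is the default aggregation.

The dissimilarity between two FC edge vectors a, b is the cosine distance
d(a, b) = 1 − ⟨a, b⟩ / (‖a‖‖b‖): 0 for proportional patterns, 1 for
orthogonal, 2 for antipodal, invariant to positive rescaling of either
argument. Euclidean distance and Pearson similarity of the edge vectors
are provided as robustness variants, as are mean (absolute or signed)
Fisher-z strength per subset.

**Graph metrics.** The FC graph uses |z| weights normalized by the matrix
maximum to [0, 1] (negative correlations enter by magnitude; a
positive-only mode is available — the weighting of negative edges is a
package decision, documented and configurable). Modularity is Newman's
weighted Q, by default on the a priori 7-network partition rather than a
data-driven one (reproducibility; a Louvain mode exists). Global
efficiency is the mean inverse shortest-path length over node pairs with
path lengths summing 1/weight; disconnected pairs contribute 0. Both
metrics are verified against explicit-enumeration oracles on all graphs
with ≤ 6 nodes.

## Inference

**JZS Bayes factor.** The default Bayes factor for one-sample/paired t
designs places a Cauchy(0, r) prior on the standardized effect under H1
(r = √2/2, "medium" — the conventional default; the prior scale is
configurable because analyses differ on it) against a point null, using
the standard auxiliary-g representation (g ~ InverseGamma(1/2, r²/2)).
The scalar implementation integrates adaptively with a relative accuracy
requirement of 1e−6 and is checked against an independent brute-force
trapezoid quadrature; the vectorized implementation used for edge-wise
screening evaluates a fixed 1024-point log-space grid in log arithmetic
(no overflow at extreme t) and agrees with the scalar route to ~1e−9
relative. BF10 > 3 is read as moderate evidence for a difference, and the
edge filter applies this threshold strictly.

**Mixed-model contrast.** Condition contrasts with covariates (age,
gender, mean FD, or valid-run counts) use a linear mixed model with a
subject random intercept, maximum-likelihood fit (statsmodels `MixedLM`).
A random slope for a two-level within-subject factor with one observation
per subject × level is not identifiable, so the random-intercept structure
is the default. With no covariates and balanced data the condition
estimate equals the paired mean difference to numerical precision (tested
to 1e−8); the Wald t is referenced to df = n − 1 − #covariates. Singular
fits fall back to the paired t test with a warning. p values are
two-sided throughout; multiplicity adjustment is Benjamini–Hochberg.

**Partial Spearman correlation.** All variables (x, y, covariates) are
rank-transformed with average ranks on ties; ranked x and y are
residualized on the ranked covariates plus intercept by least squares
(orthonormal QR basis, near-zero pivots dropped); rho is the Pearson
correlation of the residuals, with a t-approximation p value at
df = n − 2 − #covariates. Constant covariates reduce this exactly to the
plain Spearman correlation.

## Edge-level stability selection

Per subject, the edge-wise Fisher-z difference between the
modality-incompatible and modality-compatible dual task forms a subjects ×
edges panel. The screening pipeline is, in order:

1. one-sample JZS BF per edge; keep BF10 strictly > 3;
2. keep edges whose **both** endpoints overlap a localizer task-activity
   cluster;
3. partial Spearman correlation of each surviving edge with the behavioral
   difference score, controlling age, gender and mean FD (the FD covariate
   is the subject's mean over the two dual runs by default; an
   FD-difference mode exists); keep edges with uncorrected p < 0.05 — a
   deliberately lenient screen, because brain–behavior correlations are
   expected to be small.
4. leave-one-out stability: for each of the N subjects, the BF and cluster
   filters are re-applied on the remaining N−1 subjects and rho recomputed.
   Each candidate edge also receives a permutation null: 10,000 repetitions
   of (drop one random subject, permute the behavioral vector, recompute
   the partial Spearman), summarized by its 5th and 95th percentiles
   (linear/type-7 interpolation, for bit-reproducibility). An edge is
   selected iff it survives the filters on every fold **and** every fold
   rho falls outside the percentile band.

Two scope decisions were genuinely open and are fixed as follows: the
permutation null recomputes rho only (not the BF/cluster filters), and the
candidate universe is the full-sample surviving set — both match the
screening order above. Permutations are uniform (derangements are not
enforced). All permutation randomness derives from the global seed by
stage-name hashing, so any stage reproduces independently.

### Type-I behavior of the selection procedure

The cohort-level probability of any false selection under a null
(exchangeable) behavioral vector factorizes approximately as
E[#candidates after BF × cluster filters] × 0.05 × P(all folds outside the
band | screen passed). At n = 47 the BF > 3 filter corresponds to
|t| > 2.57 (≈1.3% of null edges), so the candidate count — and hence the
procedure's false-positive rate — scales with the square of the
task-cluster coverage fraction. With the generator's default coverage
(25% of regions tagged) the full pipeline yields an empty selection in
≥95% of null cohorts; at substantially denser coverage (≥40%) the
conjunction is no longer sufficient for a 5% cohort-level rate. Users
applying the procedure with broad candidate universes should tighten the
screen or the band accordingly.

## Synthetic cohort generator

The generator emulates the study design end to end so that every pipeline
stage has a ground-truth surface:

* **Time series**: zero-mean Gaussian draws obtained by multiplying white
  noise with the Cholesky factor of a block-structured target correlation
  matrix — `base_within_network_r` = 0.30 inside a network,
  `base_between_network_r` = 0.10 across networks (typical task-state FC
  magnitudes after nuisance regression). Condition-specific
  `effect_edges` add deltas to designated edges; targets pushed outside
  positive definiteness are repaired by eigenvalue clipping at 1e−8
  followed by diagonal re-normalization (logged). Defaults: 47 subjects,
  200 regions, 139 frames per dual-task run, one run per dual pairing and
  eight per single task.
* **Brain–behavior coupling**: a per-subject latent standard Gaussian u
  adds `coupling_fc_sd` · (r·u + √(1−r²)·e) (0.15 correlation units SD) to
  each coupling edge in the incompatible dual task, and shifts that
  subject's incompatible dual-task RT mean by −60 ms·u and error rate by
  −0.04·u. This yields a realized correlation between the FC difference
  and the dual-task BIS difference close to the nominal `coupling_r`
  (attenuated by FC estimation noise and trial sampling noise).
* **Behavior**: truncated-normal RTs (floor 150 ms) and Bernoulli
  correctness with per-condition parameters defaulting to the observed
  scale of this paradigm — dual RT means 752/869 ms (SD 194/230), dual
  error rates 17.2%/34.3%, single-task RTs ~508/471 ms with ~2.5% errors;
  128 trials per dual run, 16 per single block, with an easy and a
  difficult block per single run (difficult: +80 ms, +3% errors; excluded
  from BIS downstream). 20% of error trials are omissions (missing RT,
  no response modality).
* **Motion**: per-frame FD i.i.d. log-normal around a subject-specific
  median (0.08 mm group median, 0.25/0.40 log-SDs), so most runs pass the
  screening thresholds; spikes are injected explicitly when testing
  screening. Motion parameters, global/CSF/WM columns are pure noise
  regressors unless `confound_leak` mixes the global signal into the data.
* **Parcellation**: regions assigned round-robin to the 7 networks, with
  the first 25% of each network's regions tagged with a task-cluster label
  (see the calibration note above).

What the generator does **not** emulate: hemodynamic convolution and
autocorrelated noise (the analysis consumes only second-order structure),
physiological confounds, scanner drift, spatial structure within regions,
session/practice effects, and subject-level variation in the base
connectivity profile. Passing tests therefore demonstrate the statistical
machinery's correctness and calibration under the planted model, not
robustness to real-data artifacts upstream of parcellated time series.

## Problem sizes in the calibration experiments

The packaged calibration experiments use reduced but statistically faithful
sizes chosen to keep the full suite quick on a laptop: null calibration
runs 100 cohorts at n = 47 subjects, R = 50 regions, T = 300 frames with
500-draw permutation nulls; recovery runs 50 cohorts at n = 60, T = 500
with two planted edges (delta 0.3, coupling 0.6). The procedure itself is
size-agnostic; production analyses should use the full 10,000 permutation
draws (the default).

## Known limitations

* The congruent-trial exclusion scope and the between-network aggregation
  (pooled vs all-pairs) are configurable because the underlying design
  conventions vary between labs; defaults are documented above.
* The mixed model's compound-symmetry alternative is approximated by the
  random-intercept fit; richer residual structures are out of scope.
* The permutation null treats covariates as fixed when permuting behavior;
  with strongly behavior-correlated covariates a Freedman–Lane scheme
  would be preferable.
* Missing-edge handling is pairwise-complete; subsets with fewer than two
  usable edges raise rather than silently shrinking.
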