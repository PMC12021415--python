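# Methods

`flexwm` implements the computational pipeline of a flexible
working-memory (WM) study in which participants either maintain a
remembered orientation or categorize it under one of two orthogonal
boundary rules.  Every analysis stage runs on synthetic data with known
ground truth, so the whole chain is testable without any neuroimaging
download.  This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Task designs

Orientations live on the 180°-periodic circle; all angular arithmetic
is mod 180 with distances in [0°, 90°].  The standard sample sets are
30 orientations in 6° steps.  The package defaults to the 4°–178° grid
for both experiments: of the two standard 6°-step variants it is the
only one on which neither rule boundary (Rule A 20°/110°, Rule B
65°/155°) coincides with a sample orientation — 65° and 155° sit on the
5°–179° grid — so both rules split the default grid cleanly into 15 + 15
orientations, and category-aligned condition orders start at 22° as in
the standard span (22°–106° vs. 112°–16°).  The 5°–179° grid remains
available and Rule A still splits it 15/15.  Orientations exactly on a
boundary raise an error rather than being silently assigned.

The flexible-rule design (Experiment 1) counterbalances 90 trials per
condition (maintenance, categorization-A, categorization-B); the
fixed-rule design (Experiment 2) uses 90 maintenance and 180
categorization trials.  Blocks hold 6 categorization + 3 maintenance
trials, runs hold 2 blocks, rules alternate randomly over blocks with
equal frequency, cued order ("first"/"second") is balanced within
condition, and inter-trial intervals are drawn equally from {3, 5, 7} s,
making the expected trial length exactly 20 s (fixed events sum to
15 s).  The uncued sample orientation is drawn uniformly from the grid
excluding the cued one, a choice the task description leaves open.

## Synthetic BOLD generator

Each voxel carries a rectified-cosine orientation tuning curve raised to
the 8th power, with preferred orientations spread evenly over [0°, 180°)
(plus a random global rotation).  A trial's neural drive is the cued
orientation's tuning pattern, scaled by a (task × epoch) stimulus gain;
categorization trials may additionally carry a signed category signal
along a unit voxel-space axis that is constructed orthogonal to the
stimulus-tuning subspace and orthogonal across rules.  Gaussian noise is
added on a 0.25 s grid, the time course is convolved with a canonical
double-gamma hemodynamic response (peak 6 s, undershoot 16 s, ratio
1/6), and sampled at TR = 1 s on a 20-point trial grid (0–19 s).

Two windows control the gains: "early" neural drive spans trial seconds
0–5 (samples and pre-cue delay) and "late" drive spans seconds 5–11
(post-task-cue delay).  These are deliberately placed ~6 s earlier than
the corresponding analysis epochs (early 5–10 s, late 11–16 s of the
BOLD grid) so that, after hemodynamic convolution, injected effects
surface in the epochs where the analyses measure them.  The category
signal starts only at the task cue — before it the category is unknown
in the task — so the early category-gain entries are inert.

Region presets encode the qualitative regional profiles the analyses
are designed to detect: "EVC-like" (late stimulus gain higher for
maintenance), "IPS-like" (equal), "sPCS-like" (late gain higher for
categorization).  The default noise level (sd 8 in generator units) was
chosen so that desk-scale datasets land in the empirically plausible
operating range — orientation-bin and category decoding accuracies
around 0.55–0.75 and clearly sub-ceiling — rather than at the ceiling a
noiseless simulation would produce.  Defaults of 100–120 voxels keep
run times short; the functional-ROI-sized 500-voxel populations are one
argument away.

Cohorts add per-subject lognormal jitter (sd 0.3 log-units) to the
stimulus gains and generate behavioral accuracy as
`0.815 + 0.06·(coupling·z_gain + sqrt(1-coupling²)·noise)`, so
`coupling` interpolates between independence (0) and a rank-perfect
gain–behavior association (1); base accuracy and spread mirror typical
task performance (~0.81 ± 0.06).

What the generator does *not* emulate: spatial or temporal noise
correlations (an AR(1)-free i.i.d. noise model), scanner drift and
motion, voxel-size heterogeneity, and any nonlinear hemodynamics.
Passing tests therefore demonstrate correctness of the analysis chain
and its calibration under the stated statistical structure, not
robustness to real-fMRI artifacts.

## Inverted encoding model and fidelity

Nine hypothesized channels (half-wave-rectified cosine to the 8th
power, centers 1°, 21°, …, 161°, peak normalized to 1) give
C₁ (channels × trials); training data B₁ (voxels × trials) yield the
least-squares weights Ŵ = B₁C₁ᵀ(C₁C₁ᵀ)⁻¹, inverted on held-out data as
Ĉ₂ = (ŴᵀŴ)⁻¹ŴᵀB₂.  The procedure repeats for 20 one-degree shifts of
the centers, exactly tiling the 180 integer orientations; per-trial
responses are recentered on the cued orientation by circular shifting
(sample orientations are integers, so no interpolation) and averaged by
condition under leave-one-run-out cross-validation, each TR separately.
Angular differences are wrapped into [−90°, 90°] *before* rectification
so tuning never clips across the circle seam, and the rectification
point (±90°) is set to exactly zero to kill the ~1e-17 floating-point
cosine residue.

Fidelity is the mean over the 180 recentered channels of
r(θ)·cos(2θ) — angles doubled onto the full circle, projections onto
the cued direction averaged.  The implementation removes the response
mean first; mathematically a no-op (cos 2θ sums to zero over the
uniform grid), it makes the additive-offset invariance exact in
floating point.  Gram matrices are solved directly with a relative
condition threshold of 1e-10; crossing it raises a rank error instead
of silently regularizing.

## Decoding

Orientation decoding groups the samples into four 45°-wide bins
(cardinal: 90°/180°; oblique: 45°/135°), runs one two-way linear SVM
(C = 1) per pairing under leave-one-run-out cross-validation with the
larger class subsampled to the smaller within each training fold, and
averages the two accuracies.  Category decoding is two-way with
leave-one-trial-out cross-validation, per rule then averaged (flexible
design) or on random halves of 90 trials (fixed design).  The abstract
category index subtracts the orthogonal-rule decoding accuracy from the
true-rule accuracy: stimulus-similarity contributions affect both
labelings alike (the two rules are both 90° arc partitions of the same
grid, and each serves as the other's control), so the index isolates
stimulus-independent category information with chance level 0.  Voxel
patterns enter the classifier unscaled; an optional z-scoring flag
exists but defaults off.  Note that leave-one-trial-out with exactly
balanced classes carries a small pessimistic bias that shrinks with
trial count; at the standard 90 trials per rule the bias is negligible
and cancels between the two labelings in the group mean.

## RSA and mixed-effects decomposition

Neural RDMs are 30 × 30 Pearson-correlation distances (1 − r) between
orientation conditions within a task: trial-pair distances are computed
per time point, averaged within orientation pairs and across the
epoch's time points; the diagonal is fixed at 0.  Alignment is a pure
permutation: by stimulus (ascending orientation) or by category
(counter-clockwise from the rule's first boundary, so the first 15
conditions share a category), which makes RDMs from different rules
commensurable; rule RDMs are averaged after alignment where a single
categorization RDM is needed.

Three model RDMs decompose the neural ones: graded stimulus (circular
distance scaled to [0, 1]; a 1−cos(2Δ) form is a config switch),
discrete stimulus (0 diagonal, 1 elsewhere), and abstract category
(0 within, 1 between).  The mixed-effects fit stacks every subject's
off-diagonal entries and regresses them on the three predictors with a
random intercept per subject.  Because the discrete model is constant
over off-diagonal cells it *is* the constant term, so the fixed part is
fit without a separate intercept — with one, the design would be
exactly collinear.  RDM entries enter untransformed (no Fisher
z-scoring of distances).

Human–network comparison uses Kendall's tau-b (ties are common in model
and network RDMs) between vectorized off-diagonals, a one-sided
Wilcoxon signed-rank test across subjects at the group level, and a
sign-flip permutation (1000 iterations) on z-transformed tau
differences for network-vs-network contrasts.

## Inference utilities

The sign-flip test builds its null from `n_iter` (default 10,000)
means of randomly sign-flipped per-subject values; p-values use add-one
smoothing, so p ≥ 1/(n_iter+1) and is never zero.  Sidedness is an
explicit argument everywhere.  FDR correction is Benjamini–Hochberg
step-up.  Analysis epochs on the 20-point trial grid are early = 5–10 s
and late = 11–16 s.  Brain–behavior association is a Pearson
correlation across subjects with a permutation p-value from shuffling
the subject pairing (10,000 shuffles, seeded).

## Recurrent network model

Three modules of recurrent rate units form a chain; each module is 80%
excitatory / 20% inhibitory under Dale's principle.  Only module-1
excitatory units receive input (15 orientation-tuned units forming a
Gaussian ring receptive field plus 2 retro-cue and 3 task-cue units);
only module-3 excitatory units project to the output.  Between-module
connections exist only between adjacent modules, only between
excitatory units, and only from a seeded random half of the sender
module's excitatory units in each direction; inhibitory connectivity is
strictly local.  Stimuli come from a 20-orientation grid (9° steps).

Dynamics are discrete-time leaky rectified-linear rates
(h ← relu((1−α)h + α(sW + inputs + b) + noise), α = dt/τ) with
short-term synaptic plasticity on excitatory presynaptic units:
utilization u and resources x evolve as

    u ← u + dt((U−u)/τ_u + U(1−u)h),   x ← x + dt((1−x)/τ_x − u·x·h)

clipped to [0, 1], and the effective presynaptic drive is u·x·h.  Half
of each module's excitatory units are facilitating (τ_x 200 ms, τ_u
1500 ms, U 0.15) and half depressing (τ_x 1500 ms, τ_u 200 ms, U 0.45).
All constants are config-exposed.

Two output regimes: RNN1 reports a binary choice between two probe
options shown before the test window (maintenance: the cued orientation
vs. a random other; categorization: a same-category vs. an
opposite-category orientation); RNN2 reports the category through two
units — or (0,0) in maintenance — and always reproduces the cued
orientation through 15 tuned output units.  Training minimizes the mean
squared output error over the test window (first 50 ms excluded) with
Adam on block-interleaved batches (equal trials per condition, block
order shuffled per iteration) and stops once the last batch reaches 90%
accuracy on every task; category and stimulus accuracies are scored
separately for RNN2, the stimulus being correct when the
population-vector estimate from the tuned outputs falls within one grid
step (±9°) of the cued orientation.  Exact ties in the choice units
count as incorrect.

Constraints are enforced by construction, not by projection: effective
weights are |raw| × sign-mask × connectivity-mask, so Dale signs and
the topology hold after any number of gradient steps.  The magnitude is
|raw| rather than relu(raw) because the rectified form lets a single
optimizer step push a small weight permanently to zero gradient — in
practice most weights died within tens of iterations and learning
stalled — whereas the absolute value keeps every permitted synapse
trainable while binding the constraint exactly.  The backward pass is a
hand-written backpropagation-through-time that differentiates the full
recursion including the STSP updates (clipped states pass no gradient
where the pre-clip value left [0, 1]); it is verified against central
finite differences in the test suite.

Scale presets: "full" mirrors the published hyperparameters (200
units/module, 300 trials per condition per batch, up to 10,000
iterations, input/recurrent noise sd 0.01); "desk" (the default and the
scale used throughout the tests) uses 60 units/module, 64 trials per
condition, up to 3,000 iterations, dt = 20 ms, and a compressed trial
(samples 250 ms, gaps 100 ms, retro-cue 100 ms, short delay 300 ms,
task cue 100 ms, main delay 600 ms, options 2 × 200 ms, test 500 ms);
"micro" (40 units/module) exists for multi-seed directional sweeps.
The model-time epochs are a design choice — the study describes the
event order but no model-time durations — and the desk delay is long
relative to the 100 ms membrane constant, so rate decay alone cannot
bridge it and maintenance must be learned through recurrence and the
STSP traces.  Desk-scale problem sizes were likewise chosen so that a
full training run completes in minutes on a single CPU core.

Decoding of unit activity mirrors the fMRI analyses: fresh batches are
pushed through the frozen network with recurrent noise off (input noise
stays on), linear SVMs with five stratified folds decode orientation
bins (cardinal/oblique averaged) or category (true vs. orthogonal rule)
per module and time point, and delay summaries average a critical
window at the end of the main delay.  Network RDMs use the same
trial-pair correlation-distance construction as the neural RDMs and
feed the same comparison machinery.

A caveat discovered in calibration: a noise-free linear readout of a
small trained network saturates at 1.0 accuracy in every condition, so
between-condition differences — the quantities of interest — are
invisible.  The decoders therefore support a *measurement-limited
probe* (a random subsample of units plus additive Gaussian feature
noise scaled to the pooled feature sd, averaged over seeded draws),
which emulates the subsampled, noisy view that imaging gives of a
region and keeps accuracy in its sensitive range.  Even so, at the
scales that run on a single CPU the per-seed spread of the probe
statistics exceeds the small directional effects reported at full
scale (20 networks of 600 units), so small-cohort directional
contrasts should be read as protocol demonstrations: resolving the
published effects requires the full-scale preset and many seeds.

## Numerical and degenerate-input conventions

Rank-deficient Gram matrices raise errors naming the deficient
direction count; orientations on a category boundary, off-grid network
stimuli, single-run datasets, empty decoding classes and all-zero
sign-flip samples raise typed errors (or a degenerate-case warning with
p = 1 for the sign-flip test).  All stochastic procedures take explicit
seeds and reproduce bit-identically; condition averages in the IEM are
exactly invariant to run relabeling at zero noise.

## Known limitations

The generator's category axis is one plausible model of stimulus-
independent category signal (orthogonal-axis coding); real coding
geometries may mix category and stimulus subspaces.  Desk-scale
networks are an order of magnitude smaller than the published ones and
their per-seed decoding contrasts are noisier; directional claims are
therefore checked as signs of small-cohort means, not effect sizes.
The mixed-effects decomposition assumes a random intercept only — no
random slopes — which is the minimal structure consistent with a
subject-level random effect.
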