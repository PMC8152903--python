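# Methods

This note documents the models, numerical choices, and validation design
behind `erpdecode`, in the order data flows through the pipeline.

## Synthetic epochs

A simulated trial's voltage tensor (channels × time) is a sum of
class-locked signal fields and noise:

    x(trial) = g_id · e_id(t) · T_id(c_id, s(t))
             + g_ex · e_ex(t) · T_ex(c_ex, s(t))
             + ρ     · e_re(t) · T_id(c_id_prev, s(t))
             + AR(1) noise + alpha sinusoid

**Topographies** `T` are unit-norm random vectors over channels, one per
class and per *pattern segment*; across consecutive segments each class's
vector rotates with cosine similarity exactly 0.6, so the neural code
evolves over time (which is what makes the temporal-generalization matrix
diagonal-dominant). Segment boundaries default to [0, 200), [200, 500),
[500, 1500) ms. Each simulated participant draws an individual topography
set (individual anatomy).

**Envelopes** `e(t)` are raised-cosine rises (onset → peak, reaching
exactly 1) followed by raised-cosine falls (peak → peak + fall) to a
plateau that is then held *exactly* constant. An exponential tail was
considered and rejected: a plateau that is only approached asymptotically
makes "the envelope equals its plateau" untestable at any finite time,
whereas the cosine fall gives exact, clampable semantics. Defaults (ms,
units of gain fraction):

| dimension    | onset | peak | fall | plateau | gain (µV) |
|--------------|------:|-----:|-----:|--------:|----------:|
| identity     | 60    | 160  | 600  | 0.0     | 1.0       |
| expression   | 150   | 700  | 500  | 0.8     | 0.45      |
| reactivation | 60    | 250  | 350  | 0.0     | 0 (off)   |

These were designed so the generative signal difference
`g_id·e_id − g_ex·e_ex` is ≥ 0 everywhere on [0, 500) ms and ≤ 0 from
~560 ms on, with the crossing near the perception/maintenance boundary at
500 ms: identity coding is transient, expression coding sustained. The
gain/noise scale was calibrated so that group-level decodability lands in
the ranges such studies report (identity peak accuracy ≈ 0.40–0.47,
expression delay accuracy ≈ 0.30 against chance 0.25); an earlier, purely
analytic calibration overestimated decodability because it ignored the
classifier-estimation noise incurred when training on eight noisy averaged
rows in 59 dimensions.

**Noise** is AR(1) in time (stationary sd 6 µV, φ = 0.5 by default),
independent across channels, plus an alpha-band sinusoid (8–12 Hz uniform
frequency, uniform phase, amplitude 4 µV, common to all channels within a
trial). AR(1) was chosen over 1/f because the cluster-permutation test's
correctness claim concerns temporal autocorrelation, and AR(1) exposes it
through a single coefficient. Channel-to-channel noise correlation is
deliberately absent: neither the decoder nor the statistics requires it,
and adding it would only rescale effective SNR.

**Design**: labels are balanced over the 16 identity × expression cells
and drawn so that consecutive trials never repeat either dimension
(matching the task, and guaranteeing previous-trial decoding cannot reflect
stimulus repetition). Sessions can optionally include post-test-flagged
trials (720 → 640 after exclusion, 5 flagged per cell) to exercise the
bookkeeping. All randomness descends from one master seed through a fixed
`SeedSequence` splitting rule; identical configuration and seed reproduce
every tensor bit-for-bit.

**What the generator does not emulate:** volume-conducted spatial noise
correlation, non-stationary artifacts (blinks, muscle), 1/f background,
inter-participant variability beyond topography resampling, or any
behavioral-neural coupling. Passing recovery tests therefore show that the
*pipeline* is correct and well calibrated under controlled conditions — not
that real EEG satisfies these assumptions.

## Preprocessing

The 6-Hz low-pass is a zero-phase (forward–backward) Hamming-windowed-sinc
FIR of order ≈ 3·fs/cutoff (rounded to even, capped so filtfilt's padding
fits short epochs). Any kernel with unit DC gain, ≥ 20 dB attenuation at
twice the cutoff and zero phase is equivalent for this analysis, which
depends on phase-locked low-frequency content, not a specific legacy
routine. One consequence worth knowing: at 6 Hz the kernel spans several
hundred ms, so post-onset signal is smeared into the pre-onset baseline;
together with baseline subtraction this can make pre-onset accuracy deviate
slightly from chance when strong post-onset signal exists. The vs-chance
statistics are restricted to post-onset points partly for this reason.

Baseline correction subtracts the per-trial, per-channel mean over
[−500, 0) ms (or the available pre-onset part). The emulated analysis does
not state its baseline procedure; it is a config flag here, on by default.

Accuracy smoothing is a centered 5-point moving average whose window
shrinks symmetrically at the series edges — zero-padding would bias edge
accuracies toward 0 and manufacture spurious clusters. Smoothing applies
only to accuracy series, never to the voltage data.

## Decoding

The classifier is pinned for determinism: linear soft-margin SVM, C = 1,
features standardized per training fold (mean/sd of the k−1 groups' rows,
ddof 1), bias absorbed into an L2-regularized constant feature; ECOC
one-vs-rest decoding by aggregate hinge loss with ties broken to the lowest
class code. The solver is dual coordinate descent visiting points in fixed
order, vectorized so that every (iteration × fold × time point) problem in
a run trains in one batched pass; each batch element stops by its own
convergence criterion (tolerance 1e-4 on the largest dual step, chosen
because tightening it to 1e-10 changes < 0.02 % of predictions on
realistic inputs while tripling runtime), so results are independent of how
problems are batched. Scikit-learn's SVC agrees with this engine on
separable geometry in tests but is never used in the pipeline itself.

Fold assignment is drawn once per subsampling iteration and shared across
all time points; per-iteration RNGs derive from the config seed, so a
temporal-generalization run and a windowed time-course run with the same
seed share partitions exactly and the matrix diagonal equals the time
course bit-for-bit (asserted in tests).

Cross-dimension decoding trains on within-class averages computed per
control level (3 rows per class) and tests on the held-out level's class
averages. Averaging at the level granularity preserves the averaged-
exemplar design while guaranteeing no stimulus image appears on both sides;
the 4-level rotation replaces random subsampling, so there are 16 attempts
per time point instead of 120.

Previous-trial decoding relabels trial *i* with trial *i−1*'s class in
session order (`trial_index`; block breaks do not interrupt the ordering)
and drops the session's first trial. A subtlety discovered during
validation: because consecutive trials never share a dimension, the
previous-trial label is *anti-correlated* with the current-trial label, so
current-trial class signal leaks into previous-trial group means at −1/3 of
its gain with inverted topography. The reactivation validation suite
therefore zeroes current-trial gains, making ρ = 0 a clean negative
control; with current-trial signal present, "previous-trial decodability"
is partly an artifact of the design constraint — a caveat that applies to
this analysis generally, not only to synthetic data.

## Statistics

Vs-chance inference: one-tailed one-sample *t* per post-onset time point
(one-tailed because the decoder cannot produce meaningfully below-chance
accuracy), point threshold α = 0.05, maximal contiguous significant runs,
cluster mass = summed *t*. The null relabels stored test predictions: per
permutation and participant, one uniform permutation of the class codes is
applied to the true labels at *every* time point of the epoch (holding it
constant across time is what preserves the temporal dependence structure
under the null), accuracy is recomputed from stored predictions without
retraining, re-smoothed with the same 5-point rule, and the largest cluster
mass (0 if none) recorded. Permuting class *codes* rather than shuffling
the label vector is the reading that is constant across time by
construction and preserves class balance. The permuted series are smoothed
by the same code path as the observed series, so the identity relabeling
reproduces the observed statistic exactly.

Cluster p = #(null ≥ observed)/n_perm, floored at 1/n_perm (reported
"< 0.001" at 1000 permutations when floored). The counting estimator is
used in place of any percentile interpolation. Two-tailed (condition
difference) tests form positive and negative clusters separately at the
α/2 threshold and compare |mass| against a null of the largest absolute
mass under per-participant condition swaps of the already-smoothed series.

Zero-variance columns are detected exactly (range = 0) and assigned signed
infinite *t* (0 when the mean equals the null value exactly); detecting
them through a computed sd of 0 is unreliable because round-off in the
column mean can turn an exact tie into an astronomically large finite *t*.

The JZS Bayes factor integrates the alternative's marginal likelihood over
g ~ InverseGamma(1/2, r²/2) (equivalently a Cauchy(0, r) prior on the
standardized effect) by adaptive quadrature; it matches an independent
implementation (pingouin) to six significant figures and is strictly
decreasing in |t|.

## Validation suites and their problem sizes

All sizes below are the package's own choices for a single-CPU validation
run; each suite is deterministic given its seed.

* **Chance calibration** — 10 participants, 59 channels, 160 trials,
  100 post-onset time points ([0, 400) ms at 250 Hz), zero gains, AR(1)
  noise only, default decoding (10 iterations). The decoder runs directly
  on the simulated epochs: filtering a zero-signal study cannot change its
  mean and only adds temporal dependence. The grand mean is compared with
  1/4 using 3 binomial standard errors computed from the total attempt
  count; note that attempts are not independent (shared trials across
  iterations, AR(1) dependence across time), so this band is conservative
  in its assumptions and tight in practice.
* **Family-wise error rate** — 200 independent null studies of 8
  participants each (same null config, φ = 0.5), 5 subsampling iterations
  (the permutation test's error rate does not depend on the iteration
  count), 200 permutations per study; the fraction of studies with any
  cluster p < 0.05 is compared with 0.05 plus 3 Monte-Carlo standard
  errors.
* **Crossover recovery** — default generator at 125 Hz, 640 trials, 32
  participants, 200 permutations. At the emulated effect sizes the delay
  contrast has only ~50 % power at 22 participants, so the suite runs at a
  size chosen for adequate power; the assertions are that
  identity-greater clusters end by 500 ms, expression-greater clusters
  start after 500 ms, and both exist.
* **Reactivation recovery** — ρ = 0.8 vs ρ = 0, 32 participants, epoch
  [−200, 800) ms at 125 Hz, current-trial gains zero (see above);
  assertions: ρ > 0 yields significant post-onset clusters, ρ = 0 yields
  none.

## Known limitations

* The dual-CD SVM matches liblinear's formulation (regularized bias), not
  libsvm's exactly; on the averaged-ERP problems used here the predictions
  coincide with libsvm in testing, but decision values near ties may
  differ from other implementations at the last decimal.
* The vs-chance permutation null conditions on the trained classifiers
  (test-label relabeling, no retraining); it is exact for the test-stage
  randomness but does not propagate training-stage variability, the
  standard trade-off for making 1000 permutations tractable.
* The cross-dimension mode has no subsampling iterations and is
  correspondingly noisier (16 vs 120 attempts per point).
* Report plots are not generated; the bundle is TSV/JSON, and the run log
  (wall-times) is excluded from byte-identity guarantees.
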