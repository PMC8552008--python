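# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `gaitlatent`.

## Problem and pipeline

Lower-limb gait kinematics — hip, knee and ankle Euler angles (ZXY, ISB
convention, degrees) on both sides, recorded at 60 Hz — are reduced to a
two-dimensional latent space by three methods operating at two timescales:

* **PCA** on single poses (14 channels after channel selection);
* **Pose-AE**, a feed-forward autoencoder on the same poses;
* **Move-AE**, a recurrent autoencoder on one-second movement windows
  (60 frames x 14 channels).

The pipeline is: channel selection (knee frontal/transverse planes dropped
as noise-dominated, 18 -> 14 channels) → pooled per-channel z-scoring →
pelvic-velocity filtering of unscripted "natural" streams → sampling of
poses and overlapping windows every 10 frames (1/6 s at 60 Hz) → reducer
fitting → evaluation.

Evaluation uses reconstruction metrics (VAF, standardized RMSE), the
distribution of variance across latent dimensions, and latent-space
classification (RBF-kernel SVM) of movement class and of individual
identity, with repeated reducer trainings and a two-sample
Kolmogorov–Smirnov comparison of error distributions.

## Metric definitions

**VAF.** `VAF(%) = (1 − var(y − ŷ)/var(y)) · 100`. The scalar variance of
multichannel data is defined by pooling: `Σ_c var(y_c − ŷ_c) / Σ_c
var(y_c)`, with population (ddof = 0) variances. This choice reduces to the
scalar formula for one channel and makes the identity *VAF of a rank-k PCA
reconstruction = cumulative explained-variance ratio of the top-k
eigenvalues* exact (enforced at 1e-6 in the tests). Per-channel VAFs are
available for diagnostics. An alternative (averaging per-channel VAFs)
weighs low-variance channels more; pooling was chosen for the exact PCA
identity.

**RMSE** is reported in standardized units, where always answering the
pooled mean pose scores exactly 1.0 — the natural "no better than the
mean" threshold. Windows are pooled over timesteps, so sequence models are
scored on every entry.

**Dimensional variance** is the per-latent-dimension variance normalized
to sum to one (for PCA, the normalized eigenvalue distribution over the
kept components); evenness is summarized by its Shannon entropy (nats).

**Circular rank correlation.** To test that steady-gait latent
trajectories are ordered by gait phase, each latent point is mapped to the
angle around the latent centroid; that angle and the generator's true
phase are converted to circular ranks and compared with the Fisher–Lee
circular correlation coefficient (absolute value, since loop orientation
is arbitrary). The statistic is invariant to monotone circular
re-parameterization but deliberately penalizes folded (non-phase-ordered)
loops.

## Reducers

**PCA** is the eigendecomposition of the (population) covariance matrix of
the training poses. Eigenvector sign is fixed by making each component's
largest-magnitude loading positive, so repeated fits are bitwise
identical. Since inputs are standardized, covariance and correlation PCA
coincide. For classification, the "latent space" is the first two
principal-component scores, fit once on the union of the task's poses.

**Pose-AE**: encoder 14 → 64 → 32 → 16 → 2 with batch normalization and
ReLU after each encoder dense layer; linear latent; mirrored decoder
(ReLU, no batch norm); mean-squared reconstruction loss; full-batch Adam
(default learning rate 1e-3, 8 000 iterations). Batch normalization is the
only regularizer and lives only in the encoder. Hidden widths taper
64/32/16 — small enough for single-CPU full-batch training, expressive
enough to beat the linear baseline clearly.

**Move-AE**: encoder = time-distributed dense (width 64, ReLU) → two
stacked bidirectional LSTM layers (default 32 units per direction) →
concatenated final states of both directions → dense 16 (ReLU) → linear
2-unit latent. Decoder = latent repeated across all 60 timesteps → two
bidirectional LSTM layers → time-distributed dense 64 (ReLU) →
time-distributed linear output (14 channels). Loss is mean-squared error
over all 840 window entries; mini-batch Adam with batch size 32, one
iteration = one mini-batch step. Repeating the latent across timesteps is
the simplest decoder seeding consistent with reconstructing the whole
window from a single 2-vector; autoregressive decoding is out of scope.
Gradient clipping is off by default and available in the config.

Both networks are implemented directly in NumPy with manual
backpropagation (including full backpropagation through time for the LSTM
layers) and the Adam optimizer; all gradients are validated against
central finite differences in the test suite, and training is bitwise
reproducible from the config seed.

## Latent-space tasks

The SVM uses an RBF kernel with C = 1 and `gamma = "scale"`; the same
settings are used for every task and reducer. The error is resubstitution
error (misclassified / total on the fit set): the tasks measure how much
structure a latent space preserves, not generalization. Repetition
variance comes from retraining the autoencoders from fresh initializations
(10 repetitions by default); PCA is deterministic, so its single error is
recorded for each repetition. The movement task uses flat vs stair data
only; the individual task uses the 8 flat-ground subjects.

## Synthetic data generator

Real corpora of this kind are gated behind data-use agreements, so the
package bundles a generator that emulates the structure the analyses
probe, without claiming biomechanical validity.

Each channel is a sum of 2–3 harmonics of the stride frequency plus a
static offset plus white Gaussian sensor noise (default SD 1°):

`x_c(t) = o_c + A_c Σ_h w_h sin(2π h f t + h φ_c + ψ_h) + ε`

* **Cyclicity**: cadence is drawn per subject from [0.8, 1.2] strides/s
  and snapped so the stride period is an integer frame count; noise-free
  trajectories are exactly periodic, which the tests assert exactly.
* **Time asymmetry**: the harmonic shape phases ψ = (0, 1.1, 2.6) are
  non-degenerate, so a stride and its time reversal are not related by any
  circular shift — temporal direction is learnable in principle.
* **Individuality**: subjects perturb template amplitudes (±12%
  multiplicative), offsets (SD 2.5°), relative channel timing (SD 0.15
  rad), harmonic weights/phases, and walk at their own cadence. A global
  phase shift is also drawn but is uninformative for steady gait.
* **Class structure**: the flat and stair templates differ in per-channel
  offsets and amplitudes (e.g. markedly more hip/knee flexion on stairs),
  with part of the contrast placed in low-amplitude frontal/transverse
  channels that a 2-D linear projection of poses tends to discard. The
  stair template alternates ascent-like and descent-like parameter
  sub-modes of ~13 stride cycles with one-stride linear ramps, like a real
  staircase with a landing. The "natural" template concatenates cyclic,
  slow aperiodic, and idle segments (weights 0.4/0.3/0.3, lengths 3–8 s).
* **Pelvic speed** is an envelope signal — exactly zero in idle segments,
  positive elsewhere — because only the activity filter consumes it; no
  pelvis kinematic chain is simulated.

All randomness flows from one integer seed through
`numpy.random.SeedSequence([seed, class_code, subject_index, purpose])`,
so studies regenerate bitwise identically.

What the generator does **not** emulate: soft-tissue artifacts, ground
contact events and impact transients, stride-to-stride cadence drift,
pathological gait, cross-channel noise correlation, or realistic joint
coupling. Tests passing on this data show the pipeline's machinery and its
qualitative contrasts (class separability, individuality, cyclicity,
temporal asymmetry) behave as designed — not that the numerical results
would match any particular real corpus.

## Preprocessing choices

* The sampling stride is fixed at 10 frames (1/6 s at 60 Hz) — the
  integer-frame rendering of sampling every ~0.166 s.
* Standardization is per-channel z-scoring with statistics pooled over all
  recordings of all activity classes (after channel selection, and after
  pelvic filtering for natural streams). Per-channel (rather than global)
  scaling is an assumption; it is what makes the RMSE = 1 mean-pose
  threshold exact per channel.
* The pelvic-velocity filter's threshold defaults to 10% of the median
  positive pelvic speed with a minimum segment of 60 frames; both are
  exposed parameters rather than hidden constants.
* Windows never cross recording (hence subject) boundaries, and window row
  r always equals the pose that would be sampled at that frame, so pose-
  and movement-level reducers consume consistent views.

## Numerical choices and degenerate inputs

* Population variances everywhere a variance meets an eigenvalue.
* Batch-norm: eps 1e-5, running-statistics momentum 0.9; inference always
  uses frozen running statistics.
* LSTM: gate order (input, forget, cell, output), forget-gate bias
  initialized to 1, Glorot input weights, orthogonal recurrent blocks.
* Non-finite training loss aborts with the iteration index rather than
  continuing silently.
* Zero-variance channels, single-class label sets, empty runs, unknown
  templates/tasks, and shape mismatches raise named errors.
* ReLU subgradient at 0 is taken as 0; gradient checks randomize biases to
  stay off that measure-zero kink.

## Problem sizes used by the test suite

The default configurations (8 000 iterations, 32 recurrent units) are
desk-scale but slow for a test suite, so the end-to-end tests train scaled
configurations chosen by watching reconstruction-loss convergence on the
synthetic data (never the downstream test outcomes): Pose-AE 800
full-batch iterations; Move-AE 300 mini-batch steps with 16 recurrent
units per direction. The headline classification
study uses the full 8 flat + 11 stair subjects at 60 s each (≈6 800 poses,
≈6 700 windows); autoencoders train on a fixed random subsample of at most
1 500 poses (full-batch) and all windows (mini-batch), then encode every
sample for classification.

Because some Pose-AE initializations reconstruct well yet embed the gait
loop folded (angle around the centroid not monotone in phase), the
cyclic-structure check scores the *median* circular rank correlation over
repeated trainings — the same repeated-training protocol the
classification tasks use.

## Known limitations

* The reported classification errors are resubstitution errors by design;
  they say nothing about held-out generalization.
* Move-AE's latent geometry varies noticeably between trainings (as its
  per-repetition error spread shows); single-run latent plots should be
  read as one draw, not the method's canonical embedding.
* The NumPy implementation is single-threaded BLAS-bound; it is meant for
  studies of this scale, not for large corpora.
* VAF pooling weighting favors high-variance channels; use the
  per-channel output when channel-level fidelity matters.
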