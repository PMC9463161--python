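# Methods

## Problem

Postural instability and gait disorder (PIGD) is a sub-score of the motor
section of the Unified Parkinson's Disease Rating Scale: five items (arising
from chair, gait, freezing of gait, postural stability, posture), each rated
0-4 by a clinician, totalling 0-20. Patients on levodopa cycle between an ON
state (drug active, milder symptoms) and an OFF state (drug worn off, worse
symptoms). This package implements a pipeline that estimates PIGD from a
single lumbar-worn inertial sensor recorded during a clinic walk test, and
judges the estimate by whether it orders a subject's ON and OFF visits
correctly — predicted scores should be higher when the subject is OFF.

Because the clinical recordings that motivated this design are access
restricted, the package ships a synthetic cohort generator with the same
statistical structure, so every stage is runnable and testable offline.

## Feature pipeline

A session is six time series at 128 Hz: 3-axis acceleration (g) and 3-axis
angular rate (deg/s). Processing steps:

1. **Turn detection** (`detect_turns`). Cumulative rotation about the yaw
   (first gyroscope) axis is computed by trapezoidal integration over a
   sliding 2-s window; spans whose |rotation| exceeds 120 deg are marked,
   and marked spans closer than 0.5 s are merged. The 120 deg criterion is
   the turnaround definition; window length and merge gap are the package's
   own choices, config-exposed.
2. **High-pass filtering** (`highpass`). A 4th-order Butterworth with a
   0.25 Hz corner, applied zero-phase (forward-backward), removes gravity
   and drift while leaving the gait band (fundamental ~1.5-2.5 Hz) intact.
   The "0.25 cutoff" is interpreted in Hz: as a normalized frequency at
   128 Hz it would be 16 Hz and would destroy the gait band. The filter is
   applied to the **whole session before segmentation**: a 0.25 Hz corner
   has a settling time of several seconds, so filtering an isolated 3-s
   segment distorts its passband by 5-25% depending on padding (measured);
   on a full session the edge transients sit far from the walks of
   interest. Both the corner, order and phase mode are config-exposed.
3. **Segmentation** (`segment_walks`) keeps the complement of the turn
   intervals; snippets shorter than 3 s are dropped. **Truncation** takes
   the first 384 samples (3 s at 128 Hz) of each snippet — one example per
   straight walk, matching how walks are counted clinically.
4. **Log spectra** (`log_spectrum`). Per channel, `log(|DFT| + floor)` of
   the 384-point transform, keeping all 384 bins so the feature tensor is
   3 x 384 (= the generator's 1152 output units). The floor (1e-8) keeps
   the log finite on silent channels. A zero-padded one-sided variant with
   the same dimensionality is available (`spectrum="half"`); the full
   symmetric spectrum is the default.

No per-example amplitude normalization is applied: amplitude carries
severity information, and the filter already removes offsets.

## Networks

Both networks are written directly in NumPy with hand-coded
backpropagation, verified against central finite differences (relative
error < 1e-4 on random parameter probes, in float64).

**Discriminator / CNN** (6,296,994 parameters): two 1-D convolutions (32
filters of length 3, stride 1, padding 1) along the 384-sample axis, a
512-unit dense layer, and a 2-unit linear output. Unit 0 is the unbounded
PIGD score (no activation — clipping would bias paired differences); unit 1
passes through a sigmoid to give the real/fake probability D(x). ReLU and
dropout (p = 0.5) follow the three hidden layers; the output layer has
neither. Hidden layers use weight normalization (w = g·v/||v||, one learned
scale per output unit) rather than batch normalization, which would inject
cross-example noise into a regression. Convolution weights start orthogonal
(the smaller dimension of the flattened filter matrix is orthonormalized;
for the first layer, 32 filters over 9 inputs, only the 9 columns can be
orthonormal), dense weights He-uniform (±sqrt(6/fan_in)), biases 0, scales
g = 1.

**Generator** (906,368 parameters): 100 uniform [0,1) noise inputs, two
512-unit weight-normalized ReLU layers, and a linear 1152-unit output
reshaped to 3 x 384 — a fake log-spectral example. The output layer carries
an L2 penalty (default coefficient 1e-4, config-exposed; the strength is
not pinned by the recipe).

## Losses

With y the predicted and t the clinician score, and each batch example i
paired with an opposite-visit example of the same subject:

    loss_train = alpha/N * sum_i (y_i - t_i)^2
               + beta/N  * sum_i ((y_i1 - y_i2) - (t_i1 - t_i2))^2

The second term scores the within-subject between-visit difference, pushing
the network to order a subject's two visits rather than merely identify the
subject. The sum runs over all N examples, so each pair contributes its
squared difference twice — this keeps the printed 1/N normalization and
uniform per-example weighting (a per-pair N/2 reading differs only by a
constant factor).

    loss_disc = gamma * loss_train
              + delta * (mean_i (D(x_i)-1)^2 + mean_i D(G(z_i))^2)
    loss_gen  = mean_i (D(G(z_i)) - 1)^2

Least-squares adversarial objectives: the discriminator pushes D(x) to 1 on
real walks and D(G(z)) to 0 on fakes; the generator pushes D(G(z)) to 1.
Fake examples carry no PIGD label and never enter `loss_train`.

**Historical averaging** adds `coef * ||theta - theta_avg||^2` to the
discriminator objective, where `theta_avg` is an exponential moving average
of the parameters (decay 0.999), updated after every optimizer step. The
decay and coefficient (1e-3) are this package's choices — the technique
fixes neither — and are config-exposed. It is applied to the
discriminator/CNN only.

All four losses are mirrored by independent loop-based oracles in the test
suite and agree to 1e-10 on random batches.

## Training

- **Split**: a fixed development set of 10 whole subjects (no subject
  straddles the split), drawn once before training.
- **Batches**: 200 examples drawn uniformly; each is joined by a uniformly
  drawn example from the same subject's opposite visit, giving N = 400.
  Subjects may repeat within a batch.
- **Optimizer**: Adam at a fixed learning rate of 0.01 with the standard
  moment defaults (0.9, 0.999, 1e-8); moments are kept in the parameter
  dtype (float32 by default).
- **Epochs**: `ceil(n_train / N)` steps per epoch (the recipe does not
  define an epoch; this makes the 100-epoch budget data proportional).
- **GAN alternation**: per step, one discriminator update (real paired
  batch + equal-size fake batch) then one generator update evaluated
  against the just-updated discriminator on the same noise draw. Update
  order is a tie-break the recipe leaves open.
- **Convergence**: the per-epoch development MSE (plain, unpaired, dropout
  off) is declared steady when its fluctuation over a trailing 20-epoch
  window falls below 5% of a reference scale — either the window maximum
  (default) or the whole trace's range; both are exposed.
- **Randomness**: one integer seed fans out into named child streams
  (split, initializations, batch sampling, noise, dropout-on-real,
  dropout-on-fake). Real-batch streams are consumed identically by CNN and
  GAN training, so adversarial training with delta = 0 reproduces the CNN
  trajectory bit for bit — a property the test suite checks.

## Evaluation

Per-walk scores are averaged per visit (dropout off). For each subject with
at least one ON and one OFF visit, mu_ON and mu_OFF are the per-state means;
the subject is counted correct when mu_OFF > mu_ON strictly, ties incorrect
(a conservative reading of the strict inequality). TRANSITIONING visits are
excluded. R^2 is the coefficient of determination 1 - SS_res/SS_tot of the
stacked per-state means against the clinician's — not a squared correlation,
so miscalibrated but correlated predictors score poorly (squared Pearson is
available behind a flag). Accuracy depends only on orderings and is
invariant under any strictly increasing transform of the scores.

## Synthetic cohort

The generator emulates what the method assumes about clinic walk
recordings, not whole-body biomechanics:

- **Latent severity**: per subject, a gamma draw (shape 2, scale 2.5,
  right-skewed as clinical PIGD distributions are), clipped so the OFF
  shift cannot saturate the 0-20 scale. OFF visits add the full
  `on_off_gap` (default 6 points), TRANSITIONING visits half of it; the
  visit's clinician score is the shifted severity rounded and clipped.
- **Straight walks**: vertical acceleration is a 3-harmonic series at the
  cadence fundamental with per-stride timing jitter (CV 3% at severity 0
  growing to 10% at 20); antero-posterior and medio-lateral channels carry
  attenuated components at the step and half-step frequency. Severity
  lowers cadence (-0.02 Hz/point from 2.0 Hz) and amplitude (-0.008
  g/point from 0.25 g) and raises 4-6 Hz band-limited tremor energy
  (0.004 g RMS/point). Gravity (1 g) plus slow drift ride on the vertical
  channel until the high-pass removes them; white noise (0.02 g) on all
  channels. These are conventional adult gait magnitudes; the source
  cohorts' cadence/amplitude statistics were never published, so no fitting
  to them is possible or attempted.
- **Turns**: raised-cosine yaw-rate pulses integrating to 150-200 deg,
  comfortably above the 120 deg excision threshold, between successive
  walk bouts (default 4 bouts of 6 s per session).

What it does **not** model: freezing-of-gait episodes, asymmetry, arm
swing, magnetometer channels, sensor misplacement, or real-world walk
diversity. Passing the severity-recovery test therefore shows the pipeline
can extract a severity signal with the statistical structure the method
assumes — it says nothing about performance on real patients.

## Scaled study conditions

The synthetic acceptance study uses 35 subjects x 2 paired visits with
`on_off_gap = 6` (one ON and one OFF visit per subject, as in a paired
two-visit design), 4 walk bouts per session giving 280 examples, a
10-subject development set, and GAN training for 100 epochs at the
published recipe with the batch scaled to the split (`batch_pairs = 50`,
N = 100, two steps per epoch over the 200 training examples). On held-out
subjects the trained score head orders ON/OFF correctly and its per-visit
means track the latent severity (Spearman rho well above 0.6 across seeds).
The regression-loss and discriminator-loss traces settle (fluctuation over
the last 20 epochs under 5% of the trace range). The development-MSE and
generator-loss traces retain residual oscillation at this scale (roughly
7% and 20% of range respectively): with 200 training examples, two steps
per epoch, a constant 0.01 learning rate and p = 0.5 dropout, the
least-squares adversarial game keeps cycling around its equilibrium rather
than freezing onto it. The corresponding acceptance tests assert the 5%
criterion for all four traces and the two oscillating traces fail it; this
is reported as-is rather than smoothed over, since larger cohorts (more
steps per epoch averaging the traces) are what the criterion presumes.

## Numerical choices

- float32 parameters and activations by default (float64 available via
  config; gradient tests run in float64).
- Sigmoid computed in the numerically stable split form.
- Degenerate inputs: empty gyro series yield no turns; sessions yielding
  zero examples are logged, not fatal; an all-turn session yields nothing;
  `r_squared` refuses constant truths; `on_off_accuracy` refuses empty
  subject lists; non-finite samples are rejected with validation errors.
- Checkpoints are `.npz` containers with a JSON header carrying an
  architecture hash that is verified on load.

## Known limitations

- The generator's realism is limited to log-spectral structure; fake
  examples are produced directly in the log-spectral domain (the
  discriminator's input space), the natural reading of the architecture.
- R^2 on the synthetic fixture is often negative even when rank correlation
  is near 1: with only 100 GAN training steps the score head is
  well-ordered but not yet calibrated in absolute scale. The clinical
  question (ON/OFF ordering) does not require calibration.
- Mode collapse of the generator is not quantified.
- Single-machine, single-thread determinism only; no accelerator paths.
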