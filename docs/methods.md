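# Methods

## The measurement problem

Accelerometer-based PA measurement assigns each epoch of a raw body-worn
tri-axial signal to an intensity category — sedentary behavior (SB,
≤ 1.5 METs), light PA (LPA, 1.6–2.9 METs) or moderate-to-vigorous PA
(MVPA, ≥ 3.0 METs) — and derives from the categorized timeline the two
quantities health research cares about: time in category and breaks in
sedentary time. The criterion is a direct-observation (DO) record of which
of 13 protocol activities (3 sedentary, 10 non-sedentary) was being
performed at each moment. `accelpa` implements the full chain and evaluates
it per wear site (hip, thigh, left wrist, right wrist) with a separate
classifier per site.

## Signal representation

A recording is `(subject, site, rate, start_time, samples)`; per-sample
timestamps are validated on read (uniform spacing within ±10% of one sample
period) and then dropped, so sample *i* is at `start_time + i/rate`.
Device streams recorded at 40 Hz are reintegrated to 20 Hz by
non-overlapping pair means: the operator halves the sample count and
preserves the per-axis mean exactly. Averaging (rather than decimation) is
the standard epoch-reintegration semantics; the choice is isolated behind
`reintegrate_to_20hz` so decimation could be swapped in one place. All time
intervals, including the 30-s windows, are half-open `[t0, t1)`, which
prevents a sample or window boundary from being counted twice.

## Features

Each non-overlapping 30-s window (600 samples at 20 Hz; an incomplete
trailing window is dropped with a warning) is summarized by the
10/25/50/75/90th percentiles of each raw axis — 15 features, axis-major
order, recorded in model files to prevent silent permutation. No filtering,
no gravity removal, no vector magnitude, no spectral features. Percentiles
use linear interpolation between order statistics (`h = (n−1)q`); the
convention is centralized in `features._PERCENTILE_METHOD` so a
nearest-rank variant is a one-line change. Percentile features capture the
two physical quantities that distinguish activities at a given site —
gravity orientation (location of the distribution) and movement vigor
(spread) — and are deliberately blind to frequency content.

## Classifier

`IntensityNet` is a fixed-architecture feed-forward network: 15 inputs + 1
bias → 5 logistic-sigmoid hidden units → +1 bias → 3 outputs, no
skip-layer connections, 16×5 + 6×3 = 98 free weights. The output map is a
softmax, so "the category with probability closest to one" is exactly the
argmax; exact ties break toward the lower-ordinal class, the conservative
direction for activity measurement. Softmax with multinomial cross-entropy
was chosen as the standard probabilistic head for this architecture; the
hidden activation is the logistic sigmoid and both choices are isolated.

Training minimizes cross-entropy plus L2 weight decay `α/2·Σw²` on non-bias
weights by full-batch L-BFGS (a deterministic quasi-Newton method) from
uniform(−0.5, 0.5) initial weights. Defaults: `α = 1e-3`, 5 restarts
(lowest final loss kept), 500 iterations maximum, relative-loss tolerance
1e-8. Features are z-scored inside the model with training-data statistics
(zero-variance features get scale 1 with a warning); the standardizer is
stored with the weights so a serialized model predicts self-contained.
Restart seeds derive from the model's `random_state` via a SHA-256 named
stream, so fits are bit-reproducible. The analytic gradient is verified
against central finite differences in the test suite (relative error
< 1e-5).

## Cross-validation

Leave-one-subject-out: for each of n subjects a network is trained on the
other n−1 subjects' non-transition windows and predicts **all** windows of
the held-out subject. Intensity metrics then ignore the held-out subject's
transition-annotated windows, while break counting uses the full predicted
timeline — predictions exist for transition windows; they were only
excluded from training and intensity scoring. Fold seeds are a stable hash
of (global seed, subject id), so results do not depend on subject iteration
order. Subjects whose annotation yields no non-transition window carry
nothing trainable and are dropped with a warning. Sites are modeled
completely independently (four distinct networks).

## Metrics

* Sensitivity of class c: `100·cm[c,c]/row_total(c)`; specificity:
  `100·(off-row windows predicted off-class)/(off-row windows)`. Undefined
  cases (class absent from truth) are reported as NaN, never 0 or 100.
* Quadratic-weighted kappa uses agreement weights
  `w_ij = 1 − (i−j)²/(k−1)²` with k = 3 and the ordinal order
  SB < LPA < MVPA; the 95% CI uses the large-sample
  (Fleiss–Cohen–Everitt) standard error, with a window-resampling
  bootstrap available behind `method="bootstrap"` (the asymptotic form
  is the default because it is deterministic and matches the reference
  implementation in statsmodels to rounding).
* Time in category is window count × 0.5 min.
* A break in SB is an index t with `seq[t−1] = SB` and `seq[t]`
  non-sedentary. For DO sequences, TRANSITION windows count as
  non-sedentary (transitions involve standing/walking between activities);
  the `include_transitions` flag exposes the stricter reading that drops
  them first. Predicted-timeline break counts always use the full window
  sequence.
* Reporting is dual: pooled (windows summed over subjects — used for the
  pooled confusion matrix and kappa) and mean-per-subject (each subject's
  sensitivities/specificities averaged, NaN excluded). Both are labeled
  explicitly because they answer different questions and can diverge when
  subjects differ in difficulty.

## Synthetic cohort generator

The generator defines the study conditions; it is not a tuning dial.
Defaults: 20 subjects, all 13 activities exactly once each in uniformly
random order, durations uniform in 3–10 min proportionally rescaled (within
bounds) so activity time plus 10–40 s inter-activity gaps totals 90 ± 2
min; right-hand dominance with probability 0.9.

Per site and activity the signal is
`gravity orientation + amp·envelope(t)·sin(2πft+φ)·direction + noise`,
at the device's native rate (40 Hz hip/thigh, 20 Hz wrists). The
oscillation direction is the component of a fixed reference vector
orthogonal to gravity — a function of orientation only, so activities
sharing a posture are genuinely confusable when their amplitudes overlap
rather than being separable by an artificial per-activity signature.
Between-subject variability enters as a per-site orientation jitter, a
per-site amplitude multiplier, and per-(subject, activity) amplitude and
orientation perturbations; a slow (120 s) amplitude envelope makes windows
within a bout vary so misclassification is not all-or-nothing per bout.

Site difficulty is engineered, not emergent, and was calibrated once to
reproduce the qualitative site ordering by pooled weighted kappa —
thigh > left wrist > hip > right wrist for a right-dominant cohort — and
then frozen:

* **Thigh**: distinct gravity orientations for lying / sitting / standing /
  cycling / squatting and clean amplitude scaling → near-perfect
  classification and exact break recovery.
* **Hip**: sitting and standing share trunk orientation up to a small
  offset (`hip_sit_stand_gap`), and sedentary dynamics are tiny — so
  seated SB and standing LPA are confusable across subjects whose
  orientation jitter exceeds the offset.
* **Dominant wrist**: whole-body MVPA produces little wrist travel
  (`dominant_mvpa_shrink` pushes MVPA wrist amplitudes into the LPA band),
  the forearm rests in a desk-like posture during cycling (orientation
  overlapping computer use → MVPA misread as SB), and noise and
  between-subject variability are larger. Because LOSO training data are
  ~90% dominant-right, the right-wrist model faces this confusion
  irreducibly.
* **Non-dominant wrist**: mild degradation only (low wrist travel for
  squats and walking-family orientation overlap); its pooled kappa is
  dragged slightly by the ~10% left-dominant subjects whose *left* wrist is
  the dominant one.

What the generator does **not** emulate: biomechanical waveforms (gait
harmonics, impact spikes), device noise floors and clock drift, autonomic
variation within an activity, or participant dropout. Since the classifier
consumes order statistics, distributional realism beyond
location/scale/periodicity would not change what the pipeline is being
tested on; passing tests therefore demonstrate correct pipeline mechanics
and the engineered site ordering, not field accuracy on human data.

## Problem sizes and numerics

The shipped end-to-end evaluations use 20 subjects × 4 sites × ~90 min
(about 3,100 scored windows, 80 trained networks with 5 restarts each),
which completes in a few minutes on one CPU; unit tests use a shrunk
protocol (same 13-activity structure at ~12 min) and reduced restarts where
only bookkeeping is exercised. Degenerate inputs are handled explicitly:
single-class training folds raise a named error, empty recordings and empty
metric cells are legal and reported as empty/NaN, odd trailing samples and
incomplete windows are dropped with logged warnings. Kappa is undefined
(raised) when chance agreement is 1.

## Known limitations

* The classifier is a fixed 15-5-3 architecture by design; it is not meant
  to scale to more categories or feature sets without revisiting the
  training defaults.
* Asymptotic kappa CIs undercover for very small window counts; use the
  bootstrap for per-subject CIs.
* The generator's parameter values (orientations, amplitudes, jitters) are
  stylized: they reproduce ordinal site behavior, and no claim is made that
  they match any specific device's physical signal statistics.
* Real DO streams contain coder reaction-time error; the generator's
  annotations are exact, so transition-window handling is tested under
  idealized synchronization.
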