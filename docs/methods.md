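# Methods

`facetouch` implements a complete wrist-accelerometry analysis for detecting
face-touching behaviour: a signal simulator that emulates a ten-activity
laboratory protocol, a preprocessing/ingest stage, a 49-feature extractor
over non-overlapping windows, and a participant-grouped nested
cross-validation harness for four classifier families. This note records the
models, the parameters that matter, and the choices made where the design
was genuinely open.

## The recognition problem

A watch worn on the dominant wrist records tri-axial acceleration in units
of gravity (g) at 30 Hz. Ten scripted activities are performed for 3 minutes
each, in randomized order: four involve repeated hand-to-face contact
(repeated face touching, eating and drinking, simulated smoking, adjusting
eyeglasses — the FT category) and six do not (phone use, lying flat,
computer tasks, writing, leisure walk, moving items — NFT). Two tasks are
evaluated: binary FT/NFT recognition, with FT as the positive class, and
10-class individual activity recognition (IAR).

## Simulator

Each activity segment is generated as

    a(t) = g(φ(t), ψ) + m(t) + ε(t),   ε ~ N(0, σ²) i.i.d. per axis

where `g(φ, ψ) = (sin φ, cos φ cos ψ, cos φ sin ψ)` is the unit gravity
reaction parameterized by the pitch φ of the device x-axis (the forearm
axis) against the horizontal and a roll ψ; a slow sinusoidal wobble
(0.05 Hz, ~2° amplitude) makes the posture drift realistically. The movement
term `m(t)` depends on the activity class:

* **Static posture** (lying flat): none; noise floor σ = 0.01 g.
* **Sedentary tasks** (phone, computer, writing): Poisson-scheduled jitter
  bursts (20–30 per minute, ~0.8 s long) of Gaussian amplitude
  0.03–0.05 g. The three tasks differ in resting pitch/roll; with the
  between-participant orientation jitter they deliberately overlap across
  subjects, which is what makes 10-class recognition harder than the binary
  task under leave-one-subject-out evaluation.
* **Leisure walk**: sinusoidal arm swing at 2 Hz (clipped to the human
  cadence band 1.8–2.2 Hz after the participant tempo multiplier), amplitude
  0.3 g distributed over the axes, arm hanging (pitch −75°). Its vector
  magnitude is strongly periodic and its gravity angle nearly constant —
  clearly distinguishable from face touching.
* **Hand-to-face excursions** (the four FT activities): raise–dwell–lower
  cycles in which the pitch ramps from ~10° to 55–68° ("hand at face"),
  with label-specific tempo — frequent short touches (face touching:
  10/min, 0.8 s dwell), medium cycles (eating: 7/min, 1.5 s), long holds
  (smoking: 5/min, 3.5 s), brief touches (glasses: 8/min, 0.5 s). During
  the ramp a transient push acts along the forearm; during the dwell,
  touch-gesture jitter (0.04–0.08 g) is added.
* **Moving items**: the same excursion machinery with a *longer* carry dwell
  (2.2 s) at a slightly lower raised pitch (55°) and a 12/min cycle. This
  is the designed confuser: its gravity-angle trajectory (and hence the
  `mangle`/`sdangle` features) overlaps the FT distribution far more than
  the walk does, so the pooled 10-class confusion matrix shows
  moving-items ↔ FT confusion dominating walk ↔ FT confusion.

Per-participant random effects are drawn once per subject: log-normal
multipliers (σ = 0.15) on movement amplitude and tempo, and a uniform
±15° offset on the baseline pitch and roll. They create genuine
between-subject variance so that held-out-subject folds are non-trivial.
All draws flow through a single `numpy` generator seeded from the
configuration, so a fixed seed reproduces the dataset bit-for-bit.

Timestamps start at 0 per participant; a fixed 10 s idle (quiet sitting)
gap separates consecutive activities so that annotation alignment is
exercised. What the simulator does **not** emulate: biomechanically
faithful arm kinematics, gyroscope channels, sensor saturation or drift,
free-living activity transitions, or the slight over-length recordings of
real sessions. Passing tests therefore demonstrate that the pipeline is
correct and that the protocol behaves as designed under controlled signal
models — not that the specific accuracy numbers transfer to human data.

## Preprocessing

Each annotated interval is trimmed by removing the first 20 s and the last
5 s before labeling (boundary transition noise), so a full 180 s bout
retains 155 s; interval membership is half-open
(`start + 20 ≤ t < end − 5`), which makes sample counts deterministic:
10 × 10 × 155 s = 15,500 s retained on the idealized protocol. Real
recordings run slightly longer than the scripted 3 minutes, so window
censuses on real data will exceed the idealized counts — expected, not
corrected. Samples between activities are dropped, not labeled; clock skew
between the annotation log and the recording is assumed zero. The reader
validates headers, monotone timestamps, known activity names,
non-overlapping intervals, and checks the inferred sampling rate (median
timestamp spacing) against the configured rate to ±1%.

## Features

Windows are consecutive, non-overlapping, taken from the start of each
trimmed segment; trailing partial windows are dropped; a window never spans
two activities. Per window, 49 features:

* For each of vm (vector magnitude), x, y, z: mean, SD, coefficient of
  variation, min, max, 25% and 75% quantiles, third and fourth central
  moments, skewness, kurtosis (44 features).
* `mangle`, `sdangle`: mean and SD of θ = arcsin(x/vm) in degrees — the
  angle of the acceleration vector relative to the forearm axis, the
  signature of a hand raised to the face.
* `p625`, `df`, `fpdf` on the vm spectrum: fraction of spectral modulus in
  0.6–2.5 Hz, the dominant (largest-modulus) positive frequency, and the
  fraction of total modulus at that frequency.

Numerical conventions (fixed, and checked against independent naive-loop
oracles to 1e-10): SD uses the sample (n−1) denominator, central moments
and skewness/kurtosis use population (n) moments; kurtosis is plain
m₄/m₂² (not excess); quantiles use linear interpolation between order
statistics; cv divides by |mean| and is zeroed when |mean| < 1e-6 g;
skewness/kurtosis are zeroed when m₂ < 1e-12 (constant windows);
arcsin arguments are clamped to [−1, 1]. The spectral features exclude the
DC term (a band starting at 0.6 Hz cannot include it, and retaining DC
would pin fpdf near 1 for any signal riding on gravity); dominant-frequency
ties break toward the lowest frequency; no detrending or taper is applied
before the FFT; a spectrum whose positive-frequency moduli are all below
1e-12 yields (0, 0, 0).

## Evaluation protocol

Nested cross-validation with participant-grouped folds: 10 outer folds,
each holding out one participant as the test set (leave-one-subject-out);
the other nine are shuffled deterministically by the plan seed and cut into
three inner triples. Grid search trains every hyperparameter combination on
each 2-of-3 triple union (6 participants) and scores it on the held-out
triple (3 participants); the combination maximizing mean inner-validation
F1 (binary F1 of the FT class, or macro-F1 for IAR; ties to the first grid
point in documented order) refits on all nine and is evaluated once on the
test participant. Features are z-scored inside the model pipeline, so
scaling statistics always come from the data the model is fitted on —
never from validation or test windows. Reported metrics are the mean and
sample SD over the ten outer folds.

Families and grids (all searched exhaustively, in this order):

| family | grid |
|---|---|
| logistic regression | C ∈ {0.01, 0.1, 1, 10, 100} |
| SVM (RBF) | C ∈ {0.1, 1, 10} × γ ∈ {0.5, 1, 2}/49 |
| decision tree | max depth ∈ {3, 5, 10, ∞} × min leaf ∈ {1, 5, 10} |
| random forest | trees ∈ {100, 300} × max depth ∈ {5, 10, ∞} |

Forest accuracy and impurity importances plateau well below a few hundred
trees at this problem size (~3,100 windows × 49 features), so 300 trees is
the upper grid point. AUC uses trapezoidal integration of the ROC
(probability scores, or the decision-function margin for the SVM, oriented
so larger means FT). Metrics that are undefined on a degenerate fold (no
positive windows; a single-class test set for AUC) are flagged and excluded
from the average with a logged warning rather than silently zeroed — this
cannot occur under the full protocol, where every participant performs
every activity. The pooled confusion matrix concatenates all outer-fold
test predictions and row-normalizes to percent (pooling, rather than
averaging per-fold matrices, weights every window equally). Scaled
impurity importances average the fold forests' importances and divide by
the maximum.

The nested plan requires at least 7 participants: with (n−1) divisible by 3
but only one inner triple (n = 4), the inner training set would be empty.

## Problem sizes and reproducibility

The default study is the simulator's default: 10 participants × 10
activities × 180 s at 30 Hz (seed 1 in the test suite), giving 3,100
five-second windows or 1,700 nine-second windows. `scripts/acceptance.py`
re-runs the whole pipeline at these sizes — trimming arithmetic, feature
census, protocol shape, binary logistic regression at 5 s, 10-class random
forest at 9 s, the FT confusion masses of the moving-items and walk tasks,
and a label-permutation null for the AUC. Everything is deterministic given
the seed; classifier randomness (tree bootstraps) derives from the plan
seed plus the fold index.

## Known limitations

* Simulated signals are stylized; absolute performance numbers describe
  the simulator, not human recordings.
* The angle features assume the x-axis runs along the forearm; other watch
  mounting conventions would need a re-mapping.
* Irregularly sampled or gap-containing streams are rejected, not repaired.
* One window length is evaluated at a time; the window sweep re-runs the
  full protocol per length and is correspondingly expensive.
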