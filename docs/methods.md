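# Methods

This note documents the generative model, the control loop, the numerical
choices, and — where the design was genuinely open — why each default is
what it is. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Signal model

Each channel of a contraction is zero-mean Gaussian noise with three layers
of structure:

1. **Spectral tilt.** White noise is first recoloured by a first-order
   autoregressive filter `y[n] = ρ·y[n-1] + w[n]` with a class-specific
   coefficient ρ (`SimConfig.spectral_tilt`, defaults
   (+0.08, −0.15, −0.08, +0.15, 0) for wrist extension, wrist flexion,
   hand open, hand close, rest). This emulates the fact that different
   motions recruit different motor-unit pools whose spectra differ slightly;
   it is what makes the count features (ZC, SSC) carry class information
   that is *invariant to amplitude drift*. Without it, every bit of class
   information lives in amplitudes and no amount of pooled training data can
   stabilise a classifier across days — pooling then *hurts*, which is not
   how multiday EMG behaves.
2. **Acquisition band-pass.** The tilted noise passes through an 8th-order
   Butterworth band-pass (100–900 Hz at 2 kHz sampling), the recording
   chain's filter. The tilt + band-pass cascade is normalised so that
   unit-variance white input yields unit output RMS; activation values are
   therefore direct RMS targets in arbitrary units (amplifier gain and ADC
   quantisation are deliberately not modelled).
3. **Amplitude structure.** The per-channel RMS of class *c* is
   `gain_ch · sqrt((A[c,ch]·jitter_ch)² + floor²)` where `A` is the 5×3
   class-by-channel activation matrix, `jitter` is per-repetition log-normal
   contraction-level variability (σ = 0.15), `floor` = 0.10 is the baseline
   (instrumentation + distant muscle) noise, and `gain` is the drift state
   below. The default activation rows put each motion's agonist first
   (extensor digitorum, ECRL, FDS across the three channels) with partial
   co-activation; the two flexion-side classes (wrist flexion, hand close)
   are deliberately close so that same-day classification is not trivially
   perfect.

Motor-unit microstructure (spike trains, MUAP shapes) is not modelled: the
downstream analysis consumes only windowed time-domain statistics, which are
insensitive to it. A spike-train generator would be a drop-in extension at
the point where the unit-variance stream is synthesised.

## 2. Drift model

Nonstationarity is multiplicative, on log-amplitude gains and on the
activation matrix, with two temporal structures × three spatial components
(`DriftConfig`):

| component | day default | session default | emulates |
|---|---|---|---|
| common gain, fluctuation | 0.45 | 0 | tissue/interface state of the day |
| per-channel gain, fluctuation | 0.08 | 0 | channel-specific contact changes |
| channel mixing, fluctuation | 0.03 | 0 | pick-up volume shifts |
| common gain, walk | 0.05 | 0.15/session | slow electrode migration |
| per-channel gain, walk | 0.05 | 0.05/session | idem |
| channel mixing, walk | 0.02 | 0.01/session | idem |

plus a deterministic per-session gain decline of e^(−0.12) per session
(`session_gain_trend`), i.e. contraction effort fades over a day's three
test sessions.

Why this shape:

* **Fluctuation + walk.** Independent day offsets make pooling days
  informative (a model trained on several days has *seen* the range of
  states a new session can take — the mechanism by which combined-day
  training wins). The cumulative walk makes the distance between day *i*
  and day *j* grow with |i−j| (verified by test), which is what makes
  *older* training data progressively less useful.
* **Common-mode dominance.** A common gain rescales all channels together
  and therefore never maps one motion's activation pattern onto another's;
  per-channel and mixing drift can. Real interface drift is predominantly
  common-mode per channel-pair; making it dominant keeps classes
  identifiable in principle while still breaking a stale classifier.
* **Gain scales the floor too.** The drift gain multiplies the noise floor
  along with the activations (it is a property of the recording interface,
  not of the muscle). If the floor were fixed, "rest" would be the only
  drift-free class and pooled training would be asymmetrically penalised.
* **Session fatigue.** The deterministic decline makes the first test
  session of a day systematically closest to that day's calibration state —
  the reason completion rate is best in session 1 and decays by session 3,
  for every scheme, most visibly for between-day training. A pure random
  session walk cannot produce that trend structurally: from the already
  shifted state a between-day model starts at, a random walk is as likely
  to help as to hurt.

Magnitudes were chosen once so that, on average over subjects, the same-day
classifier is nearly perfect (WCE ~1%), the previous-day classifier loses
roughly a fifth of its decisions (BCE ~15–25%), and pooled training recovers
most of it — the qualitative regime the benchmark is about — and then
frozen. They are configuration, not fit parameters.

Everything is a pure function of `(seed, metadata)`: recordings are keyed by
(day, session, repetition, class), drift states by (day, session), and
closed-loop noise streams by (day, session, trial seed), so any subset can
be regenerated independently and bit-identically.

## 3. Features and windowing

200 ms windows, 50 ms increment, over the central 4 s of each 6 s
contraction (the onset and release transients are trimmed symmetrically;
the steady-state location is a convention, not data-derived). All lengths
are converted to integer sample counts before indexing, giving exactly
77 windows per calibration recording.

Six features per channel, channel-major, 18 per window: mean absolute
value, waveform length, zero crossings, slope sign changes, Willison
amplitude, cardinality. The four thresholded counts use a threshold ε
resolved per window and channel as `0.01 × window RMS` by default: the
simulator's amplitude units are arbitrary, so an absolute default would be
meaningless; relative thresholds keep the features scale-covariant (MAV,
WL) or scale-invariant (the counts). An absolute mode exists for
reproducibility tests. The slope-sign-change comparison is strict (`> ε`),
matching the printed formula.

The per-window kernel is compiled with numba (the closed loop evaluates it
at every 50 ms tick); a pure-numpy path is the fallback and the naive
per-sample loops in the test suite are the correctness reference for both.

## 4. Classifier

A single hidden layer: 18 inputs (z-scored with training-set statistics
only — no test-day leakage; zero-variance features get a unit floor),
10 tanh hidden units (the hidden size is a free choice; 10 is enough to
carve the pooled multi-day structure and small enough to train in
milliseconds), 5 linear outputs against one-hot targets, argmax decision
with ties going to the lowest class index.

Training is Levenberg–Marquardt: damped Gauss–Newton on the MSE with the
analytic residual Jacobian (~245 parameters, so the normal equations are
tiny). A step is accepted only if it does not increase the loss; the
damping λ divides by 10 on acceptance and multiplies by 10 on rejection
(bounds 1e−12, 1e12). Stopping: relative loss change < 1e−5, loss < 1e−8,
or 50 iterations. Initial weights are N(0, 1/√fan-in) from a fixed seed —
training is fully deterministic. An Adam-based first-order fallback exists;
models record which optimizer produced them.

## 5. Schemes

* WDT trains on the test day's own calibration set; BDT on the previous
  day's; CDT on all days up to and including the test day (13 non-empty
  scheme-day cells over five days).
* WCE is two-fold with folds split by repetition pairs {1,2} / {3,4} —
  random window-level folds would leak, since 77 windows of one contraction
  overlap by 150 ms.
* BCE trains on day *j−1*, tests on day *j*. CCE by default trains on all
  *former* days and tests the whole present day; `include_present=True`
  additionally pools the present day's first repetition pair and tests on
  the second (the convention matching real-time CDT), exposed as a flag
  because the two readings genuinely differ.

## 6. Closed-loop task

Cursor at the origin; target of width W at distance D along one of four
class axes (up = hand open, down = hand close, left = wrist flexion,
right = wrist extension; the vertical mapping is a fixed convention).
On-target means within W/2 of the target centre both along and across the
movement axis. Success = 1 s continuous dwell (20 full 50 ms intervals;
the dwell clock restarts on exit); failure at 15 s. Completion time
includes the final dwell second — throughput values depend on this
convention. 24 unique targets per session in seeded-random order; distinct
difficulty levels 1.81, 2.59, 3.46, 4.39 bits.

Control law: every 50 ms the simulated user emits the latest 200 ms window
for its intended class; the decoder classifies it; a majority vote over the
last 3 decisions smooths isolated flickers; the cursor moves 0.8 screen
units along the decoded class axis (rest = no motion).

* **Steering intent.** Outside the target the user intends the motion whose
  direction most reduces the remaining distance to the target centre;
  inside, rest (configurable to `continue`). Steering is essential: under a
  fixed "always the target direction" intent, any asymmetric decoding error
  accumulates off-axis until the target is unreachable, and an overshot
  cursor is pushed further away forever — neither matches how a human
  performs a 2-DOF pointing task.
* **Gain.** 0.8 units/tick makes a perfectly decoded D=100 trial take
  ≈ 7.1 s — inside the range human subjects exhibit on this task — and
  bounds the windowing lag (a class change takes ≤ 4 ticks to purge from a
  200 ms window) to 3.2 units of overrun, less than the narrowest target's
  width, so overshoot events reflect decoding errors, not quantisation.
* **Path efficiency** uses net start-to-end displacement over path length,
  so a monotone trace scores exactly 100% and PE ≤ 100 always. Throughput
  averages ID/CT over successful trials only (failures have no completion
  time). Overshoot counts target entries abandoned before dwell completion
  per 100 targets and can exceed 100.

The cursor trace is a pure function of the decision sequence and the
control configuration (`replay_decisions` reproduces it bit-exactly).

## 7. Statistics

Friedman's test uses within-block mid-ranks and the tie-corrected
chi-square statistic (Conover's form), referred to χ²(k−1); completely tied
tables return Q = 0, p = 1, and the k = 2 layout is supported (scipy's
implementation requires k ≥ 3, and serves as an oracle in the tests). At
small layouts the exact permutation null is a coarse rank lattice, so
chi-square p-values deviate from it by up to a few hundredths in the
mid-range — the test calibration check therefore targets the type-I error
at α = 0.05 rather than pointwise p agreement. Post hoc: pairwise Wilcoxon
signed-rank with Bonferroni correction at family-wise α = 0.05.

## 8. Problem sizes

The trend study in the test suite runs 20 simulated subjects through the
full design (5 calibration days; 12 scheme-day cells with three 24-target
sessions each, plus within-day cells on day 1; offline WCE/BCE/CCE), the
size at which the bootstrap confidence intervals on the scheme orderings
are decisive. `scripts/acceptance.py` runs 10 subjects, enough for stable
means of every reported quantity. Smaller fixtures (shortened recordings,
2-day designs) are used where only the mechanics are under test.

## 9. What the simulation does and does not show

The generator reproduces the statistical *structure* the analysis assumes —
band-limited class-conditioned amplitudes with controlled day/session/
repetition variability — not real iEMG. Passing tests demonstrate that the
pipeline's conclusions (pooled-day training is the robust scheme; a
previous-day model degrades, most by a day's third session; completion time
follows the difficulty index linearly) hold under that structure, and that
every computational step is correct against independent oracles. They do
not calibrate absolute error rates for real electrodes: real signals add
motor-unit structure, within-contraction amplitude dynamics, human motor
learning across days (our simulated "subject" neither learns nor
anticipates), proportional-intent behaviour near targets, and drift
mechanisms richer than multiplicative gain/mixing. Consequently absolute
levels (e.g. WCE near 1% here vs several percent in human studies, bits/s
throughput magnitudes) are not comparable to human data; the *orderings and
trends* are the reproducible content.

## 10. Known limitations

* Overshoot at high decoding accuracy is near zero — without proportional
  control or human impatience, a well-decoded cursor simply stops; human
  overshoot rates are higher across the board.
* Day-1 within-day performance is not worse than later days: subject
  learning is not modelled.
* The spectral tilt is a scalar per class (not per channel), and drift does
  not alter spectra, only amplitudes and mixing.
* The Fitts regression is fitted on per-difficulty mean completion times
  (4 points); with near-ceiling completion rates its R² is high by
  construction of the control law.
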