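# Methods

This note records the model, the numerical choices, and the judgement calls
behind `spredict`, in the spirit of a maintainer's design document.  The
README gives the pipeline overview; here we go component by component.

## Signal model and preprocessing

A recording is an (n_samples × d) matrix in microvolts at sampling rate fs
(defaults follow intracranial practice: d = 6 selected contacts, fs = 256 Hz),
with seizure annotations in seconds from recording start.  Line interference
is removed with a second-order IIR notch at 50 Hz (quality factor Q = 30)
applied forward-backward (`filtfilt`), so the filter is zero-phase and
annotation times stay aligned.  Windows are 10 s long; the analysis grid
overlaps them 50 % (5 s step).  Windows that would cross the end of the
requested span are dropped, not truncated, so every feature vector sees
exactly 2560 samples at the default rate.  Window labels: *ictal* when the
window overlaps an annotated seizure (ictal wins any tie), *preictal* when
the window ends within the half-open interval (onset − span, onset], else
*interictal*.  The preictal training span is 37.6 min, which at 10 s / 50 %
yields exactly 450 windows per seizure; the interictal pool uses 150 min of
non-overlapping windows, i.e. 900 samples.

## Empirical mode decomposition

EMD is implemented directly (sifting with cubic-spline envelopes) and
compiled with numba for the inner loop:

* **Envelopes.**  Local extrema with plateau midpoints; a natural cubic
  spline through the maxima (resp. minima), with up to two extrema
  mirror-extended about each boundary before fitting.  Mirroring tames the
  end swings that otherwise leak low-frequency artifacts into the IMFs.
* **Stopping.**  A sift iterate is accepted as an IMF when the standard
  normalized squared change SD = Σ(d_prev − d_new)²/Σd_prev² of the last
  subtraction fell below 0.25 **and** the iterate satisfies the IMF criteria
  with tolerance (|#maxima − #minima| ≤ 1, zero crossings within 1 of the
  extrema count), capped at 100 sifts.  Checking the criteria on the current
  iterate (not its predecessor) is what makes the criteria hold for the
  returned IMFs.
* **Termination.**  Decomposition stops when the residual has fewer than two
  maxima or two minima ("monotonic-like") or when `max_imf` (3 in the
  pipeline) is reached.  The residual is defined by subtraction, so
  IMFs + residual reconstructs the input to machine precision by
  construction; constant inputs yield zero IMFs.

The Hilbert transform uses the frequency-domain analytic signal
(`scipy.signal.hilbert`); phase is the four-quadrant angle in (−π, π],
instantaneous frequency is the gradient of the unwrapped phase (rad/s).
Edge behaviour of the analytic signal is why all tone tests assert on the
interior 80 % of a window.

## HHT-ELM features

Per window, each channel contributes up to 3 IMF phases; channels with fewer
IMFs (or constant channels) are zero-padded so the feature length is fixed
(n_f = d·max_imf = 18 phase columns).  A 10-neuron ELM with logistic
activation is fit to predict φ(t+1) from φ(t) (one step = one sample at the
native rate), and the output-weight matrix **B** (10 × 18), flattened
row-major, is the 180-dimensional feature vector.  Two choices deserve
emphasis:

* The random hidden layer is drawn **once per run** and shared by every
  window.  Output weights live in the basis of the hidden layer; with
  per-window random layers the features would not be comparable across
  windows and the classifier would see noise.
* Phases are fed wrapped, with no sin/cos embedding.  The wrap
  discontinuities act as symmetric noise on the regression and affect both
  classes alike; keeping the raw phase preserves the interpretation of **B**
  as phase-interaction weights.

ELM solving: SVD pseudo-inverse with cutoff 1e−12·σ_max for the feature
network (ridge 0), ridge-regularized normal equations (ridge 1e−6) for the
1000-neuron classifier, which is otherwise poorly conditioned with 1800
training samples.  Hidden weights and biases are i.i.d. uniform on [−1, 1]
from a seeded generator; every run is reproducible from one global seed.

## Pools, Mahalanobis distances, updates

Pool statistics use the sample covariance (n−1 denominator) with a
trace-scaled ridge eps = 1e−6·trace(Σ)/dim before inversion; an all-equal
(zero-trace) pool falls back to the pseudo-inverse.  The printed quadratic
form is used under a square root so the quantity is a metric; every
comparison and sort in the update rules is monotone in either convention, so
this is presentation, not behaviour.  The distance of a set to a pool is the
mean of its points' distances.

Abnormality: a set S is abnormal iff M(S, S_pre) ≤ λ·M(S, S_inter), λ = 1
(ties count as abnormal — the conservative reading, since only *normal* sets
may enter the interictal pool).  Updates rank the pooled old+new samples by
distance to the **opposite** pool and retain capacity-many, ascending by
default: keeping the samples closest to the opposite class concentrates the
pools on the decision boundary, which is the reading most consistent with
replacing "the farthest sample".  Because the direction is genuinely
arguable, it is a config switch (`sort_order`), and ties break by sample age
(older retained first) for determinism.

## Streaming state machine

Decisions (classifier output thresholded strictly at 0.5) fill a rolling
buffer of the 17 windows wholly inside the trailing 1.5-min observation
window; the preictal density is the fraction of 1s, and an alarm requires a
full buffer and Den > γ strictly.  After an alarm no new alarm is raised
until it resolves (true positive at an onset inside the horizon, false alarm
when the horizon lapses) — without this refractory rule a sustained preictal
state would emit an alarm every 5 s.  Ictal and postictal
(default 10 min, unquantified in clinical practice and therefore
configurable) windows are never classified, and any skip clears the buffer
so densities never mix non-contiguous windows.

Condition A harvests the feature rows of the buffer that raised the alarm;
Condition B harvests the windows fully inside [onset − 40 min,
onset − 30 min].  A predicted (true-positive) seizure triggers no update of
either pool; after it, observation resumes past ictal + postictal.  After a
*missed* seizure, observation resumes past ictal + postictal + H_time, and
with updates disabled the system reduces exactly to the static basic model
(no updates, no horizon skip, constant pools and model).  An alarm still
pending when the stream ends is counted as a false alarm (conservative for
fpr) but triggers no update.  Retraining refits only the classifier's output
weights; its hidden layer is part of the run's seeded state and is kept.

## Evaluation conventions

A seizure is predicted iff an alarm falls in (onset − H_time, onset); the
advance time uses the *first* such alarm (the published advance times reach
107 min at H_time = 110, which is only consistent with earliest-alarm
accounting), and a missed seizure contributes 0 min — the only convention
that reproduces the reference group means from the per-patient rows.
Interictal hours exclude the horizon span before each onset (no alarm there
can be false), the ictal period and the postictal skip.  Group aggregation
averages per-patient sensitivities and fprs, and averages advance times over
the concatenation of all tested seizures.  The performance index is
P = √((s̄_e² + s̄_p²)/2), s̄_p = 1 − mean fpr, clamped to 0 when the mean fpr
exceeds 1 h⁻¹; fpr in h⁻¹ is subtracted from the dimensionless 1 exactly as
printed, with no invented unit correction.  P is rounded to two decimals for
reporting.

## Synthetic generator

Channel j is x_j(t) = a·cos θ_j + 0.3a·cos θ′_j + line·cos(2π·50t) + noise,
with θ_j integrated per sample: natural frequencies spread over 6–12 Hz, a
secondary uncoupled component at 2.1× the natural frequency, phase diffusion
0.2 rad/√s, additive noise 0.5 µV against a 10 µV oscillation, and 2 µV of
50 Hz line (so the notch filter is exercised on every end-to-end run).  The
coupling κ(t) pulls each phase toward a common reference rhythm — frequency
entrainment plus a 2π·2 rad/s locking term, both scaled by κ — at κ = 0.05
in the interictal baseline, ramping linearly to κ = 0.8 across the 30-min
preictal period, and κ = 1 with amplitude ×4 on a common 4 Hz rhythm during
the 60 s ictal discharge.  Drift mode shifts all natural frequencies by
`drift_rate` Hz per hour.  All randomness flows through one seeded
generator and ground-truth regime labels are returned beside the data.

What it does *not* emulate: physiological EEG spectra (1/f background,
spindles, artifacts), spatial mixing, or patient heterogeneity.  Passing the
end-to-end tests therefore shows that the pipeline detects a genuine
preictal synchronization ramp under noise, line interference and drift — not
that it attains any particular clinical operating point.

## Study sizes

The synthetic patient used by the end-to-end tests and the acceptance script
is sized so the pool-construction arithmetic is exercised verbatim: 2
training seizures (450 preictal windows each from the 37.6 min before
onset), 900 interictal windows from 150 min, and 3 held-out seizure
recordings (40 min lead + 1 min ictal + 5 min tail) plus a 60-min held-out
interictal stream — about 8 h of simulated 6-channel EEG per seed at 256 Hz.
The drift study is smaller (one training seizure, 75-min interictal pool,
90-min drifting stream at 2 Hz/h) and shortens the horizon to 15 min so that
a false alarm can lapse — and Condition A can act — several times within the
stream; with the clinical 110-min horizon nothing can resolve inside a
desk-scale recording and the comparison would be vacuous.

## Known limitations

* EMD end effects are mitigated (mirrored extrema), not eliminated; the
  first and last fraction of a window's phase series is less reliable.
* The one-step phase regression at 256 Hz makes **B** dominated by
  short-lag structure; slower cross-channel interactions enter only through
  the IMF decomposition.
* The interictal pool update assumes false-alarm windows are representative
  interictal data once the abnormality check passes; adversarial
  non-stationarity (e.g. subclinical events) would poison the pool.
* EDF input is a thin adapter and expects channel units mne can convert;
  CSV is the canonical, fully-tested path.
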