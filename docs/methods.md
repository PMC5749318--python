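# Methods

## Problem and pipeline

The package predicts epileptic seizures by detecting the onset of the
preictal state in scalp EEG. A session is processed as: multichannel
recording → single surrogate channel (averaging or CSP) → EMD denoising
(sum of the last four IMFs) → nonoverlapping 1-second windows → seven
moment features per window → binary preictal/interictal classification →
alarm at the third consecutive preictal window. Evaluation reports
event-level sensitivity, window-level specificity, false alarms per
interictal hour and anticipation times.

## Surrogate channel (CSP)

Class covariances are trace-normalized per 1-second segment,
Rᵢ = XXᵀ/tr(XXᵀ), and averaged within class — averaging rather than
concatenating makes the estimate robust to unequal segment counts. The
composite R = R₁ + R₂ is eigendecomposed and whitened with
w = diag(λ)^(−1/2)Uᵀ. Since wRwᵀ = I, the whitened class covariances satisfy
S₁ + S₂ = I: they share eigenvectors, and an eigenvalue λ for the preictal
class pairs with 1 − λ for the interictal class. The ordinary symmetric
eigendecomposition of S₁ therefore solves the generalized problem, avoiding
the numerical asymmetries of a two-matrix solver. The filter bank is
Bᵀw with rows sorted by descending preictal eigenvalue; the surrogate
projection is the first row, the direction with the largest
preictal/interictal variance ratio. Which component to keep is a genuine
design choice — we take the top one because the downstream task is to make
the preictal state conspicuous.

Numerical choices: a ridge εI with ε = 1e−10·tr(R)/n is added only if R is
numerically singular (long referenced recordings can be rank-deficient);
eigenvector signs are fixed by making each vector's largest-magnitude entry
positive, so fits are deterministic across platforms. CSP is fitted per
subject on training sessions only; fitting scope is configurable but
per-subject matches how subject-specific seizure predictors are deployed.

## EMD

Sifting subtracts the mean of the cubic-spline envelopes through local
maxima and minima. Cubic splines are the de-facto standard envelope;
endpoints are handled by mirroring the two outermost extrema about each
signal end, which suppresses end swings. With only two extrema the envelope
degenerates to a straight line. Strict local extrema are used; a flat
plateau contributes its midpoint once.

Stopping: an iteration ends sifting if (a) the candidate passes the IMF test
— extrema and zero-crossing counts differing by at most one AND mean
envelope below 5% of the peak — or (b) the Cauchy criterion
Σ(h_{k−1}−h_k)²/Σh_{k−1}² < 0.2 holds *and* the extrema/zero-crossing
balance holds, or (c) 100 iterations elapse (the IMF is then flagged
not-converged). The extra count check in (b) guarantees that every IMF
flagged converged satisfies the defining count condition; on hour-scale
signals with hundreds of thousands of extrema the exact balance is rarely
attainable and such IMFs are honestly flagged, while completeness
(Σ IMFs + residue = input, exact up to roundoff by construction) always
holds. Decomposition stops when the residue has fewer than two maxima or
minima, or at `max_imfs` (default 12).

Denoising keeps the sum of the last four IMFs (clamped when fewer exist);
the residue — a drift term, not an oscillation — is never included. The
*pipeline* default caps the decomposition at 6 IMFs: at 256 Hz the EMD
filterbank is approximately dyadic, so modes 1–2 sit near 64 and 32 Hz —
broadband noise above the EEG bands — and modes 3–6 span roughly 0.5–16 Hz.
Keeping "the last four of six" therefore discards exactly the noise modes
while retaining delta through beta rhythms; a deeper decomposition would
push the retained modes into sub-physiological drift. Whole-session
decomposition is the default; a block mode (`emd_block_s`) exists for
memory-constrained use.

## Features

All time-domain moments use the population (divisor-N) form. Kurtosis is the
plain standardized fourth moment (3 for a Gaussian); an excess-kurtosis
switch exists but is off by default. The autocorrelation estimator is biased
(1/N), which keeps the lag sequence nonnegative-definite; the PSD is its
two-sided lag transform at the N-point bin grid, algebraically equal to the
periodogram |DFT(y)|²/N, with negative floating-point residues clamped at
zero. Spectral moments are computed over one-sided bins 0…N/2 in bin-index
units (one bin = fs/N Hz; exactly 1 Hz for 1-s windows at 256 Hz). A PSD
whose spread is at the roundoff floor (σ_s² below ~eps·n_bins², e.g. a pure
sinusoid) is treated as a point mass and gets zero spectral skewness, since
the standardized third moment is then 0/0. Features are computed on the
*sum* of the retained IMFs, not per IMF (a per-IMF mode would multiply the
feature count without a corresponding gain on the synthetic benchmark).

Before classification, features are z-scored with constants fitted on the
training set only and stored with the model.

## Labeling, classification, alarm

Windows fully inside [onset − horizon, onset − guard) are labeled preictal;
windows overlapping ictal or postictal intervals, or the guard band, are
excluded; the rest are interictal. The horizon defaults to 30 minutes
(configurable; the benchmark uses 10 minutes to match its generator), the
guard band to 1 minute — the minute just before onset is transitional and
would poison both classes. The default classifier is an RBF-kernel SVM with
C = 1 and γ = "scale" on standardized features; kNN (k = 5) and Gaussian
naive Bayes are available for the comparison table, which ranks classifiers
by cross-validated preictal sensitivity.

The alarm fires when the third consecutive preictal window has been fully
observed (its end time). "Consecutive" is deliberate: counting
non-consecutive windows would fire on isolated noise. For scoring, an alarm
is a true prediction only if it falls strictly inside the prediction horizon
before onset; preictal runs earlier in the session occur in interictal time
and are counted as false alarms (with a 30-minute refractory period between
false alarms), mirroring the seizure-occurrence-period convention of the
prediction literature. An alarm exactly at onset is a miss. Seizure sessions
are eligible for evaluation only when onset is at least 20 minutes into the
session, so enough interictal baseline exists.

Sensitivity is reported per seizure event (fraction alarmed before onset);
specificity per window over labeled interictal windows; a per-window
sensitivity is also reported since the two bases answer different questions.

## Synthetic data

Each state drives one narrowband source (band-passed Gaussian noise with
configured center, bandwidth and RMS amplitude) through a fixed scalp
topography — diffuse for the interictal background, focal for the preictal
source, broader for the ictal source — on top of per-channel pink (1/f)
noise high-passed at 0.5 Hz as an acquisition chain would. Defaults:
interictal 2.5 Hz / 20 µV, preictal 5 Hz / 35 µV (a theta-band shift with
increased amplitude, consistent with reported preictal slow-rhythm changes),
ictal 9 Hz / 50 µV (at least twice the interictal amplitude), postictal an
attenuated background, noise 5 µV RMS. State transitions are instantaneous
so window labels are unambiguous. Cohorts jitter per-subject center
frequencies and amplitudes by ±10%. Everything is driven by
`numpy.random.default_rng(seed)`, giving bit-identical output per seed.

What the generator does *not* emulate: artifacts (eye blinks, EMG, electrode
pops), nonstationary background drift, gradual state transitions,
between-seizure heterogeneity within a subject, and realistic 10–20 montage
correlations. Passing the synthetic benchmark therefore shows the pipeline
is implemented correctly and can exploit spatial/spectral/amplitude
contrasts of the kind it assumes — it does not certify clinical performance
on real EEG, where preictal signatures are far subtler.

## Benchmark scale

The packaged experiment uses 5 subjects × 2 sessions of 22 minutes (onset at
minute 20 — the earliest the eligibility rule admits — with 10 minutes of
preictal state, 1 minute ictal, 1 minute postictal), training on each
subject's first session and evaluating the second. These sizes keep a full
run to a few minutes while exercising every stage on hour-scale-like data;
session counts, durations, horizons and spectra are all configurable for
larger studies.

## Known limitations

- EMD has no uniqueness guarantee; mode mixing can move a rhythm between
  adjacent IMFs, which is why the retained-band choice (`max_imfs`) matters
  and is documented above.
- The EDF writer targets plain EDF (16-bit, one rate, 1-s records); EDF+
  embedded annotations, BDF and vendor formats are out of scope.
- The evaluator treats the first seizure of a session as the prediction
  target; multi-seizure sessions are parsed but anticipation is scored
  against the first onset.
- Online (streaming) prediction is not implemented; the pipeline is
  session-batch oriented.
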