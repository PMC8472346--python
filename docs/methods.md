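# Methods

This note records the models, algorithmic choices and their rationale,
what the synthetic data does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Masking EMD

Each single-channel signal is decomposed into intrinsic mode functions
by iterated sifting: natural cubic splines are drawn through the local
maxima and minima, and the envelope mean is subtracted until the
extrema and zero-crossing counts are stable (S-number criterion, S = 4,
at most 100 sifts; a Cauchy-type stopping rule, SD < 0.2, is available).
Boundary handling mirrors the two edge extrema about each record
endpoint and clamps the envelope to an endpoint when the endpoint is
more extreme than the mirrored anchor implies; this reflection rule is
the main defence against the edge swings that short epochs provoke.

For mode k (1-based), a sinusoidal mask at the dyadic schedule
frequency f_mask(k) = fs/2^(k+1) — 50, 25, 12.5, … Hz at fs = 200 —
with amplitude 2 × SD of the current remainder is added at four phases
(0, π/2, π, 3π/2); each masked variant is sifted, and the four first
modes are averaged. Opposite phases cancel the mask exactly, while its
presence pins the extrema density so that slow oscillations cannot leak
into fast modes. The averaged mode is not in general a strict IMF
(small ripples appear where the phase variants disagree), so it is
re-sifted until |#extrema − #zero-crossings| ≤ 1; this polish preserves
band content and restores the defining IMF property, which the suite
asserts for every oscillatory mode it produces.

Two departures from the plain recipe are deliberate:

- **Unrealizable masks.** When fewer than two mask periods fit the
  record (mode 6 and deeper on 1.1 s epochs), masked sifting
  degenerates — the masked signal has too few extrema to envelope. The
  mask can steer nothing at that depth, and oscillations that slow
  cannot mode-mix with faster ones, so the mode is extracted by plain
  sifting with relaxed edge handling (one extremum per side suffices,
  the mirrored extrema supplying the remaining spline knots). This is
  what allows a ~1 Hz mode to exist on a 221-sample epoch at all.
- **Early termination.** Decomposition stops when the remainder is a
  trend (or when any masked phase variant cannot be sifted, since a
  partial phase average would leave mask residue). On 1.1 s records
  this typically yields 5–7 oscillatory modes; per-epoch containers
  zero-pad the missing high-index modes.

Completeness — input = Σ IMFs + residual to ~1e−15 — holds by
construction, because every reported mode is subtracted from the
working signal exactly as reported.

With this schedule, white noise at 200 Hz splits into a dyadic filter
bank: consecutive IMFs' dominant frequencies have ratio ≈ 1/2, with
IMF4 in the theta band (4–8 Hz), IMF5 in upper delta (2–4 Hz) and IMF6
in lower delta (1–2 Hz) — the band assignment the decoding stages rely
on. A 3 Hz tone is carried by IMF5 and a 7 Hz tone by IMF4.

Known limitations, both visible in the tests: a few percent of a pure
tone's energy leaks into the adjacent mode as an edge transient
(concentration is ~93–94% on 1.1 s epochs, not 100%), and a narrow-band
burst near a dyadic band edge reads ~0.25–0.5 Hz low in its carrier
IMF's spectrum (a 7 Hz burst reports ≈ 6.5–6.75 Hz). Both are
properties of masked sifting on short records, not of the spectral
estimator — the marginal spectrum of the raw burst peaks at exactly
7.0 Hz.

## Hilbert spectra

The analytic signal is built in the frequency domain (positive
frequencies doubled, negative zeroed), so its real part is the input
exactly. Instantaneous frequency is the central-difference derivative
of the unwrapped phase; instantaneous amplitude is the modulus. The
marginal spectrum accumulates amplitude² into 0.25 Hz bins over
0–100 Hz, bins centred on multiples of the bin width so a tone at a
grid frequency occupies a single bin. The first and last 5% of samples
are excluded (Hilbert edge distortion), and samples with negative
instantaneous frequency — spline-overshoot artifacts — are excluded and
counted in a QC field. Energy is conserved exactly over the samples
kept. Dominant frequency is the centre of the maximum-energy bin, ties
resolved to the lower frequency and logged. When spectra are averaged
across participants, the peak is taken after summing spectra
(peak-of-mean), not by averaging per-participant peaks.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass (0.5–100 Hz default,
forward–backward; linear-phase FIR selectable), polyphase anti-aliased
resampling (1000 → 200 Hz default), stimulus-locked segmentation with
an endpoint-inclusive window (−100…1000 ms at 200 Hz = 221 samples),
optional (default on) mean-baseline subtraction over the pre-stimulus
interval, and peak-to-peak rejection (a trial is dropped iff any
channel's max−min exceeds the threshold; the threshold is
data-dependent and has no package default). Note the 0.5 Hz high-pass
edge rings for several seconds; filtering is meant for continuous
recordings, not for already-cut epochs. Independent-component artifact
removal is a manual judgement and is supported only as an external
hook: the package applies a caller-supplied component-rejection list
and never selects components itself.

## Synthetic data

The generator emulates the statistical structure the analysis assumes
and nothing more. Sources are points on a unit sphere; sensors sit on
a Fibonacci-spiral hemisphere of radius 1.1 with a small seeded jitter;
gains decay as a Gaussian in sensor-to-patch distance (scale 0.6). The
reference configuration — two 3 Hz supramarginal sources and one 7 Hz
right-inferior-frontal source — uses 102 sensors, 60 trials per
condition, 16 participants, 200 Hz, −100…1000 ms epochs. At
geometry seed 0 the three gain columns have pairwise |correlation|
≤ 0.62, so the inverse problem is well-posed at toy scale.

Parameter choices, fixed once:

- **Envelope**: raised-cosine burst, onset 80 ms, 50 ms rise/fall,
  ending 480 ms post-stimulus, consistent with an early evoked response
  peaking in the 100–140 ms range.
- **Phase**: the evoked component is phase-locked (fixed phase at
  envelope onset), since trial averaging of evoked responses assumes
  it; fully randomized per-trial phase is selectable.
- **Noise**: 1/f background (α = 1) generated at 20 random nuisance
  patches and projected through the same geometry — so the sensor noise
  covariance is spatially structured, as the dSPM stage assumes — plus
  white sensor noise (SD 0.5). With unit source amplitude the
  single-trial evoked-to-noise RMS ratio at the most driven sensor is
  ≈ 0.5–0.6, making single trials noisy but 60-trial averages clean.
- **Between-participant variability**: a lognormal(0, 0.2) amplitude
  multiplier per participant.

All randomness flows from explicit seeds (cohort seeds are spawned from
one master seed), so identical spec + seed reproduces byte-identical
data. What the generator does **not** emulate: cortical geometry and
orientation, volume conduction, sensor types and gradiometer physics,
eye/cardiac artifacts, or latency jitter across trials. Passing tests
therefore show the pipeline's internal consistency — band separation,
calibration, localization under the assumed forward model — not
performance on real MEG.

Group-statistics calibration uses a separate, cheaper null generator:
chance-level AUC series (0.5 + temporally smoothed Gaussian noise,
SD 0.03, symmetric per participant). The sign-flip test's validity
requires only per-participant symmetry about the null value, which this
construction satisfies by design regardless of smoothing.

## Decoding

Features at timepoint t are all channels' values of one IMF (or ROI
trace) at t — no temporal window, to keep time resolution at the
sample level. Trials are split into stratified 30-fold CV (seeded
shuffle); feature standardization is fitted on training folds only;
the classifier is scikit-learn logistic regression with L2 penalty,
C = 1.0 (exposed). The per-timepoint score is the mean over folds of
the held-out fold AUC; pooling all held-out decision values into one
AUC is available behind a flag. Fold-averaging was chosen as the
default because the per-fold test sets are small (2–4 trials) and the
mean is the natural single score per timepoint. The AUC itself is
rank-based with ties counting ½, identical to the all-pairs count.

## Group statistics

The tested quantity is per-participant AUC − 0.5 per timepoint. The
cluster test thresholds the pointwise one-sample t series at t > 2
(one-tailed default; |t| for two-tailed), forms maximal contiguous
runs, scores each by its summed t, and compares against the null
distribution of the maximal cluster mass over cohorts whose
participants' whole series are independently sign-flipped. Sign
flipping is the exchangeability argument matching a one-sample design.
P-values use (b+1)/(n_perm+1), so the floor at 1000 permutations is
≈ 0.001. Adjacency is temporal only: the clustered object is a 1-D
decoding trace, not a sensor map. The permutation t statistics are
computed vectorized (flips leave Σx² per timepoint unchanged), so a
200-cohort calibration sweep at 1000 permutations runs in seconds.
Bonferroni adjustment (min(1, m·p)) is provided for the pointwise
parametric alternative; it controls the family-wise error rate.

## Inverse

M = R Gᵀ(G R Gᵀ + λ²C)⁻¹ with R = I: fixed orientation, no depth
weighting — appropriate because the toy patches are roughly equidistant
from the sensor shell; both are flags for externally supplied forward
models. λ² defaults to 1/9 (assumed power SNR of 3). The noise
covariance is the empirical covariance of noise segments shrunk toward
its diagonal ((1−w)C + w·diag C, w = 0.1 default). dSPM divides each
source trace by √((MCMᵀ)ⱼⱼ); applying the inverse to noise drawn from
C then gives unit variance per source, which the suite checks. For
decoding in source space the inverse is applied per trial. Because the
inverse is linear and time-invariant, decomposing sensor signals and
then projecting IMF k equals projecting and then decomposing up to
sifting tolerance; the default order is decompose-then-invert.

## Validation scales

The simulation replica runs at the full reference scale (16
participants × 120 trials × 102 sensors); decomposition is applied to
each participant's trial-averaged evoked response at the three
source-dominated sensors, which is the object whose frequency content
the replica is designed to recover. The permutation-calibration sweep
uses 200 null cohorts of 16 × 221 series (200 permutations each in the
test suite, 1000 in the acceptance script); the reported empirical
family-wise error is judged against the binomial 95% band around 0.05
at n = 200, i.e. [0.02, 0.09]. Miniature configurations (≤ 48 sensors,
≤ 24 trials) are used in unit tests purely to exercise code paths.

## Out of scope

Anatomical head modelling (FreeSurfer surfaces, BEM, source
tessellation, subject-to-template morphing), MaxFilter-style
preprocessing, automatic artifact classification, ensemble/multivariate
EMD variants, temporal-generalization decoding, multiclass decoding,
TFCE and spatio-temporal clustering. Real-data analyses require an
externally computed forward matrix and channel list, which the inverse
module accepts as-is.
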