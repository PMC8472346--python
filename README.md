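# emdecode

Masking empirical mode decomposition, Hilbert spectral analysis,
time-resolved decoding, and cluster permutation statistics for epoched
MEG/EEG data — with a simplified minimum-norm/dSPM source stage and a
synthetic-data generator for validation.

## The problem

Evoked electrophysiological responses are nonstationary and nonlinear:
their frequency content drifts within a trial, which Fourier and wavelet
analyses represent poorly. Empirical mode decomposition (EMD) splits
each single-channel signal adaptively into intrinsic mode functions
(IMFs) — oscillatory components with locally zero-mean envelopes — by
iteratively subtracting the mean of the cubic-spline envelopes through
the local extrema ("sifting"). Plain EMD suffers from *mode mixing*:
an intermittent fast oscillation and a continuous slow one can end up in
the same IMF. Masking EMD adds a sinusoidal masking signal at a target
frequency before sifting and averages the extracted mode over several
mask phases (the mask cancels exactly in the average), pinning each IMF
to a dyadic frequency band.

With the signal separated into bands, the package supports the standard
decoding workflow for epoched data:

- **Hilbert spectra** — the analytic signal of each IMF gives an
  instantaneous amplitude a(t) and frequency f(t); accumulating a(t)²
  into f(t) bins yields the marginal Hilbert spectrum, whose peak bin is
  the IMF's *dominant frequency*.
- **Time-resolved decoding** — at every timepoint, an L2-regularized
  logistic regression is trained on all channels' values under
  stratified 30-fold cross-validation and scored by ROC AUC
  (0.5 = chance).
- **Group inference** — per-participant chance-centred AUC traces are
  tested with a cluster-based sign-flip permutation test: maximal runs
  of group t > 2 are scored by their summed t and compared with the
  permutation distribution of the maximal cluster mass
  (p = (b+1)/(n_perm+1), 1000 permutations, one-tailed).
- **Source estimation** — an L2 minimum-norm inverse
  M = Gᵀ(GGᵀ + λ²C)⁻¹ with dSPM noise normalization
  (each source divided by √(MCMᵀ)ⱼⱼ), applicable per trial, with ROI
  time-course extraction.

The bundled generator (`emdecode.synth`) simulates narrow-band evoked
sources through a toy distance-decay lead field: the reference
configuration has two 3 Hz (delta) sources at the left/right
supramarginal patches and one 7 Hz (theta) source at the right inferior
frontal patch, 200 Hz sampling, −100…1000 ms epochs, 16 participants,
structured 1/f background plus white sensor noise.

## Worked example

```python
import numpy as np
from emdecode import masking_emd, marginal_spectrum, dominant_frequency

fs = 200.0
t = np.arange(442) / fs
# continuous 5 Hz plus an intermittent 40 Hz burst: the classic
# mode-mixing input
gate = ((t > 0.5) & (t < 0.9)) | ((t > 1.3) & (t < 1.5))
x = np.sin(2 * np.pi * 5 * t) + 0.8 * np.sin(2 * np.pi * 40 * t) * gate

s = masking_emd(x, fs, n_imfs=8)
for k in range(1, s.n_imfs + 1):
    f = dominant_frequency(marginal_spectrum(s.imf(k), fs))
    print(f"IMF{k}: dominant {f:.2f} Hz")
```

prints

```
IMF1: dominant 40.25 Hz
IMF2: dominant 25.25 Hz
IMF3: dominant 5.25 Hz
IMF4: dominant 5.00 Hz
IMF5: dominant 3.25 Hz
IMF6: dominant 1.50 Hz
IMF7: dominant 0.75 Hz
```

The 40 Hz burst is isolated in IMF1 and the continuous 5 Hz tone is
recovered cleanly in IMF4 (correlation with the true slow component
0.991), whereas plain EMD mixes the two scales into one mode (best
correlation 0.688).

The same operations run from the shell:

```bash
emdecode simulate --seed 3 --out sim            # three-source cohort
emdecode decompose --in sim_sub-01.h5 --out imfs.h5
emdecode hht --in imfs.h5 --imf 4 --out spec.tsv
emdecode replicate-sim --out report.json        # full simulation replica
```

## Layout

| module | contents |
| --- | --- |
| `emdecode.synth` | toy lead field, source/noise models, cohort simulation |
| `emdecode.preprocess` | band-pass, resample, epoching, baseline, rejection, HDF5/FIF I/O |
| `emdecode.memd` | sifting, plain EMD, masking EMD, per-epoch decomposition |
| `emdecode.hht` | analytic signal, instantaneous frequency, marginal spectra |
| `emdecode.decode` | rank AUC, per-timepoint cross-validated decoding |
| `emdecode.stats` | one-sample t, Bonferroni, cluster sign-flip permutation |
| `emdecode.inverse` | noise covariance, minimum-norm/dSPM, ROI time courses |
| `emdecode.pipeline` | configuration, simulation replica, decoding-study driver |
| `emdecode.cli` | `emdecode` command-line verbs |

See `docs/methods.md` for the modelling assumptions, parameter choices
and known limitations.
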