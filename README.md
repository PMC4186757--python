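# alphasync

Analysis pipeline for ROI-level electrophysiological epoch data: 10 Hz
alpha-band oscillatory power (Morlet wavelets, aperiodic 1/f normalization,
pseudo-z baselining, activation/divergence interval detection), source-leakage
assessment via resolution matrices, and inter-regional phase synchrony
(debiased weighted phase lag index with jackknife pseudo-z, Stouffer pooling
across subjects, and integral-of-z cluster permutation inference).

Because the workflows target data that cannot ship with the package, a
first-class synthetic generator (`alphasync.simulate`) produces multi-subject
cohorts with known ground truth — coupling graph with von Mises phase lags,
event-related amplitude envelopes, 1/f^γ background noise and linear
cross-talk mixing — so every stage is testable end to end.

## Modules

| module | contents |
| --- | --- |
| `simulate` | `SimConfig`, 1/f noise, coupled oscillators, power envelopes, cross-talk mixing, cohort generation, array container I/O |
| `preprocess` | `EpochSet`, epoch extraction, peak-to-peak rejection, prestimulus standardization, evoked-peak localization, behavioral summary |
| `crosstalk` | resolution matrix `R = W_roi A_roi`, column normalization, subject averaging, 20 % merge/drop rules |
| `tfr` | Morlet TFR with edge-validity masks, `β/f^γ` spectral fit, pseudo-z power, active/divergence intervals, metadata subset averages |
| `synchrony` | per-pair cross-spectra, debiased WPLI, jackknife SEM, Stouffer pooling, cluster permutation test |
| `pipeline` | YAML-driven orchestration and TSV/JSON reports |

## CLI

```sh
alphasync simulate   --config sim.yaml --out data/        # synthetic cohort
alphasync preprocess --data data/ --out clean/            # standardize + behavior
alphasync crosstalk  --operators ops.npz --out xt/        # leakage decisions
alphasync power      --data data/ --out power/            # pseudo-z intervals
alphasync synchrony  --data data/ --out sync/ --n-perm 5000
alphasync run        --config pipeline.yaml --out report/ # full pipeline
alphasync compare    --report report/                     # condition table
```

A pipeline config lists one `SimConfig` per condition plus analysis settings
(analysis frequency 10 Hz, 7-cycle kernel, −500–0 ms baseline at 6–14 Hz,
5–60 Hz aperiodic fit, thresholds z>3 / 4 SE / 20 % / α=0.01, permutation
count, master seed); every threshold is echoed into the report.

## Conventions worth knowing

- Epoch windows are half-open (`[start, end)`), so −500..2000 ms at
  600 samples/s is exactly 1500 samples.
- "7 cycles" is the total kernel support (±3.5 cycles), giving the 10 Hz
  kernel a ±350 ms span; validity masks are computed against the epoch
  window bounds.
- The debiased WPLI is reported as the signed square root of the debiased
  squared estimator, so |wpli| ≤ 1 and conjugating one input negates it.
- Cluster p-values compare each observed cluster's integral of pooled
  pseudo-z against the per-permutation maximum across all ROI pairs, which
  keeps the "any significant cluster" rate calibrated across the pair family.
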