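# speechtrf

Forward temporal-response-function (TRF) analysis of speech-envelope EEG
tracking with binning-based nonlinearity compensation:

1. **synthetic data** (`speechtrf.simulate`) — band-limited (1–8 Hz) stimulus
   envelopes, P1/N1/P2-shaped ground-truth kernels, and multichannel EEG
   generated as target + masker envelope convolutions, optionally passed
   through a static nonlinearity (quadratic or saturating), plus noise.
   Default design: 30 subjects × 40 trials × 2 noise-reduction conditions,
   64 channels at 100 Hz, 31 s trials.
2. **preprocessing** (`speechtrf.preprocess`) — Hilbert-magnitude envelope
   extraction with zero-phase Butterworth band-pass (1–8 Hz, 6th order) and
   polyphase resampling to 100 Hz; stimulus-delay alignment (49.1 ms) with
   edge trimming; re-referencing and notch/band-pass EEG conditioning.
3. **TRF model** (`speechtrf.trf`) — boosting (sparse coordinate descent over
   a Hamming-tapered basis with held-out early stopping, fold-averaged over
   partition rotations) on a −100…400 ms lag grid; EEG prediction via lagged
   design matrices; mismatched-trial noise pairings.
4. **nonlinearity compensation** (`speechtrf.compensation`) — per
   channel-trial: exclude the 20 smallest/largest predicted samples, split
   the retained predicted range into three equal-width bins, fit a line
   through the outer-bin means, and shift middle-bin measured samples so
   their mean lands on the line. The pre-shift deviation is the nonlinearity
   residual (positive = concave, negative = convex).
5. **evaluation** (`speechtrf.evaluation`) — SNR differences (dB), N1/P2
   peak amplitude/latency in the [0.08, 0.12] s / [0.18, 0.25] s windows,
   across-subject TRF variance, six-scalp-region channel groups.
6. **statistics** (`speechtrf.stats`) — dependent-samples t maps,
   cluster-based permutation tests over (lag, channel) space with
   sign-flip permutations and max-cluster-mass null, Bonferroni-corrected
   channel tests, exact-binomial empirical chance level, paired behavioral
   t-tests.
7. **pipeline** (`speechtrf.pipeline`, `speechtrf.cli`) — six-stage
   orchestration (original SNR → TRF → prediction → compensation →
   compensated SNR → re-estimated TRF) with CSV/JSON outputs and a run
   manifest.

## CLI

```bash
speechtrf simulate --subjects 2 --trials 3 --channels 8 --out trials
speechtrf trf --in trials --out-dir trfs
speechtrf compensate --in trials --out trials_comp
speechtrf evaluate --orig trials --comp trials_comp --out snr.csv
speechtrf stats                      # prints the empirical chance level
speechtrf run-all --out-dir run1 --seed 7
speechtrf preprocess --in signal.txt --fs-in 1000 --fs-out 100 --out env.txt
```

`run-all` executes the full six-stage workflow on a desk-scale simulated
dataset and writes `snr_diff.csv`, `residual_map.csv`, `peaks.csv`,
`trf_variance.csv`, `clusters.csv`, `summary.json`, and `manifest.json`.

## Channel groups and montage

An idealized 64-channel montage (labels, top-view coordinates), the
six-region channel grouping, and the distance-threshold adjacency used by
the cluster tests ship as editable JSON under `src/speechtrf/data/`;
loaders in `speechtrf.montage` accept user-supplied files.
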