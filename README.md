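# replayburst

Analysis pipeline for linking spontaneous replay events to transient
network-state activations in multichannel neural time series, exercised
end-to-end on synthetic fixtures with planted ground truth.

The package implements:

- **Synthetic fixtures** (`replayburst.synthetic`) — Markov-switching hidden
  states with distinct oscillatory power/coherence signatures, functional
  localizer trials with stimulus-specific spatial patterns, resting data with
  planted sequential reactivations at a fixed 40 ms lag whose event times
  follow a Markov-modulated Poisson process, and a 600 Hz wideband twin
  carrying high-frequency (102–148 Hz) bursts coupled to one state.
- **Replay detection** (`replayburst.replay`) — L1-regularised one-vs-rest
  logistic decoders trained on localizer data at the peak-accuracy time point,
  per-sample reactivation probabilities `sigmoid(X_t · beta_i)`, lagged
  task-minus-control sequence evidence, the combined replay probability trace
  (pairwise products + noisy-OR over task sequences), and 99th-percentile
  thresholding into replay events.
- **TDE-HMM** (`replayburst.hmm`) — hidden Markov model with zero-mean
  full-covariance Gaussian emissions on time-delay-embedded, PCA-reduced
  observations; multi-restart Baum–Welch EM, forward–backward posteriors,
  Viterbi decoding, and dual estimation (fixed emissions, re-fit transitions)
  on new data. Bad samples break the chain into independent segments.
- **State geometry** (`replayburst.geometry`) — transition-matrix-derived
  state distances (self-transitions removed, `d = 1 − psi`, symmetrised),
  one-dimensional classical MDS state ordering, and visit lifetime/interval
  statistics.
- **Spectra** (`replayburst.spectral`) — state-conditioned Slepian multitaper
  power and coherence (2 s windows, 7 tapers, 0.5 Hz resolution, 1–45 Hz),
  NNMF frequency-mode decomposition, evoked time–frequency reconstruction,
  Gaussian-mixture thresholding of coherence maps, and wideband
  high-frequency analyses (state-conditioned PSD to 160 Hz; 30 ms
  replay-event windows against a subject-shuffled baseline).
- **Evoked statistics** (`replayburst.evoked`) — epoching of posterior state
  probabilities around events with per-subject session-mean baseline,
  group mean ± SEM, one-sided sign-flip cluster permutation tests (t > 3,
  run-length mass), the inflexible replication test, paired condition
  comparisons, and the 1–99 percentile threshold sweep control.
- **Burst statistics** (`replayburst.bursts`) — Fano-factor curves over
  non-overlapping windows, the interval-shuffle surrogate test of the
  IID-interval null, per-state visit Fano comparisons (ANOVA + two-sample t),
  and state-conditioned inter-replay intervals.
- **Pipeline + CLI** (`replayburst.pipeline`, `replayburst.cli`) — seeded,
  deterministic orchestration with HDF5/TSV/JSON artifacts.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (Poisson Fano
calibration, MMPP burstiness, lag recovery, HMM parameter recovery, evoked
coupling and null calibration, interval-shuffle validity, spectral fidelity,
state labeling, high-frequency exclusivity, probability conservation).

## CLI

```sh
replayburst simulate --config cfg.yaml --out fixtures/ --seed 17
replayburst detect   --data-dir fixtures/ --percentile 99 --lag-ms 40 --out events.tsv
replayburst fit-hmm  --data-dir fixtures/ --k 4 --restarts 5 --embed-lags 7 --out hmm.h5
replayburst label    --hmm hmm.h5 --out state_labels.tsv
replayburst run-all  --config cfg.yaml --out report/ --seed 1
replayburst validate --report report/summary.json
```

The YAML config mirrors `replayburst.pipeline.PipelineConfig`; every stage
default follows the published constants where one exists (99th percentile,
40 ms lag, ±0.5 s epochs, t-threshold 3, 5000/1000 permutations,
2 s / 0.5 Hz / 7-taper multitaper, 30 ms high-frequency windows, 5 restarts,
K=12 supported with K=4 fixture defaults).

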