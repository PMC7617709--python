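# tmseegkit

A tested, reusable pipeline for analyzing the effects of a phase-locked
tACS-iTBS stimulation protocol on TMS-EEG and resting-state EEG:

- **`stim_schedule`** — simulate and validate the concurrent phase-locked
  tACS-iTBS protocol (active and sham) as an explicit waveform plus
  pulse-time schedule. With the defaults (5 Hz / 1 mA tACS; 50 Hz triplets
  every 200 ms; 2-s trains, 8-s breaks, 20 trains; onset 30 s) the active
  schedule delivers 600 pulses over 240 s, every second triplet pulse on a
  tACS crest (sine convention: crest = 90°).
- **`data_model`** — epoched/evoked EEG containers (µV, ms relative to TMS
  onset, half-open windows), internal container I/O plus minimal
  BrainVision and EDF readers, baseline correction, trial averaging, and
  the scaled-MAD (×1.4826) outlier rule for subject screening.
- **`tep_gmfp`** — global mean field power (population SD across
  channels), 20-ms binning (−20 to 400 ms), and per-bin / per-channel
  2×2 (time × condition) repeated-measures ANOVAs.
- **`tanova`** — per-timepoint permutation test on GMFP-normalized maps
  (within-subject label shuffles for main effects, subject-level sign
  flips for the interaction; 1,000 permutations by default) with
  duration-of-significant-periods multiple-comparison control.
- **`tfr`** — Morlet decomposition (30 log-spaced frequencies 3–70 Hz,
  cycles 3→10, concatenated-trial convolution, 20-ms steps), dB baseline
  normalization (−400 to −200 ms), band/time/electrode ROI extraction,
  three-way RM ANOVA with generalized eta squared, Wilcoxon post-hocs, and
  Huber robust change-score regression with mean-centered predictors.
- **`microstates`** — GFP-peak extraction, polarity-invariant modified
  k-means, grand-mean templates, canonical A–D sorting, backfitting, and
  occurrence/duration/coverage with 2×2 RM ANOVAs.
- **`stats_util`** — shared within-subject statistics engine (2×2 and
  2×2×2 RM ANOVA, Wilcoxon signed rank with exact enumeration for small
  n, Huber IRLS, exact two-sided binomial test).
- **`synth_data`** — synthetic cohorts with known ground truth (TEP
  components, ROI-confined oscillatory bursts, 1/f noise; resting EEG with
  a hidden 4-state Markov topography sequence), so every stage is testable
  without any external data.
- **`pipeline` / `cli`** — end-to-end runner and command-line front end.

## CLI

```bash
# schedule summary + pulse table
tmseegkit schedule --pulse-table pulses.csv

# full synthetic end-to-end pipeline (CSV/JSON outputs in results/)
tmseegkit run --seed 1 --out results

# individual stages (YAML config optional, unknown keys rejected)
tmseegkit synth --seed 1 --out results
tmseegkit tanova --seed 1 --out results
tmseegkit microstates --seed 1 --out results
```

Every output CSV carries a header line with package version, config hash
and seed; reruns with the same config are byte-identical.

## Conventions worth knowing

- Crest of the tACS sine = phase 90°; the sham envelope ramps up and
  immediately down over 10 s total (5 s + 5 s, configurable).
- GMFP uses the divide-by-k (population) standard deviation.
- The gamma ROI starts at −20 ms by design: wavelet temporal smearing
  leaks post-stimulus gamma backwards in time.
- Channel-wise ANOVA maps are exploratory and uncorrected; familywise
  protection over electrodes/time comes from the TANOVA duration test.
- Microstate comparisons are polarity-invariant throughout (absolute
  spatial correlation on average-referenced maps).
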