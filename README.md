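# emophys

Multimodal physiological analysis pipeline for emotion-elicitation
experiments: a three-phase protocol scheduler (image-only, sound-only,
combined stimulation), per-signal preprocessing and feature extraction
(skin conductance, point-process heart-rate variability, blood volume
pulse, EEG, pupillometry) and a cross-phase nonparametric comparison
stage — all driven by a synthetic-data generator with known ground
truth, so every analysis chain ships with a recovery test.

## Layout

| module | role |
| --- | --- |
| `emophys.protocol` | timed, labeled stimulus/session windows of the three-phase design |
| `emophys.synthetic` | ground-truth generators for RR intervals (history-dependent inverse-Gaussian), SCR events, ECG/pulse coupling, band-limited EEG, pupil traces, and full experiments |
| `emophys.dsp` | shared primitives: zero-phase Butterworth filters, decimation, Welch PSD, band integrals |
| `emophys.gsr` | 2 Hz low-pass → 5 Hz, median-filter tonic/phasic split, SCR peak detection, 11 conductance features |
| `emophys.hrv` | Pan–Tompkins R-peak detection, local ML fit of the inverse-Gaussian AR interval model, instantaneous VLF/LF/HF tracking |
| `emophys.bvp` | pulse fiducials anchored to R-peaks; volume pulse and pulse arrival time |
| `emophys.eeg` | 10–20 montage repair, common-average reference, δ/θ/α/β band powers, β/θ attention index |
| `emophys.pupil` | blink handling, 10 Hz diameter trace, time/frequency features |
| `emophys.stats` | Shapiro–Wilk screen, subject-blocked Friedman omnibus, Tukey-type post hoc |
| `emophys.pipeline` / `emophys.cli` | simulate → extract → compare orchestration |

## CLI

```sh
# simulate a recording (delimited text + marker file + truth sidecar)
emophys simulate --seed 1 --signals gsr,ecg,bvp,eeg,pupil --out rec/

# per-window feature table
emophys extract --recording rec/ --out features.tsv

# cross-phase comparison of an existing table
emophys compare --table features.tsv --out comparisons.tsv

# full simulated cohort
emophys run-study --n-subjects 21 --seed 1 --signals gsr --out study/
```

A YAML config can override protocol durations/counts
(`protocol: {initial_rest_s: ..., neutral_s: ..., ...}`), extraction
parameters (`extraction: {hrv_order: ..., hrv_grid_step: ...}`) and
per-session generator effects
(`effects: {base: {...}, overrides: [{phase: IADS, kind: arousal, scr_amp_us: 1.5}]}`).

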