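# gammasift

Gamma-band event-related synchronization (ERS) analysis for
single-channel EEG, with an empirical-mode-decomposition (EMD) filter
stage.

## The problem

Motor tasks induce gamma-band oscillations (30–60 Hz) in the EEG over
the motor cortex. The conventional way to quantify them from one
channel (e.g. Cz) is: band-pass and notch filter, reject artifact
trials, estimate each trial's power spectral density (PSD), take the
mean PSD in the gamma band — the gamma-band activity, GBA, in µV² —
and normalize the task-related change by the resting level:

```
ERS(%) = (GBAm − GBAb) / GBAb × 100
```

where GBAm and GBAb are the motor and basal condition means. Induced
gamma is tiny relative to the broadband background, so this ratio is
heavily diluted. EMD offers a data-driven remedy: sifting decomposes
the trace into intrinsic mode functions (IMFs) ordered from high to low
frequency,

```
x(t) = Σⱼ IMFⱼ(t) + r_N(t)
```

and for EEG the first mode behaves like an adaptive gamma-band filter
(IMF1 ≈ gamma, IMF2 ≈ beta). Computing the same ERS ratio from IMF1
(ERS1) or IMF2 (ERS2) instead of x(t) isolates the induced component
from out-of-mode background, raising the measured synchronization.
This package implements both pipelines, a synthetic-data generator with
known ground-truth ERS to validate them, and the group-statistics
protocol (Lilliefors-gated paired t / Wilcoxon comparisons).

Intended users: electrophysiologists and BCI researchers who want a
reproducible, scriptable single-channel gamma/ERS pipeline, and anyone
needing a clean, tested EMD implementation for biomedical signals.

## Worked example

Simulate a six-subject experiment (2-s trials at 2048 Hz, a 45 Hz
induced burst over 1/f background, true ERS drawn around 50%) and run
all three methods:

```yaml
# demo.yaml
methods: [original, imf1, imf2]
seed: 42
out_dir: demo_out
synth:
  n_subjects: 6
  between_subject_sd: 15.0
  spec:
    ers_true_percent: 50.0
    gamma_basal_amp_uV: 8.0
    n_trials_per_hand: 10
    basal_minutes: 0.5
```

```sh
gammasift run --config demo.yaml
```

prints (abridged):

```
ERS   right mean    24.86% CI95 [16.54, 33.19] (n=6)
ERS1  right mean    33.30% CI95 [21.35, 45.25] (n=6)
ERS2  right mean    -3.35% CI95 [-22.91, 16.20] (n=6)
ERS   left  mean    19.27% CI95 [9.71, 28.82] (n=6)
ERS1  left  mean    27.16% CI95 [13.32, 41.00] (n=6)
ERS2  left  mean    -6.70% CI95 [-20.47, 7.07] (n=6)
```

Reading the numbers: the conventional method sees a 24.9% right-hand
gamma increase — diluted well below the programmed ~50% because the
broadband background contributes to the 30–60 Hz band in both
conditions. Filtering through IMF1 sheds part of that background and
recovers a larger synchronization (33.3%), while IMF2, which carries
the beta band, shows none; the paired comparisons in
`demo_out/comparisons.csv` confirm ERS1 > ERS (p = 0.015, paired t,
right hand). The per-subject table (`ers_subjects.csv`), per-trial GBA
values (`gba_trials.csv`) and a config-hash-stamped run log land in
`demo_out/`.

Other entry points:

```sh
gammasift simulate --spec cohort.yaml --out data/   # EDF + onset CSVs
gammasift decompose --input rec.edf --channel Cz    # per-IMF CSV
```

or use the library directly (`gammasift.sift`, `psd_multitaper`,
`band_power`, `compute_ers`, `make_cohort`, ...).

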