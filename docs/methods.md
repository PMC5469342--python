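# Methods

## Signal model and pipeline

The analysis chain is: EDF read → band-pass 1–100 Hz → notch 49–51 Hz →
epoching into 2-s trials → per-trial linear detrend → automatic
artifact rejection → (optionally) EMD → multitaper PSD → mean band
power in 30–60 Hz (GBA, µV²) → ERS = (GBAm − GBAb)/GBAb × 100 per hand
and subject → grand averages with t-based CI95 and normality-gated
paired comparisons.

Basal recordings carry no cues; they are segmented into consecutive
non-overlapping pseudo-trials of the same duration as motor trials so
both conditions share one spectral resolution. Motor trials start at
the cue (`floor(onset × fs)`, half-open window); if a protocol defines
a latency between cue and movement, shift the onsets before epoching.

## Pre-processing

Filters are Butterworth IIR applied forward–backward (`sosfiltfilt`):
order 4 band-pass and order 2 band-stop per pass (doubled by the two
passes). Zero-phase filtering is required so trial timing is not
skewed by group delay. The notch's narrow bandwidth implies a long
transient (~1 s at 2 Hz width); attenuation should be assessed in the
steady-state interior of a signal several seconds long. Mains at 60 Hz
is handled by moving `notch_hz` — note a 59–61 Hz notch eats the top
edge of the default gamma band.

Interactive artifact screening is replaced by two deterministic,
reproducible rules applied per trial after detrending: peak
|amplitude| > 100 µV, or any first-difference whose robust z-score
(median/MAD over the pooled differences of the trial set) exceeds 8.
Both thresholds are conventional EEG screening values and are
configurable; they are not calibrated to any particular dataset's
rejection rate.

## EMD

Sifting follows the classic recipe: find extrema (plateaus count once,
at their midpoint), interpolate maxima and minima separately with
natural cubic splines, subtract the envelope mean, repeat. Two details
matter numerically:

* **Boundaries.** Two extrema are mirror-reflected about each end of
  the record before spline fitting; without this the spline flares at
  the edges and contaminates IMF1. The strategy is pluggable
  (`boundary="none"` disables it).
* **Inner stop.** The mode-qualification criteria carry no tolerance
  by themselves, so the inner loop stops when the normalized squared
  change between successive sifts falls below 0.2 (the conventional
  Cauchy/SD criterion) *and* the extrema/zero-crossing balance holds
  (|Δ| ≤ 1, two boundary samples excluded at each end), with a hard cap
  of 50 sifts per mode.

Outer-loop stop rules: residue with ≤ 1 extremum (monotone), component
or residue energy below 1e-6 of the input energy, or 5 modes extracted
(`max_imfs`, configurable). Reconstruction (sum of IMFs + residue =
input) is exact to floating point by construction because the residue
is maintained as the running remainder. When only IMF1/IMF2 are
needed, sifting is truncated at that mode — truncation cannot change
earlier modes because extraction is sequential.

Mode separation requires a sampling rate of roughly five times the
highest frequency of interest; `check_sampling_margin` warns below
that margin (fs = 2048 Hz gives a 6.8× margin for a 60 Hz band edge).

## Spectral estimation

Per-trial PSD uses DPSS (Slepian) multitapers with ±2 Hz half-bandwidth
smoothing — 7 tapers on a 2-s trial (K = 2NW − 1); trials too short for
one Slepian at the requested bandwidth fall back to a single Hann
taper. Tapers are normalized to unit energy so the one-sided density
integrates to the signal variance (verified to within 5% on broadband
noise across 1–4 s trials). Each trial is analysed as a single whole
window; no sub-windowing. GBA is the arithmetic mean of the density
over bins in the closed interval [30, 60] Hz — a mean, not an
integral, so its scale matches per-bin PSD values.

## ERS and statistics

Subject-level ERS averages per-trial GBA within each condition first
and then forms the ratio of the two means; per-trial ratios would
weight noisy trials erratically. ERS is invariant to any common gain
(electrode reference, amplifier), since it cancels in the ratio.

Group comparisons screen each sample with the Lilliefors-corrected
Kolmogorov–Smirnov test (parameters are estimated from the data, so
the plain KS null is anti-conservative; plain KS remains available).
If both samples pass at 0.05 the paired Student t-test is used,
otherwise the Wilcoxon signed-rank test; all tests two-sided, α =
0.05. Identical paired samples report p = 1.0 by convention. No
multiple-comparison correction is applied across the three method
pairs.

## Synthetic data

The generator emulates the target experiment: basal fixation plus
cued motor trials for both hands, 2-s trials at fs = 2048 Hz. Default
sizes are scaled down for desk-scale runs — 20 motor trials per hand
(full experiments use hundreds) and 1 min of basal activity (vs ~18
min) — chosen so a 10-subject cohort analyses in seconds while leaving
enough trials for stable condition means.

Each trace sums (i) 1/f-shaped Gaussian background band-limited to
1–100 Hz with time-domain σ = 10 µV, (ii) continuous alpha (10 Hz,
20 µV) and beta (20 Hz, 10 µV) sinusoids so the middle IMFs have
realistic content, and (iii) a gamma burst in every trial: a
Hann-windowed 45 Hz tone with a fresh random phase per trial — induced
activity, time-locked but not phase-locked to the cue. Motor bursts
scale the basal amplitude by √(1 + ERS/100), making the
gamma-component power ratio exactly the programmed ground truth.
Artifact trials (optional) receive a 500 µV spike.

The default basal burst amplitude (30 µV) is deliberately large so the
in-band gamma dominates the 1/f background and the programmed ratio is
identifiable from a small cohort; physiological gamma is far smaller.
Validation of the EMD advantage instead uses a weak burst (8 µV,
comparable to the in-band background) — that is the regime where
filtering through IMF1 visibly raises the measured ERS. Cohorts draw
per-subject true ERS from Normal(mean, sd) truncated above −100%, with
subject seeds derived from one master seed.

What passing these simulations does **not** show: performance under
real EEG nonstationarities — eye/muscle artifact morphology, drifting
rhythms, volume conduction, electrode drift — or the behaviour of
subjects whose gamma sits above 60 Hz, where IMF1 rises out of band
and IMF2 becomes the gamma carrier.

## Numerical and design notes

* ERS estimated by the *original* method is biased toward zero by
  whatever background power shares the band; the synthetic defaults
  keep that dilution inside a small cohort's CI95, and the bias is the
  very effect the IMF1 route reduces.
* EDF output is 16-bit; round-trip error is bounded by the physical
  range divided by 2¹⁶ − 1. Recordings whose length is not a whole
  number of records are zero-padded at write time.
* The five-mode cap follows the analysis convention for this pipeline
  (gamma and beta live in IMF1/IMF2); deeper decompositions of long
  records may place slow rhythms in modes 5+, so the cap is a config
  knob, not a constant.
* EMD is applied per trial (matching per-trial GBA); a continuous-mode
  decomposition can be had by sifting the recording before epoching.
* All result CSVs embed the config hash and seed; identical config +
  seed reproduces them byte for byte.
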