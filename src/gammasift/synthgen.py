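"""Synthetic single-channel EEG experiments with known ground-truth ERS.

Each synthetic subject gets a basal (resting fixation) recording and a
motor recording of cued trials for both hands. The trace is the sum of

* 1/f-shaped broadband background noise (band-limited 1–100 Hz, σ set
  in the time domain),
* continuous alpha (10 Hz) and beta (20 Hz) rhythm sinusoids, giving
  the middle IMFs realistic content to absorb,
* a gamma burst in every trial: a Hann-windowed tone at
  ``gamma_freq_hz`` with a random phase per trial, so the activity is
  induced (time-locked to the cue but not phase-locked).

The motor-trial burst amplitude is the basal amplitude scaled by
sqrt(1 + ERS/100), which makes the gamma-component power ratio between
conditions exactly the requested ground truth. Artifact trials receive
a 500 µV spike. Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_edf import EEGRecording

__all__ = [
    "SyntheticSubjectSpec",
    "SyntheticSubject",
    "make_subject",
    "draw_cohort_specs",
    "make_cohort",
]

ARTIFACT_SPIKE_UV = 500.0


@dataclass
class SyntheticSubjectSpec:
    """Generator settings for one synthetic subject.

    Defaults emulate the target experiment at reduced size: 2-s trials
    at fs = 2048 Hz, 20 motor trials per hand (down from 500), 1 min of
    basal activity (down from 18). The gamma burst amplitude is set
    well above the in-band background so the programmed power ratio is
    identifiable from a small cohort.
    """

    fs: float = 2048.0
    trial_s: float = 2.0
    n_trials_per_hand: int = 20
    basal_minutes: float = 1.0
    background_sigma_uV: float = 10.0
    rhythm_components: tuple[tuple[float, float], ...] = ((10.0, 20.0), (20.0, 10.0))
    gamma_freq_hz: float = 45.0
    gamma_basal_amp_uV: float = 30.0
    ers_true_percent: float = 50.0
    artifact_rate: float = 0.0
    seed: int = 0
    background_band_hz: tuple[float, float] = (1.0, 100.0)

    def __post_init__(self) -> None:
        if self.ers_true_percent <= -100:
            raise ValueError("ers_true_percent must exceed -100 (power cannot go negative)")
        if self.fs < 5 * self.gamma_freq_hz:
            raise ValueError(
                f"fs={self.fs:g} Hz violates the sampling condition "
                f"fs >= 5 x gamma frequency ({5 * self.gamma_freq_hz:g} Hz)"
            )
        if not (0 <= self.artifact_rate <= 1):
            raise ValueError("artifact_rate must be a probability")
        if min(self.trial_s, self.n_trials_per_hand, self.basal_minutes) <= 0:
            raise ValueError("durations and trial counts must be positive")


@dataclass
class SyntheticSubject:
    """One generated subject: recordings plus its ground truth."""

    spec: SyntheticSubjectSpec
    basal: EEGRecording
    motor: EEGRecording
    onsets: dict[str, list[float]]
    subject_id: str = "S1"

    @property
    def ers_true_percent(self) -> float:
        return self.spec.ers_true_percent


def _pink_noise(n: int, fs: float, sigma: float, band: tuple[float, float], rng) -> np.ndarray:
    """Gaussian noise with 1/f power shape inside ``band``, RMS sigma."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    shape[mask] = 1.0 / np.sqrt(freqs[mask])
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * shape
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (sigma / rms) if rms > 0 else x


def _gamma_bursts(
    n: int, fs: float, onsets_s: Sequence[float], trial_s: float, freq: float, amp: float, rng
) -> np.ndarray:
    """Hann-windowed tone bursts, one per trial, random phase each."""
    out = np.zeros(n)
    n_per = round(trial_s * fs)
    win = np.hanning(n_per)
    tt = np.arange(n_per) / fs
    for onset in onsets_s:
        i0 = int(np.floor(onset * fs))
        phase = rng.uniform(0, 2 * np.pi)
        out[i0 : i0 + n_per] += amp * win * np.sin(2 * np.pi * freq * tt + phase)
    return out


def _rhythms(n: int, fs: float, components, rng) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros(n)
    for freq, amp in components:
        out += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return out


def _build_trace(
    n: int,
    fs: float,
    spec: SyntheticSubjectSpec,
    onsets_s: Sequence[float],
    gamma_amp: float,
    rng,
) -> np.ndarray:
    x = _pink_noise(n, fs, spec.background_sigma_uV, spec.background_band_hz, rng)
    x += _rhythms(n, fs, spec.rhythm_components, rng)
    x += _gamma_bursts(n, fs, onsets_s, spec.trial_s, spec.gamma_freq_hz, gamma_amp, rng)
    return x


def make_subject(spec: SyntheticSubjectSpec, subject_id: str = "S1") -> SyntheticSubject:
    """Generate one subject's basal and motor recordings.

    The basal recording is built over consecutive pseudo-trials of
    ``trial_s`` seconds, each holding a gamma burst at the basal
    amplitude. The motor recording alternates right- and left-hand
    trials back to back; its bursts carry the motor amplitude
    ``basal × sqrt(1 + ERS/100)``. Cue annotations (``cue_right`` /
    ``cue_left``) mark every motor trial onset.
    """
    rng = np.random.default_rng(spec.seed)
    fs, trial_s = spec.fs, spec.trial_s

    # --- basal: consecutive pseudo-trials
    n_basal_trials = int(round(spec.basal_minutes * 60.0 / trial_s))
    n_b = round(n_basal_trials * trial_s * fs)
    basal_onsets = [i * trial_s for i in range(n_basal_trials)]
    xb = _build_trace(n_b, fs, spec, basal_onsets, spec.gamma_basal_amp_uV, rng)
    basal = EEGRecording(xb, fs, "Cz", [])

    # --- motor: alternating right/left trials
    hands = ["right", "left"] * spec.n_trials_per_hand
    n_m = round(len(hands) * trial_s * fs)
    motor_onsets_all = [i * trial_s for i in range(len(hands))]
    motor_amp = spec.gamma_basal_amp_uV * np.sqrt(1.0 + spec.ers_true_percent / 100.0)
    xm = _build_trace(n_m, fs, spec, motor_onsets_all, motor_amp, rng)

    annotations: list[tuple[float, str]] = []
    onsets: dict[str, list[float]] = {"right": [], "left": []}
    for onset, hand in zip(motor_onsets_all, hands):
        onsets[hand].append(onset)
        annotations.append((onset, f"cue_{hand}"))
        if spec.artifact_rate and rng.uniform() < spec.artifact_rate:
            i0 = int(np.floor(onset * fs)) + rng.integers(0, round(trial_s * fs))
            xm[i0] += ARTIFACT_SPIKE_UV
    motor = EEGRecording(xm, fs, "Cz", annotations)
    return SyntheticSubject(spec=spec, basal=basal, motor=motor, onsets=onsets, subject_id=subject_id)


def draw_cohort_specs(
    n_subjects: int,
    spec_template: SyntheticSubjectSpec | None = None,
    between_subject_sd: float = 15.0,
    seed: int = 0,
) -> list[SyntheticSubjectSpec]:
    """Per-subject specs with ERS drawn from a truncated normal.

    Each subject's true ERS is Normal(template mean, sd) truncated to
    (−100, ∞); subject seeds derive deterministically from the master
    seed.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    template = spec_template or SyntheticSubjectSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    rng = np.random.default_rng(ss.generate_state(1)[0] % 2**31)
    specs = []
    for child in children:
        ers = rng.normal(template.ers_true_percent, between_subject_sd)
        while ers <= -100:
            ers = rng.normal(template.ers_true_percent, between_subject_sd)
        specs.append(
            replace(
                template,
                ers_true_percent=float(ers),
                seed=int(child.generate_state(1)[0] % 2**31),
            )
        )
    return specs


def make_cohort(
    n_subjects: int,
    spec_template: SyntheticSubjectSpec | None = None,
    between_subject_sd: float = 15.0,
    seed: int = 0,
) -> list[SyntheticSubject]:
    """Generate a full multi-subject experiment."""
    specs = draw_cohort_specs(n_subjects, spec_template, between_subject_sd, seed)
    return [make_subject(s, subject_id=f"S{i + 1}") for i, s in enumerate(specs)]
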