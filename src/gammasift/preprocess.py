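"""Pre-processing of the raw EEG trace into the analysis signal x(t).

The chain is: band-pass (1–100 Hz) → mains notch (49–51 Hz) → epoching →
per-trial linear detrend → automatic artifact rejection. Filtering is
zero-phase (forward–backward IIR), so trial timing relative to the cue
is undistorted. Artifact rejection replaces interactive visual
inspection with two deterministic rules: a peak-amplitude threshold and
a robust z-score threshold on sample-to-sample jumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io_edf import EEGRecording, TrialSet, epoch, epoch_basal

__all__ = [
    "PreprocessConfig",
    "CleanSignal",
    "NoCleanTrialsError",
    "bandpass_notch",
    "detrend_linear",
    "reject_artifacts",
    "preprocess_trials",
]


class NoCleanTrialsError(RuntimeError):
    """Every trial was rejected by the artifact rules."""


@dataclass
class PreprocessConfig:
    """Settings for the pre-processing chain.

    ``bandpass_hz`` and ``notch_hz`` are (low, high) edges in Hz; the
    notch pair is a stop band. ``artifact_amplitude_uV`` rejects trials
    whose peak absolute voltage exceeds it; ``artifact_zmax`` rejects
    trials containing a first-difference whose robust z-score (against
    the pooled jump distribution of the trial set) exceeds it. A 60 Hz
    mains region is accommodated by moving ``notch_hz``.
    """

    bandpass_hz: tuple[float, float] = (1.0, 100.0)
    notch_hz: tuple[float, float] = (49.0, 51.0)
    artifact_amplitude_uV: float = 100.0
    artifact_zmax: float = 8.0
    detrend: bool = True
    bandpass_order: int = 4
    notch_order: int = 2

    def validate(self, fs: float) -> None:
        for name, (lo, hi) in (("bandpass_hz", self.bandpass_hz), ("notch_hz", self.notch_hz)):
            if not (0 < lo < hi < fs / 2):
                raise ValueError(f"{name}={lo, hi} must satisfy 0 < low < high < fs/2={fs / 2}")
        if self.artifact_amplitude_uV <= 0 or self.artifact_zmax <= 0:
            raise ValueError("artifact thresholds must be strictly positive")


@dataclass
class CleanSignal:
    """Filtered continuous trace x(t) plus the trial bookkeeping."""

    x: np.ndarray
    fs: float
    rejected_trial_indices: list[int] = field(default_factory=list)
    n_kept: int = 0


def bandpass_notch(samples: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase band-pass then band-stop filtering.

    Butterworth IIR sections applied forward–backward (``sosfiltfilt``),
    doubling the effective order and cancelling group delay. Output has
    the input's length.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(fs)
    x = np.asarray(samples, dtype=float)
    sos_bp = sps.butter(cfg.bandpass_order, cfg.bandpass_hz, btype="bandpass", fs=fs, output="sos")
    sos_notch = sps.butter(cfg.notch_order, cfg.notch_hz, btype="bandstop", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos_bp, x)
    y = sps.sosfiltfilt(sos_notch, y)
    return y


def detrend_linear(samples: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line; output has zero mean and
    zero regression slope."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to detrend")
    return sps.detrend(x, type="linear")


def reject_artifacts(
    trials: TrialSet, cfg: PreprocessConfig | None = None
) -> tuple[TrialSet, list[int]]:
    """Drop trials containing amplitude or jump artifacts.

    A trial is rejected when its peak |voltage| exceeds
    ``artifact_amplitude_uV``, or when any first difference within it is
    a robust-z outlier (median/MAD computed over all trials' differences
    pooled) beyond ``artifact_zmax``. Kept trials are returned unchanged
    and in order.
    """
    cfg = cfg or PreprocessConfig()
    if trials.n_trials == 0:
        raise ValueError("trial set is empty")
    d = np.diff(trials.trials, axis=1)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    scale = 1.4826 * mad

    rejected: list[int] = []
    for i, tr in enumerate(trials.trials):
        if np.max(np.abs(tr)) > cfg.artifact_amplitude_uV:
            rejected.append(i)
            continue
        if scale > 0:
            zmax = np.max(np.abs(d[i] - med)) / scale
            if zmax > cfg.artifact_zmax:
                rejected.append(i)
    kept = [i for i in range(trials.n_trials) if i not in set(rejected)]
    if not kept:
        raise NoCleanTrialsError(
            f"all {trials.n_trials} trials rejected "
            f"(amplitude > {cfg.artifact_amplitude_uV} µV or jump z > {cfg.artifact_zmax})"
        )
    clean = replace(trials, trials=trials.trials[kept].copy())
    return clean, rejected


def preprocess_trials(
    rec: EEGRecording,
    cfg: PreprocessConfig | None = None,
    onsets: Sequence[float] | None = None,
    duration_s: float = 2.0,
    condition: str = "motor",
    hand: str = "none",
) -> tuple[TrialSet, CleanSignal]:
    """Run the full chain on one recording.

    With ``onsets`` the trace is cut at the given cue times; without,
    it is segmented into consecutive basal pseudo-trials. Returns the
    artifact-free trial set and the continuous filtered trace with
    rejection bookkeeping.
    """
    cfg = cfg or PreprocessConfig()
    x = bandpass_notch(rec.samples, rec.fs, cfg)
    filtered = EEGRecording(x, rec.fs, rec.channel_label, list(rec.annotations))
    if onsets is None:
        trials = epoch_basal(filtered, duration_s)
    else:
        trials = epoch(filtered, onsets, duration_s, condition=condition, hand=hand)
    if cfg.detrend and trials.n_trials:
        trials = replace(
            trials, trials=np.array([detrend_linear(tr) for tr in trials.trials])
        )
    if trials.n_trials:
        trials, rejected = reject_artifacts(trials, cfg)
    else:
        rejected = []
    clean = CleanSignal(x=x, fs=rec.fs, rejected_trial_indices=rejected, n_kept=trials.n_trials)
    return trials, clean
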