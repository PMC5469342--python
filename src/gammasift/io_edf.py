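"""Single-channel EEG input/output and epoching.

All voltages inside the package are expressed in microvolts (µV); power
spectral quantities downstream are therefore in µV². Recordings are read
from European Data Format (EDF/EDF+) files, the de-facto interchange
format for clinical EEG, or built directly from numeric arrays. Trial
onset annotations travel either inside the EDF+ annotation channel or in
a two-column CSV sidecar (onset_seconds,label).
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EEGRecording",
    "TrialSet",
    "ChannelNotFoundError",
    "EDFReadError",
    "read_edf",
    "write_edf",
    "epoch",
    "read_annotations_csv",
    "write_annotations_csv",
]

VALID_CONDITIONS = ("basal", "motor")
VALID_HANDS = ("right", "left", "none")


class ChannelNotFoundError(KeyError):
    """Requested channel label is absent from the EDF file."""


class EDFReadError(IOError):
    """File exists but could not be parsed as EDF/EDF+."""


@dataclass
class EEGRecording:
    """A sampled single-channel voltage trace.

    Parameters
    ----------
    samples
        Voltage series in µV.
    fs
        Sampling frequency in Hz.
    channel_label
        Electrode label in the 10/20 system, e.g. ``"Cz"``.
    annotations
        Event markers as ``(onset_seconds, label)`` pairs; onsets are
        relative to the start of the recording.
    """

    samples: np.ndarray
    fs: float
    channel_label: str = "Cz"
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not (self.fs > 0):
            raise ValueError("sampling frequency must be positive")
        dur = self.duration_s
        for onset, _label in self.annotations:
            if not (0 <= onset < dur):
                raise ValueError(
                    f"annotation onset {onset} s outside recording [0, {dur}) s"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class TrialSet:
    """Equal-length voltage segments sharing a condition and hand.

    ``trials`` is a 2-D array of shape ``(n_trials, n_samples)`` in µV.
    A basal trial set carries ``hand="none"`` since resting activity has
    no laterality.
    """

    trials: np.ndarray
    fs: float
    condition: str
    hand: str
    trial_duration_s: float

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim == 1:  # allow an empty flat array
            self.trials = self.trials.reshape(0, 0)
        if self.condition not in VALID_CONDITIONS:
            raise ValueError(f"condition must be one of {VALID_CONDITIONS}")
        if self.hand not in VALID_HANDS:
            raise ValueError(f"hand must be one of {VALID_HANDS}")
        if self.condition == "basal" and self.hand != "none":
            raise ValueError("basal trials carry hand='none'")
        if not (self.fs > 0 and self.trial_duration_s > 0):
            raise ValueError("fs and trial_duration_s must be positive")
        expected = round(self.trial_duration_s * self.fs)
        if self.n_trials and self.trials.shape[1] != expected:
            raise ValueError(
                f"each trial must hold {expected} samples, got {self.trials.shape[1]}"
            )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def __iter__(self):
        return iter(self.trials)


# ---------------------------------------------------------------------------
# EDF reading (mne) and a minimal EDF+C writer
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, channel: str = "Cz") -> EEGRecording:
    """Read one channel of an EDF/EDF+ file as an :class:`EEGRecording`.

    Voltages are converted to µV regardless of the physical dimension
    declared in the file; EDF+ annotations are carried over as
    ``(onset_seconds, label)`` pairs.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except FileNotFoundError:
        raise
    except Exception as exc:  # mne raises assorted types on malformed files
        raise EDFReadError(f"could not parse {path} as EDF: {exc}") from exc
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in file (has {raw.ch_names})"
        )
    data = raw.get_data(picks=[channel])[0]
    # mne rescales voltage channels to SI volts on load
    samples = data * 1e6
    annotations = [
        (float(onset), str(desc))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return EEGRecording(
        samples=samples,
        fs=float(raw.info["sfreq"]),
        channel_label=channel,
        annotations=annotations,
    )


def _exact_duration_repr(n: int, fs: float) -> str | None:
    """Decimal string for n/fs that fits 8 chars and recovers fs exactly."""
    for prec in range(8, 0, -1):
        s = f"{n / fs:.{prec}f}".rstrip("0")
        if len(s) <= 8 and float(s) > 0 and n / float(s) == fs:
            return s
    return None


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shrink numeric fields to fit the fixed-width header slot
        if isinstance(value, float):
            for prec in range(width - 2, 0, -1):
                s = f"{value:.{prec}g}"
                if len(s) <= width:
                    break
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording to a 16-bit EDF+C file readable by :func:`read_edf`.

    The sampling rate and annotation onsets round-trip exactly; sample
    values round-trip within the amplitude quantization of the 16-bit
    encoding over the recording's physical range. A recording whose
    duration is not an integral number of EDF data records is
    zero-padded to the next record boundary (EDF stores fixed-size
    records only); the pad appears as trailing zeros on read.
    """
    path = Path(path)
    x = rec.samples
    fs = rec.fs
    n = x.size

    # one-second records when the length allows, else a single long
    # record — but only if its duration is exactly representable in the
    # 8-char header field (fs must survive the round trip); otherwise
    # zero-pad to whole seconds.
    if float(fs).is_integer() and n % int(fs) == 0:
        spr = int(fs)
        n_records = n // spr
        record_dur = "1"
    elif _exact_duration_repr(n, fs) is not None:
        spr = n
        n_records = 1
        record_dur = _exact_duration_repr(n, fs)
    elif float(fs).is_integer():
        pad = int(fs) - n % int(fs)
        x = np.concatenate([x, np.zeros(pad)])
        n = x.size
        spr = int(fs)
        n_records = n // spr
        record_dur = "1"
    else:
        raise ValueError(
            "cannot represent this length/fs combination in EDF exactly; "
            "resample to an integer sampling rate first"
        )

    pmin = float(np.min(x))
    pmax = float(np.max(x))
    if pmax <= pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((x - pmin) / scale + dmin).astype("<i2")

    # annotation channel: a time-keeping TAL per record; user annotations
    # all stored in the first record (EDF+ permits out-of-record TALs)
    rd = float(record_dur)
    tals: list[bytes] = []
    for r in range(n_records):
        tal = f"+{r * rd:g}\x14\x14\x00".encode("ascii")
        if r == 0:
            for onset, label in sorted(rec.annotations):
                tal += f"+{onset:g}\x14{label}\x14\x00".encode("utf-8")
        tals.append(tal)
    annot_bytes = max(len(t) for t in tals)
    annot_spr = math.ceil(annot_bytes / 2)

    ns = 2
    header_bytes = 256 * (1 + ns)
    start = datetime.datetime(2000, 1, 1, 0, 0, 0)  # fixed for reproducibility

    h = b""
    h += _edf_field("0", 8)
    h += _edf_field("X X X X", 80)
    h += _edf_field("Startdate 01-JAN-2000 X X X", 80)
    h += _edf_field(start.strftime("%d.%m.%y"), 8)
    h += _edf_field(start.strftime("%H.%M.%S"), 8)
    h += _edf_field(str(header_bytes), 8)
    h += _edf_field("EDF+C", 44)
    h += _edf_field(str(n_records), 8)
    h += _edf_field(record_dur, 8)
    h += _edf_field(str(ns), 4)

    labels = [rec.channel_label, "EDF Annotations"]
    h += b"".join(_edf_field(v, 16) for v in labels)
    h += b"".join(_edf_field("", 80) for _ in range(ns))
    h += _edf_field("uV", 8) + _edf_field("", 8)
    h += _edf_field(pmin, 8) + _edf_field(-1, 8)
    h += _edf_field(pmax, 8) + _edf_field(1, 8)
    h += _edf_field(dmin, 8) + _edf_field(dmin, 8)
    h += _edf_field(dmax, 8) + _edf_field(dmax, 8)
    h += b"".join(_edf_field("", 80) for _ in range(ns))
    h += _edf_field(spr, 8) + _edf_field(annot_spr, 8)
    h += b"".join(_edf_field("", 32) for _ in range(ns))
    assert len(h) == header_bytes

    with open(path, "wb") as f:
        f.write(h)
        for r in range(n_records):
            f.write(digital[r * spr : (r + 1) * spr].tobytes())
            f.write(tals[r].ljust(annot_spr * 2, b"\x00"))
    return path


def edf_quantization_step(rec: EEGRecording) -> float:
    """Amplitude resolution of the 16-bit encoding for this recording."""
    span = float(np.max(rec.samples) - np.min(rec.samples))
    return max(span, 1.0) / 65535


# ---------------------------------------------------------------------------
# annotations as CSV sidecar
# ---------------------------------------------------------------------------

def write_annotations_csv(annotations: Sequence[tuple[float, str]], path: str | Path) -> Path:
    import pandas as pd

    path = Path(path)
    df = pd.DataFrame(annotations, columns=["onset_seconds", "label"])
    df.to_csv(path, index=False)
    return path


def read_annotations_csv(path: str | Path) -> list[tuple[float, str]]:
    import pandas as pd

    df = pd.read_csv(path)
    return [(float(o), str(l)) for o, l in zip(df["onset_seconds"], df["label"])]


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch(
    rec: EEGRecording,
    onsets: Sequence[float],
    duration_s: float,
    condition: str = "motor",
    hand: str = "none",
) -> TrialSet:
    """Cut half-open windows ``[onset, onset + duration_s)`` into trials.

    The starting sample index is ``floor(onset * fs)`` so a trial never
    begins before its cue. Onsets whose window would overrun the
    recording raise ``ValueError``.
    """
    n_per = round(duration_s * rec.fs)
    segs = []
    for onset in onsets:
        i0 = math.floor(onset * rec.fs)
        if onset < 0 or i0 + n_per > rec.n_samples:
            raise ValueError(
                f"trial at {onset} s (+{duration_s} s) exceeds the "
                f"{rec.duration_s:g} s recording"
            )
        segs.append(rec.samples[i0 : i0 + n_per])
    trials = np.array(segs) if segs else np.empty((0, n_per))
    return TrialSet(
        trials=trials,
        fs=rec.fs,
        condition=condition,
        hand=hand,
        trial_duration_s=duration_s,
    )


def epoch_basal(rec: EEGRecording, duration_s: float) -> TrialSet:
    """Split a resting recording into consecutive non-overlapping
    pseudo-trials of the same duration as the motor trials, so basal and
    motor spectra share the same frequency resolution."""
    n_trials = int(rec.duration_s / duration_s)
    onsets = [i * duration_s for i in range(n_trials)]
    return epoch(rec, onsets, duration_s, condition="basal", hand="none")
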