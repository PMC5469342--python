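"""Empirical Mode Decomposition by cubic-spline envelope sifting.

EMD expresses a non-stationary trace x(t) as a sum of intrinsic mode
functions (IMFs) plus a residue,

    x(t) = sum_j IMF_j(t) + r_N(t),

where each IMF (a) has extrema and zero-crossing counts that differ by
at most one and (b) has a locally zero envelope mean. Modes come out in
decreasing frequency order, so for EEG the first IMF carries the gamma
band and the second the beta band — the decomposition acts as an
adaptive, data-driven filter bank.

One sifting pass: locate extrema, interpolate maxima and minima with
natural cubic splines into upper/lower envelopes UE and LE, form the
envelope mean M(t) = (UE + LE)/2 and subtract it, c(t) = x(t) − M(t).
The pass repeats until c(t) qualifies as an IMF; the residue then feeds
the next mode. Extraction stops when the residue is monotone (≤ 1
extremum), the extracted component is negligibly small, or ``max_imfs``
modes (default 5) have been produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import periodogram

__all__ = [
    "EMDConfig",
    "IMFDecomposition",
    "SiftIteration",
    "SamplingMarginWarning",
    "find_extrema",
    "envelope",
    "is_imf",
    "sift",
    "mean_frequency",
    "check_sampling_margin",
]

#: interior samples at each end ignored when counting extrema/crossings,
#: so spline boundary flare does not spoil the IMF test
BOUNDARY_EXCLUDE = 2


class SamplingMarginWarning(UserWarning):
    """Sampling rate is below ~5× the highest frequency of interest."""


@dataclass
class EMDConfig:
    """Sifting controls.

    ``sift_sd_threshold`` is the Cauchy-style convergence bound on the
    normalized squared change between successive sifts (dimensionless,
    conventional default 0.2); ``max_sifts_per_imf`` caps the inner
    loop. ``residue_energy_frac`` quantifies the "component too small"
    stop rule as a fraction of the input energy. ``boundary`` selects
    the envelope end-effect strategy ("mirror" reflects two extrema
    about each end before spline fitting).
    """

    max_imfs: int = 5
    sift_sd_threshold: float = 0.2
    max_sifts_per_imf: int = 50
    residue_energy_frac: float = 1e-6
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if min(self.sift_sd_threshold, self.max_sifts_per_imf, self.residue_energy_frac) <= 0:
            raise ValueError("EMDConfig values must be positive")


@dataclass
class IMFDecomposition:
    """Ordered IMFs plus residue; summing them reproduces the input."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    fs: float

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass
class SiftIteration:
    """Intermediate quantities of one sifting pass (diagnostics)."""

    ue: np.ndarray
    le: np.ndarray
    m: np.ndarray
    c: np.ndarray


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    Extrema are sign changes of the first difference; a plateau counts
    once, at its midpoint index. Endpoints are never interior extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    d = np.sign(np.diff(x))
    nz = np.nonzero(d)[0]
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = d[nz]
    turn = np.nonzero(s[:-1] != s[1:])[0]
    # plateau between nz[t]+1 .. nz[t+1] shares one value; take midpoint
    idx = (nz[turn] + 1 + nz[turn + 1]) // 2
    maxima = idx[s[turn] > 0]
    minima = idx[s[turn] < 0]
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[:-1] != s[1:]))


def envelope(
    x: np.ndarray, extrema_indices: np.ndarray, boundary: str = "mirror"
) -> np.ndarray | None:
    """Natural cubic spline through the extrema, evaluated everywhere.

    With ``boundary="mirror"`` up to two extrema are reflected about
    each end of the record before fitting, which suppresses the spline
    flare that otherwise dominates the first mode near the edges.
    Returns ``None`` when no extrema are available (monotone segment —
    the stopping logic treats this as "no envelope").
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(extrema_indices, dtype=int)
    if t.size == 0:
        return None
    v = x[t]
    n = x.size
    if boundary == "mirror":
        k = min(2, t.size)
        lt = -t[:k][::-1]
        lv = v[:k][::-1]
        rt = 2 * (n - 1) - t[-k:][::-1]
        rv = v[-k:][::-1]
        # drop mirrored knots that coincide with originals (extremum at an end)
        Lmask = lt < t[0]
        Rmask = rt > t[-1]
        t_ext = np.concatenate([lt[Lmask], t, rt[Rmask]])
        v_ext = np.concatenate([lv[Lmask], v, rv[Rmask]])
    elif boundary == "none":
        t_ext, v_ext = t, v
    else:
        raise ValueError(f"unknown boundary strategy {boundary!r}")
    if t_ext.size < 2:
        return None
    if t_ext.size == 2:  # spline degenerates to the straight line
        return np.interp(np.arange(n), t_ext, v_ext)
    cs = CubicSpline(t_ext, v_ext, bc_type="natural")
    return cs(np.arange(n))


def _envelopes(x: np.ndarray, boundary: str) -> SiftIteration | None:
    maxima, minima = find_extrema(x)
    if maxima.size == 0 or minima.size == 0:
        return None
    ue = envelope(x, maxima, boundary)
    le = envelope(x, minima, boundary)
    if ue is None or le is None:
        return None
    m = (ue + le) / 2.0
    return SiftIteration(ue=ue, le=le, m=m, c=x - m)


def _counts_ok(c: np.ndarray, tolerance: int) -> bool:
    core = c[BOUNDARY_EXCLUDE:-BOUNDARY_EXCLUDE] if c.size > 2 * BOUNDARY_EXCLUDE else c
    maxima, minima = find_extrema(core)
    n_ext = maxima.size + minima.size
    return abs(n_ext - _zero_crossings(core)) <= tolerance


def is_imf(
    c: np.ndarray,
    tolerance_extrema_diff: int = 1,
    sd_threshold: float = 0.2,
    boundary: str = "mirror",
) -> bool:
    """Does ``c`` qualify as an intrinsic mode function?

    True iff the extrema and zero-crossing counts (boundary-adjacent
    samples excluded) differ by at most ``tolerance_extrema_diff`` and
    the envelope mean is small: RMS(M) < sd_threshold × RMS(c).
    """
    c = np.asarray(c, dtype=float)
    if c.size < 3 or not np.any(c):
        return False
    if not _counts_ok(c, tolerance_extrema_diff):
        return False
    it = _envelopes(c, boundary)
    if it is None:
        return False
    rms_c = float(np.sqrt(np.mean(c**2)))
    rms_m = float(np.sqrt(np.mean(it.m**2)))
    return rms_m < sd_threshold * rms_c


def sift(x: np.ndarray, cfg: EMDConfig | None = None, fs: float = 1.0) -> IMFDecomposition:
    """Decompose ``x`` into IMFs and a residue.

    The inner loop repeats envelope-mean subtraction until the candidate
    both satisfies the extrema/zero-crossing balance and changes by less
    than ``sift_sd_threshold`` (normalized squared difference) between
    passes, or ``max_sifts_per_imf`` is reached. The outer loop applies
    the three stop rules (monotone residue, negligible component,
    ``max_imfs``). The returned decomposition reconstructs the input to
    floating-point accuracy because the residue is maintained as the
    running remainder.
    """
    cfg = cfg or EMDConfig()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if x.size < 8:
        raise ValueError("input too short to sift (need >= 8 samples)")

    e0 = float(np.sum(x**2))
    residue = x.copy()
    imfs: list[np.ndarray] = []

    while len(imfs) < cfg.max_imfs:
        maxima, minima = find_extrema(residue)
        if maxima.size + minima.size <= 1 or maxima.size == 0 or minima.size == 0:
            break  # stop rule 1: residue is (near-)monotone
        if float(np.sum(residue**2)) < cfg.residue_energy_frac * e0:
            break  # stop rule 2: residue too small

        h = residue.copy()
        for _ in range(cfg.max_sifts_per_imf):
            it = _envelopes(h, cfg.boundary)
            if it is None:
                break
            h_new = it.c
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < cfg.sift_sd_threshold and _counts_ok(h, 1):
                break

        if float(np.sum(h**2)) < cfg.residue_energy_frac * e0:
            break  # stop rule 2: extracted component too small
        imfs.append(h)
        residue = residue - h

    return IMFDecomposition(imfs=imfs, residue=residue, fs=fs)


def mean_frequency(imf: np.ndarray, fs: float) -> float:
    """Power-weighted mean frequency of a component's periodogram.

    The mean is removed first so the DC bin never contributes; useful as
    a diagnostic for assigning IMFs to EEG bands.
    """
    y = np.asarray(imf, dtype=float)
    y = y - y.mean()
    if not np.any(y):
        raise ValueError("component is all zero (or constant)")
    f, p = periodogram(y, fs=fs)
    f, p = f[1:], p[1:]
    return float(np.sum(f * p) / np.sum(p))


def check_sampling_margin(fs: float, f_highest: float, factor: float = 5.0) -> bool:
    """Warn unless fs is at least ``factor`` × the highest frequency of
    interest — the practical condition for EMD to resolve that
    frequency into its own mode (well beyond the Nyquist minimum)."""
    ok = fs >= factor * f_highest
    if not ok:
        warnings.warn(
            f"fs={fs:g} Hz is below {factor:g}× the highest frequency of "
            f"interest ({f_highest:g} Hz); EMD mode separation degrades",
            SamplingMarginWarning,
            stacklevel=2,
        )
    return ok
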