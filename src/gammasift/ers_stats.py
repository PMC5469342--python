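"""Event-related synchronization and the group-comparison protocol.

ERS normalizes the task-induced change in gamma-band activity by the
resting level,

    ERS(%) = (GBAm − GBAb) / GBAb × 100,

computed per hand and per subject; ERS1 and ERS2 are the same ratio on
GBA extracted from IMF1 and IMF2. A negative ERS is an event-related
desynchronization. Because ERS is a ratio of band powers from the same
electrode pair, any common gain (reference, amplifier) cancels.

Group comparisons follow a normality-gated paired design: each sample
is screened with a Lilliefors-corrected Kolmogorov–Smirnov test; if
both pass at 0.05 the paired Student t-test is used, otherwise the
Wilcoxon signed-rank test. Significance threshold is p < 0.05,
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .spectral import GBAValue

__all__ = [
    "ERSResult",
    "GroupComparison",
    "compute_ers",
    "subject_ers",
    "grand_average",
    "compare_methods",
]

METHOD_TO_ERS_NAME = {"original": "ERS", "imf1": "ERS1", "imf2": "ERS2"}


@dataclass
class ERSResult:
    """Per-subject, per-hand ERS for one analysis method."""

    ers_percent: float
    method: str
    hand: str
    subject_id: str
    gba_basal: float
    gba_motor: float

    def __post_init__(self) -> None:
        if self.gba_basal <= 0:
            raise ValueError("basal GBA must be positive")
        expected = compute_ers(self.gba_motor, self.gba_basal)
        if abs(self.ers_percent - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("ers_percent inconsistent with the GBA pair")


@dataclass
class GroupComparison:
    """Outcome of one paired method comparison."""

    method_a: str
    method_b: str
    n: int
    test_name: str
    p_value: float
    normality_p_a: float
    normality_p_b: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")
        if self.test_name == "paired-t" and (
            self.normality_p_a < 0.05 or self.normality_p_b < 0.05
        ):
            raise ValueError("paired-t requires both samples to pass normality at 0.05")


def compute_ers(gba_motor: float, gba_basal: float) -> float:
    """Percentage change of motor over basal band power."""
    if gba_basal <= 0:
        raise ValueError("basal GBA must be positive")
    return (gba_motor - gba_basal) / gba_basal * 100.0


def subject_ers(
    basal_gba: Sequence[GBAValue],
    motor_gba: Sequence[GBAValue],
    method: str,
    hand: str,
    subject_id: str = "S1",
) -> ERSResult:
    """Condition means first, then the ratio.

    Per-trial GBA values are averaged within each condition and the ERS
    formula is applied to the two means (not averaged over per-trial
    ratios).
    """
    if not basal_gba or not motor_gba:
        raise ValueError("both GBA lists must be non-empty")
    for g in (*basal_gba, *motor_gba):
        if g.method != method:
            raise ValueError(f"GBA value with method {g.method!r}, expected {method!r}")
    mb = float(np.mean([g.value for g in basal_gba]))
    mm = float(np.mean([g.value for g in motor_gba]))
    return ERSResult(
        ers_percent=compute_ers(mm, mb),
        method=method,
        hand=hand,
        subject_id=subject_id,
        gba_basal=mb,
        gba_motor=mm,
    )


def grand_average(values: Sequence[float | ERSResult]) -> tuple[float, tuple[float, float]]:
    """Across-subject mean with its t-based 95% confidence interval."""
    vals = np.asarray(
        [v.ers_percent if isinstance(v, ERSResult) else float(v) for v in values], dtype=float
    )
    n = vals.size
    if n < 2:
        raise ValueError("grand average needs at least 2 subjects")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(n))
    half = float(stats.t.ppf(0.975, n - 1)) * sem
    return mean, (mean - half, mean + half)


def _normality_p(x: np.ndarray, correction: str) -> float:
    if correction == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        if np.std(x) == 0:
            return 0.0  # a point mass is maximally non-Gaussian
        _, p = lilliefors(x, dist="norm")
        return float(p)
    if correction == "ks":  # plain KS with estimated parameters
        sd = np.std(x, ddof=1)
        if sd == 0:
            return 0.0
        _, p = stats.kstest(x, "norm", args=(np.mean(x), sd))
        return float(p)
    raise ValueError(f"unknown normality correction {correction!r}")


def compare_methods(
    a: Sequence[float],
    b: Sequence[float],
    method_a: str = "a",
    method_b: str = "b",
    alpha_normality: float = 0.05,
    normality: str = "lilliefors",
) -> GroupComparison:
    """Paired comparison with a normality gate.

    Both samples are tested for Gaussianity (Lilliefors-corrected KS by
    default, since distribution parameters are estimated from the
    data); if both pass at ``alpha_normality`` the paired t-test is
    used, otherwise the Wilcoxon signed-rank test. All-zero paired
    differences report p = 1.0 by convention. Two-sided throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")

    pa = _normality_p(a, normality)
    pb = _normality_p(b, normality)
    diffs = a - b
    if not np.any(diffs):
        # degenerate: no differences at all
        test = "paired-t" if (pa >= alpha_normality and pb >= alpha_normality) else "wilcoxon"
        return GroupComparison(method_a, method_b, a.size, test, 1.0, pa, pb)

    if pa >= alpha_normality and pb >= alpha_normality:
        _, p = stats.ttest_rel(a, b)
        test = "paired-t"
    else:
        _, p = stats.wilcoxon(a, b, alternative="two-sided")
        test = "wilcoxon"
    return GroupComparison(method_a, method_b, a.size, test, float(p), pa, pb)
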