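"""Lognormal summary statistics for exposure measurement sets.

Occupational hygiene convention: airborne concentrations (8h-TWA, ppm)
within a similar exposure group are treated as lognormal and summarised by
the geometric mean (GM) and geometric standard deviation (GSD).  All logs
are natural.  The GSD uses the sample (n-1 denominator) SD of the log
values, which makes the grouped sum-of-squares identities used in model
evaluation exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Z90",
    "MeasurementSet",
    "MeasurementSummary",
    "summarize",
    "percentile90",
    "pooled_geometric_mean",
    "grouped_log_moments",
    "GroupedLogMoments",
    "exceedance_count",
]

#: The 90th-percentile normal quantile as used in the closed form
#: X_0.90 = GM * GSD**1.282 (kept at the printed 3-significant-figure value).
Z90 = 1.282


@dataclass(frozen=True)
class MeasurementSet:
    """Individual 8h-TWA concentrations (ppm) for one exposure situation."""

    situation_id: str
    values: tuple[float, ...]
    oel: float | None = None  # occupational exposure limit, ppm

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError(f"{self.situation_id!r}: needs at least one value")
        if any(v <= 0 for v in self.values):
            raise ValueError(
                f"{self.situation_id!r}: concentrations must be positive"
            )
        if self.oel is not None and self.oel <= 0:
            raise ValueError(f"{self.situation_id!r}: OEL must be positive")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MeasurementSummary:
    """n / AM / GM / GSD / min / max summary of one situation's measurements.

    ``gsd`` is None for singleton groups, where log-spread is undefined.
    """

    situation_id: str
    n: int
    am: float
    gm: float
    gsd: float | None
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.gsd is not None and self.gsd < 1.0:
            raise ValueError(f"{self.situation_id!r}: GSD must be >= 1")
        if self.n >= 2 and self.gsd is not None and self.gm > self.am * (1 + 1e-9):
            raise ValueError(
                f"{self.situation_id!r}: GM {self.gm} exceeds AM {self.am}"
            )

    @property
    def p90(self) -> float | None:
        """Closed-form 90th percentile, absent for singleton groups."""
        return None if self.gsd is None else percentile90(self.gm, self.gsd)


def summarize(ms: MeasurementSet) -> MeasurementSummary:
    """AM, GM, GSD (sample log-SD), min and max of a measurement set."""
    v = np.asarray(ms.values, dtype=float)
    logs = np.log(v)
    gsd = float(np.exp(logs.std(ddof=1))) if ms.n >= 2 else None
    return MeasurementSummary(
        situation_id=ms.situation_id,
        n=ms.n,
        am=float(v.mean()),
        gm=float(np.exp(logs.mean())),
        gsd=gsd,
        vmin=float(v.min()),
        vmax=float(v.max()),
    )


def percentile90(gm: float, gsd: float) -> float:
    """X_0.90 = GM * GSD**1.282 for a lognormal exposure distribution."""
    if gsd < 1.0:
        raise ValueError(f"GSD must be >= 1, got {gsd}")
    return gm * gsd**Z90


def pooled_geometric_mean(summaries: Sequence[MeasurementSummary]) -> float:
    """n-weighted pooled GM: exp( sum n_c ln(gm_c) / sum n_c )."""
    if not summaries:
        raise ValueError("need at least one summary")
    n = np.array([s.n for s in summaries], dtype=float)
    lg = np.log([s.gm for s in summaries])
    return float(np.exp((n * lg).sum() / n.sum()))


@dataclass(frozen=True)
class GroupedLogMoments:
    """Per-group log moments sufficient for grouped agreement statistics.

    For group c with n_c members, ``log_means`` holds m_c = ln(gm_c) and
    ``within_ss`` holds sum_i (ln y_i - m_c)^2 = (n_c - 1) * ln(gsd_c)^2
    (exactly, under the sample-SD GSD convention; zero for singletons).
    """

    situation_ids: tuple[str, ...]
    ns: tuple[int, ...]
    log_means: tuple[float, ...]
    within_ss: tuple[float, ...]

    @property
    def total_n(self) -> int:
        return int(sum(self.ns))


def grouped_log_moments(summaries: Sequence[MeasurementSummary]) -> GroupedLogMoments:
    ids, ns, means, ss = [], [], [], []
    for s in summaries:
        if s.n >= 2 and s.gsd is None:
            raise ValueError(
                f"{s.situation_id!r}: GSD required for groups with n >= 2"
            )
        ids.append(s.situation_id)
        ns.append(s.n)
        means.append(math.log(s.gm))
        ss.append(0.0 if s.n == 1 else (s.n - 1) * math.log(s.gsd) ** 2)
    return GroupedLogMoments(tuple(ids), tuple(ns), tuple(means), tuple(ss))


def exceedance_count(ms: MeasurementSet) -> tuple[int, float]:
    """Count and fraction of measurements strictly above the set's OEL."""
    if ms.oel is None:
        raise ValueError(f"{ms.situation_id!r}: no OEL set")
    count = int(sum(v > ms.oel for v in ms.values))
    return count, count / ms.n
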