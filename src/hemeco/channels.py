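"""Single-channel open-probability estimation and condition comparison.

Inside-out patch records of K_ATP channels contain a small, variable number
of channels; activity is summarized as NPo (mean number of simultaneously
open channels) and Popen = NPo / N.  Idealization uses the standard
half-amplitude multi-level threshold: a sample at current I is assigned to
open level k when I falls within half a unitary current of k * i_unit.
No event-duration correction for filter rise time is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ChannelTrace",
    "ChannelStats",
    "DEFAULT_UNITARY_CURRENT_PA",
    "idealize_popen",
    "compare_conditions",
]

#: 78 pS unitary conductance x 70 mV driving force
DEFAULT_UNITARY_CURRENT_PA = 78e-12 * 70e-3 * 1e12  # = 5.46 pA


@dataclass(frozen=True)
class ChannelTrace:
    """A multi-channel patch-clamp current record."""

    sampling_rate: float  # Hz
    current: np.ndarray  # pA
    unitary_current: float = DEFAULT_UNITARY_CURRENT_PA  # pA
    n_channels: int | None = None  # None when unknown

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        cur = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "current", cur)
        if not np.all(np.isfinite(cur)):
            raise ValueError("current samples must be finite")

    @property
    def duration(self) -> float:
        return self.current.size / self.sampling_rate

    def to_csv(self, path) -> None:
        from .io import write_xy_csv

        t = np.arange(self.current.size) / self.sampling_rate
        write_xy_csv(path, t, self.current, "time_s", "current_pA")


@dataclass(frozen=True)
class ChannelStats:
    """Open-probability summary of one idealized record."""

    popen: float
    npo: float
    n_channels: int
    level_occupancy: tuple[float, ...]  # fraction of samples at each open level

    def __post_init__(self) -> None:
        if not 0.0 <= self.popen <= 1.0:
            raise ValueError("Popen must lie in [0, 1]")


def idealize_popen(trace: ChannelTrace, n_channels: int | str = "auto") -> ChannelStats:
    """Estimate Popen by half-amplitude multi-level threshold idealization.

    Each sample is assigned to open level k = round(I / i_unit), i.e. level
    k spans [(k - 1/2) i_unit, (k + 1/2) i_unit).  NPo is the time-average
    level; Popen = NPo / N.  With ``n_channels='auto'`` N is the maximum
    observed level (at least 1).
    """
    if trace.unitary_current <= 0:
        raise ValueError("unitary current must be positive")
    levels = np.round(trace.current / trace.unitary_current).astype(int)
    levels = np.clip(levels, 0, None)
    max_level = int(levels.max()) if levels.size else 0
    if n_channels == "auto":
        n = max(max_level, 1)
    else:
        n = int(n_channels)
        if n < 1:
            raise ValueError("n_channels must be >= 1")
        levels = np.clip(levels, 0, n)
    npo = float(levels.mean())
    occupancy = np.bincount(levels, minlength=n + 1) / levels.size
    return ChannelStats(
        popen=npo / n,
        npo=npo,
        n_channels=n,
        level_occupancy=tuple(float(v) for v in occupancy),
    )


def compare_conditions(
    condition_stats: dict[str, list[float]], paired: bool = True
) -> dict:
    """Summarize Popen across experimental conditions.

    Returns per-condition mean +/- SEM, pairwise fold changes, and (for two
    conditions) a paired or independent two-sided t-test.  The test is a
    routine convenience summary, not a core result.
    """
    names = list(condition_stats)
    if any(len(v) < 2 for v in condition_stats.values()):
        raise ValueError("each condition needs at least 2 observations")
    if paired:
        sizes = {len(v) for v in condition_stats.values()}
        if len(sizes) > 1:
            raise ValueError("paired comparison requires equal-length condition lists")
    summary: dict = {"conditions": {}}
    for name in names:
        vals = np.asarray(condition_stats[name], dtype=float)
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        summary["conditions"][name] = {
            "mean": float(vals.mean()),
            "sem": sem,
            "n": int(vals.size),
        }
    summary["fold_changes"] = {}
    summary["tests"] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va = np.asarray(condition_stats[a], dtype=float)
            vb = np.asarray(condition_stats[b], dtype=float)
            mean_a = va.mean()
            summary["fold_changes"][f"{b}/{a}"] = (
                float(vb.mean() / mean_a) if mean_a != 0 else np.inf
            )
            if paired:
                t, p = stats.ttest_rel(vb, va)
            else:
                t, p = stats.ttest_ind(vb, va)
            # identical paired samples: zero difference, define t = 0, p = 1
            if np.isnan(t):
                t, p = 0.0, 1.0
            summary["tests"][f"{b} vs {a}"] = {
                "t": float(t),
                "p": float(p),
                "paired": paired,
            }
    return summary
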