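"""Pulse-train response metrics: PSTH, onset-rate/level functions, train
threshold and dynamic range, interspike-interval histograms, and per-spike
initiation incidence.

Rates are spikes/s pooled over sweeps: rate(window) = total spikes /
(n_sweeps * window length).  The train threshold is the level at which the
fitted rate-level line reaches 100 spikes/s; the dynamic range is the dB span
of levels between onset rates of 100 and 250 spikes/s (amplitude decibels,
20 log10 of the current ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .membrane import SweepResult, na_influx_onsets

__all__ = [
    "PSTH",
    "RateLevelCurve",
    "ISIHistogram",
    "WIDE_BINS_MS",
    "psth",
    "onset_rate",
    "window_rate",
    "fit_rate_level",
    "train_threshold",
    "dynamic_range",
    "isi_histogram",
    "train_initiation_nodes",
    "initiation_incidence_train",
]

WIDE_BINS_MS = ((0.0, 12.0), (12.0, 24.0), (24.0, 48.0), (48.0, 100.0), (100.0, 200.0))


@dataclass
class PSTH:
    fine_edges_ms: np.ndarray      # 1 ms bin edges over 0-200 ms
    fine_counts: np.ndarray
    fine_rates: np.ndarray         # spikes/s
    wide_windows_ms: tuple = WIDE_BINS_MS
    wide_rates: np.ndarray = field(default=None)
    wide_midpoints_ms: np.ndarray = field(default=None)
    n_sweeps: int = 0

    @property
    def total_spikes(self) -> int:
        return int(self.fine_counts.sum())


@dataclass
class RateLevelCurve:
    levels: np.ndarray             # mA
    onset_rates: np.ndarray        # spikes/s over 0-12 ms
    slope: float                   # spikes/s per mA of the fitted line
    intercept: float

    def predict(self, level):
        return self.slope * np.asarray(level, float) + self.intercept

    def level_at(self, rate: float) -> float:
        if self.slope <= 0:
            raise ValueError("non-increasing rate-level fit")
        return (rate - self.intercept) / self.slope


@dataclass
class ISIHistogram:
    window_ms: tuple[float, float]
    bin_width_ms: float
    edges_ms: np.ndarray
    counts: np.ndarray
    intervals_ms: np.ndarray
    mean_ms: float
    sd_ms: float

    @property
    def n_intervals(self) -> int:
        return int(self.intervals_ms.size)


def _all_spike_times(sweeps: list[SweepResult]) -> list[np.ndarray]:
    return [s.spike_times_c16 for s in sweeps]


def psth(sweeps: list[SweepResult], duration_ms: float = 200.0) -> PSTH:
    """Fine (1 ms) and wide-bin PSTH pooled over sweeps."""
    durations = {s.duration_ms for s in sweeps}
    if len(durations) > 1:
        raise ValueError("sweeps must share the same duration")
    n = len(sweeps)
    edges = np.arange(0.0, duration_ms + 1.0, 1.0)
    spikes = np.concatenate(_all_spike_times(sweeps)) if n else np.empty(0)
    counts, _ = np.histogram(spikes, bins=edges)
    fine_rates = counts / (n * 1e-3) if n else counts.astype(float)
    wide_rates = np.array(
        [window_rate(sweeps, w) for w in WIDE_BINS_MS]
    )
    midpoints = np.array([(a + b) / 2.0 for a, b in WIDE_BINS_MS])
    return PSTH(
        fine_edges_ms=edges, fine_counts=counts, fine_rates=fine_rates,
        wide_rates=wide_rates, wide_midpoints_ms=midpoints, n_sweeps=n,
    )


def window_rate(sweeps: list[SweepResult], window_ms: tuple[float, float]) -> float:
    """Pooled spike rate (spikes/s) in a time window."""
    lo, hi = window_ms
    n = len(sweeps)
    if n == 0 or hi <= lo:
        raise ValueError("need sweeps and a positive-length window")
    total = sum(
        int(np.count_nonzero((st >= lo) & (st < hi))) for st in _all_spike_times(sweeps)
    )
    return total / (n * (hi - lo) * 1e-3)


def onset_rate(sweeps: list[SweepResult]) -> float:
    """Spike rate over the 0-12 ms onset window."""
    return window_rate(sweeps, (0.0, 12.0))


def fit_rate_level(levels, onset_rates) -> RateLevelCurve:
    """Least-squares line through the rising portion of the rate-level data."""
    levels = np.asarray(levels, float)
    rates = np.asarray(onset_rates, float)
    if levels.size < 3:
        raise ValueError("need >= 3 levels for the rate-level fit")
    slope, intercept = np.polyfit(levels, rates, 1)
    return RateLevelCurve(
        levels=levels, onset_rates=rates, slope=float(slope), intercept=float(intercept)
    )


def train_threshold(curve: RateLevelCurve, criterion_rate: float = 100.0,
                    allow_extrapolation: bool = False) -> float:
    """Level (mA) at which the fitted onset-rate line reaches the criterion."""
    if not allow_extrapolation:
        if curve.onset_rates.max() < criterion_rate or curve.onset_rates.min() > criterion_rate:
            raise ValueError(
                f"onset rates {curve.onset_rates} do not bracket {criterion_rate} sp/s"
            )
    return curve.level_at(criterion_rate)


def dynamic_range(curve: RateLevelCurve, low_rate: float = 100.0,
                  high_rate: float = 250.0, allow_extrapolation: bool = False) -> float:
    """Dynamic range in amplitude dB between two onset-rate criteria."""
    if not allow_extrapolation:
        if curve.onset_rates.max() < high_rate or curve.onset_rates.min() > low_rate:
            raise ValueError(
                f"onset rates {curve.onset_rates} do not bracket "
                f"[{low_rate}, {high_rate}] sp/s"
            )
    i_lo = curve.level_at(low_rate)
    i_hi = curve.level_at(high_rate)
    if i_lo <= 0 or i_hi <= 0:
        raise ValueError("fitted criterion levels must be positive")
    return 20.0 * math.log10(i_hi / i_lo)


def isi_histogram(
    sweeps: list[SweepResult],
    window_ms: tuple[float, float],
    bin_width_ms: float = 0.05,
) -> ISIHistogram:
    """Interspike-interval histogram within a window (50 us bins).

    Intervals are successive-spike differences within each sweep with both
    spikes inside the window; intervals are pooled across sweeps.  An empty
    window yields an empty histogram, not an error.
    """
    lo, hi = window_ms
    intervals = []
    for st in _all_spike_times(sweeps):
        inside = st[(st >= lo) & (st < hi)]
        if inside.size >= 2:
            intervals.append(np.diff(inside))
    intervals = np.concatenate(intervals) if intervals else np.empty(0)
    max_isi = max(hi - lo, bin_width_ms)
    edges = np.arange(0.0, max_isi + bin_width_ms, bin_width_ms)
    counts, _ = np.histogram(intervals, bins=edges)
    return ISIHistogram(
        window_ms=(lo, hi), bin_width_ms=bin_width_ms, edges_ms=edges,
        counts=counts, intervals_ms=intervals,
        mean_ms=float(intervals.mean()) if intervals.size else math.nan,
        sd_ms=float(intervals.std(ddof=1)) if intervals.size > 1 else math.nan,
    )


def train_initiation_nodes(
    sweep: SweepResult, window_halfwidth_ms: float = 1.0, fraction: float = 0.25
) -> list[str]:
    """Initiation node of every spike in a train sweep.

    The single-pulse Na-influx rule is applied within +/- 1 ms of each
    recorded spike (the influx at the initiation site precedes the arrival of
    the spike at the recording node).
    """
    if sweep.ina is None:
        raise ValueError("sweep was run without Na-current recording")
    dt_ms = sweep.dt_us * 1e-3
    nt = sweep.ina.shape[1]
    nodes = []
    for t_spike in sweep.spike_times_c16:
        i0 = max(0, int((t_spike - window_halfwidth_ms) / dt_ms))
        i1 = min(nt, int((t_spike + window_halfwidth_ms) / dt_ms))
        _, node = na_influx_onsets(
            sweep.ina, dt_ms, sweep.node_labels, fraction, t_slice=slice(i0, i1)
        )
        if node is not None:
            nodes.append(node)
    return nodes


def initiation_incidence_train(sweeps_by_level: dict) -> "pd.DataFrame":
    """Per-node initiation percentage over all spikes (not sweeps) per level."""
    import pandas as pd

    rows = []
    for label, sweeps in sweeps_by_level.items():
        nodes: list[str] = []
        for s in sweeps:
            if s.spiked:
                nodes.extend(train_initiation_nodes(s))
        total = len(nodes)
        if total == 0:
            continue
        for node in sorted(set(nodes)):
            rows.append(
                {
                    "level_label": label,
                    "node": node,
                    "incidence_pct": 100.0 * nodes.count(node) / total,
                    "n_spikes": total,
                }
            )
    return pd.DataFrame(rows)
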