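"""Single-pulse response metrics: firing efficiency, threshold, relative
spread, latency/jitter, spike-initiation incidence and conduction velocity.

The firing-efficiency curve FE(I) is fitted with the integrated Gaussian

    FE(I) = Phi((I - theta) / (RS * theta))

by binomial maximum likelihood; ``theta`` is the current at FE = 0.5 and the
relative spread RS is the SD-to-mean ratio of the underlying stochastic
threshold distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import norm

from .membrane import CableDiscretization, SweepResult, run_sweep
from .stimulus_field import FieldProfile, StimulusWaveform

__all__ = [
    "FECurve",
    "LatencyStats",
    "FitError",
    "CalibrationError",
    "firing_efficiency",
    "fit_fe_curve",
    "threshold_profile_ci",
    "latency_stats",
    "initiation_node",
    "initiation_incidence",
    "propagation_velocity",
    "calibrate_amplitude",
    "run_sweeps",
    "fe_at_level",
    "level_grid",
]


class FitError(RuntimeError):
    """FE-curve fit failed (degenerate or non-monotone data)."""


class CalibrationError(RuntimeError):
    """Amplitude calibration could not bracket or reach the target."""


@dataclass
class FECurve:
    levels: np.ndarray        # mA
    fe: np.ndarray            # in [0, 1]
    n_sweeps: int
    theta: float              # mA, FE = 0.5 level
    rs: float                 # relative spread, sigma / theta

    def predict(self, levels) -> np.ndarray:
        z = (np.asarray(levels, float) - self.theta) / (self.rs * self.theta)
        return norm.cdf(z)


@dataclass
class LatencyStats:
    mean_latency_ms: float
    jitter_ms: float          # SD of first-spike latencies
    n_spikes: int


def run_sweeps(
    cable: CableDiscretization,
    profile: FieldProfile,
    waveform: StimulusWaveform,
    n_sweeps: int,
    seeds: np.ndarray | int,
    **kwargs,
) -> list[SweepResult]:
    """Run ``n_sweeps`` independent sweeps with per-sweep seeds."""
    if np.isscalar(seeds):
        seeds = np.random.SeedSequence(int(seeds)).generate_state(n_sweeps) % (2**31 - 1)
    return [
        run_sweep(cable, profile, waveform, seed=int(seeds[i]), **kwargs)
        for i in range(n_sweeps)
    ]


def firing_efficiency(sweeps: list[SweepResult]) -> float:
    """Fraction of sweeps with at least one spike at the recording node."""
    if not sweeps:
        raise ValueError("need at least one sweep")
    return sum(s.spiked for s in sweeps) / len(sweeps)


def _nll(params_vec, levels, k, n):
    theta, log_rs = params_vec
    if theta <= 0:
        return 1e12
    rs = math.exp(log_rs)
    p = norm.cdf((levels - theta) / (rs * theta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p))


def fit_fe_curve(levels, fe, n_sweeps: int) -> FECurve:
    """Binomial maximum-likelihood fit of the integrated-Gaussian FE curve.

    Requires at least four distinct levels with responses spanning both sides
    of FE = 0.5 (otherwise theta is unidentified and a FitError is raised).
    """
    levels = np.asarray(levels, float)
    fe = np.asarray(fe, float)
    if np.unique(levels).size < 4:
        raise FitError("need >= 4 distinct stimulus levels")
    if np.any((fe < 0) | (fe > 1)):
        raise FitError("firing efficiencies must lie in [0, 1]")
    if fe.max() < 0.5 or fe.min() > 0.5:
        raise FitError(
            f"FE data do not bracket 0.5 (range {fe.min():.2f}-{fe.max():.2f}); "
            "widen the level grid"
        )
    order = np.argsort(levels)
    levels, fe = levels[order], fe[order]
    k = np.rint(fe * n_sweeps)

    # initial theta: linear interpolation of the 0.5 crossing
    above = np.nonzero(fe >= 0.5)[0]
    below = np.nonzero(fe < 0.5)[0]
    i_hi = above[0]
    theta0 = levels[i_hi]
    if below.size and below[0] < i_hi:
        i_lo = below[below < i_hi][-1]
        f0, f1 = fe[i_lo], fe[i_hi]
        if f1 > f0:
            theta0 = levels[i_lo] + (0.5 - f0) / (f1 - f0) * (levels[i_hi] - levels[i_lo])
    span = (levels[-1] - levels[0]) / max(theta0, 1e-12)
    rs0 = min(max(span / 8.0, 1e-3), 0.5)

    best = None
    for rs_init in (rs0, 0.03, 0.1):
        res = minimize(
            _nll, x0=[theta0, math.log(rs_init)], args=(levels, k, float(n_sweeps)),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta, log_rs = best.x
    if not np.isfinite(theta) or theta <= 0:
        raise FitError(f"fit diverged: theta={theta}")
    return FECurve(levels=levels, fe=fe, n_sweeps=int(n_sweeps),
                   theta=float(theta), rs=float(math.exp(log_rs)))


def threshold_profile_ci(
    levels, fe, n_sweeps: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for the fitted threshold."""
    from scipy.stats import chi2

    curve = fit_fe_curve(levels, fe, n_sweeps)
    levels = np.asarray(levels, float)
    k = np.rint(np.asarray(fe, float) * n_sweeps)
    nll_hat = _nll([curve.theta, math.log(curve.rs)], levels, k, float(n_sweeps))
    crit = chi2.ppf(confidence, df=1) / 2.0

    def profile(theta: float) -> float:
        res = minimize(
            lambda lr: _nll([theta, lr[0]], levels, k, float(n_sweeps)),
            x0=[math.log(curve.rs)], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10},
        )
        return res.fun - nll_hat - crit

    lo_bracket = curve.theta * 0.8
    hi_bracket = curve.theta * 1.2
    lo = brentq(profile, lo_bracket, curve.theta) if profile(lo_bracket) > 0 else lo_bracket
    hi = brentq(profile, curve.theta, hi_bracket) if profile(hi_bracket) > 0 else hi_bracket
    return float(lo), float(hi)


def latency_stats(sweeps: list[SweepResult]) -> LatencyStats:
    """Mean and SD of first-spike latencies (stimulus onset to C16 spike)."""
    lat = np.array([s.latency_ms for s in sweeps if s.spiked])
    if lat.size < 2:
        raise ValueError("jitter undefined with fewer than two spiking sweeps")
    return LatencyStats(
        mean_latency_ms=float(lat.mean()),
        jitter_ms=float(lat.std(ddof=1)),
        n_spikes=int(lat.size),
    )


def initiation_node(sweep: SweepResult, threshold_fraction: float = 0.25) -> str:
    """Spike-initiation node: earliest Na-influx onset across nodes."""
    if not sweep.spiked:
        raise ValueError("sweep has no spike")
    if sweep.initiation_node is None:
        from .membrane import na_influx_onsets

        if sweep.ina is None:
            raise ValueError("sweep was run without Na-current recording")
        _, node = na_influx_onsets(
            sweep.ina, sweep.dt_us * 1e-3, sweep.node_labels, threshold_fraction
        )
        if node is None:
            raise ValueError("no node crossed the Na-influx criterion")
        return node
    return sweep.initiation_node


def initiation_incidence(sweeps_by_level: dict) -> "pd.DataFrame":
    """Per-node spike-initiation percentages at each labelled level.

    ``sweeps_by_level`` maps a level label (e.g. FE target) to a sweep list;
    percentages are over spiking sweeps and sum to 100 per level.
    """
    import pandas as pd

    rows = []
    for label, sweeps in sweeps_by_level.items():
        nodes = [s.initiation_node for s in sweeps if s.spiked and s.initiation_node]
        total = len(nodes)
        for node in sorted(set(nodes)):
            rows.append(
                {
                    "level_label": label,
                    "node": node,
                    "incidence_pct": 100.0 * nodes.count(node) / total,
                    "n_spiking": total,
                }
            )
    return pd.DataFrame(rows)


def propagation_velocity(
    sweep: SweepResult,
    cable: CableDiscretization,
    node_range: tuple[str, str] = ("C4", "C14"),
) -> float:
    """Conduction velocity (m/s) from arrival times along the central axon.

    Least-squares slope of node axial position against first-spike time over
    the requested node range; needs spikes at >= 3 of those nodes.
    """
    labels = sweep.node_labels
    i0, i1 = labels.index(node_range[0]), labels.index(node_range[1])
    sel = slice(i0, i1 + 1)
    times = sweep.first_spike_ms[sel]
    pos_mm = cable.active_position_mm()[sel]
    ok = np.isfinite(times)
    if ok.sum() < 3:
        raise ValueError(
            f"need spikes at >= 3 nodes in {node_range}, got {int(ok.sum())}"
        )
    slope = np.polyfit(pos_mm[ok], times[ok], 1)[0]   # ms per mm
    return float(1.0 / slope)                          # mm/ms = m/s


def fe_at_level(
    cable, profile, waveform, amplitude, n_sweeps, seed_seq, **kwargs
) -> float:
    """Firing efficiency at one amplitude with fresh per-sweep seeds."""
    sweeps = run_sweeps(
        cable, profile, waveform.scaled(amplitude), n_sweeps, seed_seq,
        record_ina=False, **kwargs,
    )
    return firing_efficiency(sweeps)


def calibrate_amplitude(
    cable: CableDiscretization,
    profile: FieldProfile,
    waveform: StimulusWaveform,
    target: float,
    seed: int,
    n_sweeps: int = 100,
    tolerance: float = 0.05,
    objective=None,
    bracket: tuple[float, float] | None = None,
    max_iter: int = 24,
    mode: str = "stochastic",
) -> float:
    """Bisect the stimulus amplitude to a target response (default: FE).

    ``objective(amplitude, rep) -> float`` defaults to the firing efficiency
    over ``n_sweeps`` sweeps; the loop stops when the achieved value is within
    ``tolerance`` of ``target`` or the bracket is exhausted.  An initial
    bracket is found automatically with the deterministic-limit model (whose
    FE is a level step function), then expanded if needed.
    """
    rng = np.random.SeedSequence(int(seed))

    def default_objective(amplitude: float, rep: int) -> float:
        seeds = np.random.SeedSequence([int(seed), rep]).generate_state(n_sweeps) % (
            2**31 - 1
        )
        return fe_at_level(
            cable, profile, waveform, amplitude, n_sweeps, seeds, mode=mode
        )

    objective = objective or default_objective

    if bracket is None:
        theta_det = deterministic_threshold(cable, profile, waveform)
        lo, hi = theta_det * 0.7, theta_det * 1.4
    else:
        lo, hi = bracket
    f_lo = objective(lo, 0)
    f_hi = objective(hi, 1)
    for _ in range(8):
        if f_lo <= target:
            break
        lo *= 0.7
        f_lo = objective(lo, 0)
    for _ in range(8):
        if f_hi >= target:
            break
        hi *= 1.4
        f_hi = objective(hi, 1)
    if f_lo > target or f_hi < target:
        raise CalibrationError(
            f"could not bracket target {target}: f({lo:.4g})={f_lo:.3g}, "
            f"f({hi:.4g})={f_hi:.3g}"
        )
    best_amp, best_err = lo, abs(f_lo - target)
    for rep in range(2, max_iter + 2):
        mid = 0.5 * (lo + hi)
        f_mid = objective(mid, rep)
        if abs(f_mid - target) < best_err:
            best_amp, best_err = mid, abs(f_mid - target)
        if abs(f_mid - target) <= tolerance:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
        if (hi - lo) / hi < 1e-4:
            break
    return best_amp


def deterministic_threshold(
    cable, profile, waveform, rel_tol: float = 1e-3
) -> float:
    """Step-threshold of the deterministic (expected-gating) limit model."""
    amp = 0.01
    for _ in range(24):
        sweeps = run_sweeps(
            cable, profile, waveform.scaled(amp), 1, 0,
            mode="deterministic", record_ina=False,
        )
        if sweeps[0].spiked:
            break
        amp *= 2.0
    else:
        raise CalibrationError("no deterministic response up to huge amplitudes")
    lo, hi = amp / 2.0, amp
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        sweeps = run_sweeps(
            cable, profile, waveform.scaled(mid), 1, 0,
            mode="deterministic", record_ina=False,
        )
        if sweeps[0].spiked:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def level_grid(
    theta_est: float, rs_est: float = 0.05, n_levels: int = 9, halfwidth_rs: float = 4.0
) -> np.ndarray:
    """Levels spanning theta * (1 +/- halfwidth_rs * rs_est)."""
    return theta_est * np.linspace(
        1.0 - halfwidth_rs * rs_est, 1.0 + halfwidth_rs * rs_est, n_levels
    )
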