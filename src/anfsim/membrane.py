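"""Multicompartment stochastic ANF membrane model.

The fiber is a chain of compartments — active nodes of Ranvier (integer-count
Na/K channel populations), myelinated passive internode segments (nine per
internode) and a passive soma — coupled by axial resistances and driven by an
extracellular potential ``Ve[k][t]``.  The cable equation is integrated by a
Crank-Nicolson scheme at a 1 us step; channel populations follow a Markov
jumping process via channel-number tracking (binomial sampling of the number
of channels making each allowed transition per step).

Spike-rate adaptation follows from extracellular potassium accumulation:
outward K charge at each node, convolved with an exponential decay kernel,
raises the perinodal [K+]
and hence the K Nernst potential; because the nodal leak is largely
K-selective, the leak reversal tracks the shift, depolarising the node and
inactivating Na channels during sustained firing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from . import _kernel
from .config import FiberMorphology, MembraneParams
from .stimulus_field import FieldProfile, StimulusWaveform, compartment_layout

__all__ = [
    "CableDiscretization",
    "SweepResult",
    "InstabilityError",
    "build_fiber",
    "pack_rate_coefficients",
    "gating_rates",
    "stationary_distribution",
    "channel_step",
    "ionic_current",
    "update_EK",
    "crank_nicolson_step",
    "run_sweep",
]

MAX_SPIKES = 512


class InstabilityError(RuntimeError):
    """The membrane solution blew up (|Vm| > 500 mV)."""


@dataclass
class CableDiscretization:
    """Flat per-compartment arrays of the discretised fiber."""

    params: MembraneParams
    morphology: FiberMorphology
    kinds: list[str]                 # "P1".."P6", "pas_p", "soma", "C1".., "pas_c"
    lengths_um: np.ndarray
    diameters_um: np.ndarray
    areas_um2: np.ndarray
    cm_nF: np.ndarray
    gl_uS: np.ndarray
    gax_uS: np.ndarray               # (n_comp - 1,), between i and i+1
    axial_pos_um: np.ndarray         # compartment centres along the fiber
    active_idx: np.ndarray           # int64, global index of active nodes
    active_labels: list[str]
    n_na: np.ndarray                 # int64 channels per active node
    n_k: np.ndarray

    @property
    def n_comp(self) -> int:
        return self.cm_nF.size

    @property
    def c16_active_index(self) -> int:
        return self.active_labels.index("C16")

    def active_position_mm(self) -> np.ndarray:
        return self.axial_pos_um[self.active_idx] * 1e-3


def build_fiber(
    morphology: FiberMorphology | None = None,
    params: MembraneParams | None = None,
) -> CableDiscretization:
    """Discretise the fiber geometry into passive electrical parameters.

    Active nodes get the full specific membrane capacitance and the nodal
    leak; internodal segments have capacitance divided and resistance
    multiplied by the myelin attenuation factor (series capacitance of the
    lamellae); the soma is a single myelin-free passive compartment.  Channel
    counts per node are the published densities times the nodal area
    ``pi * diameter * nodal_gap``.
    """
    morphology = morphology or FiberMorphology()
    params = params or MembraneParams()
    kinds, lengths = compartment_layout(morphology)
    n = len(kinds)
    diam = np.empty(n)
    area = np.empty(n)
    cm = np.empty(n)
    gl = np.empty(n)

    # two membranes per lamella wrap, all in series with the nodal membrane
    atten = 1.0 + 4.0 * morphology.myelin_thickness * 1e3 / params.myelin_lamella_nm
    cm_spec = params.cm_uF_cm2 * 1e-5          # nF per um^2
    ohm_cm2_to_ohm_um2 = 1e8

    soma_seen = False
    for i, kind in enumerate(kinds):
        if kind == "soma":
            soma_seen = True
            diam[i] = morphology.soma_diameter
            area[i] = math.pi * morphology.soma_diameter ** 2   # sphere
            soma_atten = 1.0 + morphology.soma_myelin_membranes
            cm[i] = cm_spec * area[i] / soma_atten
            gl[i] = area[i] / (
                params.rm_soma_ohm_cm2 * soma_atten * ohm_cm2_to_ohm_um2) * 1e6
            continue
        peripheral = (kind.startswith("P") or kind == "pas_p") and not soma_seen
        diam[i] = (
            morphology.peripheral_diameter if peripheral else morphology.central_diameter
        )
        area[i] = math.pi * diam[i] * lengths[i]
        if kind.startswith("pas"):
            cm[i] = cm_spec * area[i] / atten
            gl[i] = (
                area[i] / (params.rm_passive_ohm_cm2 * atten * ohm_cm2_to_ohm_um2) * 1e6
            )
        else:  # active node
            cm[i] = cm_spec * area[i]
            gl[i] = area[i] / (params.rm_node_ohm_cm2 * ohm_cm2_to_ohm_um2) * 1e6

    # axial conductances: half-segment resistances in series, through the
    # axon core (axoplasm cross-section is a fraction of the fiber outline)
    rho_ohm_um = params.rho_axial_ohm_cm * 1e4
    core = diam * params.axon_diameter_ratio
    if morphology.has_soma:
        core[kinds.index("soma")] = diam[kinds.index("soma")]
    half_r = rho_ohm_um * (lengths / 2.0) / (math.pi * core ** 2 / 4.0)
    r_pair = half_r[:-1] + half_r[1:]
    gax = 1e6 / r_pair                       # uS

    active_mask = [k[0] in "PC" and k not in ("pas_p", "pas_c") for k in kinds]
    active_idx = np.array([i for i, m in enumerate(active_mask) if m], dtype=np.int64)
    active_labels = [kinds[i] for i in active_idx]
    node_area = area[active_idx]
    n_na = np.rint(params.rho_na_per_um2 * node_area).astype(np.int64)
    n_k = np.rint(params.rho_k_per_um2 * node_area).astype(np.int64)

    axial_pos = np.cumsum(lengths) - lengths / 2.0
    return CableDiscretization(
        params=params, morphology=morphology, kinds=kinds,
        lengths_um=lengths, diameters_um=diam, areas_um2=area,
        cm_nF=cm, gl_uS=gl, gax_uS=gax, axial_pos_um=axial_pos,
        active_idx=active_idx, active_labels=active_labels,
        n_na=n_na, n_k=n_k,
    )


def pack_rate_coefficients(params: MembraneParams) -> np.ndarray:
    """Pack gating coefficients + temperature factors for the kernels."""
    g = params.gating
    q_exp = (params.temperature_C - g.reference_temperature_C) / 10.0
    rc = np.array(
        [
            *g.alpha_m, *g.beta_m, *g.alpha_h, *g.beta_h, *g.alpha_n, *g.beta_n,
            g.q10_na ** q_exp, g.q10_k ** q_exp,
        ],
        dtype=np.float64,
    )
    return rc


def gating_rates(vm_mV: float, params: MembraneParams) -> dict[str, float]:
    """Rate constants (1/ms) at absolute membrane potential ``vm_mV``."""
    rc = pack_rate_coefficients(params)
    am, bm, ah, bh, an, bn = _kernel.rates_at(vm_mV - params.v_rest_mV, rc)
    return {
        "alpha_m": am, "beta_m": bm, "alpha_h": ah,
        "beta_h": bh, "alpha_n": an, "beta_n": bn,
    }


def stationary_distribution(vm_mV: float, params: MembraneParams):
    """Stationary occupancy probabilities (Na 8-state, K 5-state) at a clamp."""
    rc = pack_rate_coefficients(params)
    p_na, p_k = _kernel.stationary_probs(vm_mV - params.v_rest_mV, rc)
    return np.asarray(p_na), np.asarray(p_k)


def channel_step(
    na_state: np.ndarray,
    k_state: np.ndarray,
    vm_mV: float,
    params: MembraneParams,
    dt_us: float = 1.0,
    rng_seed: int | None = None,
    stochastic: bool = True,
):
    """Advance one node's channel populations by one step (in place).

    Raises ValueError if any per-step transition probability exceeds one.
    """
    rc = pack_rate_coefficients(params)
    am, bm, ah, bh, an, bn = _kernel.rates_at(vm_mV - params.v_rest_mV, rc)
    dt_ms = dt_us * 1e-3
    for rate_sum in ((3 * am + bm * 3 + max(ah, bh)), (4 * an + 4 * bn)):
        if rate_sum * dt_ms > 1.0:
            raise ValueError(
                f"transition probability {rate_sum * dt_ms:.2f} > 1 at dt={dt_us} us"
            )
    if rng_seed is not None:
        _kernel.seed_rng(rng_seed)
    e1 = _kernel.na_step(na_state, am, bm, ah, bh, dt_ms, stochastic)
    e2 = _kernel.k_step(k_state, an, bn, dt_ms, stochastic)
    if e1 or e2:
        raise ValueError("per-step transition probability exceeded 1")
    return na_state, k_state


def ionic_current(
    n_open_na: float,
    n_open_k: float,
    vm_mV: float,
    params: MembraneParams,
    e_k_mV: float | None = None,
) -> tuple[float, float]:
    """Return (I_Na, I_K) in nA for given open-channel counts.

    I = gamma * N_open * (Vm - E); inward currents are negative.
    """
    e_k = params.e_k0_mV if e_k_mV is None else e_k_mV
    i_na = params.gamma_na_pS * 1e-6 * n_open_na * (vm_mV - params.e_na_mV)
    i_k = params.gamma_k_pS * 1e-6 * n_open_k * (vm_mV - e_k)
    return i_na, i_k


def update_EK(
    i_k_history_nA: np.ndarray,
    params: MembraneParams,
    node_area_um2: float,
    dt_us: float = 1.0,
) -> np.ndarray:
    """K Nernst potential trace (mV) from an outward-K-current history.

    The extracellular increment is the discrete convolution of the K current
    with the exponential decay kernel g(t) = exp(-t/tau), converted from
    charge to concentration through the perinodal shell volume; then
    E_K = (RT/F) ln([K]ext/[K]in).
    """
    acc = params.k_accumulation
    dt_ms = dt_us * 1e-3
    decay = math.exp(-dt_ms / acc.tau_ms)
    gain = _kacc_gain(node_area_um2, acc.shell_thickness_um)
    dk = 0.0
    k0 = params.k_ext0_mM
    out = np.empty(i_k_history_nA.size)
    for t, i_k in enumerate(np.asarray(i_k_history_nA, float)):
        dk = dk * decay + gain * i_k * dt_ms
        k_ext = k0 + dk
        if k_ext <= 0:
            raise ValueError("extracellular [K+] went non-positive")
        out[t] = params.rt_over_f_mV * math.log(k_ext / acc.k_in_mM)
    return out


def _kacc_gain(area_um2: float, shell_um: float) -> float:
    """mM of [K+]ext per nA*ms of outward charge at one node."""
    from .config import FARADAY

    volume_l = area_um2 * shell_um * 1e-15
    return 1e-12 / (FARADAY * volume_l) * 1e3


def crank_nicolson_step(
    vm: np.ndarray,
    ve_now: np.ndarray,
    ve_next: np.ndarray,
    i_ion_nA: np.ndarray,
    cable: CableDiscretization,
    dt_us: float = 1.0,
    el_mV: np.ndarray | None = None,
) -> np.ndarray:
    """One Crank-Nicolson update of the cable equation (reference path).

    Solves (C/dt + g_L/2 + L/2) v+ = (C/dt - g_L/2 - L/2) v
    + D ve_now + g_L E_L - I_ion with the graph Laplacian L of axial
    conductances and sealed ends.  The extracellular drive uses the value
    over the step interval (the sampled stimulus is piecewise constant);
    ``ve_next`` is accepted for interface completeness.  This numpy/scipy
    implementation mirrors the compiled kernel step and is used for
    verification.
    """
    from scipy.linalg import solve_banded

    cm = cable.cm_nF
    gl = cable.gl_uS
    gax = cable.gax_uS
    n = cm.size
    dt_ms = dt_us * 1e-3
    if el_mV is None:
        el_mV = np.full(n, cable.params.v_rest_mV)

    def axial(x: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        out[:-1] += gax * (x[1:] - x[:-1])
        out[1:] += gax * (x[:-1] - x[1:])
        return out

    g_side = np.zeros(n)
    g_side[:-1] += gax
    g_side[1:] += gax
    dia = cm / dt_ms + 0.5 * gl + 0.5 * g_side
    rhs = (
        (cm / dt_ms) * vm
        - 0.5 * gl * vm
        + 0.5 * axial(vm)
        + axial(ve_now)
        + gl * el_mV
        - i_ion_nA
    )
    ab = np.zeros((3, n))
    ab[0, 1:] = -0.5 * gax
    ab[1, :] = dia
    ab[2, :-1] = -0.5 * gax
    try:
        return solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"singular cable system: {exc}") from exc


@dataclass
class SweepResult:
    """Outcome of one stimulus sweep."""

    seed: int
    dt_us: float
    duration_ms: float
    spike_times_c16: np.ndarray          # ms
    first_spike_ms: np.ndarray           # per active node, nan if none
    node_labels: list[str]
    na_onset_ms: np.ndarray | None = None    # per active node, nan if none
    initiation_node: str | None = None
    k_shift_mM: np.ndarray | None = None     # final extracellular-K increment
    vm: np.ndarray | None = None             # (n_act, nt) float32, active nodes
    ina: np.ndarray | None = None            # (n_act, nt) float32

    @property
    def spiked(self) -> bool:
        return self.spike_times_c16.size > 0

    @property
    def latency_ms(self) -> float:
        return float(self.spike_times_c16[0]) if self.spiked else math.nan


def run_sweep(
    cable: CableDiscretization,
    profile: FieldProfile,
    waveform: StimulusWaveform,
    seed: int,
    mode: str = "stochastic",
    record_ina: bool = True,
    record_vm: bool = False,
    initiation_fraction: float = 0.25,
    kacc_enabled: bool | None = None,
) -> SweepResult:
    """Simulate one sweep from a full reset of all model state.

    The time loop interleaves the channel-number-tracking update, the
    K-accumulation update, the ionic-current evaluation and the
    Crank-Nicolson cable step at the waveform's sample step.  With
    ``record_ina`` the per-node Na-current traces are kept and the
    spike-initiation node (earliest Na-influx onset) is computed.
    """
    params = cable.params
    acc = params.k_accumulation
    stochastic = mode == "stochastic"
    if mode not in ("stochastic", "deterministic"):
        raise ValueError(f"unknown mode {mode!r}")
    if kacc_enabled is None:
        kacc_enabled = acc.enabled
    rc = pack_rate_coefficients(params)
    dt_ms = waveform.sample_step * 1e-3
    node_area = cable.areas_um2[cable.active_idx]
    kacc_gain = np.array(
        [_kacc_gain(a, acc.shell_thickness_um) for a in node_area]
    )
    spike_times, n_spk, first_spike, ina, vm, dk_final, err = _kernel.run_cable(
        cable.cm_nF, cable.gl_uS, cable.gax_uS,
        params.v_rest_mV, params.e_na_mV, params.e_k0_mV,
        cable.active_idx,
        params.gamma_na_pS * 1e-6, params.gamma_k_pS * 1e-6,
        cable.n_na, cable.n_k,
        rc,
        kacc_gain,
        math.exp(-dt_ms / acc.tau_ms),
        params.k_ext0_mM, acc.k_in_mM, params.rt_over_f_mV,
        acc.leak_k_fraction, kacc_enabled,
        profile.transfer_resistance.astype(np.float64),
        waveform.current.astype(np.float64),
        dt_ms,
        params.spike_threshold_mV, params.refractory_ms,
        cable.c16_active_index,
        stochastic, int(seed) % (2 ** 31 - 1),
        record_ina, record_vm,
        MAX_SPIKES,
    )
    if err == _kernel.ERR_BLOWUP:
        raise InstabilityError(
            f"membrane potential exceeded 500 mV (seed={seed}, "
            f"amplitude={waveform.amplitude} mA)"
        )
    first = np.asarray(first_spike, float)
    first[first < 0] = math.nan
    result = SweepResult(
        seed=int(seed), dt_us=waveform.sample_step, duration_ms=waveform.duration,
        spike_times_c16=np.asarray(spike_times[:n_spk], float),
        first_spike_ms=first,
        node_labels=list(cable.active_labels),
        k_shift_mM=np.asarray(dk_final),
        vm=np.asarray(vm) if record_vm else None,
        ina=np.asarray(ina) if record_ina else None,
    )
    if record_ina and result.spiked:
        onset, node = na_influx_onsets(
            result.ina, dt_ms, cable.active_labels, initiation_fraction
        )
        result.na_onset_ms = onset
        result.initiation_node = node
    return result


def na_influx_onsets(
    ina: np.ndarray,
    dt_ms: float,
    labels: list[str],
    fraction: float = 0.25,
    eligibility: float = 0.2,
    t_slice: slice | None = None,
) -> tuple[np.ndarray, str | None]:
    """Per-node Na-influx onset times and the spike-initiation node.

    A node's onset is the first time its inward (negative) Na current crosses
    ``fraction`` of that node's own peak inward current.  Nodes whose peak is
    below ``eligibility`` of the global peak are excluded (channel noise at
    non-spiking nodes gives meaningless crossings).  Ties break toward the
    peripheral end, which comes first in node order.
    """
    window = ina if t_slice is None else ina[:, t_slice]
    t0 = 0 if t_slice is None else (t_slice.start or 0)
    peaks = window.min(axis=1)
    global_peak = peaks.min()
    onsets = np.full(len(labels), np.nan)
    if global_peak >= 0:
        return onsets, None
    for a in range(len(labels)):
        if peaks[a] > eligibility * global_peak:  # both negative
            continue
        crossing = np.nonzero(window[a] <= fraction * peaks[a])[0]
        if crossing.size:
            onsets[a] = (t0 + crossing[0]) * dt_ms
    if np.all(np.isnan(onsets)):
        return onsets, None
    best = int(np.nanargmin(onsets))
    return onsets, labels[best]
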