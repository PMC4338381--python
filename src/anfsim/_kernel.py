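"""Numba kernels: the Crank-Nicolson time loop and stochastic channel updates.

Everything here works on flat numpy arrays prepared by :mod:`anfsim.membrane`.
Units inside the kernels: mV, ms, nA, uS, nF, mM.  Channel-state arrays hold
float64 values that remain exact integers in stochastic mode (binomial draws)
and fractional expectations in deterministic mode.

Na channels occupy 8 Markov states indexed ``s = 4*h + m`` with ``m`` open
activation gates (0..3) and ``h`` the inactivation gate (0 closed, 1 open);
the conducting state is s=7 (m3h1).  K channels occupy 5 states ``n0..n4``
with n4 conducting.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# error codes returned by the main loop
ERR_NONE = 0
ERR_PROBABILITY = 1   # per-step transition probability exceeded 1
ERR_BLOWUP = 2        # |Vm| > 500 mV


@njit(cache=True)
def _linoid(v, a, b, c):
    """a*(v-b)/(1-exp(-(v-b)/c)) with the removable singularity at v=b."""
    x = (v - b) / c
    if abs(x) < 1e-7:
        return a * c
    return a * (v - b) / (1.0 - np.exp(-x))


@njit(cache=True)
def rates_at(v_rel, rc):
    """Six gating rates (1/ms) at depolarisation v_rel = Vm - Vrest (mV).

    ``rc`` packs the 18 rate-function coefficients followed by the Na and K
    temperature factors (see membrane.pack_rate_coefficients).
    """
    qna = rc[18]
    qk = rc[19]
    am = _linoid(v_rel, rc[0], rc[1], rc[2]) * qna
    bm = _linoid(v_rel, rc[3], rc[4], rc[5]) * qna
    ah = _linoid(v_rel, rc[6], rc[7], rc[8]) * qna
    bh = rc[9] / (1.0 + np.exp((rc[10] - v_rel) / rc[11])) * qna
    an = _linoid(v_rel, rc[12], rc[13], rc[14]) * qk
    bn = _linoid(v_rel, rc[15], rc[16], rc[17]) * qk
    if am < 0.0:
        am = 0.0
    if bm < 0.0:
        bm = 0.0
    if ah < 0.0:
        ah = 0.0
    if bh < 0.0:
        bh = 0.0
    if an < 0.0:
        an = 0.0
    if bn < 0.0:
        bn = 0.0
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def _binom(n, p):
    if n <= 0:
        return 0
    if p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    return np.random.binomial(n, p)


@njit(cache=True)
def na_step(state, am, bm, ah, bh, dt_ms, stochastic):
    """Advance one node's Na population by dt.  Returns an error code.

    Each channel makes at most one transition per step: for every state the
    number of leavers is drawn from a binomial over the summed exit
    probability and split between the competing destinations by conditional
    binomials.  Deltas are applied after all states are processed, so counts
    can never go negative.
    """
    err = ERR_NONE
    d = np.zeros(8)
    for j in range(2):
        for i in range(4):
            s = 4 * j + i
            n = state[s]
            if n <= 0.0:
                continue
            p_up = (3 - i) * am * dt_ms
            p_dn = i * bm * dt_ms
            p_h = ah * dt_ms if j == 0 else bh * dt_ms
            ptot = p_up + p_dn + p_h
            if ptot <= 0.0:
                continue
            if ptot > 1.0:
                err = ERR_PROBABILITY
            if stochastic:
                k_tot = _binom(np.int64(n + 0.5), min(ptot, 1.0))
                if k_tot == 0:
                    continue
                k_up = _binom(k_tot, p_up / ptot)
                rem = k_tot - k_up
                p_rest = p_dn + p_h
                k_dn = _binom(rem, p_dn / p_rest) if p_rest > 0.0 else 0
                k_h = rem - k_dn
                f_up = float(k_up)
                f_dn = float(k_dn)
                f_h = float(k_h)
            else:
                scale = 1.0 / ptot if ptot > 1.0 else 1.0
                f_up = n * p_up * scale
                f_dn = n * p_dn * scale
                f_h = n * p_h * scale
            d[s] -= f_up + f_dn + f_h
            if i < 3:
                d[s + 1] += f_up
            if i > 0:
                d[s - 1] += f_dn
            if j == 0:
                d[s + 4] += f_h
            else:
                d[s - 4] += f_h
    for s in range(8):
        state[s] += d[s]
    return err


@njit(cache=True)
def k_step(state, an, bn, dt_ms, stochastic):
    """Advance one node's K population (5-state birth-death chain) by dt."""
    err = ERR_NONE
    d = np.zeros(5)
    for i in range(5):
        n = state[i]
        if n <= 0.0:
            continue
        p_up = (4 - i) * an * dt_ms
        p_dn = i * bn * dt_ms
        ptot = p_up + p_dn
        if ptot <= 0.0:
            continue
        if ptot > 1.0:
            err = ERR_PROBABILITY
        if stochastic:
            k_tot = _binom(np.int64(n + 0.5), min(ptot, 1.0))
            if k_tot == 0:
                continue
            k_up = _binom(k_tot, p_up / ptot)
            k_dn = k_tot - k_up
            f_up = float(k_up)
            f_dn = float(k_dn)
        else:
            scale = 1.0 / ptot if ptot > 1.0 else 1.0
            f_up = n * p_up * scale
            f_dn = n * p_dn * scale
        d[i] -= f_up + f_dn
        if i < 4:
            d[i + 1] += f_up
        if i > 0:
            d[i - 1] += f_dn
    for i in range(5):
        state[i] += d[i]
    return err


@njit(cache=True)
def stationary_probs(v_rel, rc):
    """Stationary occupancy of the Na (8) and K (5) chains at a fixed voltage.

    The per-gate equilibria factorise: p(s=4j+i) = Binom(3,i;m_inf) *
    Bernoulli(j;h_inf) and p(n_i) = Binom(4,i;n_inf).
    """
    am, bm, ah, bh, an, bn = rates_at(v_rel, rc)
    m_inf = am / (am + bm)
    h_inf = ah / (ah + bh)
    n_inf = an / (an + bn)
    p_na = np.empty(8)
    binom3 = np.array([1.0, 3.0, 3.0, 1.0])
    for j in range(2):
        ph = h_inf if j == 1 else 1.0 - h_inf
        for i in range(4):
            p_na[4 * j + i] = (
                binom3[i] * m_inf ** i * (1.0 - m_inf) ** (3 - i) * ph
            )
    p_k = np.empty(5)
    binom4 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
    for i in range(5):
        p_k[i] = binom4[i] * n_inf ** i * (1.0 - n_inf) ** (4 - i)
    return p_na, p_k


@njit(cache=True)
def _sample_multinomial(n_total, probs, out):
    """Sample counts over states by sequential conditional binomials."""
    remaining = n_total
    p_rest = 1.0
    for s in range(probs.size - 1):
        if remaining <= 0 or p_rest <= 0.0:
            out[s] = 0.0
            continue
        k = _binom(remaining, min(probs[s] / p_rest, 1.0))
        out[s] = float(k)
        remaining -= k
        p_rest -= probs[s]
    out[probs.size - 1] = float(remaining)


@njit(cache=True)
def init_channel_states(n_na, n_k, rc, stochastic, na_state, k_state):
    """Reset channel populations to the resting stationary distribution."""
    p_na, p_k = stationary_probs(0.0, rc)
    n_act = n_na.size
    for a in range(n_act):
        if stochastic:
            _sample_multinomial(n_na[a], p_na, na_state[a])
            _sample_multinomial(n_k[a], p_k, k_state[a])
        else:
            for s in range(8):
                na_state[a, s] = n_na[a] * p_na[s]
            for s in range(5):
                k_state[a, s] = n_k[a] * p_k[s]


@njit(cache=True)
def run_cable(
    cm,            # nF, (n_comp,)
    gl,            # uS, (n_comp,)
    gax,           # uS between i and i+1, (n_comp-1,)
    v_rest, e_na, e_k0,
    active_idx,    # int64 (n_act,) global compartment index of active nodes
    gamma_na, gamma_k,   # uS per channel
    n_na, n_k,     # int64 (n_act,)
    rc,            # rate coefficients, (20,)
    kacc_gain,     # mM per (nA*ms), (n_act,)
    kacc_decay,    # exp(-dt/tau_K)
    k_ext0, k_in, rtf_mv, fk_leak, kacc_enabled,
    transfer,      # Ohm (mV per mA), (n_comp,)
    stim,          # mA, (nt,)
    dt_ms,
    spike_thr, refractory_ms,
    c16_act,       # index into active arrays of the C16 node
    stochastic, seed,
    record_ina, record_vm,
    max_spikes,
):
    """Integrate the full cable for one sweep.

    Returns (spike_times_c16, n_spikes, first_spike_ms, ina, vm, err):
    ``first_spike_ms[a]`` is the first threshold-crossing time at active node
    ``a`` (-1 if none); ``ina``/``vm`` are (n_act, nt) float32 traces when
    requested, else 1x1 placeholders; ``dk`` is the final extracellular-K
    increment (mM) per active node.
    """
    np.random.seed(seed)
    n_comp = cm.size
    n_act = active_idx.size
    nt = stim.size

    # --- Crank-Nicolson tridiagonal prefactorisation (constant matrix) ---
    sub = np.zeros(n_comp)
    dia = np.zeros(n_comp)
    sup = np.zeros(n_comp)
    for i in range(n_comp):
        g_left = gax[i - 1] if i > 0 else 0.0
        g_right = gax[i] if i < n_comp - 1 else 0.0
        dia[i] = cm[i] / dt_ms + 0.5 * gl[i] + 0.5 * (g_left + g_right)
        if i > 0:
            sub[i] = -0.5 * gax[i - 1]
        if i < n_comp - 1:
            sup[i] = -0.5 * gax[i]
    cp = np.zeros(n_comp)
    denom = np.zeros(n_comp)

    # activating-function vector: D(transfer)_i; the stimulus is piecewise
    # constant over each sample interval, so the drive over step t is
    # dvec_i * stim[t] (interval value; exact in charge at any dt)
    dvec = np.zeros(n_comp)
    for i in range(n_comp):
        if i > 0:
            dvec[i] += gax[i - 1] * (transfer[i - 1] - transfer[i])
        if i < n_comp - 1:
            dvec[i] += gax[i] * (transfer[i + 1] - transfer[i])

    # --- state ---
    v = np.full(n_comp, v_rest)
    v_new = np.empty(n_comp)
    na_state = np.zeros((n_act, 8))
    k_state = np.zeros((n_act, 5))
    init_channel_states(n_na, n_k, rc, stochastic, na_state, k_state)
    dk = np.zeros(n_act)              # extracellular K+ increment (mM)
    iion = np.zeros(n_comp)           # nA
    gion = np.zeros(n_comp)           # instantaneous channel conductance (uS)
    el = np.full(n_comp, v_rest)      # leak reversal per compartment
    d_rhs = np.empty(n_comp)
    dp = np.empty(n_comp)

    # decaying envelope of the local drive, so the instability guard
    # tolerates the physical polarisation that outlives a strong pulse
    env = np.zeros(n_comp)
    env_decay = np.exp(-dt_ms / 0.1)

    spike_times = np.full(max_spikes, -1.0)
    n_spk = 0
    first_spike = np.full(n_act, -1.0)
    last_spike = np.full(n_act, -1e9)

    if record_ina:
        ina = np.zeros((n_act, nt), dtype=np.float32)
    else:
        ina = np.zeros((1, 1), dtype=np.float32)
    if record_vm:
        vm = np.zeros((n_act, nt), dtype=np.float32)
        for a in range(n_act):
            vm[a, 0] = np.float32(v_rest)
    else:
        vm = np.zeros((1, 1), dtype=np.float32)

    err = ERR_NONE
    for t in range(nt - 1):
        # --- channel populations, ionic currents, K accumulation ---
        for a in range(n_act):
            g = active_idx[a]
            v_rel = v[g] - v_rest
            am, bm, ah, bh, an, bn = rates_at(v_rel, rc)
            e1 = na_step(na_state[a], am, bm, ah, bh, dt_ms, stochastic)
            e2 = k_step(k_state[a], an, bn, dt_ms, stochastic)
            if e1 != ERR_NONE or e2 != ERR_NONE:
                err = ERR_PROBABILITY
            e_k_node = e_k0
            if kacc_enabled:
                e_k_node = rtf_mv * np.log((k_ext0 + dk[a]) / k_in)
            i_na = gamma_na * na_state[a, 7] * (v[g] - e_na)
            i_k = gamma_k * k_state[a, 4] * (v[g] - e_k_node)
            if kacc_enabled:
                # outward K charge: gated K current plus the K-carried part
                # of the nodal leak (zero at rest by construction)
                i_k_acc = i_k + fk_leak * gl[g] * (v[g] - el[g])
                dk[a] = dk[a] * kacc_decay + kacc_gain[a] * i_k_acc * dt_ms
                if dk[a] < -0.95 * k_ext0:
                    dk[a] = -0.95 * k_ext0
                el[g] = v_rest + fk_leak * (e_k_node - e_k0)
            iion[g] = i_na + i_k
            gion[g] = gamma_na * na_state[a, 7] + gamma_k * k_state[a, 4]
            if record_ina:
                ina[a, t] = np.float32(i_na)

        # --- Crank-Nicolson right-hand side ---
        i_mid = stim[t]
        for i in range(n_comp):
            axial = 0.0
            if i > 0:
                axial += gax[i - 1] * (v[i - 1] - v[i])
            if i < n_comp - 1:
                axial += gax[i] * (v[i + 1] - v[i])
            d_rhs[i] = (
                (cm[i] / dt_ms) * v[i]
                - 0.5 * gl[i] * v[i]
                + 0.5 * axial
                + dvec[i] * i_mid
                + gl[i] * el[i]
                - iion[i]
                + gion[i] * v[i]
            )

        # --- Thomas solve; the ionic term is semi-implicit, so the channel
        # conductance of the step enters the diagonal and the factorisation
        # is redone each step ---
        denom[0] = dia[0] + gion[0]
        cp[0] = sup[0] / denom[0]
        for i in range(1, n_comp):
            denom[i] = dia[i] + gion[i] - sub[i] * cp[i - 1]
            cp[i] = sup[i] / denom[i]
        dp[0] = d_rhs[0] / denom[0]
        for i in range(1, n_comp):
            dp[i] = (d_rhs[i] - sub[i] * dp[i - 1]) / denom[i]
        v_new[n_comp - 1] = dp[n_comp - 1]
        for i in range(n_comp - 2, -1, -1):
            v_new[i] = dp[i] - cp[i] * v_new[i + 1]

        # --- spike detection at active nodes ---
        t_new = (t + 1) * dt_ms
        for a in range(n_act):
            g = active_idx[a]
            if v_new[g] >= spike_thr and v[g] < spike_thr:
                if t_new - last_spike[a] > refractory_ms:
                    last_spike[a] = t_new
                    if first_spike[a] < 0.0:
                        first_spike[a] = t_new
                    if a == c16_act and n_spk < max_spikes:
                        spike_times[n_spk] = t_new
                        n_spk += 1
            if record_vm:
                vm[a, t + 1] = np.float32(v_new[g])

        # instability guard: large |Vm| is physical while the compartment is
        # strongly driven by the extracellular field, so the limit scales
        # with the local instantaneous drive
        blowup = False
        drive = abs(stim[t]) if abs(stim[t]) > abs(stim[t + 1]) else abs(stim[t + 1])
        for i in range(n_comp):
            cand = transfer[i] * drive
            env[i] *= env_decay
            if cand > env[i]:
                env[i] = cand
            if abs(v_new[i]) > 500.0 + 2.0 * env[i]:
                blowup = True
            v[i] = v_new[i]
        if blowup:
            err = ERR_BLOWUP
            break

    return spike_times, n_spk, first_spike, ina, vm, dk, err


@njit(cache=True)
def seed_rng(seed):
    """Seed the shared numba RNG used by the stochastic updates."""
    np.random.seed(seed)


@njit(cache=True)
def clamp_population(
    n_na, n_k, v_rel, rc, dt_ms, n_steps, seed, sample_every, start_closed
):
    """Evolve one clamped channel population; sample state counts periodically.

    Returns (na_samples, k_samples, open_na, open_k): state-count snapshots of
    shape (n_samples, 8) / (n_samples, 5) taken every ``sample_every`` steps,
    plus the full open-count trajectories (length n_steps).
    """
    np.random.seed(seed)
    na_state = np.zeros(8)
    k_state = np.zeros(5)
    if start_closed:
        na_state[0] = float(n_na)
        k_state[0] = float(n_k)
    else:
        p_na, p_k = stationary_probs(v_rel, rc)
        _sample_multinomial(n_na, p_na, na_state)
        _sample_multinomial(n_k, p_k, k_state)
    am, bm, ah, bh, an, bn = rates_at(v_rel, rc)
    n_samples = n_steps // sample_every
    na_samples = np.zeros((n_samples, 8))
    k_samples = np.zeros((n_samples, 5))
    open_na = np.zeros(n_steps)
    open_k = np.zeros(n_steps)
    j = 0
    for t in range(n_steps):
        na_step(na_state, am, bm, ah, bh, dt_ms, True)
        k_step(k_state, an, bn, dt_ms, True)
        open_na[t] = na_state[7]
        open_k[t] = k_state[4]
        if (t + 1) % sample_every == 0 and j < n_samples:
            for s in range(8):
                na_samples[j, s] = na_state[s]
            for s in range(5):
                k_samples[j, s] = k_state[s]
            j += 1
    return na_samples, k_samples, open_na, open_k


@njit(cache=True)
def clamp_mean_open(n_na, n_k, v_rel, rc, dt_ms, n_steps, n_reps, seed):
    """Mean open-count trajectories over many stochastic replicas.

    All channels start in the fully-closed state so the relaxation toward the
    clamp steady state can be compared with the deterministic gating ODE.
    """
    np.random.seed(seed)
    mean_na = np.zeros(n_steps)
    mean_k = np.zeros(n_steps)
    for _ in range(n_reps):
        na_state = np.zeros(8)
        k_state = np.zeros(5)
        na_state[0] = float(n_na)
        k_state[0] = float(n_k)
        am, bm, ah, bh, an, bn = rates_at(v_rel, rc)
        for t in range(n_steps):
            na_step(na_state, am, bm, ah, bh, dt_ms, True)
            k_step(k_state, an, bn, dt_ms, True)
            mean_na[t] += na_state[7]
            mean_k[t] += k_state[4]
    mean_na /= n_reps
    mean_k /= n_reps
    return mean_na, mean_k
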