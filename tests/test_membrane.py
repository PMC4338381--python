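"""Biophysical core: fiber discretisation, gating kinetics, channel-number
tracking, K-accumulation, the cable solver and full sweeps."""

import math

import numpy as np
import pytest

from anfsim import _kernel
from anfsim.config import FiberMorphology, MembraneParams
from anfsim.membrane import (
    build_fiber,
    channel_step,
    crank_nicolson_step,
    gating_rates,
    ionic_current,
    na_influx_onsets,
    pack_rate_coefficients,
    run_sweep,
    stationary_distribution,
    update_EK,
)
from anfsim.single_pulse import run_sweeps


class TestBuildFiber:
    def test_channel_counts_from_density_times_nodal_area(self, cable):
        # central node: pi * 2.3 um * 1 um = 7.23 um^2 -> 578 Na, 325 K
        central = cable.active_labels.index("C1")
        assert cable.n_na[central] == 578
        assert cable.n_k[central] == 325
        # peripheral node: pi * 1.2 * 1 = 3.77 um^2 -> 302 Na, 170 K
        assert cable.n_na[0] == 302
        assert cable.n_k[0] == 170

    def test_node_ordering_and_recording_site(self, cable):
        assert cable.active_labels[:6] == [f"P{i}" for i in range(1, 7)]
        assert cable.active_labels[6:] == [f"C{i}" for i in range(1, 21)]
        assert cable.active_labels[cable.c16_active_index] == "C16"

    def test_axial_resistance_scales_inverse_square_of_diameter(self):
        thin = build_fiber(FiberMorphology(), MembraneParams())
        fat_morph = FiberMorphology(central_diameter=4.6)
        fat = build_fiber(fat_morph, MembraneParams())
        # compare a central internodal segment pair at fixed segment length:
        # g = 1/Ra grows as diameter^2, and the internode itself lengthens
        # with diameter (length = ratio * d), so g grows linearly overall
        g_thin = thin.gax_uS[-5]
        g_fat = fat.gax_uS[-5]
        assert g_fat / g_thin == pytest.approx(2.0, rel=1e-6)

    def test_all_electrical_parameters_positive(self, cable):
        assert np.all(cable.cm_nF > 0)
        assert np.all(cable.gl_uS > 0)
        assert np.all(cable.gax_uS > 0)

    def test_too_few_central_nodes_rejected(self):
        with pytest.raises(ValueError):
            FiberMorphology(n_central_nodes=10)


class TestGatingRates:
    def test_rates_positive_and_finite_at_rest(self, config):
        rates = gating_rates(config.membrane.v_rest_mV, config.membrane)
        for value in rates.values():
            assert np.isfinite(value) and value >= 0
        assert rates["alpha_m"] > 0 and rates["beta_m"] > 0

    def test_activation_monotonicity_over_depolarisation(self, config):
        v0 = config.membrane.v_rest_mV
        grid = np.linspace(v0, v0 + 40.0, 9)
        am = [gating_rates(v, config.membrane)["alpha_m"] for v in grid]
        bm = [gating_rates(v, config.membrane)["beta_m"] for v in grid]
        assert np.all(np.diff(am) > 0)
        assert np.all(np.diff(bm) < 0)

    def test_continuity_at_linoid_singularity(self, config):
        g = config.membrane.gating
        v_sing = config.membrane.v_rest_mV + g.alpha_m[1]
        near = gating_rates(v_sing + 1e-6, config.membrane)["alpha_m"]
        at = gating_rates(v_sing, config.membrane)["alpha_m"]
        assert at == pytest.approx(near, rel=1e-4)

    @pytest.mark.parametrize("v_rel", [0.0, 20.0, 50.0])
    def test_stationary_open_mass_matches_master_equation(self, config, v_rel):
        """Product-form stationary occupancy must solve the full 8-state
        master equation (independent linear-algebra oracle)."""
        params = config.membrane
        rc = pack_rate_coefficients(params)
        am, bm, ah, bh, an, bn = _kernel.rates_at(v_rel, rc)
        # build the 8x8 generator of the Na chain, states s = 4j + i
        q = np.zeros((8, 8))
        for j in range(2):
            for i in range(4):
                s = 4 * j + i
                if i < 3:
                    q[s, s + 1] = (3 - i) * am
                if i > 0:
                    q[s, s - 1] = i * bm
                q[s, s + 4 if j == 0 else s - 4] = ah if j == 0 else bh
        np.fill_diagonal(q, -q.sum(axis=1))
        # stationary distribution: left null vector of the generator
        w, v = np.linalg.eig(q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = pi / pi.sum()
        p_na, _ = stationary_distribution(params.v_rest_mV + v_rel, params)
        np.testing.assert_allclose(p_na, pi, atol=1e-10)
        m_inf = am / (am + bm)
        h_inf = ah / (ah + bh)
        assert p_na[7] == pytest.approx(m_inf ** 3 * h_inf, rel=1e-12)


class TestChannelStep:
    def test_zero_rates_leave_state_unchanged(self):
        state = np.array([10.0, 5.0, 3.0, 1.0, 7.0, 2.0, 0.0, 4.0])
        err = _kernel.na_step(state.copy(), 0.0, 0.0, 0.0, 0.0, 1e-3, True)
        state2 = state.copy()
        _kernel.na_step(state2, 0.0, 0.0, 0.0, 0.0, 1e-3, True)
        assert err == 0
        np.testing.assert_array_equal(state2, state)

    def test_counts_conserved_and_nonnegative_over_many_steps(self, config):
        params = config.membrane
        na = np.zeros(8)
        k = np.zeros(5)
        na[0] = 302.0
        k[0] = 170.0
        _kernel.seed_rng(42)
        for step in range(2000):
            vm = params.v_rest_mV + 20.0 + 40.0 * math.sin(step / 150.0)
            channel_step(na, k, vm, params)
            assert na.sum() == 302.0
            assert k.sum() == 170.0
            assert np.all(na >= 0) and np.all(k >= 0)

    def test_oversized_step_rejected(self, config):
        na = np.zeros(8)
        k = np.zeros(5)
        na[0], k[0] = 100.0, 50.0
        with pytest.raises(ValueError):
            channel_step(na, k, config.membrane.v_rest_mV + 60.0,
                         config.membrane, dt_us=100.0)

    def test_mean_trajectory_converges_to_gating_ode(self, config):
        """Mean open count over many stochastic replicas follows the
        deterministic gating ODE (Euler oracle on m^3 h and n^4)."""
        params = config.membrane
        rc = pack_rate_coefficients(params)
        v_rel = 40.0
        n_na, n_k, n_steps, n_reps = 30, 30, 400, 1500
        dt = 1e-3
        mean_na, mean_k = _kernel.clamp_mean_open(
            n_na, n_k, v_rel, rc, dt, n_steps, n_reps, 7
        )
        am, bm, ah, bh, an, bn = _kernel.rates_at(v_rel, rc)
        m = h = n = 0.0
        ode_na = np.empty(n_steps)
        ode_k = np.empty(n_steps)
        for t in range(n_steps):
            m += dt * (am * (1 - m) - bm * m)
            h += dt * (ah * (1 - h) - bh * h)
            n += dt * (an * (1 - n) - bn * n)
            ode_na[t] = n_na * m ** 3 * h
            ode_k[t] = n_k * n ** 4
        # Monte-Carlo error of the mean ~ sqrt(N p q / reps) < 0.1 channels
        assert np.max(np.abs(mean_na - ode_na)) < 0.35
        assert np.max(np.abs(mean_k - ode_k)) < 0.35


class TestIonicCurrent:
    def test_zero_open_channels_zero_current(self, config):
        i_na, i_k = ionic_current(0, 0, -30.0, config.membrane)
        assert i_na == 0.0 and i_k == 0.0

    def test_single_open_na_channel_arithmetic(self, config):
        # 22.65 pS * (-100 mV) = -2.265 pA inward
        i_na, _ = ionic_current(1, 0, config.membrane.e_na_mV - 100.0, config.membrane)
        assert i_na == pytest.approx(-2.265e-3, rel=1e-12)   # nA

    def test_ten_open_k_channels_arithmetic(self, config):
        # 10 * 50 pS * (+50 mV) = +25 pA outward
        _, i_k = ionic_current(0, 10, config.membrane.e_k0_mV + 50.0, config.membrane)
        assert i_k == pytest.approx(25e-3, rel=1e-12)        # nA


class TestKAccumulation:
    def test_no_current_keeps_nernst_at_initial_value(self, config):
        ek = update_EK(np.zeros(500), config.membrane, node_area_um2=7.23)
        np.testing.assert_allclose(ek, config.membrane.e_k0_mV, atol=1e-9)

    def test_sustained_outward_current_raises_ek_monotonically(self, config):
        ek = update_EK(np.full(2000, 0.05), config.membrane, node_area_um2=7.23)
        assert np.all(np.diff(ek) > 0)
        assert ek[-1] > config.membrane.e_k0_mV

    def test_doubling_kext_shifts_ek_by_rt_over_f_ln2(self, config):
        """A charge pulse sized to double [K+]ext moves E_K by (RT/F) ln 2."""
        params = config.membrane
        from anfsim.membrane import _kacc_gain

        gain = _kacc_gain(7.23, params.k_accumulation.shell_thickness_um)
        i_needed = params.k_ext0_mM / (gain * 1e-3)     # nA for one 1-us step
        ek = update_EK(np.array([i_needed]), params, node_area_um2=7.23)
        shift = ek[0] - params.e_k0_mV * math.exp(-1e-3 / params.k_accumulation.tau_ms)
        expected = params.rt_over_f_mV * math.log(2.0)
        assert ek[0] - params.e_k0_mV == pytest.approx(expected, rel=1e-3)
        assert expected == pytest.approx(18.52, abs=0.02)

    def test_depleting_kext_raises_error(self, config):
        with pytest.raises(ValueError):
            update_EK(np.full(5000, -50.0), config.membrane, node_area_um2=7.23)


class TestCableSolver:
    def test_kernel_matches_reference_solver_on_passive_cable(self, config):
        """The compiled loop and the numpy Crank-Nicolson step agree on a
        channel-free cable under the same extracellular drive."""
        from anfsim.experiment import setup_for_electrode
        from anfsim.stimulus_field import field_at, make_waveform
        from dataclasses import replace

        params = MembraneParams(rho_na_per_um2=0.0, rho_k_per_um2=0.0)
        params.k_accumulation.enabled = False
        cable = build_fiber(config.morphology, params)
        cfg2 = replace(config, membrane=params)
        _, profile = setup_for_electrode(cfg2, "C")
        wf = make_waveform("single_pulse", 0.2, 40.0, duration=0.3, sample_step=1.0)
        sweep = run_sweep(cable, profile, wf, seed=0, mode="deterministic",
                          record_ina=False, record_vm=True)
        ve = field_at(profile, wf)
        vm = np.full(cable.n_comp, params.v_rest_mV)
        for t in range(ve.shape[1] - 1):
            vm = crank_nicolson_step(vm, ve[:, t], ve[:, t + 1],
                                     np.zeros(cable.n_comp), cable)
        np.testing.assert_allclose(
            vm[cable.active_idx], sweep.vm[:, -1], atol=2e-4
        )

    def test_uniform_field_produces_no_interior_response(self, cable, config):
        """Spatially uniform Ve has zero axial driving term: Vm stays at rest."""
        n = cable.n_comp
        vm = np.full(n, config.membrane.v_rest_mV)
        ve = np.full(n, -80.0)
        for _ in range(200):
            vm = crank_nicolson_step(vm, ve, ve, np.zeros(n), cable)
        np.testing.assert_allclose(vm, config.membrane.v_rest_mV, atol=1e-9)


def _zero_profile(cable):
    from anfsim.config import ElectrodeConfig
    from anfsim.stimulus_field import FieldProfile

    return FieldProfile(
        ElectrodeConfig("X", (0.0, -50.0)),
        np.full(cable.n_comp, 1e-6),
        np.full(cable.n_comp, 50.0),
        ["scala_tympani"] * cable.n_comp,
    )


class TestRunSweep:
    def test_zero_amplitude_keeps_membrane_at_rest(self, cable, single_pulse_waveform):
        sweep = run_sweep(cable, _zero_profile(cable),
                          single_pulse_waveform.scaled(0.0), seed=5, record_vm=True)
        assert not sweep.spiked
        assert np.max(np.abs(sweep.vm - cable.params.v_rest_mV)) < 1.0

    def test_same_seed_is_bit_identical(self, electrode_setups, single_pulse_waveform):
        cable, profile = electrode_setups["C"]
        a = run_sweep(cable, profile, single_pulse_waveform.scaled(0.9), seed=123,
                      record_vm=True)
        b = run_sweep(cable, profile, single_pulse_waveform.scaled(0.9), seed=123,
                      record_vm=True)
        np.testing.assert_array_equal(a.spike_times_c16, b.spike_times_c16)
        np.testing.assert_array_equal(a.vm, b.vm)
        np.testing.assert_array_equal(a.first_spike_ms, b.first_spike_ms)

    def test_suprathreshold_pulse_gives_one_spike_and_level_shortens_latency(
        self, electrode_setups, single_pulse_waveform
    ):
        cable, profile = electrode_setups["C"]
        lat = {}
        for mult in (1.3, 2.0):
            sweep = run_sweep(cable, profile, single_pulse_waveform.scaled(mult),
                              seed=0, mode="deterministic")
            assert sweep.spike_times_c16.size == 1
            assert sweep.spike_times_c16[0] < 2.0
            lat[mult] = sweep.latency_ms
        assert lat[2.0] < lat[1.3]

    def test_resting_stability_no_spontaneous_spikes(self, cable):
        """Channel noise alone must not fire the fiber over long sweeps."""
        from anfsim.stimulus_field import make_waveform

        wf = make_waveform("single_pulse", 0.0, 40.0, duration=200.0)
        sweeps = run_sweeps(cable, _zero_profile(cable), wf, 30, seeds=99,
                            record_ina=False)
        assert sum(s.spiked for s in sweeps) == 0

    def test_spike_propagates_in_both_directions_from_initiation(
        self, cable, single_pulse_waveform
    ):
        """A spike started at one interior node travels antidromically and
        orthodromically, with arrival time increasing away from the source."""
        from anfsim.config import ElectrodeConfig
        from anfsim.stimulus_field import FieldProfile

        # localized field: one strongly coupled compartment at node C5
        g_c5 = cable.active_idx[cable.active_labels.index("C5")]
        transfer = np.full(cable.n_comp, 1.0)
        transfer[g_c5] = 2000.0
        profile = FieldProfile(
            ElectrodeConfig("X", (0.0, -1.0)), transfer,
            np.full(cable.n_comp, 1.0), ["modiolus"] * cable.n_comp,
        )
        sweep = run_sweep(cable, profile, single_pulse_waveform.scaled(0.08),
                          seed=3, mode="deterministic", record_ina=True)
        assert sweep.spiked
        init = sweep.node_labels.index(sweep.initiation_node)
        assert sweep.node_labels[init] in ("C4", "C5", "C6")
        times = sweep.first_spike_ms
        central_side = times[init:][np.isfinite(times[init:])]
        peripheral_side = times[:init + 1][np.isfinite(times[:init + 1])][::-1]
        assert central_side.size >= 10 and peripheral_side.size >= 5
        assert np.all(np.diff(central_side) > 0)
        assert np.all(np.diff(peripheral_side) > 0)

    def test_na_influx_onset_of_initiation_node_is_earliest(
        self, electrode_setups, single_pulse_waveform
    ):
        cable, profile = electrode_setups["B"]
        sweep = run_sweep(cable, profile, single_pulse_waveform.scaled(1.5),
                          seed=11, record_ina=True)
        if not sweep.spiked:
            pytest.skip("non-spiking sweep at this seed/level")
        onsets = sweep.na_onset_ms
        init = sweep.node_labels.index(sweep.initiation_node)
        assert onsets[init] == np.nanmin(onsets)


class TestNaInfluxOnsets:
    def test_constructed_traces_pick_first_crossing_node(self):
        labels = ["P1", "P2", "P3", "C1"]
        ina = np.zeros((4, 100), dtype=np.float32)
        ina[2, 20:60] = -1.0        # P3 crosses first
        ina[3, 40:80] = -1.2
        ina[0, 70:90] = -0.9
        onsets, node = na_influx_onsets(ina, 1e-3, labels, 0.25)
        assert node == "P3"
        assert onsets[2] == pytest.approx(0.020, abs=1e-9)

    def test_tie_breaks_toward_peripheral_end(self):
        labels = ["P1", "P2"]
        ina = np.zeros((2, 50), dtype=np.float32)
        ina[0, 10:20] = -1.0
        ina[1, 10:20] = -1.0
        _, node = na_influx_onsets(ina, 1e-3, labels, 0.25)
        assert node == "P1"

    def test_no_spike_returns_no_node(self):
        onsets, node = na_influx_onsets(
            np.zeros((3, 50), dtype=np.float32), 1e-3, ["P1", "P2", "P3"]
        )
        assert node is None
        assert np.all(np.isnan(onsets))
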