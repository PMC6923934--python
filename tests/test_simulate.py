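"""Simulator tests: protocol construction, sweep composition against the
closed forms, determinism, presets, and CT-table generation."""

import math

import numpy as np
import pytest

import tevckit as tk


class TestBuildProtocol:
    def test_standard_protocol(self):
        # -140..+20 mV inclusive in 20 mV increments is 9 step potentials
        # (the usual prose description counts them as "10 pulses")
        proto = tk.build_protocol(-60, -140, 20, 20, 700, 1000)
        assert proto.steps == tuple(float(v) for v in range(-140, 21, 20))
        assert len(proto.steps) == 9
        assert proto.n_pulse == 700
        assert proto.V_h == -60

    def test_single_step(self):
        proto = tk.build_protocol(-60, -100, -100, 20, 700, 1000)
        assert proto.steps == (-100.0,)

    def test_increment_40(self):
        proto = tk.build_protocol(-60, -140, 20, 40, 700, 1000)
        assert len(proto.steps) == 5

    def test_non_integral_step_count_rejected(self):
        with pytest.raises(ValueError):
            tk.build_protocol(-60, -140, 20, 30, 700, 1000)

    def test_sample_count_rounds_half_up(self):
        proto = tk.VoltageStepProtocol(V_h=-60, steps=(-100.0,),
                                       pre_ms=0.5, pulse_ms=700,
                                       post_ms=0.4, sample_rate=1000)
        assert proto.n_pre == 1
        assert proto.n_post == 0


class TestSimulateSweep:
    def test_all_zero_when_everything_off(self):
        proto = tk.paper_protocol()
        cell = tk.CellParams(C_m=0.0, g_leak=0.0)
        ts = tk.simulate_sweep(proto, cell, None, None, S=0.0, noise_sd=0.0)
        assert np.all(ts.sweeps == 0.0)

    def test_transient_integral_equals_dq(self, cell, pept1a_charge):
        # 50 kHz so the trapezoid quadrature error stays below 0.1%
        proto = tk.paper_protocol(sample_rate=50000.0)
        no_cap = tk.CellParams(C_m=0.0, tau_cap=cell.tau_cap,
                               g_leak=0.0, E_leak=0.0)
        ts = tk.simulate_sweep(proto, no_cap, pept1a_charge, None, S=0.0)
        t = ts.time_ms
        i0 = proto.n_pre
        i1 = proto.n_pre + proto.n_pulse
        for k, V in enumerate(proto.steps):
            dq = tk.boltzmann_charge(V, pept1a_charge) - tk.boltzmann_charge(
                proto.V_h, pept1a_charge)
            if dq == 0:
                continue
            # nA * ms -> 1e-3 nC
            q_num = np.trapezoid(ts.sweeps[k, i0:i1], t[i0:i1]) * 1e-3
            assert q_num == pytest.approx(dq, rel=1e-3)

    def test_steady_window_is_leak_plus_transport(self, cell, presets):
        transport, charge = presets["zfPepT1a_pH6.5"]
        proto = tk.paper_protocol(sample_rate=10000.0)
        ts = tk.simulate_sweep(proto, cell, charge, transport, S=3.0)
        pts = tk.steady_state_current(ts, window_ms=100.0)
        for p in pts:
            leak = cell.g_leak * (p.V - cell.E_leak)
            i_tr = tk.dose_response_current(3.0, transport.model_at(p.V))
            assert p.I == pytest.approx(leak + i_tr, rel=1e-6, abs=1e-6)

    def test_determinism_under_seed(self, cell, presets, protocol_10k):
        transport, charge = presets["zfPepT1a_pH6.5"]
        a = tk.simulate_sweep(protocol_10k, cell, charge, transport, S=1.0,
                              noise_sd=5.0, seed=123)
        b = tk.simulate_sweep(protocol_10k, cell, charge, transport, S=1.0,
                              noise_sd=5.0, seed=123)
        assert np.array_equal(a.sweeps, b.sweeps)
        c = tk.simulate_sweep(protocol_10k, cell, charge, transport, S=1.0,
                              noise_sd=5.0, seed=124)
        assert not np.array_equal(a.sweeps, c.sweeps)

    def test_charge_conservation_on_off(self, noiseless_pss_traces,
                                        protocol_10k, pept1a_charge):
        proto = protocol_10k
        t = noiseless_pss_traces.time_ms
        i0, i1 = proto.n_pre, proto.n_pre + proto.n_pulse
        for k, V in enumerate(proto.steps):
            if V == proto.V_h:
                continue
            y = noiseless_pss_traces.sweeps[k].copy()
            # remove leak + capacitive analytically
            cellp = tk.CellParams()
            v = proto.voltage_trace(V)
            y -= cellp.g_leak * (v - cellp.E_leak)
            for j0, dV in ((i0, V - proto.V_h), (i1, proto.V_h - V)):
                tail = t[j0:] - t[j0]
                y[j0:] -= cellp.C_m * dV / cellp.tau_cap * np.exp(
                    -tail / cellp.tau_cap)
            q_on = np.trapezoid(y[i0:i1], t[i0:i1]) * 1e-3
            q_off = np.trapezoid(y[i1:], t[i1:]) * 1e-3
            assert abs(q_on + q_off) <= 0.005 * abs(q_on)

    def test_sodium_free_flag_is_metadata_only(self, cell, presets,
                                               protocol_10k):
        transport, charge = presets["zfPepT1a_pH6.5"]
        from dataclasses import replace
        na_free = replace(transport, sodium_free=True)
        a = tk.simulate_sweep(protocol_10k, cell, charge, transport, S=1.0,
                              noise_sd=0.0, seed=5)
        b = tk.simulate_sweep(protocol_10k, cell, charge, na_free, S=1.0,
                              noise_sd=0.0, seed=5)
        assert np.array_equal(a.sweeps, b.sweeps)
        assert b.metadata["sodium_free"] is True

    def test_unresolvable_tau_warns(self, cell):
        proto = tk.paper_protocol(sample_rate=100.0)  # dt = 10 ms
        charge = tk.ChargeMovementParams(41, -57.6, 33.6, tau_peak=8.0)
        with pytest.warns(UserWarning):
            tk.simulate_sweep(proto, tk.CellParams(C_m=0.0), charge, None)

    def test_negative_substrate_rejected(self, cell, protocol_10k):
        with pytest.raises(ValueError):
            tk.simulate_sweep(protocol_10k, cell, None, None, S=-1.0)


class TestSimulateExperiment:
    def test_zero_cv_gives_identical_oocytes(self, cell, presets):
        transport, charge = presets["zfPepT1a_pH6.5"]
        proto = tk.paper_protocol(sample_rate=2000.0)
        pairs = tk.simulate_experiment(proto, cell, charge, transport, S=1.0,
                                       n_oocytes=3, expression_scatter_cv=0.0,
                                       noise_sd=0.0, seed=1)
        base = pairs[0][0].sweeps
        for with_sub, _ in pairs[1:]:
            assert np.array_equal(with_sub.sweeps, base)

    def test_scatter_scales_charge_and_transport_together(self, presets):
        transport, charge = presets["zfPepT1a_pH6.5"]
        proto = tk.paper_protocol(sample_rate=2000.0)
        cell = tk.CellParams(C_m=0.0, g_leak=0.0)
        pairs = tk.simulate_experiment(proto, cell, charge, transport, S=100.0,
                                       n_oocytes=4, expression_scatter_cv=0.5,
                                       noise_sd=0.0, seed=9)
        i_end = proto.n_pre + proto.n_pulse
        for with_sub, without in pairs:
            f = with_sub.metadata["expression_factor"]
            # steady transport current at saturating S ~ f * I_max(V)
            k = proto.steps.index(-120.0)
            steady = with_sub.sweeps[k, i_end - 50:i_end].mean()
            expect = f * tk.dose_response_current(
                100.0, transport.model_at(-120.0))
            assert steady == pytest.approx(expect, rel=1e-6)
            # pss transient charge scales by the same factor
            t = without.time_ms
            q_on = np.trapezoid(without.sweeps[k, proto.n_pre:i_end],
                                t[proto.n_pre:i_end]) * 1e-3
            dq = tk.boltzmann_charge(-120.0, charge) - tk.boltzmann_charge(
                proto.V_h, charge)
            assert q_on == pytest.approx(f * dq, rel=1e-2)

    def test_mean_fitted_imax_near_truth(self, presets):
        transport, _ = presets["zfPepT1a_pH6.5"]
        df = tk.simulate_dose_response(
            transport, V=-60.0, concentrations=[0.01, 0.03, 0.1, 0.3, 1, 3, 10],
            n_oocytes=50, noise_cv=0.05, expression_scatter_cv=0.1, seed=11)
        fits = tk.fit_dose_response_frame(df)
        imaxs = np.array([f.I_max for f in fits])
        sem = imaxs.std(ddof=1) / np.sqrt(imaxs.size)
        # lognormal mean exceeds the median-1 truth by exp(sigma^2/2) ~ 0.5%
        assert abs(imaxs.mean() - (-75.76)) <= 2 * sem + 0.01 * 75.76


class TestScenarioPresets:
    def test_required_labels_present(self, presets):
        for label in ("zfPepT1a_pH6.5", "zfPepT1a_pH7.6",
                      "zfPepT1b_pH6.5", "zfPepT1b_pH7.6"):
            assert label in presets

    def test_pept1a_ph65_anchors(self, presets):
        transport, charge = presets["zfPepT1a_pH6.5"]
        assert transport.K_half(-60.0) == pytest.approx(0.24)
        assert transport.K_half(-120.0) == pytest.approx(0.45)
        assert transport.I_max(-60.0) == pytest.approx(-75.76)
        assert transport.I_max(-120.0) == pytest.approx(-157.39)
        assert charge.Q_max == 41.0
        assert charge.V_half == -57.6
        assert charge.sigma == 33.6

    def test_pept1a_ph76_charge(self, presets):
        _, charge = presets["zfPepT1a_pH7.6"]
        assert charge.V_half == -110.0
        assert charge.Q_max == 53.0

    def test_pept1b_scenarios_inward_current_comparison(self, presets):
        # asserted from scenario anchor values, not hard-coded biology
        b65, _ = presets["zfPepT1b_pH6.5"]
        b76, _ = presets["zfPepT1b_pH7.6"]
        i65 = abs(b65.current(-60.0, 1.0))
        i76 = abs(b76.current(-60.0, 1.0))
        anchors_imply = abs(b76.I_max(-60) / (1 + b76.K_half(-60))) > abs(
            b65.I_max(-60) / (1 + b65.K_half(-60)))
        assert (i76 > i65) == anchors_imply


class TestCTGeneration:
    def test_noiseless_recovery_is_exact(self):
        scen = tk.fig7a_ct_scenario(ct_noise_sd=0.0)
        table = tk.generate_ct_table(scen, seed=0)
        expr = tk.expression_2dct(table, "slc15a1a", "28S")
        for stage, truth in scen.expression["slc15a1a"].items():
            assert expr.stage_mean(stage) == pytest.approx(truth, rel=1e-12)

    def test_halving_ratio_raises_ct_by_one(self):
        expr = {"g": {"s1": 0.04, "s2": 0.02}}
        scen = tk.CTScenario(expression=expr, ct_noise_sd=0.0)
        table = tk.generate_ct_table(scen, seed=0)
        g = table[table.gene == "g"]
        ct1 = g[g.stage == "s1"].ct.mean()
        ct2 = g[g.stage == "s2"].ct.mean()
        assert ct2 - ct1 == pytest.approx(1.0)

    def test_fig7a_fold_changes_encoded(self):
        scen = tk.fig7a_ct_scenario()
        levels = scen.expression["slc15a1a"]
        base = levels["1dpf"]
        expected = {"1dpf": 1.0, "2dpf": 1.0, "3dpf": 0.61, "4dpf": 2.00,
                    "5dpf": 2.66, "6dpf": 6.73, "7dpf": 1.81}
        for stage, fc in expected.items():
            assert levels[stage] / base == pytest.approx(fc)

    def test_determinism(self):
        scen = tk.fig7a_ct_scenario()
        a = tk.generate_ct_table(scen, seed=3)
        b = tk.generate_ct_table(scen, seed=3)
        assert a.equals(b)

    def test_replicate_round_structure(self):
        scen = tk.fig7a_ct_scenario(replicates=3, rounds=2)
        table = tk.generate_ct_table(scen, seed=0)
        counts = table.groupby(["gene", "stage"]).size()
        assert (counts == 6).all()

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            tk.CTScenario(expression={"g": {"s": -1.0}})
        with pytest.raises(ValueError):
            tk.CTScenario(expression={"g": {"s": 1.0}}, replicates=0)
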