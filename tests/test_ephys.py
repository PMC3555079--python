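"""P/4 subtraction, passive-parameter estimation, Ra-corrected conductance
and Boltzmann activation fitting."""

import numpy as np
import pytest
from scipy import constants

from b2mq import ephys
from b2mq.synthetic import VcCellSpec, m_inf, simulate_vc, steady_state_vm
from b2mq.types import (
    ActivationFit,
    ConductanceCurve,
    PassiveParams,
    VoltageProtocol,
)


class TestP4Subtract:
    def test_linear_cell_nulls_to_noise_floor(self):
        spec = VcCellSpec(Gmax_nS=0.0, noise_sigma=0.03, seed=31)
        sweeps = simulate_vc(spec)
        corrected = ephys.p4_subtract(sweeps)
        proto = sweeps.protocol
        late = sweeps.time_ms > proto.pre_ms + 5.0
        late &= sweeps.time_ms < proto.pre_ms + proto.pulse_ms
        for v in (40.0, 0.0):
            dv = v - proto.holding_mV
            i_lin = dv / (spec.Ra_MOhm * 1e-3 + spec.Rm_GOhm)
            floor = 0.03 * abs(i_lin) * np.sqrt(1 + 0.25)
            assert np.sqrt(np.mean(corrected[v][late] ** 2)) <= 1.2 * floor

    def test_known_sodium_current_recovered(self, vc_noisy_sweeps):
        sweeps, spec = vc_noisy_sweeps
        corrected = ephys.p4_subtract(sweeps)
        late = (sweeps.time_ms > 10) & (sweeps.time_ms < 60)
        vm = steady_state_vm(spec, 0.0, -90.0)
        i_na = spec.Gmax_nS * m_inf(vm, spec.V_half_mV, spec.slope_mV) \
            * (vm - spec.E_rev_mV)
        assert np.mean(corrected[0.0][late]) == pytest.approx(i_na, rel=0.05)

    def test_amplitude_mismatch_raises(self, vc_noisy_sweeps):
        sweeps, _ = vc_noisy_sweeps
        tampered = dict(sweeps.sub_amplitude_mV)
        tampered[40.0] *= 1.1
        bad = type(sweeps)(time_ms=sweeps.time_ms, protocol=sweeps.protocol,
                           test=sweeps.test, subs=sweeps.subs,
                           sub_amplitude_mV=tampered)
        with pytest.raises(ValueError, match="amplitude"):
            ephys.p4_subtract(bad)

    def test_missing_subpulses_raise(self, vc_noisy_sweeps):
        sweeps, _ = vc_noisy_sweeps
        subs = {v: s for v, s in sweeps.subs.items() if v != 40.0}
        bad = type(sweeps)(time_ms=sweeps.time_ms, protocol=sweeps.protocol,
                           test=sweeps.test, subs=subs,
                           sub_amplitude_mV=sweeps.sub_amplitude_mV)
        with pytest.raises(ValueError, match="subpulses"):
            ephys.p4_subtract(bad)


class TestEstimatePassive:
    def _passive(self, spec, v=40.0):
        sweeps = simulate_vc(spec, VoltageProtocol(test_voltages_mV=(-80.0, v)))
        return ephys.estimate_passive(
            sweeps.subs[v].mean(axis=0), sweeps.sub_amplitude_mV[v],
            sweeps.time_ms, sweeps.protocol.pre_ms)

    def test_noiseless_recovery_within_one_percent(self):
        spec = VcCellSpec(Gmax_nS=0.0, Ra_MOhm=10.0, Cm_pF=10.0, Rm_GOhm=1.0,
                          noise_sigma=0.0)
        p = self._passive(spec)
        assert p.Ra_MOhm == pytest.approx(10.0, rel=0.01)
        assert p.Cm_pF == pytest.approx(10.0, rel=0.01)
        assert p.Rm_GOhm == pytest.approx(1.0, rel=0.01)

    def test_tau_proportional_to_capacitance(self):
        spec1 = VcCellSpec(Gmax_nS=0.0, Cm_pF=8.0, noise_sigma=0.0)
        spec2 = VcCellSpec(Gmax_nS=0.0, Cm_pF=16.0, noise_sigma=0.0)
        assert self._passive(spec2).tau_ms == pytest.approx(
            2.0 * self._passive(spec1).tau_ms, rel=0.01)

    def test_capacitance_under_noise(self):
        """Median Cm over seeded noisy cells stays within 5% of truth."""
        errs = []
        for seed in range(100):
            spec = VcCellSpec(Gmax_nS=0.0, Cm_pF=10.0, noise_sigma=0.05, seed=seed)
            errs.append(self._passive(spec).Cm_pF / 10.0 - 1.0)
        assert abs(np.median(errs)) < 0.05

    def test_no_transient_raises(self):
        t = np.arange(0, 10, 0.01)
        flat = np.full_like(t, 30.0)
        with pytest.raises(ValueError, match="transient"):
            ephys.estimate_passive(flat, 30.0, t, 0.0)


class TestPeakCurrent:
    def test_pure_inward_transient(self):
        t = np.arange(0, 64, 0.01)
        trace = np.zeros_like(t)
        trace[(t > 10) & (t < 20)] = -500.0
        peak = ephys.peak_current(trace, t, (2.0, 62.0), tau_ms=0.1)
        assert peak == pytest.approx(-500.0)

    def test_gmax_zero_peak_within_noise(self):
        spec = VcCellSpec(Gmax_nS=0.0, noise_sigma=0.03, seed=8)
        sweeps = simulate_vc(spec)
        corrected = ephys.p4_subtract(sweeps)
        peak = ephys.peak_current(corrected[40.0], sweeps.time_ms,
                                  sweeps.pulse_window_ms, tau_ms=0.1,
                                  exclude_tau_factor=6.0)
        dv = 130.0
        noise_sd = 0.03 * dv / (spec.Ra_MOhm * 1e-3 + spec.Rm_GOhm) * np.sqrt(1.25)
        assert abs(peak) < 3.0 * noise_sd

    def test_closed_form_without_series_resistance(self):
        spec = VcCellSpec(Gmax_nS=15.0, Ra_MOhm=0.0, noise_sigma=0.0, seed=1)
        sweeps = simulate_vc(spec)
        corrected = ephys.p4_subtract(sweeps)
        peak = ephys.peak_current(corrected[10.0], sweeps.time_ms,
                                  sweeps.pulse_window_ms, tau_ms=0.01)
        expected = 15.0 * m_inf(10.0, spec.V_half_mV, spec.slope_mV) * (10.0 - 65.0)
        assert peak == pytest.approx(expected, rel=0.005)

    def test_empty_window_raises(self):
        t = np.arange(0, 1, 0.01)
        with pytest.raises(ValueError, match="window"):
            ephys.peak_current(np.zeros_like(t), t, (2.0, 2.1), tau_ms=5.0)


class TestConductanceCurve:
    def test_no_series_resistance_keeps_command_voltage(self):
        proto = VoltageProtocol()
        peaks = {v: -10.0 for v in proto.test_voltages_mV}
        curve = ephys.conductance_curve(peaks, proto, ra_MOhm=0.0, e_rev_mV=65.0)
        np.testing.assert_allclose(curve.vm_mV, curve.vcmd_mV)

    def test_zero_peak_zero_conductance(self):
        proto = VoltageProtocol()
        peaks = {v: 0.0 for v in proto.test_voltages_mV}
        peaks[40.0] = -100.0  # non-zero anchor
        curve = ephys.conductance_curve(peaks, proto, ra_MOhm=0.0, e_rev_mV=65.0)
        assert curve.g_nS[curve.vcmd_mV == -80.0][0] == 0.0

    def test_recovers_generating_activation_curve(self, vc_clean_sweeps):
        """Analyzed with the fitted Ra, the normalized conductance matches
        the generating m_inf at every retained voltage to <1%."""
        sweeps, spec = vc_clean_sweeps
        res = ephys.analyze_cell(sweeps, e_rev_mV=spec.E_rev_mV)
        curve = res.curve
        m = m_inf(curve.vm_mV, spec.V_half_mV, spec.slope_mV)
        m_norm = m / m[curve.anchor_index]
        keep = curve.retained
        assert np.max(np.abs(curve.g_norm[keep] - m_norm[keep])) < 0.01

    def test_all_points_excluded_raises(self):
        proto = VoltageProtocol(test_voltages_mV=(-5.0, 0.0))
        with pytest.raises(ValueError, match="excluded"):
            ephys.conductance_curve({-5.0: -1.0, 0.0: -1.0}, proto,
                                    ra_MOhm=0.0, e_rev_mV=-2.0)


class TestEstimateErev:
    def test_recovered_within_two_millivolts(self):
        proto = VoltageProtocol(test_voltages_mV=tuple(range(-80, 85, 5)))
        spec = VcCellSpec(E_rev_mV=65.0, Gmax_nS=15.0, seed=3)
        sweeps = simulate_vc(spec, proto)
        res_p = ephys.estimate_passive(
            sweeps.subs[80.0].mean(axis=0), sweeps.sub_amplitude_mV[80.0],
            sweeps.time_ms, proto.pre_ms)
        corrected = ephys.p4_subtract(sweeps)
        peaks = {v: ephys.peak_current(tr, sweeps.time_ms, sweeps.pulse_window_ms,
                                       res_p.tau_ms, exclude_tau_factor=6.0)
                 for v, tr in corrected.items()}
        erev = ephys.estimate_erev(list(peaks), [peaks[v] for v in peaks])
        assert erev == pytest.approx(65.0, abs=2.0)

    def test_monotone_negative_iv_raises(self):
        with pytest.raises(ValueError, match="cross"):
            ephys.estimate_erev([-20, 0, 20], [-100.0, -300.0, -200.0])

    def test_exact_grid_zero_returned(self):
        assert ephys.estimate_erev([0, 20, 40], [-100.0, -50.0, 0.0]) == 40.0


class TestBoltzmannFit:
    def _curve_from_model(self, v_half, s, voltages=None):
        vm = np.asarray(voltages if voltages is not None
                        else np.arange(-80.0, 45.0, 5.0))
        g = 1.0 / (1.0 + np.exp((v_half - vm) / s))
        g_norm = g / g[-1]
        return ConductanceCurve(
            vcmd_mV=vm, i_peak_pA=-g, vm_mV=vm, g_nS=g, g_norm=g_norm,
            retained=np.ones_like(vm, dtype=bool), e_rev_mV=65.0,
            anchor_index=len(vm) - 1)

    def test_noiseless_recovery(self):
        fit = ephys.boltzmann_fit(self._curve_from_model(-20.0, 6.0))
        assert fit.v_half_mV == pytest.approx(-20.0, abs=0.01)
        assert fit.slope_mV == pytest.approx(6.0, abs=0.01)

    def test_half_activation_at_v_half(self):
        fit = ephys.boltzmann_fit(self._curve_from_model(-20.0, 6.0))
        value = 1.0 / (1.0 + np.exp((fit.v_half_mV - fit.v_half_mV) / fit.slope_mV))
        assert value == pytest.approx(0.5)

    def test_gating_charge_from_thermal_voltage(self):
        """s = 6.29 mV/e-fold at 295 K maps to ~4.04 elementary charges."""
        kt_over_e = constants.k * 295.0 / constants.e * 1e3  # mV
        fit = ephys.boltzmann_fit(self._curve_from_model(-18.56, 6.29),
                                  temperature_K=295.0)
        assert fit.q_gating == pytest.approx(kt_over_e / fit.slope_mV, rel=1e-9)
        assert fit.q_gating == pytest.approx(4.04, abs=0.01)

    def test_charge_slope_product_is_constant(self):
        fits = [ephys.boltzmann_fit(self._curve_from_model(-25.0, s))
                for s in (4.0, 6.0, 9.0)]
        products = [f.q_gating * f.slope_mV for f in fits]
        np.testing.assert_allclose(products, products[0], rtol=1e-9)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="6"):
            ephys.boltzmann_fit(self._curve_from_model(-20.0, 6.0,
                                                       voltages=[-30, -20, -10, 0]))


class TestSpecificConductance:
    def test_arithmetic(self):
        assert ephys.specific_conductance(14.0, 10.0) == pytest.approx(1.4)
        assert ephys.specific_conductance(0.0, 10.0) == 0.0

    def test_pipeline_recovers_target_specific_conductance(self):
        """A cell built at 1.39 nS/pF comes out of the full pipeline
        within 5%."""
        spec = VcCellSpec(Gmax_nS=1.39 * 12.0, Cm_pF=12.0, Ra_MOhm=8.0, seed=17)
        res = ephys.analyze_cell(simulate_vc(spec), e_rev_mV=spec.E_rev_mV)
        assert res.specific_nS_per_pF == pytest.approx(1.39, rel=0.05)

    def test_zero_capacitance_rejected(self):
        with pytest.raises(ValueError):
            ephys.specific_conductance(10.0, 0.0)


def _cell(cell_id, ra, slope=6.0):
    passive = PassiveParams(Ra_MOhm=ra, Rm_GOhm=1.0, Cm_pF=10.0, tau_ms=0.1,
                            fit_residual_rms=0.0)
    vm = np.arange(-80.0, 45.0, 5.0)
    g_norm = 1.0 / (1.0 + np.exp((-20.0 - vm) / slope))
    curve = ConductanceCurve(vcmd_mV=vm, i_peak_pA=-g_norm, vm_mV=vm,
                             g_nS=g_norm, g_norm=g_norm / g_norm[-1],
                             retained=np.ones_like(vm, dtype=bool),
                             e_rev_mV=65.0, anchor_index=len(vm) - 1)
    fit = ActivationFit(v_half_mV=-20.0, slope_mV=slope,
                        q_gating=ephys.thermal_voltage_mV() / slope,
                        gmax_nS=10.0, se_v_half_mV=0.1, se_slope_mV=0.1,
                        temperature_K=295.0, converged=True)
    return ephys.CellResult(cell_id=cell_id, passive=passive, curve=curve,
                            fit=fit, specific_nS_per_pF=1.0)


class TestQcFilter:
    def test_ra_above_threshold_excluded(self):
        retained, log = ephys.qc_filter([_cell("a", 16.0)])
        assert retained == []
        assert log == [("a", "Ra>15")]

    def test_ra_at_threshold_retained(self):
        retained, log = ephys.qc_filter([_cell("a", 15.0)])
        assert len(retained) == 1 and log == []

    def test_clean_cells_empty_log(self):
        retained, log = ephys.qc_filter([_cell("a", 8.0), _cell("b", 12.0)])
        assert len(retained) == 2 and log == []

    def test_space_clamp_slope_flagged(self):
        retained, log = ephys.qc_filter([_cell("a", 8.0, slope=2.0)])
        assert retained == [] and "space-clamp" in log[0][1]


class TestFullPipelineRecovery:
    def test_parameter_bias_over_population(self):
        """Over 100 seeded cells (Ra 5-12 MOhm, 3% noise) the mean fitted
        half-activation bias stays below 0.3 mV and the slope bias below
        0.2 mV/e-fold."""
        rng = np.random.default_rng(99)
        vhs, slopes = [], []
        for i in range(100):
            spec = VcCellSpec(
                V_half_mV=-18.56, slope_mV=6.29,
                Gmax_nS=float(rng.uniform(5, 25)),
                Ra_MOhm=float(rng.uniform(5, 12)),
                Cm_pF=float(rng.uniform(8, 15)), seed=5000 + i)
            res = ephys.analyze_cell(simulate_vc(spec), e_rev_mV=65.0)
            vhs.append(res.fit.v_half_mV)
            slopes.append(res.fit.slope_mV)
        assert abs(np.mean(vhs) + 18.56) < 0.3
        assert abs(np.mean(slopes) - 6.29) < 0.2
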