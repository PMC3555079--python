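"""Whole-cell voltage-clamp analysis.

The stage chain for one cell:

1. :func:`p4_subtract` — remove linear (leak + capacitive) components using
   the P/4 subpulses.
2. :func:`estimate_passive` — access resistance Ra, membrane resistance Rm
   and capacitance Cm from an exponential fit of the P/4 RC transient.
3. :func:`peak_current` — inward peak per corrected sweep, excluding the
   first 2*tau after pulse onset.
4. :func:`conductance_curve` — access-resistance-corrected membrane voltage
   Vm = Vcmd - I_peak*Ra and conductance G = I_peak/(Vm - E_rev), normalized
   to the value at the highest retained depolarizing voltage.
5. :func:`boltzmann_fit` — least-squares Boltzmann activation fit
   G_M/G_0 = 1/(1+exp((V_half - Vm)/s)), with the gating charge derived as
   q_g = (k_B T / e) / s.
6. :func:`qc_filter` — discard cells with Ra > 15 MOhm or space-clamp
   suspicion.

Sign convention: inward current negative, conductance positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .types import (
    ActivationFit,
    ConductanceCurve,
    PassiveParams,
    SweepSet,
    VoltageProtocol,
)

#: Boltzmann constant over elementary charge, in mV/K
KB_OVER_E_MV_PER_K = 1.380649e-23 / 1.602176634e-19 * 1e3
#: default bath temperature
DEFAULT_TEMP_K = 295.0
#: cells with access resistance above this are discarded
RA_MAX_MOHM = 15.0
#: points closer than this to the reversal potential are excluded from G
EREV_EXCLUSION_MV = 5.0


def thermal_voltage_mV(temperature_K: float = DEFAULT_TEMP_K) -> float:
    """k_B T / e in millivolts."""
    return KB_OVER_E_MV_PER_K * temperature_K


def p4_subtract(sweeps: SweepSet, amplitude_tol: float = 0.01) -> dict:
    """Leak/capacitance-corrected traces: test - polarity*4*mean(subpulses).

    For a purely linear (passive) cell the corrected trace is ~0 everywhere.
    Raises when subpulses are missing or their amplitude deviates from a
    quarter of the test amplitude by more than ``amplitude_tol`` (relative).
    """
    proto = sweeps.protocol
    corrected = {}
    for v, test in sweeps.test.items():
        if v not in sweeps.subs or len(sweeps.subs[v]) == 0:
            raise ValueError(f"missing P/4 subpulses for test voltage {v} mV")
        dv_test = v - proto.holding_mV
        dv_sub = sweeps.sub_amplitude_mV[v]
        expected = proto.p4_polarity * proto.p4_fraction * dv_test
        if abs(dv_test) > 0 and abs(dv_sub - expected) > amplitude_tol * abs(expected):
            raise ValueError(
                f"subpulse amplitude {dv_sub:.3f} mV is not {expected:.3f} mV "
                f"(test step {dv_test:.1f} mV) at {v} mV")
        scale = dv_test / (proto.p4_count * dv_sub)  # = polarity for exact P/4
        corrected[v] = test - scale * proto.p4_count * sweeps.subs[v].mean(axis=0)
    return corrected


def estimate_passive(sub_trace: np.ndarray, dv_mV: float, time_ms: np.ndarray,
                     pulse_start_ms: float, fit_window_ms: float = 5.0,
                     min_transient_ratio: float = 5.0) -> PassiveParams:
    """Passive parameters from one (averaged) subpulse trace.

    Fits I(t) = I0*exp(-t/tau) + Iss over ``fit_window_ms`` after pulse
    onset, then Ra = dV/I(0) (instantaneous capacitive jump),
    Rm = dV/Iss - Ra and Cm = tau * (Ra + Rm)/(Ra*Rm).
    """
    dt = time_ms[1] - time_ms[0]
    sel = (time_ms >= pulse_start_ms) & (time_ms < pulse_start_ms + fit_window_ms)
    t = time_ms[sel] - pulse_start_ms
    y = np.asarray(sub_trace)[sel]
    if t.size < 8:
        raise ValueError("too few samples in the fit window")

    i_ss0 = float(y[int(0.8 * y.size):].mean())
    i00 = float(y[0] - i_ss0)
    if abs(y[0]) < min_transient_ratio * abs(i_ss0):
        raise ValueError("no decaying transient: peak below "
                         f"{min_transient_ratio}x the steady-state current")
    # crude tau from where the transient has decayed to 1/e
    decayed = np.flatnonzero(np.abs(y - i_ss0) < abs(i00) / np.e)
    tau0 = max(float(t[decayed[0]]) if decayed.size else 1.0, 2 * dt)

    def model(tt, i0, tau, iss):
        return i0 * np.exp(-tt / tau) + iss

    try:
        popt, _ = curve_fit(model, t, y, p0=(i00, tau0, i_ss0), maxfev=10000)
    except RuntimeError as exc:
        raise ValueError(f"exponential fit did not converge: {exc}") from exc
    i0, tau, iss = (float(x) for x in popt)
    if tau < 2 * dt:
        raise ValueError(f"fitted tau {tau:.4f} ms shorter than 2 sampling intervals")
    i_total0 = i0 + iss
    ra_G = dv_mV / i_total0  # mV/pA = GOhm
    rm_G = dv_mV / iss - ra_G
    cm_pF = tau * (ra_G + rm_G) / (ra_G * rm_G)  # ms/GOhm = pF
    rms = float(np.sqrt(np.mean((y - model(t, *popt)) ** 2)))
    return PassiveParams(Ra_MOhm=ra_G * 1e3, Rm_GOhm=rm_G, Cm_pF=cm_pF,
                         tau_ms=tau, fit_residual_rms=rms)


def peak_current(trace: np.ndarray, time_ms: np.ndarray,
                 pulse_window_ms: tuple[float, float], tau_ms: float,
                 smooth_ms: float = 0.3, exclude_tau_factor: float = 2.0) -> float:
    """Peak inward (most negative) current within the pulse window.

    The first ``exclude_tau_factor * tau`` after pulse onset are excluded
    (residual capacitive settling; the default 2*tau suits clean traces,
    while the cell-level pipeline uses a larger factor because recording
    noise scales with the huge uncancelled transient amplitude).  A short
    moving average suppresses single-sample noise extrema before the
    extremum is taken.
    """
    t0, t1 = pulse_window_ms
    sel = (time_ms >= t0 + exclude_tau_factor * tau_ms) & (time_ms < t1)
    if not sel.any():
        raise ValueError("empty peak-search window")
    dt = time_ms[1] - time_ms[0]
    seg = np.asarray(trace)[sel]
    w = max(1, int(round(smooth_ms / dt)))
    if w > 1:
        seg = uniform_filter1d(seg, size=w, mode="nearest")
    return float(seg.min())


def estimate_erev(vcmd_mV: Sequence[float], i_peak_pA: Sequence[float]) -> float:
    """Reversal potential from the zero crossing of the peak I-V.

    Linear interpolation between the bracketing points on the descending
    (high-voltage) limb; an exact zero at a grid point returns that voltage.
    Raises when the I-V never changes sign.
    """
    v = np.asarray(vcmd_mV, dtype=float)
    i = np.asarray(i_peak_pA, dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    zeros = np.flatnonzero(i == 0.0)
    if zeros.size:
        return float(v[zeros[-1]])
    sign_change = np.flatnonzero(np.diff(np.signbit(i)))
    if sign_change.size == 0:
        raise ValueError("peak I-V does not cross zero; cannot estimate E_rev")
    k = int(sign_change[-1])  # crossing at the highest voltages
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))


def conductance_curve(peaks: dict, protocol: VoltageProtocol, ra_MOhm: float,
                      e_rev_mV: float, rm_GOhm: float | None = None,
                      exclusion_mV: float = EREV_EXCLUSION_MV) -> ConductanceCurve:
    """Access-resistance-corrected conductance-voltage curve.

    Single-pass correction Vm = Vcmd - I_total*Ra with the whole-cell
    current at the peak; G = I_peak/(Vm - E_rev) in nS.  The P/4-corrected
    peak excludes the linear leak the cell actually draws, so when the
    passive fit is available (``rm_GOhm``) the leak
    (Vcmd - holding)/(Ra + Rm) is added back before the Ra drop is
    computed -- with high-resistance cells the leak is small but its Ra
    drop is not negligible against a sub-millivolt voltage scale.
    Points with |Vm - E_rev| < ``exclusion_mV`` are dropped from fitting;
    G is normalized to its value at the highest retained Vm.
    """
    vcmd = np.array(sorted(peaks.keys()), dtype=float)
    i_peak = np.array([peaks[v] for v in vcmd], dtype=float)
    ra_G = ra_MOhm * 1e-3
    i_total = i_peak.copy()
    if rm_GOhm is not None:
        i_total = i_total + (vcmd - protocol.holding_mV) / (ra_G + rm_GOhm)
    vm = vcmd - i_total * ra_G
    retained = np.abs(vm - e_rev_mV) >= exclusion_mV
    if not retained.any():
        raise ValueError("all points excluded by the reversal-potential guard")
    g = np.zeros_like(i_peak)
    g[retained] = i_peak[retained] / (vm[retained] - e_rev_mV)
    anchor = int(np.flatnonzero(retained)[np.argmax(vm[retained])])
    g0 = g[anchor]
    if g0 == 0:
        raise ValueError("zero conductance at the normalization anchor")
    return ConductanceCurve(vcmd_mV=vcmd, i_peak_pA=i_peak, vm_mV=vm, g_nS=g,
                            g_norm=g / g0, retained=retained,
                            e_rev_mV=e_rev_mV, anchor_index=anchor)


def boltzmann_fit(curve: ConductanceCurve,
                  temperature_K: float = DEFAULT_TEMP_K) -> ActivationFit:
    """Boltzmann fit of the normalized activation curve.

    Fits G_M/G_0 = 1/(1 + exp((V_half - Vm)/s)) by least squares on the
    retained points (the anchor is pinned at 1 by the normalization).  The
    gating charge is q_g = (k_B T / e)/s in elementary charges.
    """
    vm = curve.vm_mV[curve.retained]
    y = curve.g_norm[curve.retained]
    if vm.size < 6:
        raise ValueError("need at least 6 retained points spanning the rise")

    def model(v, v_half, s):
        return 1.0 / (1.0 + np.exp((v_half - v) / s))

    v_half0 = float(np.interp(0.5, np.clip(y, 0, None), vm))
    try:
        popt, pcov = curve_fit(model, vm, y, p0=(v_half0, 7.0), maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"Boltzmann fit did not converge: {exc}") from exc
    v_half, s = (float(x) for x in popt)
    if s <= 0:
        raise ValueError("non-physical slope at the optimum (s <= 0)")
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    gmax = float(curve.g_nS[curve.anchor_index])
    return ActivationFit(
        v_half_mV=v_half, slope_mV=s,
        q_gating=thermal_voltage_mV(temperature_K) / s,
        gmax_nS=gmax, se_v_half_mV=float(se[0]), se_slope_mV=float(se[1]),
        temperature_K=temperature_K, converged=True,
    )


def specific_conductance(gmax_nS: float, cm_pF: float) -> float:
    """Cell-size-independent expression measure, nS/pF."""
    if not cm_pF > 0:
        raise ValueError("Cm must be > 0")
    return gmax_nS / cm_pF


@dataclass
class CellResult:
    """All per-cell analysis outputs."""

    cell_id: str
    passive: PassiveParams
    curve: ConductanceCurve
    fit: ActivationFit
    specific_nS_per_pF: float


def analyze_cell(sweeps: SweepSet, e_rev_mV: float | None = None,
                 temperature_K: float = DEFAULT_TEMP_K,
                 cell_id: str = "cell") -> CellResult:
    """Run the full per-cell chain (P/4 -> passive -> peaks -> G-V -> fit)."""
    proto = sweeps.protocol
    v_top = max(sweeps.test.keys(), key=lambda v: abs(v - proto.holding_mV))
    sub_mean = sweeps.subs[v_top].mean(axis=0)
    passive = estimate_passive(sub_mean, sweeps.sub_amplitude_mV[v_top],
                               sweeps.time_ms, proto.pre_ms)
    corrected = p4_subtract(sweeps)
    # 6*tau settling: noise riding on the (cancelled) capacitive transient
    # scales with its full amplitude, so 2*tau leaks transient noise into
    # the peak search for small-current cells
    peaks = {
        v: peak_current(tr, sweeps.time_ms, sweeps.pulse_window_ms, passive.tau_ms,
                        exclude_tau_factor=6.0)
        for v, tr in corrected.items()
    }
    if e_rev_mV is None:
        e_rev_mV = estimate_erev(list(peaks), [peaks[v] for v in peaks])
    curve = conductance_curve(peaks, proto, passive.Ra_MOhm, e_rev_mV,
                              rm_GOhm=passive.Rm_GOhm)
    fit = boltzmann_fit(curve, temperature_K)
    return CellResult(cell_id=cell_id, passive=passive, curve=curve, fit=fit,
                      specific_nS_per_pF=specific_conductance(fit.gmax_nS, passive.Cm_pF))


def qc_filter(cells: Sequence[CellResult], ra_max_MOhm: float = RA_MAX_MOHM,
              slope_min_mV: float = 3.0, rise_step_mV: float = 5.0):
    """Apply recording-quality exclusions.

    Cells with Ra strictly above ``ra_max_MOhm`` are excluded; cells whose
    fitted slope is below ``slope_min_mV`` or whose normalized curve jumps
    from <0.1 to >0.9 within one ``rise_step_mV`` step are flagged as
    space-clamp suspects and excluded.  Returns ``(retained, exclusion_log)``
    where the log lists ``(cell_id, reason)``.
    """
    retained, log = [], []
    for cell in cells:
        if cell.passive.Ra_MOhm > ra_max_MOhm:
            log.append((cell.cell_id, f"Ra>{ra_max_MOhm:g}"))
            continue
        if cell.fit.slope_mV < slope_min_mV:
            log.append((cell.cell_id, f"space-clamp: slope<{slope_min_mV:g}"))
            continue
        vm = cell.curve.vm_mV[cell.curve.retained]
        y = cell.curve.g_norm[cell.curve.retained]
        abrupt = False
        for i in range(len(vm) - 1):
            if vm[i + 1] - vm[i] <= rise_step_mV + 0.5 and y[i] < 0.1 and y[i + 1] > 0.9:
                abrupt = True
        if abrupt:
            log.append((cell.cell_id, "space-clamp: abrupt rise"))
            continue
        retained.append(cell)
    return retained, log
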