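"""Shared helpers for building small analysis objects in tests."""

import numpy as np

from b2mq import ephys
from b2mq.types import ActivationFit, ConductanceCurve, PassiveParams


def make_cell_result(cell_id: str, ra_MOhm: float, slope_mV: float = 6.0):
    passive = PassiveParams(Ra_MOhm=ra_MOhm, Rm_GOhm=1.0, Cm_pF=10.0,
                            tau_ms=0.1, fit_residual_rms=0.0)
    vm = np.arange(-80.0, 45.0, 5.0)
    g = 1.0 / (1.0 + np.exp((-20.0 - vm) / slope_mV))
    curve = ConductanceCurve(vcmd_mV=vm, i_peak_pA=-g, vm_mV=vm, g_nS=g,
                             g_norm=g / g[-1],
                             retained=np.ones_like(vm, dtype=bool),
                             e_rev_mV=65.0, anchor_index=len(vm) - 1)
    fit = ActivationFit(v_half_mV=-20.0, slope_mV=slope_mV,
                        q_gating=ephys.thermal_voltage_mV() / slope_mV,
                        gmax_nS=10.0, se_v_half_mV=0.1, se_slope_mV=0.1,
                        temperature_K=295.0, converged=True)
    return ephys.CellResult(cell_id=cell_id, passive=passive, curve=curve,
                            fit=fit, specific_nS_per_pF=1.0)
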