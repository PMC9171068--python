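"""Numerical core: adaptive exponential integrate-and-fire with an H-conductance.

State per neuron: membrane voltage V (mV), adaptation current w (pA), and
H-conductance activation h (dimensionless, 0..1).  Dynamics::

    C dV/dt = -gL (V - EL) + gL DeltaT exp((V - VT)/DeltaT)
              - gh h (V - Eh) - w + I(t)
    tauw dw/dt = a (V - EL) - w
    tauh dh/dt = hinf(V) - h,    hinf(V) = 1 / (1 + exp((V - Vh)/kh))

On V >= Vcut a spike is emitted, V resets to Vreset, w jumps by b, and V is
clamped at Vreset for tref.  Units: pF, nS, mV, pA, ms throughout (pF/nS = ms
and nS*mV = pA, so no conversion factors appear).

Integration is exponential-Euler on the conductance part (the instantaneous
linear system in V given h and w) with the spike-initiation exponential
treated as a constant current over the step, and exact exponential relaxation
for w and h.  The exponential argument is capped at (Vcut - VT)/DeltaT so the
blow-up past threshold cannot overflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Hard cap on emitted spikes per trace; 800 ms at a 1 ms refractory floor
#: cannot exceed this.
_MAX_SPIKES = 4096


@njit(cache=True)
def integrate_adex(
    I_pA,            # injected current per internal step, length n_steps
    dt_ms,           # internal step, ms
    n_sub,           # internal steps per recorded sample
    C, gL, EL, VT, DeltaT, Vreset, Vcut, tref_ms,
    a, b, tauw_ms,
    gh, Eh, Vh, kh, tauh_ms,
    V0, w0, h0,
    mark_spikes,     # if True, set the output sample covering a spike to Vcut
):
    n_steps = I_pA.shape[0]
    n_out = n_steps // n_sub + 1
    V_out = np.empty(n_out)
    spike_t = np.empty(_MAX_SPIKES)
    n_sp = 0

    V = V0
    w = w0
    h = h0
    V_out[0] = V
    ref_steps = 0
    exp_cap = (Vcut - VT) / DeltaT if DeltaT > 0 else 0.0
    decay_w = np.exp(-dt_ms / tauw_ms)
    decay_h = np.exp(-dt_ms / tauh_ms)
    spiked_in_window = False

    for i in range(n_steps):
        if ref_steps > 0:
            ref_steps -= 1
            V = Vreset
        else:
            if DeltaT > 0:
                x = (V - VT) / DeltaT
                if x > exp_cap:
                    x = exp_cap
                I_exp = gL * DeltaT * np.exp(x)
            else:
                I_exp = 0.0
            g_eff = gL + gh * h
            I_const = gL * EL + gh * h * Eh - w + I_pA[i] + I_exp
            V_eq = I_const / g_eff
            V = V_eq + (V - V_eq) * np.exp(-dt_ms * g_eff / C)

        hinf = 1.0 / (1.0 + np.exp((V - Vh) / kh))
        h = hinf + (h - hinf) * decay_h
        winf = a * (V - EL)
        w = winf + (w - winf) * decay_w

        if V >= Vcut and ref_steps == 0:
            if n_sp < _MAX_SPIKES:
                spike_t[n_sp] = (i + 1) * dt_ms
                n_sp += 1
            V = Vreset
            w = w + b
            ref_steps = int(tref_ms / dt_ms + 0.5)
            spiked_in_window = True

        if (i + 1) % n_sub == 0:
            j = (i + 1) // n_sub
            if mark_spikes and spiked_in_window:
                V_out[j] = Vcut
            else:
                V_out[j] = V
            spiked_in_window = False

    return V_out, spike_t[:n_sp].copy(), V, w, h
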