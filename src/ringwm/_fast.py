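"""Fused numba inner loops for the batched integrator.

Same update rules, operation for operation, as ``dynamics._Kernel.step``
(the readable NumPy reference); the elementwise work of the two Heun stages,
the refractory/threshold/event handling, and the background-noise
accumulation are fused into three passes so the per-step cost is dominated
by the one BLAS product for the E->E recurrent sums and the two SIMD
exponentials for the Mg2+ block.  Falls back cleanly if numba is missing
(``HAVE_NUMBA`` is False and the NumPy path is used).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False, fastmath=True)
def _stage_a(sN, y, G_in, k1s, sum_N1, sum_N2,
             alpha, inv_tauS, dt):
    """NMDA gating derivative, predictor, and the stacked GEMM input."""
    NE, B = sN.shape
    for b in range(B):
        sum_N1[b] = 0.0
        sum_N2[b] = 0.0
    for j in range(NE):
        for b in range(B):
            s = sN[j, b]
            k = alpha * y[j, b] * (1.0 - s) - s * inv_tauS
            k1s[j, b] = k
            sp = s + dt * k
            G_in[j, b] = s
            G_in[j, B + b] = sp
            sum_N1[b] += s
            sum_N2[b] += sp


@njit(cache=False, fastmath=True)
def _stage_b(V, exp1, sA, rec1, sum_N1, sum_G1, I_e, has_ie,
             dV1, Vp, NE,
             mg_c, g_EE, g_EI, g_AE, g_AI, c_gE, c_gI,
             g_LE, g_LI, invCE, invCI, V_LE, V_LI,
             V_Erev, V_Irev, f_AMPA, dt):
    """First Heun stage for the stacked populations; decays s_AMPA in place."""
    N, B = V.shape
    for i in range(N):
        isE = i < NE
        g_A = g_AE if isE else g_AI
        c_g = c_gE if isE else c_gI
        g_L = g_LE if isE else g_LI
        invC = invCE if isE else invCI
        V_L = V_LE if isE else V_LI
        for b in range(B):
            v = V[i, b]
            block = 1.0 + mg_c * exp1[i, b]
            if isE:
                g_nmda = g_EE * rec1[i, b] / block
            else:
                g_nmda = g_EI * sum_N1[b] / block
            g_exc = g_A * sA[i, b] + g_nmda
            I = (V_Erev - v) * g_exc + (V_Irev - v) * c_g * sum_G1[b]
            if has_ie and isE:
                I += I_e[i, b]
            dv = (g_L * (V_L - v) + I) * invC
            dV1[i, b] = dv
            Vp[i, b] = v + dt * dv
            sA[i, b] *= f_AMPA


@njit(cache=False, fastmath=True)
def _stage_c(V, Vp, exp2, sA, sN, y, sG, u, x, refr,
             rec2, sum_N2, sum_G2, I_e, has_ie, dV1, k1s, G_in, counts,
             spkE_n, spkE_b, spkI_n, spkI_b, NE,
             mg_c, g_EE, g_EI, g_AE, g_AI, c_gE, c_gI,
             g_LE, g_LI, invCE, invCI, V_LE, V_LI,
             V_Erev, V_Irev, alpha, inv_tauS, f_y, f_GABA,
             f_u, f_x, U, stp_enabled, pre_jump,
             V_thE, V_thI, V_resE, V_resI, n_refE, n_refI, dt):
    """Second Heun stage, corrector, refractory/threshold, and event jumps."""
    N, B = V.shape
    cE = 0
    cI = 0
    half_dt = 0.5 * dt
    for i in range(N):
        isE = i < NE
        g_A = g_AE if isE else g_AI
        c_g = c_gE if isE else c_gI
        g_L = g_LE if isE else g_LI
        invC = invCE if isE else invCI
        V_L = V_LE if isE else V_LI
        V_th = V_thE if isE else V_thI
        V_res = V_resE if isE else V_resI
        n_ref = n_refE if isE else n_refI
        for b in range(B):
            vp = Vp[i, b]
            block = 1.0 + mg_c * exp2[i, b]
            if isE:
                g_nmda = g_EE * rec2[i, b] / block
            else:
                g_nmda = g_EI * sum_N2[b] / block
            g_exc = g_A * sA[i, b] + g_nmda
            I = (V_Erev - vp) * g_exc + (V_Irev - vp) * c_g * sum_G2[b]
            if has_ie and isE:
                I += I_e[i, b]
            dv2 = (g_L * (V_L - vp) + I) * invC
            vn = V[i, b] + half_dt * (dV1[i, b] + dv2)

            if isE:
                # NMDA gating corrector (y decayed to end of step)
                sp = G_in[i, B + b]
                y2 = y[i, b] * f_y
                k2 = alpha * y2 * (1.0 - sp) - sp * inv_tauS
                sN[i, b] += half_dt * (k1s[i, b] + k2)
                if stp_enabled:
                    uu = U + (u[i, b] - U) * f_u
                    xx = 1.0 + (x[i, b] - 1.0) * f_x
                else:
                    uu = u[i, b]
                    xx = x[i, b]
                if refr[i, b] > 0:
                    vn = V_res
                    refr[i, b] -= 1
                elif vn >= V_th:
                    vn = V_res
                    refr[i, b] = n_ref
                    spkE_n[cE] = i
                    spkE_b[cE] = b
                    cE += 1
                    if stp_enabled:
                        up = uu + U * (1.0 - uu)
                        drive = (uu if pre_jump else up) * xx
                        y2 += drive
                        xx -= drive
                        uu = up
                    else:
                        y2 += 1.0
                y[i, b] = y2
                if stp_enabled:
                    u[i, b] = uu
                    x[i, b] = xx
            else:
                g2 = sG[i - NE, b] * f_GABA
                if refr[i, b] > 0:
                    vn = V_res
                    refr[i, b] -= 1
                elif vn >= V_th:
                    vn = V_res
                    refr[i, b] = n_ref
                    spkI_n[cI] = i - NE
                    spkI_b[cI] = b
                    cI += 1
                    g2 += 1.0
                sG[i - NE, b] = g2
            V[i, b] = vn
            sA[i, b] += counts[i, b]
    return cE, cI
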