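"""Compiled time-stepping kernel for the branched cable model.

Backward-Euler voltage solve by Hines elimination with gates advanced by
exact exponential updates. Gate steady states and per-step decay factors
are linearly interpolated from dense voltage tables supplied by the caller
(built from the package's GateSpec definitions), so no kinetics are defined
here.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_kernel(
    parent, g_pair, cap, dt, n_steps,
    gna_t, gkdr_t, gka_t, gca_t, gl_t, gca_dens,
    eleak, ena, ek, eca,
    inf_tab, fac_tab, v_lo, inv_dv,
    syn_idx, syn_scale, syn_e, syn_f1, syn_f2, ev_steps,
    p_start, p_end, p_amp, p_idx,
    i_hold, soma_idx,
    v, xm, xh, xn, xa, xb, xc,
    syn_a, syn_b,
    rec_idx, ica_idx, gate_idx,
):
    n = v.shape[0]
    n_rec = rec_idx.shape[0]
    n_ica = ica_idx.shape[0]
    n_grid = inf_tab.shape[1]

    v_rec = np.empty((n_steps + 1, n_rec))
    ica_rec = np.empty((n_steps + 1, n_ica))
    a_rec = np.empty(n_steps + 1)
    b_rec = np.empty(n_steps + 1)
    vmin = v.copy()

    d = np.empty(n)
    rhs = np.empty(n)

    for j in range(n_rec):
        v_rec[0, j] = v[rec_idx[j]]
    for j in range(n_ica):
        i = ica_idx[j]
        ica_rec[0, j] = gca_dens[i] * xc[i] * xc[i] * (v[i] - eca)
    a_rec[0] = xa[gate_idx]
    b_rec[0] = xb[gate_idx]

    for s in range(n_steps):
        # --- gate updates at the step's starting voltage (table lookup) ---
        for i in range(n):
            u = (v[i] - v_lo) * inv_dv
            if u < 0.0:
                u = 0.0
            elif u > n_grid - 1.001:
                u = n_grid - 1.001
            j0 = int(u)
            w = u - j0
            inf = inf_tab[0, j0] + (inf_tab[0, j0 + 1] - inf_tab[0, j0]) * w
            fac = fac_tab[0, j0] + (fac_tab[0, j0 + 1] - fac_tab[0, j0]) * w
            xm[i] = inf + (xm[i] - inf) * fac
            inf = inf_tab[1, j0] + (inf_tab[1, j0 + 1] - inf_tab[1, j0]) * w
            fac = fac_tab[1, j0] + (fac_tab[1, j0 + 1] - fac_tab[1, j0]) * w
            xh[i] = inf + (xh[i] - inf) * fac
            inf = inf_tab[2, j0] + (inf_tab[2, j0 + 1] - inf_tab[2, j0]) * w
            fac = fac_tab[2, j0] + (fac_tab[2, j0 + 1] - fac_tab[2, j0]) * w
            xn[i] = inf + (xn[i] - inf) * fac
            inf = inf_tab[3, j0] + (inf_tab[3, j0 + 1] - inf_tab[3, j0]) * w
            fac = fac_tab[3, j0] + (fac_tab[3, j0 + 1] - fac_tab[3, j0]) * w
            xa[i] = inf + (xa[i] - inf) * fac
            inf = inf_tab[4, j0] + (inf_tab[4, j0 + 1] - inf_tab[4, j0]) * w
            fac = fac_tab[4, j0] + (fac_tab[4, j0 + 1] - fac_tab[4, j0]) * w
            xb[i] = inf + (xb[i] - inf) * fac
            inf = inf_tab[5, j0] + (inf_tab[5, j0 + 1] - inf_tab[5, j0]) * w
            fac = fac_tab[5, j0] + (fac_tab[5, j0 + 1] - fac_tab[5, j0]) * w
            xc[i] = inf + (xc[i] - inf) * fac

        # --- synaptic two-state conductance ---
        syn_a *= syn_f1
        syn_b *= syn_f2
        for e in range(ev_steps.shape[0]):
            if ev_steps[e] == s:
                syn_a += 1.0
                syn_b += 1.0
        g_syn = syn_scale * (syn_b - syn_a)  # mS

        # --- assemble the implicit system ---
        for i in range(n):
            g_na = gna_t[i] * xm[i] * xm[i] * xm[i] * xh[i]
            n2 = xn[i] * xn[i]
            g_kdr = gkdr_t[i] * n2 * n2
            g_ka = gka_t[i] * xa[i] * xb[i]
            g_ca = gca_t[i] * xc[i] * xc[i]
            g_l = gl_t[i]
            cdt = cap[i] / dt
            d[i] = cdt + g_na + g_kdr + g_ka + g_ca + g_l
            rhs[i] = (
                cdt * v[i]
                + g_na * ena
                + (g_kdr + g_ka) * ek
                + g_ca * eca
                + g_l * eleak
            )
        d[syn_idx] += g_syn
        rhs[syn_idx] += g_syn * syn_e
        rhs[soma_idx] += i_hold
        for p in range(p_start.shape[0]):
            if p_start[p] <= s < p_end[p]:
                rhs[p_idx[p]] += p_amp[p]
        for i in range(1, n):
            d[i] += g_pair[i]
            d[parent[i]] += g_pair[i]

        # --- Hines elimination and back-substitution ---
        for i in range(n - 1, 0, -1):
            pi = parent[i]
            f = -g_pair[i] / d[i]
            d[pi] -= f * (-g_pair[i])
            rhs[pi] -= f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_pair[i] * v[parent[i]]) / d[i]

        # --- recording ---
        for i in range(n):
            if v[i] < vmin[i]:
                vmin[i] = v[i]
        for j in range(n_rec):
            v_rec[s + 1, j] = v[rec_idx[j]]
        for j in range(n_ica):
            i = ica_idx[j]
            ica_rec[s + 1, j] = gca_dens[i] * xc[i] * xc[i] * (v[i] - eca)
        a_rec[s + 1] = xa[gate_idx]
        b_rec[s + 1] = xb[gate_idx]

    return v_rec, ica_rec, a_rec, b_rec, vmin
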