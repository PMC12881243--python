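"""Compiled inner loop of the simulator (numba).

Semantically identical to ``Network.step`` applied ``n_steps`` times with
constant drive; addition order matches the vectorised reference path so
the two produce bit-identical trajectories.
"""

import numpy as np
from numba import njit

__all__ = ["run_steps"]


@njit(cache=True)
def run_steps(n_steps, V_e, om_a, om_r, phi, V_i, G,
              area_of,
              ee_indptr, ee_order, ee_post, ee_w,
              ee_cptr, ee_corder, ee_pre,
              ei_indptr, ei_order, ei_post, ei_w,
              lam_e, ce, lam_i, ci, lam_g, cg, lam_a, ca, lam_r, cr,
              k2, kG, s_ee, s_ie,
              thresh, psi_alpha, spike_reset,
              plastic, th_pre, th_plus, th_minus, delta, w_min, w_max,
              drive, eta, noise_amp,
              stop_idx, stop_eps,
              spikes_out, record_spikes, area_counts):
    n_e = V_e.shape[0]
    n_areas = G.shape[0]
    inp = np.zeros(n_e)
    inh_in = np.zeros(n_e)
    g_in = np.zeros(n_areas)
    new_phi = np.zeros(n_e, dtype=np.int8)

    for t in range(n_steps):
        for e in range(n_e):
            inp[e] = 0.0
            inh_in[e] = 0.0
        for a in range(n_areas):
            g_in[a] = 0.0

        # gather from last step's spikes
        for p in range(n_e):
            if phi[p]:
                for k in range(ee_indptr[p], ee_indptr[p + 1]):
                    j = ee_order[k]
                    inp[ee_post[j]] += ee_w[j]
                for k in range(ei_indptr[p], ei_indptr[p + 1]):
                    j = ei_order[k]
                    inh_in[ei_post[j]] += ei_w[j]
                g_in[area_of[p]] += 1.0

        # inhibitory units first (half-step lead over the excitatory update)
        for a in range(n_areas):
            G[a] = lam_g * G[a] + cg * g_in[a]
        for i in range(n_e):
            V_i[i] = lam_i * V_i[i] + ci * inh_in[i]

        for e in range(n_e):
            oi = V_i[e] if V_i[e] > 0.0 else 0.0
            et = eta[t, e]
            cur = (-kG * G[area_of[e]] - s_ie * oi + s_ee * inp[e]
                   + drive[e] + noise_amp * et)
            V_e[e] = lam_e * V_e[e] + ce * (cur + k2 * et)

        for e in range(n_e):
            s = np.int8(1) if V_e[e] - psi_alpha * om_a[e] > thresh else np.int8(0)
            new_phi[e] = s
            om_a[e] = lam_a * om_a[e] + ca * s
            om_r[e] = lam_r * om_r[e] + cr * s

        if plastic:
            # LTP / homosynaptic LTD: edges from active presynaptic cells
            for p in range(n_e):
                if om_r[p] >= th_pre:
                    for k in range(ee_indptr[p], ee_indptr[p + 1]):
                        j = ee_order[k]
                        v = V_e[ee_post[j]]
                        if v >= th_plus:
                            w = ee_w[j] + delta
                            ee_w[j] = w if w < w_max else w_max
                        elif v >= th_minus:
                            w = ee_w[j] - delta
                            ee_w[j] = w if w > w_min else w_min
            # heterosynaptic LTD: inactive inputs to strongly depolarised cells
            for q in range(n_e):
                if V_e[q] >= th_plus:
                    for k in range(ee_cptr[q], ee_cptr[q + 1]):
                        j = ee_corder[k]
                        if om_r[ee_pre[j]] < th_pre:
                            w = ee_w[j] - delta
                            ee_w[j] = w if w > w_min else w_min

        for e in range(n_e):
            if new_phi[e]:
                if spike_reset:
                    V_e[e] = 0.0
                area_counts[t, area_of[e]] += 1
            phi[e] = new_phi[e]
            if record_spikes:
                spikes_out[t, e] = new_phi[e]

        if stop_eps > 0.0 and stop_idx.shape[0] > 0:
            settled = True
            for h in stop_idx:
                if G[h] >= stop_eps:
                    settled = False
                    break
            if settled:
                return t + 1
    return n_steps
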