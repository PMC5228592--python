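"""Compiled per-step neuron-update kernels.

One kernel call advances a whole population by one Euler step: it sums
the conductance channels into the synaptic current (with the magnesium
block on NMDA rows), integrates the two state variables, detects
threshold crossings and applies the family-specific reset.  Spiking
neuron indices are written into a caller-provided buffer.
"""

import math

from numba import njit

_EXP_ARG_MAX = 30.0


@njit(cache=False)
def scatter_add(target, posts, val):
    for j in range(posts.shape[0]):
        target[posts[j]] += val


@njit(cache=False)
def tsodyks_deliver(target, posts, edges, u, y, z, tlast, t,
                    U, tau_fac, tau_syn, tau_rec, g0):
    """Lazy Tsodyks update at spike arrival: closed-form relaxation since
    the edge's last event, facilitation, release, conductance jump."""
    c_rec = tau_rec / (tau_syn - tau_rec)
    for j in range(edges.shape[0]):
        e = edges[j]
        d = t - tlast[e]
        if d > 0.0:
            if tau_fac > 0.0:
                u[e] *= math.exp(-d / tau_fac)
            ey = math.exp(-d / tau_syn)
            ez = math.exp(-d / tau_rec)
            cc = y[e] * c_rec
            z[e] = (z[e] - cc) * ez + cc * ey
            y[e] *= ey
        if tau_fac > 0.0:
            u[e] += U * (1.0 - u[e])
        else:
            u[e] = U
        r = u[e] * (1.0 - y[e] - z[e])
        y[e] += r
        tlast[e] = t
        target[posts[j]] += g0 * r


@njit(cache=False)
def qif_step(V, w, G, E_rev, nmda, mg_c, mg_k, C, thr, I_ext,
             k, v_r, a, b, dt, is_fsn, v_b, cutoff, c_reset, d_inc,
             spiked_out):
    n = V.shape[0]
    nc = G.shape[0]
    count = 0
    for i in range(n):
        Vi = V[i]
        Isyn = I_ext
        for c in range(nc):
            g = G[c, i]
            if g != 0.0:
                drive = E_rev[c] - Vi
                if nmda[c]:
                    drive *= 1.0 / (1.0 + mg_c * math.exp(-mg_k * Vi))
                Isyn += g * drive
        wi = w[i]
        dV = (k * (Vi - v_r) * (Vi - thr[i]) - wi + Isyn) / C[i]
        if is_fsn:
            if Vi <= v_b:
                dwdt = a * (b * (Vi - v_b) ** 3 - wi)
            else:
                dwdt = -a * wi
        else:
            dwdt = a * (b * (Vi - v_r) - wi)
        Vi += dt * dV
        wi += dt * dwdt
        if Vi >= cutoff:
            Vi = c_reset
            wi += d_inc
            spiked_out[count] = i
            count += 1
        V[i] = Vi
        w[i] = wi
    return count


@njit(cache=False)
def adex_step(V, w, G, E_rev, nmda, mg_c, mg_k, C, thr, I_ext,
              g_L, E_L, Delta_T, a_sub, tau_w, b_spike, V_r, t_f, dt,
              has_gate, gate_v, rebound, reset_offset, reset_cap,
              reset_is_max, spiked_out):
    n = V.shape[0]
    nc = G.shape[0]
    count = 0
    for i in range(n):
        Vi = V[i]
        Isyn = I_ext
        for c in range(nc):
            g = G[c, i]
            if g != 0.0:
                drive = E_rev[c] - Vi
                if nmda[c]:
                    drive *= 1.0 / (1.0 + mg_c * math.exp(-mg_k * Vi))
                Isyn += g * drive
        wi = w[i]
        arg = (Vi - thr[i]) / Delta_T
        if arg > _EXP_ARG_MAX:
            arg = _EXP_ARG_MAX
        dV = (-g_L * (Vi - E_L) + g_L * Delta_T * math.exp(arg)
              - wi + Isyn) / C[i]
        a_eff = a_sub
        if has_gate and Vi >= gate_v:
            a_eff = 0.0
        dwdt = (a_eff * (Vi - E_L) - wi) / tau_w
        Vi += dt * dV
        wi += dt * dwdt
        if Vi >= t_f:
            if rebound and wi < 0.0:
                if reset_is_max:
                    extra = max(wi - reset_offset, reset_cap)
                else:
                    extra = min(wi - reset_offset, reset_cap)
                Vi = V_r + extra
            else:
                Vi = V_r
            wi += b_spike
            spiked_out[count] = i
            count += 1
        V[i] = Vi
        w[i] = wi
    return count
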