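"""Numba inner loop of the fixed-step implicit (backward Euler) solver.

Operator splitting per step (the standard scheme for fixed-step
compartmental solvers):

1. gating variables and graded-synapse activations advance by their exact
   exponential update using the voltage of the previous step;
2. the voltage of every compartment is then solved implicitly from the
   linear system with channel/synapse conductances frozen at the updated
   gate values, using the tree-structured (Hines-ordered) elimination;
3. submembrane calcium pools advance with an implicit removal update
   driven by the freshly computed calcium currents.

Units: mV, ms, nA, uS, nF; areas cm^2; calcium mM.

All arrays are flat over the whole network (possibly several cells; the
compartment forest is encoded by a parent index of -1 for each cell root,
with every parent preceding its children).
"""

import numpy as np
from numba import njit

FARADAY = 96485.33212  # C/mol

#: voltage grid for tabulated gate kinetics
VGRID_MIN = -120.0
VGRID_MAX = 60.0
VGRID_STEP = 0.05
NV = int(round((VGRID_MAX - VGRID_MIN) / VGRID_STEP)) + 1

#: abort bounds for the blow-up diagnostic
V_ABORT_LOW = -150.0
V_ABORT_HIGH = 100.0

GATE_VOLTAGE = 0
GATE_INSTANT = 1
GATE_CALCIUM = 2


@njit(cache=True)
def simulate(
    nsteps, dt,
    # per-compartment structure
    parent, gax, cap, gleak, eleak, area,
    # stimuli
    st_comp, st_amp, st_on, st_off,
    # channels
    ch_comp, ch_gbar, ch_e, ch_nernst, ch_feed, ch_g0, ch_g1,
    # gates
    gt_comp, gt_pow, gt_kind, gt_inf, gt_tau, gt_a, gt_b,
    # calcium pools (per compartment; has_pool -> parameters valid)
    has_pool, p_depth, p_tau, p_rest, p_out, p_floor,
    # synapses
    sy_pre, sy_post, sy_g, sy_e, sy_th, sy_sl, sy_tau,
    # state (modified in place)
    v, gates, s, ca,
    # nernst prefactor 1e3*R*T/(2F) in mV
    rtf2,
    # output voltage record, shape (nsteps+1, nc); row 0 = initial state
    vrec,
):
    nc = v.shape[0]
    nch = ch_comp.shape[0]
    ng = gt_comp.shape[0]
    nsy = sy_pre.shape[0]
    nst = st_comp.shape[0]

    diag = np.empty(nc)
    rhs = np.empty(nc)
    ch_gval = np.empty(nch)
    ch_eval = np.empty(nch)
    ica = np.empty(nc)

    vrec[0, :] = v

    for k in range(1, nsteps + 1):
        t = k * dt

        # --- gates (exact exponential, previous-step voltage) -------------
        for gi in range(ng):
            c = gt_comp[gi]
            kind = gt_kind[gi]
            if kind == GATE_CALCIUM:
                a = gt_a[gi] * ca[c]
                b = gt_b[gi]
                inf = a / (a + b)
                tau = 1.0 / (a + b)
                g = inf + (gates[gi] - inf) * np.exp(-dt / tau)
            else:
                x = (v[c] - VGRID_MIN) / VGRID_STEP
                if x < 0.0:
                    x = 0.0
                elif x > NV - 1.000001:
                    x = NV - 1.000001
                i0 = int(x)
                fr = x - i0
                inf = gt_inf[gi, i0] * (1.0 - fr) + gt_inf[gi, i0 + 1] * fr
                if kind == GATE_INSTANT:
                    g = inf
                else:
                    tau = gt_tau[gi, i0] * (1.0 - fr) + gt_tau[gi, i0 + 1] * fr
                    g = inf + (gates[gi] - inf) * np.exp(-dt / tau)
            if g < 0.0:
                g = 0.0
            elif g > 1.0:
                g = 1.0
            gates[gi] = g

        # --- graded synapse activations -----------------------------------
        for si in range(nsy):
            vp = v[sy_pre[si]]
            sinf = 1.0 / (1.0 + np.exp(-(vp - sy_th[si]) / sy_sl[si]))
            sv = sinf + (s[si] - sinf) * np.exp(-dt / sy_tau[si])
            if sv < 0.0:
                sv = 0.0
            elif sv > 1.0:
                sv = 1.0
            s[si] = sv

        # --- assemble the implicit linear system --------------------------
        for c in range(nc):
            diag[c] = cap[c] / dt + gleak[c]
            rhs[c] = cap[c] / dt * v[c] + gleak[c] * eleak[c]

        for j in range(nst):
            if t > st_on[j] and t <= st_off[j]:
                rhs[st_comp[j]] += st_amp[j]

        for ci in range(nch):
            o = 1.0
            for gi in range(ch_g0[ci], ch_g1[ci]):
                gv = gates[gi]
                for _ in range(gt_pow[gi]):
                    o *= gv
            gcond = ch_gbar[ci] * o
            c = ch_comp[ci]
            if ch_nernst[ci]:
                erev = rtf2 * np.log(p_out[c] / ca[c])
            else:
                erev = ch_e[ci]
            ch_gval[ci] = gcond
            ch_eval[ci] = erev
            diag[c] += gcond
            rhs[c] += gcond * erev

        for si in range(nsy):
            gs = sy_g[si] * s[si]
            c = sy_post[si]
            diag[c] += gs
            rhs[c] += gs * sy_e[si]

        for c in range(nc):
            p = parent[c]
            if p >= 0:
                diag[c] += gax[c]
                diag[p] += gax[c]

        # --- Hines solve (parents precede children) -----------------------
        for c in range(nc - 1, 0, -1):
            p = parent[c]
            if p >= 0:
                f = gax[c] / diag[c]
                diag[p] -= f * gax[c]
                rhs[p] += f * rhs[c]
        for c in range(nc):
            p = parent[c]
            if p < 0:
                v[c] = rhs[c] / diag[c]
            else:
                v[c] = (rhs[c] + gax[c] * v[p]) / diag[c]
            if not np.isfinite(v[c]) or v[c] < V_ABORT_LOW or v[c] > V_ABORT_HIGH:
                return k, c

        # --- calcium pools -------------------------------------------------
        for c in range(nc):
            ica[c] = 0.0
        for ci in range(nch):
            if ch_feed[ci]:
                c = ch_comp[ci]
                ica[c] += ch_gval[ci] * (v[c] - ch_eval[ci])  # nA
        for c in range(nc):
            if has_pool[c]:
                i_ma_cm2 = ica[c] * 1e-6 / area[c]
                drive = -i_ma_cm2 / (2.0 * FARADAY * p_depth[c] * 1e-4)  # mM/ms
                if drive < 0.0:
                    drive = 0.0
                tau = p_tau[c]
                canew = (ca[c] + dt * (drive + p_rest[c] / tau)) / (1.0 + dt / tau)
                if canew < p_floor[c]:
                    canew = p_floor[c]
                ca[c] = canew

        vrec[k, :] = v

    return -1, -1
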