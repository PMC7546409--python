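"""Numba kernel for the double-cable myelinated axon under extracellular drive.

Theta-scheme time stepping (default Crank-Nicolson) of the coupled
axoplasmic / periaxonal cables with predictor-corrector Rush-Larsen gating
at the nodes of Ranvier.  Per compartment the unknowns are the intracellular
potential ``a`` and the periaxonal potential ``u`` (membrane potential
V = a - u; at nodes the periaxonal layer is shorted to the extracellular
potential by a large myelin conductance).  Each pass solves one
block-tridiagonal system with 2x2 blocks (block Thomas).

Units throughout: mV, ms, uS, nF, nA.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _vtrap(x: float, y: float) -> float:
    # x / (1 - exp(-x/y)) with the removable singularity at x = 0
    if abs(x / y) < 1e-6:
        return y + x / 2.0
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True, fastmath=False)
def _wave(t, pw, tau, period, n_pulses):
    """Unit biphasic pulse train: rectangular cathodic phase followed by a
    charge-balanced exponential passive-discharge phase."""
    if period > 0.0:
        k = int(t / period)
        tm = t - k * period
    else:
        k = 0
        tm = t
    if k >= n_pulses:
        return 0.0
    if tm <= pw:
        return 1.0
    return -(pw / tau) * math.exp(-(tm - pw) / tau)


@njit(cache=True, fastmath=False)
def _rates(v, qmh, qp, qs):
    am = qmh * 6.57 * _vtrap(v + 20.4, 10.3)
    bm = qmh * 0.304 * _vtrap(-(v + 25.7), 9.16)
    ah = qmh * 0.34 * _vtrap(-(v + 114.0), 11.0)
    bh = qmh * 12.6 / (1.0 + math.exp(-(v + 31.8) / 13.4))
    ap = qp * 0.0353 * _vtrap(v + 27.0, 10.2)
    bp = qp * 0.000883 * _vtrap(-(v + 34.0), 10.0)
    a_s = qs * 0.3 / (1.0 + math.exp(-(v + 53.0) / 5.0))
    b_s = qs * 0.03 / (1.0 + math.exp(-(v + 90.0) / 1.0))
    return am, bm, ah, bh, ap, bp, a_s, b_s


@njit(cache=True, fastmath=False)
def _solve_step(
    n, dt, theta, omt, node_of,
    m, h, p, s,
    gnaf, gnap, gks, gl, ena, ek, el,
    Gion_pas, Epas, Cm, Cmy, Gmy, ga, gp,
    profile_mV, w_new, e_old_arr, V, u, a_old,
    i00, i01, i10, i11, r1t, r2t, a_new, u_new,
):
    """Assemble and solve one theta-step (gates frozen); fills a_new, u_new."""
    pm00 = pm01 = pm10 = pm11 = 0.0
    pr1 = pr2 = 0.0
    for i in range(n):
        j = node_of[i]
        if j >= 0:
            m3h = m[j] * m[j] * m[j] * h[j]
            p3 = p[j] * p[j] * p[j]
            gna = gnaf[j] * m3h
            gnp = gnap[j] * p3
            gk = gks[j] * s[j]
            gion = gna + gnp + gk + gl[j]
            irhs = (gna + gnp) * ena + gk * ek + gl[j] * el
        else:
            gion = Gion_pas[i]
            irhs = Gion_pas[i] * Epas
        alpha = Cm[i] / dt + theta * gion
        beta = Cmy[i] / dt + theta * Gmy[i]
        gaL = ga[i - 1] if i > 0 else 0.0
        gaR = ga[i] if i < n - 1 else 0.0
        gpL = gp[i - 1] if i > 0 else 0.0
        gpR = gp[i] if i < n - 1 else 0.0
        # explicit old fluxes of the theta scheme
        fo_a = 0.0
        fo_p = 0.0
        if i > 0:
            fo_a += gaL * (a_old[i - 1] - a_old[i])
            fo_p += gpL * (u[i - 1] - u[i])
        if i < n - 1:
            fo_a += gaR * (a_old[i + 1] - a_old[i])
            fo_p += gpR * (u[i + 1] - u[i])
        # rows: axoplasm KCL and (negated) periaxonal KCL, unknowns (a, u)
        d00 = alpha + theta * (gaL + gaR)
        d01 = -alpha
        d10 = -alpha
        d11 = alpha + beta + theta * (gpL + gpR)
        e_new = profile_mV[i] * w_new
        r1 = (Cm[i] / dt - omt * gion) * V[i] + irhs + omt * fo_a
        r2 = (
            -r1
            + beta * e_new
            + (Cmy[i] / dt - omt * Gmy[i]) * (u[i] - e_old_arr[i])
            + omt * (fo_p + fo_a)
        )
        if i > 0:
            # subtract L * invDprev * U_prev (L = U_prev = -theta*diag(gaL, gpL))
            tgaL = theta * gaL
            tgpL = theta * gpL
            d00 -= tgaL * pm00 * tgaL
            d01 -= tgaL * pm01 * tgpL
            d10 -= tgpL * pm10 * tgaL
            d11 -= tgpL * pm11 * tgpL
            r1 += tgaL * pr1
            r2 += tgpL * pr2
        det = d00 * d11 - d01 * d10
        pm00 = d11 / det
        pm01 = -d01 / det
        pm10 = -d10 / det
        pm11 = d00 / det
        i00[i] = pm00
        i01[i] = pm01
        i10[i] = pm10
        i11[i] = pm11
        r1t[i] = r1
        r2t[i] = r2
        pr1 = pm00 * r1 + pm01 * r2
        pr2 = pm10 * r1 + pm11 * r2

    a_new[n - 1] = i00[n - 1] * r1t[n - 1] + i01[n - 1] * r2t[n - 1]
    u_new[n - 1] = i10[n - 1] * r1t[n - 1] + i11[n - 1] * r2t[n - 1]
    for i in range(n - 2, -1, -1):
        rr1 = r1t[i] + theta * ga[i] * a_new[i + 1]
        rr2 = r2t[i] + theta * gp[i] * u_new[i + 1]
        a_new[i] = i00[i] * rr1 + i01[i] * rr2
        u_new[i] = i10[i] * rr1 + i11[i] * rr2


@njit(cache=True, fastmath=False)
def integrate_axon(
    Cm,
    Gion_pas,
    Epas,
    Cmy,
    Gmy,
    ga,
    gp,
    node_idx,
    gnaf,
    gnap,
    gks,
    gl,
    ena,
    ek,
    el,
    vrest,
    qmh,
    qp,
    qs,
    profile_mV,
    pw_ms,
    tau_ms,
    period_ms,
    n_pulses,
    t_total_ms,
    dt_fine_ms,
    dt_coarse_ms,
    fine_until_ms,
    sub_exit_t_ms,
    sub_exit_v_mV,
    theta,
):
    """Integrate one axon; returns (crossed_t per node, status, vmax).

    status: 0 = ran to completion / subthreshold exit, 1 = propagation
    confirmed early, -1 = non-finite voltages (unstable integration).
    """
    n = Cm.shape[0]
    n_nodes = node_idx.shape[0]
    V = np.full(n, vrest)
    u = np.zeros(n)  # e(0) = 0
    m = np.empty(n_nodes)
    h = np.empty(n_nodes)
    p = np.empty(n_nodes)
    s = np.empty(n_nodes)
    m0 = np.empty(n_nodes)
    h0 = np.empty(n_nodes)
    p0 = np.empty(n_nodes)
    s0 = np.empty(n_nodes)
    am, bm, ah, bh, ap, bp, a_s, b_s = _rates(vrest, qmh, qp, qs)
    for j in range(n_nodes):
        m[j] = am / (am + bm)
        h[j] = ah / (ah + bh)
        p[j] = ap / (ap + bp)
        s[j] = a_s / (a_s + b_s)

    crossed_t = np.full(n_nodes, -1.0)
    node_of = np.full(n, -1, dtype=np.int64)
    for j in range(n_nodes):
        node_of[node_idx[j]] = j

    i00 = np.empty(n)
    i01 = np.empty(n)
    i10 = np.empty(n)
    i11 = np.empty(n)
    r1t = np.empty(n)
    r2t = np.empty(n)
    a_new = np.empty(n)
    u_new = np.empty(n)
    a_old = V + u
    e_arr = np.zeros(n)  # e at the previous step (zero before the stimulus)
    omt = 1.0 - theta

    vmax = vrest
    t = 0.0
    status = 0
    while t < t_total_ms - 1e-12:
        dt = dt_fine_ms if t < fine_until_ms else dt_coarse_ms
        if t + dt > t_total_ms:
            dt = t_total_ms - t
        t_new = t + dt
        w_new = _wave(t_new, pw_ms, tau_ms, period_ms, n_pulses)

        for j in range(n_nodes):
            m0[j] = m[j]
            h0[j] = h[j]
            p0[j] = p[j]
            s0[j] = s[j]
        # pass 0: gates from rates at V_old; pass 1: re-advance the same
        # gate state with rates at the predicted midpoint voltage
        for corrector in range(2):
            for j in range(n_nodes):
                i = node_idx[j]
                if corrector == 0:
                    v = V[i]
                else:
                    v = 0.5 * (V[i] + (a_new[i] - u_new[i]))
                am, bm, ah, bh, ap, bp, a_s, b_s = _rates(v, qmh, qp, qs)
                m[j] = am / (am + bm) + (m0[j] - am / (am + bm)) * math.exp(-dt * (am + bm))
                h[j] = ah / (ah + bh) + (h0[j] - ah / (ah + bh)) * math.exp(-dt * (ah + bh))
                p[j] = ap / (ap + bp) + (p0[j] - ap / (ap + bp)) * math.exp(-dt * (ap + bp))
                s[j] = a_s / (a_s + b_s) + (s0[j] - a_s / (a_s + b_s)) * math.exp(
                    -dt * (a_s + b_s)
                )
            _solve_step(
                n, dt, theta, omt, node_of, m, h, p, s,
                gnaf, gnap, gks, gl, ena, ek, el,
                Gion_pas, Epas, Cm, Cmy, Gmy, ga, gp,
                profile_mV, w_new, e_arr, V, u, a_old,
                i00, i01, i10, i11, r1t, r2t, a_new, u_new,
            )

        bad = False
        for i in range(n):
            u[i] = u_new[i]
            a_old[i] = a_new[i]
            V[i] = a_new[i] - u_new[i]
            e_arr[i] = profile_mV[i] * w_new
            if not math.isfinite(V[i]):
                bad = True
        if bad:
            return crossed_t, -1, vmax
        t = t_new

        vnow = -1.0e30
        any_crossed = False
        for j in range(n_nodes):
            v = V[node_idx[j]]
            if v > vnow:
                vnow = v
            if crossed_t[j] < 0.0 and v >= 0.0:
                crossed_t[j] = t
            if crossed_t[j] >= 0.0:
                any_crossed = True
        if vnow > vmax:
            vmax = vnow
        # early exits: propagation reached an end, or clearly subthreshold
        if (
            crossed_t[0] >= 0.0 and crossed_t[1] >= 0.0 and crossed_t[2] >= 0.0
        ) or (
            crossed_t[n_nodes - 1] >= 0.0
            and crossed_t[n_nodes - 2] >= 0.0
            and crossed_t[n_nodes - 3] >= 0.0
        ):
            status = 1
            break
        if (not any_crossed) and t > sub_exit_t_ms and vnow < sub_exit_v_mV:
            break
    return crossed_t, status, vmax
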