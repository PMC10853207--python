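"""Compiled integration kernel for the microbial-explicit model.

A numba port of the RK4 integrator in :mod:`soilprime.mend`. The Python
implementation remains the documented reference; the test suite asserts
that both produce identical trajectories to machine precision, and
:func:`soilprime.mend.simulate_mend` falls back to the Python path when
numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally installed
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(fn):
            return fn
        return deco if not (a and callable(a[0])) else a[0]

# parameter-vector layout shared with mend.MendParams.as_vector()
(P_EP, V_G, ALPHA, K_D, Y_G, R_E, FP_EM, F_D, G_D, K_YG, BETA, PSI_A2D,
 Q10, VP_O, VP_H, V_M, KP_O, KP_H, K_M, K_B, T_REF, Y_G_MIN, THETA_REF,
 PH_OPT, SIGMA_PH) = range(25)


@njit(cache=False)
def _deriv(pools, out, pv, temp_c, theta, ph, lit, a13, sp0, sp1, sp2):
    # environmental scalars
    f_t = pv[Q10] ** ((temp_c - pv[T_REF]) / 10.0)
    if theta > 0.0:
        f_w = (theta / pv[THETA_REF]) ** 0.5
        if f_w > 1.0:
            f_w = 1.0
    else:
        f_w = 0.0
    f_ph = np.exp(-0.5 * ((ph - pv[PH_OPT]) / pv[SIGMA_PH]) ** 2)
    sc = f_t * f_w * f_ph

    # combined pools and per-pool labeled fractions
    c = np.empty(8)
    fr = np.empty(8)
    for k in range(8):
        a = pools[0, k]
        b = pools[1, k]
        if a < 0.0:
            a = 0.0
        if b < 0.0:
            b = 0.0
        tot = a + b
        c[k] = tot
        fr[k] = b / tot if tot > 0.0 else 0.0

    po, ph_, m, d, ba, bd, eo, eh = (c[0], c[1], c[2], c[3], c[4], c[5],
                                     c[6], c[7])
    f_o = pv[VP_O] * eo * po / (pv[KP_O] + po) * sc
    f_h = pv[VP_H] * eh * ph_ / (pv[KP_H] + ph_) * sc
    f_m = pv[V_M] * eo * m / (pv[K_M] + m) * sc
    s_sat = d / (pv[K_D] + d)
    y_gt = pv[Y_G] - pv[K_YG] * (temp_c - pv[T_REF])
    if y_gt < pv[Y_G_MIN]:
        y_gt = pv[Y_G_MIN]
    v_mt = pv[ALPHA] * pv[V_G] / (1.0 - pv[ALPHA])
    base = s_sat * ba * sc
    growth = pv[V_G] * base
    maint = v_mt * base
    uptake = (pv[V_G] + v_mt) * base / y_gt
    overflow = uptake - growth - maint
    dorm_maint = pv[BETA] * v_mt * bd
    eprod_h = pv[P_EP] * ba
    eprod_o = pv[FP_EM] * pv[P_EP] * ba
    eturn_o = pv[R_E] * eo
    eturn_h = pv[R_E] * eh
    mort = pv[K_B] * ba
    a2d = pv[PSI_A2D] * (1.0 - s_sat) * ba
    d2a = pv[PSI_A2D] * s_sat * bd

    for ch in range(2):
        if ch == 0:
            w0, w1, w2, w3 = 1.0 - fr[0], 1.0 - fr[1], 1.0 - fr[2], \
                1.0 - fr[3]
            w4, w5, w6, w7 = 1.0 - fr[4], 1.0 - fr[5], 1.0 - fr[6], \
                1.0 - fr[7]
            li = lit * (1.0 - a13)
        else:
            w0, w1, w2, w3 = fr[0], fr[1], fr[2], fr[3]
            w4, w5, w6, w7 = fr[4], fr[5], fr[6], fr[7]
            li = lit * a13
        fo_c = f_o * w0
        fh_c = f_h * w1
        fm_c = f_m * w2
        up_c = uptake * w3
        gr_c = growth * w3
        mn_c = maint * w3
        ov_c = overflow * w3
        dm_c = dorm_maint * w5
        epo_c = eprod_o * w4
        eph_c = eprod_h * w4
        to_c = eturn_o * w6
        th_c = eturn_h * w7
        mo_c = mort * w4
        a2d_c = a2d * w4
        d2a_c = d2a * w5
        out[ch, 0] = -fo_c + li * sp0
        out[ch, 1] = -fh_c + (1.0 - pv[G_D]) * mo_c + li * sp1
        out[ch, 2] = (1.0 - pv[F_D]) * (fo_c + fh_c) - fm_c
        out[ch, 3] = (pv[F_D] * (fo_c + fh_c) + fm_c - up_c + to_c + th_c
                      + pv[G_D] * mo_c + li * sp2)
        out[ch, 4] = gr_c - epo_c - eph_c - mo_c - a2d_c + d2a_c
        out[ch, 5] = a2d_c - d2a_c - dm_c
        out[ch, 6] = epo_c - to_c
        out[ch, 7] = eph_c - th_c
        out[ch, 8] = mn_c + ov_c + dm_c


@njit(cache=False)
def integrate(pools0, pv, temp, theta, ph, lit, a13, dt_forcing,
              sp0, sp1, sp2, step_h, out_every_h, n_out):
    """RK4 with recursive step halving on negativity (iterative form).

    Returns (trajectory, status); status 0 = ok, 1 = step underflow,
    2 = non-finite state.
    """
    n_f = temp.shape[0]
    traj = np.empty((n_out + 1, 2, 9))
    state = pools0.copy()
    traj[0] = state
    k1 = np.empty((2, 9))
    k2 = np.empty((2, 9))
    k3 = np.empty((2, 9))
    k4 = np.empty((2, 9))
    tmp = np.empty((2, 9))
    nxt = np.empty((2, 9))
    t = 0.0
    t_end0 = n_out * out_every_h
    for i_out in range(n_out):
        t_target = (i_out + 1) * out_every_h
        while t < t_target - 1e-9:
            h = step_h
            if t + h > t_target:
                h = t_target - t
            halvings = 0
            while True:
                # forcing at segment start (piecewise constant)
                ok = True
                for stage in range(4):
                    if stage == 0:
                        ts = t
                        src = state
                    elif stage == 1:
                        ts = t + 0.5 * h
                        for ch in range(2):
                            for k in range(9):
                                tmp[ch, k] = state[ch, k] \
                                    + 0.5 * h * k1[ch, k]
                        src = tmp
                    elif stage == 2:
                        ts = t + 0.5 * h
                        for ch in range(2):
                            for k in range(9):
                                tmp[ch, k] = state[ch, k] \
                                    + 0.5 * h * k2[ch, k]
                        src = tmp
                    else:
                        ts = t + h
                        for ch in range(2):
                            for k in range(9):
                                tmp[ch, k] = state[ch, k] + h * k3[ch, k]
                        src = tmp
                    tt = ts
                    if tt > t_end0 - 1e-9:
                        tt = t_end0 - 1e-9
                    idx = int(tt / dt_forcing)
                    if idx >= n_f:
                        idx = n_f - 1
                    if idx < 0:
                        idx = 0
                    if stage == 0:
                        _deriv(src, k1, pv, temp[idx], theta[idx],
                               ph[idx], lit[idx], a13[idx], sp0, sp1, sp2)
                    elif stage == 1:
                        _deriv(src, k2, pv, temp[idx], theta[idx],
                               ph[idx], lit[idx], a13[idx], sp0, sp1, sp2)
                    elif stage == 2:
                        _deriv(src, k3, pv, temp[idx], theta[idx],
                               ph[idx], lit[idx], a13[idx], sp0, sp1, sp2)
                    else:
                        _deriv(src, k4, pv, temp[idx], theta[idx],
                               ph[idx], lit[idx], a13[idx], sp0, sp1, sp2)
                neg = False
                for ch in range(2):
                    for k in range(9):
                        nxt[ch, k] = state[ch, k] + (h / 6.0) * (
                            k1[ch, k] + 2.0 * k2[ch, k]
                            + 2.0 * k3[ch, k] + k4[ch, k])
                        if nxt[ch, k] < -1e-9:
                            neg = True
                        if not np.isfinite(nxt[ch, k]):
                            return traj, 2
                if not neg:
                    break
                halvings += 1
                if halvings > 40:
                    return traj, 1
                h *= 0.5
            for ch in range(2):
                for k in range(9):
                    state[ch, k] = nxt[ch, k]
            t += h
        traj[i_out + 1] = state
    return traj, 0
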