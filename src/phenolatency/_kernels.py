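"""Compiled fixed-step integrators for the within-season delay systems.

The within-season dynamics are delay differential equations whose only
delayed quantity is the infection flux ``beta * s(t - tau) * v(t - tau)``.
Because the pre-season history is identically zero, the method of steps
reduces to a single forward pass: a classical fixed-step RK4 sweep in which
the delayed flux is read back from the already-computed solution grid
(linear interpolation at half-step stage times).  Each strain's delay is
snapped to the nearest whole number of steps, so the delayed lookups land on
(or midway between) stored grid points.

These kernels are deliberately free of Python objects so numba can compile
them; the public API wraps them in ``within_season``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

OK = 0
NEGATIVE_STATE = 1

# states more negative than this abort the integration; smaller dips are
# clamped to zero as solver noise
NEG_TOL = -1e-9


@njit(inline="always")
def _g(u, tl, inv_tl):
    # uniform emergence density; half weight exactly on the window edge so
    # the RK4 stage straddling the discontinuity is sampled symmetrically
    if u < tl - 1e-12:
        return inv_tl
    if u > tl + 1e-12:
        return 0.0
    return 0.5 * inv_tl


@njit(cache=False)
def semel_season(
    s_hat,
    v0,
    taus,
    alphas,
    T,
    tl,
    beta,
    mu_s,
    mu_lat,
    mu_rec,
    mu_r,
    delta,
    n_steps,
):
    """One season of the semelparous multi-strain system.

    Returns (status, S, R, V) where S, R are length n_steps+1 grids and V is
    (n_strains, n_steps+1).  Progeny release for strain k is the delayed flux
    beta * s(t - tau_k) * v_k(t - tau_k) discounted by latent-period survival
    exp(-mu_lat * tau_k) and multiplied by alpha_k; recruitment into the
    recovered class is the same flux discounted by exp(-mu_rec * tau_k).
    """
    K = v0.shape[0]
    h = T / n_steps
    inv_tl = 1.0 / tl

    d = np.empty(K, np.int64)
    surv = np.empty(K)
    surv_rec = np.empty(K)
    for k in range(K):
        d[k] = int(round(taus[k] / h))
        surv[k] = np.exp(-mu_lat * taus[k])
        surv_rec[k] = np.exp(-mu_rec * taus[k])

    S = np.zeros(n_steps + 1)
    R = np.zeros(n_steps + 1)
    V = np.zeros((K, n_steps + 1))
    for k in range(K):
        V[k, 0] = v0[k]

    # stage workspaces
    vk1 = np.empty(K)
    vk2 = np.empty(K)
    vk3 = np.empty(K)
    vk4 = np.empty(K)
    P0 = np.empty(K)
    Pm = np.empty(K)
    P1 = np.empty(K)

    status = OK
    for j in range(n_steps):
        t = j * h
        s = S[j]
        r = R[j]

        # delayed infection fluxes at the three stage times (t, t+h/2, t+h);
        # index j-d[k] is the grid point at t - tau_k
        for k in range(K):
            jd = j - d[k]
            if d[k] == 0:
                # delay below half a step: treated as instantaneous below
                P0[k] = Pm[k] = P1[k] = -1.0
            else:
                a = S[jd] * V[k, jd] if jd >= 0 else 0.0
                bb = S[jd + 1] * V[k, jd + 1] if jd + 1 >= 0 else 0.0
                P0[k] = a
                Pm[k] = 0.5 * (a + bb)
                P1[k] = bb

        # k1
        vs = 0.0
        for k in range(K):
            vs += V[k, j]
        ds1 = s_hat * _g(t, tl, inv_tl) - mu_s * s - beta * s * vs
        dr1 = -mu_r * r
        for k in range(K):
            p = P0[k] if P0[k] >= 0.0 else s * V[k, j]
            dr1 += beta * surv_rec[k] * p
            vk1[k] = beta * alphas[k] * surv[k] * p - delta * V[k, j] - beta * s * V[k, j]

        # k2
        s2 = s + 0.5 * h * ds1
        r2 = r + 0.5 * h * dr1
        vs = 0.0
        for k in range(K):
            vs += V[k, j] + 0.5 * h * vk1[k]
        ds2 = s_hat * _g(t + 0.5 * h, tl, inv_tl) - mu_s * s2 - beta * s2 * vs
        dr2 = -mu_r * r2
        for k in range(K):
            vk = V[k, j] + 0.5 * h * vk1[k]
            p = Pm[k] if Pm[k] >= 0.0 else s2 * vk
            dr2 += beta * surv_rec[k] * p
            vk2[k] = beta * alphas[k] * surv[k] * p - delta * vk - beta * s2 * vk

        # k3
        s3 = s + 0.5 * h * ds2
        r3 = r + 0.5 * h * dr2
        vs = 0.0
        for k in range(K):
            vs += V[k, j] + 0.5 * h * vk2[k]
        ds3 = s_hat * _g(t + 0.5 * h, tl, inv_tl) - mu_s * s3 - beta * s3 * vs
        dr3 = -mu_r * r3
        for k in range(K):
            vk = V[k, j] + 0.5 * h * vk2[k]
            p = Pm[k] if Pm[k] >= 0.0 else s3 * vk
            dr3 += beta * surv_rec[k] * p
            vk3[k] = beta * alphas[k] * surv[k] * p - delta * vk - beta * s3 * vk

        # k4
        s4 = s + h * ds3
        r4 = r + h * dr3
        vs = 0.0
        for k in range(K):
            vs += V[k, j] + h * vk3[k]
        ds4 = s_hat * _g(t + h, tl, inv_tl) - mu_s * s4 - beta * s4 * vs
        dr4 = -mu_r * r4
        for k in range(K):
            vk = V[k, j] + h * vk3[k]
            p = P1[k] if P1[k] >= 0.0 else s4 * vk
            dr4 += beta * surv_rec[k] * p
            vk4[k] = beta * alphas[k] * surv[k] * p - delta * vk - beta * s4 * vk

        sn = s + (h / 6.0) * (ds1 + 2.0 * ds2 + 2.0 * ds3 + ds4)
        rn = r + (h / 6.0) * (dr1 + 2.0 * dr2 + 2.0 * dr3 + dr4)
        if sn < 0.0:
            if sn < NEG_TOL * max(1.0, s_hat):
                status = NEGATIVE_STATE
            sn = 0.0
        if rn < 0.0:
            if rn < NEG_TOL * max(1.0, s_hat):
                status = NEGATIVE_STATE
            rn = 0.0
        S[j + 1] = sn
        R[j + 1] = rn
        for k in range(K):
            vn = V[k, j] + (h / 6.0) * (vk1[k] + 2.0 * vk2[k] + 2.0 * vk3[k] + vk4[k])
            if vn < 0.0:
                if vn < NEG_TOL * max(1.0, v0[k]):
                    status = NEGATIVE_STATE
                vn = 0.0
            V[k, j + 1] = vn

    return status, S, R, V


@njit(cache=False)
def itero_season(
    s_hat,
    v0,
    taus,
    alphas,
    T,
    tl,
    beta,
    mu_s,
    mu_lat,
    mu_i,
    mu_r,
    gamma,
    delta,
    n_steps,
):
    """One season of the iteroparous multi-strain system.

    Hosts infected by strain k enter an infectious stage i_k a delay tau_k
    after infection (surviving latency with probability exp(-mu_lat*tau_k)),
    release progeny at rate alpha_k per unit time, and recover at rate gamma.
    Returns (status, S, I, R, V) with I, V shaped (n_strains, n_steps+1).
    """
    K = v0.shape[0]
    h = T / n_steps
    inv_tl = 1.0 / tl

    d = np.empty(K, np.int64)
    surv = np.empty(K)
    for k in range(K):
        d[k] = int(round(taus[k] / h))
        surv[k] = np.exp(-mu_lat * taus[k])

    S = np.zeros(n_steps + 1)
    R = np.zeros(n_steps + 1)
    I = np.zeros((K, n_steps + 1))
    V = np.zeros((K, n_steps + 1))
    for k in range(K):
        V[k, 0] = v0[k]

    ik1 = np.empty(K)
    ik2 = np.empty(K)
    ik3 = np.empty(K)
    ik4 = np.empty(K)
    vk1 = np.empty(K)
    vk2 = np.empty(K)
    vk3 = np.empty(K)
    vk4 = np.empty(K)
    P0 = np.empty(K)
    Pm = np.empty(K)
    P1 = np.empty(K)

    status = OK
    for j in range(n_steps):
        t = j * h
        s = S[j]
        r = R[j]

        for k in range(K):
            jd = j - d[k]
            if d[k] == 0:
                P0[k] = Pm[k] = P1[k] = -1.0
            else:
                a = S[jd] * V[k, jd] if jd >= 0 else 0.0
                bb = S[jd + 1] * V[k, jd + 1] if jd + 1 >= 0 else 0.0
                P0[k] = a
                Pm[k] = 0.5 * (a + bb)
                P1[k] = bb

        # k1
        vs = 0.0
        for k in range(K):
            vs += V[k, j]
        ds1 = s_hat * _g(t, tl, inv_tl) - mu_s * s - beta * s * vs
        dr1 = -mu_r * r
        for k in range(K):
            p = P0[k] if P0[k] >= 0.0 else s * V[k, j]
            ik1[k] = beta * surv[k] * p - (mu_i + gamma) * I[k, j]
            dr1 += gamma * I[k, j]
            vk1[k] = alphas[k] * I[k, j] - delta * V[k, j] - beta * s * V[k, j]

        # k2
        s2 = s + 0.5 * h * ds1
        r2 = r + 0.5 * h * dr1
        vs = 0.0
        for k in range(K):
            vs += V[k, j] + 0.5 * h * vk1[k]
        ds2 = s_hat * _g(t + 0.5 * h, tl, inv_tl) - mu_s * s2 - beta * s2 * vs
        dr2 = -mu_r * r2
        for k in range(K):
            ik = I[k, j] + 0.5 * h * ik1[k]
            vk = V[k, j] + 0.5 * h * vk1[k]
            p = Pm[k] if Pm[k] >= 0.0 else s2 * vk
            ik2[k] = beta * surv[k] * p - (mu_i + gamma) * ik
            dr2 += gamma * ik
            vk2[k] = alphas[k] * ik - delta * vk - beta * s2 * vk

        # k3
        s3 = s + 0.5 * h * ds2
        r3 = r + 0.5 * h * dr2
        vs = 0.0
        for k in range(K):
            vs += V[k, j] + 0.5 * h * vk2[k]
        ds3 = s_hat * _g(t + 0.5 * h, tl, inv_tl) - mu_s * s3 - beta * s3 * vs
        dr3 = -mu_r * r3
        for k in range(K):
            ik = I[k, j] + 0.5 * h * ik2[k]
            vk = V[k, j] + 0.5 * h * vk2[k]
            p = Pm[k] if Pm[k] >= 0.0 else s3 * vk
            ik3[k] = beta * surv[k] * p - (mu_i + gamma) * ik
            dr3 += gamma * ik
            vk3[k] = alphas[k] * ik - delta * vk - beta * s3 * vk

        # k4
        s4 = s + h * ds3
        r4 = r + h * dr3
        vs = 0.0
        for k in range(K):
            vs += V[k, j] + h * vk3[k]
        ds4 = s_hat * _g(t + h, tl, inv_tl) - mu_s * s4 - beta * s4 * vs
        dr4 = -mu_r * r4
        for k in range(K):
            ik = I[k, j] + h * ik3[k]
            vk = V[k, j] + h * vk3[k]
            p = P1[k] if P1[k] >= 0.0 else s4 * vk
            ik4[k] = beta * surv[k] * p - (mu_i + gamma) * ik
            dr4 += gamma * ik
            vk4[k] = alphas[k] * ik - delta * vk - beta * s4 * vk

        sn = s + (h / 6.0) * (ds1 + 2.0 * ds2 + 2.0 * ds3 + ds4)
        rn = r + (h / 6.0) * (dr1 + 2.0 * dr2 + 2.0 * dr3 + dr4)
        if sn < 0.0:
            if sn < NEG_TOL * max(1.0, s_hat):
                status = NEGATIVE_STATE
            sn = 0.0
        if rn < 0.0:
            if rn < NEG_TOL * max(1.0, s_hat):
                status = NEGATIVE_STATE
            rn = 0.0
        S[j + 1] = sn
        R[j + 1] = rn
        for k in range(K):
            inext = I[k, j] + (h / 6.0) * (ik1[k] + 2.0 * ik2[k] + 2.0 * ik3[k] + ik4[k])
            vn = V[k, j] + (h / 6.0) * (vk1[k] + 2.0 * vk2[k] + 2.0 * vk3[k] + vk4[k])
            if inext < 0.0:
                if inext < NEG_TOL * max(1.0, s_hat):
                    status = NEGATIVE_STATE
                inext = 0.0
            if vn < 0.0:
                if vn < NEG_TOL * max(1.0, v0[k]):
                    status = NEGATIVE_STATE
                vn = 0.0
            I[k, j + 1] = inext
            V[k, j + 1] = vn

    return status, S, I, R, V
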