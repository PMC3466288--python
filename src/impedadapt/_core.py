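"""Compiled inner loop of the trial simulation.

Repeats, in numba-compiled form, exactly the per-time-step chain of the
reference implementation (reference lengths -> feedforward -> tracking and
sliding error -> V-shaped feedback -> visco-elastic muscle tension -> field
force -> RK4 motion integration -> error accumulation for learning).  The
pure-Python engine in :mod:`impedadapt.simulate` is the readable source of
truth; an equivalence test keeps the two in lockstep.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sim_trial_core"]


@njit(cache=True)
def _dyn_eval(
    q1, q2, qd1, qd2, u, lr, lrd,
    l1, l2, m1, m2, lc1, lc2, I1, I2, Bj,
    A, l0, qref, T0, k0, k1, b0, b1,
    ftype, FB, dfp,
):
    """Joint accelerations of the muscle-driven plant at one evaluation point."""
    # muscle lengths and stretch relative to the reference
    T = np.empty(6)
    tau1 = 0.0
    tau2 = 0.0
    for m in range(6):
        lm = l0[m] - A[0, m] * (q1 - qref[0]) - A[1, m] * (q2 - qref[1])
        lmd = -A[0, m] * qd1 - A[1, m] * qd2
        e = lm - lr[m]
        ed = lmd - lrd[m]
        Tm = T0[m] * u[m] + (k0 + k1 * u[m]) * e + (b0 + b1 * u[m]) * ed
        if Tm < 0.0:
            Tm = 0.0
        T[m] = Tm
        tau1 += A[0, m] * Tm
        tau2 += A[1, m] * Tm

    # hand kinematics
    s1 = np.sin(q1)
    c1 = np.cos(q1)
    s12 = np.sin(q1 + q2)
    c12 = np.cos(q1 + q2)
    px = l1 * c1 + l2 * c12
    py = l1 * s1 + l2 * s12
    J11 = -l1 * s1 - l2 * s12
    J12 = -l2 * s12
    J21 = l1 * c1 + l2 * c12
    J22 = l2 * c12
    vx = J11 * qd1 + J12 * qd2
    vy = J21 * qd1 + J22 * qd2

    # environment force at the hand
    Fx = 0.0
    Fy = 0.0
    if ftype == 0:
        Fx = FB[0, 0] * vx + FB[0, 1] * vy
        Fy = FB[1, 0] * vx + FB[1, 1] * vy
    else:
        gain = dfp[0]
        sx = dfp[1]
        sy = dfp[2]
        gx = dfp[3]
        gy = dfp[4]
        thr = dfp[5]
        damp = dfp[6]
        rend = dfp[7]
        axx = gx - sx
        axy = gy - sy
        nrm = np.sqrt(axx * axx + axy * axy)
        nx = axx / nrm
        ny = axy / nrm
        lx = -ny
        ly = nx
        ds = np.sqrt((px - sx) ** 2 + (py - sy) ** 2)
        dg = np.sqrt((px - gx) ** 2 + (py - gy) ** 2)
        if ds >= rend and dg >= rend:
            plat = lx * (px - sx) + ly * (py - sy)
            if np.abs(plat) <= thr:
                Fx = gain * plat * lx
                Fy = gain * plat * ly
            else:
                vlat = lx * vx + ly * vy
                Fx = -damp * vlat * lx
                Fy = -damp * vlat * ly

    # rigid-body dynamics
    a = I1 + I2 + m1 * lc1 * lc1 + m2 * (l1 * l1 + lc2 * lc2)
    bb = m2 * l1 * lc2
    d = I2 + m2 * lc2 * lc2
    c2m = np.cos(q2)
    M11 = a + 2.0 * bb * c2m
    M12 = d + bb * c2m
    M22 = d
    h = bb * np.sin(q2)
    cor1 = -h * qd2 * qd1 - h * (qd1 + qd2) * qd2
    cor2 = h * qd1 * qd1
    r1 = (
        tau1
        + J11 * Fx + J21 * Fy
        - cor1
        - Bj[0, 0] * qd1 - Bj[0, 1] * qd2
    )
    r2 = (
        tau2
        + J12 * Fx + J22 * Fy
        - cor2
        - Bj[1, 0] * qd1 - Bj[1, 1] * qd2
    )
    det = M11 * M22 - M12 * M12
    qdd1 = (M22 * r1 - M12 * r2) / det
    qdd2 = (M11 * r2 - M12 * r1) / det
    return qdd1, qdd2, T, Fx, Fy, px, py, vx, vy


@njit(cache=True)
def sim_trial_core(
    dt, n_steps,
    q0, qd0,
    lr, lrd,
    lr_err, lrd_err,
    l1, l2, m1, m2, lc1, lc2, I1, I2, Bj,
    A, l0, qref,
    T0, k0, k1, b0, b1,
    aplus, aminus, kappa, d_steps,
    u_base,
    C, S, W, xm, xs,
    ftype, FB, dfp,
    cv, alpha_noise, Z, noise_on,
    max_speed,
):
    n = n_steps
    N = C.shape[0]
    Q = np.empty((n + 1, 2))
    QD = np.empty((n + 1, 2))
    HAND = np.empty((n + 1, 2))
    UFF = np.zeros((n, 6))
    UFB = np.zeros((n, 6))
    U = np.zeros((n, 6))
    TT = np.zeros((n, 6))
    E = np.zeros((n, 6))
    SARR = np.zeros((n, 6))
    ED = np.zeros((n, 6))
    FX = np.zeros((n, 2))
    Gs = np.zeros((6, N))
    Gabs = np.zeros((6, N))
    aborted = 0

    q1 = q0[0]
    q2 = q0[1]
    qd1 = qd0[0]
    qd2 = qd0[1]
    Q[0, 0] = q1
    Q[0, 1] = q2
    QD[0, 0] = qd1
    QD[0, 1] = qd2
    HAND[0, 0] = l1 * np.cos(q1) + l2 * np.cos(q1 + q2)
    HAND[0, 1] = l1 * np.sin(q1) + l2 * np.sin(q1 + q2)

    nstate = np.zeros(6)
    beta_noise = np.sqrt(1.0 - alpha_noise * alpha_noise)
    g = np.empty(N)
    u = np.empty(6)
    n_filled = 0

    for i in range(n):
        # tracking error at the step grid (error reference may differ from
        # the mechanical equilibrium reference, e.g. an empirical mean path)
        for m in range(6):
            lm = l0[m] - A[0, m] * (q1 - qref[0]) - A[1, m] * (q2 - qref[1])
            lmd = -A[0, m] * qd1 - A[1, m] * qd2
            E[i, m] = lm - lr_err[2 * i, m]
            ED[i, m] = lmd - lrd_err[2 * i, m]
            SARR[i, m] = E[i, m] + kappa * ED[i, m]

        # delayed sliding error -> V-shaped feedback
        for m in range(6):
            if i >= d_steps:
                eps = E[i - d_steps, m] + kappa * ED[i - d_steps, m]
            else:
                eps = 0.0
            if eps > 0.0:
                UFB[i, m] = aplus * eps
            else:
                UFB[i, m] = -aminus * eps

        # feedforward from the network at the current state
        for j in range(N):
            d2 = 0.0
            z0 = ((q1 - xm[0]) / xs[0] - C[j, 0]) / S[j, 0]
            z1 = ((q2 - xm[1]) / xs[1] - C[j, 1]) / S[j, 1]
            z2 = ((qd1 - xm[2]) / xs[2] - C[j, 2]) / S[j, 2]
            z3 = ((qd2 - xm[3]) / xs[3] - C[j, 3]) / S[j, 3]
            d2 = z0 * z0 + z1 * z1 + z2 * z2 + z3 * z3
            g[j] = np.exp(-0.5 * d2)
        for m in range(6):
            acc = 0.0
            for j in range(N):
                acc += W[m, j] * g[j]
            if acc < 0.0:
                acc = 0.0
            UFF[i, m] = acc

        # error-drive accumulation for between-trial learning
        for m in range(6):
            sm = SARR[i, m]
            am = np.abs(sm)
            for j in range(N):
                Gs[m, j] += sm * g[j] * dt
                Gabs[m, j] += am * g[j] * dt

        # motor command with signal-dependent, low-pass filtered noise
        for m in range(6):
            cmd = u_base + UFF[i, m] + UFB[i, m]
            if noise_on == 1:
                nstate[m] = alpha_noise * nstate[m] + beta_noise * Z[i, m]
                cmd = cmd * (1.0 + cv * nstate[m])
            if cmd < 0.0:
                cmd = 0.0
            u[m] = cmd
            U[i, m] = cmd

        # RK4 on the rigid-body + muscle dynamics, command held
        k1a, k1b, T, Fx, Fy, px, py, vx, vy = _dyn_eval(
            q1, q2, qd1, qd2, u, lr[2 * i], lrd[2 * i],
            l1, l2, m1, m2, lc1, lc2, I1, I2, Bj,
            A, l0, qref, T0, k0, k1, b0, b1, ftype, FB, dfp,
        )
        for m in range(6):
            TT[i, m] = T[m]
        FX[i, 0] = Fx
        FX[i, 1] = Fy

        h2 = dt / 2.0
        q1b = q1 + h2 * qd1
        q2b = q2 + h2 * qd2
        qd1b = qd1 + h2 * k1a
        qd2b = qd2 + h2 * k1b
        k2a, k2b, _, _, _, _, _, _, _ = _dyn_eval(
            q1b, q2b, qd1b, qd2b, u, lr[2 * i + 1], lrd[2 * i + 1],
            l1, l2, m1, m2, lc1, lc2, I1, I2, Bj,
            A, l0, qref, T0, k0, k1, b0, b1, ftype, FB, dfp,
        )
        q1c = q1 + h2 * qd1b
        q2c = q2 + h2 * qd2b
        qd1c = qd1 + h2 * k2a
        qd2c = qd2 + h2 * k2b
        k3a, k3b, _, _, _, _, _, _, _ = _dyn_eval(
            q1c, q2c, qd1c, qd2c, u, lr[2 * i + 1], lrd[2 * i + 1],
            l1, l2, m1, m2, lc1, lc2, I1, I2, Bj,
            A, l0, qref, T0, k0, k1, b0, b1, ftype, FB, dfp,
        )
        q1d = q1 + dt * qd1c
        q2d = q2 + dt * qd2c
        qd1d = qd1 + dt * k3a
        qd2d = qd2 + dt * k3b
        k4a, k4b, _, _, _, _, _, _, _ = _dyn_eval(
            q1d, q2d, qd1d, qd2d, u, lr[2 * i + 2], lrd[2 * i + 2],
            l1, l2, m1, m2, lc1, lc2, I1, I2, Bj,
            A, l0, qref, T0, k0, k1, b0, b1, ftype, FB, dfp,
        )
        q1n = q1 + dt / 6.0 * (qd1 + 2.0 * qd1b + 2.0 * qd1c + qd1d)
        q2n = q2 + dt / 6.0 * (qd2 + 2.0 * qd2b + 2.0 * qd2c + qd2d)
        qd1n = qd1 + dt / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        qd2n = qd2 + dt / 6.0 * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)

        q1, q2, qd1, qd2 = q1n, q2n, qd1n, qd2n
        Q[i + 1, 0] = q1
        Q[i + 1, 1] = q2
        QD[i + 1, 0] = qd1
        QD[i + 1, 1] = qd2
        s1 = np.sin(q1)
        c1 = np.cos(q1)
        s12 = np.sin(q1 + q2)
        c12 = np.cos(q1 + q2)
        HAND[i + 1, 0] = l1 * c1 + l2 * c12
        HAND[i + 1, 1] = l1 * s1 + l2 * s12
        hvx = (-l1 * s1 - l2 * s12) * qd1 + (-l2 * s12) * qd2
        hvy = (l1 * c1 + l2 * c12) * qd1 + (l2 * c12) * qd2
        n_filled = i + 1
        if np.sqrt(hvx * hvx + hvy * hvy) > max_speed:
            aborted = 1
            break

    return (
        Q, QD, HAND, UFF, UFB, U, TT, E, ED, SARR, FX,
        Gs, Gabs, aborted, n_filled,
    )
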