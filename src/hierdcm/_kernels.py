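"""Numba kernels for the bilinear neural ODE and the balloon model.

The neural state obeys dx/dt = [A + sum_j u_j(t) B(j)] x between driving
events; driving impulses are unit-weight Dirac deltas applied as
instantaneous increments x += C w at their onset bin, which keeps the
forward model invariant to the integration step (impulse times sit on
every admissible grid).  The forward path integrates the neural and
hemodynamic states jointly with fixed-step classical Runge-Kutta (RK4),
so the combined system is smooth within bins and converges at fourth
order; modulatory inputs are piecewise constant over bins.

A standalone hemodynamic kernel driven by a recorded neural trajectory
(linear interpolation between bin samples) is kept for the modular API;
it is second-order accurate in the input representation.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def neural_rk4(A, B, C, drive, mod, x0, dt, guard):
    """Integrate the bilinear state equation alone.

    Returns (X, status): X[t] is the state at time t*dt after the driving
    kicks of that bin; status 1 flags divergence beyond ``guard``.
    """
    T = drive.shape[0]
    n = A.shape[0]
    nmod = B.shape[0]
    ndrv = C.shape[1]
    X = np.zeros((T, n))
    x = x0.copy()
    M = np.empty((n, n))
    for t in range(T):
        for k in range(ndrv):
            w = drive[t, k]
            if w != 0.0:
                for i in range(n):
                    x[i] += C[i, k] * w
        for i in range(n):
            for j in range(n):
                m = A[i, j]
                for jm in range(nmod):
                    um = mod[t, jm]
                    if um != 0.0:
                        m += um * B[jm, i, j]
                M[i, j] = m
        for i in range(n):
            X[t, i] = x[i]
        k1 = M @ x
        k2 = M @ (x + (0.5 * dt) * k1)
        k3 = M @ (x + (0.5 * dt) * k2)
        k4 = M @ (x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        for i in range(n):
            if not (np.abs(x[i]) <= guard):
                return X, 1
    return X, 0


@njit(cache=True, fastmath=True)
def _hemo_deriv(xin, s, f, v, q, kappa, gamma, tau, ialpha, E0, lnE):
    if f < 1e-6:
        f = 1e-6
    if v < 1e-6:
        v = 1e-6
    ds = xin - kappa * s - gamma * (f - 1.0)
    df = s
    fout = np.exp(ialpha * np.log(v))  # v ** (1/alpha)
    dv = (f - fout) / tau
    # oxygen extraction E(f) = 1 - (1 - E0)^(1/f)
    dq = (f * (1.0 - np.exp(lnE / f)) / E0 - fout * q / v) / tau
    return ds, df, dv, dq


@njit(cache=True, fastmath=True)
def hemo_rk4(X, dt, kappa, gamma, tau, alpha, E0, eps, V0):
    """Balloon-type hemodynamics driven by a recorded neural trajectory.

    X is the (T, n) neural state at microtime bins; the neural input is
    linearly interpolated between samples.  Returns percent-signal-change
    BOLD on the same grid (zero at rest).
    """
    T, n = X.shape
    Y = np.zeros((T, n))
    ialpha = 1.0 / alpha
    lnE = np.log(1.0 - E0)
    k1c = 7.0 * E0
    k2c = 2.0
    k3c = 2.0 * E0 - 0.2
    half = 0.5 * dt
    for r in range(n):
        er = eps[r]
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            Y[t, r] = 100.0 * V0 * (k1c * (1.0 - q) + k2c * (1.0 - q / v) + k3c * (1.0 - v))
            x0 = er * X[t, r]
            x1 = er * X[t + 1, r] if t + 1 < T else x0
            xm = 0.5 * (x0 + x1)
            d1s, d1f, d1v, d1q = _hemo_deriv(x0, s, f, v, q, kappa, gamma, tau, ialpha, E0, lnE)
            d2s, d2f, d2v, d2q = _hemo_deriv(
                xm, s + half * d1s, f + half * d1f, v + half * d1v, q + half * d1q,
                kappa, gamma, tau, ialpha, E0, lnE)
            d3s, d3f, d3v, d3q = _hemo_deriv(
                xm, s + half * d2s, f + half * d2f, v + half * d2v, q + half * d2q,
                kappa, gamma, tau, ialpha, E0, lnE)
            d4s, d4f, d4v, d4q = _hemo_deriv(
                x1, s + dt * d3s, f + dt * d3f, v + dt * d3v, q + dt * d3q,
                kappa, gamma, tau, ialpha, E0, lnE)
            s += (dt / 6.0) * (d1s + 2.0 * d2s + 2.0 * d3s + d4s)
            f += (dt / 6.0) * (d1f + 2.0 * d2f + 2.0 * d3f + d4f)
            v += (dt / 6.0) * (d1v + 2.0 * d2v + 2.0 * d3v + d4v)
            q += (dt / 6.0) * (d1q + 2.0 * d2q + 2.0 * d3q + d4q)
    return Y


@njit(cache=True, fastmath=True)
def simulate_bold_jac(A, B, C, drive, mod, x0, dt, decim,
                      kappa, gamma, tau, alpha, E0, eps, V0, guard,
                      ptype, pri, prj, pmod, pcoef):
    """Forward model plus exact Jacobian by tangent propagation.

    Parameter directions are encoded per column p: ``ptype`` 0 perturbs the
    coupling matrix entry (pri, prj) with weight ``pcoef`` (1 for free A
    entries; the current a_ii for self log-scales), gated by modulatory
    channel ``pmod`` (-1 = always on, i.e. an A entry; >=0 = a B entry);
    ``ptype`` 1 perturbs C[pri, prj] (tangent kicks at impulses).  Tangents
    are propagated through the exact discrete RK4 scheme (forward-mode
    differentiation), so the Jacobian matches the simulated output to
    machine precision.  Returns (bold, J, status) with J of shape
    (scans, n, P).
    """
    T = drive.shape[0]
    n = A.shape[0]
    nmod = B.shape[0]
    ndrv = C.shape[1]
    P = ptype.shape[0]
    nscan = T // decim
    out = np.zeros((nscan, n))
    J = np.zeros((nscan, n, P))

    ialpha = 1.0 / alpha
    lnE = np.log(1.0 - E0)
    k1c = 7.0 * E0
    k2c = 2.0
    k3c = 2.0 * E0 - 0.2
    half = 0.5 * dt
    sixth = dt / 6.0

    # nominal states
    x = x0.copy()
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    # tangent states (P directions)
    dX = np.zeros((P, n))
    dS = np.zeros((P, n))
    dF = np.zeros((P, n))
    dV = np.zeros((P, n))
    dQ = np.zeros((P, n))

    M = np.empty((n, n))
    kx = np.empty((4, n))
    ks = np.empty((4, n))
    kf = np.empty((4, n))
    kv = np.empty((4, n))
    kq = np.empty((4, n))
    kdx = np.empty((P, 4, n))
    kds = np.empty((P, 4, n))
    kdf = np.empty((P, 4, n))
    kdv = np.empty((P, 4, n))
    kdq = np.empty((P, 4, n))
    xs = np.empty(n)
    ss = np.empty(n)
    fs = np.empty(n)
    vs = np.empty(n)
    qs = np.empty(n)
    dxs = np.empty(n)
    dss = np.empty(n)
    dfs = np.empty(n)
    dvs = np.empty(n)
    dqs = np.empty(n)
    # per-stage shared hemodynamic linearization coefficients
    c_dvdv = np.empty(n)
    c_dqdf = np.empty(n)
    c_dqdv = np.empty(n)
    c_dqdq = np.empty(n)

    for t in range(T):
        for k in range(ndrv):
            w = drive[t, k]
            if w != 0.0:
                for i in range(n):
                    x[i] += C[i, k] * w
                for p in range(P):
                    if ptype[p] == 1 and prj[p] == k:
                        dX[p, pri[p]] += w
        any_mod = False
        for jm in range(nmod):
            if mod[t, jm] != 0.0:
                any_mod = True
                break
        if any_mod:
            for i in range(n):
                for j in range(n):
                    m = A[i, j]
                    for jm in range(nmod):
                        um = mod[t, jm]
                        if um != 0.0:
                            m += um * B[jm, i, j]
                    M[i, j] = m
        else:
            for i in range(n):
                for j in range(n):
                    M[i, j] = A[i, j]

        if t % decim == 0:
            row = t // decim
            for r in range(n):
                out[row, r] = 100.0 * V0 * (
                    k1c * (1.0 - q[r]) + k2c * (1.0 - q[r] / v[r]) + k3c * (1.0 - v[r])
                )
                dy_dq = 100.0 * V0 * (-k1c - k2c / v[r])
                dy_dv = 100.0 * V0 * (k2c * q[r] / (v[r] * v[r]) - k3c)
                for p in range(P):
                    J[row, r, p] = dy_dq * dQ[p, r] + dy_dv * dV[p, r]

        for stage in range(4):
            if stage == 0:
                for i in range(n):
                    xs[i] = x[i]
                    ss[i] = s[i]
                    fs[i] = f[i]
                    vs[i] = v[i]
                    qs[i] = q[i]
            else:
                c = half if stage < 3 else dt
                pp = stage - 1
                for i in range(n):
                    xs[i] = x[i] + c * kx[pp, i]
                    ss[i] = s[i] + c * ks[pp, i]
                    fs[i] = f[i] + c * kf[pp, i]
                    vs[i] = v[i] + c * kv[pp, i]
                    qs[i] = q[i] + c * kq[pp, i]
            # nominal stage derivatives + shared linearization coefficients
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    acc += M[i, j] * xs[j]
                kx[stage, i] = acc
            for i in range(n):
                fi = fs[i] if fs[i] > 1e-6 else 1e-6
                vi = vs[i] if vs[i] > 1e-6 else 1e-6
                fout = np.exp(ialpha * np.log(vi))
                g = np.exp(lnE / fi)
                ks[stage, i] = eps[i] * xs[i] - kappa * ss[i] - gamma * (fi - 1.0)
                kf[stage, i] = ss[i]
                kv[stage, i] = (fi - fout) / tau
                kq[stage, i] = (fi * (1.0 - g) / E0 - fout * qs[i] / vi) / tau
                c_dvdv[i] = -ialpha * (fout / vi) / tau
                c_dqdf[i] = ((1.0 - g) + g * lnE / fi) / (E0 * tau)
                c_dqdv[i] = -(ialpha - 1.0) * (fout / (vi * vi)) * qs[i] / tau
                c_dqdq[i] = -(fout / vi) / tau
            # tangent stage derivatives (exact differentiation of the scheme)
            for p in range(P):
                if stage == 0:
                    for i in range(n):
                        dxs[i] = dX[p, i]
                        dss[i] = dS[p, i]
                        dfs[i] = dF[p, i]
                        dvs[i] = dV[p, i]
                        dqs[i] = dQ[p, i]
                else:
                    c = half if stage < 3 else dt
                    pp = stage - 1
                    for i in range(n):
                        dxs[i] = dX[p, i] + c * kdx[p, pp, i]
                        dss[i] = dS[p, i] + c * kds[p, pp, i]
                        dfs[i] = dF[p, i] + c * kdf[p, pp, i]
                        dvs[i] = dV[p, i] + c * kdv[p, pp, i]
                        dqs[i] = dQ[p, i] + c * kdq[p, pp, i]
                for i in range(n):
                    acc = 0.0
                    for j in range(n):
                        acc += M[i, j] * dxs[j]
                    kdx[p, stage, i] = acc
                if ptype[p] == 0:
                    gate = 1.0
                    if pmod[p] >= 0:
                        gate = mod[t, pmod[p]]
                    if gate != 0.0:
                        kdx[p, stage, pri[p]] += pcoef[p] * gate * xs[prj[p]]
                for i in range(n):
                    dxin = eps[i] * dxs[i]
                    kds[p, stage, i] = dxin - kappa * dss[i] - gamma * dfs[i]
                    kdf[p, stage, i] = dss[i]
                    kdv[p, stage, i] = dfs[i] / tau + c_dvdv[i] * dvs[i]
                    kdq[p, stage, i] = c_dqdf[i] * dfs[i] + c_dqdv[i] * dvs[i] + c_dqdq[i] * dqs[i]

        ok = True
        for i in range(n):
            x[i] += sixth * (kx[0, i] + 2.0 * kx[1, i] + 2.0 * kx[2, i] + kx[3, i])
            s[i] += sixth * (ks[0, i] + 2.0 * ks[1, i] + 2.0 * ks[2, i] + ks[3, i])
            f[i] += sixth * (kf[0, i] + 2.0 * kf[1, i] + 2.0 * kf[2, i] + kf[3, i])
            v[i] += sixth * (kv[0, i] + 2.0 * kv[1, i] + 2.0 * kv[2, i] + kv[3, i])
            q[i] += sixth * (kq[0, i] + 2.0 * kq[1, i] + 2.0 * kq[2, i] + kq[3, i])
            if (
                not (np.abs(x[i]) <= guard)
                or not (np.abs(s[i]) <= guard)
                or not (np.abs(q[i]) <= guard)
                or not (v[i] > 1e-9)
                or not (f[i] > -guard)
                or not (f[i] < guard)
                or not (v[i] < guard)
            ):
                ok = False
        if not ok:
            return out, J, 1
        for p in range(P):
            for i in range(n):
                dX[p, i] += sixth * (kdx[p, 0, i] + 2.0 * kdx[p, 1, i] + 2.0 * kdx[p, 2, i] + kdx[p, 3, i])
                dS[p, i] += sixth * (kds[p, 0, i] + 2.0 * kds[p, 1, i] + 2.0 * kds[p, 2, i] + kds[p, 3, i])
                dF[p, i] += sixth * (kdf[p, 0, i] + 2.0 * kdf[p, 1, i] + 2.0 * kdf[p, 2, i] + kdf[p, 3, i])
                dV[p, i] += sixth * (kdv[p, 0, i] + 2.0 * kdv[p, 1, i] + 2.0 * kdv[p, 2, i] + kdv[p, 3, i])
                dQ[p, i] += sixth * (kdq[p, 0, i] + 2.0 * kdq[p, 1, i] + 2.0 * kdq[p, 2, i] + kdq[p, 3, i])
    return out, J, 0


@njit(cache=True, fastmath=True)
def simulate_bold_kernel(A, B, C, drive, mod, x0, dt, decim,
                         kappa, gamma, tau, alpha, E0, eps, V0, guard):
    """Joint neural + hemodynamic forward model decimated to scan times.

    The full state (x, s, f, v, q per region) is advanced by one RK4 step
    per microtime bin with the effective coupling of that bin; driving
    kicks are applied at bin starts.  Returns (bold, status); bold is
    (T // decim, n) percent signal change at bins 0, decim, 2*decim, ...;
    status 1 flags divergence.
    """
    T = drive.shape[0]
    n = A.shape[0]
    nmod = B.shape[0]
    ndrv = C.shape[1]
    nscan = T // decim
    out = np.zeros((nscan, n))

    ialpha = 1.0 / alpha
    lnE = np.log(1.0 - E0)
    k1c = 7.0 * E0
    k2c = 2.0
    k3c = 2.0 * E0 - 0.2
    half = 0.5 * dt
    sixth = dt / 6.0

    x = x0.copy()
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    M = np.empty((n, n))
    # stage buffers
    kx = np.empty((4, n))
    ks = np.empty((4, n))
    kf = np.empty((4, n))
    kv = np.empty((4, n))
    kq = np.empty((4, n))
    xs = np.empty(n)
    ss = np.empty(n)
    fs = np.empty(n)
    vs = np.empty(n)
    qs = np.empty(n)

    for t in range(T):
        for k in range(ndrv):
            w = drive[t, k]
            if w != 0.0:
                for i in range(n):
                    x[i] += C[i, k] * w
        any_mod = False
        for jm in range(nmod):
            if mod[t, jm] != 0.0:
                any_mod = True
                break
        if any_mod:
            for i in range(n):
                for j in range(n):
                    m = A[i, j]
                    for jm in range(nmod):
                        um = mod[t, jm]
                        if um != 0.0:
                            m += um * B[jm, i, j]
                    M[i, j] = m
        else:
            for i in range(n):
                for j in range(n):
                    M[i, j] = A[i, j]

        if t % decim == 0:
            row = t // decim
            for r in range(n):
                out[row, r] = 100.0 * V0 * (
                    k1c * (1.0 - q[r]) + k2c * (1.0 - q[r] / v[r]) + k3c * (1.0 - v[r])
                )

        for stage in range(4):
            if stage == 0:
                for i in range(n):
                    xs[i] = x[i]
                    ss[i] = s[i]
                    fs[i] = f[i]
                    vs[i] = v[i]
                    qs[i] = q[i]
            else:
                c = half if stage < 3 else dt
                p = stage - 1
                for i in range(n):
                    xs[i] = x[i] + c * kx[p, i]
                    ss[i] = s[i] + c * ks[p, i]
                    fs[i] = f[i] + c * kf[p, i]
                    vs[i] = v[i] + c * kv[p, i]
                    qs[i] = q[i] + c * kq[p, i]
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    acc += M[i, j] * xs[j]
                kx[stage, i] = acc
            for i in range(n):
                ds, df, dv, dq = _hemo_deriv(
                    eps[i] * xs[i], ss[i], fs[i], vs[i], qs[i],
                    kappa, gamma, tau, ialpha, E0, lnE)
                ks[stage, i] = ds
                kf[stage, i] = df
                kv[stage, i] = dv
                kq[stage, i] = dq
        ok = True
        for i in range(n):
            x[i] += sixth * (kx[0, i] + 2.0 * kx[1, i] + 2.0 * kx[2, i] + kx[3, i])
            s[i] += sixth * (ks[0, i] + 2.0 * ks[1, i] + 2.0 * ks[2, i] + ks[3, i])
            f[i] += sixth * (kf[0, i] + 2.0 * kf[1, i] + 2.0 * kf[2, i] + kf[3, i])
            v[i] += sixth * (kv[0, i] + 2.0 * kv[1, i] + 2.0 * kv[2, i] + kv[3, i])
            q[i] += sixth * (kq[0, i] + 2.0 * kq[1, i] + 2.0 * kq[2, i] + kq[3, i])
            # divergence guards cover the hemodynamic chain too: negative
            # volume or runaway states make the observation undefined
            if (
                not (np.abs(x[i]) <= guard)
                or not (np.abs(s[i]) <= guard)
                or not (np.abs(q[i]) <= guard)
                or not (v[i] > 1e-9)
                or not (f[i] > -guard)
                or not (f[i] < guard)
                or not (v[i] < guard)
            ):
                ok = False
        if not ok:
            return out, 1
    return out, 0
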