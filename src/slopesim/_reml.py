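"""Profiled-REML kernels for the balanced three-level growth model.

The marginal covariance of one classroom with m students observed at T
shared wave times t (Z = [1, t], D = T_pi / sigma2, psi = tau_beta00 /
sigma2) is

    V0_j / sigma2 = I_m (x) A0  +  psi * 1 1',      A0 = I_T + Z D Z'.

Both Woodbury corrections (student-level via the 2x2 capacity matrix,
classroom-level via a rank-one update shared by all classrooms) are
closed-form, so after a single O(N) pass that reduces the data to small
cross-product matrices, one evaluation of the restricted likelihood
costs only 2x2/4x4/8x8 arithmetic.  The optimizer works on

    theta = (l11, l21, l22, sb),   D = L L',  psi = sb**2,

an unconstrained parameterization whose image is exactly the positive
semi-definite cone, so boundary ("singular") fits are interior
stationary points and need no box constraints.

The profiled REML deviance (-2 * restricted log-likelihood, residual
variance profiled out) is

    dev = (N - p) * (1 + log(2 pi s2)) + log|V0| + log|X' V0^-1 X|,
    s2  = (y - X b)' V0^-1 (y - X b) / (N - p),

the same convention as the mainstream mixed-model software family, so
criterion values are directly comparable.

Fixed effects are handled in a permuted column order
(intercept-block [1, Trt, Apt, Trt*Apt], then the same four times t);
``PERM`` maps permuted positions onto the package's canonical order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# permuted position -> canonical position
# canonical: (1, Trt, Apt, time, Trt:Apt, Trt:time, Apt:time, Trt:Apt:time)
PERM = np.array([0, 1, 2, 4, 3, 5, 6, 7], dtype=np.int64)

_NP = 8  # number of fixed effects


@njit(cache=True)
def _chol8(a):
    """Cholesky of an 8x8 SPD matrix; returns (L, ok)."""
    n = a.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = a[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return L, False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L, True


@njit(cache=True)
def _chol_solve8(L, b):
    n = L.shape[0]
    x = b.copy()
    for i in range(n):
        for k in range(i):
            x[i] -= L[i, k] * x[k]
        x[i] /= L[i, i]
    for i in range(n - 1, -1, -1):
        for k in range(i + 1, n):
            x[i] -= L[k, i] * x[k]
        x[i] /= L[i, i]
    return x


@njit(cache=True)
def _reml_eval(theta, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
               Tn, stt, m, J, nobs):
    """Profiled REML deviance and GLS solution at ``theta``.

    Returns (dev, beta_perm, xtvx_perm, sigma2).  ``dev`` is +inf when
    the fixed-effect cross-product matrix is numerically singular.
    """
    beta = np.zeros(_NP)
    xtvx = np.zeros((_NP, _NP))

    l11, l21, l22, sb = theta[0], theta[1], theta[2], theta[3]
    d00 = l11 * l11
    d01 = l11 * l21
    d11 = l21 * l21 + l22 * l22
    psi = sb * sb
    Tf = float(Tn)

    # B = I2 + D Zg,  Zg = diag(T, stt)
    b00 = 1.0 + d00 * Tf
    b01 = d01 * stt
    b10 = d01 * Tf
    b11 = 1.0 + d11 * stt
    detB = b00 * b11 - b01 * b10
    if detB <= 0.0 or not np.isfinite(detB):
        return np.inf, beta, xtvx, 0.0
    # E = B^-1 D  (symmetric)
    e00 = (b11 * d00 - b01 * d01) / detB
    e01 = (b11 * d01 - b01 * d11) / detB
    e11 = (-b10 * d01 + b00 * d11) / detB

    # M = Zg - Zg E Zg
    m00 = Tf - Tf * e00 * Tf
    m01 = -Tf * e01 * stt
    m11 = stt - stt * e11 * stt
    # e1 = E z1, z1 = (T, 0)
    e1_0 = e00 * Tf
    e1_1 = e01 * Tf
    # v = z1 - Zg e1
    v0 = Tf - Tf * e1_0
    v1 = -stt * e1_1
    # h = 1' A0^-1 1
    h = Tf - Tf * e1_0
    g = 1.0 + m * psi * h
    if g <= 0.0:
        return np.inf, beta, xtvx, 0.0
    c = psi / g
    logdet_v = J * m * np.log(detB) + J * np.log(g)

    # I2 - E Zg
    w00 = 1.0 - e00 * Tf
    w01 = -e01 * stt
    w10 = -e01 * Tf
    w11 = 1.0 - e11 * stt

    # X' V0^-1 X in permuted order
    vv = np.empty((2, 2))
    vv[0, 0] = m00
    vv[0, 1] = m01
    vv[1, 0] = m01
    vv[1, 1] = m11
    vw = np.empty(2)
    vw[0] = v0
    vw[1] = v1
    for a in range(2):
        for b in range(2):
            coef_m = vv[a, b]
            coef_c = c * vw[a] * vw[b]
            for i in range(4):
                for k in range(4):
                    xtvx[4 * a + i, 4 * b + k] = coef_m * phi[i, k] - coef_c * phic[i, k]

    # X' V0^-1 y
    xty = np.empty(_NP)
    c2w = np.empty(4)
    for i in range(4):
        c2w[i] = c21[i] - c2z[i, 0] * e1_0 - c2z[i, 1] * e1_1
    for i in range(4):
        ca0 = c1z[i, 0] * w00 + c1z[i, 1] * w10
        ca1 = c1z[i, 0] * w01 + c1z[i, 1] * w11
        xty[i] = ca0 - c * v0 * c2w[i]
        xty[4 + i] = ca1 - c * v1 * c2w[i]

    # y' V0^-1 y
    quad_w = r0 - 2.0 * (e1_0 * r1[0] + e1_1 * r1[1])
    quad_w += (e1_0 * (r2[0, 0] * e1_0 + r2[0, 1] * e1_1)
               + e1_1 * (r2[1, 0] * e1_0 + r2[1, 1] * e1_1))
    yvy = trq - (e00 * qz[0, 0] + 2.0 * e01 * qz[0, 1] + e11 * qz[1, 1]) - c * quad_w

    L, ok = _chol8(xtvx)
    if not ok:
        return np.inf, beta, xtvx, 0.0
    beta = _chol_solve8(L, xty)
    logdet_x = 0.0
    for i in range(_NP):
        logdet_x += 2.0 * np.log(L[i, i])

    rss = yvy - np.dot(beta, xty)
    if rss < 0.0:
        rss = 0.0
    dfres = nobs - _NP
    sigma2 = rss / dfres
    if sigma2 < 1e-300:
        sigma2 = 1e-300
    dev = dfres * (1.0 + np.log(2.0 * np.pi * sigma2)) + logdet_v + logdet_x
    return dev, beta, xtvx, sigma2


@njit(cache=True)
def _dev(x, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2, Tn, stt, m, J, nobs):
    d, _, _, _ = _reml_eval(x, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
                            Tn, stt, m, J, nobs)
    return d


@njit(cache=True)
def _nelder_mead(x0, step, maxfev, fatol, xatol,
                 phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
                 Tn, stt, m, J, nobs):
    """Bound-free Nelder-Mead; returns (x, f, nfev, hit_tol)."""
    n = x0.shape[0]
    sim = np.empty((n + 1, n))
    fsim = np.empty(n + 1)
    sim[0] = x0
    fsim[0] = _dev(x0, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
                   Tn, stt, m, J, nobs)
    for i in range(n):
        sim[i + 1] = x0.copy()
        sim[i + 1, i] += step[i]
        fsim[i + 1] = _dev(sim[i + 1], phi, phic, c1z, c21, c2z, trq, qz,
                           r0, r1, r2, Tn, stt, m, J, nobs)
    nfev = n + 1
    hit_tol = False
    while nfev < maxfev:
        order = np.argsort(fsim)
        sim = sim[order]
        fsim = fsim[order]
        fspread = fsim[n] - fsim[0]
        xspread = 0.0
        for i in range(1, n + 1):
            for k in range(n):
                d = abs(sim[i, k] - sim[0, k])
                if d > xspread:
                    xspread = d
        if fspread <= fatol or xspread <= xatol:
            hit_tol = True
            break
        xbar = np.zeros(n)
        for i in range(n):
            for k in range(n):
                xbar[k] += sim[i, k]
        xbar /= n
        xr = 2.0 * xbar - sim[n]
        fr = _dev(xr, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
                  Tn, stt, m, J, nobs)
        nfev += 1
        if fr < fsim[0]:
            xe = xbar + 2.0 * (xbar - sim[n])
            fe = _dev(xe, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
                      Tn, stt, m, J, nobs)
            nfev += 1
            if fe < fr:
                sim[n] = xe
                fsim[n] = fe
            else:
                sim[n] = xr
                fsim[n] = fr
        elif fr < fsim[n - 1]:
            sim[n] = xr
            fsim[n] = fr
        else:
            if fr < fsim[n]:  # outside contraction
                xc = xbar + 0.5 * (xbar - sim[n])
            else:  # inside contraction
                xc = xbar - 0.5 * (xbar - sim[n])
            fc = _dev(xc, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
                      Tn, stt, m, J, nobs)
            nfev += 1
            if fc < min(fr, fsim[n]):
                sim[n] = xc
                fsim[n] = fc
            else:  # shrink
                for i in range(1, n + 1):
                    sim[i] = sim[0] + 0.5 * (sim[i] - sim[0])
                    fsim[i] = _dev(sim[i], phi, phic, c1z, c21, c2z, trq, qz,
                                   r0, r1, r2, Tn, stt, m, J, nobs)
                nfev += n
    order = np.argsort(fsim)
    return sim[order[0]], fsim[order[0]], nfev, hit_tol


@njit(cache=True)
def _grad_norm(x, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
               Tn, stt, m, J, nobs):
    """Central-difference gradient norm of the profiled deviance."""
    n = x.shape[0]
    gmax = 0.0
    for i in range(n):
        h = 1e-5 * max(1.0, abs(x[i]))
        xp = x.copy()
        xp[i] += h
        xm = x.copy()
        xm[i] -= h
        fp = _dev(xp, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
                  Tn, stt, m, J, nobs)
        fm = _dev(xm, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
                  Tn, stt, m, J, nobs)
        gi = abs(fp - fm) / (2.0 * h)
        if gi > gmax:
            gmax = gi
    return gmax


@njit(cache=True)
def _fit_kernel(x0, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
                Tn, stt, m, J, nobs, maxfev, fatol, xatol):
    """Two-stage Nelder-Mead plus end-point gradient check.

    Returns (theta, dev, beta_perm, xtvx_perm, sigma2, nfev, hit_tol,
    grad_norm).
    """
    step1 = np.empty(4)
    for i in range(4):
        step1[i] = 0.2
    x1, f1, n1, ok1 = _nelder_mead(x0, step1, maxfev, fatol, xatol,
                                   phi, phic, c1z, c21, c2z, trq, qz,
                                   r0, r1, r2, Tn, stt, m, J, nobs)
    step2 = np.empty(4)
    for i in range(4):
        step2[i] = 0.02
    x2, f2, n2, ok2 = _nelder_mead(x1, step2, maxfev // 2, fatol, xatol,
                                   phi, phic, c1z, c21, c2z, trq, qz,
                                   r0, r1, r2, Tn, stt, m, J, nobs)
    gn = _grad_norm(x2, phi, phic, c1z, c21, c2z, trq, qz, r0, r1, r2,
                    Tn, stt, m, J, nobs)
    dev, beta, xtvx, sigma2 = _reml_eval(x2, phi, phic, c1z, c21, c2z, trq,
                                         qz, r0, r1, r2, Tn, stt, m, J, nobs)
    return x2, dev, beta, xtvx, sigma2, n1 + n2 + 8, ok1 and ok2, gn
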