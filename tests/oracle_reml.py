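"""Independent dense-matrix oracle for the restricted likelihood.

Builds the full N x N marginal covariance explicitly from the model
definition (classroom random intercept, correlated student intercept +
time slope, i.i.d. residual) and evaluates the profiled REML deviance

    dev = (N - p) (1 + log(2 pi s2)) + log|V0| + log|X' V0^-1 X|

with generic dense linear algebra, then minimizes it with a generic
scipy optimizer.  Shares no code with the package's structured kernel.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def design_matrix(df) -> np.ndarray:
    trt = df["treatment"].to_numpy(dtype=float)
    apt = df["aptitude"].to_numpy(dtype=float)
    t = df["time"].to_numpy(dtype=float)
    return np.column_stack(
        [np.ones(len(df)), trt, apt, t, trt * apt, trt * t, apt * t, trt * apt * t]
    )


def dense_deviance(df, theta) -> float:
    """Profiled REML deviance at theta = (l11, l21, l22, sb)."""
    df = df.sort_values(["classroom", "student", "time"], kind="stable")
    l11, l21, l22, sb = theta
    L = np.array([[l11, 0.0], [l21, l22]])
    D = L @ L.T
    psi = sb * sb
    y = df["y"].to_numpy(dtype=float)
    N = len(y)
    X = design_matrix(df)
    V = np.eye(N)
    classroom = df["classroom"].to_numpy()
    student = df["student"].to_numpy()
    time = df["time"].to_numpy(dtype=float)
    for j in np.unique(classroom):
        idx = np.where(classroom == j)[0]
        V[np.ix_(idx, idx)] += psi
    for s in np.unique(student):
        idx = np.where(student == s)[0]
        Zs = np.column_stack([np.ones(len(idx)), time[idx]])
        V[np.ix_(idx, idx)] += Zs @ D @ Zs.T
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = max(float(r @ Vi @ r) / (N - 8), 1e-300)
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtVX)
    return (N - 8) * (1.0 + np.log(2.0 * np.pi * s2)) + ld_v + ld_x


def dense_optimum(df, starts=None) -> tuple[np.ndarray, float]:
    """Best deviance found by Nelder-Mead from several generic starts."""
    if starts is None:
        starts = [
            (1.0, 0.0, 1.0, 1.0),
            (0.4, 0.1, 0.3, 0.5),
            (0.1, 0.0, 0.1, 0.1),
        ]
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            lambda th: dense_deviance(df, th),
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxfev": 4000},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    return best_x, best_f
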