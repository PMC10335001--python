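"""REML fitting of the three-level analysis model.

The analysis model mirrors the generative model: eight fixed effects
(intercept, treatment, aptitude, time and their interactions up to the
three-way), a correlated random intercept + time slope per student, and
a random intercept per classroom.  Estimation is restricted maximum
likelihood with the residual variance profiled out, optimizing over the
Cholesky factor of the student covariance (scaled by the residual SD)
and the square root of the scaled classroom variance — a
parameterization in which boundary ("singular") solutions are ordinary
stationary points, so they are reported rather than failed.

Estimation exploits the classroom-block structure of the marginal
covariance (see :mod:`slopesim._reml`); no dense N x N matrix is ever
formed, which is what makes Monte Carlo sweeps over hundreds of
thousands of fits practical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _reml
from .design import FIXED_EFFECT_NAMES
from .simulate import LongDataset

__all__ = [
    "EstimationError",
    "NotConvergedError",
    "FitOptions",
    "FitResult",
    "fit_lmm",
    "fit_arrays",
    "is_singular",
]


class EstimationError(RuntimeError):
    """The model cannot be estimated on the given data."""


class NotConvergedError(RuntimeError):
    """A downstream operation was asked to use a non-converged fit."""


@dataclass(frozen=True)
class FitOptions:
    """Optimizer and diagnostic settings.

    grad_tol
        A fit counts as converged when the optimizer terminated by
        tolerance *and* the central-difference gradient norm of the
        profiled deviance at the solution is at most this value.
    singular_tol
        Boundary tolerance on the residual-SD-relative Cholesky scale
        (the convention of the mainstream mixed-model software family).
    """

    grad_tol: float = 1e-2
    singular_tol: float = 1e-4
    maxfev: int = 4000
    fatol: float = 1e-11
    xatol: float = 1e-7
    start: tuple[float, float, float, float] = (1.0, 0.0, 1.0, 1.0)


@dataclass
class FitResult:
    """REML estimates and diagnostics for one fitted model."""

    beta_hat: np.ndarray  # length 8, FIXED_EFFECT_NAMES order
    vcov_beta: np.ndarray  # 8 x 8
    sigma2_hat: float
    tau_pi00_hat: float
    tau_pi01_hat: float
    tau_pi11_hat: float
    tau_beta00_hat: float
    reml_criterion: float
    converged: bool
    singular: bool
    diagnostics: dict = field(default_factory=dict)
    n_obs: int = 0
    n_students: int = 0
    n_classrooms: int = 0
    beta_names: tuple[str, ...] = FIXED_EFFECT_NAMES

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))

    def to_dict(self) -> dict:
        return {
            "beta_hat": dict(zip(self.beta_names, self.beta_hat.tolist())),
            "beta_se": dict(zip(self.beta_names, self.beta_se.tolist())),
            "vcov_beta": self.vcov_beta.tolist(),
            "sigma2_hat": self.sigma2_hat,
            "tau_pi00_hat": self.tau_pi00_hat,
            "tau_pi01_hat": self.tau_pi01_hat,
            "tau_pi11_hat": self.tau_pi11_hat,
            "tau_beta00_hat": self.tau_beta00_hat,
            "reml_criterion": self.reml_criterion,
            "converged": self.converged,
            "singular": self.singular,
            "diagnostics": self.diagnostics,
            "n_obs": self.n_obs,
            "n_students": self.n_students,
            "n_classrooms": self.n_classrooms,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _ordered_arrays(dataset: LongDataset | pd.DataFrame):
    """Sort to classroom/student/wave order and extract fit arrays."""
    if isinstance(dataset, pd.DataFrame):
        dataset = LongDataset.from_frame(dataset)
    else:
        dataset.validate()
    df = dataset.to_frame().sort_values(["classroom", "student", "time"], kind="stable")
    times = np.sort(np.unique(df["time"].to_numpy()))
    T = len(times)
    students = df.drop_duplicates("student")
    # class sizes are equal post-validation
    J = df["classroom"].nunique()
    m = len(students) // J
    y = df["y"].to_numpy(dtype=float)
    trt = students["treatment"].to_numpy(dtype=float)
    apt = students["aptitude"].to_numpy(dtype=float)
    return y, times, trt, apt, T, m, J


def _suffstats(y, times, trt, apt, T, m, J):
    """One O(N) pass reducing the data to the kernel's cross-products."""
    n_students = J * m
    Y = y.reshape(n_students, T)
    t = times
    if abs(t.sum()) > 1e-8 * max(1.0, float(np.max(np.abs(t)))):
        # the block algebra assumes mean-zero wave codes (the design's
        # convention); refuse rather than silently recode
        raise EstimationError("time codes must be centered (mean zero)")
    Z = np.column_stack([np.ones(T), t])
    F = np.column_stack([np.ones(n_students), trt, apt, trt * apt])
    YZ = Y @ Z
    Ybar = Y.reshape(J, m, T).sum(axis=1)
    FJ = F.reshape(J, m, 4).sum(axis=1)
    ybar1 = Ybar.sum(axis=1)
    YbarZ = Ybar @ Z
    stats = dict(
        phi=F.T @ F,
        phic=FJ.T @ FJ,
        c1z=F.T @ YZ,
        c21=FJ.T @ ybar1,
        c2z=FJ.T @ YbarZ,
        trq=float(np.sum(Y * Y)),
        qz=YZ.T @ YZ,
        r0=float(np.sum(ybar1**2)),
        r1=YbarZ.T @ ybar1,
        r2=YbarZ.T @ YbarZ,
        Tn=T,
        stt=float(np.sum(t * t)),
        m=m,
        J=J,
        nobs=n_students * T,
    )
    return stats


def _kernel_args(stats):
    return (
        stats["phi"], stats["phic"], stats["c1z"], stats["c21"], stats["c2z"],
        stats["trq"], stats["qz"], stats["r0"], stats["r1"], stats["r2"],
        stats["Tn"], stats["stt"], stats["m"], stats["J"], stats["nobs"],
    )


def reml_criterion_at(dataset: LongDataset | pd.DataFrame, theta) -> float:
    """Profiled REML deviance at a given ``(l11, l21, l22, sb)``.

    Exposed for cross-validation against independent dense-matrix
    evaluations of the restricted likelihood.
    """
    stats = _suffstats(*_ordered_arrays(dataset))
    return float(_reml._dev(np.asarray(theta, dtype=float), *_kernel_args(stats)))


def fit_lmm(
    dataset: LongDataset | pd.DataFrame, options: FitOptions | None = None
) -> FitResult:
    """Fit the three-level model by REML.

    Raises :class:`EstimationError` when the fixed-effect design is rank
    deficient (e.g. single-arm data or constant aptitude).  Optimizer
    trouble does not raise: it is reported through ``converged``.
    """
    opts = options or FitOptions()
    y, times, trt, apt, T, m, J = _ordered_arrays(dataset)
    return fit_arrays(y, times, trt, apt, T, m, J, opts)


def fit_arrays(y, times, trt, apt, T, m, J, options: FitOptions | None = None) -> FitResult:
    """Array-level fitting path (no DataFrame round-trip).

    ``y`` is occasion-major within student within classroom, ``trt`` and
    ``apt`` are per-student.  Used by the Monte Carlo engine, where the
    generator guarantees the layout that :func:`fit_lmm` validates.
    """
    opts = options or FitOptions()
    if T < 2:
        raise EstimationError("need at least 2 waves")
    n_arm = np.unique(trt)
    if len(n_arm) < 2:
        raise EstimationError("single-arm data: treatment indicator is constant")
    for arm in (0.0, 1.0):
        # classroom count per arm; trt is per student, classrooms have equal size
        if np.sum(trt.reshape(J, m)[:, 0] == arm) < 2:
            raise EstimationError("need at least 2 classrooms per arm")
    if np.ptp(apt) == 0.0:
        raise EstimationError("aptitude is constant: fixed-effect design is rank deficient")

    stats = _suffstats(y, times, trt, apt, T, m, J)
    args = _kernel_args(stats)
    x0 = np.asarray(opts.start, dtype=float)
    theta, dev, beta_p, xtvx_p, sigma2, nfev, hit_tol, grad_norm = _reml._fit_kernel(
        x0, *args, opts.maxfev, opts.fatol, opts.xatol
    )
    if not np.isfinite(dev):
        raise EstimationError("REML objective is not finite at the optimizer solution "
                              "(rank-deficient fixed-effect design?)")

    perm = _reml.PERM
    beta = np.empty(8)
    beta[perm] = beta_p
    vcov_p = sigma2 * np.linalg.inv(xtvx_p)
    vcov = np.empty((8, 8))
    vcov[np.ix_(perm, perm)] = vcov_p
    vcov = (vcov + vcov.T) / 2.0

    l11, l21, l22, sb = np.abs(theta[0]), theta[1], np.abs(theta[2]), np.abs(theta[3])
    d00 = l11**2
    d01 = theta[0] * theta[1]
    d11 = theta[1] ** 2 + l22**2
    converged = bool(hit_tol and np.isfinite(grad_norm) and grad_norm <= opts.grad_tol)
    fit = FitResult(
        beta_hat=beta,
        vcov_beta=vcov,
        sigma2_hat=float(sigma2),
        tau_pi00_hat=float(d00 * sigma2),
        tau_pi01_hat=float(d01 * sigma2),
        tau_pi11_hat=float(d11 * sigma2),
        tau_beta00_hat=float(sb**2 * sigma2),
        reml_criterion=float(dev),
        converged=converged,
        singular=False,
        diagnostics={
            "theta": theta.tolist(),
            "grad_norm": float(grad_norm),
            "n_evals": int(nfev),
            "optimizer": "nelder-mead (two-stage)",
            "hit_tolerance": bool(hit_tol),
        },
        n_obs=stats["nobs"],
        n_students=J * m,
        n_classrooms=J,
    )
    fit.singular = is_singular(fit, opts.singular_tol)
    return fit


def is_singular(fit: FitResult, tol: float = 1e-4) -> bool:
    """Boundary check on the variance-component estimates.

    True when any random-effect standard deviation, on the scale of the
    residual SD and after factoring the student covariance (so that a
    student intercept-slope correlation of +/-1 also hits the boundary),
    is at most ``tol``, or when that correlation is within ``tol`` of
    +/-1.
    """
    if fit.sigma2_hat <= 1e-12:
        # degenerate fit: the implied data covariance is itself singular
        return True
    s2 = fit.sigma2_hat
    l11 = np.sqrt(max(fit.tau_pi00_hat, 0.0) / s2)
    if fit.tau_pi00_hat > 0:
        cond_var = fit.tau_pi11_hat - fit.tau_pi01_hat**2 / fit.tau_pi00_hat
    else:
        cond_var = fit.tau_pi11_hat
    l22 = np.sqrt(max(cond_var, 0.0) / s2)
    sb = np.sqrt(max(fit.tau_beta00_hat, 0.0) / s2)
    if min(l11, l22, sb) <= tol:
        return True
    denom = fit.tau_pi00_hat * fit.tau_pi11_hat
    if denom > 0:
        corr = fit.tau_pi01_hat / np.sqrt(denom)
        if abs(corr) >= 1.0 - tol:
            return True
    return False
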