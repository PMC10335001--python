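"""Interaction probing on a fitted three-level model.

Three statistics are provided for the treatment-by-aptitude-by-time
(cross-level) interaction:

* the omnibus test of the three-way coefficient itself;
* simple slopes of time at chosen (aptitude, treatment) values;
* the slopes difference test: does the time slope of the treatment arm
  differ from the control arm at a fixed (low) aptitude?

The slopes difference test has two variance modes.  ``as_printed``
follows the published formula verbatim,

    t = (g101 - g111) / sqrt(var(g101) + var(g111) + 2 cov(g101, g111)),

while ``delta_method`` applies the general conditional-contrast variance
to the treatment-minus-control slope difference at aptitude ``a``,

    est = g101 + a * g111,
    se^2 = var(g101) + a^2 var(g111) + 2 a cov(g101, g111),

which at a = -1 carries *minus* twice the covariance.  The two agree
exactly when the covariance is zero and differ only through its sign
otherwise; both are kept because the printed formula and the general
derivation genuinely disagree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .lmm import EstimationError, FitResult, NotConvergedError

__all__ = [
    "ProbeResult",
    "omnibus_three_way_test",
    "simple_slope",
    "slopes_difference_test",
]

_IDX_TIME = 3
_IDX_TRT_TIME = 5
_IDX_APT_TIME = 6
_IDX_THREE_WAY = 7


@dataclass(frozen=True)
class ProbeResult:
    """One probing statistic: estimate, its SE, and the reference-test tail."""

    kind: str  # omnibus | simple_slope | slopes_difference
    estimate: float
    se: float
    t: float
    df: float  # np.inf under the normal reference
    p: float
    conditioning: dict

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def _two_sided_p(t: float, df: float) -> float:
    if np.isinf(df):
        return float(2.0 * sps.norm.sf(abs(t)))
    return float(2.0 * sps.t.sf(abs(t), df))


def _df_for(fit: FitResult, df_policy: str) -> float:
    """Reference distribution: unbounded normal (default) or the
    regression-convention df = N - p - 1."""
    if df_policy == "normal":
        return float("inf")
    if df_policy == "residual":
        return float(fit.n_obs - len(fit.beta_hat) - 1)
    raise ValueError(f"unknown df_policy {df_policy!r}")


def _require_converged(fit: FitResult) -> None:
    if not fit.converged:
        raise NotConvergedError(
            "fit did not converge; probing statistics are not available "
            f"(diagnostics: {fit.diagnostics})"
        )


def omnibus_three_way_test(fit: FitResult, alpha: float = 0.05,
                           df_policy: str = "normal") -> ProbeResult:
    """Significance of the treatment-by-aptitude-by-time coefficient."""
    _require_converged(fit)
    est = float(fit.beta_hat[_IDX_THREE_WAY])
    se = float(np.sqrt(fit.vcov_beta[_IDX_THREE_WAY, _IDX_THREE_WAY]))
    t = est / se if se > 0 else np.nan
    df = _df_for(fit, df_policy)
    return ProbeResult(
        kind="omnibus",
        estimate=est,
        se=se,
        t=t,
        df=df,
        p=_two_sided_p(t, df),
        conditioning={"alpha": alpha},
    )


def simple_slope(fit: FitResult, aptitude_value: float, treatment_value: int,
                 df_policy: str = "normal") -> ProbeResult:
    """Time slope at fixed moderator values, with a delta-method SE.

    slope(a, w) = g100 + g101 * w + g110 * a + g111 * a * w.
    """
    _require_converged(fit)
    a, w = float(aptitude_value), float(treatment_value)
    L = np.zeros(8)
    L[_IDX_TIME] = 1.0
    L[_IDX_TRT_TIME] = w
    L[_IDX_APT_TIME] = a
    L[_IDX_THREE_WAY] = a * w
    est = float(L @ fit.beta_hat)
    var = float(L @ fit.vcov_beta @ L)
    se = float(np.sqrt(max(var, 0.0)))
    t = est / se if se > 0 else np.nan
    df = _df_for(fit, df_policy)
    return ProbeResult(
        kind="simple_slope",
        estimate=est,
        se=se,
        t=t,
        df=df,
        p=_two_sided_p(t, df),
        conditioning={"aptitude": a, "treatment": w},
    )


def slopes_difference_test(
    fit: FitResult,
    aptitude_value: float = -1.0,
    mode: str = "as_printed",
    df_policy: str = "normal",
) -> ProbeResult:
    """Treatment-vs-control difference in the time slope at low aptitude.

    See the module docstring for the two variance modes.  In
    ``as_printed`` mode the estimate is g101 - g111 (the published
    numerator, which equals the conditional contrast at aptitude -1);
    ``aptitude_value`` only enters in ``delta_method`` mode.
    """
    _require_converged(fit)
    b5 = float(fit.beta_hat[_IDX_TRT_TIME])
    b7 = float(fit.beta_hat[_IDX_THREE_WAY])
    v55 = float(fit.vcov_beta[_IDX_TRT_TIME, _IDX_TRT_TIME])
    v77 = float(fit.vcov_beta[_IDX_THREE_WAY, _IDX_THREE_WAY])
    v57 = float(fit.vcov_beta[_IDX_TRT_TIME, _IDX_THREE_WAY])
    if mode == "as_printed":
        est = b5 - b7
        var = v55 + v77 + 2.0 * v57
        conditioning = {"aptitude": -1.0, "mode": mode}
    elif mode == "delta_method":
        a = float(aptitude_value)
        est = b5 + a * b7
        var = v55 + a * a * v77 + 2.0 * a * v57
        conditioning = {"aptitude": a, "mode": mode}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if var <= 0.0:
        raise EstimationError(
            f"non-positive variance ({var!r}) for the slopes difference; "
            "the replication should be counted as failed"
        )
    se = float(np.sqrt(var))
    t = est / se
    df = _df_for(fit, df_policy)
    return ProbeResult(
        kind="slopes_difference",
        estimate=float(est),
        se=se,
        t=float(t),
        df=df,
        p=_two_sided_p(t, df),
        conditioning=conditioning,
    )
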