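"""Population parameters and the factorial design space.

A three-level longitudinal cluster-randomized trial is described by

* level 1 (occasion): outcome grows linearly in time with residual
  variance ``sigma2_e``;
* level 2 (student): random intercept and random time slope with
  covariance matrix ``T_pi = [[tau_pi00, tau_pi01], [tau_pi01, tau_pi11]]``,
  plus a continuous aptitude/skill covariate;
* level 3 (classroom): random intercept with variance ``tau_beta00``;
  treatment is assigned at this level.

The combined model for the outcome of student *i* in classroom *j* at
occasion *t* is

    y_tij = g000 + g001*Trt + g010*Apt + g100*Time + g011*Trt*Apt
          + g101*Trt*Time + g110*Apt*Time + g111*Trt*Apt*Time
          + u00j + r0ij + r1ij*Time + e_tij.

This module holds the fixed "true" parameter values, the factorial grid
of design conditions, and the deterministic algebra that maps a design
condition (intraclass correlation, effect-size label, number of waves)
onto generating parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidParameterError",
    "PopulationParams",
    "DesignCondition",
    "FactorLevels",
    "DEFAULT_BASE_PARAMS",
    "DEFAULT_FACTOR_LEVELS",
    "EFFECT_GAMMA101",
    "FIXED_EFFECT_NAMES",
    "icc_to_tau_beta00",
    "tau_beta00_to_icc",
    "effect_label_to_gamma101",
    "wave_times",
    "build_grid",
    "resolve_params",
]


class InvalidParameterError(ValueError):
    """Raised when a parameter value is outside its valid domain."""


#: Fixed-effect names in the canonical ordering used throughout the package.
FIXED_EFFECT_NAMES: tuple[str, ...] = (
    "intercept",
    "treatment",
    "aptitude",
    "time",
    "treatment:aptitude",
    "treatment:time",
    "aptitude:time",
    "treatment:aptitude:time",
)

#: Mapping of slopes-difference effect-size labels onto the generating
#: treatment-by-time coefficient.  The implied population slopes difference
#: at aptitude -1 is gamma101 - gamma111 = 0.1 / 0.3 / 0.5.
EFFECT_GAMMA101: dict[str, float] = {"small": 0.2, "medium": 0.4, "large": 0.6}


@dataclass(frozen=True)
class PopulationParams:
    """Generating ("true") values of the three-level growth model.

    ``gamma101`` (treatment-by-time) and ``tau_beta00`` (classroom
    intercept variance) are condition-dependent and carry no meaningful
    default; :func:`resolve_params` fills them in from a
    :class:`DesignCondition`.
    """

    gamma000: float = 0.0
    gamma001: float = 0.1
    gamma010: float = 0.5
    gamma011: float = 0.3
    gamma100: float = 0.1
    gamma101: float = float("nan")  # set per condition (effect size)
    gamma110: float = 0.5
    gamma111: float = 0.1
    sigma2_e: float = 1.0
    tau_pi00: float = 0.2
    tau_pi01: float = 0.05
    tau_pi11: float = 0.1
    tau_beta00: float = float("nan")  # set per condition (ICC)
    aptitude_mean: float = 0.0
    aptitude_sd: float = 15.0

    def __post_init__(self) -> None:
        if self.sigma2_e <= 0:
            raise InvalidParameterError("sigma2_e must be > 0")
        if self.aptitude_sd <= 0:
            raise InvalidParameterError("aptitude_sd must be > 0")
        if not np.isnan(self.tau_beta00) and self.tau_beta00 < 0:
            raise InvalidParameterError("tau_beta00 must be >= 0")
        tpi = self.tau_pi_matrix
        if np.any(np.diag(tpi) < 0) or np.linalg.det(tpi) < -1e-12:
            raise InvalidParameterError(
                "student random-effect covariance T_pi must be positive semi-definite"
            )

    @property
    def tau_pi_matrix(self) -> np.ndarray:
        """2x2 student random intercept/slope covariance matrix."""
        return np.array(
            [[self.tau_pi00, self.tau_pi01], [self.tau_pi01, self.tau_pi11]]
        )

    @property
    def fixed_effects(self) -> np.ndarray:
        """Length-8 gamma vector in :data:`FIXED_EFFECT_NAMES` order."""
        return np.array(
            [
                self.gamma000,
                self.gamma001,
                self.gamma010,
                self.gamma100,
                self.gamma011,
                self.gamma101,
                self.gamma110,
                self.gamma111,
            ]
        )


#: The fixed base values used across every simulation condition.
DEFAULT_BASE_PARAMS = PopulationParams()


@dataclass(frozen=True)
class DesignCondition:
    """One cell of the factorial simulation design."""

    n_waves: int
    class_size: int
    n_classrooms: int
    prop_treatment: float
    icc: float
    effect_label: str
    condition_index: int = 0

    def __post_init__(self) -> None:
        if self.n_waves < 2:
            raise InvalidParameterError("n_waves must be >= 2")
        if self.class_size < 1 or self.n_classrooms < 1:
            raise InvalidParameterError("counts must be >= 1")
        if not 0 < self.prop_treatment < 1:
            raise InvalidParameterError("prop_treatment must be in (0, 1)")
        if not 0 < self.icc < 1:
            raise InvalidParameterError("icc must be in (0, 1)")
        if self.effect_label not in EFFECT_GAMMA101:
            raise InvalidParameterError(
                f"unknown effect_label {self.effect_label!r}; "
                f"expected one of {sorted(EFFECT_GAMMA101)}"
            )

    @property
    def n_students(self) -> int:
        return self.class_size * self.n_classrooms

    @property
    def n_obs(self) -> int:
        return self.n_waves * self.class_size * self.n_classrooms

    def factor_dict(self) -> dict:
        return {
            "n_waves": self.n_waves,
            "class_size": self.class_size,
            "n_classrooms": self.n_classrooms,
            "prop_treatment": self.prop_treatment,
            "icc": self.icc,
            "effect_label": self.effect_label,
        }


@dataclass(frozen=True)
class FactorLevels:
    """Levels of the six design factors, in grid-enumeration order."""

    n_waves: Sequence[int] = (3, 4, 5)
    class_size: Sequence[int] = (10, 20, 30)
    n_classrooms: Sequence[int] = (20, 30, 40, 50)
    prop_treatment: Sequence[float] = (0.5, 0.3)
    icc: Sequence[float] = (0.086, 0.113, 0.2)
    effect_label: Sequence[str] = ("small", "medium", "large")


#: The 3 x 3 x 4 x 2 x 3 x 3 = 648-condition design.
DEFAULT_FACTOR_LEVELS = FactorLevels()


def icc_to_tau_beta00(icc: float, sigma2_e: float = 1.0, tau_pi00: float = 0.2) -> float:
    """Classroom-level intercept variance implied by an intraclass correlation.

    The ICC of the three-level model is the share of the total
    time-0 outcome variance attributable to classrooms,

        ICC = tau_beta00 / (sigma2_e + tau_pi00 + tau_beta00),

    which inverts to ``tau_beta00 = ICC * (sigma2_e + tau_pi00) / (1 - ICC)``.

    Parameters
    ----------
    icc : float in [0, 1)
    sigma2_e : occasion-level residual variance (> 0)
    tau_pi00 : student-level intercept variance (>= 0)
    """
    if not 0 <= icc < 1:
        raise InvalidParameterError("icc must be in [0, 1)")
    if sigma2_e <= 0:
        raise InvalidParameterError("sigma2_e must be > 0")
    if tau_pi00 < 0:
        raise InvalidParameterError("tau_pi00 must be >= 0")
    return icc * (sigma2_e + tau_pi00) / (1.0 - icc)


def tau_beta00_to_icc(tau_beta00: float, sigma2_e: float = 1.0, tau_pi00: float = 0.2) -> float:
    """Inverse of :func:`icc_to_tau_beta00`."""
    if tau_beta00 < 0 or sigma2_e <= 0 or tau_pi00 < 0:
        raise InvalidParameterError("variances must be non-negative, sigma2_e > 0")
    return tau_beta00 / (sigma2_e + tau_pi00 + tau_beta00)


def effect_label_to_gamma101(effect_label: str) -> float:
    """Treatment-by-time coefficient for a named effect-size condition.

    ``small``/``medium``/``large`` map to 0.2/0.4/0.6; with the fixed
    three-way coefficient gamma111 = 0.1 these imply population slopes
    differences at low aptitude (-1) of 0.1, 0.3 and 0.5.
    """
    try:
        return EFFECT_GAMMA101[effect_label]
    except KeyError:
        raise InvalidParameterError(
            f"unknown effect_label {effect_label!r}; expected one of {sorted(EFFECT_GAMMA101)}"
        ) from None


def wave_times(n_waves: int) -> np.ndarray:
    """Centered, unit-spaced codes for the measurement occasions.

    3 waves -> (-1, 0, 1); 4 -> (-1.5, -0.5, 0.5, 1.5); 5 -> (-2, ..., 2).
    """
    if n_waves < 2:
        raise InvalidParameterError("n_waves must be >= 2")
    return np.arange(n_waves, dtype=float) - (n_waves - 1) / 2.0


def build_grid(levels: FactorLevels | None = None) -> list[DesignCondition]:
    """Enumerate the full factorial design.

    Nested-loop order (outermost to innermost): waves, class size,
    number of classrooms, treatment proportion, ICC, effect size.
    ``condition_index`` is assigned 1..N in that order.
    """
    levels = levels if levels is not None else DEFAULT_FACTOR_LEVELS
    for name in (
        "n_waves",
        "class_size",
        "n_classrooms",
        "prop_treatment",
        "icc",
        "effect_label",
    ):
        if len(getattr(levels, name)) == 0:
            raise InvalidParameterError(f"factor {name!r} has no levels")
    grid = []
    for idx, (w, m, j, p, icc, eff) in enumerate(
        itertools.product(
            levels.n_waves,
            levels.class_size,
            levels.n_classrooms,
            levels.prop_treatment,
            levels.icc,
            levels.effect_label,
        ),
        start=1,
    ):
        grid.append(
            DesignCondition(
                n_waves=w,
                class_size=m,
                n_classrooms=j,
                prop_treatment=p,
                icc=icc,
                effect_label=eff,
                condition_index=idx,
            )
        )
    return grid


def resolve_params(
    condition: DesignCondition, base: PopulationParams = DEFAULT_BASE_PARAMS
) -> PopulationParams:
    """Fill the condition-dependent parameters of ``base``.

    Sets ``gamma101`` from the effect-size label and ``tau_beta00`` from
    the ICC (at full precision); every other field is unchanged.
    Idempotent: resolving an already-resolved parameter set again gives
    the same result.
    """
    return replace(
        base,
        gamma101=effect_label_to_gamma101(condition.effect_label),
        tau_beta00=icc_to_tau_beta00(condition.icc, base.sigma2_e, base.tau_pi00),
    )
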