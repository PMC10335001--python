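"""Synthetic long-format datasets from the three-level growth model.

Each dataset is one cluster-randomized trial: classrooms are assigned to
treatment or control, every student is measured at every wave, and the
outcome is the direct sum of the combined-model terms

    y = fixed part + u00j + r0ij + r1ij * time + e_tij

with u00j ~ N(0, tau_beta00) per classroom, (r0ij, r1ij) bivariate
normal with covariance T_pi per student, e_tij ~ N(0, sigma2_e) per
occasion, and aptitude ~ N(aptitude_mean, aptitude_sd^2) per student.

Datasets are a pure function of (condition, params, seed): random draws
consume the stream in a fixed order (treatment assignment, classroom
effects, student aptitudes, student intercept/slope effects, occasion
residuals), so replications are reproducible regardless of how many
worker processes run them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    DesignCondition,
    InvalidParameterError,
    PopulationParams,
    wave_times,
)

__all__ = [
    "DATASET_COLUMNS",
    "InvalidDesignError",
    "DatasetValidationError",
    "LongDataset",
    "assign_treatment",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

#: Column order of the plain-text tabular format.
DATASET_COLUMNS = ("classroom", "student", "wave", "time", "treatment", "aptitude", "y")


class InvalidDesignError(ValueError):
    """A design that cannot produce a two-arm trial (empty arm, etc.)."""


class DatasetValidationError(ValueError):
    """A long-format dataset violating the balanced-panel contract."""


@dataclass
class LongDataset:
    """Occasion-level records of one simulated (or imported) trial.

    All arrays have length ``n_waves * class_size * n_classrooms`` and are
    ordered classroom-major, then student, then wave.  ``classroom_id``
    runs 1..J, ``student_id`` is unique across the dataset, ``wave_index``
    runs 1..T and ``time`` holds the centered wave codes.
    """

    classroom_id: np.ndarray
    student_id: np.ndarray
    wave_index: np.ndarray
    time: np.ndarray
    treatment: np.ndarray
    aptitude: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "classroom": self.classroom_id,
                "student": self.student_id,
                "wave": self.wave_index,
                "time": self.time,
                "treatment": self.treatment,
                "aptitude": self.aptitude,
                "y": self.y,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LongDataset":
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetValidationError(f"missing required column(s): {missing}")
        ds = cls(
            classroom_id=df["classroom"].to_numpy(dtype=np.int64),
            student_id=df["student"].to_numpy(dtype=np.int64),
            wave_index=df["wave"].to_numpy(dtype=np.int64),
            time=df["time"].to_numpy(dtype=float),
            treatment=df["treatment"].to_numpy(dtype=np.int64),
            aptitude=df["aptitude"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=float),
        )
        ds.validate()
        return ds

    def validate(self) -> None:
        """Check the balanced-panel invariants; raise on violation."""
        n = len(self.y)
        for name in ("classroom_id", "student_id", "wave_index", "time", "treatment", "aptitude"):
            if len(getattr(self, name)) != n:
                raise DatasetValidationError(f"column {name!r} has wrong length")
        df = self.to_frame()
        # treatment constant within classroom
        bad = df.groupby("classroom")["treatment"].nunique()
        bad = bad[bad > 1]
        if len(bad):
            raise DatasetValidationError(
                f"treatment varies within classroom(s) {list(bad.index[:5])}"
            )
        if not set(np.unique(self.treatment)) <= {0, 1}:
            raise DatasetValidationError("treatment must be coded 0/1")
        # aptitude constant within student
        bad = df.groupby("student")["aptitude"].nunique()
        bad = bad[bad > 1]
        if len(bad):
            raise DatasetValidationError(
                f"aptitude varies within student(s) {list(bad.index[:5])}"
            )
        # every student observed at the same full set of times
        times = np.sort(np.unique(self.time))
        counts = df.groupby("student")["time"].count()
        if counts.nunique() != 1 or counts.iloc[0] != len(times):
            raise DatasetValidationError(
                "panel is unbalanced: every student must have one row per wave"
            )
        per = df.groupby("student")["time"].apply(lambda s: np.array_equal(np.sort(s), times))
        if not per.all():
            raise DatasetValidationError(
                f"student(s) {list(per.index[~per][:5])} miss some wave times"
            )
        # equal class sizes
        sizes = df.groupby("classroom")["student"].nunique()
        if sizes.nunique() != 1:
            raise DatasetValidationError("class sizes are unequal across classrooms")


def assign_treatment(
    n_classrooms: int, prop_treatment: float, rng: np.random.Generator
) -> np.ndarray:
    """0/1 treatment indicator per classroom.

    Exactly ``round(prop_treatment * n_classrooms)`` classrooms (half-up
    rounding) are treated; which ones is a uniform draw without
    replacement from ``rng``.
    """
    if n_classrooms < 2:
        raise InvalidDesignError("need at least 2 classrooms")
    if not 0 < prop_treatment < 1:
        raise InvalidParameterError("prop_treatment must be in (0, 1)")
    n_treated = int(np.floor(prop_treatment * n_classrooms + 0.5))
    if n_treated == 0 or n_treated == n_classrooms:
        raise InvalidDesignError(
            f"prop_treatment={prop_treatment} with {n_classrooms} classrooms "
            "leaves an empty arm"
        )
    assignment = np.zeros(n_classrooms, dtype=np.int64)
    treated = rng.choice(n_classrooms, size=n_treated, replace=False)
    assignment[treated] = 1
    return assignment


def _tpi_cholesky(tpi: np.ndarray) -> np.ndarray:
    """Lower-triangular factor L with L L' = T_pi, allowing the PSD boundary."""
    if np.allclose(tpi, 0.0):
        return np.zeros((2, 2))
    try:
        return np.linalg.cholesky(tpi)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(tpi)
        if np.min(w) < -1e-10:
            raise InvalidParameterError("T_pi is not positive semi-definite") from None
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_dataset(
    condition: DesignCondition,
    params: PopulationParams,
    rng: np.random.Generator,
) -> LongDataset:
    """Draw one balanced trial from the generative model.

    ``params`` must be resolved for the condition (finite ``gamma101``
    and ``tau_beta00``); see :func:`slopesim.design.resolve_params`.
    """
    if np.isnan(params.gamma101) or np.isnan(params.tau_beta00):
        raise InvalidParameterError(
            "params.gamma101 / tau_beta00 are unset; call resolve_params first"
        )
    J = condition.n_classrooms
    m = condition.class_size
    T = condition.n_waves
    n_students = J * m
    t = wave_times(T)
    L = _tpi_cholesky(params.tau_pi_matrix)

    # fixed stream order: assignment, classroom effects, aptitudes,
    # student effects, residuals
    trt_class = assign_treatment(J, condition.prop_treatment, rng)
    u00 = rng.normal(0.0, np.sqrt(params.tau_beta00), size=J)
    apt = rng.normal(params.aptitude_mean, params.aptitude_sd, size=n_students)
    re = rng.standard_normal(size=(n_students, 2)) @ L.T
    e = rng.normal(0.0, np.sqrt(params.sigma2_e), size=(n_students, T))

    trt = np.repeat(trt_class, m).astype(float)
    u_student = np.repeat(u00, m)
    ta = trt * apt
    p = params
    intercept = (
        p.gamma000 + p.gamma001 * trt + p.gamma010 * apt + p.gamma011 * ta
        + u_student + re[:, 0]
    )
    slope = p.gamma100 + p.gamma101 * trt + p.gamma110 * apt + p.gamma111 * ta + re[:, 1]
    y = intercept[:, None] + slope[:, None] * t[None, :] + e

    return LongDataset(
        classroom_id=np.repeat(np.arange(1, J + 1), m * T),
        student_id=np.repeat(np.arange(1, n_students + 1), T),
        wave_index=np.tile(np.arange(1, T + 1), n_students),
        time=np.tile(t, n_students),
        treatment=np.repeat(trt_class, m * T),
        aptitude=np.repeat(apt, T),
        y=y.ravel(),
    )


def write_dataset(dataset: LongDataset, path) -> None:
    """Write the seven-column comma-separated representation."""
    dataset.to_frame().to_csv(path, index=False)


def read_dataset(path) -> LongDataset:
    """Read and validate a dataset written by :func:`write_dataset`."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DatasetValidationError(f"cannot parse {path}: {exc}") from exc
    return LongDataset.from_frame(df)
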