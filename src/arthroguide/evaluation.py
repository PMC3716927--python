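"""Skill evaluation: normal path error and cohort statistics.

The skill metric is the normal path error — for every sample of a
trainee trajectory, the shortest distance to the expert's reference
curve.  A session is summarized by the mean error (AVG, cm), the sample
standard deviation of the errors (SD), and the operation time (s).

Cohort comparisons aggregate eight-subject tables recorded with and
without force guidance, two sessions per subject (before and after five
practice repetitions).  The headline statistic is the mean over subjects
of the per-subject relative reduction on the second-session rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .nurbs import NurbsCurve, RawTrajectory, closest_point_batch

__all__ = [
    "SessionMetrics",
    "CohortTable",
    "EvaluationError",
    "CohortMismatchError",
    "normal_path_error",
    "session_metrics",
    "mean_relative_reduction",
    "practice_effect",
    "load_reference_cohort",
]

COHORT_COLUMNS = ["subject", "condition", "session", "avg_cm", "sd_cm", "time_s"]


class EvaluationError(ValueError):
    """Invalid evaluation input."""


class CohortMismatchError(EvaluationError):
    """Compared cohort tables do not cover the same subjects."""


@dataclass(frozen=True)
class SessionMetrics:
    """Per-sample normal path errors with their AVG, SD and operation time."""

    errors: np.ndarray
    avg: float
    sd: float
    time: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "errors", np.asarray(self.errors, dtype=float).ravel()
        )

    def as_dict(self) -> dict:
        return {
            "avg_cm": self.avg,
            "sd_cm": self.sd,
            "time_s": self.time,
            "n_samples": int(len(self.errors)),
        }


@dataclass(frozen=True)
class CohortTable:
    """Eight-subject performance table for one condition.

    Backed by a DataFrame with columns subject, condition, session
    (1 or 2), avg_cm, sd_cm, time_s.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise EvaluationError(f"cohort table missing columns: {missing}")
        if df[COHORT_COLUMNS].isna().any().any():
            bad = df[df[COHORT_COLUMNS].isna().any(axis=1)].index[0]
            raise EvaluationError(f"cohort table has missing cells at row {bad}")
        df["session"] = df["session"].astype(int)
        object.__setattr__(self, "data", df)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.data["subject"]))

    @property
    def condition(self) -> str:
        return str(self.data["condition"].iloc[0])

    def session(self, which: int) -> pd.DataFrame:
        out = self.data[self.data["session"] == which]
        if out.empty:
            raise EvaluationError(f"cohort table has no session {which}")
        return out.set_index("subject")

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, comment="#")
        if df.empty:
            raise EvaluationError(
                "empty cohort file; expected columns " + ",".join(COHORT_COLUMNS)
            )
        return cls(df)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def normal_path_error(trainee: RawTrajectory, expert: NurbsCurve) -> np.ndarray:
    """Shortest distance (cm) from each trainee sample to the expert curve."""
    _, _, dist = closest_point_batch(expert, trainee.positions)
    return dist


def session_metrics(errors, start_time: float, end_time: float) -> SessionMetrics:
    """Summarize one session: mean, sample SD (n-1) and elapsed time."""
    errors = np.asarray(errors, dtype=float).ravel()
    if errors.size == 0:
        raise EvaluationError("empty session: no errors to summarize")
    avg = float(np.mean(errors))
    sd = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    return SessionMetrics(errors, avg, sd, float(end_time - start_time))


def _aligned_session2(without: CohortTable, with_: CohortTable, col: str):
    if without.subjects != with_.subjects:
        raise CohortMismatchError(
            f"cohort misalignment: {without.subjects} vs {with_.subjects}"
        )
    wo = without.session(2)[col]
    wi = with_.session(2)[col]
    return wo.loc[without.subjects], wi.loc[without.subjects]


def mean_relative_reduction(
    without: CohortTable, with_: CohortTable, field: str = "avg"
) -> float:
    """Mean per-subject relative reduction (%) on the second-session rows.

    Returns 100 × mean over subjects of (1 - with/without) for the
    chosen field (``avg`` → mean error, ``time`` → operation time).
    A subject who worsened contributes negatively.
    """
    col = {"avg": "avg_cm", "time": "time_s"}.get(field)
    if col is None:
        raise EvaluationError(f"unknown field {field!r}; use 'avg' or 'time'")
    wo, wi = _aligned_session2(without, with_, col)
    if (wo <= 0).any():
        raise EvaluationError("baseline (without-guidance) values must be positive")
    return float(100.0 * np.mean(1.0 - wi.to_numpy() / wo.to_numpy()))


def practice_effect(first: pd.DataFrame, second: pd.DataFrame) -> pd.DataFrame:
    """Per-subject change from the first to the second session.

    Takes two subject-indexed session frames (see CohortTable.session)
    and returns a frame with delta_avg_cm, delta_time_s, and a boolean
    ``improved`` flag (mean error decreased).  The returned frame's
    ``attrs['n_improved']`` counts improved subjects.
    """
    if list(first.index) != list(second.index):
        raise CohortMismatchError("cohort misalignment between sessions")
    out = pd.DataFrame(
        {
            "delta_avg_cm": second["avg_cm"] - first["avg_cm"],
            "delta_time_s": second["time_s"] - first["time_s"],
        }
    )
    out["improved"] = out["delta_avg_cm"] < 0
    out.attrs["n_improved"] = int(out["improved"].sum())
    return out


def load_reference_cohort(condition: str) -> CohortTable:
    """Packaged eight-subject reference tables (conditions: with/without).

    These are the published cohort measurements shipped as fixture data;
    they are inputs to the statistics, never recomputed.
    """
    name = {
        "without": "cohort_without_guidance.csv",
        "with": "cohort_with_guidance.csv",
    }.get(condition)
    if name is None:
        raise EvaluationError("condition must be 'with' or 'without'")
    ref = resources.files("arthroguide.data").joinpath(name)
    with resources.as_file(ref) as path:
        return CohortTable.from_csv(path)
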