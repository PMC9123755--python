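"""Panel container, I/O, compliance filtering, scaling, and lagged design matrices.

The central object is :class:`EmaPanel`: a long-format table with one row per
scheduled prompt (participant x day x beep) and one column per momentary item
on the 0-100 slider scale.  Unanswered prompts are kept as rows with missing
values, so the number of rows is always ``n_participants x n_days x
beeps_per_day`` and compliance can be computed against the full schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed prompt times of the six-beep daily schedule, minutes since midnight
#: (09:00, 11:30, 14:00, 16:30, 19:00, 21:30).
DEFAULT_BEEP_TIMES = (540, 690, 840, 990, 1140, 1290)

META_COLUMNS = ["participant_id", "day", "beep", "clock_time"]


@dataclass(frozen=True)
class Schedule:
    """Sampling schedule: D days with B fixed-time beeps per day."""

    n_days: int = 14
    beeps_per_day: int = 6
    beep_times: tuple[int, ...] = DEFAULT_BEEP_TIMES

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.beeps_per_day < 1:
            raise ValueError("schedule needs at least one day and one beep per day")
        if len(self.beep_times) != self.beeps_per_day:
            raise ValueError(
                f"{self.beeps_per_day} beeps/day but {len(self.beep_times)} beep times"
            )

    @property
    def n_prompts(self) -> int:
        """Total scheduled prompts per participant (D x B)."""
        return self.n_days * self.beeps_per_day


@dataclass
class EmaPanel:
    """Long-format EMA panel.

    ``data`` holds one row per (participant, day, beep) with metadata columns
    ``participant_id, day, beep, clock_time`` followed by one numeric column
    per item; NaN marks a missing observation.
    """

    data: pd.DataFrame
    schedule: Schedule
    variable_names: list[str]

    def __post_init__(self) -> None:
        expected = META_COLUMNS + list(self.variable_names)
        missing_cols = [c for c in expected if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"panel is missing columns {missing_cols}")
        self.data = (
            self.data[expected]
            .sort_values(["participant_id", "day", "beep"], kind="mergesort")
            .reset_index(drop=True)
        )
        dup = self.data.duplicated(subset=["participant_id", "day", "beep"])
        if dup.any():
            row = self.data.loc[dup.idxmax()]
            raise ValueError(
                "duplicate (participant, day, beep) triple: "
                f"({row['participant_id']}, {row['day']}, {row['beep']})"
            )
        if len(self.data):
            days = self.data["day"].to_numpy()
            beeps = self.data["beep"].to_numpy()
            if days.min() < 1 or days.max() > self.schedule.n_days:
                raise ValueError("day index outside 1..n_days")
            if beeps.min() < 1 or beeps.max() > self.schedule.beeps_per_day:
                raise ValueError("beep index outside 1..beeps_per_day")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_vars(self) -> int:
        return len(self.variable_names)

    @property
    def participants(self) -> list:
        return list(pd.unique(self.data["participant_id"]))

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def values_matrix(self) -> np.ndarray:
        """(n_records, n_vars) float array of item values, NaN = missing."""
        return self.data[self.variable_names].to_numpy(dtype=float)

    def copy(self) -> "EmaPanel":
        return EmaPanel(self.data.copy(), self.schedule, list(self.variable_names))

    def validate_range(self) -> None:
        vals = self.values_matrix()
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            bad = finite[(finite < 0) | (finite > 100)][0]
            raise ValueError(f"value {bad} outside the 0-100 slider range")


def validate_values(panel: EmaPanel) -> EmaPanel:
    panel.validate_range()
    return panel


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_long_table(panel: EmaPanel, path) -> None:
    """Write the panel as comma-delimited text; empty cells encode missing."""
    panel.data.to_csv(path, index=False, na_rep="")


def read_long_table(path, schedule: Schedule | None = None) -> EmaPanel:
    """Read a long-format delimited panel file.

    Header must start with ``participant_id, day, beep, clock_time``; every
    later column is taken as one item variable.  If no schedule is given it is
    inferred from the day/beep indices and the per-beep clock times present in
    the file.
    """
    df = pd.read_csv(path)
    if list(df.columns[: len(META_COLUMNS)]) != META_COLUMNS:
        raise ValueError(
            f"header must begin with {META_COLUMNS}, got {list(df.columns[:4])}"
        )
    variable_names = list(df.columns[len(META_COLUMNS):])
    if not variable_names:
        raise ValueError("no item columns found after the metadata columns")
    if schedule is None:
        if len(df):
            n_days = int(df["day"].max())
            n_beeps = int(df["beep"].max())
            times = (
                df.groupby("beep")["clock_time"].first().sort_index().to_numpy()
            )
            beep_times = tuple(int(t) for t in times)
            if len(beep_times) < n_beeps:  # beeps absent from the file
                beep_times = tuple(DEFAULT_BEEP_TIMES[:n_beeps])
        else:
            n_days, n_beeps, beep_times = 14, 6, DEFAULT_BEEP_TIMES
        schedule = Schedule(n_days, n_beeps, beep_times)
    panel = EmaPanel(df, schedule, variable_names)
    panel.validate_range()
    return panel


def write_labels(labels: Mapping, path) -> None:
    pd.DataFrame(
        {"participant_id": list(labels.keys()), "cluster": list(labels.values())}
    ).to_csv(path, index=False)


def read_labels(path) -> dict:
    df = pd.read_csv(path)
    return dict(zip(df["participant_id"], df["cluster"]))


# ---------------------------------------------------------------------------
# Compliance
# ---------------------------------------------------------------------------

def compute_compliance(panel: EmaPanel) -> pd.Series:
    """Fraction of scheduled prompts each participant completed.

    A prompt counts as completed only when every item was answered; the
    denominator is the full schedule (D x B), so prompts absent from the table
    count as missed.
    """
    completed = completed_counts(panel)
    return completed / float(panel.schedule.n_prompts)


def completed_counts(panel: EmaPanel) -> pd.Series:
    vals = panel.data[panel.variable_names]
    done = vals.notna().all(axis=1)
    counts = done.groupby(panel.data["participant_id"], sort=False).sum()
    return counts.reindex(panel.participants).astype(int)


def filter_compliance(panel: EmaPanel, min_completed: int = 50) -> EmaPanel:
    """Keep participants with at least ``min_completed`` completed prompts.

    The default of 50 is the 60%-of-84 adherence rule for a 14-day, 6-beep
    schedule.  All records of retained participants are kept, including
    missing ones.
    """
    if min_completed > panel.schedule.n_prompts:
        raise ValueError(
            f"min_completed={min_completed} exceeds the {panel.schedule.n_prompts} "
            "scheduled prompts"
        )
    counts = completed_counts(panel)
    keep = set(counts.index[counts >= min_completed])
    if not keep:
        warnings.warn("compliance filter removed every participant", stacklevel=2)
    out = panel.data[panel.data["participant_id"].isin(keep)].reset_index(drop=True)
    return EmaPanel(out, panel.schedule, list(panel.variable_names))


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingRecord:
    """Pooled mean/SD per variable; allows exact inversion of z-scoring."""

    means: dict[str, float]
    sds: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": list(self.means), "mean": list(self.means.values()),
             "sd": list(self.sds.values())}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScalingRecord":
        return cls(dict(zip(df["variable"], df["mean"])),
                   dict(zip(df["variable"], df["sd"])))


def standardize(panel: EmaPanel) -> tuple[EmaPanel, ScalingRecord]:
    """z-score each variable pooled across all non-missing observations."""
    out = panel.copy()
    means, sds = {}, {}
    for name in panel.variable_names:
        col = out.data[name].to_numpy(dtype=float)
        mu = float(np.nanmean(col))
        sd = float(np.nanstd(col, ddof=0))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"variable '{name}' has zero pooled variance")
        out.data[name] = (col - mu) / sd
        means[name], sds[name] = mu, sd
    return out, ScalingRecord(means, sds)


def destandardize(panel: EmaPanel, record: ScalingRecord) -> EmaPanel:
    out = panel.copy()
    for name in panel.variable_names:
        out.data[name] = out.data[name] * record.sds[name] + record.means[name]
    return out


# ---------------------------------------------------------------------------
# Lagged design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """Exogenous-covariate coding for the design matrix.

    beep_indicators
        Time of day as B-1 indicator columns (reference = first beep); the
        default, since the daytime courses are per-beep summaries.
    clock_time
        Alternative continuous coding: clock time in hours, centred at noon.
    day_trend
        Optional linear day trend, centred.
    """

    beep_indicators: bool = True
    clock_time: bool = False
    day_trend: bool = False

    def names(self, schedule: Schedule) -> list[str]:
        out = []
        if self.beep_indicators:
            out += [f"beep_{b}" for b in range(2, schedule.beeps_per_day + 1)]
        if self.clock_time:
            out.append("clock_hours")
        if self.day_trend:
            out.append("day_trend")
        return out

    def matrix(self, df: pd.DataFrame, schedule: Schedule) -> np.ndarray:
        cols = []
        if self.beep_indicators:
            for b in range(2, schedule.beeps_per_day + 1):
                cols.append((df["beep"].to_numpy() == b).astype(float))
        if self.clock_time:
            cols.append(df["clock_time"].to_numpy(dtype=float) / 60.0 - 12.0)
        if self.day_trend:
            mid = (schedule.n_days + 1) / 2.0
            cols.append(df["day"].to_numpy(dtype=float) - mid)
        if not cols:
            return np.empty((len(df), 0))
        return np.column_stack(cols)


@dataclass
class DesignPair:
    """Aligned outcome and predictor matrices for conditional VAR estimation.

    Row r models occasion t of one participant given its p predecessors in
    the concatenated within-participant (day, beep) ordering — each day's
    last beep is the lagged predictor of the next day's first beep, with no
    overnight gap.  Predictor columns: intercept, covariates, then lag-1
    block ... lag-p block of all variables.
    """

    outcomes: np.ndarray          # (n_rows, n_vars)
    predictors: np.ndarray        # (n_rows, 1 + n_covariates + n_vars * lag)
    row_participant: np.ndarray   # participant id per row
    lag: int
    variable_names: list[str]
    covariate_names: list[str]
    participant_ids: list = field(default_factory=list)

    @property
    def n_vars(self) -> int:
        return self.outcomes.shape[1]

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def codes(self) -> np.ndarray:
        """Integer participant code per row, following participant_ids order."""
        lookup = {p: i for i, p in enumerate(self.participant_ids)}
        return np.fromiter(
            (lookup[p] for p in self.row_participant), dtype=int,
            count=len(self.row_participant),
        )

    def column_slice(self, lag: int) -> np.ndarray:
        """Column indices for a sub-model of order ``lag`` <= self.lag."""
        if lag > self.lag:
            raise ValueError("requested lag exceeds the design's lag order")
        base = 1 + self.n_covariates
        return np.r_[0:base, base: base + self.n_vars * lag]

    def predictor_names(self) -> list[str]:
        names = ["intercept"] + list(self.covariate_names)
        for l in range(1, self.lag + 1):
            names += [f"{v}_lag{l}" for v in self.variable_names]
        return names


def build_design(
    panel: EmaPanel,
    lag: int,
    covariates: CovariateSpec | None = None,
) -> DesignPair:
    """Chain each participant's occasions and build lag-p outcome/predictor rows.

    Requires a fully observed panel (run imputation first); the first ``lag``
    occasions of each participant are conditioned on and contribute no
    outcome row.  Participants with too few occasions are dropped with a
    warning.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    covariates = covariates or CovariateSpec()
    if np.isnan(panel.values_matrix()).any():
        raise ValueError("panel contains missing values; impute before build_design")

    d = panel.n_vars
    out_Y, out_X, out_pid = [], [], []
    kept = []
    for pid, grp in panel.data.groupby("participant_id", sort=False):
        grp = grp.sort_values(["day", "beep"], kind="mergesort")
        T = len(grp)
        if T <= lag:
            warnings.warn(
                f"participant {pid!r} has only {T} occasions (<= lag {lag}); dropped",
                stacklevel=2,
            )
            continue
        vals = grp[panel.variable_names].to_numpy(dtype=float)
        cov = covariates.matrix(grp, panel.schedule)
        n_rows = T - lag
        lag_blocks = [vals[lag - l: T - l] for l in range(1, lag + 1)]
        X = np.column_stack(
            [np.ones(n_rows), cov[lag:]] + lag_blocks
        )
        out_Y.append(vals[lag:])
        out_X.append(X)
        out_pid.append(np.repeat(pid, n_rows))
        kept.append(pid)

    if not out_Y:
        raise ValueError("no participant has more occasions than the lag order")
    return DesignPair(
        outcomes=np.vstack(out_Y),
        predictors=np.vstack(out_X),
        row_participant=np.concatenate(out_pid),
        lag=lag,
        variable_names=list(panel.variable_names),
        covariate_names=covariates.names(panel.schedule),
        participant_ids=kept,
    )
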