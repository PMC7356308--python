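"""Longitudinal pain-cohort and baseline endpoint-battery containers and I/O.

The canonical on-disk representation is long-format delimited text (CSV,
UTF-8, header row): one row per subject-timepoint for pain, one row per
subject with one column per endpoint for the baseline battery.  Missing
values are written as empty fields and read from empty fields or ``NA``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Timepoint",
    "DEFAULT_TIMEPOINTS",
    "DAYS_PER_MONTH",
    "LongCohort",
    "EndpointMatrix",
    "SchemaError",
    "CohortValidationError",
    "ConfigurationError",
    "read_cohort",
    "write_cohort",
    "read_endpoints",
    "write_endpoints",
    "read_direction_registry",
    "locf_impute",
]

DAYS_PER_MONTH = 30.44  # mean Gregorian month length, used to place day-scale visits


class SchemaError(ValueError):
    """A file's columns or labels do not match the declared schema."""


class CohortValidationError(ValueError):
    """Data violate a cohort invariant (range, uniqueness, coverage)."""


class ConfigurationError(ValueError):
    """A registry or configuration object is incomplete or inconsistent."""


@dataclass(frozen=True)
class Timepoint:
    """A named study visit at a fixed time (months since baseline).

    The default schedule places the first post-intervention pain rating at
    day 17 (the cohort's median first-intervention day), i.e. 17/30.44
    months, between the baseline and 6-month visits.
    """

    label: str
    time_value: float  # months since baseline

    def __post_init__(self) -> None:
        if self.time_value < 0:
            raise ValueError(f"time_value must be non-negative, got {self.time_value}")


DEFAULT_TIMEPOINTS: tuple[Timepoint, ...] = (
    Timepoint("BASELINE", 0.0),
    Timepoint("POST_INT1", 17 / DAYS_PER_MONTH),
    Timepoint("M6", 6.0),
    Timepoint("M12", 12.0),
)


def _check_timepoints(timepoints: Sequence[Timepoint]) -> tuple[Timepoint, ...]:
    tps = tuple(timepoints)
    if not tps:
        raise ValueError("at least one timepoint required")
    values = [tp.time_value for tp in tps]
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError("timepoint labels must be strictly ordered by time_value")
    if tps[0].label == "BASELINE" and tps[0].time_value != 0.0:
        raise ValueError("BASELINE must have time_value 0")
    labels = [tp.label for tp in tps]
    if len(set(labels)) != len(labels):
        raise ValueError("timepoint labels must be unique")
    return tps


class LongCohort:
    """Per-subject pain observations on a bounded 0-10 numerical rating scale.

    Parameters
    ----------
    data : DataFrame with columns ``subject``, ``timepoint``, ``pain``.
        ``pain`` may be NaN (missing); absent rows are equivalent to NaN.
    timepoints : ordered visit schedule; labels in ``data`` must come from it.
    scale_bounds : closed interval the pain scale lives on, default (0, 10).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        timepoints: Sequence[Timepoint] = DEFAULT_TIMEPOINTS,
        scale_bounds: tuple[float, float] = (0.0, 10.0),
    ) -> None:
        self.timepoints = _check_timepoints(timepoints)
        self.scale_bounds = (float(scale_bounds[0]), float(scale_bounds[1]))
        if self.scale_bounds[0] >= self.scale_bounds[1]:
            raise ValueError("scale_bounds must be an increasing pair")

        required = {"subject", "timepoint", "pain"}
        if not required.issubset(data.columns):
            raise SchemaError(f"cohort data must have columns {sorted(required)}")
        df = data.loc[:, ["subject", "timepoint", "pain"]].copy()
        df["subject"] = df["subject"].astype(str)
        df["timepoint"] = df["timepoint"].astype(str)
        df["pain"] = pd.to_numeric(df["pain"], errors="raise").astype(float)

        known = {tp.label for tp in self.timepoints}
        unknown = sorted(set(df["timepoint"]) - known)
        if unknown:
            raise SchemaError(f"unknown timepoint label(s): {unknown}")

        dup = df.duplicated(subset=["subject", "timepoint"])
        if dup.any():
            pairs = df.loc[dup, ["subject", "timepoint"]].values.tolist()
            raise CohortValidationError(f"duplicate observation(s): {pairs}")

        low, high = self.scale_bounds
        bad = df["pain"].notna() & ((df["pain"] < low) | (df["pain"] > high))
        if bad.any():
            rows = df.index[bad].tolist()
            vals = df.loc[bad, "pain"].tolist()
            raise CohortValidationError(
                f"pain outside [{low}, {high}] in row(s) {rows}: values {vals}"
            )

        empty = df.groupby("subject")["pain"].apply(lambda s: s.notna().sum() == 0)
        if empty.any():
            raise CohortValidationError(
                f"subject(s) with no non-missing observation: {sorted(empty[empty].index)}"
            )

        order = {tp.label: i for i, tp in enumerate(self.timepoints)}
        df = df.sort_values(
            ["subject", "timepoint"], key=lambda s: s.map(order) if s.name == "timepoint" else s
        ).reset_index(drop=True)
        self.data = df

    # -- accessors ---------------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject"].unique())

    @property
    def n_subjects(self) -> int:
        return self.data["subject"].nunique()

    @property
    def labels(self) -> list[str]:
        return [tp.label for tp in self.timepoints]

    @property
    def times(self) -> np.ndarray:
        """Visit times in months since baseline, in schedule order."""
        return np.array([tp.time_value for tp in self.timepoints])

    def observation_matrix(self) -> tuple[list[str], np.ndarray]:
        """Subjects and an (n_subjects, n_timepoints) array with NaN for missing."""
        wide = self.data.pivot(index="subject", columns="timepoint", values="pain")
        wide = wide.reindex(columns=self.labels).sort_index()
        return list(wide.index), wide.to_numpy(dtype=float)

    def to_wide(self) -> pd.DataFrame:
        """Wide export convenience (one row per subject); long remains canonical."""
        subjects, y = self.observation_matrix()
        return pd.DataFrame(y, index=pd.Index(subjects, name="subject"), columns=self.labels)

    def is_complete(self) -> bool:
        _, y = self.observation_matrix()
        return not np.isnan(y).any()


class EndpointMatrix:
    """Subject x endpoint baseline battery with a vulnerable-direction flag per endpoint.

    ``directions[e] = +1`` means a higher raw value on endpoint ``e`` marks a
    more vulnerable subject; ``-1`` means higher is better.  Constant columns
    are accepted here and rejected at standardization time.
    """

    def __init__(self, values: pd.DataFrame, directions: Mapping[str, int]) -> None:
        vals = values.copy()
        vals.index = vals.index.astype(str)
        vals.index.name = "subject"
        vals = vals.astype(float)
        missing = [c for c in vals.columns if c not in directions]
        if missing:
            raise ConfigurationError(
                f"endpoint(s) missing from direction registry: {missing}"
            )
        bad = {e: d for e, d in directions.items() if e in vals.columns and d not in (1, -1)}
        if bad:
            raise ConfigurationError(f"directions must be +1 or -1, got {bad}")
        self.values = vals
        self.directions = {e: int(directions[e]) for e in vals.columns}

    @property
    def endpoints(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)


# -- readers / writers -----------------------------------------------------

_NA_TOKENS = ["", "NA"]

_DEFAULT_SCHEMA = {"subject": "subject", "timepoint": "timepoint", "pain": "pain"}


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    timepoints: Sequence[Timepoint] = DEFAULT_TIMEPOINTS,
    scale_bounds: tuple[float, float] = (0.0, 10.0),
) -> LongCohort:
    """Read a long-format pain table (CSV, header row) into a validated cohort.

    ``schema`` maps the canonical roles {subject, timepoint, pain} to the
    file's column names; by default the columns are named after the roles.
    """
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(
        path, dtype={colmap["subject"]: str, colmap["timepoint"]: str},
        na_values=_NA_TOKENS, keep_default_na=False,
    )
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    return LongCohort(df, timepoints=timepoints, scale_bounds=scale_bounds)


def write_cohort(cohort: LongCohort, path: str | Path) -> None:
    """Write the cohort back to CSV; round-trips bit-identically through read_cohort."""
    cohort.data.to_csv(path, index=False, na_rep="")


def read_direction_registry(path: str | Path) -> dict[str, int]:
    """Load an endpoint -> +/-1 direction registry from JSON."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {str(k): int(v) for k, v in raw.items()}


def read_endpoints(
    path: str | Path,
    direction_registry: Mapping[str, int] | str | Path,
    subject_column: str = "subject",
) -> EndpointMatrix:
    """Read a subject x endpoint CSV and attach vulnerable directions.

    Every endpoint column must appear in the registry; an uncovered column is
    a configuration error naming the endpoint.
    """
    if isinstance(direction_registry, (str, Path)):
        direction_registry = read_direction_registry(direction_registry)
    df = pd.read_csv(path, dtype={subject_column: str}, na_values=_NA_TOKENS, keep_default_na=False)
    if subject_column not in df.columns:
        raise SchemaError(f"missing subject column {subject_column!r} in {path}")
    df = df.set_index(subject_column)
    return EndpointMatrix(df, direction_registry)


def write_endpoints(matrix: EndpointMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, na_rep="")


# -- LOCF ------------------------------------------------------------------


def locf_impute(cohort: LongCohort) -> LongCohort:
    """Last observation carried forward over the declared visit schedule.

    Each missing value is replaced by the subject's most recent earlier
    non-missing value; leading missing values stay missing and observed
    values are never altered.  Idempotent by construction.
    """
    subjects, y = cohort.observation_matrix()
    wide = pd.DataFrame(y, index=subjects, columns=cohort.labels)
    filled = wide.ffill(axis=1)
    long = (
        filled.rename_axis("subject")
        .reset_index()
        .melt(id_vars="subject", var_name="timepoint", value_name="pain")
    )
    long = long.dropna(subset=["pain"]).reset_index(drop=True)
    return LongCohort(long, timepoints=cohort.timepoints, scale_bounds=cohort.scale_bounds)
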