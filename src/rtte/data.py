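"""Long-format recurrent-event records: data model, CSV I/O and validation.

A dataset is a long-format table with one row per observation:

======== ==================================================================
ID       subject identifier (opaque; order of first appearance is kept)
TIME     weeks since the first clozapine dose (non-negative real)
DV       1 = positive-symptom improvement event, 0 = non-event observation
other    one numeric column per covariate (continuous, or 0/1 indicator)
======== ==================================================================

Within a subject, rows are time-ordered and the last row is the censoring
(end-of-follow-up) record, which must have ``DV = 0``.  Covariate values are
carried forward between records (step functions of time), which is both how
the likelihood integrates piecewise and how the simulator interpolates.

Tied improvement times within a subject (two events recorded in the same
week) are perturbed by +1e-6 weeks when subject histories are built: the
likelihood requires distinct jump times, and exact ties at weekly recording
resolution are artifacts of rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "SchemaError",
    "ValidationError",
    "EventRecord",
    "Dataset",
    "SubjectHistory",
    "read_dataset",
    "write_dataset",
    "from_frame",
    "subject_histories",
    "compute_medians",
]

REQUIRED_COLUMNS = ("ID", "TIME", "DV")
CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: default perturbation applied to the second of two tied event times (weeks)
TIE_EPS = 1e-6
#: events are clamped to at least this time; time-varying hazards may be
#: singular at exactly zero
MIN_EVENT_TIME = 1e-6


class DatasetError(ValueError):
    """Base class for dataset problems."""


class SchemaError(DatasetError):
    """Columns do not match the declared covariate schema."""


class ValidationError(DatasetError):
    """Rows violate the event-record invariants."""


@dataclass(frozen=True)
class EventRecord:
    """One observation row; ``censor`` marks the subject's terminal record."""

    subject_id: str
    time: float
    dv: int
    censor: bool
    covariates: Mapping[str, float]


@dataclass
class Dataset:
    """A validated long-format event dataset.

    ``frame`` keeps the raw rows (already validated, subject blocks in order
    of first appearance); ``schema`` maps covariate name to ``"continuous"``
    or ``"categorical"``; ``medians`` holds per-covariate medians over one
    baseline value per subject, used to centre continuous covariates.
    """

    frame: pd.DataFrame
    schema: dict[str, str]
    medians: dict[str, float] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["ID"]))

    @property
    def n_subjects(self) -> int:
        return self.frame["ID"].nunique()

    @property
    def n_events(self) -> int:
        return int((self.frame["DV"] == 1).sum())

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.schema)

    def iter_records(self) -> Iterator[EventRecord]:
        last_idx = self.frame.groupby("ID", sort=False).tail(1).index
        last = set(last_idx)
        for idx, row in self.frame.iterrows():
            yield EventRecord(
                subject_id=str(row["ID"]),
                time=float(row["TIME"]),
                dv=int(row["DV"]),
                censor=idx in last,
                covariates={k: float(row[k]) for k in self.schema},
            )


@dataclass
class SubjectHistory:
    """Ordered events, terminal (censoring) time and covariate step functions."""

    subject_id: str
    event_times: np.ndarray
    terminal_time: float
    path_times: np.ndarray
    path_values: dict[str, np.ndarray]

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)

    def covariate(self, name: str, t) -> np.ndarray | float:
        """Last-observation-carried-forward covariate value at time(s) t."""
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.path_times, t, side="right") - 1, 0, None)
        out = self.path_values[name][idx]
        return float(out) if out.ndim == 0 else out

    def baseline(self) -> dict[str, float]:
        return {k: float(v[0]) for k, v in self.path_values.items()}

    def covariates_at(self, t) -> dict[str, np.ndarray | float]:
        return {k: self.covariate(k, t) for k in self.path_values}

    def segments(self) -> list[tuple[float, float, dict[str, float]]]:
        """Covariate-constant intervals covering (0, terminal_time].

        Adjacent intervals with identical covariate values are merged, so a
        subject with static covariates yields a single segment.
        """
        names = list(self.path_values)
        end = self.terminal_time
        inner = self.path_times[(self.path_times > 0.0) & (self.path_times < end)]
        cuts = np.unique(np.concatenate([[0.0], inner, [end]]))
        starts = cuts[:-1]
        idx = np.clip(np.searchsorted(self.path_times, starts, side="right") - 1, 0, None)
        values = np.column_stack([self.path_values[k][idx] for k in names]) \
            if names else np.empty((starts.size, 0))
        keep = np.ones(starts.size, dtype=bool)
        if starts.size > 1:
            keep[1:] = np.any(values[1:] != values[:-1], axis=1)
        first = np.nonzero(keep)[0]
        t0s = starts[first]
        t1s = np.append(starts[first[1:]], cuts[-1])
        return [
            (float(a), float(b), {k: float(values[i, j]) for j, k in enumerate(names)})
            for a, b, i in zip(t0s, t1s, first)
        ]


# ---------------------------------------------------------------------------
# validation and construction
# ---------------------------------------------------------------------------

def _validate_frame(df: pd.DataFrame, schema: Mapping[str, str]) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} is missing")
    for name, kind in schema.items():
        if name not in df.columns:
            raise SchemaError(f"covariate column {name!r} declared in schema is missing")
        if kind not in (CONTINUOUS, CATEGORICAL):
            raise SchemaError(f"unknown covariate kind {kind!r} for {name!r}")
    df = df.copy()
    df["TIME"] = df["TIME"].astype(float)
    df["DV"] = df["DV"].astype(int)

    if df["TIME"].isna().any() or not np.all(np.isfinite(df["TIME"])):
        raise ValidationError("non-finite TIME value")
    if (df["TIME"] < 0).any():
        raise ValidationError("negative TIME value")
    if not df["DV"].isin((0, 1)).all():
        raise ValidationError("DV must be 0 or 1")
    for name, kind in schema.items():
        col = df[name].astype(float)
        if col.isna().any() or not np.all(np.isfinite(col)):
            raise ValidationError(f"non-finite value in covariate {name!r}")
        if kind == CATEGORICAL and not col.isin((0.0, 1.0)).all():
            raise ValidationError(f"categorical covariate {name!r} must be 0/1")
        df[name] = col

    for sid, grp in df.groupby("ID", sort=False):
        times = grp["TIME"].to_numpy()
        if np.any(np.diff(times) < 0):
            raise ValidationError(f"subject {sid!r}: times are not non-decreasing")
        if int(grp["DV"].iloc[-1]) != 0:
            raise ValidationError(
                f"subject {sid!r}: last record must be a censoring record (DV=0)"
            )
        if times[-1] <= 0:
            raise ValidationError(f"subject {sid!r}: terminal time must be positive")
    return df.reset_index(drop=True)


def compute_medians(data: "Dataset | pd.DataFrame", names: Sequence[str],
                    schema: Mapping[str, str] | None = None) -> dict[str, float]:
    """Median of each named continuous covariate over one baseline value per subject."""
    if isinstance(data, Dataset):
        frame, schema = data.frame, data.schema
    else:
        frame = data
        if schema is None:
            raise ValueError("schema is required when passing a bare frame")
    out: dict[str, float] = {}
    baseline = frame.groupby("ID", sort=False).head(1)
    for name in names:
        if schema.get(name) != CONTINUOUS:
            raise SchemaError(f"median centring requested for non-continuous covariate {name!r}")
        out[name] = float(baseline[name].median())
    return out


def from_frame(frame: pd.DataFrame, schema: Mapping[str, str]) -> Dataset:
    """Validate an in-memory long-format frame and compute centring medians."""
    schema = dict(schema)
    validated = _validate_frame(frame, schema)
    continuous = [n for n, k in schema.items() if k == CONTINUOUS]
    medians = compute_medians(validated, continuous, schema)
    return Dataset(frame=validated, schema=schema, medians=medians)


def read_dataset(path, schema: Mapping[str, str]) -> Dataset:
    """Read and validate a long-format CSV file (UTF-8, comma separated)."""
    df = pd.read_csv(path, dtype={"ID": str})
    return from_frame(df, schema)


def write_dataset(ds: Dataset, path) -> None:
    """Write the dataset in the canonical CSV dialect (round-trip stable)."""
    cols = list(REQUIRED_COLUMNS) + list(ds.schema)
    # pandas' shortest-repr float formatting is round-trip exact
    ds.frame[cols].to_csv(path, index=False)


def subject_histories(ds: Dataset, tie_eps: float = TIE_EPS,
                      min_event_time: float = MIN_EVENT_TIME) -> list[SubjectHistory]:
    """One SubjectHistory per subject, in order of first appearance.

    Event times are clamped to ``>= min_event_time`` and exact ties within a
    subject are broken by adding ``tie_eps`` increments to the later event.
    """
    out: list[SubjectHistory] = []
    names = list(ds.schema)
    for sid, grp in ds.frame.groupby("ID", sort=False):
        times = grp["TIME"].to_numpy(dtype=float)
        dv = grp["DV"].to_numpy(dtype=int)
        terminal = float(times[-1])
        ev = np.maximum(times[dv == 1], min_event_time)
        for i in range(1, ev.size):
            if ev[i] <= ev[i - 1]:
                ev[i] = ev[i - 1] + tie_eps
        if ev.size and ev[-1] > terminal:
            terminal = float(ev[-1])  # tie-break nudged past the censor record
        path_values = {k: grp[k].to_numpy(dtype=float) for k in names}
        out.append(
            SubjectHistory(
                subject_id=str(sid),
                event_times=ev,
                terminal_time=terminal,
                path_times=times,
                path_values=path_values,
            )
        )
    return out
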