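"""Reading raw EHR event streams and assembling per-stay hourly windows.

The pipeline is deliberately format-agnostic: any long-format delimited
export with (patient id, stay id, timestamp, variable label, raw value)
columns can be ingested, with a configurable column mapping.  Events are
anchored to ICU admission, assigned to half-open hourly bins
``[t, t+1)`` and truncated to an observation window (default 48 h, at
most 5000 events per stay, keeping the most recent events).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "EventRecord",
    "StayRecord",
    "ParseReport",
    "Cohort",
    "load_events",
    "load_stays",
    "assign_hour",
    "truncate_stay",
    "build_cohort",
    "DEFAULT_EVENT_COLUMNS",
    "DEFAULT_STAY_COLUMNS",
]

DEFAULT_EVENT_COLUMNS = {
    "patient_id": "patient_id",
    "stay_id": "stay_id",
    "charttime": "charttime",
    "label": "label",
    "value": "value",
}

DEFAULT_STAY_COLUMNS = {
    "stay_id": "stay_id",
    "admission_time": "admission_time",
    "outcome": "outcome",
    "length_of_stay": "length_of_stay",
}


class ConfigError(ValueError):
    """A required column or configuration field is missing or invalid."""


@dataclass(frozen=True)
class EventRecord:
    """One raw observation: who, when, what and the verbatim value string."""

    patient_id: str
    stay_id: str
    time: object  # pandas Timestamp, or float hours for numeric exports
    label: str
    value: str


@dataclass(frozen=True)
class StayRecord:
    """One ICU stay with its admission anchor and in-hospital outcome.

    ``outcome`` uses the internal convention death = 1, survival = 0, so
    model outputs read directly as mortality probabilities.
    """

    stay_id: str
    admission_time: object
    outcome: int
    length_of_stay: float


@dataclass
class ParseReport:
    """Row accounting for one :func:`load_events` call."""

    n_rows: int = 0
    n_parsed: int = 0
    n_rejected_time: int = 0
    rejected_examples: list = field(default_factory=list)


def _resolve_delimiter(path, delimiter):
    if delimiter is not None:
        return delimiter
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if ("\t" in header and "," not in header) else ","


def _parse_times(raw: pd.Series) -> pd.Series:
    """Timestamps or real-valued hours; unparseable entries become NaT/NaN."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all() and len(raw):
        return numeric.astype(float)
    return pd.to_datetime(raw, errors="coerce", format="mixed")


def load_events(path, column_map=None, delimiter=None):
    """Read a delimited event table into a canonical events frame.

    Returns ``(events, report)`` where ``events`` has columns
    ``patient_id, stay_id, time, label, value`` (label/value kept as
    verbatim strings; missing values as the empty string) and ``report``
    counts rows rejected for unparseable timestamps.

    Raises
    ------
    ConfigError
        If a required column is absent from the header.
    """
    colmap = dict(DEFAULT_EVENT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(
        path,
        sep=_resolve_delimiter(path, delimiter),
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ConfigError(f"event file {path} is missing required column(s): {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    report = ParseReport(n_rows=len(df))
    times = _parse_times(df["charttime"])
    ok = times.notna().to_numpy()
    if not ok.all():
        bad = df.loc[~ok, "charttime"].head(5).tolist()
        report.rejected_examples = bad
    report.n_rejected_time = int((~ok).sum())

    events = pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "stay_id": df["stay_id"].to_numpy(),
            "time": times,
            "label": df["label"].to_numpy(),
            "value": df["value"].to_numpy(),
        }
    )
    events = events.loc[ok].reset_index(drop=True)
    report.n_parsed = len(events)
    return events, report


def load_stays(path, column_map=None, delimiter=None):
    """Read the stay table (stay_id, admission_time, outcome, length_of_stay)."""
    colmap = dict(DEFAULT_STAY_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(
        path,
        sep=_resolve_delimiter(path, delimiter),
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ConfigError(f"stay file {path} is missing required column(s): {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    out = pd.DataFrame(
        {
            "stay_id": df["stay_id"].to_numpy(),
            "admission_time": _parse_times(df["admission_time"]),
            "outcome": pd.to_numeric(df["outcome"], errors="coerce"),
            "length_of_stay": pd.to_numeric(df["length_of_stay"], errors="coerce"),
        }
    )
    return out


def assign_hour(event: EventRecord, stay: StayRecord, window_hours: int = 48):
    """Hour index of ``event`` relative to ``stay``'s admission, or ``None``.

    Bins are 0-based and half-open: an event exactly at admission falls in
    hour 0; an event at or past ``window_hours`` (or before admission) is
    out of window and returns ``None``.
    """
    if event.stay_id != stay.stay_id:
        raise ValueError(f"event stay {event.stay_id!r} != stay {stay.stay_id!r}")
    if hasattr(event.time, "to_pydatetime") or isinstance(event.time, str):
        elapsed = (pd.Timestamp(event.time) - pd.Timestamp(stay.admission_time)) / pd.Timedelta(
            hours=1
        )
    else:
        elapsed = float(event.time) - float(stay.admission_time)
    if elapsed < 0 or elapsed >= window_hours:
        return None
    return int(np.floor(elapsed))


def truncate_stay(events: pd.DataFrame, window_hours: int = 48, max_events: int = 5000):
    """Clip one stay's time-ordered events to the window and event budget.

    Keeps events with ``0 <= hour < window_hours``; when more than
    ``max_events`` remain, only the most recent ``max_events`` are kept
    (earlier events are dropped).  Idempotent; preserves the stable input
    order for tied timestamps.
    """
    kept = events[(events["hour"] >= 0) & (events["hour"] < window_hours)]
    if len(kept) > max_events:
        kept = kept.iloc[-max_events:]
    return kept.reset_index(drop=True)


@dataclass
class Cohort:
    """Filtered stays plus their windowed, truncated, time-sorted events.

    ``stays`` is indexed by stay_id with columns outcome / length_of_stay /
    admission_time; ``events`` carries an ``hour`` column and only
    in-window rows.
    """

    stays: pd.DataFrame
    events: pd.DataFrame
    window_hours: int
    max_events: int
    n_excluded_short: int = 0
    n_excluded_unlabelled: int = 0

    @property
    def stay_ids(self):
        return list(self.stays.index)

    def outcomes(self, stay_ids=None):
        ids = self.stay_ids if stay_ids is None else list(stay_ids)
        return self.stays.loc[ids, "outcome"].to_numpy(dtype=int)

    def events_for(self, stay_id):
        return self.events[self.events["stay_id"] == stay_id]


def build_cohort(
    stays: pd.DataFrame,
    events: pd.DataFrame,
    window_hours: int = 48,
    max_events: int = 5000,
    min_stay_hours: float = 48,
) -> Cohort:
    """Attach events to stays, bin by hour, truncate, and filter the cohort.

    Stays shorter than ``min_stay_hours`` or lacking an outcome label are
    excluded (and counted).  Events are stably sorted by time within each
    stay, anchored to that stay's admission time, and clipped with
    :func:`truncate_stay`.  Accepts either the canonical frames from
    :func:`load_events` / :func:`load_stays` or raw frames still carrying
    string ``charttime`` / ``admission_time`` columns.
    """
    stays = stays.copy()
    events = events.copy()
    if "time" not in events.columns and "charttime" in events.columns:
        events["time"] = _parse_times(events["charttime"].astype(str))
    elif not (
        pd.api.types.is_datetime64_any_dtype(events["time"])
        or pd.api.types.is_numeric_dtype(events["time"])
    ):
        events["time"] = _parse_times(events["time"].astype(str))
    if not (
        pd.api.types.is_datetime64_any_dtype(stays["admission_time"])
        or pd.api.types.is_numeric_dtype(stays["admission_time"])
    ):
        stays["admission_time"] = _parse_times(stays["admission_time"].astype(str))
    stays["outcome"] = pd.to_numeric(stays["outcome"], errors="coerce")
    stays["length_of_stay"] = pd.to_numeric(stays["length_of_stay"], errors="coerce")
    unlabelled = stays["outcome"].isna() | ~stays["outcome"].isin([0, 1])
    short = stays["length_of_stay"] < min_stay_hours
    keep = ~unlabelled & ~short
    kept = stays.loc[keep].copy()
    kept["outcome"] = kept["outcome"].astype(int)
    kept = kept.set_index("stay_id")

    ev = events[events["stay_id"].isin(kept.index)].copy()
    adm = kept["admission_time"]
    if len(ev):
        adm_per_event = ev["stay_id"].map(adm)
        if pd.api.types.is_datetime64_any_dtype(ev["time"]):
            hours = (
                pd.to_datetime(ev["time"]) - pd.to_datetime(adm_per_event)
            ) / pd.Timedelta(hours=1)
        else:
            hours = ev["time"].astype(float) - adm_per_event.astype(float)
        ev["hour"] = np.floor(hours.to_numpy(dtype=float)).astype(int)
        # floor() maps (-1, 0) to -1 already; mark anything pre-admission OOW
        ev.loc[hours.to_numpy(dtype=float) < 0, "hour"] = -1
    else:
        ev["hour"] = pd.Series(dtype=int)

    # stable sort by stay then time; ties keep file order
    ev = ev.sort_values(["stay_id", "time"], kind="mergesort").reset_index(drop=True)
    parts = []
    for sid, grp in ev.groupby("stay_id", sort=False):
        parts.append(truncate_stay(grp, window_hours, max_events))
    ev = (
        pd.concat(parts, ignore_index=True)
        if parts
        else ev.iloc[0:0].reset_index(drop=True)
    )
    return Cohort(
        stays=kept,
        events=ev,
        window_hours=window_hours,
        max_events=max_events,
        n_excluded_short=int((short & ~unlabelled).sum()),
        n_excluded_unlabelled=int(unlabelled.sum()),
    )
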