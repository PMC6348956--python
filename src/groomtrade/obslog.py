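"""Focal-observation event logs: data model, CSV I/O, validation and bout segmentation.

The raw input of every analysis is a stream of timed behavioural events
recorded during individual focal samples: grooming episodes (with a
duration) and the point events used to infer dominance (supplants,
avoidances, aggression, submission).  Grooming episodes are segmented into
dyadic *bouts*: a bout runs while the pair keeps grooming, in either
direction, and ends once more than ``gap_s`` seconds (default 30 s) pass
without grooming between the two participants.  The first individual to
groom in a bout is the Groomer; a bout is *reciprocated* when both
directions occur within it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RecordError, SchemaError

logger = logging.getLogger(__name__)

EVENT_TYPES = frozenset(
    {"grooming", "supplant", "avoidance", "aggression", "submission"}
)

#: Required columns of the event-log CSV dialect, in canonical order.
LOG_COLUMNS = (
    "period_id",
    "focal_id",
    "sample_start_s",
    "event_type",
    "actor_id",
    "recipient_id",
    "start_s",
    "duration_s",
)

#: Columns identifying one physical event; duration is deliberately excluded
#: so that conflicting double records of the same event are caught.
DEDUP_KEY = ("period_id", "event_type", "actor_id", "recipient_id", "start_s")

DEFAULT_SAMPLE_LENGTH_S = 15 * 60


@dataclass(frozen=True)
class GroomingEpisode:
    """One directed, continuous stretch of grooming."""

    actor_id: str
    recipient_id: str
    start: float
    duration: float

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class GroomingBout:
    """A dyadic grooming bout: consecutive episodes separated by <= gap_s."""

    period_id: str
    pair: tuple[str, str]  # sorted unordered pair
    episodes: list[GroomingEpisode]
    groomer_id: str
    reciprocated: bool
    duration_by_direction: dict[tuple[str, str], float]

    @property
    def start(self) -> float:
        return self.episodes[0].start

    @property
    def end(self) -> float:
        return max(e.end for e in self.episodes)

    @property
    def reciprocator_id(self) -> str:
        a, b = self.pair
        return b if self.groomer_id == a else a

    def duration(self, actor: str, recipient: str) -> float:
        return self.duration_by_direction.get((actor, recipient), 0.0)


@dataclass
class EventLog:
    """Validated collection of behavioural events plus observation effort.

    ``records`` is a DataFrame with the columns of :data:`LOG_COLUMNS`;
    ``observation_seconds`` maps (individual, period) to the summed focal
    sample time, derived from the distinct focal samples present in the log.
    """

    records: pd.DataFrame
    individuals: tuple[str, ...]
    periods: tuple[str, ...]
    observation_seconds: dict[tuple[str, str], float] = field(default_factory=dict)

    def for_period(self, period_id: str) -> pd.DataFrame:
        if period_id not in self.periods:
            raise RecordError(f"unknown period {period_id!r}")
        return self.records[self.records["period_id"] == period_id]

    def grooming(self, period_id: str | None = None) -> pd.DataFrame:
        df = self.records if period_id is None else self.for_period(period_id)
        return df[df["event_type"] == "grooming"]

    @property
    def total_grooming_seconds(self) -> float:
        return float(self.grooming()["duration_s"].sum())


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    bad_type = ~df["event_type"].isin(EVENT_TYPES)
    if bad_type.any():
        row = int(df.index[bad_type][0])
        raise SchemaError(
            f"row {row}: unknown event_type {df.loc[row, 'event_type']!r}; "
            f"expected one of {sorted(EVENT_TYPES)}"
        )
    self_dir = df["actor_id"] == df["recipient_id"]
    if self_dir.any():
        row = int(df.index[self_dir][0])
        raise RecordError(f"row {row}: actor_id equals recipient_id ({df.loc[row, 'actor_id']!r})")
    if (df["duration_s"] < 0).any():
        row = int(df.index[df["duration_s"] < 0][0])
        raise RecordError(f"row {row}: negative duration")
    grooming = df["event_type"] == "grooming"
    if (grooming & (df["duration_s"] <= 0)).any():
        row = int(df.index[grooming & (df["duration_s"] <= 0)][0])
        raise RecordError(f"row {row}: grooming event with non-positive duration")
    if (df["start_s"] < 0).any():
        row = int(df.index[df["start_s"] < 0][0])
        raise RecordError(f"row {row}: negative start time")
    return df


def _deduplicate(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse double records of the same event; reject conflicting ones.

    A dyadic event seen during both members' focal samples appears twice with
    the same identity tuple.  Identical durations collapse to one record;
    different durations indicate an observation error and are rejected.
    """
    key = list(DEDUP_KEY)
    n_dur = df.groupby(key)["duration_s"].nunique()
    conflicts = n_dur[n_dur > 1]
    if len(conflicts):
        raise RecordError(
            f"conflicting durations for duplicated event(s): {list(conflicts.index[:3])}"
        )
    dups = df.duplicated(subset=key)
    if dups.any():
        logger.warning("collapsed %d duplicate event record(s)", int(dups.sum()))
        df = df[~dups]
    return df


def build_event_log(
    df: pd.DataFrame, sample_length_s: float = DEFAULT_SAMPLE_LENGTH_S
) -> EventLog:
    """Validate a raw record table and assemble an :class:`EventLog`."""
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    df = df.loc[:, list(LOG_COLUMNS)].copy()
    for col in ("sample_start_s", "start_s", "duration_s"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise SchemaError(f"row {row}: non-numeric value in {col!r}")
    for col in ("period_id", "focal_id", "actor_id", "recipient_id", "event_type"):
        df[col] = df[col].astype(str)
    df = _validate_records(df)
    df = _deduplicate(df)
    df = df.sort_values(["period_id", "start_s"], kind="stable").reset_index(drop=True)

    individuals = sorted(
        set(df["actor_id"]) | set(df["recipient_id"]) | set(df["focal_id"])
    )
    periods = tuple(sorted(df["period_id"].unique()))
    samples = df[["period_id", "focal_id", "sample_start_s"]].drop_duplicates()
    obs = {
        (str(focal), str(period)): float(n) * float(sample_length_s)
        for (period, focal), n in samples.groupby(["period_id", "focal_id"]).size().items()
    }
    return EventLog(
        records=df,
        individuals=tuple(individuals),
        periods=periods,
        observation_seconds=obs,
    )


def read_event_log(
    path: str | Path, schema_options: Mapping[str, object] | None = None
) -> EventLog:
    """Read and validate an event-log CSV.

    ``schema_options`` currently supports ``sample_length_s`` (default 900),
    used to convert distinct focal samples into observation time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opts = dict(schema_options or {})
    sample_length_s = float(opts.pop("sample_length_s", DEFAULT_SAMPLE_LENGTH_S))
    if opts:
        raise SchemaError(f"unknown schema option(s): {sorted(opts)}")
    df = pd.read_csv(path)
    return build_event_log(df, sample_length_s=sample_length_s)


def write_event_log(log: EventLog, path: str | Path) -> None:
    log.records.to_csv(path, index=False)


def _check_same_direction_overlap(episodes: Sequence[GroomingEpisode]) -> None:
    by_dir: dict[tuple[str, str], list[GroomingEpisode]] = {}
    for ep in episodes:
        by_dir.setdefault((ep.actor_id, ep.recipient_id), []).append(ep)
    for direction, eps in by_dir.items():
        eps = sorted(eps, key=lambda e: e.start)
        for prev, nxt in zip(eps, eps[1:]):
            if nxt.start < prev.end:
                raise RecordError(
                    f"overlapping grooming episodes in the same direction "
                    f"{direction[0]}->{direction[1]} at {nxt.start:.1f}s"
                )


def segment_bouts(log: EventLog, gap_s: float = 30.0) -> list[GroomingBout]:
    """Partition grooming episodes of each dyad into bouts.

    An episode joins the current bout iff its start is no more than ``gap_s``
    seconds after the end of the last grooming in the bout (in either
    direction); a gap of exactly ``gap_s`` therefore continues the bout.
    Simultaneous mutual grooming is legal (two directed episodes may
    overlap); two overlapping episodes in the *same* direction are rejected
    as an observation error.
    """
    if gap_s <= 0:
        raise ValueError("gap_s must be positive")
    bouts: list[GroomingBout] = []
    groom = log.grooming()
    if groom.empty:
        return bouts
    lo = groom[["actor_id", "recipient_id"]].min(axis=1)
    hi = groom[["actor_id", "recipient_id"]].max(axis=1)
    for (period_id, a, b), sub in groom.groupby(["period_id", lo, hi]):
        episodes = [
            GroomingEpisode(r.actor_id, r.recipient_id, float(r.start_s), float(r.duration_s))
            for r in sub.itertuples()
        ]
        episodes.sort(key=lambda e: (e.start, e.actor_id))
        _check_same_direction_overlap(episodes)
        current: list[GroomingEpisode] = []
        bout_end = -np.inf
        for ep in episodes:
            if current and ep.start > bout_end + gap_s:
                bouts.append(_finish_bout(str(period_id), (a, b), current))
                current = []
                bout_end = -np.inf
            current.append(ep)
            bout_end = max(bout_end, ep.end)
        if current:
            bouts.append(_finish_bout(str(period_id), (a, b), current))
    bouts.sort(key=lambda x: (x.period_id, x.start, x.pair))
    return bouts


def _finish_bout(
    period_id: str, pair: tuple[str, str], episodes: list[GroomingEpisode]
) -> GroomingBout:
    dur: dict[tuple[str, str], float] = {}
    for ep in episodes:
        key = (ep.actor_id, ep.recipient_id)
        dur[key] = dur.get(key, 0.0) + ep.duration
    return GroomingBout(
        period_id=period_id,
        pair=pair,
        episodes=episodes,
        groomer_id=episodes[0].actor_id,
        reciprocated=len(dur) == 2,
        duration_by_direction=dur,
    )


def bout_summary(bouts: Iterable[GroomingBout]) -> pd.DataFrame:
    """Per-dyad bout accounting: bout count, reciprocated count, seconds per direction.

    Direction columns are relative to the sorted dyad: ``dur_ab_s`` is the
    time the alphabetically first member groomed the second.
    """
    rows: dict[tuple[str, str, str], dict[str, float]] = {}
    for bout in bouts:
        a, b = bout.pair
        key = (bout.period_id, a, b)
        acc = rows.setdefault(
            key, {"bouts": 0, "reciprocated": 0, "dur_ab_s": 0.0, "dur_ba_s": 0.0}
        )
        acc["bouts"] += 1
        acc["reciprocated"] += int(bout.reciprocated)
        acc["dur_ab_s"] += bout.duration(a, b)
        acc["dur_ba_s"] += bout.duration(b, a)
    df = pd.DataFrame(
        [
            {"period_id": p, "dyad_a": a, "dyad_b": b, **acc}
            for (p, a, b), acc in sorted(rows.items())
        ],
        columns=["period_id", "dyad_a", "dyad_b", "bouts", "reciprocated", "dur_ab_s", "dur_ba_s"],
    )
    return df


def write_bout_table(bouts: Sequence[GroomingBout], path: str | Path) -> None:
    """Export one row per bout in the documented CSV dialect."""
    rows = []
    index: dict[tuple[str, str, str], int] = {}
    for bout in bouts:
        a, b = bout.pair
        key = (bout.period_id, a, b)
        index[key] = index.get(key, -1) + 1
        rows.append(
            {
                "period_id": bout.period_id,
                "dyad_a": a,
                "dyad_b": b,
                "bout_index": index[key],
                "groomer_id": bout.groomer_id,
                "reciprocated": bout.reciprocated,
                "dur_ab_s": bout.duration(a, b),
                "dur_ba_s": bout.duration(b, a),
                "start_s": bout.start,
                "end_s": bout.end,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
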