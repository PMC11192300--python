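"""Engagement logs: the raw evidence everything downstream is built from.

A log holds one record per platform event — an original post, a retweet
(verbatim reshare) or a quote tweet (reshare with added commentary).  Logs
are persisted as JSONL, one record per line, with ISO-8601 UTC timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

ENGAGEMENT_TYPES = ("post", "retweet", "quote")

#: Event types that constitute a reshare (an "infection" in the epidemic reading).
RESHARE_TYPES = ("retweet", "quote")


@dataclass(frozen=True)
class EngagementRecord:
    """A single engagement event.

    ``parent_post_id`` is ``None`` for original posts and references the
    reshared post otherwise.  ``originator_id`` is the author of the original
    post at the root of the reshare (equal to ``user_id`` for original posts).
    """

    post_id: str
    parent_post_id: str | None
    user_id: str
    originator_id: str
    type: str
    timestamp: datetime
    text: str

    def __post_init__(self) -> None:
        if self.type not in ENGAGEMENT_TYPES:
            raise ValueError(
                f"engagement type {self.type!r} not in {ENGAGEMENT_TYPES}"
            )
        if self.type in RESHARE_TYPES and self.parent_post_id is None:
            raise ValueError(f"{self.type} record {self.post_id} lacks a parent post id")

    @property
    def is_reshare(self) -> bool:
        return self.type in RESHARE_TYPES


@dataclass
class EngagementLog:
    """An ordered collection of engagement records with index helpers."""

    records: list[EngagementRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {r.post_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EngagementRecord]:
        return iter(self.records)

    def get(self, post_id: str) -> EngagementRecord | None:
        return self._by_id.get(post_id)

    @property
    def users(self) -> list[str]:
        """Sorted ids of every user appearing as poster or originator."""
        seen = {r.user_id for r in self.records} | {r.originator_id for r in self.records}
        return sorted(seen)

    def in_window(self, window: tuple[datetime, datetime]) -> "EngagementLog":
        """Records with ``start <= timestamp < end`` (half-open)."""
        start, end = window
        return EngagementLog([r for r in self.records if start <= r.timestamp < end])

    def authored_by(self, user: str, types: Iterable[str] = ("post",)) -> list[EngagementRecord]:
        wanted = set(types)
        return [r for r in self.records if r.user_id == user and r.type in wanted]

    # ------------------------------------------------------------------ io

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(
                    json.dumps(
                        {
                            "post_id": r.post_id,
                            "parent_post_id": r.parent_post_id,
                            "user_id": r.user_id,
                            "originator_id": r.originator_id,
                            "type": r.type,
                            "timestamp": r.timestamp.astimezone(timezone.utc).isoformat(),
                            "text": r.text,
                        }
                    )
                    + "\n"
                )

    @classmethod
    def read_jsonl(cls, path: str | Path) -> "EngagementLog":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                d = json.loads(line)
                records.append(
                    EngagementRecord(
                        post_id=d["post_id"],
                        parent_post_id=d.get("parent_post_id"),
                        user_id=d["user_id"],
                        originator_id=d["originator_id"],
                        type=d["type"],
                        timestamp=datetime.fromisoformat(d["timestamp"]),
                        text=d.get("text", ""),
                    )
                )
        return cls(records)


@dataclass(frozen=True)
class PeriodSpec:
    """Three labeled half-open time windows used to segment a log.

    Periods I–II feed network construction and model training; Period III is
    held out for evaluation.  Defaults cover Feb 1 – Jul 31 2021 (UTC), the
    segmentation used throughout the package's worked examples.
    """

    period_i: tuple[datetime, datetime]
    period_ii: tuple[datetime, datetime]
    period_iii: tuple[datetime, datetime]

    def __post_init__(self) -> None:
        windows = [self.period_i, self.period_ii, self.period_iii]
        for start, end in windows:
            if start >= end:
                raise ValueError(f"inverted window {start} .. {end}")
        for (_, e_prev), (s_next, _) in zip(windows, windows[1:]):
            if s_next < e_prev:
                raise ValueError("period windows overlap or are out of order")

    @classmethod
    def default(cls) -> "PeriodSpec":
        utc = timezone.utc
        return cls(
            period_i=(datetime(2021, 2, 1, tzinfo=utc), datetime(2021, 4, 1, tzinfo=utc)),
            period_ii=(datetime(2021, 4, 1, tzinfo=utc), datetime(2021, 4, 16, tzinfo=utc)),
            period_iii=(datetime(2021, 4, 16, tzinfo=utc), datetime(2021, 8, 1, tzinfo=utc)),
        )

    @property
    def training_window(self) -> tuple[datetime, datetime]:
        """Periods I–II pooled: the span used to build the network and models."""
        return (self.period_i[0], self.period_ii[1])

    @property
    def full_window(self) -> tuple[datetime, datetime]:
        return (self.period_i[0], self.period_iii[1])


def split_by_period(
    log: EngagementLog, periods: PeriodSpec
) -> tuple[EngagementLog, EngagementLog, EngagementLog, EngagementLog]:
    """Route records into Periods I, II, III by timestamp (half-open windows).

    Returns ``(log_i, log_ii, log_iii, spillover)``; records outside every
    window land in the spillover log with a logged warning.
    """
    buckets: tuple[list, list, list, list] = ([], [], [], [])
    windows = [periods.period_i, periods.period_ii, periods.period_iii]
    for r in log.records:
        for i, (start, end) in enumerate(windows):
            if start <= r.timestamp < end:
                buckets[i].append(r)
                break
        else:
            buckets[3].append(r)
    if buckets[3]:
        logger.warning("%d records fall outside all periods (spillover)", len(buckets[3]))
    logger.info(
        "period split: I=%d II=%d III=%d spillover=%d",
        len(buckets[0]), len(buckets[1]), len(buckets[2]), len(buckets[3]),
    )
    return tuple(EngagementLog(b) for b in buckets)  # type: ignore[return-value]
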