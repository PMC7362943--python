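"""Patient histories: D(u), day offsets, event merging, summary table.

D(u) = H(u) ∪ M(u), the "tweets about the disease".  Each D-tweet gets a
signed whole-day offset from the diagnosis anchor date (negative before
diagnosis, 0 on the diagnosis day, positive after), and tweets are merged
into health events: tweets sharing a manual ``event_key`` merge
unconditionally; otherwise two tweets merge when they share at least one
ontology term and their offsets differ by at most ``window_days`` (default
7), with single-linkage transitive closure.  Every remaining tweet is a
singleton event, so events partition D(u).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from phenotweet.annotate import SOURCE_HPO, CurationDecision, Match, TweetSet
from phenotweet.ingest import DiagnosisAnchor, Timeline

DEFAULT_MERGE_WINDOW_DAYS = 7


@dataclass(frozen=True)
class HealthEvent:
    """One dated statement about the patient's condition.

    ``offset_days`` equals the offset of the event's earliest supporting
    tweet; ``term_ids`` may be empty for events built from M-only tweets.
    """

    event_id: str
    offset_days: int
    summary: str
    tweet_ids: tuple[str, ...]
    term_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.tweet_ids:
            raise ValueError(f"event {self.event_id}: no supporting tweets")


@dataclass
class PatientHistory:
    user_id: str
    anchor: DiagnosisAnchor | None
    events: list[HealthEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(
            self.events, key=lambda e: (e.offset_days, min(e.tweet_ids))
        )

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class SummaryRow:
    """One user's row of the per-cohort summary table."""

    user_id: str
    n_tweets: int
    n_H: int
    n_M: int


def build_disease_set(
    H: TweetSet, M: TweetSet, timeline: Timeline | None = None
) -> TweetSet:
    """Form D(u) as the union of the curated H and M tweet sets.

    H and M must belong to the same user and be tweet-level disjoint
    (guaranteed by the H-over-M tie rule).  With a timeline, D's tweets
    follow chronological order; otherwise they are sorted by tweet id,
    which coincides with time order for ids assigned chronologically.
    """
    if H.user_id != M.user_id:
        raise ValueError(f"user mismatch: {H.user_id!r} vs {M.user_id!r}")
    overlap = set(H.tweet_ids) & set(M.tweet_ids)
    if overlap:
        raise ValueError(f"H and M overlap on tweets {sorted(overlap)}")
    ids = list(H.tweet_ids) + list(M.tweet_ids)
    if timeline is not None:
        order = {t.tweet_id: i for i, t in enumerate(timeline)}
        ids.sort(key=lambda i: (order.get(i, len(order)), i))
    else:
        ids.sort()
    return TweetSet(
        user_id=H.user_id,
        role="D",
        tweet_ids=ids,
        matches=list(H.matches) + list(M.matches),
    )


def compute_offset(tweet_date: datetime | date, anchor_date: date) -> int:
    """Signed whole-calendar-day offset of a tweet from the anchor date.

    Negative before diagnosis, 0 on the diagnosis date, positive after;
    datetimes are resolved to their UTC calendar date first.
    """
    if isinstance(tweet_date, datetime):
        tweet_date = tweet_date.astimezone(timezone.utc).date()
    return (tweet_date - anchor_date).days


class _UnionFind:
    def __init__(self, items: Sequence[str]) -> None:
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_events(
    D: TweetSet,
    anchor: DiagnosisAnchor,
    timeline: Timeline,
    window_days: int = DEFAULT_MERGE_WINDOW_DAYS,
    decisions: Sequence[CurationDecision] = (),
    term_labels: Mapping[str, str] | None = None,
) -> list[HealthEvent]:
    """Merge the D(u) tweets into health events.

    Tweets sharing a manual ``event_key`` (from curation decisions) merge
    unconditionally.  Otherwise two tweets merge iff they share at least
    one ontology term and their day offsets differ by at most
    ``window_days``; merging closes transitively (single linkage).  Every
    other tweet forms a singleton event, so Σ|event.tweet_ids| = |D(u)|.

    The event summary is the curation summary of the earliest supporting
    tweet when one exists, else the joined labels of the event's terms
    (via ``term_labels``), else the earliest matched surface.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    by_id = timeline.by_id()
    missing = [i for i in D.tweet_ids if i not in by_id]
    if missing:
        raise ValueError(f"D references tweets not in the timeline: {missing}")
    offsets = {
        i: compute_offset(by_id[i].created_at, anchor.anchor_date)
        for i in D.tweet_ids
    }
    match_by_id: dict[str, Match] = {m.match_id: m for m in D.matches}
    terms: dict[str, set[str]] = {i: set() for i in D.tweet_ids}
    surfaces: dict[str, list[tuple[tuple[int, int], str]]] = {
        i: [] for i in D.tweet_ids
    }
    for m in D.matches:
        if m.tweet_id not in terms:
            continue
        if m.source == SOURCE_HPO and m.term_id is not None:
            terms[m.tweet_id].add(m.term_id)
        surfaces[m.tweet_id].append((m.span, m.surface))

    uf = _UnionFind(list(D.tweet_ids))

    # Manual grouping keys override everything else.
    key_groups: dict[str, list[str]] = {}
    summaries: dict[str, str] = {}
    for d in decisions:
        m = match_by_id.get(d.match_id)
        if d.event_key is not None:
            if m is None:
                raise ValueError(
                    f"event_key {d.event_key!r} references match "
                    f"{d.match_id!r} outside D"
                )
            key_groups.setdefault(d.event_key, []).append(m.tweet_id)
        if d.summary and m is not None and m.tweet_id not in summaries:
            summaries[m.tweet_id] = d.summary
    for group in key_groups.values():
        for other in group[1:]:
            uf.union(group[0], other)

    # Same-term temporal single linkage.
    ids = list(D.tweet_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if terms[a] & terms[b] and abs(offsets[a] - offsets[b]) <= window_days:
                uf.union(a, b)

    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(uf.find(i), []).append(i)

    events: list[HealthEvent] = []
    ordered = sorted(
        clusters.values(),
        key=lambda members: min((offsets[i], i) for i in members),
    )
    for n, members in enumerate(ordered, 1):
        members = sorted(members, key=lambda i: (offsets[i], i))
        earliest = members[0]
        event_terms = tuple(sorted(set().union(*(terms[i] for i in members))))
        if earliest in summaries:
            summary = summaries[earliest]
        elif event_terms and term_labels:
            summary = "; ".join(
                term_labels.get(t, t) for t in event_terms
            )
        elif event_terms:
            summary = "; ".join(event_terms)
        else:
            first_surfaces = sorted(surfaces[earliest])
            summary = first_surfaces[0][1] if first_surfaces else ""
        events.append(
            HealthEvent(
                event_id=f"E{n:03d}",
                offset_days=offsets[earliest],
                summary=summary,
                tweet_ids=tuple(members),
                term_ids=event_terms,
            )
        )
    return events


def build_history(
    user_id: str, anchor: DiagnosisAnchor | None, events: Sequence[HealthEvent]
) -> PatientHistory:
    """Assemble a patient history, events sorted ascending by day offset.

    Ties on offset break by the lexicographically earliest tweet id.
    """
    return PatientHistory(user_id=user_id, anchor=anchor, events=list(events))


def summarize_users(
    users: Sequence[tuple[str, Timeline, TweetSet, TweetSet]],
) -> pd.DataFrame:
    """Build the per-user summary table plus its Total row.

    Each input tuple is (user_id, filtered timeline, H, M).  Columns:
    ``User``, ``#Tweets`` (original tweets after retweet/reply filtering),
    ``#H``, ``#M``.  The Total row equals the column sums, and by the
    H-over-M partition rule #H + #M = |D(u)| per user.
    """
    rows = []
    for user_id, timeline, h_set, m_set in users:
        rows.append(
            {
                "User": user_id,
                "#Tweets": len(timeline),
                "#H": len(h_set),
                "#M": len(m_set),
            }
        )
    total = {
        "User": "Total",
        "#Tweets": sum(r["#Tweets"] for r in rows),
        "#H": sum(r["#H"] for r in rows),
        "#M": sum(r["#M"] for r in rows),
    }
    return pd.DataFrame(rows + [total], columns=["User", "#Tweets", "#H", "#M"])


def write_summary(summary: pd.DataFrame, out: str | Path) -> None:
    summary.to_csv(out, sep="\t", index=False, lineterminator="\n")


def export_history(
    history: PatientHistory, out: str | Path, format: str = "json"
) -> None:
    """Serialize a patient history deterministically.

    JSON round-trips losslessly via :func:`read_history`; TSV writes one
    event per row with semicolon-joined tweet and term ids.
    """
    path = Path(out)
    if format == "json":
        payload = {
            "user_id": history.user_id,
            "anchor": None
            if history.anchor is None
            else {
                "user_id": history.anchor.user_id,
                "disease": history.anchor.disease,
                "anchor_date": history.anchor.anchor_date.isoformat(),
                "tweet_id": history.anchor.tweet_id,
                "pattern": history.anchor.pattern,
            },
            "events": [
                {
                    "event_id": e.event_id,
                    "offset_days": e.offset_days,
                    "summary": e.summary,
                    "tweet_ids": list(e.tweet_ids),
                    "term_ids": list(e.term_ids),
                }
                for e in history.events
            ],
        }
        path.write_text(
            json.dumps(payload, indent=2, ensure_ascii=False, sort_keys=True)
            + "\n",
            encoding="utf-8",
        )
    elif format == "tsv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["event_id", "offset_days", "summary", "tweet_ids", "term_ids"]
            )
            for e in history.events:
                writer.writerow(
                    [
                        e.event_id,
                        e.offset_days,
                        e.summary,
                        ";".join(e.tweet_ids),
                        ";".join(e.term_ids),
                    ]
                )
    else:
        raise ValueError(f"unknown format {format!r} (expected json or tsv)")


def read_history(file: str | Path) -> PatientHistory:
    """Load a JSON-serialized patient history."""
    payload = json.loads(Path(file).read_text(encoding="utf-8"))
    anchor = None
    if payload.get("anchor") is not None:
        a = payload["anchor"]
        anchor = DiagnosisAnchor(
            user_id=a["user_id"],
            disease=a["disease"],
            anchor_date=date.fromisoformat(a["anchor_date"]),
            tweet_id=a["tweet_id"],
            pattern=a["pattern"],
        )
    events = [
        HealthEvent(
            event_id=e["event_id"],
            offset_days=e["offset_days"],
            summary=e["summary"],
            tweet_ids=tuple(e["tweet_ids"]),
            term_ids=tuple(e["term_ids"]),
        )
        for e in payload["events"]
    ]
    return PatientHistory(
        user_id=payload["user_id"], anchor=anchor, events=events
    )
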