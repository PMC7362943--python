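"""Timeline ingestion, status filtering, diagnosis anchoring, cohort selection.

Timelines arrive as file dumps rather than live API responses: JSON-lines
in a Twitter API v1.1 field subset (``id_str``, ``created_at``,
``full_text``, ``retweeted_status``, ``in_reply_to_status_id``) or CSV with
header ``tweet_id,created_at,text,is_retweet,is_reply``.  All timestamps
are resolved to UTC before any date arithmetic.

The diagnosis anchor is the earliest original tweet that contains both a
diagnosis phrase (default ``"I was diagnosed"``) and the disease name or an
alias; its UTC calendar date is day 0 of the patient history.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

from phenotweet.lexicon import normalize_phrase

logger = logging.getLogger(__name__)

DEFAULT_DIAGNOSIS_PATTERNS = ("i was diagnosed",)

#: Twitter v1.1 created_at dialect, e.g. "Wed Mar 01 10:00:00 +0000 2018".
_TWITTER_TIME_FORMAT = "%a %b %d %H:%M:%S %z %Y"


class TimelineParseError(ValueError):
    """A record-level problem in a timeline dump, with its line number."""


def parse_created_at(value: str) -> datetime:
    """Parse a timestamp in the Twitter created_at dialect or ISO-8601.

    The result is always timezone-aware and converted to UTC; a naive
    ISO-8601 timestamp is taken to be UTC already.
    """
    value = value.strip()
    for attempt in (
        lambda v: datetime.strptime(v, _TWITTER_TIME_FORMAT),
        lambda v: datetime.fromisoformat(v.replace("Z", "+00:00")),
    ):
        try:
            dt = attempt(value)
        except ValueError:
            continue
        if dt.tzinfo is None:
            dt = dt.replace(tzinfo=timezone.utc)
        return dt.astimezone(timezone.utc)
    raise ValueError(f"unparseable timestamp: {value!r}")


@dataclass(frozen=True)
class Tweet:
    tweet_id: str
    created_at: datetime
    text: str
    is_retweet: bool = False
    is_reply: bool = False

    def __post_init__(self) -> None:
        if self.created_at.tzinfo is None:
            raise ValueError(f"tweet {self.tweet_id}: naive timestamp")

    @property
    def utc_date(self) -> date:
        return self.created_at.astimezone(timezone.utc).date()


@dataclass
class Timeline:
    """Ordered tweets of one pseudonymized user (e.g. ``"ALS1"``)."""

    user_id: str
    tweets: list[Tweet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.user_id:
            raise ValueError("user_id must be non-empty")
        self.tweets = sorted(
            self.tweets, key=lambda t: (t.created_at, t.tweet_id)
        )

    def __len__(self) -> int:
        return len(self.tweets)

    def __iter__(self):
        return iter(self.tweets)

    def by_id(self) -> dict[str, Tweet]:
        return {t.tweet_id: t for t in self.tweets}


@dataclass(frozen=True)
class DiagnosisAnchor:
    """The dated diagnosis-announcement tweet defining day 0."""

    user_id: str
    disease: str
    anchor_date: date
    tweet_id: str
    pattern: str


def _dedupe(user_id: str, tweets: Iterable[Tweet]) -> list[Tweet]:
    seen: dict[str, Tweet] = {}
    for t in tweets:
        if t.tweet_id in seen:
            logger.warning(
                "user %s: duplicate tweet_id %s collapsed to first occurrence",
                user_id,
                t.tweet_id,
            )
            continue
        seen[t.tweet_id] = t
    return list(seen.values())


def _tweet_from_jsonl(record: dict, lineno: int) -> Tweet:
    for key in ("id_str", "created_at"):
        if key not in record:
            raise TimelineParseError(f"line {lineno}: missing field {key!r}")
    text = record.get("full_text", record.get("text"))
    if text is None:
        raise TimelineParseError(f"line {lineno}: missing field 'full_text'")
    try:
        created = parse_created_at(record["created_at"])
    except ValueError as exc:
        raise TimelineParseError(f"line {lineno}: {exc}") from exc
    return Tweet(
        tweet_id=str(record["id_str"]),
        created_at=created,
        text=text,
        is_retweet="retweeted_status" in record
        and record["retweeted_status"] is not None,
        is_reply=record.get("in_reply_to_status_id") is not None,
    )


_CSV_COLUMNS = ["tweet_id", "created_at", "text", "is_retweet", "is_reply"]
_TRUE = {"true", "1", "yes"}


def _tweet_from_csv(row: dict, lineno: int) -> Tweet:
    for col in _CSV_COLUMNS:
        if row.get(col) is None:
            raise TimelineParseError(f"line {lineno}: missing column {col!r}")
    try:
        created = parse_created_at(row["created_at"])
    except ValueError as exc:
        raise TimelineParseError(f"line {lineno}: {exc}") from exc
    return Tweet(
        tweet_id=row["tweet_id"],
        created_at=created,
        text=row["text"],
        is_retweet=row["is_retweet"].strip().lower() in _TRUE,
        is_reply=row["is_reply"].strip().lower() in _TRUE,
    )


def read_timeline(
    file: str | Path, dialect: str = "jsonl", user_id: str | None = None
) -> Timeline:
    """Read one user's timeline dump.

    ``user_id`` defaults to the file's stem.  Tweets are returned sorted
    ascending by ``created_at``; duplicate tweet ids are collapsed to the
    first occurrence with a logged warning; an empty file yields an empty
    timeline with a warning.
    """
    path = Path(file)
    uid = user_id or path.stem
    tweets: list[Tweet] = []
    if dialect == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise TimelineParseError(
                        f"line {lineno}: invalid JSON: {exc}"
                    ) from exc
                tweets.append(_tweet_from_jsonl(record, lineno))
    elif dialect == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, 2):
                tweets.append(_tweet_from_csv(row, lineno))
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected jsonl or csv)")
    if not tweets:
        logger.warning("timeline file %s is empty", path)
    return Timeline(user_id=uid, tweets=_dedupe(uid, tweets))


def write_timeline(
    timeline: Timeline, file: str | Path, dialect: str = "jsonl"
) -> None:
    """Serialize a timeline in either dump dialect (lossless round trip)."""
    path = Path(file)
    if dialect == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for t in timeline:
                record: dict = {
                    "id_str": t.tweet_id,
                    "created_at": t.created_at.astimezone(timezone.utc).strftime(
                        _TWITTER_TIME_FORMAT
                    ),
                    "full_text": t.text,
                }
                if t.is_retweet:
                    record["retweeted_status"] = {}
                if t.is_reply:
                    record["in_reply_to_status_id"] = "0"
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")
    elif dialect == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for t in timeline:
                writer.writerow(
                    [
                        t.tweet_id,
                        t.created_at.astimezone(timezone.utc).isoformat(),
                        t.text,
                        str(t.is_retweet).lower(),
                        str(t.is_reply).lower(),
                    ]
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected jsonl or csv)")


def filter_statuses(timeline: Timeline) -> Timeline:
    """Drop retweets and replies, keeping original tweets in order.

    Idempotent: filtering a filtered timeline is a no-op.
    """
    kept = [t for t in timeline if not t.is_retweet and not t.is_reply]
    for t in timeline:
        if t.is_retweet or t.is_reply:
            logger.debug(
                "user %s: dropped %s (%s)",
                timeline.user_id,
                t.tweet_id,
                "retweet" if t.is_retweet else "reply",
            )
    return Timeline(user_id=timeline.user_id, tweets=kept)


def detect_diagnosis(
    timeline: Timeline,
    disease_names: Sequence[str],
    patterns: Sequence[str] = DEFAULT_DIAGNOSIS_PATTERNS,
) -> DiagnosisAnchor | None:
    """Locate the diagnosis-announcement tweet and build the day-0 anchor.

    A tweet qualifies when, after normalization, it contains a diagnosis
    pattern and any disease name or alias as contiguous token sequences.
    The EARLIEST qualifying original tweet wins; later candidates are
    logged.  Returns ``None`` when no tweet qualifies (an expected outcome,
    not an error).
    """
    if not disease_names:
        raise ValueError("disease_names must be non-empty")
    norm_patterns = [p for p in (normalize_phrase(x) for x in patterns) if p]
    norm_diseases = [d for d in (normalize_phrase(x) for x in disease_names) if d]
    candidates: list[tuple[Tweet, str]] = []
    for tweet in timeline:
        if tweet.is_retweet:
            continue
        body = f" {normalize_phrase(tweet.text)} "
        pattern_hit = next(
            (p for p in norm_patterns if f" {p} " in body), None
        )
        if pattern_hit is None:
            continue
        if any(f" {d} " in body for d in norm_diseases):
            candidates.append((tweet, pattern_hit))
    if not candidates:
        return None
    if len(candidates) > 1:
        logger.info(
            "user %s: %d diagnosis candidates (%s); keeping earliest",
            timeline.user_id,
            len(candidates),
            ", ".join(t.tweet_id for t, _ in candidates),
        )
    tweet, pattern = min(
        candidates, key=lambda c: (c[0].created_at, c[0].tweet_id)
    )
    return DiagnosisAnchor(
        user_id=timeline.user_id,
        disease=disease_names[0],
        anchor_date=tweet.utc_date,
        tweet_id=tweet.tweet_id,
        pattern=pattern,
    )


def select_users(
    timelines: Sequence[Timeline],
    anchors: Sequence[DiagnosisAnchor | None],
    min_original_tweets: int = 100,
    max_years_since_diagnosis: float = 5,
    reference_date: date | None = None,
) -> list[str]:
    """Apply the cohort-selection criteria and return kept user ids.

    A user is kept when they have a diagnosis anchor, strictly more than
    ``min_original_tweets`` tweets after retweet/reply filtering, and an
    anchor date within ``max_years_since_diagnosis`` (x 365.25 days) before
    ``reference_date``.  Users failing a criterion are excluded with a
    logged reason, never an error.
    """
    if reference_date is None:
        reference_date = datetime.now(timezone.utc).date()
    anchor_by_user = {a.user_id: a for a in anchors if a is not None}
    window_days = max_years_since_diagnosis * 365.25
    kept: list[str] = []
    for timeline in timelines:
        uid = timeline.user_id
        anchor = anchor_by_user.get(uid)
        if anchor is None:
            logger.info("user %s excluded: no diagnosis anchor", uid)
            continue
        n_original = len(filter_statuses(timeline))
        if n_original <= min_original_tweets:
            logger.info(
                "user %s excluded: %d original tweets (need > %d)",
                uid,
                n_original,
                min_original_tweets,
            )
            continue
        age_days = (reference_date - anchor.anchor_date).days
        if age_days < 0 or age_days > window_days:
            logger.info(
                "user %s excluded: diagnosed %s, outside %.1f-year window "
                "before %s",
                uid,
                anchor.anchor_date,
                max_years_since_diagnosis,
                reference_date,
            )
            continue
        kept.append(uid)
    return kept
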