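"""Ontology and watchlist matching plus the manual-curation round trip.

``match_ontology`` produces candidate matches for H(u) ("tweets by HPO"),
``match_watchlist`` for M(u) ("tweets by manual").  Both record
character-level spans so the original surface can always be audited, even
though the sets themselves are tweet-level.

Matching semantics: a lexicon key hits when its tokens occur as a
contiguous normalized token sequence in the tweet.  Overlapping matches
from different start positions are all reported; when several keys share a
start token only the longest is kept.  Raw substring matching (no token
boundaries) is available behind a flag for a literal reading of
"included ... terms in the text".

Curation: candidates are exported to a TSV that a human fills with
keep/remove decisions, reasons, optional privacy-preserving summaries and
manual event-grouping keys; ``apply_curation`` folds the decisions back
into the final H(u)/M(u) tweet sets.  Watchlist candidates are kept only
on an explicit keep decision under the default ``strict_M`` policy, since
most common-word hits are not health-related ("It's cold today").
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from phenotweet.ingest import Timeline, Tweet
from phenotweet.lexicon import OntologyLexicon, Watchlist, normalize_text

logger = logging.getLogger(__name__)

SOURCE_HPO = "HPO"
SOURCE_WATCHLIST = "WATCHLIST"

REMOVAL_REASONS = ("other_person", "not_health", "figurative", "duplicate", "other")


@dataclass(frozen=True)
class Match:
    """One surface-form hit in one tweet.

    ``span`` is a 0-based half-open character interval in the raw tweet
    text and ``surface == text[span[0]:span[1]]``.  ``term_id`` is present
    for every HPO-source match and absent for watchlist matches.
    """

    match_id: str
    tweet_id: str
    source: str
    term_id: str | None
    surface: str
    span: tuple[int, int]
    status: str = "candidate"
    removal_reason: str | None = None

    def __post_init__(self) -> None:
        if self.source == SOURCE_HPO and self.term_id is None:
            raise ValueError(f"match {self.match_id}: HPO match without term_id")
        if self.status == "removed" and not self.removal_reason:
            raise ValueError(f"match {self.match_id}: removed without a reason")


@dataclass
class TweetSet:
    """A user's H, M or D tweet set with its kept matches."""

    user_id: str
    role: str  # "H", "M" or "D"
    tweet_ids: list[str] = field(default_factory=list)
    matches: list[Match] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("H", "M", "D"):
            raise ValueError(f"unknown role {self.role!r}")
        if len(set(self.tweet_ids)) != len(self.tweet_ids):
            raise ValueError("duplicate tweet_ids in TweetSet")

    def __len__(self) -> int:
        return len(self.tweet_ids)


@dataclass(frozen=True)
class CurationDecision:
    """One manual keep/remove judgment for a candidate match."""

    match_id: str
    action: str  # "keep" or "remove"
    reason: str | None = None
    summary: str | None = None
    event_key: str | None = None

    def __post_init__(self) -> None:
        if self.action not in ("keep", "remove"):
            raise ValueError(f"decision {self.match_id}: bad action {self.action!r}")
        if self.action == "remove" and not self.reason:
            raise ValueError(f"decision {self.match_id}: remove without a reason")
        if self.summary and ("@" in self.summary or "http" in self.summary.lower()):
            raise ValueError(
                f"decision {self.match_id}: summary must not carry mentions/URLs"
            )


def _make_match_id(
    tweet_id: str, span: tuple[int, int], source: str, term_id: str | None
) -> str:
    return f"{tweet_id}:{span[0]}-{span[1]}:{source}:{term_id or '-'}"


def _scan_tokens(
    tweet: Tweet, keys: dict[tuple[str, ...], Iterable[str | None]], max_len: int
) -> list[Match]:
    """Longest-match-per-start scan of one tweet against tokenized keys."""
    tokens = normalize_text(tweet.text)
    words = [t.text for t in tokens]
    out: list[Match] = []
    for i in range(len(tokens)):
        hit: tuple[tuple[str, ...], int] | None = None
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            cand = tuple(words[i : i + length])
            if cand in keys:
                hit = (cand, length)
                break  # longest key starting here wins
        if hit is None:
            continue
        cand, length = hit
        span = (tokens[i].start, tokens[i + length - 1].end)
        surface = tweet.text[span[0] : span[1]]
        for term_id in keys[cand]:
            source = SOURCE_HPO if term_id is not None else SOURCE_WATCHLIST
            out.append(
                Match(
                    match_id=_make_match_id(tweet.tweet_id, span, source, term_id),
                    tweet_id=tweet.tweet_id,
                    source=source,
                    term_id=term_id,
                    surface=surface,
                    span=span,
                )
            )
    return out


def _scan_substring(
    tweet: Tweet, keys: dict[str, Iterable[str | None]]
) -> list[Match]:
    """Literal lowercase substring scan (no token boundaries)."""
    lowered = tweet.text.lower()
    out: list[Match] = []
    for key, term_ids in keys.items():
        start = 0
        while (pos := lowered.find(key, start)) != -1:
            span = (pos, pos + len(key))
            for term_id in term_ids:
                source = SOURCE_HPO if term_id is not None else SOURCE_WATCHLIST
                out.append(
                    Match(
                        match_id=_make_match_id(
                            tweet.tweet_id, span, source, term_id
                        ),
                        tweet_id=tweet.tweet_id,
                        source=source,
                        term_id=term_id,
                        surface=tweet.text[span[0] : span[1]],
                        span=span,
                    )
                )
            start = pos + 1
    return out


def _match(
    timeline: Timeline,
    key_terms: dict[str, Iterable[str | None]],
    substring: bool,
) -> list[Match]:
    matches: list[Match] = []
    if substring:
        for tweet in timeline:
            matches.extend(
                sorted(
                    _scan_substring(tweet, key_terms),
                    key=lambda m: (m.span, m.term_id or ""),
                )
            )
        return matches
    tokenized = {tuple(k.split(" ")): v for k, v in key_terms.items()}
    max_len = max((len(k) for k in tokenized), default=0)
    for tweet in timeline:  # timeline is chronologically sorted
        matches.extend(_scan_tokens(tweet, tokenized, max_len))
    return matches


def match_ontology(
    timeline: Timeline, lexicon: OntologyLexicon, substring: bool = False
) -> list[Match]:
    """Find every ontology-term occurrence in a filtered timeline.

    Returns candidate matches sorted by (tweet time, span start), one per
    (tweet, key occurrence, term id).  Multi-token keys require consecutive
    tokens; keys equal to the lexicon's excluded forms were never entered,
    so they can never match.
    """
    key_terms = {k: sorted(v) for k, v in lexicon.entries.items()}
    return _match(timeline, key_terms, substring)


def match_watchlist(
    timeline: Timeline, watchlist: Watchlist, substring: bool = False
) -> list[Match]:
    """Find watchlist-word occurrences; all are mandatory-review candidates."""
    key_terms: dict[str, Iterable[str | None]] = {
        w: [None] for w in sorted(watchlist.words)
    }
    return _match(timeline, key_terms, substring)


_CURATION_COLUMNS = [
    "match_id",
    "tweet_id",
    "date",
    "source",
    "term_id",
    "surface",
    "text",
    "action",
    "reason",
    "summary",
    "event_key",
]


def _flatten(text: str) -> str:
    return text.replace("\t", " ").replace("\r", " ").replace("\n", " ")


def export_curation(
    matches: Sequence[Match], timeline: Timeline, out: str | Path
) -> None:
    """Write candidate matches to the curation TSV for manual review.

    One row per match with the tweet date and full text for context and
    empty action/reason/summary/event_key columns; row order is
    deterministic, so re-export of identical input is byte-identical.
    """
    by_id = timeline.by_id()
    dangling = [m.tweet_id for m in matches if m.tweet_id not in by_id]
    if dangling:
        raise ValueError(f"matches reference unknown tweets: {sorted(set(dangling))}")
    rows = sorted(
        matches,
        key=lambda m: (
            by_id[m.tweet_id].created_at,
            m.tweet_id,
            m.span,
            m.source,
            m.term_id or "",
        ),
    )
    with Path(out).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CURATION_COLUMNS)
        for m in rows:
            tweet = by_id[m.tweet_id]
            writer.writerow(
                [
                    m.match_id,
                    m.tweet_id,
                    tweet.utc_date.isoformat(),
                    m.source,
                    m.term_id or "",
                    _flatten(m.surface),
                    _flatten(tweet.text),
                    "",
                    "",
                    "",
                    "",
                ]
            )


def read_curation(file: str | Path) -> list[CurationDecision]:
    """Read decisions back from a (possibly hand-edited) curation TSV.

    Rows with an empty ``action`` and no summary/event_key carry no
    decision and are skipped; a summary or event_key on a row without an
    explicit action implies ``keep``.
    """
    decisions: list[CurationDecision] = []
    with Path(file).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            action = (row.get("action") or "").strip().lower()
            summary = (row.get("summary") or "").strip() or None
            event_key = (row.get("event_key") or "").strip() or None
            if not action:
                if summary is None and event_key is None:
                    continue
                action = "keep"
            decisions.append(
                CurationDecision(
                    match_id=row["match_id"],
                    action=action,
                    reason=(row.get("reason") or "").strip() or None,
                    summary=summary,
                    event_key=event_key,
                )
            )
    return decisions


def apply_curation(
    matches: Sequence[Match],
    decisions: Sequence[CurationDecision] = (),
    policy: str = "strict_M",
    user_id: str = "user",
) -> tuple[TweetSet, TweetSet]:
    """Fold curation decisions into the final H(u) and M(u) tweet sets.

    HPO-source matches default to *kept* unless explicitly removed.
    Watchlist matches are kept only on an explicit keep decision under
    ``policy="strict_M"`` (the default, mirroring heavy manual pruning of
    common-word hits); ``policy="default"`` keeps them unless removed.

    H(u) = tweets with at least one kept HPO match; M(u) = tweets with at
    least one kept watchlist match and no kept HPO match, so the two sets
    partition D(u) with ties going to H.

    ``matches`` must be in timeline order (as the matchers produce them);
    tweet order inside each set follows first match occurrence.
    """
    if policy not in ("strict_M", "default"):
        raise ValueError(f"unknown policy {policy!r}")
    known = {m.match_id for m in matches}
    by_match: dict[str, CurationDecision] = {}
    for d in decisions:
        if d.match_id not in known:
            raise ValueError(f"decision references unknown match_id {d.match_id!r}")
        prior = by_match.get(d.match_id)
        if prior is not None and prior.action != d.action:
            raise ValueError(
                f"conflicting decisions for {d.match_id!r}: "
                f"{prior.action!r} vs {d.action!r}"
            )
        by_match[d.match_id] = d

    kept: list[Match] = []
    for m in matches:
        decision = by_match.get(m.match_id)
        if decision is not None and decision.action == "remove":
            logger.debug(
                "match %s removed: %s", m.match_id, decision.reason
            )
            kept_flag = False
        elif m.source == SOURCE_HPO:
            kept_flag = True
        else:  # watchlist
            kept_flag = (
                decision is not None and decision.action == "keep"
                if policy == "strict_M"
                else True
            )
        if kept_flag:
            kept.append(replace(m, status="kept"))

    h_ids: list[str] = []
    for m in kept:
        if m.source == SOURCE_HPO and m.tweet_id not in h_ids:
            h_ids.append(m.tweet_id)
    m_ids: list[str] = []
    for m in kept:
        if (
            m.source == SOURCE_WATCHLIST
            and m.tweet_id not in h_ids
            and m.tweet_id not in m_ids
        ):
            m_ids.append(m.tweet_id)

    h_set = TweetSet(
        user_id=user_id,
        role="H",
        tweet_ids=h_ids,
        matches=[m for m in kept if m.source == SOURCE_HPO],
    )
    m_set = TweetSet(
        user_id=user_id,
        role="M",
        tweet_ids=m_ids,
        matches=[
            m
            for m in kept
            if m.source == SOURCE_WATCHLIST and m.tweet_id in m_ids
        ],
    )
    return h_set, m_set
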