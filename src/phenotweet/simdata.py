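"""Synthetic tweet cohorts with planted ground truth.

Every pipeline stage needs test data that no live service can provide, so
this module generates per-user timelines that structurally mirror a real
diagnosed patient's feed: exactly one diagnosis-announcement tweet
("I was diagnosed with <disease> ...") anchoring day 0, symptom tweets
embedding ontology term labels at known day offsets, common-word false
positives ("It's cold today."), other-person health mentions paired with
pre-written remove decisions, retweets/replies, and non-health filler.

The generator writes what it knows to a truth file as it plants each
tweet, then *checks* that truth against the generated corpus by running
the actual matcher -- an infeasible or self-contradictory configuration
fails before anything is written.  Template texts carry deliberate casing
and punctuation variation to exercise normalization, but are chosen so
that no template accidentally contains another lexicon key or watchlist
word; that containment guarantee is what makes the planted sets exact.

Identical (config, seed) pairs reproduce byte-identical output files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta, timezone
from pathlib import Path
from typing import Sequence

from phenotweet.annotate import match_ontology, match_watchlist
from phenotweet.ingest import Timeline, Tweet, detect_diagnosis, filter_statuses, write_timeline
from phenotweet.lexicon import Watchlist, build_lexicon, save_watchlist

DEFAULT_MERGE_WINDOW_DAYS = 7


class SimDataError(ValueError):
    """Infeasible configuration or generation-time consistency failure."""


#: (term id, label, synonyms) for the bundled fixture ontology.  "All" is a
#: real HPO root label and is present precisely so the default exclusion
#: list has something to drop.
FIXTURE_TERMS: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("HP:0000001", "All", ()),
    ("HP:0012531", "Pain", ("ache",)),
    ("HP:0002094", "Dyspnea", ("shortness of breath",)),
    ("HP:0001337", "Tremor", ()),
    ("HP:0012378", "Fatigue", ()),
    ("HP:0002099", "Asthma", ()),
    ("HP:0000739", "Anxiety", ()),
    ("HP:0001324", "Muscle weakness", ()),
    ("HP:0002315", "Headache", ()),
    ("HP:0012735", "Cough", ()),
)

DEFAULT_WATCHLIST_WORDS = ("cold", "sick", "flu", "sore")

# Template banks.  Constraint: a symptom template may contain no watchlist
# word; a manual/FP/noise template no ontology label or synonym token; the
# diagnosis template neither.  Violations surface in the generation-time
# consistency check.
_SYMPTOM_TEMPLATES = (
    "The {term} won't stop today.",
    "{term} again today…",
    "Dealing with {term} since this morning.",
    "This {term} is wearing me out.",
    "Woke up with {term} AGAIN.",
)
_MANUAL_TEMPLATES = (
    "Caught a {word}, staying in bed today.",
    "This {word} has me resting at home.",
    "Down with a {word} since yesterday.",
)
_FP_TEMPLATES = {
    "cold": ("It's cold today.", "So cold outside right now."),
    "sick": ("That guitar solo was sick!", "Sick new skateboard at the park."),
    "flu": ("Flu shots available at the pharmacy downtown."),
    "sore": ("Sore loser much?", "Don't be a sore loser about the game."),
}
_OTHER_PERSON_TEMPLATES = (
    "My son's {term} is back again.",
    "Worried about my daughter's {term}.",
    "My mother has been dealing with {term} for weeks.",
)
_NOISE_TEMPLATES = (
    "Beautiful sunrise over the bay this morning.",
    "Finally finished that book, loved the ending.",
    "Traffic was terrible on the way to work.",
    "New coffee place opened downtown, great espresso.",
    "Watching the game tonight with friends.",
    "Weekend plans: hiking and photography.",
    "Can't believe how fast this year is going.",
    "All the leaves turned red, left the park right at sunset.",
)
_DIAGNOSIS_TEMPLATE = "I was diagnosed with {disease} today. Still processing."


@dataclass(frozen=True)
class SimConfig:
    """Generator knobs; the defaults are the study conditions.

    Ranges are inclusive ``(lo, hi)`` pairs; a fixed value is ``(v, v)``.
    ``n_symptom_tweets`` counts *singleton* symptom tweets, each with its
    own distinct term; ``merge_pairs`` adds pairs of same-term tweets
    whose offsets differ by at most the merge window, so the expected
    number of H tweets per user is ``n_symptom_tweets + 2 * merge_pairs``.
    """

    n_users: int = 4
    disease: str = "ALS"
    aliases: tuple[str, ...] = ("amyotrophic lateral sclerosis",)
    tweets_per_user: tuple[int, int] = (160, 260)
    fraction_retweets: float = 0.2
    fraction_replies: float = 0.1
    n_symptom_tweets: tuple[int, int] = (1, 5)
    merge_pairs: int = 1
    n_manual_tweets: tuple[int, int] = (0, 4)
    n_watchlist_fp: int = 3
    n_other_person: int = 1
    offset_range_days: tuple[int, int] = (-2200, 700)
    merge_window_days: int = DEFAULT_MERGE_WINDOW_DAYS
    reference_date: date = date(2020, 1, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tweets_per_user", "n_symptom_tweets", "n_manual_tweets"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise SimDataError(f"bad range for {name}: ({lo}, {hi})")
        if not 0 <= self.fraction_retweets + self.fraction_replies <= 1:
            raise SimDataError("retweet + reply fractions must lie in [0, 1]")
        if self.offset_range_days[0] > self.offset_range_days[1]:
            raise SimDataError("bad offset_range_days")
        if self.n_users < 1:
            raise SimDataError("n_users must be >= 1")


@dataclass
class SimCohort:
    """A generated cohort: file paths plus the in-memory planted truth."""

    config: SimConfig
    out_dir: Path
    ontology_path: Path
    watchlist_path: Path
    timeline_paths: dict[str, Path]
    decisions_path: Path
    truth_path: Path
    truth: dict
    timelines: dict[str, Timeline]


def make_fixture_ontology(
    terms: Sequence[tuple[str, str, Sequence[str]]], out: str | Path
) -> Path:
    """Write a minimal valid OBO file with one [Term] stanza per entry."""
    ids = [t[0] for t in terms]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SimDataError(f"duplicate term ids: {dupes}")
    lines = ["format-version: 1.2", "ontology: phenotweet-fixture", ""]
    for term_id, label, synonyms in terms:
        if ":" not in term_id:
            raise SimDataError(f"invalid term id {term_id!r}")
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        lines.append(f"name: {label}")
        for syn in synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        lines.append("")
    path = Path(out)
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


@dataclass
class _PlannedTweet:
    offset_days: int
    text: str
    role: str  # diagnosis | symptom | manual | fp | other_person | noise | retweet | reply
    term_id: str | None = None
    pair_key: str | None = None
    summary: str | None = None
    tweet_id: str = ""
    created_at: datetime | None = None


def _plan_user(
    uid: str, config: SimConfig, rng: random.Random, term_pool: list[tuple[str, str]]
) -> tuple[date, list[_PlannedTweet]]:
    total = rng.randint(*config.tweets_per_user)
    n_singles = rng.randint(*config.n_symptom_tweets)
    n_manual = rng.randint(*config.n_manual_tweets)
    n_rt = round(config.fraction_retweets * total)
    n_reply = round(config.fraction_replies * total)
    n_planted = (
        1  # diagnosis
        + n_singles
        + 2 * config.merge_pairs
        + n_manual
        + config.n_watchlist_fp
        + config.n_other_person
    )
    n_noise = total - n_planted - n_rt - n_reply
    if n_noise < 0:
        raise SimDataError(
            f"user {uid}: {n_planted} planted + {n_rt + n_reply} RT/reply "
            f"tweets exceed tweets_per_user={total}"
        )
    n_terms_needed = n_singles + config.merge_pairs
    if n_terms_needed > len(term_pool):
        raise SimDataError(
            f"user {uid}: needs {n_terms_needed} distinct symptom terms, "
            f"fixture ontology offers {len(term_pool)}"
        )

    # Anchor within the 5-year selection window before the reference date.
    anchor_age = rng.randint(200, 1700)
    anchor_date = config.reference_date - timedelta(days=anchor_age)

    lo, hi = config.offset_range_days
    terms = rng.sample(term_pool, n_terms_needed)
    used_offsets: set[int] = {0}

    def fresh_offset(margin: int = 0) -> int:
        # distinct offsets keep same-day coincidences out of the truth
        for _ in range(10_000):
            d = rng.randint(lo, hi - margin)
            if all(
                abs(d + k - u) > 0 for u in used_offsets for k in range(margin + 1)
            ):
                used_offsets.update(d + k for k in range(margin + 1))
                return d
        raise SimDataError(f"user {uid}: offset range too narrow for planting")

    planned: list[_PlannedTweet] = [
        _PlannedTweet(0, _DIAGNOSIS_TEMPLATE.format(disease=config.disease), "diagnosis")
    ]

    idx = 0
    for _ in range(n_singles):
        term_id, label = terms[idx]
        idx += 1
        text = rng.choice(_SYMPTOM_TEMPLATES).format(term=label.lower())
        planned.append(_PlannedTweet(fresh_offset(), text, "symptom", term_id))
    for p in range(config.merge_pairs):
        term_id, label = terms[idx]
        idx += 1
        gap = rng.randint(1, config.merge_window_days)
        start = fresh_offset(margin=gap)
        for k, d in enumerate((start, start + gap)):
            text = rng.choice(_SYMPTOM_TEMPLATES).format(term=label.lower())
            planned.append(
                _PlannedTweet(d, text, "symptom", term_id, pair_key=f"{uid}-pair{p}")
            )
    for _ in range(n_manual):
        word = rng.choice(DEFAULT_WATCHLIST_WORDS)
        text = rng.choice(_MANUAL_TEMPLATES).format(word=word)
        planned.append(
            _PlannedTweet(fresh_offset(), text, "manual", summary=f"had a {word}")
        )
    for _ in range(config.n_watchlist_fp):
        word = rng.choice(DEFAULT_WATCHLIST_WORDS)
        templates = _FP_TEMPLATES[word]
        if isinstance(templates, str):
            templates = (templates,)
        planned.append(_PlannedTweet(rng.randint(lo, hi), rng.choice(templates), "fp"))
    for _ in range(config.n_other_person):
        term_id, label = rng.choice(term_pool)
        text = rng.choice(_OTHER_PERSON_TEMPLATES).format(term=label.lower())
        planned.append(_PlannedTweet(rng.randint(lo, hi), text, "other_person", term_id))
    for _ in range(n_noise):
        planned.append(_PlannedTweet(rng.randint(lo, hi), rng.choice(_NOISE_TEMPLATES), "noise"))
    for _ in range(n_rt):
        text = "RT @someone: " + rng.choice(_NOISE_TEMPLATES + _SYMPTOM_TEMPLATES).format(
            term="pain"
        )
        planned.append(_PlannedTweet(rng.randint(lo, hi), text, "retweet"))
    for _ in range(n_reply):
        planned.append(
            _PlannedTweet(rng.randint(lo, hi), rng.choice(_NOISE_TEMPLATES), "reply")
        )

    # Materialize timestamps and chronologically sortable ids.
    for p in planned:
        p.created_at = datetime.combine(
            anchor_date + timedelta(days=p.offset_days),
            time(rng.randint(0, 23), rng.randint(0, 59), rng.randint(0, 59)),
            tzinfo=timezone.utc,
        )
    planned.sort(key=lambda p: p.created_at)
    for i, p in enumerate(planned):
        p.tweet_id = f"{uid}-{i:05d}"
    return anchor_date, planned


def _expected_events(
    uid: str, planned: list[_PlannedTweet], labels: dict[str, str]
) -> list[dict]:
    """Events implied by the plant, mirroring the merge rule by construction."""
    groups: dict[str, list[_PlannedTweet]] = {}
    for p in planned:
        if p.role == "symptom" and p.pair_key is not None:
            groups.setdefault(p.pair_key, []).append(p)
        elif p.role in ("symptom", "manual"):
            groups[p.tweet_id] = [p]
    events = []
    for members in groups.values():
        members = sorted(members, key=lambda p: (p.offset_days, p.tweet_id))
        term_ids = sorted({p.term_id for p in members if p.term_id})
        first = members[0]
        summary = first.summary or "; ".join(labels[t] for t in term_ids)
        events.append(
            {
                "offset_days": first.offset_days,
                "tweet_ids": [p.tweet_id for p in members],
                "term_ids": term_ids,
                "summary": summary,
            }
        )
    events.sort(key=lambda e: (e["offset_days"], e["tweet_ids"][0]))
    return events


def generate_cohort(config: SimConfig, out_dir: str | Path) -> SimCohort:
    """Generate a cohort of timelines with planted, verified ground truth.

    Writes per-user JSONL timelines, the fixture OBO ontology, the default
    watchlist, a pre-filled curation-decision TSV (remove decisions for
    other-person tweets, keep decisions with summaries for planted manual
    tweets), and a truth JSON.  Raises :class:`SimDataError` before
    writing anything when the configuration is infeasible, and after a
    full consistency check when the generated corpus contradicts the
    planted truth.
    """
    rng = random.Random(config.seed)
    out = Path(out_dir)
    term_pool = [
        (tid, label)
        for tid, label, _ in FIXTURE_TERMS
        if label.lower() not in ("all", "left", "right")
    ]

    plans: dict[str, tuple[date, list[_PlannedTweet]]] = {}
    for i in range(1, config.n_users + 1):
        uid = f"{config.disease}{i}"
        plans[uid] = _plan_user(uid, config, rng, term_pool)

    out.mkdir(parents=True, exist_ok=True)
    (out / "timelines").mkdir(exist_ok=True)
    ontology_path = make_fixture_ontology(FIXTURE_TERMS, out / "ontology.obo")
    watchlist_path = out / "watchlist.txt"
    save_watchlist(Watchlist(frozenset(DEFAULT_WATCHLIST_WORDS)), watchlist_path)
    lexicon = build_lexicon(ontology_path)
    watchlist = Watchlist(frozenset(DEFAULT_WATCHLIST_WORDS))

    timelines: dict[str, Timeline] = {}
    timeline_paths: dict[str, Path] = {}
    truth_users: dict[str, dict] = {}
    decision_rows: list[dict] = []

    for uid, (anchor_date, planned) in plans.items():
        tweets = [
            Tweet(
                tweet_id=p.tweet_id,
                created_at=p.created_at,
                text=p.text,
                is_retweet=p.role == "retweet",
                is_reply=p.role == "reply",
            )
            for p in planned
        ]
        timeline = Timeline(user_id=uid, tweets=tweets)
        timelines[uid] = timeline
        path = out / "timelines" / f"{uid}.jsonl"
        write_timeline(timeline, path, dialect="jsonl")
        timeline_paths[uid] = path

        filtered = filter_statuses(timeline)
        anchor = detect_diagnosis(
            filtered, [config.disease, *config.aliases]
        )
        diag = next(p for p in planned if p.role == "diagnosis")
        if anchor is None or anchor.tweet_id != diag.tweet_id:
            raise SimDataError(f"user {uid}: planted diagnosis tweet not recovered")
        if anchor.anchor_date != anchor_date:
            raise SimDataError(f"user {uid}: anchor date mismatch")

        h_truth = {
            p.tweet_id: [p.term_id] for p in planned if p.role == "symptom"
        }
        m_truth = [p.tweet_id for p in planned if p.role == "manual"]
        removed = {
            p.tweet_id: "other_person" for p in planned if p.role == "other_person"
        }

        # Consistency: the matcher over the generated text must find
        # exactly the planted mentions, nothing more, nothing less.
        hpo_matches = match_ontology(filtered, lexicon)
        hpo_tweets = {m.tweet_id for m in hpo_matches}
        if hpo_tweets != set(h_truth) | set(removed):
            raise SimDataError(
                f"user {uid}: ontology matches {sorted(hpo_tweets)} disagree "
                f"with planted H + other-person tweets"
            )
        wl_matches = match_watchlist(filtered, watchlist)
        wl_tweets = {m.tweet_id for m in wl_matches}
        fp_tweets = {p.tweet_id for p in planned if p.role == "fp"}
        if wl_tweets != set(m_truth) | fp_tweets:
            raise SimDataError(
                f"user {uid}: watchlist matches disagree with planted M + FP tweets"
            )

        summaries = {p.tweet_id: p.summary for p in planned if p.summary}
        for m in hpo_matches + wl_matches:
            if m.tweet_id in removed:
                decision_rows.append(
                    {"match": m, "action": "remove", "reason": "other_person"}
                )
            elif m.source == "WATCHLIST" and m.tweet_id in set(m_truth):
                decision_rows.append(
                    {
                        "match": m,
                        "action": "keep",
                        "reason": "",
                        "summary": summaries.get(m.tweet_id, ""),
                    }
                )

        n_original = len(filtered)
        truth_users[uid] = {
            "anchor_date": anchor_date.isoformat(),
            "anchor_tweet_id": diag.tweet_id,
            "H": h_truth,
            "M": m_truth,
            "removed": removed,
            "offsets": {
                p.tweet_id: p.offset_days
                for p in planned
                if p.role in ("symptom", "manual")
            },
            "events": _expected_events(uid, planned, lexicon.labels),
            "summary_row": {
                "n_tweets": n_original,
                "n_H": len(h_truth),
                "n_M": len(m_truth),
            },
        }

    decisions_path = out / "decisions.tsv"
    _write_decisions(decision_rows, timelines, decisions_path)

    truth = {
        "disease": config.disease,
        "reference_date": config.reference_date.isoformat(),
        "users": truth_users,
        "total": {
            "n_tweets": sum(u["summary_row"]["n_tweets"] for u in truth_users.values()),
            "n_H": sum(u["summary_row"]["n_H"] for u in truth_users.values()),
            "n_M": sum(u["summary_row"]["n_M"] for u in truth_users.values()),
        },
    }
    truth_path = out / "truth.json"
    truth_path.write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    return SimCohort(
        config=config,
        out_dir=out,
        ontology_path=ontology_path,
        watchlist_path=watchlist_path,
        timeline_paths=timeline_paths,
        decisions_path=decisions_path,
        truth_path=truth_path,
        truth=truth,
        timelines=timelines,
    )


def _write_decisions(
    decision_rows: list[dict], timelines: dict[str, Timeline], out: Path
) -> None:
    """Write the combined curation TSV with pre-filled decision columns."""
    import csv

    with out.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
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
        )
        by_tweet = {}
        for timeline in timelines.values():
            by_tweet.update(timeline.by_id())
        rows = sorted(decision_rows, key=lambda r: r["match"].match_id)
        for row in rows:
            m = row["match"]
            tweet = by_tweet[m.tweet_id]
            writer.writerow(
                [
                    m.match_id,
                    m.tweet_id,
                    tweet.utc_date.isoformat(),
                    m.source,
                    m.term_id or "",
                    m.surface,
                    tweet.text.replace("\t", " ").replace("\n", " "),
                    row["action"],
                    row.get("reason", ""),
                    row.get("summary", ""),
                    "",
                ]
            )
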