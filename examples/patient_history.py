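"""Build a patient history: D(u), event merging, signed day offsets.

Replicates the structure of a five-tweet disease set: two ontology
tweets sharing one term a few days apart (they merge into a single
event) plus three manually kept watchlist tweets, giving four events.
"""

import tempfile
from datetime import datetime, timedelta, timezone
from pathlib import Path

from phenotweet import (
    CurationDecision,
    Watchlist,
    apply_curation,
    build_disease_set,
    build_history,
    build_lexicon,
    detect_diagnosis,
    match_ontology,
    match_watchlist,
    merge_events,
)
from phenotweet.ingest import Timeline, Tweet
from phenotweet.simdata import FIXTURE_TERMS, make_fixture_ontology

base = datetime(2018, 3, 1, 10, 0, tzinfo=timezone.utc)


def t(tid, days, text):
    return Tweet(tid, base + timedelta(days=days), text)


timeline = Timeline(
    "ALS1",
    [
        t("t0", 0, "I was diagnosed with ALS today."),
        t("t1", 270, "pain in my hands"),
        t("t2", 273, "the pain again, worse"),
        t("t3", 400, "caught a cold, in bed"),
        t("t4", 520, "feeling sick all day"),
        t("t5", 644, "got the flu, resting"),
    ],
)

with tempfile.TemporaryDirectory() as tmp:
    obo = make_fixture_ontology(FIXTURE_TERMS, Path(tmp) / "f.obo")
    lexicon = build_lexicon(obo)

anchor = detect_diagnosis(timeline, ["ALS"])
matches = match_ontology(timeline, lexicon) + match_watchlist(
    timeline, Watchlist(frozenset({"cold", "sick", "flu"}))
)
decisions = [
    CurationDecision(m.match_id, "keep", summary=f"had {m.surface}")
    for m in matches
    if m.term_id is None
]
H, M = apply_curation(matches, decisions, user_id="ALS1")
D = build_disease_set(H, M, timeline)
events = merge_events(D, anchor, timeline, window_days=7,
                      decisions=decisions, term_labels=lexicon.labels)
history = build_history("ALS1", anchor, events)

print(f"|H|={len(H)} |M|={len(M)} |D|={len(D)} -> {len(history)} events")
for e in history.events:
    print(f"  day {e.offset_days:+5d}: {e.summary:12} ({len(e.tweet_ids)} tweet(s))")

# t1 and t2 share the "pain" term three days apart, so they merge into
# one event at the earlier offset (+270); five D-tweets become four
# dated events relative to the diagnosis date.
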