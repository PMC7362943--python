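"""Extract H(u) and M(u) candidates and run the curation round trip.

Ontology matches (H candidates) are kept by default unless a curator
removes them; watchlist matches (M candidates) are kept only on an
explicit keep decision, because most common-word hits ("It's cold
today.") are not about the user's health.
"""

import tempfile
from pathlib import Path

from phenotweet import (
    CurationDecision,
    Watchlist,
    apply_curation,
    build_lexicon,
    export_curation,
    match_ontology,
    match_watchlist,
)
from phenotweet.ingest import Timeline, Tweet
from phenotweet.simdata import FIXTURE_TERMS, make_fixture_ontology
from datetime import datetime, timedelta, timezone

base = datetime(2018, 3, 1, tzinfo=timezone.utc)
timeline = Timeline(
    "ALS1",
    [
        Tweet("t1", base, "the pain won't stop"),
        Tweet("t2", base + timedelta(days=1), "It's cold today."),
        Tweet("t3", base + timedelta(days=2), "my son's tremor is back"),
        Tweet("t4", base + timedelta(days=3), "caught a cold, staying in bed"),
    ],
)

with tempfile.TemporaryDirectory() as tmp:
    obo = make_fixture_ontology(FIXTURE_TERMS, Path(tmp) / "f.obo")
    lexicon = build_lexicon(obo)
    matches = match_ontology(timeline, lexicon) + match_watchlist(
        timeline, Watchlist(frozenset({"cold"}))
    )
    export_curation(matches, timeline, Path(tmp) / "curation.tsv")
    print(f"{len(matches)} candidates exported for review:")
    for m in matches:
        print(f"  {m.match_id}  {m.source:9}  {m.surface!r}")

decisions = [
    CurationDecision(  # tweet about the user's son, not the user
        next(m.match_id for m in matches if m.tweet_id == "t3"),
        "remove",
        reason="other_person",
    ),
    CurationDecision(  # genuine health mention via a common word
        next(m.match_id for m in matches if m.tweet_id == "t4"),
        "keep",
        summary="had a cold",
    ),
]
H, M = apply_curation(matches, decisions, user_id="ALS1")
print(f"H(u) = {H.tweet_ids}  (ontology matches, other-person tweet removed)")
print(f"M(u) = {M.tweet_ids}  (only the explicitly kept watchlist tweet)")
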