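from __future__ import annotations

import random
import string
from datetime import datetime, timedelta, timezone

import pytest

from phenotweet.ingest import Timeline, Tweet
from phenotweet.lexicon import build_lexicon
from phenotweet.simdata import FIXTURE_TERMS, make_fixture_ontology

BASE_TIME = datetime(2018, 3, 1, 10, 0, 0, tzinfo=timezone.utc)


def mk_tweet(i, text, days=0, hours=0, rt=False, reply=False):
    return Tweet(
        tweet_id=f"t{i:04d}",
        created_at=BASE_TIME + timedelta(days=days, hours=hours),
        text=text,
        is_retweet=rt,
        is_reply=reply,
    )


def mk_timeline(texts_or_tweets, user_id="u1"):
    tweets = [
        t if isinstance(t, Tweet) else mk_tweet(i, t)
        for i, t in enumerate(texts_or_tweets)
    ]
    return Timeline(user_id=user_id, tweets=tweets)


@pytest.fixture(scope="session")
def fixture_obo(tmp_path_factory):
    path = tmp_path_factory.mktemp("onto") / "fixture.obo"
    return make_fixture_ontology(FIXTURE_TERMS, path)


@pytest.fixture(scope="session")
def lexicon(fixture_obo):
    return build_lexicon(fixture_obo)


_WORDS = (
    ["pain", "ache", "cold", "fever", "tremor", "muscle", "weakness", "breath"]
    + ["painting", "colder", "scold", "the", "a", "today", "again", "x1", "n2"]
    + ["".join(random.Random(7).choices(string.ascii_lowercase, k=k)) for k in (3, 4, 5, 6, 7)]
)
_SEPS = [" ", "  ", ". ", ", ", "! ", "—", " - ", ": ", "' ", " '", "\n"]


def random_text(rng: random.Random, n_words: int) -> str:
    parts = []
    for i in range(n_words):
        word = rng.choice(_WORDS)
        if rng.random() < 0.3:
            word = word.upper() if rng.random() < 0.5 else word.capitalize()
        parts.append(word)
        if i < n_words - 1:
            parts.append(rng.choice(_SEPS))
    return "".join(parts)


def random_corpus(rng: random.Random, n_tweets: int, n_keys: int):
    """A random timeline plus a random {key: [term_ids]} lexicon mapping."""
    timeline = mk_timeline(
        [
            mk_tweet(i, random_text(rng, rng.randint(1, 12)), days=i // 10, hours=i % 10)
            for i in range(n_tweets)
        ]
    )
    keys = {}
    while len(keys) < n_keys:
        phrase = " ".join(rng.sample(_WORDS, rng.randint(1, 3)))
        keys.setdefault(phrase, []).append(f"HP:{rng.randint(0, 99):07d}")
    return timeline, {k: sorted(set(v)) for k, v in keys.items()}
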