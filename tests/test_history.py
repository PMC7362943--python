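"""D(u) construction, day offsets, event merging, summaries, export."""

from __future__ import annotations

import itertools
import random
from datetime import date, datetime, timedelta, timezone

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import BASE_TIME, mk_timeline, mk_tweet
from phenotweet.annotate import (
    CurationDecision,
    Watchlist,
    apply_curation,
    match_ontology,
    match_watchlist,
)
from phenotweet.history import (
    HealthEvent,
    build_disease_set,
    build_history,
    compute_offset,
    export_history,
    merge_events,
    read_history,
    summarize_users,
)
from phenotweet.ingest import DiagnosisAnchor


def _anchor(anchor_date=None, user_id="u1"):
    return DiagnosisAnchor(
        user_id=user_id,
        disease="ALS",
        anchor_date=anchor_date or BASE_TIME.date(),
        tweet_id="t0000",
        pattern="i was diagnosed",
    )


def _curate(tl, lexicon, watch_words=(), keep_watch=True, decisions=()):
    matches = match_ontology(tl, lexicon) + match_watchlist(
        tl, Watchlist(frozenset(watch_words))
    )
    ds = list(decisions)
    if keep_watch:
        ds += [
            CurationDecision(m.match_id, "keep")
            for m in matches
            if m.term_id is None
        ]
    return matches, apply_curation(matches, ds, user_id=tl.user_id)


class TestBuildDiseaseSet:
    def test_union_2_plus_3(self, lexicon):
        tl = mk_timeline(
            [
                mk_tweet(0, "pain today", days=1),
                mk_tweet(1, "pain again", days=3),
                mk_tweet(2, "caught a cold", days=5),
                mk_tweet(3, "still sick", days=6),
                mk_tweet(4, "got the flu", days=8),
            ]
        )
        _, (h, m) = _curate(tl, lexicon, watch_words=("cold", "sick", "flu"))
        assert (len(h), len(m)) == (2, 3)
        d = build_disease_set(h, m, tl)
        assert len(d) == 5
        assert d.tweet_ids == [f"t{i:04d}" for i in range(5)]  # chronological

    def test_empty_union(self):
        from phenotweet.annotate import TweetSet

        d = build_disease_set(TweetSet("u1", "H"), TweetSet("u1", "M"))
        assert len(d) == 0

    def test_union_3_plus_1(self, lexicon):
        tl = mk_timeline(
            [
                mk_tweet(0, "asthma attack", days=-2102),
                mk_tweet(1, "anxiety is bad", days=-375),
                mk_tweet(2, "tremor in my hand", days=-100),
                mk_tweet(3, "feeling sick", days=10),
            ]
        )
        _, (h, m) = _curate(tl, lexicon, watch_words=("sick",))
        assert (len(h), len(m)) == (3, 1)
        assert len(build_disease_set(h, m, tl)) == 4

    def test_user_mismatch_errors(self):
        from phenotweet.annotate import TweetSet

        with pytest.raises(ValueError, match="user mismatch"):
            build_disease_set(TweetSet("u1", "H"), TweetSet("u2", "M"))

    def test_overlap_errors(self):
        from phenotweet.annotate import TweetSet

        with pytest.raises(ValueError, match="overlap"):
            build_disease_set(
                TweetSet("u1", "H", ["a"]), TweetSet("u1", "M", ["a"])
            )


class TestComputeOffset:
    def test_anchor_day_zero(self):
        assert compute_offset(BASE_TIME, BASE_TIME.date()) == 0

    def test_before_diagnosis_negative(self):
        d = BASE_TIME.date()
        assert compute_offset(d - timedelta(days=2102), d) == -2102

    def test_after_diagnosis_positive(self):
        d = BASE_TIME.date()
        assert compute_offset(d + timedelta(days=270), d) == 270

    def test_utc_date_used_for_datetimes(self):
        # 23:30 UTC-5 is already the next UTC day
        local = datetime(2018, 3, 1, 23, 30, tzinfo=timezone(timedelta(hours=-5)))
        assert compute_offset(local, date(2018, 3, 1)) == 1

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(a=st.dates(date(1990, 1, 1), date(2030, 1, 1)), b=st.dates(date(1990, 1, 1), date(2030, 1, 1)))
    def test_antisymmetry(self, a, b):
        assert compute_offset(a, b) == -compute_offset(b, a)


def _merge_scene(lexicon, texts_days, watch_words=(), decisions=()):
    tl = mk_timeline([mk_tweet(i, text, days=d) for i, (text, d) in enumerate(texts_days)])
    matches, (h, m) = _curate(tl, lexicon, watch_words=watch_words, decisions=decisions)
    d_set = build_disease_set(h, m, tl)
    return tl, d_set


class TestMergeEvents:
    def test_pair_within_window_gives_four_events(self, lexicon):
        tl, d = _merge_scene(
            lexicon,
            [
                ("pain is awful", 10),
                ("pain again", 13),  # same term, 3 days later -> merges
                ("caught a cold", 30),
                ("feeling sick", 60),
                ("got the flu", 90),
            ],
            watch_words=("cold", "sick", "flu"),
        )
        events = merge_events(d, _anchor(), tl)
        assert len(d) == 5 and len(events) == 4
        merged = next(e for e in events if len(e.tweet_ids) == 2)
        assert merged.term_ids == ("HP:0012531",)
        assert merged.offset_days == 10

    def test_distinct_terms_never_merge(self, lexicon):
        tl, d = _merge_scene(
            lexicon, [("pain", 1), ("tremor", 2), ("cough", 3), ("anxiety", 4)]
        )
        events = merge_events(d, _anchor(), tl)
        assert len(events) == 4

    def test_transitive_chain_single_event(self, lexicon):
        # A-B 5 days, B-C 5 days, A-C 10 days: single linkage joins all three
        tl, d = _merge_scene(lexicon, [("pain a", 0), ("pain b", 5), ("pain c", 10)])
        events = merge_events(d, _anchor(), tl, window_days=7)
        assert len(events) == 1
        assert events[0].tweet_ids == ("t0000", "t0001", "t0002")
        # exhaustive pairwise union-find oracle over all pairs
        offsets = {"t0000": 0, "t0001": 5, "t0002": 10}
        parent = {k: k for k in offsets}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in itertools.combinations(offsets, 2):
            if abs(offsets[a] - offsets[b]) <= 7:
                parent[find(b)] = find(a)
        assert len({find(k) for k in offsets}) == len(events)

    def test_window_zero_distinct_days_all_singletons(self, lexicon):
        tl, d = _merge_scene(lexicon, [("pain a", 0), ("pain b", 5), ("tremor", 9)])
        events = merge_events(d, _anchor(), tl, window_days=0)
        assert len(events) == len(d)

    def test_event_key_merges_unconditionally(self, lexicon):
        tl = mk_timeline(
            [mk_tweet(0, "pain early", days=0), mk_tweet(1, "tremor late", days=500)]
        )
        matches = match_ontology(tl, lexicon)
        keys = [
            CurationDecision(m.match_id, "keep", event_key="ev1") for m in matches
        ]
        _, (h, m) = _curate(tl, lexicon, decisions=keys)
        d = build_disease_set(h, m, tl)
        events = merge_events(d, _anchor(), tl, decisions=keys)
        assert len(events) == 1 and len(events[0].tweet_ids) == 2

    def test_event_key_outside_d_errors(self, lexicon):
        tl, d = _merge_scene(lexicon, [("pain", 0)])
        bad = CurationDecision("t9999:0-4:HPO:HP:0012531", "keep", event_key="x")
        with pytest.raises(ValueError, match="outside D"):
            merge_events(d, _anchor(), tl, decisions=[bad])

    def test_summary_precedence(self, lexicon):
        tl = mk_timeline([mk_tweet(0, "pain again", days=3)])
        matches = match_ontology(tl, lexicon)
        with_summary = [
            CurationDecision(matches[0].match_id, "keep", summary="hand hurts")
        ]
        _, (h, m) = _curate(tl, lexicon)
        d = build_disease_set(h, m, tl)
        ev = merge_events(d, _anchor(), tl, decisions=with_summary, term_labels=lexicon.labels)
        assert ev[0].summary == "hand hurts"
        ev_fallback = merge_events(d, _anchor(), tl, term_labels=lexicon.labels)
        assert ev_fallback[0].summary == "Pain"

    def test_conservation(self, lexicon):
        rng = random.Random(3)
        terms = ["pain", "tremor", "cough", "anxiety", "fatigue"]
        texts = [(f"{rng.choice(terms)} now", rng.randint(-300, 300)) for _ in range(25)]
        tl, d = _merge_scene(lexicon, texts)
        events = merge_events(d, _anchor(), tl)
        supported = [tid for e in events for tid in e.tweet_ids]
        assert sorted(supported) == sorted(d.tweet_ids)

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_in_window(self, lexicon, seed):
        rng = random.Random(seed)
        terms = ["pain", "tremor", "cough"]
        texts = [(f"{rng.choice(terms)} now", rng.randint(-60, 60)) for _ in range(15)]
        tl, d = _merge_scene(lexicon, texts)
        counts = [
            len(merge_events(d, _anchor(), tl, window_days=w)) for w in (0, 3, 7, 30, 365)
        ]
        assert counts == sorted(counts, reverse=True)


class TestBuildHistory:
    def test_sorted_positive_offsets(self):
        events = [
            HealthEvent("E1", 644, "cannot walk", ("b",)),
            HealthEvent("E2", 270, "can walk", ("a",)),
        ]
        h = build_history("u1", _anchor(), events)
        assert [e.offset_days for e in h.events] == [270, 644]

    def test_sorted_negative_offsets(self):
        events = [
            HealthEvent("E1", -375, "anxiety drug", ("b",)),
            HealthEvent("E2", -2102, "asthma attack", ("a",)),
        ]
        h = build_history("u1", _anchor(), events)
        assert [e.offset_days for e in h.events] == [-2102, -375]

    def test_empty_history_valid(self):
        assert len(build_history("u1", _anchor(), [])) == 0

    def test_offset_tie_breaks_on_tweet_id(self):
        events = [
            HealthEvent("E1", 5, "x", ("t0009",)),
            HealthEvent("E2", 5, "y", ("t0001",)),
        ]
        h = build_history("u1", _anchor(), events)
        assert [e.tweet_ids[0] for e in h.events] == [("t0001"), ("t0009")]


class TestSummarizeUsers:
    def test_zero_user(self):
        from phenotweet.annotate import TweetSet

        tl = mk_timeline(["a", "b"])
        df = summarize_users([("u1", tl, TweetSet("u1", "H"), TweetSet("u1", "M"))])
        assert df.iloc[0].tolist() == ["u1", 2, 0, 0]
        assert df.iloc[-1].tolist() == ["Total", 2, 0, 0]

    def test_total_is_column_sum(self, lexicon):
        rows = []
        rng = random.Random(11)
        for uid in ("u1", "u2", "u3"):
            texts = ["pain day"] * rng.randint(1, 4) + ["caught a cold"] * rng.randint(0, 3) + ["noise"] * 5
            tl = mk_timeline(
                [mk_tweet(i, t, days=i) for i, t in enumerate(texts)], user_id=uid
            )
            _, (h, m) = _curate(tl, lexicon, watch_words=("cold",))
            rows.append((uid, tl, h, m))
        df = summarize_users(rows)
        body, total = df.iloc[:-1], df.iloc[-1]
        for col in ("#Tweets", "#H", "#M"):
            assert total[col] == body[col].sum()

    def test_h_plus_m_equals_d(self, lexicon):
        tl = mk_timeline(
            [
                mk_tweet(0, "pain and a cold", days=0),
                mk_tweet(1, "caught a cold", days=1),
                mk_tweet(2, "tremor", days=2),
            ]
        )
        _, (h, m) = _curate(tl, lexicon, watch_words=("cold",))
        d = build_disease_set(h, m, tl)
        assert len(h) + len(m) == len(d)


class TestExportHistory:
    @pytest.fixture
    def history(self):
        events = [
            HealthEvent("E001", -10, "asthma attack", ("t0001",), ("HP:0002099",)),
            HealthEvent("E002", 270, "can walk", ("t0002", "t0003"), ("HP:0012531",)),
        ]
        return build_history("u1", _anchor(), events)

    def test_tsv_rows_equal_events(self, history, tmp_path):
        out = tmp_path / "h.tsv"
        export_history(history, out, "tsv")
        assert len(out.read_text().splitlines()) == len(history.events) + 1

    def test_json_round_trip_byte_identical(self, history, tmp_path):
        p1, p2 = tmp_path / "h1.json", tmp_path / "h2.json"
        export_history(history, p1, "json")
        export_history(read_history(p1), p2, "json")
        assert p1.read_bytes() == p2.read_bytes()

    def test_json_round_trip_lossless(self, history, tmp_path):
        p = tmp_path / "h.json"
        export_history(history, p, "json")
        back = read_history(p)
        assert back.user_id == history.user_id
        assert back.anchor == history.anchor
        assert back.events == history.events

    @pytest.mark.parametrize("seed", range(3))
    def test_random_history_tsv_cardinality(self, tmp_path, seed):
        rng = random.Random(seed)
        events = [
            HealthEvent(f"E{i:03d}", rng.randint(-2000, 700), f"s{i}", (f"t{i:04d}",))
            for i in range(rng.randint(0, 12))
        ]
        h = build_history("u1", _anchor(), events)
        out = tmp_path / "h.tsv"
        export_history(h, out, "tsv")
        assert len(out.read_text().splitlines()) == len(events) + 1
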