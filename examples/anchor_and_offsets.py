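"""Find the diagnosis-announcement tweet and compute signed day offsets.

The earliest original tweet containing "I was diagnosed" together with
the disease name (or an alias) becomes day 0; every other tweet gets a
signed whole-day offset -- negative before the diagnosis, positive after.
"""

from datetime import datetime, timezone

from phenotweet import Timeline, Tweet, compute_offset, detect_diagnosis, filter_statuses


def tweet(tid, iso, text, **kw):
    return Tweet(tid, datetime.fromisoformat(iso).replace(tzinfo=timezone.utc), text, **kw)


timeline = Timeline(
    user_id="ALS1",
    tweets=[
        tweet("t1", "2012-06-02T08:00", "had an asthma attack this morning"),
        tweet("t2", "2018-03-01T10:00", "I was diagnosed with ALS today. Still processing."),
        tweet("t3", "2018-03-05T12:00", "RT @x: I was diagnosed with ALS", is_retweet=True),
        tweet("t4", "2018-11-26T19:00", "can still work, walk and talk"),
    ],
)

anchor = detect_diagnosis(
    filter_statuses(timeline), ["ALS", "amyotrophic lateral sclerosis"]
)
print(f"anchor: {anchor.anchor_date} via tweet {anchor.tweet_id} ({anchor.pattern!r})")
for t in filter_statuses(timeline):
    print(f"  {t.tweet_id}: offset {compute_offset(t.created_at, anchor.anchor_date):+6d} d  {t.text[:40]}")

# The retweet can never anchor the history; t1 lands at a large negative
# offset (years before diagnosis) and t4 at +270 days after it.
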