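# phenotweet

Patients with rare and intractable diseases — amyotrophic lateral
sclerosis (ALS) or multiple sclerosis (MS), say — are few, scattered, and
often undiagnosed for years, so patient-centric information is scarce in
clinical registries. Their communities, however, are highly active on
social media. `phenotweet` mines a diagnosed user's tweet timeline for
mentions of their health condition and assembles them into a **patient
history**: a sequence of dated health events anchored on the
diagnosis-announcement tweet.

The pipeline, per user *u*:

1. **Ingest** a timeline dump (JSON-lines in the Twitter API v1.1 field
   subset, or CSV), drop retweets and replies, and keep users with more
   than 100 original tweets diagnosed within the last 5 years.
2. **Anchor**: the earliest original tweet containing "I was diagnosed"
   plus the disease name (or an alias) fixes day 0.
3. **H(u)** — "tweets by HPO": tweets containing a term of the Human
   Phenotype Ontology (labels and, by default, synonyms; the labels
   *all*, *left* and *right* are excluded as hopeless free-text anchors).
   Matching is word-boundary token matching over normalized text
   (NFKC, lowercased, apostrophe-aware), so "painting" never matches
   *pain*. Hits are kept unless a curator removes them (e.g. tweets about
   someone else's health).
4. **M(u)** — "tweets by manual": tweets hit by a watchlist of common lay
   health words ("cold", …). Because most such hits are not about health
   ("It's cold today."), watchlist matches are kept **only** on an
   explicit curator keep decision. Curation is a file round trip: export
   candidates to a TSV, edit the action/reason/summary/event-key columns,
   apply.
5. **D(u) = H(u) ∪ M(u)** — "tweets about the disease" (a tweet matched
   by both routes counts for H, so #H + #M = |D|).
6. **History**: each D-tweet gets a signed whole-day offset from the
   anchor date (negative before diagnosis, positive after); tweets
   sharing an ontology term within a 7-day window merge into one event
   (single linkage; manual event keys override), and events are reported
   sorted by offset with privacy-preserving summaries from curation.

A synthetic-data module generates timelines with planted ground truth
(diagnosis tweet, symptom tweets at known offsets, watchlist false
positives, other-person mentions with pre-written remove decisions,
retweets/replies, noise) so the full pipeline is testable end to end
without any network access.

## Worked example

`examples/patient_history.py` builds a six-tweet timeline (one diagnosis
announcement, two *pain* tweets three days apart, three kept watchlist
tweets) and prints:

```
|H|=2 |M|=3 |D|=5 -> 4 events
  day  +270: Pain         (2 tweet(s))
  day  +400: had cold     (1 tweet(s))
  day  +520: had sick     (1 tweet(s))
  day  +644: had flu      (1 tweet(s))
```

The two same-term tweets merge into a single event at the earlier offset,
so five disease-related tweets yield four dated events after diagnosis.
The other examples cover lexicon construction, anchoring and offsets,
the curation round trip, and a full synthetic cohort run.

## Command line

A thin CLI wraps the library:

```sh
phenotweet simulate --seed 42 --users 4 --out cohort/
phenotweet run --ontology cohort/ontology.obo --watchlist cohort/watchlist.txt \
    --timelines cohort/timelines --decisions cohort/decisions.tsv \
    --disease ALS --ref-date 2020-01-15 --out out/
```

`run` writes per-user H/M/D sets, anchors, patient histories (JSON and
TSV), a `User / #Tweets / #H / #M` summary table with a Total row, an
audit log with one line per discarded tweet or match, and a manifest with
input digests. Subcommands `lexicon`, `ingest`, `anchor`, `select-users`,
`match`, `watch`, `curate export|apply`, `history` and `summarize` expose
the individual stages. Exit codes: 0 success, 2 configuration error,
3 data error.

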