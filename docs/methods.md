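# Methods

## Problem and data model

The package reconstructs a patient's health-condition history from their
own social-media timeline. A timeline is an ordered list of tweets
(id, UTC timestamp, text, retweet flag, reply flag) for one pseudonymized
user. All analysis operates on *original* tweets only — retweets and
replies are removed first, because they usually relay other people's
words. Cohort selection keeps users with a diagnosis announcement,
strictly more than `min_original_tweets` (default 100) original tweets,
and a diagnosis date at most `max_years_since_diagnosis` (default 5,
counted as 365.25-day years) before an explicit `reference_date`. The
reference date is a parameter rather than "now" so that a selection run
is reproducible; "more than 100" is read as a strict inequality and both
thresholds are exposed.

## Diagnosis anchoring

The anchor is the earliest original tweet whose normalized text contains
a diagnosis phrase (default `"i was diagnosed"`) and the disease name or
any alias as contiguous token sequences. Its UTC calendar date is day 0.
When several tweets qualify, the earliest wins — the first announcement
best approximates the diagnosis event — and the others are logged.
Relative-date statements ("I was diagnosed last year") are *not*
resolved; the anchor date is always the announcing tweet's own date.
This is a known, logged limitation.

## Text normalization and term matching

Tokens are maximal runs of Unicode letters/digits in the raw text, with
apostrophes kept when they join two runs (`it's` is one token); each
token is NFKC-folded and lowercased. Character offsets always refer to
the raw string, so every match surface can be sliced from the original
tweet for audit.

The ontology lexicon maps each normalized label (and synonym, unless
`include_synonyms=False`) of every non-obsolete term to its term ids.
Whether the original study used synonyms, case folding or substring
matching is not determinable, so all three are configuration: synonyms
default to on (labels alone miss lay phrasing), matching defaults to
word-boundary token matching (raw substring matching floods on fragments
like "painting"; `substring=True` restores the literal reading), and
exclusions default to `{"all", "left", "right"}` — ontology labels that
are ordinary English words — applied at lexicon-build time so the
matcher stays generic. Obsolete terms are skipped: they are not current
phenotype vocabulary.

Matching walks the token sequence; at each start token the longest
matching key wins (so "muscle weakness" suppresses a same-start
"muscle"), while overlapping matches from *different* start positions
are all reported, one match per (tweet, occurrence, term id). Although
the extracted sets are tweet-level, matches carry character spans so
downstream merging and review remain auditable.

## Curation semantics

Candidates go out as a TSV (match id, tweet id, date, source, term id,
surface, full text, and empty action/reason/summary/event-key columns)
in deterministic order; a curator edits and the file is read back.
Ontology (H) matches default to **kept** unless removed; watchlist (M)
matches are kept only on an explicit keep decision under the default
`strict_M` policy, mirroring the observation that most common-word hits
are not health-related. A removal must carry a reason from
{other_person, not_health, figurative, duplicate, other}; summaries must
be free of mentions and URLs (they exist to conceal sensitive detail).
A tweet with kept matches from both routes counts for H only, so H and M
partition D and per-user counts add up exactly. Conflicting decisions
for one match and decisions naming unknown matches are hard errors.

## Event merging

Each D-tweet's offset is the signed whole-calendar-day difference (UTC)
between its date and the anchor date — calendar days rather than 24-hour
intervals, because histories are reported as day counts relative to a
diagnosis date. Tweets merge into one event when they share an ontology
term and their offsets differ by at most `window_days` (default 7), with
single-linkage transitive closure via union–find; a manual `event_key`
from curation merges unconditionally and overrides the automatic rule.
Manual merges in the original workflow were human judgment; the
same-term-within-window rule is the auditable approximation, and the
package deliberately does not claim to recover any specific manual merge
on real data. Event summaries come from the curation summary of the
earliest supporting tweet, falling back to the joined term labels, then
to the earliest matched surface; events report the earliest tweet's
offset and ties sort by lexicographically smallest tweet id for
determinism. With `window_days=0` and no shared terms or keys, every
tweet is its own event; for any window, events partition D exactly.

## Synthetic cohorts

The generator emulates the structural features the pipeline must
survive: exactly one diagnosis tweet per user at the anchor date;
singleton symptom tweets, each with a distinct fixture-ontology term at
a distinct random offset in `offset_range_days` (default −2200..+700,
spanning multi-year pre- and post-diagnosis mentions); `merge_pairs`
same-term tweet pairs 1–7 days apart that must merge; manual-keep
watchlist tweets (0–4 per user, matching the low per-user counts such
data shows) with pre-written keep decisions and summaries; watchlist
false positives with *no* decision; other-person tweets that always
contain a kinship word and a pre-written `other_person` remove decision;
and retweet/reply/noise filler. Default cohort shape: 4 users,
160–260 tweets each, 20 % retweets and 10 % replies — which leaves every
user above the >100-original-tweet selection bar — diagnosed 200–1700
days before the reference date 2020-01-15, inside the 5-year window.

Texts come from a fixed template bank with casing/punctuation variation
to exercise normalization. The templates are chosen so no template
contains a lexicon key or watchlist word other than the planted one;
generation *verifies* this by running the real matcher and fails if the
corpus contradicts the planted truth. Tweet ids are zero-padded
chronological sequence numbers, so lexicographic order equals time
order. A configuration whose retweet/reply budget leaves no room for the
planted original tweets (e.g. `fraction_retweets=1.0`, which cannot host
the mandatory original diagnosis tweet) is rejected before anything is
written.

What the generator does **not** emulate: linguistic variety beyond the
template bank, misspellings, negation ("no pain today"), figurative
language, posting-frequency dynamics, or disease progression. Exact
end-to-end recovery on synthetic cohorts therefore demonstrates that the
machinery is correct and deterministic, not that real-timeline recall or
precision would be high — on real data the dictionary approach extracts
few tweets and manual curation remains essential.

## Numerical and design choices

- Timestamps: Twitter `created_at` dialect and ISO-8601, both resolved
  to UTC before any date arithmetic; naive ISO timestamps are taken as
  UTC.
- Duplicate tweet ids collapse to the first occurrence with a warning;
  empty inputs warn rather than fail.
- All serializations (curation TSV, history JSON/TSV, summary table,
  manifest) are deterministic; rerunning on identical inputs is
  byte-identical.
- The pipeline writes nothing until every stage has succeeded, so a
  failed run leaves no partial outputs.
- Problem sizes in the test suite and acceptance script — corpora up to
  1,000 tweets and 200 lexicon keys, 20 two-user cohorts — are chosen as
  comfortable desk-scale sizes at which the brute-force oracles remain
  exact and fast.

## Known limitations

- English only; no fuzzy matching, no machine-learned recognition, no
  negation or uncertainty handling.
- No ontology graph reasoning: a tweet matching "pain" is not linked to
  ancestors or descendants of the term.
- Diagnosis dating trusts the announcement tweet's date; the true
  diagnosis may precede it.
- The common-word watchlist is user-supplied; no default list is claimed
  to reproduce any particular manual extraction.
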