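"""Ontology term lexicon and common-word watchlist.

The lexicon maps normalized surface forms (lowercased, whitespace-canonical
token sequences) of Human Phenotype Ontology term labels -- and optionally
synonyms -- to the set of term ids bearing that form.  A small exclusion
list removes forms that are ontology vocabulary but hopeless as free-text
anchors; the default exclusions are ``{"all", "left", "right"}``, the three
HPO labels that are ordinary English function/direction words.

Normalization dialect
---------------------
Tokens are maximal runs of Unicode letters and digits in the *raw* text,
with apostrophes (``'`` or ``’``) kept when they sit between two such runs
(so ``it's`` is one token).  Each token is then NFKC-folded and lowercased,
with curly apostrophes mapped to ``'``.  Character offsets always refer to
the raw input string (0-based, half-open), so matched surfaces can be
sliced straight out of the original tweet.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import obonet

logger = logging.getLogger(__name__)

#: Forms never entered into the lexicon (normalized before comparison).
DEFAULT_EXCLUSIONS = frozenset({"all", "left", "right"})

# Maximal alphanumeric runs, optionally joined by intra-word apostrophes.
_TOKEN_RE = re.compile(r"[^\W_]+(?:['’][^\W_]+)*", re.UNICODE)

# Scalar part of an OBO synonym line: the first quoted string.
_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


class Token(NamedTuple):
    """One normalized token with its raw-text character span."""

    text: str
    start: int
    end: int


def _fold(raw: str) -> str:
    return unicodedata.normalize("NFKC", raw).lower().replace("’", "'")


def normalize_text(text: str) -> list[Token]:
    """Tokenize ``text`` into normalized tokens with raw-text offsets.

    >>> [t.text for t in normalize_text("It's cold today.")]
    ["it's", 'cold', 'today']
    """
    return [
        Token(_fold(m.group(0)), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


def normalize_phrase(text: str) -> str:
    """Collapse a phrase to its canonical lexicon-key form.

    Tokens joined by single spaces; the empty string when no token survives.
    """
    return " ".join(t.text for t in normalize_text(text))


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term as read from an OBO stanza."""

    term_id: str
    label: str
    synonyms: tuple[str, ...] = ()
    obsolete: bool = False


@dataclass
class OntologyLexicon:
    """Normalized surface forms mapped to the ontology term ids bearing them.

    ``entries`` never contains a key in ``excluded_forms``; every key is a
    non-empty normalized phrase.  ``labels`` keeps the primary name per term
    id so downstream event summaries can fall back to it.
    """

    entries: dict[str, frozenset[str]] = field(default_factory=dict)
    excluded_forms: frozenset[str] = DEFAULT_EXCLUSIONS
    include_synonyms: bool = True
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def max_key_tokens(self) -> int:
        """Longest key length in tokens (0 for an empty lexicon)."""
        return max((k.count(" ") + 1 for k in self.entries), default=0)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Watchlist:
    """Common lay health words whose matches always require manual review."""

    words: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.words)


class OboParseError(ValueError):
    """Raised when the OBO file cannot be parsed into term stanzas."""


def _iter_terms(obo_file: str | Path) -> Iterable[OntologyTerm]:
    try:
        # Keep obsolete stanzas: obsoleteness is our own skip decision.
        graph = obonet.read_obo(str(obo_file), ignore_obsolete=False)
    except OSError:
        raise
    except Exception as exc:  # malformed stanza
        raise OboParseError(f"cannot parse OBO file {obo_file!r}: {exc}") from exc
    for term_id, data in graph.nodes(data=True):
        name = data.get("name", "")
        synonyms = []
        for line in data.get("synonym", []):
            m = _SYNONYM_RE.search(line)
            if m:
                synonyms.append(m.group(1).replace('\\"', '"'))
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        yield OntologyTerm(term_id, name, tuple(synonyms), obsolete)


def build_lexicon(
    obo_file: str | Path,
    exclusions: Iterable[str] = DEFAULT_EXCLUSIONS,
    include_synonyms: bool = True,
) -> OntologyLexicon:
    """Parse an OBO ontology into a normalized surface-form lexicon.

    Every non-obsolete term contributes its label, and its synonyms when
    ``include_synonyms`` is set, as normalized keys.  Keys whose normalized
    form equals a normalized exclusion are dropped.  Construction is
    deterministic: equal inputs give equal lexica.

    Parameters
    ----------
    obo_file:
        Path to an OBO 1.2/1.4 flat file.
    exclusions:
        Raw strings; normalized before comparison against candidate keys.
        Multi-word exclusions are compared as whole keys.
    include_synonyms:
        Whether synonym lines contribute surface forms in addition to the
        primary label.
    """
    excluded = frozenset(
        norm for raw in exclusions if (norm := normalize_phrase(raw))
    )
    entries: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    n_terms = 0
    for term in _iter_terms(obo_file):
        if term.obsolete:
            continue
        if not term.label:
            continue
        n_terms += 1
        labels[term.term_id] = term.label
        surfaces = [term.label]
        if include_synonyms:
            surfaces.extend(term.synonyms)
        for surface in surfaces:
            key = normalize_phrase(surface)
            if not key or key in excluded:
                continue
            entries.setdefault(key, set()).add(term.term_id)
    if n_terms == 0:
        logger.warning("ontology %s contributed no terms: empty lexicon", obo_file)
    return OntologyLexicon(
        entries={k: frozenset(v) for k, v in sorted(entries.items())},
        excluded_forms=excluded,
        include_synonyms=include_synonyms,
        labels=labels,
    )


def load_watchlist(file: str | Path) -> Watchlist:
    """Read a plain-text watchlist: one word or phrase per line, ``#`` comments.

    Entries are normalized and deduplicated.  A missing file raises; an
    empty file yields an empty watchlist with a logged warning.
    """
    path = Path(file)
    words: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        norm = normalize_phrase(stripped)
        if norm:
            words.add(norm)
    if not words:
        logger.warning("watchlist %s is empty", path)
    return Watchlist(frozenset(words))


def save_watchlist(watchlist: Watchlist, file: str | Path) -> None:
    """Write a watchlist back to disk, sorted, one entry per line."""
    Path(file).write_text(
        "".join(f"{w}\n" for w in sorted(watchlist.words)), encoding="utf-8"
    )
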