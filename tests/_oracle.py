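"""Independent brute-force oracles used by the test suite.

The matcher oracle regex-scans each lexicon key with word boundaries over
the lowercased raw text, keeping the longest hit per start position.  It
shares no code with the production matcher (which walks normalized token
sequences), so agreement between the two is a real cross-check.
"""

from __future__ import annotations

import re

_B_LEFT = r"(?<![a-zA-Z0-9])(?<![a-zA-Z0-9]')"
_B_RIGHT = r"(?![a-zA-Z0-9])(?!'[a-zA-Z0-9])"


def oracle_scan(text: str, key_terms: dict[str, list[str | None]]):
    """All (start, end, term_id) hits of the keys in one text."""
    lowered = text.lower()
    raw_hits: list[tuple[int, int, str]] = []
    for key in key_terms:
        tokens = [re.escape(t) for t in key.split(" ")]
        pattern = _B_LEFT + r"[^a-zA-Z0-9]+".join(tokens) + _B_RIGHT
        for m in re.finditer(pattern, lowered):
            raw_hits.append((m.start(), m.end(), key))
    best: dict[int, tuple[int, str]] = {}
    for start, end, key in raw_hits:
        if start not in best or end > best[start][0]:
            best[start] = (end, key)
    out = []
    for start, (end, key) in best.items():
        for term_id in key_terms[key]:
            out.append((start, end, term_id))
    return sorted(out, key=lambda h: (h[0], h[1], h[2] or ""))


def oracle_token_offsets(text: str):
    """Character-scan tokenizer oracle: spans of alnum runs with inner
    apostrophes, computed by a direct left-to-right scan."""
    spans = []
    i, n = 0, len(text)
    is_word = lambda c: c.isalnum() and not c == "_"
    while i < n:
        if not is_word(text[i]):
            i += 1
            continue
        start = i
        while i < n:
            if is_word(text[i]):
                i += 1
            elif (
                text[i] in "'’"
                and i + 1 < n
                and is_word(text[i + 1])
                and i > start
            ):
                i += 1
            else:
                break
        spans.append((start, i))
    return spans
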