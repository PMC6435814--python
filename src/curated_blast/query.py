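"""Text-query matching against curated descriptions.

Three matching modes, all case-insensitive:

* default — the description matches when it contains the query as a
  substring;
* wildcard — ``%`` in the query matches any run of zero or more characters
  (only ``%`` is special; ``_`` is literal), so ``chl%reduct`` matches
  "Perchlorate reductase subunit alpha";
* whole-word — the query must occur with both ends on word boundaries, so
  ``chlorate`` matches "Chlorate reductase" but not "Perchlorate reductase".

Word characters are letters and digits, plus ``.`` and ``-`` when flanked by
letters or digits on both sides — so an EC number such as ``1.1.1.1`` or a
hyphenated compound behaves as a single word and can be searched for with
the whole-word option.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

from curated_blast.errors import InvalidQueryError

if TYPE_CHECKING:  # pragma: no cover
    from curated_blast.db import CuratedDatabase, CuratedEntry, CuratedSequence


@dataclass(frozen=True)
class Query:
    """A validated text query with its matching options."""

    text: str
    word_mode: bool = False

    def __post_init__(self) -> None:
        text = self.text.strip()
        if not text:
            raise InvalidQueryError("query text is empty")
        if set(text) == {"%"}:
            raise InvalidQueryError("query consists only of wildcards")
        object.__setattr__(self, "text", text)

    @property
    def has_wildcard(self) -> bool:
        return "%" in self.text

    @property
    def _regex(self) -> re.Pattern:
        # '%' -> '.*' (greedy is fine for containment tests); everything
        # else literal.
        parts = self.text.split("%")
        return re.compile(
            ".*".join(re.escape(p) for p in parts), re.IGNORECASE | re.DOTALL
        )


def _is_word_char(s: str, i: int) -> bool:
    c = s[i]
    if c.isalnum():
        return True
    if c in ".-" and 0 < i < len(s) - 1:
        return s[i - 1].isalnum() and s[i + 1].isalnum()
    return False


def description_matches(query: Query, description: str) -> bool:
    """True when ``description`` matches ``query`` under its mode."""
    if not description:
        return False
    rx = query._regex
    if not query.word_mode:
        return rx.search(description) is not None

    # Whole-word mode: some occurrence must have both ends on word
    # boundaries. Between '%'s only the overall ends are constrained.
    # Descriptions are short, so trying all boundary-legal spans is cheap.
    n = len(description)
    starts = [i for i in range(n)
              if i == 0 or not _is_word_char(description, i - 1)]
    ends = [j for j in range(1, n + 1)
            if j == n or not _is_word_char(description, j)]
    for i in starts:
        for j in ends:
            if j <= i:
                continue
            if rx.fullmatch(description, i, j):
                return True
    return False


def select_curated(
    db: "CuratedDatabase", query: Query
) -> list[tuple["CuratedSequence", list["CuratedEntry"]]]:
    """Curated sequences having at least one entry whose description matches.

    Each result carries exactly the matching entries; a sequence described by
    several matching entries is returned once. Order is deterministic
    (ascending seq_id). An empty result is not an error — the caller reports
    that no curated proteins matched.
    """
    results = []
    for seq in db.iter_sequences():
        matched = [e for e in seq.entries
                   if description_matches(query, e.description)]
        if matched:
            results.append((seq, matched))
    return results
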