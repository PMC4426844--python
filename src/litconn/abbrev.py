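"""Parenthetical abbreviation definitions and short-form expansion.

Articles almost always define region abbreviations explicitly — "the
ventral tegmental area (VTA)" — and then use only the short form.  This
module finds such definitions with right-to-left character alignment
(every short-form character must appear, in order, in the long form, and
the first character must start a word) and exposes a position-scoped alias
map so the dictionary NER can match later "VTA" occurrences against the
long form.  Expansion is aliasing, never text rewriting: offsets are
preserved.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass

from .corpus import Document, Sentence, TextSpan

logger = logging.getLogger(__name__)

__all__ = ["AbbrevDefinition", "AliasMap", "detect_definitions", "expand"]

_YEAR_RE = re.compile(r"^(1[89]|20)\d\d[a-c]?$")
_HAS_LETTER_RE = re.compile(r"[A-Za-z]")


@dataclass(frozen=True)
class AbbrevDefinition:
    doc_id: str
    short_form: str
    long_form_span: TextSpan
    definition_site: TextSpan  # the parenthetical, including parentheses

    def __post_init__(self) -> None:
        if len(self.short_form) >= self.long_form_span.length():
            raise ValueError("short form must be shorter than its long form")
        if self.definition_site.start < self.long_form_span.end:
            raise ValueError("definition site must follow the long form")


def _valid_short_form(sf: str) -> bool:
    if not (2 <= len(sf) <= 10):
        return False
    if not _HAS_LETTER_RE.search(sf):
        return False
    if sf.isdigit() or _YEAR_RE.match(sf):
        return False
    return True


def _align(short: str, window: str) -> int | None:
    """Schwartz–Hearst right-to-left alignment.

    Returns the index in ``window`` where the long form starts, or None when
    the alignment fails.  The first short-form character must match at a
    word start.
    """
    i_s = len(short) - 1
    i_l = len(window) - 1
    while i_s >= 0:
        ch = short[i_s].lower()
        if not ch.isalnum():
            i_s -= 1
            continue
        while i_l >= 0 and (
            window[i_l].lower() != ch
            or (i_s == 0 and i_l > 0 and window[i_l - 1].isalnum())
        ):
            i_l -= 1
        if i_l < 0:
            return None
        i_s -= 1
        i_l -= 1
    # Extend left to the start of the word containing the first match.
    start = i_l + 1
    return start


def _candidate_sites(sentence: Sentence) -> list[tuple[int, int, int]]:
    """Indices (open, inner, close) of single-token parentheticals."""
    toks = sentence.tokens
    sites = []
    for i, tok in enumerate(toks):
        if tok.surface != "(":
            continue
        # find matching close paren within a small window
        depth = 1
        for j in range(i + 1, min(i + 6, len(toks))):
            if toks[j].surface == "(":
                depth += 1
            elif toks[j].surface == ")":
                depth -= 1
                if depth == 0:
                    if j == i + 2:  # exactly one inner token
                        sites.append((i, i + 1, j))
                    break
    return sites


def detect_definitions(document: Document) -> list[AbbrevDefinition]:
    """Find parenthetical abbreviation definitions in a segmented document.

    Citations ("(Dworkin, 1988)"), years and measures never produce
    definitions: multi-token parentheticals are skipped outright and
    single-token ones must pass the short-form validity and alignment
    tests.
    """
    defs: list[AbbrevDefinition] = []
    for sentence in document.sentences:
        toks = sentence.tokens
        for i_open, i_inner, i_close in _candidate_sites(sentence):
            sf = toks[i_inner].surface
            if not _valid_short_form(sf):
                continue
            letters = sum(ch.isalnum() for ch in sf)
            max_words = min(letters + 5, letters * 2)
            first = max(0, i_open - max_words)
            window_toks = toks[first:i_open]
            if not window_toks:
                continue
            win_start = window_toks[0].span.start
            window = document.text[win_start : toks[i_open].span.start]
            rel = _align(sf, window)
            if rel is None:
                continue
            lf_start = win_start + rel
            # snap to the start of the covering word
            while lf_start > win_start and document.text[lf_start - 1].isalnum():
                lf_start -= 1
            lf_end = toks[i_open - 1].span.end
            if lf_end - lf_start <= len(sf):
                continue
            surface = document.text[lf_start:lf_end]
            if surface.strip().lower() == sf.lower():
                continue
            defs.append(
                AbbrevDefinition(
                    doc_id=document.id,
                    short_form=sf,
                    long_form_span=TextSpan(document.id, lf_start, lf_end),
                    definition_site=TextSpan(
                        document.id, toks[i_open].span.start, toks[i_close].span.end
                    ),
                )
            )
    return defs


class AliasMap:
    """Position-scoped short-form → long-form-surface mapping.

    A short form resolves only at positions after its definition site; when
    the same short form is defined twice, occurrences between the sites map
    to the first definition and later occurrences to the second.
    """

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self._defs: dict[str, list[tuple[int, str]]] = {}

    def _add(self, definition: AbbrevDefinition, long_surface: str) -> None:
        lst = self._defs.setdefault(definition.short_form, [])
        if lst:
            logger.info(
                "short form %r redefined in %s; later definition shadows earlier",
                definition.short_form, self.doc_id,
            )
        lst.append((definition.definition_site.end, long_surface))
        lst.sort()

    def resolve(self, short_form: str, position: int) -> str | None:
        """Long-form surface for an occurrence starting at ``position``."""
        lst = self._defs.get(short_form)
        if not lst:
            return None
        idx = bisect_right(lst, (position, chr(0x10FFFF))) - 1
        if idx < 0:
            return None
        return lst[idx][1]

    def short_forms(self) -> set[str]:
        return set(self._defs)

    def __len__(self) -> int:
        return len(self._defs)


def expand(document: Document, defs: list[AbbrevDefinition]) -> AliasMap:
    """Build the alias map for a document from its detected definitions.

    Pure function of ``(document, defs)``; short-form matching downstream is
    case-sensitive exact token match.
    """
    aliases = AliasMap(document.id)
    for d in defs:
        if d.doc_id != document.id:
            raise ValueError(f"definition for {d.doc_id!r} applied to {document.id!r}")
        long_surface = document.text[d.long_form_span.start : d.long_form_span.end]
        aliases._add(d, long_surface)
    return aliases
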