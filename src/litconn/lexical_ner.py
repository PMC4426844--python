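"""Dictionary NER: longest contiguous stemmed match of lexicon terms.

Matching is token-aligned and greedy left-to-right: at each position the
longest matching term wins and shorter terms nested inside it are
suppressed ("midbrain" inside "midbrain ventral tegmental area" is never
emitted).  Ties between equal-length terms resolve by lexicon listing
order.  Hyphens act as token separators but do not break contiguity;
matches never cross sentence boundaries.  Abbreviation short forms match
via their long form when an alias map is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .abbrev import AliasMap
from .corpus import Document, Sentence, TextSpan
from .lexicon import DEFAULT_STOPLIST, Lexicon, normalize_term

__all__ = ["Mention", "NERConfig", "TermMatcher", "match", "write_mentions_tsv"]


@dataclass(frozen=True)
class Mention:
    span: TextSpan
    surface: str
    region_id: str | None
    source: str  # "lexical" | "crf"
    matched_via: str | None = None  # "name" | "synonym" | "abbreviation"
    lexicon_tag: str = ""

    def __post_init__(self) -> None:
        if self.source == "lexical" and self.region_id is None:
            raise ValueError("lexical mentions must carry a region_id")

    def key(self) -> tuple[str, int, int]:
        return (self.span.doc_id, self.span.start, self.span.end)


@dataclass
class NERConfig:
    stoplist: frozenset[str] = DEFAULT_STOPLIST
    use_abbreviations: bool = True


class TermMatcher:
    """Pre-indexed lexicon terms as normalized token tuples."""

    def __init__(self, lexicon: Lexicon):
        self.lexicon = lexicon
        # normalized token tuple -> (region_id, matched_via); first entry wins
        self.index: dict[tuple[str, ...], tuple[str, str]] = {}
        self.max_len = 1
        for entry in lexicon.entries:
            for via, term in [("name", entry.preferred_name)] + [
                ("synonym", s) for s in sorted(entry.synonyms)
            ]:
                key = tuple(normalize_term(term).split())
                if not key:
                    continue
                self.index.setdefault(key, (entry.region_id, via))
                self.max_len = max(self.max_len, len(key))

    def lookup(self, key: tuple[str, ...]) -> tuple[str, str] | None:
        return self.index.get(key)


def _word_units(sentence: Sentence) -> tuple[list[int], list[bool]]:
    """Indices of word tokens and contiguity flags between adjacent units.

    ``contiguous[k]`` is True when units k and k+1 are separated only by
    hyphens/slashes (or nothing), i.e. a multi-token term may span them.
    """
    toks = sentence.tokens
    units = [i for i, t in enumerate(toks) if any(c.isalnum() for c in t.surface)]
    contiguous = []
    for a, b in zip(units, units[1:]):
        between = toks[a + 1 : b]
        contiguous.append(all(t.surface in {"-", "/"} for t in between))
    return units, contiguous


def match(
    document: Document,
    lexicon: Lexicon | TermMatcher,
    aliases: AliasMap | None = None,
    config: NERConfig | None = None,
) -> list[Mention]:
    """Run dictionary NER over a segmented, tokenized document."""
    config = config or NERConfig()
    matcher = lexicon if isinstance(lexicon, TermMatcher) else TermMatcher(lexicon)
    stop_norms = {normalize_term(t) for t in config.stoplist}
    mentions: list[Mention] = []
    for sentence in document.sentences:
        mentions.extend(
            _match_sentence(document, sentence, matcher, aliases, stop_norms, config)
        )
    return mentions


def _match_sentence(
    document: Document,
    sentence: Sentence,
    matcher: TermMatcher,
    aliases: AliasMap | None,
    stop_norms: set[str],
    config: NERConfig,
) -> list[Mention]:
    toks = sentence.tokens
    units, contiguous = _word_units(sentence)
    n = len(units)
    out: list[Mention] = []
    u = 0
    while u < n:
        best: Mention | None = None
        best_len = 0
        # longest contiguous dictionary match starting at unit u
        max_l = min(matcher.max_len, n - u)
        key: list[str] = []
        for length in range(1, max_l + 1):
            if length > 1 and not contiguous[u + length - 2]:
                break
            key.append(toks[units[u + length - 1]].stem)
            hit = matcher.lookup(tuple(key))
            if hit is not None:
                region_id, via = hit
                start = toks[units[u]].span.start
                end = toks[units[u + length - 1]].span.end
                best = Mention(
                    span=TextSpan(document.id, start, end),
                    surface=document.text[start:end],
                    region_id=region_id,
                    source="lexical",
                    matched_via=via,
                    lexicon_tag=matcher.lexicon.name,
                )
                best_len = length
        if best is None and aliases is not None and config.use_abbreviations:
            tok = toks[units[u]]
            long_surface = aliases.resolve(tok.surface, tok.span.start)
            if long_surface is not None:
                hit = matcher.lookup(tuple(normalize_term(long_surface).split()))
                if hit is not None:
                    best = Mention(
                        span=tok.span,
                        surface=tok.surface,
                        region_id=hit[0],
                        source="lexical",
                        matched_via="abbreviation",
                        lexicon_tag=matcher.lexicon.name,
                    )
                    best_len = 1
        if best is not None:
            if normalize_term(best.surface) not in stop_norms:
                out.append(best)
            u += best_len
        else:
            u += 1
    return out


def write_mentions_tsv(mentions: Iterable[Mention], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("doc_id\tstart\tend\tsurface\tregion_id\tsource\tmatched_via\n")
        for m in sorted(mentions, key=Mention.key):
            fh.write(
                f"{m.span.doc_id}\t{m.span.start}\t{m.span.end}\t{m.surface}\t"
                f"{m.region_id or ''}\t{m.source}\t{m.matched_via or ''}\n"
            )
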