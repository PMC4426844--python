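"""Sentence-level connectivity extraction: FILTERS cascade, RULES grammar,
and boolean ensembles over extractor outputs.

A candidate is an unordered pair of region mentions co-located in one
sentence.  Co-occurrence alone is weak evidence of connectivity, so each
extractor trades recall for precision in its own way: FILTERS prunes
candidates with sentence-level heuristics (length, mention count, trigger
substrings, nearest neighbors); RULES matches hand-written patterns of the
kind "projection from A to B and C"; the kernel classifier lives in
:mod:`litconn.kernel`.  Directionality is not extracted, so pairs are
unordered throughout.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Document, Sentence
from .lexical_ner import Mention

__all__ = [
    "CandidatePair",
    "ConnectivityStatement",
    "FilterConfig",
    "DEFAULT_TRIGGERS",
    "enumerate_pairs",
    "nearest_neighbor_pairs",
    "filters_extract",
    "RulePattern",
    "RuleSet",
    "load_rules",
    "default_rules",
    "rules_extract",
    "ensemble",
    "write_statements_tsv",
]

EXTRACTOR_NAMES = ("FILTERS", "KERNEL", "RULES")


@dataclass(frozen=True)
class CandidatePair:
    doc_id: str
    sentence_index: int
    mention_a: Mention
    mention_b: Mention

    def __post_init__(self) -> None:
        a, b = self.mention_a, self.mention_b
        if a.span == b.span:
            raise ValueError("pair mentions must be distinct")
        if a.span.start > b.span.start:
            raise ValueError("mention_a must precede mention_b")

    def key(self) -> tuple:
        return (
            self.doc_id,
            self.sentence_index,
            self.mention_a.span.start,
            self.mention_a.span.end,
            self.mention_b.span.start,
            self.mention_b.span.end,
        )

    def region_ids(self) -> frozenset[str] | None:
        a, b = self.mention_a.region_id, self.mention_b.region_id
        if a is None or b is None:
            return None
        return frozenset((a, b))


def make_pair(doc_id: str, sentence_index: int, m1: Mention, m2: Mention) -> CandidatePair:
    a, b = sorted([m1, m2], key=lambda m: (m.span.start, m.span.end))
    return CandidatePair(doc_id, sentence_index, a, b)


@dataclass
class ConnectivityStatement:
    pair: CandidatePair
    fired_by: frozenset[str]
    kernel_score: float | None = None

    def __post_init__(self) -> None:
        if not self.fired_by:
            raise ValueError("fired_by must be non-empty")
        unknown = set(self.fired_by) - set(EXTRACTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown extractors {unknown}")

    def key(self) -> tuple:
        return self.pair.key()


# ---------------------------------------------------------------------------
# Candidate enumeration and FILTERS cascade
# ---------------------------------------------------------------------------


def enumerate_pairs(sentence: Sentence, mentions: Sequence[Mention]) -> list[CandidatePair]:
    """All C(n, 2) unordered mention pairs of one sentence, canonically ordered."""
    ms = sorted(mentions, key=lambda m: (m.span.start, m.span.end))
    for m in ms:
        if not sentence.span.contains(m.span):
            raise ValueError(f"mention {m.span} outside sentence {sentence.span}")
    return [
        CandidatePair(sentence.doc_id, sentence.index, a, b)
        for a, b in itertools.combinations(ms, 2)
    ]


DEFAULT_TRIGGERS = ("afferent", "efferent", "project", "connecti", "pathway", "inputs")


@dataclass
class FilterConfig:
    max_chars: int = 500
    max_regions: int = 7
    triggers: tuple[str, ...] = DEFAULT_TRIGGERS
    nearest_neighbor: bool = True


def _gap(earlier: Mention, later: Mention) -> int:
    return later.span.start - earlier.span.end


def nearest_neighbor_pairs(mentions: Sequence[Mention]) -> set[frozenset]:
    """Mention pairs where either member is the other's closest mention.

    Distance is the character gap between the earlier mention's end and the
    later mention's start; ties break toward the earlier-starting candidate.
    The one-sided-or rule keeps chains (A-B, B-C) intact.
    """
    ms = sorted(mentions, key=lambda m: (m.span.start, m.span.end))
    kept: set[frozenset] = set()
    for m in ms:
        best = None
        best_gap = None
        for other in ms:
            if other.span == m.span:
                continue
            lo, hi = sorted([m, other], key=lambda x: (x.span.start, x.span.end))
            g = _gap(lo, hi)
            if best_gap is None or g < best_gap or (
                g == best_gap and other.span.start < best.span.start
            ):
                best, best_gap = other, g
        if best is not None:
            kept.add(frozenset((m.span, best.span)))
    return kept


def filters_extract(
    document: Document,
    sentence: Sentence,
    pairs: Sequence[CandidatePair],
    config: FilterConfig | None = None,
) -> list[ConnectivityStatement]:
    """Apply the filter cascade to candidate pairs of one sentence.

    Survivors satisfy all of: sentence length <= max_chars, sentence mention
    count <= max_regions, at least one trigger character sequence present
    (case-insensitive substring), and pair is a nearest-neighbor pair.
    """
    config = config or FilterConfig()
    if not pairs:
        return []
    sent_text = document.sentence_text(sentence)
    if len(sent_text) > config.max_chars:
        return []
    mentions = {m.span: m for p in pairs for m in (p.mention_a, p.mention_b)}
    if len(mentions) > config.max_regions:
        return []
    low = sent_text.lower()
    if not any(trig.lower() in low for trig in config.triggers):
        return []
    keep = (
        nearest_neighbor_pairs(list(mentions.values()))
        if config.nearest_neighbor
        else None
    )
    out = []
    for p in pairs:
        if keep is not None and frozenset((p.mention_a.span, p.mention_b.span)) not in keep:
            continue
        out.append(ConnectivityStatement(pair=p, fired_by=frozenset({"FILTERS"})))
    return out


# ---------------------------------------------------------------------------
# RULES: pattern grammar over a simplified token stream
# ---------------------------------------------------------------------------

#: Tokens dropped from the rule-matching stream (determiners etc.); the
#: stream also drops parenthetical groups, so interleaved abbreviation or
#: citation parentheticals never break a literal pattern.
SKIP_WORDS = frozenset({"the", "a", "an", "both", "either"})

LIST_SEPARATORS = frozenset({"and", "or", ","})

_GAP_MAX = 5


@dataclass(frozen=True)
class _Item:
    kind: str  # "REGION" | "WORD"
    word: str = ""  # lowercased surface for WORD items
    mention: Mention | None = None


def _simplify(sentence: Sentence, mentions: Sequence[Mention]) -> list[_Item]:
    ms = sorted(mentions, key=lambda m: (m.span.start, m.span.end))
    items: list[_Item] = []
    depth = 0
    mi = 0
    i = 0
    toks = sentence.tokens
    while i < len(toks):
        tok = toks[i]
        while mi < len(ms) and ms[mi].span.end <= tok.span.start:
            mi += 1
        if mi < len(ms) and ms[mi].span.start <= tok.span.start < ms[mi].span.end:
            if depth == 0:
                items.append(_Item("REGION", mention=ms[mi]))
            # skip remaining tokens of this mention
            while i < len(toks) and toks[i].span.start < ms[mi].span.end:
                i += 1
            continue
        if tok.surface == "(":
            depth += 1
        elif tok.surface == ")":
            depth = max(0, depth - 1)
        elif depth == 0:
            low = tok.surface.lower()
            if low not in SKIP_WORDS and any(c.isalnum() for c in low) or low == ",":
                items.append(_Item("WORD", word=low))
        i += 1
    return items


@dataclass(frozen=True)
class _Elem:
    kind: str  # "LIT" | "REGION" | "RLIST" | "GAP"
    alternatives: tuple[str, ...] = ()
    optional: bool = False


@dataclass
class RulePattern:
    """One connection-extraction rule.

    The element sequence mixes literal tokens (with ``|`` alternation and
    ``?`` optionality), ``REGION`` slots, ``REGION-LIST`` slots (regions
    joined by "and"/"or"/commas/"as well as") and bounded ``GAP``
    wildcards.  Every region bound by the first slot is paired with every
    region bound by the second.
    """

    name: str
    elements: list[_Elem]

    def __post_init__(self) -> None:
        slots = [e for e in self.elements if e.kind in {"REGION", "RLIST"}]
        if len(slots) < 2:
            raise ValueError(f"rule {self.name!r} needs at least two region slots")


def parse_rule(line: str) -> RulePattern:
    if ":" in line:
        name, _, body = line.partition(":")
        name = name.strip()
    else:
        name, body = "rule", line
    elements: list[_Elem] = []
    for raw in body.split():
        optional = raw.endswith("?")
        tok = raw[:-1] if optional else raw
        if tok == "REGION":
            elements.append(_Elem("REGION", optional=optional))
        elif tok in {"REGION-LIST", "RLIST"}:
            elements.append(_Elem("RLIST", optional=optional))
        elif tok == "GAP":
            elements.append(_Elem("GAP"))
        else:
            elements.append(
                _Elem("LIT", alternatives=tuple(tok.lower().split("|")), optional=optional)
            )
    if not elements:
        raise ValueError(f"rule {name!r} is empty")
    return RulePattern(name=name, elements=elements)


class RuleSet:
    def __init__(self, rules: Iterable[RulePattern]):
        self.rules = list(rules)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self):
        return len(self.rules)


def load_rules(path: str | Path) -> RuleSet:
    rules = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rules.append(parse_rule(line))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return RuleSet(rules)


def default_rules() -> RuleSet:
    from importlib.resources import files

    return load_rules(files("litconn.data") / "default_rules.txt")


def _match_rlist(items: list[_Item], i: int) -> list[tuple[int, list[Mention]]]:
    """Possible (next index, bound mentions) for a REGION-LIST starting at i."""
    if i >= len(items) or items[i].kind != "REGION":
        return []
    bound = [items[i].mention]
    results = [(i + 1, list(bound))]
    j = i + 1
    while True:
        k = j
        # separators: ",", "and", "or", "as well as", possibly combined (", and")
        seen_sep = False
        while k < len(items) and items[k].kind == "WORD":
            w = items[k].word
            if w in LIST_SEPARATORS:
                k += 1
                seen_sep = True
            elif w == "as" and k + 2 < len(items) and items[k + 1].word == "well" and items[k + 2].word == "as":
                k += 3
                seen_sep = True
            else:
                break
        if not seen_sep or k >= len(items) or items[k].kind != "REGION":
            break
        bound.append(items[k].mention)
        results.append((k + 1, list(bound)))
        j = k + 1
    return results


def _match_here(
    items: list[_Item], i: int, elements: list[_Elem], ei: int, slots: list[list[Mention]]
) -> list[list[list[Mention]]]:
    """All slot bindings for elements[ei:] matched at items[i:]."""
    if ei == len(elements):
        return [slots]
    elem = elements[ei]
    out: list[list[list[Mention]]] = []
    if elem.optional:
        out.extend(_match_here(items, i, elements, ei + 1, slots))
    if elem.kind == "LIT":
        if (
            i < len(items)
            and items[i].kind == "WORD"
            and items[i].word in elem.alternatives
        ):
            out.extend(_match_here(items, i + 1, elements, ei + 1, slots))
    elif elem.kind == "REGION":
        if i < len(items) and items[i].kind == "REGION":
            out.extend(
                _match_here(items, i + 1, elements, ei + 1, slots + [[items[i].mention]])
            )
    elif elem.kind == "RLIST":
        for nxt, bound in _match_rlist(items, i):
            out.extend(_match_here(items, nxt, elements, ei + 1, slots + [bound]))
    elif elem.kind == "GAP":
        for gap in range(0, _GAP_MAX + 1):
            j = i + gap
            if j > len(items):
                break
            if any(it.kind == "REGION" for it in items[i:j]):
                break
            out.extend(_match_here(items, j, elements, ei + 1, slots))
    return out


def rules_extract(
    document: Document,
    sentence: Sentence,
    mentions: Sequence[Mention],
    ruleset: RuleSet | None = None,
) -> list[ConnectivityStatement]:
    """Match rule patterns against one sentence; emit paired statements.

    Matching is token-based and case-insensitive; region slots bind only to
    NER mentions.  Each match pairs every region of its first slot with
    every region of its second slot.
    """
    ruleset = ruleset or default_rules()
    items = _simplify(sentence, mentions)
    seen: set[tuple] = set()
    out: list[ConnectivityStatement] = []
    for rule in ruleset:
        for start in range(len(items)):
            for slots in _match_here(items, start, rule.elements, 0, []):
                if len(slots) < 2:
                    continue
                for m1 in slots[0]:
                    for m2 in slots[1]:
                        if m1.span == m2.span:
                            continue
                        pair = make_pair(document.id, sentence.index, m1, m2)
                        if pair.key() in seen:
                            continue
                        seen.add(pair.key())
                        out.append(
                            ConnectivityStatement(pair=pair, fired_by=frozenset({"RULES"}))
                        )
    return out


# ---------------------------------------------------------------------------
# Boolean ensembles
# ---------------------------------------------------------------------------


class _ExprParser:
    """Tiny recursive-descent parser: expr := term ("or" term)*;
    term := factor ("and" factor)*; factor := NAME | "(" expr ")"."""

    def __init__(self, text: str):
        self.tokens = re.findall(r"\(|\)|\w+", text.lower())
        self.pos = 0

    def parse(self):
        node = self._expr()
        if self.pos != len(self.tokens):
            raise ValueError(f"trailing tokens in ensemble expression at {self.pos}")
        return node

    def _expr(self):
        node = self._term()
        while self._peek() == "or":
            self.pos += 1
            node = ("or", node, self._term())
        return node

    def _term(self):
        node = self._factor()
        while self._peek() == "and":
            self.pos += 1
            node = ("and", node, self._factor())
        return node

    def _factor(self):
        tok = self._peek()
        if tok == "(":
            self.pos += 1
            node = self._expr()
            if self._peek() != ")":
                raise ValueError("unbalanced parenthesis in ensemble expression")
            self.pos += 1
            return node
        if tok is None:
            raise ValueError("unexpected end of ensemble expression")
        name = tok.upper()
        if name not in EXTRACTOR_NAMES:
            raise ValueError(f"unknown extractor {name!r} in ensemble expression")
        self.pos += 1
        return ("name", name)

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None


def _eval_expr(node, present: set[str]) -> bool:
    op = node[0]
    if op == "name":
        return node[1] in present
    if op == "and":
        return _eval_expr(node[1], present) and _eval_expr(node[2], present)
    return _eval_expr(node[1], present) or _eval_expr(node[2], present)


def ensemble(
    statements_by_extractor: dict[str, Sequence[ConnectivityStatement]], mode: str
) -> list[ConnectivityStatement]:
    """Combine per-extractor statements with a boolean expression.

    ``mode`` examples: ``"FILTERS and KERNEL and RULES"``,
    ``"(FILTERS or KERNEL) and RULES"``.  A pair is emitted when the
    expression holds for the set of extractors that fired it; ``fired_by``
    is the union of those extractors and a kernel score is carried over
    when present.
    """
    tree = _ExprParser(mode).parse()
    by_key: dict[tuple, dict] = {}
    for name, stmts in statements_by_extractor.items():
        if name not in EXTRACTOR_NAMES:
            raise ValueError(f"unknown extractor {name!r}")
        for st in stmts:
            slot = by_key.setdefault(
                st.key(), {"pair": st.pair, "fired": set(), "score": None}
            )
            slot["fired"].add(name)
            slot["fired"].update(st.fired_by)
            if st.kernel_score is not None:
                slot["score"] = st.kernel_score
    out = []
    for key in sorted(by_key):
        slot = by_key[key]
        if _eval_expr(tree, slot["fired"]):
            out.append(
                ConnectivityStatement(
                    pair=slot["pair"],
                    fired_by=frozenset(slot["fired"]),
                    kernel_score=slot["score"],
                )
            )
    return out


def write_statements_tsv(statements: Iterable[ConnectivityStatement], path: str | Path) -> None:
    cols = [
        "doc_id", "sentence_index",
        "a_start", "a_end", "a_surface", "a_region_id",
        "b_start", "b_end", "b_surface", "b_region_id",
        "fired_by", "kernel_score",
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for st in sorted(statements, key=ConnectivityStatement.key):
            a, b = st.pair.mention_a, st.pair.mention_b
            fh.write(
                "\t".join(
                    [
                        st.pair.doc_id,
                        str(st.pair.sentence_index),
                        str(a.span.start), str(a.span.end), a.surface, a.region_id or "",
                        str(b.span.start), str(b.span.end), b.surface, b.region_id or "",
                        "+".join(sorted(st.fired_by)),
                        "" if st.kernel_score is None else f"{st.kernel_score:.6f}",
                    ]
                )
                + "\n"
            )
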