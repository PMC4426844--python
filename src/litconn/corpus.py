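"""Text data model: offset-bearing documents, sentences and tokens.

Every downstream stage (abbreviation detection, NER, relation extraction)
operates on this model.  Offsets are 0-based, half-open, counted in Unicode
code points, so ``document.text[span.start:span.end]`` always returns the
span surface.  Readers/writers are provided for a JSONL corpus format and
for BRAT-style standoff gold annotations.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "TextSpan",
    "Token",
    "Sentence",
    "Document",
    "GoldAnnotationSet",
    "segment_and_tokenize",
    "simple_pos_tag",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "read_standoff",
    "write_standoff",
]


@dataclass(frozen=True, order=True)
class TextSpan:
    """A half-open character interval ``[start, end)`` within one document."""

    doc_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) in doc {self.doc_id!r}"
            )

    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "TextSpan") -> bool:
        """True when ``other`` lies within (is equal to or smaller than) self."""
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "TextSpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Token:
    span: TextSpan
    surface: str
    pos: str
    stem: str


@dataclass
class Sentence:
    span: TextSpan
    index: int
    tokens: list[Token] = field(default_factory=list)

    @property
    def doc_id(self) -> str:
        return self.span.doc_id


@dataclass
class Document:
    id: str
    source_class: str  # "abstract" | "fulltext"
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def sentence_text(self, sentence: Sentence) -> str:
        return self.text[sentence.span.start : sentence.span.end]

    def validate_offsets(self) -> None:
        """Assert offset integrity of every sentence and token."""
        n = len(self.text)
        prev_end = 0
        for sent in self.sentences:
            if not (0 <= sent.span.start < sent.span.end <= n):
                raise ValueError(f"sentence span out of range in {self.id}")
            if sent.span.start < prev_end:
                raise ValueError(f"overlapping sentences in {self.id}")
            prev_end = sent.span.end
            tprev = sent.span.start
            for tok in sent.tokens:
                if self.text[tok.span.start : tok.span.end] != tok.surface:
                    raise ValueError(
                        f"token surface mismatch at {tok.span} in {self.id}"
                    )
                if tok.span.start < tprev:
                    raise ValueError(f"overlapping tokens in {self.id}")
                tprev = tok.span.end


@dataclass
class GoldAnnotationSet:
    """Gold entities (span, label) and binary relations between them.

    Relations are unordered pairs of entity indices; the canonical form
    stores ``i < j``.
    """

    doc_id: str
    entities: list[tuple[TextSpan, str]] = field(default_factory=list)
    relations: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        canon = []
        for i, j, label in self.relations:
            if i == j:
                raise ValueError("relation endpoints must be distinct entities")
            if not (0 <= i < len(self.entities) and 0 <= j < len(self.entities)):
                raise ValueError(f"relation references missing entity ({i}, {j})")
            canon.append((min(i, j), max(i, j), label))
        self.relations = canon

    def relation_span_pairs(self) -> set[frozenset[TextSpan]]:
        return {
            frozenset((self.entities[i][0], self.entities[j][0]))
            for i, j, _ in self.relations
        }


# ---------------------------------------------------------------------------
# Segmentation and tokenization
# ---------------------------------------------------------------------------

#: Abbreviations whose trailing period never ends a sentence.
SENTENCE_ABBREVIATIONS = frozenset(
    {
        "e.g",
        "i.e",
        "cf",
        "vs",
        "al",
        "et al",
        "fig",
        "figs",
        "eq",
        "ref",
        "refs",
        "dr",
        "no",
        "ca",
        "approx",
    }
)

_TOKEN_RE = re.compile(r"[A-Za-z]+|\d+|\S")
_WORD_BEFORE_RE = re.compile(r"([A-Za-z][A-Za-z.]*)$")


def _is_sentence_break(text: str, i: int) -> bool:
    """Decide whether the terminator at position ``i`` ends a sentence."""
    ch = text[i]
    if ch in "!?":
        return True
    # ch == "."
    # Not a break inside a number (e.g. "0.5").
    if i > 0 and text[i - 1].isdigit() and i + 1 < len(text) and text[i + 1].isdigit():
        return False
    m = _WORD_BEFORE_RE.search(text[:i])
    if m:
        word = m.group(1).lower().rstrip(".")
        if word in SENTENCE_ABBREVIATIONS:
            return False
        prior = text[: i - len(m.group(1))].rstrip().lower()
        if word == "al" and prior.endswith("et"):
            return False
        # Single capital letter followed by period: an initial, not an end.
        if len(m.group(1)) == 1 and m.group(1).isupper():
            return False
    # Require following whitespace then an uppercase letter, digit or EOF.
    j = i + 1
    while j < len(text) and text[j] in ")]\"'":
        j += 1
    if j >= len(text):
        return True
    if not text[j].isspace():
        return False
    while j < len(text) and text[j].isspace():
        j += 1
    if j >= len(text):
        return True
    return text[j].isupper() or text[j].isdigit()


def _split_sentences(text: str) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        if text[i] in ".!?" and _is_sentence_break(text, i):
            end = i + 1
            while end < n and text[end] in ")]\"'":
                end += 1
            seg = text[start:end].strip()
            if seg:
                s = start + (len(text[start:end]) - len(text[start:end].lstrip()))
                spans.append((s, s + len(seg)))
            start = end
            i = end
        elif text[i] == "\n" and i + 1 < n and text[i + 1] == "\n":
            seg = text[start:i].strip()
            if seg:
                s = start + (len(text[start:i]) - len(text[start:i].lstrip()))
                spans.append((s, s + len(seg)))
            start = i + 1
            i += 1
        else:
            i += 1
    seg = text[start:].strip()
    if seg:
        s = start + (len(text[start:]) - len(text[start:].lstrip()))
        spans.append((s, s + len(seg)))
    return spans


_DETERMINERS = frozenset({"the", "a", "an", "this", "these", "that", "those"})
_PREPOSITIONS = frozenset(
    {
        "of", "in", "to", "from", "with", "by", "on", "at", "between", "into",
        "within", "through", "via", "for", "as", "after", "before", "during",
    }
)
_CONJUNCTIONS = frozenset({"and", "or", "but", "nor"})
_PRONOUNS = frozenset({"it", "its", "we", "they", "their", "our", "both", "all"})
_VERB_LIST = frozenset(
    {
        "is", "are", "was", "were", "be", "been", "has", "have", "had",
        "receive", "receives", "received", "project", "projects", "projected",
        "projecting", "send", "sends", "sent", "innervate", "innervates",
        "innervated", "originate", "originates", "arise", "arises", "found",
        "show", "shows", "shown", "suggest", "suggests", "contain", "contains",
        "terminate", "terminates", "form", "forms",
    }
)


def simple_pos_tag(surface: str) -> str:
    """Heuristic part-of-speech tagger.

    Coarse by design: the CRF and kernel features only need stable,
    deterministic tags, not treebank-quality ones.  Any callable with this
    signature can replace it via the tokenizer config.
    """
    low = surface.lower()
    if surface.isdigit():
        return "CD"
    if not surface[0].isalnum():
        return "PUNCT"
    if low in _DETERMINERS:
        return "DT"
    if low in _PREPOSITIONS:
        return "IN"
    if low in _CONJUNCTIONS:
        return "CC"
    if low in _PRONOUNS:
        return "PRP"
    if low in _VERB_LIST:
        return "VB"
    if low.endswith("ly"):
        return "RB"
    if low.endswith("ing") or low.endswith("ed"):
        return "VBG"
    if surface[0].isupper():
        return "NNP"
    if low.endswith("s"):
        return "NNS"
    return "NN"


def segment_and_tokenize(
    document: Document,
    pos_tagger: Callable[[str], str] = simple_pos_tag,
    stemmer: Callable[[str], str] | None = None,
) -> Document:
    """Populate ``document.sentences`` with tokenized sentences.

    Deterministic for a fixed input and config.  Empty text yields zero
    sentences.  Hyphens and other punctuation become single-character
    tokens, so parenthesized abbreviations like "(AC)" tokenize as
    ``(``, ``AC``, ``)``.
    """
    from .lexicon import stem_token  # deferred: lexicon owns the stemmer

    stem = stemmer or stem_token
    sentences: list[Sentence] = []
    for idx, (s, e) in enumerate(_split_sentences(document.text)):
        sent_text = document.text[s:e]
        tokens = []
        for m in _TOKEN_RE.finditer(sent_text):
            surface = m.group(0)
            span = TextSpan(document.id, s + m.start(), s + m.end())
            tokens.append(
                Token(
                    span=span,
                    surface=surface,
                    pos=pos_tagger(surface),
                    stem=stem(surface.lower()),
                )
            )
        sentences.append(
            Sentence(span=TextSpan(document.id, s, e), index=idx, tokens=tokens)
        )
    document.sentences = sentences
    return document


# ---------------------------------------------------------------------------
# JSONL corpus I/O
# ---------------------------------------------------------------------------


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    """Read one document per JSON line (fields: id, source_class, text, metadata)."""
    docs: list[Document] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            for key in ("id", "source_class", "text"):
                if key not in obj:
                    raise ValueError(f"{path}: line {lineno} missing field {key!r}")
            docs.append(
                Document(
                    id=str(obj["id"]),
                    source_class=obj["source_class"],
                    text=obj["text"],
                    metadata=obj.get("metadata", {}),
                )
            )
    return docs


def write_corpus_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "id": doc.id,
                        "source_class": doc.source_class,
                        "text": doc.text,
                        "metadata": doc.metadata,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BRAT-style standoff I/O
# ---------------------------------------------------------------------------

_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_R_LINE = re.compile(r"^(R\d+)\t(\S+) Arg1:(T\d+) Arg2:(T\d+)\s*$")


def read_standoff(
    txt_path: str | Path, ann_path: str | Path, source_class: str = "abstract"
) -> tuple[Document, GoldAnnotationSet]:
    """Read a ``.txt`` + ``.ann`` standoff pair.

    Entity surfaces recorded in the ``.ann`` file are checked against the
    text; a mismatch or out-of-range offset raises with the entity id.
    """
    txt_path, ann_path = Path(txt_path), Path(ann_path)
    text = txt_path.read_text(encoding="utf-8")
    doc_id = txt_path.stem
    entities: list[tuple[TextSpan, str]] = []
    tid_to_index: dict[str, int] = {}
    relations: list[tuple[int, int, str]] = []
    for raw in ann_path.read_text(encoding="utf-8").splitlines():
        if not raw.strip():
            continue
        if raw.startswith("T"):
            m = _T_LINE.match(raw)
            if not m:
                raise ValueError(f"{ann_path}: malformed entity line: {raw!r}")
            tid, label, start, end, surface = (
                m.group(1), m.group(2), int(m.group(3)), int(m.group(4)), m.group(5),
            )
            if end > len(text):
                raise ValueError(f"{ann_path}: entity {tid} offset out of range")
            if text[start:end] != surface:
                raise ValueError(
                    f"{ann_path}: entity {tid} surface mismatch: "
                    f"{text[start:end]!r} != {surface!r}"
                )
            tid_to_index[tid] = len(entities)
            entities.append((TextSpan(doc_id, start, end), label))
        elif raw.startswith("R"):
            m = _R_LINE.match(raw)
            if not m:
                raise ValueError(f"{ann_path}: malformed relation line: {raw!r}")
            _, label, a, b = m.groups()
            if a not in tid_to_index or b not in tid_to_index:
                raise ValueError(f"{ann_path}: relation references unknown entity")
            relations.append((tid_to_index[a], tid_to_index[b], label))
    doc = Document(id=doc_id, source_class=source_class, text=text)
    return doc, GoldAnnotationSet(doc_id=doc_id, entities=entities, relations=relations)


def write_standoff(
    document: Document,
    annotations: GoldAnnotationSet,
    txt_path: str | Path,
    ann_path: str | Path,
) -> None:
    Path(txt_path).write_text(document.text, encoding="utf-8")
    lines = []
    for k, (span, label) in enumerate(annotations.entities, start=1):
        surface = document.text[span.start : span.end]
        lines.append(f"T{k}\t{label} {span.start} {span.end}\t{surface}")
    for k, (i, j, label) in enumerate(annotations.relations, start=1):
        lines.append(f"R{k}\t{label} Arg1:T{i + 1} Arg2:T{j + 1}")
    Path(ann_path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
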