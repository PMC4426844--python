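"""Brain-region vocabulary: loading, synonym merging, normalization, depth.

A :class:`Lexicon` maps normalized terms to region identifiers.  Term
normalization lowercases, strips punctuation, collapses whitespace and
applies a Porter-style stemmer to every token longer than three characters;
short tokens (abbreviations such as "VTA" or "CA1") are left unstemmed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "RegionEntry",
    "Lexicon",
    "stem_token",
    "normalize_term",
    "load_lexicon_tsv",
    "write_lexicon_tsv",
    "merge_synonyms",
    "depth",
    "load_stoplist",
    "DEFAULT_STOPLIST",
]

#: Generic terms excluded from mention output by default.
DEFAULT_STOPLIST = frozenset({"brain", "nerves"})


# ---------------------------------------------------------------------------
# Porter stemmer (classic algorithm, measure-based suffix stripping)
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in the word form [C](VC)^m[V]."""
    forms = ""
    for i in range(len(stem)):
        forms += "C" if _is_cons(stem, i) else "V"
    m = 0
    prev = None
    for ch in forms:
        if prev == "V" and ch == "C":
            m += 1
        prev = ch
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]
_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]
_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _porter(word: str) -> str:
    if len(word) <= 2:
        return word
    # Step 1a
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith("ies"):
        word = word[:-2]
    elif word.endswith("ss"):
        pass
    elif word.endswith("s"):
        word = word[:-1]
    # Step 1b
    flag = False
    if word.endswith("eed"):
        if _measure(word[:-3]) > 0:
            word = word[:-1]
    elif word.endswith("ed") and _has_vowel(word[:-2]):
        word = word[:-2]
        flag = True
    elif word.endswith("ing") and _has_vowel(word[:-3]):
        word = word[:-3]
        flag = True
    if flag:
        if word.endswith(("at", "bl", "iz")):
            word += "e"
        elif _ends_double_cons(word) and word[-1] not in "lsz":
            word = word[:-1]
        elif _measure(word) == 1 and _cvc(word):
            word += "e"
    # Step 1c
    if word.endswith("y") and _has_vowel(word[:-1]):
        word = word[:-1] + "i"
    # Step 2
    for suf, rep in _STEP2:
        if word.endswith(suf):
            if _measure(word[: -len(suf)]) > 0:
                word = word[: -len(suf)] + rep
            break
    # Step 3
    for suf, rep in _STEP3:
        if word.endswith(suf):
            if _measure(word[: -len(suf)]) > 0:
                word = word[: -len(suf)] + rep
            break
    # Step 4
    for suf in _STEP4:
        if word.endswith(suf):
            stem = word[: -len(suf)]
            if suf == "ion" and not stem.endswith(("s", "t")):
                break
            if _measure(stem) > 1:
                word = stem
            break
    else:
        if word.endswith("ion") and _measure(word[:-3]) > 1 and word[:-4:-1] and word[-4] in "st":
            word = word[:-3]
    # Step 5a
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _cvc(stem)):
            word = stem
    # Step 5b
    if _measure(word) > 1 and _ends_double_cons(word) and word.endswith("l"):
        word = word[:-1]
    return word


def stem_token(token: str) -> str:
    """Stem a single lowercase token; tokens of length <= 3 are unchanged.

    Iterates the suffix stripper to its fixed point so that stemming (and
    hence term normalization) is idempotent, which the term index relies
    on; common English forms converge in one pass.
    """
    if len(token) <= 3:
        return token
    for _ in range(5):
        out = _porter(token)
        if out == token:
            return out
        token = out
    return token


_NORM_STRIP_RE = re.compile(r"[^\w\s]+", re.UNICODE)
_WS_RE = re.compile(r"[\s_]+")


def normalize_term(term: str, stemmer: Callable[[str], str] = stem_token) -> str:
    """Normalize a term for dictionary lookup.

    Lowercase, strip punctuation (hyphens act as separators), collapse
    whitespace, then stem each token longer than three characters.
    Idempotent: ``normalize_term(normalize_term(t)) == normalize_term(t)``.
    """
    low = term.lower().replace("-", " ")
    low = _NORM_STRIP_RE.sub(" ", low)
    tokens = [stemmer(t) for t in _WS_RE.split(low) if t]
    return " ".join(tokens)


# ---------------------------------------------------------------------------
# Lexicon model
# ---------------------------------------------------------------------------


@dataclass
class RegionEntry:
    region_id: str
    preferred_name: str
    synonyms: set[str] = field(default_factory=set)
    parent_id: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.synonyms = {s for s in self.synonyms if s and s != self.preferred_name}

    def all_terms(self) -> list[str]:
        return [self.preferred_name, *sorted(self.synonyms)]


class Lexicon:
    """Ordered collection of region entries with a normalized-term index.

    Lookup is order dependent: when two entries normalize to the same term,
    the earlier-listed entry wins and a collision is recorded.
    """

    def __init__(self, entries: Iterable[RegionEntry] = (), name: str = "lexicon"):
        self.name = name
        self.entries: list[RegionEntry] = []
        self._by_id: dict[str, RegionEntry] = {}
        self.term_index: dict[str, str] = {}
        #: normalized term -> list of region ids that claimed it (collisions)
        self.collisions: dict[str, list[str]] = {}
        for entry in entries:
            self.add(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def __getitem__(self, region_id: str) -> RegionEntry:
        return self._by_id[region_id]

    def add(self, entry: RegionEntry) -> None:
        if entry.region_id in self._by_id:
            raise ValueError(f"duplicate region_id {entry.region_id!r}")
        self.entries.append(entry)
        self._by_id[entry.region_id] = entry
        for term in entry.all_terms():
            self._index_term(term, entry.region_id)

    def _index_term(self, term: str, region_id: str) -> None:
        norm = normalize_term(term)
        if not norm:
            return
        if norm in self.term_index:
            owners = self.collisions.setdefault(norm, [self.term_index[norm]])
            if region_id not in owners:
                owners.append(region_id)
                logger.warning(
                    "term collision on %r: kept %s, ignored %s",
                    norm, self.term_index[norm], region_id,
                )
            return
        self.term_index[norm] = region_id

    def attach_synonym(self, region_id: str, synonym: str) -> bool:
        """Add a synonym to an existing entry; returns True if it was new."""
        entry = self._by_id[region_id]
        if synonym == entry.preferred_name or synonym in entry.synonyms:
            return False
        entry.synonyms.add(synonym)
        self._index_term(synonym, region_id)
        return True

    def lookup(self, term: str) -> str | None:
        return self.term_index.get(normalize_term(term))

    def term_count(self) -> int:
        return len(self.term_index)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

TSV_HEADER = ["region_id", "preferred_name", "synonyms", "parent_id", "source"]


def load_lexicon_tsv(path: str | Path, name: str | None = None) -> Lexicon:
    """Load a lexicon from TSV (synonyms pipe-separated, blank parent = root)."""
    path = Path(path)
    lex = Lexicon(name=name or path.stem)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[:2] == TSV_HEADER[:2]:  # header row
                continue
            if len(cols) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
            cols += [""] * (5 - len(cols))
            region_id, preferred, syns, parent, source = cols[:5]
            lex.add(
                RegionEntry(
                    region_id=region_id,
                    preferred_name=preferred,
                    synonyms={s.strip() for s in syns.split("|") if s.strip()},
                    parent_id=parent.strip() or None,
                    source=source or lex.name,
                )
            )
    return lex


def write_lexicon_tsv(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TSV_HEADER) + "\n")
        for e in lexicon.entries:
            fh.write(
                "\t".join(
                    [
                        e.region_id,
                        e.preferred_name,
                        "|".join(sorted(e.synonyms)),
                        e.parent_id or "",
                        e.source,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Synonym merging and ontology depth
# ---------------------------------------------------------------------------


def merge_synonyms(base: Lexicon, donors: Iterable[Lexicon]) -> Lexicon:
    """Augment ``base`` with synonyms from donor lexica.

    A donor entry is linked to a base entry when their preferred names are
    equal under :func:`normalize_term` (or when the donor entry carries an
    explicit cross-reference in ``synonyms`` of the form ``xref:<id>``).
    The merged lexicon has exactly the entries of ``base``; donor preferred
    names and synonyms of linked entries are attached as synonyms.
    """
    merged = Lexicon(name=f"{base.name}+syn")
    for e in base.entries:
        merged.add(
            RegionEntry(
                region_id=e.region_id,
                preferred_name=e.preferred_name,
                synonyms=set(e.synonyms),
                parent_id=e.parent_id,
                source=e.source,
            )
        )
    base_by_norm = {
        normalize_term(e.preferred_name): e.region_id for e in reversed(base.entries)
    }
    for donor in donors:
        for de in donor.entries:
            xrefs = {s[5:] for s in de.synonyms if s.startswith("xref:")}
            plain_syns = {s for s in de.synonyms if not s.startswith("xref:")}
            target = None
            for xref in xrefs:
                if xref in merged:
                    target = xref
                    break
            if target is None:
                target = base_by_norm.get(normalize_term(de.preferred_name))
            if target is None:
                continue
            for syn in sorted(plain_syns | {de.preferred_name}):
                merged.attach_synonym(target, syn)
    return merged


def depth(lexicon: Lexicon, region_id: str) -> int:
    """Number of ancestors on the path from ``region_id`` to its root."""
    if region_id not in lexicon:
        raise KeyError(f"unknown region {region_id!r}")
    seen = set()
    d = 0
    current = lexicon[region_id].parent_id
    while current is not None:
        if current in seen:
            raise ValueError(f"parent cycle at {current!r}")
        seen.add(current)
        if current not in lexicon:
            raise KeyError(f"parent {current!r} of {region_id!r} not in lexicon")
        d += 1
        current = lexicon[current].parent_id
    return d


def load_stoplist(path: str | Path) -> frozenset[str]:
    """One generic term per line; blank lines and # comments ignored."""
    terms = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            terms.add(line.lower())
    return frozenset(terms)
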