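"""Synthetic test substrate: lexica, corpora with planted mentions and
connectivity sentences, gold annotations, and tri-state reference matrices.

Region names are assembled from neuroanatomical part lists (direction +
structure + qualifier, e.g. "dorsal pontine nucleus"), so dictionary
matching, stemming and the CRF all see realistically shaped multi-word
names.  Sentence templates (bundled as data, see
``data/sentence_templates.txt``) model common connectivity constructs —
"receives projections from", "project to", "connections between ... and"
— together with negative co-mentions, hedged statements, citation strings,
digit-heavy table rows and over-long run-on sentences.  Every planted
mention and relation is recorded as gold truth, and generation is fully
determined by the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib.resources import as_file, files

import numpy as np

from .corpus import Document, GoldAnnotationSet, TextSpan, segment_and_tokenize
from .connectome import CONNECTED, NOT_CONNECTED, NOT_EVALUATED, ReferenceMatrix
from .lexicon import Lexicon, RegionEntry, normalize_term

__all__ = [
    "SynthConfig",
    "make_lexicon",
    "make_corpus",
    "make_reference",
    "load_worked_examples",
]

_DIRECTIONS = [
    "dorsal", "ventral", "lateral", "medial", "rostral", "caudal",
    "anterior", "posterior", "superior", "inferior", "central", "basal",
]
_STRUCTURES = [
    "tegmental", "pontine", "raphe", "thalamic", "hypothalamic",
    "cerebellar", "olivary", "septal", "amygdalar", "entorhinal",
    "habenular", "parabrachial", "geniculate", "accumbal", "pallidal",
    "striatal", "cortical", "collicular", "vestibular", "reticular",
]
_QUALIFIERS = [
    "nucleus", "area", "cortex", "field", "complex", "formation", "region",
    "tract",
]
_LATIN_HEADS = ["nucleus", "nuclei", "regio", "area", "campus"]


@dataclass
class SynthConfig:
    n_regions: int = 50
    synonyms_per_region: int = 2
    n_documents: int = 100
    sentences_per_document: int = 5
    positive_sentence_rate: float = 0.4
    abbreviation_rate: float = 0.2
    distractor_rate: float = 0.15
    long_sentence_rate: float = 0.05
    hedge_rate: float = 0.02
    donor_overlap: float = 0.3
    n_donors: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "positive_sentence_rate", "abbreviation_rate", "distractor_rate",
            "long_sentence_rate", "hedge_rate", "donor_overlap",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_regions", "n_documents", "sentences_per_document"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Lexicon generation
# ---------------------------------------------------------------------------


def _region_names(rng: random.Random, n: int) -> list[str]:
    """Distinct multi-word names whose normalized forms are also distinct."""
    names: list[str] = []
    seen_norm: set[str] = set()
    combos = [
        (d, s, q) for d in _DIRECTIONS for s in _STRUCTURES for q in _QUALIFIERS
    ]
    rng.shuffle(combos)
    for d, s, q in combos:
        name = f"{d} {s} {q}"
        norm = normalize_term(name)
        # reject names nested inside an already chosen name and vice versa
        if norm in seen_norm or any(
            norm in other or other in norm for other in seen_norm
        ):
            continue
        names.append(name)
        seen_norm.add(norm)
        if len(names) == n:
            break
    if len(names) < n:
        raise ValueError(f"cannot generate {n} distinct region names")
    return names


def _synonym_for(rng: random.Random, name: str, k: int, taken: set[str]) -> str:
    d, s, q = name.split(" ", 2)
    for attempt in range(20):
        head = rng.choice(_LATIN_HEADS)
        cand = (
            f"{head} {s}us {d}is" if (k + attempt) % 2 == 0
            else f"{s} {q} pars {d}is"
        )
        norm = normalize_term(cand)
        if norm not in taken and not any(norm in t or t in norm for t in taken):
            taken.add(norm)
            return cand
    # fall back to an indexed latin form, unique by construction
    cand = f"{rng.choice(_LATIN_HEADS)} {s}alis {len(taken)}"
    taken.add(normalize_term(cand))
    return cand


def make_lexicon(config: SynthConfig) -> tuple[Lexicon, list[Lexicon]]:
    """Base lexicon (names only, like an atlas ontology) plus donor lexica
    that share a fraction of preferred names and contribute synonyms."""
    rng = random.Random(config.seed * 7919 + 1)
    names = _region_names(rng, config.n_regions)
    taken = {normalize_term(n) for n in names}
    base = Lexicon(name="synthetic-atlas")
    for i, name in enumerate(names):
        parent = None
        if i > 0:
            # parent chosen among earlier entries -> varying tree depths
            parent = f"SYN:{rng.randrange(i):04d}"
        base.add(
            RegionEntry(
                region_id=f"SYN:{i:04d}",
                preferred_name=name,
                synonyms=set(),
                parent_id=parent,
                source="synthetic-atlas",
            )
        )
    donors: list[Lexicon] = []
    for d in range(config.n_donors):
        donor = Lexicon(name=f"donor-{d}")
        shared = [
            i for i in range(config.n_regions) if rng.random() < config.donor_overlap
        ]
        for j, i in enumerate(shared):
            syns = {
                _synonym_for(rng, names[i], k, taken)
                for k in range(config.synonyms_per_region)
            }
            donor.add(
                RegionEntry(
                    region_id=f"D{d}:{j:04d}",
                    preferred_name=names[i],
                    synonyms=syns,
                    parent_id=None,
                    source=f"donor-{d}",
                )
            )
        donors.append(donor)
    return base, donors


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def _load_templates() -> dict[str, list[tuple[str, list[tuple[str, str]]]]]:
    by_type: dict[str, list] = {"POS": [], "NEG": [], "HYP": [], "CIT": [], "TAB": []}
    text = (files("litconn.data") / "sentence_templates.txt").read_text("utf-8")
    for raw in text.splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        ttype, template = cols[0], cols[1]
        rels = []
        if len(cols) > 2 and cols[2].strip():
            rels = [tuple(p.split("-")) for p in cols[2].split(",")]
        by_type[ttype].append((template, rels))
    return by_type


def _abbrev_of(name: str, taken: set[str]) -> str | None:
    """Initialism of a region name; None when it collides in this document
    (a digit-suffixed form would not align with the long form)."""
    sf = "".join(w[0].upper() for w in name.split())
    if sf in taken:
        return None
    taken.add(sf)
    return sf


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.length = 0
        self.entities: list[tuple[TextSpan, str]] = []
        self.entity_regions: list[str] = []
        self.relations: list[tuple[int, int, str]] = []

    def add_sentence(
        self,
        template: str,
        fills: dict[str, tuple[str, str]],
        rels: list[tuple[str, str]],
        defining: dict[str, str] | None = None,
    ) -> None:
        """Render a template; record gold mention spans and relations.

        ``fills`` maps placeholder -> (region_id, surface); ``defining``
        maps placeholder -> short form to append as "(SF)" after the
        surface.
        """
        if self.parts:
            self.length += 1  # joining space
        offset = self.length
        out = []
        idx_of: dict[str, int] = {}
        pos = 0
        i = 0
        while i < len(template):
            ch = template[i]
            if ch == "{":
                j = template.index("}", i)
                slot = template[i + 1 : j]
                region_id, surface = fills[slot]
                start = offset + pos
                out.append(surface)
                pos += len(surface)
                idx_of[slot] = len(self.entities)
                self.entities.append(
                    (TextSpan(self.doc_id, start, start + len(surface)), "REGION")
                )
                self.entity_regions.append(region_id)
                if defining and slot in defining:
                    extra = f" ({defining[slot]})"
                    out.append(extra)
                    pos += len(extra)
                i = j + 1
            else:
                out.append(ch)
                pos += 1
                i += 1
        for a, b in rels:
            self.relations.append((idx_of[a], idx_of[b], "connected"))
        self.parts.append("".join(out))
        self.length = offset + pos

    def build(self, source_class: str) -> tuple[Document, GoldAnnotationSet]:
        text = " ".join(self.parts)
        doc = Document(id=self.doc_id, source_class=source_class, text=text)
        segment_and_tokenize(doc)
        gold = GoldAnnotationSet(
            doc_id=self.doc_id, entities=self.entities, relations=self.relations
        )
        return doc, gold


def make_corpus(
    config: SynthConfig, lexicon: Lexicon
) -> tuple[list[tuple[Document, GoldAnnotationSet]], set[frozenset[str]]]:
    """Generate documents with planted mentions, relations and distractors.

    Returns the (document, gold) list and the global set of true region-id
    pairs planted as connectivity statements.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon must be non-empty")
    rng = random.Random(config.seed * 7919 + 2)
    templates = _load_templates()
    corpus: list[tuple[Document, GoldAnnotationSet]] = []
    true_pairs: set[frozenset[str]] = set()

    def pick_regions(k: int) -> list[RegionEntry]:
        return rng.sample(lexicon.entries, k)

    def surface_of(entry: RegionEntry) -> str:
        choices = [entry.preferred_name, *sorted(entry.synonyms)]
        return rng.choice(choices)

    for di in range(config.n_documents):
        builder = _DocBuilder(f"synth-{di:04d}")
        taken_sf: set[str] = set()
        n_sent = config.sentences_per_document
        for si in range(n_sent):
            r = rng.random()
            if r < config.positive_sentence_rate:
                template, rels = rng.choice(templates["POS"])
                slots = sorted({p for pair in rels for p in pair} | set(_slots(template)))
                entries = pick_regions(len(slots))
                fills = {
                    s: (e.region_id, surface_of(e)) for s, e in zip(slots, entries)
                }
                use_abbrev = rng.random() < config.abbreviation_rate
                defining = None
                if use_abbrev:
                    defining = {}
                    for s in slots:
                        sf = _abbrev_of(fills[s][1], taken_sf)
                        if sf is not None:
                            defining[s] = sf
                    use_abbrev = len(defining) >= 2 and all(
                        s in defining for s in slots[:2]
                    )
                    if not use_abbrev:
                        defining = None
                builder.add_sentence(template, fills, rels, defining)
                for a, b in rels:
                    true_pairs.add(frozenset((fills[a][0], fills[b][0])))
                if use_abbrev and len(slots) >= 2:
                    # reuse the short forms in a follow-up statement
                    a, b = slots[0], slots[1]
                    builder.add_sentence(
                        "The {A} also projects to the {B}.",
                        {
                            "A": (fills[a][0], defining[a]),
                            "B": (fills[b][0], defining[b]),
                        },
                        [("A", "B")],
                    )
                    true_pairs.add(frozenset((fills[a][0], fills[b][0])))
            elif r < config.positive_sentence_rate + config.distractor_rate:
                template, _ = rng.choice(templates["CIT"] + templates["TAB"])
                builder.add_sentence(template, {}, [])
            elif (
                r
                < config.positive_sentence_rate
                + config.distractor_rate
                + config.long_sentence_rate
            ):
                _add_long_sentence(builder, rng, lexicon)
            elif (
                r
                < config.positive_sentence_rate
                + config.distractor_rate
                + config.long_sentence_rate
                + config.hedge_rate
            ):
                template, _ = rng.choice(templates["HYP"])
                slots = _slots(template)
                entries = pick_regions(len(slots))
                fills = {
                    s: (e.region_id, surface_of(e)) for s, e in zip(slots, entries)
                }
                builder.add_sentence(template, fills, [])
            else:
                template, _ = rng.choice(templates["NEG"])
                slots = _slots(template)
                entries = pick_regions(len(slots))
                fills = {
                    s: (e.region_id, surface_of(e)) for s, e in zip(slots, entries)
                }
                builder.add_sentence(template, fills, [])
        source = "abstract" if rng.random() < 0.5 else "fulltext"
        corpus.append(builder.build(source))
    return corpus, true_pairs


def _slots(template: str) -> list[str]:
    out = []
    i = 0
    while i < len(template):
        if template[i] == "{":
            j = template.index("}", i)
            out.append(template[i + 1 : j])
            i = j + 1
        else:
            i += 1
    return sorted(set(out))


def _add_long_sentence(builder: _DocBuilder, rng: random.Random, lexicon: Lexicon) -> None:
    """A run-on, list-heavy sentence exceeding 500 characters with more
    than seven region mentions; carries no gold relations."""
    k = min(9, len(lexicon.entries))
    entries = rng.sample(lexicon.entries, k)
    filler = (
        "together with adjacent structures sampled in an extensive series of "
        "experiments spanning several decades of archival material concerning "
        "projections of every kind"
    )
    template_parts = ["In this material, the {S0}"]
    fills = {"S0": (entries[0].region_id, entries[0].preferred_name)}
    for i, e in enumerate(entries[1:], start=1):
        template_parts.append(", the {S%d}" % i)
        fills[f"S{i}"] = (e.region_id, e.preferred_name)
    template = (
        "".join(template_parts)
        + " and further territories were examined, "
        + ", ".join([filler] * 2)
        + "."
    )
    builder.add_sentence(template, fills, [])


# ---------------------------------------------------------------------------
# Reference matrix generation
# ---------------------------------------------------------------------------


def make_reference(
    true_pairs: set[frozenset[str]],
    regions: list[str],
    noise_rate: float = 0.0,
    coverage_rate: float = 1.0,
    seed: int = 0,
) -> ReferenceMatrix:
    """Tri-state reference built from the generator's true pairs.

    Pair states start from the truth (connected iff planted), flip with
    probability ``noise_rate`` and drop to not-evaluated with probability
    ``1 - coverage_rate``; the matrix is symmetric with a not-evaluated
    diagonal.
    """
    if not (0.0 <= noise_rate <= 1.0 and 0.0 <= coverage_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(regions)
    states = np.full((n, n), NOT_EVALUATED, dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() > coverage_rate:
                continue
            state = (
                CONNECTED
                if frozenset((regions[i], regions[j])) in true_pairs
                else NOT_CONNECTED
            )
            if rng.random() < noise_rate:
                state = NOT_CONNECTED if state == CONNECTED else CONNECTED
            states[i, j] = states[j, i] = state
    return ReferenceMatrix(regions=list(regions), states=states)


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------


def load_worked_examples() -> tuple[list[Document], Lexicon, dict[str, set[frozenset[str]]]]:
    """Bundled worked sentences with their small lexicon and expected pairs.

    Returns segmented documents, the lexicon resolving their region names,
    and a map doc_id -> expected set of region-id pairs.
    """
    import json

    from .lexicon import load_lexicon_tsv

    data = files("litconn.data")
    docs: list[Document] = []
    expected: dict[str, set[frozenset[str]]] = {}
    for line in (data / "worked_sentences.jsonl").read_text("utf-8").splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        doc = Document(
            id=obj["id"],
            source_class=obj["source_class"],
            text=obj["text"],
            metadata=obj.get("metadata", {}),
        )
        segment_and_tokenize(doc)
        docs.append(doc)
        expected[doc.id] = {
            frozenset(p) for p in obj.get("metadata", {}).get("expected_pairs", [])
        }
    with as_file(data / "worked_lexicon.tsv") as p:
        lex = load_lexicon_tsv(p, name="worked")
    return docs, lex, expected
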