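"""Scoring of NER and relation extraction against gold annotations.

Span matching comes in two modes: *strict* requires identical offsets;
*lenient* also credits a prediction whose span is contained within (equal
to or smaller than) a gold span — one-sided by design, so a prediction
strictly containing a gold span is a false positive in both modes.  Each
gold span can satisfy at most one prediction.  Relation scoring treats a
prediction as the unordered pair of entity spans within a sentence.
Cross-validation splits at document level with repeated reshuffles.
"""

from __future__ import annotations

import random
import statistics
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .corpus import Document, GoldAnnotationSet, TextSpan
from .extractors import CandidatePair, ConnectivityStatement
from .lexical_ner import Mention

__all__ = [
    "PRF",
    "CVConfig",
    "CVResult",
    "match_spans",
    "score_relations",
    "cross_validate",
]


@dataclass(frozen=True)
class PRF:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def __add__(self, other: "PRF") -> "PRF":
        return PRF(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def _as_span(item) -> TextSpan:
    if isinstance(item, TextSpan):
        return item
    if isinstance(item, Mention):
        return item.span
    if isinstance(item, tuple) and isinstance(item[0], TextSpan):
        return item[0]
    raise TypeError(f"cannot interpret {item!r} as a span")


def match_spans(predicted: Sequence, gold: Sequence, mode: str = "strict") -> PRF:
    """Score predicted spans/mentions against gold spans.

    strict TP: identical offsets.  lenient TP: the predicted span is equal
    to or contained in a gold span.  Each gold span credits at most one
    prediction (greedy in text order); remaining predictions are FP and
    uncredited gold spans are FN.
    """
    if mode not in {"strict", "lenient"}:
        raise ValueError(f"unknown mode {mode!r}")
    pred = sorted((_as_span(p) for p in predicted), key=lambda s: (s.start, s.end))
    gold_spans = sorted((_as_span(g) for g in gold), key=lambda s: (s.start, s.end))
    docs = {s.doc_id for s in pred} | {s.doc_id for s in gold_spans}
    if len(docs) > 1:
        raise ValueError(f"cross-document comparison: {sorted(docs)}")
    used = [False] * len(gold_spans)
    tp = 0
    for p in pred:
        hit = None
        for gi, g in enumerate(gold_spans):
            if used[gi]:
                continue
            ok = (p == g) if mode == "strict" else g.contains(p)
            if ok:
                hit = gi
                break
        if hit is not None:
            used[hit] = True
            tp += 1
    fp = len(pred) - tp
    fn = len(gold_spans) - tp
    return PRF(tp=tp, fp=fp, fn=fn)


def _pair_key(item) -> frozenset[TextSpan]:
    if isinstance(item, ConnectivityStatement):
        item = item.pair
    if isinstance(item, CandidatePair):
        return frozenset((item.mention_a.span, item.mention_b.span))
    if isinstance(item, frozenset):
        return item
    raise TypeError(f"cannot interpret {item!r} as a pair")


def score_relations(predicted: Iterable, gold: Iterable) -> PRF:
    """Score predicted pairs against gold-connected pairs.

    Identity is the unordered pair of entity spans; duplicates collapse.
    ``gold`` may be a GoldAnnotationSet, an iterable of them, or pair keys.
    """
    gold_keys: set[frozenset[TextSpan]] = set()
    gold_list = [gold] if isinstance(gold, GoldAnnotationSet) else list(gold)
    for g in gold_list:
        if isinstance(g, GoldAnnotationSet):
            gold_keys |= g.relation_span_pairs()
        else:
            gold_keys.add(_pair_key(g))
    pred_keys = {_pair_key(p) for p in predicted}
    tp = len(pred_keys & gold_keys)
    return PRF(tp=tp, fp=len(pred_keys) - tp, fn=len(gold_keys) - tp)


@dataclass
class CVConfig:
    folds: int = 8
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CVResult:
    scores: list[PRF] = field(default_factory=list)  # one per fold x repeat

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = [getattr(s, attr) for s in self.scores]
        mean = statistics.fmean(vals)
        sd = statistics.stdev(vals) if len(vals) > 1 else 0.0
        return mean, sd

    @property
    def precision(self) -> tuple[float, float]:
        return self._agg("precision")

    @property
    def recall(self) -> tuple[float, float]:
        return self._agg("recall")

    @property
    def f1(self) -> tuple[float, float]:
        return self._agg("f1")


def cross_validate(
    corpus: Sequence[tuple[Document, GoldAnnotationSet]],
    trainer: Callable[[Sequence[tuple[Document, GoldAnnotationSet]]], object],
    scorer: Callable[[object, Sequence[tuple[Document, GoldAnnotationSet]]], PRF],
    config: CVConfig | None = None,
) -> CVResult:
    """Repeated k-fold cross-validation with splits at document level.

    Each repeat reshuffles documents with a seed derived from the config
    seed, partitions them into ``folds`` test folds, trains on the
    complement and scores on the fold.  The result aggregates mean and
    standard deviation over all fold x repeat scores.
    """
    config = config or CVConfig()
    n = len(corpus)
    if config.folds > n:
        raise ValueError(f"folds ({config.folds}) exceed corpus size ({n})")
    result = CVResult()
    for rep in range(config.repeats):
        rng = random.Random(config.seed * 100003 + rep)
        order = list(range(n))
        rng.shuffle(order)
        folds: list[list[int]] = [[] for _ in range(config.folds)]
        for pos, idx in enumerate(order):
            folds[pos % config.folds].append(idx)
        for fold in folds:
            test = [corpus[i] for i in fold]
            train_set = [corpus[i] for i in range(n) if i not in set(fold)]
            model = trainer(train_set)
            result.scores.append(scorer(model, test))
    return result
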