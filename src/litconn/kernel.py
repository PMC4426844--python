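"""Shallow linguistic relation classifier for region pairs.

Classifies whether a sentence states a connection between two region
mentions using only shallow information: token/stem n-grams (n <= 3) over
the fore-between, between and between-after windows of the pair (global
context), plus surface/stem/POS/shape of the +/-2 tokens around each
mention (local context).  Mention tokens are masked by a placeholder, so
the feature map is invariant to the specific region names.  The model is
an explicit sparse feature map with a linear (logistic) classifier, which
keeps training deterministic and probabilities calibrated by the usual
logistic link.

:class:`KernelRelationClassifier` is a scikit-learn style estimator;
:func:`kernel_train` / :func:`kernel_predict` are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus import Sentence
from .crf import _shape  # orthographic shape shared with the CRF features
from .extractors import CandidatePair

__all__ = [
    "KernelConfig",
    "kernel_featurize",
    "KernelRelationClassifier",
    "kernel_train",
    "kernel_predict",
]

_ENTITY = "__ENTITY__"


@dataclass
class KernelConfig:
    C: float = 1.0
    threshold: float = 0.5
    ngram_max: int = 3
    local_window: int = 2
    seed: int = 0
    max_iter: int = 1000


def _masked_tokens(sentence: Sentence, pair: CandidatePair) -> list[tuple[str, str, str, str]]:
    """(word, stem, pos, shape) per token with pair mentions masked."""
    spans = (pair.mention_a.span, pair.mention_b.span)
    out = []
    prev_masked = False
    for tok in sentence.tokens:
        inside = any(s.start <= tok.span.start < s.end for s in spans)
        if inside:
            if not prev_masked:  # collapse a multi-token mention to one mask
                out.append((_ENTITY, _ENTITY, _ENTITY, _ENTITY))
            prev_masked = True
        else:
            out.append(
                (tok.surface.lower(), tok.stem, tok.pos, _shape(tok.surface))
            )
            prev_masked = False
    return out


def _mask_index(sentence: Sentence, pair: CandidatePair, which: int) -> int:
    """Index of the mask token for mention `which` in the masked stream."""
    spans = (pair.mention_a.span, pair.mention_b.span)
    target = spans[which]
    idx = -1
    prev_masked = False
    for tok in sentence.tokens:
        inside = any(s.start <= tok.span.start < s.end for s in spans)
        if inside:
            if not prev_masked:
                idx += 1
                if target.start <= tok.span.start < target.end:
                    return idx
            prev_masked = True
        else:
            idx += 1
            prev_masked = False
    raise ValueError("pair mentions not found in sentence")


def kernel_featurize(
    sentence: Sentence, pair: CandidatePair, config: KernelConfig | None = None
) -> dict[str, float]:
    """Sparse feature map for one candidate pair."""
    config = config or KernelConfig()
    toks = _masked_tokens(sentence, pair)
    ia = _mask_index(sentence, pair, 0)
    ib = _mask_index(sentence, pair, 1)
    feats: dict[str, float] = {}

    def add(name: str) -> None:
        feats[name] = feats.get(name, 0.0) + 1.0

    def ngrams(prefix: str, seq: list[tuple[str, str, str, str]]) -> None:
        words = [t[0] for t in seq]
        stems = [t[1] for t in seq]
        for n in range(1, config.ngram_max + 1):
            for k in range(len(seq) - n + 1):
                add(f"{prefix}:w:{'_'.join(words[k : k + n])}")
                add(f"{prefix}:s:{'_'.join(stems[k : k + n])}")

    # Global context windows (mentions included as masks)
    ngrams("FB", toks[: ib + 1])          # fore-between
    ngrams("B", toks[ia : ib + 1])        # between
    ngrams("BA", toks[ia:])               # between-after

    # Local context windows around each mention
    for label, center in (("L1", ia), ("L2", ib)):
        for off in range(-config.local_window, config.local_window + 1):
            if off == 0:
                continue
            j = center + off
            if 0 <= j < len(toks):
                w, s, p, sh = toks[j]
            else:
                w = s = p = sh = "__BOS__" if j < 0 else "__EOS__"
            add(f"{label}[{off}]:w:{w}")
            add(f"{label}[{off}]:s:{s}")
            add(f"{label}[{off}]:p:{p}")
            add(f"{label}[{off}]:sh:{sh}")
    return feats


class KernelRelationClassifier(BaseEstimator, ClassifierMixin):
    """Binary connected/not-connected classifier over candidate pairs.

    ``fit`` takes a list of ``(sentence, pair)`` instances with binary
    labels; ``predict_proba_pairs`` returns connection probabilities.
    """

    def __init__(
        self,
        C: float = 1.0,
        threshold: float = 0.5,
        ngram_max: int = 3,
        local_window: int = 2,
        seed: int = 0,
        max_iter: int = 1000,
    ):
        self.C = C
        self.threshold = threshold
        self.ngram_max = ngram_max
        self.local_window = local_window
        self.seed = seed
        self.max_iter = max_iter

    def _config(self) -> KernelConfig:
        return KernelConfig(
            C=self.C,
            threshold=self.threshold,
            ngram_max=self.ngram_max,
            local_window=self.local_window,
            seed=self.seed,
            max_iter=self.max_iter,
        )

    def fit(self, instances: Sequence[tuple[Sentence, CandidatePair]], y):
        y = np.asarray(y, dtype=int)
        if len(instances) != len(y):
            raise ValueError("instances and labels differ in length")
        cfg = self._config()
        maps = [kernel_featurize(s, p, cfg) for s, p in instances]
        self.vectorizer_ = DictVectorizer()
        X = self.vectorizer_.fit_transform(maps)
        self.model_ = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.seed
        )
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise ValueError("KernelRelationClassifier is not fitted")

    def predict_proba_pairs(
        self, instances: Sequence[tuple[Sentence, CandidatePair]]
    ) -> np.ndarray:
        self._check_fitted()
        cfg = self._config()
        maps = [kernel_featurize(s, p, cfg) for s, p in instances]
        X = self.vectorizer_.transform(maps)
        proba = self.model_.predict_proba(X)
        pos = list(self.model_.classes_).index(1)
        return proba[:, pos]

    def predict(self, instances: Sequence[tuple[Sentence, CandidatePair]]) -> np.ndarray:
        return (self.predict_proba_pairs(instances) >= self.threshold).astype(int)


def kernel_train(
    labeled: Sequence[tuple[Sentence, CandidatePair, int]],
    config: KernelConfig | None = None,
) -> KernelRelationClassifier:
    config = config or KernelConfig()
    model = KernelRelationClassifier(
        C=config.C,
        threshold=config.threshold,
        ngram_max=config.ngram_max,
        local_window=config.local_window,
        seed=config.seed,
        max_iter=config.max_iter,
    )
    instances = [(s, p) for s, p, _ in labeled]
    y = [lab for _, _, lab in labeled]
    return model.fit(instances, y)


def kernel_predict(
    model: KernelRelationClassifier, sentence: Sentence, pair: CandidatePair
) -> float:
    """Connection probability for one pair."""
    return float(model.predict_proba_pairs([(sentence, pair)])[0])
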