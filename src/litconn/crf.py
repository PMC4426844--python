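"""Trainable brain-region NER: linear-chain CRF over BIO tags.

The sequence model scores per-token feature vectors plus first-order label
transitions and is trained by maximizing the L2-penalized conditional
log-likelihood with L-BFGS; decoding is Viterbi.  Feature families cover
token identity/stem/POS, orthographic shape, length, lexicon membership,
directionality words (dorsal, ventral, ...), a +/-2 token context window,
and document/sentence-level signals that matter on full text: species
presence, measure entities ("10 mm", "10(-7) molar") and
citation/table-like boilerplate.

:class:`CRFTagger` follows the scikit-learn estimator protocol
(``get_params``/``set_params``, fitted attributes with a trailing
underscore); :func:`train` / :func:`predict` are thin wrappers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .corpus import Document, GoldAnnotationSet, Sentence, TextSpan
from .lexicon import Lexicon
from .lexical_ner import Mention, TermMatcher

__all__ = [
    "DIRECTIONALITY_WORDS",
    "SPECIES_GAZETTEER",
    "FeatureResources",
    "TrainConfig",
    "detect_measures",
    "detect_boilerplate",
    "featurize",
    "spans_to_bio",
    "bio_to_spans",
    "CRFTagger",
    "train",
    "predict",
    "normalize_mentions",
]

TEMPLATE_VERSION = "1"

DIRECTIONALITY_WORDS = frozenset(
    {
        "dorsal", "ventral", "lateral", "medial", "anterior", "posterior",
        "rostral", "caudal", "superior", "inferior", "central", "basal",
        "contralateral", "ipsilateral", "proximal", "distal",
    }
)

#: Small species gazetteer; only document-level presence is needed.
SPECIES_GAZETTEER = frozenset(
    {
        "rat", "rats", "mouse", "mice", "macaque", "macaques", "cat", "cats",
        "human", "humans", "monkey", "monkeys", "rattus", "mus", "ferret",
        "primate", "primates",
    }
)

_UNITS = frozenset(
    {
        "mm", "cm", "nm", "um", "µm", "m", "ml", "ul", "µl", "l",
        "mg", "ug", "µg", "kg", "g", "ms", "s", "min", "h", "hz", "khz",
        "molar", "m", "mm", "nm", "mv", "na", "pa", "%",
    }
)
_MOLAR_UNITS = frozenset({"molar", "m", "mm", "nm", "um", "µm", "pm"})


def _is_number_token(surface: str) -> bool:
    return surface.isdigit()


def detect_measures(sentence: Sentence) -> list[TextSpan]:
    """Spans of number+unit measures, including parenthesized exponents.

    Handles plain quantities ("10 mm", "0.5 ml"), scientific notation with
    a parenthesized exponent ("10(-7) molar") and caret exponents
    ("10^-3 M").
    """
    toks = sentence.tokens
    n = len(toks)
    spans: list[TextSpan] = []
    i = 0
    while i < n:
        if not _is_number_token(toks[i].surface):
            i += 1
            continue
        start = toks[i].span.start
        j = i + 1
        # decimal point:  "0" "." "5"
        while (
            j + 1 < n
            and toks[j].surface == "."
            and _is_number_token(toks[j + 1].surface)
        ):
            j += 2
        # parenthesized or caret exponent: "(" "-" "7" ")"  /  "^" "-" "3"
        if j < n and toks[j].surface in {"(", "^"}:
            k = j + 1
            if k < n and toks[k].surface in {"-", "+"}:
                k += 1
            if k < n and _is_number_token(toks[k].surface):
                k += 1
                if toks[j].surface == "(" and k < n and toks[k].surface == ")":
                    k += 1
                    j = k
                elif toks[j].surface == "^":
                    j = k
        # unit token
        if j < n and toks[j].surface.lower() in (_UNITS | _MOLAR_UNITS):
            spans.append(TextSpan(sentence.doc_id, start, toks[j].span.end))
            i = j + 1
            continue
        # bare exponent consumed (e.g. "10(-7)") without a unit: not a measure
        i += 1
    return spans


_FUNCTION_WORDS = frozenset(
    {
        "the", "a", "an", "of", "in", "to", "and", "or", "is", "are", "was",
        "were", "that", "this", "with", "from", "by", "for", "as", "on", "at",
    }
)


def detect_boilerplate(sentence: Sentence, digit_density_threshold: float = 0.4) -> set[str]:
    """Flags {citation_like, table_like} for bibliography/table boilerplate."""
    toks = sentence.tokens
    flags: set[str] = set()
    if not toks:
        return flags
    chars = "".join(t.surface for t in toks)
    digit_density = sum(c.isdigit() for c in chars) / max(1, len(chars))
    if digit_density >= digit_density_threshold:
        flags.add("table_like")
    words = [t for t in toks if t.surface[0].isalnum()]
    if words:
        fw_ratio = sum(t.surface.lower() in _FUNCTION_WORDS for t in words) / len(words)
        if len(words) >= 6 and fw_ratio < 0.08 and digit_density > 0.15:
            flags.add("table_like")
    # author-year: capitalized word within 3 tokens before a plausible year
    for i, t in enumerate(toks):
        s = t.surface
        if s.isdigit() and len(s) == 4 and 1800 <= int(s) <= 2099:
            window = toks[max(0, i - 4) : i]
            if any(w.surface[0].isupper() and w.surface.isalpha() for w in window):
                flags.add("citation_like")
                break
        if s.lower() == "al" and i > 0 and toks[i - 1].surface.lower() == "et":
            flags.add("citation_like")
            break
    return flags


@dataclass
class FeatureResources:
    """Static resources consulted by the feature extractor."""

    lexicon: Lexicon | None = None
    directionality: frozenset[str] = DIRECTIONALITY_WORDS
    species: frozenset[str] = SPECIES_GAZETTEER
    _lexicon_stems: frozenset[str] | None = None
    _lexicon_index: TermMatcher | None = None

    def lexicon_stems(self) -> frozenset[str]:
        if self._lexicon_stems is None:
            stems: set[str] = set()
            if self.lexicon is not None:
                if self._lexicon_index is None:
                    self._lexicon_index = TermMatcher(self.lexicon)
                for key in self._lexicon_index.index:
                    stems.update(key)
            self._lexicon_stems = frozenset(stems)
        return self._lexicon_stems


def _shape(surface: str) -> str:
    out = []
    for ch in surface:
        if ch.isupper():
            c = "A"
        elif ch.islower():
            c = "a"
        elif ch.isdigit():
            c = "0"
        else:
            c = "-"
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def species_present(document: Document, resources: FeatureResources) -> bool:
    for sent in document.sentences:
        for tok in sent.tokens:
            if tok.surface.lower() in resources.species:
                return True
    return False


def featurize(
    sentence: Sentence,
    document: Document,
    resources: FeatureResources,
    doc_species: bool | None = None,
) -> list[list[str]]:
    """One binary-feature list per token.

    Document-level flags (species presence) are identical for every token
    of a document; pass ``doc_species`` to avoid recomputation.
    """
    if doc_species is None:
        doc_species = species_present(document, resources)
    lex_stems = resources.lexicon_stems()
    measure_spans = detect_measures(sentence)
    boiler = detect_boilerplate(sentence)
    toks = sentence.tokens
    feats_per_token: list[list[str]] = []
    for i, tok in enumerate(toks):
        low = tok.surface.lower()
        f = [
            "bias",
            f"w={low}",
            f"stem={tok.stem}",
            f"pos={tok.pos}",
            f"shape={_shape(tok.surface)}",
            f"len={min(len(tok.surface), 10)}",
        ]
        if tok.surface.isdigit():
            f.append("is_number")
        if tok.surface.isupper() and len(tok.surface) > 1:
            f.append("all_caps")
        if tok.surface[0].isupper():
            f.append("init_cap")
        if low in resources.directionality:
            f.append("directionality")
        if tok.stem in lex_stems:
            f.append("in_lexicon")
        if any(m.start <= tok.span.start < m.end for m in measure_spans):
            f.append("in_measure")
        for flag in sorted(boiler):
            f.append(f"sent_{flag}")
        if doc_species:
            f.append("doc_species")
        for off in (-2, -1, 1, 2):
            j = i + off
            if 0 <= j < len(toks):
                f.append(f"w[{off}]={toks[j].surface.lower()}")
                f.append(f"pos[{off}]={toks[j].pos}")
            else:
                f.append(f"w[{off}]={'__BOS__' if j < 0 else '__EOS__'}")
        feats_per_token.append(f)
    return feats_per_token


# ---------------------------------------------------------------------------
# BIO encoding
# ---------------------------------------------------------------------------

LABELS = ("B", "I", "O")
_LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}


def spans_to_bio(sentence: Sentence, spans: Sequence[TextSpan]) -> list[str]:
    """Encode entity spans as per-token B/I/O labels.

    Spans not aligned to token boundaries are snapped outward to the
    covering tokens.
    """
    labels = ["O"] * len(sentence.tokens)
    for span in sorted(spans, key=lambda s: (s.start, s.end)):
        covered = [
            i
            for i, tok in enumerate(sentence.tokens)
            if tok.span.start < span.end and span.start < tok.span.end
        ]
        if not covered:
            continue
        labels[covered[0]] = "B"
        for i in covered[1:]:
            labels[i] = "I"
    return labels


def bio_to_spans(sentence: Sentence, labels: Sequence[str]) -> list[TextSpan]:
    """Decode maximal B/I runs back to character spans."""
    spans: list[TextSpan] = []
    start_tok: int | None = None
    for i, lab in enumerate(labels):
        if lab == "B":
            if start_tok is not None:
                spans.append(_tok_span(sentence, start_tok, i - 1))
            start_tok = i
        elif lab == "I":
            if start_tok is None:  # orphan I starts a span
                start_tok = i
        else:
            if start_tok is not None:
                spans.append(_tok_span(sentence, start_tok, i - 1))
                start_tok = None
    if start_tok is not None:
        spans.append(_tok_span(sentence, start_tok, len(labels) - 1))
    return spans


def _tok_span(sentence: Sentence, i: int, j: int) -> TextSpan:
    return TextSpan(
        sentence.doc_id, sentence.tokens[i].span.start, sentence.tokens[j].span.end
    )


# ---------------------------------------------------------------------------
# Linear-chain CRF
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    l2: float = 1.0
    max_iter: int = 100
    seed: int = 0
    template_version: str = TEMPLATE_VERSION


class CRFTagger(BaseEstimator):
    """Linear-chain CRF for BIO brain-region tagging.

    Parameters
    ----------
    l2 : float
        L2 penalty weight on all parameters.
    max_iter : int
        L-BFGS iteration cap.
    seed : int
        Recorded for provenance; optimization itself is deterministic
        (zero initialization).
    template_version : str
        Version tag of the feature template; predict refuses a mismatch.
    """

    def __init__(
        self,
        l2: float = 1.0,
        max_iter: int = 100,
        seed: int = 0,
        template_version: str = TEMPLATE_VERSION,
        resources: FeatureResources | None = None,
    ):
        self.l2 = l2
        self.max_iter = max_iter
        self.seed = seed
        self.template_version = template_version
        self.resources = resources

    # -- data preparation ---------------------------------------------------

    def _resources(self) -> FeatureResources:
        return self.resources if self.resources is not None else FeatureResources()

    def _gold_labels(self, document: Document, gold: GoldAnnotationSet) -> list[list[str]]:
        spans = [s for s, _label in gold.entities]
        return [spans_to_bio(sent, spans) for sent in document.sentences]

    def _build_matrix(
        self, seqs: list[list[list[str]]], grow: bool
    ) -> tuple[sp.csr_matrix, list[tuple[int, int]]]:
        """Stack per-token feature lists into one CSR matrix.

        Returns the matrix and (start, stop) row ranges per sentence.
        """
        indptr = [0]
        indices: list[int] = []
        ranges = []
        row = 0
        for seq in seqs:
            start = row
            for feats in seq:
                for name in feats:
                    idx = self.feature_index_.get(name)
                    if idx is None and grow:
                        idx = len(self.feature_index_)
                        self.feature_index_[name] = idx
                    if idx is not None:
                        indices.append(idx)
                indptr.append(len(indices))
                row += 1
            ranges.append((start, row))
        n_feat = len(self.feature_index_)
        data = np.ones(len(indices), dtype=np.float64)
        mat = sp.csr_matrix(
            (data, np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
            shape=(row, n_feat),
        )
        return mat, ranges

    # -- objective ----------------------------------------------------------

    @staticmethod
    def _pad_batch(unary_all: np.ndarray, ranges) -> tuple[np.ndarray, np.ndarray]:
        """Pad per-sentence unary scores into an (S, T_max, K) batch."""
        lengths = np.asarray([stop - start for start, stop in ranges])
        S, T_max, K = len(ranges), int(lengths.max()), unary_all.shape[1]
        unary = np.full((S, T_max, K), -np.inf)
        for s, (start, stop) in enumerate(ranges):
            unary[s, : stop - start] = unary_all[start:stop]
        return unary, lengths

    @staticmethod
    def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
        m = np.max(a, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        out = np.log(np.sum(np.exp(a - m), axis=axis)) + np.squeeze(m, axis=axis)
        return out

    def _batch_forward_backward(self, unary: np.ndarray, lengths: np.ndarray, trans):
        """Vectorized forward/backward over a padded sentence batch.

        Returns (log Z per sentence, token marginals, summed expected
        transition counts).  Padding rows hold -inf unary scores and are
        masked out of the marginals.
        """
        S, T_max, K = unary.shape
        alpha = np.zeros((S, T_max, K))
        beta = np.zeros((S, T_max, K))
        alpha[:, 0] = unary[:, 0]
        for t in range(1, T_max):
            active = lengths > t
            if not active.any():
                break
            prev = alpha[active, t - 1][:, :, None] + trans[None, :, :]
            alpha[active, t] = unary[active, t] + self._logsumexp(prev, axis=1)
        # beta[s, len-1] = 0 by initialization
        for t in range(T_max - 2, -1, -1):
            active = lengths > t + 1
            if not active.any():
                continue
            nxt = (unary[active, t + 1] + beta[active, t + 1])[:, None, :]
            beta[active, t] = self._logsumexp(trans[None, :, :] + nxt, axis=2)
        last = np.clip(lengths - 1, 0, None)
        log_z = self._logsumexp(alpha[np.arange(S), last], axis=1)
        with np.errstate(invalid="ignore"):
            marg = np.exp(alpha + beta - log_z[:, None, None])
        token_mask = np.arange(T_max)[None, :] < lengths[:, None]
        marg[~token_mask] = 0.0
        pair = np.zeros((K, K))
        for t in range(1, T_max):
            active = lengths > t
            if not active.any():
                break
            lp = (
                alpha[active, t - 1][:, :, None]
                + trans[None, :, :]
                + (unary[active, t] + beta[active, t])[:, None, :]
                - log_z[active][:, None, None]
            )
            pair += np.exp(lp).sum(axis=0)
        return log_z, marg, pair

    def _nll_grad(self, params, X, ranges, y_idx):
        K = len(LABELS)
        F = X.shape[1]
        W = params[: F * K].reshape(F, K)
        trans = params[F * K :].reshape(K, K)
        unary_all = X @ W
        unary, lengths = self._pad_batch(unary_all, ranges)
        log_z, marg, pair = self._batch_forward_backward(unary, lengths, trans)
        # gold path score and observed statistics
        gold_score = unary_all[np.arange(len(y_idx)), y_idx].sum()
        obs_trans = np.zeros((K, K))
        for s, (start, stop) in enumerate(ranges):
            y = y_idx[start:stop]
            gold_score += trans[y[:-1], y[1:]].sum()
            np.add.at(obs_trans, (y[:-1], y[1:]), 1.0)
        nll = float(log_z.sum() - gold_score)
        # flatten padded marginals back to token rows
        marg_all = np.empty_like(unary_all)
        for s, (start, stop) in enumerate(ranges):
            marg_all[start:stop] = marg[s, : stop - start]
        obs_onehot = np.zeros_like(marg_all)
        obs_onehot[np.arange(len(y_idx)), y_idx] = 1.0
        grad_W = X.T @ (marg_all - obs_onehot)
        grad_trans = pair - obs_trans
        nll += 0.5 * self.l2 * float(params @ params)
        grad = np.concatenate([np.asarray(grad_W).ravel(), grad_trans.ravel()])
        grad += self.l2 * params
        return nll, grad

    # -- estimator API ------------------------------------------------------

    def fit(self, corpus: Sequence[tuple[Document, GoldAnnotationSet]], y=None):
        """Fit on (document, gold annotations) pairs; documents must be segmented."""
        if len(corpus) == 0:
            raise ValueError("empty training corpus")
        self.feature_index_: dict[str, int] = {}
        resources = self._resources()
        seqs: list[list[list[str]]] = []
        labels: list[int] = []
        for document, gold in corpus:
            doc_species = species_present(document, resources)
            gold_bio = self._gold_labels(document, gold)
            for sent, sent_labels in zip(document.sentences, gold_bio):
                if not sent.tokens:
                    continue
                seqs.append(featurize(sent, document, resources, doc_species))
                labels.extend(_LABEL_INDEX[lab] for lab in sent_labels)
        X, ranges = self._build_matrix(seqs, grow=True)
        y_idx = np.asarray(labels, dtype=np.int64)
        K = len(LABELS)
        x0 = np.zeros(X.shape[1] * K + K * K)
        result = scipy.optimize.minimize(
            self._nll_grad,
            x0,
            args=(X, ranges, y_idx),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": 1e-8},
        )
        F = X.shape[1]
        self.weights_ = result.x[: F * K].reshape(F, K)
        self.transitions_ = result.x[F * K :].reshape(K, K)
        self.classes_ = list(LABELS)
        self.n_iter_ = int(result.nit)
        self.template_version_ = self.template_version
        return self

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise ValueError("CRFTagger is not fitted")

    def _viterbi(self, unary: np.ndarray) -> list[int]:
        T, K = unary.shape
        delta = unary[0].copy()
        back = np.zeros((T, K), dtype=np.int64)
        for t in range(1, T):
            scores = delta[:, None] + self.transitions_
            back[t] = np.argmax(scores, axis=0)
            delta = unary[t] + np.max(scores, axis=0)
        path = [int(np.argmax(delta))]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return path

    def predict_labels(self, document: Document) -> list[list[str]]:
        """BIO label sequence per sentence."""
        self._check_fitted()
        if self.template_version != self.template_version_:
            raise ValueError(
                f"feature template mismatch: model {self.template_version_!r} "
                f"vs tagger {self.template_version!r}"
            )
        resources = self._resources()
        doc_species = species_present(document, resources)
        out: list[list[str]] = []
        for sent in document.sentences:
            if not sent.tokens:
                out.append([])
                continue
            seq = featurize(sent, document, resources, doc_species)
            X, _ = self._build_matrix([seq], grow=False)
            unary = np.asarray(X @ self.weights_)
            path = self._viterbi(unary)
            out.append([LABELS[k] for k in path])
        return out

    def predict(self, document: Document) -> list[Mention]:
        """Decode mentions (source="crf", region_id=None)."""
        mentions: list[Mention] = []
        for sent, labels in zip(document.sentences, self.predict_labels(document)):
            for span in bio_to_spans(sent, labels):
                mentions.append(
                    Mention(
                        span=span,
                        surface=document.text[span.start : span.end],
                        region_id=None,
                        source="crf",
                        matched_via=None,
                        lexicon_tag="",
                    )
                )
        return mentions

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self._check_fitted()
        payload = {
            "format": "litconn-crf",
            "template_version": self.template_version_,
            "l2": self.l2,
            "max_iter": self.max_iter,
            "seed": self.seed,
            "labels": list(LABELS),
            "feature_index": self.feature_index_,
            "weights": self.weights_.tolist(),
            "transitions": self.transitions_.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, resources: FeatureResources | None = None) -> "CRFTagger":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "litconn-crf":
            raise ValueError(f"{path}: not a CRF model file")
        model = cls(
            l2=payload["l2"],
            max_iter=payload["max_iter"],
            seed=payload["seed"],
            template_version=payload["template_version"],
            resources=resources,
        )
        model.feature_index_ = {k: int(v) for k, v in payload["feature_index"].items()}
        model.weights_ = np.asarray(payload["weights"], dtype=np.float64)
        model.transitions_ = np.asarray(payload["transitions"], dtype=np.float64)
        model.classes_ = payload["labels"]
        model.template_version_ = payload["template_version"]
        return model


def train(
    corpus: Sequence[tuple[Document, GoldAnnotationSet]],
    config: TrainConfig | None = None,
    resources: FeatureResources | None = None,
) -> CRFTagger:
    config = config or TrainConfig()
    tagger = CRFTagger(
        l2=config.l2,
        max_iter=config.max_iter,
        seed=config.seed,
        template_version=config.template_version,
        resources=resources,
    )
    return tagger.fit(corpus)


def predict(model: CRFTagger, document: Document) -> list[Mention]:
    return model.predict(document)


def normalize_mentions(mentions: Iterable[Mention], lexicon: Lexicon) -> list[Mention]:
    """Optional dictionary normalization of CRF mentions (off by default
    in the pipeline): look the mention surface up in the lexicon and attach
    the region id when it resolves."""
    out = []
    for m in mentions:
        if m.region_id is None:
            rid = lexicon.lookup(m.surface)
            if rid is not None:
                m = Mention(
                    span=m.span,
                    surface=m.surface,
                    region_id=rid,
                    source=m.source,
                    matched_via=m.matched_via,
                    lexicon_tag=lexicon.name,
                )
        out.append(m)
    return out
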