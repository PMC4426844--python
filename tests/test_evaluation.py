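"""Scoring: strict/lenient span matching, relation PRF, cross-validation."""

import random

import pytest
from oracles import oracle_match_spans, oracle_score_relations

from litconn.corpus import TextSpan
from litconn.evaluation import CVConfig, PRF, cross_validate, match_spans, score_relations


def _span(s, e, d="d"):
    return TextSpan(d, s, e)


class TestMatchSpans:
    def test_contained_prediction_lenient_only(self):
        prf_s = match_spans([_span(10, 25)], [_span(5, 30)], "strict")
        assert (prf_s.tp, prf_s.fp, prf_s.fn) == (0, 1, 1)
        prf_l = match_spans([_span(10, 25)], [_span(5, 30)], "lenient")
        assert (prf_l.tp, prf_l.fp, prf_l.fn) == (1, 0, 0)

    def test_identical_span_matches_both_modes(self):
        for mode in ("strict", "lenient"):
            prf = match_spans([_span(3, 9)], [_span(3, 9)], mode)
            assert (prf.tp, prf.fp, prf.fn) == (1, 0, 0)

    def test_containing_prediction_fails_both_modes(self):
        for mode in ("strict", "lenient"):
            prf = match_spans([_span(5, 35)], [_span(10, 30)], mode)
            assert (prf.tp, prf.fp, prf.fn) == (0, 1, 1)

    def test_each_gold_credits_one_prediction(self):
        prf = match_spans([_span(10, 15), _span(16, 20)], [_span(5, 30)], "lenient")
        assert (prf.tp, prf.fp, prf.fn) == (1, 1, 0)

    def test_cross_document_comparison_errors(self):
        with pytest.raises(ValueError, match="cross-document"):
            match_spans([_span(0, 5, "a")], [_span(0, 5, "b")])

    def test_random_instances_match_bipartite_oracle(self):
        rng = random.Random(19)
        for _ in range(500):
            gold, pos = [], 0
            for _ in range(rng.randint(0, 6)):
                s = pos + rng.randint(1, 10)
                e = s + rng.randint(1, 12)
                gold.append((s, e))
                pos = e
            pred = []
            for _ in range(rng.randint(0, 8)):
                if gold and rng.random() < 0.6:
                    gs, ge = rng.choice(gold)
                    s = gs + rng.randint(0, max(0, ge - gs - 1))
                    e = min(ge, s + rng.randint(1, ge - s)) if ge > s else ge
                    pred.append((s, max(e, s + 1)))
                else:
                    s = rng.randint(0, 120)
                    pred.append((s, s + rng.randint(1, 15)))
            for mode in ("strict", "lenient"):
                prf = match_spans(
                    [_span(*p) for p in pred], [_span(*g) for g in gold], mode
                )
                tp, fp, fn = oracle_match_spans(sorted(pred), gold, mode)
                assert (prf.tp, prf.fp, prf.fn) == (tp, fp, fn)
                assert prf.tp + prf.fn == len(gold)
                assert prf.tp + prf.fp == len(pred)

    def test_lenient_dominates_strict(self):
        rng = random.Random(29)
        for _ in range(200):
            gold = [(i * 20, i * 20 + rng.randint(5, 15)) for i in range(rng.randint(1, 5))]
            pred = []
            for gs, ge in gold:
                if rng.random() < 0.7:
                    s = gs + rng.randint(0, 3)
                    pred.append((s, max(s + 1, ge - rng.randint(0, 3))))
            pred.append((300, 310))
            strict = match_spans([_span(*p) for p in pred], [_span(*g) for g in gold], "strict")
            lenient = match_spans([_span(*p) for p in pred], [_span(*g) for g in gold], "lenient")
            assert lenient.precision >= strict.precision
            assert lenient.recall >= strict.recall


class TestScoreRelations:
    def test_all_pairs_baseline_has_perfect_recall(self):
        gold = [frozenset((_span(0, 5), _span(10, 15))),
                frozenset((_span(10, 15), _span(20, 25)))]
        all_pairs = gold + [frozenset((_span(0, 5), _span(20, 25)))]
        prf = score_relations(all_pairs, gold)
        assert prf.recall == 1.0
        assert prf.tp == 2 and prf.fp == 1

    def test_zero_predictions(self):
        gold = [frozenset((_span(0, 5), _span(10, 15)))]
        prf = score_relations([], gold)
        assert prf.precision == 0.0 and prf.recall == 0.0 and prf.fn == 1

    def test_random_subsets_match_count_oracle(self):
        rng = random.Random(37)
        for _ in range(200):
            universe = [
                frozenset((_span(i * 10, i * 10 + 3), _span(j * 10, j * 10 + 3)))
                for i in range(6) for j in range(i + 1, 6)
            ]
            gold = [p for p in universe if rng.random() < 0.4]
            pred = [p for p in universe if rng.random() < 0.4]
            prf = score_relations(pred, gold)
            tp, fp, fn = oracle_score_relations(pred, gold)
            assert (prf.tp, prf.fp, prf.fn) == (tp, fp, fn)


class _MemorizingTrainer:
    """Degenerate trainer: predicts exactly the surfaces seen in training."""

    def __init__(self, train):
        self.vocab = {
            doc.text[s.start:s.end] for doc, gold in train for s, _ in gold.entities
        }

    def predict(self, doc):
        out = []
        for surface in self.vocab:
            i = doc.text.find(surface)
            if i >= 0:
                out.append(TextSpan(doc.id, i, i + len(surface)))
        return out


class TestCrossValidate:
    def _corpus(self, n=16, disjoint=False):
        from litconn.corpus import Document, GoldAnnotationSet, segment_and_tokenize

        corpus = []
        for i in range(n):
            word = f"region{'x' * (i + 1)}" if disjoint else "regionalpha"
            text = f"The {word} was examined carefully."
            doc = segment_and_tokenize(
                Document(id=f"c{i}", source_class="abstract", text=text)
            )
            s = text.index(word)
            gold = GoldAnnotationSet(
                doc_id=doc.id, entities=[(TextSpan(doc.id, s, s + len(word)), "REGION")]
            )
            corpus.append((doc, gold))
        return corpus

    @staticmethod
    def _scorer(model, test):
        total = PRF(0, 0, 0)
        for doc, gold in test:
            total = total + match_spans(
                model.predict(doc), [s for s, _ in gold.entities], "strict"
            )
        return total

    def test_fold_sizes_and_partition(self):
        corpus = self._corpus(16)
        seen = []

        def trainer(train):
            seen.append(len(train))
            return _MemorizingTrainer(train)

        result = cross_validate(
            corpus, trainer, self._scorer, CVConfig(folds=8, repeats=1, seed=0)
        )
        assert len(result.scores) == 8
        assert seen == [14] * 8  # every test fold holds exactly 2 documents

    def test_same_seed_reproduces_scores(self):
        corpus = self._corpus(12)
        cfg = CVConfig(folds=4, repeats=2, seed=5)
        r1 = cross_validate(corpus, _MemorizingTrainer, self._scorer, cfg)
        r2 = cross_validate(corpus, _MemorizingTrainer, self._scorer, cfg)
        assert [(s.tp, s.fp, s.fn) for s in r1.scores] == [
            (s.tp, s.fp, s.fn) for s in r2.scores
        ]

    def test_memorizer_on_disjoint_vocabulary_scores_zero(self):
        corpus = self._corpus(8, disjoint=True)
        result = cross_validate(
            corpus, _MemorizingTrainer, self._scorer,
            CVConfig(folds=4, repeats=1, seed=1),
        )
        mean_f1, _sd = result.f1
        assert mean_f1 == 0.0

    def test_too_many_folds_errors(self):
        with pytest.raises(ValueError, match="folds"):
            cross_validate(
                self._corpus(4), _MemorizingTrainer, self._scorer,
                CVConfig(folds=8, repeats=1),
            )
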