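"""Relation extractors: pair enumeration, filter cascade, rules, ensembles."""

import itertools
import random

import pytest
from oracles import oracle_ensemble, oracle_filters, oracle_nearest_neighbor

from litconn.abbrev import detect_definitions, expand
from litconn.corpus import Document, TextSpan, segment_and_tokenize
from litconn.extractors import (
    ConnectivityStatement,
    FilterConfig,
    enumerate_pairs,
    ensemble,
    filters_extract,
    load_rules,
    make_pair,
    nearest_neighbor_pairs,
    parse_rule,
    rules_extract,
)
from litconn.lexical_ner import Mention, match


def _doc(text, doc_id="d"):
    return segment_and_tokenize(Document(id=doc_id, source_class="abstract", text=text))


def _mention(doc_id, start, end, rid="R"):
    return Mention(
        span=TextSpan(doc_id, start, end), surface="x" * (end - start),
        region_id=rid, source="lexical",
    )


def _layout(doc_id, spans):
    return [_mention(doc_id, s, e, f"R{i}") for i, (s, e) in enumerate(spans)]


def _fake_sentence(doc_id, length):
    doc = _doc("x" * length, doc_id)
    return doc, doc.sentences[0]


class TestEnumeratePairs:
    @pytest.mark.parametrize("n,expected", [(1, 0), (2, 1), (3, 3), (7, 21)])
    def test_pair_counts(self, n, expected):
        doc, sent = _fake_sentence("d", 10 * n + 10)
        mentions = _layout("d", [(i * 10, i * 10 + 4) for i in range(n)])
        pairs = enumerate_pairs(sent, mentions)
        assert len(pairs) == expected
        for p in pairs:
            assert p.mention_a.span.start < p.mention_b.span.start


class TestFilters:
    def test_worked_sentence_keeps_chain_pairs(self, worked):
        docs, lex, _ = worked
        doc = docs[0]
        aliases = expand(doc, detect_definitions(doc))
        ms = match(doc, lex, aliases)
        sent = doc.sentences[0]
        out = filters_extract(doc, sent, enumerate_pairs(sent, ms))
        got = {tuple(sorted(s.pair.region_ids())) for s in out}
        assert got == {("WE:AC", "WE:SN"), ("WE:SN", "WE:VTA")}

    def test_long_sentence_removes_all_pairs(self):
        text = "projections " + "x" * 600
        doc, sent = _doc(text), None
        sent = doc.sentences[0]
        mentions = _layout("d", [(0, 5), (20, 28)])
        assert filters_extract(doc, sent, enumerate_pairs(sent, mentions)) == []

    def test_eight_mentions_removes_all_pairs(self):
        doc, sent = _fake_sentence("d", 200)
        doc.text = "projections " + doc.text[12:]
        mentions = _layout("d", [(i * 12, i * 12 + 5) for i in range(8)])
        assert filters_extract(doc, sent, enumerate_pairs(sent, mentions)) == []

    def test_trigger_matches_as_substring(self):
        doc = _doc("There is connectivity between the first area and the second area.")
        sent = doc.sentences[0]
        mentions = _layout("d", [(26, 36), (52, 63)])
        out = filters_extract(doc, sent, enumerate_pairs(sent, mentions))
        assert len(out) == 1
        assert all(s.fired_by == frozenset({"FILTERS"}) for s in out)

    def test_no_trigger_removes_all_pairs(self):
        doc = _doc("The first area and the second area were compared.")
        sent = doc.sentences[0]
        mentions = _layout("d", [(4, 14), (23, 34)])
        assert filters_extract(doc, sent, enumerate_pairs(sent, mentions)) == []

    def test_random_layouts_match_brute_force_oracle(self):
        rng = random.Random(17)
        for trial in range(300):
            n_mentions = rng.randint(2, 9)
            length = rng.choice([80, 200, 480, 520, 700])
            spans, pos = [], 0
            for _ in range(n_mentions):
                start = pos + rng.randint(1, 30)
                end = start + rng.randint(3, 10)
                if end >= length - 1:
                    break
                spans.append((start, end))
                pos = end
            if len(spans) < 2:
                continue
            body = list("x" * length)
            if rng.random() < 0.7:
                trig = rng.choice(["project", "pathway", "connecti", "inputs"])
                tpos = length - len(trig) - 1
                body[tpos : tpos + len(trig)] = trig
            text = "".join(body)
            doc = Document(id=f"t{trial}", source_class="abstract", text=text)
            segment_and_tokenize(doc)
            sent = doc.sentences[0]
            mentions = _layout(doc.id, spans)
            got = {
                frozenset(
                    ((s.pair.mention_a.span.start, s.pair.mention_a.span.end),
                     (s.pair.mention_b.span.start, s.pair.mention_b.span.end))
                )
                for s in filters_extract(doc, sent, enumerate_pairs(sent, mentions))
            }
            expected = oracle_filters(doc.sentence_text(sent), spans)
            assert got == expected, f"trial {trial}"

    def test_nearest_neighbor_matches_oracle(self):
        rng = random.Random(23)
        for _ in range(300):
            n = rng.randint(2, 8)
            spans, pos = [], 0
            for _ in range(n):
                start = pos + rng.randint(1, 20)
                end = start + rng.randint(2, 8)
                spans.append((start, end))
                pos = end
            mentions = _layout("d", spans)
            got = {
                frozenset(((a.start, a.end), (b.start, b.end)))
                for pair in nearest_neighbor_pairs(mentions)
                for a, b in [tuple(pair)]
            }
            assert got == oracle_nearest_neighbor(spans)

    def test_cascade_is_anti_monotone(self):
        """Each individual filter only removes pairs."""
        rng = random.Random(31)
        for _ in range(100):
            n = rng.randint(2, 9)
            spans, pos = [], 0
            for _ in range(n):
                start = pos + rng.randint(1, 25)
                end = start + rng.randint(2, 8)
                spans.append((start, end))
                pos = end
            length = pos + rng.randint(1, 120)
            text = "project" + "x" * (length - 7)
            doc = Document(id="c", source_class="abstract", text=text)
            segment_and_tokenize(doc)
            sent = doc.sentences[0]
            mentions = _layout("c", spans)
            pairs = enumerate_pairs(sent, mentions)
            configs = [
                FilterConfig(max_chars=10**9, max_regions=10**9, triggers=("x",),
                             nearest_neighbor=False),
                FilterConfig(max_regions=10**9, triggers=("x",), nearest_neighbor=False),
                FilterConfig(triggers=("x",), nearest_neighbor=False),
                FilterConfig(nearest_neighbor=False),
                FilterConfig(),
            ]
            sizes = [len(filters_extract(doc, sent, pairs, c)) for c in configs]
            assert sizes[0] == len(pairs)
            assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestRules:
    def test_worked_sentences_reproduce_printed_pairs(self, worked):
        docs, lex, expected = worked
        for doc in docs:
            aliases = expand(doc, detect_definitions(doc))
            ms = match(doc, lex, aliases)
            sent = doc.sentences[0]
            got = {s.pair.region_ids() for s in rules_extract(doc, sent, ms)}
            assert got == expected[doc.id]

    def test_trigger_without_rule_construct_yields_nothing(self, worked):
        _, lex, _ = worked
        doc = _doc(
            "Heavy projections were observed near both the substantia nigra and "
            "the ventral tegmental area."
        )
        ms = match(doc, lex)
        assert len(ms) == 2
        assert rules_extract(doc, doc.sentences[0], ms) == []

    def test_region_list_with_as_well_as(self, worked):
        _, lex, _ = worked
        doc = _doc(
            "The nucleus accumbens receives inputs from the substantia nigra as "
            "well as the dorsal raphe nucleus."
        )
        ms = match(doc, lex)
        got = {tuple(sorted(s.pair.region_ids())) for s in rules_extract(doc, doc.sentences[0], ms)}
        assert got == {("WE:AC", "WE:SN"), ("WE:AC", "WE:DR")}

    def test_malformed_rule_file_names_rule(self, tmp_path):
        path = tmp_path / "rules.txt"
        path.write_text("bad_rule: only REGION here\n")
        with pytest.raises(ValueError, match="bad_rule"):
            load_rules(path)

    def test_rule_requires_two_slots(self):
        with pytest.raises(ValueError, match="two region slots"):
            parse_rule("r: REGION projects strongly")


class TestEnsemble:
    def _stmt(self, key, fired):
        m1 = _mention("d", key * 20, key * 20 + 4, "Ra")
        m2 = _mention("d", key * 20 + 8, key * 20 + 12, "Rb")
        return ConnectivityStatement(
            pair=make_pair("d", 0, m1, m2), fired_by=frozenset(fired)
        )

    def test_and_excludes_partial_firing(self):
        per = {"FILTERS": [self._stmt(0, {"FILTERS"})], "KERNEL": [], "RULES": []}
        assert ensemble(per, "FILTERS and KERNEL") == []

    def test_all_three_pass_any_mode(self):
        per = {
            "FILTERS": [self._stmt(0, {"FILTERS"})],
            "KERNEL": [self._stmt(0, {"KERNEL"})],
            "RULES": [self._stmt(0, {"RULES"})],
        }
        for mode in (
            "FILTERS and KERNEL and RULES",
            "(FILTERS or KERNEL) and RULES",
            "FILTERS or KERNEL or RULES",
        ):
            out = ensemble(per, mode)
            assert len(out) == 1
            assert out[0].fired_by == frozenset({"FILTERS", "KERNEL", "RULES"})

    def test_malformed_expression_errors(self):
        with pytest.raises(ValueError):
            ensemble({}, "FILTERS and (KERNEL")
        with pytest.raises(ValueError):
            ensemble({}, "FILTERS and NOPE")

    def test_random_firing_patterns_match_set_algebra_oracle(self):
        rng = random.Random(41)
        modes = [
            ("FILTERS or KERNEL or RULES", lambda f: bool(f)),
            ("FILTERS and KERNEL and RULES", lambda f: f == {"FILTERS", "KERNEL", "RULES"}),
            ("(FILTERS or KERNEL) and RULES",
             lambda f: ("FILTERS" in f or "KERNEL" in f) and "RULES" in f),
            ("FILTERS and KERNEL", lambda f: {"FILTERS", "KERNEL"} <= f),
            ("KERNEL and RULES", lambda f: {"KERNEL", "RULES"} <= f),
        ]
        for trial in range(200):
            n_pairs = rng.randint(1, 12)
            fired_by_key = {}
            per = {"FILTERS": [], "KERNEL": [], "RULES": []}
            for k in range(n_pairs):
                fired = {
                    name for name in ("FILTERS", "KERNEL", "RULES") if rng.random() < 0.5
                }
                if not fired:
                    continue
                st_key = self._stmt(k, {next(iter(fired))}).key()
                fired_by_key[st_key] = fired
                for name in fired:
                    per[name].append(self._stmt(k, {name}))
            mode, fn = modes[trial % len(modes)]
            got = {s.key() for s in ensemble(per, mode)}
            assert got == oracle_ensemble(fired_by_key, fn)
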