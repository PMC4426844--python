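"""Independent brute-force oracles used to cross-check the implementation.

Each oracle re-derives the expected result from first principles (explicit
enumeration, set algebra, truth tables) without calling the code path it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from litconn.connectome import CONNECTED, NOT_CONNECTED, NOT_EVALUATED


def oracle_nearest_neighbor(spans: list[tuple[int, int]]) -> set[frozenset]:
    """Kept pairs under the one-sided-or nearest-neighbor rule."""

    def gap(x, y):
        (s1, e1), (s2, e2) = sorted([x, y])
        return s2 - e1

    kept = set()
    for m in spans:
        candidates = [o for o in spans if o != m]
        if not candidates:
            continue
        best = min(candidates, key=lambda o: (gap(m, o), o[0]))
        kept.add(frozenset((m, best)))
    return kept


def oracle_filters(
    sent_text: str,
    spans: list[tuple[int, int]],
    max_chars: int = 500,
    max_regions: int = 7,
    triggers=("afferent", "efferent", "project", "connecti", "pathway", "inputs"),
) -> set[frozenset]:
    """Surviving unordered span pairs under the full filter cascade."""
    if len(sent_text) > max_chars:
        return set()
    if len(spans) > max_regions:
        return set()
    if not any(t in sent_text.lower() for t in triggers):
        return set()
    all_pairs = {frozenset(p) for p in itertools.combinations(spans, 2)}
    return all_pairs & oracle_nearest_neighbor(spans)


def oracle_match_spans(pred, gold, mode):
    """TP/FP/FN by per-gold capacity counting (each gold credits one)."""
    credit = 0
    used_pred = set()
    for g in gold:
        for i, p in enumerate(pred):
            if i in used_pred:
                continue
            ok = (p == g) if mode == "strict" else (g[0] <= p[0] and p[1] <= g[1])
            if ok:
                credit += 1
                used_pred.add(i)
                break
    return credit, len(pred) - credit, len(gold) - credit


def oracle_score_relations(pred_pairs, gold_pairs):
    pred = set(map(frozenset, pred_pairs))
    gold = set(map(frozenset, gold_pairs))
    tp = len(pred & gold)
    return tp, len(pred) - tp, len(gold) - tp


def oracle_aggregate(statements, weights):
    """statements: iterable of (frozenset{region_a, region_b}, fired_by set)."""
    acc: dict[frozenset, float] = {}
    for ids, fired in statements:
        w = max(weights[f] for f in fired)
        acc[ids] = acc.get(ids, 0.0) + w
    return acc


def oracle_symmetrize(states: np.ndarray) -> np.ndarray:
    n = states.shape[0]
    out = np.full((n, n), NOT_EVALUATED, dtype=np.int8)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = states[i, j], states[j, i]
            if a == CONNECTED or b == CONNECTED:
                out[i, j] = CONNECTED
            elif a == NOT_CONNECTED and b == NOT_CONNECTED:
                out[i, j] = NOT_CONNECTED
    return out


def oracle_compare(lit_regions, lit_values, ref_regions, ref_states, threshold=0.0):
    """(n_pairs, tp, fp, unevaluable) by explicit pair classification."""
    ref_idx = {r: i for i, r in enumerate(ref_regions)}
    n_pairs = tp = fp = un = 0
    for i in range(len(lit_regions)):
        for j in range(i + 1, len(lit_regions)):
            if lit_values[i, j] <= threshold:
                continue
            n_pairs += 1
            a, b = lit_regions[i], lit_regions[j]
            if a not in ref_idx or b not in ref_idx:
                un += 1
                continue
            state = ref_states[ref_idx[a], ref_idx[b]]
            if state == CONNECTED:
                tp += 1
            elif state == NOT_CONNECTED:
                fp += 1
            else:
                un += 1
    return n_pairs, tp, fp, un


def oracle_ensemble(fired_by_key: dict, mode_fn) -> set:
    """Keys whose fired-extractor set satisfies a python predicate."""
    return {k for k, fired in fired_by_key.items() if mode_fn(fired)}


def oracle_window_matcher(norm_tokens, contiguous, index, max_len):
    """All (start, length, region_id) matches by trying every window.

    Mirrors only the term-index contract: a window of normalized tokens
    matches when its tuple is indexed and all internal gaps are
    contiguous.
    """
    hits = []
    n = len(norm_tokens)
    for i in range(n):
        for length in range(1, min(max_len, n - i) + 1):
            if length > 1 and not all(contiguous[i : i + length - 1]):
                continue
            key = tuple(norm_tokens[i : i + length])
            if key in index:
                hits.append((i, length, index[key][0]))
    return hits
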