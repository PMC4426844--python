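"""Literature connectome: aggregation, reference comparison, permutation test.

Extracted statements are aggregated into a symmetric region-by-region
matrix whose entries sum, over the statements on a pair, the estimated
precision of the best extractor that fired each statement (default
weights: FILTERS 0.45, KERNEL 0.60, RULES 0.72).  The matrix is compared
against a tri-state experimental reference (connected / not connected /
not evaluated): literature pairs found connected in the reference are true
positives, pairs found not-connected are false positives, and pairs the
reference cannot judge are unevaluable.  Statistical support comes from a
permutation test that shuffles region labels identically on rows and
columns, preserving degree distribution and density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .extractors import ConnectivityStatement
from .lexicon import Lexicon, depth as lexicon_depth

logger = logging.getLogger(__name__)

__all__ = [
    "CONNECTED",
    "NOT_CONNECTED",
    "NOT_EVALUATED",
    "DEFAULT_WEIGHTS",
    "ConnectivityMatrix",
    "ReferenceMatrix",
    "ComparisonResult",
    "aggregate",
    "symmetrize",
    "compare",
    "permutation_test",
    "mean_depth",
]

CONNECTED = 1
NOT_CONNECTED = 0
NOT_EVALUATED = -1

#: Extractor precisions used as aggregation weights.
DEFAULT_WEIGHTS: Mapping[str, float] = {"FILTERS": 0.45, "KERNEL": 0.60, "RULES": 0.72}


@dataclass
class ConnectivityMatrix:
    regions: list[str]
    values: np.ndarray  # (n, n) non-negative weights
    symmetric: bool = True

    def __post_init__(self) -> None:
        n = len(self.regions)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("value grid shape does not match region count")
        if (self.values < 0).any():
            raise ValueError("weights must be non-negative")
        if np.diag(self.values).any():
            raise ValueError("diagonal must be zero")
        if self.symmetric and not np.allclose(self.values, self.values.T):
            raise ValueError("matrix flagged symmetric but is not")
        self._index = {r: i for i, r in enumerate(self.regions)}

    def weight(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def pairs_above(self, threshold: float = 0.0) -> list[tuple[str, str]]:
        """Unordered region pairs with weight strictly above threshold."""
        out = []
        for i in range(len(self.regions)):
            for j in range(i + 1, len(self.regions)):
                if self.values[i, j] > threshold:
                    out.append((self.regions[i], self.regions[j]))
        return out

    def normalized(self) -> "ConnectivityMatrix":
        """Copy with values rescaled to [0, 1] (display option)."""
        top = self.values.max()
        vals = self.values / top if top > 0 else self.values.copy()
        return ConnectivityMatrix(list(self.regions), vals, self.symmetric)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.regions, columns=self.regions).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, symmetric: bool = True) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), symmetric)


@dataclass
class ReferenceMatrix:
    """Tri-state experimental reference (e.g. a tracer-based connectome)."""

    regions: list[str]
    states: np.ndarray  # (n, n) of {CONNECTED, NOT_CONNECTED, NOT_EVALUATED}

    def __post_init__(self) -> None:
        n = len(self.regions)
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (n, n):
            raise ValueError("state grid shape does not match region count")
        valid = np.isin(self.states, (CONNECTED, NOT_CONNECTED, NOT_EVALUATED))
        if not valid.all():
            raise ValueError("states must be connected/not_connected/not_evaluated")
        self._index = {r: i for i, r in enumerate(self.regions)}

    def summary(self) -> dict[str, float]:
        """Counts of evaluated cells and percent connected among them."""
        n_conn = int((self.states == CONNECTED).sum())
        n_not = int((self.states == NOT_CONNECTED).sum())
        pct = 100.0 * n_conn / (n_conn + n_not) if (n_conn + n_not) else float("nan")
        return {
            "n_connected": n_conn,
            "n_not_connected": n_not,
            "pct_connected": pct,
        }

    def to_csv(self, path: str | Path) -> None:
        cell = np.where(
            self.states == NOT_EVALUATED, "NA", self.states.astype(str)
        )
        pd.DataFrame(cell, index=self.regions, columns=self.regions).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceMatrix":
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        raw = df.to_numpy()
        states = np.full(raw.shape, NOT_EVALUATED, dtype=np.int8)
        states[raw == "1"] = CONNECTED
        states[raw == "0"] = NOT_CONNECTED
        bad = ~np.isin(raw, ("1", "0", "NA", ""))
        if bad.any():
            raise ValueError(f"{path}: invalid reference cells {set(raw[bad])}")
        return cls(list(df.index.astype(str)), states)


@dataclass
class ComparisonResult:
    n_lit_pairs: int
    n_tp: int
    n_fp: int
    n_unevaluable: int
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.n_lit_pairs != self.n_tp + self.n_fp + self.n_unevaluable:
            raise ValueError("pair counts do not add up")

    @property
    def precision(self) -> float | None:
        d = self.n_tp + self.n_fp
        return self.n_tp / d if d else None


def aggregate(
    statements: Iterable[ConnectivityStatement],
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
    regions: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Accumulate statements into a symmetric weighted matrix.

    Each statement contributes the maximum weight among its firing
    extractors to its (unordered) region pair; statements with an
    unnormalized region id, or whose two mentions resolve to the same
    region, are skipped with a logged count.
    """
    stmts = list(statements)
    pair_weights: dict[frozenset[str], float] = {}
    skipped = 0
    for st in stmts:
        ids = st.pair.region_ids()
        if ids is None or len(ids) != 2:
            skipped += 1
            continue
        w = max(weights[e] for e in st.fired_by if e in weights)
        pair_weights[ids] = pair_weights.get(ids, 0.0) + w
    if skipped:
        logger.info("aggregate: skipped %d statements without two region ids", skipped)
    if regions is None:
        regions = sorted({r for ids in pair_weights for r in ids})
    regions = list(regions)
    index = {r: i for i, r in enumerate(regions)}
    values = np.zeros((len(regions), len(regions)))
    for ids, w in pair_weights.items():
        a, b = sorted(ids)
        if a not in index or b not in index:
            continue
        values[index[a], index[b]] += w
        values[index[b], index[a]] += w
    return ConnectivityMatrix(regions=regions, values=values, symmetric=True)


def symmetrize(reference: ReferenceMatrix) -> ReferenceMatrix:
    """Fold directionality away: a pair is connected when either direction
    is, not-connected when both directions are, and not-evaluated
    otherwise.  The diagonal becomes not-evaluated."""
    s = reference.states
    t = s.T
    out = np.full(s.shape, NOT_EVALUATED, dtype=np.int8)
    out[(s == CONNECTED) | (t == CONNECTED)] = CONNECTED
    out[(s == NOT_CONNECTED) & (t == NOT_CONNECTED)] = NOT_CONNECTED
    np.fill_diagonal(out, NOT_EVALUATED)
    return ReferenceMatrix(regions=list(reference.regions), states=out)


def _pair_states(
    lit: ConnectivityMatrix, ref: ReferenceMatrix, threshold: float
) -> np.ndarray:
    """State per literature pair above threshold: CONNECTED/NOT_CONNECTED
    for evaluable pairs, NOT_EVALUATED otherwise."""
    states = []
    for a, b in lit.pairs_above(threshold):
        if a not in ref._index or b not in ref._index:
            states.append(NOT_EVALUATED)
        else:
            states.append(int(ref.states[ref._index[a], ref._index[b]]))
    return np.asarray(states, dtype=np.int8)


def compare(
    lit: ConnectivityMatrix,
    ref: ReferenceMatrix,
    threshold: float = 0.0,
) -> ComparisonResult:
    """Classify literature pairs (weight > threshold) against the reference.

    ``ref`` must already be symmetrized.  Pairs involving regions absent
    from the reference, or marked not-evaluated there, are unevaluable.
    """
    states = _pair_states(lit, ref, threshold)
    n_tp = int((states == CONNECTED).sum())
    n_fp = int((states == NOT_CONNECTED).sum())
    n_un = int((states == NOT_EVALUATED).sum())
    return ComparisonResult(
        n_lit_pairs=len(states), n_tp=n_tp, n_fp=n_fp, n_unevaluable=n_un
    )


def permutation_test(
    lit: ConnectivityMatrix,
    ref: ReferenceMatrix,
    n_shuffles: int = 1000,
    seed: int = 0,
    threshold: float = 0.0,
) -> float:
    """Permutation p-value for the comparison precision.

    The null model shuffles literature region labels identically on rows
    and columns (preserving symmetry, degree distribution and density) and
    recomputes the precision; the add-one estimator gives
    ``p = (1 + #{shuffled >= observed}) / (n_shuffles + 1)``.
    """
    observed = compare(lit, ref, threshold).precision
    if observed is None:
        raise ValueError("no evaluable literature pairs; precision undefined")
    rng = np.random.default_rng(seed)
    regions = np.asarray(lit.regions, dtype=object)
    n = len(regions)
    count = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        shuffled = ConnectivityMatrix(
            regions=list(regions[perm]), values=lit.values, symmetric=lit.symmetric
        )
        prec = compare(shuffled, ref, threshold).precision
        if prec is not None and prec >= observed:
            count += 1
    return (1 + count) / (n_shuffles + 1)


def mean_depth(
    pairs: Iterable[tuple[str, str] | frozenset[str]], lexicon: Lexicon
) -> float | None:
    """Mean ontology depth over the endpoints of the given region pairs.

    Depth is the ancestor count to the root.  Endpoints not resolvable in
    the lexicon are skipped with a logged count; an empty pair set yields
    None.
    """
    depths = []
    skipped = 0
    for pair in pairs:
        for rid in sorted(pair):
            if rid in lexicon:
                depths.append(lexicon_depth(lexicon, rid))
            else:
                skipped += 1
    if skipped:
        logger.info("mean_depth: skipped %d unresolvable endpoints", skipped)
    if not depths:
        return None
    return float(np.mean(depths))
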