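# Methods

This note records the models implemented in `litconn`, the design choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish.

## Text model and preprocessing

Documents carry raw text plus derived sentences and tokens; all offsets
are 0-based, half-open, counted in Unicode code points, so any span slices
the document text exactly. Sentence segmentation is rule-based: a
terminator ends a sentence unless it follows a known abbreviation
("e.g.", "Fig.", "et al.", single initials) or sits inside a number, and
the next character must begin an uppercase/digit context. Tokenization
splits words, digit runs and single punctuation characters, so "(AC)"
becomes three tokens and "10(-7)" five. The POS tagger is a deterministic
heuristic (closed-class word lists plus suffix rules); it is pluggable,
and nothing downstream depends on exact tag values — the CRF and kernel
use tags only as categorical features. These components are deliberately
simple: determinism and offset integrity matter more here than linguistic
sophistication, and the evaluation machinery (strict/lenient matching,
span snapping) absorbs tokenizer differences.

## Term normalization and the lexicon

`normalize_term` lowercases, treats hyphens as separators, strips
punctuation, collapses whitespace, and stems every token longer than
three characters with a Porter-style suffix stripper; three-character
tokens and shorter (abbreviations like "VTA", fields like "CA1") are left
intact. The stripper is iterated to its fixed point so normalization is
idempotent, which the term index requires (a handful of adversarial
letter sequences would otherwise restem on a second pass; ordinary
English converges in one).

Synonym merging attaches donor-lexicon terms to a base entry when the
preferred names are equal under normalization, or when the donor entry
carries an explicit `xref:<id>` cross-reference (the vehicle for manual
augmentation). Name equality is a contract of this package, not a claim
about how any particular pair of published atlases aligns; the join is
kept replaceable. Term collisions resolve to the earlier-listed entry
(order-dependent lookup) and are logged and recorded. A configurable
stoplist (default: *brain*, *nerves*) drops generic terms after matching.
Ontology depth of a region is its ancestor count to the root (root = 0),
computed by parent-link traversal with cycle detection.

## Abbreviation handling

Parenthetical definitions are detected by right-to-left character
alignment: every short-form character must appear in order in a window of
at most `min(|SF|+5, 2·|SF|)` words before the parenthesis, and the first
character must start a word. Short forms must be 2–10 characters with at
least one letter and must not be a bare number or a year; multi-token
parentheticals (citations, "(Dworkin, 1988)") are never candidates.
Expansion is *aliasing*, not text rewriting: a position-scoped map lets
the dictionary NER match a later "VTA" token via its long form while all
offsets stay untouched. Scope starts after the definition site; a
redefinition shadows the earlier one from its own site onward. The
alignment is greedy and occasionally prefers a short suffix of the true
long form ("accumbens" for "nucleus accumbens (AC)"); the alias still
resolves through the lexicon only when the recovered long form is an
indexed term, so the failure mode is a missed alias, not a wrong one.

## Dictionary NER

Matching operates on normalized token sequences within one sentence:
greedy left-to-right, longest contiguous term first, ties by lexicon
listing order, shorter terms nested inside an accepted match suppressed
("midbrain" inside "midbrain ventral tegmental area" is a known
dictionary-NER error mode and is deliberately not emitted). Hyphens and
slashes between word tokens do not break contiguity; other punctuation
does. Matches never cross sentence boundaries because extraction is
sentence-scoped. The implementation is checked against an exhaustive
window-enumeration oracle on generated corpora.

## CRF tagger

The trainable NER is a linear-chain CRF over BIO labels with an explicit
binary feature map per token: identity/lowercase/stem/POS, orthographic
shape, length bucket, capitalization, number flag, lexicon-stem
membership, directionality-word flag, ±2-token context (word and POS,
with boundary placeholders), sentence-level boilerplate flags
(citation-like via author–year patterns, table-like via digit density ≥
0.4 or very low function-word ratio), measure membership (number+unit
patterns including parenthesized and caret exponents), and a
document-level species-presence flag from a small bundled gazetteer (rat,
mouse, macaque, ...). Feature templates are versioned; predicting with a
mismatched template version is refused.

Training maximizes the L2-penalized conditional log-likelihood with
L-BFGS (penalty weight `l2 = 1.0`, iteration cap 100, zero
initialization — the optimization is deterministic, the `seed` parameter
is recorded for provenance). The forward–backward recursions run in log
space, vectorized across a padded sentence batch; decoding is Viterbi.
Gold spans that cross token boundaries are snapped outward to covering
tokens. BIO (not BIOES) encoding keeps the codec trivially invertible,
which is property-tested. Models serialize to a self-describing JSON file.
CRF mentions carry no region id by default; a dictionary-lookup
normalizer is available but off, since normalizing model-found names is a
separate problem from finding them.

## Relation extractors

Candidates are the C(n,2) unordered mention pairs of a sentence — the
system does not extract directionality, so ordered pairs would be
redundant duplicates.

**FILTERS** applies, in order: sentence length ≤ 500 characters, mention
count ≤ 7, at least one trigger substring (*afferent, efferent, project,
connecti, pathway, inputs*; raw case-insensitive substring so "connecti"
covers "connection" and "connectivity"), and a nearest-neighbor
criterion: pair (a, b) survives iff b is a's closest mention or a is b's,
with distance the character gap between spans and ties to the earlier
mention. The one-sided-or form (rather than mutual-nearest) keeps chains
A–B, B–C, which list-like connectivity sentences need; the cost is that
in "A receives projections from B and C" the cascade keeps the spurious
adjacent pair B–C while dropping the true long-range pair A–C. That
trade is intentional and is documented by the worked-example tests.

**RULES** is a pattern grammar over a simplified token stream: mention
spans collapse to REGION symbols, parenthetical groups are dropped
(abbreviation definitions and citations would otherwise split literals),
and determiners ("the", "both", ...) are skipped. A rule line mixes
literals (with `|` alternation and `?` optionality), `REGION`,
`REGION-LIST` (regions joined by "and"/"or"/commas/"as well as") and
`GAP` (at most five non-region tokens — the bounded wildcard that lets
`REGION-LIST GAP project to REGION-LIST` match "cells in X were found to
project to Y"). Every region bound by a rule's first slot pairs with
every region of its second. Nine default rules ship as an editable text
file; they are this package's own reconstruction of the classic
projection/input/efferent/pathway/innervation/connection constructs, and
only the "receives ... from" and "project to" rules are pinned by the
worked-sentence tests.

**KERNEL** is a binary classifier over shallow features of a pair:
token/stem n-grams (n ≤ 3) over the fore-between, between and
between-after windows plus surface/stem/POS/shape of ±2 tokens around
each mention, with the pair's mentions masked by a placeholder so the
features are invariant to the specific region names. The model is an
explicit sparse feature map with logistic regression (C = 1.0, decision
threshold 0.5) rather than a kernelized dual solver: identical feature
semantics, deterministic, and probabilities come from the logistic link.

Ensembles evaluate a boolean expression ("FILTERS and KERNEL",
"(FILTERS or KERNEL) and RULES", ...) per pair key; the emitted
statement's `fired_by` is the union of extractors that fired it.

## Scoring

Strict span matching requires identical offsets; lenient matching also
credits predictions contained within (equal to or smaller than) a gold
span — one-sided, so an over-long prediction is always a false positive.
Each gold span credits at most one prediction (greedy in text order);
with non-overlapping gold spans this equals maximum bipartite matching,
which the tests verify against an independent counting oracle. Relation
scoring uses gold mentions: identity is the unordered pair of entity
spans in a sentence. Cross-validation splits at document level with
repeated reshuffles from derived seeds; the reported standard deviation
is over all fold × repeat scores (per-repeat aggregation would be the
other defensible reading; this one is documented and tested).

## Connectome aggregation and reference comparison

Each statement contributes `max(weight[e] for e in fired_by)` to its
unordered region pair; max rather than sum avoids counting one sentence
twice when several extractors agree, and the default weights are the
extractors' estimated precisions (FILTERS 0.45, KERNEL 0.60, RULES 0.72).
Aggregation is additive over statement lists, which is property-tested.

A tri-state reference matrix (connected / not connected / not evaluated)
is symmetrized with an or-rule — a pair is connected if either direction
is, not-connected only if both directions are — because the extractors
are direction-blind. Comparison classifies every literature pair with
weight above a threshold (default 0; a higher threshold reproduces
minimum-evidence analyses): connected in the reference → true positive,
not-connected → false positive, absent or not-evaluated → unevaluable.
Precision over the evaluable pairs is the comparison statistic; recall is
deliberately not reported because the set of articles a literature search
*should* have found is unknowable. A reference matrix may carry any
tri-state value on its diagonal as loaded (experimental grids commonly
report all cells); symmetrization and pair classification ignore the
diagonal.

The permutation test shuffles region labels identically on rows and
columns of the literature matrix — preserving symmetry, degree
distribution and density — and recomputes precision;
`p = (1 + #{shuffled ≥ observed}) / (n_shuffles + 1)` (add-one estimator;
minimum attainable p is 1/(n+1), so p is never zero). Precision is the
only distance notion used; a spectral or edit distance between matrices
would be a different, also defensible, statistic.

## Synthetic data generator

The generator is the test substrate for every stage. Region names are
direction + structure + qualifier compounds ("dorsal pontine nucleus")
with latinized synonyms ("nucleus pontineus dorsalis", "pontine nucleus
pars dorsalis") contributed by donor lexica that share 30% of preferred
names; parent links form random trees of varying depth. Documents mix,
per sentence: connectivity templates (40%; "receives projections from",
"project to", "connections between ... and", some with three regions),
citation-like and digit-heavy table-like distractors (15%), over-long
run-on list sentences (5%), hedged co-mentions ("it has been proposed
that ...", 2% — hedged connectivity phrasing is rare in practice, and the
extractors deliberately do not model hedging), and neutral co-mention
negatives (the remainder). Abbreviation definitions with later short-form
reuse are planted in 20% of positive sentences. Every planted mention and
relation is recorded as gold, and generation is a pure function of the
seed.

Default problem sizes used by the tests and the acceptance script — 50
regions; 60–400 documents of ~5 sentences; 300/100 train/test documents
for the CRF; 400 training pairs for the kernel; 200 documents for
end-to-end extraction; 1000 permutation shuffles — are chosen so each
experiment has enough signal for stable statistics while the whole suite
stays quick to run.

What passing these tests shows: the implementation is internally correct
(oracle-equivalent), deterministic, and recovers structure it is supposed
to recover under clean, template-generated prose. What it does not show:
performance on real scientific text, whose syntactic variety, nested
region names, cross-sentence relations and inconsistent nomenclature are
far harder than the templates; published evaluations on manually
annotated corpora put dictionary-NER recall and filter-cascade precision
far below the near-ceiling numbers seen here. The synthetic numbers
validate machinery, not field performance.

## Known limitations

- No anaphora ("this latter nucleus") and no cross-sentence relations; a
  substantial fraction of real connectivity statements span sentences.
- No directionality: the output matrix is symmetric by construction.
- Hedged, hypothesized or negated connections are not distinguished from
  asserted ones; a configurable hedge-word list exists but defaults off.
- The dictionary NER cannot find names absent from its lexica, and the
  CRF does not normalize what it finds.
- Rule patterns are a reconstruction; the grammar file is meant to be
  edited per deployment.
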