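# litconn

Mining brain-region connectivity from neuroscience text.

Experimental results about which brain regions project to which are
scattered across decades of publications as free prose, not as structured
records. Manual literature search misses synonyms ("Basolateral amygdala
nucleus" vs "Nucleus amygdalae basolateralis") and undefined abbreviations
("VTA"), and most sentence-level co-occurrences of two region names do not
actually state a connection. `litconn` implements the standard text-mining
answer to this problem for neuroanatomists and neuroinformaticians who
want a literature-derived connectome they can screen against experimental
data:

1. **Named entity recognition.** Brain-region mentions are found either by
   dictionary matching against an atlas lexicon — order-dependent lookup,
   longest contiguous match, with a stemmer applied to tokens longer than
   three characters, cross-lexicon synonym merging, and expansion of
   parenthetical abbreviation definitions (Schwartz–Hearst-style character
   alignment) — or by a trainable linear-chain CRF over BIO tags whose
   features include token shape and stems, lexicon membership,
   directionality words (*dorsal*, *ventral*, ...), a ±2 context window,
   and document-level signals (species presence, measure entities such as
   "10 mm" or "10(-7) molar", citation/table boilerplate).
2. **Relation extraction.** Each sentence containing two or more region
   mentions yields candidate pairs; three extractors with different
   precision/recall trade-offs decide which pairs state a connection:
   * **FILTERS** — a cascade keeping only nearest-neighbor pairs in
     sentences that are ≤ 500 characters long, contain ≤ 7 region
     mentions, and contain a trigger character sequence (*afferent,
     efferent, project, connecti, pathway, inputs*);
   * **RULES** — nine editable patterns of the kind
     `REGION receives projections from REGION-LIST`;
   * **KERNEL** — a shallow-linguistic pair classifier over token/stem
     n-grams of the fore-between/between/between-after windows plus local
     context, with mentions masked; logistic model, probability output.
   Extractors compose with boolean ensembles such as
   `(FILTERS or KERNEL) and RULES`. Directionality and cross-sentence
   (anaphoric) relations are out of scope.
3. **Aggregation and evaluation.** Statements aggregate into a symmetric
   region × region matrix, each statement weighted by the estimated
   precision of the best extractor that fired it (defaults: FILTERS 0.45,
   KERNEL 0.60, RULES 0.72). The matrix is compared against a tri-state
   experimental reference (connected / not connected / not evaluated):
   literature pairs found connected are true positives, found
   not-connected are false positives, and precision
   `TP / (TP + FP)` is the comparison statistic, with significance from a
   permutation test that shuffles region labels identically on rows and
   columns. NER and extractors are scored against gold annotations with
   strict (exact-span) and lenient (prediction contained in gold)
   matching, and document-level repeated k-fold cross-validation.

A synthetic-data generator (`litconn.synth`) plants region mentions,
abbreviation definitions, connectivity sentences and distractors with
known ground truth, so every stage is testable end to end without any
external corpus. Converters for external corpora and atlas lexica are
deliberately thin: lexica load from TSV, corpora from JSONL, gold
annotations from BRAT-style standoff.

## Worked example

```python
from litconn import (detect_definitions, expand, match, rules_extract,
                     enumerate_pairs, filters_extract, ensemble, aggregate)
from litconn.synth import load_worked_examples

docs, lexicon, _ = load_worked_examples()
doc = docs[0]   # "The nucleus accumbens (AC) receives projections from
                #  both the substantia nigra (SN) and the ventral
                #  tegmental area (VTA) (Dworkin, 1988)."
aliases = expand(doc, detect_definitions(doc))
mentions = match(doc, lexicon, aliases)
for m in mentions:
    print(f"{m.span.start:>3}-{m.span.end:<3} {m.surface!r} -> {m.region_id}")
sent = doc.sentences[0]
per = {"FILTERS": filters_extract(doc, sent, enumerate_pairs(sent, mentions)),
       "RULES": rules_extract(doc, sent, mentions),
       "KERNEL": []}
combined = ensemble(per, "FILTERS or RULES")
matrix = aggregate(combined)
print(matrix.regions)
print(matrix.values)
```

prints

```
  4-21  'nucleus accumbens' -> WE:AC
 62-78  'substantia nigra' -> WE:SN
 92-114 'ventral tegmental area' -> WE:VTA
['WE:AC', 'WE:SN', 'WE:VTA']
[[0.   0.72 0.72]
 [0.72 0.   0.45]
 [0.72 0.45 0.  ]]
```

The rules recover the stated pairs (accumbens–nigra, accumbens–tegmental
area; weight 0.72 each), while the nearest-neighbor filter instead keeps
the chain pairs — its nigra–tegmental pair enters the union at the FILTERS
weight 0.45. Note the citation parenthetical "(Dworkin, 1988)" produced no
abbreviation definition and no mention.

The same flow runs from the shell:

```bash
litconn simulate --out-dir sim --seed 5 --n-documents 100
litconn extract --corpus sim/corpus.jsonl --lexicon sim/lexicon.tsv \
    --ensemble-mode "FILTERS or RULES" --out-dir out
litconn compare --matrix out/matrix.csv --reference sim/reference.csv \
    --permutations 1000
```

Further subcommands: `build-lexicon`, `ner`, `train-crf`, `predict-crf`,
`evaluate`, `aggregate`, `run` (end-to-end from a YAML config).

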