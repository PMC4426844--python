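"""End-to-end pipeline: read -> segment -> abbreviations -> NER -> extract
-> ensemble -> aggregate, with a per-stage run report.

Output is a pure function of (inputs, config, seeds): statements and
matrix files are written in sorted order and the report has sorted keys,
so reruns are byte-identical.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import abbrev as abbrev_mod
from .connectome import DEFAULT_WEIGHTS, aggregate
from .corpus import Document, read_corpus_jsonl, segment_and_tokenize
from .extractors import (
    ConnectivityStatement,
    DEFAULT_TRIGGERS,
    FilterConfig,
    RuleSet,
    default_rules,
    ensemble,
    enumerate_pairs,
    filters_extract,
    load_rules,
    rules_extract,
    write_statements_tsv,
)
from .kernel import KernelRelationClassifier
from .lexical_ner import Mention, NERConfig, TermMatcher, match, write_mentions_tsv
from .lexicon import DEFAULT_STOPLIST, Lexicon, load_lexicon_tsv, merge_synonyms

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "extract_statements"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage and document."""


@dataclass
class PipelineConfig:
    corpus: str
    lexicon: str
    output_dir: str
    donors: list[str] = field(default_factory=list)
    rules: str | None = None
    ensemble_mode: str = "FILTERS or KERNEL or RULES"
    max_chars: int = 500
    max_regions: int = 7
    triggers: tuple[str, ...] = DEFAULT_TRIGGERS
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    stoplist: tuple[str, ...] = tuple(sorted(DEFAULT_STOPLIST))
    kernel_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_chars <= 0 or self.max_regions <= 0:
            raise ValueError("filter thresholds must be positive")


def extract_statements(
    documents: Sequence[Document],
    lexicon: Lexicon,
    ruleset: RuleSet | None = None,
    filter_config: FilterConfig | None = None,
    ner_config: NERConfig | None = None,
    kernel_model: KernelRelationClassifier | None = None,
    kernel_threshold: float = 0.5,
) -> tuple[dict[str, list[ConnectivityStatement]], dict]:
    """Run NER plus all available extractors over segmented documents.

    Returns per-extractor statement lists and a count report.
    """
    ruleset = ruleset or default_rules()
    filter_config = filter_config or FilterConfig()
    matcher = TermMatcher(lexicon)
    per_extractor: dict[str, list[ConnectivityStatement]] = {
        "FILTERS": [],
        "KERNEL": [],
        "RULES": [],
    }
    counts = Counter(
        {
            "documents": 0,
            "sentences": 0,
            "abbrev_definitions": 0,
            "mentions": 0,
            "candidate_pairs": 0,
        }
    )
    for doc in documents:
        counts["documents"] += 1
        counts["sentences"] += len(doc.sentences)
        try:
            defs = abbrev_mod.detect_definitions(doc)
            aliases = abbrev_mod.expand(doc, defs)
            counts["abbrev_definitions"] += len(defs)
            mentions = match(doc, matcher, aliases, ner_config)
            counts["mentions"] += len(mentions)
            by_sentence: dict[int, list[Mention]] = {}
            for m in mentions:
                for sent in doc.sentences:
                    if sent.span.contains(m.span):
                        by_sentence.setdefault(sent.index, []).append(m)
                        break
            for sent in doc.sentences:
                ms = by_sentence.get(sent.index, [])
                if len(ms) < 2:
                    continue
                pairs = enumerate_pairs(sent, ms)
                counts["candidate_pairs"] += len(pairs)
                per_extractor["FILTERS"].extend(
                    filters_extract(doc, sent, pairs, filter_config)
                )
                per_extractor["RULES"].extend(rules_extract(doc, sent, ms, ruleset))
                if kernel_model is not None:
                    probs = kernel_model.predict_proba_pairs(
                        [(sent, p) for p in pairs]
                    )
                    for p, prob in zip(pairs, probs):
                        if prob >= kernel_threshold:
                            per_extractor["KERNEL"].append(
                                ConnectivityStatement(
                                    pair=p,
                                    fired_by=frozenset({"KERNEL"}),
                                    kernel_score=float(prob),
                                )
                            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage=extract doc={doc.id}: {exc}") from exc
    for name, stmts in per_extractor.items():
        counts[f"statements_{name}"] = len(stmts)
    # extractor-overlap counts over pair keys (which extractors fired a pair)
    fired_by_key: dict[tuple, set[str]] = {}
    for name, stmts in per_extractor.items():
        for st in stmts:
            fired_by_key.setdefault(st.key(), set()).add(name)
    overlap = Counter(
        "+".join(sorted(fired)) for fired in fired_by_key.values()
    )
    report = {
        "counts": dict(sorted(counts.items())),
        "extractor_overlap": dict(sorted(overlap.items())),
    }
    return per_extractor, report


def run_pipeline(
    config: PipelineConfig, kernel_model: KernelRelationClassifier | None = None
) -> dict:
    """Execute the full pipeline and write statements, matrix and report."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        documents = read_corpus_jsonl(config.corpus)
    except Exception as exc:
        raise PipelineError(f"stage=read: {exc}") from exc
    for doc in documents:
        try:
            segment_and_tokenize(doc)
        except Exception as exc:
            raise PipelineError(f"stage=segment doc={doc.id}: {exc}") from exc
    lexicon = load_lexicon_tsv(config.lexicon)
    if config.donors:
        donors = [load_lexicon_tsv(p) for p in config.donors]
        lexicon = merge_synonyms(lexicon, donors)
    ruleset = load_rules(config.rules) if config.rules else default_rules()
    filter_config = FilterConfig(
        max_chars=config.max_chars,
        max_regions=config.max_regions,
        triggers=tuple(config.triggers),
    )
    ner_config = NERConfig(stoplist=frozenset(config.stoplist))
    per_extractor, report = extract_statements(
        documents,
        lexicon,
        ruleset,
        filter_config,
        ner_config,
        kernel_model,
        config.kernel_threshold,
    )
    combined = ensemble(per_extractor, config.ensemble_mode)
    report["counts"]["statements_ensemble"] = len(combined)
    matrix = aggregate(combined, config.weights)
    write_statements_tsv(combined, out_dir / "statements.tsv")
    matrix.to_csv(out_dir / "matrix.csv")
    report["config"] = {
        "ensemble_mode": config.ensemble_mode,
        "max_chars": config.max_chars,
        "max_regions": config.max_regions,
        "triggers": list(config.triggers),
        "weights": dict(sorted(config.weights.items())),
        "seed": config.seed,
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
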