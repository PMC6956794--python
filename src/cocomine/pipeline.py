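"""End-to-end pipeline: label, split, downsample, train, score, evaluate.

This is the library-level realization of the full workflow: distant
supervision against a gold standard, pair-level 80/20 train/test
splitting, capping of training co-mentions per pair, sentence-classifier
training, scoring of the held-out pairs with both the context-aware
model and the count baseline, and bootstrap comparison of the two. The
command-line ``run`` subcommand is a thin wrapper around
:func:`run_pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .data_model import Comention, GoldStandard
from .distant_supervision import LabelSummary, label_comentions
from .evaluation import (
    ADJUST_PRIOR,
    BootstrapResult,
    EvalResult,
    bootstrap_compare,
    downsample_train,
    evaluate_pairs,
    pair_labels,
    split_pairs,
)
from .scoring import (
    BASELINE_ALPHA,
    DEFAULT_ALPHA,
    ScoreTable,
    baseline_counts,
    co_occurrence_counts,
    combine,
    document_scores,
)
from .sentence_model import (
    EmbeddingTable,
    Hyperparams,
    SentenceClassifier,
    predict_comentions,
    train,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    classifier: SentenceClassifier
    context_scores: ScoreTable
    baseline_scores: ScoreTable
    context_eval: EvalResult
    baseline_eval: EvalResult
    comparison: BootstrapResult | None
    label_summary: LabelSummary
    test_comentions: list[Comention]
    n_train_pairs: int
    n_test_pairs: int


def run_pipeline(
    comentions: Sequence[Comention],
    gold: GoldStandard,
    hp: Hyperparams = Hyperparams(),
    alpha: float = DEFAULT_ALPHA,
    baseline_alpha: float = BASELINE_ALPHA,
    test_fraction: float = 0.2,
    max_per_pair: int = 100,
    n_boot: int = 1000,
    adjust_prior: float = ADJUST_PRIOR,
    seed: int = 0,
    pretrained: EmbeddingTable | None = None,
) -> PipelineResult:
    """Run the full scoring and evaluation workflow on raw co-mentions.

    Grey-listed and unknown-entity pairs are excluded after labeling;
    downsampling applies to the training side only. Set ``n_boot`` to 0
    to skip the bootstrap comparison. Deterministic given ``seed`` (which
    also drives the split and downsampling) and ``hp.seed`` (classifier
    training).
    """
    labeled, summary = label_comentions(comentions, gold)
    usable = [r for r in labeled if r.label in ("positive", "negative")]
    if not usable:
        raise ValueError("no labelable co-mentions (all grey-listed or unknown)")
    train_pairs, test_pairs = split_pairs(sorted({r.pair for r in usable}), test_fraction, seed=seed)
    train_side = downsample_train(
        [r for r in usable if r.pair in train_pairs], max_per_pair, seed=seed
    )
    test_side = [r for r in usable if r.pair in test_pairs]

    classifier = train(train_side, hp, pretrained=pretrained)
    scored_test = predict_comentions(classifier, test_side)
    context_table = combine(co_occurrence_counts(document_scores(scored_test)), alpha)
    baseline_table = combine(baseline_counts(test_side), baseline_alpha)

    labels = pair_labels(test_side)
    context_eval = evaluate_pairs(context_table.scores, labels, a=adjust_prior)
    baseline_eval = evaluate_pairs(baseline_table.scores, labels, a=adjust_prior)
    comparison = None
    if n_boot:
        comparison = bootstrap_compare(
            context_table.scores, baseline_table.scores, labels,
            n_boot=n_boot, seed=seed, a=adjust_prior,
        )
    return PipelineResult(
        classifier=classifier,
        context_scores=context_table,
        baseline_scores=baseline_table,
        context_eval=context_eval,
        baseline_eval=baseline_eval,
        comparison=comparison,
        label_summary=summary,
        test_comentions=scored_test,
        n_train_pairs=len(train_pairs),
        n_test_pairs=len(test_pairs),
    )
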