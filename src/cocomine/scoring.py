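"""Corpus-level aggregation of sentence scores into pair scores.

For an entity pair (i, j) the per-document evidence s_k(i, j) is the
maximum sentence score among sentences in document k co-mentioning the
pair (0 when the pair is not co-mentioned in k). Summing s_k over
documents yields the soft co-occurrence count C(i, j), converted to the
final score by

    S(i, j) = C(i, j)^alpha * ( C(i, j) * C(.,.) / (C(i, .) * C(., j)) )^(1 - alpha)

where C(i, .) and C(., j) are the marginal counts of each entity,
C(.,.) the grand total, and alpha in [0, 1] trades off raw count against
the observed-over-expected enrichment ratio. The context-aware model
uses learned sentence scores (default alpha 0.65 after cross-validation);
the count-based baseline sets s_k = 1 for every co-mentioning document
(default alpha 0.55), which reduces C(i, j) to the number of distinct
documents co-mentioning the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .data_model import Comention, EntityId, EntityPair

__all__ = [
    "DEFAULT_ALPHA",
    "BASELINE_ALPHA",
    "DocumentScore",
    "ScoreTable",
    "document_scores",
    "co_occurrence_counts",
    "combine",
    "baseline_counts",
    "apply_score_filter",
    "write_scores",
    "read_scores",
]

DEFAULT_ALPHA = 0.65  # context-aware model, cross-validated optimum
BASELINE_ALPHA = 0.55  # count-based baseline, cross-validated optimum


@dataclass(frozen=True)
class DocumentScore:
    """Max sentence score for a pair within one document."""

    document_id: str
    pair: EntityPair
    s_k: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_k <= 1.0:
            raise ValueError(f"document score outside [0, 1]: {self.s_k}")


@dataclass
class ScoreTable:
    """Per-pair co-occurrence counts, marginals, and final scores.

    Invariants: every count is finite and non-negative; each entity's
    marginal equals the sum of counts of pairs containing it, so entity
    marginals sum to twice the grand total.
    """

    counts: dict[EntityPair, float] = field(default_factory=dict)
    marginals: dict[EntityId, float] = field(default_factory=dict)
    total: float = 0.0
    scores: dict[EntityPair, float] = field(default_factory=dict)
    alpha: float | None = None


def document_scores(comentions: Sequence[Comention]) -> list[DocumentScore]:
    """Collapse scored co-mentions to one record per (document, pair),
    keeping the maximum sentence score. Pairs absent from a document
    produce no record (they contribute zero)."""
    best: dict[tuple[str, EntityPair], float] = {}
    for rec in comentions:
        if rec.sentence_score is None:
            raise ValueError(
                f"co-mention without sentence score: {rec.document_id} "
                f"#{rec.sentence_index} {rec.pair.a}/{rec.pair.b}"
            )
        key = (rec.document_id, rec.pair)
        prev = best.get(key)
        if prev is None or rec.sentence_score > prev:
            best[key] = rec.sentence_score
    return [DocumentScore(doc, pair, s) for (doc, pair), s in best.items()]


def co_occurrence_counts(doc_scores: Iterable[DocumentScore]) -> ScoreTable:
    """Sum per-document scores into C(i, j) and compute marginals."""
    counts: dict[EntityPair, float] = {}
    for ds in doc_scores:
        counts[ds.pair] = counts.get(ds.pair, 0.0) + ds.s_k
    marginals: dict[EntityId, float] = {}
    total = 0.0
    for pair, c in counts.items():
        marginals[pair.a] = marginals.get(pair.a, 0.0) + c
        marginals[pair.b] = marginals.get(pair.b, 0.0) + c
        total += c
    return ScoreTable(counts=counts, marginals=marginals, total=total)


def combine(table: ScoreTable, alpha: float) -> ScoreTable:
    """Fill final scores S(i, j) from counts and marginals.

    Pairs with zero count are omitted rather than scored zero. Marginals
    are taken over all pairs present in the table, i.e. over the dataset
    being scored.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    scores: dict[EntityPair, float] = {}
    for pair, c in table.counts.items():
        if c <= 0.0:
            continue
        ratio = c * table.total / (table.marginals[pair.a] * table.marginals[pair.b])
        scores[pair] = c ** alpha * ratio ** (1.0 - alpha)
    return ScoreTable(
        counts=dict(table.counts),
        marginals=dict(table.marginals),
        total=table.total,
        scores=scores,
        alpha=alpha,
    )


def baseline_counts(comentions: Sequence[Comention]) -> ScoreTable:
    """Count-based co-occurrence counts: C(i, j) = number of distinct
    documents co-mentioning the pair; sentence scores and labels are
    ignored."""
    docs: set[tuple[str, EntityPair]] = {(r.document_id, r.pair) for r in comentions}
    return co_occurrence_counts(
        DocumentScore(doc, pair, 1.0) for doc, pair in docs
    )


def apply_score_filter(
    comentions: Sequence[Comention], threshold: float
) -> list[Comention]:
    """Retain co-mentions whose sentence score is >= threshold (an
    optional variant: filter low-scoring sentences before aggregation)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    out = []
    for rec in comentions:
        if rec.sentence_score is None:
            raise ValueError(f"co-mention without sentence score: {rec.document_id} #{rec.sentence_index}")
        if rec.sentence_score >= threshold:
            out.append(rec)
    return out


def write_scores(table: ScoreTable, path: str | Path) -> None:
    """Write scored pairs as TSV (ns1, id1, ns2, id2, count, score),
    ordered by descending score then canonical pair for diffability."""
    rows = sorted(table.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ns1\tid1\tns2\tid2\tcount\tscore\n")
        for pair, s in rows:
            fh.write(
                f"{pair.a.namespace}\t{pair.a.identifier}\t{pair.b.namespace}\t"
                f"{pair.b.identifier}\t{table.counts[pair]!r}\t{s!r}\n"
            )


def read_scores(path: str | Path) -> ScoreTable:
    """Read a score TSV written by :func:`write_scores`; marginals and
    totals are recomputed from the counts."""
    counts: dict[EntityPair, float] = {}
    scores: dict[EntityPair, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("ns1\t")):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            ns1, id1, ns2, id2, count, score = parts
            pair = EntityPair.make(EntityId(ns1, id1), EntityId(ns2, id2))
            counts[pair] = float(count)
            scores[pair] = float(score)
    marginals: dict[EntityId, float] = {}
    total = 0.0
    for pair, c in counts.items():
        marginals[pair.a] = marginals.get(pair.a, 0.0) + c
        marginals[pair.b] = marginals.get(pair.b, 0.0) + c
        total += c
    return ScoreTable(counts=counts, marginals=marginals, total=total, scores=scores)
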