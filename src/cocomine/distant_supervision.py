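"""Distant supervision: weak labeling of co-mentions from a gold standard.

A sentence co-mentioning an entity pair is labeled *positive* when the
pair is in the gold standard, *negative* when both entities occur in the
gold standard but not as an associated pair, *excluded_grey* when the
pair is grey-listed (intermediate evidence — neither positive nor
negative), and *excluded_unknown* when either entity is absent from the
gold standard entirely (the pair is unlabelable under distant
supervision). Only positive/negative records are used for classifier
training and evaluation.

Gold standards over ontology-structured namespaces (diseases, tissues)
can be propagated: a pair involving a parent term also holds for every
descendant term, which enlarges the labeled dataset without loss of
quality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .data_model import Comention, EntityPair, GoldStandard, Ontology

__all__ = ["LabelSummary", "propagate_gold", "label_comentions"]


@dataclass(frozen=True)
class LabelSummary:
    """Counts per assigned label; sums to the number of input co-mentions."""

    n_positive: int = 0
    n_negative: int = 0
    n_excluded_grey: int = 0
    n_excluded_unknown: int = 0

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative + self.n_excluded_grey + self.n_excluded_unknown

    @property
    def positive_fraction(self) -> float:
        """Fraction of positives among labeled (positive + negative) records."""
        labeled = self.n_positive + self.n_negative
        return self.n_positive / labeled if labeled else float("nan")


def propagate_gold(gold: GoldStandard, ontology: Ontology, namespace: str) -> GoldStandard:
    """Propagate gold pairs down an ontology hierarchy.

    For every gold pair ``(t, e)`` whose entity ``t`` lies in
    ``namespace``, and every descendant ``t'`` of ``t`` in the ontology,
    the pair ``(t', e)`` is added with the same class. Rationale: a
    sentence linking a gene to a specific disease subtype also supports
    the association with the ancestral disease term, so descendant-term
    pairs inherit the ancestor's gold status. Original pairs are
    retained; a propagated grey pair never overrides a positive one.
    """
    onto_nodes = {n for e in ontology.edges for n in e}
    for n in onto_nodes:
        if n.namespace != namespace:
            raise ValueError(f"ontology node {n} outside propagation namespace {namespace!r}")

    # descendants[t] = all t' that reach t via child->parent edges
    descendants: dict = {}
    for node in onto_nodes:
        for anc in ontology.ancestors(node):
            descendants.setdefault(anc, set()).add(node)

    def expanded(pairs: Iterable[EntityPair]) -> set[EntityPair]:
        out: set[EntityPair] = set()
        for pair in pairs:
            out.add(pair)
            for ent, other in ((pair.a, pair.b), (pair.b, pair.a)):
                if ent.namespace != namespace:
                    continue
                for desc in descendants.get(ent, ()):
                    if desc != other:
                        out.add(EntityPair.make(desc, other))
        return out

    positives = expanded(gold.positives)
    grey = expanded(gold.grey) - positives
    return GoldStandard(positives=positives, grey=grey, entities=set(gold.entities))


def label_comentions(
    comentions: Sequence[Comention], gold: GoldStandard
) -> tuple[list[Comention], LabelSummary]:
    """Assign weak labels to co-mentions; existing labels are overwritten.

    Deterministic and independent of input order; returns the relabeled
    records (input order preserved) and a :class:`LabelSummary`.
    """
    counts = {"positive": 0, "negative": 0, "excluded_grey": 0, "excluded_unknown": 0}
    out: list[Comention] = []
    for rec in comentions:
        pair = rec.pair
        if pair in gold.positives:
            label = "positive"
        elif pair in gold.grey:
            label = "excluded_grey"
        elif pair.a in gold.entities and pair.b in gold.entities:
            label = "negative"
        else:
            label = "excluded_unknown"
        counts[label] += 1
        out.append(replace(rec, label=label))
    summary = LabelSummary(
        n_positive=counts["positive"],
        n_negative=counts["negative"],
        n_excluded_grey=counts["excluded_grey"],
        n_excluded_unknown=counts["excluded_unknown"],
    )
    return out, summary
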