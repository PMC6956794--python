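"""Domain types and file I/O for co-mention datasets.

The central objects are sentence-level *co-mentions*: one record per
sentence in which two named biomedical entities (genes, proteins,
diseases, tissues, ...) both occur after named-entity recognition. Entity
names are assumed to have been *blanked*, i.e. replaced by a class
placeholder token such as ``GENE_``, so that downstream models score the
sentence context rather than entity identity.

All on-disk formats are plain TSV without quoting; tab characters are
therefore forbidden inside fields. This keeps read/write round trips
bit-exact and diffs readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "EntityId",
    "EntityPair",
    "Comention",
    "GoldStandard",
    "Ontology",
    "LABELS",
    "DEFAULT_PLACEHOLDERS",
    "placeholder_for",
    "blank_sentence",
    "read_comentions",
    "write_comentions",
    "read_gold",
    "write_gold",
    "read_ontology",
    "write_ontology",
]

#: Valid co-mention labels. ``excluded_grey`` and ``excluded_unknown``
#: mark records dropped from both training and evaluation.
LABELS = ("positive", "negative", "excluded_grey", "excluded_unknown", "unlabeled")

#: Default placeholder token per entity class; overridable wherever a
#: ``placeholders`` mapping is accepted.
DEFAULT_PLACEHOLDERS = {
    "gene": "GENE_",
    "protein": "PROTEIN_",
    "disease": "DISEASE_",
    "tissue": "TISSUE_",
}


class EntityId(NamedTuple):
    """A namespaced entity identifier, e.g. ``('gene', 'ENSG...')``."""

    namespace: str
    identifier: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.namespace}:{self.identifier}"


def _check_entity(e: EntityId) -> None:
    if not e.namespace or not e.identifier:
        raise ValueError(f"entity namespace and identifier must be non-empty: {e!r}")
    if "\t" in e.namespace or "\t" in e.identifier:
        raise ValueError(f"tab character forbidden in entity fields: {e!r}")


class EntityPair(NamedTuple):
    """An unordered entity pair stored in canonical order.

    Construct via :meth:`make` so that ``(i, j)`` and ``(j, i)`` map to
    the same object; pairs sort lexicographically by namespace then
    identifier, making same-class pairs (protein-protein) unordered and
    cross-class pairs namespace-ordered.
    """

    a: EntityId
    b: EntityId

    @classmethod
    def make(cls, x: EntityId, y: EntityId) -> "EntityPair":
        x, y = EntityId(*x), EntityId(*y)
        _check_entity(x)
        _check_entity(y)
        if x == y:
            raise ValueError(f"self-pair not allowed: {x}")
        return cls(x, y) if x <= y else cls(y, x)

    @property
    def entities(self) -> tuple[EntityId, EntityId]:
        return (self.a, self.b)


@dataclass(frozen=True)
class Comention:
    """One sentence-level co-occurrence of an entity pair.

    ``text`` is the blanked sentence. ``sentence_score`` is the context
    score in (0, 1) assigned by the sentence classifier, or ``None``
    before prediction.
    """

    document_id: str
    sentence_index: int
    pair: EntityPair
    text: str
    label: str = "unlabeled"
    sentence_score: float | None = None

    def __post_init__(self) -> None:
        if self.sentence_index < 0:
            raise ValueError("sentence_index must be non-negative")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if "\t" in self.text or "\n" in self.text:
            raise ValueError("tab/newline forbidden in co-mention text")

    @property
    def key(self) -> tuple[str, int, EntityPair]:
        return (self.document_id, self.sentence_index, self.pair)


@dataclass
class GoldStandard:
    """Curated positive pairs, grey-listed pairs, and the entity universe.

    ``entities`` is the union of all entities in ``positives`` plus any
    explicitly supplied ones; distant supervision labels a pair negative
    only when both of its entities are known to the gold standard.
    """

    positives: set[EntityPair] = field(default_factory=set)
    grey: set[EntityPair] = field(default_factory=set)
    entities: set[EntityId] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.positives & self.grey
        if overlap:
            raise ValueError(f"pairs both positive and grey: {sorted(overlap)[:3]}")
        for p in self.positives | self.grey:
            self.entities.update(p.entities)


@dataclass(frozen=True)
class Ontology:
    """A child -> parent edge list (is-a hierarchy), acyclic by invariant."""

    edges: frozenset[tuple[EntityId, EntityId]]

    def __init__(self, edges: Iterable[tuple[EntityId, EntityId]]) -> None:
        edges = frozenset((EntityId(*c), EntityId(*p)) for c, p in edges)
        for c, p in edges:
            if c.namespace != p.namespace:
                raise ValueError(f"ontology edge across namespaces: {c} -> {p}")
        cycle = _find_cycle(edges)
        if cycle is not None:
            pretty = " -> ".join(str(e) for e in cycle)
            raise ValueError(f"ontology contains a cycle: {pretty}")
        object.__setattr__(self, "edges", edges)

    def parents(self) -> dict[EntityId, set[EntityId]]:
        out: dict[EntityId, set[EntityId]] = {}
        for c, p in self.edges:
            out.setdefault(c, set()).add(p)
        return out

    def ancestors(self, node: EntityId) -> set[EntityId]:
        """All nodes reachable from ``node`` by following child->parent edges."""
        par = self.parents()
        seen: set[EntityId] = set()
        stack = [EntityId(*node)]
        while stack:
            for p in par.get(stack.pop(), ()):  # pragma: no branch
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen


def _find_cycle(
    edges: frozenset[tuple[EntityId, EntityId]],
) -> list[EntityId] | None:
    adj: dict[EntityId, list[EntityId]] = {}
    for c, p in edges:
        adj.setdefault(c, []).append(p)
    WHITE, GREY_, BLACK = 0, 1, 2
    color: dict[EntityId, int] = {}
    for start in adj:
        if color.get(start, WHITE) != WHITE:
            continue
        path: list[EntityId] = []
        stack: list[tuple[EntityId, int]] = [(start, 0)]
        color[start] = GREY_
        path.append(start)
        while stack:
            node, i = stack[-1]
            succs = adj.get(node, [])
            if i < len(succs):
                stack[-1] = (node, i + 1)
                nxt = succs[i]
                c = color.get(nxt, WHITE)
                if c == GREY_:
                    return path[path.index(nxt):] + [nxt]
                if c == WHITE:
                    color[nxt] = GREY_
                    stack.append((nxt, 0))
                    path.append(nxt)
            else:
                color[node] = BLACK
                stack.pop()
                path.pop()
    return None


# ---------------------------------------------------------------------------
# Entity-name blanking
# ---------------------------------------------------------------------------

def placeholder_for(entity_class: str, placeholders: dict[str, str] | None = None) -> str:
    """Placeholder token for an entity class; unknown classes get ``CLASS_``."""
    table = DEFAULT_PLACEHOLDERS if placeholders is None else placeholders
    return table.get(entity_class, entity_class.upper() + "_")


def blank_sentence(
    raw_text: str,
    entity_spans: Sequence[tuple[int, int, str]],
    placeholders: dict[str, str] | None = None,
) -> str:
    """Replace entity spans with class placeholder tokens.

    Spans are 0-based half-open ``(start, end, entity_class)`` character
    offsets into ``raw_text``; they must lie in range and not overlap.
    Text outside the spans is returned unchanged.
    """
    spans = sorted(entity_spans)
    prev_end = 0
    parts: list[str] = []
    for start, end, cls in spans:
        if start < 0 or end > len(raw_text) or start >= end:
            raise ValueError(f"span ({start}, {end}) out of range for text of length {len(raw_text)}")
        if start < prev_end:
            raise ValueError(f"overlapping spans at offset {start}")
        parts.append(raw_text[prev_end:start])
        parts.append(placeholder_for(cls, placeholders))
        prev_end = end
    parts.append(raw_text[prev_end:])
    return "".join(parts)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_COMENTION_HEADER = ["document_id", "sentence_index", "ns1", "id1", "ns2", "id2", "text", "label", "score"]


def read_comentions(path: str | Path) -> list[Comention]:
    """Read co-mentions from TSV.

    Columns: document_id, sentence_index, ns1, id1, ns2, id2, text
    [, label] [, score]. A header row matching the canonical column names
    is skipped if present. Raises ``ValueError`` naming the offending line
    on malformed rows or duplicate (document, sentence, pair) keys.
    """
    records: list[Comention] = []
    seen: dict[tuple, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[: len(_COMENTION_HEADER)] == _COMENTION_HEADER[: len(parts)]:
                continue
            if not 7 <= len(parts) <= 9:
                raise ValueError(f"{path}:{lineno}: expected 7-9 tab-separated fields, got {len(parts)}")
            doc, sent, ns1, id1, ns2, id2, text = parts[:7]
            label = parts[7] if len(parts) >= 8 and parts[7] else "unlabeled"
            score_s = parts[8] if len(parts) == 9 else ""
            try:
                rec = Comention(
                    document_id=doc,
                    sentence_index=int(sent),
                    pair=EntityPair.make(EntityId(ns1, id1), EntityId(ns2, id2)),
                    text=text,
                    label=label,
                    sentence_score=float(score_s) if score_s else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if rec.key in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate co-mention (first seen at line {seen[rec.key]}): "
                    f"{doc} #{sent} {rec.pair.a}/{rec.pair.b}"
                )
            seen[rec.key] = lineno
            records.append(rec)
    return records


def write_comentions(records: Iterable[Comention], path: str | Path) -> None:
    """Write co-mentions as TSV with header; round-trips through
    :func:`read_comentions` exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COMENTION_HEADER) + "\n")
        for r in records:
            score = "" if r.sentence_score is None else repr(float(r.sentence_score))
            fh.write(
                "\t".join(
                    [
                        r.document_id,
                        str(r.sentence_index),
                        r.pair.a.namespace,
                        r.pair.a.identifier,
                        r.pair.b.namespace,
                        r.pair.b.identifier,
                        r.text,
                        r.label,
                        score,
                    ]
                )
                + "\n"
            )


def read_gold(path: str | Path) -> GoldStandard:
    """Read a gold standard TSV with columns ns1, id1, ns2, id2, class
    (class in {positive, grey})."""
    positives: set[EntityPair] = set()
    grey: set[EntityPair] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:1] == ["ns1"]:
                continue
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            ns1, id1, ns2, id2, cls = parts
            try:
                pair = EntityPair.make(EntityId(ns1, id1), EntityId(ns2, id2))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if cls == "positive":
                positives.add(pair)
            elif cls == "grey":
                grey.add(pair)
            else:
                raise ValueError(f"{path}:{lineno}: unknown class {cls!r} (expected positive|grey)")
    try:
        return GoldStandard(positives=positives, grey=grey)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_gold(gold: GoldStandard, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ns1\tid1\tns2\tid2\tclass\n")
        for cls, pairs in (("positive", gold.positives), ("grey", gold.grey)):
            for p in sorted(pairs):
                fh.write(f"{p.a.namespace}\t{p.a.identifier}\t{p.b.namespace}\t{p.b.identifier}\t{cls}\n")


def read_ontology(path: str | Path) -> Ontology:
    """Read an ontology edge list TSV: child_ns, child_id, parent_ns,
    parent_id. Acyclicity is verified; a cycle raises ``ValueError``
    listing one offending cycle."""
    edges: set[tuple[EntityId, EntityId]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:1] == ["child_ns"]:
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            cns, cid, pns, pid = parts
            edges.add((EntityId(cns, cid), EntityId(pns, pid)))
    return Ontology(edges)


def write_ontology(onto: Ontology, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("child_ns\tchild_id\tparent_ns\tparent_id\n")
        for c, p in sorted(onto.edges):
            fh.write(f"{c.namespace}\t{c.identifier}\t{p.namespace}\t{p.identifier}\n")
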