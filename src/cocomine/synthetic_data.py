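"""Synthetic co-mention worlds with a planted, controllable context signal.

The generator emulates the statistical structure that distant
supervision relies on: sentences about truly associated entity pairs
contain association-stating language more often than sentences about
unassociated pairs. Each sentence is a bag of background tokens drawn
from a Zipf distribution, the two class placeholder tokens, and — with
probability ``pi1`` for truly associated pairs and ``pi0 <= pi1``
otherwise — one trigger token (e.g. "interacts") standing in for
association-stating phrasing. Setting ``pi1 == pi0`` produces a corpus
whose sentence context carries no information about association, the
null condition under which context-aware scoring cannot beat plain
counting.

Gold-standard incompleteness is modeled by withholding a fraction of the
truly associated pairs from the gold standard: their sentences keep the
planted trigger signal but distant supervision labels them negative.

Everything is deterministic per seed and produces objects that pass the
data-model invariants and round-trip through the TSV writers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
import numpy as np

from .data_model import (
    Comention,
    EntityId,
    EntityPair,
    GoldStandard,
    Ontology,
    placeholder_for,
)

__all__ = ["GeneratorConfig", "generate_world", "generate_corpus", "write_config", "read_config"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic world.

    Defaults define the standard recovery experiment: ~50 entities over
    two classes, 300 truly associated pairs, 5000 documents averaging two
    sentences, strong context signal (pi1 = 0.8 vs pi0 = 0.1) over a
    2000-word Zipf(1.1) background vocabulary.
    """

    n_entities: dict[str, int] = field(default_factory=lambda: {"disease": 25, "gene": 25})
    n_gold_positive: int = 300  # truly associated pairs (before withholding)
    n_grey: int = 15
    n_documents: int = 5000
    sentences_per_document: float = 2.0  # mean; every document has >= 1
    vocab_size: int = 2000
    zipf_exponent: float = 1.1
    triggers: tuple[str, ...] = ("interacts", "binds", "associates", "complex", "regulates")
    pi1: float = 0.8  # P(trigger | sentence about associated pair)
    pi0: float = 0.1  # P(trigger | sentence about non-associated pair)
    trigger_pair_prob: float = 0.3  # P(second trigger token | trigger fired)
    trigger_zipf_exponent: float = 1.0  # frequency skew across trigger synonyms
    gold_incompleteness: float = 0.0  # fraction of true pairs withheld from gold
    assoc_sentence_fraction: float = 0.5  # mixture weight of associated pairs
    background_tokens_mean: float = 8.0
    n_hidden_entities: int = 0  # per class, present in corpus but unknown to gold
    ontology_children: int = 0  # children per parent in the optional 2-level tree
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi1", "pi0", "gold_incompleteness", "assoc_sentence_fraction", "trigger_pair_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pi0 > self.pi1:
            raise ValueError("pi0 must not exceed pi1")
        if self.n_gold_positive < 0 or self.n_grey < 0 or self.n_documents <= 0:
            raise ValueError("counts must be positive")
        if self.vocab_size <= 0 or not self.n_entities:
            raise ValueError("vocabulary and entity classes must be non-empty")
        if self.sentences_per_document < 1.0:
            raise ValueError("sentences_per_document mean must be >= 1")


def _entity(cls: str, i: int, hidden: bool = False) -> EntityId:
    tag = "X" if hidden else cls[:1].upper()
    return EntityId(cls, f"{tag}{i:04d}")


def _candidate_pairs(entities_by_class: dict[str, list[EntityId]]) -> list[EntityPair]:
    classes = sorted(entities_by_class)
    if len(classes) == 1:
        pool = entities_by_class[classes[0]]
        return sorted(EntityPair.make(a, b) for a, b in combinations(pool, 2))
    # cross pairs between the first two classes
    return sorted(
        EntityPair.make(a, b)
        for a, b in product(entities_by_class[classes[0]], entities_by_class[classes[1]])
    )


def generate_world(
    config: GeneratorConfig,
) -> tuple[GoldStandard, Ontology, frozenset[EntityPair]]:
    """Sample entities, true associations, the (possibly incomplete) gold
    standard, a grey list, and an optional small ontology.

    Returns ``(gold, ontology, true_associations)``; with
    ``gold_incompleteness == 0`` the gold positives equal the true set.
    """
    rng = np.random.default_rng(config.seed)
    entities_by_class = {
        cls: [_entity(cls, i) for i in range(n)] for cls, n in config.n_entities.items()
    }
    known_entities = {e for pool in entities_by_class.values() for e in pool}
    if config.n_hidden_entities:
        for cls in list(entities_by_class):
            entities_by_class[cls] = entities_by_class[cls] + [
                _entity(cls, i, hidden=True) for i in range(config.n_hidden_entities)
            ]
    candidates = _candidate_pairs(entities_by_class)
    known_candidates = [p for p in candidates if p.a in known_entities and p.b in known_entities]

    if config.n_gold_positive + config.n_grey > len(known_candidates):
        raise ValueError(
            f"requested {config.n_gold_positive} positive + {config.n_grey} grey pairs "
            f"but only {len(known_candidates)} candidate pairs exist"
        )
    picked = rng.choice(len(known_candidates), size=config.n_gold_positive + config.n_grey, replace=False)
    true_assoc = frozenset(known_candidates[i] for i in picked[: config.n_gold_positive])
    grey = {known_candidates[i] for i in picked[config.n_gold_positive:]}

    n_withheld = int(round(config.gold_incompleteness * len(true_assoc)))
    withheld_idx = rng.choice(len(true_assoc), size=n_withheld, replace=False)
    true_sorted = sorted(true_assoc)
    withheld = {true_sorted[i] for i in withheld_idx}
    positives = set(true_assoc) - withheld

    gold = GoldStandard(positives=positives, grey=grey, entities=set(known_entities))

    edges: set[tuple[EntityId, EntityId]] = set()
    if config.ontology_children:
        onto_cls = sorted(config.n_entities)[0]
        parents = entities_by_class[onto_cls][: min(3, config.n_entities[onto_cls])]
        for p in parents:
            for j in range(config.ontology_children):
                child = EntityId(onto_cls, f"{p.identifier}c{j}")
                edges.add((child, p))
    return gold, Ontology(edges), true_assoc


def generate_corpus(
    world: tuple[GoldStandard, Ontology, frozenset[EntityPair]],
    config: GeneratorConfig,
) -> list[Comention]:
    """Emit blanked co-mention sentences over the generated world.

    Each sentence picks a pair (a mixture of truly associated and
    non-associated pairs), lays out the two class placeholders among
    Zipf-distributed background tokens, and plants trigger tokens with
    probability ``pi1`` or ``pi0`` depending on the pair's *true*
    association status (not its gold status, so withheld pairs keep the
    signal). When the trigger fires, one token is drawn from the trigger
    set with Zipf-skewed synonym frequencies and a second co-occurring
    trigger follows with probability ``trigger_pair_prob`` — mimicking
    association-stating language, where near-synonymous expressions have
    skewed usage frequencies and tend to appear together, which gives
    skipgram pretraining a learnable synonym structure.
    """
    gold, _onto, true_assoc = world
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    entities_by_class: dict[str, list[EntityId]] = {}
    universe = set(gold.entities)
    for p in true_assoc:
        universe.update(p.entities)
    # hidden entities only exist in the corpus; regenerate their ids
    if config.n_hidden_entities:
        for cls in config.n_entities:
            universe.update(_entity(cls, i, hidden=True) for i in range(config.n_hidden_entities))
    for e in sorted(universe):
        entities_by_class.setdefault(e.namespace, []).append(e)
    candidates = _candidate_pairs(entities_by_class)
    assoc_pool = sorted(true_assoc)
    non_assoc_pool = [p for p in candidates if p not in true_assoc]
    if not assoc_pool or not non_assoc_pool:
        raise ValueError("corpus generation needs both associated and non-associated pairs")

    background = [f"w{i}" for i in range(config.vocab_size)]
    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    zipf_p = ranks ** -config.zipf_exponent
    zipf_p /= zipf_p.sum()
    trig_ranks = np.arange(1, len(config.triggers) + 1, dtype=float)
    trig_p = trig_ranks ** -config.trigger_zipf_exponent
    trig_p /= trig_p.sum()

    records: list[Comention] = []
    for d in range(config.n_documents):
        doc_id = f"doc{d:06d}"
        n_sent = 1 + rng.poisson(config.sentences_per_document - 1.0)
        for s in range(n_sent):
            if rng.random() < config.assoc_sentence_fraction:
                pair = assoc_pool[rng.integers(len(assoc_pool))]
                p_trig = config.pi1
            else:
                pair = non_assoc_pool[rng.integers(len(non_assoc_pool))]
                p_trig = config.pi0
            n_bg = int(rng.poisson(config.background_tokens_mean))
            tokens = [background[i] for i in rng.choice(config.vocab_size, size=n_bg, p=zipf_p)]
            if rng.random() < p_trig:
                n_trig = 1 + int(rng.random() < config.trigger_pair_prob)
                pos = int(rng.integers(len(tokens) + 1))
                for ti in rng.choice(len(config.triggers), size=n_trig, p=trig_p):
                    tokens.insert(pos, config.triggers[ti])
            for ent in (pair.a, pair.b):
                tokens.insert(int(rng.integers(len(tokens) + 1)), placeholder_for(ent.namespace))
            records.append(
                Comention(
                    document_id=doc_id,
                    sentence_index=s,
                    pair=pair,
                    text=" ".join(tokens) + " .",
                )
            )
    return records


# ---------------------------------------------------------------------------
# Flat key=value config files
# ---------------------------------------------------------------------------

def write_config(config: GeneratorConfig, path: str | Path) -> None:
    """Write a generator config as a flat ``key=value`` file. Dict and
    tuple fields are comma-separated (``disease:25,gene:25``)."""
    with open(path, "w", encoding="utf-8") as fh:
        for f in dataclasses.fields(config):
            v = getattr(config, f.name)
            if isinstance(v, dict):
                v = ",".join(f"{k}:{n}" for k, n in sorted(v.items()))
            elif isinstance(v, tuple):
                v = ",".join(v)
            fh.write(f"{f.name}={v}\n")


def read_config(path: str | Path) -> GeneratorConfig:
    raw: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
    kwargs: dict = {}
    for f in dataclasses.fields(GeneratorConfig):
        if f.name not in raw:
            continue
        val = raw[f.name]
        if f.name == "n_entities":
            kwargs[f.name] = {
                k: int(n) for k, n in (item.split(":") for item in val.split(",") if item)
            }
        elif f.name == "triggers":
            kwargs[f.name] = tuple(t for t in val.split(",") if t)
        elif f.type in ("int", int):
            kwargs[f.name] = int(val)
        elif f.type in ("float", float):
            kwargs[f.name] = float(val)
        else:
            kwargs[f.name] = val
    return GeneratorConfig(**kwargs)
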