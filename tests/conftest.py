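import numpy as np
import pytest

from cocomine.data_model import Comention, EntityId, EntityPair


def make_pair(i: int, j: int, ns_a: str = "disease", ns_b: str = "gene") -> EntityPair:
    return EntityPair.make(EntityId(ns_a, f"D{i}"), EntityId(ns_b, f"G{j}"))


def random_comentions(rng: np.random.Generator, n: int = 20, n_docs: int = 6,
                      with_scores: bool = False) -> list[Comention]:
    """Random well-formed co-mentions over a small pair universe; keys unique."""
    out, used = [], set()
    while len(out) < n:
        doc = f"doc{rng.integers(n_docs)}"
        sent = int(rng.integers(5))
        pair = make_pair(int(rng.integers(4)), int(rng.integers(4)))
        if (doc, sent, pair) in used:
            continue
        used.add((doc, sent, pair))
        out.append(
            Comention(
                document_id=doc,
                sentence_index=sent,
                pair=pair,
                text=f"DISEASE_ w{rng.integers(30)} links GENE_ .",
                label=("positive", "negative", "unlabeled")[int(rng.integers(3))],
                sentence_score=float(rng.uniform(0.01, 0.99)) if with_scores else None,
            )
        )
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
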