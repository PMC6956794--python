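"""Sentence-level context classifier.

Scores a blanked sentence with the probability that it states an
association between the two co-mentioned entities. The model averages
unigram embeddings and hashed-bigram embeddings over the sentence and
feeds the resulting vector to a logistic regression layer; embeddings
and logistic weights are trained jointly by stochastic gradient descent
on the distantly supervised positive/negative labels. Unigram vectors
may be initialized from skipgram embeddings pretrained on a larger
unlabeled corpus (transfer learning); bigram bucket vectors always start
from seeded random initialization.

Defaults follow the reference configuration: 300-dimensional embeddings,
50 SGD epochs at learning rate 0.005 with linear decay, unigrams plus
hashed bigrams. The bigram hash is 64-bit FNV-1a of ``"tok1 tok2"``
modulo the bucket count — fixed and platform-independent, so identical
seeds give bit-identical models.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .data_model import DEFAULT_PLACEHOLDERS, Comention

__all__ = [
    "Hyperparams",
    "EmbeddingTable",
    "SentenceClassifier",
    "tokenize",
    "bigram_bucket",
    "featurize",
    "sentence_vector",
    "train",
    "predict",
    "predict_comentions",
    "pretrain_embeddings",
    "save_classifier",
    "load_classifier",
    "read_word2vec",
    "write_word2vec",
]


@dataclass(frozen=True)
class Hyperparams:
    """Training configuration for the sentence classifier.

    ``dim`` must match pretrained vectors when those are supplied.
    ``n_buckets`` is the hash space for bigram features; small test
    configurations may shrink it (e.g. to 10_000) without changing
    behavior other than hash collision rates.
    """

    dim: int = 300
    epochs: int = 50
    learning_rate: float = 0.005
    use_bigrams: bool = True
    n_buckets: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim <= 0 or self.epochs <= 0 or self.n_buckets <= 0:
            raise ValueError("dim, epochs and n_buckets must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EmbeddingTable:
    """Unigram vocabulary plus vectors, and optional bigram bucket vectors."""

    vocabulary: dict[str, int]
    vectors: np.ndarray  # (|V|, dim)
    bigram_vectors: np.ndarray | None = None  # (n_buckets, dim)

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __post_init__(self) -> None:
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError("vocabulary size does not match vector rows")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite unigram vectors")


@dataclass
class SentenceClassifier:
    """Trained sentence scorer: embeddings plus logistic weights."""

    embeddings: EmbeddingTable
    weights: np.ndarray  # (dim,)
    bias: float
    hyperparams: Hyperparams


_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize(text: str, placeholders: Iterable[str] | None = None) -> list[str]:
    """Lowercase and split a blanked sentence into tokens.

    Punctuation is split from words; placeholder tokens (default: the
    standard class placeholders such as ``GENE_``) are preserved
    verbatim. Idempotent on its own space-joined output.
    """
    keep = set(DEFAULT_PLACEHOLDERS.values()) if placeholders is None else set(placeholders)
    out: list[str] = []
    for tok in _TOKEN_RE.findall(text):
        out.append(tok if tok in keep else tok.lower())
    return out


def _fnv1a64(data: bytes) -> int:
    h = 0xCBF29CE484222325
    for byte in data:
        h ^= byte
        h = (h * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return h


def bigram_bucket(tok1: str, tok2: str, n_buckets: int) -> int:
    """Hash an adjacent token pair into a bigram bucket (FNV-1a 64-bit)."""
    return _fnv1a64(f"{tok1} {tok2}".encode("utf-8")) % n_buckets


def featurize(
    tokens: Sequence[str], vocabulary: dict[str, int], hp: Hyperparams
) -> tuple[np.ndarray, np.ndarray]:
    """Map tokens to feature indices.

    Returns ``(unigram_rows, bigram_buckets)``: one unigram index per
    in-vocabulary token (out-of-vocabulary tokens are skipped) and, when
    bigrams are enabled, exactly ``len(tokens) - 1`` hashed bucket
    indices for adjacent token pairs (bigrams hash regardless of
    vocabulary membership).
    """
    uni = np.array([vocabulary[t] for t in tokens if t in vocabulary], dtype=np.int64)
    if hp.use_bigrams and len(tokens) >= 2:
        bi = np.array(
            [bigram_bucket(tokens[i], tokens[i + 1], hp.n_buckets) for i in range(len(tokens) - 1)],
            dtype=np.int64,
        )
    else:
        bi = np.empty(0, dtype=np.int64)
    return uni, bi


def sentence_vector(
    features: tuple[np.ndarray, np.ndarray], embeddings: EmbeddingTable
) -> np.ndarray:
    """Arithmetic mean of all selected feature vectors; zero vector when
    the feature set is empty."""
    uni, bi = features
    n = len(uni) + len(bi)
    if n == 0:
        return np.zeros(embeddings.dim)
    total = embeddings.vectors[uni].sum(axis=0) if len(uni) else 0.0
    if len(bi):
        if embeddings.bigram_vectors is None:
            raise ValueError("bigram features requested but table has no bigram vectors")
        total = total + embeddings.bigram_vectors[bi].sum(axis=0)
    return np.asarray(total) / n


def _sigmoid(z: float | np.ndarray):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30.0, 30.0)))


def train(
    comentions: Sequence[Comention],
    hp: Hyperparams = Hyperparams(),
    pretrained: EmbeddingTable | None = None,
) -> SentenceClassifier:
    """Train the sentence classifier on distantly supervised co-mentions.

    Records labeled other than positive/negative are dropped. Embedding
    rows and logistic weights are updated jointly by per-sentence SGD on
    the binary cross-entropy loss, with the learning rate decaying
    linearly to zero over all updates; sentence order is reshuffled each
    epoch with the run seed, so training is deterministic given
    ``hp.seed``.

    When ``pretrained`` is given, unigram rows for words present in the
    pretrained vocabulary are initialized from it (dimension must match);
    all other rows, and all bigram buckets, get small seeded random
    initialization.
    """
    texts: list[str] = []
    ys: list[float] = []
    for rec in comentions:
        if rec.label == "positive":
            texts.append(rec.text)
            ys.append(1.0)
        elif rec.label == "negative":
            texts.append(rec.text)
            ys.append(0.0)
    if not texts or min(ys) == max(ys):
        raise ValueError("training requires at least one positive and one negative sentence")
    if pretrained is not None and pretrained.dim != hp.dim:
        raise ValueError(f"pretrained dim {pretrained.dim} != hyperparameter dim {hp.dim}")

    tokenized = [tokenize(t) for t in texts]
    vocab_words = sorted({tok for toks in tokenized for tok in toks})
    vocabulary = {w: i for i, w in enumerate(vocab_words)}

    rng = np.random.default_rng(hp.seed)
    bound = 1.0 / hp.dim
    vectors = rng.uniform(-bound, bound, size=(len(vocabulary), hp.dim))
    if pretrained is not None:
        for word, row in vocabulary.items():
            src = pretrained.vocabulary.get(word)
            if src is not None:
                vectors[row] = pretrained.vectors[src]
    bigram_vectors = (
        rng.uniform(-bound, bound, size=(hp.n_buckets, hp.dim)) if hp.use_bigrams else None
    )
    table = EmbeddingTable(vocabulary=vocabulary, vectors=vectors, bigram_vectors=bigram_vectors)

    feats = [featurize(toks, vocabulary, hp) for toks in tokenized]
    y = np.asarray(ys)
    weights = np.zeros(hp.dim)
    bias = 0.0

    n = len(feats)
    total_updates = hp.epochs * n
    t = 0
    order = np.arange(n)
    for _epoch in range(hp.epochs):
        rng.shuffle(order)
        for i in order:
            uni, bi = feats[i]
            nf = len(uni) + len(bi)
            lr = hp.learning_rate * (1.0 - t / total_updates)
            t += 1
            if nf == 0:
                # bias-only update
                g = _sigmoid(bias) - y[i]
                bias -= lr * g
                continue
            v = sentence_vector((uni, bi), table)
            g = float(_sigmoid(weights @ v + bias) - y[i])
            grad_v = (lr * g / nf) * weights  # backprop through the mean
            weights = weights - lr * g * v
            bias -= lr * g
            if len(uni):
                np.subtract.at(vectors, uni, grad_v)
            if len(bi):
                np.subtract.at(bigram_vectors, bi, grad_v)
    return SentenceClassifier(embeddings=table, weights=weights, bias=bias, hyperparams=hp)


def predict(classifier: SentenceClassifier, text: str) -> float:
    """Score a blanked sentence: probability in (0, 1) that it states an
    association."""
    hp = classifier.hyperparams
    feats = featurize(tokenize(text), classifier.embeddings.vocabulary, hp)
    v = sentence_vector(feats, classifier.embeddings)
    return float(_sigmoid(classifier.weights @ v + classifier.bias))


def predict_comentions(
    classifier: SentenceClassifier, comentions: Sequence[Comention]
) -> list[Comention]:
    """Attach a sentence score to every co-mention."""
    cache: dict[str, float] = {}
    out = []
    for rec in comentions:
        score = cache.get(rec.text)
        if score is None:
            score = predict(classifier, rec.text)
            cache[rec.text] = score
        out.append(replace(rec, sentence_score=score))
    return out


# ---------------------------------------------------------------------------
# Skipgram pretraining
# ---------------------------------------------------------------------------

def pretrain_embeddings(
    sentences: Sequence[Sequence[str]],
    dim: int,
    seed: int,
    window: int = 5,
    epochs: int = 3,
    negative: int = 5,
    learning_rate: float = 0.05,
) -> EmbeddingTable:
    """Pretrain unigram vectors with skipgram + negative sampling.

    Each center word's vector is trained to score true context words
    (within ``window``) above ``negative`` noise words drawn from the
    unigram distribution raised to 3/4. Deterministic per seed. Intended
    for moderate corpus sizes; the classifier consumes the result via
    :func:`train`'s ``pretrained`` argument.
    """
    sentences = [list(s) for s in sentences if len(s) > 0]
    if not sentences:
        raise ValueError("empty corpus")
    vocab_words = sorted({tok for s in sentences for tok in s})
    vocabulary = {w: i for i, w in enumerate(vocab_words)}
    nv = len(vocabulary)

    counts = np.zeros(nv)
    encoded = []
    for s in sentences:
        idx = np.array([vocabulary[t] for t in s], dtype=np.int64)
        encoded.append(idx)
        np.add.at(counts, idx, 1.0)
    noise = counts ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    in_vec = rng.uniform(-0.5 / dim, 0.5 / dim, size=(nv, dim))
    out_vec = np.zeros((nv, dim))

    n_sent = len(encoded)
    total = epochs * n_sent
    step = 0
    order = np.arange(n_sent)
    for _epoch in range(epochs):
        rng.shuffle(order)
        for si in order:
            lr = learning_rate * max(1e-4, 1.0 - step / total)
            step += 1
            sent = encoded[si]
            for pos, center in enumerate(sent):
                lo = max(0, pos - window)
                hi = min(len(sent), pos + window + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    targets = np.empty(1 + negative, dtype=np.int64)
                    targets[0] = sent[cpos]
                    targets[1:] = rng.choice(nv, size=negative, p=noise)
                    labels = np.zeros(1 + negative)
                    labels[0] = 1.0
                    v = in_vec[center]
                    outs = out_vec[targets]
                    g = _sigmoid(outs @ v) - labels  # (k+1,)
                    grad_in = g @ outs
                    np.subtract.at(out_vec, targets, lr * g[:, None] * v[None, :])
                    in_vec[center] = v - lr * grad_in
    return EmbeddingTable(vocabulary=vocabulary, vectors=in_vec)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_word2vec(table: EmbeddingTable, path: str | Path) -> None:
    """Write unigram vectors in word2vec text format."""
    words = sorted(table.vocabulary, key=table.vocabulary.get)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {table.dim}\n")
        for w in words:
            row = " ".join(repr(float(x)) for x in table.vectors[table.vocabulary[w]])
            fh.write(f"{w} {row}\n")


def read_word2vec(path: str | Path) -> EmbeddingTable:
    """Read vectors in word2vec text format (header ``<n> <dim>``)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        n, dim = int(header[0]), int(header[1])
        vocabulary: dict[str, int] = {}
        vectors = np.zeros((n, dim))
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: row {i} has {len(parts) - 1} values, expected {dim}")
            vocabulary[parts[0]] = i
            vectors[i] = [float(x) for x in parts[1:]]
    return EmbeddingTable(vocabulary=vocabulary, vectors=vectors)


def save_classifier(classifier: SentenceClassifier, path: str | Path) -> None:
    """Save a classifier to a flat text file: hyperparameters (JSON line),
    unigram vectors in word2vec layout, bigram bucket vectors, logistic
    weights and bias."""
    hp = classifier.hyperparams
    emb = classifier.embeddings
    words = sorted(emb.vocabulary, key=emb.vocabulary.get)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cocomine-classifier 1\n")
        fh.write(json.dumps(hp.__dict__) + "\n")
        fh.write(f"unigrams {len(words)} {emb.dim}\n")
        for w in words:
            fh.write(w + " " + " ".join(repr(float(x)) for x in emb.vectors[emb.vocabulary[w]]) + "\n")
        if emb.bigram_vectors is not None:
            fh.write(f"bigrams {emb.bigram_vectors.shape[0]} {emb.dim}\n")
            for row in emb.bigram_vectors:
                fh.write(" ".join(repr(float(x)) for x in row) + "\n")
        else:
            fh.write("bigrams 0 0\n")
        fh.write("weights " + " ".join(repr(float(x)) for x in classifier.weights) + "\n")
        fh.write(f"bias {classifier.bias!r}\n")


def load_classifier(path: str | Path) -> SentenceClassifier:
    with open(path, encoding="utf-8") as fh:
        magic = fh.readline().split()
        if magic[:1] != ["cocomine-classifier"]:
            raise ValueError(f"{path}: not a classifier file")
        hp = Hyperparams(**json.loads(fh.readline()))
        tag, n, dim = fh.readline().split()
        assert tag == "unigrams"
        n, dim = int(n), int(dim)
        vocabulary: dict[str, int] = {}
        vectors = np.zeros((n, dim))
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            vocabulary[parts[0]] = i
            vectors[i] = [float(x) for x in parts[1:]]
        tag, nb, bdim = fh.readline().split()
        assert tag == "bigrams"
        nb, bdim = int(nb), int(bdim)
        bigram_vectors = None
        if nb:
            bigram_vectors = np.zeros((nb, bdim))
            for i in range(nb):
                bigram_vectors[i] = [float(x) for x in fh.readline().split()]
        wparts = fh.readline().split()
        assert wparts[0] == "weights"
        weights = np.array([float(x) for x in wparts[1:]])
        bparts = fh.readline().split()
        assert bparts[0] == "bias"
        bias = float(bparts[1])
    emb = EmbeddingTable(vocabulary=vocabulary, vectors=vectors, bigram_vectors=bigram_vectors)
    return SentenceClassifier(embeddings=emb, weights=weights, bias=bias, hyperparams=hp)
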