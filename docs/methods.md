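# Methods

## Problem and model

The package scores candidate associations between pairs of named
biomedical entities (gene–disease, protein–protein, tissue–gene, ...)
from sentence-level co-mentions in a literature corpus. It combines two
components:

1. **A distantly supervised sentence classifier.** Sentences
   co-mentioning a pair found in a curated gold standard are weakly
   labeled positive; sentences whose two entities are known to the gold
   standard but not associated in it are labeled negative. Grey-listed
   pairs (intermediate evidence) and pairs with entities absent from the
   gold standard are excluded from both classes. The classifier maps a
   blanked sentence (entity names replaced by class placeholders such as
   `GENE_`) to the probability that it states an association. It
   averages unigram embeddings and hashed-bigram embeddings over the
   sentence and applies a logistic layer; embeddings and logistic
   weights are trained jointly by per-sentence SGD on binary
   cross-entropy.

2. **A corpus-level aggregation scheme.** For a pair (i, j), each
   document contributes its maximum sentence score
   s_k(i,j) = max_u r_u(i,j); summing over documents gives the soft
   co-occurrence count C(i,j). Final scores are

   S(i,j) = C(i,j)^α · ( C(i,j)·C(·,·) / (C(i,·)·C(·,j)) )^(1−α)

   where C(i,·), C(·,j) are entity marginals and C(·,·) the grand total.
   α ∈ [0,1] trades raw evidence volume against the observed-over-expected
   enrichment ratio. The count-based **baseline** replaces every
   document's contribution with 1 (C̃ = number of distinct co-mentioning
   documents) and uses the same combination formula; it represents the
   classical co-occurrence scoring used by association databases.

Evaluation is pair-level: an 80/20 train/test split is drawn over entity
pairs (never over sentences, preventing identity leakage), training-side
co-mentions are capped at 100 per pair, and performance is the area
under the precision–recall curve with precision rescaled to a fixed 10%
positive prior,

    precision_adj = (a/b)·TP / ( (a/b)·TP + ((1−a)/(1−b))·FP ),

with a = 0.1 the target prior and b the observed positive fraction. The
adjustment makes areas comparable across datasets with different class
balance; with a = b it reduces to ordinary precision, a perfect ranker
scores 1 and a random one scores ≈ a. Areas are integrated by
average-precision (rectangular) summation — linear PR interpolation is
known to be optimistic. AUROC is computed by the Mann–Whitney statistic
with half-credit for ties. α is tuned by 3-fold pair-level
cross-validation; model comparisons use 1000 pair-level bootstrap
replicates, reporting per-model SDs and a paired t-test on replicate
differences (paired, because both models are evaluated on the same
replicate).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.65 (context) / 0.55 (baseline) | count vs enrichment exponent; cross-validated optima |
| `dim` | 300 | embedding dimensionality |
| `epochs` | 50 | SGD passes over the training sentences |
| `learning_rate` | 0.005 | initial SGD step, decayed linearly to 0 |
| `use_bigrams` | on | hashed bigram features capturing local word order |
| `n_buckets` | 2,000,000 | bigram hash space (tests and desk-scale runs use 10,000) |
| `max_per_pair` | 100 | training-side co-mention cap per pair |
| `test_fraction` | 0.2 | pair-level test share |
| `a` | 0.1 | target positive prior of the adjusted PR analysis |
| `n_boot` | 1000 | bootstrap replicates for model comparison |

Bigram features use a fixed 64-bit FNV-1a hash of `"tok1 tok2"` modulo
`n_buckets`, so feature identities are stable across platforms and runs.
The tokenizer lowercases, splits punctuation from words, and preserves
placeholder tokens verbatim.

## Numerical and design choices

- **Training determinism.** All randomness (embedding init, per-epoch
  shuffling) flows from one seed; two runs with the same seed produce
  bit-identical models. The logistic pre-activation is clipped to ±30
  before the sigmoid to avoid overflow without affecting scores
  materially.
- **Empty sentences** predict `sigmoid(bias)`; an empty feature set
  yields the zero sentence vector.
- **Out-of-vocabulary unigrams** are skipped; bigrams hash regardless of
  vocabulary, so unseen word pairs still map to (shared) buckets.
- **Pretraining** is a seeded skipgram with negative sampling (window 5,
  unigram^0.75 noise distribution) producing unigram vectors only;
  bigram buckets always start from small seeded random values. When
  pretrained vectors are supplied, rows for known words are copied and
  the logistic layer rescales them as needed.
- **Marginals** in the combination formula are computed over the pair
  set actually being scored (e.g. the test side after the split), not
  over an unrestricted corpus — self-contained and reproducible.
- **Zero-count pairs** are omitted from score tables rather than given
  S = 0; the evaluation treats gold pairs absent from the score table as
  scored 0, so they count toward recall.
- **Ties** in scores share one PR/ROC threshold — no ordering luck.
- **Scale law.** Multiplying all sentence scores by c multiplies every
  count by c and every final score by c^α: the enrichment ratio is
  scale-invariant, so only the count factor responds. Rankings are
  unchanged, which is why an approximately-constant sentence scorer
  cannot beat the baseline.
- **Ontology propagation** adds, for every gold pair involving an
  ontology term, the same pair for every descendant term, in one
  configured namespace; grey status propagates the same way but never
  overrides positive status. Child pairs become first-class gold
  entries; no remapping onto ancestors is performed.
- **Degenerate bootstrap replicates** (single class after resampling)
  are redrawn, with the redraw count capped at 100× the replicate count
  and reported.
- **CV tie-breaks** go to the smaller α; folds whose held-out side is
  single-class are skipped.

## The synthetic-data generator

Real corpora cannot be redistributed, so the generator plants the
statistical structure distant supervision assumes and the method
exploits: sentences about truly associated pairs contain
association-stating language more often than others. Each sentence is a
bag of Zipf(1.1)-distributed background tokens (vocabulary 2000), the
two class placeholders, and — with probability π1 = 0.8 for associated
pairs, π0 = 0.1 otherwise — trigger tokens standing in for phrases like
"interacts with". Trigger synonyms have Zipf-skewed usage frequencies
and co-occur in pairs 30% of the time, mimicking the redundancy of
association language; this is what gives skipgram pretraining a synonym
structure worth transferring to small supervised sets. Gold
incompleteness is modeled by withholding a configurable fraction of
truly associated pairs from the gold standard while their sentences keep
the planted signal.

The default world has 25 diseases × 25 genes, 300 truly associated
pairs, 15 grey pairs and 5000 documents averaging two sentences. At
these sizes the per-pair co-mention counts of associated and
non-associated pairs are nearly equal, so plain counting carries little
signal and the benefit of context-aware scoring is isolated; with
π1 = π0 the context signal vanishes by construction and both models
perform alike (their score tables become monotone transforms of each
other up to classifier noise).

What the generator does **not** emulate: English syntax, NER errors,
entity-frequency skew across pairs, document-length structure, negation
and modality phrasing (a small template bank could be layered on top),
and correlations between gold membership and publication volume. Passing
the recovery tests therefore shows the machinery is correct and the
planted signal is recoverable — not that any particular real-corpus
performance level will be reached.

## Desk-scale test settings

The test suite and example runs use reduced sizes chosen to keep full
runs fast while leaving the planted signal clearly recoverable:
embedding dimension 16–50, 10,000 or fewer hash buckets, vocabulary
200–2000, corpora of 400–5000 documents, and higher learning rates
(0.05) for the very small training sets where 50 epochs × 0.005 moves
the weights too little. The recovery experiment (10 seeds, 5000
documents each) trains in roughly 15 s per seed on one CPU.

## Known limitations

- The classifier is a bag-of-embeddings model: word order enters only
  through bigrams, so long-range negation scope is out of reach.
- Scores depend on the evaluated pair set through the marginals;
  restricting the pair universe changes S (not the counts).
- The skipgram pretrainer is written for clarity and determinism, not
  throughput; for corpora beyond ~10^5 sentences an external embedding
  trainer producing word2vec-format text files is the practical route
  (the loader accepts any such file).
- Distant supervision inherits gold-standard incompleteness: withheld
  true associations are counted as false positives in evaluation, which
  deflates measured precision (observable directly with the generator's
  `gold_incompleteness` knob).
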