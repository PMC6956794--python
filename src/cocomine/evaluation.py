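"""Pair-level evaluation: splitting, downsampling, PR/ROC analysis with
class-prior adjustment, cross-validation over alpha, and bootstrap model
comparison.

Train/test splitting and cross-validation folding operate on entity
pairs, never on individual sentences, so all co-mentions of a pair land
on one side — this prevents leakage of pair identity between training
and evaluation.

Precision can be *adjusted* to a fixed positive-class prior ``a``
(default 10%) so that areas under the precision–recall curve are
comparable across datasets with different positive fractions ``b``:

    precision_adj = (a/b) TP / ( (a/b) TP + ((1-a)/(1-b)) FP )

With ``a = b`` this reduces to ordinary precision. Areas are integrated
by average-precision (rectangular) summation over threshold steps; a
random scorer then has adjusted area ~= a, and a perfect scorer 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import Comention, EntityPair
from .scoring import baseline_counts, co_occurrence_counts, combine, document_scores
from .sentence_model import Hyperparams, predict_comentions, train

__all__ = [
    "ADJUST_PRIOR",
    "PRCurve",
    "EvalResult",
    "BootstrapResult",
    "split_pairs",
    "downsample_train",
    "pair_labels",
    "adjusted_precision",
    "pr_curve",
    "auprc",
    "auroc",
    "evaluate_pairs",
    "cv_alpha",
    "DEFAULT_ALPHA_GRID",
    "bootstrap_compare",
]

#: Target positive fraction used for the class-prior adjustment.
ADJUST_PRIOR = 0.1

#: Cross-validation grid for the count/enrichment trade-off exponent.
DEFAULT_ALPHA_GRID = tuple(round(0.05 * k, 2) for k in range(21))


# ---------------------------------------------------------------------------
# Splitting and downsampling
# ---------------------------------------------------------------------------

def split_pairs(
    pairs: Sequence[EntityPair], test_fraction: float = 0.2, seed: int = 0
) -> tuple[set[EntityPair], set[EntityPair]]:
    """Partition pairs into train/test sets at the pair level.

    Deterministic per seed; the test side receives
    ``round(n * test_fraction)`` pairs.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    uniq = sorted(set(pairs))
    if not uniq:
        raise ValueError("no pairs to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    n_test = int(round(len(uniq) * test_fraction))
    test = {uniq[i] for i in order[:n_test]}
    train_ = {uniq[i] for i in order[n_test:]}
    return train_, test


def downsample_train(
    comentions: Sequence[Comention], max_per_pair: int = 100, seed: int = 0
) -> list[Comention]:
    """Cap the number of co-mentions per pair by uniform subsampling
    without replacement (training side only, so the classifier does not
    overfit to heavily published pairs). Deterministic per seed; input
    order is preserved among kept records."""
    if max_per_pair < 1:
        raise ValueError("max_per_pair must be >= 1")
    by_pair: dict[EntityPair, list[int]] = {}
    for i, rec in enumerate(comentions):
        by_pair.setdefault(rec.pair, []).append(i)
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for pair in sorted(by_pair):
        idx = by_pair[pair]
        if len(idx) <= max_per_pair:
            keep.update(idx)
        else:
            chosen = rng.choice(len(idx), size=max_per_pair, replace=False)
            keep.update(idx[j] for j in chosen)
    return [rec for i, rec in enumerate(comentions) if i in keep]


def pair_labels(comentions: Sequence[Comention]) -> dict[EntityPair, bool]:
    """Pair-level binary labels from distantly supervised co-mentions:
    True iff labeled positive. Grey-listed and unknown-entity pairs are
    excluded entirely."""
    out: dict[EntityPair, bool] = {}
    for rec in comentions:
        if rec.label == "positive":
            out[rec.pair] = True
        elif rec.label == "negative":
            out[rec.pair] = False
    return out


# ---------------------------------------------------------------------------
# PR / ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class PRCurve:
    """Step precision–recall curve, one point per distinct score
    threshold in descending order; tied scores share a threshold."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    adjusted_precision: np.ndarray
    a: float
    b: float


@dataclass(frozen=True)
class EvalResult:
    auprc: float
    adjusted_auprc: float
    auroc: float
    n_pairs: int
    n_positives: int
    bootstrap_sd: float = float("nan")


def adjusted_precision(tp, fp, a: float, b: float):
    """Precision rescaled to a target positive prior ``a`` from the
    observed prior ``b``; equals TP/(TP+FP) when a == b."""
    if not (0.0 < a < 1.0 and 0.0 < b < 1.0):
        raise ValueError(f"priors must be strictly inside (0, 1): a={a}, b={b}")
    wt = (a / b) * np.asarray(tp, dtype=float)
    wf = ((1.0 - a) / (1.0 - b)) * np.asarray(fp, dtype=float)
    return wt / (wt + wf)


def _as_arrays(
    scores: Mapping[EntityPair, float], labels: Mapping[EntityPair, bool]
) -> tuple[np.ndarray, np.ndarray]:
    pairs = sorted(labels)
    y = np.array([bool(labels[p]) for p in pairs])
    s = np.array([float(scores.get(p, 0.0)) for p in pairs])
    return s, y


def pr_curve(
    scores: Mapping[EntityPair, float],
    labels: Mapping[EntityPair, bool],
    a: float = ADJUST_PRIOR,
) -> PRCurve:
    """Precision–recall curve over labeled pairs.

    Pairs present in ``labels`` but missing from ``scores`` are scored 0
    (never co-mentioned above threshold, they still count toward P).
    Requires at least one positive and one negative pair. ``b`` is the
    observed positive fraction of the evaluated set.
    """
    s, y = _as_arrays(scores, labels)
    pos_total = int(y.sum())
    if pos_total == 0 or pos_total == len(y):
        raise ValueError("pr_curve requires both a positive and a negative pair")
    b = pos_total / len(y)

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    cum_tp = np.cumsum(y_sorted)
    cum_fp = np.cumsum(~y_sorted)
    # last index of each distinct threshold group
    last = np.nonzero(np.diff(s_sorted, append=np.nan))[0]
    thresholds = s_sorted[last]
    tp = cum_tp[last].astype(float)
    fp = cum_fp[last].astype(float)
    fn = pos_total - tp
    precision = tp / (tp + fp)
    return PRCurve(
        thresholds=thresholds,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=tp / pos_total,
        adjusted_precision=adjusted_precision(tp, fp, a, b),
        a=a,
        b=b,
    )


def auprc(curve: PRCurve, adjusted: bool = False) -> float:
    """Area under the (adjusted-)precision vs recall step curve by
    average-precision summation: sum over threshold steps of
    (delta recall x precision at that step)."""
    prec = curve.adjusted_precision if adjusted else curve.precision
    drec = np.diff(curve.recall, prepend=0.0)
    return float(np.sum(drec * prec))


def auroc(
    scores: Mapping[EntityPair, float], labels: Mapping[EntityPair, bool]
) -> float:
    """Area under the ROC curve via the Mann–Whitney statistic:
    P(score_pos > score_neg) + 0.5 P(tie)."""
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_pairs(
    scores: Mapping[EntityPair, float],
    labels: Mapping[EntityPair, bool],
    a: float = ADJUST_PRIOR,
) -> EvalResult:
    """AUPRC, adjusted AUPRC and AUROC for one scored pair set."""
    curve = pr_curve(scores, labels, a=a)
    return EvalResult(
        auprc=auprc(curve),
        adjusted_auprc=auprc(curve, adjusted=True),
        auroc=auroc(scores, labels),
        n_pairs=len(labels),
        n_positives=int(sum(labels.values())),
    )


# ---------------------------------------------------------------------------
# Cross-validation over alpha
# ---------------------------------------------------------------------------

def _score_pairs(
    train_side: Sequence[Comention],
    eval_side: Sequence[Comention],
    model: str,
    hp: Hyperparams,
    pretrained=None,
):
    """Score eval-side pairs with either the context-aware model (train a
    sentence classifier on the train side, aggregate max-per-document
    sentence scores) or the count-based baseline. Returns the count table
    (scores not yet combined)."""
    if model == "baseline":
        return baseline_counts(eval_side)
    clf = train(train_side, hp, pretrained=pretrained)
    scored = predict_comentions(clf, eval_side)
    return co_occurrence_counts(document_scores(scored))


def cv_alpha(
    comentions: Sequence[Comention],
    folds: int = 3,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    seed: int = 0,
    model: str = "context",
    hp: Hyperparams = Hyperparams(),
    pretrained=None,
    a: float = ADJUST_PRIOR,
) -> tuple[float, dict[float, float]]:
    """Tune alpha by pair-level k-fold cross-validation on the training
    co-mentions.

    For each fold, the sentence classifier is retrained on the fold's
    training pairs (no leakage), the held-out pairs are scored, and each
    alpha in the grid is evaluated by adjusted AUPRC; the returned alpha
    maximizes the mean across usable folds, ties broken toward smaller
    alpha. Folds whose held-out side ends up single-class are skipped.
    """
    if not alpha_grid:
        raise ValueError("alpha_grid must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labeled = [r for r in comentions if r.label in ("positive", "negative")]
    pairs = sorted({r.pair for r in labeled})
    if len(pairs) < folds:
        raise ValueError(f"cannot make {folds} folds from {len(pairs)} pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    fold_of = {pairs[i]: int(k % folds) for k, i in enumerate(order)}

    perf: dict[float, list[float]] = {float(al): [] for al in alpha_grid}
    for f in range(folds):
        tr = [r for r in labeled if fold_of[r.pair] != f]
        va = [r for r in labeled if fold_of[r.pair] == f]
        va_labels = pair_labels(va)
        if not va_labels or len(set(va_labels.values())) < 2:
            continue
        try:
            table = _score_pairs(tr, va, model, hp, pretrained)
        except ValueError:
            continue  # fold train side single-class
        for al in perf:
            scored = combine(table, al)
            curve = pr_curve(scored.scores, va_labels, a=a)
            perf[al].append(auprc(curve, adjusted=True))
    means = {al: float(np.mean(v)) for al, v in perf.items() if v}
    if not means:
        raise ValueError("no usable folds (single-class folds everywhere)")
    best = min(means, key=lambda al: (-means[al], al))
    return best, means


# ---------------------------------------------------------------------------
# Bootstrap model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    sd_a: float
    sd_b: float
    mean_diff: float  # mean over replicates of (adjusted AUPRC A - B)
    p_value: float
    n_boot: int
    n_degenerate_redraws: int


def bootstrap_compare(
    scores_a: Mapping[EntityPair, float],
    scores_b: Mapping[EntityPair, float],
    labels: Mapping[EntityPair, bool],
    n_boot: int = 1000,
    seed: int = 0,
    a: float = ADJUST_PRIOR,
) -> BootstrapResult:
    """Compare two scorers on the same labeled pair set by bootstrap.

    Pairs are resampled with replacement ``n_boot`` times; each replicate
    yields an adjusted AUPRC for both scorers. Reports the SD of each
    scorer's replicate distribution and a paired t-test p-value on the
    replicate differences. Single-class replicates are redrawn (the
    redraw count is capped at 100 x n_boot and reported).
    """
    pairs = sorted(labels)
    y = np.array([bool(labels[p]) for p in pairs])
    sa = np.array([float(scores_a.get(p, 0.0)) for p in pairs])
    sb = np.array([float(scores_b.get(p, 0.0)) for p in pairs])
    if y.sum() in (0, len(y)):
        raise ValueError("bootstrap_compare requires both classes")
    rng = np.random.default_rng(seed)
    reps_a = np.empty(n_boot)
    reps_b = np.empty(n_boot)
    redraws = 0
    max_redraws = 100 * n_boot
    i = 0
    while i < n_boot:
        idx = rng.integers(0, len(pairs), size=len(pairs))
        yy = y[idx]
        if yy.sum() in (0, len(yy)):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        reps_a[i] = _adjusted_auprc_arrays(sa[idx], yy, a)
        reps_b[i] = _adjusted_auprc_arrays(sb[idx], yy, a)
        i += 1
    diff = reps_a - reps_b
    if np.allclose(diff.std(ddof=1), 0.0):
        p = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
    else:
        p = float(stats.ttest_rel(reps_a, reps_b).pvalue)
    return BootstrapResult(
        sd_a=float(reps_a.std(ddof=1)),
        sd_b=float(reps_b.std(ddof=1)),
        mean_diff=float(diff.mean()),
        p_value=p,
        n_boot=n_boot,
        n_degenerate_redraws=redraws,
    )


def _adjusted_auprc_arrays(s: np.ndarray, y: np.ndarray, a: float) -> float:
    """Adjusted AUPRC on raw arrays (bootstrap replicates may repeat
    pairs, so the mapping interface does not apply)."""
    pos_total = int(y.sum())
    b = pos_total / len(y)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    cum_tp = np.cumsum(y_sorted)
    cum_fp = np.cumsum(~y_sorted)
    last = np.nonzero(np.diff(s_sorted, append=np.nan))[0]
    tp = cum_tp[last].astype(float)
    fp = cum_fp[last].astype(float)
    prec = adjusted_precision(tp, fp, a, b)
    rec = tp / pos_total
    return float(np.sum(np.diff(rec, prepend=0.0) * prec))
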