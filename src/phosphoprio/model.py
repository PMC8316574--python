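"""Functional-phosphosite scoring: training, evaluation, normalization.

The scorer is a binary logistic regression over the eight feature columns
(``features.FEATURE_COLUMNS``).  Training follows a benchmark protocol for
a small positive class: the positives are fixed, and ``n_sets`` benchmark
sets are drawn by sampling ``ratio`` negatives per positive without
replacement from a large negative pool.  Each benchmark is evaluated by
stratified 10-fold cross-validation; the final model is the one refit on
the benchmark with the highest cross-validated AUC.

Raw decision scores are mapped to [0, 1] by an outlier-robust min-max map:
Tukey-style fences at Q1 - 3*IQ and Q3 + 3*IQ clip extreme scores to 0/1,
and in-fence scores are rescaled linearly between the extreme in-fence
scores S_min and S_max.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

DEFAULT_RIDGE = 1e-8
DEFAULT_SEED = 20210727


@dataclass
class BenchmarkSet:
    """One positive/negative benchmark: features indexed by site_id."""

    positives: pd.DataFrame
    negatives: pd.DataFrame
    ratio: int
    seed: int
    index: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.positives.index) & set(self.negatives.index)
        if overlap:
            raise ValueError(f"positives and negatives overlap: {sorted(overlap)[:5]}")

    @property
    def features(self) -> pd.DataFrame:
        return pd.concat([self.positives, self.negatives])

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.positives), dtype=int),
             np.zeros(len(self.negatives), dtype=int)]
        )


@dataclass
class TrainedModel:
    """Logistic weights plus training provenance."""

    weights: np.ndarray
    intercept: float
    feature_names: list[str]
    ratio: int | None = None
    seed: int | None = None
    benchmark_index: int | None = None
    cv_auc: float | None = None

    def decision_scores(self, features: pd.DataFrame) -> np.ndarray:
        """Raw linear scores w.x + b (log-odds of functional importance)."""
        X = features[self.feature_names].to_numpy(dtype=float)
        return X @ self.weights + self.intercept

    def to_dict(self) -> dict:
        return {
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "feature_names": list(self.feature_names),
            "ratio": self.ratio,
            "seed": self.seed,
            "benchmark_index": self.benchmark_index,
            "cv_auc": self.cv_auc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            feature_names=list(d["feature_names"]),
            ratio=d.get("ratio"),
            seed=d.get("seed"),
            benchmark_index=d.get("benchmark_index"),
            cv_auc=d.get("cv_auc"),
        )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float, float]:
    """Sn = TP/(TP+FN); Sp = TN/(TN+FP).  Undefined denominators are errors."""
    if counts.tp + counts.fn == 0:
        raise ValueError("Sn undefined: no positive samples (TP+FN=0)")
    if counts.tn + counts.fp == 0:
        raise ValueError("Sp undefined: no negative samples (TN+FP=0)")
    sn = counts.tp / (counts.tp + counts.fn)
    sp = counts.tn / (counts.tn + counts.fp)
    return sn, sp


def build_benchmarks(
    positives: pd.DataFrame,
    negative_pool: pd.DataFrame,
    ratio: int = 5,
    n_sets: int = 10,
    seed: int = DEFAULT_SEED,
) -> list[BenchmarkSet]:
    """Draw ``n_sets`` benchmark sets of ``ratio`` negatives per positive.

    Negatives are sampled without replacement (within each set) from the
    pool after removing any site also present among the positives.  The
    positives are identical across sets.  Reproducible given ``seed``.
    """
    pool = negative_pool.drop(
        index=set(negative_pool.index) & set(positives.index), errors="ignore"
    )
    n_neg = ratio * len(positives)
    if len(pool) < n_neg:
        raise ValueError(
            f"negative pool of {len(pool)} cannot supply {n_neg} negatives"
        )
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_sets):
        idx = rng.choice(len(pool), size=n_neg, replace=False)
        sets.append(
            BenchmarkSet(
                positives=positives.copy(),
                negatives=pool.iloc[np.sort(idx)],
                ratio=ratio,
                seed=seed,
                index=i,
            )
        )
    return sets


def fit_logistic(
    features: pd.DataFrame,
    labels: np.ndarray,
    l2: float = DEFAULT_RIDGE,
) -> TrainedModel:
    """Fit the binary logistic regression with a small ridge penalty.

    The ridge (default 1e-8) only guards against divergence on separable
    data; it leaves coefficients essentially at their maximum-likelihood
    values otherwise.  Deterministic given inputs (convex problem, lbfgs).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present to fit")
    X = features.to_numpy(dtype=float)
    # exact-Newton solver: reaches the penalized optimum even when a
    # feature is collinear with the intercept (tiny ridge curvature)
    clf = LogisticRegression(
        penalty="l2",
        C=1.0 / l2,
        solver="newton-cholesky",
        max_iter=10_000,
        tol=1e-10,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lbfgs line-search chatter at tiny tol
        clf.fit(X, labels)
    if clf.n_iter_[0] >= 10_000:
        logger.warning("logistic fit hit max_iter=%d without convergence", 10_000)
    return TrainedModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_names=list(features.columns),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(score+ > score-) + 0.5 P(tie), via the rank statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def sn_sp_curve(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Sensitivity/specificity at every distinct score threshold (>= rule)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    thresholds = np.unique(scores)[::-1]
    rows = []
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        rows.append(
            {
                "threshold": t,
                "sn": tp / n_pos,
                "sp": (n_neg - fp) / n_neg,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CVResult:
    oof_scores: np.ndarray
    labels: np.ndarray
    auc: float
    sn_sp: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def cross_validate(
    benchmark: BenchmarkSet,
    k: int = 10,
    seed: int = DEFAULT_SEED,
    l2: float = DEFAULT_RIDGE,
) -> CVResult:
    """Stratified k-fold CV; AUC from the pooled out-of-fold scores.

    Every sample is scored exactly once by a model that never saw it.
    Pooling the out-of-fold scores (rather than averaging per-fold AUCs)
    keeps the estimate well defined when the positive class is small.
    """
    features = benchmark.features
    labels = benchmark.labels
    counts = np.bincount(labels)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot make {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(labels), np.nan)
    for train_idx, test_idx in skf.split(features, labels):
        model = fit_logistic(features.iloc[train_idx], labels[train_idx], l2=l2)
        oof[test_idx] = model.decision_scores(features.iloc[test_idx])
    assert not np.isnan(oof).any()
    return CVResult(
        oof_scores=oof,
        labels=labels,
        auc=roc_auc(oof, labels),
        sn_sp=sn_sp_curve(oof, labels),
    )


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = DEFAULT_SEED,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC with within-class resampling.

    Stratified resampling preserves the class sizes, so every replicate has
    both classes and the AUC is always defined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 samples per class to bootstrap")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    ones = np.ones(pos.size, dtype=int)
    zeros = np.zeros(neg.size, dtype=int)
    lbl = np.concatenate([ones, zeros])
    for b in range(n_boot):
        sample = np.concatenate(
            [rng.choice(pos, size=pos.size, replace=True),
             rng.choice(neg, size=neg.size, replace=True)]
        )
        aucs[b] = roc_auc(sample, lbl)
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def select_final_model(
    benchmarks: list[BenchmarkSet],
    k: int = 10,
    seed: int = DEFAULT_SEED,
    l2: float = DEFAULT_RIDGE,
) -> tuple[TrainedModel, list[float]]:
    """Cross-validate every benchmark and refit on the best one.

    The final model is refit on the full benchmark whose CV AUC is maximal;
    ties break toward the lowest benchmark index (with a warning).  Returns
    the model and the per-benchmark CV AUCs.
    """
    if not benchmarks:
        raise ValueError("no benchmarks supplied")
    aucs = [cross_validate(b, k=k, seed=seed, l2=l2).auc for b in benchmarks]
    best = int(np.argmax(aucs))
    if aucs.count(max(aucs)) > 1:
        logger.warning("CV AUC tie at %.4f; selecting benchmark %d", max(aucs), best)
    chosen = benchmarks[best]
    model = fit_logistic(chosen.features, chosen.labels, l2=l2)
    model.ratio = chosen.ratio
    model.seed = seed
    model.benchmark_index = best
    model.cv_auc = aucs[best]
    return model, aucs


@dataclass
class ScoreNormalizer:
    """Fence-clipped min-max map of raw scores onto [0, 1].

    Fences are Q1 - 3*IQ and Q3 + 3*IQ of the raw score distribution;
    scores beyond them map to 0/1 and in-fence scores are rescaled between
    the extreme in-fence values S_min and S_max.
    """

    q1: float
    q3: float
    s_min: float
    s_max: float

    @property
    def iq(self) -> float:
        return self.q3 - self.q1

    @property
    def lower_fence(self) -> float:
        return self.q1 - 3.0 * self.iq

    @property
    def upper_fence(self) -> float:
        return self.q3 + 3.0 * self.iq

    def normalize(self, score):
        """Map raw score(s) into [0, 1]; monotone non-decreasing."""
        arr = np.asarray(score, dtype=float)
        if self.s_max == self.s_min:
            out = np.full_like(arr, 0.5)
        else:
            out = (arr - self.s_min) / (self.s_max - self.s_min)
        out = np.where(arr > self.upper_fence, 1.0, out)
        out = np.where(arr < self.lower_fence, 0.0, out)
        out = np.clip(out, 0.0, 1.0)
        return float(out) if np.isscalar(score) else out

    def to_dict(self) -> dict:
        return {
            "q1": self.q1, "q3": self.q3,
            "s_min": self.s_min, "s_max": self.s_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreNormalizer":
        return cls(q1=d["q1"], q3=d["q3"], s_min=d["s_min"], s_max=d["s_max"])


def fit_normalizer(raw_scores: np.ndarray) -> ScoreNormalizer:
    """Fit the fence normalizer to a population of raw scores (n >= 4)."""
    arr = np.asarray(raw_scores, dtype=float)
    if arr.size < 4:
        raise ValueError(f"need >= 4 raw scores, got {arr.size}")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iq = q3 - q1
    lower, upper = q1 - 3.0 * iq, q3 + 3.0 * iq
    within = arr[(arr >= lower) & (arr <= upper)]
    if within.size == 0:  # cannot happen: quartiles always lie inside the fences
        raise ValueError("no scores within fences")
    s_min, s_max = float(within.min()), float(within.max())
    if s_min == s_max:
        logger.warning("degenerate score distribution: all in-fence scores equal")
    return ScoreNormalizer(q1=float(q1), q3=float(q3), s_min=s_min, s_max=s_max)


def prioritize_top_fraction(scores: pd.Series, fraction: float = 0.05) -> set[str]:
    """Smallest top-scoring set covering at least ``fraction`` of all sites.

    At least ceil(fraction * n) sites are returned and no excluded site
    outscores an included one; ties at the cutoff are all included.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if scores.empty:
        raise ValueError("no scores to prioritize")
    n_target = math.ceil(fraction * len(scores))
    ordered = scores.sort_values(ascending=False, kind="mergesort")
    cutoff = ordered.iloc[n_target - 1]
    selected = set(ordered[ordered >= cutoff].index)
    if len(selected) > n_target:
        logger.info(
            "tie at the top-%g cutoff: returning %d sites instead of %d",
            fraction, len(selected), n_target,
        )
    return selected


def intersect_lirp(
    prioritized: set[str],
    regulated: pd.DataFrame,
    normalized_scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Intersect top-scoring sites with differentially regulated sites.

    ``regulated`` is the site-level call table (columns site_id, direction,
    log2fc, ...).  The intersection — regulated sites that also rank in the
    prioritized set — is the final candidate table, with direction and
    (optionally) normalized score attached.
    """
    hits = regulated[regulated["site_id"].isin(prioritized)].copy()
    if normalized_scores is not None:
        hits["score"] = hits["site_id"].map(normalized_scores)
        hits = hits.sort_values(["score", "site_id"], ascending=[False, True])
    else:
        hits = hits.sort_values("site_id")
    return hits.reset_index(drop=True)
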