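"""Feature screening for encoded drug-pair matrices.

The primary selector is a geometric frequency-contrast rule: features are
binarized, and for each feature we compute

* ``p1`` — frequency of a nonzero value among the negative samples, and
* ``p2`` — the same frequency over all labeled samples (positives and
  negatives mixed).

A feature carrying no class signal has ``p2 ~ p1``; the tolerated
deviation ``|p2 - p1|`` depends on ``p1`` through the ellipse

    (p1 - 0.5)^2 / 0.5^2 + (p2 - p1)^2 / a^2 = 1,

whose vertical semi-axis ``a`` plays the role of a significance level.
For each feature we report the *critical* semi-axis ``a*`` — the smallest
``a`` whose ellipse still contains the point ``(p1, p2 - p1)``.  Ranking
by ``a*`` descending and keeping the top ``m`` reproduces any fixed-``a``
"outside the ellipse" selection as a special case.

A greedy mRMR selector (MID scheme, plug-in mutual information on the
discrete codes) is provided as a comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score


def binarize(X: np.ndarray) -> np.ndarray:
    """Map every nonzero entry to 1 (dose codes collapse to presence)."""
    X = np.asarray(X)
    if X.size and X.min() < 0:
        raise ValueError("binarize expects non-negative entries")
    return (X != 0).astype(int)


def class_frequencies(X01: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature nonzero frequency in negatives (p1) and in all labeled
    samples (p2)."""
    X01 = np.asarray(X01)
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    neg = y == 0
    if not neg.any():
        raise ValueError("at least one negative sample is required")
    p1 = X01[neg].mean(axis=0)
    p2 = X01.mean(axis=0)
    return p1, p2


def ellipse_statistic(p1, delta):
    """Critical vertical semi-axis a* for points (p1, delta = p2 - p1).

    a* = |delta| / sqrt(1 - (p1 - 0.5)^2 / 0.25); the point lies outside
    the ellipse with semi-axis ``a`` iff a* > a.  At p1 in {0, 1} any
    nonzero delta is outside every ellipse (a* = inf); delta = 0 gives
    a* = 0 regardless of p1.
    """
    p1 = np.asarray(p1, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any((p1 < 0) | (p1 > 1)):
        raise ValueError("p1 must lie in [0, 1]")
    radicand = 1.0 - (p1 - 0.5) ** 2 / 0.25
    radicand = np.clip(radicand, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_star = np.abs(delta) / np.sqrt(radicand)
    a_star = np.where(delta == 0, 0.0, a_star)
    a_star = np.where((radicand == 0) & (delta != 0), np.inf, a_star)
    if a_star.ndim == 0:
        return float(a_star)
    return a_star


@dataclass
class FeatureScreenResult:
    """Per-feature screening frequencies, critical semi-axes and the
    selected subset (indices ordered by rank)."""

    p1: np.ndarray
    p2: np.ndarray
    a_star: np.ndarray
    selected: list[int]
    m: int

    @property
    def delta(self) -> np.ndarray:
        return self.p2 - self.p1

    def to_frame(self, feature_ids=None) -> pd.DataFrame:
        n = len(self.p1)
        order = rank_features(self.a_star)
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(1, n + 1)
        df = pd.DataFrame({
            "feature": feature_ids if feature_ids is not None else np.arange(n),
            "p1": self.p1, "p2": self.p2, "delta": self.delta,
            "a_star": self.a_star, "rank": rank,
            "selected": np.isin(np.arange(n), self.selected),
        })
        return df

    def to_tsv(self, path: str | Path, feature_ids=None) -> None:
        self.to_frame(feature_ids).to_csv(path, sep="\t", index=False)


def rank_features(a_star: np.ndarray) -> np.ndarray:
    """Feature order by a* descending, ties broken by ascending index."""
    a = np.asarray(a_star, dtype=float)
    return np.lexsort((np.arange(len(a)), -a))


def select_by_ellipse(X01: np.ndarray, y: np.ndarray, m: int = 30) -> FeatureScreenResult:
    """Rank features by the critical ellipse semi-axis and keep the top m."""
    X01 = np.asarray(X01)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > X01.shape[1]:
        raise ValueError(f"m={m} exceeds the {X01.shape[1]} available features")
    p1, p2 = class_frequencies(X01, y)
    a_star = np.asarray(ellipse_statistic(p1, p2 - p1))
    order = rank_features(a_star)
    return FeatureScreenResult(p1=p1, p2=p2, a_star=a_star,
                               selected=[int(i) for i in order[:m]], m=m)


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    # plug-in mutual information in nats over discrete codes
    return float(mutual_info_score(a, b))


def select_by_mrmr(X: np.ndarray, y: np.ndarray, m: int = 30) -> list[int]:
    """Greedy minimum-redundancy maximum-relevance selection (MID scheme).

    The first feature maximizes MI with the label; each subsequent pick
    maximizes MI(feature; y) minus the mean MI with the already-selected
    features.  Ties break toward the lower feature index.
    """
    X = np.asarray(X)
    n_feat = X.shape[1]
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > n_feat:
        raise ValueError(f"m={m} exceeds the {n_feat} available features")
    y = np.asarray(y)
    relevance = np.array([_mi(X[:, j], y) for j in range(n_feat)])
    selected: list[int] = [int(np.argmax(relevance))]
    redundancy_sum = np.zeros(n_feat)
    while len(selected) < m:
        last = selected[-1]
        redundancy_sum += np.array([_mi(X[:, j], X[:, last]) for j in range(n_feat)])
        score = relevance - redundancy_sum / len(selected)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    return selected


def null_calibration(X01: np.ndarray, y: np.ndarray, n_permutations: int = 20,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Null distribution of the critical semi-axis a* under label permutation.

    Returns the pooled a* values (n_permutations x n_features,) from which
    a fixed significance semi-axis ``a`` can be calibrated (e.g. as a high
    quantile) instead of hand-picking it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X01 = np.asarray(X01)
    y = np.asarray(y)
    out = []
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        p1, p2 = class_frequencies(X01, yp)
        out.append(np.asarray(ellipse_statistic(p1, p2 - p1)))
    return np.concatenate(out)
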