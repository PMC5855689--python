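"""Evaluation protocol: confusion-matrix metrics, ROC/AUC, leave-one-out
cross-validation with in-fold feature selection, 75/25 independent-test
splits, positive-to-negative ratio sweeps and y-randomization.

Metric definitions (TP/TN/FP/FN the usual confusion counts, the
effective class being positive):

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    recall      = TP / (TP + FN)            (sensitivity)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F-measure   = 2 * recall * precision / (recall + precision)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

A ratio whose denominator vanishes because the corresponding error count
is zero is defined as 1; an undefined MCC or F-measure is 0.  Reported
tables round to 4 decimals, half-up.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.base import clone
from sklearn.metrics import roc_curve as _sk_roc_curve

from .pairs import DrugFeatureTable, DrugPair, build_pair_dataset, generate_negative_pairs

__all__ = [
    "ConfusionMatrix", "MetricsReport", "ROCCurve", "round_half_up",
    "compute_metrics", "roc_auc", "loocv", "split_train_test",
    "ratio_sweep", "y_randomization", "recover_confusion_from_metrics",
]


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal rounding with ties away from zero (0.69565 -> 0.6957)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(tp=int(((y_true == 1) & (y_pred == 1)).sum()),
                   tn=int(((y_true == 0) & (y_pred == 0)).sum()),
                   fp=int(((y_true == 0) & (y_pred == 1)).sum()),
                   fn=int(((y_true == 1) & (y_pred == 0)).sum()))


@dataclass
class MetricsReport:
    accuracy: float
    recall: float
    specificity: float
    precision: float
    f_measure: float
    mcc: float
    confusion: ConfusionMatrix | None = None

    def rounded(self) -> dict[str, float]:
        return {k: round_half_up(getattr(self, k)) for k in
                ("accuracy", "recall", "specificity", "precision", "f_measure", "mcc")}

    def to_dict(self) -> dict:
        d = {k: float(getattr(self, k)) for k in
             ("accuracy", "recall", "specificity", "precision", "f_measure", "mcc")}
        if self.confusion is not None:
            d["confusion"] = {"tp": self.confusion.tp, "tn": self.confusion.tn,
                              "fp": self.confusion.fp, "fn": self.confusion.fn}
        return d


def _ratio(num: int, den: int) -> float:
    # degenerate denominator: perfect score when the error count is zero
    return num / den if den > 0 else 1.0


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    precision = _ratio(tp, tp + fp)
    f = (2 * recall * precision / (recall + precision)
         if (recall + precision) > 0 else 0.0)
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return MetricsReport(accuracy=(tp + tn) / cm.total, recall=recall,
                         specificity=specificity, precision=precision,
                         f_measure=f, mcc=float(mcc), confusion=cm)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray          # sensitivity
    fpr: np.ndarray          # 1 - specificity
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC by threshold sweep over the observed scores; AUC by the
    trapezoidal rule (equal to the concordant-pair statistic with half
    credit for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def _score(est, X) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


def _clone(estimator):
    try:
        return clone(estimator)
    except Exception:
        return copy.deepcopy(estimator)


def loocv(estimator, X, y):
    """Leave-one-out cross-validation.

    The estimator is re-fitted from scratch on every fold (any embedded
    feature selection included, so held-out labels never leak).  Returns
    ``(scores, predictions, MetricsReport, ROCCurve)`` with out-of-fold
    entries; folds whose training part loses a class are skipped with a
    warning and carry NaN scores.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    scores = np.full(n, np.nan)
    preds = np.full(n, -1)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            warnings.warn(f"fold {i}: a class vanished from the training part; skipped")
            continue
        est = _clone(estimator).fit(X[mask], y[mask])
        scores[i] = _score(est, X[i:i + 1])[0]
        preds[i] = est.predict(X[i:i + 1])[0]
    ok = ~np.isnan(scores)
    cm = ConfusionMatrix.from_labels(y[ok], preds[ok])
    roc = roc_auc(scores[ok], y[ok])
    return scores, preds, compute_metrics(cm), roc


def split_train_test(X, y, train_fraction: float = 0.75,
                     seed: int | np.random.Generator = 0):
    """Uniform random (non-stratified) split; the training size is the
    floor of ``train_fraction * n``.  Returns (X_tr, y_tr, X_te, y_te)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    X = np.asarray(X)
    y = np.asarray(y)
    n = len(y)
    n_train = int(np.floor(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves one side empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    return X[tr], y[tr], X[te], y[te]


def evaluate_split(estimator, X_tr, y_tr, X_te, y_te):
    """Fit on the training part, report metrics and ROC on the test part."""
    est = _clone(estimator).fit(X_tr, y_tr)
    pred = est.predict(X_te)
    scores = _score(est, X_te)
    report = compute_metrics(ConfusionMatrix.from_labels(y_te, pred))
    roc = roc_auc(scores, y_te) if len(np.unique(y_te)) > 1 else None
    return report, roc


def ratio_sweep(table: DrugFeatureTable, positives: list[DrugPair], estimator,
                ratios=(1, 2, 3), strategy: str = "N2", universe=None,
                train_fraction: float = 0.75, seed: int = 0):
    """For each positive-to-negative ratio 1:r, sample negatives, split
    75/25, train and report independent-test metrics.

    Returns ``{r: (MetricsReport, ROCCurve)}``.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for r in ratios:
        n_neg = r * len(positives)
        negs = generate_negative_pairs(strategy, positives, universe, n_neg, rng)
        ds = build_pair_dataset(table, positives, negs)
        X_tr, y_tr, X_te, y_te = split_train_test(
            ds.X_labeled, ds.y_labeled, train_fraction, rng)
        out[r] = evaluate_split(estimator, X_tr, y_tr, X_te, y_te)
    return out


def y_randomization(estimator, X, y, n_shuffles: int = 3,
                    seed: int | np.random.Generator = 0, permutations=None):
    """Compare LOOCV performance on the original labels against label
    permutations (class counts preserved).

    Returns ``(original, shuffled)`` where each entry is a
    ``(MetricsReport, ROCCurve)`` tuple.  ``permutations`` may supply
    explicit index arrays (e.g. the identity, as a determinism check).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=int)
    _, _, rep0, roc0 = loocv(estimator, X, y)
    if permutations is None:
        permutations = [rng.permutation(len(y)) for _ in range(n_shuffles)]
    shuffled = []
    for perm in permutations:
        _, _, rep, roc = loocv(estimator, X, y[np.asarray(perm)])
        shuffled.append((rep, roc))
    return (rep0, roc0), shuffled


def _round4_eq(num: int, den: int, target: float) -> bool:
    # integer-exact half-up rounding of num/den to 4 decimals
    if den == 0:
        return False
    return (num * 10_000 * 2 + den) // (2 * den) == round(target * 10_000)


def recover_confusion_from_metrics(accuracy: float, recall: float, precision: float,
                                   n_range) -> list[ConfusionMatrix]:
    """Exhaustively find all integer confusion matrices whose accuracy,
    recall and precision round (4 decimals, half-up) to the given values,
    with total count in ``n_range`` (an inclusive (lo, hi) pair or an
    iterable of totals).  Raises if no matrix matches."""
    for v in (accuracy, recall, precision):
        if not 0 <= v <= 1:
            raise ValueError("metrics must lie in [0, 1]")
    if isinstance(n_range, tuple) and len(n_range) == 2:
        totals = range(int(n_range[0]), int(n_range[1]) + 1)
    else:
        totals = [int(v) for v in n_range]
    matches = []
    for n in totals:
        for tp in range(n + 1):
            # recall = tp / (tp + fn): admissible positive-count values
            pos_ok = [p for p in range(max(tp, 1), n + 1) if _round4_eq(tp, p, recall)]
            if tp == 0 and recall == 0:
                pos_ok = list(range(1, n + 1))
            # precision = tp / (tp + fp): admissible predicted-positive counts
            pp_ok = [q for q in range(max(tp, 1), n + 1) if _round4_eq(tp, q, precision)]
            if tp == 0 and precision == 0:
                pp_ok = list(range(1, n + 1))
            for p in pos_ok:
                fn = p - tp
                for q in pp_ok:
                    fp = q - tp
                    tn = n - tp - fn - fp
                    if tn < 0:
                        continue
                    if _round4_eq(tp + tn, n, accuracy):
                        matches.append(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
    if not matches:
        raise ValueError("no confusion matrix in range reproduces the given metrics")
    return matches
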