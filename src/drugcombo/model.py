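"""Correlation-eigenbasis naive Bayes for drug-pair classification.

The classifier is a Gaussian discriminant that relaxes naive Bayes'
conditional-independence assumption by working in the eigenbasis of the
feature correlation matrix.  Crucially, the correlation structure (and
the marginal transform) may be estimated from *all* available samples —
labeled pairs plus a potentially much larger unlabeled candidate pool —
because neither depends on class labels.  This makes the method
semi-supervised in its second moments while remaining a simple
class-conditional Gaussian model in its first moments.

Fitting proceeds in three steps:

1. A rank-based inverse normal transform (Blom offset 3/8, average ranks
   for ties) maps each raw feature column of all samples to approximately
   standard-normal scores ``x_hat``.
2. The correlation matrix ``R`` of the transformed features is
   eigendecomposed, ``R = P diag(lambda) P^T``.
3. Class-conditional means/SDs ``(mu_k, sigma_k)`` are estimated on the
   labeled transformed rows; overall means/SDs ``(mu, sigma)`` on all
   transformed rows.

Scoring a sample x_hat uses two whitened projections,

    beta  = ((x_hat - mu)   / sigma)   P        (overall-standardized)
    gamma_k = ((x_hat - mu_k) / sigma_k) P      (class-standardized)

from which two decision scores follow:

    H_k = ln P(C_k) - sum_i ( gamma_ki^2 / (2 lambda_i) + ln sigma_ki )
    L_k = sum_i ( beta_i^2 - gamma_ki^2 ) / lambda_i

``H_k`` is a class-conditional log-score used with known priors (predict
the argmax); ``L_k`` is prior-free — the larger it is, the more the
sample looks like class k relative to the pooled population — and is
thresholded via a ROC curve on a calibration set.

With ``R = I`` (lambda_i = 1, P = I) the ``H_k`` ranking reduces termwise
to the log-posterior of an independent-Gaussian naive Bayes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "NormalTransform", "WhitenedBasis", "ScoreBreakdown",
    "ImprovedNaiveBayes", "ImprovedNaiveBayesResults",
    "ImprovedNBClassifier", "choose_threshold",
]


class NormalTransform:
    """Per-column rank-based inverse normal transform (Blom scores).

    Each fitted column maps its values monotonically to
    ``Phi^{-1}((r - 3/8) / (n + 1/4))`` where ``r`` is the (average) rank.
    New values are mapped by monotone interpolation between fitted
    (value, score) knots; values beyond the fitted range clip to the
    extreme fitted scores.  Constant columns are flagged and map to 0.
    """

    def __init__(self) -> None:
        self.knots_: list[tuple[np.ndarray, np.ndarray]] | None = None
        self.constant_: np.ndarray | None = None
        self.n_fitted_: int = 0

    def fit(self, X: np.ndarray) -> "NormalTransform":
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 3:
            raise ValueError("normal transform needs at least 3 samples")
        self.n_fitted_ = n
        self.knots_ = []
        const = np.zeros(X.shape[1], dtype=bool)
        for j in range(X.shape[1]):
            col = X[:, j]
            uniq, inv = np.unique(col, return_inverse=True)
            if uniq.size == 1:
                const[j] = True
                self.knots_.append((uniq, np.zeros(1)))
                continue
            # average rank per unique value, then its Blom score
            r = rankdata(col, method="average")
            avg_rank = np.bincount(inv, weights=r) / np.bincount(inv)
            uniq_scores = norm.ppf((avg_rank - 0.375) / (n + 0.25))
            self.knots_.append((uniq, uniq_scores))
        self.constant_ = const
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.knots_ is None:
            raise ValueError("transform is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.knots_):
            raise ValueError(
                f"column count mismatch: fitted {len(self.knots_)}, got {X.shape[1]}")
        Z = np.empty_like(X)
        for j, (vals, scores) in enumerate(self.knots_):
            if self.constant_[j]:
                Z[:, j] = 0.0
            else:
                Z[:, j] = np.interp(X[:, j], vals, scores)  # clips at the ends
        return Z

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass
class WhitenedBasis:
    """Correlation matrix of the transformed features with its
    eigendecomposition R = P diag(lambdas) P^T (eigenvalues descending,
    floored and rescaled so their sum equals the feature count)."""

    R: np.ndarray
    lambdas: np.ndarray
    P: np.ndarray

    @classmethod
    def from_transformed(cls, Z: np.ndarray, lambda_floor_scale: float = 1e-6
                         ) -> "WhitenedBasis":
        Z = np.asarray(Z, dtype=float)
        n_feat = Z.shape[1]
        sd = Z.std(axis=0)
        R = np.eye(n_feat)
        ok = sd > 0
        if ok.sum() >= 2:
            sub = np.corrcoef(Z[:, ok], rowvar=False)
            R[np.ix_(ok, ok)] = sub
        lam, P = np.linalg.eigh(R)
        order = np.argsort(lam)[::-1]
        lam, P = lam[order], P[:, order]
        lam = np.maximum(lam, lambda_floor_scale * n_feat)
        lam *= n_feat / lam.sum()
        return cls(R=R, lambdas=lam, P=P)


@dataclass
class ScoreBreakdown:
    """Whitened projections and decision scores for a batch of samples."""

    beta: np.ndarray                       # (n_samples, n_features)
    gamma_by_class: dict[int, np.ndarray]  # class -> (n_samples, n_features)
    H_by_class: dict[int, np.ndarray]      # class -> (n_samples,)
    L_by_class: dict[int, np.ndarray]      # class -> (n_samples,)


class ImprovedNaiveBayes:
    """Correlation-eigenbasis naive Bayes model.

    Parameters
    ----------
    endog : array of 0/1 labels for the labeled samples.
    exog : raw (integer-coded) feature matrix of the labeled samples.
    exog_unlabeled : optional raw feature matrix of an unlabeled candidate
        pool; used (together with ``exog``) for the marginal transform,
        the correlation matrix and the overall means/SDs, never for the
        class-conditional statistics.
    priors : optional mapping class -> prior probability; defaults to
        empirical class frequencies of ``endog``.
    sigma_floor, lambda_floor_scale : numerical floors for the standard
        deviations and (scaled by the feature count) the eigenvalues.
    """

    def __init__(self, endog, exog, exog_unlabeled=None, priors=None,
                 sigma_floor: float = 1e-6, lambda_floor_scale: float = 1e-6):
        self.endog = np.asarray(endog)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be 2-D with one row per label")
        if self.exog.shape[0] == 0:
            raise ValueError("empty input")
        self.exog_unlabeled = (None if exog_unlabeled is None or len(exog_unlabeled) == 0
                               else np.asarray(exog_unlabeled, dtype=float))
        if self.exog_unlabeled is not None and \
                self.exog_unlabeled.shape[1] != self.exog.shape[1]:
            raise ValueError("unlabeled pool has a different feature count")
        self.classes = np.unique(self.endog).astype(int)
        for c in self.classes:
            if (self.endog == c).sum() < 2:
                raise ValueError(f"class {c} has fewer than 2 samples")
        if priors is not None:
            total = sum(priors.values())
            self.priors = {int(k): float(v) / total for k, v in priors.items()}
        else:
            self.priors = {int(c): float((self.endog == c).mean()) for c in self.classes}
        self.sigma_floor = sigma_floor
        self.lambda_floor_scale = lambda_floor_scale

    @classmethod
    def from_pair_dataset(cls, dataset, selected=None, use_pool: bool = True, **kw):
        """Build the model from a :class:`~drugcombo.pairs.PairDataset`,
        optionally restricted to selected feature indices."""
        Xl, yl = dataset.X_labeled, dataset.y_labeled
        Xu = dataset.X_unlabeled if use_pool else None
        if selected is not None:
            sel = np.asarray(list(selected), dtype=int)
            Xl = Xl[:, sel]
            Xu = None if Xu is None or Xu.size == 0 else Xu[:, sel]
        return cls(yl, Xl, exog_unlabeled=Xu, **kw)

    def fit(self) -> "ImprovedNaiveBayesResults":
        X_all = (self.exog if self.exog_unlabeled is None
                 else np.vstack([self.exog, self.exog_unlabeled]))
        transform = NormalTransform().fit(X_all)
        Z_all = transform.transform(X_all)
        Z_lab = Z_all[: self.exog.shape[0]]
        basis = WhitenedBasis.from_transformed(Z_all, self.lambda_floor_scale)
        class_means, class_sds = {}, {}
        for c in self.classes:
            zc = Z_lab[self.endog == c]
            class_means[int(c)] = zc.mean(axis=0)
            class_sds[int(c)] = np.maximum(zc.std(axis=0), self.sigma_floor)
        overall_mean = Z_all.mean(axis=0)
        overall_sd = np.maximum(Z_all.std(axis=0), self.sigma_floor)
        return ImprovedNaiveBayesResults(
            model=self, transform=transform, basis=basis,
            class_means=class_means, class_sds=class_sds,
            overall_mean=overall_mean, overall_sd=overall_sd,
            priors=dict(self.priors), n_labeled=self.exog.shape[0],
            n_unlabeled=0 if self.exog_unlabeled is None else self.exog_unlabeled.shape[0],
        )


@dataclass
class ImprovedNaiveBayesResults:
    """Fitted parameters and scoring interface."""

    transform: NormalTransform
    basis: WhitenedBasis
    class_means: dict[int, np.ndarray]
    class_sds: dict[int, np.ndarray]
    overall_mean: np.ndarray
    overall_sd: np.ndarray
    priors: dict[int, float]
    n_labeled: int
    n_unlabeled: int
    model: ImprovedNaiveBayes | None = None

    @property
    def classes(self) -> list[int]:
        return sorted(self.class_means)

    @property
    def n_features(self) -> int:
        return len(self.overall_mean)

    def score_samples(self, X_raw: np.ndarray) -> ScoreBreakdown:
        """Compute beta, per-class gamma, H and L for raw-coded samples."""
        Z = self.transform.transform(np.asarray(X_raw, dtype=float))
        lam, P = self.basis.lambdas, self.basis.P
        beta = ((Z - self.overall_mean) / self.overall_sd) @ P
        gamma, H, L = {}, {}, {}
        b2_over_lam = (beta ** 2 / lam).sum(axis=1)
        for c in self.classes:
            g = ((Z - self.class_means[c]) / self.class_sds[c]) @ P
            gamma[c] = g
            g2 = g ** 2
            H[c] = (np.log(self.priors[c])
                    - (g2 / (2.0 * lam)).sum(axis=1)
                    - np.log(self.class_sds[c]).sum())
            L[c] = b2_over_lam - (g2 / lam).sum(axis=1)
        return ScoreBreakdown(beta=beta, gamma_by_class=gamma,
                              H_by_class=H, L_by_class=L)

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Argmax of H_k; ties break toward the non-effective class (the
        smallest class label)."""
        sb = self.score_samples(X_raw)
        classes = self.classes
        Hmat = np.column_stack([sb.H_by_class[c] for c in classes])
        # argmax returns the first (smallest-label) class on exact ties
        return np.asarray(classes)[np.argmax(Hmat, axis=1)]

    def decision_scores(self, X_raw: np.ndarray, target_class: int = 1) -> np.ndarray:
        """Prior-free membership score L for the target class."""
        return self.score_samples(X_raw).L_by_class[int(target_class)]

    def predict_by_threshold(self, X_raw, target_class: int = 1,
                             threshold: float | None = None,
                             calibration: tuple | None = None,
                             rule: str = "youden"):
        """Assign the target class where L >= threshold.

        The threshold is either given or chosen on a calibration set
        ``(X_cal, y_cal)`` from the ROC over L (default rule: maximize
        Youden's J; alternative ``"closest"``: closest point to (0, 1)).
        Returns ``(labels, L)``.
        """
        L = self.decision_scores(X_raw, target_class)
        if threshold is None:
            if calibration is None:
                raise ValueError("need a threshold or a calibration set")
            X_cal, y_cal = calibration
            L_cal = self.decision_scores(X_cal, target_class)
            threshold = choose_threshold(L_cal, np.asarray(y_cal) == target_class, rule)
        other = min(c for c in self.classes if c != target_class) if len(self.classes) > 1 else 0
        labels = np.where(L >= threshold, target_class, other)
        return labels, L

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lam = self.basis.lambdas
        lines = [
            "Correlation-Eigenbasis Naive Bayes Results",
            "=" * 46,
            f"No. labeled samples:    {self.n_labeled}",
            f"No. unlabeled samples:  {self.n_unlabeled}",
            f"No. features:           {self.n_features}",
            f"Classes:                {self.classes}",
            "Priors:                 "
            + ", ".join(f"P(C{c})={self.priors[c]:.4f}" for c in self.classes),
            f"Eigenvalue range:       [{lam.min():.4f}, {lam.max():.4f}]"
            f"  (sum {lam.sum():.4f})",
            "-" * 46,
        ]
        df = self.params
        lines.append(df.round(4).to_string())
        return "\n".join(lines)

    @property
    def params(self) -> pd.DataFrame:
        cols = {}
        for c in self.classes:
            cols[f"mu_{c}"] = self.class_means[c]
            cols[f"sigma_{c}"] = self.class_sds[c]
        cols["mu_all"] = self.overall_mean
        cols["sigma_all"] = self.overall_sd
        return pd.DataFrame(cols)

    # ---- serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": "improved-nb-v1",
            "knots": [[v.tolist(), s.tolist()] for v, s in self.transform.knots_],
            "constant": self.transform.constant_.tolist(),
            "n_fitted": self.transform.n_fitted_,
            "R": self.basis.R.tolist(),
            "lambdas": self.basis.lambdas.tolist(),
            "P": self.basis.P.tolist(),
            "class_means": {str(c): m.tolist() for c, m in self.class_means.items()},
            "class_sds": {str(c): s.tolist() for c, s in self.class_sds.items()},
            "overall_mean": self.overall_mean.tolist(),
            "overall_sd": self.overall_sd.tolist(),
            "priors": {str(c): p for c, p in self.priors.items()},
            "n_labeled": self.n_labeled,
            "n_unlabeled": self.n_unlabeled,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ImprovedNaiveBayesResults":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        d = json.loads(text)
        t = NormalTransform()
        t.knots_ = [(np.asarray(v, dtype=float), np.asarray(s, dtype=float))
                    for v, s in d["knots"]]
        t.constant_ = np.asarray(d["constant"], dtype=bool)
        t.n_fitted_ = int(d["n_fitted"])
        basis = WhitenedBasis(R=np.asarray(d["R"]), lambdas=np.asarray(d["lambdas"]),
                              P=np.asarray(d["P"]))
        return cls(
            transform=t, basis=basis,
            class_means={int(c): np.asarray(m) for c, m in d["class_means"].items()},
            class_sds={int(c): np.asarray(s) for c, s in d["class_sds"].items()},
            overall_mean=np.asarray(d["overall_mean"]),
            overall_sd=np.asarray(d["overall_sd"]),
            priors={int(c): float(p) for c, p in d["priors"].items()},
            n_labeled=int(d["n_labeled"]), n_unlabeled=int(d["n_unlabeled"]),
        )


def choose_threshold(scores: np.ndarray, is_target: np.ndarray,
                     rule: str = "youden") -> float:
    """Pick an operating threshold on membership scores from a labeled
    calibration set.

    ``youden`` maximizes sensitivity + specificity - 1; ``closest`` picks
    the ROC point nearest (0, 1).  Ties break toward the higher (more
    conservative) threshold.
    """
    scores = np.asarray(scores, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    if is_target.all() or not is_target.any():
        raise ValueError("calibration set must contain both classes")
    cand = np.unique(scores)
    n_pos, n_neg = is_target.sum(), (~is_target).sum()
    best_t, best_val = cand[-1], -np.inf
    for t in cand:
        pred = scores >= t
        sens = (pred & is_target).sum() / n_pos
        spec = (~pred & ~is_target).sum() / n_neg
        val = (sens + spec - 1.0 if rule == "youden"
               else -np.hypot(1.0 - sens, 1.0 - spec))
        if val >= best_val:  # >= keeps the highest threshold among ties
            best_val, best_t = val, t
    return float(best_t)


class ImprovedNBClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn adapter around :class:`ImprovedNaiveBayes`.

    Optionally refits feature selection inside ``fit`` (``selector`` in
    {"ellipse", "mrmr", None}) so cross-validation never leaks labels,
    and accepts an unlabeled pool used only for the transform and
    correlation estimates.
    """

    def __init__(self, selector: str | None = None, n_features: int = 30,
                 unlabeled=None, priors=None):
        self.selector = selector
        self.n_features = n_features
        self.unlabeled = unlabeled
        self.priors = priors

    def fit(self, X, y):
        from .selection import binarize, select_by_ellipse, select_by_mrmr
        X = np.asarray(X)
        y = np.asarray(y).astype(int)
        pool = None if self.unlabeled is None else np.asarray(self.unlabeled)
        if self.selector is None:
            self.selected_ = np.arange(X.shape[1])
        else:
            m = min(self.n_features, X.shape[1])
            if self.selector == "ellipse":
                self.selected_ = np.asarray(select_by_ellipse(binarize(X), y, m).selected)
            elif self.selector == "mrmr":
                self.selected_ = np.asarray(select_by_mrmr(X, y, m))
            else:
                raise ValueError(f"unknown selector {self.selector!r}")
        Xs = X[:, self.selected_]
        pool_s = None if pool is None else pool[:, self.selected_]
        self.results_ = ImprovedNaiveBayes(
            y, Xs, exog_unlabeled=pool_s, priors=self.priors).fit()
        self.classes_ = np.asarray(self.results_.classes)
        return self

    def predict(self, X):
        return self.results_.predict(np.asarray(X)[:, self.selected_])

    def decision_function(self, X):
        return self.results_.decision_scores(np.asarray(X)[:, self.selected_], 1)
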