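"""Drug-pair feature encoding and dataset construction.

A drug is a sparse binary feature vector over one feature category
(targets, pathways, metabolic enzymes, transporters) or a dose-coded
vector over side effects (0 = none, 1 = low dose, 2 = high dose).
A drug *pair* is encoded as the elementwise sum of its two member
vectors, giving entries in {0, 1, 2} (binary categories) or {0..4}
(side effects).

Negative (non-effective) pairs are sampled either from the drugs that
occur in the positive pairs (strategy ``N1``) or from a wider drug
universe (strategy ``N2``); known positive pairs are always excluded.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("target", "pathway", "enzyme", "transporter", "side_effect")

#: maximum per-drug entry for each feature category
DRUG_MAX = {c: (2 if c == "side_effect" else 1) for c in CATEGORIES}


def pair_max(category: str) -> int:
    """Maximum encoded pair entry for a category (2x the per-drug max)."""
    return 2 * DRUG_MAX[category]


@dataclass(frozen=True, order=True)
class DrugPair:
    """An unordered pair of distinct drugs, stored canonically as
    (lexicographic min, lexicographic max) so that equality and set
    membership are order-insensitive."""

    drug_a: str
    drug_b: str

    def __post_init__(self) -> None:
        a, b = str(self.drug_a), str(self.drug_b)
        if a == b:
            raise ValueError(f"a drug cannot be paired with itself: {a!r}")
        if b < a:
            a, b = b, a
        object.__setattr__(self, "drug_a", a)
        object.__setattr__(self, "drug_b", b)

    def __iter__(self):
        return iter((self.drug_a, self.drug_b))


@dataclass
class DrugFeatureTable:
    """Per-drug feature matrix for one category (drugs x features)."""

    drug_ids: list[str]
    category: str
    matrix: np.ndarray
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (drugs x features)")
        if len(self.drug_ids) != self.matrix.shape[0]:
            raise ValueError("drug_ids length does not match matrix rows")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("drug_ids must be unique")
        vmax = DRUG_MAX[self.category]
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() > vmax):
            raise ValueError(
                f"entries for category {self.category!r} must lie in 0..{vmax}"
            )
        if self.feature_ids is None:
            self.feature_ids = [f"F{j}" for j in range(self.matrix.shape[1])]
        elif len(self.feature_ids) != self.matrix.shape[1]:
            raise ValueError("feature_ids length does not match matrix columns")
        self._index = {d: i for i, d in enumerate(self.drug_ids)}

    @property
    def n_drugs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._index

    def row(self, drug_id: str) -> np.ndarray:
        return self.matrix[self._index[drug_id]]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, index=self.drug_ids, columns=self.feature_ids)
        df.index.name = "drug_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, category: str) -> "DrugFeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            drug_ids=[str(i) for i in df.index],
            category=category,
            matrix=df.to_numpy(dtype=int),
            feature_ids=[str(c) for c in df.columns],
        )


def encode_pair(a_vec: np.ndarray, b_vec: np.ndarray, category: str = "target") -> np.ndarray:
    """Encode a drug pair as the elementwise sum of the two drug vectors.

    Symmetric in its arguments; entries of the result lie in
    ``0..2*DRUG_MAX[category]``.
    """
    a = np.asarray(a_vec, dtype=int)
    b = np.asarray(b_vec, dtype=int)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    vmax = DRUG_MAX[category]
    for name, v in (("a_vec", a), ("b_vec", b)):
        if v.size and (v.min() < 0 or v.max() > vmax):
            raise ValueError(f"{name} has entries outside 0..{vmax} for {category!r}")
    return a + b


@dataclass
class PairDataset:
    """Encoded drug-pair vectors with labels.

    ``y`` uses 1 for effective, 0 for non-effective and NaN for
    unlabeled pool members.
    """

    pairs: list[DrugPair]
    X: np.ndarray
    y: np.ndarray
    category: str
    feature_ids: list[str] | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.pairs) != self.X.shape[0] or len(self.pairs) != self.y.shape[0]:
            raise ValueError("pairs, X and y must have equal length")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in dataset")
        vmax = pair_max(self.category)
        if self.X.size and (self.X.min() < 0 or self.X.max() > vmax):
            raise ValueError(f"encoded entries must lie in 0..{vmax}")
        lab = self.y[~np.isnan(self.y)]
        if lab.size and not np.isin(lab, (0.0, 1.0)).all():
            raise ValueError("labels must be 0, 1 or NaN")
        if self.feature_ids is None:
            self.feature_ids = [f"F{j}" for j in range(self.X.shape[1])]

    @property
    def labeled_mask(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def X_labeled(self) -> np.ndarray:
        return self.X[self.labeled_mask]

    @property
    def y_labeled(self) -> np.ndarray:
        return self.y[self.labeled_mask].astype(int)

    @property
    def X_unlabeled(self) -> np.ndarray:
        return self.X[~self.labeled_mask]

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_ids)
        df.insert(0, "drug_a", [p.drug_a for p in self.pairs])
        df.insert(1, "drug_b", [p.drug_b for p in self.pairs])
        df["label"] = ["" if np.isnan(v) else int(v) for v in self.y]
        df.to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            meta = {"category": self.category, "n_pairs": len(self.pairs),
                    "n_dropped": self.n_dropped, "format": "pair-tsv-v1"}
            Path(sidecar).write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path, category: str) -> "PairDataset":
        df = pd.read_csv(path, sep="\t")
        pairs = [DrugPair(a, b) for a, b in zip(df["drug_a"], df["drug_b"])]
        feats = [c for c in df.columns if c not in ("drug_a", "drug_b", "label")]
        y = pd.to_numeric(df["label"], errors="coerce").to_numpy(dtype=float)
        return cls(pairs=pairs, X=df[feats].to_numpy(dtype=int), y=y,
                   category=category, feature_ids=feats)


def build_pair_dataset(
    table: DrugFeatureTable,
    positives: Sequence[DrugPair],
    negatives: Sequence[DrugPair],
    unlabeled: Sequence[DrugPair] = (),
) -> PairDataset:
    """Encode positive/negative (and optionally unlabeled) pairs against a
    drug feature table.

    Pairs referencing a drug absent from the table are dropped and
    counted (``n_dropped``); a pair appearing in both the positive and
    negative lists is an error.
    """
    pos, neg, unl = set(positives), set(negatives), set(unlabeled)
    clash = pos & neg
    if clash:
        raise ValueError(f"{len(clash)} pair(s) listed as both positive and negative")
    rows, pair_list, labels = [], [], []
    n_dropped = 0
    for group, label in ((positives, 1.0), (negatives, 0.0), (unlabeled, np.nan)):
        for p in group:
            if p.drug_a not in table or p.drug_b not in table:
                n_dropped += 1
                continue
            rows.append(encode_pair(table.row(p.drug_a), table.row(p.drug_b), table.category))
            pair_list.append(p)
            labels.append(label)
    if n_dropped:
        logger.info("dropped %d pair(s) with missing drug feature data", n_dropped)
    X = np.vstack(rows) if rows else np.empty((0, table.n_features), dtype=int)
    return PairDataset(pairs=pair_list, X=X, y=np.asarray(labels, dtype=float),
                       category=table.category, feature_ids=list(table.feature_ids),
                       n_dropped=n_dropped)


def generate_negative_pairs(
    strategy: str,
    positives: Sequence[DrugPair],
    universe: Sequence[str] | None,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[DrugPair]:
    """Sample ``n`` unique non-positive drug pairs.

    ``N1`` pairs drugs occurring in the positive set; ``N2`` pairs drugs
    from the supplied universe. No sampled pair ever coincides with a
    positive pair, and a drug is never paired with itself.
    """
    pos = set(positives)
    if strategy == "N1":
        drugs = sorted({d for p in positives for d in p})
    elif strategy == "N2":
        if universe is None:
            raise ValueError("strategy N2 requires a drug universe")
        drugs = sorted(set(map(str, universe)))
    else:
        raise ValueError(f"unknown negative-sampling strategy {strategy!r}")
    m = len(drugs)
    n_pos_inside = sum(1 for p in pos if p.drug_a in set(drugs) and p.drug_b in set(drugs))
    available = m * (m - 1) // 2 - n_pos_inside
    if n > available:
        raise ValueError(f"requested {n} negative pairs but only {available} exist")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen: set[DrugPair] = set()
    out: list[DrugPair] = []
    # rejection sampling without replacement; fall back to full enumeration
    # when the request is a large fraction of the pair space
    if n > available // 2:
        all_pairs = [DrugPair(a, b) for a, b in itertools.combinations(drugs, 2)
                     if DrugPair(a, b) not in pos]
        idx = rng.permutation(len(all_pairs))[:n]
        return [all_pairs[i] for i in idx]
    while len(out) < n:
        i, j = rng.choice(m, size=2, replace=False)
        p = DrugPair(drugs[i], drugs[j])
        if p in pos or p in chosen:
            continue
        chosen.add(p)
        out.append(p)
    return out


def coverage_summary(
    tables: Mapping[str, Iterable[str] | DrugFeatureTable],
    pairs: Sequence[DrugPair],
) -> dict[tuple[str, ...], int]:
    """Count, for every nonempty subset of feature categories, how many
    pairs have both drugs covered by all categories in the subset."""
    drug_sets = {}
    for cat, t in tables.items():
        drug_sets[cat] = set(t.drug_ids) if isinstance(t, DrugFeatureTable) else set(t)
    cats = sorted(drug_sets)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(cats) + 1):
        for subset in itertools.combinations(cats, r):
            covered = set.intersection(*(drug_sets[c] for c in subset))
            out[subset] = sum(1 for p in pairs if p.drug_a in covered and p.drug_b in covered)
    return out


def read_pair_list(path: str | Path) -> tuple[list[DrugPair], np.ndarray | None]:
    """Read a two- or three-column TSV of drug pairs (optional 0/1 label)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    pairs = [DrugPair(a, b) for a, b in zip(df[0], df[1])]
    labels = df[2].astype(int).to_numpy() if df.shape[1] > 2 else None
    return pairs, labels


def write_pair_list(path: str | Path, pairs: Sequence[DrugPair],
                    labels: Sequence[int] | None = None) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(pairs):
            lab = "" if labels is None else f"\t{int(labels[i])}"
            fh.write(f"{p.drug_a}\t{p.drug_b}{lab}\n")
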