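"""Synthetic drug universes and pair studies.

Real per-drug feature tables (targets, pathways, enzymes, transporters,
dose-coded side effects) are sparse binary vectors with correlated
columns.  The generator emulates that shape:

* Drug vectors are sampled from a latent Gaussian copula with
  equicorrelated feature blocks and thresholded to hit per-feature
  target prevalences (side effects additionally split occurrences into
  low-dose 1 / high-dose 2 codes).
* Positive (effective) pairs carry a planted class signal: a chosen set
  of informative features is enriched in the drugs of positive pairs so
  that, after pair-sum encoding and binarization, the nonzero frequency
  of an informative feature is higher in positives than in negatives by
  ``effect_size``.  At a 1:1 class ratio this makes the screening
  contrast ``p2 - p1`` approximately ``effect_size / 2`` on planted
  features while null features fluctuate at the binomial O(n^-1/2) scale.
* Negatives come from the N1 or N2 sampling strategy and an unlabeled
  candidate pool is drawn from the same universe.

Each positive pair uses its own two (enriched) drug rows; N2 negatives
and the pool draw from the remaining, unenriched drugs.  Under N1 the
negatives reuse the enriched positive drugs, which attenuates the
observed contrast — the same phenomenon that makes N1 benchmarks harder
than N2 ones on real data.

Feature dimensionalities of the real data sets are available as presets
(``TABLE_DIMENSIONS``), e.g. enzymes 135 (N1) / 146 (N2) features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .pairs import DrugFeatureTable, DrugPair, PairDataset, build_pair_dataset, \
    generate_negative_pairs

__all__ = ["SyntheticConfig", "PairStudy", "TABLE_DIMENSIONS",
           "preset_config", "generate_drug_universe", "generate_pair_study"]

#: feature-vector dimensions of the real data per category and negative set
TABLE_DIMENSIONS = {
    "target": {"N1": 681, "N2": 787},
    "pathway": {"N1": 255, "N2": 263},
    "enzyme": {"N1": 135, "N2": 146},
    "transporter": {"N1": 76, "N2": 86},
    "side_effect": {"N1": 3005, "N2": 3889},
}


@dataclass
class SyntheticConfig:
    """Study-generation parameters.

    ``effect_size`` is the target difference in binarized pair-level
    feature frequency between positive and negative pairs on the
    informative features; ``block_correlation`` is the latent Gaussian
    correlation within consecutive feature blocks of ``block_size``.
    """

    n_drugs: int = 400
    n_features: int = 200
    category: str = "target"
    prevalence: float | np.ndarray = 0.1
    block_size: int = 5
    block_correlation: float = 0.4
    n_informative: int = 20
    effect_size: float = 0.2
    n_positive_pairs: int = 100
    negative_ratio: int = 1
    negative_strategy: str = "N2"
    unlabeled_pool_size: int = 200
    high_dose_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if not -1 / max(self.block_size - 1, 1) < self.block_correlation < 1:
            raise ValueError("block_correlation gives an invalid latent covariance")
        if self.negative_strategy not in ("N1", "N2"):
            raise ValueError("negative_strategy must be N1 or N2")


def preset_config(category: str, negative_set: str = "N2", **overrides) -> SyntheticConfig:
    """Config with the real feature dimensionality of a category."""
    n_feat = TABLE_DIMENSIONS[category][negative_set]
    base = SyntheticConfig(category=category, n_features=n_feat,
                           negative_strategy=negative_set)
    return replace(base, **overrides)


def _prevalences(cfg: SyntheticConfig) -> np.ndarray:
    p = np.broadcast_to(np.asarray(cfg.prevalence, dtype=float), (cfg.n_features,))
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("prevalences must lie strictly in (0, 1)")
    return np.asarray(p)


def generate_drug_universe(cfg: SyntheticConfig,
                           rng: np.random.Generator | None = None) -> DrugFeatureTable:
    """Sample a drug universe from the latent block-correlated copula."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p = _prevalences(cfg)
    rho = cfg.block_correlation
    n_blocks = -(-cfg.n_features // cfg.block_size)
    # equicorrelated latent block: z = sqrt(rho)*shared + sqrt(1-rho)*own
    shared = rng.standard_normal((cfg.n_drugs, n_blocks))
    own = rng.standard_normal((cfg.n_drugs, cfg.n_features))
    block_of = np.arange(cfg.n_features) // cfg.block_size
    z = np.sqrt(max(rho, 0.0)) * shared[:, block_of] + np.sqrt(1 - max(rho, 0.0)) * own
    t1 = norm.ppf(1 - p)
    if cfg.category == "side_effect":
        t2 = norm.ppf(1 - p * cfg.high_dose_fraction)
        matrix = np.where(z > t2, 2, np.where(z > t1, 1, 0))
    else:
        matrix = (z > t1).astype(int)
    ids = [f"D{i:05d}" for i in range(cfg.n_drugs)]
    return DrugFeatureTable(drug_ids=ids, category=cfg.category,
                            matrix=matrix, feature_ids=None)


def _spread_informative(cfg: SyntheticConfig) -> np.ndarray:
    """Informative feature indices spread round-robin across the
    correlation blocks (block 0 offset 0, block 1 offset 0, ..., then
    offset 1, ...)."""
    n_blocks = -(-cfg.n_features // cfg.block_size)
    idx = [block * cfg.block_size + offset
           for offset in range(cfg.block_size)
           for block in range(n_blocks)
           if block * cfg.block_size + offset < cfg.n_features]
    return np.asarray(idx[: cfg.n_informative], dtype=int)


@dataclass
class PairStudy:
    """A generated study: universe, labeled pairs, pool, ground truth."""

    dataset: PairDataset
    table: DrugFeatureTable
    positives: list[DrugPair]
    negatives: list[DrugPair]
    pool: list[DrugPair]
    planted: np.ndarray
    config: SyntheticConfig


def generate_pair_study(cfg: SyntheticConfig,
                        rng: np.random.Generator | None = None) -> PairStudy:
    """Generate a labeled pair study plus unlabeled pool.

    Drugs ``0 .. 2k-1`` form the ``k`` positive pairs (one dedicated,
    enriched pair of rows each); the remaining drugs supply N2 negatives
    and the unlabeled pool.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    k = cfg.n_positive_pairs
    n_free = cfg.n_drugs - 2 * k
    if n_free < 2:
        raise ValueError(f"n_drugs={cfg.n_drugs} cannot host {k} dedicated positive "
                         "pairs plus a free pool")
    table = generate_drug_universe(cfg, rng)
    planted = _spread_informative(cfg)

    # per-feature enrichment probability so that the binarized pair-level
    # frequency rises by effect_size over the unenriched baseline
    p_hat = (table.matrix != 0).mean(axis=0)
    q_base = 1.0 - (1.0 - p_hat) ** 2
    e = np.zeros(cfg.n_features)
    with np.errstate(divide="ignore", invalid="ignore"):
        e[planted] = cfg.effect_size / (1.0 - q_base[planted])
    if np.any(e > 1):
        warnings.warn("effect_size not reachable for some features; clipping")
        e = np.clip(e, 0.0, 1.0)

    # enrich exactly round(e*k) positive pairs per planted feature (one of
    # the two drugs carries the feature); the deterministic hit count keeps
    # the realized effect at its target up to baseline sampling noise
    for f in planted:
        n_hit = int(round(e[f] * k))
        for i in rng.choice(k, size=n_hit, replace=False):
            row = 2 * i + int(rng.integers(0, 2))
            table.matrix[row, f] = max(table.matrix[row, f], 1)
    positives = [DrugPair(table.drug_ids[2 * i], table.drug_ids[2 * i + 1])
                 for i in range(k)]

    n_neg = cfg.negative_ratio * k
    free_ids = table.drug_ids[2 * k:]
    if cfg.negative_strategy == "N1":
        negatives = generate_negative_pairs("N1", positives, None, n_neg, rng)
    else:
        negatives = generate_negative_pairs("N2", positives, free_ids, n_neg, rng)

    pool: list[DrugPair] = []
    if cfg.unlabeled_pool_size:
        # exclude every already-used pair so the dataset stays duplicate-free
        used = positives + negatives
        pool = generate_negative_pairs("N2", used, free_ids,
                                       cfg.unlabeled_pool_size, rng)

    dataset = build_pair_dataset(table, positives, negatives, unlabeled=pool)
    return PairStudy(dataset=dataset, table=table, positives=positives,
                     negatives=negatives, pool=pool, planted=planted, config=cfg)
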