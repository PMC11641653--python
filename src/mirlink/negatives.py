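"""Distance-threshold construction of the balanced negative set.

Unknown miRNA-gene pairs are admitted as negative candidates only when, in
embedding space, they sit farther from each other than positive pairs do on
average under every one of three metrics: Euclidean distance, cosine
distance (1 - cosine similarity), and Mahalanobis distance. Each metric's
threshold is the arithmetic mean of that metric over all positive pairs;
candidates must exceed all three strictly (conjunction; configurable to
"any"). A balanced negative set is then drawn uniformly without replacement.

The Mahalanobis covariance is estimated from the pooled set of all miRNA
and gene embedding vectors and regularized as Sigma + epsilon*I so it is
symmetric positive definite even for degenerate embeddings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .embedding import EmbeddingTable
from .sequence_io import AssociationTable

logger = logging.getLogger("mirlink")

DEFAULT_EPSILON = 1e-6

Metric = Literal["euclidean", "cosine", "mahalanobis"]
FilterMode = Literal["all", "any"]


@dataclass
class DistanceThresholds:
    """Mean positive-pair distance per metric, plus the covariance used."""

    tau_euclidean: float
    tau_cosine: float
    tau_mahalanobis: float
    covariance: np.ndarray
    epsilon: float

    def as_dict(self) -> dict:
        return {
            "tau_euclidean": self.tau_euclidean,
            "tau_cosine": self.tau_cosine,
            "tau_mahalanobis": self.tau_mahalanobis,
            "epsilon": self.epsilon,
        }


@dataclass
class LabeledPairSet:
    """The balanced training corpus: positives (label 1) + negatives (label 0)."""

    positives: AssociationTable
    negatives: AssociationTable
    seed: int

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError(
                f"unbalanced set: {len(self.positives)} positives vs "
                f"{len(self.negatives)} negatives"
            )
        if self.positives.keys() & self.negatives.keys():
            raise ValueError("positives and negatives overlap")

    @property
    def pairs(self) -> list[tuple[str, str, int]]:
        return [(m, g, 1) for m, g, _ in self.positives] + [
            (m, g, 0) for m, g, _ in self.negatives
        ]

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.pairs], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


def pair_distance(
    u: np.ndarray,
    v: np.ndarray,
    metric: Metric,
    covariance: np.ndarray | None = None,
) -> float:
    """Distance between two embedding vectors under one of the three metrics."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch {u.shape} vs {v.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            raise ValueError("cosine distance undefined for zero vector")
        return float(1.0 - np.dot(u, v) / (nu * nv))
    if metric == "mahalanobis":
        if covariance is None:
            raise ValueError("mahalanobis requires a covariance matrix")
        d = u - v
        prec = _precision(covariance)
        return float(np.sqrt(d @ prec @ d))
    raise ValueError(f"unknown metric {metric!r}")


def _precision(covariance: np.ndarray) -> np.ndarray:
    cov = np.asarray(covariance, dtype=np.float64)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0:
        raise ValueError(
            f"covariance not positive definite (min eigenvalue {eigvals.min():g})"
        )
    return np.linalg.inv(cov)


def pooled_covariance(table: EmbeddingTable, epsilon: float = DEFAULT_EPSILON
                      ) -> np.ndarray:
    """Covariance of all embedding vectors (miRNA and gene pooled) + eps*I."""
    X = table.matrix()
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    return cov + epsilon * np.eye(cov.shape[0])


def _pair_matrix(pairs: AssociationTable, table: EmbeddingTable
                 ) -> tuple[np.ndarray, np.ndarray]:
    U = np.stack([table[m] for m, _, _ in pairs])
    V = np.stack([table[g] for _, g, _ in pairs])
    return U, V


def _all_distances(U: np.ndarray, V: np.ndarray, prec: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (euclidean, cosine, mahalanobis) for row-aligned pairs."""
    diff = U - V
    euc = np.linalg.norm(diff, axis=1)
    nu = np.linalg.norm(U, axis=1)
    nv = np.linalg.norm(V, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("cosine distance undefined for zero vector")
    cos = 1.0 - np.einsum("ij,ij->i", U, V) / (nu * nv)
    mah = np.sqrt(np.einsum("ij,jk,ik->i", diff, prec, diff))
    return euc, cos, mah


def compute_thresholds(
    positives: AssociationTable,
    table: EmbeddingTable,
    epsilon: float = DEFAULT_EPSILON,
) -> DistanceThresholds:
    """Mean distance over positive pairs for each metric."""
    if len(positives) < 2:
        raise ValueError(
            f"need >= 2 positive pairs to set thresholds, got {len(positives)}"
        )
    cov = pooled_covariance(table, epsilon)
    prec = _precision(cov)
    U, V = _pair_matrix(positives, table)
    euc, cos, mah = _all_distances(U, V, prec)
    return DistanceThresholds(
        tau_euclidean=float(euc.mean()),
        tau_cosine=float(cos.mean()),
        tau_mahalanobis=float(mah.mean()),
        covariance=cov,
        epsilon=epsilon,
    )


def filter_negative_candidates(
    universe: AssociationTable,
    positives: AssociationTable,
    table: EmbeddingTable,
    thresholds: DistanceThresholds,
    mode: FilterMode = "all",
) -> AssociationTable:
    """Pairs of `universe` strictly farther than every (or any) threshold.

    Positives present in the universe are removed first (logged). Output is
    sorted by (miRNA_id, gene_id) for determinism.
    """
    pos_keys = positives.keys()
    pool = [(m, g) for m, g, _ in universe if (m, g) not in pos_keys]
    n_removed = len(universe) - len(pool)
    if n_removed:
        logger.info(
            "filter_negative_candidates: removed %d positive pair(s) from universe",
            n_removed,
        )
    if not pool:
        return AssociationTable([])
    prec = _precision(thresholds.covariance)
    U = np.stack([table[m] for m, _ in pool])
    V = np.stack([table[g] for _, g in pool])
    euc, cos, mah = _all_distances(U, V, prec)
    passes = np.stack([
        euc > thresholds.tau_euclidean,
        cos > thresholds.tau_cosine,
        mah > thresholds.tau_mahalanobis,
    ])
    keep = passes.all(axis=0) if mode == "all" else passes.any(axis=0)
    kept = sorted(
        (pool[i] for i in np.flatnonzero(keep)), key=lambda p: (p[0], p[1])
    )
    return AssociationTable([(m, g, None) for m, g in kept])


def sample_negatives(
    candidates: AssociationTable, n: int, seed: int
) -> AssociationTable:
    """Uniform sample without replacement; labels set to 0; seeded."""
    if len(candidates) < n:
        raise ValueError(
            f"cannot sample {n} negatives from {len(candidates)} candidates "
            f"(short by {n - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    idx.sort()
    chosen = [candidates.pairs[i] for i in idx]
    return AssociationTable([(m, g, 0) for m, g, _ in chosen])


def build_labeled_set(
    positives: AssociationTable,
    universe: AssociationTable,
    table: EmbeddingTable,
    seed: int,
    epsilon: float = DEFAULT_EPSILON,
    mode: FilterMode = "all",
) -> tuple[LabeledPairSet, DistanceThresholds]:
    """End-to-end: thresholds -> candidate filter -> balanced sample."""
    thresholds = compute_thresholds(positives, table, epsilon)
    candidates = filter_negative_candidates(
        universe, positives, table, thresholds, mode
    )
    logger.info(
        "negative filtering: %d candidate(s) from %d unknown pair(s)",
        len(candidates),
        len(universe),
    )
    negatives = sample_negatives(candidates, len(positives), seed)
    return (
        LabeledPairSet(positives.with_label(1), negatives, seed),
        thresholds,
    )
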