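"""Ranked discovery of novel miRNA-gene associations.

The Unknown Data Pool is the full miRNA x gene cross-product minus the
known (documented) pairs. At full scale this pool is tens of millions of
pairs, so it is enumerated lazily and scored in chunks; ranking keeps only
the running top-k. Chunked scoring is exactly equivalent to scoring the
whole pool at once. Ties are broken deterministically by
(miRNA_id, gene_id) lexicographic order.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .autoencoder import AutoencoderModel, FeatureMode, augment_features
from .embedding import EmbeddingTable, embed_pairs
from .lstm import ClassifierModel, predict_scores
from .sequence_io import AssociationTable, SequenceRecord

DEFAULT_CHUNK = 65_536
DEFAULT_TOP_K = 30
DEFAULT_TOP_K_PER_GENE = 10


@dataclass(frozen=True)
class RankedPrediction:
    rank: int
    mirna_id: str
    gene_id: str
    score: float


def unknown_pool_size(n_mirna: int, n_gene: int, n_known: int) -> int:
    """|pool| = n_mirna * n_gene - n_known (known pairs inside the universe)."""
    return n_mirna * n_gene - n_known


def iter_unknown_pool(
    mirnas: Sequence[SequenceRecord] | Sequence[str],
    genes: Sequence[SequenceRecord] | Sequence[str],
    known: AssociationTable,
) -> Iterator[tuple[str, str]]:
    """Lazily yield cross-product pairs absent from `known`, sorted order."""
    mirna_ids = sorted(r.id if isinstance(r, SequenceRecord) else r for r in mirnas)
    gene_ids = sorted(r.id if isinstance(r, SequenceRecord) else r for r in genes)
    known_keys = known.keys()
    for m in mirna_ids:
        for g in gene_ids:
            if (m, g) not in known_keys:
                yield (m, g)


def build_unknown_pool(
    mirnas: Sequence[SequenceRecord] | Sequence[str],
    genes: Sequence[SequenceRecord] | Sequence[str],
    known: AssociationTable,
) -> AssociationTable:
    """Materialize the unknown pool (use iter_unknown_pool at large scale)."""
    return AssociationTable(
        [(m, g, None) for m, g in iter_unknown_pool(mirnas, genes, known)]
    )


def _chunks(pairs: Iterable[tuple[str, str]], size: int
            ) -> Iterator[list[tuple[str, str]]]:
    buf: list[tuple[str, str]] = []
    for p in pairs:
        buf.append(p)
        if len(buf) >= size:
            yield buf
            buf = []
    if buf:
        yield buf


def score_pairs(
    pairs: Sequence[tuple[str, str]],
    model: ClassifierModel,
    ae: AutoencoderModel,
    table: EmbeddingTable,
    mode: FeatureMode = "original_plus_latent",
) -> np.ndarray:
    """Association scores for explicit (miRNA_id, gene_id) pairs."""
    X = embed_pairs(table, pairs)
    F = augment_features(X, ae, mode)
    return predict_scores(model, F)


def rank_pairs(
    pool: AssociationTable | Iterable[tuple[str, str]],
    model: ClassifierModel,
    ae: AutoencoderModel,
    table: EmbeddingTable,
    k: int = DEFAULT_TOP_K,
    mode: FeatureMode = "original_plus_latent",
    chunk_size: int = DEFAULT_CHUNK,
) -> list[RankedPrediction]:
    """Global top-k of the pool by score, scored chunk by chunk.

    A running heap holds only k entries, so memory stays bounded regardless
    of pool size. Sorting key: score descending, then (miRNA_id, gene_id)
    ascending; ranks are consecutive from 1.
    """
    if isinstance(pool, AssociationTable):
        pair_iter: Iterable[tuple[str, str]] = ((m, g) for m, g, _ in pool)
    else:
        pair_iter = pool
    # heap of (score, neg-lexicographic key) keeping the k best; since heapq
    # is a min-heap and lexicographic order cannot be negated directly, keep
    # (score, key_rank) tuples where smaller is worse via a sortable wrapper
    best: list[tuple[float, _RevKey, str, str]] = []
    for chunk in _chunks(pair_iter, chunk_size):
        scores = score_pairs(chunk, model, ae, table, mode)
        for (m, g), s in zip(chunk, scores):
            item = (float(s), _RevKey((m, g)), m, g)
            if len(best) < k:
                heapq.heappush(best, item)
            elif item > best[0]:
                heapq.heapreplace(best, item)
    ordered = sorted(best, key=lambda it: (-it[0], it[2], it[3]))
    return [
        RankedPrediction(rank, m, g, s)
        for rank, (s, _, m, g) in enumerate(ordered, start=1)
    ]


class _RevKey:
    """Wraps a key so that lexicographically smaller compares as larger."""

    __slots__ = ("key",)

    def __init__(self, key: tuple[str, str]):
        self.key = key

    def __lt__(self, other: "_RevKey") -> bool:
        return self.key > other.key

    def __gt__(self, other: "_RevKey") -> bool:
        return self.key < other.key

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _RevKey) and self.key == other.key


def rank_mirnas_for_gene(
    pool: AssociationTable | Iterable[tuple[str, str]],
    gene_id: str,
    model: ClassifierModel,
    ae: AutoencoderModel,
    table: EmbeddingTable,
    k: int = DEFAULT_TOP_K_PER_GENE,
    mode: FeatureMode = "original_plus_latent",
    chunk_size: int = DEFAULT_CHUNK,
) -> list[RankedPrediction]:
    """Top-k miRNAs predicted to associate with one fixed gene."""
    if gene_id not in table:
        raise KeyError(f"unknown gene id {gene_id!r}")
    if isinstance(pool, AssociationTable):
        pair_iter: Iterable[tuple[str, str]] = ((m, g) for m, g, _ in pool)
    else:
        pair_iter = pool
    restricted = (p for p in pair_iter if p[1] == gene_id)
    return rank_pairs(restricted, model, ae, table, k, mode, chunk_size)


def predictions_to_tsv(preds: Sequence[RankedPrediction], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tmiRNA_id\tgene_id\tscore\n")
        for p in preds:
            fh.write(f"{p.rank}\t{p.mirna_id}\t{p.gene_id}\t{p.score:.6f}\n")
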