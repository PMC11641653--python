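"""K-mer tokenization and paragraph-vector sequence embedding.

Each sequence (miRNA or gene) is tokenized into overlapping, strand-
symmetric ("canonical") k-mers and treated as one document; a paragraph-
vector model is trained over the union of both sequence classes, yielding
one fixed-dimension vector per sequence id. A pair is represented by
concatenating its miRNA and gene vectors (miRNA first).

Canonical tokenization maps every k-mer to the lexicographic minimum of
itself and its reverse complement, the convention used by k-mer counters
for double-stranded DNA. It matters here because miRNA targeting is
complementarity-based: a miRNA's seed and the matching site on its target
gene are reverse complements, so without canonicalization the two
sequences share no vocabulary at all and their embeddings cannot reflect
the interaction. With it, binding partners literally share tokens.

The trainer is a compact numpy implementation of the paragraph-vector
model, distributed-memory variant (PV-DM) by default: each token position
predicts its center k-mer from the mean of the surrounding token vectors
plus the document vector, against `negative` noise samples drawn from the
unigram^0.75 distribution. Positions are processed in large vectorized
chunks with summed gradients; per-row update norms are clipped, which
keeps the aggregated steps stable at any document length. Context sums
are refreshed once per epoch. A distributed-bag-of-words variant
(`variant="dbow"`, document vector alone predicts each token) is also
available. With a fixed seed training is single-threaded and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .sequence_io import SequenceRecord

DEFAULT_K = 5
DEFAULT_DIMENSION = 64
DEFAULT_WINDOW = 5
DEFAULT_EPOCHS = 40

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class EmbeddingLookupError(KeyError):
    """Raised when a sequence id has no embedding vector."""


@dataclass(frozen=True)
class KmerDocument:
    """A sequence rendered as an ordered list of k-mer tokens."""

    id: str
    tokens: tuple[str, ...]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def tokenize(record: SequenceRecord | str, k: int = DEFAULT_K,
             doc_id: str | None = None, canonical: bool = True) -> KmerDocument:
    """Overlapping k-mers in sequence order; windows containing N are skipped.

    Accepts a SequenceRecord or a bare sequence string (then `doc_id` names
    the document). With `canonical` (default) each k-mer is replaced by the
    minimum of itself and its reverse complement. k longer than the
    sequence yields an empty token list.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if isinstance(record, SequenceRecord):
        seq, did = record.sequence, record.id
    else:
        seq, did = record, doc_id or "doc"
    raw = (seq[i : i + k] for i in range(len(seq) - k + 1))
    if canonical:
        tokens = tuple(canonical_kmer(t) for t in raw if "N" not in t)
    else:
        tokens = tuple(t for t in raw if "N" not in t)
    return KmerDocument(did, tokens)


@dataclass
class EmbeddingTable:
    """id -> fixed-dimension vector for all embedded sequences."""

    dimension: int
    vectors: dict[str, np.ndarray]
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for did, v in self.vectors.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {did!r} has shape {v.shape}, "
                    f"expected ({self.dimension},)"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite entries in vector for {did!r}")
            self.vectors[did] = v

    def __contains__(self, did: str) -> bool:
        return did in self.vectors

    def __getitem__(self, did: str) -> np.ndarray:
        try:
            return self.vectors[did]
        except KeyError:
            raise EmbeddingLookupError(f"no embedding for id {did!r}") from None

    def matrix(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """Stack vectors for `ids` (or all ids in insertion order) into rows."""
        if ids is None:
            ids = list(self.vectors)
        return np.stack([self[i] for i in ids])

    # --- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for did, vec in self.vectors.items():
                fh.write(did + "\t" + "\t".join(repr(float(x)) for x in vec) + "\n")

    def to_npz(self, path: str | Path) -> None:
        """Compact binary container (ids + one matrix)."""
        ids = list(self.vectors)
        np.savez(
            path,
            ids=np.array(ids),
            matrix=self.matrix(ids),
            dimension=np.array(self.dimension),
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "EmbeddingTable":
        data = np.load(path, allow_pickle=False)
        ids = [str(x) for x in data["ids"]]
        M = data["matrix"]
        if M.ndim != 2 or M.shape[1] != int(data["dimension"]):
            raise ValueError(f"{path}: inconsistent embedding container")
        return cls(int(data["dimension"]), dict(zip(ids, M)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        dim: int | None = None
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed embedding row")
                vec = np.array([float(x) for x in parts[1:]])
                if dim is None:
                    dim = vec.size
                elif vec.size != dim:
                    raise ValueError(
                        f"{path}:{lineno}: dimension {vec.size} != {dim}"
                    )
                vectors[parts[0]] = vec
        if dim is None:
            raise ValueError(f"{path}: empty embedding table")
        return cls(dim, vectors)


def train_embedding(
    docs: Iterable[KmerDocument],
    dimension: int = DEFAULT_DIMENSION,
    window: int = DEFAULT_WINDOW,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    negative: int = 5,
    variant: Literal["dm", "dbow"] = "dm",
    clip: float = 1.0,
    chunk: int = 8192,
) -> EmbeddingTable:
    """Train paragraph vectors over a k-mer document corpus.

    Requires at least two documents with at least one token each. Returns
    one `dimension`-length vector per document id. Deterministic for a
    fixed seed (single-threaded numpy, float32 parameters).
    """
    docs = list(docs)
    nonempty = [d for d in docs if d.tokens]
    if len(nonempty) < 2:
        raise ValueError(
            f"need >= 2 documents with >= 1 token, got {len(nonempty)}"
        )
    ids = [d.id for d in docs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate document ids in corpus")

    vocab: dict[str, int] = {}
    for d in nonempty:
        for t in d.tokens:
            if t not in vocab:
                vocab[t] = len(vocab)
    V = len(vocab)
    corpus = [np.array([vocab[t] for t in d.tokens], dtype=np.intp)
              for d in nonempty]

    T = np.concatenate(corpus)
    doc_of = np.concatenate([
        np.full(t.size, i, dtype=np.intp) for i, t in enumerate(corpus)
    ])
    doc_starts = np.concatenate([[0], np.cumsum([t.size for t in corpus])])
    N = T.size

    # unigram^0.75 noise distribution, word2vec convention
    counts = np.bincount(T, minlength=V).astype(np.float64)
    noise_cum = np.cumsum(counts ** 0.75)

    rng = np.random.default_rng(seed)
    scale = 1.0 / dimension
    D = rng.uniform(-scale, scale, (len(corpus), dimension)).astype(np.float32)
    W_out = np.zeros((V, dimension), dtype=np.float32)
    dm = variant == "dm"
    W_in = (
        rng.uniform(-scale, scale, (V, dimension)).astype(np.float32)
        if dm else None
    )

    if dm:
        pos = np.arange(N)
        lo = np.maximum(pos - window, doc_starts[doc_of])
        hi = np.minimum(pos + window + 1, doc_starts[doc_of + 1])
        denom_all = (hi - lo - 1).astype(np.float32) + 1.0  # +1: doc vector
        # per-shift validity: position i may read neighbor i+delta only
        # inside the same document
        shift_masks = {
            delta: (doc_of[:-delta] == doc_of[delta:]).astype(np.float32)[:, None]
            for delta in range(1, window + 1)
            if delta < N
        }

    n_chunks = max(1, int(np.ceil(N / chunk)))
    total_steps = max(1, epochs * n_chunks)
    step = 0
    for _epoch in range(epochs):
        if dm:
            # context sums refreshed once per epoch (stale within the epoch)
            TV = W_in[T]
            CTX = np.zeros_like(TV)
            for delta, mask in shift_masks.items():
                CTX[:-delta] += TV[delta:] * mask
                CTX[delta:] += TV[:-delta] * mask
            del TV
        for a in range(0, N, chunk):
            b = min(a + chunk, N)
            m = b - a
            lr = alpha + (min_alpha - alpha) * (step / total_steps)
            step += 1

            di = doc_of[a:b]
            centers = T[a:b]
            if dm:
                denom = denom_all[a:b]
                h = (CTX[a:b] + D[di]) / denom[:, None]
            else:
                h = D[di]

            neg = np.searchsorted(
                noise_cum, rng.random((m, negative)) * noise_cum[-1]
            )

            pos_vecs = W_out[centers]
            g_pos = _sigmoid(np.einsum("nd,nd->n", h, pos_vecs)) - 1.0
            neg_vecs = W_out[neg]                      # (m, K, dim)
            g_neg = _sigmoid(np.einsum("nd,nkd->nk", h, neg_vecs))
            grad_h = g_pos[:, None] * pos_vecs + np.einsum(
                "nk,nkd->nd", g_neg, neg_vecs
            )

            # output-vector update: aggregate rows per word, clip, apply
            idx = np.concatenate([centers, neg.ravel()])
            vals = np.concatenate([
                g_pos[:, None] * h,
                (g_neg[:, :, None] * h[:, None, :]).reshape(-1, dimension),
            ])
            _scatter_sub(W_out, idx, vals, lr, clip)

            grad_in = grad_h / denom[:, None] if dm else grad_h
            # doc-vector update: documents are contiguous -> segment reduce
            bounds = np.concatenate([[0], np.flatnonzero(np.diff(di)) + 1])
            dD = np.add.reduceat(grad_in, bounds, axis=0)
            _clip_rows(dD, clip)
            D[di[bounds]] -= lr * dD

            if dm:
                # context tokens receive grad_in over the windows covering
                # them (contributors clipped to the chunk)
                recv = np.zeros_like(grad_in)
                for delta, mask in shift_masks.items():
                    if delta >= m:
                        continue
                    msk = mask[a : b - delta]
                    recv[:-delta] += grad_in[delta:] * msk
                    recv[delta:] += grad_in[:-delta] * msk
                _scatter_sub(W_in, centers, recv, lr, clip)

    vectors: dict[str, np.ndarray] = {}
    ne_index = {d.id: i for i, d in enumerate(nonempty)}
    for d in docs:
        if d.id in ne_index:
            vectors[d.id] = D[ne_index[d.id]].astype(np.float64)
        else:  # tokenless document: zero vector, still addressable
            vectors[d.id] = np.zeros(dimension)
    return EmbeddingTable(
        dimension,
        vectors,
        training_meta={
            "k": len(nonempty[0].tokens[0]),
            "window": window,
            "epochs": epochs,
            "seed": seed,
            "negative": negative,
            "variant": variant,
            "vocab_size": V,
        },
    )


def _scatter_sub(W: np.ndarray, idx: np.ndarray, vals: np.ndarray,
                 lr: float, clip: float) -> None:
    """W[idx] -= lr * vals, rows aggregated per index and norm-clipped."""
    order = np.argsort(idx, kind="stable")
    si = idx[order]
    sv = vals[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(si)) + 1])
    sums = np.add.reduceat(sv, starts, axis=0)
    _clip_rows(sums, clip)
    W[si[starts]] -= lr * sums


def _clip_rows(rows: np.ndarray, max_norm: float) -> None:
    nrm = np.linalg.norm(rows, axis=1, keepdims=True)
    rows *= np.minimum(1.0, max_norm / np.maximum(nrm, 1e-12))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def embed_pair(table: EmbeddingTable, mirna_id: str, gene_id: str) -> np.ndarray:
    """Concatenated [miRNA vector || gene vector]; length 2 x dimension."""
    return np.concatenate([table[mirna_id], table[gene_id]])


def embed_pairs(
    table: EmbeddingTable, pairs: Iterable[tuple[str, str]]
) -> np.ndarray:
    """Row-stack embed_pair over (miRNA_id, gene_id) tuples."""
    rows = [embed_pair(table, m, g) for m, g in pairs]
    if not rows:
        return np.empty((0, 2 * table.dimension))
    return np.stack(rows)


def build_corpus(
    records: Iterable[SequenceRecord], k: int = DEFAULT_K,
    canonical: bool = True,
) -> list[KmerDocument]:
    return [tokenize(r, k, canonical=canonical) for r in records]
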