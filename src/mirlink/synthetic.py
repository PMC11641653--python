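"""Synthetic miRNA/gene corpora with a planted, learnable association rule.

The generator emulates the pipeline's real inputs — a miRNA FASTA (RNA
alphabet, 18-25 nt), a gene FASTA (DNA alphabet), and a positive-pair TSV —
with a planted seed-complement association: a positive (miRNA, gene) pair
means the gene sequence carries the reverse complement of the miRNA's seed
region (positions 2-8, the canonical target-recognition element) as an
embedded motif. Each planted pair writes `motif_copies` copies of the
7-mer site at random non-overlapping positions, so the compositional
footprint of the site is detectable by k-mer-level embeddings; a single
copy in a 300-1500 nt gene shifts each affected 3-mer frequency by well
under one standard deviation and would be statistically invisible.

Only a configurable fraction of genes receive planted partners; the rest
are motif-free background, which both makes the signal testable
(foreground vs background composition) and populates the negative pool
with clean non-targets. A fraction `label_noise` of the emitted positive
pairs are replaced by random unplanted pairs (false-positive labels); the
returned ground-truth table always lists the true planted pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import (
    Alphabet,
    AssociationTable,
    SequenceKind,
    SequenceRecord,
    write_fasta,
    write_pairs,
)

_RNA = "ACGU"
_DNA = "ACGT"
# DNA base pairing with the RNA seed (A-T, U-A, C-G, G-C)
_RC = {"A": "T", "U": "A", "C": "G", "G": "C"}

SEED_START, SEED_END = 1, 8  # 0-based slice of miRNA positions 2-8


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic corpus."""

    n_mirna: int = 200
    n_gene: int = 500
    mirna_length_range: tuple[int, int] = (18, 25)
    gene_length_range: tuple[int, int] = (300, 1500)
    positives_per_gene: int = 4
    target_gene_fraction: float = 0.8
    motif_copies: int = 10
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna < 2 or self.n_gene < 2:
            raise ValueError("need at least 2 miRNAs and 2 genes")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        for lo, hi in (self.mirna_length_range, self.gene_length_range):
            if lo > hi or lo < 1:
                raise ValueError("invalid length range")
        if self.mirna_length_range[0] < SEED_END:
            raise ValueError("miRNAs must be long enough to carry a seed")
        if self.positives_per_gene < 1:
            raise ValueError("positives_per_gene must be >= 1")
        if not 0 < self.target_gene_fraction <= 1:
            raise ValueError("target_gene_fraction must be in (0, 1]")


def seed_site(mirna_rna: str) -> str:
    """DNA reverse complement of the miRNA seed (positions 2-8)."""
    seed = mirna_rna[SEED_START:SEED_END]
    return "".join(_RC[b] for b in reversed(seed))


@dataclass
class SyntheticDataset:
    mirnas: list[SequenceRecord]
    genes: list[SequenceRecord]
    positives: AssociationTable     # emitted (noisy) labels
    ground_truth: AssociationTable  # planted pairs, pre-noise
    config: SyntheticConfig = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirna_fasta": outdir / "miRNA.fa",
            "gene_fasta": outdir / "genes.fa",
            "positives": outdir / "positives.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.mirnas, paths["mirna_fasta"])
        write_fasta(self.genes, paths["gene_fasta"])
        write_pairs(self.positives, paths["positives"])
        write_pairs(self.ground_truth, paths["truth"])
        return paths


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset; deterministic under config.seed."""
    rng = np.random.default_rng(config.seed)

    width = max(3, len(str(config.n_mirna)))
    mirna_raw: list[str] = []
    mirnas: list[SequenceRecord] = []
    for i in range(config.n_mirna):
        length = int(rng.integers(config.mirna_length_range[0],
                                  config.mirna_length_range[1] + 1))
        seq_rna = "".join(rng.choice(list(_RNA), size=length))
        mirna_raw.append(seq_rna)
        mirnas.append(
            SequenceRecord(
                f"syn-miR-{i + 1:0{width}d}", SequenceKind.MIRNA,
                seq_rna.replace("U", "T"), Alphabet.RNA,
            )
        )

    gwidth = max(3, len(str(config.n_gene)))
    gene_seqs: list[list[str]] = []
    gene_ids: list[str] = []
    for j in range(config.n_gene):
        length = int(rng.integers(config.gene_length_range[0],
                                  config.gene_length_range[1] + 1))
        gene_seqs.append(list(rng.choice(list(_DNA), size=length)))
        gene_ids.append(f"SYNG{j + 1:0{gwidth}d}")

    # choose target genes and their planted miRNA partners
    n_target = max(1, int(round(config.target_gene_fraction * config.n_gene)))
    target_idx = rng.choice(config.n_gene, size=n_target, replace=False)
    if config.positives_per_gene > config.n_mirna:
        raise ValueError(
            f"positives_per_gene={config.positives_per_gene} exceeds "
            f"n_mirna={config.n_mirna}"
        )
    planted: list[tuple[int, int]] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    for j in sorted(target_idx):
        partners = rng.choice(config.n_mirna, size=config.positives_per_gene,
                              replace=False)
        for i in partners:
            planted.append((int(i), j))
            # cap copies so planted sites never exceed ~25% of the gene
            site = seed_site(mirna_raw[i])
            cap = max(1, int(0.25 * len(gene_seqs[j])
                             / (len(site) * config.positives_per_gene)))
            _plant_motif(gene_seqs[j], site,
                         min(config.motif_copies, cap), rng,
                         occupied.setdefault(j, []))

    genes = [
        SequenceRecord(gene_ids[j], SequenceKind.GENE, "".join(seq),
                       Alphabet.DNA)
        for j, seq in enumerate(gene_seqs)
    ]

    truth_pairs = [(mirnas[i].id, gene_ids[j], 1) for i, j in planted]
    ground_truth = AssociationTable(truth_pairs)

    # label noise: replace a fraction of emitted positives with random
    # unplanted pairs (false positives)
    emitted = list(truth_pairs)
    n_noise = int(round(config.label_noise * len(emitted)))
    if n_noise:
        flip_idx = rng.choice(len(emitted), size=n_noise, replace=False)
        planted_keys = {(m, g) for m, g, _ in truth_pairs}
        emitted_keys = set(planted_keys)
        for fi in flip_idx:
            while True:
                i = int(rng.integers(config.n_mirna))
                j = int(rng.integers(config.n_gene))
                key = (mirnas[i].id, gene_ids[j])
                if key not in emitted_keys:
                    emitted_keys.add(key)
                    emitted[fi] = (key[0], key[1], 1)
                    break
    positives = AssociationTable(sorted(set(emitted)))
    return SyntheticDataset(mirnas, genes, positives, ground_truth, config)


def _plant_motif(gene_seq: list[str], site: str, copies: int,
                 rng: np.random.Generator,
                 occupied: list[tuple[int, int]] | None = None) -> None:
    """Overwrite `copies` non-overlapping windows of the gene with `site`.

    `occupied` carries already-planted windows of the same gene so that
    sites for different partner miRNAs never clobber each other.
    """
    L = len(gene_seq)
    w = len(site)
    if L < w:
        raise ValueError("gene shorter than motif")
    if occupied is None:
        occupied = []
    placed = 0
    attempts = 0
    while placed < copies and attempts < 200 * copies:
        attempts += 1
        pos = int(rng.integers(0, L - w + 1))
        if any(pos < e and pos + w > s for s, e in occupied):
            continue
        gene_seq[pos : pos + w] = list(site)
        occupied.append((pos, pos + w))
        placed += 1
    if placed < copies:
        raise ValueError(
            f"could not place {copies} non-overlapping motif copies in a "
            f"{L} nt gene"
        )


def kmer_counts(seq: str, k: int = 3) -> dict[str, int]:
    """Overlapping k-mer counts (N windows skipped); test-support helper."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts
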