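"""Reading, validation and normalization of sequence and association inputs.

Two sequence populations enter the pipeline: mature miRNAs (RNA alphabet,
typically 18-25 nt) and gene sequences (DNA alphabet). Both are normalized
to a single DNA-style alphabet (U mapped to T) so that one k-mer vocabulary
serves both classes downstream. Association pairs arrive as 2- or 3-column
TSV of (miRNA_id, gene_id[, label]).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("mirlink")

_VALID_BASES = frozenset("ACGTN")
MIRNA_LENGTH_RANGE = (15, 30)  # warn (not fail) outside this for miRNAs


class SequenceKind(str, Enum):
    MIRNA = "miRNA"
    GENE = "gene"


class Alphabet(str, Enum):
    RNA = "RNA"
    DNA = "DNA"


class SequenceValidationError(ValueError):
    """Raised when a sequence record violates an invariant."""


class PairValidationError(ValueError):
    """Raised when an association table violates an invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """One identified sequence, normalized to uppercase {A,C,G,T,N}."""

    id: str
    kind: SequenceKind
    sequence: str
    raw_alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("empty sequence id")
        if not self.sequence:
            raise SequenceValidationError(f"empty sequence for id {self.id!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise SequenceValidationError(
                f"invalid characters {sorted(bad)} in sequence {self.id!r}"
            )
        if self.kind is SequenceKind.MIRNA:
            lo, hi = MIRNA_LENGTH_RANGE
            if not lo <= len(self.sequence) <= hi:
                warnings.warn(
                    f"miRNA {self.id!r} has length {len(self.sequence)} outside "
                    f"the typical {lo}-{hi} nt range",
                    stacklevel=2,
                )


def normalize_sequence(raw: str) -> tuple[str, Alphabet]:
    """Uppercase and map U->T; report which alphabet the input used."""
    seq = raw.strip().upper()
    alphabet = Alphabet.RNA if "U" in seq else Alphabet.DNA
    return seq.replace("U", "T"), alphabet


@dataclass
class AssociationTable:
    """Ordered (miRNA_id, gene_id, label) triples; label is None when unlabeled."""

    pairs: list[tuple[str, str, Optional[int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for m, g, lab in self.pairs:
            if (m, g) in seen:
                raise PairValidationError(f"duplicate pair ({m!r}, {g!r})")
            seen.add((m, g))
            if lab is not None and lab not in (0, 1):
                raise PairValidationError(
                    f"label for pair ({m!r}, {g!r}) must be 0 or 1, got {lab!r}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def keys(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.pairs}

    def with_label(self, label: Optional[int]) -> "AssociationTable":
        return AssociationTable([(m, g, label) for m, g, _ in self.pairs])

    def subset(self, keys: Iterable[tuple[str, str]]) -> "AssociationTable":
        wanted = set(keys)
        return AssociationTable([p for p in self.pairs if (p[0], p[1]) in wanted])


def read_fasta(path: str | Path, kind: SequenceKind) -> list[SequenceRecord]:
    """Parse a FASTA file into normalized :class:`SequenceRecord` objects.

    Ids are taken from the header up to the first whitespace; duplicate ids
    within one file raise. An empty file yields an empty list.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise SequenceValidationError(f"{path}: FASTA entry with empty header id")
        if entry.id in seen:
            raise SequenceValidationError(f"{path}: duplicate id {entry.id!r}")
        seen.add(entry.id)
        seq, alphabet = normalize_sequence(str(entry.seq))
        records.append(SequenceRecord(entry.id, kind, seq, alphabet))
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records in input order (normalized alphabet, 60-column wrap)."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_pairs(path: str | Path) -> AssociationTable:
    """Read a 2- or 3-column TSV of association pairs.

    Lines starting with '#' are comments. A first row whose third column is
    not an integer (or whose ids repeat common header words) is treated as a
    header. Duplicate pairs are collapsed with a warning; labels must be 0/1.
    """
    path = Path(path)
    rows: list[tuple[str, str, Optional[int]]] = []
    ncols: Optional[int] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise PairValidationError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if ncols is None:
                ncols = len(fields)
                if _looks_like_header(fields):
                    continue
            elif len(fields) != ncols:
                raise PairValidationError(
                    f"{path}:{lineno}: ragged row ({len(fields)} columns, "
                    f"expected {ncols})"
                )
            label: Optional[int] = None
            if len(fields) == 3:
                try:
                    label = int(fields[2])
                except ValueError:
                    raise PairValidationError(
                        f"{path}:{lineno}: label {fields[2]!r} is not an integer"
                    ) from None
                if label not in (0, 1):
                    raise PairValidationError(
                        f"{path}:{lineno}: label must be 0 or 1, got {label}"
                    )
            rows.append((fields[0], fields[1], label))

    deduped: list[tuple[str, str, Optional[int]]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for m, g, lab in rows:
        if (m, g) in seen:
            n_dup += 1
            continue
        seen.add((m, g))
        deduped.append((m, g, lab))
    if n_dup:
        logger.warning("read_pairs(%s): collapsed %d duplicate pair(s)", path, n_dup)
    return AssociationTable(deduped)


def _looks_like_header(fields: Sequence[str]) -> bool:
    known = {"mirna", "mirna_id", "gene", "gene_id", "label", "mir"}
    return any(f.strip().lower() in known for f in fields)


def write_pairs(table: AssociationTable, path: str | Path) -> None:
    """Write pairs as TSV in table order (2 or 3 columns depending on labels)."""
    with open(path, "w", encoding="utf-8") as fh:
        for m, g, lab in table:
            if lab is None:
                fh.write(f"{m}\t{g}\n")
            else:
                fh.write(f"{m}\t{g}\t{lab}\n")


def join_pairs_to_sequences(
    pairs: AssociationTable,
    mirnas: Sequence[SequenceRecord],
    genes: Sequence[SequenceRecord],
) -> tuple[AssociationTable, int]:
    """Keep only pairs whose miRNA and gene ids both have sequence records.

    Mirrors the refinement step in which interaction pairs without sequence
    information on either side are dropped. Returns (retained, n_dropped);
    the dropped count is also logged.
    """
    mirna_ids = {r.id for r in mirnas}
    gene_ids = {r.id for r in genes}
    kept = [
        (m, g, lab) for m, g, lab in pairs if m in mirna_ids and g in gene_ids
    ]
    n_dropped = len(pairs) - len(kept)
    if n_dropped:
        logger.info(
            "join_pairs_to_sequences: dropped %d of %d pair(s) lacking sequences",
            n_dropped,
            len(pairs),
        )
    return AssociationTable(kept), n_dropped
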