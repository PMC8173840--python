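"""Sequence records, standard-format IO, assembly statistics and read trimming.

The pipeline's carrier type is a minimal :class:`SeqRecord` (id + residue
string, with an opaque quality string for reads).  FASTA/FASTQ/PHYLIP
parsing and writing is delegated to Biopython; records cross the module
boundary as :class:`SeqRecord` so downstream stages stay independent of the
IO backend.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioRecord

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
# 20 canonical residues; ambiguity codes B/Z/X and stops are tolerated on
# input but excluded from composition arithmetic downstream.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "BZX*")


@dataclass
class SeqRecord:
    """A named sequence.

    Parameters
    ----------
    id : str
        Non-empty identifier.
    seq : str
        Residue string (uppercased on construction).
    quality : str, optional
        Phred quality string for FASTQ reads; carried opaquely and only ever
        truncated in step with the residues.
    """

    id: str
    seq: str
    quality: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.seq):
            raise ValueError(f"record {self.id!r}: quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AssemblyStats:
    """Contig-count, length and GC summary of an assembly."""

    n_contigs: int
    contig_lengths: tuple[int, ...]  # descending
    total_length: int
    gc_fraction: float

    @property
    def gc_percent(self) -> int:
        """GC as the integer percent a genome report would print."""
        return int(round(self.gc_fraction * 100))


@dataclass(frozen=True)
class ReadPrepParams:
    """Hard-trimming parameters: bases clipped from each end, minimum
    surviving length."""

    trim_5p: int = 5
    trim_3p: int = 5
    min_len: int = 30

    def __post_init__(self) -> None:
        if min(self.trim_5p, self.trim_3p, self.min_len) < 0:
            raise ValueError("trimming parameters must be non-negative")


def _check_nucleotide(records: Iterable[SeqRecord]) -> None:
    for rec in records:
        bad = set(rec.seq) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-nucleotide residues: "
                f"{''.join(sorted(bad))}"
            )


def assembly_stats(contigs: Sequence[SeqRecord]) -> AssemblyStats:
    """Summarize an assembly: contig count, lengths, total size and GC.

    GC is computed over unambiguous bases only: ``(#G + #C) / (#A + #C +
    #G + #T)``; ``N`` contributes to neither numerator nor denominator.
    """
    if not contigs:
        raise ValueError("assembly_stats requires at least one contig")
    _check_nucleotide(contigs)
    lengths = sorted((len(c) for c in contigs), reverse=True)
    gc = at = 0
    for rec in contigs:
        gc += rec.seq.count("G") + rec.seq.count("C")
        at += rec.seq.count("A") + rec.seq.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases in assembly")
    return AssemblyStats(
        n_contigs=len(contigs),
        contig_lengths=tuple(lengths),
        total_length=sum(lengths),
        gc_fraction=gc / (gc + at),
    )


def trim_reads(
    reads: Sequence[SeqRecord], params: ReadPrepParams
) -> list[SeqRecord]:
    """Hard-trim fixed base counts off both read ends.

    Reads shorter than ``min_len`` after trimming are dropped; input order
    is preserved.  Qualities, when present, are truncated in step.
    """
    _check_nucleotide(reads)
    out: list[SeqRecord] = []
    for rec in reads:
        stop = len(rec.seq) - params.trim_3p
        if stop <= params.trim_5p:
            continue
        seq = rec.seq[params.trim_5p : stop]
        if len(seq) < params.min_len:
            continue
        qual = (
            rec.quality[params.trim_5p : stop] if rec.quality is not None else None
        )
        out.append(SeqRecord(rec.id, seq, qual))
    return out


# ---------------------------------------------------------------------------
# format IO (Biopython-backed)
# ---------------------------------------------------------------------------


def _from_bio(rec: _BioRecord) -> SeqRecord:
    qual = rec.letter_annotations.get("phred_quality")
    quality = (
        "".join(chr(q + 33) for q in qual) if qual is not None else None
    )
    return SeqRecord(rec.id, str(rec.seq), quality)


def _to_bio(rec: SeqRecord, with_quality: bool) -> _BioRecord:
    bio = _BioRecord(_BioSeq(rec.seq), id=rec.id, description="")
    if with_quality:
        qual = rec.quality or "I" * len(rec.seq)  # Q40 placeholder
        bio.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
    return bio


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return [_from_bio(r) for r in _BioSeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    _BioSeqIO.write(
        [_to_bio(r, with_quality=False) for r in records], str(path), "fasta"
    )


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return [_from_bio(r) for r in _BioSeqIO.parse(str(path), "fastq")]


def write_fastq(records: Sequence[SeqRecord], path: str | Path) -> None:
    _BioSeqIO.write(
        [_to_bio(r, with_quality=True) for r in records], str(path), "fastq"
    )


def read_phylip(path: str | Path) -> list[SeqRecord]:
    """Read a sequential PHYLIP alignment (relaxed names)."""
    return [
        _from_bio(r)
        for r in _BioSeqIO.parse(str(path), "phylip-relaxed")
    ]


def write_phylip(records: Sequence[SeqRecord], path: str | Path) -> None:
    buf = io.StringIO()
    _BioSeqIO.write(
        [_to_bio(r, with_quality=False) for r in records], buf, "phylip-relaxed"
    )
    Path(path).write_text(buf.getvalue())


def stats_table(named_stats: dict[str, AssemblyStats]) -> "pd.DataFrame":
    """Tabulate assembly statistics, one row per named assembly."""
    import pandas as pd

    rows = [
        {
            "name": name,
            "n_contigs": s.n_contigs,
            "total_length": s.total_length,
            "gc_percent": s.gc_percent,
            "gc_fraction": s.gc_fraction,
        }
        for name, s in named_stats.items()
    ]
    return pd.DataFrame(rows)
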