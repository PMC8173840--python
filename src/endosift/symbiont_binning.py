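"""Isolating an endosymbiont genome from a mixed sequencing library.

A whole-insect DNA library mixes the host genome, the symbiont genome and
assorted contaminants.  The symbiont bin is isolated by two orthogonal
signals: shared canonical k-mers with labeled reference panels (taxonomic
votes) and read coverage (an intracellular symbiont present in many copies
per cell sits far above the low-coverage contaminant band).  The module
also recruits the symbiont-origin read pairs back out of the library,
validates assembled sequence by mapping-based consensus, flags
suspiciously high-coverage contig ends (the footprint of collapsed
rRNA/tRNA repeats at contig junctions) and scores completeness against a
marker-gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kmers
from .seq_io import SeqRecord

LABEL_SYMBIONT = "symbiont"
LABEL_HOST = "host"
LABEL_CONTAMINANT = "contaminant"
LABEL_UNASSIGNED = "unassigned"

#: reference-panel label -> contig label when that panel wins the vote
_REFERENCE_LABEL_MAP = {
    "symbiont-like": LABEL_SYMBIONT,
    "host": LABEL_HOST,
    "other": LABEL_CONTAMINANT,
}

_CONSENSUS_SEED_K = 21


@dataclass(frozen=True)
class BinningParams:
    """Tunables for contig classification and read recruitment.

    ``k_classify``/``min_vote_fraction`` control the reference k-mer vote;
    ``min_coverage`` is the retention cutoff separating the symbiont
    coverage band from contaminants; ``k_recruit``/``min_recruit_matches``
    control read-pair recruitment to the bin.
    """

    k_classify: int = 31
    min_vote_fraction: float = 0.02
    min_coverage: float = 30.0
    k_recruit: int = 25
    min_recruit_matches: int = 15

    def __post_init__(self) -> None:
        for k in (self.k_classify, self.k_recruit):
            if k < 15 or k % 2 == 0:
                raise ValueError("k-mer lengths must be odd and >= 15")
        if not (0.0 <= self.min_vote_fraction <= 1.0):
            raise ValueError("min_vote_fraction must be in [0, 1]")


@dataclass
class ContigProfile:
    """Per-contig evidence vector for binning."""

    contig_id: str
    length: int
    gc_fraction: float
    mean_coverage: float
    votes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise ValueError("coverage must be non-negative")
        if any(v < 0 for v in self.votes.values()):
            raise ValueError("votes must be non-negative")


@dataclass
class BinResult:
    """Exhaustive, exclusive labeling of every input contig."""

    labels: dict[str, str]
    profiles: dict[str, ContigProfile]
    symbiont_contigs: list[str]


def _gc_fraction(seq: str) -> float:
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    return gc / (gc + at) if gc + at else 0.0


def classify_contigs(
    contigs: Sequence[SeqRecord],
    coverage: Mapping[str, float],
    references: Mapping[str, Sequence[SeqRecord]],
    params: BinningParams | None = None,
) -> BinResult:
    """Label contigs by reference k-mer votes, then apply the coverage rule.

    Per contig, canonical k-mers shared with each reference panel are
    counted; the panel with the most votes wins when its vote fraction
    reaches ``min_vote_fraction`` (ties and no-evidence contigs stay
    unassigned).  Contigs voted symbiont-like but sitting below
    ``min_coverage`` are relabeled contaminant — the coverage filter that
    separates the true symbiont from low-coverage bacterial contamination.
    """
    params = params or BinningParams()
    unknown = set(references) - set(_REFERENCE_LABEL_MAP)
    if unknown:
        raise ValueError(f"unknown reference labels: {sorted(unknown)}")
    missing = [c.id for c in contigs if c.id not in coverage]
    if missing:
        raise ValueError(f"coverage missing for contigs: {missing}")
    panel_sets = {
        label: _kmers.kmer_set_many([r.seq for r in refs], params.k_classify)
        for label, refs in references.items()
    }
    labels: dict[str, str] = {}
    profiles: dict[str, ContigProfile] = {}
    for contig in contigs:
        votes: dict[str, int] = {}
        if len(contig.seq) < params.k_classify:
            warnings.warn(
                f"contig {contig.id!r} shorter than k_classify; unassigned"
            )
            n_valid = 0
        else:
            arr = _kmers.encode(contig.seq)[None, :]
            codes, valid = _kmers.canonical_codes(arr, params.k_classify)
            n_valid = int(valid.sum())
            for ref_label, panel in panel_sets.items():
                hits = _kmers.membership(codes, panel) & valid
                votes[ref_label] = int(hits.sum())
        profiles[contig.id] = ContigProfile(
            contig_id=contig.id,
            length=len(contig.seq),
            gc_fraction=_gc_fraction(contig.seq),
            mean_coverage=float(coverage[contig.id]),
            votes=votes,
        )
        label = LABEL_UNASSIGNED
        if n_valid > 0 and votes:
            top = max(votes.values())
            winners = [lb for lb, v in votes.items() if v == top]
            if top > 0 and len(winners) == 1:
                if top / n_valid >= params.min_vote_fraction:
                    label = _REFERENCE_LABEL_MAP[winners[0]]
        if (
            label == LABEL_SYMBIONT
            and coverage[contig.id] < params.min_coverage
        ):
            label = LABEL_CONTAMINANT
        labels[contig.id] = label
    symbiont = [c.id for c in contigs if labels[c.id] == LABEL_SYMBIONT]
    return BinResult(labels=labels, profiles=profiles, symbiont_contigs=symbiont)


def recruit_reads(
    reads: tuple[Sequence[SeqRecord], Sequence[SeqRecord]],
    bin_contigs: Sequence[SeqRecord],
    params: BinningParams | None = None,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Recruit read pairs whose mates both share k-mers with the bin.

    The contract-level stand-in for concordant end-to-end mapping: a pair
    is kept when each mate shares at least ``min_recruit_matches``
    canonical ``k_recruit``-mers with the bin contigs.  Pairing and input
    order are preserved.
    """
    params = params or BinningParams()
    if not bin_contigs:
        raise ValueError("empty bin")
    r1, r2 = reads
    if len(r1) != len(r2):
        raise ValueError("mate lists differ in length")
    if not r1:
        return [], []
    bin_set = _kmers.kmer_set_many(
        [c.seq for c in bin_contigs], params.k_recruit
    )
    c1 = _kmers.match_counts([r.seq for r in r1], params.k_recruit, bin_set)
    c2 = _kmers.match_counts([r.seq for r in r2], params.k_recruit, bin_set)
    keep = (c1 >= params.min_recruit_matches) & (
        c2 >= params.min_recruit_matches
    )
    idx = np.flatnonzero(keep)
    return [r1[i] for i in idx], [r2[i] for i in idx]


# ---------------------------------------------------------------------------
# mapping consensus
# ---------------------------------------------------------------------------


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _seed_index(seq: str, k: int) -> dict[int, list[int]]:
    arr = _kmers.encode(seq)[None, :]
    codes, valid = _kmers._forward_codes(arr, k)
    index: dict[int, list[int]] = {}
    for pos in np.flatnonzero(valid[0]):
        index.setdefault(int(codes[0, pos]), []).append(int(pos))
    return index


def _place_read(
    read: str,
    ref_arr: np.ndarray,
    index: dict[int, list[int]],
    k: int,
    stride: int,
) -> tuple[int, str, int] | None:
    """Best ungapped placement: (offset, oriented sequence, n_matches)."""
    best: tuple[int, str, int] | None = None
    ref_len = ref_arr.size
    for oriented in (read, _revcomp(read)):
        arr = _kmers.encode(oriented)[None, :]
        codes, valid = _kmers._forward_codes(arr, k)
        offsets: set[int] = set()
        for pos in range(0, codes.shape[1], stride):
            if not valid[0, pos]:
                continue
            for ref_pos in index.get(int(codes[0, pos]), ()):
                offsets.add(ref_pos - pos)
        read_arr = arr[0]
        for off in sorted(offsets):
            lo = max(0, -off)
            hi = min(len(oriented), ref_len - off)
            if hi - lo < k:
                continue
            matches = int(
                (read_arr[lo:hi] == ref_arr[off + lo : off + hi]).sum()
            )
            if best is None or matches > best[2]:
                best = (off, oriented, matches)
    return best


def consensus_by_mapping(
    reads: Sequence[SeqRecord],
    reference: SeqRecord,
    min_depth: int = 2,
) -> SeqRecord:
    """Majority-rule consensus of reads placed on a reference.

    Reads are placed by best ungapped k-mer-seeded alignment (both
    orientations).  Columns with depth >= ``min_depth`` take the majority
    base, ties resolved toward the reference; columns below depth keep the
    reference base.  This mirrors validating an assembly by aligning the
    raw library to a relative's gene and calling the consensus.
    """
    ref_arr = _kmers.encode(reference.seq)
    index = _seed_index(reference.seq, _CONSENSUS_SEED_K)
    counts = np.zeros((4, len(reference.seq)), dtype=np.int64)
    placed = 0
    for read in reads:
        if len(read.seq) < _CONSENSUS_SEED_K:
            continue
        hit = _place_read(read.seq, ref_arr, index, _CONSENSUS_SEED_K, 4)
        if hit is None:
            continue
        off, oriented, _ = hit
        arr = _kmers.encode(oriented)
        lo = max(0, -off)
        hi = min(arr.size, ref_arr.size - off)
        seg = arr[lo:hi]
        cols = np.arange(off + lo, off + hi)
        ok = seg >= 0
        np.add.at(counts, (seg[ok], cols[ok]), 1)
        placed += 1
    if placed == 0:
        warnings.warn("no reads placed on the reference; returning it as-is")
        return SeqRecord(f"{reference.id}_consensus", reference.seq)
    depth = counts.sum(axis=0)
    bases = np.array(list("ACGT"))
    winner = counts.argmax(axis=0)
    top = counts.max(axis=0)
    out = []
    for j, ref_ch in enumerate(reference.seq):
        if depth[j] < min_depth:
            out.append(ref_ch)
            continue
        ties = np.flatnonzero(counts[:, j] == top[j])
        ref_state = _kmers.encode(ref_ch)[0]
        if ref_state in ties:
            out.append(ref_ch)  # ties break toward the reference
        else:
            out.append(bases[winner[j]])
    return SeqRecord(f"{reference.id}_consensus", "".join(out))


# ---------------------------------------------------------------------------
# coverage profiles and terminal-ambiguity flagging
# ---------------------------------------------------------------------------


def window_coverage_profile(
    contigs: Sequence[SeqRecord],
    reads: Sequence[SeqRecord],
    window: int = 500,
    k: int = 31,
    stride: int = 8,
) -> dict[str, np.ndarray]:
    """Approximate per-window fold coverage by k-mer seed placement.

    Every reference position matching one of a read's sampled k-mers is
    credited with the read's span, so a segment duplicated across contig
    ends accumulates the reads of all its copies — exactly the multi-
    mapping inflation that betrays collapsed repeats.
    """
    indexes = {
        c.id: (_kmers.encode(c.seq), _seed_index_canonical(c.seq, k))
        for c in contigs
    }
    depth = {c.id: np.zeros(len(c.seq)) for c in contigs}
    lengths = {c.id: len(c.seq) for c in contigs}
    for read in reads:
        if len(read.seq) < k:
            continue
        arr = _kmers.encode(read.seq)[None, :]
        codes, valid = _kmers.canonical_codes(arr, k)
        for cid, (_, index) in indexes.items():
            credited = False
            for pos in range(0, codes.shape[1], stride):
                if not valid[0, pos]:
                    continue
                hits = index.get(int(codes[0, pos]))
                if not hits:
                    continue
                for ref_pos in hits:
                    start = max(0, ref_pos - pos)
                    stop = min(lengths[cid], start + len(read.seq))
                    depth[cid][start:stop] += 1.0
                credited = True
                break
            if credited:
                continue
    profiles = {}
    for c in contigs:
        d = depth[c.id]
        n_win = max(1, len(d) // window)
        profiles[c.id] = np.array(
            [
                d[i * window : (i + 1) * window if i < n_win - 1 else None].mean()
                for i in range(n_win)
            ]
        )
    return profiles


def _seed_index_canonical(seq: str, k: int) -> dict[int, list[int]]:
    arr = _kmers.encode(seq)[None, :]
    codes, valid = _kmers.canonical_codes(arr, k)
    index: dict[int, list[int]] = {}
    for pos in np.flatnonzero(valid[0]):
        index.setdefault(int(codes[0, pos]), []).append(int(pos))
    return index


def flag_terminal_ambiguity(
    contigs: Sequence[SeqRecord],
    coverage_profile: Mapping[str, np.ndarray],
    window: int = 500,
    factor: float = 3.0,
) -> pd.DataFrame:
    """Flag contig ends whose coverage exceeds ``factor`` x the contig
    median — the signature of repeats (rRNA/tRNA operons) collapsed at
    contig junctions.  Returns one row per flagged terminal window with
    columns contig, end (5p/3p), window_coverage, median_coverage.
    """
    rows = []
    for contig in contigs:
        if len(contig.seq) < window:
            warnings.warn(
                f"contig {contig.id!r} shorter than window; skipped"
            )
            continue
        profile = np.asarray(coverage_profile[contig.id], dtype=float)
        if profile.size == 0:
            continue
        median = float(np.median(profile))
        for end, value in (("5p", profile[0]), ("3p", profile[-1])):
            if np.isfinite(factor) and value > median * factor:
                rows.append(
                    {
                        "contig": contig.id,
                        "end": end,
                        "window_coverage": float(value),
                        "median_coverage": median,
                    }
                )
    return pd.DataFrame(
        rows, columns=["contig", "end", "window_coverage", "median_coverage"]
    )


def marker_completeness(
    present_genes: Iterable[str], marker_set: Iterable[str]
) -> float:
    """Fraction of a marker-gene set present in the annotation — the
    simplified completeness score for a draft symbiont genome."""
    markers = set(marker_set)
    if not markers:
        raise ValueError("marker set must be non-empty")
    return len(set(present_genes) & markers) / len(markers)
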