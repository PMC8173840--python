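"""Amino-acid composition prediction for feather keratins.

Feather barbs are nearly pure keratin, so the residue composition of a
bird's feather-keratin gene complement predicts the dietary amino-acid
supply of a feather-feeding louse.  The procedure: search a proteome for
the best local-alignment hit of each known feather-keratin query, pool the
residues of the accepted hits, and compare the resulting profile to a
biochemically determined reference — with special attention to the ten
amino acids insects cannot synthesize (His, Lys, Met and Trp being the
ones feathers essentially lack).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import AMINO_ACIDS, SeqRecord

logger = logging.getLogger(__name__)

#: the ten amino acids insects require from an exogenous source
ESSENTIAL_RESIDUES = ("F", "H", "I", "K", "L", "M", "R", "T", "V", "W")

#: residues excluded from composition arithmetic
AMBIGUOUS_RESIDUES = frozenset("BZX*")


@dataclass(frozen=True)
class AlignParams:
    """Protein local-alignment scoring parameters.

    A gap of length L costs ``gap_open + L * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_report_score: float = 50.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


@dataclass(frozen=True)
class AAProfile:
    """Relative frequencies over the 20 amino acids."""

    frequencies: Mapping[str, float]
    n_residues: int

    def __post_init__(self) -> None:
        freqs = {aa: float(self.frequencies.get(aa, 0.0)) for aa in AMINO_ACIDS}
        object.__setattr__(self, "frequencies", freqs)
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if min(freqs.values()) < 0:
            raise ValueError("negative frequency")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "AAProfile":
        clean = {
            aa: int(c)
            for aa, c in counts.items()
            if aa in AMINO_ACIDS and c > 0
        }
        total = sum(clean.values())
        if total == 0:
            raise ValueError("no countable residues")
        return cls(
            frequencies={aa: clean.get(aa, 0) / total for aa in AMINO_ACIDS},
            n_residues=total,
        )

    @property
    def essential_view(self) -> dict[str, float]:
        """Frequencies of the ten insect-essential residues."""
        return {aa: self.frequencies[aa] for aa in ESSENTIAL_RESIDUES}

    def as_percent(self, ndigits: int = 1) -> dict[str, float]:
        """Report-layer rounding to percentages (half-up at 0.1 pp by
        default); internal comparisons always use full precision."""
        out = {}
        for aa, f in self.frequencies.items():
            scaled = f * 100 * 10**ndigits
            out[aa] = float(np.floor(scaled + 0.5) / 10**ndigits)
        return out


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def smith_waterman(
    query: SeqRecord, target: SeqRecord, params: AlignParams | None = None
) -> tuple[float, tuple[tuple[int, int], tuple[int, int]] | None]:
    """Optimal local alignment score and aligned region.

    Returns ``(score, ((q_start, q_end), (t_start, t_end)))`` with 0-based
    half-open coordinates, or ``(0.0, None)`` when no positive-scoring
    local alignment exists.  Traceback is deterministic (first optimal
    path).
    """
    params = params or AlignParams()
    if not query.seq or not target.seq:
        raise ValueError("empty sequence")
    aligner = _aligner(params)
    score = float(aligner.score(query.seq, target.seq))
    if score <= 0.0:
        return 0.0, None
    alignment = aligner.align(query.seq, target.seq)[0]
    q_blocks, t_blocks = alignment.aligned
    region = (
        (int(q_blocks[0][0]), int(q_blocks[-1][1])),
        (int(t_blocks[0][0]), int(t_blocks[-1][1])),
    )
    return score, region


@dataclass
class BestHitResult:
    """Best proteome hit per query, plus the queries nothing matched."""

    hits: dict[str, SeqRecord]
    scores: dict[str, float]
    unmatched: list[str] = field(default_factory=list)


def best_hit_keratins(
    queries: Sequence[SeqRecord],
    proteome: Sequence[SeqRecord],
    params: AlignParams | None = None,
) -> BestHitResult:
    """Best local-alignment hit in the proteome for each keratin query.

    A hit is accepted when its score reaches ``min_report_score``; ties go
    to the earlier proteome record.  Multiple queries may share one best
    hit; duplicates are kept (and logged) since each query represents a
    distinct keratin gene.
    """
    if not queries:
        raise ValueError("no query sequences")
    params = params or AlignParams()
    aligner = _aligner(params)
    hits: dict[str, SeqRecord] = {}
    scores: dict[str, float] = {}
    unmatched: list[str] = []
    for q in queries:
        best: SeqRecord | None = None
        best_score = -np.inf
        for rec in proteome:
            s = float(aligner.score(q.seq, rec.seq))
            if s > best_score:
                best, best_score = rec, s
        if best is None or best_score < params.min_report_score:
            unmatched.append(q.id)
        else:
            hits[q.id] = best
            scores[q.id] = best_score
    seen: dict[str, list[str]] = {}
    for qid, rec in hits.items():
        seen.setdefault(rec.id, []).append(qid)
    for hit_id, qids in seen.items():
        if len(qids) > 1:
            logger.info("hit %s shared by queries %s", hit_id, qids)
    return BestHitResult(hits=hits, scores=scores, unmatched=unmatched)


def aa_composition(proteins: Sequence[SeqRecord]) -> AAProfile:
    """Pooled relative amino-acid composition across all records.

    Residues are pooled record-wise (long keratins weigh more, as in a
    bulk biochemical assay); ambiguity codes B/Z/X and stops are excluded
    from both numerator and denominator.
    """
    if not proteins:
        raise ValueError("no protein sequences")
    counts: dict[str, int] = {}
    for rec in proteins:
        bad = set(rec.seq) - set(AMINO_ACIDS) - AMBIGUOUS_RESIDUES
        if bad:
            raise ValueError(
                f"record {rec.id!r} has non-amino-acid residues: "
                f"{''.join(sorted(bad))}"
            )
        for ch in rec.seq:
            if ch in AMBIGUOUS_RESIDUES:
                continue
            counts[ch] = counts.get(ch, 0) + 1
    return AAProfile.from_counts(counts)


def compare_profiles(
    predicted: AAProfile,
    reference: Mapping[str, float],
    residues: Sequence[str] = ESSENTIAL_RESIDUES,
) -> tuple[pd.DataFrame, float]:
    """Per-residue difference table (percentage points) and L1 distance.

    ``reference`` maps residues to fractions.  Residues where the
    reference is zero but the prediction is positive are flagged — the
    signature pattern of His/Lys/Met/Trp, present at trace levels in
    predicted keratin sets yet undetected biochemically.
    """
    if not residues:
        raise ValueError("empty residue subset")
    rows = []
    for aa in residues:
        pred = predicted.frequencies.get(aa, 0.0) * 100
        ref = float(reference.get(aa, 0.0)) * 100
        rows.append(
            {
                "residue": aa,
                "predicted_pct": pred,
                "reference_pct": ref,
                "diff_pp": pred - ref,
                "flag_absent_in_reference": ref == 0.0 and pred > 0.0,
            }
        )
    table = pd.DataFrame(rows)
    l1 = float(table["diff_pp"].abs().sum())
    return table, l1


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return importlib.resources.files("endosift").joinpath("data", name)


def load_reference_profile(name: str = "arai_chicken") -> dict[str, float]:
    """A packaged reference composition as residue -> fraction.

    ``arai_chicken`` is the biochemically determined feather-barb keratin
    composition of the chicken over the ten insect-essential residues.
    """
    table = pd.read_csv(_data_path(f"{name}.tsv"), sep="\t")
    return {
        row["residue"]: row["percent"] / 100.0 for _, row in table.iterrows()
    }


def load_predicted_keratin_table() -> pd.DataFrame:
    """Packaged predicted keratin compositions (percent) for the rock dove
    (Cliv_1.0) and chicken (GRCg6a) over the essential residues."""
    return pd.read_csv(_data_path("predicted_keratin.tsv"), sep="\t")
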