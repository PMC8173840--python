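"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its configuration and seed and emits
planted ground truth alongside the data, so every downstream stage can be
tested for planted-signal recovery without touching real accessions:

- a mixed read community (high-coverage AT-rich symbiont, larger
  moderate-coverage host, low-coverage contaminants),
- keratin proteomes with controlled residue composition plus uniform
  decoys,
- gene-presence tables realizing requested pathway statuses,
- multi-gene codon alignments with planted substitution-model classes and
  optional per-branch GC drift.

Defaults for the community mirror the sequencing regime the pipeline is
built for: a ~100 kb symbiont genome at 30% GC and 90x coverage against a
host at moderate coverage and contaminants in the 3-25x band, 151-base
paired reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .keratin_composition import AAProfile
from .pathway_scoring import PathwayDef
from .phylo_partition import (
    CodonAlignment,
    GTRGammaFit,
    _gtr_eigen,
    _transition_matrices,
    discrete_gamma_rates,
)
from .nonstationary_phylo import t92_equilibrium, t92_transition_matrix
from .seq_io import AMINO_ACIDS, SeqRecord
from .trees import Tree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# mixed community
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunityConfig:
    """Composition of the simulated whole-insect sequencing library."""

    symbiont_length: int = 100_000
    symbiont_gc: float = 0.30
    symbiont_coverage: float = 90.0
    host_length: int = 1_000_000
    host_gc: float = 0.42
    host_coverage: float = 40.0
    contaminant_specs: tuple[tuple[int, float, float], ...] = (
        (40_000, 0.50, 3.0),
        (40_000, 0.55, 25.0),
    )
    read_length: int = 151
    error_rate: float = 0.002
    insert_size: int = 350
    shared_rrna: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        covs = [self.symbiont_coverage, self.host_coverage] + [
            c for _, _, c in self.contaminant_specs
        ]
        gcs = [self.symbiont_gc, self.host_gc] + [
            g for _, g, _ in self.contaminant_specs
        ]
        if min(covs) <= 0:
            raise ValueError("coverages must be positive")
        if not all(0.0 < g < 1.0 for g in gcs):
            raise ValueError("GC fractions must lie in (0, 1)")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")


@dataclass
class CommunityTruth:
    """Planted origin of every contig and read, plus the true symbiont."""

    contig_origin: dict[str, str]
    read_origin: dict[str, str]
    symbiont_sequence: str


def _random_genome(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _split_contigs(
    genome: np.ndarray, fractions: Sequence[float], prefix: str
) -> list[tuple[str, np.ndarray]]:
    bounds = np.cumsum(np.array(fractions) / np.sum(fractions)) * genome.size
    bounds = bounds.astype(int)
    out, start = [], 0
    for i, stop in enumerate(bounds, start=1):
        stop = genome.size if i == len(fractions) else stop
        out.append((f"{prefix}_c{i}", genome[start:stop]))
        start = stop
    return out


def simulate_community(
    config: CommunityConfig | None = None,
) -> tuple[
    list[SeqRecord],
    tuple[list[SeqRecord], list[SeqRecord]],
    dict[str, float],
    CommunityTruth,
]:
    """Simulate genomes, contigs and paired reads for the mixed library.

    Genomes are i.i.d. draws with per-genome GC bias; the symbiont is
    emitted as two contigs (the larger ~3x the smaller), the host as five,
    each contaminant as one.  Paired 151-base reads are drawn uniformly
    along each genome at its fold coverage with substitution errors only.
    With ``shared_rrna`` a 1.5-kb segment is duplicated at all four
    symbiont contig ends and inside the first contaminant, reproducing the
    repeat structure that breaks assemblies at rRNA operons.

    Returns ``(contigs, (reads1, reads2), per-contig mean coverage,
    truth)``; identical config and seed give identical output.
    """
    config = config or CommunityConfig()
    rng = np.random.default_rng(config.seed)

    genomes: list[tuple[str, np.ndarray, float, list[tuple[str, np.ndarray]]]] = []

    sym = _random_genome(config.symbiont_length, config.symbiont_gc, rng)
    if config.shared_rrna:
        repeat = _random_genome(1_500, config.symbiont_gc, rng)
        half = sym.size // 2
        core1, core2 = sym[:half], sym[half:]
        c1 = np.concatenate([repeat, core1, repeat])
        c2 = np.concatenate([repeat, core2, repeat])
        sym = np.concatenate([c1, c2])
        sym_contigs = [("symbiont_c1", c1), ("symbiont_c2", c2)]
    else:
        sym_contigs = _split_contigs(sym, (0.745, 0.255), "symbiont")
    genomes.append(("symbiont", sym, config.symbiont_coverage, sym_contigs))

    host = _random_genome(config.host_length, config.host_gc, rng)
    genomes.append(
        (
            "host",
            host,
            config.host_coverage,
            _split_contigs(host, (0.2,) * 5, "host"),
        )
    )

    for i, (length, gc, cov) in enumerate(config.contaminant_specs, start=1):
        g = _random_genome(length, gc, rng)
        if config.shared_rrna and i == 1:
            mid = g.size // 2
            g = np.concatenate([g[:mid], repeat, g[mid:]])
        genomes.append(
            (f"contaminant_{i}", g, cov, [(f"contaminant_{i}_c1", g)])
        )

    rl = config.read_length
    contigs: list[SeqRecord] = []
    reads1: list[SeqRecord] = []
    reads2: list[SeqRecord] = []
    coverage_table: dict[str, float] = {}
    contig_origin: dict[str, str] = {}
    read_origin: dict[str, str] = {}

    for origin, genome, cov, parts in genomes:
        frag = min(max(config.insert_size, 2 * rl), genome.size)
        n_pairs = int(round(cov * genome.size / (2 * rl)))
        if n_pairs < 1:
            raise ValueError(
                f"infeasible config: {origin} coverage yields no reads"
            )
        pos = rng.integers(0, genome.size - frag + 1, size=n_pairs)
        offsets = np.arange(rl)
        r1 = genome[pos[:, None] + offsets]
        r2 = genome[pos[:, None] + (frag - rl) + offsets]
        r2 = 3 - r2[:, ::-1]  # reverse complement
        for mat in (r1, r2):
            err = rng.random(mat.shape) < config.error_rate
            if err.any():
                mat[err] = (mat[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
        for i in range(n_pairs):
            rid = f"{origin}_r{i:06d}"
            reads1.append(SeqRecord(rid, _codes_to_str(r1[i])))
            reads2.append(SeqRecord(rid, _codes_to_str(r2[i])))
            read_origin[rid] = origin

        # realized per-contig coverage from the sampled fragment positions
        delta = np.zeros(genome.size + 1)
        np.add.at(delta, pos, 1.0)
        np.add.at(delta, pos + rl, -1.0)
        np.add.at(delta, pos + frag - rl, 1.0)
        np.add.at(delta, pos + frag, -1.0)
        depth = np.cumsum(delta[:-1])
        start = 0
        for cid, part in parts:
            contigs.append(SeqRecord(cid, _codes_to_str(part)))
            contig_origin[cid] = origin
            coverage_table[cid] = float(
                depth[start : start + part.size].mean()
            )
            start += part.size

    truth = CommunityTruth(
        contig_origin=contig_origin,
        read_origin=read_origin,
        symbiont_sequence=_codes_to_str(sym),
    )
    return contigs, (reads1, reads2), coverage_table, truth


# ---------------------------------------------------------------------------
# keratin proteomes
# ---------------------------------------------------------------------------


def simulate_keratin_proteome(
    target_profile: AAProfile,
    n_keratins: int = 50,
    mean_len: int = 100,
    decoy_count: int = 100,
    seed: int = 0,
) -> tuple[list[SeqRecord], AAProfile]:
    """Keratins drawn residue-wise from a target composition plus uniform
    decoys.  Truth is the empirical composition of the emitted keratins
    (what a perfect best-hit search would recover)."""
    if n_keratins < 1:
        raise ValueError("n_keratins must be >= 1")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    probs = np.array([target_profile.frequencies[a] for a in aas])
    probs = probs / probs.sum()
    proteome: list[SeqRecord] = []
    counts: dict[str, int] = {a: 0 for a in AMINO_ACIDS}
    for i in range(n_keratins):
        length = max(30, int(rng.poisson(mean_len)))
        seq = "".join(rng.choice(aas, size=length, p=probs))
        for ch in seq:
            counts[ch] += 1
        proteome.append(SeqRecord(f"keratin_{i:04d}", seq))
    for i in range(decoy_count):
        length = max(30, int(rng.poisson(mean_len)))
        proteome.append(
            SeqRecord(f"decoy_{i:04d}", "".join(rng.choice(aas, size=length)))
        )
    return proteome, AAProfile.from_counts(counts)


def perturb_proteins(
    records: Sequence[SeqRecord], sub_rate: float = 0.05, seed: int = 0
) -> list[SeqRecord]:
    """Substitute a fraction of residues at random — divergent query
    sequences for exercising the homolog search."""
    rng = np.random.default_rng(seed)
    aas = list(AMINO_ACIDS)
    out = []
    for rec in records:
        chars = list(rec.seq)
        for j in range(len(chars)):
            if rng.random() < sub_rate:
                chars[j] = aas[rng.integers(len(aas))]
        out.append(SeqRecord(f"{rec.id}_query", "".join(chars)))
    return out


# ---------------------------------------------------------------------------
# gene-presence tables
# ---------------------------------------------------------------------------


def simulate_gene_content(
    pathways: Sequence[PathwayDef],
    statuses: Mapping[str, str],
    seed: int = 0,
    absence_threshold: float = 0.0,
) -> tuple[set[str], pd.DataFrame]:
    """Draw a gene-presence table realizing the requested pathway statuses.

    intact: all genes present.  incomplete: a strict nonempty proper
    subset (at least one present, at least one missing).  absent: at most
    ``floor(absence_threshold * n)`` genes present (zero by default).
    """
    missing = {p.name for p in pathways} - set(statuses)
    if missing:
        raise ValueError(f"statuses missing for pathways: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    present: set[str] = set()
    for pathway in pathways:
        status = statuses[pathway.name]
        genes = list(pathway.gene_ids)
        n = len(genes)
        if status == "intact":
            present.update(genes)
        elif status == "incomplete":
            if n < 2:
                raise ValueError(
                    f"pathway {pathway.name!r} has <2 genes; cannot be incomplete"
                )
            n_present = int(rng.integers(1, n))
            keep = rng.choice(n, size=n_present, replace=False)
            present.update(genes[i] for i in keep)
        elif status == "absent":
            cap = int(np.floor(absence_threshold * n))
            n_present = int(rng.integers(0, cap + 1))
            keep = rng.choice(n, size=n_present, replace=False)
            present.update(genes[i] for i in keep)
        else:
            raise ValueError(f"unknown status {status!r}")
    universe = [g for p in pathways for g in p.gene_ids]
    table = pd.DataFrame(
        {
            "gene_id": universe,
            "present": [1 if g in present else 0 for g in universe],
        }
    )
    return present, table


# ---------------------------------------------------------------------------
# partitioned codon alignments
# ---------------------------------------------------------------------------


def _sample_states(
    probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized categorical draw: one state per row of ``probs``."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])
    return (u[:, None] > cum).sum(axis=1).clip(0, 3)


def _evolve_sites(
    tree: Tree,
    p_for_branch_cat,
    root_freqs: np.ndarray,
    site_cats: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    n_sites = site_cats.size
    states = {tree.root.id: _sample_states(
        np.tile(root_freqs, (n_sites, 1)), rng
    )}
    leaves: dict[str, np.ndarray] = {}
    for node in reversed(tree.postorder()):  # preorder
        if node.parent is None:
            continue
        parent_states = states[node.parent.id]
        child = np.empty(n_sites, dtype=np.int64)
        for cat in np.unique(site_cats):
            sel = site_cats == cat
            pm = p_for_branch_cat(node, int(cat))
            child[sel] = _sample_states(pm[parent_states[sel]], rng)
        states[node.id] = child
        if node.is_leaf:
            leaves[node.name] = child
    return leaves


def simulate_partitioned_alignments(
    tree: Tree,
    n_genes: int,
    class_params: Sequence[GTRGammaFit],
    class_assignment: Sequence[int],
    sites_per_gene: int = 300,
    nonstationary: Mapping[int, float] | None = None,
    nonstationary_kappa: float = 2.0,
    nonstationary_base_theta: float = 0.4,
    n_categories: int = 4,
    seed: int = 0,
) -> tuple[list[CodonAlignment], list[int]]:
    """Evolve gene alignments down a tree under planted model classes.

    Each gene's sites evolve under its class's GTR parameters with
    discrete-Gamma rate heterogeneity (4 categories).  When a
    ``nonstationary`` map (branch node id -> GC equilibrium theta) is
    given, branch transition matrices switch to the T92 model at that
    branch's theta (``nonstationary_base_theta`` for unlisted branches),
    planting composition drift along chosen lineages.

    Returns the gene alignments and the planted class per gene.
    """
    if len(tree.leaf_names()) < 3:
        raise ValueError("tree must have at least 3 leaves")
    if len(class_assignment) != n_genes:
        raise ValueError("class_assignment must cover every gene")
    if sites_per_gene % 3 != 0:
        raise ValueError("sites_per_gene must be a multiple of 3")
    rng = np.random.default_rng(seed)
    branch_nodes = [n for n in tree.postorder() if n.parent is not None]

    alignments: list[CodonAlignment] = []
    for g in range(n_genes):
        cls = class_params[class_assignment[g]]
        cat_rates = discrete_gamma_rates(cls.alpha, n_categories)
        if nonstationary is None:
            eig = _gtr_eigen(np.array(cls.rates), np.array(cls.freqs))
            lengths = np.array([max(n.length, 1e-6) for n in branch_nodes])
            pmats = _transition_matrices(eig, lengths, cat_rates)
            index = {n.id: b for b, n in enumerate(branch_nodes)}
            root_freqs = np.array(cls.freqs)

            def p_fn(node, cat, pmats=pmats, index=index):
                return pmats[index[node.id], cat]

        else:
            theta_of = {
                n.id: nonstationary.get(n.id, nonstationary_base_theta)
                for n in branch_nodes
            }
            cache: dict[tuple[int, int], np.ndarray] = {}

            def p_fn(node, cat, theta_of=theta_of, cache=cache,
                     cat_rates=cat_rates):
                key = (node.id, cat)
                if key not in cache:
                    cache[key] = t92_transition_matrix(
                        theta_of[node.id],
                        nonstationary_kappa,
                        max(node.length, 1e-6) * cat_rates[cat],
                    )
                return cache[key]

            root_freqs = t92_equilibrium(nonstationary_base_theta)

        site_cats = rng.integers(0, n_categories, size=sites_per_gene)
        leaves = _evolve_sites(tree, p_fn, root_freqs, site_cats, rng)
        records = [
            SeqRecord(name, _codes_to_str(states))
            for name, states in leaves.items()
        ]
        alignments.append(CodonAlignment(f"gene_{g:03d}", records))
    return alignments, list(class_assignment)
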