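"""Planted-truth recovery runs for every pipeline stage.

Each function simulates inputs with known ground truth under the study
conditions the pipeline targets (symbiont at 90x vs contaminants at
3-25x, ~5,000-residue keratin sets, well-separated substitution-model
classes, seven alternative placements of one taxon) and measures how well
the corresponding stage recovers the planted signal.  All functions are
deterministic given their seed.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import _kmers
from .keratin_composition import (
    AAProfile,
    aa_composition,
    best_hit_keratins,
)
from .pathway_scoring import load_pathways, score_pathways
from .phylo_partition import (
    GTRGammaFit,
    fit_gtr_gamma,
    partition_workflow,
)
from .nonstationary_phylo import optimize_model, rell_rank, uniform_model
from .seq_io import AMINO_ACIDS, SeqRecord, assembly_stats
from .symbiont_binning import BinningParams, classify_contigs, recruit_reads
from .synthetic_data import (
    CommunityConfig,
    perturb_proteins,
    simulate_community,
    simulate_gene_content,
    simulate_keratin_proteome,
    simulate_partitioned_alignments,
)
from .trees import Tree, random_topology, regraft_leaf


def _mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    codes = _kmers.encode(seq).copy()
    m = rng.random(codes.size) < rate
    codes[m] = (codes[m] + rng.integers(1, 4, int(m.sum()))) % 4
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()


def binning_benchmark(
    seed: int,
    config: CommunityConfig | None = None,
    reference_divergence: float = 0.03,
) -> dict[str, float]:
    """Symbiont contig and read-recruitment recovery on a simulated
    community.

    Reference panels are 3%-divergent relatives of the true genomes,
    emulating a custom library of related bacterial and host genomes.
    Returns contig recall/precision, read recall/precision and the GC
    percent of the recovered bin.
    """
    config = config or CommunityConfig(seed=seed)
    if config.seed != seed:
        config = CommunityConfig(**{**config.__dict__, "seed": seed})
    contigs, (r1, r2), coverage, truth = simulate_community(config)
    rng = np.random.default_rng(seed + 1)
    host_genome = "".join(
        c.seq for c in contigs if truth.contig_origin[c.id] == "host"
    )
    contaminant_genomes = [
        c.seq for c in contigs
        if truth.contig_origin[c.id].startswith("contaminant")
    ]
    references = {
        "symbiont-like": [
            SeqRecord(
                "rel_symbiont",
                _mutate_dna(truth.symbiont_sequence, reference_divergence, rng),
            )
        ]
        + [
            # low-coverage contaminants are themselves bacteria-like, so
            # they hit the symbiont panel too: the coverage rule must sort
            # them out, as in the real analysis
            SeqRecord(
                f"rel_contam_{i}", _mutate_dna(g, reference_divergence, rng)
            )
            for i, g in enumerate(contaminant_genomes)
        ],
        "host": [
            SeqRecord("rel_host", _mutate_dna(host_genome, reference_divergence, rng))
        ],
    }
    result = classify_contigs(contigs, coverage, references, BinningParams())

    true_sym = {
        c.id for c in contigs if truth.contig_origin[c.id] == "symbiont"
    }
    called_sym = set(result.symbiont_contigs)
    contig_recall = len(true_sym & called_sym) / len(true_sym)
    contig_precision = (
        len(true_sym & called_sym) / len(called_sym) if called_sym else 0.0
    )

    bin_contigs = [c for c in contigs if c.id in called_sym]
    k1, _ = recruit_reads((r1, r2), bin_contigs, BinningParams())
    recruited = {r.id for r in k1}
    sym_reads = {
        rid for rid, origin in truth.read_origin.items() if origin == "symbiont"
    }
    read_recall = len(recruited & sym_reads) / len(sym_reads)
    read_precision = (
        len(recruited & sym_reads) / len(recruited) if recruited else 0.0
    )
    gc_percent = (
        assembly_stats(bin_contigs).gc_percent if bin_contigs else float("nan")
    )
    return {
        "contig_recall": contig_recall,
        "contig_precision": contig_precision,
        "read_recall": read_recall,
        "read_precision": read_precision,
        "bin_gc_percent": float(gc_percent),
        "n_contigs": len(contigs),
        "n_read_pairs": len(r1),
    }


def default_keratin_target() -> AAProfile:
    """A feather-keratin-like target composition.

    The ten insect-essential residues follow the predicted chicken keratin
    column of the packaged reference table; the remainder is spread over
    the non-essential residues in keratin-typical proportions (Ser/Gly/
    Pro/Cys-rich).
    """
    from .keratin_composition import load_predicted_keratin_table

    table = load_predicted_keratin_table().set_index("residue")
    essential = (table["gallus_gallus_pct"] / 100.0).to_dict()
    non_essential_weights = {
        "S": 14.0, "G": 13.0, "P": 10.0, "C": 7.0, "A": 6.0,
        "N": 4.0, "D": 4.0, "E": 4.0, "Q": 3.0, "Y": 2.0,
    }
    remainder = 1.0 - sum(essential.values())
    total_w = sum(non_essential_weights.values())
    freqs = {aa: 0.0 for aa in AMINO_ACIDS}
    freqs.update(essential)
    for aa, w in non_essential_weights.items():
        freqs[aa] = remainder * w / total_w
    return AAProfile(frequencies=freqs, n_residues=0)


def keratin_benchmark(
    seed: int,
    n_keratins: int = 50,
    mean_len: int = 100,
    decoy_count: int = 100,
    query_divergence: float = 0.08,
) -> dict[str, float]:
    """End-to-end keratin pipeline on a planted proteome.

    Simulates keratins from the default target plus uniform decoys, builds
    divergent queries, runs the best-hit search and pooled composition,
    and reports the largest per-residue deviation (percentage points) from
    the planted truth, plus search purity against decoys.
    """
    target = default_keratin_target()
    proteome, truth = simulate_keratin_proteome(
        target, n_keratins=n_keratins, mean_len=mean_len,
        decoy_count=decoy_count, seed=seed,
    )
    keratins = [r for r in proteome if r.id.startswith("keratin")]
    queries = perturb_proteins(keratins, query_divergence, seed=seed + 1)
    result = best_hit_keratins(queries, proteome)
    profile = aa_composition(list(result.hits.values()))
    max_err = max(
        abs(profile.frequencies[aa] - truth.frequencies[aa]) * 100
        for aa in AMINO_ACIDS
    )
    decoy_hits = sum(
        1 for rec in result.hits.values() if rec.id.startswith("decoy")
    )
    return {
        "max_abs_error_pp": max_err,
        "n_residues": profile.n_residues,
        "decoy_hits": decoy_hits,
        "unmatched_queries": len(result.unmatched),
    }


def pathway_roundtrip_benchmark(seed: int) -> dict[str, float]:
    """Round-trip accuracy of pathway calls over every status combination.

    Cycles intact/incomplete/absent across the packaged pathway set in
    three rotations plus uniform all-intact / all-incomplete / all-absent
    draws, scoring each simulated presence table.
    """
    pathways = load_pathways()
    total = correct = 0
    rotations = [
        dict(zip((p.name for p in pathways), itertools.islice(
            itertools.cycle(order), len(pathways))))
        for order in (
            ("intact", "incomplete", "absent"),
            ("incomplete", "absent", "intact"),
            ("absent", "intact", "incomplete"),
            ("intact",),
            ("incomplete",),
            ("absent",),
        )
    ]
    for i, statuses in enumerate(rotations):
        present, _ = simulate_gene_content(pathways, statuses, seed=seed + i)
        rescored = score_pathways(present, pathways)
        for s in rescored:
            total += 1
            correct += s.status == statuses[s.pathway]
    return {"status_accuracy": correct / total, "n_calls": total}


_CLASS_LIBRARY = [
    GTRGammaFit((1.0, 6.0, 1.0, 1.0, 6.0, 1.0),
                (0.40, 0.10, 0.10, 0.40), 0.2, 4, 0.0),
    GTRGammaFit((1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
                (0.25, 0.25, 0.25, 0.25), 8.0, 4, 0.0),
    GTRGammaFit((4.0, 0.5, 3.0, 0.3, 0.5, 1.0),
                (0.12, 0.38, 0.38, 0.12), 1.0, 4, 0.0),
]


def partition_benchmark(
    seed: int,
    n_classes: int = 3,
    genes_per_class: int = 8,
    sites_per_gene: int = 600,
) -> dict[str, float]:
    """Planted substitution-model class recovery through the full
    fit -> PCoA -> K-means workflow.  Returns the selected k and the
    adjusted Rand index against the planted assignment."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    tree = random_topology([f"t{i}" for i in range(6)], rng, (0.05, 0.3))
    classes = _CLASS_LIBRARY[:n_classes]
    assignment = [c for c in range(n_classes) for _ in range(genes_per_class)]
    alignments, truth = simulate_partitioned_alignments(
        tree, len(assignment), classes, assignment,
        sites_per_gene=sites_per_gene, seed=seed,
    )
    _, scheme = partition_workflow(
        alignments, tree, k_range=range(1, 7), n_restarts=25, seed=seed
    )
    labels = [scheme.assignment[i] for i in range(len(assignment))]
    return {
        "selected_k": float(scheme.k),
        "ari": float(adjusted_rand_score(truth, labels)),
        "n_genes": len(assignment),
    }


def alpha_recovery_benchmark(
    seed: int, alpha_true: float = 0.5, n_sites: int = 5001
) -> dict[str, float]:
    """Gamma-shape recovery of the GTR+Gamma fit at realistic depth."""
    rng = np.random.default_rng(seed)
    tree = random_topology([f"t{i}" for i in range(6)], rng, (0.05, 0.3))
    cls = GTRGammaFit(
        (1.2, 3.0, 0.8, 1.1, 3.5, 1.0), (0.3, 0.2, 0.2, 0.3),
        alpha_true, 4, 0.0,
    )
    alignments, _ = simulate_partitioned_alignments(
        tree, 1, [cls], [0], sites_per_gene=n_sites, seed=seed
    )
    fit = fit_gtr_gamma(alignments[0], tree, max_sweeps=4)
    return {
        "alpha_true": alpha_true,
        "alpha_estimate": fit.alpha,
        "rel_error": abs(fit.alpha - alpha_true) / alpha_true,
        "n_sites": n_sites,
    }


def placement_benchmark(
    seed: int,
    n_replicates: int = 20,
    n_background_taxa: int = 8,
    n_sites: int = 1998,
    n_candidates: int = 7,
) -> dict[str, float]:
    """RELL ranking of alternative placements of a drifted taxon.

    Per replicate: simulate an alignment on a random tree whose
    "symbiont" branch drifts to low GC, build seven candidate trees (the
    generating placement plus regrafts onto other clades), fit the
    nonstationary model on each fixed topology and rank by RELL.  Reports
    the fraction of replicates in which the generating placement ranks
    first.
    """
    wins = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + 1000 * rep)
        names = [f"t{i}" for i in range(n_background_taxa)] + ["symbiont"]
        tree = random_topology(names, rng, (0.05, 0.25))
        sym_leaf = next(n for n in tree.leaves() if n.name == "symbiont")
        cls = GTRGammaFit(
            (1.0, 2.0, 1.0, 1.0, 2.0, 1.0), (0.25, 0.25, 0.25, 0.25),
            1.0, 4, 0.0,
        )
        alignments, _ = simulate_partitioned_alignments(
            tree, 1, [cls], [0], sites_per_gene=n_sites,
            nonstationary={sym_leaf.id: 0.15}, seed=seed + 1000 * rep + 1,
        )
        aln = alignments[0].records
        candidates = [tree]
        edge = 0
        while len(candidates) < n_candidates:
            moved = regraft_leaf(tree, "symbiont", edge)
            edge += 1
            if any(moved.same_topology(c) for c in candidates):
                continue
            candidates.append(moved)
        site_lls = []
        for cand in candidates:
            groups = {
                n.id: 0 for n in cand.postorder() if n.parent is not None
            }
            fit = optimize_model(
                cand, aln, uniform_model(cand, 0.4, 2.0),
                max_sweeps=2, theta_groups=groups,
            )
            site_lls.append(fit.site_likelihoods)
        ranking = rell_rank(site_lls, n_boot=2000, seed=seed + rep)
        best = int(ranking.loc[ranking["rank"] == 1, "tree"].iloc[0])
        wins += best == 0
    return {
        "top_rank_fraction": wins / n_replicates,
        "n_replicates": n_replicates,
        "n_sites": n_sites,
    }
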