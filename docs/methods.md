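# Methods

This note documents the models, defaults and design choices behind
`endosift`, and what its synthetic-data tests do and do not establish
about real data.

## Symbiont isolation

### Contig classification

Real isolation pipelines call contigs by BLAST hits against a custom
library of candidate relatives, then drop low-coverage contigs as
contamination. `endosift` keeps the decision structure but replaces the
alignment search with canonical k-mer voting, which is deterministic and
dependency-free: for each contig, the count of canonical
(lexicographically smaller of forward/reverse-complement) k-mers shared
with each labeled reference panel is its vote; the winning panel must
reach a minimum vote *fraction* of the contig's k-mers.

Defaults (`BinningParams`): `k_classify = 31` and
`min_vote_fraction = 0.02`. A 31-mer survives point divergence d with
probability (1−d)^31, so a 3%-divergent relative still shares ~39% of
k-mers — far above the 2% call floor — while unrelated sequence shares
essentially none; the floor's job is only to suppress chance collisions.
Ties are left unassigned (conservative binning). The coverage cutoff
`min_coverage = 30x` sits between the contaminant band (≤25x) and the
symbiont regime (~90x): contigs that vote symbiont-like but sit below it
are relabeled contaminant. Contig order never affects labels; every
contig gets exactly one label from {symbiont, host, contaminant,
unassigned}.

### Read recruitment

A read pair is recruited to the bin when *both* mates share at least
`min_recruit_matches = 15` canonical `k_recruit = 25`-mers with the bin
contigs — the contract-level analog of "aligned concordantly,
end-to-end". With 151-base reads hard-trimmed to 141 there are 117
25-mer windows per mate, so 15 matches tolerates several sequencing
errors while random matches at k = 25 are vanishingly rare. Pairing and
input order are preserved; the output is always a subset of the input.

### Consensus and terminal flags

`consensus_by_mapping` places reads by best ungapped k-mer-seeded
alignment (21-mer seeds, both orientations, best match count wins) and
emits per-column majority bases where depth ≥ `min_depth`, falling back
to the reference base below depth or on ties. It is idempotent:
consensus against its own output reproduces itself.

`flag_terminal_ambiguity` flags contig-end windows whose coverage
exceeds `factor = 3.0` times the contig's median window coverage. The
biology: assemblies of reduced genomes typically break at rRNA/tRNA
operons, whose collapsed copies accumulate the reads of all their
genomic instances and show up as coverage spikes at contig ends. The
companion estimator `window_coverage_profile` deliberately credits
*every* matching position of a read's seed k-mer, so multi-mapping
inflation is visible rather than hidden. The synthetic community's
`shared_rrna` knob plants a duplicated 1.5-kb segment at all four
symbiont contig ends (and inside one contaminant), reproducing that
footprint.

### Completeness

`marker_completeness` is the transparent core of marker-based
completeness estimates: the fraction of a supplied marker-gene set found
in the annotation. It does not attempt lineage-specific marker choice or
collocation scoring; the marker set is the caller's responsibility.

## Keratin composition

Queries (known feather keratins) are matched to a proteome by local
alignment with BLOSUM62 and affine gaps (a gap of length L costs
open + L·extend; defaults 11/1, the classic protein-search setting).
Per query the best-scoring proteome record is accepted if its score
reaches `min_report_score = 50`; ties go to the earlier proteome record,
multiple queries may share a hit (kept and logged — each query is a
distinct gene). Accepted hits are pooled residue-wise — long keratins
weigh more, as in a bulk biochemical assay — and frequencies exclude
ambiguity codes B/Z/X and stops from numerator and denominator.
Percentages are rounded half-up to 0.1 pp only at the report layer.

The packaged reference tables carry the biochemically determined chicken
feather-barb composition and predicted chicken/rock-dove keratin
compositions over the ten insect-essential residues (F, H, I, K, L, M,
R, T, V, W). `compare_profiles` reports per-residue differences in
percentage points, an L1 distance over a residue subset, and flags
residues the reference puts at zero but the prediction does not — the
His/Lys/Met/Trp trace pattern that frames the dietary question.

## Pathway scoring

A pathway is *intact* iff every gene is present, *absent* iff its
present fraction is ≤ `absence_threshold`, *incomplete* otherwise. The
boundary between incomplete and absent is genuinely a convention, so the
threshold is explicit config with 0 as the conservative default (absent
means not one gene found). Status is monotone in the present set. The
packaged pathway lists (His/Lys/Met/Trp biosynthesis, pantothenate
panB/panC/panE, coenzyme A coaA-D, folate, biotin, riboflavin) use
standard bacterial gene names and are plain YAML — data, not code —
because exact pathway definitions are annotation-system-dependent.

## Partition selection

Protein-coding alignments are split by codon phase; third positions are
typically excluded because their base composition drifts strongly in
AT-biased lineages (the synthetic check plants exactly this contrast and
verifies that position-3 GC variance across taxa exceeds positions 1-2).

Each sub-alignment gets a GTR+Γ fit on a fixed guide tree (user-supplied
or neighbor-joining from Jukes-Cantor distances): Felsenstein pruning
over compressed site patterns, 4 equiprobable discrete Γ categories
(category means via truncated-Γ expectations), and bounded coordinate
ascent over log rates, frequency logits, log α and log branch lengths
(branch-length floor 1e-6, line-search tolerance 1e-4, relative logL
tolerance 1e-6). The ascent is monotone by construction — a coordinate
move is kept only if it improves the log-likelihood. Fixed topology is
deliberate: the downstream clustering consumes parameters, not trees.

Feature vectors (5 free rates, 3 free frequencies, log α) are
standardized per column, embedded by classical scaling (double-centered
squared distances, eigendecomposition, positive-eigenvalue axes), and
clustered by K-means. Two stabilizers matter in practice:

- **Leading axes.** Clustering uses the dominant PCoA axes covering 80%
  of the positive eigenvalue mass (`leading_axes`). Trailing axes are
  dominated by parameter-estimation noise; including them lets the
  silhouette criterion split a genuine class in two.
- **Null-calibrated k.** A k ≥ 2 solution must beat both a silhouette
  floor of 0.25 and the 95th percentile of best silhouettes from 20
  unstructured Gaussian reference draws matched to the data's spread.
  The calibration is needed because even a single Gaussian blob scores
  k = 2 silhouettes of 0.3-0.5, so no fixed floor alone can recognize
  the no-structure case.

The supermatrix writer concatenates sub-alignments over the taxon union
(gap-padding absentees) and emits RAxML-style partition lines
(`DNA, part1 = 1-3, 7-9`; 1-based inclusive ranges).

## Nonstationary placement testing

The T92 rate matrix at GC equilibrium θ has π_G = π_C = θ/2,
π_A = π_T = (1−θ)/2 and transitions scaled by κ, normalized to mean rate
1 at its own equilibrium. Making θ branch-specific yields a
nonhomogeneous model in which base composition drifts along lineages —
the standard guard against long-branch attraction among independently
AT-drifted endosymbionts. Consequences handled explicitly:

- the likelihood is root-dependent; the root is the tree's (trifurcating)
  top node and should be placed by outgroup knowledge;
- unconstrained per-branch θ overfits small alignments, so
  `optimize_model` accepts `theta_groups` tying branches (e.g. one θ per
  clade, or one global θ);
- optimization is the same monotone coordinate ascent (branch lengths,
  κ, θ groups, root-frequency logits), returning a convergence flag
  after at most `max_sweeps` sweeps.

`nni_hill_climb` greedily accepts the best nearest-neighbor-interchange
move while it improves logL by more than 0.01, so the search never
leaves the accepted path's NNI neighborhood; every evaluated topology is
logged for audit. Candidate placements are ranked by RELL: site patterns
are resampled with replacement (multiplicities respected), per-tree
totals re-summed, bootstrap proportions credit ties fractionally, and
SH-style p-values use the centered-maximum null (each tree's replicate
totals centered at its own mean). This is one ranking and one p-value
family, not a full multi-test battery, and no multiscale (AU-style)
bootstrap is attempted.

## Synthetic data: what it does and does not show

Generators are pure functions of (config, seed). The community default
mirrors the sequencing regime the pipeline targets: a 100-kb symbiont at
30% GC and 90x, a 1-Mb host at 42% GC and 40x (the host is scaled down
from insect-genome size to keep desk-scale runtimes; its role — a large
moderate-coverage background — is preserved), contaminants at 3x and
25x, 151-base pairs with substitution errors at 0.2% (a typical
short-read regime) and a fixed 350-bp insert. Genomes are i.i.d. with GC
bias: no repeat structure (beyond the optional shared-rRNA segment), no
indels, no quality-score profiles, no structural variation. Passing the
planted-recovery tests therefore shows the *decision logic* is correct
under the stated coverage/composition regime; it does not certify
performance on repeat-rich genomes, indel-heavy platforms or diverged
references beyond the ~3% used in the benchmarks.

Alignment simulation evolves i.i.d. sites down the tree per gene class
(4-category discrete Γ; optional per-branch T92 θ map for composition
drift). Planted-class benchmarks use a 6-taxon tree, 600 sites and 8
genes per class with classes separated in α (0.2 / 8.0 / 1.0),
composition and transition bias — "well-separated" conditions;
overlapping classes will not yield ARI 1.0 and are out of scope for the
benchmark. The placement benchmark regrafts a composition-drifted taxon
(θ = 0.15 against a 0.4 background) onto seven alternative positions of
an 8-taxon background at ~2,000 sites, fitting a globally tied θ per
candidate (2 coordinate sweeps) before RELL ranking — problem sizes
chosen to keep the full benchmark suite in the minutes range on one CPU.

## Known limitations

- No de novo assembly, SAM/BAM emission, or quality-aware trimming; the
  pipeline starts from contigs and hard-trims only.
- The k-mer vote is a stand-in for alignment search: sensitive to the
  reference panel's divergence (k = 31 degrades steeply past ~5-7%
  divergence).
- GTR fits use a fixed guide topology; badly wrong guide trees bias the
  fitted parameters.
- The nonstationary engine has no Γ rate heterogeneity (θ drift and rate
  variation are not jointly modeled); placement ranking, not absolute
  fit, is its job.
- Completeness is plain marker presence; no lineage-specific marker sets
  ship with the package.
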