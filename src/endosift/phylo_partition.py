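"""Codon-position partition selection for phylogenomic supermatrices.

Workflow: split each gene alignment by codon position (third positions are
typically discarded for compositional bias), fit a GTR+Gamma substitution
model to every sub-alignment on a fixed guide tree, embed the fitted
parameter vectors by principal coordinates analysis, cluster them with
K-means choosing k by mean silhouette, and emit a concatenated supermatrix
with a RAxML-style partition file.

The GTR+Gamma engine maximizes the pruning likelihood by bounded
coordinate ascent over the five free exchange rates, three free base
frequencies, the Gamma shape alpha (4 discrete categories by default) and
all branch lengths.  It is deliberately a fixed-topology estimator: the
downstream clustering consumes parameters, not trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._pruning import compress_patterns, pruning_site_loglik
from .seq_io import SeqRecord
from .trees import Tree

# order of the six exchangeabilities; the last (GT) is fixed to 1
RATE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
RATE_NAMES = ("AC", "AG", "AT", "CG", "CT", "GT")

BL_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """A protein-coding nucleotide alignment with implicit codon phase
    (column 1 is codon position 1, cycling 1,2,3)."""

    name: str
    records: list[SeqRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"alignment {self.name!r} is empty")
        length = len(self.records[0].seq)
        if any(len(r.seq) != length for r in self.records):
            raise ValueError(f"alignment {self.name!r}: unequal row lengths")
        if len({r.id for r in self.records}) != len(self.records):
            raise ValueError(f"alignment {self.name!r}: duplicate taxa")

    @property
    def n_sites(self) -> int:
        return len(self.records[0].seq)

    @property
    def taxa(self) -> list[str]:
        return [r.id for r in self.records]


def split_codon_positions(
    aln: CodonAlignment, keep: Iterable[int] = (1, 2)
) -> dict[int, CodonAlignment]:
    """Extract per-codon-position sub-alignments.

    Position p keeps columns p-1, p+2, p+5, ... (1-based phase cycling
    from the first column).  The alignment length must be a multiple of 3.
    """
    keep = sorted(set(keep))
    if not keep or any(p not in (1, 2, 3) for p in keep):
        raise ValueError("keep must be a nonempty subset of {1, 2, 3}")
    if aln.n_sites % 3 != 0:
        raise ValueError(
            f"alignment {aln.name!r} length {aln.n_sites} is not a multiple of 3"
        )
    out = {}
    for pos in keep:
        recs = [
            SeqRecord(r.id, r.seq[pos - 1 :: 3]) for r in aln.records
        ]
        out[pos] = CodonAlignment(f"{aln.name}_pos{pos}", recs)
    return out


# ---------------------------------------------------------------------------
# GTR + Gamma
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GTRGammaFit:
    """Fitted GTR+Gamma parameters for one sub-alignment."""

    rates: tuple[float, ...]  # 6 exchangeabilities, GT fixed to 1
    freqs: tuple[float, ...]  # 4 base frequencies, sum 1
    alpha: float
    n_categories: int
    log_likelihood: float

    def __post_init__(self) -> None:
        if len(self.rates) != 6 or len(self.freqs) != 4:
            raise ValueError("expected 6 rates and 4 frequencies")
        if min(self.rates) <= 0 or self.alpha <= 0:
            raise ValueError("rates and alpha must be positive")
        if abs(sum(self.freqs) - 1.0) > 1e-6 or min(self.freqs) < 0:
            raise ValueError("frequencies must be a distribution")

    def feature_vector(self) -> np.ndarray:
        """Clustering features: 5 free exchange rates, 3 free frequencies
        and log alpha."""
        return np.array(
            list(self.rates[:5]) + list(self.freqs[:3]) + [np.log(self.alpha)]
        )


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Category mean rates of the mean-1 Gamma(alpha, alpha) split into
    ``n_categories`` equiprobable bins."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(
        np.linspace(0.0, 1.0, n_categories + 1), a=alpha, scale=1.0 / alpha
    )
    # mean of the truncated distribution on [a, b], via the regularized
    # lower incomplete gamma of shape alpha+1
    upper = gammainc(alpha + 1.0, edges[1:] * alpha)
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    rates = n_categories * (upper - lower)
    return np.maximum(rates, 1e-8)


def gtr_rate_matrix(rates: Sequence[float], freqs: Sequence[float]) -> np.ndarray:
    """GTR rate matrix (states A,C,G,T) normalized to mean rate 1 at its
    stationary frequencies."""
    q = np.zeros((4, 4))
    for r, (i, j) in zip(rates, RATE_PAIRS):
        q[i, j] = r * freqs[j]
        q[j, i] = r * freqs[i]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(freqs, np.diag(q))
    return q / scale


def _gtr_eigen(rates: np.ndarray, freqs: np.ndarray):
    """Symmetric-similarity eigendecomposition of the GTR matrix, so that
    P(t) = U exp(lam t) V for any t."""
    q = gtr_rate_matrix(rates, freqs)
    sq = np.sqrt(freqs)
    sym = q * sq[:, None] / sq[None, :]
    sym = (sym + sym.T) / 2  # symmetric up to rounding for reversible Q
    lam, w = np.linalg.eigh(sym)
    u = w / sq[:, None]
    v = w.T * sq[None, :]
    return u, lam, v


def _transition_matrices(
    eig, branch_lengths: np.ndarray, cat_rates: np.ndarray
) -> np.ndarray:
    """P matrices of shape (n_branches, n_cats, 4, 4)."""
    u, lam, v = eig
    t = branch_lengths[:, None, None] * cat_rates[None, :, None]  # (B, C, 1)
    expl = np.exp(lam[None, None, :] * t)  # (B, C, 4)
    p = np.einsum("ik,bck,kj->bcij", u, expl, v)
    return np.clip(p, 0.0, None)


class _GTRLikelihood:
    """Pattern-compressed GTR+Gamma log-likelihood on a fixed topology."""

    def __init__(self, sub_aln: CodonAlignment, tree: Tree, n_categories: int):
        missing = set(sub_aln.taxa) - set(tree.leaf_names())
        if missing:
            raise ValueError(f"tree lacks taxa: {sorted(missing)}")
        if len(sub_aln.taxa) < 4:
            raise ValueError("need at least 4 taxa")
        self.tree = tree.copy()
        self.taxon_rows, self.patterns, self.weights = compress_patterns(
            sub_aln.records
        )
        self.n_categories = n_categories
        self.branch_nodes = [
            n for n in self.tree.postorder() if n.parent is not None
        ]
        self.branch_index = {n.id: b for b, n in enumerate(self.branch_nodes)}
        lengths = np.array([max(n.length, BL_FLOOR) for n in self.branch_nodes])
        if any(n.length <= 0 for n in self.branch_nodes):
            warnings.warn("non-positive branch lengths reset to floor")
        self.lengths = lengths

    def loglik(
        self, rates: np.ndarray, freqs: np.ndarray, alpha: float
    ) -> float:
        eig = _gtr_eigen(rates, freqs)
        cat_rates = discrete_gamma_rates(alpha, self.n_categories)
        pmats = _transition_matrices(eig, self.lengths, cat_rates)

        def p_fn(node, cat):
            return pmats[self.branch_index[node.id], cat]

        site = pruning_site_loglik(
            self.tree,
            self.taxon_rows,
            self.patterns,
            p_fn,
            freqs,
            self.n_categories,
        )
        return float(self.weights @ site)


def _coordinate_ascent(
    x0: np.ndarray,
    bounds: list[tuple[float, float]],
    fun: Callable[[np.ndarray], float],
    max_sweeps: int,
    rel_tol: float,
) -> tuple[np.ndarray, float, list[float]]:
    """Maximize ``fun`` by bounded scalar line searches, one coordinate at
    a time.  Monotone by construction: a move is kept only if it improves."""
    x = x0.copy()
    best = fun(x)
    history = [best]
    for _ in range(max_sweeps):
        prev = best
        for i in range(len(x)):
            lo, hi = bounds[i]

            def neg(v: float, i: int = i) -> float:
                trial = x.copy()
                trial[i] = v
                return -fun(trial)

            res = minimize_scalar(
                neg, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-4},
            )
            if -res.fun > best:
                x[i] = res.x
                best = -res.fun
        history.append(best)
        if best - prev <= rel_tol * (abs(prev) + 1.0):
            break
    return x, best, history


def fit_gtr_gamma(
    sub_aln: CodonAlignment,
    tree: Tree,
    n_categories: int = 4,
    max_sweeps: int = 5,
    rel_tol: float = 1e-6,
) -> GTRGammaFit:
    """Maximum-likelihood GTR+Gamma parameters on a fixed guide topology.

    Branch lengths, the five free exchange rates, three free frequency
    logits and log(alpha) are optimized jointly by coordinate ascent; the
    log-likelihood is non-decreasing across sweeps.
    """
    engine = _GTRLikelihood(sub_aln, tree, n_categories)
    nb = len(engine.lengths)
    # parameter vector: [log rates (5) | freq logits (3) | log alpha | log bl]
    x0 = np.concatenate(
        [np.zeros(5), np.zeros(3), [0.0], np.log(engine.lengths)]
    )
    bounds = (
        [(-4.0, 4.0)] * 5
        + [(-4.0, 4.0)] * 3
        + [(np.log(0.02), np.log(50.0))]
        + [(np.log(BL_FLOOR), np.log(10.0))] * nb
    )

    def unpack(x: np.ndarray):
        rates = np.append(np.exp(x[:5]), 1.0)
        logits = np.append(x[5:8], 0.0)
        freqs = np.exp(logits) / np.exp(logits).sum()
        alpha = float(np.exp(x[8]))
        lengths = np.exp(x[9:])
        return rates, freqs, alpha, lengths

    def objective(x: np.ndarray) -> float:
        rates, freqs, alpha, lengths = unpack(x)
        engine.lengths = lengths
        return engine.loglik(rates, freqs, alpha)

    x, best, _ = _coordinate_ascent(x0, bounds, objective, max_sweeps, rel_tol)
    rates, freqs, alpha, lengths = unpack(x)
    engine.lengths = lengths
    return GTRGammaFit(
        rates=tuple(rates),
        freqs=tuple(freqs),
        alpha=alpha,
        n_categories=n_categories,
        log_likelihood=best,
    )


# ---------------------------------------------------------------------------
# guide tree
# ---------------------------------------------------------------------------


def nj_guide_tree(aln: CodonAlignment) -> Tree:
    """Neighbor-joining guide tree from Jukes-Cantor-corrected pairwise
    distances (scikit-bio's NJ behind the scenes)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    taxa = aln.taxa
    n = len(taxa)
    mat = np.zeros((n, n))
    seqs = [r.seq for r in aln.records]
    for i in range(n):
        for j in range(i + 1, n):
            pairs = [
                (a, b)
                for a, b in zip(seqs[i], seqs[j])
                if a in "ACGT" and b in "ACGT"
            ]
            p = (
                sum(a != b for a, b in pairs) / len(pairs) if pairs else 0.0
            )
            p = min(p, 0.70)
            d = -0.75 * np.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0
            mat[i, j] = mat[j, i] = d
    import io as _io

    buf = _io.StringIO()
    nj(DistanceMatrix(mat, ids=taxa)).write(buf, format="newick")
    tree = Tree.from_newick(buf.getvalue())
    for node in tree.postorder():
        if node.parent is not None and node.length <= 0:
            node.length = BL_FLOOR
    return tree


# ---------------------------------------------------------------------------
# PCoA + K-means
# ---------------------------------------------------------------------------


def pcoa_embed(
    features: np.ndarray, distance: str = "euclidean"
) -> tuple[np.ndarray, np.ndarray]:
    """Classical scaling (PCoA) of standardized parameter vectors.

    Columns are standardized to zero mean and unit variance (constant
    columns dropped with a warning); the squared distance matrix is double
    centered and eigendecomposed; coordinates are returned for the
    positive-eigenvalue axes in descending order.
    """
    feats = np.asarray(features, dtype=float)
    if feats.ndim != 2 or feats.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with >= 2 rows")
    sd = feats.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature column(s)")
        feats = feats[:, keep]
        sd = sd[keep]
    feats = (feats - feats.mean(axis=0)) / sd
    d = squareform(pdist(feats, metric=distance))
    d2 = d**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-10, 1e-10 * abs(eigval[0]))
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])[None, :]
    return coords, eigval[pos]


@dataclass
class PartitionScheme:
    """A clustering of sub-alignments into substitution-model partitions."""

    k: int
    assignment: dict[int, int]  # sub-alignment index -> partition id (1..k)
    selection_scores: dict[int, float] = field(default_factory=dict)


def _best_silhouette(
    coords: np.ndarray, ks: list[int], n_restarts: int, seed: int
) -> tuple[dict[int, float], dict[int, np.ndarray]]:
    scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    n = coords.shape[0]
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(coords)
        labelings[k] = labels
        if len(set(labels)) < 2 or k >= n:
            scores[k] = -1.0
        else:
            scores[k] = float(silhouette_score(coords, labels))
    return scores, labelings


def select_partitions(
    coords: np.ndarray,
    k_range: Sequence[int] = (1, 2, 3, 4, 5),
    n_restarts: int = 25,
    seed: int = 0,
    silhouette_floor: float = 0.25,
    null_references: int = 20,
) -> PartitionScheme:
    """Choose the number of partitions by K-means + mean silhouette.

    The best-silhouette k over k >= 2 wins; k = 1 is selected when that
    silhouette falls below ``silhouette_floor`` or fails to beat the 95th
    percentile of best silhouettes from ``null_references`` unstructured
    Gaussian reference draws matched to the data's per-axis spread.  The
    null calibration matters because even a single Gaussian blob scores a
    silhouette of 0.3-0.5 at k = 2, so a fixed floor alone cannot detect
    the no-structure case.  Assignment comes from the best-inertia K-means
    run at the chosen k.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = coords.shape[0]
    ks = [k for k in sorted(set(k_range)) if 2 <= k <= n]
    scores, labelings = _best_silhouette(coords, ks, n_restarts, seed)
    labelings[1] = np.zeros(n, dtype=int)
    best_k = 1
    if scores:
        cand = max(scores, key=lambda k: scores[k])
        threshold = silhouette_floor
        if null_references > 0:
            null_rng = np.random.default_rng(seed + 1)
            mu = coords.mean(axis=0)
            sd = coords.std(axis=0) + 1e-12
            null_best = []
            for _ in range(null_references):
                ref = null_rng.normal(mu, sd, size=coords.shape)
                ref_scores, _ = _best_silhouette(
                    ref, ks, max(5, n_restarts // 5), seed
                )
                null_best.append(max(ref_scores.values()))
            threshold = max(threshold, float(np.quantile(null_best, 0.95)))
        if scores[cand] >= threshold:
            best_k = cand
    if best_k not in labelings:
        labelings[best_k] = np.zeros(n, dtype=int)
    labels = labelings[best_k]
    # renumber partition ids to 1..k in order of first appearance
    remap: dict[int, int] = {}
    assignment = {}
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        assignment[i] = remap[lab]
    return PartitionScheme(k=best_k, assignment=assignment, selection_scores=scores)


# ---------------------------------------------------------------------------
# supermatrix
# ---------------------------------------------------------------------------


def build_supermatrix(
    sub_alignments: Sequence[CodonAlignment],
    scheme: PartitionScheme,
) -> tuple[list[SeqRecord], str]:
    """Concatenate sub-alignments and write a RAxML-style partition file.

    Taxa missing from a sub-alignment are padded with gaps over its column
    range.  The partition file lists, per partition, the 1-based inclusive
    column ranges of its member sub-alignments.
    """
    if not sub_alignments:
        raise ValueError("no sub-alignments to concatenate")
    taxa: list[str] = []
    for aln in sub_alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    ranges: dict[int, list[tuple[int, int]]] = {}
    start = 1
    for idx, aln in enumerate(sub_alignments):
        length = aln.n_sites
        rows = {r.id: r.seq for r in aln.records}
        for t in taxa:
            pieces[t].append(rows.get(t, "-" * length))
        part = scheme.assignment.get(idx, 1)
        ranges.setdefault(part, []).append((start, start + length - 1))
        start += length
    records = [SeqRecord(t, "".join(pieces[t])) for t in taxa]
    lines = [
        "DNA, part{0} = {1}".format(
            part, ", ".join(f"{a}-{b}" for a, b in ranges[part])
        )
        for part in sorted(ranges)
    ]
    return records, "\n".join(lines) + "\n"


def fit_features(fits: Sequence[GTRGammaFit]) -> np.ndarray:
    """Stack clustering feature vectors from a list of fits."""
    return np.stack([f.feature_vector() for f in fits])


def leading_axes(
    coords: np.ndarray, eigenvalues: np.ndarray, mass: float = 0.80
) -> np.ndarray:
    """Keep the leading PCoA axes covering ``mass`` of the positive
    eigenvalue total.

    Trailing axes of a PCoA of fitted-parameter vectors are dominated by
    estimation noise; clustering on the dominant axes makes the silhouette
    k-selection markedly more stable.
    """
    if not (0.0 < mass <= 1.0):
        raise ValueError("mass must be in (0, 1]")
    cum = np.cumsum(eigenvalues) / eigenvalues.sum()
    n = int(np.searchsorted(cum, mass) + 1)
    return coords[:, : min(n, coords.shape[1])]


def partition_workflow(
    sub_alignments: Sequence[CodonAlignment],
    tree: Tree,
    k_range: Sequence[int] = (1, 2, 3, 4, 5),
    n_restarts: int = 25,
    seed: int = 0,
    axis_mass: float = 0.80,
    n_categories: int = 4,
    max_sweeps: int = 3,
) -> tuple[list[GTRGammaFit], PartitionScheme]:
    """Fit GTR+Gamma per sub-alignment, embed, cluster, select k.

    The end-to-end partition-selection stage: returns the per-alignment
    fits and the chosen :class:`PartitionScheme`.
    """
    fits = [
        fit_gtr_gamma(a, tree, n_categories=n_categories, max_sweeps=max_sweeps)
        for a in sub_alignments
    ]
    coords, eigvals = pcoa_embed(fit_features(fits))
    coords = leading_axes(coords, eigvals, axis_mass)
    scheme = select_partitions(coords, k_range, n_restarts, seed)
    return fits, scheme
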