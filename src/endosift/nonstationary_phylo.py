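"""Nonstationary T92 likelihood, NNI search and RELL topology ranking.

Reduced endosymbiont genomes drift toward AT-rich base composition, which
violates the stationarity assumption of time-reversible models and invites
long-branch attraction among unrelated symbionts.  The model here is the
Tamura 1992 two-parameter composition model made nonhomogeneous: a single
transition/transversion parameter kappa is shared across the tree while
every branch carries its own GC equilibrium theta_b, so base composition
can drift away from the root frequencies along any lineage.

Because the model is not reversible in time, the likelihood depends on the
root node (where the root base frequencies apply); trees should be built
with the intended (out)rooting.  Alternative placements of a taxon are
compared by RELL: per-site log-likelihoods are bootstrapped by resampling
site patterns, yielding bootstrap proportions and SH-style p-values
without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from ._pruning import compress_patterns, pruning_site_loglik
from .seq_io import SeqRecord
from .trees import Node, Tree

BL_FLOOR = 1e-6


def t92_equilibrium(theta: float) -> np.ndarray:
    """Stationary frequencies (A,C,G,T) at GC content theta."""
    return np.array(
        [(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2]
    )


def t92_rate_matrix(theta: float, kappa: float) -> np.ndarray:
    """T92 rate matrix (states A,C,G,T), mean rate 1 at its own
    equilibrium.  Transitions (A<->G, C<->T) are scaled by kappa."""
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    pi = t92_equilibrium(theta)
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(pi @ np.diag(q))
    return q / scale


def t92_transition_matrix(theta: float, kappa: float, t: float) -> np.ndarray:
    """P(t) = exp(Q t) for the T92 matrix at (theta, kappa)."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if t == 0.0:
        return np.eye(4)
    return expm(t92_rate_matrix(theta, kappa) * t)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class NonStatModel:
    """Tree + branch lengths + kappa + per-branch GC equilibria.

    ``theta`` maps node id (the child end of each branch) to that branch's
    GC equilibrium; ``root_freqs`` are the base frequencies at the root
    node.  Branch lengths live on the tree itself.
    """

    tree: Tree
    kappa: float
    theta: dict[int, float]
    root_freqs: np.ndarray

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for nid, th in self.theta.items():
            if not (0.0 < th < 1.0):
                raise ValueError(f"theta for branch {nid} outside (0, 1)")
        self.root_freqs = np.asarray(self.root_freqs, dtype=float)
        if abs(self.root_freqs.sum() - 1.0) > 1e-6:
            raise ValueError("root frequencies must sum to 1")

    def branch_nodes(self) -> list[Node]:
        return [n for n in self.tree.postorder() if n.parent is not None]

    def copy(self) -> "NonStatModel":
        return NonStatModel(
            tree=self.tree.copy(),
            kappa=self.kappa,
            theta=dict(self.theta),
            root_freqs=self.root_freqs.copy(),
        )


def uniform_model(
    tree: Tree, theta: float = 0.5, kappa: float = 2.0
) -> NonStatModel:
    """A homogeneous starting model: one theta everywhere, root at its
    equilibrium."""
    theta_map = {
        n.id: theta for n in tree.postorder() if n.parent is not None
    }
    return NonStatModel(
        tree=tree.copy(),
        kappa=kappa,
        theta=theta_map,
        root_freqs=t92_equilibrium(theta),
    )


@dataclass
class SiteLikelihoods:
    """Per-pattern log-likelihoods with pattern multiplicities."""

    log_likelihoods: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.log_likelihoods.shape != self.weights.shape:
            raise ValueError("pattern/weight length mismatch")
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")

    @property
    def total(self) -> float:
        return float(self.weights @ self.log_likelihoods)


def tree_log_likelihood(
    model: NonStatModel, aln: Sequence[SeqRecord]
) -> tuple[SiteLikelihoods, float]:
    """Pruning likelihood with branch-specific T92 transition matrices."""
    taxon_rows, patterns, weights = compress_patterns(list(aln))
    missing = set(taxon_rows) - set(model.tree.leaf_names())
    if missing:
        raise ValueError(f"model tree lacks taxa: {sorted(missing)}")
    cache: dict[int, np.ndarray] = {}

    def p_fn(node: Node, cat: int) -> np.ndarray:
        if node.id not in cache:
            cache[node.id] = t92_transition_matrix(
                model.theta[node.id], model.kappa, max(node.length, 0.0)
            )
        return cache[node.id]

    site = pruning_site_loglik(
        model.tree, taxon_rows, patterns, p_fn, model.root_freqs, 1
    )
    sl = SiteLikelihoods(site, weights)
    return sl, sl.total


def stationary_t92_log_likelihood(
    tree: Tree, aln: Sequence[SeqRecord], theta: float, kappa: float
) -> float:
    """Homogeneous, stationary T92 likelihood via the independent GTR
    engine (T92 is the GTR special case with transition rates kappa and
    frequencies tied to theta).  Serves as the stationary-limit check."""
    from .phylo_partition import _transition_matrices, _gtr_eigen

    taxon_rows, patterns, weights = compress_patterns(list(aln))
    rates = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
    freqs = t92_equilibrium(theta)
    eig = _gtr_eigen(rates, freqs)
    nodes = [n for n in tree.postorder() if n.parent is not None]
    lengths = np.array([max(n.length, 0.0) for n in nodes])
    pm = _transition_matrices(eig, lengths, np.array([1.0]))
    index = {n.id: i for i, n in enumerate(nodes)}

    def p_fn(node, cat):
        return pm[index[node.id], 0]

    site = pruning_site_loglik(tree, taxon_rows, patterns, p_fn, freqs, 1)
    return float(weights @ site)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    model: NonStatModel
    log_likelihood: float
    converged: bool
    n_sweeps: int
    site_likelihoods: SiteLikelihoods | None = None


def optimize_model(
    topology: Tree,
    aln: Sequence[SeqRecord],
    init: NonStatModel | None = None,
    max_sweeps: int = 200,
    rel_tol: float = 1e-6,
    theta_groups: dict[int, int] | None = None,
    optimize_root: bool = True,
) -> FitResult:
    """Coordinate-ascent fit of the nonstationary model on a fixed tree.

    Sweeps over every branch length, kappa, every (optionally tied) theta
    and the root frequencies until the relative log-likelihood gain drops
    below ``rel_tol``.  ``theta_groups`` maps branch node ids to group
    labels; branches sharing a label share one theta (the clade-tying
    device that keeps the parameter count sane on small alignments).
    """
    model = uniform_model(topology)
    if init is not None:
        model.kappa = init.kappa
        model.root_freqs = np.asarray(init.root_freqs, dtype=float).copy()
        for nid in list(model.theta):
            model.theta[nid] = init.theta.get(nid, model.theta[nid])
    taxon_rows, patterns, weights = compress_patterns(list(aln))
    branch_nodes = model.branch_nodes()
    groups: dict[int, list[int]] = {}
    for n in branch_nodes:
        key = theta_groups.get(n.id, n.id) if theta_groups else n.id
        groups.setdefault(key, []).append(n.id)

    def loglik() -> float:
        cache: dict[int, np.ndarray] = {}

        def p_fn(node, cat):
            if node.id not in cache:
                cache[node.id] = t92_transition_matrix(
                    model.theta[node.id], model.kappa, max(node.length, 0.0)
                )
            return cache[node.id]

        site = pruning_site_loglik(
            model.tree, taxon_rows, patterns, p_fn, model.root_freqs, 1
        )
        return float(weights @ site)

    def line_search(getter, setter, lo, hi, current_best):
        """Maximize over one (transformed) parameter; restore the original
        value unless the optimum improves on ``current_best``."""
        orig = getter()

        def neg(v):
            setter(v)
            return -loglik()

        res = minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
        )
        if -res.fun > current_best:
            setter(res.x)
            return -res.fun
        setter(orig)
        return None

    best = loglik()
    converged = False
    sweeps_done = max_sweeps
    for sweep in range(max_sweeps):
        prev = best
        # branch lengths (log space)
        for n in branch_nodes:
            got = line_search(
                lambda n=n: np.log(max(n.length, BL_FLOOR)),
                lambda v, n=n: setattr(n, "length", float(np.exp(v))),
                np.log(BL_FLOOR),
                np.log(10.0),
                best,
            )
            if got is not None:
                best = got
        # kappa (log space)
        got = line_search(
            lambda: np.log(model.kappa),
            lambda v: setattr(model, "kappa", float(np.exp(v))),
            np.log(0.05),
            np.log(40.0),
            best,
        )
        if got is not None:
            best = got

        # theta groups
        def set_theta(v, members):
            for nid in members:
                model.theta[nid] = float(v)

        for key, members in groups.items():
            got = line_search(
                lambda members=members: model.theta[members[0]],
                lambda v, members=members: set_theta(v, members),
                1e-3,
                1.0 - 1e-3,
                best,
            )
            if got is not None:
                best = got
        # root frequencies (3 free logits, T as reference)
        if optimize_root:

            def get_logit(i):
                logits = np.log(np.maximum(model.root_freqs, 1e-12))
                return float(logits[i] - logits[3])

            def set_logit(v, i):
                logits = np.log(np.maximum(model.root_freqs, 1e-12))
                logits -= logits[3]
                logits[i] = v
                f = np.exp(logits)
                model.root_freqs = f / f.sum()

            for i in range(3):
                got = line_search(
                    lambda i=i: get_logit(i),
                    lambda v, i=i: set_logit(v, i),
                    -6.0,
                    6.0,
                    best,
                )
                if got is not None:
                    best = got
        if best - prev <= rel_tol * (abs(prev) + 1.0):
            converged = True
            sweeps_done = sweep + 1
            break
    sl, total = tree_log_likelihood(model, aln)
    return FitResult(
        model=model,
        log_likelihood=total,
        converged=converged,
        n_sweeps=sweeps_done,
        site_likelihoods=sl,
    )


# ---------------------------------------------------------------------------
# NNI
# ---------------------------------------------------------------------------


def nni_neighbors(tree: Tree, edge_id: int) -> tuple[Tree, Tree]:
    """The two alternative topologies from one nearest-neighbor
    interchange across an internal edge (given by its child node id)."""
    node = tree.node_by_id(edge_id)
    if node.is_leaf or node.parent is None:
        raise ValueError("NNI requires an internal edge")
    out = []
    for which in (0, 1):
        t = tree.copy()
        v = t.node_by_id(edge_id)
        u = v.parent
        sibling = next(c for c in u.children if c is not v)
        a = v.children[which]
        u.children[u.children.index(sibling)] = a
        a.parent = u
        v.children[which] = sibling
        sibling.parent = v
        t._reindex()
        out.append(Tree(t.root))
    return out[0], out[1]


@dataclass
class SearchResult:
    fit: FitResult
    visited: list[str] = field(default_factory=list)  # newicks evaluated
    n_moves: int = 0


def nni_hill_climb(
    start: Tree,
    aln: Sequence[SeqRecord],
    init_params: NonStatModel | None = None,
    improve_tol: float = 0.01,
    opt_sweeps: int = 3,
    theta_groups: dict[int, int] | None = None,
) -> SearchResult:
    """Greedy NNI local search under the nonstationary model.

    Each neighbor is scored with parameters re-optimized (a bounded number
    of coordinate sweeps); the best neighbor is accepted while it improves
    the log-likelihood by more than ``improve_tol``.  The search therefore
    never strays beyond the accepted path's NNI distance from the start;
    every evaluated topology is logged in ``visited``.
    """
    if len(start.leaf_names()) < 4:
        raise ValueError("need at least 4 taxa")

    def fit_tree(tree: Tree) -> FitResult:
        init = uniform_model(tree)
        if init_params is not None:
            init.kappa = init_params.kappa
            init.root_freqs = init_params.root_freqs.copy()
        return optimize_model(
            tree, aln, init, max_sweeps=opt_sweeps,
            theta_groups=theta_groups,
        )

    current_tree = start.copy()
    current = fit_tree(current_tree)
    visited = [current_tree.to_newick()]
    moves = 0
    while True:
        best_neigh: tuple[Tree, FitResult] | None = None
        for edge_id in current_tree.internal_edge_ids():
            for neigh in nni_neighbors(current_tree, edge_id):
                fit = fit_tree(neigh)
                visited.append(neigh.to_newick())
                if (
                    best_neigh is None
                    or fit.log_likelihood > best_neigh[1].log_likelihood
                ):
                    best_neigh = (neigh, fit)
        if (
            best_neigh is not None
            and best_neigh[1].log_likelihood
            > current.log_likelihood + improve_tol
        ):
            current_tree, current = best_neigh
            moves += 1
        else:
            break
    current.model.tree = current_tree
    return SearchResult(fit=current, visited=visited, n_moves=moves)


# ---------------------------------------------------------------------------
# RELL ranking
# ---------------------------------------------------------------------------


def rell_rank(
    site_likelihoods: Sequence[SiteLikelihoods],
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """RELL bootstrap ranking of candidate trees with SH-style p-values.

    Site patterns are resampled with replacement (respecting weights) and
    per-tree totals re-summed.  Reported per tree: observed total logL,
    rank, bootstrap proportion (ties split evenly among co-winners), and
    an SH-style p-value from the centered-maximum null.
    """
    if len(site_likelihoods) < 2:
        raise ValueError("need at least two candidate trees")
    n_pat = site_likelihoods[0].log_likelihoods.size
    for sl in site_likelihoods:
        if sl.log_likelihoods.size != n_pat or not np.array_equal(
            sl.weights, site_likelihoods[0].weights
        ):
            raise ValueError("candidates must share the same site patterns")
    weights = site_likelihoods[0].weights.astype(float)
    n_sites = int(weights.sum())
    mat = np.stack([sl.log_likelihoods for sl in site_likelihoods])  # (T, P)
    observed = mat @ weights

    rng = np.random.default_rng(seed)
    probs = weights / weights.sum()
    counts = rng.multinomial(n_sites, probs, size=n_boot)  # (B, P)
    boot = counts @ mat.T  # (B, T)

    # bootstrap proportions with fractional credit on ties
    best = boot.max(axis=1, keepdims=True)
    winners = np.isclose(boot, best, rtol=0.0, atol=1e-9)
    bp = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)

    # SH-style: center each tree's replicate totals, compare the observed
    # logL deficit to the null distribution of (max - tree) deficits
    centered = boot - boot.mean(axis=0, keepdims=True)
    null_deficit = centered.max(axis=1, keepdims=True) - centered  # (B, T)
    obs_deficit = observed.max() - observed  # (T,)
    p_sh = (null_deficit >= obs_deficit[None, :] - 1e-9).mean(axis=0)

    order = np.argsort(-observed)
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(observed) + 1)
    return pd.DataFrame(
        {
            "tree": np.arange(len(observed)),
            "log_likelihood": observed,
            "rank": rank,
            "rell_bp": bp,
            "p_sh": p_sh,
        }
    )
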