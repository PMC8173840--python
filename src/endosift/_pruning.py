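"""Shared Felsenstein-pruning machinery.

Both likelihood engines (stationary GTR+Gamma and the nonstationary
per-branch-GC model) funnel through :func:`pruning_site_loglik`, which is
parameterized only by a per-(branch, rate-category) transition-matrix
provider.  Alignment columns are compressed to unique site patterns with
multiplicities before any likelihood work; gaps/ambiguities contribute a
partial likelihood of 1 in every state.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .seq_io import SeqRecord
from .trees import Node, Tree

_STATE = {"A": 0, "C": 1, "G": 2, "T": 3}


def compress_patterns(
    records: Sequence[SeqRecord],
) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    """Compress an alignment into unique site patterns.

    Returns ``(taxon_rows, patterns, weights)`` where ``patterns`` is an
    int8 array of shape (n_taxa, n_patterns) with -1 for gap/ambiguous and
    ``weights`` the column multiplicities.  All-gap columns are dropped
    with a warning.
    """
    if not records:
        raise ValueError("empty alignment")
    length = len(records[0].seq)
    if any(len(r.seq) != length for r in records):
        raise ValueError("alignment rows differ in length")
    mat = np.full((len(records), length), -1, dtype=np.int8)
    for i, rec in enumerate(records):
        for j, ch in enumerate(rec.seq):
            mat[i, j] = _STATE.get(ch, -1)
    keep = (mat >= 0).any(axis=0)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} all-gap column(s)")
        mat = mat[:, keep]
    if mat.shape[1] == 0:
        raise ValueError("no informative columns in alignment")
    cols, weights = np.unique(mat, axis=1, return_counts=True)
    taxon_rows = {rec.id: i for i, rec in enumerate(records)}
    if len(taxon_rows) != len(records):
        raise ValueError("duplicate taxon labels in alignment")
    return taxon_rows, cols, weights.astype(np.int64)


def pruning_site_loglik(
    tree: Tree,
    taxon_rows: dict[str, int],
    patterns: np.ndarray,
    p_matrix: Callable[[Node, int], np.ndarray],
    root_freqs: np.ndarray,
    n_categories: int = 1,
) -> np.ndarray:
    """Per-pattern log-likelihood by postorder pruning.

    Rate categories are equiprobable; ``p_matrix(node, cat)`` must return
    the 4x4 transition matrix for the branch above ``node`` under category
    ``cat``.  Per-node rescaling keeps partials in floating range.
    """
    n_pat = patterns.shape[1]
    nodes = tree.postorder()
    per_cat = np.empty((n_categories, n_pat))
    arange = np.arange(n_pat)
    for cat in range(n_categories):
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_pat)
        for node in nodes:
            if node.is_leaf:
                if node.name not in taxon_rows:
                    # taxon absent from the alignment: uninformative tip
                    partial[node.id] = np.ones((n_pat, 4))
                    continue
                states = patterns[taxon_rows[node.name]]
                lk = np.zeros((n_pat, 4))
                obs = states >= 0
                lk[arange[obs], states[obs]] = 1.0
                lk[~obs] = 1.0
                partial[node.id] = lk
            else:
                lk = np.ones((n_pat, 4))
                for child in node.children:
                    pm = p_matrix(child, cat)
                    lk *= partial.pop(child.id) @ pm.T
                mx = lk.max(axis=1)
                mx = np.where(mx > 0.0, mx, 1.0)
                lk /= mx[:, None]
                logscale += np.log(mx)
                partial[node.id] = lk
        site = partial[tree.root.id] @ root_freqs
        per_cat[cat] = np.log(np.maximum(site, 1e-300)) + logscale
    return logsumexp(per_cat, axis=0) - np.log(n_categories)
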