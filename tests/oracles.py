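"""Independent brute-force oracles for the likelihood engines.

Everything here is deliberately naive — exhaustive enumeration over
internal-node states and unrooted-topology enumeration by edge insertion —
and shares no code with the pruning implementations it checks.
"""

from __future__ import annotations

import numpy as np

from endosift.trees import Node, Tree

_STATE = {"A": 0, "C": 1, "G": 2, "T": 3}


def exhaustive_site_loglik(
    tree: Tree,
    leaf_states: dict[str, int],
    p_fn,
    root_freqs: np.ndarray,
    n_categories: int,
) -> float:
    """Log-likelihood of one site by summing over every assignment of
    states to internal nodes, averaged over rate categories."""
    internal = [n for n in tree.postorder() if not n.is_leaf]
    total = 0.0
    for cat in range(n_categories):
        cat_sum = 0.0
        for combo in np.ndindex(*(4,) * len(internal)):
            assign = {n.id: s for n, s in zip(internal, combo)}
            prob = root_freqs[assign[tree.root.id]]
            for node in tree.postorder():
                if node.parent is None:
                    continue
                parent_state = assign[node.parent.id]
                child_state = (
                    leaf_states[node.name] if node.is_leaf else assign[node.id]
                )
                prob *= p_fn(node, cat)[parent_state, child_state]
            cat_sum += prob
        total += cat_sum / n_categories
    return float(np.log(total))


def exhaustive_alignment_loglik(
    tree: Tree, records, p_fn, root_freqs, n_categories
) -> float:
    """Total log-likelihood of an ungapped alignment, site by site."""
    length = len(records[0].seq)
    total = 0.0
    for j in range(length):
        states = {r.id: _STATE[r.seq[j]] for r in records}
        total += exhaustive_site_loglik(
            tree, states, p_fn, root_freqs, n_categories
        )
    return total


def enumerate_unrooted_topologies(leaf_names: list[str]) -> list[Tree]:
    """All distinct unrooted binary topologies by sequential edge
    insertion (3, 15, 105, ... trees for 4, 5, 6, ... leaves)."""
    if len(leaf_names) < 3:
        raise ValueError("need >= 3 leaves")

    def base() -> Tree:
        root = Node()
        for name in leaf_names[:3]:
            root.add(Node(name, 0.1))
        return Tree(root)

    trees = [base()]
    for name in leaf_names[3:]:
        grown: list[Tree] = []
        for tree in trees:
            edges = [n for n in tree.postorder() if n.parent is not None]
            for i in range(len(edges)):
                t = tree.copy()
                target = [n for n in t.postorder() if n.parent is not None][i]
                parent = target.parent
                mid = Node(length=0.1)
                parent.children[parent.children.index(target)] = mid
                mid.parent = parent
                mid.add(target)
                mid.add(Node(name, 0.1))
                grown.append(Tree(t.root))
        trees = grown
    return trees
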