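"""Fritz & Purvis D: phylogenetic signal of a binary trait.

The statistic scales the observed sum of sister-clade differences of nodal
character values between two null expectations: random shuffling of tip
states (D = 1, no signal) and threshold Brownian evolution matching the
trait's prevalence (D = 0, Brownian-like clumping).  D < 0 indicates
stronger-than-Brownian clumping; D > 1 overdispersion.

Trees come in as dendropy objects (or newick strings); internally they are
flattened to index arrays so many trait vectors can be scored in one
bottom-up pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["TreeArrays", "sum_of_changes", "estimate_D"]


@dataclass
class TreeArrays:
    """Flattened rooted tree: tips first, internal nodes in postorder after."""

    tip_labels: list[str]
    children: list[list[int]]  # per internal node, indices into the value array
    internal_order: list[int]  # postorder indices of internal nodes
    parent: np.ndarray  # parent index per node (-1 at root)
    edge_length: np.ndarray  # branch length above each node (0 at root)
    preorder: list[int]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "TreeArrays":
        tips = [lf for lf in tree.leaf_node_iter()]
        if len(tips) < 2:
            raise ValueError("tree must have at least 2 tips")
        labels = [t.taxon.label if t.taxon else "" for t in tips]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        index: dict[int, int] = {id(t): i for i, t in enumerate(tips)}
        internals = [
            nd for nd in tree.postorder_node_iter() if not nd.is_leaf()
        ]
        for k, nd in enumerate(internals):
            index[id(nd)] = len(tips) + k

        n = len(tips) + len(internals)
        parent = np.full(n, -1, dtype=int)
        elen = np.zeros(n)
        children: list[list[int]] = [[] for _ in internals]
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            elen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
        for k, nd in enumerate(internals):
            children[k] = [index[id(c)] for c in nd.child_nodes()]
        preorder = [index[id(nd)] for nd in tree.preorder_node_iter()]
        return cls(
            tip_labels=labels,
            children=children,
            internal_order=list(range(len(tips), n)),
            parent=parent,
            edge_length=elen,
            preorder=preorder,
        )


def _d_values(arr: TreeArrays, traits: np.ndarray) -> np.ndarray:
    """Fritz-Purvis d for each column of ``traits`` (n_tips x B).

    Nodal values are equal-weight averages of daughter values estimated from
    the tips up; d sums the absolute daughter differences over internal
    nodes (all unordered daughter pairs at a polytomy).
    """
    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    if traits.shape[0] != arr.n_tips:
        traits = traits.T
    B = traits.shape[1]
    vals = np.zeros((arr.n_nodes, B))
    vals[: arr.n_tips] = traits
    d = np.zeros(B)
    for k, node in enumerate(arr.internal_order):
        kids = arr.children[k]
        kid_vals = vals[kids]
        vals[node] = kid_vals.mean(axis=0)
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                d += np.abs(kid_vals[a] - kid_vals[b])
    return d


def _coerce_tree(tree: dendropy.Tree | str) -> TreeArrays:
    if isinstance(tree, TreeArrays):
        return tree
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    return TreeArrays.from_tree(tree)


def _trait_vector(arr: TreeArrays, trait) -> np.ndarray:
    if isinstance(trait, dict):
        missing = [t for t in arr.tip_labels if t not in trait]
        if missing:
            raise ValueError(f"trait missing for tips: {missing}")
        states = np.array([trait[t] for t in arr.tip_labels], dtype=float)
    else:
        states = np.asarray(trait, dtype=float)
        if len(states) != arr.n_tips:
            raise ValueError("trait vector length does not match number of tips")
    if not set(np.unique(states)) <= {0.0, 1.0}:
        raise ValueError("trait must be binary 0/1")
    return states


def sum_of_changes(tree: dendropy.Tree | str, trait) -> float:
    """Observed sum of sister-clade differences (Fritz-Purvis d) for a binary trait."""
    arr = _coerce_tree(tree)
    return float(_d_values(arr, _trait_vector(arr, trait)[:, None])[0])


def _brownian_tips(arr: TreeArrays, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """Tip values of variance-1 Brownian motion simulated along the tree."""
    incr = rng.standard_normal((arr.n_nodes, n_sim)) * np.sqrt(
        arr.edge_length
    )[:, None]
    vals = np.zeros((arr.n_nodes, n_sim))
    for node in arr.preorder:
        p = arr.parent[node]
        vals[node] = incr[node] if p < 0 else vals[p] + incr[node]
    return vals[: arr.n_tips]


def _threshold_to_prevalence(tip_values: np.ndarray, k: int) -> np.ndarray:
    """Binary states: 1 for the k largest tip values in each column."""
    n, B = tip_values.shape
    order = np.argsort(tip_values, axis=0)
    states = np.zeros((n, B))
    rows = order[n - k :, :]
    np.put_along_axis(states, rows, 1.0, axis=0)
    return states


def estimate_D(
    tree: dendropy.Tree | str,
    trait,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Fritz-Purvis D with permutation and Brownian-threshold nulls.

    D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian).
    ``p_random`` is the fraction of random-shuffle d values <= d_obs (small
    values mean the trait is more phylogenetically clumped than chance);
    ``p_brownian`` the fraction of Brownian-threshold d values >= d_obs.
    Brownian simulations use variance-1 motion with a per-simulation
    threshold matching the observed prevalence.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = _coerce_tree(tree)
    states = _trait_vector(arr, trait)
    k = int(states.sum())
    if k == 0 or k == arr.n_tips:
        raise ValueError("trait must have both states present")

    d_obs = float(_d_values(arr, states[:, None])[0])

    shuffled = np.tile(states[:, None], (1, n_perm))
    shuffled = rng.permuted(shuffled, axis=0)
    d_rand = _d_values(arr, shuffled)

    bm_states = _threshold_to_prevalence(_brownian_tips(arr, n_perm, rng), k)
    d_brown = _d_values(arr, bm_states)

    denom = d_rand.mean() - d_brown.mean()
    if denom == 0:
        raise ValueError("degenerate nulls: random and Brownian means coincide")
    D = (d_obs - d_brown.mean()) / denom
    p_random = (np.count_nonzero(d_rand <= d_obs) + 1) / (n_perm + 1)
    p_brownian = (np.count_nonzero(d_brown >= d_obs) + 1) / (n_perm + 1)
    return {
        "D": float(D),
        "d_obs": d_obs,
        "p_random": float(p_random),
        "p_brownian": float(p_brownian),
        "mean_d_random": float(d_rand.mean()),
        "mean_d_brownian": float(d_brown.mean()),
    }
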