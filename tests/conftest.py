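"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use a different computational route from
the package (dense linear algebra instead of pruning, exhaustive
enumeration instead of dynamic programming) so agreement is meaningful.
"""

import itertools

import numpy as np
import pytest

from renschkit import Phylogeny, simulate_yule_tree


@pytest.fixture
def three_taxon_tree() -> Phylogeny:
    """The worked example: ((A:1,B:1):1,C:2); V = [[2,1,0],[1,2,0],[0,0,2]]."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def tree50() -> Phylogeny:
    """A fixed 50-tip Yule tree for calibration tests."""
    return simulate_yule_tree(n_tips=50, birth_rate=0.3, seed=20250925)


def dense_gls_asr(tree: Phylogeny, tip_values: dict) -> dict:
    """Oracle: ancestral BM estimates by a dense GLS solve.

    Builds the full tip covariance matrix V and the ancestor-tip
    covariance vectors from shared root-to-MRCA path lengths, then
    evaluates mu_hat + C V^-1 (x - mu_hat 1) for every internal node.
    """
    tips_order, V = tree.vcv()
    x = np.array([float(tip_values[t]) for t in tips_order])
    Vi = np.linalg.inv(V)
    one = np.ones(len(x))
    mu = one @ Vi @ x / (one @ Vi @ one)
    depths = tree.depths()
    below_cache = {}
    for node in tree.postorder():
        if node.is_leaf():
            below_cache[node._node_id] = {node.taxon.label}
        else:
            below_cache[node._node_id] = set().union(
                *(below_cache[c._node_id] for c in node.child_nodes())
            )
    out = {}
    for node in tree.preorder():
        nid = node._node_id
        if node.is_leaf():
            out[nid] = float(tip_values[nid])
            continue
        c = np.zeros(len(x))
        for i, tip in enumerate(tips_order):
            a = node
            while tip not in below_cache[a._node_id]:
                a = a.parent_node
            c[i] = depths[a._node_id]
        out[nid] = float(mu + c @ Vi @ (x - mu * one))
    return out


def brute_force_parsimony_length(tree: Phylogeny, tip_states: dict) -> int:
    """Oracle: exhaustive minimum changes over all internal 0/1 labelings."""
    internal = [n._node_id for n in tree.preorder() if not n.is_leaf()]
    edges = [
        (n.parent_node._node_id, n._node_id)
        for n in tree.preorder()
        if n.parent_node is not None
    ]
    best = len(edges) + 1
    for combo in itertools.product((0, 1), repeat=len(internal)):
        lab = dict(zip(internal, combo))
        lab.update(tip_states)
        changes = sum(1 for p, c in edges if lab[p] != lab[c])
        best = min(best, changes)
    return best


def random_tree_battery(n_trees: int, seed: int, min_tips: int = 3, max_tips: int = 8):
    """Deterministic battery of small random Yule trees."""
    rng = np.random.default_rng(seed)
    for i in range(n_trees):
        n = int(rng.integers(min_tips, max_tips + 1))
        yield simulate_yule_tree(n_tips=n, birth_rate=1.0, seed=int(rng.integers(2**31)))
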