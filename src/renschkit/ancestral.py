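"""Ancestral state reconstruction.

Two reconstructions are provided, matching the two kinds of characters
analysed downstream:

* :func:`asr_bm` — maximum-likelihood (GLS) reconstruction of a continuous
  trait under Brownian motion on a fixed, binary, time-calibrated tree.
  Point estimates come from the classic two-pass pruning algorithm
  (tip-to-root reweighted averaging, then a root-to-tip finishing pass);
  the root estimate is the phylogenetic (GLS) mean.  BM reconstruction is
  inherently shrunk toward intermediate values — a property of the null
  model, not a defect — so reconstructed per-branch changes tend to
  understate true rates.

* :func:`asr_parsimony` — Fitch parsimony for binary characters
  (secondary sexual characters coded 0/1), with most-parsimonious state
  sets per node and per-branch gain/loss lists under a delayed-
  transformation (DELTRAN-style) resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Phylogeny

__all__ = ["AncestralReconstruction", "ParsimonyReconstruction", "asr_bm", "asr_parsimony"]


@dataclass
class AncestralReconstruction:
    """Per-node BM estimates for one continuous trait.

    ``estimates`` maps node id -> point estimate (trait units); tips carry
    their observed values exactly.  ``ci`` maps node id -> (low, high) 95%
    interval from the conditional normal variance scaled by the ML rate
    ``sigma2`` (trait-units^2 / My).
    """

    trait: str
    estimates: dict[str, float]
    ci: dict[str, tuple[float, float]]
    sigma2: float

    def as_table(self) -> pd.DataFrame:
        rows = [
            {
                "node": k,
                "estimate": v,
                "ci_low": self.ci[k][0],
                "ci_high": self.ci[k][1],
            }
            for k, v in self.estimates.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class ParsimonyReconstruction:
    """Fitch-parsimony summary for one binary character.

    ``state_sets`` holds the most-parsimonious state set per node;
    ``states`` one minimum-length labeling (DELTRAN-style: changes pushed
    tipward).  ``gains``/``losses`` list child node ids of branches on
    which the resolved state flips 0->1 / 1->0.
    """

    character: str
    state_sets: dict[str, frozenset]
    states: dict[str, int]
    length: int
    gains: list[str]
    losses: list[str]
    root_ambiguous: bool
    n_ambiguous_nodes: int = 0
    extra: dict = field(default_factory=dict)


def _combine(values, variances):
    """Precision-weighted mean; zero-variance observations dominate."""
    zeros = [v for v, s in zip(values, variances) if s == 0.0]
    if zeros:
        return float(np.mean(zeros)), 0.0
    w = np.array([1.0 / s for s in variances])
    return float(np.dot(w, values) / w.sum()), float(1.0 / w.sum())


def asr_bm(tree: Phylogeny, tip_values: dict[str, float], trait: str = "trait") -> AncestralReconstruction:
    """ML/GLS ancestral reconstruction of a continuous trait under BM.

    Parameters
    ----------
    tree:
        Binary rooted tree with branch durations in My; every root-to-tip
        path must be positive.
    tip_values:
        Observed trait value per tip label (all tips required).

    Returns
    -------
    AncestralReconstruction
        Point estimates for every node (tips exact), 95% intervals and the
        ML Brownian rate estimate ``sigma2``.
    """
    if not tree.is_binary():
        raise ValueError("tree has polytomies; run resolve_polytomies first")
    tips = tree.tip_labels
    missing = sorted(set(tips) - set(tip_values))
    if missing:
        raise ValueError(f"missing tip values for species: {missing}")
    depths = tree.depths()
    if max(depths[t] for t in tips) <= 0:
        raise ValueError("all root-to-tip depths are zero: singular BM covariance")

    # Upward (pruning) pass: conditional subtree estimates.
    sub_val: dict[str, float] = {}
    sub_var: dict[str, float] = {}   # conditional variance factor at node
    eff_var: dict[str, float] = {}   # sub_var + branch length above node
    ss = 0.0                         # sum of squared standardized contrasts
    n_contrasts = 0
    for node in tree.postorder():
        nid = node._node_id
        if node.is_leaf():
            sub_val[nid] = float(tip_values[nid])
            sub_var[nid] = 0.0
        else:
            kids = node.child_nodes()
            xs = [sub_val[c._node_id] for c in kids]
            ds = [eff_var[c._node_id] for c in kids]
            denom = ds[0] + ds[1]
            if denom == 0.0 and xs[0] != xs[1]:
                raise ValueError(
                    f"zero-variance contrast with unequal values at node {nid}"
                )
            if denom > 0.0:
                ss += (xs[0] - xs[1]) ** 2 / denom
                n_contrasts += 1
            sub_val[nid], sub_var[nid] = _combine(xs, ds)
        if node.parent_node is not None:
            eff_var[nid] = sub_var[nid] + float(node.edge.length)

    n = len(tips)
    sigma2 = ss / n  # ML estimate

    # Downward finishing pass: fold in the rest-of-tree pseudo-observation.
    rest_val: dict[str, float] = {}
    rest_var: dict[str, float] = {}  # variance factor of the rest estimate at the node
    est: dict[str, float] = {}
    varf: dict[str, float] = {}
    for node in tree.preorder():
        nid = node._node_id
        if node.parent_node is None:
            est[nid] = sub_val[nid]
            varf[nid] = sub_var[nid]
            continue
        pid = node.parent_node._node_id
        vals, vars_ = [], []
        for sib in node.parent_node.child_nodes():
            if sib is node:
                continue
            vals.append(sub_val[sib._node_id])
            vars_.append(eff_var[sib._node_id])
        if pid in rest_val:
            vals.append(rest_val[pid])
            vars_.append(rest_var[pid])
        u, w = _combine(vals, vars_)
        rest_val[nid] = u
        rest_var[nid] = w + float(node.edge.length)
        est[nid], varf[nid] = _combine(
            [sub_val[nid], rest_val[nid]], [sub_var[nid], rest_var[nid]]
        )

    z = 1.959963984540054
    ci = {
        k: (est[k] - z * np.sqrt(sigma2 * varf[k]), est[k] + z * np.sqrt(sigma2 * varf[k]))
        for k in est
    }
    return AncestralReconstruction(trait=trait, estimates=est, ci=ci, sigma2=sigma2)


def _fitch_downpass(tree: Phylogeny, tip_states: dict[str, int]):
    down: dict[str, frozenset] = {}
    length = 0
    for node in tree.postorder():
        nid = node._node_id
        if node.is_leaf():
            down[nid] = frozenset({int(tip_states[nid])})
        else:
            sets = [down[c._node_id] for c in node.child_nodes()]
            inter = frozenset.intersection(*sets)
            if inter:
                down[nid] = inter
            else:
                down[nid] = frozenset.union(*sets)
                length += len(sets) - 1  # binary tree: +1 per union
    return down, length


def asr_parsimony(tree: Phylogeny, tip_states: dict[str, int], character: str = "character") -> ParsimonyReconstruction:
    """Fitch parsimony reconstruction of a binary (0/1) character.

    Returns per-node most-parsimonious state sets, the minimum number of
    changes, and gain (0->1) / loss (1->0) branches under one minimum
    labeling in which changes are delayed toward the tips.  When the
    most-parsimonious root state is not unique the reconstruction is
    flagged ambiguous rather than silently committed.
    """
    if not tree.is_binary():
        raise ValueError("tree has polytomies; run resolve_polytomies first")
    tips = tree.tip_labels
    missing = sorted(set(tips) - set(tip_states))
    if missing:
        raise ValueError(f"missing tip states for species: {missing}")
    bad = sorted(t for t in tips if tip_states[t] not in (0, 1))
    if bad:
        raise ValueError(f"non-binary states for species: {bad}")

    down, length = _fitch_downpass(tree, tip_states)

    # Uppass: most-parsimonious (MPR) state sets.
    up: dict[str, frozenset] = {}
    for node in tree.preorder():
        nid = node._node_id
        if node.parent_node is None:
            up[nid] = down[nid]
            continue
        fp = up[node.parent_node._node_id]
        if fp <= down[nid]:
            up[nid] = fp
        elif node.is_leaf():
            up[nid] = down[nid]
        else:
            kid_sets = [down[c._node_id] for c in node.child_nodes()]
            if frozenset.intersection(*kid_sets):
                up[nid] = down[nid] | (fp & frozenset.union(*kid_sets))
            else:
                up[nid] = down[nid] | fp

    # One minimum labeling via classic Fitch backtracking on downpass sets:
    # keep the parent's state whenever allowed (delays changes tipward).
    states: dict[str, int] = {}
    gains: list[str] = []
    losses: list[str] = []
    root_id = tree.root_id
    root_ambiguous = len(down[root_id]) > 1
    for node in tree.preorder():
        nid = node._node_id
        if node.parent_node is None:
            states[nid] = min(down[nid])
            continue
        ps = states[node.parent_node._node_id]
        if ps in down[nid]:
            states[nid] = ps
        else:
            states[nid] = min(down[nid])
        if states[nid] != ps:
            (gains if states[nid] == 1 else losses).append(nid)

    n_amb = sum(1 for s in up.values() if len(s) > 1)
    return ParsimonyReconstruction(
        character=character,
        state_sets=up,
        states=states,
        length=length,
        gains=gains,
        losses=losses,
        root_ambiguous=root_ambiguous,
        n_ambiguous_nodes=n_amb,
    )
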