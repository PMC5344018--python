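"""Tree data model, Newick/NEXUS I/O and topology utilities.

The package works on rooted, time-calibrated phylogenies whose branch
lengths are durations (million years, My).  :class:`Phylogeny` is a thin
validated wrapper around a :class:`dendropy.Tree`; every node carries a
stable string id (tip label for leaves, assigned ``N<k>`` labels for
unlabeled internal nodes) so downstream tables can refer to nodes.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass
from typing import Iterator, Sequence

import dendropy

__all__ = [
    "Branch",
    "Phylogeny",
    "read_tree",
    "write_tree",
    "resolve_polytomies",
    "branches",
]


@dataclass(frozen=True)
class Branch:
    """A parent -> child edge with its duration in My."""

    parent: str
    child: str
    duration: float


class Phylogeny:
    """Rooted phylogeny with unique node ids and branch durations in My.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree`.  The instance takes ownership;
        callers should not mutate the dendropy tree afterwards.

    Raises
    ------
    ValueError
        If tip labels are missing/duplicated or a branch duration is
        negative.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._assign_ids()
        self._validate()

    # -- construction ----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def _assign_ids(self) -> None:
        used = set()
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("every tip must carry a species label")
            leaf._node_id = leaf.taxon.label
            used.add(leaf._node_id)
        counter = 1
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                continue
            label = node.label
            if label is None or label in used:
                while f"N{counter}" in used:
                    counter += 1
                label = f"N{counter}"
            node._node_id = label
            used.add(label)

    def _validate(self) -> None:
        tips = self.tip_labels
        if len(tips) != len(set(tips)):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                if node.edge.length is None:
                    node.edge.length = 0.0
                if node.edge.length < 0:
                    raise ValueError(
                        f"negative branch duration on node {node._node_id}"
                    )

    # -- basic accessors -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root_id(self) -> str:
        return self._tree.seed_node._node_id

    @property
    def tip_labels(self) -> list[str]:
        return [l.taxon.label for l in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def node_ids(self) -> list[str]:
        return [n._node_id for n in self._tree.preorder_node_iter()]

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_internal_node_iter()
        )

    def node(self, node_id: str) -> dendropy.Node:
        for n in self._tree.preorder_node_iter():
            if n._node_id == node_id:
                return n
        raise KeyError(node_id)

    def postorder(self) -> Iterator[dendropy.Node]:
        return self._tree.postorder_node_iter()

    def preorder(self) -> Iterator[dendropy.Node]:
        return self._tree.preorder_node_iter()

    def depths(self) -> dict[str, float]:
        """Root-to-node path lengths (My) keyed by node id."""
        out: dict[str, float] = {}
        for n in self._tree.preorder_node_iter():
            if n.parent_node is None:
                out[n._node_id] = 0.0
            else:
                out[n._node_id] = out[n.parent_node._node_id] + n.edge.length
        return out

    def max_depth(self) -> float:
        d = self.depths()
        return max(d[t] for t in self.tip_labels)

    def patristic_matrix(self) -> tuple[list[str], "np.ndarray"]:
        """Tip-by-tip patristic distance matrix (sorted tip order)."""
        import numpy as np

        tips = sorted(self.tip_labels)
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        m = np.zeros((len(tips), len(tips)))
        for i, a in enumerate(tips):
            for j, b in enumerate(tips):
                if i < j:
                    m[i, j] = m[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
        return tips, m

    def vcv(self) -> tuple[list[str], "np.ndarray"]:
        """BM covariance structure: shared root-to-MRCA path length per tip pair."""
        import numpy as np

        tips = sorted(self.tip_labels)
        idx = {t: i for i, t in enumerate(tips)}
        n = len(tips)
        V = np.zeros((n, n))
        # accumulate each edge's length onto all tip pairs below it
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            below = [l.taxon.label for l in node.leaf_iter()]
            ii = [idx[t] for t in below]
            V[np.ix_(ii, ii)] += node.edge.length
        return tips, V

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- output ----------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    def write(self, path: str, format: str = "newick") -> None:
        write_tree(self, path, format)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips>"


def read_tree(path: str, format: str = "newick") -> Phylogeny:
    """Read a rooted tree from a Newick or NEXUS file.

    Branch lengths are preserved as written; unlabeled internal nodes get
    synthetic ``N<k>`` ids.  Malformed files raise the parser's error
    (which names the offending position); duplicate tip labels raise
    :class:`ValueError`.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format: {format!r}")
    tree = dendropy.Tree.get(
        path=path, schema=format, preserve_underscores=True
    )
    return Phylogeny(tree)


def write_tree(tree: Phylogeny, path: str, format: str = "newick") -> None:
    """Write a tree in Newick or NEXUS (TREES block) format."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format: {format!r}")
    tree.dendropy_tree.write(
        path=path,
        schema=format,
        suppress_rooting=(format == "newick"),
        unquoted_underscores=True,
    )


def resolve_polytomies(tree: Phylogeny, seed: int) -> Phylogeny:
    """Randomly resolve multifurcations into a strictly binary tree.

    Inserted branches have duration 0, so every tip-to-root (and tip-to-tip
    patristic) distance is unchanged.  A fixed seed fixes the resolution;
    an already-binary tree is returned as an identical copy.
    """
    out = tree.dendropy_tree.clone(depth=1)
    out.resolve_polytomies(rng=random.Random(seed))
    for node in out.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
    return Phylogeny(out)


def branches(tree: Phylogeny) -> list[Branch]:
    """All parent -> child edges (terminal branches included), each once."""
    out = []
    for node in tree.preorder():
        if node.parent_node is None:
            continue
        out.append(
            Branch(
                parent=node.parent_node._node_id,
                child=node._node_id,
                duration=float(node.edge.length),
            )
        )
    return out
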