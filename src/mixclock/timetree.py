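"""Rooted, dated, binary phylogenies with indexed branches.

The container used throughout the package is an array-backed tree in which
nodes are indexed ``0 .. 2P-2`` for ``P`` tips, the root is node 0 and node
order is a preorder traversal.  Every non-root node ``j`` identifies the
branch leading to it from its parent, so a tree has exactly ``2P-2``
branches and per-branch vectors (rates, effective lengths, sufficient
statistics) align with node indices ``1 .. 2P-2``.

Ages are measured in Myr before present: extant tips sit at age 0, fossil
tips at age > 0, and every parent is strictly older than its children.
Branch *durations* (Myr) and molecular *effective lengths* (expected
substitutions per site) are kept in separate fields and never mixed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["TimeTree", "MIN_AGE_GAP"]

#: Minimum parent-child age gap (Myr) tolerated before a tree is rejected.
MIN_AGE_GAP = 1e-6


@dataclass
class TimeTree:
    """A rooted binary time tree.

    Parameters
    ----------
    parent : (2P-1,) int array, parent index per node, -1 for the root.
    children : (2P-1, 2) int array, child indices per node, -1 for tips.
    ages : (2P-1,) float array, node ages in Myr before present.
    labels : dict mapping tip node index -> taxon label.
    fossil : (2P-1,) bool array, True for fossil (serially sampled) tips.
    """

    parent: np.ndarray
    children: np.ndarray
    ages: np.ndarray
    labels: dict[int, str]
    fossil: np.ndarray = field(default=None)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.children = np.asarray(self.children, dtype=np.int64)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.fossil is None:
            self.fossil = np.zeros(self.n_nodes, dtype=bool)
        self.fossil = np.asarray(self.fossil, dtype=bool)
        self._validate()

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def n_tips(self) -> int:
        return (self.n_nodes + 1) // 2

    @property
    def n_branches(self) -> int:
        """2P-2: every node except the root subtends one branch."""
        return self.n_nodes - 1

    @property
    def root(self) -> int:
        return 0

    @property
    def root_age(self) -> float:
        return float(self.ages[0])

    @property
    def is_tip(self) -> np.ndarray:
        return self.children[:, 0] < 0

    @property
    def internal(self) -> np.ndarray:
        """Indices of internal nodes (root included), in preorder."""
        return np.flatnonzero(~self.is_tip)

    @property
    def tips(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def branches(self) -> np.ndarray:
        """Branch indices = all non-root nodes (child-node convention)."""
        return np.arange(1, self.n_nodes)

    def durations(self) -> np.ndarray:
        """Per-branch durations Delta-t_j (Myr), indexed by child node 1..2P-2."""
        return self.ages[self.parent[1:]] - self.ages[1:]

    @property
    def tip_label_to_node(self) -> dict[str, int]:
        return {lab: i for i, lab in self.labels.items()}

    def _validate(self) -> None:
        n = self.n_nodes
        if n < 3 or n % 2 == 0:
            raise ValueError("a rooted binary tree has an odd node count >= 3")
        is_tip = self.is_tip
        n_tips = int(is_tip.sum())
        if n != 2 * n_tips - 1:
            raise ValueError("node count inconsistent with a rooted binary tree")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise ValueError("node 0 must be the unique root")
        if set(self.labels) != set(np.flatnonzero(is_tip).tolist()):
            raise ValueError("tip labels must cover exactly the tip nodes")
        if len(set(self.labels.values())) != n_tips:
            raise ValueError("duplicate taxon labels")
        dt = self.durations()
        if np.any(dt <= 0):
            j = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise ValueError(
                f"non-positive branch duration on branch to node {j} "
                f"(child age {self.ages[j]:g} >= parent age {self.ages[self.parent[j]]:g})"
            )
        bad = is_tip & ~self.fossil & (np.abs(self.ages) > 1e-9)
        if np.any(bad):
            labs = [self.labels[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"extant tips must have age 0; offending tips: {labs}")
        if np.any(self.fossil & is_tip & (self.ages <= 0)):
            raise ValueError("fossil tips must have age > 0")

    # ------------------------------------------------------------------
    # traversals
    # ------------------------------------------------------------------
    def preorder(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def postorder(self) -> np.ndarray:
        return np.arange(self.n_nodes)[::-1]

    def depths(self) -> np.ndarray:
        """Topological depth (edge count from root) per node."""
        d = np.zeros(self.n_nodes, dtype=np.int64)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + 1
        return d

    def tipset_below(self, v: int) -> set[str]:
        out: set[str] = set()
        stack = [v]
        while stack:
            u = stack.pop()
            if self.is_tip[u]:
                out.add(self.labels[u])
            else:
                stack.extend(self.children[u])
        return out

    def mrca(self, tip_labels) -> int:
        """Most recent common ancestor of a set of tip labels."""
        lab2node = self.tip_label_to_node
        try:
            nodes = [lab2node[lab] for lab in tip_labels]
        except KeyError as e:
            raise KeyError(f"unknown tip label {e.args[0]!r}") from None
        if len(nodes) < 2:
            raise ValueError("an MRCA needs at least two tips")
        depth = self.depths()
        cur = set(nodes)
        while len(cur) > 1:
            v = max(cur, key=lambda u: (depth[u], u))
            cur.discard(v)
            cur.add(int(self.parent[v]))
        return cur.pop()

    # ------------------------------------------------------------------
    # construction / round-trip
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, fossil_tips=None) -> "TimeTree":
        fossil_tips = set(fossil_tips or ())
        seed = dtree.seed_node
        # collapse a knuckle at the root (single-child seed), common in Newick
        while len(seed.child_nodes()) == 1:
            seed = seed.child_nodes()[0]
        for nd in seed.preorder_iter():
            nch = len(nd.child_nodes())
            if nch not in (0, 2):
                name = nd.taxon.label if nd.taxon else "<internal>"
                raise ValueError(f"polytomy (or unifurcation) at node {name!r}: "
                                 f"{nch} children; only binary trees are supported")
            if nd is not seed and (nd.edge.length is None or nd.edge.length <= 0):
                raise ValueError("all branch durations must be strictly positive")
        order = list(seed.preorder_iter())
        index = {id(nd): i for i, nd in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=np.int64)
        children = np.full((n, 2), -1, dtype=np.int64)
        depth = np.zeros(n)
        labels: dict[int, str] = {}
        for i, nd in enumerate(order):
            if nd is not seed:
                p = index[id(nd.parent_node)]
                parent[i] = p
                depth[i] = depth[p] + nd.edge.length
            for k, ch in enumerate(nd.child_nodes()):
                children[i, k] = index[id(ch)]
            if not nd.child_nodes():
                if nd.taxon is None:
                    raise ValueError("unlabelled tip")
                labels[i] = nd.taxon.label
        is_tip = children[:, 0] < 0
        tip_idx = np.flatnonzero(is_tip)
        fossil = np.zeros(n, dtype=bool)
        for i in tip_idx:
            if labels[i] in fossil_tips:
                fossil[i] = True
        extant_depths = depth[tip_idx][~fossil[tip_idx]]
        if extant_depths.size == 0:
            raise ValueError("a tree needs at least one extant tip")
        root_age = float(extant_depths.max())
        rel = np.abs(extant_depths - root_age)
        if np.any(rel > 1e-6 * max(root_age, 1.0)):
            bad = [labels[i] for i in tip_idx[~fossil[tip_idx]][rel > 1e-6 * max(root_age, 1.0)]]
            raise ValueError(
                "tree is not ultrametric over extant tips (unequal root-to-tip "
                f"path lengths); offending tips: {bad}; declare fossil tips explicitly"
            )
        ages = root_age - depth
        ages[tip_idx[~fossil[tip_idx]]] = 0.0  # absorb float noise
        return cls(parent, children, ages, labels, fossil)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            if v > 0:
                nodes[self.parent[v]].add_child(nodes[v])
                nodes[v].edge.length = float(self.ages[self.parent[v]] - self.ages[v])
            if self.is_tip[v]:
                nodes[v].taxon = taxa.new_taxon(self.labels[v])
        dtree.seed_node = nodes[0]
        return dtree

    def copy(self) -> "TimeTree":
        return TimeTree(self.parent.copy(), self.children.copy(), self.ages.copy(),
                        dict(self.labels), self.fossil.copy())

    @classmethod
    def from_newick(cls, text: str, fossil_tips=None) -> "TimeTree":
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
        return cls.from_dendropy(dtree, fossil_tips=fossil_tips)

    def to_newick(self) -> str:
        s = _io.StringIO()
        self._write_newick_node(0, s, annot=None)
        s.write(";")
        return s.getvalue()

    def to_annotated_newick(self, annot: dict[str, np.ndarray]) -> str:
        """Newick with per-branch metadata comments, for rate-history painting.

        ``annot`` maps names (e.g. ``rBM``, ``R``, ``l``) to per-node arrays of
        length 2P-1 whose entries for non-root nodes annotate the subtending
        branch.
        """
        s = _io.StringIO()
        self._write_newick_node(0, s, annot=annot)
        s.write(";")
        return s.getvalue()

    def _write_newick_node(self, v: int, s, annot) -> None:
        if self.is_tip[v]:
            s.write(self.labels[v].replace(" ", "_"))
        else:
            s.write("(")
            self._write_newick_node(self.children[v, 0], s, annot)
            s.write(",")
            self._write_newick_node(self.children[v, 1], s, annot)
            s.write(")")
        if v != 0:
            dur = self.ages[self.parent[v]] - self.ages[v]
            if annot:
                items = ",".join(f"{k}={val[v]:.6g}" for k, val in annot.items())
                s.write(f"[&{items}]")
            s.write(f":{dur:.12g}")
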