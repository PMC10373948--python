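"""Conditional clade probabilities (CCP) from a sample of gene trees.

A bootstrap or MCMC sample of gene trees is summarised by counting, for
every directed edge of every (unrooted) tree, the induced leaf subset
("clade") and its resolution into two child clades ("split").  The
conditional probability q(split | clade) = split count / clade count is the
amalgamation weight used by the reconciliation likelihood: it lets the
dynamic program sum over every gene-tree topology assemblable from observed
clades instead of conditioning on a single tree.

Clades are stored as bitmasks over an internal leaf index, which makes
hashing exact and set operations cheap.  The full leaf set (the "root
clade") counts every edge of every tree as a potential root split; its
count is inflated by the edge multiplicity m = max(1, 2n - 3) so that the
stored conditionals still sum to one.  The likelihood multiplies its root
term by m to convert the mean over rootings into the sum over rootings that
the generative model implies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import InputError
from .treeio import LeafMap, Tree, TreeNode

__all__ = ["CCPTable", "build_ccp", "split_conditional"]


@dataclass
class CCPTable:
    """Clade and split observation counts for one gene family."""

    labels: list[str]                       # gene-leaf labels, index order
    n_trees: int
    root_mult: int                          # edges per tree: max(1, 2n-3)
    clade_counts: dict[int, float]          # bitmask -> count
    split_counts: dict[int, dict[tuple[int, int], float]]
    leaf_map: Optional[LeafMap] = None
    _compiled: dict = field(default_factory=dict, repr=False)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root_mask(self) -> int:
        return (1 << self.n_leaves) - 1

    def leaf_index(self) -> dict[str, int]:
        return {lbl: i for i, lbl in enumerate(self.labels)}

    def mask_of(self, leaves: Iterable[str]) -> int:
        idx = self.leaf_index()
        mask = 0
        for lbl in leaves:
            if lbl not in idx:
                raise InputError(f"unknown gene leaf {lbl!r}")
            mask |= 1 << idx[lbl]
        return mask

    def leaves_of(self, mask: int) -> frozenset:
        return frozenset(self.labels[i] for i in range(self.n_leaves) if mask >> i & 1)

    def clade_count(self, mask: int) -> float:
        return self.clade_counts.get(mask, 0.0)

    def splits_of(self, mask: int) -> list[tuple[int, int, float]]:
        """Observed splits of a clade as (left, right, q) with q conditional."""
        total = self.clade_counts.get(mask)
        if not total:
            return []
        out = []
        for (v, w), c in self.split_counts.get(mask, {}).items():
            out.append((v, w, c / total))
        return out

    def observed_clades(self) -> list[int]:
        """All clade bitmasks ordered by size then value (deterministic)."""
        return sorted(self.clade_counts, key=lambda m: (m.bit_count(), m))

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        def unmask(m: int) -> list[int]:
            return [i for i in range(self.n_leaves) if m >> i & 1]

        clades = []
        for mask in self.observed_clades():
            entry = {
                "leaves": unmask(mask),
                "count": self.clade_counts[mask],
                "splits": [
                    {"left": unmask(v), "right": unmask(w), "count": c}
                    for (v, w), c in sorted(self.split_counts.get(mask, {}).items())
                ],
            }
            clades.append(entry)
        return json.dumps(
            {
                "labels": self.labels,
                "n_trees": self.n_trees,
                "root_mult": self.root_mult,
                "clades": clades,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CCPTable":
        data = json.loads(text)

        def mask(idxs) -> int:
            m = 0
            for i in idxs:
                m |= 1 << i
            return m

        clade_counts: dict[int, float] = {}
        split_counts: dict[int, dict[tuple[int, int], float]] = {}
        for entry in data["clades"]:
            cm = mask(entry["leaves"])
            clade_counts[cm] = entry["count"]
            for sp in entry["splits"]:
                v, w = mask(sp["left"]), mask(sp["right"])
                if v > w:
                    v, w = w, v
                split_counts.setdefault(cm, {})[(v, w)] = sp["count"]
        return cls(
            labels=list(data["labels"]),
            n_trees=int(data["n_trees"]),
            root_mult=int(data["root_mult"]),
            clade_counts=clade_counts,
            split_counts=split_counts,
        )


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _unrooted_adjacency(tree: Tree) -> tuple[dict, dict]:
    """Adjacency map of the unrooted form of a tree.

    Returns (adj, leaf_label) keyed by node ids; a rooted (degree-2) outer
    node is suppressed so its two children become direct neighbours.
    """
    adj: dict[int, list[int]] = {}
    label: dict[int, str] = {}

    def visit(node: TreeNode):
        adj.setdefault(id(node), [])
        if node.is_leaf:
            label[id(node)] = node.label
        for c in node.children:
            adj[id(node)].append(id(c))
            adj.setdefault(id(c), []).append(id(node))
            visit(c)

    visit(tree.root)
    root = tree.root
    if len(root.children) == 2:
        a, b = (id(c) for c in root.children)
        adj[a] = [x for x in adj[a] if x != id(root)] + [b]
        adj[b] = [x for x in adj[b] if x != id(root)] + [a]
        del adj[id(root)]
    elif len(root.children) == 1:  # pragma: no cover - parse suppresses these
        raise InputError("unary outer node in gene tree")
    return adj, label


def build_ccp(
    trees: list[Tree],
    leaf_map: Optional[LeafMap] = None,
    smoothing: float = 0.0,
) -> CCPTable:
    """Count clades and splits over a sample of gene trees.

    Every tree is treated as unrooted; all trees must share one leaf-label
    set and be fully resolved.  `smoothing` > 0 adds a Laplace-style
    pseudocount to every observed split (off by default: conditionals are
    plain observed frequencies).
    """
    if not trees:
        raise InputError("empty gene-tree sample")
    labels = sorted(trees[0].leaf_labels())
    labelset = set(labels)
    if len(labelset) != len(labels):
        raise InputError("duplicate gene-leaf labels")
    idx = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)
    full = (1 << n) - 1
    root_mult = max(1, 2 * n - 3)

    clade_counts: dict[int, float] = {}
    split_counts: dict[int, dict[tuple[int, int], float]] = {}

    def add_split(cm: int, v: int, w: int, c: float = 1.0) -> None:
        if v > w:
            v, w = w, v
        split_counts.setdefault(cm, {})
        split_counts[cm][(v, w)] = split_counts[cm].get((v, w), 0.0) + c

    for t_i, tree in enumerate(trees):
        if set(tree.leaf_labels()) != labelset:
            raise InputError(f"tree {t_i} has a different leaf set than tree 0")
        if n == 1:
            clade_counts[full] = clade_counts.get(full, 0.0) + 1.0
            continue
        adj, leaf_label = _unrooted_adjacency(tree)
        for nid, nbrs in adj.items():
            deg = len(nbrs)
            if nid in leaf_label:
                if deg != 1:
                    raise InputError("leaf with degree != 1 in gene tree")
            elif deg != 3:
                raise InputError("gene trees must be fully resolved (binary)")

        # directed clade masks: clade[(x, y)] = leaves on the y side of x-y
        clade: dict[tuple[int, int], int] = {}

        def down(x: int, y: int) -> int:
            key = (x, y)
            if key in clade:
                return clade[key]
            if y in leaf_label:
                m = 1 << idx[leaf_label[y]]
            else:
                m = 0
                for z in adj[y]:
                    if z != x:
                        m |= down(y, z)
            clade[key] = m
            return m

        seen = set()
        seen_edges = []  # insertion-ordered: keeps summation order stable
        for x in adj:
            for y in adj[x]:
                down(x, y)
                key = (min(x, y), max(x, y))
                if key not in seen:
                    seen.add(key)
                    seen_edges.append(key)

        # each directed clade observed once per tree
        for (x, y), m in clade.items():
            clade_counts[m] = clade_counts.get(m, 0.0) + 1.0
            if y not in leaf_label:
                kids = [down(y, z) for z in adj[y] if z != x]
                add_split(m, kids[0], kids[1])
        # root clade: every edge is a candidate root split
        clade_counts[full] = clade_counts.get(full, 0.0) + float(root_mult)
        for x, y in seen_edges:
            side = clade[(x, y)]
            add_split(full, side, full & ~side)

    if smoothing > 0.0:
        for cm, splits in split_counts.items():
            for key in splits:
                splits[key] += smoothing
            clade_counts[cm] += smoothing * len(splits)

    return CCPTable(
        labels=labels,
        n_trees=len(trees),
        root_mult=root_mult,
        clade_counts=clade_counts,
        split_counts=split_counts,
        leaf_map=leaf_map,
    )


def split_conditional(table: CCPTable, clade: Iterable[str], split: Iterable[str]) -> float:
    """q(split | clade) for leaf-name sets; 0.0 for an unobserved split of an
    observed clade; raises InputError for a clade never observed."""
    cm = table.mask_of(clade)
    total = table.clade_counts.get(cm)
    if not total:
        raise InputError(f"clade {sorted(clade)} was never observed")
    sm = table.mask_of(split)
    other = cm & ~sm
    if sm | other != cm or sm & other:
        raise InputError("split is not a subset partition of the clade")
    v, w = (sm, other) if sm <= other else (other, sm)
    return table.split_counts.get(cm, {}).get((v, w), 0.0) / total
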