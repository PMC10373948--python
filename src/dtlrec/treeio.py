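"""Tree input/output and indexing.

Parses Newick (via dendropy), assigns stable integer branch IDs to rooted
binary species trees, enumerates candidate rootings of an unrooted tree,
and serialises reconciliation output: per-family plain-text reports and
event-annotated Newick strings for sampled reconciled gene trees.

Branch IDs are assigned in postorder with children ordered by their
lexicographically smallest descendant leaf, so the numbering is
deterministic across runs and platforms.  The root branch receives the
highest ID (N - 1, with N = 2 * leaves - 1).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .errors import InputError, NewickParseError, TreeStructureError

__all__ = [
    "TreeNode",
    "Tree",
    "SpeciesTree",
    "LeafMap",
    "GeneEventNode",
    "parse_newick",
    "write_newick",
    "read_newick_list",
    "index_species_tree",
    "enumerate_rootings",
    "unroot",
    "edge_adjacency",
    "normalize_edge",
    "format_event_newick",
    "parse_event_newick",
    "write_rec_report",
]


# ---------------------------------------------------------------------------
# Basic tree structure
# ---------------------------------------------------------------------------

class TreeNode:
    """A node of a (possibly unrooted) tree stored with parent/child links."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)


class Tree:
    """A tree with an outermost node.

    Rooted trees have a binary outermost node (degree 2); unrooted trees are
    stored with a single trifurcation at the outermost node.  Branch lengths
    are preserved but ignored by the undated model.
    """

    def __init__(self, root: TreeNode):
        self.root = root

    @property
    def rooted(self) -> bool:
        return len(self.root.children) != 3

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "Tree":
        def rec(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for c in node.children:
                new.add(rec(c))
            return new

        return Tree(rec(self.root))

    def is_binary(self) -> bool:
        """True if every internal node (root included) is binary."""
        for n in self.root.preorder():
            if n.children and len(n.children) != 2:
                return False
        return True

    def bipartitions(self) -> frozenset:
        """Normalised internal-edge bipartitions (unrooted-topology key)."""
        labels = sorted(self.leaf_labels())
        if len(labels) < 4:
            return frozenset()
        anchor = labels[0]
        full = frozenset(labels)
        bips = set()
        below: dict[int, frozenset] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        for node in self.root.preorder():
            if node is self.root:
                continue
            side = below[id(node)]
            if len(side) < 2 or len(side) > len(labels) - 2:
                continue
            bips.add(side if anchor not in side else full - side)
        return frozenset(bips)

    def newick(self, lengths: bool = True) -> str:
        return write_newick(self, lengths=lengths)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.newick()!r})"


_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}:;,'%]")


def _fmt_label(label: str) -> str:
    if _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, lengths: bool = True) -> str:
    """Serialise a Tree to a single Newick statement."""

    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            s = _fmt_label(node.label or "")
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.label:
                s += _fmt_label(node.label)
        if lengths and node.length is not None:
            s += f":{node.length:g}"
        return s

    return rec(tree.root) + ";"


def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into a Tree.

    Rootedness is inferred from the degree of the outermost node (2 children
    -> rooted, 3 -> unrooted).  Raises NewickParseError on malformed input,
    duplicate leaf labels, or empty input.
    """
    if text is None or not text.strip():
        raise NewickParseError("empty Newick input")
    s = text.strip()
    if not s.endswith(";"):
        raise NewickParseError(
            f"Newick statement must end with ';' (got ...{s[-10:]!r} at position {len(s)})"
        )
    try:
        dtree = dendropy.Tree.get(
            data=s,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer/parser errors
        raise NewickParseError(f"Newick parse failed: {exc}") from None

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = TreeNode(label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    root = convert(dtree.seed_node)
    # Suppress a unary outermost node (e.g. "((A,B));").
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    tree = Tree(root)
    labels = tree.leaf_labels()
    if any(lbl is None or lbl == "" for lbl in labels):
        raise NewickParseError("tree contains an unlabeled leaf")
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate leaf labels: {', '.join(dup)}")
    return tree


def read_newick_list(source) -> list[Tree]:
    """Read a multi-tree Newick file (one statement per line).

    `source` may be a path or a file-like object.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    trees = [parse_newick(line) for line in lines if line.strip()]
    if not trees:
        raise InputError("no trees found in input")
    return trees


# ---------------------------------------------------------------------------
# Species-tree indexing
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTree:
    """A rooted binary species tree with stable postorder branch IDs.

    Every node corresponds to one branch (the branch above it); the root
    branch is the origination slot above the root node.  Arrays `left` and
    `right` hold child branch IDs (-1 for leaves); `names[i]` is the leaf
    name for terminal branches and the decimal ID for internal ones.
    """

    tree: Tree
    n_branches: int
    left: np.ndarray
    right: np.ndarray
    parent: np.ndarray
    names: list[str]
    leaf_ids: dict[str, int]
    root_edge: Optional[frozenset] = None

    @property
    def root_id(self) -> int:
        return self.n_branches - 1

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def is_leaf_branch(self, branch_id: int) -> bool:
        return self.left[branch_id] < 0

    def branch_category(self, branch_id: int) -> str:
        if self.is_leaf_branch(branch_id):
            return "leaf"
        return "root" if branch_id == self.root_id else "internal"

    def newick(self, lengths: bool = True) -> str:
        return self.tree.newick(lengths=lengths)

    def clade_leaves(self, branch_id: int) -> frozenset:
        """Leaf names descending from a branch."""
        out = []
        stack = [branch_id]
        while stack:
            b = stack.pop()
            if self.left[b] < 0:
                out.append(self.names[b])
            else:
                stack.extend((int(self.left[b]), int(self.right[b])))
        return frozenset(out)


def _min_leaf(node: TreeNode, memo: dict) -> str:
    if id(node) in memo:
        return memo[id(node)]
    if node.is_leaf:
        val = node.label
    else:
        val = min(_min_leaf(c, memo) for c in node.children)
    memo[id(node)] = val
    return val


def index_species_tree(tree: Tree) -> SpeciesTree:
    """Assign deterministic postorder branch IDs to a rooted binary tree.

    Children are visited in order of their lexicographically smallest
    descendant leaf, so the assignment does not depend on the Newick child
    order of the input.  N = 2 * leaves - 1 branches.
    """
    if not tree.rooted:
        raise TreeStructureError("species tree must be rooted (outermost node of degree 2)")
    if not tree.is_binary():
        raise TreeStructureError("species tree must be binary at every internal node")
    tree = tree.copy()
    memo: dict = {}
    for node in tree.root.preorder():
        if not node.is_leaf:
            node.children.sort(key=lambda c: _min_leaf(c, memo))

    n_leaves = tree.n_leaves()
    n = 2 * n_leaves - 1
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    names: list[str] = [""] * n
    leaf_ids: dict[str, int] = {}

    counter = 0
    ids: dict[int, int] = {}

    def assign(node: TreeNode) -> int:
        nonlocal counter
        for c in node.children:
            assign(c)
        bid = counter
        counter += 1
        ids[id(node)] = bid
        if node.is_leaf:
            names[bid] = node.label
            leaf_ids[node.label] = bid
        else:
            names[bid] = str(bid)
            left[bid] = ids[id(node.children[0])]
            right[bid] = ids[id(node.children[1])]
            parent[left[bid]] = bid
            parent[right[bid]] = bid
        return bid

    assign(tree.root)
    return SpeciesTree(
        tree=tree, n_branches=n, left=left, right=right, parent=parent,
        names=names, leaf_ids=leaf_ids,
    )


# ---------------------------------------------------------------------------
# Rooting enumeration (unrooted tree -> candidate rooted species trees)
# ---------------------------------------------------------------------------

def normalize_edge(side: Iterable[str], all_labels: Iterable[str]) -> frozenset:
    """Canonical key for an unrooted-tree edge: the side NOT holding the
    alphabetically smallest leaf."""
    side = frozenset(side)
    labels = frozenset(all_labels)
    missing = side - labels
    if missing:
        raise InputError(f"unknown leaf names in edge spec: {sorted(missing)}")
    anchor = min(labels)
    return labels - side if anchor in side else side


def _edges_in_order(tree: Tree):
    """All edges (parent_node, child_node, child-side leafset) in preorder."""
    below: dict[int, frozenset] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    edges = []
    for node in tree.root.preorder():
        for c in node.children:
            edges.append((node, c, below[id(c)]))
    return edges


def enumerate_rootings(
    tree: Tree, candidates: Optional[Sequence[Iterable[str]]] = None
) -> list[SpeciesTree]:
    """Root an unrooted tree on each candidate branch.

    By default all 2n - 3 branches are used, in deterministic enumeration
    order (preorder of the stored structure).  `candidates` may restrict the
    set: each entry is the leaf set of either side of the desired branch.
    Each returned SpeciesTree carries `root_edge`, the normalised
    bipartition key of the branch it was rooted on.
    """
    if tree.rooted:
        raise TreeStructureError("enumerate_rootings expects an unrooted tree")
    if tree.n_leaves() < 3:
        raise TreeStructureError("need at least 3 leaves to enumerate rootings")
    labels = tree.leaf_labels()
    edges = _edges_in_order(tree)
    keyed = {normalize_edge(side, labels): (p, c) for p, c, side in edges}
    if candidates is None:
        order = [normalize_edge(side, labels) for _, _, side in edges]
    else:
        order = []
        for cand in candidates:
            key = normalize_edge(cand, labels)
            if key not in keyed:
                raise InputError(f"candidate branch not present in tree: {sorted(key)}")
            order.append(key)

    # adjacency over nodes for re-rooting
    out = []
    for key in order:
        pnode, cnode = keyed[key]
        rooted = _root_on_edge(tree, pnode, cnode)
        st = index_species_tree(rooted)
        st.root_edge = key
        out.append(st)
    return out


def _root_on_edge(tree: Tree, a: TreeNode, b: TreeNode) -> Tree:
    """Return a new rooted Tree with the root inserted on edge (a, b)."""
    adj: dict[int, list] = {}
    node_of: dict[int, TreeNode] = {}
    for node in tree.root.preorder():
        node_of[id(node)] = node
        adj.setdefault(id(node), [])
        for c in node.children:
            adj[id(node)].append((id(c), c.length))
            adj.setdefault(id(c), []).append((id(node), c.length))

    def build(nid: int, came_from: int, length) -> TreeNode:
        src = node_of[nid]
        new = TreeNode(src.label, length)
        for nbr, ln in adj[nid]:
            if nbr != came_from:
                new.add(build(nbr, nid, ln))
        return new

    elen = b.length
    half = elen / 2.0 if elen is not None else None
    root = TreeNode(None, None)
    root.add(build(id(a), id(b), half))
    root.add(build(id(b), id(a), half))
    return Tree(root)


def unroot(tree: Tree) -> Tree:
    """Suppress a degree-2 outermost node, yielding the unrooted topology.

    The root's two subtrees are joined on a single edge (lengths summed);
    the deeper subtree's top node becomes the stored trifurcation."""
    if not tree.rooted:
        return tree.copy()
    if tree.n_leaves() < 3:
        raise TreeStructureError("cannot unroot a tree with fewer than 3 leaves")
    t = tree.copy()
    a, b = t.root.children
    if a.is_leaf:
        a, b = b, a
    if a.length is not None and b.length is not None:
        b.length = a.length + b.length
    a.parent = None
    a.length = None
    a.add(b)
    return Tree(a)


def edge_adjacency(tree: Tree) -> dict[frozenset, set[frozenset]]:
    """Adjacency between edges of an unrooted tree (edges sharing a node)."""
    labels = tree.leaf_labels()
    edges = _edges_in_order(tree)
    incident: dict[int, list[frozenset]] = {}
    keys = []
    for p, c, side in edges:
        key = normalize_edge(side, labels)
        keys.append(key)
        incident.setdefault(id(p), []).append(key)
        incident.setdefault(id(c), []).append(key)
    out: dict[frozenset, set[frozenset]] = {k: set() for k in keys}
    for node_edges in incident.values():
        for k1 in node_edges:
            for k2 in node_edges:
                if k1 != k2:
                    out[k1].add(k2)
    return out


# ---------------------------------------------------------------------------
# Gene leaf -> species leaf mapping
# ---------------------------------------------------------------------------

@dataclass
class LeafMap:
    """Maps gene-leaf labels to species-leaf names.

    Default convention: the species name is the prefix of the gene label
    before the first `separator` (underscore).  An explicit mapping overrides
    the convention.
    """

    mapping: Optional[dict[str, str]] = None
    separator: str = "_"

    def species_of(self, gene_label: str) -> str:
        if self.mapping is not None:
            try:
                return self.mapping[gene_label]
            except KeyError:
                raise InputError(f"gene leaf {gene_label!r} missing from leaf map") from None
        if self.separator in gene_label:
            return gene_label.split(self.separator, 1)[0]
        return gene_label

    def validate(self, gene_labels: Iterable[str], species_leaves: Iterable[str]) -> None:
        species = set(species_leaves)
        for g in gene_labels:
            sp = self.species_of(g)
            if sp not in species:
                raise InputError(
                    f"gene leaf {g!r} maps to {sp!r}, which is not a species-tree leaf"
                )

    @classmethod
    def from_tsv(cls, source) -> "LeafMap":
        """Two-column TSV: gene label <tab> species name."""
        if hasattr(source, "read"):
            lines = source.read().splitlines()
        else:
            with open(source, "rt", encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        mapping = {}
        for i, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise InputError(f"leaf map line {i}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
        return cls(mapping=mapping)

    def to_tsv(self, gene_labels: Iterable[str]) -> str:
        rows = [f"{g}\t{self.species_of(g)}" for g in gene_labels]
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Event-annotated Newick (sampled reconciliations)
# ---------------------------------------------------------------------------

@dataclass
class GeneEventNode:
    """A node of a reconciled gene tree.

    `events` lists, in root-to-tip order, the events on the lineage leading
    into this node, ending (for internal nodes) with the node's own
    branching event.  Event tuples:

        ("O", branch)            origination
        ("S", branch)            speciation (both sides survive)
        ("SL", branch, lost)     speciation, sister copy lost on `lost`
        ("D", branch)            duplication
        ("T", donor, recipient)  transfer, donor copy survives (first child
                                 stays on the donor, second child is the
                                 transferred copy)
        ("TL", donor, recipient) transfer, donor copy lost
    """

    label: Optional[str] = None
    children: list["GeneEventNode"] = field(default_factory=list)
    events: list[tuple] = field(default_factory=list)

    def event_multiset(self):
        from collections import Counter

        cnt: Counter = Counter()
        stack = [self]
        while stack:
            n = stack.pop()
            cnt.update(n.events)
            stack.extend(n.children)
        return cnt


_EVENT_1 = {"O", "S", "D"}
_EVENT_2 = {"SL", "T", "TL"}


def _event_token(ev: tuple) -> str:
    kind = ev[0]
    if kind in _EVENT_1:
        return f"{kind}@{ev[1]}"
    if kind in _EVENT_2:
        return f"{kind}@{ev[1]}-{ev[2]}"
    raise InputError(f"unknown event type {kind!r}")


def _parse_event_token(tok: str) -> tuple:
    m = re.fullmatch(r"([A-Z]+)@(\d+)(?:-(\d+))?", tok)
    if not m:
        raise NewickParseError(f"malformed event token {tok!r}")
    kind, a, b = m.group(1), int(m.group(2)), m.group(3)
    if kind in _EVENT_1 and b is None:
        return (kind, a)
    if kind in _EVENT_2 and b is not None:
        return (kind, a, int(b))
    raise NewickParseError(f"event token {tok!r} has wrong arity for {kind}")


def format_event_newick(rec: GeneEventNode, st: Optional[SpeciesTree] = None) -> str:
    """Serialise a reconciled gene tree with inline event annotations.

    Grammar:  node := "(" node "," node ")" tags | leaf-label tags
              tags := ("%" EVENT "@" BRANCH ["-" BRANCH])*
    Events on the lineage into a node are attached to that node, in
    root-to-tip order.  If `st` is given, every referenced branch ID is
    checked against it.
    """

    def check(ev: tuple) -> None:
        if st is None:
            return
        for b in ev[1:]:
            if not (0 <= b < st.n_branches):
                raise InputError(f"event {ev} references unknown branch ID {b}")

    def rec_fmt(node: GeneEventNode) -> str:
        for ev in node.events:
            check(ev)
        tags = "".join("%" + _event_token(ev) for ev in node.events)
        if not node.children:
            return (node.label or "") + tags
        inner = ",".join(rec_fmt(c) for c in node.children)
        return "(" + inner + ")" + tags

    return rec_fmt(rec) + ";"


def parse_event_newick(text: str) -> GeneEventNode:
    """Parse the annotated-Newick grammar emitted by format_event_newick."""
    s = text.strip()
    if not s.endswith(";"):
        raise NewickParseError("annotated Newick must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str):
        raise NewickParseError(f"{msg} at position {pos}")

    def parse_node() -> GeneEventNode:
        nonlocal pos
        node = GeneEventNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                error("expected ')'")
            pos += 1
        else:
            start = pos
            while pos < len(s) and s[pos] not in "(),%;":
                pos += 1
            if pos == start:
                error("expected leaf label")
            node.label = s[start:pos]
        while pos < len(s) and s[pos] == "%":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),%;":
                pos += 1
            node.events.append(_parse_event_token(s[start:pos]))
        return node

    node = parse_node()
    if pos != len(s):
        error("trailing characters")
    return node


# ---------------------------------------------------------------------------
# Per-family reconciliation report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "category", "branch", "duplications", "transfers", "losses",
    "originations", "copies", "singletons", "presence",
]


def write_rec_report(summary) -> str:
    """Plain-text per-family reconciliation report.

    `summary` must provide: family (name), rates (delta/tau/lam attributes),
    loglik, n_samples, totals (dict with duplications/transfers/losses/
    speciations), sample_newicks (list of annotated Newick strings), and
    branch_table (pandas DataFrame with REPORT_COLUMNS).
    """
    buf = io.StringIO()
    r = summary.rates
    t = summary.totals
    buf.write("# dtlrec reconciliation report\n")
    buf.write(f"family:\t{summary.family}\n")
    buf.write(f"rates:\tdelta={r.delta:.10g}\ttau={r.tau:.10g}\tlambda={r.lam:.10g}\n")
    buf.write(f"loglik:\t{summary.loglik:.6f}\n")
    buf.write(f"n_samples:\t{summary.n_samples}\n")
    buf.write(
        "totals:\tduplications={:g}\ttransfers={:g}\tlosses={:g}\tspeciations={:g}\n".format(
            t["duplications"], t["transfers"], t["losses"], t["speciations"]
        )
    )
    buf.write("# sampled reconciliations (annotated Newick, one per line)\n")
    for line in summary.sample_newicks:
        buf.write(line + "\n")
    buf.write("# per-branch statistics (means over samples)\n")
    buf.write("\t".join(REPORT_COLUMNS) + "\n")
    table = summary.branch_table
    for _, row in table.iterrows():
        cells = [str(row["category"]), str(row["branch"])]
        cells += [f"{row[c]:g}" for c in REPORT_COLUMNS[2:]]
        buf.write("\t".join(cells) + "\n")
    return buf.getvalue()
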