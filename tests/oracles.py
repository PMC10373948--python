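"""Independent oracles used by the test suite.

These deliberately avoid the package's amalgamation dynamic program:

* `direct_unrooted_loglik` scores a single fixed gene tree by enumerating
  its rootings explicitly and solving each gene node's cross-branch linear
  system exactly with numpy (no CCP table, no Jacobi sweeps).
* `enumerate_observable_histories` expands the forward generative process
  event by event with a probability floor, conditions on an observed tip
  configuration, and projects every history onto its observable event
  signature — an exhaustive posterior for tiny instances.
* `ccp_expansion_total` recursively expands a CCP table over all
  amalgamated rooted trees (normalisation check) and
  `ccp_unrooted_tree_probability` scores one unrooted topology under it.
"""

from collections import Counter

import numpy as np

from dtlrec.dtlmodel import DTLRates, event_probabilities, extinction_probabilities
from dtlrec.treeio import SpeciesTree, Tree, TreeNode


# ---------------------------------------------------------------------------
# Direct (non-CCP) likelihood of one fixed gene tree
# ---------------------------------------------------------------------------

def _gene_rootings(tree: Tree):
    """All rooted versions of a gene tree (root inserted on each edge)."""
    leaves = tree.leaf_labels()
    if len(leaves) == 1:
        yield tree.copy().root
        return
    # adjacency of the unrooted form
    adj = {}
    label = {}

    def visit(node):
        adj.setdefault(id(node), [])
        if node.is_leaf:
            label[id(node)] = node.label
        for c in node.children:
            adj[id(node)].append(id(c))
            adj.setdefault(id(c), []).append(id(node))
            visit(c)

    visit(tree.root)
    if len(tree.root.children) == 2:
        a, b = (id(c) for c in tree.root.children)
        adj[a] = [x for x in adj[a] if x != id(tree.root)] + [b]
        adj[b] = [x for x in adj[b] if x != id(tree.root)] + [a]
        del adj[id(tree.root)]

    def build(nid, came):
        node = TreeNode(label.get(nid))
        for nbr in adj[nid]:
            if nbr != came:
                node.add(build(nbr, nid))
        return node

    seen = set()
    for x in adj:
        for y in adj[x]:
            key = (min(x, y), max(x, y))
            if key in seen:
                continue
            seen.add(key)
            root = TreeNode(None)
            root.add(build(x, y))
            root.add(build(y, x))
            yield root


def direct_unrooted_loglik(
    st: SpeciesTree, gene_tree: Tree, species_of: dict, rates: DTLRates,
    prior=None,
) -> float:
    """log P(observed unrooted gene tree) by explicit sum over rootings.

    Each gene node's P(node, .) satisfies a linear system over species
    branches (SL descent, invisible duplications/transfers, and the
    transfer-with-donor-loss coupling); it is solved exactly.
    """
    ep = event_probabilities(rates)
    ext = extinction_probabilities(st, ep)
    E, Ebar = ext.E, ext.Ebar
    N = st.n_branches
    if prior is None:
        prior = np.full(N, 1.0 / N)
    nrec = N - 1 if N > 1 else 1

    # cross-branch coupling matrix, identical for every gene node
    M = np.zeros((N, N))
    for e in range(N):
        M[e, e] += 2.0 * ep.pD * E[e] + ep.pT * Ebar[e]
        if N > 1:
            for h in range(N):
                if h != e:
                    M[e, h] += ep.pT * E[e] / nrec
        f, g = int(st.left[e]), int(st.right[e])
        if f >= 0:
            M[e, f] += ep.pS * E[g]
            M[e, g] += ep.pS * E[f]
    A = np.eye(N) - M

    def node_prob(gnode) -> np.ndarray:
        b = np.zeros(N)
        if gnode.is_leaf:
            b[st.leaf_ids[species_of[gnode.label]]] = ep.pS
        else:
            p1 = node_prob(gnode.children[0])
            p2 = node_prob(gnode.children[1])
            t1 = (p1.sum() - p1) / nrec
            t2 = (p2.sum() - p2) / nrec
            for e in range(N):
                b[e] = ep.pD * p1[e] * p2[e]
                if N > 1:
                    b[e] += ep.pT * (p1[e] * t2[e] + p2[e] * t1[e])
                f, g = int(st.left[e]), int(st.right[e])
                if f >= 0:
                    b[e] += ep.pS * (p1[f] * p2[g] + p1[g] * p2[f])
        return np.linalg.solve(A, b)

    total = 0.0
    for root in _gene_rootings(gene_tree):
        if len(root.children) == 2:
            # score the rooted tree: its root is an ordinary gene node
            x = node_prob(root)
        else:
            x = node_prob(root)
        total += float(prior @ x)
    return float(np.log(total)) if total > 0 else float("-inf")


# ---------------------------------------------------------------------------
# Exhaustive forward-history enumeration (tiny instances)
# ---------------------------------------------------------------------------

def enumerate_observable_histories(
    st: SpeciesTree,
    rates: DTLRates,
    target_tips: dict,
    floor: float = 1e-9,
):
    """Exhaustive posterior over observable event signatures.

    Expands the generative process from every origination branch (uniform
    prior), dropping partial histories whose probability falls below
    `floor`, keeps those whose sampled tips match `target_tips` (species
    branch id -> copy count), and accumulates probability by the sorted
    tuple of observable events (same projection as the simulator and the
    same vocabulary as the sampler).  Returns (signature -> probability,
    truncated mass).
    """
    ep = event_probabilities(rates)
    ext = extinction_probabilities(st, ep)
    E = ext.E
    N = st.n_branches
    nrec = N - 1 if N > 1 else 1
    truncated = [0.0]

    def expand(e: int, cap: float):
        """Fates of one copy entering branch e with path probability cap.

        Yields (prob, tips Counter, observable events tuple).  The entire
        extinct fate class is emitted as a single outcome of exact mass
        cap * E(e) (E is verified separately against closed forms), so the
        explicit recursion only follows surviving structure plus the
        geometrically decaying invisible-event chains; sub-fate
        combinations in which every copy dies are skipped so that mass is
        not counted twice."""
        if cap < floor:
            truncated[0] += cap
            return
        # all descendants die: closed form
        yield cap * E[e], Counter(), ()
        # speciation / sampling
        f, g = int(st.left[e]), int(st.right[e])
        if f < 0:
            yield cap * ep.pS, Counter({e: 1}), ()
        else:
            for p1, t1, ev1 in expand(f, cap * ep.pS):
                for p2, t2, ev2 in expand(g, p1):
                    if t1 and t2:
                        ev = (("S", e),)
                    elif t1:
                        ev = (("SL", e, g),)
                    elif t2:
                        ev = (("SL", e, f),)
                    else:
                        continue
                    yield p2, t1 + t2, ev1 + ev2 + ev
        # duplication (invisible when one copy leaves no descendants)
        for p1, t1, ev1 in expand(e, cap * ep.pD):
            for p2, t2, ev2 in expand(e, p1):
                if not (t1 or t2):
                    continue
                ev = (("D", e),) if (t1 and t2) else ()
                yield p2, t1 + t2, ev1 + ev2 + ev
        # transfer (invisible when the recipient copy dies out)
        if N > 1 and ep.pT > 0:
            for h in range(N):
                if h == e:
                    continue
                for p1, t1, ev1 in expand(e, cap * ep.pT / nrec):
                    for p2, t2, ev2 in expand(h, p1):
                        if t1 and t2:
                            ev = (("T", e, h),)
                        elif t2:
                            ev = (("TL", e, h),)
                        elif t1:
                            ev = ()
                        else:
                            continue
                        yield p2, t1 + t2, ev1 + ev2 + ev

    target = Counter(target_tips)
    acc: dict = {}
    for e0 in range(N):
        for p, tips, ev in expand(e0, 1.0 / N):
            if tips == target:
                sig = tuple(sorted(ev + (("O", e0),)))
                acc[sig] = acc.get(sig, 0.0) + p
    return acc, truncated[0]


# ---------------------------------------------------------------------------
# CCP expansion oracles
# ---------------------------------------------------------------------------

def ccp_expansion_total(table) -> float:
    """Total probability of the amalgamated rooted-tree distribution."""
    memo: dict = {}

    def f(mask: int) -> float:
        if mask.bit_count() == 1:
            return 1.0
        if mask in memo:
            return memo[mask]
        val = sum(q * f(v) * f(w) for v, w, q in table.splits_of(mask))
        memo[mask] = val
        return val

    return f(table.root_mask)


def ccp_unrooted_tree_probability(table, tree: Tree) -> float:
    """Probability of one unrooted topology under the amalgamated
    distribution: sum of its rootings' probabilities."""
    from dtlrec.ccp import build_ccp

    single = build_ccp([tree])  # convenient edge/split extraction
    remap = {}
    for i, lbl in enumerate(single.labels):
        remap[1 << i] = 1 << table.labels.index(lbl)

    def conv(mask: int) -> int:
        out = 0
        for i in range(mask.bit_length()):
            if mask >> i & 1:
                out |= remap[1 << i]
        return out

    def rooted(mask: int) -> float:
        if mask.bit_count() == 1:
            return 1.0
        splits = single.splits_of(mask)
        assert len(splits) == 1
        v, w, _ = splits[0]
        cm = conv(mask)
        q = 0.0
        cv, cw = conv(v), conv(w)
        for tv, tw, tq in table.splits_of(cm):
            if {tv, tw} == {cv, cw}:
                q = tq
        return q * rooted(v) * rooted(w)

    total = 0.0
    for v, w, _ in single.splits_of(single.root_mask):
        cm = table.root_mask
        cv, cw = conv(v), conv(w)
        q = 0.0
        for tv, tw, tq in table.splits_of(cm):
            if {tv, tw} == {cv, cw}:
                q = tq
        total += q * rooted(v) * rooted(w)
    return total
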