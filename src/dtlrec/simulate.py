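"""Forward simulation of gene families under the undated DTL process.

The simulator implements exactly the generative model the likelihood is
derived from: a family originates on a branch drawn from the origination
prior, and every copy on a branch draws one event — speciation/vertical
descent (advance to both children, or be sampled at a tip), duplication
(fork on the same branch), transfer (copy to a uniformly chosen other
branch while the donor continues), or loss.  Ground-truth event logs and
per-branch tallies are retained, which makes the simulator the validation
oracle for every inference module.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .dtlmodel import DTLRates, ModelConfig, event_probabilities
from .errors import InputError, NumericalError
from .treeio import LeafMap, SpeciesTree, Tree, TreeNode

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "Dataset",
    "simulate_family",
    "simulate_dataset",
    "observable_events",
    "simulate_presence_patterns",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults: uniform origination, survivors-only filtering ON (only
    observable families reach inference; the discard count stays reported
    so the extinction fraction remains testable), no copy-number ceiling,
    and a 10,000-event cap flagging super-critical parameter draws.
    """

    rates: DTLRates = field(default_factory=lambda: DTLRates(0.05, 0.3, 0.1))
    origination: object = "uniform"
    survivors_only: bool = True
    min_copies: int = 1
    max_copies: Optional[int] = None
    max_events: int = 10_000
    seed: int = 0

    def model_config(self) -> ModelConfig:
        return ModelConfig(origination=self.origination)

    def echo(self) -> str:
        """YAML-style key: value dump sufficient to reproduce the run."""
        lines = [
            f"delta: {self.rates.delta!r}",
            f"tau: {self.rates.tau!r}",
            f"lambda: {self.rates.lam!r}",
            f"origination: {self.origination!r}",
            f"survivors_only: {self.survivors_only}",
            f"min_copies: {self.min_copies}",
            f"max_copies: {self.max_copies}",
            f"max_events: {self.max_events}",
            f"seed: {self.seed}",
        ]
        return "\n".join(lines) + "\n"


class _Lineage:
    __slots__ = ("branch", "kind", "children", "label", "recipient")

    def __init__(self, branch: int):
        self.branch = branch
        self.kind = None          # "S" | "D" | "T" | "L" | "tip"
        self.children: list["_Lineage"] = []
        self.label: Optional[str] = None
        self.recipient: Optional[int] = None  # for T: branch of children[1]


@dataclass
class SimulatedFamily:
    """One simulated family with its full ground truth."""

    gene_tree: Optional[Tree]          # None when the family went extinct
    leaf_map: LeafMap
    origination_branch: int
    events: list[tuple]                # raw log: (O,e) (S,e) (D,e) (T,d,r) (L,e)
    n_tips: int
    capped: bool
    _root: Optional[_Lineage] = field(default=None, repr=False)

    @property
    def extinct(self) -> bool:
        return self.n_tips == 0

    def branch_counts(self, st: SpeciesTree) -> pd.DataFrame:
        """Per-branch true counts of D, T received, T donated, L, origination."""
        n = st.n_branches
        cols = {k: np.zeros(n) for k in
                ("duplications", "transfers_in", "transfers_out", "losses", "originations")}
        for ev in self.events:
            if ev[0] == "D":
                cols["duplications"][ev[1]] += 1
            elif ev[0] == "T":
                cols["transfers_out"][ev[1]] += 1
                cols["transfers_in"][ev[2]] += 1
            elif ev[0] == "L":
                cols["losses"][ev[1]] += 1
            elif ev[0] == "O":
                cols["originations"][ev[1]] += 1
        df = pd.DataFrame(cols)
        df.insert(0, "branch", [st.names[i] for i in range(n)])
        return df

    def event_totals(self) -> Counter:
        return Counter(ev[0] for ev in self.events)


def simulate_family(
    st: SpeciesTree,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedFamily:
    """Simulate one family; fully reproducible from cfg.seed when rng is None."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ep = event_probabilities(cfg.rates)
    prior = cfg.model_config().origination_prior(st)
    n = st.n_branches

    e0 = int(rng.choice(n, p=prior))
    root = _Lineage(e0)
    events: list[tuple] = [("O", e0)]
    stack = [root]
    capped = False
    n_events = 0
    tip_count: Counter = Counter()

    while stack:
        lin = stack.pop()
        e = lin.branch
        r = rng.random()
        n_events += 1
        if n_events > cfg.max_events:
            capped = True
            break
        if r < ep.pS:
            f = int(st.left[e])
            if f < 0:  # terminal branch: speciation slot = sampling
                lin.kind = "tip"
                tip_count[e] += 1
                lin.label = f"{st.names[e]}_{tip_count[e]}"
            else:
                lin.kind = "S"
                events.append(("S", e))
                lin.children = [_Lineage(f), _Lineage(int(st.right[e]))]
                stack.extend(lin.children)
        elif r < ep.pS + ep.pD:
            lin.kind = "D"
            events.append(("D", e))
            lin.children = [_Lineage(e), _Lineage(e)]
            stack.extend(lin.children)
        elif r < ep.pS + ep.pD + ep.pT:
            if n > 1:
                h = int(rng.integers(n - 1))
                if h >= e:
                    h += 1
                lin.kind = "T"
                lin.recipient = h
                events.append(("T", e, h))
                lin.children = [_Lineage(e), _Lineage(h)]
                stack.extend(lin.children)
            else:  # no recipient exists: the draw falls through to loss
                lin.kind = "L"
                events.append(("L", e))
        else:
            lin.kind = "L"
            events.append(("L", e))

    gene_tree, n_tips, mapping = _observed_tree(root, st)
    return SimulatedFamily(
        gene_tree=gene_tree,
        leaf_map=LeafMap(mapping=mapping or None),
        origination_branch=e0,
        events=events,
        n_tips=n_tips,
        capped=capped,
        _root=root,
    )


def _observed_tree(root: _Lineage, st: SpeciesTree):
    """Prune extinct lineages and suppress unary nodes -> observed gene tree.

    Iterative post-order: lineage trees can be thousands of events deep."""
    built: dict[int, Optional[TreeNode]] = {}
    stack: list[tuple[_Lineage, bool]] = [(root, False)]
    while stack:
        lin, done = stack.pop()
        if not done:
            stack.append((lin, True))
            for c in lin.children:
                stack.append((c, False))
            continue
        if lin.kind == "tip":
            built[id(lin)] = TreeNode(lin.label)
            continue
        kids = [built[id(c)] for c in lin.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            built[id(lin)] = None
        elif len(kids) == 1:
            built[id(lin)] = kids[0]
        else:
            node = TreeNode()
            for k in kids:
                k.parent = None
                node.add(k)
            built[id(lin)] = node

    top = built[id(root)]
    if top is None:
        return None, 0, {}
    tree = Tree(top)
    labels = tree.leaf_labels() if top.children or top.label else []
    mapping = {}
    for lbl in labels:
        mapping[lbl] = lbl.rsplit("_", 1)[0]
    return tree, len(labels), mapping


def observable_events(fam: SimulatedFamily) -> list[tuple]:
    """Project the raw event log onto the observable history.

    Events on lineages with no sampled descendants vanish; a speciation with
    one extinct side becomes SL (the loss charged to the extinct child
    branch), a transfer whose donor side died becomes TL, and duplications
    or transfers with only one surviving side disappear entirely.  The
    result uses the same vocabulary as sampled reconciliations, so forward
    simulation can be compared against posterior sampling event for event.
    """
    if fam._root is None:
        raise InputError("family lacks its lineage record")

    surv: dict[int, bool] = {}
    post: list[tuple[_Lineage, bool]] = [(fam._root, False)]
    while post:
        lin, done = post.pop()
        if not done:
            post.append((lin, True))
            for c in lin.children:
                post.append((c, False))
            continue
        if lin.kind == "tip":
            surv[id(lin)] = True
        elif lin.kind == "L" or lin.kind is None:
            surv[id(lin)] = False
        else:
            surv[id(lin)] = any(surv[id(c)] for c in lin.children)

    if not surv[id(fam._root)]:
        return []

    out: list[tuple] = [("O", fam.origination_branch)]
    todo = [fam._root]
    while todo:
        lin = todo.pop()
        if lin.kind in ("tip", "L", None):
            continue
        e = lin.branch
        a, b = lin.children
        sa, sb = surv[id(a)], surv[id(b)]
        if lin.kind == "S":
            if sa and sb:
                out.append(("S", e))
            elif sa or sb:
                lost = b.branch if sa else a.branch
                out.append(("SL", e, lost))
        elif lin.kind == "D":
            if sa and sb:
                out.append(("D", e))
        elif lin.kind == "T":
            if sa and sb:
                out.append(("T", e, lin.recipient))
            elif sb:
                out.append(("TL", e, lin.recipient))
        for c in lin.children:
            if surv[id(c)]:
                todo.append(c)
    return out


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    families: list[SimulatedFamily]
    truth: pd.DataFrame
    n_attempts: int
    n_extinct: int
    n_filtered: int
    n_capped: int
    config: SimulationConfig

    def family_names(self) -> list[str]:
        return list(self.truth["family"])


def simulate_dataset(
    st: SpeciesTree,
    n_families: int,
    cfg: SimulationConfig,
    acceptance_floor: float = 1e-3,
) -> Dataset:
    """Simulate until `n_families` pass the survivors/copy-number filters.

    Aborts with a diagnostic if the acceptance rate drops below
    `acceptance_floor` (checked after 1,000 attempts).
    """
    if n_families < 1:
        raise InputError("n_families must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    kept: list[SimulatedFamily] = []
    rows = []
    attempts = extinct = filtered = capped = 0
    while len(kept) < n_families:
        attempts += 1
        if attempts > 1000 and len(kept) / attempts < acceptance_floor:
            raise NumericalError(
                f"acceptance rate {len(kept)}/{attempts} below floor "
                f"{acceptance_floor}; check rates/filters"
            )
        fam = simulate_family(st, cfg, rng)
        if fam.capped:
            capped += 1
            continue
        if cfg.survivors_only and fam.extinct:
            extinct += 1
            continue
        if fam.n_tips < cfg.min_copies or (
            cfg.max_copies is not None and fam.n_tips > cfg.max_copies
        ):
            filtered += 1
            continue
        kept.append(fam)
        totals = fam.event_totals()
        rows.append(
            {
                "family": f"fam{len(kept):04d}",
                "delta": cfg.rates.delta,
                "tau": cfg.rates.tau,
                "lambda": cfg.rates.lam,
                "origination_branch": fam.origination_branch,
                "n_tips": fam.n_tips,
                "n_duplications": totals.get("D", 0),
                "n_transfers": totals.get("T", 0),
                "n_losses": totals.get("L", 0),
            }
        )
    truth = pd.DataFrame(rows)
    return Dataset(
        families=kept, truth=truth, n_attempts=attempts, n_extinct=extinct,
        n_filtered=filtered, n_capped=capped, config=cfg,
    )


def write_dataset(ds: Dataset, outdir) -> None:
    """One Newick gene tree per family, a leaf-map TSV, the truth table and
    a config echo."""
    import os

    os.makedirs(outdir, exist_ok=True)
    map_lines = []
    for name, fam in zip(ds.family_names(), ds.families):
        with open(os.path.join(outdir, f"{name}.nwk"), "wt", encoding="utf-8") as fh:
            fh.write(fam.gene_tree.newick(lengths=False) + "\n")
        for lbl in fam.gene_tree.leaf_labels():
            map_lines.append(f"{lbl}\t{fam.leaf_map.species_of(lbl)}")
    with open(os.path.join(outdir, "leafmap.tsv"), "wt", encoding="utf-8") as fh:
        fh.write("\n".join(map_lines) + "\n")
    ds.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "config.yaml"), "wt", encoding="utf-8") as fh:
        fh.write(ds.config.echo())
        fh.write(f"n_attempts: {ds.n_attempts}\n")
        fh.write(f"n_extinct: {ds.n_extinct}\n")
        fh.write(f"n_filtered: {ds.n_filtered}\n")
        fh.write(f"n_capped: {ds.n_capped}\n")


# ---------------------------------------------------------------------------
# Fast presence-pattern path (million-replicate distributional checks)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sim_patterns(left, right, leafbit, pD, pT, pL, n_sims, seed, max_events):
    """Presence-pattern outcomes of n_sims forward simulations.

    Codes: -1 extinct; -2 some species with >1 sampled copy (or event cap
    hit); otherwise the bitmask of species with exactly one copy.
    """
    np.random.seed(seed)
    N = left.shape[0]
    n_leaves = 0
    for e in range(N):
        if left[e] < 0:
            n_leaves += 1
    out = np.empty(n_sims, dtype=np.int64)
    stack = np.empty(4096, dtype=np.int64)
    counts = np.zeros(n_leaves, dtype=np.int64)
    pS = 1.0 - pD - pT - pL
    for i in range(n_sims):
        for b in range(n_leaves):
            counts[b] = 0
        top = 0
        stack[top] = np.random.randint(0, N)  # uniform origination
        top += 1
        nev = 0
        bad = False
        while top > 0:
            top -= 1
            e = stack[top]
            nev += 1
            if nev > max_events or top > 4090:
                bad = True
                break
            r = np.random.random()
            if r < pS:
                f = left[e]
                if f < 0:
                    counts[leafbit[e]] += 1
                else:
                    stack[top] = f
                    stack[top + 1] = right[e]
                    top += 2
            elif r < pS + pD:
                stack[top] = e
                stack[top + 1] = e
                top += 2
            elif r < pS + pD + pT:
                if N > 1:
                    h = np.random.randint(0, N - 1)
                    if h >= e:
                        h += 1
                    stack[top] = e
                    stack[top + 1] = h
                    top += 2
            # else: loss, copy just dies
        if bad:
            out[i] = -2
            continue
        mask = 0
        multi = False
        total = 0
        for b in range(n_leaves):
            total += counts[b]
            if counts[b] == 1:
                mask |= 1 << b
            elif counts[b] > 1:
                multi = True
        if total == 0:
            out[i] = -1
        elif multi:
            out[i] = -2
        else:
            out[i] = mask
    return out


def simulate_presence_patterns(
    st: SpeciesTree, rates: DTLRates, n_sims: int, seed: int, max_events: int = 10_000
) -> np.ndarray:
    """Vectorised forward simulation reporting only presence patterns.

    Returns one code per simulation: -1 extinct, -2 any species with more
    than one sampled copy, else the bitmask over leaf branches (bit order =
    `leaf_bit_order(st)`).  Uses a uniform origination prior.
    """
    ep = event_probabilities(rates)
    leafbit = np.full(st.n_branches, -1, dtype=np.int64)
    b = 0
    for e in range(st.n_branches):
        if st.left[e] < 0:
            leafbit[e] = b
            b += 1
    return _sim_patterns(
        st.left, st.right, leafbit, ep.pD, ep.pT, ep.pL,
        n_sims, seed % (2**31), max_events,
    )


def leaf_bit_order(st: SpeciesTree) -> list[str]:
    """Leaf names in the bit order used by simulate_presence_patterns."""
    return [st.names[e] for e in range(st.n_branches) if st.left[e] < 0]
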