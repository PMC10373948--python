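"""Sampling reconciled gene trees and summarising per-branch events.

Histories are drawn by stochastic backtracking through the likelihood
dynamic program: the origination branch is drawn proportionally to
prior x root-clade likelihood, and at every (clade, branch) state one of
the terms composing P(u, e) is drawn proportionally to its contribution.
Unobservable event chains (a duplication whose second copy went extinct, a
transfer into a doomed recipient) are geometric self-loops already folded
into the DP denominators, so they are marginalised analytically and never
appear in sampled histories; every event in a sample shaped the observed
gene tree.

Event vocabulary (shared with the forward simulator's observable
projection): O origination, S speciation, SL speciation + loss of the
sister copy, D duplication, T transfer (donor copy survives), TL transfer
(donor copy lost).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ccp import CCPTable
from .dtlmodel import DPResult, DTLRates, ModelConfig, DEFAULT_CONFIG, compute_dp
from .errors import InputError
from .treeio import (
    GeneEventNode,
    LeafMap,
    SpeciesTree,
    format_event_newick,
    REPORT_COLUMNS,
)

__all__ = [
    "SampledReconciliation",
    "BranchEventSummary",
    "FamilyReconciliationSummary",
    "sample_reconciliations",
    "summarize_branch_events",
    "aggregate_summaries",
    "verticality",
    "transfer_duplication_ratio",
    "reconcile_family",
]


@dataclass
class SampledReconciliation:
    """One sampled event history mapped onto species branches."""

    events: list[tuple]                    # in sampled (root-to-tip) order
    root: Optional[GeneEventNode]          # reconciled gene tree with tags
    origination_branch: int
    tip_branches: list[int]                # species branch of each sampled tip
    posterior_logprob: float               # log P(history | data, rates)

    def newick(self, st: Optional[SpeciesTree] = None) -> str:
        if self.root is None:
            raise InputError("sample has no gene-tree record")
        return format_event_newick(self.root, st)

    def event_totals(self) -> Counter:
        return Counter(ev[0] for ev in self.events)


def _draw(rng: np.random.Generator, weights: list[float]) -> tuple[int, float]:
    total = math.fsum(weights)
    if not (total > 0.0) or not math.isfinite(total):
        raise InputError("zero-probability state reached while backtracking")
    r = rng.random() * total
    acc = 0.0
    for i, w in enumerate(weights):
        acc += w
        if r <= acc:
            return i, math.log(w / total)
    return len(weights) - 1, math.log(weights[-1] / total)


def sample_reconciliations(
    st: SpeciesTree,
    ccp: CCPTable,
    rates: DTLRates,
    n: int,
    seed: int,
    cfg: ModelConfig = DEFAULT_CONFIG,
    leaf_map: Optional[LeafMap] = None,
    dp: Optional[DPResult] = None,
) -> list[SampledReconciliation]:
    """Draw n independent reconciled histories under the joint likelihood.

    Reproducible given `seed`.  Raises InputError when the family has zero
    likelihood under `rates` (there is nothing to sample).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if dp is None:
        dp = compute_dp(st, ccp, rates, cfg, leaf_map)
    if not math.isfinite(dp.loglik):
        raise InputError("family likelihood is zero under these rates; cannot sample")

    rng = np.random.default_rng(seed)
    P, ell = dp.P, dp.ell
    comp = dp.compiled
    E = dp.ext.E
    Ebar = dp.ext.Ebar
    ep = dp.ep
    N = st.n_branches
    nrec = N - 1 if N > 1 else 1
    tots = P.sum(axis=1)
    left, right = st.left, st.right
    root_row = comp.n_clades - 1
    leaf_label_of = {}  # singleton clade row -> gene leaf label
    for i, m in enumerate(comp.masks):
        if m.bit_count() == 1:
            leaf_label_of[i] = comp.labels[m.bit_length() - 1]

    def splits_of(u: int):
        s0, s1 = comp.cstart[u], comp.cstart[u + 1]
        for s in range(s0, s1):
            v, w = int(comp.sv[s]), int(comp.sw[s])
            yield v, w, comp.sq[s] * math.exp(ell[v] + ell[w] - ell[u])

    def draw_recipient(row: int, donor: int) -> tuple[int, float]:
        weights = [P[row, h] if h != donor else 0.0 for h in range(N)]
        h, lp = _draw(rng, weights)
        return h, lp

    out = []
    for _ in range(n):
        events: list[tuple] = []
        logp = 0.0

        def visit(u: int, e: int, pending: list[tuple]) -> GeneEventNode:
            nonlocal logp
            while True:
                f, g = int(left[e]), int(right[e])
                weights: list[float] = []
                actions: list[tuple] = []
                for v, w, fac in splits_of(u):
                    if f >= 0:
                        weights.append(ep.pS * fac * P[v, f] * P[w, g])
                        actions.append(("S", v, f, w, g))
                        weights.append(ep.pS * fac * P[v, g] * P[w, f])
                        actions.append(("S", v, g, w, f))
                    weights.append(ep.pD * fac * P[v, e] * P[w, e])
                    actions.append(("D", v, w))
                    if N > 1:
                        weights.append(ep.pT * fac * P[v, e] * (tots[w] - P[w, e]) / nrec)
                        actions.append(("T", v, w))  # v stays on e, w moves
                        weights.append(ep.pT * fac * P[w, e] * (tots[v] - P[v, e]) / nrec)
                        actions.append(("T", w, v))
                if f >= 0:
                    weights.append(ep.pS * P[u, f] * E[g])
                    actions.append(("SL", f, g))
                    weights.append(ep.pS * P[u, g] * E[f])
                    actions.append(("SL", g, f))
                elif comp.single_branch[u] == e:
                    weights.append(ep.pS * math.exp(-ell[u]))
                    actions.append(("tip",))
                if N > 1:
                    weights.append(ep.pT * E[e] * (tots[u] - P[u, e]) / nrec)
                    actions.append(("TL",))

                i, lp = _draw(rng, weights)
                logp += lp
                act = actions[i]
                kind = act[0]
                if kind == "tip":
                    node = GeneEventNode(label=leaf_label_of[u], events=list(pending))
                    tip_branches.append(e)
                    return node
                if kind == "S":
                    _, v, bf, w, bg = act
                    ev = ("S", e)
                    events.append(ev)
                    node = GeneEventNode(events=list(pending) + [ev])
                    node.children.append(visit(v, bf, []))
                    node.children.append(visit(w, bg, []))
                    return node
                if kind == "D":
                    _, v, w = act
                    ev = ("D", e)
                    events.append(ev)
                    node = GeneEventNode(events=list(pending) + [ev])
                    node.children.append(visit(v, e, []))
                    node.children.append(visit(w, e, []))
                    return node
                if kind == "T":
                    _, v, w = act
                    h, lp2 = draw_recipient(w, e)
                    logp += lp2
                    ev = ("T", e, h)
                    events.append(ev)
                    node = GeneEventNode(events=list(pending) + [ev])
                    node.children.append(visit(v, e, []))   # donor side first
                    node.children.append(visit(w, h, []))
                    return node
                if kind == "SL":
                    cont, lost = act[1], act[2]
                    ev = ("SL", e, lost)
                    events.append(ev)
                    pending = list(pending) + [ev]
                    e = cont
                    continue
                # TL: lineage moves, donor copy lost
                h, lp2 = draw_recipient(u, e)
                logp += lp2
                ev = ("TL", e, h)
                events.append(ev)
                pending = list(pending) + [ev]
                e = h

        tip_branches: list[int] = []
        w0 = [dp.prior[e] * P[root_row, e] for e in range(N)]
        e0, lp0 = _draw(rng, w0)
        logp += lp0
        events.append(("O", e0))
        root = visit(root_row, e0, [("O", e0)])
        out.append(
            SampledReconciliation(
                events=events, root=root, origination_branch=e0,
                tip_branches=tip_branches, posterior_logprob=logp,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Per-branch summaries
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "category", "branch", "duplications", "transfers", "losses",
    "originations", "copies", "singletons", "presence", "vertical",
]


@dataclass
class BranchEventSummary:
    """Mean per-branch event statistics.

    `table` has one row per species branch.  For a single family the values
    are means over its samples; an aggregated summary sums those means over
    families ("presence" and "singletons" then count families, not
    probabilities).  "transfers" counts transfers *received*; "vertical"
    counts copies entering the branch from its parent, so verticality(e) =
    vertical / (vertical + transfers).
    """

    table: pd.DataFrame
    n_families: int = 1


def _tally_one(sample: SampledReconciliation, st: SpeciesTree) -> dict[str, np.ndarray]:
    n = st.n_branches
    z = lambda: np.zeros(n)
    t = {k: z() for k in ("duplications", "transfers", "losses", "originations",
                          "copies", "vertical", "entered")}
    for ev in sample.events:
        kind = ev[0]
        if max(ev[1:], default=0) >= n or min(ev[1:], default=0) < 0:
            raise InputError(f"event {ev} references a branch outside this species tree")
        if kind == "O":
            t["originations"][ev[1]] += 1
            t["entered"][ev[1]] = 1
        elif kind == "S":
            e = ev[1]
            t["copies"][e] += 1
            for c in (int(st.left[e]), int(st.right[e])):
                t["vertical"][c] += 1
                t["entered"][c] = 1
        elif kind == "SL":
            e, lost = ev[1], ev[2]
            cont = int(st.right[e]) if lost == int(st.left[e]) else int(st.left[e])
            t["copies"][e] += 1
            for c in (cont, lost):
                t["vertical"][c] += 1
                t["entered"][c] = 1
            t["losses"][lost] += 1
        elif kind == "D":
            t["duplications"][ev[1]] += 1
        elif kind == "T":
            t["transfers"][ev[2]] += 1
            t["entered"][ev[2]] = 1
        elif kind == "TL":
            t["transfers"][ev[2]] += 1
            t["entered"][ev[2]] = 1
            t["losses"][ev[1]] += 1
        else:
            raise InputError(f"unknown event type {kind!r}")
    tips = np.zeros(n)
    for b in sample.tip_branches:
        tips[b] += 1
    t["copies"] += tips  # copies leaving a terminal branch = sampled tips
    t["tips"] = tips
    return t


def summarize_branch_events(
    samples: Sequence[SampledReconciliation], st: SpeciesTree
) -> BranchEventSummary:
    """Mean per-branch statistics over one family's samples."""
    if not samples:
        raise InputError("need at least one sample")
    n = st.n_branches
    acc = {k: np.zeros(n) for k in ("duplications", "transfers", "losses",
                                    "originations", "copies", "vertical",
                                    "presence", "singletons")}
    for s in samples:
        t = _tally_one(s, st)
        for k in ("duplications", "transfers", "losses", "originations",
                  "copies", "vertical"):
            acc[k] += t[k]
        acc["presence"] += (t["entered"] > 0) | (t["tips"] > 0)
        acc["singletons"] += t["tips"] == 1
    m = float(len(samples))
    data = {k: v / m for k, v in acc.items()}
    df = pd.DataFrame(data)
    df.insert(0, "branch", [st.names[i] for i in range(n)])
    df.insert(0, "category", [st.branch_category(i) for i in range(n)])
    return BranchEventSummary(table=df[SUMMARY_COLUMNS], n_families=1)


def aggregate_summaries(summaries: Sequence[BranchEventSummary]) -> BranchEventSummary:
    """Sum per-family mean tables into a dataset-level summary."""
    if not summaries:
        raise InputError("nothing to aggregate")
    base = summaries[0].table
    num_cols = SUMMARY_COLUMNS[2:]
    acc = base[num_cols].copy()
    for s in summaries[1:]:
        if len(s.table) != len(base):
            raise InputError("summaries refer to different species trees")
        acc += s.table[num_cols].values
    out = base[["category", "branch"]].copy()
    for c in num_cols:
        out[c] = acc[c].values
    return BranchEventSummary(table=out, n_families=sum(s.n_families for s in summaries))


def verticality(summary: BranchEventSummary) -> pd.Series:
    """V(e) = vertical(e) / (vertical(e) + transfers received(e)).

    NaN where the denominator is zero (no copy ever entered the branch)."""
    t = summary.table
    denom = t["vertical"] + t["transfers"]
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom > 0, t["vertical"] / denom, np.nan)
    return pd.Series(v, index=t["branch"], name="verticality")


def transfer_duplication_ratio(summary: BranchEventSummary) -> pd.Series:
    """Per-branch T/D; NaN (undefined) where no duplications were inferred —
    a ratio over a zero count is not reportable, not infinite."""
    t = summary.table
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(t["duplications"] > 0,
                     t["transfers"] / t["duplications"], np.nan)
    return pd.Series(r, index=t["branch"], name="t_over_d")


# ---------------------------------------------------------------------------
# Full per-family reconciliation summary (report payload)
# ---------------------------------------------------------------------------

@dataclass
class FamilyReconciliationSummary:
    family: str
    rates: DTLRates
    loglik: float
    n_samples: int
    totals: dict
    sample_newicks: list[str]
    branch_table: pd.DataFrame
    summary: BranchEventSummary = field(repr=False, default=None)


def reconcile_family(
    st: SpeciesTree,
    ccp: CCPTable,
    rates: DTLRates,
    n_samples: int,
    seed: int,
    cfg: ModelConfig = DEFAULT_CONFIG,
    leaf_map: Optional[LeafMap] = None,
    family: str = "family",
) -> FamilyReconciliationSummary:
    """Sample histories and assemble the per-family report payload."""
    dp = compute_dp(st, ccp, rates, cfg, leaf_map)
    samples = sample_reconciliations(
        st, ccp, rates, n_samples, seed, cfg, leaf_map, dp=dp
    )
    summ = summarize_branch_events(samples, st)
    mean = lambda kind: float(np.mean([s.event_totals().get(kind, 0) for s in samples]))
    totals = {
        "duplications": mean("D"),
        "transfers": mean("T") + mean("TL"),
        "losses": float(np.mean([
            sum(1 for ev in s.events if ev[0] in ("SL", "TL")) for s in samples
        ])),
        "speciations": mean("S") + mean("SL"),
    }
    table = summ.table[REPORT_COLUMNS].copy()
    return FamilyReconciliationSummary(
        family=family, rates=rates, loglik=dp.loglik, n_samples=n_samples,
        totals=totals, sample_newicks=[s.newick(st) for s in samples],
        branch_table=table, summary=summ,
    )
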