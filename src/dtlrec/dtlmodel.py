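"""The undated duplication-transfer-loss (DTL) reconciliation model.

A gene family originates on some branch of a rooted species tree and each
copy then draws, per branch, one of four events: duplication (D), transfer
(T), loss (L), or vertical descent / speciation (S).  Three nonnegative
per-family parameters delta, tau, lambda set the relative probabilities of
D, T, L against a unit weight for speciation:

    PD = delta / (1 + delta + tau + lambda)
    PT = tau   / (1 + delta + tau + lambda)
    PL = lambda/ (1 + delta + tau + lambda)
    PS = 1 - PD - PT - PL

The model is undated: branch lengths are ignored and transfers may connect
any pair of distinct branches, ancestors and descendants included.  The
family likelihood amalgamates over gene-tree topologies using conditional
clade probabilities (see `ccp`), via a dynamic program over
(gene clade x species branch) with analytic treatment of unobservable
event chains (extinct duplicate copies, transfers into doomed recipients).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._core import dtl_dp, extinction_fixed_point
from .ccp import CCPTable
from .errors import InputError, NumericalError
from .treeio import LeafMap, SpeciesTree

__all__ = [
    "RATE_MIN",
    "RATE_MAX",
    "DTLRates",
    "EventProbs",
    "ExtinctionTable",
    "ModelConfig",
    "CompiledFamily",
    "DPResult",
    "event_probabilities",
    "extinction_probabilities",
    "compile_family",
    "compute_dp",
    "family_loglik",
]

# Rate box constraints: the lower bound is the boundary value reported for
# effectively-zero rates; the upper bound matches the order of magnitude of
# the random-restart interval.
RATE_MIN = 1e-10
RATE_MAX = 10.0


@dataclass(frozen=True)
class DTLRates:
    """Per-family relative event weights (dimensionless, not rates per time)."""

    delta: float
    tau: float
    lam: float

    def __post_init__(self):
        for name, val in (("delta", self.delta), ("tau", self.tau), ("lam", self.lam)):
            if not math.isfinite(val) or val < 0.0:
                raise InputError(f"rate {name} must be finite and nonnegative, got {val}")

    def clamped(self) -> "DTLRates":
        clip = lambda x: min(max(x, RATE_MIN), RATE_MAX)
        return DTLRates(clip(self.delta), clip(self.tau), clip(self.lam))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.delta, self.tau, self.lam)


@dataclass(frozen=True)
class EventProbs:
    """Per-branch event probabilities; pS is the complement, so the four sum
    to one exactly."""

    pD: float
    pT: float
    pL: float
    pS: float


def event_probabilities(rates: DTLRates) -> EventProbs:
    """Normalise (delta, tau, lambda) against the unit speciation weight."""
    s = 1.0 + rates.delta + rates.tau + rates.lam
    pD = rates.delta / s
    pT = rates.tau / s
    pL = rates.lam / s
    return EventProbs(pD=pD, pT=pT, pL=pL, pS=1.0 - pD - pT - pL)


@dataclass
class ModelConfig:
    """Model structure and numerical settings.

    origination: "uniform" (every branch weight 1/N), "root" (all mass on
    the root branch), or a custom weight array of length N (normalised).
    Transfers go to a uniformly chosen branch other than the donor.
    condition_on_survival divides the likelihood by 1 - P(extinct);
    off by default.
    """

    origination: object = "uniform"
    condition_on_survival: bool = False
    e_max_iter: int = 50_000
    e_tol: float = 1e-14
    dp_max_sweeps: int = 16
    dp_tol: float = 1e-12

    def origination_prior(self, st: SpeciesTree) -> np.ndarray:
        n = st.n_branches
        if isinstance(self.origination, str):
            if self.origination == "uniform":
                return np.full(n, 1.0 / n)
            if self.origination == "root":
                prior = np.zeros(n)
                prior[st.root_id] = 1.0
                return prior
            raise InputError(f"unknown origination prior {self.origination!r}")
        prior = np.asarray(self.origination, dtype=float)
        if prior.shape != (n,) or np.any(prior < 0) or prior.sum() <= 0:
            raise InputError("custom origination prior must be N nonnegative weights")
        return prior / prior.sum()


DEFAULT_CONFIG = ModelConfig()


@dataclass
class ExtinctionTable:
    """E(e): probability that one copy entering branch e leaves no sampled
    descendants; Ebar(e): mean E over the permissible transfer recipients
    of e."""

    E: np.ndarray
    Ebar: np.ndarray
    residual: float


def extinction_probabilities(
    st: SpeciesTree, ep: EventProbs, cfg: ModelConfig = DEFAULT_CONFIG
) -> ExtinctionTable:
    """Solve the extinction fixed point on every branch."""
    E, resid = extinction_fixed_point(
        st.left, st.right, ep.pD, ep.pT, ep.pL, ep.pS, cfg.e_max_iter, cfg.e_tol
    )
    # Near-critical rate corners converge only linearly; anything below 1e-9
    # is far inside the accuracy the likelihood needs.
    if resid > max(cfg.e_tol * 10, 1e-9):
        raise NumericalError(
            f"extinction fixed point did not converge (residual {resid:.3e})"
        )
    n = st.n_branches
    if n > 1:
        Ebar = (E.sum() - E) / (n - 1)
    else:
        Ebar = np.zeros(1)
    return ExtinctionTable(E=E, Ebar=Ebar, residual=resid)


# ---------------------------------------------------------------------------
# Family compilation: CCP table + species tree -> flat DP arrays
# ---------------------------------------------------------------------------

@dataclass
class CompiledFamily:
    """Flat-array view of one family's CCP against one species tree."""

    masks: list[int]                  # clade bitmasks, ascending size; full set last
    index: dict[int, int]             # mask -> clade row
    sv: np.ndarray                    # split left-child rows
    sw: np.ndarray                    # split right-child rows
    sq: np.ndarray                    # split conditionals q
    cstart: np.ndarray                # per-clade split ranges
    single_branch: np.ndarray         # species branch of singleton clades, else -1
    root_mult: int
    labels: list[str]                 # gene-leaf labels (bit order)

    @property
    def n_clades(self) -> int:
        return len(self.masks)


def compile_family(
    st: SpeciesTree, ccp: CCPTable, leaf_map: Optional[LeafMap] = None
) -> CompiledFamily:
    """Order clades, resolve splits to row indices, and map singletons to
    species branches.  Results are cached on the CCP table per species tree."""
    if leaf_map is None:
        leaf_map = ccp.leaf_map or LeafMap()
    key = (id(st), id(leaf_map))
    hit = ccp._compiled.get(key)
    if hit is not None:
        return hit[2]

    leaf_map.validate(ccp.labels, st.leaf_ids)
    masks = ccp.observed_clades()
    index = {m: i for i, m in enumerate(masks)}
    n_clades = len(masks)
    single_branch = np.full(n_clades, -1, dtype=np.int64)
    for i, m in enumerate(masks):
        if m.bit_count() == 1:
            lbl = ccp.labels[m.bit_length() - 1]
            single_branch[i] = st.leaf_ids[leaf_map.species_of(lbl)]

    sv, sw, sq = [], [], []
    cstart = np.zeros(n_clades + 1, dtype=np.int64)
    for i, m in enumerate(masks):
        for v, w, q in ccp.splits_of(m):
            sv.append(index[v])
            sw.append(index[w])
            sq.append(q)
        cstart[i + 1] = len(sv)

    compiled = CompiledFamily(
        masks=masks,
        index=index,
        sv=np.asarray(sv, dtype=np.int64),
        sw=np.asarray(sw, dtype=np.int64),
        sq=np.asarray(sq, dtype=float),
        cstart=cstart,
        single_branch=single_branch,
        root_mult=ccp.root_mult,
        labels=list(ccp.labels),
    )
    ccp._compiled[key] = (st, leaf_map, compiled)
    return compiled


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

@dataclass
class DPResult:
    """Full DP state for one (family, species tree, rates) evaluation;
    consumed by the reconciliation sampler."""

    st: SpeciesTree
    compiled: CompiledFamily
    rates: DTLRates
    cfg: ModelConfig
    ep: EventProbs
    ext: ExtinctionTable
    prior: np.ndarray
    P: np.ndarray        # scaled clade x branch probabilities
    ell: np.ndarray      # per-clade log offsets
    loglik: float


def compute_dp(
    st: SpeciesTree,
    ccp: CCPTable,
    rates: DTLRates,
    cfg: ModelConfig = DEFAULT_CONFIG,
    leaf_map: Optional[LeafMap] = None,
) -> DPResult:
    """Run extinction + DP and keep the tables (for sampling/backtracking)."""
    compiled = compile_family(st, ccp, leaf_map)
    ep = event_probabilities(rates)
    ext = extinction_probabilities(st, ep, cfg)
    prior = cfg.origination_prior(st)
    P, ell, loglik = dtl_dp(
        st.left, st.right,
        compiled.sv, compiled.sw, compiled.sq, compiled.cstart,
        compiled.single_branch,
        ep.pD, ep.pT, ep.pS, ext.E, prior,
        float(compiled.root_mult), cfg.dp_max_sweeps, cfg.dp_tol,
    )
    if cfg.condition_on_survival and math.isfinite(loglik):
        p_ext = float(prior @ ext.E)
        if p_ext >= 1.0:
            loglik = -math.inf
        else:
            loglik -= math.log1p(-p_ext)
    return DPResult(
        st=st, compiled=compiled, rates=rates, cfg=cfg, ep=ep, ext=ext,
        prior=prior, P=P, ell=ell, loglik=float(loglik),
    )


def family_loglik(
    st: SpeciesTree,
    ccp: CCPTable,
    rates: DTLRates,
    cfg: ModelConfig = DEFAULT_CONFIG,
    leaf_map: Optional[LeafMap] = None,
) -> float:
    """Natural-log amalgamated reconciliation likelihood of one family.

    Returns -inf (not an exception) when the family is impossible under the
    given rates, e.g. a multi-species family with tau = delta = 0 and
    origination restricted to a terminal branch.
    """
    return compute_dp(st, ccp, rates, cfg, leaf_map).loglik
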