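"""Maximum-likelihood estimation of per-family DTL parameters.

Rates are optimised independently for each family (no pooling) with
Nelder-Mead in log-parameter space, box-clamped to [1e-10, 10].  A ratio
constraint removes one free parameter by substitution — "DT = 0.02" fixes
delta = 0.02 * tau (i.e. tau is 50 times delta) — so the constraint holds
to machine precision in every output.  Robustness to the start point is
assessed by random restarts drawn uniformly from [0.01, 10] per free
parameter; all replicates are kept in the diagnostics, never silently
discarded.

Model comparison between the free (k = 3) and ratio-constrained (k = 2)
fits uses AIC = 2k - 2 logL, per family and summed over the dataset.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ccp import CCPTable
from .dtlmodel import (
    DEFAULT_CONFIG,
    DTLRates,
    ModelConfig,
    RATE_MAX,
    RATE_MIN,
    compile_family,
    family_loglik,
)
from .errors import InputError, NumericalError
from .treeio import LeafMap, SpeciesTree

__all__ = [
    "RatioConstraint",
    "FitResult",
    "fit_rates",
    "aic",
    "ModelComparison",
    "model_comparison",
    "fits_to_tsv",
]

_PARAM_OF = {"D": "delta", "T": "tau", "L": "lam"}


@dataclass(frozen=True)
class RatioConstraint:
    """Fix the ratio of two of (delta, tau, lam).

    `pair` is the two-letter code naming numerator and denominator, e.g.
    "DT" with ratio r enforces delta = r * tau.  The denominator parameter
    and the remaining third parameter stay free (k = 2).
    """

    pair: str
    ratio: float

    def __post_init__(self):
        if self.pair not in ("DT", "DL", "TL"):
            raise InputError(f"constraint pair must be DT, DL or TL, got {self.pair!r}")
        if not (math.isfinite(self.ratio) and self.ratio > 0):
            raise InputError(f"constraint ratio must be a positive real, got {self.ratio}")

    @property
    def numerator(self) -> str:
        return _PARAM_OF[self.pair[0]]

    @property
    def denominator(self) -> str:
        return _PARAM_OF[self.pair[1]]

    @classmethod
    def parse(cls, text: str) -> "RatioConstraint":
        """Parse e.g. "DT=0.02" (delta fixed to 0.02 x tau)."""
        m = re.fullmatch(r"\s*(DT|DL|TL)\s*=\s*([0-9.eE+-]+)\s*", text or "")
        if not m:
            raise InputError(
                f"malformed constraint {text!r}: expected NAME=float with NAME in DT, DL, TL"
            )
        try:
            ratio = float(m.group(2))
        except ValueError:
            raise InputError(f"malformed constraint ratio {m.group(2)!r}") from None
        return cls(m.group(1), ratio)

    def free_names(self) -> list[str]:
        return [p for p in ("delta", "tau", "lam") if p != self.numerator]

    def rates_from_free(self, free: dict[str, float]) -> DTLRates:
        vals = dict(free)
        vals[self.numerator] = self.ratio * vals[self.denominator]
        return DTLRates(vals["delta"], vals["tau"], vals["lam"])


@dataclass
class FitResult:
    """Best replicate of a per-family rate optimisation."""

    rates: DTLRates
    loglik: float
    k: int
    converged: bool
    n_iter: int
    start: tuple
    family: str = "family"
    constraint: Optional[RatioConstraint] = None
    n_restarts: int = 1
    seed: int = 0
    replicates: list = field(default_factory=list, repr=False)
    # replicates: list of (start tuple, DTLRates, loglik, converged)


def _free_bounds(names: Sequence[str], constraint: Optional[RatioConstraint]):
    bounds = []
    for name in names:
        hi = RATE_MAX
        if constraint is not None and name == constraint.denominator:
            # keep the derived numerator inside the box as well
            hi = min(RATE_MAX, RATE_MAX / constraint.ratio)
        bounds.append((math.log(RATE_MIN), math.log(hi)))
    return bounds


def fit_rates(
    st: SpeciesTree,
    ccp: CCPTable,
    constraint: Optional[RatioConstraint] = None,
    n_restarts: int = 1,
    seed: int = 0,
    cfg: ModelConfig = DEFAULT_CONFIG,
    leaf_map: Optional[LeafMap] = None,
    start: tuple = (0.1, 0.1, 0.1),
    fatol: float = 1e-6,
    xatol: float = 1e-6,
    maxiter: int = 2000,
    family: str = "family",
) -> FitResult:
    """Maximise the family log-likelihood over the free DTL parameters.

    One deterministic start (default 0.1 for every parameter) plus
    n_restarts - 1 random starts drawn uniformly from [0.01, 10] per free
    parameter.  Returns the best replicate; all replicates are retained in
    `replicates`.  Raises NumericalError only if every replicate fails to
    produce a finite likelihood (the best partial result is attached).
    """
    if n_restarts < 1:
        raise InputError("n_restarts must be >= 1")
    compile_family(st, ccp, leaf_map)  # fail fast on bad leaf maps
    names = ["delta", "tau", "lam"] if constraint is None else constraint.free_names()
    k = len(names)
    bounds = _free_bounds(names, constraint)

    def rates_of(x: np.ndarray) -> DTLRates:
        # exp(log(bound)) can land one ulp outside the box
        vals = {n: float(np.clip(np.exp(v), RATE_MIN, RATE_MAX))
                for n, v in zip(names, x)}
        if constraint is None:
            return DTLRates(vals["delta"], vals["tau"], vals["lam"])
        return constraint.rates_from_free(vals)

    def objective(x: np.ndarray) -> float:
        try:
            ll = family_loglik(st, ccp, rates_of(x), cfg, leaf_map)
        except NumericalError:
            # near-critical rate corner: not reliably evaluable, steer away
            return 1e12
        return 1e12 if not math.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    start_full = dict(zip(("delta", "tau", "lam"), start))
    starts = [tuple(start_full[n] for n in names)]
    for _ in range(n_restarts - 1):
        starts.append(tuple(rng.uniform(0.01, 10.0, size=k)))

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    options = {"fatol": fatol, "xatol": xatol, "maxiter": maxiter,
               "maxfev": 2 * maxiter}

    replicates = []
    for s in starts:
        x0 = np.clip(np.log(np.clip(s, RATE_MIN, RATE_MAX)), lo, hi)
        best_res = None
        for _polish in range(4):
            # keep the start half a log-unit inside the box: a start pinned
            # on the boundary yields a clipped, degenerate initial simplex
            # that stalls Nelder-Mead immediately
            x0 = np.clip(x0, lo + 0.5, hi - 0.5)
            res = minimize(objective, x0, method="Nelder-Mead", bounds=bounds,
                           options=options)
            if best_res is not None and best_res.fun - res.fun < fatol:
                if res.fun < best_res.fun:
                    best_res = res
                break
            best_res = res
            x0 = res.x
        res = best_res
        rates = rates_of(res.x)
        ll = -res.fun if res.fun < 1e11 else -math.inf
        replicates.append((s, rates, ll, bool(res.success), int(res.nit)))

    best = max(replicates, key=lambda r: r[2])
    if not math.isfinite(best[2]):
        err = NumericalError(f"all {n_restarts} replicate(s) failed for family {family}")
        err.partial = replicates  # best partial result carried on the error
        raise err
    return FitResult(
        rates=best[1], loglik=best[2], k=k, converged=best[3], n_iter=best[4],
        start=best[0], family=family, constraint=constraint,
        n_restarts=n_restarts, seed=seed, replicates=replicates,
    )


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion: 2 * (parameter count) - 2 * log-likelihood."""
    if not math.isfinite(loglik):
        raise InputError("AIC requires a finite log-likelihood")
    if k < 0:
        raise InputError("parameter count must be nonnegative")
    return 2.0 * k - 2.0 * loglik


@dataclass
class ModelComparison:
    """Per-family and dataset-level comparison of free vs constrained fits."""

    per_family: pd.DataFrame
    summed_loglik_free: float
    summed_loglik_constrained: float
    summed_aic_free: float
    summed_aic_constrained: float
    k_total_free: int
    k_total_constrained: int
    n_reject_simpler: int
    frac_reject_simpler: float


def model_comparison(
    free: Sequence[FitResult], constrained: Sequence[FitResult]
) -> ModelComparison:
    """Pair free (k=3) and ratio-constrained (k=2) fits family by family.

    The simpler model is rejected for a family when its AIC exceeds the
    full model's.  Dataset totals treat parameters as 3F vs 2F.
    """
    if len(free) != len(constrained):
        raise InputError("free and constrained fit lists differ in length")
    rows = []
    for fr, co in zip(free, constrained):
        if fr.family != co.family:
            raise InputError(
                f"family mismatch in comparison: {fr.family!r} vs {co.family!r}"
            )
        a_free = aic(fr.loglik, fr.k)
        a_con = aic(co.loglik, co.k)
        rows.append(
            {
                "family": fr.family,
                "loglik_free": fr.loglik,
                "loglik_constrained": co.loglik,
                "delta_loglik": fr.loglik - co.loglik,
                "aic_free": a_free,
                "aic_constrained": a_con,
                "delta_aic": a_con - a_free,
                "reject_simpler": a_con > a_free,
            }
        )
    df = pd.DataFrame(rows)
    n_reject = int(df["reject_simpler"].sum())
    return ModelComparison(
        per_family=df,
        summed_loglik_free=float(df["loglik_free"].sum()),
        summed_loglik_constrained=float(df["loglik_constrained"].sum()),
        summed_aic_free=float(df["aic_free"].sum()),
        summed_aic_constrained=float(df["aic_constrained"].sum()),
        k_total_free=3 * len(df),
        k_total_constrained=2 * len(df),
        n_reject_simpler=n_reject,
        frac_reject_simpler=n_reject / len(df) if len(df) else float("nan"),
    )


def fits_to_tsv(fits: Sequence[FitResult]) -> str:
    """Serialise fit results: family, delta, tau, lambda, logL, k, converged,
    n_restarts, seed."""
    lines = ["family\tdelta\ttau\tlambda\tlogL\tk\tconverged\tn_restarts\tseed"]
    for f in fits:
        lines.append(
            f"{f.family}\t{f.rates.delta:.10g}\t{f.rates.tau:.10g}\t"
            f"{f.rates.lam:.10g}\t{f.loglik:.6f}\t{f.k}\t{int(f.converged)}\t"
            f"{f.n_restarts}\t{f.seed}"
        )
    return "\n".join(lines) + "\n"
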