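"""Species-tree rooting by summed reconciliation log-likelihoods.

Different root positions imply different origination, descent and loss
scenarios for every gene family, hence different reconciliation
likelihoods.  Each candidate rooting is scored by refitting the per-family
DTL rates (rate estimates are root-dependent) and summing the maximised
per-family log-likelihoods.  Candidates are then compared with an
approximately unbiased (AU) test in which gene families are the resampling
units — the analogue of sites in sequence-based tree selection — using
multiscale RELL bootstrap and the signed-distance/curvature fit on the
probit scale.  The set of candidates not rejected at level alpha is the
"root region".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ccp import CCPTable
from .dtlmodel import DEFAULT_CONFIG, ModelConfig
from .errors import InputError
from .mlfit import FitResult, fit_rates
from .treeio import LeafMap, SpeciesTree

__all__ = [
    "RootTestResult",
    "root_label",
    "per_root_loglik",
    "au_test",
    "root_region",
    "run_root_test",
]

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4


def root_label(st: SpeciesTree) -> str:
    """Stable label for a candidate rooting: its root-edge bipartition."""
    if st.root_edge is None:
        return "root"
    return ",".join(sorted(st.root_edge))


@dataclass
class RootTestResult:
    """Per-family x per-root log-likelihoods with AU test results."""

    matrix: pd.DataFrame            # families x roots
    summed: pd.Series               # per-root summed log-likelihood
    pvalues: pd.Series              # AU p per root
    region: list                    # root labels with p >= alpha (incl. ML root)
    alpha: float

    @property
    def best_root(self) -> str:
        return str(self.summed.idxmax())

    def report_tsv(self) -> str:
        best = self.summed.max()
        lines = ["root\tsummed_logL\tdelta_logL\tau_p\tin_region"]
        for root in self.summed.index:
            lines.append(
                f"{root}\t{self.summed[root]:.6f}\t{self.summed[root] - best:.6f}\t"
                f"{self.pvalues[root]:.6g}\t{int(root in self.region)}"
            )
        return "\n".join(lines) + "\n"


def per_root_loglik(
    families: Sequence[tuple[CCPTable, Optional[LeafMap]]],
    rootings: Sequence[SpeciesTree],
    n_restarts: int = 1,
    seed: int = 0,
    cfg: ModelConfig = DEFAULT_CONFIG,
    family_names: Optional[Sequence[str]] = None,
    fatol: float = 1e-4,
    collect_fits: bool = False,
):
    """Fit rates for every (family, candidate root) and collect the
    maximised log-likelihoods.

    All rootings must share one unrooted topology.  Each cell uses a seed
    derived from (seed, family index, root index), so results do not depend
    on execution order.  Returns the matrix DataFrame, or (matrix, fits)
    when collect_fits is set.
    """
    if not families:
        raise InputError("need at least one family")
    if len(rootings) < 2:
        raise InputError("need at least two candidate rootings")
    topos = {st.tree.bipartitions() for st in rootings}
    if len(topos) != 1:
        raise InputError("candidate rootings do not share one unrooted topology")
    labels = [root_label(st) for st in rootings]
    if len(set(labels)) != len(labels):
        raise InputError("duplicate candidate roots")
    if family_names is None:
        family_names = [f"fam{i:04d}" for i in range(len(families))]

    mat = np.empty((len(families), len(rootings)))
    fits: dict[tuple[str, str], FitResult] = {}
    for fi, fam in enumerate(families):
        ccp, leaf_map = fam
        warm = None  # rates fitted under the first root warm-start the rest
        for ri, st in enumerate(rootings):
            cell_seed = int(np.random.SeedSequence([seed, fi, ri]).generate_state(1)[0] % (2**31))
            fit = fit_rates(
                st, ccp, n_restarts=n_restarts, seed=cell_seed, cfg=cfg,
                leaf_map=leaf_map, fatol=fatol, xatol=1e-3,
                start=warm if warm is not None else (0.1, 0.1, 0.1),
                family=family_names[fi],
            )
            if warm is None:
                warm = fit.rates.as_tuple()
            mat[fi, ri] = fit.loglik
            if collect_fits:
                fits[(family_names[fi], labels[ri])] = fit
    df = pd.DataFrame(mat, index=list(family_names), columns=labels)
    return (df, fits) if collect_fits else df


def _rell_bp(M: np.ndarray, m: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap proportions (fraction of replicates in which each root is
    best) for resample size m; ties share their weight equally."""
    F, R = M.shape
    bp = np.zeros(R)
    chunk = max(1, min(n_boot, 2_000_000 // max(1, m * R)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, F, size=(b, m))
        sums = M[idx].sum(axis=1)                      # (b, R)
        best = sums.max(axis=1, keepdims=True)
        ties = sums >= best - 1e-9
        bp += (ties / ties.sum(axis=1, keepdims=True)).sum(axis=0)
        done += b
    return bp / n_boot


def au_test(
    matrix: pd.DataFrame,
    n_boot: int = 10_000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
    min_families: int = 10,
) -> pd.Series:
    """Approximately unbiased p-value per candidate root.

    Multiscale RELL bootstrap over family rows: at each scale r, ceil(r*F)
    rows are resampled with replacement n_boot times and the frequency with
    which each root attains the best summed log-likelihood is recorded.
    The bootstrap proportions are then fit, on the probit scale, to
    z(sigma) = d/sigma + c*sigma (d the signed distance, c the boundary
    curvature; sigma = 1/sqrt(r)) by weighted least squares, and
    p_AU = 1 - Phi(d - c).  Degenerate fits (a root never or
    always best at every scale, or a singular fit) fall back to the plain
    bootstrap proportion at the scale nearest 1.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise InputError("need a families x roots matrix with >= 2 roots")
    F, R = M.shape
    if F < min_families:
        raise InputError(
            f"AU test needs >= {min_families} families as resampling units, got {F}"
        )
    if not np.all(np.isfinite(M)):
        raise InputError("log-likelihood matrix contains non-finite entries")
    scales = [float(s) for s in scales]
    if any(s <= 0 for s in scales):
        raise InputError("scales must be positive")

    rng = np.random.default_rng(seed)
    bp = np.zeros((len(scales), R))
    for j, r in enumerate(scales):
        m = max(1, math.ceil(r * F))
        bp[j] = _rell_bp(M, m, n_boot, rng)

    ref = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    sigma = 1.0 / np.sqrt(np.asarray(scales))
    X = np.column_stack([sigma, 1.0 / sigma])

    eps = 1.0 / (2.0 * n_boot)
    pvals = np.empty(R)
    for k in range(R):
        b = bp[:, k]
        if np.all(b <= eps) or np.all(b >= 1 - eps):
            pvals[k] = b[ref]
            continue
        bc = np.clip(b, eps, 1 - eps)
        z = norm.ppf(1.0 - bc)
        w = n_boot * norm.pdf(z) ** 2 / (bc * (1 - bc))
        W = np.sqrt(w)
        try:
            coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            pvals[k] = b[ref]
            continue
        c, d = coef  # columns of X are [sigma, 1/sigma] = (curvature, distance)
        p = 1.0 - norm.cdf(d - c)
        pvals[k] = min(max(p, 0.0), 1.0)
    return pd.Series(pvals, index=matrix.columns, name="au_p")


def root_region(
    pvals: pd.Series, alpha: float = 0.05, summed: Optional[pd.Series] = None
) -> list:
    """Candidates with p >= alpha; the ML root (argmax summed LL, when
    given) is always retained."""
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must be in (0, 1)")
    keep = [str(i) for i in pvals.index[pvals >= alpha]]
    if summed is not None:
        ml = str(summed.idxmax())
        if ml not in keep:
            keep.append(ml)
    return keep


def run_root_test(
    families,
    rootings: Sequence[SpeciesTree],
    alpha: float = 0.05,
    n_boot: int = 10_000,
    seed: int = 0,
    n_restarts: int = 1,
    cfg: ModelConfig = DEFAULT_CONFIG,
    family_names: Optional[Sequence[str]] = None,
) -> RootTestResult:
    """Full rooting analysis: per-root refits, AU test, root region."""
    matrix = per_root_loglik(
        families, rootings, n_restarts=n_restarts, seed=seed, cfg=cfg,
        family_names=family_names,
    )
    summed = matrix.sum(axis=0)
    pvals = au_test(matrix, n_boot=n_boot, seed=seed + 1)
    region = root_region(pvals, alpha=alpha, summed=summed)
    return RootTestResult(
        matrix=matrix, summed=summed, pvalues=pvals, region=region, alpha=alpha
    )
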