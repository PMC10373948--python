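"""Numba-compiled numerical core of the undated DTL likelihood.

Two routines live here: the extinction-probability fixed point and the
(gene clade x species branch) dynamic program that amalgamates over CCP
splits.  Both operate on flat integer/float arrays prepared by `dtlmodel`;
branch IDs are postorder, so iterating branches in index order visits
children before parents.

Underflow control: each clade row carries a log offset `ell[u]` so the
stored values P[u, e] * exp(ell[u]) are the true probabilities; split terms
rescale sub-clade products into the parent's offset frame, and rows whose
maximum drifts outside [1e-120, 1e120] are renormalised.
"""

import numpy as np
from numba import njit

__all__ = ["extinction_fixed_point", "dtl_dp"]


@njit(cache=True)
def extinction_fixed_point(left, right, pD, pT, pL, pS, max_iter, tol):
    """Solve E(e) = base(e) + pD E(e)^2 + pT Ebar(e) E(e) for all branches.

    base(e) = pL + pS E(f) E(g) on internal branches (children f, g) and
    pL on terminals (the speciation slot at a tip is sampling, which cannot
    go extinct).  Plain Jacobi iteration from E = 0: every coefficient is
    nonnegative, so the iterates increase monotonically to the least fixed
    point — no damping needed and limit cycles are impossible.
    Returns (E, final residual).
    """
    N = left.shape[0]
    E = np.zeros(N)
    Enew = np.zeros(N)
    resid = 1.0
    for _ in range(max_iter):
        resid = 0.0
        Esum = E.sum()
        for e in range(N):
            if N > 1:
                Ebar = (Esum - E[e]) / (N - 1)
            else:
                Ebar = 0.0
            f = left[e]
            if f >= 0:
                base = pL + pS * E[f] * E[right[e]]
            else:
                base = pL
            x = base + pD * E[e] * E[e] + pT * Ebar * E[e]
            if x > 1.0:
                x = 1.0
            d = abs(x - E[e])
            if d > resid:
                resid = d
            Enew[e] = x
        E, Enew = Enew, E
        if resid < tol:
            break
    return E, resid


@njit(cache=True)
def dtl_dp(left, right, sv, sw, sq, cstart, single_branch,
           pD, pT, pS, E, prior, root_mult, max_sweeps, tol):
    """Amalgamated undated-DTL dynamic program.

    For each observed clade u (ascending size; the full leaf set last) and
    species branch e:

      P(u,e) = [ pS ( sum_splits q (P(v,f)P(w,g) + P(v,g)P(w,f))
                      + P(u,f)E(g) + P(u,g)E(f) )            # S and SL
               + pS * 1{u singleton mapping to terminal e}    # sampling
               + pD sum_splits q P(v,e)P(w,e)                 # D
               + pT sum_splits q (P(v,e)Tbar(w,e) + P(w,e)Tbar(v,e))  # T
               + pT E(e) Tbar(u,e) ]                          # TL
               / (1 - 2 pD E(e) - pT Ebar(e))                 # invisible D/T

    with Tbar(x,e) = sum_{h != e} P(x,h) / (N-1).  The TL self-coupling is
    resolved by convergence-checked Jacobi sweeps.  Returns (P, ell, logL)
    where logL = log( sum_e prior(e) P(root,e) ) plus offsets and the
    root-split multiplicity, or -inf for an impossible family.
    """
    N = left.shape[0]
    C = single_branch.shape[0]
    P = np.zeros((C, N))
    ell = np.zeros(C)
    tot = np.zeros(C)
    Esum = E.sum()
    nrec = N - 1 if N > 1 else 1

    for u in range(C):
        s0 = cstart[u]
        s1 = cstart[u + 1]
        lu = 0.0
        first = True
        for s in range(s0, s1):
            lvw = ell[sv[s]] + ell[sw[s]]
            if first or lvw > lu:
                lu = lvw
                first = False
        if first:
            lu = 0.0
        ell[u] = lu

        for _sweep in range(max_sweeps):
            tot_u = 0.0
            for e in range(N):
                tot_u += P[u, e]
            maxdiff = 0.0
            cmax = 0.0
            for e in range(N):
                f = left[e]
                g = right[e]
                num = 0.0
                for s in range(s0, s1):
                    v = sv[s]
                    w = sw[s]
                    fac = sq[s] * np.exp(ell[v] + ell[w] - lu)
                    if f >= 0:
                        num += pS * fac * (P[v, f] * P[w, g] + P[v, g] * P[w, f])
                    num += pD * fac * P[v, e] * P[w, e]
                    if N > 1:
                        num += pT * fac * (
                            P[v, e] * (tot[w] - P[w, e])
                            + P[w, e] * (tot[v] - P[v, e])
                        ) / nrec
                if f >= 0:
                    num += pS * (P[u, f] * E[g] + P[u, g] * E[f])
                elif single_branch[u] == e:
                    num += pS * np.exp(-lu)
                if N > 1:
                    num += pT * E[e] * (tot_u - P[u, e]) / nrec
                    Ebar_e = (Esum - E[e]) / nrec
                else:
                    Ebar_e = 0.0
                denom = 1.0 - 2.0 * pD * E[e] - pT * Ebar_e
                if denom < 1e-12:
                    denom = 1e-12
                newP = num / denom
                d = abs(newP - P[u, e])
                if d > maxdiff:
                    maxdiff = d
                P[u, e] = newP
                if newP > cmax:
                    cmax = newP
            if maxdiff <= tol * (cmax + 1e-300):
                break

        m = 0.0
        for e in range(N):
            if P[u, e] > m:
                m = P[u, e]
        if m > 0.0 and (m < 1e-120 or m > 1e120):
            for e in range(N):
                P[u, e] /= m
            ell[u] += np.log(m)
        t = 0.0
        for e in range(N):
            t += P[u, e]
        tot[u] = t

    ru = C - 1
    L = 0.0
    for e in range(N):
        L += prior[e] * P[ru, e]
    if L <= 0.0:
        return P, ell, -np.inf
    return P, ell, np.log(L) + ell[ru] + np.log(root_mult)
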