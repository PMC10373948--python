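# Methods

## Model

`dtlrec` implements the undated duplication–transfer–loss (DTL) process on
a rooted binary species tree. A family originates on a branch drawn from
an origination prior; every copy on a branch draws exactly one event:
speciation/vertical descent (advance into both child branches, or be
sampled if the branch is terminal), duplication (fork on the same branch),
transfer (a copy starts on another branch while the donor continues), or
loss. The per-family parameters δ, τ, λ ≥ 0 are relative probabilities
against a unit speciation weight, normalised as
P_D = δ/(1+δ+τ+λ) etc. They are **not** rates per unit time and not event
counts; counts are inferences read off sampled reconciliations.

Assumptions worth stating explicitly:

* homogeneous parameters across species branches (no branch-specific
  multipliers, no transfer highways);
* transfers are undated: any of the N−1 other branches is a permissible
  recipient with weight 1/(N−1), ancestors and descendants included;
* one event per copy per branch *step* — repeated events on a branch arise
  as chains of steps, which the likelihood sums analytically;
* every extant species is sampled; a copy reaching a terminal branch is
  observed with the speciation slot's probability P_S.

## Extinction probabilities

E(e) is the probability that one copy entering branch e leaves no sampled
descendants. It solves

    E(e) = P_L + P_S·E(f)·E(g) + P_D·E(e)² + P_T·Ē(e)·E(e)

with E(f)E(g) replaced by 0 on terminal branches (a tip copy is sampled,
never silently unobserved) and Ē(e) the mean over permissible recipients.
The system is solved by plain Jacobi iteration from E ≡ 0: since all
coefficients are nonnegative the iterates increase monotonically to the
least fixed point, so the iteration cannot cycle; it stops when the sweep
residual drops below 1e-14 (default; `ModelConfig.e_tol`). Near-critical
parameter corners converge only linearly; residuals below 1e-9 are
accepted there, far inside the accuracy the likelihood needs, and anything
worse raises a `NumericalError` (the optimiser treats such corners as
unevaluable and steers away).

## CCP amalgamation and the likelihood

A sample of gene trees is summarised into **conditional clade
probabilities**. Every tree is treated as unrooted; each edge contributes
its two directed leaf subsets as clades, and each internal directed edge
records the resolution of its clade into two child clades. The conditional
q(split | clade) is the split count over the clade count. For the full
leaf set ("root clade") every edge of every tree is a candidate root
split; its stored count carries the edge multiplicity m = max(1, 2n−3) so
q still sums to one per clade, and the likelihood multiplies its root term
by m — the generative probability of an unrooted topology is the *sum*
over its rootings, not the mean. Identical trees are counted once per
occurrence (no deduplication); no pseudocounts are added by default (an
optional Laplace-style `smoothing` exists but changes the estimator and is
off).

The family likelihood is computed by dynamic programming over
(observed gene clade u × species branch e), clades in increasing size:

    P(u,e) = [ P_S( Σ_splits q·(P(v,f)P(w,g) + P(v,g)P(w,f))
                    + P(u,f)E(g) + P(u,g)E(f) )              (S, SL)
             + P_S·1{u singleton mapping to terminal e}       (sampling)
             + P_D Σ_splits q·P(v,e)P(w,e)                    (D)
             + P_T Σ_splits q·(P(v,e)T̄(w,e) + P(w,e)T̄(v,e))  (T)
             + P_T E(e) T̄(u,e) ]                             (TL)
             / (1 − 2 P_D E(e) − P_T Ē(e))

where T̄(x,e) = Σ_{h≠e} P(x,h)/(N−1). The denominator folds in the
geometric chains of *invisible* events (a duplication whose second copy
dies out, a transfer into a doomed recipient). The TL term couples P(u,·)
across branches; it is resolved by convergence-checked Jacobi sweeps
(`dp_max_sweeps` = 16, `dp_tol` = 1e-12 — the coupling coefficient is
P_T·E(e)/(N−1), so a handful of sweeps reaches machine precision; the cap
is generous rather than tight). The family likelihood is
Σ_e prior(e)·P(Γ,e) with Γ the full clade; an impossible family returns
−∞, not an exception. Underflow is controlled by a per-clade log offset:
stored rows are rescaled when their maximum leaves [1e-120, 1e120], and
split terms convert between offset frames exactly, so the result is exact
in log space. The core is `numba`-compiled (`dtlrec._core`).

Defaults left open by the model family and fixed here: origination prior
uniform over all N branches ("root" and custom priors available); no
conditioning on survival (a `condition_on_survival` flag divides by
1 − Σ prior·E; inference on survivor-filtered datasets should enable it);
transfer recipients uniform excluding only the donor.

### Labeled-copy convention

The DP computes the standard likelihood of the *labeled* gene tree:
speciation and transfer resolutions are summed over both ordered child
assignments, duplication over the unordered split once. When gene-copy
labels within a species are regarded as exchangeable, this convention and
the generative class probability differ by assignment-multiplicity factors
in two corner cases: a transfer whose two descendant lineages end in
species-symmetric fates is counted twice here and once generatively, and a
cross-species duplication assignment once here and twice generatively.
The distortion is second-order in P_D, P_T for realistic parameters
(verified against a million-replicate forward simulation at pattern level,
agreement within Monte-Carlo error), and the posterior-enumeration tests
use instances (transfer-only two-species, duplication-only same-species)
on which the two conventions provably coincide, where enumeration matches
the likelihood to ~1e-6 relative.

## Maximum-likelihood fitting

Per family (never pooled), Nelder–Mead in log-parameter space with box
clamps [1e-10, 10] — the lower bound is the conventional boundary value
for "effectively zero", the upper bound matches the random-restart
interval's order of magnitude. Convergence: absolute log-likelihood
tolerance 1e-6, simplex tolerance 1e-6, 2,000 iterations (looser 1e-4/1e-3
settings are used inside the root scan, where only differences of order
unity matter). Each run is *polished*: Nelder–Mead restarts from its own
optimum, with the start pulled half a log-unit inside the box, until no
improvement — a start pinned on a clipped bound otherwise produces a
degenerate initial simplex that stalls immediately. With this protocol 20
random restarts drawn uniformly from [0.01, 10] agree to ~1e-13
log-likelihood units and ~1e-7 relative parameter spread on informative
simulated families.

Ratio constraints are enforced by substitution — `DT=0.02` sets
δ = 0.02·τ exactly, with τ and λ free (k = 2) — so the ratio holds to
machine precision. Model comparison uses AIC = 2k − 2 log L per family and
summed (3F vs 2F parameters); "simpler model rejected" means its AIC
exceeds the full model's.

## Sampling reconciliations and branch summaries

Histories are drawn by stochastic backtracking through the converged DP:
origination ∝ prior × root-clade likelihood, then at every (clade, branch)
state one term of P(u,e) ∝ its contribution; transfer recipients ∝ the
recipient-side likelihood. Invisible-event chains are already marginalised
by the DP denominators, so sampled histories contain only events that
shaped the observed tree: O, S, SL, D, T, TL. Ties carry no deterministic
preference; only the seeded RNG stream decides. Each sample records its
conditional log-probability; a zero-probability state aborts loudly.

Per-branch summaries are means over samples, and dataset tables sum those
means over families. Conventions (the reference tools expose these columns
without printed definitions; ours are):

* **transfers** counts transfers *received* (recipient side);
* **losses** are charged to the branch where the copy died (the lost child
  for SL, the donor for TL);
* **copies** is the number of lineages leaving the branch (sampled tips on
  terminals);
* **presence** is the fraction of samples in which ≥1 copy entered the
  branch;
* **singletons** is the fraction of samples with exactly one copy on a
  terminal branch (a documented interpretation);
* **vertical** counts copies entering the branch from its parent, so
  verticality V(e) = vertical/(vertical + transfers received) is the
  fraction of incoming lineages that are vertical; V is undefined (NaN)
  where nothing entered, and T/D is undefined where no duplications were
  inferred — a ratio over a zero count is not reportable as infinite.

## Rooting

Each candidate root (by default every branch of the unrooted topology; a
subset can be supplied) is scored by refitting every family's rates —
rate estimates are root-dependent — and summing the maximised
log-likelihoods. Within a family the first root's fit warm-starts the
remaining roots' optimisations (each root is still refit to convergence).
The AU test resamples *families* (the exchangeable units, as sites are in
sequence-based tree selection): multiscale RELL bootstrap at scales
0.5–1.4 (10 scales, n_boot = 10,000 by default), probit-scale weighted
least squares of z(σ) = d/σ + c·σ, p = 1 − Φ(d − c); degenerate fits fall
back to the plain bootstrap proportion nearest scale 1. Ties in the
per-replicate argmax are split fractionally, so an all-equal matrix yields
equal p-values. Fewer than 10 families is refused. The root region is
{candidates with p ≥ α} plus always the ML root.

## Simulator

`dtlrec.simulate` runs the same generative process forward with full event
logs, so the distributional agreement between simulator and likelihood is
the central cross-module oracle. Survivors-only filtering is on by default
for dataset generation (only observable families reach inference), with
discard counts reported so the extinction fraction stays testable; an
event cap (10,000) flags super-critical parameter draws instead of
truncating them silently. `observable_events` projects a raw log onto the
surviving history (extinct subtrees collapse into SL/TL losses or vanish),
producing the same vocabulary as the sampler — forward simulation and
posterior sampling are compared event for event in the tests. A vectorised
presence-pattern path (`simulate_presence_patterns`) supports
million-replicate checks in seconds.

What the synthetic studies do *not* show: robustness to gene-tree
reconstruction error (inputs are true simulated topologies or clean
CCP samples), to incomplete lineage sorting or hybridisation (unmodeled,
and known to inflate inferred transfers on real data), to incomplete
taxon sampling, or to branchwise rate variation. Conclusions about real
datasets inherit those caveats.

## Problem sizes and known limitations

The shipped test suite and `scripts/acceptance.py` run desk-scale studies
(8–16 leaf species trees, 10–300 families, 10⁴–10⁶ simulation replicates)
chosen so the full battery completes in minutes while keeping every
statistical check at its stated tolerance.

* **δ attenuation at low duplication rates.** At δ = 0.05 on a 16-leaf
  tree, the median per-family ML δ̂ over ≥10-copy families is ≈ 0.45× the
  truth (τ and λ medians are within 10%): a third of such families contain
  no surviving duplication, pinning their ML at the 1e-10 boundary, and in
  the undated model short-distance transfers absorb part of the remaining
  duplication signal. Medians are within a factor of two of truth for
  δ ≥ 0.15, or with ≥12-copy families. Per-family boundary estimates are
  expected behaviour, not optimiser failure (restart spread ~1e-7).
* **Survivorship bias.** Fitting survivor-filtered data without
  `condition_on_survival` biases λ̂ downward, increasingly so at high λ.
* AU p-values are asymptotic in the number of families; with few families
  the region is conservative (wide), which the tests exercise as the
  power/no-power contrast.
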