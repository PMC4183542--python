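# Methods

This note documents the statistical model the package implements, the
conventions and numerical choices behind it, what the synthetic-data
generators do and do not emulate, and the known limitations.

## The model

All analyses rest on the constant-rate birth–death process with speciation
rate λ and extinction rate μ, parameterised by the net diversification rate
`r = λ − μ` (per Myr) and the turnover `ε = μ/λ ∈ [0, 1)`. Three transition
quantities at an age `t` (Myr before present) drive everything:

    β(t) = (e^{rt} − 1) / (e^{rt} − ε)          geometric clade-size parameter
    α(t) = ε β(t)                                P(no extant descendant)
    P_s(t) = (1 − ε) / (1 − ε e^{−rt})           survival probability

A lineage of age `t`, conditioned on having extant descendants, leaves
`N ~ Geometric(1 − β(t))` species: `P(N = n) = (1 − β) β^{n−1}`, with mean
`e^{rt} / (1 − α(t))`. Unconditioned, `P(N = 0) = α(t)` and the positive
part is scaled by `1 − α`. Quantiles are closed-form
(`smallest n with 1 − β^n ≥ q`); no summation loops are used anywhere.

### Combined likelihood of a dated higher-taxon tree

The data are a rooted ultrametric chronogram whose terminals are higher taxa
(families, superfamilies), each carrying an extant species count `n_i` and a
stem age `t_i` (the age of its parent node), plus the observed internal
split times. The log-likelihood combines a phylogenetic part (density of
the internal splits under the reconstructed process, after Nee et al.) and a
taxonomic part (the geometric probability of each terminal's richness given
its stem age, conditioned on survival because sampled terminals are extant).

The reconstructed process conditioned on survival is a time-inhomogeneous
pure-birth process with per-lineage splitting rate `λ P_s(u)`, which yields
an exactly branch-additive form:

* every internal node at age `t_v` except the root contributes
  `ln(λ P_s(t_v)) = ln r − ln(1 − ε e^{−r t_v})`;
* every branch between internal nodes (parent age `a`, child age `b`)
  contributes `ln[(1 − β(a)) / (1 − β(b))]` (probability of no reconstructed
  split along the branch);
* every terminal contributes `ln(1 − β(t_i)) + (n_i − 1) ln β(t_i)`, which
  subsumes its pendant branch (for `n_i = 1` it reduces exactly to the
  pendant no-split factor).

Conventions: the likelihood is conditioned on the crown (root) age — the
root split contributes no term — and no labelled-topology constant
(`(N−1)!`) is included. With `ε = 0` the whole expression collapses to the
Yule likelihood `(#splits) ln r − r S` (`S` = summed branch time), whose
internal-only maximiser is the classic `r̂ = (N−2)/S`. On species-level
trees the expression equals the Nee et al. likelihood as coded in
`ape::birthdeath` minus exactly `ln (N−1)!`, and the maximum-likelihood
estimates agree with `ape::birthdeath` to the optimiser tolerance (both
facts are asserted in the test suite). Every model comparison in the
package uses likelihood differences, which are invariant to such additive
constants.

Additivity over branches means a partition of the tree into rate regimes
makes the total log-likelihood the sum of independent per-regime terms, so
"joint" refitting after a regime change decomposes into independent
per-regime optimisations.

### Maximum likelihood fitting

Optimisation works in transformed coordinates `(log r, logit(ε/0.999))`
with bounds `r ∈ [10⁻⁸, 10]` per Myr and `ε ∈ [0, 0.999]`. Analytic
gradients of the log-likelihood in `(r, ε)` are propagated through the
transform and used by L-BFGS-B from five deterministic starts (a moment
initialiser for `r` crossed with spread turnover values); the best solution
is polished by Nelder–Mead at tolerance 1e-10. During candidate scans a
"quick" mode runs two gradient starts (warm start from the incumbent regime
plus one heuristic) at looser tolerance; accepted models are re-polished
with the full schedule. With ε fixed, `r` is profiled by bounded Brent
search. A regime with no usable information (e.g. a single monotypic
terminal) raises a fit error; inside the stepwise search such candidates
are marked infeasible and skipped.

## Shift detection (stepwise AIC search)

A shift at node `v` uses *cut-at-stem* placement by default: the new regime
owns `v`'s stem branch, the split at `v`, and everything below except where
a deeper nested shift takes over (a node-cut variant that leaves the stem
with the parent regime is available behind a flag). Each accepted shift
adds three parameters (r, ε, location), so a model with `s` shifts has
`k = 2 + 3s` and `AIC = 2k − 2 lnL`.

Forward selection evaluates every node (root excluded) at each step. For
speed, a donor-fixed profile first scores all candidates by fitting only
the prospective new regime with the donor regime frozen at its current
parameters — a lower bound on the true gain — and the best 25 candidates
are then refitted exactly (both affected regimes). Ties break to the
smallest node id, making the search order-independent and deterministic.

**Acceptance threshold.** The default threshold corrects for the search
over candidate placements. With `m` candidate nodes, the best spurious
improvement on a shift-free tree behaves like the maximum of about `m`
χ²(3) variates; the default accepts a shift only if its AIC improvement
exceeds `qchisq(0.95^{1/m}, 3) − 6` (floored at 4; ≈ 14.6 for a 200-tip
tree). Correlation between nested candidates makes this conservative.
A fixed ΔAIC ≥ 4 rule is available but is *not* the default: on 200-tip
shift-free trees it accepts a spurious shift in essentially every
replicate, because the per-candidate penalty ignores the multiplicity of
the search. The measured operating characteristics at the default
(false-positive acceptance ≤ 10%, power ≥ 90% on a five-fold upshift of a
~50-terminal clade) are asserted by the acceptance tests and recomputed by
`scripts/acceptance.py`.

Direction of an accepted shift is classified by the richness-ratio
statistic below: "up" iff the clade's corrected richness exceeds its
expectation under the parental regime at the clade's stem age.

## Single-shift placement comparisons

The placement scan mirrors the classic two-rate likelihood-ratio analysis:
turnover is estimated once under the homogeneous model and then fixed; each
named candidate clade gets a two-regime fit in which only the two net rates
(`r_root`, `r_clade`) are free; candidates are ranked by likelihood and
compared by `χ² = 2 ΔlnL` (clipped at zero) against a caller-supplied
degrees of freedom — 3 against the uniform model and 1 between alternative
placements by the conventional accounting, which the package reports
without endorsing its derivation. Candidates are resolved from terminal
labels via their MRCA, never from node numbers.

## Richness ratios at shifts

For a shift clade with stem age `t`, the observed richness *corrected for
nested shifts* is the sum of `n_i` over terminals governed by the focal
regime plus one lineage per immediately nested shift (each nested radiation
re-enters as a single stem lineage; the field leaves this correction
undefined, so the rule is isolated in one function and documented here as a
swappable choice). The expectation and the 2.5/97.5% quantiles come from
the survival-conditioned clade-size distribution at the stem age under the
*parental* regime; the interval on the ratio is the clade-size interval
transformed (`obs/q_hi`, `obs/q_lo`) rather than an interval computed on
the ratio directly. Ages are stem ages, consistent with cut-at-stem
placement. The discrete 95% interval slightly over-covers (e.g. 0.952
theoretical at mean clade size ≈ 150); the coverage test accounts for this.

## Ensemble robustness

Dating uncertainty is propagated by rerunning the identical stepwise search
on each member of a fixed-topology ensemble of dated trees and tallying,
per candidate shift clade, the fraction of trees in which a shift with
exactly that terminal leafset is accepted. Matching is exact-leafset only
(auditable; well defined under shared topology); shifts placed at a
reference clade's parent or child are reported separately as near-misses
rather than fuzzily merged. Fractions are binned at 80/50/30%. Reference
shifts recovered nowhere still appear with fraction 0. Per-tree results
can be cached to disk, making long scans resumable.

## Lineage-through-time curves

Reconstructed-lineage counts as step functions of age: 1 on the stem, 2
from the crown split, +1 per subsequent split. Ensemble envelopes evaluate
each tree's curve on a common grid (200 points from the oldest crown age to
the present by default) and take 2.5/50/97.5% quantiles across trees. Only
extant-surviving lineages are counted. For pure-birth trees the slope of
the mean log-lineage curve estimates `r` (tested property).

## Synthetic data

Four generators cover the data shapes the analyses assume; all randomness
flows through seeded `numpy` generators and identical seeds give identical
trees.

* **Birth–death simulator** (`simulate_bd`): per-regime Gillespie
  simulation; extinct lineages pruned to the reconstructed tree. Stopping
  rules: crown age (two founding lineages, conditioned on both surviving by
  resimulation), stem age (one founder; optionally unconditioned), or a
  tip-count stop (simple first-passage sampling). `simulate_with_shift`
  switches one lineage alive at a set time to a second regime and records
  the true shifted clade for scoring.
* **Higher-taxon collapse** (`collapse`): terminals are the lineages
  crossing a collapse age, carrying the extant richness beneath them;
  structure older than the collapse age is retained. *Known limitation:*
  threshold-defined terminals condition their stem branches on having no
  split older than the collapse age, which the stem-age geometric terminal
  likelihood (the field's convention, kept here) ignores. On Yule trees
  with mean clade size ~10–30 this mismatch biases `r̂` downward by ~8–9%.
  The bias is a property of the emulation, not of the estimator; it is
  measured and reported by `scripts/acceptance.py`.
* **Exact taxon-tree sampler** (`simulate_taxon_tree`): simulates the
  backbone directly as the reconstructed process (pure birth at rate
  `λ P_s(u)`, via thinning) and decides *at each lineage's birth*, by an
  independent coin flip, whether it becomes a terminal higher taxon (with
  geometric richness at its stem age) or stays on the backbone. Because
  terminal status is exogenous, the fitted likelihood is the exact density
  of the output; this is the generator used for parameter-recovery oracles
  (measured median |r̂ − r|/r ≈ 3% at ~200 terminals) and for shift-free
  null trees.
* **Pseudo-posterior** (`pseudo_posterior`): multiplies each internal node
  age by an independent lognormal factor `exp(σZ)` (median-unbiased) and
  restores parent-older-than-child top-down by shrinking violators back to
  their original fraction of the parent age. This emulates only "node ages
  vary, topology fixed"; it is not a model of any real dating posterior
  (no covariance between neighbouring nodes, no calibration effects), which
  is all the robustness machinery requires.

### What passing tests show — and don't

The simulation designs are idealised: constant rates within regimes, one
regime change per shift, exogenous taxonomy in the recovery oracle, and
independent node-age jitter. Passing them shows the estimators and the
search are correct and well-calibrated *under the model's own assumptions*;
it does not certify behaviour under rate variation through time,
diversity-dependence, incomplete sampling of higher taxa, or realistically
correlated dating uncertainty, all of which are out of scope.

### Study-scale problem sizes

The statistical checks run at sizes chosen to be representative yet
economical: ~200-terminal trees for recovery and false-positive studies
(100 replicates each), 10⁴ replicates for Monte-Carlo agreement of the
simulator with the transients, 10³ for interval coverage, and tens of
ensemble samples for robustness demonstrations (the machinery accepts any
ensemble size; 500 is the conventional scale for real analyses).

## Degenerate inputs and edge cases

Polytomies are resolved arbitrarily into zero-length branches with a
warning. Tips are snapped to age 0 within a relative tolerance of 1e-6 of
the root age; larger deviations are errors naming the worst offender.
A shift placed at the root is accepted by `try_shift` as a degenerate
refit (ΔlnL = 0) but is excluded from the search's candidate set. Regimes
emptied by later shifts keep their parameters and are flagged. β is
evaluated in log space throughout; at extreme `r·t` (where `β` rounds to 1)
quantiles switch to a `log β ≈ −(1−β)` expansion rather than overflowing.
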