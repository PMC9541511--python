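# Methods

## Model

The character is a three-state continuous-time Markov chain (CTMC) on
(NON, FT, SYM) = (nonnodulating, fixation-thread nodules, symbiosome
nodules), indices (0, 1, 2), evolving independently along each branch of a
rooted, ultrametric chronogram with lengths in Myr. A model is a boolean
off-diagonal mask of allowed transitions, one non-negative rate per allowed
transition (events · lineage⁻¹ · Myr⁻¹), and a root prior. The default mask
allows only FT→NON, FT→SYM and SYM→NON — the single-gain, multiple-losses
reading of nodule evolution: nodulation is never regained once lost (NON
absorbing) and the FT→SYM change is not reversed. The default root prior is
degenerate at FT. The implementation is a general masked CTMC, not a
reversible one, so an all-transitions mask or a uniform root prior are
ordinary configurations rather than different code paths.

Assumptions worth stating: rates are homogeneous across branches and clades
(no hidden states, no rate shifts); the chronogram is treated as known
(node-age uncertainty from the dating analysis is not propagated); tips are
conditionally independent given the tree and Q.

## Likelihood and fitting

Tip observations map to state-likelihood vectors (`nonnodulating` (1,0,0),
`ft` (0,1,0), `sym` (0,0,1), `nodulating_unknown_type` (0,1,1), `unknown`
(1,1,1)); the vectors per category are configurable, so alternative
weightings of missing data (e.g. half weight on nonnodulating, a quarter on
each nodulating type) are expressible without code changes.

The likelihood is computed by the pruning recursion with per-node rescaling
by the maximum partial likelihood and log accumulation, which keeps deep
trees away from underflow. Polytomies are handled natively (the recursion
multiplies over any number of children). Branch transition matrices
P(t) = exp(Qt) come from a batched scaling-and-squaring Padé(7)
exponential specialized to stacked 3×3 generators (one call per likelihood
evaluation for all branches; cross-checked against `scipy.linalg.expm` in
the tests, agreement ~1e-15). Entries that are unreachable under the mask's
transitive closure are pinned to exactly zero, so irreversibility is
structural rather than approximate; t = 0 returns the identity without an
exponential call. Data that are impossible under the constraints (e.g. an
FT tip that would require a disallowed transition) raise an explicit
impossible-data error rather than returning −inf.

Rates are fitted by L-BFGS-B on log-rates, bounds [1e-8, 10] events/Myr,
with five seeded log-uniform random starts plus one start at 1/tree-height
(the scale at which roughly one event per root-to-tip path is expected);
convergence tolerance 1e-8 on the log-likelihood. A fit on all-uninformative
tips raises a non-identifiability error. When no change is observed the MLE
sits at the lower bound; the optimizer stops within its tolerance of the
bound, so "zero" rates are reported as ~1e-7 or smaller — negligible at any
tree scale used here.

## Stochastic mapping

Each map is one exact draw from the joint posterior of the full history
given the tips:

1. **Node states** by pre-order sampling: root ∝ root_prior × partial,
   each child ∝ P[parent state, ·](branch) × partial. Ambiguous tips get a
   concrete state like any node.
2. **Branch paths** by endpoint-conditioned uniformization: dominating rate
   μ = 1.05 × max|q_ii|; the jump count is drawn from its exact conditional
   distribution (Poisson(μt) weighted by powers of the uniformized chain
   R = I + Q/μ, with the Poisson series truncated at cumulative mass
   1 − 1e-12); jump states by a forward pass against backward powers of R;
   self-jumps discarded; event times are uniform order statistics.
   Uniformization is used instead of rejection sampling because conditioned
   rare transitions (a single FT→SYM gain on one branch) make rejection
   arbitrarily slow; rejection survives as the independent oracle in the
   tests. A branch whose endpoints are equal and whose state cannot leave
   and return under the mask is emitted with zero events directly.

Randomness is counter-based: history i uses stream (seed, i) for node
states and (seed, i, branch) for each branch path, so runs are reproducible
byte-for-byte regardless of traversal order, and histories are independent
across indices.

## Summaries

* **Node proportions**: fraction of maps in each state per node.
* **Majority-rule transitions**: each node takes its modal state; every
  branch whose endpoints have different modal states contributes one
  transition (so a parent in FT with both children in NON yields two
  simultaneous "double losses"). Exact modal ties are flagged and their
  incident branches reported unresolved, never broken randomly.
* **Age bounds**: a transition on a branch happened between the parent's
  age (max) and the child's age (min); per-class spans aggregate the maximum
  ages, matching how "maximum ages of losses" are quoted in comparative
  work.
* **Loss rates**, two readings: the fitted Q entries (primary), and
  realized per-history rates (events of a class ÷ dwelling time in the
  source state, with 2.5/97.5 percentiles; histories with zero source dwell
  are excluded and counted). Both are reported because published rate
  figures can refer to either.

## Synthetic data

The generator emulates the statistical structure the analysis assumes: a
Gillespie birth–death tree conditioned on the number of extant tips by
rejection (observed just before the next event after reaching n, so the
n-tip interval has positive length; extinct lineages pruned; optional
rescaling to a target crown age), a forward CTMC simulation of the trait
from a known root state, and independent per-tip masking into `unknown`
(probability p_unknown) or, for nodulating tips, `nodulating_unknown_type`
(p_type_unknown). Truth tables are emitted before masking.

Default scenario: 150 tips, birth 0.15 / death 0.05 per Myr, crown age
60 Myr, root FT, rates FT→NON 0.0174, SYM→NON 0.0028 (published fitted
values for this system) and FT→SYM 0.002 — a construction chosen to yield
on the order of one gain per tree, not an estimate; masking 10% unknown,
15% type-unknown, roughly matching the share of unscored and
unknown-type genera in such genus-level datasets.

What the generator does **not** emulate: the empirical system's single
*early* FT→SYM gain that founded one large SYM clade. Under homogeneous
rates, gains arise anywhere on the FT-dwelling part of the tree and are
usually recent, so synthetic replicates carry only a handful of SYM tips.
Consequently the SYM→NON rate is often unidentified in a replicate (no SYM
losses to observe), and the ensemble summaries report medians for fitted
rates for robustness against the resulting optimizer-boundary fits, with the
FT/SYM rate ratio reported as 0 when the denominator is not identified.
Passing tests on these data therefore demonstrate correctness of the
machinery and recoverability of FT-ancestry quantities at study scale — not
that every quantity of a specific empirical dataset is recoverable.

## Validation experiments and problem sizes

The test suite validates each stage against an independent route: the
pruning likelihood against brute-force enumeration over internal-node state
assignments (100 random trees of ≤ 6 tips, agreement 1e-10); transition
probabilities against closed forms (1e-12) and `scipy.linalg.expm`; the
conditioned path sampler against a vectorized rejection oracle (10⁵ draws,
every count class within 3 SE); the joint node-state sampler against
enumerated exact conditionals on a 4-tip tree (10⁵ draws, 3 SE); the
forward generator against pruning pattern probabilities (2×10⁴ draws).

Two ensemble experiments run at reduced but informative sizes chosen for a
desk-scale suite. Rate recovery: 20 replicates of a 300-tip, 80 Myr
chronogram under rates (0.02, 0.01, 0.005), refitted from tips alone. This
regime is deliberately harsh — q·height = 1.6 for FT loss means many
replicates are heavily absorbed into NON, and the smallest rate is then
weakly identified, so joint ±50% recovery of all three rates holds only in a
minority of replicates; the test documents that bar even though the present
estimator (verified exact in likelihood and optimum) does not clear it.
End-to-end transition recovery: 20 replicates at 200 tips, 60 Myr, rates
(0.0008, 0.0003, 0.0004) and 2% + 2% masking — a strong-signal operating
point chosen by power analysis, since true transitions hidden on the pendant
branch of a masked tip are unrecoverable by any method — requiring the
majority-rule transitions to equal the true simulated branch-level
transitions in ≥ 90% of replicates.

## Limitations

* No rate heterogeneity, hidden precursor states, or MCMC over Q: maps are
  empirical-Bayes draws under the single ML-fitted Q, so downstream spreads
  understate total uncertainty relative to integrating over Q.
* Node-age uncertainty of the input chronogram is not propagated; age
  bounds are conditional on the supplied tree.
* Majority-rule transitions are a point summary of marginal modal states;
  adjacent-branch placements of a transition can flip when a node's
  posterior is nearly tied (ties themselves are flagged).
* The taxon matcher is deliberately conservative (exact match after
  whitespace/underscore normalization, no fuzzy matching).
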