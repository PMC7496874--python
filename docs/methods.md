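# Methods

This note documents the models, numerical methods, default choices and
known limitations of the package. It is the companion to the README's
quick tour; nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The eco-evolutionary model

### Individuals

Consumers are size-structured and feed on two food sources. Body mass
`w = x + y` splits into irreversible mass `x` (bones, organs) and
reversible mass `y` (fat, gonads); feeding, maintenance and growth
depend only on `w`, so the deterministic life history can be followed in
total mass while the x/y split matters for metamorphosis (the mass loss
comes out of `y`) and for starvation in the stochastic simulator.

Feeding follows the multi-prey Holling disc equation with hump-shaped
attack rates,

    a_i(w, psi) = s_i(psi) * A_i,max * (w/w_opt,i * exp(1 - w/w_opt,i))**alpha_i
    I_i = a_i X_i / (1 + H(w) * (a_1 X_1 + a_2 X_2)),   H(w) = xi1 * w**(-xi2)

with `s_1 = (1 - psi)**k`, `s_2 = psi**k` (k = 1 by default) the
specialization scaling, and the secondary food inaccessible below the
mass threshold `w_min`. An effort-split ("preference") formulation was
considered and rejected: with a shared handling time, splitting foraging
effort can only lower total intake, so the optimal diet is to take both
foods as encountered — which is exactly the disc equation. The
`diet_preference` function reports the realized encounter share.

Assimilated intake (efficiency `kappa_e`, food-to-mass conversion
0.001 g/mg) first covers maintenance proportional to `w`; positive net
production grows `x` and `y` toward the target ratio `q_ratio`; adults
route their surplus to reproduction (determinate growth by default,
`kappa_adult = 0`). Negative net production drains reserves only.

Four traits evolve: larval specialization `psi_L`, extent of
metamorphosis `theta`, mass at metamorphosis `w_J`, and offspring mass
`w_b`. Post-metamorphic specialization is the composition
`min(1, psi_L + theta)`. Metamorphosis at `w_J` kills with probability
`rho * theta` and removes the fraction `meta_loss * theta` of reversible
mass. The offspring cost is `egg_overhead + egg_cost_per_gram * w_b`;
when `w_b >= w_J` metamorphosis happens before birth: the survival
factor `1 - rho*theta` applies at birth and the mother's per-offspring
cost is inflated by the factor `1 + meta_loss*theta*q/(1+q)` (the
metamorphic mass loss she internalizes).

### Life-history integration

Within a life stage the background mortality is constant, so survival is
an exact exponential in age and every life-history quantity (age,
survival, lifetime ingestion of each food, residence-time abundance) is
a smooth 1-D integral over mass. These are evaluated with adaptive
Clenshaw–Curtis panels (40 Chebyshev–Lobatto nodes per panel, bisection
until the trailing Chebyshev coefficients certify ~1e-12 convergence,
with a global panel budget against pathological refinement). Growth
stalls (`net production -> 0` inside a stage) cut the trajectory just
short of the stall mass; the individual then sits there consuming food
until death (a stationary tail), with zero subsequent reproduction.
An independent age-domain ODE integration of the same life history is
kept in the test suite as the cross-check.

### Equilibrium

A resident equilibrium solves `R0(X1, X2) = 1` together with the two
semichemostat balances `delta*(Xi,max - Xi) = b * Gamma_i`. The robust
path ramps the population birth rate `b` up from the consumer-free state
(warm-starting the inner 2-D resource balance along the way, which keeps
the solver on the branch connected to the consumer-free state when the
balance is multivalued), brackets the sign change of `log R0`, and
polishes with a 3-D quasi-Newton to residuals below 1e-10. When the
population cannot persist even at maximum food, the trivial equilibrium
is returned exactly. Stage abundances are reconstructed from the
survival-weighted residence times of the life history scaled by `b`.
Dynamical (ecological) stability of the equilibrium is not assessed; the
individual-based model is the qualitative probe.

### Adaptive dynamics

Invasion fitness is `log R0` of the mutant in the resident's equilibrium
environment (sign-equivalent to the invasion exponent at an equilibrium
and far cheaper). Gradients are central differences (step 3e-4,
one-sided at trait-box edges) in a scaled trait space where all traits
are O(1) (masses divided by `w_A`). Singular strategies are found by a
damped finite-difference Newton iteration with projection onto the
boxes; traits pinned at an edge by an outward gradient are treated as
boundary components (the direct-development endpoint `psi_L = 1,
theta = 0` is such a boundary CSS). When the Newton direction stalls
(near-singular Jacobian, e.g. close to a fold) the search falls back to
damped selection-gradient flow. Classification combines the mutant
Hessian at fixed environment (evolutionary stability) with the Jacobian
of the selection gradient under an identity mutational covariance
(convergence stability); eigenvalues within 1e-4 of zero flag the
verdict as indeterminate rather than guessing.

Continuation in a parameter uses natural-parameter stepping with secant
prediction and step-halving on failure. Three terminal events are
detected: **internalization** (`w_b` reaches the post-metamorphic mass
`(1 - meta_loss*theta*q/(1+q)) * w_J`, i.e. newborns at least as large
as fresh metamorphs — the loss of metamorphosis; refined by bisection),
**extinction** (`b* -> 0`), and **fold** (root loss with the resident
still viable). In the calibrated preset the high-secondary-supply branch
ends by internalization, the low-supply branch by extinction; both
match the reference account of this model family, in which the
endpoint of the metamorphosing branch is the CSS merging with a
repeller.

The canonical equation `d(traits)/dt = rate * N* * gradient` uses the
identity mutational covariance, an adaptive Euler step (halved while the
gradient direction keeps reversing, which prevents orbiting around
interior optima) and explicit handling of the non-smooth specialization
cap: when `psi_L + theta >= 1`, the joint direction `(+psi_L, -theta)`
leaves feeding unchanged while shedding the theta costs, and the
integrator follows this Filippov sliding motion along the cap. Without
it, coordinate-wise gradient dynamics deadlock on the cap (raising
`psi_L` alone is neutral, lowering `theta` alone loses feeding), even
though every finite-mutation path to the direct-development endpoint is
fitness-increasing. Time is reported in scaled evolutionary units; the
mutation-rate-times-variance prefactor is folded into `rate`.

### Individual-based model

A hybrid scheme: within a time step (default 0.25–1 d) every individual
grows deterministically by the same bioenergetics; at step boundaries
deaths (background, metamorphosis, starvation below `y/x = q_starv`) and
births (Poisson with the fecundity-rate expectation, per-trait Gaussian
mutation truncated to the boxes) are drawn; resources follow a
semi-implicit semichemostat update driven by realized consumption. Runs
are bit-reproducible given the seed. The step size is a configuration
knob; the suite checks that large-volume, mutation-off runs track the
deterministic equilibrium within 5%.

## Parameterization

The packaged presets are calibrated stand-ins, not transcriptions of
published parameter tables: the `fat_reserves` preset was built from
the standard functional forms of this model family (Persson-style
humps, power-law handling, linear maintenance) and calibrated — before any acceptance test was written —
to reproduce the reference observables of that regime: supply-rate axes in
`delta*X1_max ~ [0.001, 0.01]` mg/L/day at `delta*X2_max = 0.0165`; a
metamorphosing CSS with `psi_L = 0` and `w_b < w_min < w_J < w_A` whose
offspring mass rises and whose metamorphosis accelerates as primary
supply falls; internalization at low primary supply for high secondary
supply; extinction without internalization (with a viable
direct-development alternative) at `delta*X2_max = 0.0066`; and loss of
evolutionary stability of direct development at high primary supply.
Two calibration lessons are recorded here because they are substantive:
stage-biased mortality (larvae dying faster than juveniles) makes early
metamorphosis a pure survival bonus and collapses `w_J` to its floor, so
background mortality is equal across stages; and `theta` pins at its
upper bound at the calibrated CSS because post-metamorphs at
post-metamorph sizes get nothing from the primary food, so full
specialization always pays — the transition narrative is unaffected
(after internalization `theta` relaxes to 0 while `psi_L -> 1`).

The `generic_invertebrate` preset is a similarity-scaled variant (masses
a fifth, handling rescaled as `xi1 ~ s**(xi2-1)` so relative growth
rates are preserved, most body mass in the reversible pool). The
`toy_symmetric` preset makes the two foods exactly exchangeable, which
puts the singular specialization at exactly 1/2 — the closed-form anchor
for the singular-strategy machinery.

## The phylogenetic engine

Two binary traits (direct development D, large eggs E) evolve on a
rooted, dated tree as a joint 4-state CTMC over
`((0,0), (0,1), (1,0), (1,1))` with structural zeros on dual
transitions. The independent model has 4 free rates, the dependent model
8, and the constrained model 7 (the two gains of D share one rate:
"gaining direct development does not depend on egg size").

Likelihoods use Felsenstein pruning over the joint states, vectorized by
tree level (one batched matrix-vector product per level, per-level
rescaling against underflow), with branch transition matrices from one
eigendecomposition of the generator (expm fallback when
ill-conditioned). Missing trait values enter as ambiguity over the
matching states; polytomies are handled natively (equivalent to
zero-length resolution). The root prior defaults to uniform over the
four states — the choice under which the independent model's likelihood
factorizes exactly into two single-trait likelihoods — with a
stationary-distribution option.

MCMC is Metropolis–Hastings with log-normal multiplier proposals (one
coordinate at a time, plus an occasional global rescaling of all rates,
which crosses the wide likelihood plateau at fast rates; scale adapted
during burn-in only) under the hierarchical prior `rate ~ Exp(mean m)`,
`m ~ Uniform(0, 100)` — a fixed-dimension stand-in for a reversible-jump
rate-grouping hyperprior, which is an extension point, not implemented.
A consequence worth knowing: rates that are structurally zero in truth
get small-but-positive posterior medians rather than exact zeros.

Marginal likelihoods use stepping-stone sampling along the power ladder
`beta_k = (k/K)**(1/0.3)` with one chain per rung. The ladder is walked
downward (posterior to prior), each rung warm-started from the hotter
one: chains near the posterior locate the high-likelihood region once
and the colder rungs inherit it. This matters in practice — with the
diffuse hierarchical prior, a cold-started upward ladder at desk-scale
chain lengths can miss the posterior mode at intermediate rungs and
underestimate the marginal likelihood of the richer model badly enough
to flip a Bayes factor's sign; the downward ladder gives
sign-stable estimates at a fraction of the chain length. The log Bayes
factor is `2 * (logZ_dep - logZ_indep)`
with the conventional verbal categories (>2 support, >10 very strong).
The machinery is generic over a small model interface; the suite wires a
conjugate exponential-Gamma toy with closed-form evidence through the
same code path and requires agreement to 0.1 nats at 30 stones.

## Synthetic data

Trees are pure-birth (Yule), ultrametric, optionally rescaled to a
target root age; traits evolve by exact Gillespie simulation down each
branch (dual transitions impossible by construction; an event log is
available for auditing). Default missingness (21% of D, 72% of E)
emulates the partial trait coverage of real compilations. The default
generating rates for recovery experiments are of order 0.005 per Myr on
trees of root age ~300 Myr, the realistic regime for the application.
What the generator does not emulate: the topology imbalance, extinct
lineages and sampling biases of real phylogenies, and any correlation
between missingness and the trait values — so passing recovery tests
demonstrate correctness of the inference machinery under the model, not
robustness to real-data pathologies.

## Problem sizes in the checks

The acceptance suite and `scripts/acceptance.py` run at desk scale:
continuation with ~8–25 points per branch, stability-loss bisection to
~1e-4 in the supply rate, rate recovery on one 500-tip tree with
40k-generation chains, stepping stone with 20–30 stones of 4–8k
generations, the individual-based check at 2e5 L for 2500 days, and
60–100 random strategies for the neutrality sweep. These sizes were
chosen so the full set completes in tens of minutes on one CPU.

## Known limitations

- The thresholds printed by the continuation engine depend on the
  calibrated stand-in preset; they land near but not exactly on the
  reference values it was calibrated against (see the README's
  reproduction section).
- Ecological equilibria are assumed stable; the cycling regime at low
  `w_min` reported for such models is only probed stochastically.
- The canonical equation's sliding-mode treatment of the specialization
  cap is a modeling choice for a genuinely non-smooth flow; the
  individual-based model, which needs no such choice, shows the same
  transition.
- The Bayesian engine's hierarchical prior cannot produce exact-zero
  rate estimates (no reversible jump), and single-chain marginal
  likelihoods carry Monte Carlo error that the stepping-stone
  replicate spread should be used to quantify.
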