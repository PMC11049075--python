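# Methods

`protentia` implements a discrete multi-agent active-inference stack in
three layers: finite categorical probability and polynomial interfaces,
a single-agent POMDP engine, and a multi-agent layer whose shared world
models are treated sheaf-theoretically.  This note records the models,
the conventions that were genuinely open, the defaults and why, and what
the synthetic scenarios do and do not establish.

## Generative models and state inference

An agent's model is a finite POMDP `(S, O, U, A, B, C, D, E, γ)`:
likelihood `A(o|s)`, per-action transitions `B_u(s'|s)`, an observation
preference distribution `C`, state prior `D`, action habit `E`, and an
action precision `γ ≥ 0`.  All tables are column-stochastic to 1e-9 and
vectors are aligned by label order only — operations never align by
position across differently labelled sets.

Perception evaluates the variational free energy of a belief `q` given
observation `o` and prior `p`:

    F = E_q[ln q(s) − ln A(o|s) − ln p(s)]
      = D_KL[q ‖ posterior] − ln P(o)        (divergence − log evidence)
      = D_KL[q ‖ p] − E_q[ln A(o|s)]         (complexity − accuracy)

Because state spaces are finite and small, the variational minimum is
attained exactly by the Bayesian posterior `q(s) ∝ A(o|s)·p(s)`, so
`exact_posterior` *is* the inference step and the divergence term
vanishes there; an iterative optimizer would add nothing but error.
Degenerate inputs: an observation with zero marginal likelihood is an
error (there is no posterior), and logarithms inside energy evaluations
clamp probabilities at `1e-16` so objectives stay finite.
`kl_divergence` alone returns `+inf` on an absolute-continuity failure,
because it is a diagnostic rather than an optimization target.

## Action selection

Each candidate action's one-step predicted state distribution
`q_u = B_u·q` is scored by the expected free energy

    G(u) = D_KL[Q(o|u) ‖ C] + E_{q_u}[H[A(·|s)]]     (risk + ambiguity)
         = −(expected information gain) − E[ln C(o)]  (epistemic + value)

with the predictive joint fixed as `Q(o,s|u) = A(o|s)·q_u(s)` and the
posterior term inside the information gain given by exact Bayes under
that joint.  This convention is what makes the two printed
decompositions *identities* of one another (verified to 1e-9 on random
models) rather than approximations.  Preferences are time-invariant and
apply to the next observation; if `C` puts zero mass on a predicted
observation the risk is reported as `+inf` and flagged, not raised.

Actions are drawn from `P(u) = σ(ln E − γ·G(u))`.  Exact zeros in the
habit survive (a hard habit dominates any finite `G`), and a uniform
habit reduces the rule exactly to the precision-weighted softmax
`σ(−γ·G)`.  Ties in any argmax are broken by label order.  The step
order is: observe → infer → evaluate G → act → propagate the prior
through the chosen action's transition.

Depth-limited planning (`rollout_policies`) enumerates all `|U|^depth`
action sequences and accumulates per-step `G` additively, propagating
the belief open-loop (`q ← B_u q`, never conditioned on imagined
observations).  This is deliberately the simplest, fully enumerable
convention; it evaluates fixed sequences, not closed-loop decision
trees, and consequences of this choice for the T-maze are discussed
below.

## Polynomial interfaces

A polynomial `p = Σ_{i:p(1)} y^{p[i]}` stores finitely many positions
(configurations an agent may adopt) with one finite direction set each
(sense data admissible there).  Monomials `A·y^S` recover the classical
Markov blanket with total set `A×S`.  Morphisms are forward-on-positions,
backward-on-directions pairs; the stochastic variant makes each backward
component a conditional distribution (stochastic feedback).  The tensor
`p⊗q` juxtaposes interfaces; the hom `[p,q]` internalizes interaction
patterns, its positions being the morphisms `p → q`.

Enumeration is exhaustive and eager below an explicit cap (default 10^5
morphisms) and refuses above it with the predicted count — nothing is
silently sampled.  Isomorphism of finite polynomials is decided by
cardinality profile (position count plus the sorted multiset of
direction-set sizes), which characterizes them up to relabelling.  For
the currying law `[p,[q,r]] ≅ [p⊗q,r]` the direction-set size of a hom
position depends only on the forward component, so both sides' profiles
are computed combinatorially in exact integer arithmetic; the
combinatorial profile is cross-checked against literal enumeration
wherever the latter is feasible.  Morphism equality is on-the-nose (not
up to relabelling) throughout.

A POMDP corresponds to a dynamical system `S·y^S → O·y^U`: the output
function emits the observation, the update applies `B_u`.  Output
emission is stochastic (sampled from `A`) by default, which is the
faithful POMDP reading; a deterministic-output mode exists and is
admissible only for noiseless likelihoods.  The translation round-trips
the tables exactly, and its trajectories are bit-identical to a direct
simulation loop given the same generator, because all sampling flows
through one shared primitive.

## Multi-agent ensembles

In an ensemble every agent's model conditions its transitions on the
*joint* action of the group (its action set is the product of all
agents' action sets), while it observes through its own channel.  The
group's boundary is the tensor of individual interfaces.

Theory of mind is recursive simulation under a shared-model assumption:
each agent holds veridical copies of its companions' models and predicts
a companion's action distribution by simulating that companion's
decision from the agent's own current belief; inside the simulation the
companion's own predictions recurse one level shallower, bottoming out
at the habit marginal (depth 0).  Default depth is 1.  The agent then
marginalizes its joint-action `G` over these predictions and selects its
own action by the habit-weighted softmax on the marginal — the minimal
decision rule consistent with joint-action models.  Agents never observe
companions' actions directly; the next prior likewise marginalizes the
transition model over predicted companion actions.  A one-agent ensemble
reduces bit-identically to the single-agent loop.  Misspecified (non-
veridical) companion models are expressible by constructing `AgentSpec`s
by hand but are not part of the tested contract.  Predicting companions'
*beliefs* as explicit hidden states, rather than their actions via
simulation, is a possible extension not implemented here.

Synchrony metrics per step: mean pairwise symmetrized KL between
posteriors, mean log-probability assigned to companions' realized
actions (≤ 0, with 0 exactly under deterministic correct prediction),
and the summed variational free energy as a joint free-energy proxy.

## Sheaf layer

The shared base space is a finite set of sites; each agent owns a patch
and the patches cover the base.  A section assigns one categorical
vector per site of the patch; restriction maps are identity on shared
sites, the minimal faithful instance for finite covers (marginalization-
style restrictions are an extension point).  Gluing requires agreement
on overlaps: the obstruction report carries per-pair, per-site squared
Euclidean distances, their total (the disagreement energy), and the
maximum site discrepancy in total variation; `check_gluing` compares the
TV discrepancy against the tolerance, and `glue` averages the agreeing
vectors per site.

Consensus is synchronous mean-diffusion: every agent's vector at a
shared site moves a fraction `η ∈ (0,1]` toward the mean of the agents
present there.  The update is a convex combination of normalized
vectors, so renormalization only guards floating-point drift.
Differences at a fully shared site contract by `(1−η)` per step, so the
energy decays geometrically (factor `(1−η)²` in the two-agent case) and
the trace is provably non-increasing — the reason squared Euclidean
distance, not KL, is the energy; a KL-based figure is available as a
diagnostic through the KL utilities.  The literature offers many
consensus schemes; none being fixed by the problem, the simplest rule
with a convergence proof is canonical here.

Spatial generative models respect base geometry: every hidden state is
assigned a site and every site lists its admissible observations;
`validate_spatial_model` passes iff the likelihood puts zero mass on
inadmissible (state, observation) pairs and otherwise lists the
violations.  Disagreement energy over sections built from agents'
predictive beliefs is the package's quantitative operationalization of
*shared protentions*: a group shares protentions to the degree that its
members' anticipatory world models glue.

## Synthetic scenarios

**Random models** draw all columns from a documented uniform-primitive
recipe: weights `(−ln U_i)^{1/c}` normalized, exactly a flat Dirichlet
at concentration `c = 1` and approaching uniform as `c → ∞`.  The
recipe avoids depending on any library's Dirichlet stream, so the models
are reproducible from any uniform generator.

**T-maze.**  Four locations (center, two absorbing arms, a cue site)
crossed with two static reward contexts; the cue observation reveals the
context with accuracy 0.98 by default.  Preferences are neutral at the
cue site; the reward observation carries log-preference +3 and the null
outcome −4.  The punishment-heavier asymmetry is what makes blind arm
entry expensive relative to the cue's mild ambiguity cost
(`H(0.98) ≈ 0.098` nats): under the open-loop rollout convention each
step's `G` takes one of a few values, a cue step costing
`H(a) + (c_reward + c_null)/2 ≈ −0.40` nats *less* than a blind arm
step, so every depth-2 policy that starts at the cue strictly undercuts
every policy that commits to an arm.  With symmetric preferences
(`c_null = −c_reward`) the two step costs would differ only by the
ambiguity term and blind arm entry would win — the fixture is built so
that information-seeking is the rational policy, which is the behavior
the acceptance suite pins down.  Open-loop evaluation cannot express
"read the cue, then go to the indicated arm" as a single policy; in the
closed loop (`agent_step` re-planning each step) the agent does exactly
that, as the worked example shows.

**Shared worlds.**  The world state is a token on a ring of `n_sites`
sites; each agent votes left/stay/right and the summed vote is applied
with probability 0.9.  Observation channels are noisy identities
(accuracy 0.8 by default — informative but fallible, so tracking is
non-trivial); priors diverge by mixing a per-agent point mass (weight
0.9) into the uniform distribution.  Sections over the chained cover are
generated from a single consistent base assignment (Dirichlet draw mixed
half-and-half with uniform, so every coordinate retains at least 1/6
mass), then each overlap site of the higher-indexed agent is perturbed
by moving exactly ε mass from its largest to its smallest coordinate —
hence the maximum site discrepancy equals ε in total variation by
construction, and ε = 0 glues at tolerance 1e-12.

What these scenarios do not show: the generators produce small, fully
specified, stationary worlds with veridical agent models.  Passing tests
demonstrate the internal consistency of the objectives, the algebra, and
the dynamics — not that the method scales to large state spaces, handles
model misspecification, or describes any particular empirical system.

## Problem sizes and numerical defaults

Identity suites run 200 seeded random models (3–4 states); the
polynomial grid covers all shapes with ≤2 positions and ≤2 directions
(125 triples) plus ≤3×3 section-count checks; ensembles run 2 agents ×
100 steps × 20 seeds; consensus sweeps 50 seeded 3-agent covers.  These
sizes make every property exhaustively or densely checkable while
keeping the whole suite around half a minute.  Normalization tolerance
is 1e-9 everywhere a distribution is constructed; identity assertions
use 1e-9 (accumulated sums) or 1e-12 (direct algebraic identities);
the log clamp is 1e-16.
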