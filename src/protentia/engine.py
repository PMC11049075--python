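"""Discrete active inference: state inference and action selection.

An agent's generative model is a finite POMDP: a likelihood ``A`` mapping
hidden states to observations, per-action transition matrices ``B``, an
observation-preference distribution ``C``, a state prior ``D``, an action
habit ``E``, and a precision ``γ``.

Perception minimizes variational free energy

    F = E_q[ln q(s) − ln A(o|s) − ln prior(s)]
      = D_KL[q || posterior] − ln P(o)          (divergence − log evidence)
      = D_KL[q || prior] − E_q[ln A(o|s)]       (complexity − accuracy)

which on a finite state space is minimized exactly by the Bayesian
posterior, making the divergence term vanish and F equal the negative
log evidence.  Action selection scores each action's one-step predicted
state distribution by the expected free energy

    G = D_KL[Q(o|u) || C] + E_q[H[A(·|s)]]      (risk + ambiguity)
      = −(expected information gain) − (expected value)

and actions are drawn from ``σ(ln E − γ·G)``, which reduces to the pure
precision-weighted softmax ``σ(−γ·G)`` under a uniform habit.

The POMDP also *is* a polynomial dynamical system on the monomial
interface ``O·y^U`` — :func:`to_stoch_poly` performs that translation
and round-trips the tables exactly.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .categorical import (
    Categorical,
    FiniteSet,
    StochasticMap,
    ValidationError,
    clamped_log,
    entropy,
    kl_divergence,
    sample_index,
)
from .poly import DynamicalSystem, make_monomial

__all__ = [
    "GenerativeModel",
    "FreeEnergyReport",
    "EFEReport",
    "Policy",
    "StepResult",
    "POMDPSystem",
    "exact_posterior",
    "free_energy",
    "expected_free_energy",
    "habit_weighted_softmax",
    "action_posterior",
    "rollout_policies",
    "agent_step",
    "to_stoch_poly",
    "from_stoch_poly",
]


@dataclass(frozen=True)
class GenerativeModel:
    """A finite POMDP generative model (A, B, C, D, E, γ).

    ``A``: likelihood ``P(o|s)``; ``B[u]``: transition ``P(s'|s,u)``;
    ``C``: preference distribution over observations; ``D``: initial
    state prior; ``E``: action habit; ``gamma``: action precision.
    """

    states: FiniteSet
    observations: FiniteSet
    actions: FiniteSet
    A: StochasticMap
    B: Mapping[str, StochasticMap]
    C: Categorical
    D: Categorical
    E: Categorical
    gamma: float = 1.0

    def __post_init__(self):
        if self.A.source.labels != self.states.labels or \
           self.A.target.labels != self.observations.labels:
            raise ValidationError("A must map states to observations")
        for u in self.actions:
            b = self.B.get(u)
            if b is None:
                raise ValidationError(f"missing transition matrix for action {u!r}")
            if b.source.labels != self.states.labels or b.target.labels != self.states.labels:
                raise ValidationError(f"B[{u!r}] must map states to states")
        extra = [u for u in self.B if u not in self.actions]
        if extra:
            raise ValidationError(f"B has tables for unknown actions {extra}")
        if self.C.support.labels != self.observations.labels:
            raise ValidationError("C must be a distribution over observations")
        if self.D.support.labels != self.states.labels:
            raise ValidationError("D must be a distribution over states")
        if self.E.support.labels != self.actions.labels:
            raise ValidationError("E must be a distribution over actions")
        if not (self.gamma >= 0):
            raise ValidationError("gamma must be non-negative")

    def log_preferences(self) -> np.ndarray:
        """``ln C`` with zero-probability observations clamped at EPS."""
        return clamped_log(self.C.probs)

    def predict(self, q: Categorical, u: str) -> Categorical:
        """One-step predicted state distribution ``B_u · q``."""
        return self.B[u].push(q)


@dataclass(frozen=True)
class FreeEnergyReport:
    """Variational free energy with both printed decompositions."""

    F: float
    divergence: float
    log_evidence: float
    complexity: float
    accuracy: float


@dataclass(frozen=True)
class EFEReport:
    """Expected free energy with both printed decompositions."""

    G: float
    info_gain: float
    expected_value: float
    risk: float
    ambiguity: float

    @property
    def risk_is_infinite(self) -> bool:
        """Flagged when preferences put zero mass on a predicted observation."""
        return not np.isfinite(self.risk)


def exact_posterior(model: GenerativeModel, prior: Categorical, o: str) -> Categorical:
    """Exact Bayesian state posterior ``q(s) ∝ A(o|s) · prior(s)``.

    On a finite state space this attains the free-energy minimum of the
    variational problem exactly.  Raises if the observation has zero
    marginal likelihood under the model and prior.
    """
    if o not in model.observations:
        raise ValidationError(f"observation {o!r} not in observation set")
    if prior.support.labels != model.states.labels:
        raise ValidationError("prior must be a distribution over model states")
    lik = model.A.table[model.observations.index(o), :]
    joint = lik * prior.probs
    mass = joint.sum()
    if mass <= 0:
        raise ValidationError(f"observation {o!r} impossible under model and prior")
    return Categorical(model.states, joint / mass)


def free_energy(model: GenerativeModel, q: Categorical, prior: Categorical,
                o: str) -> FreeEnergyReport:
    """Evaluate the variational free energy of belief ``q`` given ``o``.

    All three decompositions are computed independently (with clamped
    logarithms) and agree within floating-point error; the divergence
    term vanishes when ``q`` is the exact posterior, at which point
    ``F = −ln P(o)``.
    """
    if q.support.labels != model.states.labels or prior.support.labels != model.states.labels:
        raise ValidationError("belief and prior must share the model's state support")
    o_idx = model.observations.index(o)
    lik = model.A.table[o_idx, :]
    qs = q.probs
    nz = qs > 0

    ln_q = clamped_log(qs)
    ln_lik = clamped_log(lik)
    ln_prior = clamped_log(prior.probs)

    F = float(np.sum(qs[nz] * (ln_q[nz] - ln_lik[nz] - ln_prior[nz])))

    evidence = float(np.sum(lik * prior.probs))
    log_evidence = float(np.log(max(evidence, 1e-300)))
    post = lik * prior.probs
    post = post / post.sum() if post.sum() > 0 else post
    divergence = float(np.sum(qs[nz] * (ln_q[nz] - clamped_log(post)[nz])))

    complexity = float(np.sum(qs[nz] * (ln_q[nz] - ln_prior[nz])))
    accuracy = float(np.sum(qs[nz] * ln_lik[nz]))

    return FreeEnergyReport(F=F, divergence=divergence, log_evidence=log_evidence,
                            complexity=complexity, accuracy=accuracy)


def expected_free_energy(model: GenerativeModel, q_next: Categorical) -> EFEReport:
    """Expected free energy of the predicted state distribution ``q_next``.

    The predictive joint is ``Q(o,s|u) = A(o|s)·q_next(s)``; the
    posterior term in the information gain uses exact Bayes under this
    joint, which makes the risk+ambiguity and info-gain/expected-value
    decompositions agree identically.  If the preferences place zero
    mass on a predicted observation, the risk (and G) are ``+inf`` —
    reported, not fatal.
    """
    if q_next.support.labels != model.states.labels:
        raise ValidationError("q_next must be a distribution over model states")
    A = model.A.table  # (|O|, |S|)
    qs = q_next.probs
    q_o = A @ qs  # predicted observation distribution
    q_obs = Categorical(model.observations, q_o / q_o.sum())

    risk = kl_divergence(q_obs, model.C)
    ambiguity = float(np.sum(qs * np.array([entropy(A[:, j]) for j in range(A.shape[1])])))

    # expected information gain: E_{Q(o)} KL[ Q(s|o) || q_next ]
    info_gain = 0.0
    for oi in range(A.shape[0]):
        po = q_obs.probs[oi]
        if po <= 0:
            continue
        post = A[oi, :] * qs / po
        nz = post > 0
        info_gain += po * float(np.sum(post[nz] * (np.log(post[nz]) - clamped_log(qs)[nz])))

    ln_c = model.log_preferences()
    expected_value = float(np.sum(q_obs.probs * ln_c)) if np.all(model.C.probs[q_obs.probs > 0] > 0) \
        else float("-inf")

    G = risk + ambiguity
    return EFEReport(G=G, info_gain=info_gain, expected_value=expected_value,
                     risk=risk, ambiguity=ambiguity)


def habit_weighted_softmax(habit: Categorical, g: np.ndarray, gamma: float) -> Categorical:
    """``σ(ln habit − γ·g)`` with exact habit zeros preserved."""
    if not np.all(np.isfinite(g)):
        raise ValidationError("expected free energies must be finite for action selection")
    e = habit.probs
    logits = np.where(e > 0, np.log(np.where(e > 0, e, 1.0)), -np.inf) - gamma * g
    m = logits[np.isfinite(logits)].max()
    w = np.where(np.isfinite(logits), np.exp(logits - m), 0.0)
    return Categorical(habit.support, w / w.sum())


def action_posterior(model: GenerativeModel,
                     efe_per_action: Mapping[str, float] | Sequence[float]) -> Categorical:
    """Action distribution ``P(u) = σ(ln E − γ·G(u))``.

    Exact zeros in the habit ``E`` stay exact zeros; with a uniform
    habit this reduces exactly to the softmax of ``−γ·G``.
    """
    if isinstance(efe_per_action, Mapping):
        g = np.array([float(efe_per_action[u]) for u in model.actions])
    else:
        g = np.asarray(efe_per_action, dtype=float)
        if g.shape != (len(model.actions),):
            raise ValidationError("one expected free energy per action required")
    return habit_weighted_softmax(model.E, g, model.gamma)


@dataclass(frozen=True)
class Policy:
    """A fixed action sequence with its habit prior weight ``Π_t E(u_t)``."""

    actions: tuple[str, ...]
    prior_weight: float = 1.0

    def __post_init__(self):
        if len(self.actions) < 1:
            raise ValidationError("a policy needs at least one action")


def rollout_policies(model: GenerativeModel, q: Categorical, depth: int,
                     cap: int = 100_000) -> list[tuple[Policy, float]]:
    """Exhaustive depth-limited policy evaluation.

    Enumerates all ``|U|^depth`` action sequences; for each, the belief
    is propagated open-loop (``q ← B_u q``, never conditioned on
    imagined observations) and per-step expected free energies are
    accumulated additively.  Returns ``(policy, cumulative G)`` pairs in
    enumeration order.
    """
    if depth < 1:
        raise ValidationError("depth must be ≥ 1")
    n_pol = len(model.actions) ** depth
    if n_pol > cap:
        raise ValidationError(f"{n_pol} policies exceed cap {cap}")
    results: list[tuple[Policy, float]] = []

    def _recurse(prefix: tuple[str, ...], q_cur: Categorical, g_acc: float, weight: float):
        if len(prefix) == depth:
            results.append((Policy(prefix, prior_weight=weight), g_acc))
            return
        for u in model.actions:
            q_pred = model.predict(q_cur, u)
            g = expected_free_energy(model, q_pred).G
            _recurse(prefix + (u,), q_pred, g_acc + g, weight * model.E[u])

    _recurse((), q, 0.0, 1.0)
    return results


@dataclass(frozen=True)
class StepResult:
    """Everything one perception-action cycle produces."""

    posterior: Categorical
    action: str
    next_prior: Categorical
    free_energy: FreeEnergyReport
    efe: Mapping[str, EFEReport]
    action_probs: Categorical


def agent_step(model: GenerativeModel, belief: Categorical, o: str,
               rng: np.random.Generator) -> StepResult:
    """One cycle: observe → infer → evaluate G per action → act → propagate.

    ``belief`` is the prior for this step; the posterior is exact Bayes;
    the action is sampled from ``σ(ln E − γG)``; the returned
    ``next_prior`` is ``B_action · posterior``.
    """
    posterior = exact_posterior(model, belief, o)
    fe = free_energy(model, posterior, belief, o)
    efe = {u: expected_free_energy(model, model.predict(posterior, u))
           for u in model.actions}
    probs = action_posterior(model, {u: r.G for u, r in efe.items()})
    action = model.actions.labels[sample_index(probs.probs, rng)]
    next_prior = model.predict(posterior, action)
    return StepResult(posterior=posterior, action=action, next_prior=next_prior,
                      free_energy=fe, efe=efe, action_probs=probs)


# ---------------------------------------------------------------------------
# POMDP <-> polynomial dynamical system bridge
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class POMDPSystem(DynamicalSystem):
    """A dynamical system on ``O·y^U`` carrying its POMDP tables.

    ``output`` emits an observation per state (sampled from the
    likelihood, or the deterministic image when the likelihood is
    noiseless and deterministic mode is requested); ``update`` applies
    the action-indexed transition kernel.
    """

    likelihood: StochasticMap = field(default=None)  # type: ignore[assignment]
    transitions: Mapping[str, StochasticMap] = field(default=None)  # type: ignore[assignment]


def to_stoch_poly(model: GenerativeModel, deterministic_output: bool = False) -> POMDPSystem:
    """Translate a POMDP into a system ``S·y^S → O·y^U``.

    By default the observation is emitted stochastically by sampling the
    likelihood column — the faithful POMDP reading.  With
    ``deterministic_output=True`` (admissible only for a noiseless
    likelihood) the output function is the literal function
    ``ρ_o : S → O``.
    """
    interface = make_monomial(model.observations, model.actions)
    A, B = model.A, dict(model.B)
    if deterministic_output and not A.is_deterministic():
        raise ValidationError("deterministic output requires a noiseless likelihood")

    if deterministic_output:
        img = {s: model.observations.labels[int(np.argmax(A.table[:, j]))]
               for j, s in enumerate(model.states)}

        def output(s: str, rng: np.random.Generator) -> str:
            return img[s]
    else:
        def output(s: str, rng: np.random.Generator) -> str:
            col = A.table[:, model.states.index(s)]
            return model.observations.labels[sample_index(col, rng)]

    def update(s: str, u: str, rng: np.random.Generator) -> str:
        col = B[u].table[:, model.states.index(s)]
        return model.states.labels[sample_index(col, rng)]

    return POMDPSystem(states=model.states, interface=interface,
                       output=output, update=update,
                       likelihood=A, transitions=B)


def from_stoch_poly(sys: POMDPSystem) -> tuple[StochasticMap, Mapping[str, StochasticMap]]:
    """Read the likelihood and transition tables back from the system."""
    return sys.likelihood, sys.transitions
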