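"""Ensembles of active-inference agents over a joint interface.

Each agent ``j`` carries a monomial interface ``O_j · y^{U_j}`` and a
generative model whose *action set is the joint action set* of the whole
group — every agent believes the hidden dynamics depend on what everyone
does.  The ensemble's joint interface is the tensor of the individual
interfaces.

At every step each agent observes through its own channel, performs
exact Bayesian inference, predicts its companions' actions by recursive
simulation (a finite-depth theory of mind: depth 0 falls back to the
companion's habit), marginalizes its joint-action expected free energy
over those predictions, and selects its own action.  Mutual
predictability — declining inter-agent belief divergence and prediction
log-scores — is the operational reading of generalized synchrony.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .categorical import (
    Categorical,
    FiniteSet,
    StochasticMap,
    ValidationError,
    clamped_log,
    sample_index,
    symmetrized_kl,
)
from .engine import (
    FreeEnergyReport,
    GenerativeModel,
    exact_posterior,
    expected_free_energy,
    free_energy,
    habit_weighted_softmax,
)
from .poly import Polynomial, tensor_all

__all__ = [
    "JOINT_SEP",
    "AgentSpec",
    "WorldEnv",
    "StepRecord",
    "EnsembleTrajectory",
    "joint_action_set",
    "joint_label",
    "split_joint",
    "build_joint_interface",
    "predict_other",
    "simulate_ensemble",
    "synchrony_trace",
]

#: Separator used to build joint-action labels from per-agent labels.
JOINT_SEP = ","


def joint_label(parts: Sequence[str]) -> str:
    return JOINT_SEP.join(parts)


def split_joint(label: str, n: int) -> tuple[str, ...]:
    parts = tuple(label.split(JOINT_SEP))
    if len(parts) != n:
        raise ValidationError(f"joint label {label!r} does not split into {n} parts")
    return parts


def joint_action_set(action_sets: Sequence[FiniteSet]) -> FiniteSet:
    """Cartesian product of per-agent action sets, in agent order."""
    for s in action_sets:
        for lbl in s:
            if JOINT_SEP in lbl:
                raise ValidationError(
                    f"action label {lbl!r} may not contain {JOINT_SEP!r}")
    return FiniteSet([joint_label(combo)
                      for combo in itertools.product(*[s.labels for s in action_sets])])


@dataclass(frozen=True)
class AgentSpec:
    """One agent: its interface, joint-action model, and ToM depth.

    ``model.actions`` must be the joint action set of the whole
    ensemble; ``own_actions`` is this agent's factor, at position
    ``agent_index`` of every joint label.
    """

    id: str
    interface: Polynomial
    model: GenerativeModel
    own_actions: FiniteSet
    agent_index: int
    tom_depth: int = 1

    def __post_init__(self):
        if self.tom_depth < 0:
            raise ValidationError("tom_depth must be ≥ 0")

    def own_marginal(self, joint_dist: Categorical, n_agents: int) -> Categorical:
        """Marginalize a joint-action distribution onto this agent's factor."""
        acc = {u: 0.0 for u in self.own_actions}
        for lbl, p in zip(joint_dist.support, joint_dist.probs):
            acc[split_joint(lbl, n_agents)[self.agent_index]] += float(p)
        return Categorical(self.own_actions, [acc[u] for u in self.own_actions])


@dataclass(frozen=True)
class WorldEnv:
    """Ground-truth shared world: one state, one channel per agent."""

    states: FiniteSet
    channels: Mapping[str, StochasticMap]  # agent id -> S* ⇝ O_j
    transition: Mapping[str, StochasticMap]  # joint-action label -> S* ⇝ S*
    joint_actions: FiniteSet
    init: Categorical

    def __post_init__(self):
        for aid, ch in self.channels.items():
            if ch.source.labels != self.states.labels:
                raise ValidationError(f"channel for {aid!r} must condition on world states")
        for u in self.joint_actions:
            b = self.transition.get(u)
            if b is None:
                raise ValidationError(f"missing world transition for joint action {u!r}")
            if b.source.labels != self.states.labels or b.target.labels != self.states.labels:
                raise ValidationError(f"world transition for {u!r} has wrong spaces")
        if self.init.support.labels != self.states.labels:
            raise ValidationError("init must be a distribution over world states")


def build_joint_interface(agents: Sequence[AgentSpec]) -> Polynomial:
    """Tensor of the agents' interfaces: the group's joint boundary."""
    if not agents:
        raise ValidationError("need at least one agent")
    return tensor_all([a.interface for a in agents])


# ---------------------------------------------------------------------------
# recursive theory of mind
# ---------------------------------------------------------------------------

def _other_assignments(agents: Sequence[AgentSpec], skip_index: int):
    """All joint assignments of actions to every agent except one."""
    choices = [a.own_actions.labels for a in agents if a.agent_index != skip_index]
    return itertools.product(*choices)


def _marginal_efe(spec: AgentSpec, belief: Categorical, agents: Sequence[AgentSpec],
                  predictions: Mapping[str, Categorical],
                  efe_cache: Mapping[str, float] | None = None) -> dict[str, float]:
    """Per-own-action G, marginalized over predicted companion actions."""
    n = len(agents)
    others = [a for a in agents if a.agent_index != spec.agent_index]
    if efe_cache is None:
        efe_cache = {u: expected_free_energy(spec.model, spec.model.predict(belief, u)).G
                     for u in spec.model.actions}
    g_marg: dict[str, float] = {}
    for own_u in spec.own_actions:
        total = 0.0
        for assignment in _other_assignments(agents, spec.agent_index):
            w = 1.0
            for other, act in zip(others, assignment):
                w *= predictions[other.id][act]
            if w == 0.0:
                continue
            parts = [""] * n
            parts[spec.agent_index] = own_u
            for other, act in zip(others, assignment):
                parts[other.agent_index] = act
            total += w * efe_cache[joint_label(parts)]
        g_marg[own_u] = total
    return g_marg


def _action_posterior_at_depth(spec: AgentSpec, belief: Categorical,
                               agents: Sequence[AgentSpec], depth: int) -> Categorical:
    """Simulated action distribution of ``spec`` at a given ToM depth.

    Depth 0 returns the habit marginal (no modelling); depth ``d``
    computes the agent's marginal expected free energy assuming the
    companions act as predicted at depth ``d − 1``.
    """
    n = len(agents)
    habit_marg = spec.own_marginal(spec.model.E, n)
    if depth <= 0:
        return habit_marg
    predictions = {a.id: _action_posterior_at_depth(a, belief, agents, depth - 1)
                   for a in agents if a.agent_index != spec.agent_index}
    g_marg = _marginal_efe(spec, belief, agents, predictions)
    g = np.array([g_marg[u] for u in spec.own_actions])
    return habit_weighted_softmax(habit_marg, g, spec.model.gamma)


def predict_other(agent: AgentSpec, other_id: str, own_belief: Categorical,
                  agents: Sequence[AgentSpec]) -> Categorical:
    """Agent's prediction of a companion's action distribution.

    Under the shared-model assumption the agent holds a veridical copy
    of the companion's model and simulates the companion's decision from
    the agent's own belief about the shared hidden state; inside that
    simulation the companion's own predictions recurse one level
    shallower, bottoming out at the habit.  ``tom_depth = 0`` performs
    no modelling at all and returns the companion's habit directly.
    """
    others = {a.id: a for a in agents}
    if other_id not in others:
        raise ValidationError(f"unknown agent {other_id!r}")
    other = others[other_id]
    return _action_posterior_at_depth(other, own_belief, agents, agent.tom_depth)


# ---------------------------------------------------------------------------
# ensemble simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepRecord:
    """One synchronous step of the whole ensemble."""

    step: int
    true_state: str
    observations: Mapping[str, str]
    beliefs: Mapping[str, Categorical]
    actions: Mapping[str, str]
    predictions: Mapping[str, Mapping[str, Categorical]]  # j -> k -> dist over k's actions
    free_energy: Mapping[str, FreeEnergyReport]
    action_probs: Mapping[str, Categorical]
    efe_marginal: Mapping[str, Mapping[str, float]]  # j -> own action -> marginal G


@dataclass(frozen=True)
class EnsembleTrajectory:
    agent_ids: tuple[str, ...]
    steps: tuple[StepRecord, ...]

    def __len__(self) -> int:
        return len(self.steps)


def _validate_ensemble(env: WorldEnv, agents: Sequence[AgentSpec]) -> None:
    ids = [a.id for a in agents]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate agent ids")
    joint = joint_action_set([a.own_actions for a in agents])
    if joint.labels != env.joint_actions.labels:
        raise ValidationError("env joint actions do not match the agents' product")
    for a in agents:
        if a.model.actions.labels != joint.labels:
            raise ValidationError(f"agent {a.id!r}: model actions must be the joint set")
        if a.model.states.labels != env.states.labels:
            raise ValidationError(f"agent {a.id!r}: model states must match the world")
        ch = env.channels.get(a.id)
        if ch is None:
            raise ValidationError(f"no observation channel for agent {a.id!r}")
        if ch.target.labels != a.model.observations.labels:
            raise ValidationError(f"agent {a.id!r}: channel target must match model observations")


def simulate_ensemble(env: WorldEnv, agents: Sequence[AgentSpec], T: int,
                      rng: np.random.Generator) -> EnsembleTrajectory:
    """Run the coupled agents-world loop for ``T`` steps.

    Per step: every agent observes through its channel, infers by exact
    Bayes, predicts its companions, marginalizes its joint-action G over
    those predictions, and acts; the world then transitions on the
    realized joint action.  Each agent's next prior marginalizes its
    transition model over its *predicted* companion actions (agents do
    not see others' actions directly).  With a single agent this reduces
    bit-identically to the single-agent perception-action loop.
    """
    if T < 1:
        raise ValidationError("T must be ≥ 1")
    _validate_ensemble(env, agents)
    n = len(agents)
    s = env.states.labels[sample_index(env.init.probs, rng)]
    priors = {a.id: a.model.D for a in agents}
    records: list[StepRecord] = []

    for t in range(T):
        obs = {a.id: env.channels[a.id].column(s).sample(rng) for a in agents}
        posteriors = {a.id: exact_posterior(a.model, priors[a.id], obs[a.id]) for a in agents}
        fes = {a.id: free_energy(a.model, posteriors[a.id], priors[a.id], obs[a.id])
               for a in agents}

        actions: dict[str, str] = {}
        probs: dict[str, Categorical] = {}
        predictions: dict[str, dict[str, Categorical]] = {}
        efe_marg: dict[str, dict[str, float]] = {}
        for a in agents:
            preds = {k.id: predict_other(a, k.id, posteriors[a.id], agents)
                     for k in agents if k.id != a.id}
            predictions[a.id] = preds
            g_marg = _marginal_efe(a, posteriors[a.id], agents, preds)
            efe_marg[a.id] = g_marg
            habit_marg = a.own_marginal(a.model.E, n)
            g = np.array([g_marg[u] for u in a.own_actions])
            p = habit_weighted_softmax(habit_marg, g, a.model.gamma)
            probs[a.id] = p
            actions[a.id] = a.own_actions.labels[sample_index(p.probs, rng)]

        joint = joint_label([actions[a.id] for a in agents])
        records.append(StepRecord(step=t, true_state=s, observations=obs,
                                  beliefs=posteriors, actions=actions,
                                  predictions=predictions, free_energy=fes,
                                  action_probs=probs, efe_marginal=efe_marg))

        # next priors marginalize the transition model over predicted companions
        new_priors = {}
        for a in agents:
            others = [k for k in agents if k.agent_index != a.agent_index]
            if not others:
                # single agent: exact reduction to the plain perception-action loop
                new_priors[a.id] = a.model.predict(posteriors[a.id], actions[a.id])
                continue
            acc = np.zeros(len(a.model.states))
            for assignment in _other_assignments(agents, a.agent_index):
                wgt = 1.0
                for other, act in zip(others, assignment):
                    wgt *= predictions[a.id][other.id][act]
                if wgt == 0.0:
                    continue
                parts = [""] * n
                parts[a.agent_index] = actions[a.id]
                for other, act in zip(others, assignment):
                    parts[other.agent_index] = act
                acc += wgt * a.model.B[joint_label(parts)].push(posteriors[a.id]).probs
            new_priors[a.id] = Categorical(a.model.states, acc / acc.sum())
        priors = new_priors

        s = env.transition[joint].column(s).sample(rng)

    return EnsembleTrajectory(agent_ids=tuple(a.id for a in agents), steps=tuple(records))


def synchrony_trace(traj: EnsembleTrajectory) -> list[dict[str, float]]:
    """Per-step synchrony metrics for an ensemble trajectory.

    ``mean_pairwise_kl``: mean symmetrized KL between agents' beliefs;
    ``mean_prediction_logscore``: mean log probability each agent's
    prediction assigned to the companions' realized actions (≤ 0, with
    0 only for deterministic correct prediction);
    ``total_free_energy``: the sum of the agents' variational free
    energies — the joint free-energy proxy.
    """
    ids = traj.agent_ids
    if len(ids) < 2:
        raise ValidationError("synchrony metrics need at least two agents")
    out = []
    for rec in traj.steps:
        kls = [symmetrized_kl(rec.beliefs[a], rec.beliefs[b])
               for a, b in itertools.combinations(ids, 2)]
        scores = []
        for j in ids:
            for k in ids:
                if k == j:
                    continue
                scores.append(float(clamped_log(rec.predictions[j][k][rec.actions[k]])))
        out.append({
            "step": float(rec.step),
            "mean_pairwise_kl": float(np.mean(kls)),
            "mean_prediction_logscore": float(np.mean(scores)),
            "total_free_energy": float(sum(r.F for r in rec.free_energy.values())),
        })
    return out
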