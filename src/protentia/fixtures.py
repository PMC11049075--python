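"""Seeded generators for every scenario the package needs.

No external data anywhere: random well-formed generative models, a
T-maze epistemic-foraging scenario, and N-agent shared-world scenarios
with controllable patch overlap and controllable disagreement ε.  Every
generator is a pure function of its parameters and seed.

Random probability columns use a documented uniform-primitive recipe:
weights ``(−ln U_i)^(1/c)`` normalized, where ``U_i`` are uniform draws
and ``c`` is the concentration.  At ``c = 1`` this is exactly a flat
Dirichlet; as ``c → ∞`` the columns approach uniform.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .categorical import Categorical, FiniteSet, StochasticMap, ValidationError
from .engine import GenerativeModel
from .multiagent import AgentSpec, WorldEnv, joint_action_set
from .poly import make_monomial
from .sheaf import Cover, Section

__all__ = [
    "ScenarioBundle",
    "dirichlet_like",
    "random_model",
    "make_tmaze",
    "make_shared_world",
    "perturb_sections",
]


@dataclass(frozen=True)
class ScenarioBundle:
    """A fully wired scenario: world, agents, cover, sections, metadata."""

    env: WorldEnv | None
    agents: tuple[AgentSpec, ...]
    cover: Cover | None
    sections: tuple[Section, ...] | None
    metadata: dict = field(default_factory=dict)


def dirichlet_like(rng: np.random.Generator, k: int, concentration: float = 1.0) -> np.ndarray:
    """A random probability vector from uniform primitives.

    ``w_i = (−ln U_i)^(1/concentration)`` normalized.  Exact flat
    Dirichlet at concentration 1; approaches the uniform vector as the
    concentration grows.
    """
    if concentration <= 0:
        raise ValidationError("concentration must be positive")
    u = np.clip(rng.random(k), 1e-12, 1.0 - 1e-12)
    w = (-np.log(u)) ** (1.0 / concentration)
    return w / w.sum()


def _stochastic(rng: np.random.Generator, source: FiniteSet, target: FiniteSet,
                concentration: float) -> StochasticMap:
    cols = {s: dirichlet_like(rng, len(target), concentration) for s in source}
    return StochasticMap.from_columns(source, target, cols)


def random_model(n_states: int, n_obs: int, n_actions: int,
                 concentration: float = 1.0, seed: int = 0) -> GenerativeModel:
    """A random, always-valid generative model with named sets.

    Same dimensions and seed give a byte-identical model (and JSON form).
    """
    if min(n_states, n_obs, n_actions) < 1:
        raise ValidationError("all dimensions must be ≥ 1")
    rng = np.random.default_rng(seed)
    S = FiniteSet([f"s{i}" for i in range(n_states)])
    O = FiniteSet([f"o{i}" for i in range(n_obs)])
    U = FiniteSet([f"u{i}" for i in range(n_actions)])
    A = _stochastic(rng, S, O, concentration)
    B = {u: _stochastic(rng, S, S, concentration) for u in U}
    C = Categorical(O, dirichlet_like(rng, n_obs, concentration))
    D = Categorical(S, dirichlet_like(rng, n_states, concentration))
    E = Categorical(U, dirichlet_like(rng, n_actions, concentration))
    return GenerativeModel(states=S, observations=O, actions=U,
                           A=A, B=B, C=C, D=D, E=E, gamma=1.0)


# ---------------------------------------------------------------------------
# T-maze epistemic foraging
# ---------------------------------------------------------------------------

TMAZE_LOCATIONS = ("center", "left", "right", "cue")
TMAZE_CONTEXTS = ("reward-left", "reward-right")
TMAZE_OBSERVATIONS = ("o-center", "o-reward", "o-null", "o-cue-left", "o-cue-right")
TMAZE_ACTIONS = ("go-center", "go-left", "go-right", "go-cue")


def make_tmaze(cue_accuracy: float = 0.98, seed: int = 0,
               reward_logpref: float = 3.0, null_logpref: float = -4.0,
               gamma: float = 4.0) -> ScenarioBundle:
    """A T-maze with a reward-side cue: the canonical epistemic-foraging task.

    Four locations (center, two arms, a cue site) crossed with two
    latent reward contexts.  The cue observation reveals the rewarded
    side with probability ``cue_accuracy``; the arms are absorbing, so
    committing blind risks the aversive null outcome.  Preferences are
    neutral at the cue site (the cue observations carry zero
    log-preference), reward carries ``reward_logpref`` and the null
    outcome ``null_logpref`` — the asymmetry that makes cue-seeking pay.
    """
    if not (0.5 < cue_accuracy <= 1.0):
        raise ValidationError("cue_accuracy must lie in (0.5, 1]")
    locs, ctxs = TMAZE_LOCATIONS, TMAZE_CONTEXTS
    S = FiniteSet([f"{l}:{c}" for l in locs for c in ctxs])
    O = FiniteSet(TMAZE_OBSERVATIONS)
    U = FiniteSet(TMAZE_ACTIONS)
    a = cue_accuracy

    def obs_dist(loc: str, ctx: str) -> dict[str, float]:
        if loc == "center":
            return {"o-center": 1.0}
        if loc in ("left", "right"):
            rewarded = (loc == "left") == (ctx == "reward-left")
            return {"o-reward": 1.0} if rewarded else {"o-null": 1.0}
        # cue site
        if ctx == "reward-left":
            return {"o-cue-left": a, "o-cue-right": 1.0 - a}
        return {"o-cue-left": 1.0 - a, "o-cue-right": a}

    A_cols = {}
    for s in S:
        loc, ctx = s.split(":")
        d = obs_dist(loc, ctx)
        A_cols[s] = [d.get(o, 0.0) for o in O]
    A = StochasticMap.from_columns(S, O, A_cols)

    def move(loc: str, action: str) -> str:
        if loc in ("left", "right"):
            return loc  # arms absorb
        return {"go-center": "center", "go-left": "left",
                "go-right": "right", "go-cue": "cue"}[action]

    B = {}
    for u in U:
        mapping = {f"{l}:{c}": f"{move(l, u)}:{c}" for l in locs for c in ctxs}
        B[u] = StochasticMap.deterministic(S, S, mapping)

    logpref = {"o-center": 0.0, "o-reward": reward_logpref, "o-null": null_logpref,
               "o-cue-left": 0.0, "o-cue-right": 0.0}
    w = np.exp([logpref[o] for o in O])
    C = Categorical(O, w / w.sum())
    D = Categorical.from_dict(S, {"center:reward-left": 0.5, "center:reward-right": 0.5})
    E = Categorical.uniform(U)
    model = GenerativeModel(states=S, observations=O, actions=U,
                            A=A, B=B, C=C, D=D, E=E, gamma=gamma)

    agent = AgentSpec(id="forager", interface=make_monomial(O, U), model=model,
                      own_actions=U, agent_index=0, tom_depth=1)
    env = WorldEnv(states=S, channels={"forager": A}, transition=dict(B),
                   joint_actions=U, init=D)

    base = FiniteSet(list(locs))
    cover = Cover(base, {"forager": list(locs)})
    sections = (Section("forager", {l: Categorical.uniform(FiniteSet(list(ctxs)))
                                    for l in locs}),)
    site_assignment = {s: s.split(":")[0] for s in S}
    admissibility = {"center": ("o-center",), "left": ("o-reward", "o-null"),
                     "right": ("o-reward", "o-null"),
                     "cue": ("o-cue-left", "o-cue-right")}
    meta = {"generator": "make_tmaze", "seed": seed, "cue_accuracy": cue_accuracy,
            "reward_logpref": reward_logpref, "null_logpref": null_logpref,
            "gamma": gamma, "site_assignment": site_assignment,
            "admissibility": admissibility}
    return ScenarioBundle(env=env, agents=(agent,), cover=cover,
                          sections=sections, metadata=meta)


# ---------------------------------------------------------------------------
# shared worlds with controllable overlap and disagreement
# ---------------------------------------------------------------------------

SHARED_WORLD_OUTCOMES = ("w0", "w1", "w2")
SHARED_WORLD_ACTIONS = ("left", "stay", "right")


def _chain_patches(n_agents: int, n_sites: int, overlap: int) -> list[list[str]]:
    sites = [f"site{i}" for i in range(n_sites)]
    if n_agents == 1:
        return [sites]
    if overlap < 0:
        raise ValidationError("overlap must be ≥ 0")
    num = n_sites + overlap * (n_agents - 1)
    if num % n_agents != 0:
        raise ValidationError(
            f"impossible cover geometry: {n_sites} sites cannot be chained over "
            f"{n_agents} agents with overlap {overlap}")
    length = num // n_agents
    stride = length - overlap
    if stride < 1 or length < 1:
        raise ValidationError("impossible cover geometry: patches would not advance")
    return [sites[j * stride: j * stride + length] for j in range(n_agents)]


def make_shared_world(n_agents: int = 2, n_sites: int = 5, overlap: int = 1,
                      epsilon: float = 0.0, seed: int = 0,
                      obs_accuracy: float = 0.8, prior_divergence: float = 0.9,
                      move_prob: float = 0.9, gamma: float = 2.0) -> ScenarioBundle:
    """An N-agent shared world over a ring of sites, with a chained cover.

    The world state is a token on a ring of ``n_sites`` sites; each
    agent votes to shift it (left/stay/right) and the summed vote is
    applied with probability ``move_prob``.  Every agent observes the
    site through an identity channel of accuracy ``obs_accuracy`` and
    holds a veridical model of the joint dynamics; priors diverge by
    mixing a per-agent point mass (weight ``prior_divergence``) with the
    uniform distribution.

    The agents' world-model sections over their patches are generated
    consistently from a single base assignment, then every overlap site
    is perturbed by exactly ``epsilon`` in total variation (mass moved
    from the donor to the recipient coordinate of the higher-indexed
    agent's vector).  ``epsilon = 0`` therefore glues at tolerance 1e-12.
    """
    if epsilon < 0:
        raise ValidationError("epsilon must be ≥ 0")
    rng = np.random.default_rng(seed)
    patches = _chain_patches(n_agents, n_sites, overlap)
    base = FiniteSet([f"site{i}" for i in range(n_sites)])
    agent_ids = [f"agent{j}" for j in range(n_agents)]
    cover = Cover(base, dict(zip(agent_ids, patches)))

    # --- sections: consistent base assignment, then ε-perturbed overlaps
    outcomes = FiniteSet(list(SHARED_WORLD_OUTCOMES))
    k = len(outcomes)
    base_assignment = {site: 0.5 * dirichlet_like(rng, k) + 0.5 / k for site in base}
    section_vectors = {aid: {site: base_assignment[site].copy()
                             for site in cover.patches[aid]}
                       for aid in agent_ids}
    if epsilon > 0:
        for site in base:
            owners = cover.owners(site)
            for aid in owners[1:]:
                v = section_vectors[aid][site]
                donor = int(np.argmax(v))
                recip = int(np.argmin(v))
                if donor == recip:
                    donor, recip = 0, 1
                if v[donor] < epsilon:
                    raise ValidationError(
                        f"epsilon {epsilon} exceeds donor mass {v[donor]:.3f} at {site!r}")
                v[donor] -= epsilon
                v[recip] += epsilon
    sections = tuple(
        Section(aid, {site: Categorical(outcomes, vec)
                      for site, vec in section_vectors[aid].items()})
        for aid in agent_ids)

    # --- world and agents
    S = base  # world states are the sites
    own_actions = FiniteSet(list(SHARED_WORLD_ACTIONS))
    joint = joint_action_set([own_actions] * n_agents)
    vote = {"left": -1, "stay": 0, "right": 1}

    def channel() -> StochasticMap:
        n = len(S)
        obs = FiniteSet([f"see-{site}" for site in S])
        t = np.full((n, n), (1.0 - obs_accuracy) / (n - 1)) if n > 1 else np.ones((1, 1))
        np.fill_diagonal(t, obs_accuracy if n > 1 else 1.0)
        return StochasticMap(S, obs, t)

    transition = {}
    n = len(S)
    for jl in joint:
        parts = jl.split(",")
        shift = sum(vote[p] for p in parts)
        t = np.zeros((n, n))
        for idx in range(n):
            t[(idx + shift) % n, idx] += move_prob
            t[idx, idx] += 1.0 - move_prob
        transition[jl] = StochasticMap(S, S, t)

    agents = []
    offset = max(1, n_sites // max(n_agents, 1))
    for j, aid in enumerate(agent_ids):
        ch = channel()
        d = np.full(n, (1.0 - prior_divergence) / n)
        d[(j * offset) % n] += prior_divergence
        model = GenerativeModel(
            states=S, observations=ch.target, actions=joint,
            A=ch, B=transition, C=Categorical.uniform(ch.target),
            D=Categorical(S, d), E=Categorical.uniform(joint), gamma=gamma)
        agents.append(AgentSpec(id=aid, interface=make_monomial(ch.target, own_actions),
                                model=model, own_actions=own_actions,
                                agent_index=j, tom_depth=1))

    env = WorldEnv(states=S, channels={a.id: a.model.A for a in agents},
                   transition=transition, joint_actions=joint,
                   init=Categorical.uniform(S))
    meta = {"generator": "make_shared_world", "seed": seed, "n_agents": n_agents,
            "n_sites": n_sites, "overlap": overlap, "epsilon": epsilon,
            "obs_accuracy": obs_accuracy, "prior_divergence": prior_divergence,
            "move_prob": move_prob, "gamma": gamma}
    return ScenarioBundle(env=env, agents=tuple(agents), cover=cover,
                          sections=sections, metadata=meta)


def perturb_sections(sections: Sequence[Section], epsilon: float,
                     seed: int = 0) -> list[Section]:
    """Mix every site vector with a fresh random vector at weight ε.

    ``epsilon = 0`` is the identity; ``epsilon = 1`` replaces each
    vector by its random replacement.  Starting from consistent
    sections, the disagreement energy grows monotonically in ε for a
    fixed seed.
    """
    if not (0.0 <= epsilon <= 1.0):
        raise ValidationError("epsilon must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for sec in sections:
        data = {}
        for site, vec in sec.data.items():
            r = dirichlet_like(rng, len(vec.support))
            mixed = (1.0 - epsilon) * vec.probs + epsilon * r
            data[site] = Categorical(vec.support, mixed / mixed.sum())
        out.append(Section(sec.agent, data))
    return out
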