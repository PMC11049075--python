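"""Agents' world models as sections over a finite cover.

The shared base space is a finite set of *sites*; each agent owns a
patch of sites, and the patches jointly cover the base.  A *section* is
one agent's local world-model data: a categorical vector per site of
its patch.  Restriction maps are identities on shared sites, so the
gluing condition is literal agreement on overlaps.

When sections agree on every overlap they glue to a global section — a
single world model all agents inhabit.  When they do not, the failure
is quantified by a disagreement energy (summed squared Euclidean
distance over overlap sites), and synchronous mean-diffusion dynamics
drive the sections toward a glueable state: at each step every agent
moves a fraction ``eta`` toward the site-wise mean of all agents
present there.  Differences contract linearly by ``(1 − eta)`` per
step, so the energy trace decays geometrically and never increases.

A *spatial* generative model additionally respects the base geometry:
its likelihood may only predict observations at sites where they can be
made; :func:`validate_spatial_model` checks exactly that.
"""

from __future__ import annotations

import itertools
from collections.abc import Collection, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .categorical import Categorical, FiniteSet, ValidationError, total_variation
from .engine import GenerativeModel

__all__ = [
    "Cover",
    "Section",
    "GlobalSection",
    "ObstructionReport",
    "SpatialModelCheck",
    "ConsensusResult",
    "GluingError",
    "restrict",
    "disagreement",
    "check_gluing",
    "glue",
    "consensus_step",
    "run_consensus",
    "validate_spatial_model",
]


@dataclass(frozen=True)
class Cover:
    """A finite base space with one patch of sites per agent.

    The union of patches must equal the base; pairwise overlaps are
    precomputed in base order.
    """

    base: FiniteSet
    patches: Mapping[str, tuple[str, ...]]

    def __init__(self, base: FiniteSet, patches: Mapping[str, Sequence[str]]):
        patches = {aid: tuple(sites) for aid, sites in patches.items()}
        covered = set()
        for aid, sites in patches.items():
            if not sites:
                raise ValidationError(f"patch of {aid!r} is empty")
            for site in sites:
                if site not in base:
                    raise ValidationError(f"patch of {aid!r} has unknown site {site!r}")
            if len(set(sites)) != len(sites):
                raise ValidationError(f"patch of {aid!r} repeats sites")
            covered |= set(sites)
        if covered != set(base.labels):
            raise ValidationError("union of patches must equal the base space")
        object.__setattr__(self, "base", base)
        object.__setattr__(self, "patches", patches)

    @property
    def agent_ids(self) -> tuple[str, ...]:
        return tuple(self.patches)

    def overlaps(self) -> dict[tuple[str, str], tuple[str, ...]]:
        """All pairwise patch intersections, sites in base order."""
        out = {}
        for j, k in itertools.combinations(self.agent_ids, 2):
            shared = set(self.patches[j]) & set(self.patches[k])
            out[(j, k)] = tuple(s for s in self.base if s in shared)
        return out

    def owners(self, site: str) -> tuple[str, ...]:
        return tuple(aid for aid in self.agent_ids if site in self.patches[aid])


@dataclass(frozen=True)
class Section:
    """One agent's local data: a categorical vector per site of its patch."""

    agent: str
    data: Mapping[str, Categorical]

    def __init__(self, agent: str, data: Mapping[str, Categorical]):
        data = dict(data)
        if not data:
            raise ValidationError("a section needs at least one site")
        object.__setattr__(self, "agent", agent)
        object.__setattr__(self, "data", data)

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.data)


@dataclass(frozen=True)
class GlobalSection:
    """One categorical vector per site of the whole base."""

    data: Mapping[str, Categorical]

    def restrict_to(self, sites: Sequence[str]) -> dict[str, Categorical]:
        return {s: self.data[s] for s in sites}


@dataclass(frozen=True)
class ObstructionReport:
    """Quantified failure of the gluing condition.

    ``pairwise[(j,k)][site]`` is the squared Euclidean distance between
    the two agents' vectors at a shared site; ``energy`` sums all of
    them; ``max_discrepancy`` is the largest total-variation distance at
    any shared site.  ``vacuous`` marks covers without overlaps, which
    glue trivially.
    """

    pairwise: Mapping[tuple[str, str], Mapping[str, float]]
    energy: float
    max_discrepancy: float
    vacuous: bool


class GluingError(ValidationError):
    """Gluing attempted on sections that disagree beyond tolerance."""

    def __init__(self, report: ObstructionReport):
        self.report = report
        super().__init__(
            f"sections do not glue: energy={report.energy:.6g}, "
            f"max site discrepancy={report.max_discrepancy:.6g}")


def restrict(section: Section, sites: Sequence[str]) -> Section:
    """Restriction to a subset of the section's sites (identity on data)."""
    for s in sites:
        if s not in section.data:
            raise ValidationError(f"site {s!r} outside patch of {section.agent!r}")
    return Section(section.agent, {s: section.data[s] for s in sites})


def _sections_by_agent(sections: Sequence[Section], cover: Cover) -> dict[str, Section]:
    by_agent = {sec.agent: sec for sec in sections}
    if set(by_agent) != set(cover.agent_ids):
        raise ValidationError("need exactly one section per covering agent")
    for aid, sec in by_agent.items():
        if set(sec.sites) != set(cover.patches[aid]):
            raise ValidationError(f"section of {aid!r} does not match its patch")
    return by_agent


def disagreement(sections: Sequence[Section], cover: Cover) -> ObstructionReport:
    """Obstruction to gluing: squared-distance energy over all overlaps."""
    by_agent = _sections_by_agent(sections, cover)
    pairwise: dict[tuple[str, str], dict[str, float]] = {}
    energy = 0.0
    max_tv = 0.0
    any_overlap = False
    for (j, k), shared in cover.overlaps().items():
        if not shared:
            continue
        any_overlap = True
        per_site = {}
        for site in shared:
            vj, vk = by_agent[j].data[site], by_agent[k].data[site]
            if vj.support.labels != vk.support.labels:
                raise ValidationError(
                    f"sections of {j!r} and {k!r} disagree on the outcome set at {site!r}")
            d2 = float(np.sum((vj.probs - vk.probs) ** 2))
            per_site[site] = d2
            energy += d2
            max_tv = max(max_tv, total_variation(vj, vk))
        pairwise[(j, k)] = per_site
    return ObstructionReport(pairwise=pairwise, energy=energy,
                             max_discrepancy=max_tv, vacuous=not any_overlap)


def check_gluing(sections: Sequence[Section], cover: Cover,
                 tol: float) -> tuple[bool, ObstructionReport]:
    """True iff every overlap agrees within ``tol`` (total variation)."""
    report = disagreement(sections, cover)
    return report.max_discrepancy <= tol, report


def glue(sections: Sequence[Section], cover: Cover, tol: float = 1e-9) -> GlobalSection:
    """Glue agreeing sections into a global world model.

    Each base site receives the renormalized average of all sections
    covering it (identical up to ``tol`` by the gluing precondition).
    Raises :class:`GluingError` carrying the obstruction otherwise.
    """
    ok, report = check_gluing(sections, cover, tol)
    if not ok:
        raise GluingError(report)
    by_agent = _sections_by_agent(sections, cover)
    data = {}
    for site in cover.base:
        owners = cover.owners(site)
        stacked = np.mean([by_agent[a].data[site].probs for a in owners], axis=0)
        data[site] = Categorical(by_agent[owners[0]].data[site].support,
                                 stacked / stacked.sum())
    return GlobalSection(data)


def consensus_step(sections: Sequence[Section], cover: Cover,
                   eta: float) -> list[Section]:
    """One synchronous diffusion step toward site-wise means.

    Every agent's vector at a shared site moves a fraction ``eta``
    toward the mean of all agents present at that site, then
    renormalizes (a defence against floating-point drift only — the
    convex combination is already normalized).  Solo sites are left
    untouched.  Already-consistent sections are a fixed point.
    """
    if not (0.0 < eta <= 1.0):
        raise ValidationError("eta must lie in (0, 1]")
    by_agent = _sections_by_agent(sections, cover)
    means: dict[str, np.ndarray] = {}
    for site in cover.base:
        owners = cover.owners(site)
        if len(owners) >= 2:
            means[site] = np.mean([by_agent[a].data[site].probs for a in owners], axis=0)
    out = []
    for aid in cover.agent_ids:
        sec = by_agent[aid]
        new_data = {}
        for site, vec in sec.data.items():
            if site in means:
                moved = (1.0 - eta) * vec.probs + eta * means[site]
                new_data[site] = Categorical(vec.support, moved / moved.sum())
            else:
                new_data[site] = vec
        out.append(Section(aid, new_data))
    return out


@dataclass(frozen=True)
class ConsensusResult:
    sections: tuple[Section, ...]
    energies: tuple[float, ...]
    discrepancies: tuple[float, ...]
    converged: bool
    iterations: int


def run_consensus(sections: Sequence[Section], cover: Cover, eta: float = 0.5,
                  max_iter: int = 1000, tol: float = 1e-12) -> ConsensusResult:
    """Iterate :func:`consensus_step` until the energy falls to ``tol``.

    The energy trace (including the initial energy) and the matching
    max-site-discrepancy trace are recorded at every iteration; the
    energy is non-increasing for ``eta ≤ 1``.  On non-convergence the
    best sections so far are returned with ``converged=False``.
    """
    current = list(sections)
    rep = disagreement(current, cover)
    energies = [rep.energy]
    discrepancies = [rep.max_discrepancy]
    it = 0
    while energies[-1] > tol and it < max_iter:
        current = consensus_step(current, cover, eta)
        rep = disagreement(current, cover)
        energies.append(rep.energy)
        discrepancies.append(rep.max_discrepancy)
        it += 1
    return ConsensusResult(sections=tuple(current), energies=tuple(energies),
                           discrepancies=tuple(discrepancies),
                           converged=energies[-1] <= tol, iterations=it)


@dataclass(frozen=True)
class SpatialModelCheck:
    """Result of checking observation admissibility against site geometry."""

    site_assignment: Mapping[str, str]
    admissibility: Mapping[str, tuple[str, ...]]
    passed: bool
    violations: tuple[tuple[str, str, str, float], ...]  # (state, site, observation, mass)


def validate_spatial_model(model: GenerativeModel,
                           site_assignment: Mapping[str, str],
                           admissibility: Mapping[str, Collection[str]]) -> SpatialModelCheck:
    """Check that observations are predicted only where they may be made.

    Every hidden state is assigned a site; ``admissibility[site]`` lists
    the observations that can occur there.  The model passes iff its
    likelihood places zero mass on every inadmissible (state,
    observation) pair; violations are listed, not raised.
    """
    for s in model.states:
        if s not in site_assignment:
            raise ValidationError(f"state {s!r} has no site assignment")
    violations = []
    for j, s in enumerate(model.states):
        site = site_assignment[s]
        allowed = set(admissibility.get(site, ()))
        for i, o in enumerate(model.observations):
            mass = float(model.A.table[i, j])
            if mass > 0.0 and o not in allowed:
                violations.append((s, site, o, mass))
    return SpatialModelCheck(
        site_assignment=dict(site_assignment),
        admissibility={k: tuple(v) for k, v in admissibility.items()},
        passed=not violations,
        violations=tuple(violations),
    )
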