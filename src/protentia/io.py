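"""Serialization and run logging: JSON models/scenarios, CSV traces.

Formats are deliberately plain: strict-schema JSON for models,
polynomials, covers and scenarios; CSV for trajectories and consensus
traces; JSON-lines for structured per-step records.  Unknown fields are
rejected, and every load error names the offending entity.
"""

from __future__ import annotations

import csv
import hashlib
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np

from .categorical import Categorical, FiniteSet, StochasticMap, ValidationError
from .engine import GenerativeModel
from .multiagent import AgentSpec, EnsembleTrajectory, WorldEnv
from .poly import Polynomial, make_monomial
from .sheaf import ConsensusResult, Cover, Section

__all__ = [
    "model_to_dict", "model_from_dict", "save_model", "load_model",
    "poly_to_dict", "poly_from_dict", "save_poly", "load_poly",
    "cover_sections_to_dict", "cover_sections_from_dict",
    "save_cover_sections", "load_cover_sections",
    "scenario_to_dict", "scenario_from_dict", "save_scenario", "load_scenario",
    "canonical_json", "write_trajectory_csv", "write_trajectory_jsonl",
    "write_consensus_csv", "write_manifest",
]

_MODEL_FIELDS = {"states", "observations", "actions", "A", "B", "C", "D", "E",
                 "gamma", "site_assignment", "admissibility"}


def canonical_json(obj) -> str:
    """Stable, diffable JSON form (sorted keys, fixed separators)."""
    return json.dumps(obj, sort_keys=True, indent=1)


def _check_fields(d: Mapping, allowed: set[str], required: set[str], what: str) -> None:
    unknown = sorted(set(d) - allowed)
    if unknown:
        raise ValidationError(f"{what}: unknown field(s) {unknown}")
    missing = sorted(required - set(d))
    if missing:
        raise ValidationError(f"{what}: missing field(s) {missing}")


def _table(rows: Sequence[Sequence[float]], source: FiniteSet, target: FiniteSet,
           name: str) -> StochasticMap:
    try:
        return StochasticMap(source, target, rows)
    except ValidationError as exc:
        raise ValidationError(f"table {name!r}: {exc}") from None


# ---------------------------------------------------------------------------
# generative models
# ---------------------------------------------------------------------------

def model_to_dict(model: GenerativeModel, site_assignment: Mapping[str, str] | None = None,
                  admissibility: Mapping[str, Sequence[str]] | None = None) -> dict:
    d = {
        "states": list(model.states),
        "observations": list(model.observations),
        "actions": list(model.actions),
        "A": model.A.table.tolist(),
        "B": {u: model.B[u].table.tolist() for u in model.actions},
        "C": model.C.probs.tolist(),
        "D": model.D.probs.tolist(),
        "E": model.E.probs.tolist(),
        "gamma": float(model.gamma),
    }
    if site_assignment is not None:
        d["site_assignment"] = dict(site_assignment)
    if admissibility is not None:
        d["admissibility"] = {k: list(v) for k, v in admissibility.items()}
    return d


def model_from_dict(d: Mapping) -> GenerativeModel:
    _check_fields(d, _MODEL_FIELDS,
                  {"states", "observations", "actions", "A", "B", "C", "D", "E", "gamma"},
                  "model")
    S = FiniteSet(d["states"])
    O = FiniteSet(d["observations"])
    U = FiniteSet(d["actions"])
    A = _table(d["A"], S, O, "A")
    B = {}
    for u in U:
        if u not in d["B"]:
            raise ValidationError(f"model: B is missing action {u!r}")
        B[u] = _table(d["B"][u], S, S, f"B[{u}]")
    extra_b = sorted(set(d["B"]) - set(U.labels))
    if extra_b:
        raise ValidationError(f"model: B has unknown action(s) {extra_b}")
    try:
        C = Categorical(O, d["C"])
        D = Categorical(S, d["D"])
        E = Categorical(U, d["E"])
    except ValidationError as exc:
        raise ValidationError(f"model vector: {exc}") from None
    return GenerativeModel(states=S, observations=O, actions=U, A=A, B=B,
                           C=C, D=D, E=E, gamma=float(d["gamma"]))


def save_model(model: GenerativeModel, path: str | Path, **extras) -> None:
    Path(path).write_text(canonical_json(model_to_dict(model, **extras)) + "\n")


def load_model(path: str | Path) -> GenerativeModel:
    return model_from_dict(_read_json(path))


def load_model_extras(path: str | Path) -> tuple[GenerativeModel, dict, dict]:
    """Model plus optional spatial annotations (site_assignment, admissibility)."""
    d = _read_json(path)
    model = model_from_dict(d)
    return model, d.get("site_assignment", {}), d.get("admissibility", {})


def _read_json(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"file not found: {p}")
    try:
        return json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{p}: invalid JSON ({exc})") from None


# ---------------------------------------------------------------------------
# polynomials
# ---------------------------------------------------------------------------

def poly_to_dict(p: Polynomial) -> dict:
    return {"positions": list(p.positions),
            "directions": {i: list(p.directions[i]) for i in p.positions}}


def poly_from_dict(d: Mapping) -> Polynomial:
    _check_fields(d, {"positions", "directions"}, {"positions", "directions"}, "polynomial")
    positions = FiniteSet(d["positions"])
    return Polynomial(positions, {i: FiniteSet(d["directions"][i]) for i in positions})


def save_poly(p: Polynomial, path: str | Path) -> None:
    Path(path).write_text(canonical_json(poly_to_dict(p)) + "\n")


def load_poly(path: str | Path) -> Polynomial:
    return poly_from_dict(_read_json(path))


# ---------------------------------------------------------------------------
# covers and sections
# ---------------------------------------------------------------------------

def cover_sections_to_dict(cover: Cover, sections: Sequence[Section]) -> dict:
    outcomes = None
    sec_d = {}
    for sec in sections:
        sec_d[sec.agent] = {site: vec.probs.tolist() for site, vec in sec.data.items()}
        for vec in sec.data.values():
            outcomes = list(vec.support)
    return {"base": list(cover.base),
            "patches": {aid: list(cover.patches[aid]) for aid in cover.agent_ids},
            "outcomes": outcomes,
            "sections": sec_d}


def cover_sections_from_dict(d: Mapping) -> tuple[Cover, list[Section]]:
    _check_fields(d, {"base", "patches", "outcomes", "sections"},
                  {"base", "patches", "sections"}, "cover")
    base = FiniteSet(d["base"])
    cover = Cover(base, d["patches"])
    outcomes = FiniteSet(d["outcomes"]) if d.get("outcomes") else None
    sections = []
    for aid, sites in d["sections"].items():
        data = {}
        for site, probs in sites.items():
            sup = outcomes if outcomes is not None else FiniteSet(
                [f"x{i}" for i in range(len(probs))])
            try:
                data[site] = Categorical(sup, probs)
            except ValidationError as exc:
                raise ValidationError(f"section {aid!r} at {site!r}: {exc}") from None
        sections.append(Section(aid, data))
    return cover, sections


def save_cover_sections(cover: Cover, sections: Sequence[Section], path: str | Path) -> None:
    Path(path).write_text(canonical_json(cover_sections_to_dict(cover, sections)) + "\n")


def load_cover_sections(path: str | Path) -> tuple[Cover, list[Section]]:
    return cover_sections_from_dict(_read_json(path))


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def scenario_to_dict(bundle) -> dict:
    env, agents = bundle.env, bundle.agents
    d: dict = {"metadata": dict(bundle.metadata)}
    if env is not None:
        d["env"] = {
            "states": list(env.states),
            "joint_actions": list(env.joint_actions),
            "init": env.init.probs.tolist(),
            "channels": {aid: {"observations": list(ch.target),
                               "table": ch.table.tolist()}
                         for aid, ch in env.channels.items()},
            "transition": {u: env.transition[u].table.tolist() for u in env.joint_actions},
        }
    d["agents"] = [{"id": a.id, "agent_index": a.agent_index, "tom_depth": a.tom_depth,
                    "own_actions": list(a.own_actions),
                    "model": model_to_dict(a.model)} for a in agents]
    if bundle.cover is not None and bundle.sections is not None:
        d["cover_sections"] = cover_sections_to_dict(bundle.cover, bundle.sections)
    return d


def scenario_from_dict(d: Mapping):
    from .fixtures import ScenarioBundle  # deferred: fixtures imports this module's peers
    _check_fields(d, {"metadata", "env", "agents", "cover_sections"}, {"agents"}, "scenario")
    agents = []
    for ad in d["agents"]:
        _check_fields(ad, {"id", "agent_index", "tom_depth", "own_actions", "model"},
                      {"id", "agent_index", "own_actions", "model"}, f"agent {ad.get('id')!r}")
        model = model_from_dict(ad["model"])
        own = FiniteSet(ad["own_actions"])
        agents.append(AgentSpec(id=ad["id"],
                                interface=make_monomial(model.observations, own),
                                model=model, own_actions=own,
                                agent_index=int(ad["agent_index"]),
                                tom_depth=int(ad.get("tom_depth", 1))))
    env = None
    if "env" in d:
        ed = d["env"]
        _check_fields(ed, {"states", "joint_actions", "init", "channels", "transition"},
                      {"states", "joint_actions", "init", "channels", "transition"}, "env")
        S = FiniteSet(ed["states"])
        joint = FiniteSet(ed["joint_actions"])
        channels = {aid: _table(cd["table"], S, FiniteSet(cd["observations"]),
                                f"channel[{aid}]")
                    for aid, cd in ed["channels"].items()}
        transition = {u: _table(ed["transition"][u], S, S, f"transition[{u}]")
                      for u in joint}
        env = WorldEnv(states=S, channels=channels, transition=transition,
                       joint_actions=joint, init=Categorical(S, ed["init"]))
    cover = sections = None
    if "cover_sections" in d:
        cover, secs = cover_sections_from_dict(d["cover_sections"])
        sections = tuple(secs)
    return ScenarioBundle(env=env, agents=tuple(agents), cover=cover,
                          sections=sections, metadata=dict(d.get("metadata", {})))


def save_scenario(bundle, path: str | Path) -> None:
    Path(path).write_text(canonical_json(scenario_to_dict(bundle)) + "\n")


def load_scenario(path: str | Path):
    return scenario_from_dict(_read_json(path))


# ---------------------------------------------------------------------------
# trajectory and trace writers
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: EnsembleTrajectory, path: str | Path) -> None:
    """One row per step; per-agent observation/action/F/G/belief columns.

    For a single agent this is the plain trajectory format
    (step, observation, action, belief:<state>..., F, G:<action>...).
    """
    ids = traj.agent_ids
    single = len(ids) == 1
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["step"] if single else ["step", "true_state"]
        for aid in ids:
            tag = "" if single else f":{aid}"
            rec0 = traj.steps[0]
            header += [f"observation{tag}", f"action{tag}"]
            header += [f"belief{tag}:{s}" for s in rec0.beliefs[aid].support]
            header += [f"F{tag}"]
            header += [f"G{tag}:{u}" for u in sorted(rec0.efe_marginal[aid])]
        w.writerow(header)
        for rec in traj.steps:
            row = [rec.step] if single else [rec.step, rec.true_state]
            for aid in ids:
                row += [rec.observations[aid], rec.actions[aid]]
                row += [f"{p:.12g}" for p in rec.beliefs[aid].probs]
                row += [f"{rec.free_energy[aid].F:.12g}"]
                row += [f"{rec.efe_marginal[aid][u]:.12g}"
                        for u in sorted(rec.efe_marginal[aid])]
            w.writerow(row)


def write_trajectory_jsonl(traj: EnsembleTrajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in traj.steps:
            fh.write(json.dumps({
                "step": rec.step,
                "true_state": rec.true_state,
                "observations": dict(rec.observations),
                "actions": dict(rec.actions),
                "beliefs": {aid: b.probs.tolist() for aid, b in rec.beliefs.items()},
                "F": {aid: r.F for aid, r in rec.free_energy.items()},
                "G": {aid: dict(g) for aid, g in rec.efe_marginal.items()},
            }, sort_keys=True) + "\n")


def write_consensus_csv(result: ConsensusResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "energy", "max_discrepancy"])
        for i, (e, d) in enumerate(zip(result.energies, result.discrepancies)):
            w.writerow([i, f"{e:.12g}", f"{d:.12g}"])


def write_manifest(config: Mapping, seed: int | None, path: str | Path) -> None:
    """Machine-readable run manifest written beside outputs."""
    from . import __version__
    blob = canonical_json(dict(config))
    manifest = {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "package": "protentia",
        "version": __version__,
        "numpy": np.__version__,
    }
    Path(path).write_text(canonical_json(manifest) + "\n")
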