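"""Finite polynomial functors: the interface algebra of agents.

A polynomial ``p = Σ_{i : p(1)} y^{p[i]}`` is stored as a finite set of
*positions* (the configurations or actions an agent can adopt) together
with one finite *direction* set per position (the sense data admissible
in that configuration).  A monomial ``A·y^S`` with a constant direction
set recovers the classical Markov blanket: its total set has cardinality
``|A|·|S|``.

Morphisms ``φ: p → q`` are pairs of a forward map on positions and a
family of backward maps on directions; they compose like lenses.  The
tensor ``p ⊗ q`` places two interfaces side by side, and the hom
polynomial ``[p, q]`` internalizes patterns of interaction: its
positions are the morphisms ``p → q``.

All enumeration here is eager and exhaustive below an explicit cap;
nothing is sampled silently.  Isomorphism of finite polynomials is
compared by *cardinality profile* — position count plus the multiset of
direction-set sizes — which characterizes polynomials up to relabelling.
"""

from __future__ import annotations

import itertools
from collections import Counter
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .categorical import FiniteSet, StochasticMap, ValidationError

__all__ = [
    "Polynomial",
    "PolyMorphism",
    "StochPolyMorphism",
    "DynamicalSystem",
    "CapExceeded",
    "CurryReport",
    "identity_poly",
    "make_monomial",
    "total_set",
    "tensor",
    "tensor_all",
    "count_morphisms",
    "enumerate_morphisms",
    "hom",
    "hom_profile",
    "curry_check",
    "run_system",
]


class CapExceeded(ValidationError):
    """Raised when an enumeration would exceed its declared cap."""

    def __init__(self, predicted: int, cap: int, what: str = "morphisms"):
        self.predicted = predicted
        self.cap = cap
        super().__init__(f"predicted {predicted} {what} exceeds cap {cap}")


def _pair(a: str, b: str) -> str:
    return f"({a},{b})"


@dataclass(frozen=True)
class Polynomial:
    """``Σ_{i : positions} y^{directions[i]}``."""

    positions: FiniteSet
    directions: Mapping[str, FiniteSet]

    def __init__(self, positions: FiniteSet, directions: Mapping[str, FiniteSet]):
        directions = dict(directions)
        missing = [i for i in positions if i not in directions]
        extra = [i for i in directions if i not in positions]
        if missing or extra:
            raise ValidationError(
                f"directions must be keyed exactly by positions (missing={missing}, extra={extra})")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "directions", directions)

    def direction_sizes(self) -> tuple[int, ...]:
        """Direction-set sizes in position order."""
        return tuple(len(self.directions[i]) for i in self.positions)

    def profile(self) -> tuple[int, tuple[int, ...]]:
        """(position count, sorted direction-size multiset) — the
        relabelling-invariant shadow of the polynomial."""
        return (len(self.positions), tuple(sorted(self.direction_sizes())))

    def is_monomial(self) -> bool:
        sets = [self.directions[i].labels for i in self.positions]
        return all(s == sets[0] for s in sets)


def identity_poly() -> Polynomial:
    """The tensor unit ``y``: one position, one direction."""
    star = FiniteSet(["*"])
    return Polynomial(star, {"*": star})


def make_monomial(configs: FiniteSet, senses: FiniteSet) -> Polynomial:
    """``configs · y^senses``: every position shares one direction set.

    This is the classical Markov blanket: ``Σ_{a:A} S = A × S``.
    """
    return Polynomial(configs, {i: senses for i in configs})


def total_set(p: Polynomial) -> FiniteSet:
    """The disjoint union ``Σp = Σ_i p[i]`` with labels ``(i,d)``."""
    labels = [_pair(i, d) for i in p.positions for d in p.directions[i]]
    return FiniteSet(labels)


def tensor(p: Polynomial, q: Polynomial) -> Polynomial:
    """``p ⊗ q``: interfaces side by side.

    Positions are pairs of positions, and the direction set at
    ``(i, i')`` is the product ``p[i] × q[i']``.
    """
    positions = FiniteSet([_pair(i, j) for i in p.positions for j in q.positions])
    directions = {}
    for i in p.positions:
        for j in q.positions:
            directions[_pair(i, j)] = FiniteSet(
                [_pair(d, e) for d in p.directions[i] for e in q.directions[j]])
    return Polynomial(positions, directions)


def tensor_all(polys: Sequence[Polynomial]) -> Polynomial:
    """Left fold of :func:`tensor`; a single polynomial is returned as-is."""
    if not polys:
        raise ValidationError("tensor_all needs at least one polynomial")
    out = polys[0]
    for p in polys[1:]:
        out = tensor(out, p)
    return out


@dataclass(frozen=True)
class PolyMorphism:
    """A morphism ``φ: source → target``.

    ``forward`` maps source positions to target positions (φ1);
    ``backward[i]`` maps each direction of ``target[forward[i]]`` back
    to a direction of ``source[i]`` (φ♯).
    """

    source: Polynomial
    target: Polynomial
    forward: Mapping[str, str]
    backward: Mapping[str, Mapping[str, str]]

    def __init__(self, source: Polynomial, target: Polynomial,
                 forward: Mapping[str, str], backward: Mapping[str, Mapping[str, str]]):
        forward = dict(forward)
        backward = {i: dict(m) for i, m in backward.items()}
        for i in source.positions:
            if i not in forward:
                raise ValidationError(f"forward map undefined at position {i!r}")
            j = forward[i]
            if j not in target.positions:
                raise ValidationError(f"forward image {j!r} not a target position")
            dom = target.directions[j]
            bw = backward.get(i)
            if bw is None:
                raise ValidationError(f"backward map missing at position {i!r}")
            for e in dom:
                if e not in bw:
                    raise ValidationError(f"backward map at {i!r} undefined on {e!r}")
                if bw[e] not in source.directions[i]:
                    raise ValidationError(
                        f"backward image {bw[e]!r} not a direction of source at {i!r}")
        object.__setattr__(self, "source", source)
        object.__setattr__(self, "target", target)
        object.__setattr__(self, "forward", forward)
        object.__setattr__(self, "backward", backward)

    @classmethod
    def identity(cls, p: Polynomial) -> "PolyMorphism":
        return cls(p, p,
                   {i: i for i in p.positions},
                   {i: {d: d for d in p.directions[i]} for i in p.positions})

    def compose(self, inner: "PolyMorphism") -> "PolyMorphism":
        """``self ∘ inner`` for ``inner: p → q`` and ``self: q → r``."""
        if inner.target.positions.labels != self.source.positions.labels:
            raise ValidationError("compose: middle polynomials do not match")
        forward = {i: self.forward[inner.forward[i]] for i in inner.source.positions}
        backward = {}
        for i in inner.source.positions:
            j = inner.forward[i]
            backward[i] = {e: inner.backward[i][self.backward[j][e]]
                           for e in self.target.directions[forward[i]]}
        return PolyMorphism(inner.source, self.target, forward, backward)

    def key(self) -> str:
        """Canonical string encoding (used as a hom-polynomial position label)."""
        fw = ";".join(f"{i}>{self.forward[i]}" for i in self.source.positions)
        bw = ";".join(
            f"{i}:" + ",".join(f"{e}>{self.backward[i][e]}"
                               for e in self.target.directions[self.forward[i]])
            for i in self.source.positions)
        return f"[{fw}|{bw}]"


@dataclass(frozen=True)
class StochPolyMorphism:
    """A morphism with stochastic feedback.

    Like :class:`PolyMorphism`, but each backward component is a
    stochastic map ``target[forward[i]] ⇝ source[i]``: a column-
    stochastic table of conditional distributions over the source's
    sense data.
    """

    source: Polynomial
    target: Polynomial
    forward: Mapping[str, str]
    backward: Mapping[str, StochasticMap]

    def __init__(self, source: Polynomial, target: Polynomial,
                 forward: Mapping[str, str], backward: Mapping[str, StochasticMap]):
        forward = dict(forward)
        backward = dict(backward)
        for i in source.positions:
            j = forward.get(i)
            if j is None or j not in target.positions:
                raise ValidationError(f"forward map invalid at {i!r}")
            sm = backward.get(i)
            if sm is None:
                raise ValidationError(f"stochastic backward missing at {i!r}")
            if sm.source.labels != target.directions[j].labels:
                raise ValidationError(f"backward at {i!r}: wrong domain")
            if sm.target.labels != source.directions[i].labels:
                raise ValidationError(f"backward at {i!r}: wrong codomain")
        object.__setattr__(self, "source", source)
        object.__setattr__(self, "target", target)
        object.__setattr__(self, "forward", forward)
        object.__setattr__(self, "backward", backward)


# ---------------------------------------------------------------------------
# morphism enumeration and hom polynomials
# ---------------------------------------------------------------------------

def count_morphisms(p: Polynomial, q: Polynomial) -> int:
    """Exact number of morphisms ``p → q``.

    For each forward map φ1 there are ``Π_i |p[i]|^{|q[φ1(i)]|}``
    backward families; the count sums this over all forward maps.
    """
    total = 0
    for fw in itertools.product(q.positions.labels, repeat=len(p.positions)):
        n = 1
        for i, j in zip(p.positions, fw):
            n *= len(p.directions[i]) ** len(q.directions[j])
        total += n
    return total


def enumerate_morphisms(p: Polynomial, q: Polynomial, cap: int = 100_000) -> list[PolyMorphism]:
    """Exhaustive, duplicate-free list of all morphisms ``p → q``.

    Refuses (with the predicted count) if more than ``cap`` morphisms
    would be produced.
    """
    predicted = count_morphisms(p, q)
    if predicted > cap:
        raise CapExceeded(predicted, cap)
    out: list[PolyMorphism] = []
    src_pos = p.positions.labels
    for fw in itertools.product(q.positions.labels, repeat=len(src_pos)):
        forward = dict(zip(src_pos, fw))
        # per position, all functions q[fw(i)] -> p[i]
        per_pos_choices = []
        for i in src_pos:
            dom = q.directions[forward[i]].labels
            cod = p.directions[i].labels
            per_pos_choices.append([dict(zip(dom, img))
                                    for img in itertools.product(cod, repeat=len(dom))])
        for combo in itertools.product(*per_pos_choices):
            backward = dict(zip(src_pos, combo))
            out.append(PolyMorphism(p, q, forward, backward))
    return out


def hom(p: Polynomial, q: Polynomial, cap: int = 100_000) -> Polynomial:
    """The hom polynomial ``[p, q] = Σ_{φ : p→q} y^{Σ_i q[φ1(i)]}``.

    Positions are the morphisms ``p → q`` (labelled canonically); the
    direction set at φ is the disjoint union over source positions ``i``
    of the target directions ``q[φ1(i)]``.
    """
    morphisms = enumerate_morphisms(p, q, cap=cap)
    labels = []
    directions = {}
    for m in morphisms:
        lbl = m.key()
        labels.append(lbl)
        directions[lbl] = FiniteSet(
            [_pair(i, e) for i in p.positions for e in q.directions[m.forward[i]]])
    return Polynomial(FiniteSet(labels), directions)


def hom_profile(p: Polynomial, q: Polynomial,
                forward_cap: int = 10_000_000) -> tuple[int, Counter]:
    """Cardinality profile of ``[p, q]`` without materializing it.

    The direction-set size of a hom position depends only on its forward
    component (``Σ_i |q[φ1(i)]|``), while each forward map carries
    ``Π_i |p[i]|^{|q[φ1(i)]|}`` backward families.  Iterating over
    forward maps alone therefore yields the exact position count and the
    exact multiset of direction sizes, as a ``Counter`` {size: count}.
    Counts are exact Python integers (no overflow).
    """
    n_forward = len(q.positions) ** len(p.positions)
    if n_forward > forward_cap:
        raise CapExceeded(n_forward, forward_cap, what="forward maps")
    sizes: Counter = Counter()
    total = 0
    psizes = [len(p.directions[i]) for i in p.positions]
    qsizes = {j: len(q.directions[j]) for j in q.positions}
    for fw in itertools.product(q.positions.labels, repeat=len(p.positions)):
        mult = 1
        dirsize = 0
        for pi, j in zip(psizes, fw):
            qs = qsizes[j]
            mult *= pi ** qs
            dirsize += qs
        sizes[dirsize] += mult
        total += mult
    return total, sizes


@dataclass(frozen=True)
class CurryReport:
    """Comparison of ``[p, [q, r]]`` against ``[p ⊗ q, r]``."""

    lhs_positions: int
    rhs_positions: int
    lhs_direction_sizes: Mapping[int, int]
    rhs_direction_sizes: Mapping[int, int]
    isomorphic: bool


def curry_check(p: Polynomial, q: Polynomial, r: Polynomial,
                cap: int = 100_000, forward_cap: int = 10_000_000) -> CurryReport:
    """Check the currying isomorphism ``[p, [q, r]] ≅ [p ⊗ q, r]``.

    Both sides are compared by cardinality profile: position count and
    the multiset of direction-set sizes.  The inner hom ``[q, r]`` is
    materialized (subject to ``cap``); the outer homs are profiled
    combinatorially (subject to ``forward_cap`` forward maps).
    """
    inner = hom(q, r, cap=cap)
    lhs_count, lhs_sizes = hom_profile(p, inner, forward_cap=forward_cap)
    rhs_count, rhs_sizes = hom_profile(tensor(p, q), r, forward_cap=forward_cap)
    return CurryReport(
        lhs_positions=lhs_count,
        rhs_positions=rhs_count,
        lhs_direction_sizes=dict(lhs_sizes),
        rhs_direction_sizes=dict(rhs_sizes),
        isomorphic=(lhs_count == rhs_count and lhs_sizes == rhs_sizes),
    )


# ---------------------------------------------------------------------------
# dynamical systems on an interface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DynamicalSystem:
    """A discrete-time system ``ϑ : S·y^S → p``.

    ``output(state, rng)`` picks the interface configuration the system
    presents in that state (may consume the generator when stochastic);
    ``update(state, direction, rng)`` maps an admissible input back to a
    successor state.
    """

    states: FiniteSet
    interface: Polynomial
    output: Callable[[str, np.random.Generator], str]
    update: Callable[[str, str, np.random.Generator], str]


def run_system(sys: DynamicalSystem, inputs: Sequence[str], s0: str,
               rng: np.random.Generator) -> list[tuple[str, str]]:
    """Unroll a dynamical system over a sequence of inputs.

    Returns the trajectory ``[(state, configuration), ...]`` of length
    ``len(inputs) + 1``; the output function is called exactly once per
    trajectory entry, and each input must be admissible for the
    configuration emitted at its step.
    """
    if s0 not in sys.states:
        raise ValidationError(f"initial state {s0!r} not in state set")
    s = s0
    traj: list[tuple[str, str]] = []
    for t, x in enumerate(inputs):
        cfg = sys.output(s, rng)
        traj.append((s, cfg))
        if x not in sys.interface.directions[cfg]:
            raise ValidationError(
                f"input {x!r} inadmissible at step {t} for configuration {cfg!r}")
        s = sys.update(s, x, rng)
    traj.append((s, sys.output(s, rng)))
    return traj
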