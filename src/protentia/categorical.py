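"""Finite categorical probability primitives.

Everything downstream (generative models, polynomial feedback, sheaf
sections) is built on three types: a labelled finite set, a categorical
distribution over such a set, and a column-stochastic conditional table
between two such sets.

Label order is the single source of truth for vector alignment: two
distributions are only ever combined when their supports carry identical
labels in identical order.  Probabilities of zero are legal; logarithms
inside energy computations clamp at ``EPS`` so that objectives stay
finite, while :func:`kl_divergence` deliberately returns ``+inf`` on an
absolute-continuity failure because it is used as a diagnostic.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPS",
    "ValidationError",
    "FiniteSet",
    "Categorical",
    "StochasticMap",
    "softmax",
    "kl_divergence",
    "symmetrized_kl",
    "total_variation",
    "compose_stochastic",
    "entropy",
    "clamped_log",
    "sample_index",
]

#: Floor applied to probabilities before taking logarithms inside
#: entropy/energy computations (never inside kl_divergence).
EPS = 1e-16

#: Tolerance for "sums to one" checks on probability vectors.
_NORM_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates a declared invariant."""


def clamped_log(p: np.ndarray | float) -> np.ndarray | float:
    """Natural log with probabilities floored at ``EPS``."""
    return np.log(np.clip(p, EPS, None))


def entropy(probs: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*log(0)=0 convention."""
    p = np.asarray(probs, dtype=float)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def sample_index(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one index from a probability vector.

    Shared by every stochastic component in the package so that two
    simulation loops consuming the same generator stay bit-identical.
    """
    return int(rng.choice(len(probs), p=probs))


@dataclass(frozen=True)
class FiniteSet:
    """An ordered, non-empty set of distinct string labels.

    Iteration order equals construction order and is part of the
    contract: probability vectors are aligned by this order.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Sequence[str]):
        labels = tuple(labels)
        if not labels:
            raise ValidationError("FiniteSet must be non-empty")
        if not all(isinstance(x, str) for x in labels):
            raise ValidationError("FiniteSet labels must be strings")
        if len(set(labels)) != len(labels):
            raise ValidationError(f"FiniteSet labels must be unique: {labels}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"label {label!r} not in {self.labels}") from None

    @property
    def size(self) -> int:
        return len(self.labels)


def _as_prob_vector(probs: Sequence[float] | np.ndarray, n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != (n,):
        raise ValidationError(f"expected a vector of length {n}, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValidationError("probabilities must be finite")
    if np.any(p < -1e-12):
        raise ValidationError(f"probabilities must be non-negative, got {p}")
    p = np.clip(p, 0.0, None)
    total = float(p.sum())
    if abs(total - 1.0) > _NORM_TOL:
        raise ValidationError(f"probabilities sum to {total}, expected 1 within {_NORM_TOL}")
    return p


@dataclass(frozen=True)
class Categorical:
    """A categorical distribution over a :class:`FiniteSet`.

    ``probs[i]`` is the probability of ``support.labels[i]``; the vector
    must be non-negative and sum to one within 1e-9.
    """

    support: FiniteSet
    probs: np.ndarray = field(repr=False)

    def __init__(self, support: FiniteSet, probs: Sequence[float] | np.ndarray):
        p = _as_prob_vector(probs, len(support))
        p.setflags(write=False)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", p)

    # -- constructors ---------------------------------------------------
    @classmethod
    def uniform(cls, support: FiniteSet) -> "Categorical":
        n = len(support)
        return cls(support, np.full(n, 1.0 / n))

    @classmethod
    def point(cls, support: FiniteSet, label: str) -> "Categorical":
        p = np.zeros(len(support))
        p[support.index(label)] = 1.0
        return cls(support, p)

    @classmethod
    def from_dict(cls, support: FiniteSet, d: Mapping[str, float]) -> "Categorical":
        return cls(support, [d.get(lbl, 0.0) for lbl in support])

    # -- queries --------------------------------------------------------
    def __getitem__(self, label: str) -> float:
        return float(self.probs[self.support.index(label)])

    def to_dict(self) -> dict[str, float]:
        return {lbl: float(p) for lbl, p in zip(self.support, self.probs)}

    def entropy(self) -> float:
        return entropy(self.probs)

    def argmax(self) -> str:
        """Most probable label; ties broken by label order."""
        return self.support.labels[int(np.argmax(self.probs))]

    def sample(self, rng: np.random.Generator) -> str:
        return self.support.labels[sample_index(self.probs, rng)]

    def same_support(self, other: "Categorical") -> bool:
        return self.support.labels == other.support.labels


@dataclass(frozen=True)
class StochasticMap:
    """A conditional distribution ``P(target | source)``.

    ``table[i, j] = P(target_i | source_j)``; every column is a
    categorical distribution over the target set.
    """

    source: FiniteSet
    target: FiniteSet
    table: np.ndarray = field(repr=False)

    def __init__(self, source: FiniteSet, target: FiniteSet,
                 table: Sequence[Sequence[float]] | np.ndarray):
        t = np.asarray(table, dtype=float)
        if t.shape != (len(target), len(source)):
            raise ValidationError(
                f"table shape {t.shape} != (|target|={len(target)}, |source|={len(source)})")
        for j, src in enumerate(source):
            try:
                _as_prob_vector(t[:, j], len(target))
            except ValidationError as exc:
                raise ValidationError(f"column {src!r}: {exc}") from None
        t = np.clip(t, 0.0, None)
        t.setflags(write=False)
        object.__setattr__(self, "source", source)
        object.__setattr__(self, "target", target)
        object.__setattr__(self, "table", t)

    @classmethod
    def identity(cls, s: FiniteSet) -> "StochasticMap":
        return cls(s, s, np.eye(len(s)))

    @classmethod
    def deterministic(cls, source: FiniteSet, target: FiniteSet,
                      mapping: Mapping[str, str]) -> "StochasticMap":
        t = np.zeros((len(target), len(source)))
        for j, src in enumerate(source):
            t[target.index(mapping[src]), j] = 1.0
        return cls(source, target, t)

    @classmethod
    def from_columns(cls, source: FiniteSet, target: FiniteSet,
                     cols: Mapping[str, Sequence[float]]) -> "StochasticMap":
        t = np.column_stack([np.asarray(cols[s], dtype=float) for s in source])
        return cls(source, target, t)

    def column(self, src_label: str) -> Categorical:
        return Categorical(self.target, self.table[:, self.source.index(src_label)])

    def __call__(self, src_label: str) -> Categorical:
        return self.column(src_label)

    def prob(self, tgt_label: str, src_label: str) -> float:
        return float(self.table[self.target.index(tgt_label), self.source.index(src_label)])

    def push(self, dist: Categorical) -> Categorical:
        """Pushforward of a distribution on the source (matrix-vector product)."""
        if dist.support.labels != self.source.labels:
            raise ValidationError("pushforward support mismatch")
        out = self.table @ dist.probs
        return Categorical(self.target, out / out.sum())

    def is_deterministic(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.max(self.table, axis=0) >= 1.0 - tol))


def softmax(values: Sequence[float] | np.ndarray, gamma: float,
            support: FiniteSet | None = None) -> Categorical:
    """Softmax of negated, precision-weighted values: ``σ(−γ·values)``.

    ``gamma`` is the precision: ``gamma=0`` erases all differences and
    yields the uniform distribution.  The result is invariant to adding
    a constant to every value.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("softmax requires finite values")
    if gamma < 0:
        raise ValidationError("softmax precision gamma must be non-negative")
    if support is None:
        support = FiniteSet([f"x{i}" for i in range(len(v))])
    if len(support) != len(v):
        raise ValidationError("softmax support size mismatch")
    z = -gamma * v
    z -= z.max()  # shift invariance, numerical stability
    w = np.exp(z)
    return Categorical(support, w / w.sum())


def kl_divergence(q: Categorical, p: Categorical) -> float:
    """Kullback-Leibler divergence ``D_KL[q || p]`` in nats.

    Returns ``+inf`` when ``p`` lacks mass somewhere ``q`` has it
    (absolute-continuity failure); uses the 0*log(0)=0 convention.
    """
    if not q.same_support(p):
        raise ValidationError("kl_divergence requires identical supports")
    qs, ps = q.probs, p.probs
    nz = qs > 0
    if np.any(ps[nz] == 0):
        return float("inf")
    return float(np.sum(qs[nz] * (np.log(qs[nz]) - np.log(ps[nz]))))


def symmetrized_kl(q: Categorical, p: Categorical) -> float:
    """Jeffreys divergence ``(KL[q||p] + KL[p||q]) / 2``."""
    return 0.5 * (kl_divergence(q, p) + kl_divergence(p, q))


def total_variation(q: Categorical, p: Categorical) -> float:
    """Total-variation distance ``max_A |q(A) - p(A)| = 0.5 * L1``."""
    if not q.same_support(p):
        raise ValidationError("total_variation requires identical supports")
    return 0.5 * float(np.abs(q.probs - p.probs).sum())


def compose_stochastic(g: StochasticMap, f: StochasticMap) -> StochasticMap:
    """Chapman-Kolmogorov composite ``g ∘ f`` (first f, then g)."""
    if f.target.labels != g.source.labels:
        raise ValidationError(
            f"cannot compose: f.target {f.target.labels} != g.source {g.source.labels}")
    table = g.table @ f.table
    # columns of a product of column-stochastic matrices are stochastic;
    # renormalize only to absorb floating-point drift
    table = table / table.sum(axis=0, keepdims=True)
    return StochasticMap(f.source, g.target, table)
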