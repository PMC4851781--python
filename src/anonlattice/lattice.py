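"""Generalization lattices: de-identification policies and their partial order.

A *policy* assigns one generalization level to each quasi-identifying
attribute; it is represented as a plain tuple of non-negative integers, so
policies are immutable, hashable and compare componentwise.  The set of all
policies for given hierarchy heights forms a bounded, ranked lattice under
the componentwise order.  The lattice is never materialized: :class:`LatticeSpec`
only stores the per-attribute heights, and :func:`enumerate_rank_order`
generates elements on the fly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Policy",
    "LatticeSpec",
    "precedes",
    "strict_precedes",
    "rank",
    "lattice_size",
    "direct_generalizations",
    "enumerate_rank_order",
    "is_antichain",
]

#: A de-identification policy: one generalization level per attribute.
Policy = tuple[int, ...]


@dataclass(frozen=True)
class LatticeSpec:
    """Shape of a generalization lattice.

    Parameters
    ----------
    heights
        Per-attribute hierarchy heights ``h_i >= 1``; attribute ``i`` admits
        generalization levels ``0 .. h_i - 1``.
    attribute_names
        Optional display names; defaults to ``attr0, attr1, ...``.
    """

    heights: tuple[int, ...]
    attribute_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        heights = tuple(int(h) for h in self.heights)
        if len(heights) == 0:
            raise ValueError("a lattice needs at least one attribute")
        if any(h < 1 for h in heights):
            raise ValueError(f"hierarchy heights must be >= 1, got {heights}")
        object.__setattr__(self, "heights", heights)
        names = tuple(self.attribute_names)
        if not names:
            names = tuple(f"attr{i}" for i in range(len(heights)))
        if len(names) != len(heights):
            raise ValueError("attribute_names and heights differ in length")
        object.__setattr__(self, "attribute_names", names)

    @property
    def m(self) -> int:
        """Number of attributes."""
        return len(self.heights)

    @property
    def size(self) -> int:
        """Number of policies in the lattice (product of heights)."""
        return prod(self.heights)

    @property
    def bottom(self) -> Policy:
        return (0,) * self.m

    @property
    def top(self) -> Policy:
        return tuple(h - 1 for h in self.heights)

    @property
    def max_rank(self) -> int:
        return sum(h - 1 for h in self.heights)

    def contains(self, x: Policy) -> bool:
        return len(x) == self.m and all(0 <= v < h for v, h in zip(x, self.heights))

    def validate(self, x: Policy) -> Policy:
        """Return ``x`` as a tuple, raising ``ValueError`` if invalid here."""
        x = tuple(int(v) for v in x)
        if not self.contains(x):
            raise ValueError(f"policy {x} invalid for heights {self.heights}")
        return x


def precedes(x: Policy, y: Policy) -> bool:
    """Componentwise order: ``x`` precedes ``y`` iff ``x_i <= y_i`` for all i.

    Reflexive: ``precedes(x, x)`` is true.  ``x`` is then a *specialization*
    of ``y`` and ``y`` a *generalization* of ``x``.
    """
    if len(x) != len(y):
        raise ValueError(f"policies differ in length: {len(x)} vs {len(y)}")
    return all(a <= b for a, b in zip(x, y))


def strict_precedes(x: Policy, y: Policy) -> bool:
    """Proper specialization: ``precedes(x, y)`` and ``x != y``."""
    return x != y and precedes(x, y)


def rank(x: Policy) -> int:
    """Total generalization level of a policy: the sum of its components."""
    return sum(x)


def lattice_size(spec: LatticeSpec) -> int:
    """Number of policies, exponential in the number of attributes."""
    return spec.size


def direct_generalizations(x: Policy, spec: LatticeSpec) -> list[Policy]:
    """Policies obtained by raising exactly one component of ``x`` by one.

    Empty for the top element.  Every result has rank ``rank(x) + 1``.
    """
    x = spec.validate(x)
    out: list[Policy] = []
    for i, h in enumerate(spec.heights):
        if x[i] + 1 < h:
            out.append(x[:i] + (x[i] + 1,) + x[i + 1 :])
    return out


def enumerate_rank_order(spec: LatticeSpec) -> Iterator[Policy]:
    """Yield every policy exactly once, grouped by non-decreasing rank.

    Within one rank the order is lexicographic.  Generation is odometer
    style with constant memory per step; the lattice is never stored.
    """
    heights = spec.heights
    m = spec.m
    # suffix_max[i] = max rank attainable by components i..m-1
    suffix_max = [0] * (m + 1)
    for i in range(m - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + heights[i] - 1

    def gen(i: int, remaining: int, prefix: tuple[int, ...]) -> Iterator[Policy]:
        if i == m:
            if remaining == 0:
                yield prefix
            return
        lo = max(0, remaining - suffix_max[i + 1])
        hi = min(heights[i] - 1, remaining)
        for v in range(lo, hi + 1):
            yield from gen(i + 1, remaining - v, prefix + (v,))

    for r in range(suffix_max[0] + 1):
        yield from gen(0, r, ())


def is_antichain(policies: Iterable[Policy]) -> bool:
    """True iff no two distinct elements are comparable under ``precedes``."""
    items: Sequence[Policy] = list(policies)
    for i, x in enumerate(items):
        for y in items[i + 1 :]:
            if x == y:
                continue
            if precedes(x, y) or precedes(y, x):
                return False
    return True
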