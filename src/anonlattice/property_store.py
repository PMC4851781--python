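"""Implicit storage of predictive properties over a generalization lattice.

A *predictive property* discovered for one policy is inherited either by
all of its generalizations (direction UP, e.g. "insufficient quality") or
by all of its specializations (direction DOWN, e.g. "insufficient
protection").  A store keeps the policies for which the property has been
*observed*; whether any other policy carries the property is answered by an
inheritance query, so complete information about an exponentially large
region of the lattice is held implicitly.

Four interchangeable implementations are provided for benchmarking:

1. a simple list scanned on every query;
2. a list maintaining the antichain invariant (inserting ``x`` removes all
   stored elements that inherit from it);
3. a prefix tree over policy components with the antichain invariant,
   answering queries by range descent;
4. the tree of option 3 with a per-node rank bound (min of stored ranks
   below for UP, max for DOWN) that prunes subtrees whose elements cannot
   precede (resp. succeed) the queried policy.

All four answer every query identically; only cost and stored-set size
differ.  The DOWN direction is the exact mirror of UP: comparisons and the
min/max role of the bound are flipped.
"""

from __future__ import annotations

import json
from enum import Enum
from typing import IO

from .lattice import Policy, rank

__all__ = ["StoreDirection", "PropertyStore", "ListStore", "AntichainListStore", "TreeStore", "make_store"]


class StoreDirection(Enum):
    """Inheritance direction of the stored property."""

    UP = "up"  # inherited by generalizations
    DOWN = "down"  # inherited by specializations


class PropertyStore:
    """Common surface and statistics of the four implementations.

    In the search context inserts are *unguarded*: a policy associated with
    a property is excluded from the search and therefore never inserted, so
    the antichain invariant holds without a pre-insert query.  For
    standalone use ``guarded=True`` performs that query and skips inserts of
    already-associated elements.
    """

    option: int = 0

    def __init__(self, m: int, direction: StoreDirection = StoreDirection.UP, guarded: bool = False):
        if m < 1:
            raise ValueError("stores require at least one attribute (m >= 1)")
        self.m = m
        self.direction = direction
        self.guarded = guarded
        self.insert_count = 0  # attempted inserts, symbol of the cost analyses
        self.query_count = 0
        self.hit_count = 0
        self.max_size = 0

    # -- implementation hooks ---------------------------------------------

    def _query(self, x: Policy) -> bool:
        raise NotImplementedError

    def _insert(self, x: Policy) -> None:
        raise NotImplementedError

    def elements(self) -> set[Policy]:
        """The currently stored set; an antichain for options 2-4."""
        raise NotImplementedError

    def __len__(self) -> int:
        raise NotImplementedError

    def exact_contains(self, x: Policy) -> bool:
        raise NotImplementedError

    # -- public surface ----------------------------------------------------

    def query(self, x: Policy) -> bool:
        """True iff ``x`` inherits the property from some *other* stored policy.

        The range query deliberately cannot find ``x`` itself; use
        :meth:`exact_contains` where membership of ``x`` matters.
        """
        self._check(x)
        self.query_count += 1
        result = self._query(x)
        if result:
            self.hit_count += 1
        return result

    def insert(self, x: Policy) -> None:
        x = tuple(x)
        self._check(x)
        self.insert_count += 1
        if self.guarded and (self._query(x) or self.exact_contains(x)):
            return
        self._insert(x)
        self.max_size = max(self.max_size, len(self))

    def _check(self, x: Policy) -> None:
        if len(x) != self.m:
            raise ValueError(f"policy of length {len(x)} in a store for m={self.m}")

    def _covers(self, y: Policy, x: Policy) -> bool:
        """Does stored ``y`` propagate the property to ``x``?"""
        if self.direction is StoreDirection.UP:
            return all(a <= b for a, b in zip(y, x))
        return all(a >= b for a, b in zip(y, x))

    def dump_json(self, stream: IO[str]) -> None:
        """Sorted element list, for debugging and cross-implementation diffs."""
        json.dump(sorted(self.elements()), stream)


class ListStore(PropertyStore):
    """Option 1: a plain list, scanned linearly; nothing is ever removed."""

    option = 1

    def __init__(self, m: int, direction: StoreDirection = StoreDirection.UP, guarded: bool = False):
        super().__init__(m, direction, guarded)
        self._items: list[Policy] = []

    def _query(self, x: Policy) -> bool:
        return any(y != x and self._covers(y, x) for y in self._items)

    def _insert(self, x: Policy) -> None:
        self._items.append(x)

    def elements(self) -> set[Policy]:
        return set(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def exact_contains(self, x: Policy) -> bool:
        return tuple(x) in self._items


class AntichainListStore(PropertyStore):
    """Option 2: a list that keeps only pairwise incomparable elements.

    An element covered by a newly inserted one is redundant — the new
    element already propagates the property to it and beyond — so inserting
    ``x`` removes every stored ``y`` that inherits from ``x``.
    """

    option = 2

    def __init__(self, m: int, direction: StoreDirection = StoreDirection.UP, guarded: bool = False):
        super().__init__(m, direction, guarded)
        self._items: list[Policy] = []

    def _query(self, x: Policy) -> bool:
        return any(y != x and self._covers(y, x) for y in self._items)

    def _insert(self, x: Policy) -> None:
        self._items = [y for y in self._items if not self._covers(x, y)]
        self._items.append(x)

    def elements(self) -> set[Policy]:
        return set(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def exact_contains(self, x: Policy) -> bool:
        return tuple(x) in self._items


class _Node:
    __slots__ = ("children", "bound")

    def __init__(self, bound: int) -> None:
        self.children: dict[int, _Node] = {}
        self.bound = bound


class TreeStore(PropertyStore):
    """Options 3 and 4: a prefix tree over policy components.

    Depth ``i`` of the tree holds generalization levels for attribute ``i``;
    each root-to-leaf path spells one stored policy.  A query for ``x``
    descends, at depth ``i``, only children whose level could belong to a
    specialization (UP: ``level <= x_i``; DOWN mirrored); reaching a leaf
    proves inheritance.  With ``use_bounds`` (option 4) each node carries
    the minimum (UP) or maximum (DOWN) rank of the policies below it, and a
    subtree is skipped when that bound shows none of its elements can have
    rank strictly below (resp. above) ``rank(x)``.

    ``last_query_visited`` records the ``(depth, level)`` pairs of nodes
    descended into by the most recent range query, for inspection of the
    pruning behavior.
    """

    def __init__(
        self,
        m: int,
        direction: StoreDirection = StoreDirection.UP,
        guarded: bool = False,
        use_bounds: bool = True,
    ):
        super().__init__(m, direction, guarded)
        self.use_bounds = use_bounds
        self.option = 4 if use_bounds else 3
        self._root = _Node(0)
        self._size = 0
        self.last_query_visited: list[tuple[int, int]] = []

    # children are visited in ascending level order for determinism
    def _sorted_children(self, node: _Node) -> list[tuple[int, _Node]]:
        return sorted(node.children.items())

    def _query(self, x: Policy) -> bool:
        self.last_query_visited = []
        r = rank(x)
        up = self.direction is StoreDirection.UP

        # ``exact`` tracks whether the path so far equals x; a leaf reached
        # along the exact path is x itself, which a range query must not
        # report (the rank bound of option 4 excludes it automatically).
        def descend(node: _Node, depth: int, exact: bool) -> bool:
            if depth == self.m:
                return not exact
            for level, child in self._sorted_children(node):
                if up:
                    if level > x[depth]:
                        break  # ascending order: no further child qualifies
                    if self.use_bounds and child.bound >= r:
                        continue
                else:
                    if level < x[depth]:
                        continue
                    if self.use_bounds and child.bound <= r:
                        continue
                self.last_query_visited.append((depth, level))
                if descend(child, depth + 1, exact and level == x[depth]):
                    return True
            return False

        return descend(self._root, 0, True)

    def _remove_covered(self, x: Policy) -> None:
        """Remove every stored policy that inherits from ``x`` (mirrored range
        query), reclaiming emptied inner nodes while backtracking."""
        up = self.direction is StoreDirection.UP

        def descend(node: _Node, depth: int) -> bool:
            # returns True when this subtree became empty and can be dropped
            if depth == self.m:
                self._size -= 1
                return True
            for level in sorted(node.children):
                if up:
                    if level < x[depth]:
                        continue
                else:
                    if level > x[depth]:
                        continue
                if descend(node.children[level], depth + 1):
                    del node.children[level]
            return not node.children

        descend(self._root, 0)

    def _insert(self, x: Policy) -> None:
        self._remove_covered(x)
        r = rank(x)
        up = self.direction is StoreDirection.UP
        node = self._root
        for depth in range(self.m):
            child = node.children.get(x[depth])
            if child is None:
                child = _Node(r)
                node.children[x[depth]] = child
            elif self.use_bounds:
                # removal never invalidates remaining bounds, so only the
                # insert path is updated
                child.bound = min(child.bound, r) if up else max(child.bound, r)
            node = child
        self._size += 1

    def elements(self) -> set[Policy]:
        out: set[Policy] = set()

        def walk(node: _Node, prefix: tuple[int, ...]) -> None:
            if len(prefix) == self.m:
                out.add(prefix)
                return
            for level, child in node.children.items():
                walk(child, prefix + (level,))

        walk(self._root, ())
        return out

    def __len__(self) -> int:
        return self._size

    def exact_contains(self, x: Policy) -> bool:
        node = self._root
        for depth in range(self.m):
            node = node.children.get(x[depth])
            if node is None:
                return False
        return True

    def check_bounds(self, exact: bool = False) -> bool:
        """Verify every node's bound against a full subtree traversal.

        Bounds are maintained along insert paths only; a removal never
        updates them (a removed element below a node cannot carry that
        node's min for UP — nor its max for DOWN — without the antichain
        argument applying to it first, so the stored bound stays *sound*:
        never above the true minimum rank for UP, never below the true
        maximum for DOWN).  After removals a bound may therefore be
        conservative rather than tight.  With ``exact=True`` (valid when no
        removal has occurred) tightness is asserted as well.  Raises
        ``AssertionError`` on the first violation.
        """
        if not self.use_bounds:
            return True
        up = self.direction is StoreDirection.UP

        def ranks_below(node: _Node, depth: int, acc: int) -> list[int]:
            if depth == self.m:
                return [acc]
            out: list[int] = []
            for level, child in node.children.items():
                sub = ranks_below(child, depth + 1, acc + level)
                tight = min(sub) if up else max(sub)
                sound = child.bound <= tight if up else child.bound >= tight
                if not sound or (exact and child.bound != tight):
                    raise AssertionError(
                        f"node at depth {depth} level {level}: "
                        f"bound {child.bound} vs subtree {'min' if up else 'max'} {tight}"
                    )
                out.extend(sub)
            return out

        ranks_below(self._root, 0, 0)
        return True


def make_store(
    m: int,
    direction: StoreDirection = StoreDirection.UP,
    option: int = 4,
    guarded: bool = False,
) -> PropertyStore:
    """Build one of the four store implementations (default: option 4)."""
    if option == 1:
        return ListStore(m, direction, guarded)
    if option == 2:
        return AntichainListStore(m, direction, guarded)
    if option == 3:
        return TreeStore(m, direction, guarded, use_bounds=False)
    if option == 4:
        return TreeStore(m, direction, guarded, use_bounds=True)
    raise ValueError(f"unknown store option {option!r}; expected 1, 2, 3 or 4")
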