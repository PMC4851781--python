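"""Lattice search strategies for optimal de-identification.

Three strategies share the evaluation and property-store machinery:

``search_exhaustive``
    Brute force over the whole lattice; the correctness oracle.

``search_optimal``
    Globally-optimal rank-order sweep using *complete* information about
    both predictive properties: policies providing insufficient protection
    (inherited by specializations) and policies whose generalization-only
    quality bound cannot beat the incumbent (inherited by generalizations).

``search_bfs``
    Best-first branch-and-bound, bottom-up.  The priority queue is ordered
    by evaluated output quality, highest first.  A popped policy whose
    quality bound cannot beat the incumbent is recorded in the
    insufficient-quality store and not expanded; a popped policy already
    covered by that store is discarded outright.  Run to queue exhaustion it
    is globally optimal; under a time or evaluation budget it is an anytime
    heuristic returning the best solution found so far.
"""

from __future__ import annotations

import heapq
import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

from .data_io import Dataset, Hierarchy, lattice_spec_for
from .evaluation import EvaluationResult, Evaluator, PrivacyConfig
from .lattice import Policy, direct_generalizations, enumerate_rank_order, rank
from .property_store import PropertyStore, StoreDirection, make_store

__all__ = [
    "SearchConfig",
    "PropertyStats",
    "SearchStats",
    "SearchResult",
    "search_exhaustive",
    "search_optimal",
    "search_bfs",
    "search",
    "report_stats",
]

logger = logging.getLogger(__name__)

INSUFFICIENT_QUALITY = "insufficient_quality"
INSUFFICIENT_PROTECTION = "insufficient_protection"


@dataclass(frozen=True)
class SearchConfig:
    """Privacy requirements plus search strategy and budgets.

    Defaults reflect common practice for biomedical data: ``k = 5`` with a
    5 % suppression limit.  Setting ``time_limit`` or ``evaluation_budget``
    turns the BFS strategy into an anytime heuristic; the other strategies
    ignore budgets.
    """

    privacy: PrivacyConfig = field(default_factory=PrivacyConfig)
    algorithm: str = "bfs"  # exhaustive | optimal | bfs
    use_prediction: bool = True
    time_limit: float | None = None
    evaluation_budget: int | None = None
    seed: int = 0
    store_option: int = 4
    oracle_cap: int = 100_000
    bfs_use_protection_store: bool = False  # optional extension, off by default

    def __post_init__(self) -> None:
        if self.algorithm not in ("exhaustive", "optimal", "bfs"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.store_option not in (1, 2, 3, 4):
            raise ValueError(f"store_option must be 1..4, got {self.store_option}")
        budgeted = self.time_limit is not None or self.evaluation_budget is not None
        if budgeted and self.algorithm != "bfs":
            raise ValueError("time/evaluation budgets apply to the bfs algorithm only")


@dataclass
class PropertyStats:
    """Counters for one predictive property, mirroring the store's bookkeeping."""

    inserts: int = 0
    queries: int = 0
    hits: int = 0
    max_antichain: int = 0
    final_size: int = 0

    @classmethod
    def from_store(cls, store: PropertyStore) -> "PropertyStats":
        return cls(
            inserts=store.insert_count,
            queries=store.query_count,
            hits=store.hit_count,
            max_antichain=store.max_size,
            final_size=len(store),
        )


@dataclass
class SearchStats:
    """Workload counters: policies checked, per-property inserts/hits/antichain."""

    checked: int = 0
    lattice_size: int = 0
    properties: dict[str, PropertyStats] = field(default_factory=dict)
    time_total: float = 0.0
    time_to_optimum: float = 0.0
    trajectory: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class SearchResult:
    solution: tuple[Policy, EvaluationResult] | None
    optimal_guarantee: bool
    stats: SearchStats

    @property
    def quality(self) -> float | None:
        return None if self.solution is None else self.solution[1].quality


class _Incumbent:
    """Best anonymous policy so far; strict improvement on quality only, so
    with rank-then-lexicographic visiting order ties keep the first find."""

    def __init__(self) -> None:
        self.policy: Policy | None = None
        self.result: EvaluationResult | None = None
        self.quality = float("-inf")

    def offer(self, res: EvaluationResult) -> bool:
        if res.anonymous and res.quality > self.quality:
            self.policy = res.policy
            self.result = res
            self.quality = res.quality
            return True
        return False

    def solution(self) -> tuple[Policy, EvaluationResult] | None:
        if self.policy is None or self.result is None:
            return None
        return (self.policy, self.result)


def search_exhaustive(
    dataset: Dataset, hierarchies: Sequence[Hierarchy], config: SearchConfig
) -> SearchResult:
    """Evaluate every policy in rank order; ties resolved by lowest rank,
    then lexicographic order (the visiting order)."""
    spec = lattice_spec_for(hierarchies)
    if spec.size > config.oracle_cap:
        raise ValueError(
            f"lattice of {spec.size} policies exceeds the exhaustive cap "
            f"({config.oracle_cap}); use the bfs algorithm instead"
        )
    evaluator = Evaluator(dataset, hierarchies, config.privacy)
    best = _Incumbent()
    stats = SearchStats(lattice_size=spec.size)
    t0 = time.perf_counter()
    for x in enumerate_rank_order(spec):
        res = evaluator.evaluate(x)
        stats.checked += 1
        if best.offer(res):
            stats.time_to_optimum = time.perf_counter() - t0
            stats.trajectory.append((stats.checked, best.quality))
    stats.time_total = time.perf_counter() - t0
    return SearchResult(solution=best.solution(), optimal_guarantee=True, stats=stats)


def search_optimal(
    dataset: Dataset, hierarchies: Sequence[Hierarchy], config: SearchConfig
) -> SearchResult:
    """Globally-optimal sweep with complete predictive information.

    Policies are visited in rank order.  A policy covered by either
    property store is skipped without evaluation; otherwise it is evaluated
    and, when found non-anonymous or bound-dominated by the incumbent,
    inserted into the corresponding store.  Memory is proportional to the
    number of checked policies, never to the lattice size.
    """
    spec = lattice_spec_for(hierarchies)
    evaluator = Evaluator(dataset, hierarchies, config.privacy)
    protection = make_store(spec.m, StoreDirection.DOWN, config.store_option)
    quality_store = make_store(spec.m, StoreDirection.UP, config.store_option)
    best = _Incumbent()
    stats = SearchStats(lattice_size=spec.size)
    t0 = time.perf_counter()
    for x in enumerate_rank_order(spec):
        if config.use_prediction and (protection.query(x) or quality_store.query(x)):
            continue
        res = evaluator.evaluate(x)
        stats.checked += 1
        if config.use_prediction and not res.anonymous:
            protection.insert(x)
        if config.use_prediction and res.quality_bound <= best.quality:
            quality_store.insert(x)
            continue
        if best.offer(res):
            stats.time_to_optimum = time.perf_counter() - t0
            stats.trajectory.append((stats.checked, best.quality))
    stats.time_total = time.perf_counter() - t0
    stats.properties = {
        INSUFFICIENT_PROTECTION: PropertyStats.from_store(protection),
        INSUFFICIENT_QUALITY: PropertyStats.from_store(quality_store),
    }
    return SearchResult(solution=best.solution(), optimal_guarantee=True, stats=stats)


def search_bfs(
    dataset: Dataset, hierarchies: Sequence[Hierarchy], config: SearchConfig
) -> SearchResult:
    """Best-first branch-and-bound, bottom-up.

    Each policy is evaluated exactly once, when first reached; the queue is
    ordered by output quality (descending), ties by lower rank then
    lexicographic order.  Without prediction no pruning is performed and the
    whole lattice is traversed.  The "seen" set keeps memory proportional to
    the number of evaluated policies.
    """
    spec = lattice_spec_for(hierarchies)
    evaluator = Evaluator(dataset, hierarchies, config.privacy)
    quality_store = make_store(spec.m, StoreDirection.UP, config.store_option)
    protection = (
        make_store(spec.m, StoreDirection.DOWN, config.store_option)
        if config.bfs_use_protection_store
        else None
    )
    best = _Incumbent()
    stats = SearchStats(lattice_size=spec.size)
    t0 = time.perf_counter()
    budget = config.evaluation_budget
    deadline = None if config.time_limit is None else t0 + config.time_limit
    budgeted = budget is not None or deadline is not None
    exhausted_budget = False

    def out_of_budget() -> bool:
        if budget is not None and stats.checked >= budget:
            return True
        if deadline is not None and time.perf_counter() >= deadline:
            return True
        return False

    def evaluate(x: Policy) -> EvaluationResult:
        res = evaluator.evaluate(x)
        stats.checked += 1
        if best.offer(res):
            stats.time_to_optimum = time.perf_counter() - t0
            stats.trajectory.append((stats.checked, best.quality))
        return res

    heap: list[tuple[float, int, Policy]] = []
    seen: set[Policy] = {spec.bottom}
    if budget is None or budget >= 1:
        res = evaluate(spec.bottom)
        heapq.heappush(heap, (-res.quality, rank(spec.bottom), spec.bottom))
        results: dict[Policy, EvaluationResult] = {spec.bottom: res}
    else:
        results = {}

    while heap:
        if out_of_budget():
            exhausted_budget = True
            break
        _, _, x = heapq.heappop(heap)
        res = results.pop(x)
        if config.use_prediction and quality_store.query(x):
            continue
        if protection is not None and res.anonymous is False:
            protection.insert(x)
        if config.use_prediction and res.quality_bound <= best.quality:
            quality_store.insert(x)
            continue
        for y in direct_generalizations(x, spec):
            if y in seen:
                continue
            if protection is not None and protection.query(y):
                seen.add(y)
                continue
            if out_of_budget():
                exhausted_budget = True
                break
            seen.add(y)
            res_y = evaluate(y)
            results[y] = res_y
            heapq.heappush(heap, (-res_y.quality, rank(y), y))
        if exhausted_budget:
            break

    stats.time_total = time.perf_counter() - t0
    stats.properties = {INSUFFICIENT_QUALITY: PropertyStats.from_store(quality_store)}
    if protection is not None:
        stats.properties[INSUFFICIENT_PROTECTION] = PropertyStats.from_store(protection)
    guarantee = not exhausted_budget
    if budgeted and exhausted_budget:
        logger.info("bfs stopped on budget after %d evaluations", stats.checked)
    return SearchResult(solution=best.solution(), optimal_guarantee=guarantee, stats=stats)


_ALGORITHMS = {
    "exhaustive": search_exhaustive,
    "optimal": search_optimal,
    "bfs": search_bfs,
}


def search(
    dataset: Dataset, hierarchies: Sequence[Hierarchy], config: SearchConfig
) -> SearchResult:
    """Dispatch on ``config.algorithm``."""
    return _ALGORITHMS[config.algorithm](dataset, hierarchies, config)


def report_stats(result: SearchResult) -> dict:
    """Structured report: checked %, per-property inserts/hit rate/antichain."""
    stats = result.stats
    size = stats.lattice_size
    report: dict = {
        "checked": stats.checked,
        "lattice_size": size,
        "checked_pct": 100.0 * stats.checked / size if size else 0.0,
        "optimal_guarantee": result.optimal_guarantee,
        "time_total_s": stats.time_total,
        "time_to_optimum_s": stats.time_to_optimum,
        "time_to_optimum_fraction": (
            stats.time_to_optimum / stats.time_total if stats.time_total > 0 else 0.0
        ),
        "properties": {},
    }
    if result.solution is not None:
        policy, res = result.solution
        report["solution"] = {
            "policy": list(policy),
            "quality": res.quality,
            "quality_bound": res.quality_bound,
            "suppressed_count": res.suppressed_count,
        }
    else:
        report["solution"] = None
    for name, p in stats.properties.items():
        report["properties"][name] = {
            "inserts": p.inserts,
            "queries": p.queries,
            "hits": p.hits,
            "hit_rate_pct": 100.0 * p.hits / p.queries if p.queries else 0.0,
            "max_antichain": p.max_antichain,
            "antichain_pct_of_inserts": (
                100.0 * p.max_antichain / p.inserts if p.inserts else 0.0
            ),
            "final_size": p.final_size,
        }
    report["trajectory"] = [list(t) for t in stats.trajectory]
    return report
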