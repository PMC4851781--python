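"""Policy evaluation: k-anonymity with record suppression and loss-based quality.

Applying a policy is a three-step procedure: (1) generalize every attribute
to the policy's level, (2) suppress all records in equivalence classes
smaller than *k*, (3) the policy is a solution candidate ("anonymous") if
the number of suppressed records stays within the suppression limit.

Data quality follows Iyengar's loss model.  Each cell contributes the
fraction of its attribute's domain covered by its (generalized) value,
normalized as ``(M_g - 1) / (M - 1)`` where ``M_g`` is the number of base
values merged into the label and ``M`` the domain size; ungeneralized cells
contribute 0, suppressed cells 1.  Quality is one minus the mean cell loss,
so the original data scores 100 % and fully removed data 0 %.

Quality after suppression is not monotone along generalization (coarser
levels may need less suppression), but the *generalization-only* quality
``u'`` is, and it bounds the achievable quality ``u`` from above — the basis
of the bound-pruning used by the search algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Sequence

import numpy as np

from .data_io import Dataset, Hierarchy
from .lattice import Policy

__all__ = [
    "PrivacyConfig",
    "EvaluationResult",
    "Evaluator",
    "equivalence_class_sizes",
    "is_k_anonymous",
    "max_reidentification_risk",
    "cell_loss",
    "quality",
    "quality_bound",
    "evaluate",
]


@dataclass(frozen=True)
class PrivacyConfig:
    """Privacy requirements: k-anonymity level and suppression budget.

    ``k`` bounds the re-identification risk of every kept record by ``1/k``.
    ``suppression_limit`` is the fraction of records that may be suppressed;
    the budget in records is ``floor(limit * n)``.
    """

    k: int = 5
    suppression_limit: float = 0.05

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not 0.0 <= self.suppression_limit <= 1.0:
            raise ValueError(f"suppression_limit must be in [0, 1], got {self.suppression_limit}")

    def record_budget(self, n: int) -> int:
        # small epsilon so exact fractions like 0.05 * 60 are not floored away
        return floor(self.suppression_limit * n + 1e-9)


@dataclass(frozen=True)
class EvaluationResult:
    """Outcome of applying one policy under a privacy configuration."""

    policy: Policy
    anonymous: bool
    suppressed_count: int
    quality: float
    quality_bound: float
    class_sizes: tuple[int, ...]


class Evaluator:
    """Evaluates policies against one dataset; built once, queried many times.

    Values are integer-coded per attribute; for each attribute and level a
    lookup array maps codes to generalized-label codes and to per-cell loss,
    so one evaluation is a handful of vectorized operations.
    """

    def __init__(
        self,
        dataset: Dataset,
        hierarchies: Sequence[Hierarchy],
        config: PrivacyConfig | None = None,
    ) -> None:
        if len(hierarchies) != dataset.m:
            raise ValueError("one hierarchy per attribute is required")
        self.dataset = dataset
        self.hierarchies = tuple(hierarchies)
        self.config = config or PrivacyConfig()
        self.n = dataset.n
        self.m = dataset.m
        self._budget = self.config.record_budget(self.n)

        self._codes: list[np.ndarray] = []
        self._level_codes: list[list[np.ndarray]] = []
        self._level_loss: list[list[np.ndarray]] = []
        for i, h in enumerate(self.hierarchies):
            values = list(h.rows)
            index = {v: c for c, v in enumerate(values)}
            self._codes.append(
                np.fromiter((index[rec[i]] for rec in dataset.records), dtype=np.intp, count=self.n)
            )
            per_level_codes: list[np.ndarray] = []
            per_level_loss: list[np.ndarray] = []
            for level in range(h.height):
                label_ids: dict[str, int] = {}
                codes = np.empty(len(values), dtype=np.intp)
                loss = np.empty(len(values), dtype=np.float64)
                for c, v in enumerate(values):
                    label = h.rows[v][level]
                    codes[c] = label_ids.setdefault(label, len(label_ids))
                    loss[c] = cell_loss(h, level, label, suppressed=False)
                per_level_codes.append(codes)
                per_level_loss.append(loss)
            self._level_codes.append(per_level_codes)
            self._level_loss.append(per_level_loss)

    # -- internals ---------------------------------------------------------

    def _generalized(self, policy: Policy) -> np.ndarray:
        return np.column_stack(
            [self._level_codes[i][policy[i]][self._codes[i]] for i in range(self.m)]
        )

    def _loss_matrix(self, policy: Policy) -> np.ndarray:
        return np.column_stack(
            [self._level_loss[i][policy[i]][self._codes[i]] for i in range(self.m)]
        )

    # -- public surface ----------------------------------------------------

    def class_sizes(self, policy: Policy) -> tuple[int, ...]:
        if self.n == 0:
            return ()
        _, counts = np.unique(self._generalized(policy), axis=0, return_counts=True)
        return tuple(sorted(int(c) for c in counts))

    def suppressed_flags(self, policy: Policy) -> np.ndarray:
        """Boolean mask of records suppressed in step 2 (class size < k)."""
        if self.n == 0:
            return np.zeros(0, dtype=bool)
        _, inverse, counts = np.unique(
            self._generalized(policy), axis=0, return_inverse=True, return_counts=True
        )
        return counts[inverse.reshape(-1)] < self.config.k

    def quality_bound(self, policy: Policy) -> float:
        if self.n == 0:
            return 1.0
        total = float(self._loss_matrix(policy).sum())
        return 1.0 - total / (self.n * self.m)

    def evaluate(self, policy: Policy) -> EvaluationResult:
        policy = tuple(policy)
        if self.n == 0:
            return EvaluationResult(policy, True, 0, 1.0, 1.0, ())
        gen = self._generalized(policy)
        _, inverse, counts = np.unique(gen, axis=0, return_inverse=True, return_counts=True)
        mask = counts[inverse.reshape(-1)] < self.config.k
        suppressed = int(mask.sum())
        anonymous = suppressed <= self._budget
        loss = self._loss_matrix(policy)
        base = float(loss.sum())
        bound = 1.0 - base / (self.n * self.m)
        # suppressed cells switch from their generalization loss to 1;
        # clamping keeps u <= u' exactly under float summation
        extra = max(0.0, suppressed * self.m - float(loss[mask].sum()))
        u = bound - extra / (self.n * self.m)
        return EvaluationResult(
            policy=policy,
            anonymous=anonymous,
            suppressed_count=suppressed,
            quality=max(0.0, u),
            quality_bound=max(0.0, bound),
            class_sizes=tuple(sorted(int(c) for c in counts)),
        )


# ---------------------------------------------------------------------------
# functional surface (one-off use; search builds an Evaluator once)
# ---------------------------------------------------------------------------


def equivalence_class_sizes(
    dataset: Dataset, hierarchies: Sequence[Hierarchy], policy: Policy
) -> tuple[int, ...]:
    """Sizes of the groups of records identical on all generalized values."""
    return Evaluator(dataset, hierarchies).class_sizes(tuple(policy))


def is_k_anonymous(class_sizes: Sequence[int], k: int) -> bool:
    """Every equivalence class has at least ``k`` members (vacuously true when empty)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return all(size >= k for size in class_sizes)


def max_reidentification_risk(class_sizes: Sequence[int]) -> float:
    """Worst-case linkage probability: 1 over the smallest class size."""
    sizes = list(class_sizes)
    if not sizes:
        raise ValueError("re-identification risk is undefined for an empty dataset")
    return 1.0 / min(sizes)


def cell_loss(hierarchy: Hierarchy, level: int, label: str, suppressed: bool = False) -> float:
    """Loss of one cell: the covered fraction of the attribute's domain.

    ``(M_g - 1)/(M - 1)`` for a label merging ``M_g`` of ``M`` base values;
    0 for an ungeneralized value, 1 for a suppressed cell.  A singleton
    domain (M = 1) contributes 0 unless suppressed: a constant column
    carries no information to lose.
    """
    if suppressed:
        return 1.0
    if hierarchy.domain_size == 1:
        return 0.0
    try:
        merged = hierarchy.leaf_count[(level, label)]
    except KeyError:
        raise KeyError(
            f"{hierarchy.attribute_name}: no label {label!r} at level {level}"
        ) from None
    return (merged - 1) / (hierarchy.domain_size - 1)


def quality(
    dataset: Dataset,
    hierarchies: Sequence[Hierarchy],
    policy: Policy,
    suppressed_flags: Sequence[bool],
) -> float:
    """Quality ``1 - mean cell loss`` of the generalized-and-suppressed output.

    Returns 1 for an empty dataset by convention.
    """
    n, m = dataset.n, dataset.m
    if len(suppressed_flags) != n:
        raise ValueError("suppressed_flags length must equal the record count")
    if n == 0:
        return 1.0
    loss_maps = [
        {v: cell_loss(h, policy[i], labels[policy[i]]) for v, labels in h.rows.items()}
        for i, h in enumerate(hierarchies)
    ]
    total = 0.0
    for rec, sup in zip(dataset.records, suppressed_flags):
        if sup:
            total += m
        else:
            total += sum(loss_maps[i][v] for i, v in enumerate(rec))
    return 1.0 - total / (n * m)


def quality_bound(dataset: Dataset, hierarchies: Sequence[Hierarchy], policy: Policy) -> float:
    """Generalization-only quality ``u'``: an upper bound on any achievable ``u``.

    Monotone non-increasing along generalization, which makes "insufficient
    quality" a property inherited by all generalizations.
    """
    return quality(dataset, hierarchies, policy, [False] * dataset.n)


def evaluate(
    dataset: Dataset,
    hierarchies: Sequence[Hierarchy],
    policy: Policy,
    config: PrivacyConfig,
) -> EvaluationResult:
    """Run steps 1-3 for one policy and report the full outcome."""
    return Evaluator(dataset, hierarchies, config).evaluate(tuple(policy))
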