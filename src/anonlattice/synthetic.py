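"""Synthetic datasets and balanced hierarchies for testing and benchmarking.

Generates categorical quasi-identifier tables with balanced interval
hierarchies, optionally skewed value distributions (Zipf) and a controlled
fraction of *outlier* records — unique attribute combinations that create
genuine suppression pressure, the situation record suppression exists for.
Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log

import numpy as np

from .data_io import Dataset, Hierarchy

__all__ = ["SyntheticSpec", "generate_hierarchy", "generate_dataset", "figure2_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape of a synthetic workload.

    ``domain_sizes`` gives the number of distinct base values per attribute;
    ``branching`` the fan-in of each hierarchy level (scalar or per
    attribute).  ``distribution`` is ``uniform`` or ``zipf`` (exponent
    ``zipf_exponent``, default 1.0 — realistic class-size skew).
    ``outlier_fraction`` of the records (floored) are forced to be unique
    attribute combinations.
    """

    n: int = 100
    domain_sizes: tuple[int, ...] = (8, 8)
    branching: int | tuple[int, ...] = 2
    distribution: str = "uniform"
    zipf_exponent: float = 1.0
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not self.domain_sizes or any(d < 1 for d in self.domain_sizes):
            raise ValueError("domain_sizes must be positive")
        if self.distribution not in ("uniform", "zipf"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must be in [0, 1]")

    @property
    def m(self) -> int:
        return len(self.domain_sizes)

    def branching_for(self, i: int) -> int:
        b = self.branching
        return b[i] if isinstance(b, tuple) else b


def generate_hierarchy(domain_size: int, branching: int, seed: int = 0,
                       attribute_name: str = "attr") -> Hierarchy:
    """Balanced interval hierarchy over an integer-coded domain.

    Base values are ``"0" .. str(domain_size - 1)``; level ``l >= 1`` groups
    runs of ``branching ** l`` consecutive values under a label
    ``"[lo-hi]"``.  The top level is always a single root.  Height is
    ``ceil(log_b(domain_size)) + 1`` (1 for a singleton domain).
    Deterministic; ``seed`` is accepted for interface uniformity.
    """
    if domain_size < 1:
        raise ValueError("domain_size must be >= 1")
    if branching < 2:
        raise ValueError("branching must be >= 2")
    if domain_size == 1:
        height = 1
    else:
        height = ceil(log(domain_size) / log(branching) - 1e-12) + 1
        # guard against float log edge cases
        while branching ** (height - 1) < domain_size:
            height += 1
    rows = []
    for v in range(domain_size):
        labels = [str(v)]
        for level in range(1, height):
            width = branching ** level
            lo = (v // width) * width
            hi = min(lo + width - 1, domain_size - 1)
            labels.append(f"[{lo}-{hi}]")
        rows.append(labels)
    return Hierarchy.from_rows(attribute_name, rows)


def _value_weights(spec: SyntheticSpec, domain_size: int) -> np.ndarray:
    if spec.distribution == "uniform":
        return np.full(domain_size, 1.0 / domain_size)
    ranks = np.arange(1, domain_size + 1, dtype=np.float64)
    w = ranks ** -spec.zipf_exponent
    return w / w.sum()


def generate_dataset(spec: SyntheticSpec) -> tuple[Dataset, list[Hierarchy]]:
    """Sample a dataset and its hierarchies; byte-identical for a fixed seed.

    Outlier records are unique combinations drawn from the top of the
    mixed-radix combination space (skipping any combination already
    sampled), so each is a singleton equivalence class under the bottom
    policy.
    """
    rng = np.random.default_rng(spec.seed)
    hierarchies = [
        generate_hierarchy(d, spec.branching_for(i), spec.seed, attribute_name=f"attr{i}")
        for i, d in enumerate(spec.domain_sizes)
    ]
    n_out = int(spec.outlier_fraction * spec.n)
    n_body = spec.n - n_out
    columns = [
        rng.choice(d, size=n_body, p=_value_weights(spec, d)) for d in spec.domain_sizes
    ]
    body = [tuple(str(int(columns[i][r])) for i in range(spec.m)) for r in range(n_body)]
    records = list(body)
    if n_out:
        present = set(body)
        total = int(np.prod([int(d) for d in spec.domain_sizes]))
        outliers: list[tuple[str, ...]] = []
        idx = total - 1
        while len(outliers) < n_out and idx >= 0:
            combo, rem = [], idx
            for d in reversed(spec.domain_sizes):
                combo.append(str(rem % d))
                rem //= d
            rec = tuple(reversed(combo))
            if rec not in present:
                outliers.append(rec)
                present.add(rec)
            idx -= 1
        if len(outliers) < n_out:
            raise ValueError(
                "combination space too small for the requested number of unique outliers"
            )
        records.extend(outliers)
    dataset = Dataset(
        attribute_names=tuple(h.attribute_name for h in hierarchies),
        records=tuple(records),
    )
    return dataset, hierarchies


def figure2_fixture() -> tuple[Dataset, list[Hierarchy], dict]:
    """Two-attribute demonstration instance: age (height 3) and sex (height 2).

    Constructed so that exactly one record is unique after generalizing age
    one level, making the policy ``(1, 0)`` 2-anonymous once that record is
    suppressed, with a residual re-identification risk of 50 %.  The
    returned dict states the machine-checkable facts.
    """
    age = Hierarchy.from_rows(
        "age",
        [
            ["34", "[20-39]", "*"],
            ["38", "[20-39]", "*"],
            ["66", "[60-79]", "*"],
            ["70", "[60-79]", "*"],
        ],
    )
    sex = Hierarchy.from_rows("sex", [["male", "*"], ["female", "*"]])
    dataset = Dataset(
        attribute_names=("age", "sex"),
        records=(
            ("34", "male"),
            ("38", "male"),
            ("66", "female"),
            ("70", "female"),
            ("70", "male"),
        ),
    )
    facts = {
        "lattice_size": 6,
        "policy": (1, 0),
        "k": 2,
        "suppressed_at_policy": 1,
        "max_risk_after": 0.5,
    }
    return dataset, [age, sex], facts
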