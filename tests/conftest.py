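"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from anonlattice import (
    Dataset,
    Hierarchy,
    LatticeSpec,
    PrivacyConfig,
    figure2_fixture,
    generate_dataset,
)
from anonlattice.property_store import StoreDirection
from anonlattice.synthetic import SyntheticSpec


class HistoryOracle:
    """Naive reference for property stores: the full insert history, scanned.

    Answers "does any previously inserted policy propagate the property to
    x" by brute force, independently of any antichain or tree machinery.
    """

    def __init__(self, direction: StoreDirection) -> None:
        self.direction = direction
        self.history: list[tuple[int, ...]] = []

    def covers(self, y, x) -> bool:
        if self.direction is StoreDirection.UP:
            return all(a <= b for a, b in zip(y, x))
        return all(a >= b for a, b in zip(y, x))

    def insert(self, x) -> None:
        self.history.append(tuple(x))

    def query(self, x) -> bool:
        x = tuple(x)
        return any(y != x and self.covers(y, x) for y in self.history)


def random_policy(rng: random.Random, heights) -> tuple[int, ...]:
    return tuple(rng.randrange(h) for h in heights)


def random_instance(rng: random.Random, max_m: int = 4, max_domain: int = 8,
                    max_n: int = 60) -> tuple[Dataset, list[Hierarchy], PrivacyConfig]:
    """A small random de-identification problem with suppression pressure."""
    m = rng.randint(2, max_m)
    n = rng.randint(10, max_n)
    domain_sizes = tuple(rng.choice([2, 4, max_domain]) for _ in range(m))
    combos = 1
    for d in domain_sizes:
        combos *= d
    # unique outlier combos must fit next to the sampled body records
    outlier_fraction = rng.choice([0.0, 0.05, 0.1]) if combos >= 2 * n else 0.0
    spec = SyntheticSpec(
        n=n,
        domain_sizes=domain_sizes,
        branching=2,
        distribution=rng.choice(["uniform", "zipf"]),
        zipf_exponent=1.0,
        outlier_fraction=outlier_fraction,
        seed=rng.randrange(2**31),
    )
    dataset, hierarchies = generate_dataset(spec)
    privacy = PrivacyConfig(
        k=rng.choice([2, 3, 5]),
        suppression_limit=rng.choice([0.0, 0.05, 0.1, 0.25]),
    )
    return dataset, hierarchies, privacy


@pytest.fixture
def fig2():
    """Two-attribute demonstration instance (age height 3, sex height 2)."""
    return figure2_fixture()


@pytest.fixture
def two_attr_single_root():
    """Two attributes whose hierarchies both end in a single root label."""
    first = Hierarchy.from_rows(
        "first",
        [[str(v), f"[{v - v % 2}-{v - v % 2 + 1}]", "*"] for v in range(4)],
    )
    second = Hierarchy.from_rows("second", [["a", "*"], ["b", "*"]])
    records = tuple(
        (str(v), s) for v in range(4) for s in ("a", "b")
    )
    dataset = Dataset(attribute_names=("first", "second"), records=records)
    return dataset, [first, second]


@pytest.fixture
def small_spec():
    return LatticeSpec(heights=(3, 2))
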