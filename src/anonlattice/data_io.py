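"""Hierarchies and datasets: file formats, validation, leaf-count bookkeeping.

Hierarchy files follow the convention of widely used de-identification
tooling: semicolon-separated, no header, one row per base value, the columns
being the value's labels at levels ``0 .. h-1`` (level 0 is the value
itself).  Datasets are ordinary CSV with a header naming the
quasi-identifiers; only quasi-identifiers are handled here.  Values are
case- and whitespace-sensitive exactly as read — silent normalization would
hide linkage errors.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import pandas as pd

from .lattice import LatticeSpec, Policy

__all__ = [
    "HierarchyFormatError",
    "DatasetValidationError",
    "Hierarchy",
    "Dataset",
    "load_hierarchy",
    "load_dataset",
    "write_hierarchy",
    "write_dataset",
    "generalize_value",
    "apply_policy",
    "lattice_spec_for",
    "SUPPRESSION_TOKEN",
]

SUPPRESSION_TOKEN = "*"

TextSource = Union[str, Path, IO[str]]


class HierarchyFormatError(ValueError):
    """Raised for malformed hierarchy files (ragged rows, duplicates, non-tree)."""


class DatasetValidationError(ValueError):
    """Raised when a dataset does not validate against its hierarchies."""


@dataclass(frozen=True)
class Hierarchy:
    """Generalization rules for one attribute.

    ``rows`` maps each base value to its labels at levels ``0 .. height-1``;
    the label at level 0 is the base value itself.  ``leaf_count[(level,
    label)]`` is the number of base values generalized into ``label`` at
    ``level`` — the bookkeeping the loss-based quality model needs.
    ``domain_size`` is the number of distinct base values.
    """

    attribute_name: str
    height: int
    rows: Mapping[str, tuple[str, ...]]
    leaf_count: Mapping[tuple[int, str], int] = field(repr=False)
    domain_size: int = 0

    @classmethod
    def from_rows(cls, attribute_name: str, raw_rows: Iterable[Sequence[str]]) -> "Hierarchy":
        rows: dict[str, tuple[str, ...]] = {}
        height = None
        for idx, raw in enumerate(raw_rows):
            labels = tuple(str(v) for v in raw)
            if not labels:
                continue
            if height is None:
                height = len(labels)
            elif len(labels) != height:
                raise HierarchyFormatError(
                    f"{attribute_name}: row {idx + 1} has {len(labels)} columns, expected {height}"
                )
            base = labels[0]
            if base in rows:
                raise HierarchyFormatError(f"{attribute_name}: duplicate base value {base!r}")
            rows[base] = labels
        if height is None or not rows:
            raise HierarchyFormatError(f"{attribute_name}: hierarchy has no rows")
        # tree-structured generalization: a label at level l maps to exactly
        # one label at level l+1
        for level in range(height - 1):
            parent: dict[str, str] = {}
            for labels in rows.values():
                seen = parent.get(labels[level])
                if seen is None:
                    parent[labels[level]] = labels[level + 1]
                elif seen != labels[level + 1]:
                    raise HierarchyFormatError(
                        f"{attribute_name}: label {labels[level]!r} at level {level} "
                        f"generalizes to both {seen!r} and {labels[level + 1]!r}"
                    )
        leaf_count: Counter[tuple[int, str]] = Counter()
        for labels in rows.values():
            for level, label in enumerate(labels):
                leaf_count[(level, label)] += 1
        return cls(
            attribute_name=attribute_name,
            height=height,
            rows=rows,
            leaf_count=dict(leaf_count),
            domain_size=len(rows),
        )

    @property
    def domain(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def labels_at(self, level: int) -> tuple[str, ...]:
        """Distinct labels occurring at ``level``, in first-seen order."""
        seen: dict[str, None] = {}
        for labels in self.rows.values():
            seen.setdefault(labels[level], None)
        return tuple(seen)


@dataclass(frozen=True)
class Dataset:
    """A table of categorical quasi-identifier values."""

    attribute_names: tuple[str, ...]
    records: tuple[tuple[str, ...], ...]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def m(self) -> int:
        return len(self.attribute_names)


def _open(source: TextSource) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def load_hierarchy(source: TextSource, attribute_name: str) -> Hierarchy:
    """Read a semicolon-separated hierarchy file (no header)."""
    stream, close = _open(source)
    try:
        reader = csv.reader(stream, delimiter=";")
        return Hierarchy.from_rows(attribute_name, reader)
    finally:
        if close:
            stream.close()


def write_hierarchy(hierarchy: Hierarchy, dest: TextSource) -> None:
    stream, close = _open_w(dest)
    try:
        writer = csv.writer(stream, delimiter=";", lineterminator="\n")
        for labels in hierarchy.rows.values():
            writer.writerow(labels)
    finally:
        if close:
            stream.close()


def _open_w(dest: TextSource) -> tuple[IO[str], bool]:
    if isinstance(dest, (str, Path)):
        return open(dest, "w", encoding="utf-8", newline=""), True
    return dest, False


def load_dataset(source: TextSource, hierarchies: Sequence[Hierarchy]) -> Dataset:
    """Read a CSV dataset and validate it against the hierarchies.

    The header must name the hierarchies' attributes in the same order, and
    every value must appear as a base value of its attribute's hierarchy.
    """
    stream, close = _open(source)
    try:
        frame = pd.read_csv(stream, dtype=str, keep_default_na=False)
    finally:
        if close:
            stream.close()
    names = tuple(h.attribute_name for h in hierarchies)
    header = tuple(str(c) for c in frame.columns)
    if header != names:
        raise DatasetValidationError(f"header {header} does not match hierarchy attributes {names}")
    records = tuple(tuple(row) for row in frame.itertuples(index=False, name=None))
    for i, hierarchy in enumerate(hierarchies):
        domain = hierarchy.rows
        for r, rec in enumerate(records):
            if rec[i] not in domain:
                raise DatasetValidationError(
                    f"attribute {hierarchy.attribute_name!r}, row {r + 1}: "
                    f"value {rec[i]!r} not in hierarchy"
                )
    return Dataset(attribute_names=names, records=records)


def write_dataset(dataset: Dataset, dest: TextSource) -> None:
    stream, close = _open_w(dest)
    try:
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow(dataset.attribute_names)
        writer.writerows(dataset.records)
    finally:
        if close:
            stream.close()


def generalize_value(hierarchy: Hierarchy, value: str, level: int) -> str:
    """Label of ``value`` at ``level``; the value itself at level 0."""
    if not 0 <= level < hierarchy.height:
        raise ValueError(
            f"{hierarchy.attribute_name}: level {level} out of range 0..{hierarchy.height - 1}"
        )
    try:
        return hierarchy.rows[value][level]
    except KeyError:
        raise KeyError(
            f"{hierarchy.attribute_name}: value {value!r} not in hierarchy"
        ) from None


def apply_policy(
    dataset: Dataset,
    hierarchies: Sequence[Hierarchy],
    policy: Policy,
    suppressed_flags: Sequence[bool] | None = None,
    token: str = SUPPRESSION_TOKEN,
) -> Dataset:
    """Transformed dataset: generalized rows, suppressed rows as token rows.

    Suppressed records remain in the output with every cell replaced by
    ``token``, so the output always has the input's row count.
    """
    if suppressed_flags is None:
        suppressed_flags = [False] * dataset.n
    if len(suppressed_flags) != dataset.n:
        raise ValueError("suppressed_flags length must equal the record count")
    maps = [
        {v: labels[policy[i]] for v, labels in h.rows.items()}
        for i, h in enumerate(hierarchies)
    ]
    token_row = (token,) * dataset.m
    out = []
    for rec, sup in zip(dataset.records, suppressed_flags):
        if sup:
            out.append(token_row)
        else:
            out.append(tuple(maps[i][v] for i, v in enumerate(rec)))
    return Dataset(attribute_names=dataset.attribute_names, records=tuple(out))


def lattice_spec_for(hierarchies: Sequence[Hierarchy]) -> LatticeSpec:
    """Lattice shape induced by a sequence of hierarchies."""
    return LatticeSpec(
        heights=tuple(h.height for h in hierarchies),
        attribute_names=tuple(h.attribute_name for h in hierarchies),
    )
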