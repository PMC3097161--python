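"""Domain model for phenotype-microarray kinetic data.

A phenotype-microarray (PM) run records, for every well of a 96-well
plate, an optical-intensity time series ("kinetic curve") as the organism
grows, fails to grow, or is inhibited by the substrate in that well.
This module defines the atomic measurement (:class:`KineticCurve`), its
metadata coordinate (:class:`WellRecord`), an ordered, uniqueness-checked
collection (:class:`RecordSet`), and the hierarchical record-selection
layer (:class:`FilterCriteria`, :func:`filter_records`,
:func:`group_replicates`) that stands in for a query interface: records
are drilled down by project, strain, phenotype, plate, well, replicate
and temperature.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "WELL_IDS",
    "PLATE_IDS",
    "KineticCurve",
    "WellRecord",
    "RecordSet",
    "FilterCriteria",
    "filter_records",
    "group_replicates",
]

WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")

#: Canonical well identifiers in row-major plate order (A01 .. H12).
WELL_IDS: tuple[str, ...] = tuple(
    f"{row}{col:02d}" for row in "ABCDEFGH" for col in range(1, 13)
)

#: Standard bacterial PM panel plate labels (PM01 .. PM20).
PLATE_IDS: tuple[str, ...] = tuple(f"PM{i:02d}" for i in range(1, 21))


class KineticCurve:
    """One well's intensity time series.

    Parameters
    ----------
    times:
        Minutes since incubation start; strictly increasing, length >= 2.
    values:
        Instrument intensity units, one per time point.  Raw instrument
        data are non-negative; set ``require_nonnegative=False`` only for
        derived curves (e.g. z-scored profiles).
    """

    __slots__ = ("times", "values")

    def __init__(
        self,
        times: Iterable[float],
        values: Iterable[float],
        *,
        require_nonnegative: bool = True,
    ) -> None:
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if t.shape != v.shape:
            raise ValueError(
                f"times (n={t.size}) and values (n={v.size}) differ in length"
            )
        if t.size < 2:
            raise ValueError("a kinetic curve needs at least 2 time points")
        if not np.all(np.isfinite(t)):
            raise ValueError("times must be finite")
        if np.any(t < 0):
            raise ValueError("times must be non-negative minutes")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if require_nonnegative and np.any(v < 0):
            raise ValueError("intensity values must be non-negative")
        t.setflags(write=False)
        v.setflags(write=False)
        self.times = t
        self.values = v

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KineticCurve):
            return NotImplemented
        return np.array_equal(self.times, other.times) and np.array_equal(
            self.values, other.values
        )

    def __repr__(self) -> str:
        return (
            f"KineticCurve(n={len(self)}, "
            f"t=[{self.times[0]:g}..{self.times[-1]:g}] min)"
        )

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) observation time in minutes."""
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class WellRecord:
    """A kinetic curve together with its full metadata coordinate.

    The tuple (project, strain, phenotype, plate, well, replicate,
    temperature) uniquely identifies a record within a :class:`RecordSet`.
    ``averaged`` marks records produced by replicate averaging; those carry
    ``replicate == 0``.
    """

    project: str
    species: str
    strain: str
    phenotype: str
    plate: str
    well: str
    replicate: int
    temperature: float
    curve: KineticCurve
    averaged: bool = False

    def __post_init__(self) -> None:
        if not WELL_RE.match(self.well):
            raise ValueError(
                f"well {self.well!r} does not match [A-H](01-12)"
            )
        if not self.plate:
            raise ValueError("plate label must be non-empty")
        if self.averaged:
            if self.replicate != 0:
                raise ValueError("averaged records use replicate index 0")
        elif self.replicate < 1:
            raise ValueError("replicate index must be a positive integer")

    @property
    def key(self) -> tuple:
        """Uniqueness key within a RecordSet."""
        return (
            self.project,
            self.strain,
            self.phenotype,
            self.plate,
            self.well,
            self.replicate,
            self.temperature,
        )

    @property
    def group_key(self) -> tuple:
        """Replicate-group key: everything but project and replicate."""
        return (self.strain, self.phenotype, self.plate, self.well, self.temperature)

    @property
    def label(self) -> tuple:
        """Human-facing identity used in report tables."""
        return (self.strain, self.phenotype, self.plate, self.well, self.replicate)


class RecordSet:
    """Ordered collection of :class:`WellRecord` with a uniqueness invariant.

    Iteration order is insertion order and is deterministic; duplicate
    metadata coordinates are rejected on insertion.
    """

    def __init__(self, records: Iterable[WellRecord] = ()) -> None:
        self._records: list[WellRecord] = []
        self._index: dict[tuple, int] = {}
        for rec in records:
            self.append(rec)

    def append(self, record: WellRecord) -> None:
        if record.key in self._index:
            raise ValueError(f"duplicate record coordinate: {record.key}")
        self._index[record.key] = len(self._records)
        self._records.append(record)

    def __iter__(self) -> Iterator[WellRecord]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, i: int) -> WellRecord:
        return self._records[i]

    def __contains__(self, key: tuple) -> bool:
        return key in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecordSet):
            return NotImplemented
        return len(self) == len(other) and all(
            a == b and a.curve == b.curve
            for a, b in zip(self._records, other._records)
        )

    def __repr__(self) -> str:
        return f"RecordSet(n={len(self)})"

    def field_values(self, name: str) -> set:
        """Distinct values of a metadata field across the set."""
        return {getattr(r, name) for r in self._records}

    def strains(self) -> set[str]:
        return self.field_values("strain")


_CRITERIA_FIELDS = (
    "project",
    "strain",
    "phenotype",
    "plate",
    "well",
    "replicate",
    "temperature",
)


@dataclass(frozen=True)
class FilterCriteria:
    """Conjunctive selection over metadata fields.

    Each field holds an optional set of admissible values; ``None`` means
    "no constraint".  A record matches when every constrained field takes
    one of the listed values (disjunction within a field, conjunction
    across fields) — the composed-filter equivalent of a step-wise
    drill-down through project, strain, phenotype, replicate and
    temperature.
    """

    project: Optional[frozenset] = None
    strain: Optional[frozenset] = None
    phenotype: Optional[frozenset] = None
    plate: Optional[frozenset] = None
    well: Optional[frozenset] = None
    replicate: Optional[frozenset] = None
    temperature: Optional[frozenset] = None

    @classmethod
    def of(cls, **kwargs) -> "FilterCriteria":
        """Build criteria from scalars or iterables, e.g. ``of(strain="WT")``."""
        norm = {}
        for name, val in kwargs.items():
            if name not in _CRITERIA_FIELDS:
                raise TypeError(f"unknown filter field {name!r}")
            if val is None:
                continue
            if isinstance(val, (str, int, float)):
                norm[name] = frozenset([val])
            else:
                norm[name] = frozenset(val)
        return cls(**norm)

    def matches(self, record: WellRecord) -> bool:
        for name in _CRITERIA_FIELDS:
            allowed = getattr(self, name)
            if allowed is not None and getattr(record, name) not in allowed:
                return False
        return True

    def __and__(self, other: "FilterCriteria") -> "FilterCriteria":
        """Conjunction of two criteria (intersection per field)."""
        merged = {}
        for name in _CRITERIA_FIELDS:
            a, b = getattr(self, name), getattr(other, name)
            if a is None:
                merged[name] = b
            elif b is None:
                merged[name] = a
            else:
                merged[name] = a & b
        return FilterCriteria(**merged)


def filter_records(catalog: RecordSet, criteria: FilterCriteria) -> RecordSet:
    """Select the records matching every provided constraint.

    The catalog is not modified and record order is preserved.  Criteria
    naming values absent from the catalog simply yield a smaller (possibly
    empty) subset.
    """
    return RecordSet(r for r in catalog if criteria.matches(r))


def group_replicates(rs: RecordSet) -> dict[tuple, list[WellRecord]]:
    """Group records by (strain, phenotype, plate, well, temperature).

    Members of a group differ only in replicate index (and possibly
    project); every record lands in exactly one group, so the union of all
    groups reconstitutes the input.  Singleton groups are allowed.
    """
    groups: dict[tuple, list[WellRecord]] = {}
    for rec in rs:
        groups.setdefault(rec.group_key, []).append(rec)
    return groups
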