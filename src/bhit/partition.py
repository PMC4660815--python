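"""Set partitions of dataset columns, in canonical labeling.

A partition assigns every column a group id.  Two indicator vectors that
induce the same grouping are identified by relabeling groups 1..H in order of
first appearance ("restricted growth" form), so e.g. (1, 3, 2) and (1, 2, 3)
over three columns denote the same object and only the latter is stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = ["Partition", "canonicalize", "iter_set_partitions"]


def canonicalize(indicators: Sequence[int]) -> tuple[int, ...]:
    """Relabel group ids 1..H by first appearance; idempotent."""
    mapping: dict[int, int] = {}
    out = []
    for g in indicators:
        if g not in mapping:
            mapping[g] = len(mapping) + 1
        out.append(mapping[g])
    return tuple(out)


@dataclass(frozen=True)
class Partition:
    """Canonical group-indicator vector over the columns of a dataset."""

    indicators: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.indicators) == 0:
            raise ValueError("partition over zero columns")
        object.__setattr__(self, "indicators", canonicalize(self.indicators))

    @classmethod
    def singletons(cls, n_columns: int) -> "Partition":
        return cls(tuple(range(1, n_columns + 1)))

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[int]], n_columns: int) -> "Partition":
        ind = [0] * n_columns
        for gid, members in enumerate(groups, start=1):
            for i in members:
                ind[i] = gid
        if any(g == 0 for g in ind):
            raise ValueError("groups do not cover all columns")
        return cls(tuple(ind))

    @property
    def n_columns(self) -> int:
        return len(self.indicators)

    @property
    def n_groups(self) -> int:
        return max(self.indicators)

    def groups(self) -> list[tuple[int, ...]]:
        """Member column indices per group, ordered by group id."""
        out: dict[int, list[int]] = {}
        for i, g in enumerate(self.indicators):
            out.setdefault(g, []).append(i)
        return [tuple(out[g]) for g in sorted(out)]

    def group_of(self, column: int) -> tuple[int, ...]:
        gid = self.indicators[column]
        return tuple(i for i, g in enumerate(self.indicators) if g == gid)

    def as_sets(self) -> frozenset[frozenset[int]]:
        """Label-free representation, for equality across labelings."""
        return frozenset(frozenset(g) for g in self.groups())

    def move(self, column: int, target_group: int) -> "Partition":
        """Reassign one column; ``target_group`` 0 means a fresh group."""
        ind = list(self.indicators)
        ind[column] = target_group if target_group > 0 else max(ind) + 2
        return Partition(tuple(ind))


def iter_set_partitions(n: int) -> Iterator[Partition]:
    """All Bell(n) set partitions of n columns, in canonical form."""
    def rec(prefix: list[int], h: int) -> Iterator[tuple[int, ...]]:
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for g in range(1, h + 2):
            yield from rec(prefix + [g], max(h, g))

    for ind in rec([], 0):
        yield Partition(ind)
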