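"""In-memory container for aligned mixed discrete/continuous sample-by-column data.

A :class:`MixedDataset` holds the genotype matrix (additively coded SNPs,
0 = homozygous major, 1 = heterozygous, 2 = homozygous minor) alongside any
number of phenotype columns, which may be categorical (discrete codes) or
quantitative (real-valued).  All partition-model machinery operates on this
container; missing values are rejected at construction (imputation is an
upstream concern).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = ["Column", "MixedDataset"]

ColumnKind = Literal["discrete", "continuous"]
ColumnRole = Literal["genotype", "phenotype"]


@dataclass(frozen=True)
class Column:
    """A single aligned data column.

    Parameters
    ----------
    label
        Unique column name, e.g. a SNP id or trait name.
    kind
        ``"discrete"`` (small non-negative integer codes) or ``"continuous"``.
    role
        ``"genotype"`` or ``"phenotype"``.
    values
        Length-G vector.  Discrete codes must lie in ``[0, cardinality)``.
    cardinality
        Number of possible codes (discrete columns only).  Genotype columns
        always have cardinality 3.
    """

    label: str
    kind: ColumnKind
    role: ColumnRole
    values: np.ndarray
    cardinality: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.role not in ("genotype", "phenotype"):
            raise ValueError(f"unknown column role {self.role!r}")
        values = np.asarray(self.values)
        if values.ndim != 1 or values.shape[0] < 1:
            raise ValueError(f"column {self.label!r}: values must be a non-empty 1-D vector")
        if self.kind == "discrete":
            if self.cardinality is None or self.cardinality < 1:
                raise ValueError(f"column {self.label!r}: discrete column needs cardinality >= 1")
            codes = values.astype(np.int64)
            if not np.array_equal(codes, values):
                raise ValueError(f"column {self.label!r}: discrete values must be integers")
            if codes.min() < 0 or codes.max() >= self.cardinality:
                raise ValueError(
                    f"column {self.label!r}: codes outside [0, {self.cardinality})"
                )
            object.__setattr__(self, "values", codes)
        else:
            floats = values.astype(np.float64)
            if not np.all(np.isfinite(floats)):
                raise ValueError(f"column {self.label!r}: non-finite continuous values")
            object.__setattr__(self, "values", floats)
            if self.cardinality is not None:
                raise ValueError(f"column {self.label!r}: continuous column has no cardinality")

    @property
    def is_discrete(self) -> bool:
        return self.kind == "discrete"


@dataclass
class MixedDataset:
    """Aligned matrix of ``n_samples`` observations over mixed-type columns."""

    columns: list[Column] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("dataset needs at least one column")
        lengths = {len(c.values) for c in self.columns}
        if len(lengths) != 1:
            raise ValueError(f"columns have differing lengths: {sorted(lengths)}")
        labels = [c.label for c in self.columns]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate column labels")

    @property
    def n_samples(self) -> int:
        return len(self.columns[0].values)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.columns]

    def column_index(self, label: str) -> int:
        for i, c in enumerate(self.columns):
            if c.label == label:
                return i
        raise KeyError(label)

    def discrete_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.is_discrete]

    def continuous_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if not c.is_discrete]

    def genotype_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.role == "genotype"]

    def phenotype_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.role == "phenotype"]

    def subset_columns(self, indices: Iterable[int]) -> "MixedDataset":
        return MixedDataset([self.columns[i] for i in indices])

    def subset_rows(self, row_idx: np.ndarray) -> "MixedDataset":
        cols = [
            Column(c.label, c.kind, c.role, c.values[row_idx], c.cardinality)
            for c in self.columns
        ]
        return MixedDataset(cols)

    # ------------------------------------------------------------------
    # pandas interoperability

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({c.label: c.values for c in self.columns})

    @classmethod
    def from_arrays(
        cls,
        genotypes: np.ndarray | None = None,
        genotype_labels: Sequence[str] | None = None,
        phenotypes: pd.DataFrame | None = None,
        phenotype_kinds: dict[str, ColumnKind] | None = None,
    ) -> "MixedDataset":
        """Build a dataset from an additive genotype matrix and a phenotype table.

        ``genotypes`` is samples x SNPs with codes 0/1/2.  Phenotype columns
        with float dtype become continuous, integer dtype becomes discrete
        (override with ``phenotype_kinds``).
        """
        cols: list[Column] = []
        if genotypes is not None:
            genotypes = np.asarray(genotypes)
            if genotype_labels is None:
                genotype_labels = [f"SNP{i + 1}" for i in range(genotypes.shape[1])]
            for j, label in enumerate(genotype_labels):
                cols.append(Column(label, "discrete", "genotype", genotypes[:, j], 3))
        if phenotypes is not None:
            kinds = phenotype_kinds or {}
            for label in phenotypes.columns:
                vals = phenotypes[label].to_numpy()
                kind = kinds.get(label)
                if kind is None:
                    kind = "discrete" if np.issubdtype(vals.dtype, np.integer) else "continuous"
                if kind == "discrete":
                    card = int(np.max(vals)) + 1 if len(vals) else 1
                    cols.append(Column(str(label), "discrete", "phenotype", vals, card))
                else:
                    cols.append(Column(str(label), "continuous", "phenotype", vals))
        return cls(cols)
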