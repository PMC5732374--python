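"""Core value types: genotype matrices, truth labels, partitions.

Genotypes use additive coding: 0 = homozygous common allele (AA),
1 = heterozygous (AB), 2 = homozygous rare allele (BB). Internally all
indices are 0-based; cluster labels are written 1-based to files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

VALID_GENOTYPES = frozenset((0, 1, 2))


def _as_label_array(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValidationError(f"label vector must be 1-D, got shape {arr.shape}")
    return arr


@dataclass
class GenotypeMatrix:
    """N individuals x l SNP markers, additively coded {0,1,2}."""

    values: np.ndarray
    individual_ids: list[str] = field(default=None)  # type: ignore[assignment]
    marker_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("genotype matrix must be 2-D")
        n, l = self.values.shape
        if n < 2:
            raise ValidationError(f"need at least 2 individuals, got {n}")
        if l < 1:
            raise ValidationError(f"need at least 1 marker, got {l}")
        bad = ~np.isin(self.values, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype entry {self.values[i, j]!r} at row {i}, column {j} "
                "is not in {0, 1, 2}"
            )
        self.values = self.values.astype(np.int8)
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i}" for i in range(n)]
        self.individual_ids = [str(s) for s in self.individual_ids]
        if len(self.individual_ids) != n:
            raise ValidationError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if len(set(self.individual_ids)) != n:
            raise ValidationError("individual ids must be unique")
        if self.marker_ids is not None and len(self.marker_ids) != l:
            raise ValidationError(f"{len(self.marker_ids)} marker ids for {l} columns")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class PopulationLabels:
    """Truth population label per individual, aligned with genotype rows."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _as_label_array(self.labels)
        if len(self.labels) < 1:
            raise ValidationError("labels are empty")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_populations(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class Partition:
    """A hard clustering of N individuals into k clusters (labels 1..k)."""

    assignment: np.ndarray
    k: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.assignment = _as_label_array(self.assignment).astype(np.int64)
        if len(self.assignment) == 0:
            raise ValidationError("empty partition")
        if self.assignment.min() < 1:
            raise ValidationError("cluster labels must be >= 1")
        if self.k is None:
            self.k = int(self.assignment.max())
        elif self.assignment.max() > self.k:
            raise ValidationError(
                f"label {self.assignment.max()} exceeds declared k={self.k}"
            )

    def __len__(self) -> int:
        return len(self.assignment)

    @property
    def n_clusters_nonempty(self) -> int:
        return len(np.unique(self.assignment))


def as_labels(p) -> np.ndarray:
    """Coerce a Partition, PopulationLabels or array-like to a 1-D array."""
    if isinstance(p, Partition):
        return p.assignment
    if isinstance(p, PopulationLabels):
        return p.labels
    return _as_label_array(p)
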