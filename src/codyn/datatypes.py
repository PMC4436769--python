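"""Core domain objects for protein-complex co-expression dynamics.

The analysis compares, complex by complex, the gene–gene Pearson correlation
structure of a *case* group against a *control* group at each timepoint of a
time-course expression experiment.  The objects here carry that data through
the pipeline: an expression matrix with per-sample (group, timepoint) labels,
a catalog of protein complexes as gene-symbol sets, per-complex upper-triangular
correlation matrices, and the per-complex comparison results (significance
quadruplets, matrix distances and their z-scores against a random-complex null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

GROUPS = ("case", "control")
LEVELS = ("probe", "gene")


class CodynError(Exception):
    """Base class for all package errors."""


class ValidationError(CodynError):
    """An object or input file violates a structural invariant."""


class DegenerateProfileError(CodynError):
    """A gene expression profile has zero variance within a sample cell,
    making its Pearson correlations undefined."""


@dataclass(frozen=True)
class SampleInfo:
    """One array/sample: identifier, group label and timepoint label."""

    sample_id: str
    group: str
    timepoint: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: group must be one of {GROUPS}, "
                f"got {self.group!r}"
            )


class ExpressionDataset:
    """Expression values (features × samples) with sample annotations.

    Parameters
    ----------
    feature_ids
        Probe or gene identifiers, one per row. Must be unique.
    values
        Real matrix of shape ``(len(feature_ids), len(samples))``; expression
        on a log-ratio scale. Missing values are rejected.
    samples
        Per-column :class:`SampleInfo`, in column order.
    level
        ``"probe"`` or ``"gene"``.
    probe_to_gene
        Optional mapping from feature id to gene symbol. For gene-level
        datasets this is the identity map by convention.

    Every observed (group, timepoint) cell must contain at least 3 samples:
    Pearson correlation over fewer profiles carries no structure.
    """

    def __init__(
        self,
        feature_ids: Sequence[str],
        values: np.ndarray,
        samples: Sequence[SampleInfo],
        level: str = "gene",
        probe_to_gene: Mapping[str, str] | None = None,
    ) -> None:
        feature_ids = list(feature_ids)
        values = np.asarray(values, dtype=float)
        samples = list(samples)
        if level not in LEVELS:
            raise ValidationError(f"level must be one of {LEVELS}, got {level!r}")
        if values.ndim != 2 or values.shape != (len(feature_ids), len(samples)):
            raise ValidationError(
                f"value matrix shape {values.shape} does not match "
                f"{len(feature_ids)} features x {len(samples)} samples"
            )
        if len(set(feature_ids)) != len(feature_ids):
            seen: set[str] = set()
            dup = next(f for f in feature_ids if f in seen or seen.add(f))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate feature id {dup!r}")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in sample metadata")
        if np.isnan(values).any():
            i, j = map(int, np.argwhere(np.isnan(values))[0])
            raise ValidationError(
                f"missing value at feature {feature_ids[i]!r}, "
                f"sample {ids[j]!r}; incomplete matrices are not supported"
            )
        cells: dict[tuple[str, str], int] = {}
        for s in samples:
            cells[(s.group, s.timepoint)] = cells.get((s.group, s.timepoint), 0) + 1
        for (g, t), m in cells.items():
            if m < 3:
                raise ValidationError(
                    f"cell (group={g}, timepoint={t}) has only {m} samples; "
                    "at least 3 are required"
                )

        self.feature_ids: list[str] = feature_ids
        self.values: np.ndarray = values
        self.samples: list[SampleInfo] = samples
        self.level: str = level
        self.probe_to_gene: dict[str, str] | None = (
            dict(probe_to_gene) if probe_to_gene is not None else None
        )
        self._row_index = {f: i for i, f in enumerate(feature_ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def timepoints(self) -> list[str]:
        """Timepoint labels in order of first appearance."""
        seen: list[str] = []
        for s in self.samples:
            if s.timepoint not in seen:
                seen.append(s.timepoint)
        return seen

    def groups(self) -> list[str]:
        return sorted({s.group for s in self.samples})

    def cell_columns(self, group: str, timepoint: str) -> np.ndarray:
        """Column indices of the (group, timepoint) sample cell."""
        idx = [
            j
            for j, s in enumerate(self.samples)
            if s.group == group and s.timepoint == timepoint
        ]
        return np.asarray(idx, dtype=int)

    def cell_values(self, group: str, timepoint: str) -> np.ndarray:
        """Expression sub-matrix (all features × cell samples)."""
        cols = self.cell_columns(group, timepoint)
        if cols.size == 0:
            raise ValidationError(
                f"no samples for group={group!r}, timepoint={timepoint!r}"
            )
        return self.values[:, cols]

    def rows(self, feature_ids: Iterable[str]) -> np.ndarray:
        """Row indices for the given feature ids (hard error if absent)."""
        out = []
        for f in feature_ids:
            if f not in self._row_index:
                raise ValidationError(f"feature {f!r} not present in dataset")
            out.append(self._row_index[f])
        return np.asarray(out, dtype=int)

    def equals(self, other: "ExpressionDataset") -> bool:
        """Exact equality of annotation and values (bit-for-bit)."""
        return (
            self.feature_ids == other.feature_ids
            and self.samples == other.samples
            and self.level == other.level
            and self.probe_to_gene == other.probe_to_gene
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionDataset({self.n_features} {self.level}s x "
            f"{self.n_samples} samples, timepoints={self.timepoints()})"
        )


@dataclass
class ComplexCatalog:
    """Named protein complexes as sets of gene symbols."""

    entries: dict[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.entries.items():
            if not genes:
                raise ValidationError(f"complex {name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class MappedComplex:
    """A catalog complex restricted to genes measured in the dataset.

    Genes are kept in canonical (lexicographic) order so every derived
    matrix and report is deterministic. ``n`` is the complex size and
    ``N = n(n-1)/2`` the number of gene pairs.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.genes) != sorted(self.genes):
            raise ValidationError(
                f"complex {self.name!r}: genes must be in lexicographic order"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"complex {self.name!r}: duplicate genes")
        if self.n < 3:
            raise ValidationError(
                f"complex {self.name!r} has size {self.n} < 3"
            )

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2


def _check_upper(name: str, genes: tuple[str, ...], upper: np.ndarray, bound: float) -> np.ndarray:
    upper = np.asarray(upper, dtype=float)
    n = len(genes)
    n_pairs = n * (n - 1) // 2
    if upper.shape != (n_pairs,):
        raise ValidationError(
            f"{name!r}: expected {n_pairs} upper-triangular entries, got {upper.shape}"
        )
    if np.any(np.abs(upper) > bound + 1e-9):
        raise ValidationError(f"{name!r}: entries outside [-{bound}, {bound}]")
    return np.clip(upper, -bound, bound)


@dataclass
class CorrelationMatrix:
    """Upper-triangular pairwise Pearson matrix of one complex in one
    (group, timepoint) cell.

    ``upper`` holds the N = n(n-1)/2 values in row-major pair order
    ``(0,1), (0,2), ..., (0,n-1), (1,2), ...`` over the canonical gene order.
    """

    complex_name: str
    group: str
    timepoint: str
    genes: tuple[str, ...]
    upper: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        self.genes = tuple(self.genes)
        self.upper = _check_upper(self.complex_name, self.genes, self.upper, 1.0)

    @property
    def n(self) -> int:
        return len(self.genes)

    def square(self) -> np.ndarray:
        """Full symmetric matrix with unit diagonal (for export/plots)."""
        n = self.n
        m = np.eye(n)
        iu = np.triu_indices(n, k=1)
        m[iu] = self.upper
        m[(iu[1], iu[0])] = self.upper
        return m


@dataclass
class DifferenceMatrix:
    """Entrywise case-minus-control correlation differences of one complex."""

    complex_name: str
    timepoint: str
    genes: tuple[str, ...]
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.upper = _check_upper(self.complex_name, self.genes, self.upper, 2.0)

    @property
    def n(self) -> int:
        return len(self.genes)

    def square(self) -> np.ndarray:
        n = self.n
        m = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        m[iu] = self.upper
        m[(iu[1], iu[0])] = self.upper
        return m


@dataclass
class NullDistribution:
    """Empirical null of the case/control matrix distance for random gene
    sets of a fixed size at one timepoint."""

    size: int
    timepoint: str
    n_random: int
    mean_d: float
    sd_d: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_random < 2:
            raise ValidationError("n_random must be >= 2")
        if self.sd_d < 0:
            raise ValidationError("sd_d must be non-negative")


@dataclass
class TimepointComparison:
    """Case-vs-control comparison of one complex at one timepoint."""

    timepoint: str
    avg_case: float
    avg_control: float
    t_stat: float
    p_value: float
    code: int
    distance: float
    z_score: float | None = None

    def __post_init__(self) -> None:
        if self.code not in (-1, 0, 1):
            raise ValidationError("code must be in {-1, 0, +1}")
        if self.distance < 0:
            raise ValidationError("distance must be non-negative")


@dataclass
class ComparisonResult:
    """All per-timepoint comparisons of one complex, in timepoint order."""

    complex_name: str
    genes: tuple[str, ...]
    comparisons: list[TimepointComparison] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def timepoints(self) -> tuple[str, ...]:
        return tuple(c.timepoint for c in self.comparisons)

    @property
    def quadruplet(self) -> tuple[int, ...]:
        """Significance codes over timepoints (+1 / 0 / -1)."""
        return tuple(c.code for c in self.comparisons)

    @property
    def distances(self) -> tuple[float, ...]:
        return tuple(c.distance for c in self.comparisons)

    @property
    def z_scores(self) -> tuple[float | None, ...]:
        return tuple(c.z_score for c in self.comparisons)

    def max_z(self) -> float:
        zs = [z for z in self.z_scores if z is not None and not math.isnan(z)]
        return max(zs) if zs else float("-inf")
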