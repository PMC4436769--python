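"""The computational core: correlation matrices and their comparison.

For a complex of size *n* measured in one (group, timepoint) sample cell, the
co-expression matrix holds the N = n(n-1)/2 pairwise Pearson correlations of
the members' expression profiles, arranged as an upper triangle over the
canonical (lexicographic) gene order.  Case and control matrices at the same
timepoint are compared two ways:

* **average shift** — a paired t statistic over the N matched entries,

      t = sum(D_ij) / sqrt[ (N * sum(D_ij^2) - (sum D_ij)^2) / (N - 1) ],

  with D = A - B (case minus control), referred to a t distribution with
  N - 1 degrees of freedom (two-sided); a significant shift is coded +1 or
  -1 by its direction, otherwise 0.  Over the timepoints these codes form
  the complex's *quadruplet*.

* **rewiring distance** — the root mean squared entrywise difference,

      d = sqrt[ sum(D_ij^2) / N ],

  which has no fixed upper bound, so it is calibrated against an empirical
  null: the distances of ``n_random`` size-matched random gene sets, reduced
  to a z-score  z = (d - <x>) / S.  Positive z above a threshold (1.9 by
  convention here) flags a complex whose internal wiring differs between the
  groups more than random gene sets do; negative z means less than random.

The paired t treats the N gene pairs as independent observations, which they
are not (pairs share genes); this is the published procedure and is kept
as-is — see the methods note for the calibration caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import (
    ComparisonResult,
    CorrelationMatrix,
    DegenerateProfileError,
    DifferenceMatrix,
    ExpressionDataset,
    MappedComplex,
    NullDistribution,
    TimepointComparison,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_Z_THRESHOLD = 1.9
DEFAULT_N_RANDOM = 1000


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

def pearson(x, y) -> float:
    """Pearson product-moment correlation of two profiles (length >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson: inputs must be 1-D of equal length")
    if x.size < 3:
        raise ValidationError("pearson: need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt((xc * xc).sum()))
    ny = float(np.sqrt((yc * yc).sum()))
    if nx == 0.0 or ny == 0.0:
        raise DegenerateProfileError("pearson: zero-variance profile")
    r = float((xc * yc).sum() / (nx * ny))
    return min(1.0, max(-1.0, r))


def _standardize_rows(values: np.ndarray, labels=None) -> np.ndarray:
    """Center each row and scale to unit norm; correlations of any subset are
    then plain inner products. Raises naming the offending feature."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    bad = np.nonzero(norms == 0)[0]
    if bad.size:
        name = labels[bad[0]] if labels is not None else f"row {bad[0]}"
        raise DegenerateProfileError(f"zero-variance profile for {name!r}")
    return centered / norms[:, None]


def _upper(mat: np.ndarray) -> np.ndarray:
    return mat[np.triu_indices(mat.shape[0], k=1)]


def complex_correlation_matrix(
    dataset: ExpressionDataset,
    cx: MappedComplex,
    group: str,
    timepoint: str,
) -> CorrelationMatrix:
    """All pairwise Pearson values of one complex over one cell's samples."""
    sub = dataset.cell_values(group, timepoint)[dataset.rows(cx.genes), :]
    if sub.shape[1] < 3:
        raise ValidationError(
            f"complex {cx.name!r}: cell ({group}, {timepoint}) has "
            f"{sub.shape[1]} samples; need >= 3"
        )
    try:
        z = _standardize_rows(sub, labels=cx.genes)
    except DegenerateProfileError as e:
        raise DegenerateProfileError(f"complex {cx.name!r}, cell ({group}, {timepoint}): {e}") from e
    return CorrelationMatrix(
        complex_name=cx.name,
        group=group,
        timepoint=timepoint,
        genes=cx.genes,
        upper=_upper(z @ z.T),
    )


def average_upper(m: CorrelationMatrix) -> float:
    """Mean of the upper-triangular entries (diagonal excluded)."""
    return float(np.mean(m.upper))


def _check_match(a: CorrelationMatrix, b: CorrelationMatrix) -> None:
    if a.genes != b.genes or a.complex_name != b.complex_name:
        raise ValidationError(
            f"matrices do not match: {a.complex_name!r}/{a.genes} vs "
            f"{b.complex_name!r}/{b.genes}"
        )


# ---------------------------------------------------------------------------
# average-shift test
# ---------------------------------------------------------------------------

def paired_t_statistic(a: CorrelationMatrix, b: CorrelationMatrix) -> tuple[float, float]:
    """Paired t over the matched upper-triangular entries.

    Returns ``(t, p)`` with p two-sided from a t distribution with N-1
    degrees of freedom.  Degenerate spreads are resolved by the sign of the
    (constant) difference: all-zero differences give ``(0, 1)``; identical
    nonzero differences give ``(±inf, 0)`` — a real shift with zero spread —
    both with a logged warning.
    """
    _check_match(a, b)
    d = a.upper - b.upper
    n_pairs = d.size
    if n_pairs < 2:
        raise ValidationError("paired t needs at least 2 gene pairs")
    s = float(d.sum())
    ss = float((d * d).sum())
    denom_sq = (n_pairs * ss - s * s) / (n_pairs - 1)
    if denom_sq <= 0 or np.isclose(denom_sq, 0.0, atol=1e-24):
        if np.allclose(d, 0.0):
            logger.warning(
                "complex %r: identical matrices at %s; t undefined, p=1",
                a.complex_name, a.timepoint,
            )
            return 0.0, 1.0
        logger.warning(
            "complex %r: constant nonzero differences at %s; treated as "
            "maximally significant", a.complex_name, a.timepoint,
        )
        return float(np.sign(s)) * float("inf"), 0.0
    t = s / np.sqrt(denom_sq)
    p = 2.0 * float(stats.t.sf(abs(t), df=n_pairs - 1))
    return float(t), min(1.0, p)


def significance_code(
    a: CorrelationMatrix,
    b: CorrelationMatrix,
    alpha: float = DEFAULT_ALPHA,
) -> int:
    """+1 / -1 for a significant positive / negative average shift of the
    case matrix relative to control at level ``alpha``; else 0."""
    _, p = paired_t_statistic(a, b)
    if p >= alpha:
        return 0
    return int(np.sign(average_upper(a) - average_upper(b))) or 0


def quadruplet(
    dataset: ExpressionDataset,
    cx: MappedComplex,
    timepoints,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[int, ...]:
    """Significance codes of one complex over the given timepoints."""
    codes = []
    for tp in timepoints:
        a = complex_correlation_matrix(dataset, cx, "case", tp)
        b = complex_correlation_matrix(dataset, cx, "control", tp)
        codes.append(significance_code(a, b, alpha))
    return tuple(codes)


# ---------------------------------------------------------------------------
# rewiring distance and its null
# ---------------------------------------------------------------------------

def matrix_distance(a: CorrelationMatrix, b: CorrelationMatrix) -> float:
    """Root mean squared entrywise difference between matched matrices."""
    _check_match(a, b)
    d = a.upper - b.upper
    return float(np.sqrt((d * d).mean()))


def build_null(
    dataset: ExpressionDataset,
    size: int,
    timepoint: str,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int | None = None,
) -> NullDistribution:
    """Empirical distance null for random complexes of a given size.

    Draws ``n_random`` gene sets of ``size`` genes uniformly without
    replacement from the dataset's full gene universe, computes the
    case-vs-control matrix distance of each at ``timepoint``, and summarizes
    the draw by its mean and (sample) standard deviation.  Genes whose
    profile is constant in either cell are excluded from the universe with a
    warning, since their correlations are undefined.
    """
    if dataset.level != "gene":
        raise ValidationError("build_null requires a gene-level dataset")
    if seed is None:
        raise ValidationError("build_null requires an explicit seed")
    if n_random < 2:
        raise ValidationError("n_random must be >= 2")
    case = dataset.cell_values("case", timepoint)
    ctrl = dataset.cell_values("control", timepoint)

    def usable(values):
        c = values - values.mean(axis=1, keepdims=True)
        return (c * c).sum(axis=1) > 0

    keep = usable(case) & usable(ctrl)
    n_univ = int(keep.sum())
    if n_univ < dataset.n_features:
        logger.warning(
            "null universe at %s: excluded %d zero-variance gene(s)",
            timepoint, dataset.n_features - n_univ,
        )
    if size > n_univ:
        raise ValidationError(
            f"random complex size {size} exceeds usable gene universe ({n_univ})"
        )
    zc = _standardize_rows(case[keep])
    zk = _standardize_rows(ctrl[keep])
    rng = np.random.default_rng(seed)
    dists = np.empty(n_random)
    iu = np.triu_indices(size, k=1)
    for r in range(n_random):
        idx = rng.choice(n_univ, size=size, replace=False)
        da = (zc[idx] @ zc[idx].T)[iu] - (zk[idx] @ zk[idx].T)[iu]
        dists[r] = np.sqrt((da * da).mean())
    return NullDistribution(
        size=size,
        timepoint=timepoint,
        n_random=n_random,
        mean_d=float(dists.mean()),
        sd_d=float(dists.std(ddof=1)),
        seed=int(seed),
    )


def z_score(d: float, null: NullDistribution) -> float:
    """Standardize an observed distance against its random-complex null."""
    if null.sd_d <= 0:
        raise ValidationError(
            f"degenerate null (sd=0) for size {null.size} at {null.timepoint}"
        )
    return (float(d) - null.mean_d) / null.sd_d


# ---------------------------------------------------------------------------
# difference matrices and descriptive operations
# ---------------------------------------------------------------------------

def difference_matrix(a: CorrelationMatrix, b: CorrelationMatrix) -> DifferenceMatrix:
    """Entrywise case-minus-control matrix, used to locate rewired genes."""
    _check_match(a, b)
    if a.timepoint != b.timepoint:
        raise ValidationError("difference_matrix: timepoints differ")
    return DifferenceMatrix(
        complex_name=a.complex_name,
        timepoint=a.timepoint,
        genes=a.genes,
        upper=a.upper - b.upper,
    )


def rank_gene_decorrelation(diff: DifferenceMatrix) -> list[tuple[str, float]]:
    """Rank genes by their mean difference entry, most anti-correlated
    (in the case group relative to control) first; ties lexicographic."""
    n = diff.n
    if n < 3:
        raise ValidationError("rank_gene_decorrelation needs n >= 3")
    sq = diff.square()
    means = sq.sum(axis=1) / (n - 1)  # diagonal is zero
    order = sorted(range(n), key=lambda i: (means[i], diff.genes[i]))
    return [(diff.genes[i], float(means[i])) for i in order]


@dataclass
class CorrelationDistribution:
    """Pooled correlation-value histograms split by complex size class."""

    bin_edges: np.ndarray
    small_counts: np.ndarray
    large_counts: np.ndarray
    small_mean: float
    large_mean: float
    small_n: int
    large_n: int


def correlation_value_distribution(
    matrices: list[CorrelationMatrix],
    size_threshold: int = 10,
) -> CorrelationDistribution:
    """Pool upper entries into small (n <= threshold) and large (n > threshold)
    complex classes; histogram at bin width 0.1 over [-1, 1], plus class means."""
    if not matrices:
        raise ValidationError("correlation_value_distribution: no matrices")
    edges = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)
    small = np.concatenate(
        [m.upper for m in matrices if m.n <= size_threshold] or [np.empty(0)]
    )
    large = np.concatenate(
        [m.upper for m in matrices if m.n > size_threshold] or [np.empty(0)]
    )
    return CorrelationDistribution(
        bin_edges=edges,
        small_counts=np.histogram(small, bins=edges)[0],
        large_counts=np.histogram(large, bins=edges)[0],
        small_mean=float(small.mean()) if small.size else float("nan"),
        large_mean=float(large.mean()) if large.size else float("nan"),
        small_n=int(small.size),
        large_n=int(large.size),
    )


# ---------------------------------------------------------------------------
# per-complex comparison (used by the pipeline)
# ---------------------------------------------------------------------------

def compare_complex(
    dataset: ExpressionDataset,
    cx: MappedComplex,
    timepoints,
    nulls: dict | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> ComparisonResult:
    """Full case-vs-control comparison of one complex over all timepoints.

    ``nulls`` maps ``(size, timepoint)`` to a :class:`NullDistribution`;
    when absent, z-scores are left unset.
    """
    result = ComparisonResult(complex_name=cx.name, genes=cx.genes)
    for tp in timepoints:
        a = complex_correlation_matrix(dataset, cx, "case", tp)
        b = complex_correlation_matrix(dataset, cx, "control", tp)
        t, p = paired_t_statistic(a, b)
        avg_a, avg_b = average_upper(a), average_upper(b)
        code = 0 if p >= alpha else (int(np.sign(avg_a - avg_b)) or 0)
        d = matrix_distance(a, b)
        z = None
        if nulls is not None and (cx.n, tp) in nulls:
            null = nulls[(cx.n, tp)]
            if null.sd_d > 0:
                z = z_score(d, null)
            else:
                logger.warning(
                    "degenerate null (sd=0) for size %d at %s; z left unset",
                    cx.n, tp,
                )
        result.comparisons.append(
            TimepointComparison(
                timepoint=tp,
                avg_case=avg_a,
                avg_control=avg_b,
                t_stat=t,
                p_value=p,
                code=code,
                distance=d,
                z_score=z,
            )
        )
    return result
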