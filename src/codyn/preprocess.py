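"""Probe selection and catalog mapping.

Microarray platforms carry several probes per gene; before any gene-level
correlation analysis one probe per gene must be chosen.  Probes are scored by
a two-class one-way ANOVA (case vs. control, samples pooled across
timepoints) and, per gene, the probe discriminating the classes best
(smallest p, largest F on ties, lexicographic probe id on exact ties) is
kept.  The complex catalog is then restricted to measured genes and complexes
falling below the minimum size are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import (
    ComplexCatalog,
    ExpressionDataset,
    MappedComplex,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProbeScore:
    """Two-class ANOVA discrimination score of one probe."""

    probe_id: str
    gene_symbol: str
    f_stat: float
    p_value: float


def score_probes(dataset: ExpressionDataset) -> list[ProbeScore]:
    """One-way two-class ANOVA (case vs. control) per probe.

    Samples are pooled across timepoints. Probes with zero variance in both
    groups cannot discriminate and get ``p = 1`` (logged), rather than an
    error, so flat control probes on real arrays pass through.
    """
    if dataset.probe_to_gene is None:
        raise ValidationError("score_probes requires a probe_to_gene map")
    case_cols = [j for j, s in enumerate(dataset.samples) if s.group == "case"]
    ctrl_cols = [j for j, s in enumerate(dataset.samples) if s.group == "control"]
    n1, n2 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"ANOVA needs >= 2 samples per group; got case={n1}, control={n2}"
        )
    x1 = dataset.values[:, case_cols]
    x2 = dataset.values[:, ctrl_cols]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    gm = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
    ssw = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df2 = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / df2)
    p = stats.f.sf(f, 1, df2)
    # degenerate probes: no within- and no between-group variation
    flat = (ssw == 0) & (ssb == 0)
    if flat.any():
        logger.warning("%d probe(s) with zero variance in both groups; p set to 1", int(flat.sum()))
        f = np.where(flat, 0.0, f)
        p = np.where(flat, 1.0, p)
    # perfect separation with zero within-group variance: maximally significant
    sep = (ssw == 0) & (ssb > 0)
    if sep.any():
        f = np.where(sep, np.inf, f)
        p = np.where(sep, 0.0, p)
    return [
        ProbeScore(pid, dataset.probe_to_gene.get(pid, pid), float(f[i]), float(p[i]))
        for i, pid in enumerate(dataset.feature_ids)
    ]


def select_best_probes(scores: list[ProbeScore]) -> dict[str, str]:
    """Per gene, the probe with the smallest p (largest F, then smallest
    probe_id, on ties). Deterministic regardless of input order."""
    if not scores:
        raise ValidationError("select_best_probes: empty score list")
    best: dict[str, ProbeScore] = {}
    for s in scores:
        cur = best.get(s.gene_symbol)
        if cur is None or (s.p_value, -s.f_stat, s.probe_id) < (
            cur.p_value,
            -cur.f_stat,
            cur.probe_id,
        ):
            best[s.gene_symbol] = s
    return {gene: s.probe_id for gene, s in sorted(best.items())}


def collapse_to_genes(dataset: ExpressionDataset, best: dict[str, str]) -> ExpressionDataset:
    """Gene-level dataset holding exactly the selected probes' rows,
    re-labeled by gene symbol (rows in lexicographic gene order)."""
    genes = sorted(best)
    rows = dataset.rows(best[g] for g in genes)  # hard error if a probe is absent
    return ExpressionDataset(
        genes,
        dataset.values[rows, :].copy(),
        dataset.samples,
        level="gene",
        probe_to_gene={g: g for g in genes},
    )


def map_complexes(
    catalog: ComplexCatalog,
    dataset: ExpressionDataset,
    min_size: int = 3,
) -> list[MappedComplex]:
    """Restrict each catalog complex to measured genes; drop those that fall
    below ``min_size`` (logged). Genes are sorted into canonical order."""
    if dataset.level != "gene":
        raise ValidationError("map_complexes requires a gene-level dataset")
    if min_size < 3:
        raise ValidationError("min_size must be >= 3")
    measured = set(dataset.feature_ids)
    mapped: list[MappedComplex] = []
    dropped = 0
    for name in sorted(catalog.entries):
        genes = sorted(catalog.entries[name] & measured)
        if len(genes) < min_size:
            dropped += 1
            logger.info(
                "complex %r: %d/%d genes measured, below min_size=%d; dropped",
                name, len(genes), len(catalog.entries[name]), min_size,
            )
            continue
        mapped.append(MappedComplex(name=name, genes=tuple(genes)))
    logger.info(
        "mapped %d/%d complexes (dropped %d below size %d)",
        len(mapped), len(catalog.entries), dropped, min_size,
    )
    return mapped
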