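"""Readers and writers for the pipeline's tab-delimited interfaces.

Formats
-------
expression matrix
    TSV; first column ``feature_id``, remaining columns one per sample.
sample metadata
    TSV with header ``sample_id``, ``group`` (case/control), ``timepoint``.
probe map
    TSV with header ``probe_id``, ``gene_symbol``.
complex catalog
    Either CORUM-style (complex-name column plus a semicolon-separated
    gene-symbol column) or a simple two-column (complex, gene) TSV.
result tables
    Quadruplet and distance/z reports at fixed precision, and a "full"
    long-format table at full float precision that round-trips.

Floats in the full table are rendered with ``repr`` (shortest round-trip
representation); report tables use 2 decimals for d and z, matching the
granularity such tables are usually published at.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ComparisonResult,
    ComplexCatalog,
    ExpressionDataset,
    SampleInfo,
    TimepointComparison,
    ValidationError,
)

logger = logging.getLogger(__name__)

CATALOG_DIALECTS = ("corum", "two_column")
RESULT_TABLES = ("quadruplets", "distances", "full")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> dict[str, SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "timepoint"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"metadata {path}: missing columns {sorted(required - set(df.columns))}"
        )
    out: dict[str, SampleInfo] = {}
    for _, row in df.iterrows():
        info = SampleInfo(str(row["sample_id"]), str(row["group"]), str(row["timepoint"]))
        if info.sample_id in out:
            raise ValidationError(f"metadata {path}: duplicate sample_id {info.sample_id!r}")
        out[info.sample_id] = info
    return out


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_symbol"}.issubset(df.columns):
        raise ValidationError(f"probe map {path}: needs columns probe_id, gene_symbol")
    return dict(zip(df["probe_id"].astype(str), df["gene_symbol"].astype(str)))


def read_expression_matrix(
    path: str | Path,
    metadata_path: str | Path,
    probe_map_path: str | Path | None = None,
    level: str | None = None,
) -> ExpressionDataset:
    """Load an expression TSV plus its sample metadata (and optional probe map).

    Samples are attached in file (column) order. Any header sample missing
    from the metadata, non-numeric cell, duplicate feature id or missing
    value is a hard error.  ``level`` defaults to ``"probe"`` when a probe
    map is supplied and ``"gene"`` otherwise.
    """
    meta = read_sample_metadata(metadata_path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    feature_ids = [str(f) for f in df.index]
    if len(set(feature_ids)) != len(feature_ids):
        seen: set[str] = set()
        dup = next(f for f in feature_ids if f in seen or seen.add(f))  # type: ignore[func-returns-value]
        raise ValidationError(f"expression {path}: duplicate feature id {dup!r}")
    samples = []
    for sid in df.columns:
        if str(sid) not in meta:
            raise ValidationError(
                f"expression {path}: sample {str(sid)!r} absent from metadata"
            )
        samples.append(meta[str(sid)])
    # locate the first non-numeric cell for a precise error message
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.index[coerced.isna() & df[col].notna()]
            row = str(bad[0]) if len(bad) else "?"
            raise ValidationError(
                f"expression {path}: non-numeric cell at feature {row!r}, sample {col!r}"
            )
    values = df.to_numpy(dtype=float)
    if level is None:
        level = "probe" if probe_map_path is not None else "gene"
    probe_to_gene = read_probe_map(probe_map_path) if probe_map_path is not None else None
    return ExpressionDataset(feature_ids, values, samples, level=level, probe_to_gene=probe_to_gene)


def write_expression_matrix(
    dataset: ExpressionDataset,
    path: str | Path,
    metadata_path: str | Path,
    probe_map_path: str | Path | None = None,
) -> None:
    """Write a dataset (and its metadata / probe map) so that re-reading
    reproduces it to full numeric precision."""
    df = pd.DataFrame(dataset.values, index=dataset.feature_ids, columns=dataset.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")  # pandas renders floats via repr -> exact round-trip
    meta = pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "group": [s.group for s in dataset.samples],
            "timepoint": [s.timepoint for s in dataset.samples],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)
    if probe_map_path is not None:
        if dataset.probe_to_gene is None:
            raise ValidationError("dataset has no probe_to_gene map to write")
        pm = pd.DataFrame(
            {
                "probe_id": list(dataset.probe_to_gene.keys()),
                "gene_symbol": list(dataset.probe_to_gene.values()),
            }
        )
        pm.to_csv(probe_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# complex catalogs
# ---------------------------------------------------------------------------

def read_complex_catalog(
    path: str | Path,
    dialect: str = "corum",
    name_column: str = "ComplexName",
    genes_column: str = "subunits(Gene name)",
) -> ComplexCatalog:
    """Read a complex catalog.

    ``corum`` dialect: tab-delimited with a complex-name column and a
    semicolon-separated gene-symbol column (column names configurable,
    defaulting to the CORUM release headers). ``two_column`` dialect: one
    ``complex<TAB>gene`` pair per line, no header.

    Gene symbols are whitespace-trimmed; duplicates within a complex are
    collapsed; complexes left with no genes are dropped with a warning.
    """
    if dialect not in CATALOG_DIALECTS:
        raise ValidationError(f"unknown catalog dialect {dialect!r}; use one of {CATALOG_DIALECTS}")
    entries: dict[str, set[str]] = {}
    if dialect == "corum":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in (name_column, genes_column):
            if col not in df.columns:
                raise ValidationError(f"catalog {path}: missing column {col!r}")
        for _, row in df.iterrows():
            name = str(row[name_column]).strip()
            raw = row[genes_column]
            genes = set()
            if isinstance(raw, str):
                genes = {g.strip() for g in raw.split(";") if g.strip()}
            entries.setdefault(name, set()).update(genes)
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ValidationError(
                        f"catalog {path}: line {lineno}: expected 2 tab-separated "
                        f"fields, got {len(parts)}"
                    )
                name, gene = parts[0].strip(), parts[1].strip()
                entries.setdefault(name, set())
                if gene:
                    entries[name].add(gene)
    dropped = [name for name, genes in entries.items() if not genes]
    for name in dropped:
        logger.warning("catalog %s: complex %r has no genes; dropped", path, name)
        del entries[name]
    return ComplexCatalog(
        entries={name: frozenset(genes) for name, genes in entries.items()},
        provenance=str(path),
    )


def write_complex_catalog(catalog: ComplexCatalog, path: str | Path, dialect: str = "two_column") -> None:
    if dialect not in CATALOG_DIALECTS:
        raise ValidationError(f"unknown catalog dialect {dialect!r}")
    if dialect == "two_column":
        with open(path, "w") as fh:
            for name in sorted(catalog.entries):
                for gene in sorted(catalog.entries[name]):
                    fh.write(f"{name}\t{gene}\n")
    else:
        df = pd.DataFrame(
            {
                "ComplexName": sorted(catalog.entries),
                "subunits(Gene name)": [
                    ";".join(sorted(catalog.entries[name])) for name in sorted(catalog.entries)
                ],
            }
        )
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def write_results_table(
    results: Sequence[ComparisonResult],
    path: str | Path,
    table: str = "full",
) -> None:
    """Write comparison results as a TSV.

    ``quadruplets``: one row per complex with its significance codes.
    ``distances``: one row per complex with d and z per timepoint (2 decimals).
    ``full``: long format, one row per (complex, timepoint), all fields at
    full precision; round-trips through :func:`read_results_table`.
    """
    if table not in RESULT_TABLES:
        raise ValidationError(f"unknown table {table!r}; use one of {RESULT_TABLES}")
    if not results:
        raise ValidationError("cannot write an empty result table")
    timepoints = results[0].timepoints
    lines: list[str] = []
    if table == "quadruplets":
        lines.append("\t".join(["complex", "size"] + [f"t{t}" for t in timepoints]))
        for r in results:
            lines.append("\t".join([r.complex_name, str(r.n)] + [str(c) for c in r.quadruplet]))
    elif table == "distances":
        header = ["complex", "size"]
        for t in timepoints:
            header += [f"d{t}", f"z{t}"]
        lines.append("\t".join(header))
        for r in results:
            row = [r.complex_name, str(r.n)]
            for c in r.comparisons:
                row.append(f"{c.distance:.2f}")
                row.append("" if c.z_score is None else f"{c.z_score:.2f}")
            lines.append("\t".join(row))
    else:
        lines.append(
            "\t".join(
                [
                    "complex", "size", "genes", "timepoint", "avg_case", "avg_control",
                    "t_stat", "p_value", "code", "distance", "z_score",
                ]
            )
        )
        for r in results:
            for c in r.comparisons:
                lines.append(
                    "\t".join(
                        [
                            r.complex_name,
                            str(r.n),
                            ",".join(r.genes),
                            c.timepoint,
                            _fmt(c.avg_case),
                            _fmt(c.avg_control),
                            _fmt(c.t_stat),
                            _fmt(c.p_value),
                            str(c.code),
                            _fmt(c.distance),
                            _fmt(c.z_score),
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_results_table(path: str | Path) -> list[ComparisonResult]:
    """Read back a ``full``-format results table."""
    df = pd.read_csv(
        path, sep="\t", dtype={"complex": str, "timepoint": str},
        float_precision="round_trip",
    )
    results: dict[str, ComparisonResult] = {}
    for _, row in df.iterrows():
        name = str(row["complex"])
        if name not in results:
            results[name] = ComparisonResult(
                complex_name=name, genes=tuple(str(row["genes"]).split(","))
            )
        z = row["z_score"]
        results[name].comparisons.append(
            TimepointComparison(
                timepoint=str(row["timepoint"]),
                avg_case=float(row["avg_case"]),
                avg_control=float(row["avg_control"]),
                t_stat=float(row["t_stat"]),
                p_value=float(row["p_value"]),
                code=int(row["code"]),
                distance=float(row["distance"]),
                z_score=None if pd.isna(z) else float(z),
            )
        )
    return list(results.values())


def write_null_table(nulls, path: str | Path) -> None:
    """Write null-distribution summaries (size, timepoint, n_random, mean, sd)."""
    lines = ["size\ttimepoint\tn_random\tmean_d\tsd_d\tseed"]
    for nd in nulls:
        lines.append(
            f"{nd.size}\t{nd.timepoint}\t{nd.n_random}\t{_fmt(nd.mean_d)}\t{_fmt(nd.sd_d)}\t{nd.seed}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_difference_matrix(diff, path: str | Path) -> None:
    """Write a difference matrix in square layout with gene headers."""
    m = diff.square()
    df = pd.DataFrame(m, index=diff.genes, columns=diff.genes)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
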