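"""Pipeline orchestration and report logic.

``run_pipeline`` chains the stages — load or simulate, probe selection and
gene collapse, catalog mapping, per-complex comparison with distance nulls —
and writes the output tables.  The report operations mirror how such results
are usually published: the quadruplet table keeps complexes of size > 3 with
a non-trivial quadruplet; the distance table keeps complexes of size > 3
with at least one z-score above the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datatypes import (
    CodynError,
    ComparisonResult,
    DegenerateProfileError,
    ExpressionDataset,
    NullDistribution,
    ValidationError,
)
from . import io as cio
from . import metrics
from .preprocess import collapse_to_genes, map_complexes, score_probes, select_best_probes
from .simulate import SimulationConfig, planted_catalog, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Either the four input paths or ``simulation`` must be provided. All
    thresholds default to the conventional values for this analysis:
    alpha = 0.05 for the paired t, z > 1.9 for distance significance,
    1000 random complexes per null, analysis size filter >= 3 and report
    size filter > 3.
    """

    seed: int
    out_dir: str | Path | None = None
    expression_path: str | Path | None = None
    metadata_path: str | Path | None = None
    probe_map_path: str | Path | None = None
    catalog_path: str | Path | None = None
    catalog_dialect: str = "corum"
    simulation: SimulationConfig | None = None
    alpha: float = metrics.DEFAULT_ALPHA
    z_threshold: float = metrics.DEFAULT_Z_THRESHOLD
    n_random: int = metrics.DEFAULT_N_RANDOM
    min_size: int = 3
    report_min_size: int = 4
    timepoints: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.report_min_size < self.min_size:
            raise ValidationError("report_min_size must be >= min_size")
        if self.n_random < 100:
            logger.warning(
                "n_random=%d is small; null summaries will be noisy", self.n_random
            )
        has_paths = self.expression_path is not None and self.metadata_path is not None
        if self.simulation is None and not has_paths:
            raise ValidationError(
                "provide either input paths (expression+metadata) or a simulation config"
            )
        if self.timepoints is not None:
            self.timepoints = tuple(str(t) for t in self.timepoints)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim.setdefault("seed", raw.get("seed", 0))
            raw["simulation"] = SimulationConfig(
                seed=int(sim["seed"]),
                n_background_genes=int(sim.get("n_background_genes", 0)),
                complex_specs=_specs_from_raw(sim.get("complex_specs", [])),
                timepoints=tuple(str(t) for t in sim.get("timepoints", ("1", "3", "6", "15"))),
                samples_per_cell=int(sim.get("samples_per_cell", 15)),
                noise_sd=float(sim.get("noise_sd", 1.0)),
            )
        if "timepoints" in raw and raw["timepoints"] is not None:
            raw["timepoints"] = tuple(str(t) for t in raw["timepoints"])
        raw.update(overrides)
        return cls(**raw)


def _specs_from_raw(items):
    from .simulate import ComplexSpec

    specs = []
    for s in items:
        anti_cells = s.get("anti_cells")
        if anti_cells is not None:
            anti_cells = tuple((c[0], str(c[1])) for c in anti_cells)
        specs.append(
            ComplexSpec(
                name=s["name"],
                size=int(s["size"]),
                rho=s.get("rho", 0.0),
                anti_member=s.get("anti_member"),
                rho_anti=float(s.get("rho_anti", 0.0)),
                anti_cells=anti_cells,
            )
        )
    return specs


def null_seed(master_seed: int, size: int, timepoint_index: int) -> int:
    """Deterministic sub-seed for the (size, timepoint) null draw."""
    ss = np.random.SeedSequence([int(master_seed), int(size), int(timepoint_index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineOutput:
    results: list[ComparisonResult]
    nulls: list[NullDistribution]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (complex, reason)


def run_pipeline(config: PipelineConfig) -> PipelineOutput:
    """Execute all stages and (if ``out_dir`` is set) write the tables.

    Outputs under ``out_dir``: ``quadruplets.tsv``, ``distances.tsv``,
    ``full.tsv``, ``nulls.tsv`` and one square difference matrix per
    (complex, timepoint) under ``difference_matrices/``.  Deterministic —
    byte-identical outputs for identical configs and seeds.
    """
    # --- stage 1: obtain data ------------------------------------------------
    if config.simulation is not None:
        dataset = simulate_dataset(config.simulation)
        catalog = planted_catalog(config.simulation)
        logger.info("simulated dataset: %s", dataset)
    else:
        dataset = cio.read_expression_matrix(
            config.expression_path, config.metadata_path, config.probe_map_path
        )
        if config.catalog_path is None:
            raise ValidationError("catalog_path is required for file-based runs")
        catalog = cio.read_complex_catalog(config.catalog_path, dialect=config.catalog_dialect)
        logger.info("loaded dataset: %s; catalog: %d complexes", dataset, len(catalog))

    # --- stage 2: probe selection -------------------------------------------
    if dataset.level == "probe":
        scores = score_probes(dataset)
        best = select_best_probes(scores)
        n_probes = dataset.n_features
        dataset = collapse_to_genes(dataset, best)
        logger.info("probe selection: %d probes -> %d genes", n_probes, dataset.n_features)

    # --- stage 3: catalog mapping --------------------------------------------
    mapped = map_complexes(catalog, dataset, min_size=config.min_size)

    timepoints = config.timepoints or tuple(dataset.timepoints())

    # --- stage 4: nulls per (size, timepoint) --------------------------------
    sizes = sorted({cx.n for cx in mapped})
    nulls: dict[tuple[int, str], NullDistribution] = {}
    for size in sizes:
        for k, tp in enumerate(timepoints):
            nulls[(size, tp)] = metrics.build_null(
                dataset,
                size,
                tp,
                n_random=config.n_random,
                seed=null_seed(config.seed, size, k),
            )

    # --- stage 5: per-complex comparison -------------------------------------
    results: list[ComparisonResult] = []
    skipped: list[tuple[str, str]] = []
    diffs = []
    for cx in mapped:
        try:
            results.append(
                metrics.compare_complex(dataset, cx, timepoints, nulls=nulls, alpha=config.alpha)
            )
            for tp in timepoints:
                a = metrics.complex_correlation_matrix(dataset, cx, "case", tp)
                b = metrics.complex_correlation_matrix(dataset, cx, "control", tp)
                diffs.append(metrics.difference_matrix(a, b))
        except DegenerateProfileError as e:
            skipped.append((cx.name, str(e)))
            logger.warning("complex %r skipped: %s", cx.name, e)
    logger.info(
        "compared %d complexes (%d skipped) over %d timepoints",
        len(results), len(skipped), len(timepoints),
    )

    # --- stage 6: write tables ------------------------------------------------
    if config.out_dir is not None and results:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        quad_rows = report_quadruplets(results, config.report_min_size)
        if quad_rows:
            cio.write_results_table(quad_rows, out / "quadruplets.tsv", table="quadruplets")
        else:
            header = "\t".join(["complex", "size"] + [f"t{t}" for t in timepoints])
            (out / "quadruplets.tsv").write_text(header + "\n")
        dist_rows = report_distances(results, config.z_threshold, config.report_min_size)
        if dist_rows:
            cio.write_results_table(dist_rows, out / "distances.tsv", table="distances")
        else:
            header = ["complex", "size"]
            for t in timepoints:
                header += [f"d{t}", f"z{t}"]
            (out / "distances.tsv").write_text("\t".join(header) + "\n")
        cio.write_results_table(results, out / "full.tsv", table="full")
        cio.write_null_table(
            sorted(nulls.values(), key=lambda nd: (nd.size, timepoints.index(nd.timepoint))),
            out / "nulls.tsv",
        )
        dm_dir = out / "difference_matrices"
        dm_dir.mkdir(exist_ok=True)
        for diff in diffs:
            cio.write_difference_matrix(
                diff, dm_dir / f"{diff.complex_name}_{diff.timepoint}.tsv"
            )

    return PipelineOutput(results=results, nulls=list(nulls.values()), skipped=skipped)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def report_quadruplets(
    results: list[ComparisonResult],
    report_min_size: int = 4,
) -> list[ComparisonResult]:
    """Complexes of size >= ``report_min_size`` whose quadruplet is not all
    zero, sorted by descending size then name."""
    rows = [
        r
        for r in results
        if r.n >= report_min_size and any(c != 0 for c in r.quadruplet)
    ]
    return sorted(rows, key=lambda r: (-r.n, r.complex_name))


def report_distances(
    results: list[ComparisonResult],
    z_threshold: float = metrics.DEFAULT_Z_THRESHOLD,
    report_min_size: int = 4,
) -> list[ComparisonResult]:
    """Complexes of size >= ``report_min_size`` with at least one z-score
    above ``z_threshold`` (one-sided: only positive z counts), ordered by the
    timepoint of earliest significance, then size descending, then name."""
    rows = [r for r in results if r.n >= report_min_size and r.max_z() > z_threshold]

    def first_sig(r: ComparisonResult) -> int:
        for k, c in enumerate(r.comparisons):
            if c.z_score is not None and c.z_score > z_threshold:
                return k
        return len(r.comparisons)

    return sorted(rows, key=lambda r: (first_sig(r), -r.n, r.complex_name))


def significant_timepoint_count(z_values, z_threshold: float = metrics.DEFAULT_Z_THRESHOLD) -> int:
    """How many of a complex's z-scores exceed the (one-sided) threshold."""
    return int(sum(1 for z in z_values if z is not None and z > z_threshold))


def summarize_quadruplets(rows) -> dict[str, int]:
    """Summary counts over quadruplet report rows.

    Accepts :class:`ComparisonResult` rows or plain code tuples.  Returns the
    number of rows whose first code is non-zero (``nonzero_t1``), how many of
    those are +1 (``plus_one_t1``), and how many all-zero rows were present
    (``all_zero_excluded``).
    """
    quads = [r.quadruplet if isinstance(r, ComparisonResult) else tuple(r) for r in rows]
    nonzero_t1 = sum(1 for q in quads if q and q[0] != 0)
    plus_one_t1 = sum(1 for q in quads if q and q[0] == 1)
    all_zero = sum(1 for q in quads if all(c == 0 for c in q))
    return {
        "nonzero_t1": nonzero_t1,
        "plus_one_t1": plus_one_t1,
        "all_zero_excluded": all_zero,
    }
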