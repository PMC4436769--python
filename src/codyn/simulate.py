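"""Synthetic expression data with planted complex-level correlation structure.

The generator emulates a two-group (case vs. control), multi-timepoint
expression study: for every (group, timepoint) sample cell, the genes of each
planted complex are drawn from a multivariate normal whose correlation matrix
is an equicorrelation block at a per-cell target ``rho``, optionally with one
*anti-member* gene whose correlation to every other member is ``-rho_anti``
(the single-gene dissociation pattern the difference-matrix ranking is meant
to detect).  Background genes are independent Gaussian noise.  Defaults mirror
the study design this pipeline targets: 4 timepoints (months 1, 3, 6, 15) and
15 case + 15 control samples per timepoint.

Correlation is location/scale-free, so Gaussian zero-mean marginals lose no
generality for the downstream metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .datatypes import CodynError, ExpressionDataset, SampleInfo, ValidationError
from .io import write_complex_catalog, write_expression_matrix
from .datatypes import ComplexCatalog

logger = logging.getLogger(__name__)

DEFAULT_TIMEPOINTS = ("1", "3", "6", "15")

_PSD_TOL = -1e-8


class SimulationError(CodynError):
    """Invalid simulation request (e.g., a non-PSD planted correlation)."""


@dataclass
class ComplexSpec:
    """One planted complex.

    Parameters
    ----------
    name, size
        Complex name and number of genes (>= 3).
    rho
        Target intra-complex correlation. Either a scalar applied to every
        (group, timepoint) cell, or a nested mapping
        ``{group: {timepoint: rho, "default": rho}, "default": rho}``.
        Equicorrelation requires ``rho > -1/(size-1)``.
    anti_member
        Optional gene index (0-based) that is given correlation
        ``-rho_anti`` to every other member instead of ``rho``.
    anti_cells
        Cells ``(group, timepoint)`` in which the anti-member pattern is
        active; ``None`` means all cells.
    """

    name: str
    size: int
    rho: float | Mapping = 0.0
    anti_member: int | None = None
    rho_anti: float = 0.0
    anti_cells: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValidationError(f"complex {self.name!r}: size must be >= 3")
        if self.anti_member is not None and not (0 <= self.anti_member < self.size):
            raise ValidationError(f"complex {self.name!r}: anti_member index out of range")
        if not (0.0 <= self.rho_anti < 1.0):
            raise ValidationError(f"complex {self.name!r}: rho_anti must be in [0, 1)")
        if self.anti_cells is not None:
            self.anti_cells = tuple((str(g), str(t)) for g, t in self.anti_cells)

    def rho_for(self, group: str, timepoint: str) -> float:
        r = self.rho
        if isinstance(r, Mapping):
            g = r.get(group, None)
            val = None
            if isinstance(g, Mapping):
                val = g.get(timepoint, g.get("default"))
            elif g is not None:
                val = g
            if val is None:
                val = r.get("default")
            if val is None:
                raise ValidationError(
                    f"complex {self.name!r}: no rho for cell ({group}, {timepoint}) "
                    "and no 'default' entry"
                )
            return float(val)
        return float(r)

    def anti_active(self, group: str, timepoint: str) -> bool:
        if self.anti_member is None:
            return False
        return self.anti_cells is None or (group, timepoint) in self.anti_cells

    def correlation_matrix(self, group: str, timepoint: str) -> np.ndarray:
        """Planted correlation matrix for one cell; PSD-checked."""
        rho = self.rho_for(group, timepoint)
        n = self.size
        if not (-1.0 / (n - 1) < rho < 1.0):
            raise SimulationError(
                f"complex {self.name!r}: rho={rho} outside (-1/(n-1), 1) for n={n}"
            )
        c = np.full((n, n), rho)
        np.fill_diagonal(c, 1.0)
        if self.anti_active(group, timepoint):
            k = self.anti_member
            c[k, :] = -self.rho_anti
            c[:, k] = -self.rho_anti
            c[k, k] = 1.0
        min_eig = float(np.linalg.eigvalsh(c)[0])
        if min_eig < _PSD_TOL:
            raise SimulationError(
                f"complex {self.name!r}: requested correlation for cell "
                f"({group}, {timepoint}) is not positive semi-definite "
                f"(min eigenvalue {min_eig:.3g})"
            )
        return c

    def gene_names(self) -> list[str]:
        # zero-padded so lexicographic order equals index order
        return [f"{self.name}_g{k:03d}" for k in range(self.size)]


@dataclass
class SimulationConfig:
    """Full description of one synthetic dataset."""

    seed: int
    n_background_genes: int = 0
    complex_specs: list[ComplexSpec] = field(default_factory=list)
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    samples_per_cell: int = 15
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("simulation seed is mandatory")
        if self.samples_per_cell < 3:
            raise ValidationError("samples_per_cell must be >= 3")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        self.timepoints = tuple(str(t) for t in self.timepoints)
        names = [s.name for s in self.complex_specs]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate complex names in simulation config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        specs = []
        for s in raw.get("complex_specs", []):
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
        return cls(
            seed=int(raw["seed"]),
            n_background_genes=int(raw.get("n_background_genes", 0)),
            complex_specs=specs,
            timepoints=tuple(str(t) for t in raw.get("timepoints", DEFAULT_TIMEPOINTS)),
            samples_per_cell=int(raw.get("samples_per_cell", 15)),
            noise_sd=float(raw.get("noise_sd", 1.0)),
        )


def planted_catalog(config: SimulationConfig) -> ComplexCatalog:
    """Catalog of the planted complexes (for fixture bundles / pipelines)."""
    return ComplexCatalog(
        entries={s.name: frozenset(s.gene_names()) for s in config.complex_specs},
        provenance="synthetic:planted",
    )


def simulate_dataset(config: SimulationConfig) -> ExpressionDataset:
    """Draw a gene-level dataset from the configured generative model.

    Deterministic given ``config.seed``: cells are visited in timepoint order,
    case before control, and within each cell complexes are drawn in spec
    order before the background block.
    """
    rng = np.random.default_rng(config.seed)
    complex_genes: list[str] = []
    for spec in config.complex_specs:
        complex_genes.extend(spec.gene_names())
    bg_genes = [f"bg_{i:05d}" for i in range(config.n_background_genes)]
    feature_ids = complex_genes + bg_genes
    if not feature_ids:
        raise ValidationError("simulation has no genes (no complexes, no background)")

    m = config.samples_per_cell
    samples: list[SampleInfo] = []
    blocks: list[np.ndarray] = []
    for tp in config.timepoints:
        for group in ("case", "control"):
            cell = np.empty((len(feature_ids), m))
            row = 0
            for spec in config.complex_specs:
                c = spec.correlation_matrix(group, tp)
                draw = rng.multivariate_normal(
                    np.zeros(spec.size), c, size=m, method="eigh"
                )
                cell[row : row + spec.size, :] = config.noise_sd * draw.T
                row += spec.size
            if config.n_background_genes:
                cell[row:, :] = rng.normal(
                    0.0, config.noise_sd, size=(config.n_background_genes, m)
                )
            blocks.append(cell)
            samples.extend(
                SampleInfo(f"{group}_{tp}_{r:03d}", group, tp) for r in range(m)
            )
    values = np.concatenate(blocks, axis=1)
    return ExpressionDataset(
        feature_ids,
        values,
        samples,
        level="gene",
        probe_to_gene={g: g for g in feature_ids},
    )


def make_probe_level(
    dataset: ExpressionDataset,
    probes_per_gene: int,
    decoy_noise_sd: float,
    seed: int,
) -> ExpressionDataset:
    """Expand a gene-level dataset into probes with planted best probes.

    Probe 1 of each gene carries the gene's signal unchanged; the remaining
    ``probes_per_gene - 1`` decoy probes add independent Gaussian noise of
    standard deviation ``decoy_noise_sd``, so probe selection by group
    discrimination has a known right answer.
    """
    if dataset.level != "gene":
        raise ValidationError("make_probe_level requires a gene-level dataset")
    if probes_per_gene < 1:
        raise ValidationError("probes_per_gene must be >= 1")
    if decoy_noise_sd <= 0:
        raise ValidationError("decoy_noise_sd must be positive")
    rng = np.random.default_rng(seed)
    probe_ids: list[str] = []
    probe_to_gene: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for i, gene in enumerate(dataset.feature_ids):
        base = dataset.values[i]
        for j in range(1, probes_per_gene + 1):
            pid = f"{gene}__p{j}"
            probe_ids.append(pid)
            probe_to_gene[pid] = gene
            if j == 1:
                rows.append(base.copy())
            else:
                rows.append(base + rng.normal(0.0, decoy_noise_sd, size=base.shape))
    return ExpressionDataset(
        probe_ids,
        np.vstack(rows),
        dataset.samples,
        level="probe",
        probe_to_gene=probe_to_gene,
    )


def write_fixture_bundle(
    config: SimulationConfig,
    out_dir: str | Path,
    probes_per_gene: int = 1,
    decoy_noise_sd: float = 3.0,
) -> dict[str, Path]:
    """Simulate and write a complete loadable bundle.

    Writes ``expression.tsv``, ``samples.tsv``, ``probe_map.tsv`` and a
    two-column ``complexes.tsv`` catalog of the planted complexes. With
    ``probes_per_gene > 1`` the expression matrix is probe-level with planted
    decoys.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = simulate_dataset(config)
    if probes_per_gene > 1:
        dataset = make_probe_level(
            dataset, probes_per_gene, decoy_noise_sd, seed=config.seed + 1
        )
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "samples.tsv",
        "probe_map": out / "probe_map.tsv",
        "catalog": out / "complexes.tsv",
    }
    write_expression_matrix(dataset, paths["expression"], paths["metadata"], paths["probe_map"])
    write_complex_catalog(planted_catalog(config), paths["catalog"], dialect="two_column")
    logger.info(
        "fixture bundle: %d features, %d samples, %d complexes -> %s",
        dataset.n_features, dataset.n_samples, len(config.complex_specs), out,
    )
    return paths
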