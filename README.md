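# codyn — time dynamics of protein-complex co-expression

`codyn` quantifies how the internal wiring of protein complexes changes
between two conditions over a time course, using only gene expression data
and a complex catalog.  It was built for case/control transcriptomics of
neurodegeneration models (e.g. the AD11 anti-NGF mouse vs. its VH controls,
profiled at 1, 3, 6 and 15 months), but applies to any two-group,
multi-timepoint expression design with a CORUM-style complex annotation.

For each complex of size *n*, the genes' pairwise Pearson correlations over
one (group, timepoint) sample cell form an upper-triangular co-expression
matrix with N = n(n−1)/2 entries: A (case) and B (control).  Two statistics
compare them at every timepoint:

* **Average-shift quadruplet.**  A paired t over matched entries,

  t = Σ(A_ij − B_ij) / sqrt[(N·ΣD_ij² − (ΣD_ij)²)/(N−1)],  D = A − B,

  with N−1 degrees of freedom, two-sided at α = 0.05, coded +1 / −1 / 0 per
  timepoint (sign of the average difference when significant).  The code
  vector over timepoints — the *quadruplet*, e.g. (+1, 0, 0, 0) — shows at a
  glance when the complex's average co-expression diverges.

* **Rewiring distance with a random-complex null.**  The distance
  d = sqrt[Σ_{i<j}(A_ij − B_ij)²/N] detects re-organization even when the
  averages match.  Since d has no fixed maximum, it is standardized against
  1000 size-matched random gene sets: z = (d − ⟨x⟩)/S, significant one-sided
  at z > 1.9.

A third view, the difference matrix A − B with a per-gene mean-difference
ranking, localizes the change to single members (e.g. one subunit
anti-correlated with the rest of its complex in the case group only).

See `docs/methods.md` for assumptions, calibration caveats, and what the
synthetic data generator does and does not emulate.

## Worked example

Plant one 8-gene complex whose intra-complex correlation is elevated in the
case group at the first timepoint only (ρ_case = 0.7 vs ρ_control = 0.2,
both groups at ρ = 0.2 thereafter), against 200 background genes, then run
the full pipeline:

```python
from codyn import ComplexSpec, PipelineConfig, SimulationConfig, run_pipeline

spec = ComplexSpec(
    name="Proteasome-like", size=8,
    rho={"case": {"1": 0.7, "default": 0.2}, "control": 0.2},
)
sim = SimulationConfig(seed=11, n_background_genes=200,
                       complex_specs=[spec], samples_per_cell=15)
out = run_pipeline(PipelineConfig(seed=11, simulation=sim, n_random=1000))

r = out.results[0]
print("complex:", r.complex_name, " size:", r.n)
print("quadruplet:", r.quadruplet)
for c in r.comparisons:
    print(f"  t={c.timepoint:>2}  avg_case={c.avg_case:+.3f}  avg_control={c.avg_control:+.3f}"
          f"  p={c.p_value:.2e}  code={c.code:+d}  d={c.distance:.3f}  z={c.z_score:+.2f}")
```

prints

```
complex: Proteasome-like  size: 8
quadruplet: (1, 0, 0, 0)
  t= 1  avg_case=+0.451  avg_control=+0.272  p=2.08e-03  code=+1  d=0.327  z=-1.03
  t= 3  avg_case=+0.153  avg_control=+0.239  p=2.85e-01  code=+0  d=0.421  z=+0.96
  t= 6  avg_case=+0.146  avg_control=+0.114  p=6.18e-01  code=+0  d=0.328  z=-0.99
  t=15  avg_case=+0.145  avg_control=+0.103  p=4.82e-01  code=+0  d=0.305  z=-1.55
```

The planted month-1 shift is recovered as quadruplet (+1, 0, 0, 0): the
case average (0.451) significantly exceeds control (0.272) at month 1
(p ≈ 0.002) and nowhere else.  The distance z-scores stay below the 1.9
threshold: a uniform correlation shift moves the *average* strongly but is a
mild re-organization compared to random 8-gene sets, illustrating why the
two metrics target different features.

The same analysis runs from the shell on TSV inputs:

```sh
codyn simulate   --config sim.yaml --out bundle/
codyn analyze    --expr bundle/expression.tsv --meta bundle/samples.tsv \
                 --complexes bundle/complexes.tsv --seed 11 --out results/
codyn report     --full results/full.tsv --out reports/
```

`analyze` accepts probe-level data (`--probes probe_map.tsv`), selecting the
most group-discriminative probe per gene by two-class ANOVA before the
correlation analysis, and reads CORUM-format catalogs via
`--dialect corum`.  Real-data runs (e.g. GEO series GSE63617 plus a CORUM
release, both supplied by the user as TSVs) use exactly this path.

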