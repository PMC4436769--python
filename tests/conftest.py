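import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from codyn import ComplexSpec, ExpressionDataset, SampleInfo, SimulationConfig, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SEED = 0  # suite-wide convention for fixed seeds


def make_samples(timepoints=("1", "3"), per_cell=3, groups=("case", "control")):
    out = []
    for tp in timepoints:
        for g in groups:
            for r in range(per_cell):
                out.append(SampleInfo(f"{g}_{tp}_{r}", g, tp))
    return out


def make_dataset(n_features=5, timepoints=("1", "3"), per_cell=3, seed=SEED, level="gene"):
    samples = make_samples(timepoints, per_cell)
    rng = np.random.default_rng(seed)
    features = [f"G{i:03d}" for i in range(n_features)]
    values = rng.normal(size=(n_features, len(samples)))
    return ExpressionDataset(
        features, values, samples, level=level,
        probe_to_gene={f: f for f in features} if level == "gene" else None,
    )


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def null_sim_dataset():
    """One 6-gene complex with no planted structure, 2 timepoints."""
    cfg = SimulationConfig(
        seed=SEED,
        n_background_genes=20,
        complex_specs=[ComplexSpec(name="CxNull", size=6, rho=0.0)],
        timepoints=("1", "3"),
        samples_per_cell=15,
    )
    return cfg, simulate_dataset(cfg)
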