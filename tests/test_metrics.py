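"""Correlation matrices, paired-t codes, distances, nulls and rankings."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from codyn import (
    ComplexCatalog,
    ComplexSpec,
    CorrelationMatrix,
    DegenerateProfileError,
    ExpressionDataset,
    MappedComplex,
    SimulationConfig,
    ValidationError,
    average_upper,
    build_null,
    complex_correlation_matrix,
    correlation_value_distribution,
    difference_matrix,
    map_complexes,
    matrix_distance,
    paired_t_statistic,
    pearson,
    planted_catalog,
    quadruplet,
    rank_gene_decorrelation,
    significance_code,
    simulate_dataset,
    z_score,
)
from codyn.datatypes import NullDistribution

from conftest import SEED, make_samples

GENES3 = ("a", "b", "c")


def corr(upper, genes=GENES3, group="case", name="Cx", tp="1"):
    return CorrelationMatrix(name, group, tp, genes, np.asarray(upper, dtype=float))


def random_pair(rng, n):
    n_pairs = n * (n - 1) // 2
    genes = tuple(sorted(f"g{k:02d}" for k in range(n)))
    a = corr(rng.uniform(-1, 1, n_pairs), genes)
    b = corr(rng.uniform(-1, 1, n_pairs), genes, group="control")
    return a, b


class TestPearson:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(DegenerateProfileError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValidationError):
            pearson([1, 2], [3, 4])

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_positive_scale_invariance(self, c):
        x = np.array([0.3, -1.2, 0.7, 2.0, -0.5])
        y = np.array([1.0, 0.4, -0.2, 1.5, 0.9])
        assert pearson(c * x, y) == pytest.approx(pearson(x, y), abs=1e-12)


class TestComplexCorrelationMatrix:
    def _ds(self, values, genes):
        samples = make_samples(("1",), per_cell=values.shape[1] // 2)
        return ExpressionDataset(list(genes), values, samples, level="gene")

    def test_pair_count_bookkeeping(self):
        rng = np.random.default_rng(SEED)
        ds = self._ds(rng.normal(size=(3, 8)), GENES3)
        m = complex_correlation_matrix(ds, MappedComplex("Cx", GENES3), "case", "1")
        assert m.upper.shape == (3,)
        # entries match the pairwise pearson definition
        cols = ds.cell_columns("case", "1")
        expected = [
            pearson(ds.values[i, cols], ds.values[j, cols])
            for i in range(3) for j in range(i + 1, 3)
        ]
        assert np.allclose(m.upper, expected, atol=1e-12)

    def test_identical_rows_give_unit_correlation(self):
        rng = np.random.default_rng(SEED)
        row = rng.normal(size=8)
        ds = self._ds(np.vstack([row, row, row]), GENES3)
        m = complex_correlation_matrix(ds, MappedComplex("Cx", GENES3), "case", "1")
        assert np.allclose(m.upper, 1.0)

    def test_zero_variance_gene_named(self):
        rng = np.random.default_rng(SEED)
        values = rng.normal(size=(3, 8))
        values[1] = 0.0
        ds = self._ds(values, GENES3)
        with pytest.raises(DegenerateProfileError, match="'b'"):
            complex_correlation_matrix(ds, MappedComplex("Cx", GENES3), "case", "1")

    def test_equicorrelated_block_recovered(self):
        spec = ComplexSpec(name="Cx", size=6, rho=0.7)
        cfg = SimulationConfig(seed=SEED, complex_specs=[spec],
                               timepoints=("1",), samples_per_cell=500)
        ds = simulate_dataset(cfg)
        cx = map_complexes(planted_catalog(cfg), ds)[0]
        m = complex_correlation_matrix(ds, cx, "case", "1")
        assert abs(average_upper(m) - 0.7) < 0.05


class TestAverageUpper:
    def test_worked_example(self):
        assert average_upper(corr([0.2, 0.4, 0.6])) == pytest.approx(0.4)

    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_constant_matrix(self, c):
        assert average_upper(corr([c, c, c])) == pytest.approx(c)

    def test_against_independent_resummation(self):
        rng = np.random.default_rng(SEED)
        u = rng.uniform(-1, 1, 45)
        genes = tuple(sorted(f"g{k:02d}" for k in range(10)))
        total = 0.0
        for v in u:
            total += float(v)
        assert average_upper(corr(u, genes)) == pytest.approx(total / 45, abs=1e-12)


class TestPairedT:
    def test_identical_matrices(self):
        a = corr([0.1, 0.5, -0.3])
        b = corr([0.1, 0.5, -0.3], group="control")
        t, p = paired_t_statistic(a, b)
        assert t == 0.0 and p == 1.0
        assert significance_code(a, b) == 0

    def test_symmetric_differences_give_zero_t(self):
        a = corr([1.0, -1.0, 0.0])
        b = corr([0.0, 0.0, 0.0], group="control")
        t, _ = paired_t_statistic(a, b)
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_worked_value(self):
        a = corr([0.1, 0.2, 0.3])
        b = corr([0.0, 0.0, 0.0], group="control")
        t, p = paired_t_statistic(a, b)
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert round(t, 4) == 3.4641
        assert p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), df=2), abs=1e-15)

    def test_matches_textbook_oracle(self):
        """The printed-sum formula equals mean/(sd/sqrt(N)) with N-1 df."""
        rng = np.random.default_rng(SEED)
        for _ in range(200):
            n = int(rng.integers(3, 12))
            a, b = random_pair(rng, n)
            t, p = paired_t_statistic(a, b)
            d = a.upper - b.upper
            t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
            assert t == pytest.approx(t_ref, abs=1e-10)
            ref = stats.ttest_rel(a.upper, b.upper)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_nonzero_differences_max_significant(self, caplog):
        a = corr([0.2, 0.2, 0.2])
        b = corr([0.0, 0.0, 0.0], group="control")
        with caplog.at_level("WARNING"):
            t, p = paired_t_statistic(a, b)
        assert p == 0.0 and t == np.inf

    def test_code_antisymmetry(self):
        rng = np.random.default_rng(SEED)
        for _ in range(100):
            a, b = random_pair(rng, 6)
            assert significance_code(a, b) == -significance_code(b, a)

    def test_planted_direction(self):
        genes = tuple(sorted(f"g{k:02d}" for k in range(12)))
        rng = np.random.default_rng(SEED)
        a = corr(np.clip(rng.normal(0.5, 0.05, 66), -1, 1), genes)
        b = corr(np.clip(rng.normal(0.0, 0.05, 66), -1, 1), genes, group="control")
        assert significance_code(a, b) == 1
        assert significance_code(b, a) == -1


class TestQuadruplet:
    def test_null_complex_mostly_all_zero(self):
        """Type-I per timepoint ~ alpha, so (0,0,0,0) dominates null complexes."""
        zeros = 0
        for i in range(40):
            cfg = SimulationConfig(
                seed=1000 + i,
                complex_specs=[ComplexSpec(name="Cx", size=5, rho=0.0)],
                samples_per_cell=15,
            )
            ds = simulate_dataset(cfg)
            cx = map_complexes(planted_catalog(cfg), ds)[0]
            if quadruplet(ds, cx, ds.timepoints()) == (0, 0, 0, 0):
                zeros += 1
        # P(all four zero) ~ 0.95^4 ~ 0.81; 40 trials, allow wide slack
        assert zeros >= 25

    def test_planted_shift_at_first_timepoint(self):
        spec = ComplexSpec(
            name="Cx", size=10,
            rho={"case": {"1": 0.8, "default": 0.0}, "control": 0.0},
        )
        cfg = SimulationConfig(seed=SEED, complex_specs=[spec], samples_per_cell=50)
        ds = simulate_dataset(cfg)
        cx = map_complexes(planted_catalog(cfg), ds)[0]
        q = quadruplet(ds, cx, ds.timepoints())
        assert q[0] == 1


class TestMatrixDistance:
    def test_identity(self):
        a = corr([0.1, 0.5, -0.3])
        b = corr([0.1, 0.5, -0.3], group="control")
        assert matrix_distance(a, b) == 0.0

    def test_uniform_differences(self):
        a = corr([0.4, 0.4, 0.4])
        b = corr([0.0, 0.0, 0.0], group="control")
        assert matrix_distance(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_single_entry_difference(self):
        a = corr([0.3, 0.0, 0.0])
        b = corr([0.0, 0.0, 0.0], group="control")
        assert matrix_distance(a, b) == pytest.approx(np.sqrt(0.09 / 3), abs=1e-12)
        assert matrix_distance(a, b) == pytest.approx(0.173205, abs=1e-6)

    def test_naive_double_loop_oracle(self):
        rng = np.random.default_rng(SEED)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            a, b = random_pair(rng, n)
            acc, k = 0.0, 0
            sq_a, sq_b = a.square(), b.square()
            for i in range(n):
                for j in range(i + 1, n):
                    acc += (sq_a[i, j] - sq_b[i, j]) ** 2
                    k += 1
            assert matrix_distance(a, b) == pytest.approx(np.sqrt(acc / k), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(SEED)
        a, b = random_pair(rng, 7)
        assert matrix_distance(a, b) == matrix_distance(b, a)

    def test_gene_order_mismatch_error(self):
        a = corr([0.1, 0.2, 0.3])
        b = corr([0.1, 0.2, 0.3], genes=("a", "b", "d"), group="control")
        with pytest.raises(ValidationError):
            matrix_distance(a, b)


def identical_groups_dataset(n_genes=30, per_cell=6, seed=SEED):
    """Case columns are copies of control columns: zero distance everywhere."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:02d}" for i in range(n_genes)]
    block = rng.normal(size=(n_genes, per_cell))
    samples = make_samples(("1",), per_cell)
    values = np.empty((n_genes, 2 * per_cell))
    case_cols = [j for j, s in enumerate(samples) if s.group == "case"]
    ctrl_cols = [j for j, s in enumerate(samples) if s.group == "control"]
    values[:, case_cols] = block
    values[:, ctrl_cols] = block
    return ExpressionDataset(genes, values, samples, level="gene",
                             probe_to_gene={g: g for g in genes})


class TestBuildNull:
    def test_degenerate_identical_groups(self):
        ds = identical_groups_dataset()
        nd = build_null(ds, 4, "1", n_random=2, seed=SEED)
        assert nd.mean_d == 0.0 and nd.sd_d == 0.0
        with pytest.raises(ValidationError):
            z_score(0.1, nd)

    def test_seed_determinism(self, null_sim_dataset):
        _, ds = null_sim_dataset
        a = build_null(ds, 5, "1", n_random=50, seed=11)
        b = build_null(ds, 5, "1", n_random=50, seed=11)
        c = build_null(ds, 5, "1", n_random=50, seed=12)
        assert (a.mean_d, a.sd_d) == (b.mean_d, b.sd_d)
        assert (a.mean_d, a.sd_d) != (c.mean_d, c.sd_d)

    def test_size_exceeding_universe(self, null_sim_dataset):
        _, ds = null_sim_dataset
        with pytest.raises(ValidationError):
            build_null(ds, ds.n_features + 1, "1", n_random=10, seed=SEED)

    def test_matches_direct_recomputation(self, null_sim_dataset):
        """The vectorized null equals per-draw pairwise-pearson distances."""
        _, ds = null_sim_dataset
        nd = build_null(ds, 4, "1", n_random=25, seed=3)
        rng = np.random.default_rng(3)
        dists = []
        for _ in range(25):
            idx = rng.choice(ds.n_features, size=4, replace=False)
            genes = tuple(sorted(ds.feature_ids[i] for i in idx))
            cx = MappedComplex("rand", genes)
            a = complex_correlation_matrix(ds, cx, "case", "1")
            b = complex_correlation_matrix(ds, cx, "control", "1")
            dists.append(matrix_distance(a, b))
        assert nd.mean_d == pytest.approx(np.mean(dists), abs=1e-12)
        assert nd.sd_d == pytest.approx(np.std(dists, ddof=1), abs=1e-12)


class TestZScore:
    def test_trivial_points(self):
        nd = NullDistribution(size=4, timepoint="1", n_random=100,
                              mean_d=0.2, sd_d=0.05, seed=0)
        assert z_score(0.2, nd) == pytest.approx(0.0)
        assert z_score(0.25, nd) == pytest.approx(1.0)


class TestDifferenceMatrix:
    def test_zero_and_antisymmetry(self):
        rng = np.random.default_rng(SEED)
        a, b = random_pair(rng, 5)
        d_ab = difference_matrix(a, b)
        d_ba = difference_matrix(b, a)
        assert np.allclose(d_ab.upper, -d_ba.upper)
        assert np.allclose(difference_matrix(a, a).upper, 0.0)

    def test_entries_match_per_pair_subtraction(self):
        rng = np.random.default_rng(SEED)
        a, b = random_pair(rng, 6)
        d = difference_matrix(a, b)
        k = 0
        for i in range(6):
            for j in range(i + 1, 6):
                assert d.upper[k] == pytest.approx(
                    a.square()[i, j] - b.square()[i, j], abs=1e-12
                )
                k += 1


class TestRankGeneDecorrelation:
    def test_all_zero_lexicographic(self):
        d = difference_matrix(corr([0.0] * 3), corr([0.0] * 3, group="control"))
        ranked = rank_gene_decorrelation(d)
        assert [g for g, _ in ranked] == ["a", "b", "c"]
        assert all(m == 0.0 for _, m in ranked)

    def test_brute_force_row_scan(self):
        rng = np.random.default_rng(SEED)
        a, b = random_pair(rng, 8)
        d = difference_matrix(a, b)
        ranked = dict(rank_gene_decorrelation(d))
        sq = d.square()
        for i, g in enumerate(d.genes):
            manual = sum(sq[i, j] for j in range(8) if j != i) / 7
            assert ranked[g] == pytest.approx(manual, abs=1e-12)

    def test_planted_anti_member_ranks_first(self):
        spec = ComplexSpec(
            name="Cx", size=8,
            rho={"case": 0.6, "control": 0.1},
            anti_member=0, rho_anti=0.6, anti_cells=(("case", "1"),),
        )
        cfg = SimulationConfig(seed=SEED, complex_specs=[spec],
                               timepoints=("1",), samples_per_cell=15)
        ds = simulate_dataset(cfg)
        cx = map_complexes(planted_catalog(cfg), ds)[0]
        a = complex_correlation_matrix(ds, cx, "case", "1")
        b = complex_correlation_matrix(ds, cx, "control", "1")
        ranked = rank_gene_decorrelation(difference_matrix(a, b))
        assert ranked[0][0] == cx.genes[0]
        assert ranked[0][1] < 0


class TestCorrelationValueDistribution:
    def test_small_class_only(self):
        dist = correlation_value_distribution([corr([0.05, 0.15, 0.25])])
        assert dist.small_n == 3 and dist.large_n == 0
        assert dist.small_counts.sum() == 3

    def test_count_conservation(self):
        rng = np.random.default_rng(SEED)
        mats = [random_pair(rng, n)[0] for n in (3, 5, 11, 14)]
        dist = correlation_value_distribution(mats)
        total = sum(m.upper.size for m in mats)
        assert dist.small_n + dist.large_n == total
        assert dist.small_counts.sum() + dist.large_counts.sum() == total
        assert dist.large_n == sum(m.upper.size for m in mats if m.n > 10)

    def test_null_data_centered_near_zero(self):
        cfg = SimulationConfig(
            seed=SEED,
            complex_specs=[
                ComplexSpec(name="CxS", size=8, rho=0.0),
                ComplexSpec(name="CxL", size=14, rho=0.0),
            ],
            timepoints=("1",), samples_per_cell=15,
        )
        ds = simulate_dataset(cfg)
        mats = [
            complex_correlation_matrix(ds, cx, g, "1")
            for cx in map_complexes(planted_catalog(cfg), ds)
            for g in ("case", "control")
        ]
        dist = correlation_value_distribution(mats)
        assert abs(dist.small_mean) < 0.05 or dist.small_n < 50
        assert abs(dist.large_mean) < 0.05


class TestScaleInvariance:
    def test_gene_rescaling_changes_nothing(self):
        """Positive per-gene rescaling leaves every metric output unchanged."""
        rng = np.random.default_rng(SEED)
        genes = tuple(sorted(f"g{k}" for k in range(5)))
        samples = make_samples(("1",), per_cell=8)
        base = rng.normal(size=(5, 16))
        scales = rng.uniform(0.1, 10.0, size=5)
        ds1 = ExpressionDataset(list(genes), base, samples, level="gene")
        ds2 = ExpressionDataset(list(genes), base * scales[:, None], samples, level="gene")
        cx = MappedComplex("Cx", genes)
        for group in ("case", "control"):
            m1 = complex_correlation_matrix(ds1, cx, group, "1")
            m2 = complex_correlation_matrix(ds2, cx, group, "1")
            assert np.allclose(m1.upper, m2.upper, atol=1e-12)
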