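import numpy as np
import pytest

from stclust import ExpressionMatrix, SpatialCoords, ValidationError
from stclust.containers import GeneStatTable
from stclust.feature_selection import (
    HighlyVariableGenes,
    SpatiallyVariableGenes,
    concatenate,
    hv_loess_cv,
    hv_residual_variance,
    sv_score_moran,
    threshold_hv,
    threshold_sv,
)
from stclust.simulate import SyntheticConfig, generate_dataset

LEVELS = ("low", "medium", "high")


def em(values, layer="raw"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        np.array([f"c{i}" for i in range(values.shape[0])]),
        np.array([f"g{j}" for j in range(values.shape[1])]),
        layer=layer,
    )


def _unit_vector(n, rng):
    """Exact zero-mean, unit-sample-sd (ddof=1) noise vector."""
    z = rng.normal(size=n)
    z -= z.mean()
    return z / z.std(ddof=1)


class TestLoessCV:
    def make_matrix(self, cv_boost_gene=None, n_genes=30, n_cells=200, seed=0):
        """Genes lying on one mean-CV curve, optionally one with doubled CV."""
        rng = np.random.default_rng(seed)
        z = _unit_vector(n_cells, rng)
        cols, means = [], np.linspace(5.0, 50.0, n_genes)
        for j, m in enumerate(means):
            cv = 0.05 + 0.02 * np.log(m)
            if j == cv_boost_gene:
                cv *= 2
            cols.append(m * (1 + cv * z))
        return em(np.column_stack(cols))

    def test_boosted_gene_has_largest_statistic(self):
        table = hv_loess_cv(self.make_matrix(cv_boost_gene=13))
        assert int(np.argmax(table.statistic)) == 13

    def test_duplicated_gene_gets_equal_statistic(self):
        m = self.make_matrix()
        values = np.column_stack([m.to_dense(), m.to_dense()[:, 4]])
        dup = em(values)
        table = hv_loess_cv(dup)
        assert table.statistic[4] == pytest.approx(table.statistic[-1], abs=1e-12)

    def test_constant_gene_scores_negative_and_is_never_selected(self):
        m = self.make_matrix()
        values = np.column_stack([m.to_dense(), np.full(m.n_cells, 10.0)])
        table = hv_loess_cv(em(values))
        assert table.statistic[-1] < 0
        for level in LEVELS:
            assert "g30" not in threshold_hv(table, level).gene_ids

    def test_zero_mean_gene_gets_sentinel(self):
        m = self.make_matrix()
        values = np.column_stack([m.to_dense(), np.zeros(m.n_cells)])
        table = hv_loess_cv(em(values))
        assert table.statistic[-1] == -np.inf

    def test_too_few_genes_error(self):
        with pytest.raises(ValidationError):
            hv_loess_cv(em(np.ones((10, 5))))


class TestResidualVariance:
    def test_statistic_is_exact_sample_variance(self):
        rng = np.random.default_rng(1)
        z = _unit_vector(50, rng)
        values = np.column_stack([z * np.sqrt(v) for v in (2.0, 0.5, 1.5)])
        table = hv_residual_variance(em(values, layer="pearson"))
        np.testing.assert_allclose(table.statistic, [2.0, 0.5, 1.5], rtol=1e-12)

    def test_variance_exactly_one_is_not_a_candidate(self):
        rng = np.random.default_rng(2)
        z = _unit_vector(50, rng)
        values = np.column_stack([z, z * 2.0])  # variances exactly 1 and 4
        table = hv_residual_variance(em(values, layer="pearson"))
        sel = threshold_hv(table, "low")
        assert list(sel.gene_ids) == ["g1"]

    def test_requires_pearson_layer(self):
        with pytest.raises(ValidationError):
            hv_residual_variance(em(np.ones((5, 3)), layer="raw"))

    def test_homogeneous_poisson_data_yields_few_candidates(self):
        from stclust.preprocess import pearson_residuals

        rng = np.random.default_rng(3)
        counts = rng.poisson(3.0, size=(2000, 100)).astype(float)
        res = pearson_residuals(em(counts))
        table = hv_residual_variance(res)
        assert np.mean(table.statistic > 1) < 0.20


class TestThresholds:
    def test_hv_percentile_arithmetic(self):
        table = GeneStatTable(
            np.array([f"g{j}" for j in range(10)]),
            np.arange(1.0, 11.0),
            "cv_excess",
        )
        assert list(threshold_hv(table, "high").gene_ids) == ["g9"]
        two = GeneStatTable(np.array(["a", "b"]), np.array([1.0, 3.0]), "cv_excess")
        assert list(threshold_hv(two, "low").gene_ids) == ["b"]

    def test_hv_no_candidates_warns_and_returns_empty(self):
        table = GeneStatTable(np.array(["a", "b"]), np.array([-1.0, -2.0]), "cv_excess")
        with pytest.warns(UserWarning):
            sel = threshold_hv(table, "low")
        assert len(sel) == 0

    def test_sv_low_threshold(self):
        table = GeneStatTable(
            np.array(["a", "b", "c"]), np.array([0.01, 0.04, 0.2]), "p_value"
        )
        assert list(threshold_sv(table, "low").gene_ids) == ["a", "b"]

    def test_sv_all_insignificant_gives_empty_levels(self):
        table = GeneStatTable(np.array(["a", "b"]), np.array([1.0, 1.0]), "p_value")
        for level in LEVELS:
            assert len(threshold_sv(table, level)) == 0

    @pytest.mark.parametrize("kind", ["cv_excess", "residual_variance", "p_value"])
    def test_levels_nest(self, kind):
        rng = np.random.default_rng(11)
        for trial in range(20):
            n = rng.integers(5, 60)
            if kind == "p_value":
                stats = rng.uniform(size=n)
                table = GeneStatTable(np.array([f"g{j}" for j in range(n)]), stats, kind)
                sels = [set(threshold_sv(table, lv).gene_ids) for lv in LEVELS]
            else:
                stats = rng.normal(1.0, 1.0, size=n)
                table = GeneStatTable(np.array([f"g{j}" for j in range(n)]), stats, kind)
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sels = [set(threshold_hv(table, lv).gene_ids) for lv in LEVELS]
            low, medium, high = sels
            assert high <= medium <= low


class TestConcatenate:
    def mk(self, source, genes):
        from stclust.containers import GeneSelection

        return GeneSelection(source, "low", np.asarray(genes, dtype=str))

    def test_union_order_and_dedup(self):
        u = concatenate(self.mk("hv", ["g1", "g2"]), self.mk("sv", ["g2", "g3"]))
        assert list(u.gene_ids) == ["g1", "g2", "g3"]
        assert u.source == "union"

    def test_empty_sv_gives_hv(self):
        u = concatenate(self.mk("hv", ["g1", "g2"]), self.mk("sv", []))
        assert list(u.gene_ids) == ["g1", "g2"]

    def test_inclusion_exclusion(self):
        rng = np.random.default_rng(4)
        pool = [f"g{j}" for j in range(30)]
        for _ in range(20):
            hv = list(rng.choice(pool, size=rng.integers(1, 20), replace=False))
            sv = list(rng.choice(pool, size=rng.integers(1, 20), replace=False))
            u = concatenate(self.mk("hv", hv), self.mk("sv", sv))
            assert len(u) == len(hv) + len(sv) - len(set(hv) & set(sv))


class TestMoranScorer:
    def grid_coords(self, m=10):
        gx, gy = np.meshgrid(np.arange(m, dtype=float), np.arange(m, dtype=float))
        ids = np.array([f"c{i}" for i in range(m * m)])
        return SpatialCoords(ids, gx.ravel(), gy.ravel())

    def test_coordinate_gene_maximally_significant(self):
        coords = self.grid_coords()
        values = np.column_stack([coords.x, np.ones(100)])
        m = ExpressionMatrix(values, coords.cell_ids, np.array(["gx", "gc"]), "raw")
        table = sv_score_moran(m, coords, n_perm=99, seed=0)
        assert table.statistic[0] == pytest.approx(1 / 100)
        assert table.statistic[1] == 1.0  # constant gene by convention

    def test_spatially_shuffled_genes_have_uniform_pvalues(self):
        rng = np.random.default_rng(6)
        coords = self.grid_coords(12)
        n = 144
        values = rng.poisson(5.0, size=(n, 200)).astype(float)
        m = ExpressionMatrix(
            values, coords.cell_ids, np.array([f"g{j}" for j in range(200)]), "raw"
        )
        table = sv_score_moran(m, coords, n_perm=199, seed=1)
        assert 0.4 < table.statistic.mean() < 0.6

    def test_deterministic_under_seed(self):
        ds = generate_dataset(SyntheticConfig(n_cells=120, n_sv_genes=5, n_hv_genes=5,
                                              n_noise_genes=5, seed=3))
        a = sv_score_moran(ds.matrix, ds.coords, n_perm=99, seed=5)
        b = sv_score_moran(ds.matrix, ds.coords, n_perm=99, seed=5)
        np.testing.assert_array_equal(a.statistic, b.statistic)


class TestSelectorEstimators:
    def test_highly_variable_selector_support(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(100, 12))
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        scales = np.array([0.5, 0.8, 1.2, 1.5, 2.0, 0.9, 1.1, 3.0, 0.7, 1.3, 0.6, 2.5])
        X = z * scales
        sel = HighlyVariableGenes(method="residual_variance", level="low").fit(X)
        assert sel.get_support().sum() >= 1
        assert sel.scores_[7] == pytest.approx(9.0, rel=1e-12)
        # high-level support nests within low-level support
        high = HighlyVariableGenes(method="residual_variance", level="high").fit(X)
        assert set(np.flatnonzero(high.get_support())) <= set(
            np.flatnonzero(sel.get_support())
        )

    def test_spatially_variable_selector_with_supplied_pvalues(self):
        X = np.random.default_rng(9).poisson(2.0, size=(30, 4)).astype(float)
        sel = SpatiallyVariableGenes(level="low").fit(
            X, pvalues=[0.001, 0.5, 0.04, 0.9]
        )
        np.testing.assert_array_equal(sel.get_support(), [True, False, True, False])

    def test_selector_get_params_round_trip(self):
        sel = HighlyVariableGenes(level="medium")
        params = sel.get_params()
        assert params["level"] == "medium"
        sel.set_params(level="high")
        assert sel.level == "high"
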