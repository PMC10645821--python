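import numpy as np
import pytest
import scipy.stats as st

from bsp.core import Dataset, ExpressionMatrix, SpotCoordinates
from bsp.statistic import (
    BSPParams,
    augment_null_genes,
    build_patch_index,
    compute_pvalues,
    fit_null_distribution,
    gene_weights,
    local_means,
    patch_variance,
    ratio_statistic,
    run_bsp,
)
from tests.conftest import random_dataset


def brute_force_neighbors(positions, i, radius):
    d = np.linalg.norm(positions - positions[i], axis=1)
    idx = np.where((d < radius) & (np.arange(len(positions)) != i))[0]
    return set(idx.tolist())


class TestPatchIndex:
    def test_collinear_middle_spot(self, collinear_coords):
        index = build_patch_index(collinear_coords)
        assert set(index.query(1, 1.5)) == {0, 2}

    def test_zero_radius_empty(self, collinear_coords):
        index = build_patch_index(collinear_coords)
        assert index.query(0, 0.0).size == 0

    def test_strict_inequality(self, collinear_coords):
        index = build_patch_index(collinear_coords)
        # spots at distance exactly 1 are NOT neighbors at D = 1
        assert set(index.query(1, 1.0)) == set()

    @pytest.mark.parametrize("d", [2, 3])
    def test_matches_brute_force(self, d):
        rng = np.random.default_rng(17 + d)
        pos = rng.uniform(0, 5, size=(200, d))
        pos[50] = pos[10]  # duplicate position
        coords = SpotCoordinates(
            spot_ids=np.array([f"s{i}" for i in range(200)], dtype=object),
            positions=pos,
            is_rescaled=True,
        )
        index = build_patch_index(coords)
        for radius in (0.5, 1.0, 2.5):
            for i in rng.integers(0, 200, size=25):
                assert set(index.query(int(i), radius)) == brute_force_neighbors(
                    pos, int(i), radius
                )

    def test_duplicates_are_mutual_neighbors(self):
        pos = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        coords = SpotCoordinates(
            spot_ids=np.array(["a", "b", "c"], dtype=object),
            positions=pos,
            is_rescaled=True,
        )
        index = build_patch_index(coords)
        assert set(index.query(0, 0.1)) == {1}
        assert set(index.query(1, 0.1)) == {0}

    def test_requires_rescaled(self, collinear_coords):
        raw = SpotCoordinates(
            spot_ids=collinear_coords.spot_ids,
            positions=collinear_coords.positions,
            is_rescaled=False,
        )
        with pytest.raises(ValueError, match="rescaled"):
            build_patch_index(raw)


class TestLocalMeans:
    def test_collinear_fixture(self, collinear_coords, collinear_gene):
        index = build_patch_index(collinear_coords)
        lm = local_means(collinear_gene, index, 1.5)
        np.testing.assert_allclose(lm[0], [1.0, 0.0, 1.0])

    def test_constant_gene(self, collinear_coords):
        expr = ExpressionMatrix(
            gene_ids=np.array(["g"], dtype=object),
            spot_ids=collinear_coords.spot_ids,
            values=np.full((1, 3), 0.7),
            normalization_state="minmax",
        )
        index = build_patch_index(collinear_coords)
        for radius in (0.5, 1.5, 10.0):
            np.testing.assert_allclose(local_means(expr, index, radius)[0], 0.7)

    def test_isolated_spot_falls_back_to_own_value(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [50.0, 50.0]])
        coords = SpotCoordinates(
            spot_ids=np.array(["a", "b", "far"], dtype=object),
            positions=pos,
            is_rescaled=True,
        )
        expr = ExpressionMatrix(
            gene_ids=np.array(["g"], dtype=object),
            spot_ids=coords.spot_ids,
            values=np.array([[0.1, 0.9, 0.4]]),
            normalization_state="minmax",
        )
        lm = local_means(expr, build_patch_index(coords), 1.5)
        np.testing.assert_allclose(lm[0], [0.9, 0.1, 0.4])

    def test_include_center(self, collinear_coords, collinear_gene):
        index = build_patch_index(collinear_coords)
        lm = local_means(collinear_gene, index, 1.5, include_center=True)
        np.testing.assert_allclose(lm[0], [0.5, 1.0 / 3.0, 0.5])

    def test_whole_sample_radius_gives_equal_means(self, collinear_coords, collinear_gene):
        index = build_patch_index(collinear_coords)
        lm = local_means(collinear_gene, index, 100.0, include_center=True)
        assert np.ptp(lm[0]) == 0.0


class TestPatchVariance:
    def test_hand_example(self):
        np.testing.assert_allclose(patch_variance(np.array([1.0, 0.0, 1.0])), [2.0 / 9.0])

    def test_constant_is_zero(self):
        assert patch_variance(np.full(10, 3.3))[0] == 0.0

    def test_population_divisor(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(patch_variance(x), [np.var(x)])  # ddof=0


class TestGeneWeights:
    def test_two_gene_ratio(self):
        g1 = np.array([0.0, 0.2, 0.2, 0.2, 1.0])
        g2 = np.array([0.0, 0.5, 0.5, 0.5, 1.0])
        expr = ExpressionMatrix(
            gene_ids=np.array(["a", "b"], dtype=object),
            spot_ids=np.array([f"s{i}" for i in range(5)], dtype=object),
            values=np.vstack([g1, g2]),
            normalization_state="minmax",
        )
        w = gene_weights(expr)
        v1, v2 = np.var(g1), np.var(g2)  # independent hand-oracle
        vmax = max(v1, v2)
        np.testing.assert_allclose(w, [v1 / vmax, v2 / vmax])
        assert w.max() == 1.0

    def test_half_variance_weight(self):
        # two genes with patch variances in ratio 0.02 : 0.04 -> weights (0.5, 1)
        w = np.array([0.02, 0.04])
        np.testing.assert_allclose(w / w.max(), [0.5, 1.0])

    def test_constant_gene_zero_weight(self):
        expr = ExpressionMatrix(
            gene_ids=np.array(["a", "b"], dtype=object),
            spot_ids=np.array(["s0", "s1"], dtype=object),
            values=np.array([[0.0, 0.0], [0.0, 1.0]]),
            normalization_state="minmax",
        )
        np.testing.assert_allclose(gene_weights(expr), [0.0, 1.0])

    def test_all_constant_rejected(self):
        expr = ExpressionMatrix(
            gene_ids=np.array(["a"], dtype=object),
            spot_ids=np.array(["s0", "s1"], dtype=object),
            values=np.zeros((1, 2)),
            normalization_state="minmax",
        )
        with pytest.raises(ValueError, match="constant"):
            gene_weights(expr)


class TestRatioStatistic:
    def test_direct(self):
        r, und = ratio_statistic(np.array([0.2]), np.array([0.4]), np.array([1.0]))
        np.testing.assert_allclose(r, [0.5])
        assert not und[0]

    def test_undefined_flag(self):
        r, und = ratio_statistic(np.array([0.0]), np.array([0.0]), np.array([0.0]))
        assert und[0] and np.isnan(r[0])


class TestFit:
    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(11)
        mu, sigma = -1.3, 0.6
        draws = np.exp(mu + sigma * rng.standard_normal(10_000))
        fit = fit_null_distribution(draws, "lognormal")
        assert abs(fit.params["mu"] - mu) / abs(mu) < 0.05
        assert abs(fit.params["sigma"] - sigma) / sigma < 0.05

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_null_distribution(np.full(100, 2.0), "lognormal")

    def test_too_few_ratios(self):
        with pytest.raises(ValueError, match="augmentation"):
            fit_null_distribution(np.array([1.0, 2.0, 3.0]), "lognormal")

    def test_beta_domain_map_recorded(self):
        rng = np.random.default_rng(12)
        draws = rng.gamma(2.0, 0.5, size=500)
        fit = fit_null_distribution(draws, "beta")
        assert fit.family == "beta"
        assert fit.params["domain_scale"] > draws.max()
        # survival function is finite and decreasing on the data range
        p = fit.sf(np.sort(draws))
        assert np.all(np.diff(p) <= 1e-12)

    def test_pvalues_uniform_under_null(self):
        rng = np.random.default_rng(13)
        fit = fit_null_distribution(
            np.exp(-2.0 + 0.5 * rng.standard_normal(1000)), "lognormal"
        )
        draws = st.lognorm.rvs(
            s=fit.params["sigma"],
            scale=np.exp(fit.params["mu"]),
            size=10_000,
            random_state=rng,
        )
        p = compute_pvalues(draws, fit)
        ks = st.kstest(p, "uniform").statistic
        assert ks < 0.02

    def test_quantile_pvalue(self):
        rng = np.random.default_rng(14)
        fit = fit_null_distribution(
            np.exp(-1.0 + 0.4 * rng.standard_normal(1000)), "lognormal"
        )
        q95 = st.lognorm.ppf(0.95, s=fit.params["sigma"], scale=np.exp(fit.params["mu"]))
        np.testing.assert_allclose(compute_pvalues(np.array([q95]), fit), [0.05], atol=1e-9)

    def test_undefined_ratio_p_one(self):
        rng = np.random.default_rng(15)
        fit = fit_null_distribution(
            np.exp(0.3 * rng.standard_normal(200)), "lognormal"
        )
        assert compute_pvalues(np.array([np.nan]), fit)[0] == 1.0


class TestAugmentation:
    def test_counts(self):
        rng = np.random.default_rng(21)
        expr = ExpressionMatrix(
            gene_ids=np.array([f"g{j}" for j in range(28)], dtype=object),
            spot_ids=np.array([f"s{i}" for i in range(40)], dtype=object),
            values=rng.gamma(2.0, 1.0, size=(28, 40)),
        )
        aug, flags = augment_null_genes(expr, 10_000, rng)
        assert aug.n_genes == 10_000
        assert flags.sum() == 9_972
        assert not flags[:28].any()

    def test_null_preserves_multiset(self):
        rng = np.random.default_rng(22)
        expr = ExpressionMatrix(
            gene_ids=np.array(["g0", "g1"], dtype=object),
            spot_ids=np.array([f"s{i}" for i in range(30)], dtype=object),
            values=rng.gamma(2.0, 1.0, size=(2, 30)),
        )
        aug, flags = augment_null_genes(expr, 10, rng)
        for k in range(2, 10):
            src = (k - 2) % 2
            np.testing.assert_array_equal(
                np.sort(aug.values[k]), np.sort(expr.values[src])
            )

    def test_seeded_determinism(self):
        rng1 = np.random.default_rng(23)
        rng2 = np.random.default_rng(23)
        expr = ExpressionMatrix(
            gene_ids=np.array(["g0"], dtype=object),
            spot_ids=np.array([f"s{i}" for i in range(20)], dtype=object),
            values=np.random.default_rng(0).gamma(2.0, 1.0, size=(1, 20)),
        )
        a1, _ = augment_null_genes(expr, 50, rng1)
        a2, _ = augment_null_genes(expr, 50, rng2)
        np.testing.assert_array_equal(a1.values, a2.values)


class TestRunBsp:
    def test_deterministic(self):
        ds = random_dataset(60, 80, seed=31)
        params = BSPParams(null_augment_threshold=100, null_total=300, seed=7)
        r1 = run_bsp(ds, params)
        r2 = run_bsp(ds, params)
        np.testing.assert_array_equal(r1.p_value, r2.p_value)
        np.testing.assert_array_equal(r1.ratio, r2.ratio)

    def test_spot_reordering_equivariance(self):
        ds = random_dataset(60, 80, seed=32)
        params = BSPParams(null_augment_threshold=0)
        base = run_bsp(ds, params)
        rng = np.random.default_rng(0)
        perm = rng.permutation(80)
        shuffled = Dataset(
            expression=ExpressionMatrix(
                gene_ids=ds.expression.gene_ids,
                spot_ids=ds.expression.spot_ids[perm],
                values=ds.expression.values[:, perm],
            ),
            coordinates=SpotCoordinates(
                spot_ids=ds.coordinates.spot_ids[perm],
                positions=ds.coordinates.positions[perm],
            ),
        )
        out = run_bsp(shuffled, params)
        # patch sums accumulate in a different order after the permutation,
        # so equality holds to floating-point roundoff, not bitwise
        np.testing.assert_allclose(out.p_value, base.p_value, rtol=1e-11)

    def test_translation_invariance(self):
        ds = random_dataset(60, 80, seed=33)
        params = BSPParams(null_augment_threshold=0)
        base = run_bsp(ds, params)
        moved = Dataset(
            expression=ds.expression,
            coordinates=SpotCoordinates(
                spot_ids=ds.coordinates.spot_ids,
                positions=ds.coordinates.positions + np.array([100.0, -40.0]),
            ),
        )
        np.testing.assert_array_equal(base.p_value, run_bsp(moved, params).p_value)

    def test_p_monotone_in_ratio(self):
        ds = random_dataset(80, 60, seed=34)
        res = run_bsp(ds, BSPParams(null_augment_threshold=0))
        ok = ~res.undefined_ratio
        order = np.argsort(res.ratio[ok])
        assert np.all(np.diff(res.p_value[ok][order]) <= 1e-15)

    def test_constant_gene_p_one(self):
        ds = random_dataset(60, 50, seed=35)
        vals = ds.expression.values.copy()
        vals[0] = 2.5
        ds = Dataset(
            expression=ExpressionMatrix(
                gene_ids=ds.expression.gene_ids,
                spot_ids=ds.expression.spot_ids,
                values=vals,
            ),
            coordinates=ds.coordinates,
        )
        res = run_bsp(ds, BSPParams(null_augment_threshold=0))
        assert res.constant_gene[0]
        assert res.p_value[0] == 1.0

    def test_gradient_gene_ranks_first(self):
        rng = np.random.default_rng(36)
        m = 260
        coords = SpotCoordinates(
            spot_ids=np.array([f"s{i}" for i in range(m)], dtype=object),
            positions=rng.uniform(0, 10, size=(m, 2)),
        )
        grad = coords.positions[:, 0] + coords.positions[:, 1]
        base = rng.gamma(2.0, 1.0, size=(500, m))
        values = np.vstack([grad[None, :], base])
        ds = Dataset(
            expression=ExpressionMatrix(
                gene_ids=np.array([f"g{j}" for j in range(501)], dtype=object),
                spot_ids=coords.spot_ids,
                values=values,
            ),
            coordinates=coords,
        )
        res = run_bsp(ds, BSPParams(null_augment_threshold=0))
        assert res.ranked_order()[0] == 0

    def test_pattern_ratio_exceeds_noise_ratio(self):
        # 100 iid-noise genes vs 100 large-scale pattern genes
        rng = np.random.default_rng(37)
        m = 400
        coords = SpotCoordinates(
            spot_ids=np.array([f"s{i}" for i in range(m)], dtype=object),
            positions=rng.uniform(0, 20, size=(m, 2)),
        )
        pattern = (coords.positions[:, 0] > 10).astype(float)
        genes = []
        for _ in range(100):
            genes.append(pattern * 3.0 + rng.gamma(2.0, 0.5, size=m))
        for _ in range(100):
            genes.append(rng.gamma(2.0, 0.5, size=m))
        ds = Dataset(
            expression=ExpressionMatrix(
                gene_ids=np.array([f"g{j}" for j in range(200)], dtype=object),
                spot_ids=coords.spot_ids,
                values=np.array(genes),
            ),
            coordinates=coords,
        )
        res = run_bsp(ds, BSPParams(null_augment_threshold=0))
        assert np.nanmean(res.ratio[:100]) > np.nanmean(res.ratio[100:])

    def test_ratio_shrinks_with_bigger_d2_for_noise(self):
        ds = random_dataset(100, 300, seed=38)
        r_small = run_bsp(ds, BSPParams(d2=2.0, null_augment_threshold=0))
        r_big = run_bsp(ds, BSPParams(d2=5.0, null_augment_threshold=0))
        assert np.nanmean(r_big.ratio) < np.nanmean(r_small.ratio)

    def test_augmentation_trigger(self):
        ds = random_dataset(30, 100, seed=39)
        res = run_bsp(ds, BSPParams(null_augment_threshold=1000, null_total=500, seed=1))
        # report covers only the 30 original genes
        assert res.n_genes == 30
        assert res.fit_params.n_fit > 30

    def test_is_svg_definition(self):
        ds = random_dataset(80, 80, seed=40)
        res = run_bsp(ds, BSPParams(null_augment_threshold=0, alpha=0.2))
        np.testing.assert_array_equal(res.is_svg, res.p_value < 0.2)
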