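import numpy as np
import pytest

from nervedti.stats import (
    RatingTable,
    SliceSeries,
    coefficient_of_variation,
    compartment_contrast,
    cov_within_between,
    fascicle_correlation_test,
    icc_oneway,
    slice_trend,
)


def brute_force_icc1(r: np.ndarray) -> float:
    """Independent sums-of-squares oracle for ICC(1), written longhand."""
    n, k = r.shape
    grand = r.sum() / (n * k)
    ss_between = 0.0
    ss_within = 0.0
    for i in range(n):
        mean_i = sum(r[i]) / k
        ss_between += k * (mean_i - grand) ** 2
        for j in range(k):
            ss_within += (r[i][j] - mean_i) ** 2
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestCoV:
    def test_constant_is_zero(self):
        assert coefficient_of_variation([1, 1, 1, 1]) == 0.0

    def test_hand_arithmetic(self):
        assert coefficient_of_variation([8, 12]) == pytest.approx(0.2828, abs=1e-4)

    def test_scale_invariance(self):
        v = np.array([0.3, 0.5, 0.45, 0.38])
        assert coefficient_of_variation(7.3 * v) == pytest.approx(
            coefficient_of_variation(v), rel=1e-12
        )

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError, match="zero mean"):
            coefficient_of_variation([-1, 1])


class TestCoVWithinBetween:
    def test_constant_table(self):
        w, b, skipped = cov_within_between(np.full((3, 4), 0.5))
        np.testing.assert_allclose(w, 0.0)
        np.testing.assert_allclose(b, 0.0)
        assert skipped == 0

    def test_slice_only_variation(self):
        table = np.tile([0.4, 0.5, 0.6, 0.45], (3, 1))  # rows identical
        w, b, _ = cov_within_between(table)
        assert np.all(w > 0)
        np.testing.assert_allclose(b, 0.0, atol=1e-15)

    def test_nan_cells_skipped_and_counted(self):
        table = np.array([[0.4, 0.5, np.nan], [0.5, 0.6, 0.55]])
        w, b, skipped = cov_within_between(table)
        assert skipped == 1
        assert np.isfinite(w).all()

    def test_jittered_table_matches_analytic_cov(self):
        rng = np.random.default_rng(11)
        fa, sigma = 0.44, 0.05
        table = rng.normal(fa, sigma, size=(40, 40))
        w, b, _ = cov_within_between(table)
        assert w.mean() == pytest.approx(sigma / fa, rel=0.1)
        assert b.mean() == pytest.approx(sigma / fa, rel=0.1)


class TestICC:
    def test_perfect_agreement(self):
        table = np.array([[0.2, 0.2], [0.5, 0.5], [0.8, 0.8], [0.4, 0.4]])
        assert icc_oneway(table) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            table = rng.uniform(0, 1, size=(5, 2))
            assert icc_oneway(table) == pytest.approx(
                brute_force_icc1(table), abs=1e-10
            )

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(6)
        table = rng.uniform(0, 1, size=(8, 3))
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(8), 3),
                "raters": np.tile(np.arange(3), 8),
                "ratings": table.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            long, targets="targets", raters="raters", ratings="ratings"
        )
        icc1 = ref.loc[ref.Type == "ICC(1,1)", "ICC"].iloc[0]
        assert icc_oneway(table) == pytest.approx(icc1, abs=1e-9)
        icc1k = ref.loc[ref.Type == "ICC(1,k)", "ICC"].iloc[0]
        assert icc_oneway(table, average=True) == pytest.approx(icc1k, abs=1e-9)

    def test_identical_subject_means_floor_value(self):
        # observed subject means all equal (MSB = 0) -> ICC(1) = -1/(k-1) exactly
        rng = np.random.default_rng(7)
        for k in (2, 3):
            noise = rng.normal(0, 1, size=(10, k))
            table = noise - noise.mean(axis=1, keepdims=True) + 0.5
            assert icc_oneway(table) == pytest.approx(-1 / (k - 1), abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero total variance"):
            icc_oneway(np.full((4, 2), 0.3))

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            RatingTable(np.array([[1.0, 2.0]]))


class TestSliceTrend:
    def test_perfect_line(self):
        slope, r, p = slice_trend(SliceSeries(np.arange(10), 0.3 + 0.01 * np.arange(10)))
        assert slope == pytest.approx(0.01)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_constant_series(self):
        slope, r, p = slice_trend(SliceSeries(np.arange(5), np.full(5, 0.4)))
        assert slope == 0.0 and r == 0.0

    def test_constant_positions_error(self):
        with pytest.raises(ValueError, match="constant slice positions"):
            slice_trend(SliceSeries(np.zeros(5), np.arange(5.0)))


class TestFascicleCorrelationTest:
    def test_exact_common_slope(self):
        pairs = [(np.arange(5.0), 2 * np.arange(5.0)) for _ in range(3)]
        res = fascicle_correlation_test(pairs)
        np.testing.assert_allclose(res["slopes"], 2.0)
        assert res["p"] == 0.0
        assert res["pooled_r"] == pytest.approx(1.0)

    def test_symmetric_slopes_cancel(self):
        x = np.arange(6.0)
        pairs = [(x, x), (x, -x)]
        res = fascicle_correlation_test(pairs)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_constant_x_nerve_dropped(self):
        x = np.arange(5.0)
        pairs = [(x, x), (np.full(5, 2.0), x), (x, 2 * x)]
        with pytest.warns(RuntimeWarning, match="constant x"):
            res = fascicle_correlation_test(pairs)
        assert res["n_dropped"] == 1
        assert len(res["slopes"]) == 2

    def test_type_i_error_near_alpha(self):
        """Under independence the slope t-test rejects at ~alpha."""
        rng = np.random.default_rng(13)
        n_reps, alpha = 1000, 0.05
        rejections = 0
        for _ in range(n_reps):
            pairs = [
                (rng.normal(size=10), rng.normal(size=10)) for _ in range(5)
            ]
            if fascicle_correlation_test(pairs)["p"] < alpha:
                rejections += 1
        assert rejections / n_reps == pytest.approx(alpha, abs=0.02)


class TestCompartmentContrast:
    def test_fixed_ratio(self):
        b = np.array([0.5, 0.6, 0.7])
        mean, sd = compartment_contrast(1.5 * b, b)
        assert mean == pytest.approx(50.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_equal_inputs(self):
        a = np.array([0.5, 0.6])
        assert compartment_contrast(a, a) == (0.0, 0.0)

    def test_scale_invariance(self):
        a, b = np.array([1.2, 1.5, 1.1]), np.array([0.9, 1.0, 0.8])
        assert compartment_contrast(3 * a, 3 * b) == pytest.approx(
            compartment_contrast(a, b)
        )

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="zero reference"):
            compartment_contrast(np.ones(3), np.array([1.0, 0.0, 1.0]))

    def test_phantom_perineurium_vs_fascicle_md(self, straight_noiseless_phantom):
        from nervedti.morphometry import compartment_index_table

        ph = straight_noiseless_phantom
        table = compartment_index_table(ph.dwi, ph.labels, slices=[4, 8, 12])
        paired = table.pivot_table(index="slice", columns="compartment", values="md")
        mean, sd = compartment_contrast(
            paired["perineurium"].to_numpy(), paired["fascicle"].to_numpy()
        )
        # 100*(0.7833 - 0.53)/0.53 from the default eigenvalue triples
        assert mean == pytest.approx(47.8, abs=0.2)
        assert sd == pytest.approx(0.0, abs=1e-6)
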