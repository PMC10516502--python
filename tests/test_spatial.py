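"""Spatial weights, Moran statistics and ESF regression."""

import numpy as np
import pandas as pd
import pytest

from paleocoex.chronology.kde import haversine_km
from paleocoex.spatial import (
    ESFConfig,
    build_weights,
    fit_esf,
    moran_eigenvectors,
    moran_i,
    resample_correlation,
)


@pytest.fixture(scope="module")
def scattered_weights():
    rng = np.random.default_rng(0)
    n = 30
    return build_weights(rng.uniform(36, 54, n), rng.uniform(-10, 29, n))


class TestBuildWeights:
    def test_equidistant_regions_get_equal_weights(self):
        # two regions symmetric about a third on the same meridian
        w = build_weights([40.0, 42.0, 44.0], [10.0, 10.0, 10.0])
        assert w.matrix[1, 0] == pytest.approx(w.matrix[1, 2], rel=1e-6)

    def test_inverse_distance_homogeneity(self):
        lat = np.array([40.0, 41.0, 42.0, 43.0])
        lon = np.zeros(4)
        w1 = build_weights(lat, lon)
        w2 = build_weights(40.0 + 2 * (lat - 40.0), lon)  # doubled spacing
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(w2.matrix[off], w1.matrix[off] / 2, rtol=0.01)

    def test_line_of_four_matches_hand_computation(self):
        lat = np.array([40.0, 41.0, 42.0, 43.0])
        lon = np.zeros(4)
        w = build_weights(lat, lon)
        d01 = haversine_km(40.0, 0.0, 41.0, 0.0)
        assert w.matrix[0, 1] == pytest.approx(1.0 / d01, rel=1e-9)
        assert w.matrix[0, 2] == pytest.approx(1.0 / (2 * d01), rel=1e-4)
        assert w.matrix[0, 3] == pytest.approx(1.0 / (3 * d01), rel=1e-4)
        assert np.allclose(np.diag(w.matrix), 0.0)
        assert np.allclose(w.row_standardized.sum(axis=1), 1.0)

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            build_weights([40.0, 40.0, 42.0], [5.0, 5.0, 6.0])


class TestMoranI:
    def test_checkerboard_on_a_line_is_negative(self):
        lat = 40.0 + np.arange(8.0)
        w = build_weights(lat, np.zeros(8))
        values = np.resize([1.0, -1.0], 8)
        i, p = moran_i(values, w, n_permutations=199, seed=0)
        assert i < 0

    def test_first_eigenvector_attains_high_autocorrelation(self, scattered_weights):
        eig = moran_eigenvectors(scattered_weights)
        i_vals = [
            moran_i(eig.vectors[:, j], scattered_weights, n_permutations=0)[0]
            for j in range(eig.vectors.shape[1])
        ]
        rng = np.random.default_rng(1)
        random_i = [
            moran_i(rng.normal(size=30), scattered_weights, n_permutations=0)[0]
            for _ in range(200)
        ]
        assert i_vals[0] == max(i_vals)
        assert i_vals[0] > np.percentile(random_i, 99)

    def test_null_pvalues_roughly_uniform(self, scattered_weights):
        rng = np.random.default_rng(2)
        ps = [
            moran_i(rng.normal(size=30), scattered_weights, 99, seed=k)[1]
            for k in range(200)
        ]
        frac = np.mean(np.asarray(ps) <= 0.05)
        assert 0.005 <= frac <= 0.12  # binomial tolerance around 0.05

    def test_constant_vector_rejected(self, scattered_weights):
        with pytest.raises(ValueError, match="constant"):
            moran_i(np.ones(30), scattered_weights)


class TestMoranEigenvectors:
    def test_centered_orthonormal_and_bounded(self, scattered_weights):
        eig = moran_eigenvectors(scattered_weights)
        v = eig.vectors
        assert v.shape[1] <= 29  # at most n - 1 candidates
        assert np.abs(v.sum(axis=0)).max() < 1e-10  # orthogonal to constant
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-10)

    def test_path_graph_matches_reference_decomposition(self):
        # 4-node path with unit weights: eigenvectors of M W M up to sign
        w_mat = np.array(
            [
                [0.0, 1.0, 0.0, 0.0],
                [1.0, 0.0, 1.0, 0.0],
                [0.0, 1.0, 0.0, 1.0],
                [0.0, 0.0, 1.0, 0.0],
            ]
        )
        from paleocoex.spatial import SpatialWeights

        rs = w_mat / w_mat.sum(axis=1, keepdims=True)
        weights = SpatialWeights(["a", "b", "c", "d"], w_mat, rs, "binary")
        eig = moran_eigenvectors(weights, ESFConfig(candidate_threshold=0.01))
        m = np.eye(4) - np.ones((4, 4)) / 4
        ref_vals, ref_vecs = np.linalg.eigh(m @ w_mat @ m)
        order = np.argsort(ref_vals)[::-1]
        top = ref_vecs[:, order[0]]
        got = eig.vectors[:, 0]
        assert min(np.linalg.norm(got - top), np.linalg.norm(got + top)) < 1e-10


class TestFitESF:
    def test_exact_linear_relation(self, scattered_weights):
        eig = moran_eigenvectors(scattered_weights)
        x = np.arange(30, dtype=float)
        fit = fit_esf(x.copy(), x, eig, scattered_weights, ESFConfig(seed=0))
        assert fit["coefficient"] == pytest.approx(1.0)
        assert fit["p_value"] < 1e-12
        assert fit["selected"] == []

    def test_planted_eigenvector_recovered(self, scattered_weights):
        eig = moran_eigenvectors(scattered_weights)
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + 3.0 * eig.vectors[:, 0] + 0.01 * rng.normal(size=30)
        fit = fit_esf(y, x, eig, scattered_weights, ESFConfig(seed=1))
        assert 0 in fit["selected"]
        assert fit["coefficient"] == pytest.approx(1.0, abs=0.05)

    def test_type_one_error_under_spatial_null(self, scattered_weights):
        """Spatially structured y, independent x: rejection rate should sit
        at the nominal 5% level."""
        eig = moran_eigenvectors(scattered_weights)
        hits = 0
        reps = 400
        for r in range(reps):
            rng = np.random.default_rng(10_000 + r)
            y = 1.5 * eig.vectors[:, 0] + 0.8 * eig.vectors[:, 1] + rng.normal(0, 1, 30)
            x = rng.normal(0, 1, 30)
            fit = fit_esf(y, x, eig, scattered_weights,
                          ESFConfig(n_permutations=99, seed=r))
            hits += fit["p_value"] <= 0.05
        assert 0.02 <= hits / reps <= 0.08

    def test_selection_strictly_reduces_residual_moran(self, scattered_weights):
        eig = moran_eigenvectors(scattered_weights)
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = x + 2.0 * eig.vectors[:, 0] + 1.0 * eig.vectors[:, 1] + 0.1 * rng.normal(size=30)
        cfg = ESFConfig(n_permutations=99, seed=5)
        base = fit_esf(y, x, eig, scattered_weights, cfg)
        if base["selected"]:
            # residual I with the selected set must be below the unfiltered one
            import statsmodels.api as sm

            naive = sm.OLS(y, np.column_stack([np.ones(30), x])).fit()
            i_naive, _ = moran_i(naive.resid, scattered_weights, 0)
            assert abs(base["residual_moran_i"]) < abs(i_naive)


class TestResampleCorrelation:
    def test_zero_width_cis_degenerate_to_single_fit(self, scattered_weights):
        eig = moran_eigenvectors(scattered_weights)
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = 2.0 * x + 0.1 * rng.normal(size=30)
        idx = [f"R_{i}" for i in range(30)]
        yt = pd.DataFrame({"estimate": y, "ci_low": y, "ci_high": y}, index=idx)
        xt = pd.DataFrame({"estimate": x, "ci_low": x, "ci_high": x}, index=idx)
        res = resample_correlation(yt, xt, eig, scattered_weights,
                                   ESFConfig(n_resamples=20, seed=0))
        assert np.ptp(res.coefficients) == 0.0
        assert np.ptp(res.p_values) == 0.0

    def test_degenerate_ci_rejected(self, scattered_weights):
        eig = moran_eigenvectors(scattered_weights)
        idx = [f"R_{i}" for i in range(30)]
        y = np.arange(30.0)
        yt = pd.DataFrame({"estimate": y, "ci_low": y + 1, "ci_high": y - 1}, index=idx)
        xt = pd.DataFrame({"estimate": y, "ci_low": y, "ci_high": y}, index=idx)
        with pytest.raises(ValueError, match="degenerate CI"):
            resample_correlation(yt, xt, eig, scattered_weights)
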