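"""Feature extraction: projections, semi-dense connectomes and variants."""

import numpy as np
import pytest

from restpred.core import Parcellation, RestScan, UsageError
from restpred.features import (
    Connectome,
    ProjectionMatrix,
    activity_flow_features,
    dual_regression_features,
    gaussian_random_projection,
    group_ica,
    normalize_features,
    parcel_projection,
    pcr_semipartial_connectome,
    semi_dense_connectome,
)
from restpred.synthetic import make_geometry, make_parcellation

from conftest import make_preprocessed_scan


class TestParcelProjection:
    def test_region_averaging(self):
        p = Parcellation(labels=np.array([1, 1, 2]), K=2)
        A = parcel_projection(p).A
        np.testing.assert_allclose(A, [[0.5, 0.0], [0.5, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(A.T @ np.array([2.0, 4.0, 6.0]), [3.0, 6.0])

    def test_column_sums_one(self, tiny_cohort):
        A = parcel_projection(tiny_cohort.parcellation).A
        np.testing.assert_allclose(A.sum(axis=0), 1.0)


class TestGaussianRandomProjection:
    def test_entry_variance(self):
        A = gaussian_random_projection(2000, 100, seed=0).A
        assert abs(A.var() * 100 - 1.0) < 0.05
        assert abs(A.mean()) < 0.01

    def test_deterministic_under_seed(self):
        a = gaussian_random_projection(50, 7, seed=3).A
        b = gaussian_random_projection(50, 7, seed=3).A
        np.testing.assert_array_equal(a, b)

    def test_norm_preservation_in_expectation(self, rng):
        # E ||A^T x||^2 = ||x||^2: Monte Carlo over 200 seeds
        x = rng.standard_normal(300)
        sq = [
            np.sum((gaussian_random_projection(300, 40, seed=s).A.T @ x) ** 2)
            for s in range(200)
        ]
        assert abs(np.mean(sq) / np.sum(x**2) - 1.0) < 0.05


class TestSemiDenseConnectome:
    def test_identity_projection_gives_covariance(self, rng):
        scan = make_preprocessed_scan(rng, 12, 40)
        A = ProjectionMatrix(np.eye(12), kind="parcel_mean")
        G = semi_dense_connectome(scan, A).G
        np.testing.assert_allclose(G, scan.data @ scan.data.T, atol=1e-10)

    def test_orthogonal_rows_hand_example(self):
        # X has orthogonal rows with norms a, b, 1; A one-hot on row 1
        X = np.array(
            [
                [2.0, 0.0, 0.0, 0.0],
                [0.0, 3.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.0],
            ]
        )
        scan = RestScan("s", X, [4], preprocessed=True)
        A = ProjectionMatrix(np.array([[1.0], [0.0], [0.0]]), kind="x")
        G = semi_dense_connectome(scan, A).G
        # brute-force oracle: G = A^T X X^T computed element-wise
        oracle = np.array([[X[0] @ X[r] for r in range(3)]])
        np.testing.assert_allclose(G, oracle)
        np.testing.assert_allclose(G, [[4.0, 0.0, 0.0]])

    def test_quadratic_scaling(self, rng):
        scan = make_preprocessed_scan(rng, 8, 30)
        A = ProjectionMatrix(rng.standard_normal((8, 3)), kind="x")
        G1 = semi_dense_connectome(scan, A).G
        scaled = RestScan("s", 2.0 * scan.data, [30], preprocessed=True)
        G2 = semi_dense_connectome(scaled, A).G
        np.testing.assert_allclose(G2, 4.0 * G1, rtol=1e-12)

    def test_requires_preprocessed(self, rng):
        scan = RestScan("s", rng.standard_normal((8, 30)), [30], preprocessed=False)
        A = ProjectionMatrix(np.eye(8), kind="x")
        with pytest.raises(UsageError, match="preprocess"):
            semi_dense_connectome(scan, A)

    def test_block_linearity(self, rng):
        # stacking projections row-stacks the connectomes exactly
        scan = make_preprocessed_scan(rng, 10, 25)
        A1 = rng.standard_normal((10, 2))
        A2 = rng.standard_normal((10, 3))
        G12 = semi_dense_connectome(scan, ProjectionMatrix(np.hstack([A1, A2]), "x")).G
        G1 = semi_dense_connectome(scan, ProjectionMatrix(A1, "x")).G
        G2 = semi_dense_connectome(scan, ProjectionMatrix(A2, "x")).G
        np.testing.assert_array_equal(G12, np.vstack([G1, G2]))

    def test_parcel_rows_equal_brute_force_covariance(self, rng):
        # each parcel-mean feature row equals the dot product of the
        # parcel's mean time series with every grayordinate's series
        scan = make_preprocessed_scan(rng, 15, 40)
        labels = rng.integers(1, 4, size=15)
        labels[:3] = [1, 2, 3]
        parc = Parcellation(labels=labels, K=3)
        G = semi_dense_connectome(scan, parcel_projection(parc)).G
        for k in range(1, 4):
            mean_ts = scan.data[labels == k].mean(axis=0)
            oracle = np.array([mean_ts @ scan.data[v] for v in range(15)])
            np.testing.assert_allclose(G[k - 1], oracle, atol=1e-8)


class TestNormalizeFeatures:
    def test_direct_example(self):
        conn = Connectome("s", np.array([[1.0, 2.0, 3.0]]), "x")
        out = normalize_features(conn)
        np.testing.assert_allclose(
            out.G, [[-1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)]], atol=1e-12
        )

    def test_rows_zero_mean_unit_norm(self, rng):
        conn = Connectome("s", rng.standard_normal((6, 30)) * 7 + 2, "x")
        out = normalize_features(conn)
        assert np.abs(out.G.mean(axis=1)).max() < 1e-10
        assert np.abs(np.linalg.norm(out.G, axis=1) - 1.0).max() < 1e-10

    def test_idempotent(self, rng):
        conn = Connectome("s", rng.standard_normal((4, 20)), "x")
        once = normalize_features(conn)
        twice = normalize_features(once)
        np.testing.assert_allclose(twice.G, once.G, atol=1e-12)

    def test_degenerate_row_zeroed(self):
        conn = Connectome("s", np.array([[5.0, 5.0, 5.0], [1.0, 0.0, 2.0]]), "x")
        out = normalize_features(conn)
        assert np.all(out.G[0] == 0.0)
        assert list(out.degenerate_rows) == [0]


class TestGroupICA:
    def _planted_scans(self, seed=0, n_subj=5, v=400, t=300, n_src=3, noise=0.1):
        rng = np.random.default_rng(seed)
        S = rng.laplace(size=(v, n_src))
        scans = []
        for i in range(n_subj):
            T = rng.standard_normal((n_src, t))
            X = S @ T + noise * rng.standard_normal((v, t))
            scans.append(
                RestScan(f"s{i}", X - X.mean(1, keepdims=True), [t], preprocessed=True)
            )
        return S, scans

    def test_recovers_planted_supergaussian_sources(self):
        S, scans = self._planted_scans()
        A = group_ica(scans, n_components=3, seed=0)
        corr = np.abs(np.corrcoef(A.A.T, S.T)[:3, 3:])
        best = corr.max(axis=1)
        assert np.all(best > 0.95)
        # distinct assignment: each recovered map matches a different source
        assert len(set(corr.argmax(axis=1).tolist())) == 3

    def test_subject_order_invariant_subspace(self):
        from scipy.linalg import subspace_angles

        _, scans = self._planted_scans(seed=1)
        A1 = group_ica(scans, n_components=3, seed=0)
        A2 = group_ica(scans[::-1], n_components=3, seed=0)
        assert subspace_angles(A1.A, A2.A).max() < 1e-3

    def test_sign_convention(self):
        _, scans = self._planted_scans(seed=2)
        A = group_ica(scans, n_components=3, seed=0).A
        peaks = A[np.abs(A).argmax(axis=0), np.arange(A.shape[1])]
        assert np.all(peaks > 0)

    def test_needs_two_scans(self, rng):
        scan = make_preprocessed_scan(rng, 10, 20)
        with pytest.raises(UsageError):
            group_ica([scan], n_components=2)


class TestDualRegression:
    def test_noiseless_exact_recovery(self, rng):
        # X built exactly from orthonormal group maps: stage 1 recovers
        # the time courses exactly
        v, f, t = 40, 4, 60
        q, _ = np.linalg.qr(rng.standard_normal((v, f)))
        T = rng.standard_normal((f, t))
        scan = RestScan("s", q @ T, [t], preprocessed=True)
        t_hat = np.linalg.lstsq(q, scan.data, rcond=None)[0]
        assert np.abs(t_hat - T).max() < 1e-8
        conn = dual_regression_features(scan, ProjectionMatrix(q, "group_ica"))
        assert conn.G.shape == (f, v)

    def test_noisy_recovery_of_subject_maps(self, rng):
        v, f, t = 300, 4, 400
        maps_g = rng.standard_normal((v, f))
        subj = maps_g + 0.3 * rng.standard_normal((v, f))
        T = rng.standard_normal((f, t))
        X = subj @ T + 0.5 * rng.standard_normal((v, t))
        scan = RestScan("s", X - X.mean(1, keepdims=True), [t], preprocessed=True)
        conn = dual_regression_features(scan, ProjectionMatrix(maps_g, "group_ica"))
        for k in range(f):
            assert np.corrcoef(conn.G[k], subj[:, k])[0, 1] > 0.9

    def test_single_map_reduces_to_slope(self, rng):
        # with f=1 the second stage is the univariate regression slope of
        # each vertex's series on the subject time course
        scan = make_preprocessed_scan(rng, 20, 50)
        a = rng.standard_normal((20, 1))
        conn = dual_regression_features(scan, ProjectionMatrix(a, "x"))
        t_hat = np.linalg.lstsq(a, scan.data, rcond=None)[0].ravel()
        slope_oracle = scan.data @ t_hat / (t_hat @ t_hat)
        np.testing.assert_allclose(conn.G[0], slope_oracle, atol=1e-8)

    def test_rank_deficient_rejected(self, rng):
        scan = make_preprocessed_scan(rng, 10, 30)
        a = np.ones((10, 2))
        with pytest.raises(UsageError, match="rank"):
            dual_regression_features(scan, ProjectionMatrix(a, "x"))


@pytest.fixture(scope="module")
def pcr_setup():
    from restpred.synthetic import SimConfig

    cfg = SimConfig(
        n_subjects=1, n_total=60, n_cortex=50, t_per_run=40, n_runs=1, n_latent=3, seed=2
    )
    geom = make_geometry(cfg)
    parc = make_parcellation(geom, K=5, seed=2)
    return geom, parc


class TestPCRSemipartial:
    def test_excluded_vertices_exactly_zero(self, pcr_setup, rng):
        from restpred.distances import exclusion_mask

        geom, parc = pcr_setup
        scan = make_preprocessed_scan(rng, geom.n_total, 40)
        conn = pcr_semipartial_connectome(scan, parc, geom, n_pcs=10, seed=0)
        for k in range(1, parc.K + 1):
            mask = exclusion_mask(geom, parc.region_indices(k), 10.0)
            assert np.all(conn.G[k - 1, mask] == 0.0)

    def test_masking_invariant_under_parcellation_fuzzing(self, pcr_setup, rng):
        from restpred.distances import exclusion_mask

        geom, _ = pcr_setup
        scan = make_preprocessed_scan(rng, geom.n_total, 40)
        for seed in range(3):
            parc = make_parcellation(geom, K=4, seed=seed + 10)
            conn = pcr_semipartial_connectome(scan, parc, geom, n_pcs=8, seed=seed)
            for k in range(1, parc.K + 1):
                mask = exclusion_mask(geom, parc.region_indices(k), 10.0)
                assert np.all(conn.G[k - 1, mask] == 0.0)

    def test_planted_remote_driver_dominates(self, pcr_setup, rng):
        # one far-away vertex carries exactly the region-mean signal; its
        # back-projected coefficient must dominate its feature row
        geom, parc = pcr_setup
        data = rng.standard_normal((geom.n_total, 40))
        region = parc.region_indices(1)
        region_ctx = [i for i in region if i < geom.n_cortex]
        # pick the cortical vertex farthest from region 1
        from restpred.distances import cortical_distance_matrix

        dist = cortical_distance_matrix(geom)
        far = int(np.argmax(dist[region_ctx].min(axis=0)))
        data[far] = data[region].mean(axis=0)
        data -= data.mean(axis=1, keepdims=True)
        data /= data.std(axis=1, keepdims=True)
        scan = RestScan("s", data, [40], preprocessed=True)
        conn = pcr_semipartial_connectome(scan, parc, geom, n_pcs=20, seed=0)
        row = np.abs(conn.G[0])
        assert np.argmax(row) == far

    def test_full_rank_matches_ols_projection(self, pcr_setup, rng):
        # with n_pcs >= rank, the fitted region series equals the OLS
        # projection of the region mean onto the masked data's row space
        # (dense-SVD / lstsq oracle)
        from restpred.distances import exclusion_mask

        geom, parc = pcr_setup
        scan = make_preprocessed_scan(rng, geom.n_total, 30)
        with pytest.warns(RuntimeWarning, match="truncating"):
            conn = pcr_semipartial_connectome(scan, parc, geom, n_pcs=512, seed=0)
        k = 1
        region = parc.region_indices(k)
        mask = exclusion_mask(geom, region, 10.0)
        Xm = scan.data[~mask]
        y = scan.data[region].mean(axis=0)
        fitted = Xm.T @ conn.G[k - 1, ~mask]
        coef_ols = np.linalg.lstsq(Xm.T, y, rcond=None)[0]
        np.testing.assert_allclose(fitted, Xm.T @ coef_ols, atol=1e-6)

    def test_total_exclusion_rejected(self, pcr_setup, rng):
        geom, _ = pcr_setup
        labels = np.ones(geom.n_total, dtype=int)
        parc = Parcellation(labels=labels, K=1)
        scan = make_preprocessed_scan(rng, geom.n_total, 30)
        with pytest.raises(UsageError, match="covers all"):
            pcr_semipartial_connectome(scan, parc, geom, n_pcs=5, seed=0)


class TestActivityFlow:
    def test_zero_template_gives_zero_row(self, tiny_cohort, rng):
        geom = tiny_cohort.geometry
        scan = make_preprocessed_scan(rng, geom.n_total, 30)
        conn = activity_flow_features(scan, np.zeros(geom.n_cortex), geom)
        assert conn.f == 1
        assert np.all(conn.G == 0.0)

    def test_one_hot_template_approximates_covariance_row(self, tiny_cohort):
        # independent unit-variance rows: the feature row converges to
        # the sample covariance of vertex m with every grayordinate
        geom = tiny_cohort.geometry
        rng = np.random.default_rng(0)
        t = 2000
        data = rng.standard_normal((geom.n_total, t))
        data -= data.mean(1, keepdims=True)
        data /= data.std(1, keepdims=True)
        scan = RestScan("s", data, [t], preprocessed=True)
        template = np.zeros(geom.n_cortex)
        m = 7
        template[m] = 1.0
        conn = activity_flow_features(scan, template, geom)
        oracle = data @ data[geom.cortex_index[m]]
        np.testing.assert_allclose(conn.G[0], oracle, atol=1e-9)
        # and that equals t at the template vertex, near 0 elsewhere
        assert abs(conn.G[0, geom.cortex_index[m]] - t) < 1e-6

    def test_template_length_checked(self, tiny_cohort, rng):
        geom = tiny_cohort.geometry
        scan = make_preprocessed_scan(rng, geom.n_total, 30)
        with pytest.raises(UsageError, match="template"):
            activity_flow_features(scan, np.zeros(geom.n_cortex + 1), geom)
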