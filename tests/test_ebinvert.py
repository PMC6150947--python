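"""Empirical-Bayes inversion: temporal modes, priors, ReML, MAP, prediction."""

import numpy as np
import pytest
import scipy.linalg

import meshbench as mb
from meshbench import ebinvert as eb


class TestTemporalReduce:
    def test_rank1_epochs_need_single_mode(self, rng):
        u = rng.standard_normal(6)
        v = rng.standard_normal(20)
        epochs = np.stack([np.outer(u * rng.standard_normal(), v) for _ in range(5)])
        with pytest.warns(UserWarning, match="temporal modes"):
            tm = eb.temporal_reduce(epochs, R=4)
        assert tm.R == 1
        assert tm.variance_retained == pytest.approx(1.0)

    def test_modes_orthonormal(self, rng):
        epochs = rng.standard_normal((30, 272, 50))
        tm = eb.temporal_reduce(epochs, R=16)
        assert np.allclose(tm.modes.T @ tm.modes, np.eye(16), atol=1e-9)
        assert tm.reduced_data.shape == (272, 30 * 16)

    def test_variance_retained_matches_svd_oracle(self, rng):
        epochs = rng.standard_normal((10, 8, 20))
        tm = eb.temporal_reduce(epochs, R=5)
        tcov = sum(ep.T @ ep for ep in epochs) / 10
        s = np.sort(np.linalg.eigvalsh(tcov))[::-1]
        assert tm.variance_retained == pytest.approx(s[:5].sum() / s.sum(), abs=1e-10)

    def test_r_larger_than_epoch_raises(self, rng):
        with pytest.raises(ValueError):
            eb.temporal_reduce(rng.standard_normal((3, 4, 10)), R=11)


class TestPriors:
    def test_mmn_is_identity(self):
        pri = eb.prior_mmn(5)
        enc, payload = pri.components[0]
        assert enc == "scaled_identity" and payload == 1.0
        L = np.eye(5)
        kind, Q = pri.sensor_components(L)[0]
        assert np.array_equal(Q, np.eye(5))

    def test_lor_zero_smoothing_is_identity(self, small_mesh):
        pri = eb.prior_lor(small_mesh, smooth_s=0.0)
        _, G = pri.components[0]
        assert np.allclose(G, np.eye(small_mesh.n_vertices), atol=1e-12)

    def test_lor_kernel_matches_dense_expm_oracle(self):
        mesh = mb.gen_mesh(20, fold_amplitude=1.0, fold_frequency=3, seed=5)
        pri = eb.prior_lor(mesh, smooth_s=0.6)
        _, G = pri.components[0]
        A = eb._mesh_graph(mesh).toarray()
        ref = scipy.linalg.expm(0.6 * A)
        assert np.allclose(G, ref, atol=1e-6)
        Q = G @ G.T
        assert np.allclose(Q, Q.T)
        assert np.linalg.eigvalsh(Q).min() > -1e-10

    def test_ebb_identity_covariance_reduces_to_column_norms(self, rng):
        L = rng.standard_normal((6, 12))
        Y = rng.standard_normal((6, 5000))
        Cy = Y @ Y.T / Y.shape[1]
        Yw = np.linalg.solve(np.linalg.cholesky(Cy), Y)  # sample covariance = I
        pri = eb.prior_ebb(L, Yw)
        _, v = pri.components[0]
        expected = 1.0 / np.sum(L**2, axis=0)
        expected /= expected.sum()
        assert np.allclose(v, expected, rtol=1e-8)

    def test_ebb_unit_trace(self, small_gain, rng):
        Y = rng.standard_normal((16, 300))
        pri = eb.prior_ebb(small_gain, Y)
        _, v = pri.components[0]
        assert v.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ebb_peaks_near_simulated_source(self, small_mesh, small_gain, rng):
        v_true = 37
        course = rng.standard_normal(400)
        Y = np.outer(small_gain.values[:, v_true], course)
        # high SNR: a trace of sensor noise keeps the covariance full rank
        # (the beamformer power estimate is undefined on a singular one)
        Y += 1e-3 * np.abs(Y).max() * rng.standard_normal(Y.shape)
        pri = eb.prior_ebb(small_gain, Y)
        _, var = pri.components[0]
        peak = int(np.argmax(var))
        from meshbench.meshlib import vertex_adjacency

        nbrs = set(vertex_adjacency(small_mesh)[v_true]) | {v_true}
        assert peak in nbrs

    def test_msp_components_rank1_and_count(self, small_mesh):
        pri = eb.prior_msp(small_mesh, n_patches=32, seed=0)
        assert len(pri) == 32
        assert all(enc == "vec" for enc, _ in pri.components)

    def test_msp_patch_count_capped_with_warning(self, small_mesh):
        with pytest.warns(UserWarning, match="capped"):
            pri = eb.prior_msp(small_mesh, n_patches=10_000, seed=0)
        assert len(pri) == small_mesh.n_vertices

    def test_msp_seeds_quasi_uniform(self):
        mesh = mb.gen_mesh(200, fold_amplitude=0.0, radius=70.0, seed=0)
        n_patches = 16
        seeds = eb._farthest_point_seeds(mesh, n_patches, seed=0)
        assert len(set(seeds.tolist())) == n_patches
        # min pairwise euclidean (lower-bounds geodesic) vs even-tiling scale
        P = mesh.vertices[seeds]
        d = np.linalg.norm(P[:, None] - P[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        even_spacing = np.sqrt(4 * np.pi * 70.0**2 / n_patches)
        assert d.min() >= 0.5 * even_spacing


class TestReml:
    def test_recovers_noise_scale_within_10pct(self, rng):
        C, n = 8, 800
        Y = rng.standard_normal((C, n)) * np.sqrt(2.0)
        res = eb.reml_fit(np.zeros((C, 4)), Y, eb.prior_mmn(4))
        assert res.h_noise == pytest.approx(2.0, rel=0.10)

    def test_objective_trace_nondecreasing(self, small_gain, rng):
        Y = small_gain.values @ rng.standard_normal((small_gain.shape[1], 60))
        Y += 0.1 * rng.standard_normal(Y.shape)
        for pri in (eb.prior_mmn(small_gain.shape[1]),
                    eb.prior_ebb(small_gain, Y)):
            res = eb.reml_fit(small_gain, Y, pri)
            assert np.all(np.diff(res.f_trace) >= -1e-10)

    def test_msp_pruning_keeps_objective_ascending(self, small_mesh, rng):
        G = mb.gain_matrix(small_mesh, mb.gen_sensor_array(16, seed=0))
        pri = eb.prior_msp(small_mesh, n_patches=24, seed=0)
        Y = G.values @ rng.standard_normal((small_mesh.n_vertices, 80))
        res = eb.reml_fit(G, Y, pri)
        assert np.all(np.diff(res.f_trace) >= -1e-10)
        assert res.model_cov.shape == (16, 16)

    def test_fixed_model_free_energy_matches_closed_form(self, rng):
        # the production accuracy path (trace form) vs the independent
        # quadratic-form Gaussian evidence, on a 2-channel toy
        Y = rng.standard_normal((2, 50))
        S1 = np.array([[2.0, 0.3], [0.3, 1.0]])
        S2 = np.array([[1.5, -0.2], [-0.2, 2.5]])
        diff_reml = eb.reml_accuracy(Y, S1) - eb.reml_accuracy(Y, S2)
        diff_exact = eb.gaussian_log_evidence(Y, S1) - eb.gaussian_log_evidence(Y, S2)
        assert diff_reml == pytest.approx(diff_exact, abs=1e-6)

    def test_model_ranking_invariant_to_channel_order(self, small_gain, rng):
        Y = small_gain.values @ rng.standard_normal((small_gain.shape[1], 50))
        Y += 0.5 * rng.standard_normal(Y.shape)
        pri = eb.prior_mmn(small_gain.shape[1])
        f0 = eb.reml_fit(small_gain.values, Y, pri).free_energy
        perm = rng.permutation(Y.shape[0])
        f1 = eb.reml_fit(small_gain.values[perm], Y[perm], pri).free_energy
        assert f1 == pytest.approx(f0, abs=1e-3 * abs(f0))

    def test_hyperparameter_error_shrinks_with_samples(self, rng):
        errs = []
        for n in (100, 10_000):
            Y = rng.standard_normal((6, n)) * np.sqrt(3.0)
            res = eb.reml_fit(np.zeros((6, 2)), Y, eb.prior_mmn(2))
            errs.append(abs(res.h_noise - 3.0))
        assert errs[1] < errs[0]


class TestMapAndPredict:
    def test_zero_data_zero_sources(self, small_gain):
        Y = np.zeros((16, 10))
        pri = eb.prior_mmn(small_gain.shape[1])
        res = eb.reml_fit(small_gain, np.ones((16, 10)), pri)  # fit on dummy
        J = eb.map_sources(res, small_gain, Y)
        assert np.all(J == 0.0)

    def test_mmn_map_matches_minimum_norm_closed_form(self, rng):
        L = rng.standard_normal((4, 6))
        Y = rng.standard_normal((4, 12))
        res = eb.reml_fit(L, Y, eb.prior_mmn(6))
        J = eb.map_sources(res, L, Y)
        hs, hn = res.h_source[0], res.h_noise
        J_ref = hs * L.T @ np.linalg.solve(hs * (L @ L.T) + hn * np.eye(4), Y)
        assert np.allclose(J, J_ref, atol=1e-8)

    def test_ebb_localizes_noiseless_source(self, small_mesh, small_gain, rng):
        v_true = 101
        Y = np.outer(small_gain.values[:, v_true], rng.standard_normal(200))
        Y += 1e-3 * np.abs(Y).max() * rng.standard_normal(Y.shape)
        pri = eb.prior_ebb(small_gain, Y)
        res = eb.reml_fit(small_gain, Y, pri)
        J = eb.map_sources(res, small_gain, Y)
        peak = int(np.argmax(np.sum(J**2, axis=1)))
        from meshbench.meshlib import vertex_adjacency

        nbrs = set(vertex_adjacency(small_mesh)[v_true]) | {v_true}
        assert peak in nbrs

    def test_prediction_linear_in_sources(self, small_gain, rng):
        res = eb.reml_fit(small_gain, rng.standard_normal((16, 20)),
                          eb.prior_mmn(small_gain.shape[1]))
        J = rng.standard_normal((small_gain.shape[1], 8))
        p1 = eb.predict_heldout(res, small_gain.values[:3], J)
        p2 = eb.predict_heldout(res, small_gain.values[:3], 2.0 * J)
        assert np.allclose(p2, 2.0 * p1, rtol=1e-12)
        assert np.all(eb.predict_heldout(res, small_gain.values[:3],
                                         np.zeros_like(J)) == 0.0)

    def test_heldout_channel_predicted_from_noiseless_data(
        self, small_mesh, rng
    ):
        # single stationary source, true mesh and gain, all-but-one channel
        sensors = mb.gen_sensor_array(16, seed=0)
        G = mb.gain_matrix(small_mesh, sensors)
        # a source the held-out sensor (index 15) actually observes
        v_src = int(np.argmax(np.abs(G.values[15])))
        epochs = np.stack(
            [
                np.einsum(
                    "c,s->cs",
                    G.values[:, v_src],
                    rng.standard_normal(50),
                )
                for _ in range(20)
            ]
        )
        epochs += 1e-4 * np.abs(epochs).max() * rng.standard_normal(epochs.shape)
        fit_idx = np.arange(15)
        tm = eb.temporal_reduce(epochs[:, fit_idx, :], R=8)
        pri = eb.prior_ebb(G.values[fit_idx], tm.reduced_data)
        res = eb.reml_fit(G.values[fit_idx], tm.reduced_data, pri)
        J = eb.map_sources(res, G.values[fit_idx], tm.reduced_data)
        pred = eb.predict_heldout(res, G.values[[15]], J, modes=tm.modes)
        # compare within the retained temporal subspace: a temporally white
        # source has variance in all 50 dims, of which R=8 are modelled
        truth = np.einsum("ecs,sr->ecr", epochs[:, [15], :], tm.modes)
        pred_r = np.einsum("ecs,sr->ecr", pred, tm.modes)
        r = np.corrcoef(pred_r.ravel(), truth.ravel())[0, 1]
        assert r > 0.99

    def test_channel_overlap_rejected(self, small_gain, rng):
        res = eb.reml_fit(small_gain, rng.standard_normal((16, 10)),
                          eb.prior_mmn(small_gain.shape[1]))
        with pytest.raises(ValueError, match="overlap"):
            eb.predict_heldout(
                res, small_gain.values[:2], np.zeros((small_gain.shape[1], 4)),
                fit_labels=["a", "b"], heldout_labels=["b", "c"],
            )
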