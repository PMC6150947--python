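"""Preprocessing, PCA reduction, HMM partitioning and epoching."""

import numpy as np
import pytest

import meshbench as mb
from meshbench import statehmm


def _rec(data, fs=250.0):
    return mb.SensorRecording(
        data=np.asarray(data, float), fs=fs,
        labels=[f"c{i}" for i in range(np.asarray(data).shape[0])],
    )


class TestPreprocess:
    def test_notch_rejects_50hz(self):
        t = np.arange(0, 20.0, 1.0 / 1200.0)
        rec = _rec(np.sin(2 * np.pi * 50.0 * t)[None, :], fs=1200.0)
        out = mb.preprocess(rec)
        # measure away from the zero-phase filter's edge transients
        interior = out.data[:, 2 * 250 : -2 * 250]
        assert np.sqrt(np.mean(interior**2)) < 0.05 * np.sqrt(np.mean(rec.data**2))

    def test_passband_preserves_10hz(self):
        t = np.arange(0, 20.0, 1.0 / 1200.0)
        rec = _rec(np.sin(2 * np.pi * 10.0 * t)[None, :], fs=1200.0)
        out = mb.preprocess(rec)
        # compare RMS away from filter edge transients
        sl = slice(1000, -1000)
        rms_in = np.sqrt(np.mean(rec.data[:, 2 * 1200 : -2 * 1200] ** 2))
        rms_out = np.sqrt(np.mean(out.data[:, 2 * 250 : -2 * 250] ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_600s_at_1200hz_gives_150000_samples(self, rng):
        rec = _rec(rng.standard_normal((2, 720_000)), fs=1200.0)
        out = mb.preprocess(rec)
        assert out.n_samples == 150_000
        assert out.fs == 250.0

    def test_low_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            mb.preprocess(_rec(rng.standard_normal((2, 1000)), fs=160.0))


class TestPCA:
    def test_standardized_scores(self, rng):
        # 272-channel data reduced to 40 unit-variance zero-mean components
        mixing = rng.standard_normal((272, 50))
        data = mixing @ rng.standard_normal((50, 3000))
        comps = mb.pca_reduce(_rec(data), n_comp=40)
        assert comps.shape == (40, 3000)
        assert np.allclose(comps.mean(axis=1), 0.0, atol=1e-8)
        assert np.allclose(comps.std(axis=1), 1.0, atol=1e-8)

    def test_rank1_input_yields_single_component(self, rng):
        data = np.outer(rng.standard_normal(8), rng.standard_normal(500))
        with pytest.warns(UserWarning, match="rank"):
            comps = mb.pca_reduce(_rec(data), n_comp=4)
        assert comps.shape[0] == 1

    def test_matches_eigendecomposition_oracle(self, rng):
        data = rng.standard_normal((10, 1000))
        comps = mb.pca_reduce(_rec(data), n_comp=3)
        X = data - data.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(X @ X.T / (X.shape[1] - 1))
        order = np.argsort(evals)[::-1][:3]
        for i, j in enumerate(order):
            ref = evecs[:, j] @ X
            ref = (ref - ref.mean()) / ref.std()
            agreement = abs(np.corrcoef(comps[i], ref)[0, 1])
            assert agreement == pytest.approx(1.0, abs=1e-10)


class TestHMM:
    def test_single_state_path_all_ones(self, rng):
        comps = rng.standard_normal((3, 500))
        _, path = mb.fit_hmm(comps, K=1, seed=0)
        assert np.all(path.states == 1)

    def test_recovers_well_separated_states(self, rng):
        # two states with very different covariance scale, 200 ms dwell at 250 Hz
        T, D = 5000, 4
        truth = np.ones(T, dtype=int)
        state = 1
        t = 0
        while t < T:
            run = int(rng.exponential(50)) + 1
            truth[t : t + run] = state
            state = 3 - state
            t += run
        X = rng.standard_normal((D, T))
        X[:, truth == 2] *= 6.0
        model, path = mb.fit_hmm(X, K=2, seed=0)
        matched = statehmm.match_states(path.states, truth[: len(path.states)], 2)
        acc = np.mean(matched == truth[: len(path.states)])
        assert acc > 0.90

    def test_likelihood_matches_bruteforce_enumeration(self, rng):
        # T=6, K=2: total likelihood equals the sum over all 2^6 paths
        from itertools import product
        from scipy.stats import multivariate_normal

        X = rng.standard_normal((2, 6))
        model, _ = mb.fit_hmm(X, K=2, seed=1, n_restarts=1, max_iter=5)
        ll_model = model.score(X.T)
        total = 0.0
        for states in product(range(2), repeat=6):
            p = model.startprob_[states[0]]
            for a, b in zip(states, states[1:]):
                p *= model.transmat_[a, b]
            for t, s in enumerate(states):
                p *= multivariate_normal.pdf(
                    X[:, t], mean=model.means_[s], cov=model.covars_[s]
                )
            total += p
        assert ll_model == pytest.approx(np.log(total), abs=1e-9)

    def test_seed_deterministic(self, rng):
        X = rng.standard_normal((3, 800))
        _, p1 = mb.fit_hmm(X, K=3, seed=7, n_restarts=2)
        _, p2 = mb.fit_hmm(X, K=3, seed=7, n_restarts=2)
        assert np.array_equal(p1.states, p2.states)


class TestEpoching:
    def test_200ms_at_250hz_is_50_samples(self, rng):
        rec = _rec(rng.standard_normal((4, 1000)), fs=250.0)
        path = statehmm.StatePath(states=np.ones(1000, int), K=1, fs=250.0)
        tagged = mb.epoch_modal(rec, path, epoch_ms=200.0)
        assert all(ep.shape == (4, 50) for ep, _ in tagged)
        assert len(tagged) == 20

    def test_constant_statepath_tags_every_epoch(self, rng):
        rec = _rec(rng.standard_normal((2, 500)), fs=250.0)
        path = statehmm.StatePath(states=np.full(500, 3), K=4, fs=250.0)
        tagged = mb.epoch_modal(rec, path, epoch_ms=200.0)
        assert all(tag == 3 for _, tag in tagged)

    def test_modal_tag_and_tie_rule(self, rng):
        rec = _rec(rng.standard_normal((1, 50)), fs=250.0)
        # 30 samples of state 1 then 20 of state 2 -> tagged 1
        states = np.concatenate([np.ones(30, int), np.full(20, 2)])
        path = statehmm.StatePath(states=states, K=2, fs=250.0)
        assert mb.epoch_modal(rec, path, epoch_ms=200.0)[0][1] == 1
        # 25/25 tie -> lower state index wins
        states = np.concatenate([np.full(25, 2), np.ones(25, int)])
        path = statehmm.StatePath(states=states, K=2, fs=250.0)
        assert mb.epoch_modal(rec, path, epoch_ms=200.0)[0][1] == 1

    def test_epoching_lossless_up_to_trailing_partial(self, rng):
        rec = _rec(rng.standard_normal((3, 1013)), fs=250.0)
        path = statehmm.StatePath(states=np.ones(1013, int), K=1, fs=250.0)
        tagged = mb.epoch_modal(rec, path, epoch_ms=200.0)
        rebuilt = np.concatenate([ep for ep, _ in tagged], axis=1)
        assert np.array_equal(rebuilt, rec.data[:, : rebuilt.shape[1]])
        assert rebuilt.shape[1] == (1013 // 50) * 50

    def test_epoch_longer_than_recording_raises(self, rng):
        rec = _rec(rng.standard_normal((1, 30)), fs=250.0)
        path = statehmm.StatePath(states=np.ones(30, int), K=1, fs=250.0)
        with pytest.raises(ValueError):
            mb.epoch_modal(rec, path, epoch_ms=200.0)


class TestPartitionAndDominance:
    def _tagged(self, rng, tags):
        return [(rng.standard_normal((2, 10)), t) for t in tags]

    def test_epoch_count_conserved(self, rng):
        tags = [1, 2, 2, 3, 1, 2]
        dsets = mb.partition_states(self._tagged(rng, tags), K=4, fs=250.0,
                                    labels=["a", "b"])
        assert sum(d.n_epochs for d in dsets) == len(tags)
        assert dsets[3].n_epochs == 0  # empty state is fine

    def test_815_epochs_of_200ms_is_163s(self):
        assert 815 * 0.200 == pytest.approx(163.0)

    def test_dominant_selects_top_counts(self, rng):
        counts = [10, 40, 30, 20, 5, 1, 2, 3]
        tags = [s + 1 for s, c in enumerate(counts) for _ in range(c)]
        dsets = mb.partition_states(self._tagged(rng, tags), K=8, fs=250.0,
                                    labels=["a", "b"])
        dom = mb.dominant_states(dsets, n=4)
        assert [d.n_epochs for d in dom] == [40, 30, 20, 10]
        assert [d.state_id for d in dom] == [2, 3, 4, 1]

    def test_dominant_ties_prefer_lower_index(self, rng):
        tags = [1, 1, 2, 2, 3, 3]
        dsets = mb.partition_states(self._tagged(rng, tags), K=3, fs=250.0,
                                    labels=["a", "b"])
        dom = mb.dominant_states(dsets, n=2)
        assert [d.state_id for d in dom] == [1, 2]

    def test_dominant_n_equals_k_returns_all(self, rng):
        tags = [1, 2, 3]
        dsets = mb.partition_states(self._tagged(rng, tags), K=3, fs=250.0,
                                    labels=["a", "b"])
        assert len(mb.dominant_states(dsets, n=3)) == 3

    def test_h5_roundtrip(self, rng, tmp_path):
        ds = mb.partition_states(self._tagged(rng, [1, 1]), K=1, fs=250.0,
                                 labels=["a", "b"])[0]
        ds.save_h5(tmp_path / "d.h5")
        back = mb.StateDataset.load_h5(tmp_path / "d.h5")
        assert np.array_equal(back.epochs, ds.epochs)
        assert back.state_id == 1 and back.fs == 250.0


class TestStateSensorMap:
    def test_active_channel_positively_correlated(self, rng):
        T = 2000
        states = np.where(np.arange(T) % 200 < 100, 1, 2)
        data = 0.1 * rng.standard_normal((3, T))
        data[0, states == 1] += 5.0 * rng.standard_normal(int((states == 1).sum()))
        rec = _rec(data, fs=250.0)
        path = statehmm.StatePath(states=states, K=2, fs=250.0)
        corr = mb.state_sensor_map(rec, path, 1)
        assert corr[0] > 0.3
        assert corr[0] > abs(corr[1]) and corr[0] > abs(corr[2])

    def test_unvisited_state_raises(self, rng):
        rec = _rec(rng.standard_normal((2, 100)), fs=250.0)
        path = statehmm.StatePath(states=np.ones(100, int), K=2, fs=250.0)
        with pytest.raises(ValueError):
            mb.state_sensor_map(rec, path, 2)

    def test_matches_bruteforce_pearson(self, rng):
        from scipy.signal import hilbert

        data = rng.standard_normal((4, 600))
        states = rng.integers(1, 3, size=600)
        rec = _rec(data, fs=250.0)
        path = statehmm.StatePath(states=states, K=2, fs=250.0)
        corr = mb.state_sensor_map(rec, path, 1)
        env = np.abs(hilbert(data, axis=1))
        ind = (states == 1).astype(float)
        ref = [np.corrcoef(env[c], ind)[0, 1] for c in range(4)]
        assert np.allclose(corr, ref, atol=1e-10)
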