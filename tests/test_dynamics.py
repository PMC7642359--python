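import numpy as np
import pandas as pd
import pytest

from envnet.dynamics import (
    EnvelopeHMM,
    StatePath,
    concat_pca_prewhiten,
    fit_hmm,
    normalize_subject,
    state_power_maps,
    states_to_binary,
    temporal_metrics,
    viterbi_path,
)
from envnet.simulate import MarkovPlan, sample_state_sequence
from envnet.spectral import EnvelopeSet


def _env(rng, n_ch=4, n=500, fs=40.0):
    return EnvelopeSet(rng.random((n_ch, n)) + 0.5, fs=fs, subject="s")


def _planted_1d(seed=0, T=2000, p_stay=0.95, sep=3.0):
    plan = MarkovPlan(
        np.array([[p_stay, 1 - p_stay], [1 - p_stay, p_stay]]),
        np.array([0.5, 0.5]), np.zeros((2, 1)),
    )
    s = sample_state_sequence(plan, T, seed=seed) - 1
    rng = np.random.default_rng(seed + 1)
    X = (np.where(s == 0, -sep, sep) + rng.standard_normal(T))[:, None]
    return X, s


class TestNormalizeSubject:
    def test_demean_and_pooled_variance(self, rng):
        out = normalize_subject(_env(rng))
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
        assert out.values.std() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        env = _env(rng)
        a = normalize_subject(env).values
        scaled = EnvelopeSet(5.0 * env.values, fs=env.fs)
        b = normalize_subject(scaled).values
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_variance_rejected(self):
        env = EnvelopeSet(np.ones((2, 100)), fs=40.0)
        with pytest.raises(ValueError, match="variance"):
            normalize_subject(env)


class TestConcatPCA:
    def test_lossless_at_full_rank(self, rng):
        envs = [normalize_subject(_env(rng, n_ch=5, n=300)) for _ in range(3)]
        pcs = concat_pca_prewhiten(envs, n_pcs=5)
        X = np.concatenate([e.values.T for e in envs], axis=0)
        Xc = X - X.mean(axis=0, keepdims=True)
        recon = pcs.data @ np.linalg.pinv(pcs.weights)
        assert np.allclose(recon, Xc, atol=1e-8)

    def test_prewhitened_unit_variance(self, rng):
        envs = [normalize_subject(_env(rng, n_ch=6, n=400)) for _ in range(2)]
        pcs = concat_pca_prewhiten(envs, n_pcs=4)
        assert np.allclose(pcs.data.var(axis=0), 1.0, atol=1e-10)

    def test_explained_variance_matches_eigh_oracle(self, rng):
        envs = [normalize_subject(_env(rng, n_ch=6, n=400))]
        pcs = concat_pca_prewhiten(envs, n_pcs=6)
        X = envs[0].values.T
        Xc = X - X.mean(axis=0)
        w = np.linalg.eigvalsh(Xc.T @ Xc / Xc.shape[0])[::-1]
        assert np.allclose(pcs.explained_variance, w[:6], atol=1e-10)

    def test_rank_cap_warns(self, rng, caplog):
        envs = [normalize_subject(_env(rng, n_ch=3, n=200))]
        with caplog.at_level("WARNING"):
            pcs = concat_pca_prewhiten(envs, n_pcs=40)
        assert pcs.n_pcs <= 3
        assert any("capped" in r.message for r in caplog.records)

    def test_split_boundaries(self, rng):
        envs = [normalize_subject(_env(rng, n_ch=4, n=n)) for n in (100, 250)]
        pcs = concat_pca_prewhiten(envs, n_pcs=2)
        parts = pcs.split()
        assert [p.shape[0] for p in parts] == [100, 250]


class TestEnvelopeHMM:
    def test_single_state_moments(self, rng):
        X = rng.standard_normal((500, 2))
        est = EnvelopeHMM(K=1, n_restarts=1, random_state=0).fit(X)
        assert np.allclose(est.means_[0], X.mean(axis=0), atol=1e-6)
        assert np.allclose(est.covars_[0], np.cov(X.T, bias=True), atol=1e-4)

    def test_two_state_recovery(self):
        X, s = _planted_1d()
        est = EnvelopeHMM(K=2, n_restarts=3, random_state=1).fit(X)
        means = np.sort(est.means_.ravel())
        assert np.allclose(means, [-3.0, 3.0], atol=0.2)
        lab = est.predict(X)
        agree = max(np.mean(lab == s), np.mean(lab == 1 - s))
        assert agree >= 0.95

    def test_seed_determinism(self):
        X, _ = _planted_1d()
        a = EnvelopeHMM(K=2, n_restarts=3, random_state=7).fit(X)
        b = EnvelopeHMM(K=2, n_restarts=3, random_state=7).fit(X)
        assert np.array_equal(a.means_, b.means_)
        assert a.selected_restart_ == b.selected_restart_

    def test_selected_restart_is_best(self):
        X, _ = _planted_1d()
        est = EnvelopeHMM(K=2, n_restarts=4, random_state=2).fit(X)
        assert est.restart_scores_[est.selected_restart_] == \
            est.restart_scores_.max()

    def test_sklearn_params_roundtrip(self):
        est = EnvelopeHMM(K=3, tol=0.5)
        params = est.get_params()
        assert params["K"] == 3
        est.set_params(K=5)
        assert est.K == 5

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            EnvelopeHMM().predict(np.zeros((10, 1)))


class TestViterbiPath:
    def test_exclusivity_and_split(self):
        X, _ = _planted_1d(T=1200)
        fit = fit_hmm(X, K=2, n_restarts=2, seed=0)
        paths = viterbi_path(fit, X, lengths=[700, 500], fs_states=40.0)
        assert [p.n_samples for p in paths] == [700, 500]
        for p in paths:
            assert np.all(p.binary.sum(axis=0) == 1)

    def test_planted_agreement(self):
        X, s = _planted_1d(seed=5, T=4000)
        fit = fit_hmm(X, K=2, n_restarts=3, seed=3)
        path = viterbi_path(fit, X, fs_states=40.0)[0]
        lab = np.argmax(path.binary, axis=0)
        agree = max(np.mean(lab == s), np.mean(lab == 1 - s))
        assert agree >= 0.95

    def test_single_state_all_ones(self, rng):
        X = rng.standard_normal((200, 1))
        fit = fit_hmm(X, K=1, n_restarts=1, seed=0)
        path = viterbi_path(fit, X, fs_states=40.0)[0]
        assert np.all(path.binary == 1)


class TestTemporalMetrics:
    def test_hand_counted_example(self):
        x = np.array([0, 0, 1, 1, 1, 0, 1, 0, 0, 0])
        path = StatePath(states_to_binary(x, 2), fs_states=40.0)
        m = temporal_metrics(path).set_index("state")
        assert m.loc[2, "MLT_s"] == pytest.approx(0.050)
        assert m.loc[2, "FO"] == pytest.approx(0.4)
        assert m.loc[2, "MIL_s"] == pytest.approx(0.025)
        assert m.loc[2, "n_visits"] == 2

    def test_always_active_state(self):
        path = StatePath(states_to_binary(np.zeros(50, dtype=int), 2), 40.0)
        m = temporal_metrics(path).set_index("state")
        assert m.loc[1, "FO"] == 1.0
        assert np.isnan(m.loc[1, "MIL_s"])
        assert m.loc[2, "FO"] == 0.0
        assert np.isnan(m.loc[2, "MLT_s"])

    def test_fo_sums_to_one_and_identity(self, rng):
        labels = rng.integers(0, 4, 5000)
        path = StatePath(states_to_binary(labels, 4), fs_states=40.0)
        m = temporal_metrics(path)
        assert m["FO"].sum() == pytest.approx(1.0, abs=1e-12)
        # FO = MLT * n_visits / T exactly, in samples
        T = path.n_samples
        for _, row in m.iterrows():
            if row["n_visits"]:
                assert row["FO"] == pytest.approx(
                    row["MLT_s"] * 40.0 * row["n_visits"] / T, abs=1e-12)

    def test_renewal_identity(self):
        """FO ~ MLT/(MLT+MIL) on long two-state paths with many visits."""
        plan = MarkovPlan(np.array([[0.9, 0.1], [0.05, 0.95]]),
                          np.array([0.5, 0.5]), np.zeros((2, 1)))
        s = sample_state_sequence(plan, 20_000, seed=9) - 1
        path = StatePath(states_to_binary(s, 2), fs_states=40.0)
        m = temporal_metrics(path).set_index("state")
        for k in (1, 2):
            assert m.loc[k, "n_visits"] >= 50
            pred = m.loc[k, "MLT_s"] / (m.loc[k, "MLT_s"] + m.loc[k, "MIL_s"])
            assert abs(pred - m.loc[k, "FO"]) / m.loc[k, "FO"] < 0.05


class TestStatePowerMaps:
    def test_own_indicator_perfect_coupling(self, rng):
        labels = rng.integers(0, 3, 2000)
        path = StatePath(states_to_binary(labels, 3), fs_states=40.0)
        env = path.binary[1].astype(float)[None, :]
        maps = state_power_maps(path, env)
        assert maps[1, 0] == pytest.approx(1.0, abs=1e-8)

    def test_independent_noise_null(self, rng):
        labels = rng.integers(0, 3, 100_000)
        path = StatePath(states_to_binary(labels, 3), fs_states=40.0)
        env = rng.standard_normal((2, 100_000))
        maps = state_power_maps(path, env)
        assert np.all(np.abs(maps) < 0.05)

    def test_planted_modulation_localizes(self, rng):
        """Positive modulation of ROI j in state k gives the largest map entry."""
        labels = rng.integers(0, 3, 50_000)
        base = rng.random((4, 50_000)) + 1.0
        mod = np.ones((4, 50_000))
        mod[2, labels == 1] = 1.5  # ROI 2 active during state 1 (0-based)
        env = base * mod
        path = StatePath(states_to_binary(labels, 3), fs_states=40.0)
        maps = state_power_maps(path, env - env.mean(axis=1, keepdims=True))
        assert maps[1, 2] > 0
        assert maps[1, 2] > max(maps[1, j] for j in (0, 1, 3))

    def test_label_permutation_equivariance(self, rng):
        labels = rng.integers(0, 3, 5000)
        env = rng.random((3, 5000))
        path = StatePath(states_to_binary(labels, 3), fs_states=40.0)
        perm = np.array([2, 0, 1])
        relabeled = StatePath(path.binary[perm], fs_states=40.0)
        m1 = state_power_maps(path, env)
        m2 = state_power_maps(relabeled, env)
        assert np.allclose(m2, m1[perm], atol=1e-10)
        t1 = temporal_metrics(path).set_index("state")
        t2 = temporal_metrics(relabeled).set_index("state")
        for new_k, old_k in enumerate(perm):
            assert t2.loc[new_k + 1, "FO"] == t1.loc[old_k + 1, "FO"]

    def test_never_active_state_missing(self, rng):
        labels = rng.integers(0, 2, 1000)  # state 3 never active
        b = np.zeros((3, 1000), dtype=np.int8)
        b[labels, np.arange(1000)] = 1
        path = StatePath(b, fs_states=40.0)
        maps = state_power_maps(path, rng.random((2, 1000)))
        assert np.all(np.isnan(maps[2]))
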