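import numpy as np
import pandas as pd
import pytest

from envnet.connectome import (
    ConnectomeMatrix,
    build_connectome,
    envelope_correlation_pair,
    node_power,
    orthogonalize_pair,
    regress_confounds,
    summarize_connectome,
    uncorrected_envelope_correlation,
    PowerVector,
)
from envnet.bands import BANDS
from envnet.simulate import (
    Recording,
    apply_mixing,
    synth_envelopes,
    synth_recording,
)
from envnet.spectral import analytic, bandpass

FS = 250.0


def _analytic_noise(rng, dur=60.0, n=1, band="alpha"):
    x = bandpass(rng.standard_normal((n, int(dur * FS))), FS, band)
    return analytic(x, FS)


class TestOrthogonalize:
    def test_self_orthogonalization_zero(self, rng):
        z = _analytic_noise(rng)[0]
        assert np.allclose(orthogonalize_pair(z, z), 0.0, atol=1e-10)

    def test_quadrature_passes(self, rng):
        z = _analytic_noise(rng)[0]
        assert np.allclose(orthogonalize_pair(z, 1j * z), np.abs(z), atol=1e-10)

    def test_direct_evaluation(self):
        x = np.array([1, 1j, 1 + 1j, 2])
        y = np.array([1j, 1, 1, 1j])
        expected = [1.0, -1.0, -1.0 / np.sqrt(2), 1.0]
        assert np.allclose(orthogonalize_pair(x, y), expected, atol=1e-5)

    def test_linear_in_y(self, rng):
        x, y1, y2 = (_analytic_noise(rng, dur=10.0)[0] for _ in range(3))
        lhs = orthogonalize_pair(x, 2.0 * y1 + 3.0 * y2)
        rhs = 2.0 * orthogonalize_pair(x, y1) + 3.0 * orthogonalize_pair(x, y2)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_zero_magnitude_handled(self):
        x = np.array([0.0 + 0j, 1.0, 1j])
        y = np.array([1.0 + 0j, 1j, 1.0])
        out = orthogonalize_pair(x, y)
        assert out[0] == 0.0


class TestEnvelopeCorrelationPair:
    def test_collinear_returns_zero(self, rng):
        z = _analytic_noise(rng)[0]
        assert envelope_correlation_pair(z, 2.0 * z, FS) == 0.0

    def test_independent_sources_null(self, rng):
        z = _analytic_noise(rng, dur=300.0, n=2)
        assert abs(envelope_correlation_pair(z[0], z[1], FS)) < 0.05

    def test_monotone_recovery(self):
        """Recovered r grows with the planted envelope correlation."""
        recovered = []
        for target in (0.2, 0.8):
            c = np.eye(2)
            c[0, 1] = c[1, 0] = target
            env = synth_envelopes(
                c, np.ones(int(300 * FS), dtype=int), np.zeros((1, 2)), FS, seed=5
            )
            rec = synth_recording(env, "alpha", FS, seed=6)
            z = analytic(bandpass(rec.data, FS, "alpha"), FS)
            recovered.append(envelope_correlation_pair(z[0], z[1], FS))
        assert recovered[1] > recovered[0] > 0.05

    def test_too_short_rejected(self, rng):
        z = _analytic_noise(rng, dur=5.0, n=2)
        with pytest.raises(ValueError, match="10 s"):
            envelope_correlation_pair(z[0], z[1], FS)


def test_leakage_nulling_single_seed():
    """Mixed independent narrowband sources: raw envelope correlation is
    inflated, orthogonalized correlation is nulled."""
    rng = np.random.default_rng(0)
    rec = synth_recording(np.ones((2, int(300 * FS))), "alpha", FS, seed=0)
    mixed = apply_mixing(rec, np.array([[1.0, 0.3], [0.3, 1.0]]))
    z = analytic(bandpass(mixed.data, FS, "alpha"), FS)
    assert uncorrected_envelope_correlation(z[0], z[1], FS) > 0.2
    assert abs(envelope_correlation_pair(z[0], z[1], FS)) < 0.05


@pytest.fixture(scope="module")
def conn(parc):
    rng = np.random.default_rng(1)
    rec = Recording(rng.standard_normal((32, int(20 * FS))), fs=FS,
                    subject="s1")
    return build_connectome(rec, "alpha", parc), rec


class TestBuildConnectome:

    def test_structure(self, conn, parc):
        c, _ = conn
        assert c.values.shape == (32, 32)
        assert np.array_equal(c.values, c.values.T)
        assert np.all(np.diag(c.values) == 0)
        assert len(c.upper_triangle()) == 496

    def test_permutation_equivariance(self, conn, parc):
        c, rec = conn
        perm = np.random.default_rng(2).permutation(32)
        rec_p = Recording(rec.data[perm], fs=FS, subject="s1")
        c_p = build_connectome(rec_p, "alpha", parc)
        assert np.allclose(c_p.values, c.values[np.ix_(perm, perm)], atol=1e-10)

    def test_channel_mismatch_rejected(self, parc):
        rec = Recording(np.zeros((5, int(20 * FS))), fs=FS)
        with pytest.raises(ValueError, match="channels"):
            build_connectome(rec, "alpha", parc)


class TestNodePower:
    def test_unit_variance_carrier(self):
        # re-filtering an already band-limited signal trims its band-edge
        # power (squared transition response), so ~0.9 is the expected level
        rec = synth_recording(np.ones((2, int(30 * FS))), "alpha", FS, seed=1)
        p = node_power(rec, "alpha")
        assert np.allclose(p.values, 1.0, rtol=0.15)

    def test_quadratic_scaling(self):
        rec = synth_recording(np.ones((1, int(30 * FS))), "alpha", FS, seed=2)
        p1 = node_power(rec, "alpha").values
        rec3 = Recording(3.0 * rec.data, fs=FS)
        assert np.allclose(node_power(rec3, "alpha").values, 9.0 * p1, rtol=1e-10)

    def test_cross_band_rejection(self):
        rec = synth_recording(np.ones((1, int(30 * FS))), "alpha", FS, seed=3)
        theta = node_power(rec, "theta").values[0]
        alpha = node_power(rec, "alpha").values[0]
        assert theta < 0.05 * alpha


class TestSummarize:
    def _constant_conn(self, parc, c=0.3):
        v = np.full((32, 32), c)
        np.fill_diagonal(v, 0.0)
        return ConnectomeMatrix(v, band=BANDS["alpha"], subject="s")

    def test_constant_matrix_means(self, parc):
        conn = self._constant_conn(parc)
        power = PowerVector(np.ones(32), band=BANDS["alpha"], subject="s")
        table = summarize_connectome(conn, power, parc)
        assert np.allclose(table["connectivity"], 0.3, atol=1e-12)
        assert np.allclose(table["power"], 1.0, atol=1e-12)

    def test_pvis_is_single_entry(self, parc, rng):
        v = rng.uniform(-0.5, 0.5, (32, 32))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        conn = ConnectomeMatrix(v, band=BANDS["alpha"], subject="s")
        power = PowerVector(np.ones(32), band=BANDS["alpha"], subject="s")
        table = summarize_connectome(conn, power, parc).set_index("scope")
        i, j = parc.network_indices("pVIS")
        assert table.loc["pVIS", "connectivity"] == pytest.approx(v[i, j], abs=1e-15)

    def test_summaries_recomputable(self, parc, rng):
        """Global summary equals an independent mean over the matrix."""
        v = rng.uniform(-0.5, 0.5, (32, 32))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        conn = ConnectomeMatrix(v, band=BANDS["alpha"], subject="s")
        power = PowerVector(rng.uniform(0, 2, 32), band=BANDS["alpha"], subject="s")
        table = summarize_connectome(conn, power, parc).set_index("scope")
        iu = np.triu_indices(32, k=1)
        assert table.loc["global", "connectivity"] == pytest.approx(
            v[iu].mean(), abs=1e-12)
        assert table.loc["global", "power"] == pytest.approx(
            power.values.mean(), abs=1e-12)


class TestRegressConfounds:
    def test_orthogonal_covariate_no_change(self, rng):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        x = y - y.mean()
        cov = pd.DataFrame({"c": np.array([1, -1, 0, 0, -1, 1]) * 0.0 +
                            np.array([1, -1, 1, -1, 1, -1])})
        # make covariate exactly uncorrelated with y
        c = cov["c"] - np.dot(cov["c"], x) / np.dot(x, x) * x
        out = regress_confounds(y[:, None], pd.DataFrame({"c": c}))
        assert np.allclose(out[:, 0], y, atol=1e-10)

    def test_perfect_fit_leaves_intercept(self, rng):
        c = rng.standard_normal(20)
        y = 5.0 + 2.0 * c
        out = regress_confounds(y[:, None], pd.DataFrame({"c": c}))
        assert np.allclose(out[:, 0], 5.0, atol=1e-10)

    def test_group_effect_preserved(self, rng):
        """Power dependence removed, planted group offset retained."""
        n = 60
        group = np.repeat([0.0, 1.0], n // 2)
        power = rng.standard_normal(n)
        y = 2.0 * power + 1.0 * group + 0.1 * rng.standard_normal(n)
        out = regress_confounds(
            y[:, None], pd.DataFrame({"power": power}))[:, 0]
        assert abs(np.corrcoef(out, power)[0, 1]) < 1e-8
        diff = out[group == 1].mean() - out[group == 0].mean()
        assert abs(diff - 1.0) / 1.0 < 0.1

    def test_categorical_encoding(self, rng):
        y = rng.standard_normal((10, 2))
        cov = pd.DataFrame({"sex": ["F", "M"] * 5})
        out = regress_confounds(pd.DataFrame(y), cov)
        assert out.shape == (10, 2)

    def test_rank_deficiency_named(self, rng):
        y = rng.standard_normal((10, 1))
        c = rng.standard_normal(10)
        cov = pd.DataFrame({"a": c, "b": 2 * c})
        with pytest.raises(ValueError, match="collinear.*b"):
            regress_confounds(y, cov)

    def test_too_few_subjects_rejected(self, rng):
        cov = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="subjects"):
            regress_confounds(np.ones((3, 1)), cov)
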