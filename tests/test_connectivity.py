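"""Instantaneous phase, PLV, surrogate thresholds and binarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wkpnet import connectivity as conn
from wkpnet.containers import MultichannelEpoch
from wkpnet.spectral import BANDS
from wkpnet.synth import OscillatorSpec, generate_epoch


def sine(freq, rate=500.0, seconds=10.0, phase=0.0):
    t = np.arange(int(rate * seconds)) / rate
    return np.cos(2 * np.pi * freq * t + phase)


class TestAnalyticPhase:
    def test_cosine_phase_advances_at_carrier_rate(self):
        rate = 500.0
        phi = conn.analytic_phase(sine(10.0, rate=rate))
        interior = np.unwrap(phi)[500:-500]
        slope = np.polyfit(np.arange(interior.size) / rate, interior, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10, rel=0.01)

    def test_quadrature_offset(self):
        rate = 500.0
        t = np.arange(5000) / rate
        pc = conn.analytic_phase(np.cos(2 * np.pi * 10 * t))
        ps = conn.analytic_phase(np.sin(2 * np.pi * 10 * t))
        diff = np.angle(np.exp(1j * (pc - ps)))[500:-500]
        np.testing.assert_allclose(diff, np.pi / 2, atol=0.01)

    def test_sign_flip_shifts_phase_by_pi(self):
        x = sine(10.0)
        d = np.angle(np.exp(1j * (conn.analytic_phase(-x)
                                  - conn.analytic_phase(x))))[500:-500]
        np.testing.assert_allclose(np.abs(d), np.pi, atol=0.01)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            conn.analytic_phase(np.ones(1000))


class TestPlvPair:
    def test_identical_signals_give_exactly_one(self):
        x = sine(10.0)
        assert conn.plv_pair(x, x) == 1.0

    def test_constant_lag_gives_one(self):
        assert conn.plv_pair(sine(10.0), sine(10.0, phase=1.2),
                             rate=500.0) == pytest.approx(1.0, abs=1e-3)

    def test_symmetry_exact(self, coupled_pair_epoch):
        x1, x2 = coupled_pair_epoch.data.T
        assert conn.plv_pair(x1, x2) == conn.plv_pair(x2, x1)

    def test_amplitude_scale_invariance(self, coupled_pair_epoch):
        x1, x2 = coupled_pair_epoch.data.T
        a = conn.plv_pair(x1, x2, rate=500.0)
        b = conn.plv_pair(10.0 * x1, x2, rate=500.0)
        assert abs(a - b) < 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conn.plv_pair(sine(10.0), sine(10.0)[:-1])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.floats(min_value=-np.pi, max_value=np.pi))
    def test_phase_plv_bounded_and_offset_invariant(self, seed, offset):
        """PLV of any phase pair lies in [0, 1] and is unchanged by a
        common constant phase offset of one series."""
        rng = np.random.default_rng(seed)
        p1, p2 = rng.uniform(-np.pi, np.pi, (2, 500))
        v = conn.plv_from_phases(p1, p2)
        assert 0.0 <= v <= 1.0
        assert conn.plv_from_phases(p1 + offset, p2 + offset) == (
            pytest.approx(v, abs=1e-12))

    def test_uniform_phase_null_floor(self):
        """i.i.d. uniform phase differences: E[PLV] ~ sqrt(pi)/(2 sqrt(N))."""
        rng = np.random.default_rng(0)
        n = 5000
        vals = [conn.plv_from_phases(rng.uniform(-np.pi, np.pi, n),
                                     np.zeros(n)) for _ in range(200)]
        target = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert np.mean(vals) == pytest.approx(target, rel=0.10)


class TestPlvMatrix:
    def test_identical_channels_give_all_ones(self):
        x = sine(10.0)
        ep = MultichannelEpoch(np.column_stack([x, x, x]), 500.0,
                               ("A", "B", "C"))
        m = conn.plv_matrix(ep)
        np.testing.assert_allclose(m.values, 1.0, atol=1e-12)

    def test_matrix_invariants(self, coupled_pair_epoch):
        m = conn.plv_matrix(coupled_pair_epoch, BANDS["theta"])
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert (m.values >= 0).all() and (m.values <= 1).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((2000, 4))
        ep = MultichannelEpoch(data, 500.0, ("A", "B", "C", "D"))
        perm = [2, 0, 3, 1]
        ep_p = MultichannelEpoch(data[:, perm], 500.0,
                                 tuple(ep.channels[i] for i in perm))
        m = conn.plv_matrix(ep).values
        m_p = conn.plv_matrix(ep_p).values
        np.testing.assert_allclose(m[np.ix_(perm, perm)], m_p, atol=1e-12)

    def test_matches_pairwise_calls(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3000, 4))
        ep = MultichannelEpoch(data, 500.0, ("A", "B", "C", "D"))
        m = conn.plv_matrix(ep, BANDS["alpha"]).values
        from wkpnet.spectral import band_filter
        filt = band_filter(ep, BANDS["alpha"])
        for i in range(4):
            for j in range(i + 1, 4):
                expected = conn.plv_pair(filt.data[:, i], filt.data[:, j],
                                         rate=500.0)
                assert m[i, j] == pytest.approx(expected, abs=1e-9)

    def test_single_channel_rejected(self):
        ep = MultichannelEpoch(sine(10.0)[:, None], 500.0, ("A",))
        with pytest.raises(ValueError):
            conn.plv_matrix(ep)


@pytest.fixture(scope="module")
def uncoupled_epoch():
    spec = OscillatorSpec(band_center=5.0, band_width=4.0,
                          phase_jitter_sigma=0.0,
                          amplitude_noise_sigma=0.0,
                          channels=tuple(f"X{i}" for i in range(8)))
    return generate_epoch(spec, seed=5)


class TestSurrogateThreshold:
    def test_coupled_pair_always_exceeds_threshold(self, coupled_pair_epoch):
        thr = conn.surrogate_threshold([coupled_pair_epoch],
                                       BANDS["theta"], seed=0)
        m = conn.plv_matrix(coupled_pair_epoch, BANDS["theta"])
        assert m.values[0, 1] > thr.threshold

    def test_threshold_decreases_with_alpha_level(self, uncoupled_epoch):
        t_loose = conn.surrogate_threshold([uncoupled_epoch], None,
                                           alpha=0.5, seed=1).threshold
        t_strict = conn.surrogate_threshold([uncoupled_epoch], None,
                                            alpha=0.01, seed=1).threshold
        assert t_loose < t_strict

    def test_deterministic_given_seed(self, uncoupled_epoch):
        t1 = conn.surrogate_threshold([uncoupled_epoch], None, seed=9)
        t2 = conn.surrogate_threshold([uncoupled_epoch], None, seed=9)
        assert t1.threshold == t2.threshold

    def test_too_few_surrogates_rejected(self, uncoupled_epoch):
        with pytest.raises(ValueError):
            conn.surrogate_threshold([uncoupled_epoch], None,
                                     n_surrogates=10)

    def test_short_epoch_rejected(self):
        ep = MultichannelEpoch(np.random.default_rng(0).standard_normal(
            (500, 2)), 500.0, ("A", "B"))
        with pytest.raises(ValueError):
            conn.surrogate_threshold([ep], None)


class TestBinarize:
    def plv_of(self, epoch):
        return conn.plv_matrix(epoch, BANDS["theta"])

    def thr(self, t, band="theta"):
        return conn.ThresholdSpec(band=band, threshold=t, n_surrogates=19)

    def test_threshold_one_gives_empty_network(self, coupled_pair_epoch):
        net = conn.binarize(self.plv_of(coupled_pair_epoch), self.thr(1.0))
        assert net.n_edges == 0

    def test_threshold_zero_gives_complete_network(self, coupled_pair_epoch):
        net = conn.binarize(self.plv_of(coupled_pair_epoch), self.thr(0.0))
        n = net.n_nodes
        assert net.n_edges == n * (n - 1) // 2
        assert np.diag(net.adjacency).sum() == 0

    def test_band_mismatch_rejected(self, coupled_pair_epoch):
        with pytest.raises(ValueError):
            conn.binarize(self.plv_of(coupled_pair_epoch),
                          self.thr(0.5, band="beta"))

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((3000, 6))
        ep = MultichannelEpoch(data, 500.0, tuple("ABCDEF"))
        plv = conn.plv_matrix(ep)
        counts = [conn.binarize(plv, self.thr(t, band="broadband")).n_edges
                  for t in np.linspace(0, 1, 51)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
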