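import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from nanodmr.slm import (SLMParams, eta, truncated_gaussian_logpdf,
                         state_grid, estimate_params, viterbi_path,
                         viterbi_segment)
from conftest import make_track, brute_force_viterbi


class TestEta:
    @pytest.mark.parametrize("theta", [0.01, 0.1, 0.3, 0.49])
    def test_limits_and_midpoint(self, theta):
        d_norm = 1000.0
        assert eta(1e-12, theta, d_norm) == pytest.approx(theta / 2, abs=1e-12)
        assert eta(1e15, theta, d_norm) == pytest.approx((1 - theta) / 2,
                                                         abs=1e-9)
        assert eta(d_norm, theta, d_norm) == pytest.approx(
            theta - theta ** 2, abs=1e-12)

    @pytest.mark.parametrize("theta", [0.01, 0.1, 0.3, 0.49])
    def test_monotone_and_bounded(self, theta):
        d = np.logspace(-3, 8, 400)
        vals = eta(d, theta, 500.0)
        assert np.all(np.diff(vals) >= 0)
        assert np.all(vals > theta / 2 - 1e-15)
        assert np.all(vals < (1 - theta) / 2 + 1e-15)

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            eta(100.0, 0.6, 1000.0)
        with pytest.raises(ValueError):
            eta(100.0, 0.0, 1000.0)


class TestTruncatedGaussian:
    def test_flat_limit(self):
        # huge sigma: truncation dominates, density ~ uniform = 1/2
        x = np.linspace(-1, 1, 9)
        assert np.allclose(np.exp(truncated_gaussian_logpdf(x, 0.0, 100.0)),
                           0.5, atol=1e-3)

    def test_closed_form_value(self):
        # m=0, sigma=0.1: phi(0)/(0.1 * (Phi(10)-Phi(-10))) = 3.98942...
        assert truncated_gaussian_logpdf(0.0, 0.0, 0.1) == pytest.approx(
            np.log(3.9894228), abs=1e-6)

    @pytest.mark.parametrize("m,sigma", [(0.3, 0.2), (-0.9, 0.05), (0.0, 1.5)])
    def test_normalizes_on_support(self, m, sigma):
        val, _ = quad(lambda x: np.exp(truncated_gaussian_logpdf(x, m, sigma)),
                      -1, 1)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            truncated_gaussian_logpdf(1.5, 0.0, 0.1)


class TestEstimateParams:
    def test_white_noise_recovery(self, rng):
        x = np.clip(rng.normal(0, 0.1, 10_000), -1, 1)
        p = estimate_params(make_track(x))
        assert 0.09 <= p.sigma_eps <= 0.11

    def test_constant_track_floored(self):
        with pytest.warns(RuntimeWarning):
            p = estimate_params(make_track(np.zeros(100)))
        assert p.sigma_eps == pytest.approx(1e-3)

    def test_robust_to_single_jump(self, rng):
        # naive s.d. of a two-level track overestimates; lag-1 MAD does not
        x = np.concatenate([rng.normal(0, 0.05, 500),
                            rng.normal(0.6, 0.05, 500)])
        p = estimate_params(make_track(np.clip(x, -1, 1)))
        assert p.sigma_eps == pytest.approx(0.05, rel=0.15)
        assert np.std(x) > 2 * p.sigma_eps

    def test_sigma_mu_ratio(self, rng):
        x = np.clip(rng.normal(0, 0.1, 1000), -1, 1)
        p = estimate_params(make_track(x), omega=0.9)
        assert p.sigma_mu == pytest.approx(3.0 * p.sigma_eps)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            estimate_params(make_track(np.zeros(5)))


class TestViterbi:
    def test_all_zero_single_segment(self):
        tr = make_track(np.zeros(30))
        seg = viterbi_segment(tr, SLMParams())
        assert len(seg.segments) == 1
        assert seg.segments[0].level == 0.0
        assert seg.segments[0].n_cpg_groups == 30

    def test_two_block_recovery(self, rng):
        x = np.clip(np.concatenate([rng.normal(0, 0.05, 20),
                                    rng.normal(0.6, 0.05, 20)]), -1, 1)
        seg = viterbi_segment(make_track(x),
                              SLMParams(sigma_eps=0.05, sigma_mu=0.3))
        assert len(seg.segments) == 2
        assert abs(seg.segments[1].first_index - 20) <= 1

    def test_segments_partition_track(self, rng):
        x = np.clip(rng.normal(0, 0.3, 200), -1, 1)
        seg = viterbi_segment(make_track(x), SLMParams())
        idx = [i for s in seg.segments
               for i in range(s.first_index, s.last_index + 1)]
        assert idx == list(range(200))
        for a, b in zip(seg.segments, seg.segments[1:]):
            assert a.level != b.level

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force(self, data):
        n = data.draw(st.integers(2, 8))
        k = data.draw(st.sampled_from([3, 5]))
        x = np.array(data.draw(st.lists(
            st.floats(-1, 1, allow_nan=False), min_size=n, max_size=n)))
        d = np.array(data.draw(st.lists(
            st.floats(1, 50_000, allow_nan=False), min_size=n - 1,
            max_size=n - 1)))
        params = SLMParams(
            theta=data.draw(st.floats(0.02, 0.45)),
            d_norm=data.draw(st.floats(50, 5000)),
            sigma_eps=data.draw(st.floats(0.05, 0.5)),
            sigma_mu=data.draw(st.floats(0.1, 0.6)),
            n_states=k)
        assert np.array_equal(viterbi_path(x, d, params),
                              brute_force_viterbi(x, d, params))

    def test_distance_rescaling_invariance(self, rng):
        x = np.clip(rng.normal(0.2, 0.1, 50), -1, 1)
        pos = np.cumsum(rng.integers(10, 2000, 50))
        tr1 = make_track(x, positions=pos)
        tr2 = make_track(x, positions=pos * 10)
        p1 = SLMParams(d_norm=1000.0)
        p2 = SLMParams(d_norm=10_000.0)
        assert np.array_equal(viterbi_path(tr1.delta_beta, tr1.distances, p1),
                              viterbi_path(tr2.delta_beta, tr2.distances, p2))

    def test_large_gap_never_removes_breakpoint(self, rng):
        """A 100 kb gap at a level change keeps any breakpoint found at
        100 bp spacing (jumps get easier with distance, never harder)."""
        for trial in range(20):
            r = np.random.default_rng(trial)
            x = np.clip(np.concatenate([r.normal(0, 0.1, 15),
                                        r.normal(0.5, 0.1, 15)]), -1, 1)
            params = SLMParams()
            pos_small = np.arange(30) * 100 + 1
            pos_big = pos_small.copy()
            pos_big[15:] += 100_000
            path_small = viterbi_path(x, np.diff(pos_small).astype(float),
                                      params)
            path_big = viterbi_path(x, np.diff(pos_big).astype(float), params)
            if path_small[15] != path_small[14]:
                assert path_big[15] != path_big[14]

    def test_transition_rows_normalize(self):
        """Stay + jump probabilities leave every state with total mass 1."""
        from nanodmr.slm import _log_jump_kernel
        levels = state_grid(41)
        logJ = _log_jump_kernel(levels, 0.3)
        for d in (10.0, 1000.0, 1e6):
            e = eta(d, 0.1, 1000.0)
            rows = (1 - e) + e * np.exp(logJ).sum(axis=1)
            assert np.allclose(rows, 1.0, atol=1e-12)

    def test_parameter_recovery_generative(self):
        """Segment counts on tracks simulated from the model itself stay
        within ±20% of the planted count over replicates."""
        planted, recovered = 0, 0
        for s in range(100):
            r = np.random.default_rng(s)
            n_seg = int(r.integers(2, 6))
            lengths = r.integers(15, 40, n_seg)
            levels = [0.0]
            for _ in range(n_seg - 1):
                nxt = levels[-1] + r.normal(0, 0.3)
                levels.append(float(np.clip(nxt, -0.9, 0.9)))
            x = np.concatenate([np.clip(r.normal(m, 0.1, L), -1, 1)
                                for m, L in zip(levels, lengths)])
            seg = viterbi_segment(make_track(x),
                                  SLMParams(sigma_eps=0.1, sigma_mu=0.3))
            planted += n_seg
            recovered += len(seg.segments)
        assert 0.8 * planted <= recovered <= 1.2 * planted


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SLMParams(theta=0.7)
    with pytest.raises(ValueError):
        SLMParams(n_states=40)
    with pytest.raises(ValueError):
        SLMParams(sigma_eps=0.0)
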