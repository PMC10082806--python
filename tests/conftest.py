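import numpy as np
import pytest

from nanodmr.io import DeltaBetaTrack
from nanodmr.slm import (SLMParams, state_grid, truncated_gaussian_logpdf,
                         eta, _log_init, _log_jump_kernel)


def make_track(delta_beta, positions=None, chrom="chr1", num_motifs=None):
    """Build a DeltaBetaTrack from a Δβ array (β arrays chosen consistently)."""
    x = np.asarray(delta_beta, dtype=np.float64)
    n = len(x)
    if positions is None:
        positions = np.arange(n, dtype=np.int64) * 100 + 1
    positions = np.asarray(positions, dtype=np.int64)
    beta_test = (x + 1.0) / 2.0
    beta_control = (1.0 - x) / 2.0
    return DeltaBetaTrack(
        chrom=chrom, positions=positions, ends=positions + 2,
        num_motifs=(np.ones(n, dtype=np.int64) if num_motifs is None
                    else np.asarray(num_motifs)),
        beta_test=beta_test, beta_control=beta_control,
        delta_beta=beta_test - beta_control)


def brute_force_viterbi(x, distances, params: SLMParams) -> np.ndarray:
    """Exhaustive MAP path over all n_states**n paths (independent oracle).

    Scores every path directly from the model definition (initial stationary
    weights, distance-dependent stay/jump probabilities, truncated-Gaussian
    emissions) without any dynamic programming.
    """
    levels = state_grid(params.n_states)
    K, n = params.n_states, len(x)
    emit = np.atleast_2d(truncated_gaussian_logpdf(
        np.asarray(x)[:, None], levels[None, :], params.sigma_eps))
    logJ = _log_jump_kernel(levels, params.sigma_mu)
    init = _log_init(levels, params.sigma_mu)
    paths = np.indices((K,) * n).reshape(n, -1).T.astype(np.int64)
    lp = init[paths[:, 0]] + emit[0, paths[:, 0]]
    for i in range(1, n):
        e = eta(distances[i - 1], params.theta, params.d_norm)
        same = paths[:, i] == paths[:, i - 1]
        lp = lp + np.where(same, np.log1p(-e),
                           np.log(e) + logJ[paths[:, i - 1], paths[:, i]])
        lp = lp + emit[i, paths[:, i]]
    return paths[int(np.argmax(lp))]


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
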