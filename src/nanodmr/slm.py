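"""Heterogeneous truncated-Gaussian shifting-level model (HTGSLM).

A shifting-level model treats the observed Δβ sequence as the sum of two
independent processes, Δβ_i = m_i + ε_i: an unobserved piecewise-constant
mean level m_i and truncated-Gaussian white noise ε_i ~ N(0, σ_ε²) bounded
to [−1, 1] (the range of Δβ).  The level persists for geometrically
distributed stretches; when it jumps it moves by a Gaussian increment
δ_i ~ N(0, σ_μ²).  The model is *heterogeneous* because the jump probability
η depends on the genomic distance d between consecutive CpG groups:

    η(d) = θ/2 + (1/2 − θ) · exp[ log(θ) / (d / d_Norm) ]

η rises monotonically from θ/2 (adjacent CpGs, e.g. inside a CpG island)
towards (1 − θ)/2 (distant CpGs), so sparse-CpG stretches are allowed to
change level more readily than dense islands.

Decoding runs the Viterbi algorithm over a finite, symmetric grid of
candidate mean levels on [−1, 1].  Parameter estimation is two-step: the
noise s.d. σ_ε is estimated robustly from lag-1 differences of the track,
σ_μ is tied to it through a variance-ratio parameter ω, and the decoded
state path is then merged into constant-level segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .io import DeltaBetaTrack

__all__ = [
    "SLMParams",
    "Segment",
    "Segmentation",
    "eta",
    "truncated_gaussian_logpdf",
    "state_grid",
    "estimate_params",
    "viterbi_path",
    "viterbi_segment",
]

SIGMA_FLOOR = 1e-3


@dataclass(frozen=True)
class SLMParams:
    """Parameters of the heterogeneous truncated-Gaussian SLM.

    theta
        Baseline jump parameter θ ∈ (0, 0.5); sets both limits of η(d).
    d_norm
        Distance scale d_Norm in bp at which η(d_Norm) = θ − θ².
    sigma_eps
        Noise standard deviation σ_ε of the truncated-Gaussian emissions.
    sigma_mu
        Standard deviation σ_μ of the level-jump increments.
    n_states
        Size of the symmetric mean-level grid on [−1, 1]; odd so that the
        grid contains 0.
    """

    theta: float = 0.1
    d_norm: float = 1000.0
    sigma_eps: float = 0.1
    sigma_mu: float = 0.3
    n_states: int = 41

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 0.5:
            raise ValueError("theta must lie in (0, 0.5)")
        if self.d_norm <= 0:
            raise ValueError("d_norm must be positive")
        if self.sigma_eps <= 0 or self.sigma_mu <= 0:
            raise ValueError("sigma_eps and sigma_mu must be positive")
        if self.n_states < 3 or self.n_states % 2 == 0:
            raise ValueError("n_states must be odd and >= 3")


def eta(d, theta: float, d_norm: float):
    """Distance-dependent jump probability η(d).

    Monotone non-decreasing in d, with limits η(0⁺) = θ/2 and
    η(∞) = (1 − θ)/2; at d = d_Norm, η = θ − θ².
    """
    if not 0.0 < theta < 0.5:
        raise ValueError("theta must lie in (0, 0.5)")
    if d_norm <= 0:
        raise ValueError("d_norm must be positive")
    d = np.asarray(d, dtype=np.float64)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    out = 0.5 * theta + (0.5 - theta) * np.exp(np.log(theta) * d_norm / d)
    return float(out) if out.ndim == 0 else out


def truncated_gaussian_logpdf(x, m, sigma: float):
    """Log-density of N(m, σ²) truncated to [−1, 1], evaluated at x."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < -1.0) or np.any(x > 1.0):
        raise ValueError("x outside [-1, 1]")
    m = np.asarray(m, dtype=np.float64)
    a = (-1.0 - m) / sigma
    b = (1.0 - m) / sigma
    out = truncnorm.logpdf(x, a, b, loc=m, scale=sigma)
    return float(out) if np.ndim(out) == 0 else out


def state_grid(n_states: int = 41) -> np.ndarray:
    """Symmetric grid of candidate mean levels on [−1, 1] containing 0."""
    if n_states < 3 or n_states % 2 == 0:
        raise ValueError("n_states must be odd and >= 3")
    return np.linspace(-1.0, 1.0, n_states)


def estimate_params(track: DeltaBetaTrack, omega: float = 0.9,
                    theta: float = 0.1, d_norm: float = 1000.0,
                    n_states: int = 41) -> SLMParams:
    """Estimate σ_ε and σ_μ from a Δβ track; θ and d_Norm come from config.

    σ_ε is the robust scale of the lag-1 differences: successive differences
    of a piecewise-constant-plus-noise track are noise-dominated except at
    the (rare) level changes, so the normalized median absolute deviation of
    the differences divided by √2 recovers the noise s.d. while staying
    insensitive to jumps.  σ_μ² = ω/(1−ω) · σ_ε² links the level-jump
    variance to the noise variance through the ratio ω ∈ (0, 1).
    """
    if not 0.0 < omega < 1.0:
        raise ValueError("omega must lie in (0, 1)")
    if len(track) < 10:
        raise ValueError("track must contain at least 10 CpG groups")
    diffs = np.diff(track.delta_beta)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    sigma_eps = 1.4826 * mad / np.sqrt(2.0)
    if sigma_eps < SIGMA_FLOOR:
        warnings.warn("track variance ~0; flooring sigma_eps at 1e-3",
                      RuntimeWarning, stacklevel=2)
        sigma_eps = SIGMA_FLOOR
    sigma_mu = float(np.sqrt(omega / (1.0 - omega)) * sigma_eps)
    return SLMParams(theta=theta, d_norm=d_norm, sigma_eps=float(sigma_eps),
                     sigma_mu=max(sigma_mu, SIGMA_FLOOR), n_states=n_states)


@dataclass(frozen=True)
class Segment:
    """A maximal run of constant decoded mean level."""

    first_index: int
    last_index: int            # inclusive
    level: float               # assigned grid level
    mean_delta_beta: float     # empirical mean of member Δβ

    @property
    def n_cpg_groups(self) -> int:
        return self.last_index - self.first_index + 1


@dataclass
class Segmentation:
    """Decoded segments of one chromosome, partitioning the track indices."""

    chrom: str
    segments: list[Segment]
    state_path: np.ndarray     # per-CpG grid-state indices (diagnostic)


def _log_init(levels: np.ndarray, sigma_mu: float) -> np.ndarray:
    # stationary weights ∝ N(level; 0, σ_μ²), normalized on the grid
    ll = -0.5 * (levels / sigma_mu) ** 2
    ll -= np.log(np.sum(np.exp(ll - ll.max()))) + ll.max()
    return ll


def _log_jump_kernel(levels: np.ndarray, sigma_mu: float) -> np.ndarray:
    """log J[j, k]: jump-target distribution ∝ N(levels[k]−levels[j]; 0, σ_μ²)
    restricted to k ≠ j and renormalized per row."""
    diff = levels[None, :] - levels[:, None]
    ll = -0.5 * (diff / sigma_mu) ** 2
    np.fill_diagonal(ll, -np.inf)
    mx = ll.max(axis=1, keepdims=True)
    ll = ll - (np.log(np.sum(np.exp(ll - mx), axis=1, keepdims=True)) + mx)
    return ll


def viterbi_path(delta_beta: np.ndarray, distances: np.ndarray,
                 params: SLMParams) -> np.ndarray:
    """Maximum a posteriori grid-state path for one Δβ sequence.

    Transitions at step i use d_i = distances[i−1]: stay with probability
    1 − η(d_i), jump to a different level with probability η(d_i) spread over
    targets by the Gaussian increment density.  Ties in the backtracking are
    broken toward the lower state index so output is deterministic.
    """
    x = np.asarray(delta_beta, dtype=np.float64)
    n = len(x)
    if n == 0:
        raise ValueError("empty track")
    if len(distances) != n - 1:
        raise ValueError("need exactly n-1 distances")
    levels = state_grid(params.n_states)
    emit = truncated_gaussian_logpdf(x[:, None], levels[None, :],
                                     params.sigma_eps)
    emit = np.atleast_2d(emit)
    logJ = _log_jump_kernel(levels, params.sigma_mu)
    score = _log_init(levels, params.sigma_mu) + emit[0]
    back = np.zeros((n, params.n_states), dtype=np.int64)
    etas = eta(np.asarray(distances, dtype=np.float64), params.theta,
               params.d_norm) if n > 1 else np.empty(0)
    for i in range(1, n):
        log_eta = np.log(etas[i - 1])
        log_stay = np.log1p(-etas[i - 1])
        # candidate[j, k] = score[j] + log T[j, k]
        cand = score[:, None] + log_eta + logJ
        diag = score + log_stay
        idx = np.arange(params.n_states)
        cand[idx, idx] = diag
        back[i] = np.argmax(cand, axis=0)           # first max = lowest j
        score = cand[back[i], idx] + emit[i]
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(np.argmax(score))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def viterbi_segment(track: DeltaBetaTrack, params: SLMParams) -> Segmentation:
    """Decode a Δβ track and merge equal consecutive states into segments."""
    path = viterbi_path(track.delta_beta, track.distances, params)
    levels = state_grid(params.n_states)
    segments: list[Segment] = []
    start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or path[i] != path[start]:
            segments.append(Segment(
                first_index=start, last_index=i - 1,
                level=float(levels[path[start]]),
                mean_delta_beta=float(np.mean(track.delta_beta[start:i])),
            ))
            start = i
    return Segmentation(chrom=track.chrom, segments=segments, state_path=path)
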