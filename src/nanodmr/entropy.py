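"""Methylation entropy of read-level CpG patterns.

Over a window of b consecutive CpG sites, every read covering all b sites
with unambiguous calls contributes one binary methylation pattern.  The
methylation entropy of the window is the per-site Shannon entropy of the
pattern distribution:

    ME = (1/b) · Σ_i −(n_i/N) · log2(n_i/N)

where n_i counts reads carrying pattern i and N is the total number of
contributing reads.  ME is 0 when all reads share one pattern (an
epigenetically homogeneous locus) and 1 when all 2^b patterns are
equifrequent (maximal epiallele diversity).  Feature-level entropy slides a
b-site window across the feature's CpG sites (step one site) and averages
the eligible windows.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReadPatternMatrix", "window_entropy", "feature_entropy",
           "patterns_from_calls"]

DEFAULT_B = 3
DEFAULT_MIN_READS = 5


@dataclass
class ReadPatternMatrix:
    """Per-read binary methylation patterns over one window of b CpG sites."""

    sites: tuple[int, ...]                 # ordered CpG site coordinates
    patterns: tuple[tuple[int, ...], ...]  # one length-b 0/1 vector per read

    def __post_init__(self) -> None:
        b = len(self.sites)
        if any(len(p) != b for p in self.patterns):
            raise ValueError("pattern length must equal window size b")

    @property
    def b(self) -> int:
        return len(self.sites)

    @property
    def n_reads(self) -> int:
        return len(self.patterns)

    def counts(self) -> Counter:
        return Counter(self.patterns)


def window_entropy(m: ReadPatternMatrix) -> float:
    """Per-site Shannon entropy (bits) of the window's pattern distribution."""
    N = m.n_reads
    if N == 0:
        raise ValueError("window has no reads")
    freqs = np.array(list(m.counts().values()), dtype=np.float64) / N
    return float(-np.sum(freqs * np.log2(freqs)) / m.b) + 0.0


def patterns_from_calls(calls: pd.DataFrame, start: int, end: int,
                        b: int = DEFAULT_B,
                        chrom: str | None = None) -> list[ReadPatternMatrix]:
    """Build the sliding b-site windows of a feature from per-read calls.

    ``calls`` is the labelled per-read DataFrame (``io.calls_to_frame``).
    CpG sites are the distinct group start coordinates inside
    [start, end); a read contributes to a window only if it has an
    unambiguous call at every one of its b sites.
    """
    if b < 2:
        raise ValueError("b must be >= 2")
    sub = calls[(calls["start"] >= start) & (calls["start"] < end)
                & (calls["label"] != "ambiguous")]
    if chrom is not None:
        sub = sub[sub["chrom"] == chrom]
    if sub.empty:
        return []
    sites = np.sort(sub["start"].unique())
    if len(sites) < b:
        return []
    state = {(r.read_id, r.start): 1 if r.label == "methylated" else 0
             for r in sub.itertuples(index=False)}
    reads = sub["read_id"].unique()
    windows = []
    for w in range(len(sites) - b + 1):
        wsites = tuple(int(s) for s in sites[w:w + b])
        pats = []
        for rid in reads:
            vec = tuple(state.get((rid, s), -1) for s in wsites)
            if -1 not in vec:
                pats.append(vec)
        windows.append(ReadPatternMatrix(sites=wsites, patterns=tuple(pats)))
    return windows


def feature_entropy(calls: pd.DataFrame, start: int, end: int,
                    b: int = DEFAULT_B,
                    min_reads: int = DEFAULT_MIN_READS,
                    chrom: str | None = None,
                    ) -> tuple[float | None, int]:
    """Mean methylation entropy of a feature interval.

    Returns ``(mean_entropy, n_windows)`` over eligible windows (those with
    at least ``min_reads`` fully covering reads); ``(None, 0)`` when no
    window is eligible.
    """
    windows = patterns_from_calls(calls, start, end, b=b, chrom=chrom)
    values = [window_entropy(w) for w in windows if w.n_reads >= min_reads]
    if not values:
        return None, 0
    return float(np.mean(values)), len(values)
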