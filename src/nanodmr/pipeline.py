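"""End-to-end convenience: frequency tables in, called DMRs out."""

from __future__ import annotations

import pandas as pd

from . import io as mio
from . import slm, dmr

__all__ = ["call_pair"]


def call_pair(test_freq: pd.DataFrame, control_freq: pd.DataFrame,
              min_called_sites: int = mio.DEFAULT_MIN_CALLED_SITES,
              cutoff: float = dmr.DEFAULT_CUTOFF,
              alpha: float = dmr.DEFAULT_ALPHA,
              min_cpgs: int = dmr.DEFAULT_MIN_CPGS,
              theta: float = 0.1, d_norm: float = 1000.0,
              omega: float = 0.9, n_states: int = 41,
              fdr: bool = False,
              ) -> tuple[dict[str, mio.DeltaBetaTrack], list[dmr.DMR]]:
    """Join two frequency tables, segment each chromosome, call DMRs.

    The SLM noise parameters are estimated separately per chromosome;
    chromosomes shorter than 10 joined CpG groups are skipped.
    Returns the per-chromosome Δβ tracks and the pooled DMR list.
    """
    tracks = mio.build_delta_track(test_freq, control_freq,
                                   min_called_sites=min_called_sites)
    dmrs: list[dmr.DMR] = []
    for chrom in sorted(tracks):
        track = tracks[chrom]
        if len(track) < 10:
            continue
        params = slm.estimate_params(track, omega=omega, theta=theta,
                                     d_norm=d_norm, n_states=n_states)
        seg = slm.viterbi_segment(track, params)
        dmrs.extend(dmr.call_dmrs(seg, track, cutoff=cutoff, alpha=alpha,
                                  min_cpgs=min_cpgs, fdr=fdr))
    return tracks, dmrs
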