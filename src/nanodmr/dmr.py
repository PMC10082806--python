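"""Turning SLM segments into tested, classified DMRs.

A segment becomes a differentially methylated region (DMR) when three
conditions hold: |mean Δβ| exceeds the calling cutoff (default 0.3), the
Wilcoxon rank-sum test comparing the per-CpG-group β values of test and
control within the segment is significant (default p < 0.05), and the
segment spans at least ``min_cpgs`` CpG groups.  DMRs are labelled hyper-
(Δβ > cutoff) or hypo-methylated (Δβ < −cutoff), and annotated with their
CpG density (CpG sites per 100 bp) and a resolution class relative to the
practical limits of short-read bisulfite assays (≤2 CpG/100 bp for WGBS,
≤3 for ERRBS, >3 dense).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io import DeltaBetaTrack
from .slm import Segmentation

__all__ = ["DMR", "wilcoxon_segment_test", "call_dmrs", "cpg_density",
           "resolution_class", "dmrs_to_frame", "write_dmr_bed",
           "run_summary", "benjamini_hochberg"]

DEFAULT_CUTOFF = 0.3
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_CPGS = 5
#: exact rank-sum distribution is used up to this combined sample size
EXACT_MAX_N = 20


@dataclass(frozen=True)
class DMR:
    """A called differentially methylated region."""

    chrom: str
    start: int
    end: int
    n_cpg_groups: int
    n_cpg_sites: int
    mean_delta_beta: float
    p_value: float
    direction: str              # "hyper" | "hypo"
    cpg_density: float          # CpG sites per 100 bp
    resolution_class: str       # "<=2" | "<=3" | ">3"


def wilcoxon_segment_test(beta_test: np.ndarray,
                          beta_control: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value for one segment.

    Uses the exact null distribution when the combined sample size is at
    most 20 and the pooled values contain no ties; otherwise the normal
    approximation with midranks, tie-corrected variance and continuity
    correction.  Untestable segments (fewer than 2 values) return p = 1.
    """
    x = np.asarray(beta_test, dtype=np.float64)
    y = np.asarray(beta_control, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("segment arrays must have equal length")
    if len(x) < 2:
        warnings.warn("segment with < 2 CpG groups is untestable; p = 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(min(res.pvalue, 1.0))


def cpg_density(n_cpg_sites: int, start: int, end: int) -> float:
    """CpG sites per 100 bp over a genomic interval."""
    if end <= start:
        raise ValueError("zero-length interval")
    return 100.0 * n_cpg_sites / (end - start)


def resolution_class(density: float) -> str:
    """Density class with inclusive boundaries at 2 and 3 CpG/100 bp."""
    if density <= 2.0:
        return "<=2"
    if density <= 3.0:
        return "<=3"
    return ">3"


def call_dmrs(seg: Segmentation, track: DeltaBetaTrack,
              cutoff: float = DEFAULT_CUTOFF, alpha: float = DEFAULT_ALPHA,
              min_cpgs: int = DEFAULT_MIN_CPGS,
              fdr: bool = False) -> list[DMR]:
    """Filter and classify segments into DMRs.

    With ``fdr=True`` the per-segment rank-sum p-values are Benjamini–
    Hochberg adjusted across all candidate segments (those passing the Δβ
    and size filters) before the significance filter; the default is raw
    p-values.
    """
    candidates = []
    for s in seg.segments:
        if s.n_cpg_groups < min_cpgs or abs(s.mean_delta_beta) <= cutoff:
            continue
        p = wilcoxon_segment_test(
            track.beta_test[s.first_index:s.last_index + 1],
            track.beta_control[s.first_index:s.last_index + 1])
        candidates.append((s, p))
    if fdr and candidates:
        adj = benjamini_hochberg(np.array([p for _, p in candidates]))
        candidates = [(s, float(q)) for (s, _), q in zip(candidates, adj)]
    dmrs: list[DMR] = []
    for s, p in candidates:
        if p >= alpha:
            continue
        start = int(track.positions[s.first_index])
        end = int(track.ends[s.last_index])
        sites = int(np.sum(track.num_motifs[s.first_index:s.last_index + 1]))
        dens = cpg_density(sites, start, end)
        dmrs.append(DMR(
            chrom=track.chrom, start=start, end=end,
            n_cpg_groups=s.n_cpg_groups, n_cpg_sites=sites,
            mean_delta_beta=s.mean_delta_beta, p_value=p,
            direction="hyper" if s.mean_delta_beta > 0 else "hypo",
            cpg_density=dens, resolution_class=resolution_class(dens)))
    return dmrs


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, dtype=np.float64)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """DMRs as a coordinate-sorted BED6+ DataFrame."""
    rows = []
    for i, d in enumerate(sorted(dmrs, key=lambda d: (d.chrom, d.start))):
        rows.append({
            "chrom": d.chrom, "start": d.start, "end": d.end,
            "dmr_id": f"dmr_{i + 1}",
            "mean_delta_beta": round(d.mean_delta_beta, 6),
            "strand": ".", "n_cpg_groups": d.n_cpg_groups,
            "p_value": d.p_value, "direction": d.direction,
            "cpg_density": round(d.cpg_density, 4),
            "resolution_class": d.resolution_class,
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "dmr_id",
                                       "mean_delta_beta", "strand",
                                       "n_cpg_groups", "p_value", "direction",
                                       "cpg_density", "resolution_class"])


def write_dmr_bed(dmrs: list[DMR], path) -> None:
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", index=False)


def run_summary(dmrs: list[DMR]) -> dict:
    """Counts and total kb of hyper- and hypo-methylated DMRs."""
    out = {}
    for direction in ("hyper", "hypo"):
        sub = [d for d in dmrs if d.direction == direction]
        out[direction] = {
            "n": len(sub),
            "total_kb": round(sum(d.end - d.start for d in sub) / 1000.0, 3),
        }
    out["total"] = {"n": len(dmrs),
                    "total_kb": round(sum(d.end - d.start for d in dmrs)
                                      / 1000.0, 3)}
    return out
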