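"""Synthetic nanopore methylome pairs with planted DMRs, and benchmark scoring.

The generator emulates the spatial and statistical structure the DMR caller
assumes: long sparse-CpG stretches alternating with short dense CpG islands
(a two-rate spacing process), a bimodal baseline methylation level (islands
hypomethylated, β ≈ 0.1; background hypermethylated, β ≈ 0.9), read
coverage Poisson around a mean depth, and beta-binomial methylated counts to
carry biological plus calling overdispersion.  Differential regions are
planted in the test sample only, as contiguous runs of CpG groups whose true
β is shifted by ±effect (clipped to [0, 1]).

By default planted direction follows genomic context — hypermethylation of
CpG islands and hypomethylation of the methylated background, the canonical
aberration pattern in cancer methylomes — so that the planted |Δβ| is not
silently eroded by clipping; a random-direction mode is available.

Scoring is done both per CpG group (each group labelled hyper/hypo/null by
truth and by the calls; precision/recall/F1 per direction and pooled) and
per DMR (a called DMR is a true positive when it has ≥ 50% reciprocal
overlap with a same-direction truth DMR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import DeltaBetaTrack, frequency_from_calls

__all__ = ["SimConfig", "SimulatedPair", "BenchmarkScore", "simulate_pair",
           "score_calls"]


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one synthetic test/control methylome pair.

    Spacing/block defaults give an overall density near 1 CpG group per
    100 bp, with dense islands (mean 20 bp spacing) embedded in sparse
    background (mean 150 bp spacing).
    """

    seed: int = 0
    n_chroms: int = 2
    blocks_per_chrom: int = 12        # background+island block pairs
    island_spacing: float = 20.0      # mean bp between island CpG groups
    background_spacing: float = 150.0 # mean bp between background groups
    island_n_groups: int = 30         # mean CpG groups per island
    background_n_groups: int = 60     # mean CpG groups per background block
    coverage: float = 25.0            # mean reads per CpG group
    beta_island: float = 0.1
    beta_background: float = 0.9
    n_dmrs: int = 8
    dmr_length_cpgs: int = 20
    effect: float = 0.5               # planted |Δβ|
    cgi_fraction: float = 0.5         # fraction of DMRs placed inside islands
    hyper_fraction: float = 0.5       # used only with direction_mode="random"
    direction_mode: str = "by_context"  # "by_context" | "random"
    bb_precision: float | None = 20.0 # beta-binomial precision; None=binomial
    read_length_cpgs: int = 10        # CpG groups per synthetic read
    emit_reads: bool = False

    def __post_init__(self) -> None:
        if self.effect < 0 or self.effect > 1:
            raise ValueError("effect must lie in [0, 1]")
        if not 0 <= self.cgi_fraction <= 1:
            raise ValueError("cgi_fraction must lie in [0, 1]")
        if self.direction_mode not in ("by_context", "random"):
            raise ValueError("direction_mode must be 'by_context' or 'random'")
        for name in ("island_spacing", "background_spacing", "coverage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulatedPair:
    """Everything one simulation produces."""

    config: SimConfig
    test_freq: pd.DataFrame
    control_freq: pd.DataFrame
    truth: pd.DataFrame               # chrom, start, end, direction, n_groups
    truth_labels: dict[str, np.ndarray]  # per-chrom per-group −1/0/+1
    positions: dict[str, np.ndarray]
    islands: dict[str, np.ndarray]    # per-chrom [start, end) island intervals
    chrom_sizes: dict[str, int]
    test_calls: pd.DataFrame | None = None
    control_calls: pd.DataFrame | None = None


def _spacings(rng, n: int, mean: float) -> np.ndarray:
    return np.maximum(2, np.round(rng.exponential(mean, size=n))).astype(np.int64)


def _layout_chrom(rng, cfg: SimConfig):
    """CpG group positions, island membership and island intervals."""
    positions, is_island, islands = [], [], []
    pos = 1000
    for _ in range(cfg.blocks_per_chrom):
        n_bg = max(2, rng.poisson(cfg.background_n_groups))
        for d in _spacings(rng, n_bg, cfg.background_spacing):
            pos += int(d)
            positions.append(pos)
            is_island.append(False)
        n_isl = max(2, rng.poisson(cfg.island_n_groups))
        pos += int(rng.exponential(cfg.background_spacing)) + 200
        first = pos
        for d in _spacings(rng, n_isl, cfg.island_spacing):
            pos += int(d)
            positions.append(pos)
            is_island.append(True)
        islands.append((first, pos + 2))
    return (np.asarray(positions, dtype=np.int64),
            np.asarray(is_island, dtype=bool),
            np.asarray(islands, dtype=np.int64))


def _plant_dmrs(rng, cfg: SimConfig, is_island: np.ndarray,
                chrom_budget: int) -> list[tuple[int, int, bool]]:
    """Choose non-overlapping index runs (start, stop, in_island) for DMRs."""
    runs = []
    # maximal runs of constant context
    boundaries = np.flatnonzero(np.diff(is_island.astype(int)) != 0) + 1
    blocks = np.split(np.arange(len(is_island)), boundaries)
    island_blocks = [b for b in blocks if len(b) >= cfg.dmr_length_cpgs + 4
                     and is_island[b[0]]]
    bg_blocks = [b for b in blocks if len(b) >= cfg.dmr_length_cpgs + 4
                 and not is_island[b[0]]]
    n_cgi = int(round(chrom_budget * cfg.cgi_fraction))
    n_bg = chrom_budget - n_cgi
    if n_cgi > len(island_blocks) or n_bg > len(bg_blocks):
        raise ValueError("DMR placement impossible: too many or too long "
                         "DMRs for the simulated CpG landscape")
    for pool, count, in_island in ((island_blocks, n_cgi, True),
                                   (bg_blocks, n_bg, False)):
        chosen = rng.choice(len(pool), size=count, replace=False)
        for ci in chosen:
            block = pool[int(ci)]
            lo = int(block[0]) + 2
            hi = int(block[-1]) - 2 - cfg.dmr_length_cpgs + 1
            start = int(rng.integers(lo, max(lo + 1, hi + 1)))
            runs.append((start, start + cfg.dmr_length_cpgs, in_island))
    return sorted(runs)


def _sample_counts(rng, beta_true: np.ndarray, coverage: np.ndarray,
                   precision: float | None) -> np.ndarray:
    """Methylated counts per group: beta-binomial (or binomial) sampling."""
    if precision is None:
        return rng.binomial(coverage, beta_true)
    p = np.empty_like(beta_true)
    interior = (beta_true > 0) & (beta_true < 1)
    p[~interior] = beta_true[~interior]
    a = beta_true[interior] * precision
    b = (1.0 - beta_true[interior]) * precision
    p[interior] = rng.beta(a, b)
    return rng.binomial(coverage, p)


def _freq_frame(chroms, starts, ends, coverage, meth) -> pd.DataFrame:
    keep = coverage > 0
    return pd.DataFrame({
        "chrom": np.asarray(chroms)[keep],
        "start": starts[keep], "end": ends[keep],
        "num_motifs": np.ones(int(keep.sum()), dtype=np.int64),
        "called_sites": coverage[keep],
        "called_sites_methylated": meth[keep],
        "beta": meth[keep] / coverage[keep],
    })


def _emit_reads(rng, cfg: SimConfig, chrom: str, positions: np.ndarray,
                ends: np.ndarray, beta_true: np.ndarray,
                sample_tag: str) -> pd.DataFrame:
    """Synthetic per-read calls: reads span consecutive CpG groups and share
    one read-level β draw (within-read correlation)."""
    rows = []
    L = cfg.read_length_cpgs
    rate = cfg.coverage / L
    read_no = 0
    for i in range(len(positions)):
        for _ in range(rng.poisson(rate)):
            read_no += 1
            span = slice(i, min(i + L, len(positions)))
            bbar = float(np.mean(beta_true[span]))
            if cfg.bb_precision is not None and 0 < bbar < 1:
                p_read = rng.beta(bbar * cfg.bb_precision,
                                  (1 - bbar) * cfg.bb_precision)
            else:
                p_read = bbar
            meth = rng.random(span.stop - span.start) < p_read
            rid = f"{sample_tag}_read_{chrom}_{read_no}"
            for k, j in enumerate(range(span.start, span.stop)):
                rows.append((chrom, "+", int(positions[j]), int(ends[j]), rid,
                             5.0 if meth[k] else -5.0, 1))
    df = pd.DataFrame(rows, columns=["chrom", "strand", "start", "end",
                                     "read_id", "log_lik_ratio", "num_motifs"])
    df["label"] = np.where(df["log_lik_ratio"] > 2.5, "methylated",
                           "unmethylated")
    return df


def simulate_pair(cfg: SimConfig) -> SimulatedPair:
    """Generate one deterministic test/control pair with planted DMRs."""
    rng = np.random.default_rng(cfg.seed)
    per_chrom = np.full(cfg.n_chroms, cfg.n_dmrs // cfg.n_chroms,
                        dtype=np.int64)
    per_chrom[:cfg.n_dmrs % cfg.n_chroms] += 1

    test_frames, control_frames, truth_rows = [], [], []
    truth_labels, positions_out, islands_out, chrom_sizes = {}, {}, {}, {}
    test_call_frames, control_call_frames = [], []
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        positions, is_island, islands = _layout_chrom(rng, cfg)
        ends = positions + 2
        n = len(positions)
        beta_base = np.where(is_island, cfg.beta_island, cfg.beta_background)
        beta_control_true = beta_base.copy()
        beta_test_true = beta_base.copy()
        labels = np.zeros(n, dtype=np.int64)
        for (i0, i1, in_island) in _plant_dmrs(rng, cfg, is_island,
                                               int(per_chrom[c])):
            if cfg.direction_mode == "by_context":
                sign = 1 if in_island else -1
            else:
                sign = 1 if rng.random() < cfg.hyper_fraction else -1
            beta_test_true[i0:i1] = np.clip(
                beta_test_true[i0:i1] + sign * cfg.effect, 0.0, 1.0)
            labels[i0:i1] = sign
            truth_rows.append((chrom, int(positions[i0]), int(ends[i1 - 1]),
                               "hyper" if sign > 0 else "hypo", i1 - i0))
        if cfg.emit_reads:
            tcalls = _emit_reads(rng, cfg, chrom, positions, ends,
                                 beta_test_true, "test")
            ccalls = _emit_reads(rng, cfg, chrom, positions, ends,
                                 beta_control_true, "control")
            test_call_frames.append(tcalls)
            control_call_frames.append(ccalls)
            test_frames.append(frequency_from_calls(tcalls))
            control_frames.append(frequency_from_calls(ccalls))
        else:
            cov_t = rng.poisson(cfg.coverage, size=n)
            cov_c = rng.poisson(cfg.coverage, size=n)
            meth_t = _sample_counts(rng, beta_test_true, cov_t,
                                    cfg.bb_precision)
            meth_c = _sample_counts(rng, beta_control_true, cov_c,
                                    cfg.bb_precision)
            test_frames.append(_freq_frame([chrom] * n, positions, ends,
                                           cov_t, meth_t))
            control_frames.append(_freq_frame([chrom] * n, positions, ends,
                                              cov_c, meth_c))
        truth_labels[chrom] = labels
        positions_out[chrom] = positions
        islands_out[chrom] = islands
        chrom_sizes[chrom] = int(positions[-1] + 1000)

    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end",
                                              "direction", "n_groups"])
    return SimulatedPair(
        config=cfg,
        test_freq=pd.concat(test_frames, ignore_index=True),
        control_freq=pd.concat(control_frames, ignore_index=True),
        truth=truth.sort_values(["chrom", "start"]).reset_index(drop=True),
        truth_labels=truth_labels, positions=positions_out,
        islands=islands_out, chrom_sizes=chrom_sizes,
        test_calls=(pd.concat(test_call_frames, ignore_index=True)
                    if cfg.emit_reads else None),
        control_calls=(pd.concat(control_call_frames, ignore_index=True)
                       if cfg.emit_reads else None))


@dataclass
class BenchmarkScore:
    """CpG-level and DMR-level agreement between calls and planted truth."""

    cpg_precision: float
    cpg_recall: float
    cpg_f1: float
    per_direction: dict = field(default_factory=dict)
    dmr_tp: int = 0
    dmr_fp: int = 0
    dmr_fn: int = 0
    n_cpg_groups: int = 0
    n_called: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def _label_positions(positions: np.ndarray,
                     regions: list[tuple[int, int, int]]) -> np.ndarray:
    labels = np.zeros(len(positions), dtype=np.int64)
    for start, end, sign in regions:
        labels[(positions >= start) & (positions < end)] = sign
    return labels


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def score_calls(called: pd.DataFrame, truth: pd.DataFrame,
                tracks: dict[str, DeltaBetaTrack],
                reciprocal: float = 0.5) -> BenchmarkScore:
    """Score called DMRs against the planted truth on the same coordinates.

    ``called`` and ``truth`` need columns chrom/start/end/direction.  Raises
    when a called DMR lies on a chromosome absent from the track set.
    """
    sign = {"hyper": 1, "hypo": -1}
    missing = set(called["chrom"]) - set(tracks)
    if missing:
        raise ValueError(f"called DMRs on chromosomes absent from the "
                         f"track: {sorted(missing)}")
    tp = fp = fn = 0
    per_dir = {d: {"tp": 0, "fp": 0, "fn": 0} for d in ("hyper", "hypo")}
    n_groups = n_called_groups = 0
    for chrom, track in tracks.items():
        t_regions = [(r.start, r.end, sign[r.direction])
                     for r in truth[truth["chrom"] == chrom].itertuples()]
        c_regions = [(r.start, r.end, sign[r.direction])
                     for r in called[called["chrom"] == chrom].itertuples()]
        t_lab = _label_positions(track.positions, t_regions)
        c_lab = _label_positions(track.positions, c_regions)
        n_groups += len(track)
        n_called_groups += int(np.sum(c_lab != 0))
        for d, s in sign.items():
            per_dir[d]["tp"] += int(np.sum((c_lab == s) & (t_lab == s)))
            per_dir[d]["fp"] += int(np.sum((c_lab == s) & (t_lab != s)))
            per_dir[d]["fn"] += int(np.sum((t_lab == s) & (c_lab != s)))
    tp = sum(per_dir[d]["tp"] for d in per_dir)
    fp = sum(per_dir[d]["fp"] for d in per_dir)
    fn = sum(per_dir[d]["fn"] for d in per_dir)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    per_direction = {}
    for d, v in per_dir.items():
        p = v["tp"] / (v["tp"] + v["fp"]) if v["tp"] + v["fp"] else 1.0
        r = v["tp"] / (v["tp"] + v["fn"]) if v["tp"] + v["fn"] else 1.0
        per_direction[d] = {"precision": p, "recall": r,
                            "f1": 2 * p * r / (p + r) if p + r else 0.0}

    # DMR-level matching at >= `reciprocal` reciprocal overlap, same direction
    dmr_tp = dmr_fp = 0
    matched_truth: set[int] = set()
    truth_list = list(truth.itertuples())
    for r in called.itertuples():
        hit = False
        for ti, t in enumerate(truth_list):
            if (t.chrom == r.chrom and t.direction == r.direction
                    and _reciprocal_overlap((r.start, r.end),
                                            (t.start, t.end)) >= reciprocal):
                hit = True
                matched_truth.add(ti)
        if hit:
            dmr_tp += 1
        else:
            dmr_fp += 1
    dmr_fn = len(truth_list) - len(matched_truth)
    return BenchmarkScore(cpg_precision=precision, cpg_recall=recall,
                          cpg_f1=f1, per_direction=per_direction,
                          dmr_tp=dmr_tp, dmr_fp=dmr_fp, dmr_fn=dmr_fn,
                          n_cpg_groups=n_groups, n_called=n_called_groups)
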