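"""Reading and writing of methylation call/frequency tables and Δβ tracks.

The on-disk dialects are those produced by nanopore methylation callers:

* per-read calls — tab-separated with columns ``chromosome``, ``strand``,
  ``start``, ``end``, ``read_name``, ``log_lik_ratio``, ``num_motifs`` (the
  "call-methylation" dialect; extra columns are preserved but ignored);
* per-CpG-group frequencies — tab-separated with columns ``chromosome``,
  ``start``, ``end``, ``num_motifs_in_group``, ``called_sites``,
  ``called_sites_methylated``, ``methylated_frequency`` (the
  "methylation frequency" dialect).

Coordinates are 0-based half-open throughout.  A *CpG group* is one or more
adjacent CpG sites called jointly (nanopore signal depends on several bases);
``num_motifs`` counts the CpG sites in the group.  The methylation frequency
β of a group is the ratio of methylated to analyzed CpG calls across reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MethCallRecord",
    "MethFreqRecord",
    "DeltaBetaTrack",
    "MethFormatError",
    "read_methylation_calls",
    "calls_to_frame",
    "frequency_from_calls",
    "read_frequency_table",
    "write_frequency_table",
    "build_delta_track",
    "write_delta_track_bed",
]

#: default per-read call-confidence threshold on |log-likelihood ratio|
DEFAULT_MIN_ABS_LLR = 2.5
#: default per-sample coverage required to join a CpG group into a Δβ track
DEFAULT_MIN_CALLED_SITES = 5

CALL_COLUMNS = ("chromosome", "strand", "start", "end", "read_name",
                "log_lik_ratio", "num_motifs")
FREQ_COLUMNS = ("chromosome", "start", "end", "num_motifs_in_group",
                "called_sites", "called_sites_methylated",
                "methylated_frequency")


class MethFormatError(ValueError):
    """Raised for malformed methylation tables (missing columns, bad rows)."""


@dataclass(frozen=True)
class MethCallRecord:
    """One CpG-group methylation call on one read.

    ``label`` is ``"methylated"`` when the log-likelihood ratio exceeds the
    confidence threshold, ``"unmethylated"`` when it is below its negative,
    and ``"ambiguous"`` otherwise (strict inequalities); ambiguous calls are
    excluded from downstream counting.
    """

    chrom: str
    strand: str
    start: int
    end: int
    read_id: str
    log_lik_ratio: float
    num_motifs: int
    label: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start at {self.chrom}:{self.start}")
        if self.num_motifs < 1:
            raise ValueError("num_motifs must be >= 1")


@dataclass(frozen=True)
class MethFreqRecord:
    """Aggregated methylation frequency of one CpG group in one sample."""

    chrom: str
    start: int
    end: int
    num_motifs: int
    called_sites: int
    called_sites_methylated: int
    beta: float

    def __post_init__(self) -> None:
        if self.called_sites_methylated > self.called_sites:
            raise ValueError("called_sites_methylated > called_sites")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta outside [0, 1]")


def classify_llr(llr: float, min_abs_llr: float = DEFAULT_MIN_ABS_LLR) -> str:
    """Label a per-read call from its log-likelihood ratio (strict threshold)."""
    if llr > min_abs_llr:
        return "methylated"
    if llr < -min_abs_llr:
        return "unmethylated"
    return "ambiguous"


def _read_tsv(path_or_buf, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, comment=None)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MethFormatError(
            f"missing mandatory column(s): {', '.join(missing)}")
    return df


def _to_numeric(df: pd.DataFrame, column: str, kind: str = "float") -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna()
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise MethFormatError(
            f"non-numeric value in column '{column}' at line {line}")
    if converted.isna().any():
        line = int(converted.isna().idxmax()) + 2
        raise MethFormatError(f"empty value in column '{column}' at line {line}")
    return converted.astype(np.int64 if kind == "int" else np.float64)


def calls_to_frame(path_or_buf, min_abs_llr: float = DEFAULT_MIN_ABS_LLR) -> pd.DataFrame:
    """Load a per-read call table into a DataFrame with a ``label`` column."""
    df = _read_tsv(path_or_buf, CALL_COLUMNS)
    out = pd.DataFrame({
        "chrom": df["chromosome"].astype(str),
        "strand": df["strand"].astype(str),
        "start": _to_numeric(df, "start", "int"),
        "end": _to_numeric(df, "end", "int"),
        "read_id": df["read_name"].astype(str),
        "log_lik_ratio": _to_numeric(df, "log_lik_ratio"),
        "num_motifs": _to_numeric(df, "num_motifs", "int"),
    })
    llr = out["log_lik_ratio"].to_numpy()
    label = np.where(llr > min_abs_llr, "methylated",
                     np.where(llr < -min_abs_llr, "unmethylated", "ambiguous"))
    out["label"] = label
    return out


def read_methylation_calls(path_or_buf,
                           min_abs_llr: float = DEFAULT_MIN_ABS_LLR,
                           ) -> Iterator[MethCallRecord]:
    """Stream labelled :class:`MethCallRecord` from a per-read call table."""
    df = calls_to_frame(path_or_buf, min_abs_llr=min_abs_llr)
    for row in df.itertuples(index=False):
        yield MethCallRecord(row.chrom, row.strand, int(row.start),
                             int(row.end), row.read_id,
                             float(row.log_lik_ratio), int(row.num_motifs),
                             row.label)


def frequency_from_calls(calls) -> pd.DataFrame:
    """Aggregate per-read calls into per-group methylation frequencies.

    CpG groups are strand-collapsed and keyed by (chrom, start, end).  Each
    unambiguous read contributes ``num_motifs`` called sites; reads labelled
    methylated contribute the same number of methylated sites.  Groups with
    no unambiguous coverage are dropped (β undefined).
    """
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame([r.__dict__ for r in calls])
    if calls.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "num_motifs",
                                     "called_sites", "called_sites_methylated",
                                     "beta"])
    usable = calls[calls["label"] != "ambiguous"]
    if usable.empty:
        return frequency_from_calls(pd.DataFrame(columns=calls.columns))
    grouped = usable.groupby(["chrom", "start", "end"], sort=True)
    n_motifs = grouped["num_motifs"].first()
    called = grouped["num_motifs"].sum()
    methylated = usable.assign(
        _meth=np.where(usable["label"] == "methylated",
                       usable["num_motifs"], 0)
    ).groupby(["chrom", "start", "end"], sort=True)["_meth"].sum()
    out = pd.DataFrame({
        "num_motifs": n_motifs.astype(np.int64),
        "called_sites": called.astype(np.int64),
        "called_sites_methylated": methylated.astype(np.int64),
    }).reset_index()
    out["beta"] = out["called_sites_methylated"] / out["called_sites"]
    return out


def read_frequency_table(path_or_buf) -> pd.DataFrame:
    """Read a methylation-frequency table into canonical column names."""
    df = _read_tsv(path_or_buf, FREQ_COLUMNS)
    out = pd.DataFrame({
        "chrom": df["chromosome"].astype(str),
        "start": _to_numeric(df, "start", "int"),
        "end": _to_numeric(df, "end", "int"),
        "num_motifs": _to_numeric(df, "num_motifs_in_group", "int"),
        "called_sites": _to_numeric(df, "called_sites", "int"),
        "called_sites_methylated": _to_numeric(df, "called_sites_methylated",
                                               "int"),
        "beta": _to_numeric(df, "methylated_frequency"),
    })
    bad = out["called_sites_methylated"] > out["called_sites"]
    if bad.any():
        raise MethFormatError(
            f"called_sites_methylated > called_sites at line {int(bad.idxmax()) + 2}")
    return out


def write_frequency_table(freq: pd.DataFrame, path) -> None:
    """Write a frequency DataFrame in the methylation-frequency dialect."""
    out = pd.DataFrame({
        "chromosome": freq["chrom"],
        "start": freq["start"],
        "end": freq["end"],
        "num_motifs_in_group": freq["num_motifs"],
        "called_sites": freq["called_sites"],
        "called_sites_methylated": freq["called_sites_methylated"],
        "methylated_frequency": freq["beta"].map(lambda b: format(b, ".6f")),
        "group_sequence": ".",
    })
    out.to_csv(path, sep="\t", index=False)


@dataclass
class DeltaBetaTrack:
    """Per-chromosome ordered Δβ profile over CpG groups shared by two samples.

    ``positions`` are group start coordinates (the segmentation anchors) and
    are strictly increasing; ``delta_beta = beta_test − beta_control``.
    """

    chrom: str
    positions: np.ndarray          # group starts, strictly increasing
    ends: np.ndarray               # group ends (half-open)
    num_motifs: np.ndarray         # CpG sites per group
    beta_test: np.ndarray
    beta_control: np.ndarray
    delta_beta: np.ndarray
    called_test: np.ndarray = field(default=None)  # type: ignore[assignment]
    called_control: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.num_motifs = np.asarray(self.num_motifs, dtype=np.int64)
        self.beta_test = np.asarray(self.beta_test, dtype=np.float64)
        self.beta_control = np.asarray(self.beta_control, dtype=np.float64)
        self.delta_beta = np.asarray(self.delta_beta, dtype=np.float64)
        n = len(self.positions)
        for name in ("ends", "num_motifs", "beta_test", "beta_control",
                     "delta_beta"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array length mismatch for {name}")
        if self.called_test is None:
            self.called_test = np.zeros(n, dtype=np.int64)
        if self.called_control is None:
            self.called_control = np.zeros(n, dtype=np.int64)
        if n and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"positions not strictly increasing on {self.chrom}")
        if np.any(np.abs(self.delta_beta
                         - (self.beta_test - self.beta_control)) > 1e-12):
            raise ValueError("delta_beta inconsistent with beta_test - beta_control")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def distances(self) -> np.ndarray:
        """Inter-group distances d_i = positions[i] − positions[i−1], i ≥ 1."""
        return np.diff(self.positions).astype(np.float64)


def _check_sorted_unique(freq: pd.DataFrame, sample: str) -> None:
    for chrom, sub in freq.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise ValueError(f"{sample}: input not sorted by (chrom, start) "
                             f"on {chrom}")
        dup = np.diff(starts) == 0
        if np.any(dup):
            pos = int(starts[1:][dup][0])
            raise ValueError(f"{sample}: duplicated CpG group at "
                             f"{chrom}:{pos}")


def build_delta_track(test: pd.DataFrame, control: pd.DataFrame,
                      min_called_sites: int = DEFAULT_MIN_CALLED_SITES,
                      ) -> dict[str, DeltaBetaTrack]:
    """Join two frequency tables into per-chromosome Δβ tracks.

    Only CpG groups present in both samples with ``called_sites ≥
    min_called_sites`` on each side are joined; Δβ = β_test − β_control.
    """
    _check_sorted_unique(test, "test")
    _check_sorted_unique(control, "control")
    t = test[test["called_sites"] >= min_called_sites]
    c = control[control["called_sites"] >= min_called_sites]
    merged = t.merge(c, on=["chrom", "start", "end"], suffixes=("_t", "_c"))
    tracks: dict[str, DeltaBetaTrack] = {}
    for chrom, sub in merged.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        tracks[str(chrom)] = DeltaBetaTrack(
            chrom=str(chrom),
            positions=sub["start"].to_numpy(),
            ends=sub["end"].to_numpy(),
            num_motifs=sub["num_motifs_t"].to_numpy(),
            beta_test=sub["beta_t"].to_numpy(),
            beta_control=sub["beta_c"].to_numpy(),
            delta_beta=(sub["beta_t"] - sub["beta_c"]).to_numpy(),
            called_test=sub["called_sites_t"].to_numpy(),
            called_control=sub["called_sites_c"].to_numpy(),
        )
    return tracks


def write_delta_track_bed(tracks: Mapping[str, DeltaBetaTrack], path) -> None:
    """Export Δβ tracks as BED3+ (one row per joined CpG group)."""
    rows = []
    for chrom in sorted(tracks):
        tr = tracks[chrom]
        for i in range(len(tr)):
            rows.append((tr.chrom, tr.positions[i], tr.ends[i],
                         format(tr.delta_beta[i], ".6f"),
                         format(tr.beta_test[i], ".6f"),
                         format(tr.beta_control[i], ".6f"),
                         tr.called_test[i], tr.called_control[i]))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "delta_beta",
                                "beta_test", "beta_control",
                                "called_sites_test", "called_sites_control"]
                 ).to_csv(path, sep="\t", index=False, header=False)
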