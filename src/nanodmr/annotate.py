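"""DMR annotation: CpG-island context, genic elements and region groups.

Genic elements follow the usual annotation vocabulary: 1to5Kb (1–5 kb
upstream of the TSS), promoter (1 kb upstream of the TSS), 5'UTR, first
exon, internal exons, introns and 3'UTR, with anything else intergenic.
Two groupings are used downstream: 5' regulatory regions ("Reg" = 1to5Kb,
promoter, 5'UTR, first exon) and gene bodies ("GB" = internal exons and
introns).  A DMR overlapping a CpG island by at least 1 bp is in CGI
context, otherwise NoCGI (sparse-CpG sequence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .dmr import DMR

__all__ = ["GenomicFeature", "Transcript", "AnnotatedDMR",
           "derive_elements", "annotate_dmrs", "read_feature_bed",
           "read_gene_model_tsv", "annotated_to_frame"]

CATEGORIES = frozenset({"1to5Kb", "promoter", "5UTR", "first_exon", "exon",
                        "intron", "3UTR", "intergenic", "CGI", "DHS", "TFBS",
                        "enhancer"})
REG_CATEGORIES = frozenset({"1to5Kb", "promoter", "5UTR", "first_exon"})
GB_CATEGORIES = frozenset({"exon", "intron"})


@dataclass(frozen=True)
class GenomicFeature:
    """One annotated interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    category: str
    gene: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty feature interval {self.name}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class Transcript:
    """Minimal gene model: strand-aware exon structure plus optional CDS."""

    gene: str
    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]   # sorted, 0-based half-open
    cds_start: int | None = None
    cds_end: int | None = None

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]


@dataclass
class AnnotatedDMR:
    """A DMR with CGI context, overlapping elements and region groups."""

    dmr: DMR
    cgi_context: str                      # "CGI" | "NoCGI"
    elements: set[tuple[str, str | None]] = field(default_factory=set)
    region_groups: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)


def _clip(start: int, end: int) -> tuple[int, int]:
    return max(start, 0), max(end, 0)


def derive_elements(transcripts: list[Transcript]) -> list[GenomicFeature]:
    """Expand gene models into genic-element features.

    Per transcript: 1to5Kb ([TSS−5000, TSS−1000) on the + strand, mirrored
    on −), promoter ([TSS−1000, TSS)), first exon, internal exons, introns,
    and, when CDS coordinates are given, 5'UTR/3'UTR as the exonic sequence
    upstream/downstream of the CDS.  Coordinates are clipped at 0.
    Transcripts with no exons are skipped with a warning.
    """
    feats: list[GenomicFeature] = []
    for tx in transcripts:
        if not tx.exons:
            warnings.warn(f"transcript {tx.name} has no exons; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        exons = sorted(tx.exons)
        tss = tx.tss

        def emit(start: int, end: int, category: str) -> None:
            start, end = _clip(start, end)
            if end > start:
                feats.append(GenomicFeature(tx.chrom, start, end,
                                            f"{tx.name}:{category}", category,
                                            gene=tx.gene, strand=tx.strand))

        if tx.strand == "+":
            emit(tss - 5000, tss - 1000, "1to5Kb")
            emit(tss - 1000, tss, "promoter")
            ordered = exons
        else:
            emit(tss, tss + 1000, "promoter")
            emit(tss + 1000, tss + 5000, "1to5Kb")
            ordered = exons[::-1]          # transcription order

        emit(ordered[0][0], ordered[0][1], "first_exon")
        for s, e in ordered[1:]:
            emit(s, e, "exon")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            emit(e1, s2, "intron")

        if tx.cds_start is not None and tx.cds_end is not None:
            for s, e in exons:
                # exonic sequence outside the CDS, split by strand
                left_s, left_e = s, min(e, tx.cds_start)
                right_s, right_e = max(s, tx.cds_end), e
                if left_e > left_s:
                    emit(left_s, left_e,
                         "5UTR" if tx.strand == "+" else "3UTR")
                if right_e > right_s:
                    emit(right_s, right_e,
                         "3UTR" if tx.strand == "+" else "5UTR")
    return feats


def read_feature_bed(path, category: str, gene_column: int | None = None,
                     ) -> list[GenomicFeature]:
    """Read BED4/BED6 intervals as features of one category.

    ``gene_column`` (0-based) optionally names the column holding the target
    gene symbol, for tables such as enhancer→gene maps.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    feats = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = row[3] if len(row) > 3 else f"{category}_{i + 1}"
        gene = row[gene_column] if gene_column is not None else None
        strand = row[5] if len(row) > 5 else "."
        feats.append(GenomicFeature(str(row[0]), int(row[1]), int(row[2]),
                                    str(name), category, gene=gene,
                                    strand=strand))
    return feats


def read_gene_model_tsv(path) -> list[Transcript]:
    """Read a gene-model TSV: gene, transcript, chrom, strand, exon_starts,
    exon_ends (comma-separated), optional cds_start/cds_end columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    txs = []
    for r in df.itertuples(index=False):
        starts = [int(x) for x in str(r.exon_starts).rstrip(",").split(",") if x]
        ends = [int(x) for x in str(r.exon_ends).rstrip(",").split(",") if x]
        cds_s = int(r.cds_start) if hasattr(r, "cds_start") and pd.notna(r.cds_start) else None
        cds_e = int(r.cds_end) if hasattr(r, "cds_end") and pd.notna(r.cds_end) else None
        txs.append(Transcript(gene=str(r.gene), name=str(r.transcript),
                              chrom=str(r.chrom), strand=str(r.strand),
                              exons=tuple(zip(starts, ends)),
                              cds_start=cds_s, cds_end=cds_e))
    return txs


def _build_trees(features: list[GenomicFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return trees


def annotate_dmrs(dmrs: list[DMR], features: list[GenomicFeature],
                  known_chroms: set[str] | None = None) -> list[AnnotatedDMR]:
    """Attach CGI context, overlapping elements and region groups to DMRs.

    Overlap is any-basepair (≥ 1 bp); a DMR may carry several elements and
    region groups.  DMRs overlapping no feature are intergenic.
    """
    if known_chroms is not None:
        unknown = {f.chrom for f in features} - known_chroms
        if unknown:
            warnings.warn(f"features on unknown chromosomes ignored: "
                          f"{sorted(unknown)}", RuntimeWarning, stacklevel=2)
            features = [f for f in features if f.chrom in known_chroms]
    trees = _build_trees(features)
    out: list[AnnotatedDMR] = []
    for d in dmrs:
        hits = [iv.data for iv in trees.get(d.chrom, IntervalTree())
                .overlap(d.start, d.end)]
        ann = AnnotatedDMR(dmr=d, cgi_context="NoCGI")
        for f in hits:
            if f.category == "CGI":
                ann.cgi_context = "CGI"
            ann.elements.add((f.category, f.gene))
            if f.gene:
                ann.genes.add(f.gene)
            if f.category in REG_CATEGORIES:
                ann.region_groups.add("Reg")
            elif f.category in GB_CATEGORIES:
                ann.region_groups.add("GB")
            elif f.category == "3UTR":
                ann.region_groups.add("3UTR")
            elif f.category == "enhancer":
                ann.region_groups.add("enhancer")
        if not ann.region_groups:
            # no genic/enhancer overlap: genically intergenic (a CGI hit
            # only sets the context, not the region group)
            ann.region_groups.add("intergenic")
            if not hits:
                ann.elements.add(("intergenic", None))
        out.append(ann)
    return out


def annotated_to_frame(annotated: list[AnnotatedDMR]) -> pd.DataFrame:
    """Annotated DMRs as a flat table (one row per DMR)."""
    rows = []
    for a in annotated:
        d = a.dmr
        rows.append({
            "chrom": d.chrom, "start": d.start, "end": d.end,
            "mean_delta_beta": round(d.mean_delta_beta, 6),
            "p_value": d.p_value, "direction": d.direction,
            "cgi_context": a.cgi_context,
            "elements": ",".join(sorted(c for c, _ in a.elements)),
            "region_group": ",".join(sorted(a.region_groups)),
            "genes": ",".join(sorted(a.genes)),
        })
    return pd.DataFrame(rows)
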