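import pytest

from nanodmr.annotate import (GenomicFeature, Transcript, derive_elements,
                              annotate_dmrs, annotated_to_frame)
from nanodmr.dmr import DMR


def dmr_at(chrom, start, end, direction="hyper"):
    return DMR(chrom=chrom, start=start, end=end, n_cpg_groups=10,
               n_cpg_sites=10, mean_delta_beta=0.5 if direction == "hyper"
               else -0.5, p_value=0.01, direction=direction,
               cpg_density=1.0, resolution_class="<=2")


class TestDeriveElements:
    def tx_plus(self):
        return Transcript(gene="G1", name="T1", chrom="chr1", strand="+",
                          exons=((10_000, 10_500), (12_000, 12_300),
                                 (14_000, 14_800)),
                          cds_start=10_200, cds_end=14_300)

    def test_plus_strand_upstream(self):
        feats = {f.category: f for f in derive_elements([self.tx_plus()])
                 if f.category in ("promoter", "1to5Kb")}
        assert (feats["promoter"].start, feats["promoter"].end) == (9000, 10_000)
        assert (feats["1to5Kb"].start, feats["1to5Kb"].end) == (5000, 9000)

    def test_minus_strand_mirror(self):
        tx = Transcript(gene="G2", name="T2", chrom="chr1", strand="-",
                        exons=((5000, 6000), (8000, 10_000)))
        feats = {f.category: f for f in derive_elements([tx])
                 if f.category in ("promoter", "1to5Kb", "first_exon")}
        assert (feats["promoter"].start, feats["promoter"].end) == (10_000, 11_000)
        assert (feats["1to5Kb"].start, feats["1to5Kb"].end) == (11_000, 15_000)
        # first exon in transcription order is the rightmost on '-'
        assert (feats["first_exon"].start, feats["first_exon"].end) == (8000, 10_000)

    def test_single_exon_no_introns(self):
        tx = Transcript(gene="G3", name="T3", chrom="chr1", strand="+",
                        exons=((100, 400),))
        cats = [f.category for f in derive_elements([tx])]
        assert "intron" not in cats and cats.count("first_exon") == 1
        assert "exon" not in cats

    def test_utrs_from_cds(self):
        feats = derive_elements([self.tx_plus()])
        utr5 = [f for f in feats if f.category == "5UTR"]
        utr3 = [f for f in feats if f.category == "3UTR"]
        assert [(f.start, f.end) for f in utr5] == [(10_000, 10_200)]
        assert [(f.start, f.end) for f in utr3] == [(14_300, 14_800)]

    def test_coordinates_clipped_at_zero(self):
        tx = Transcript(gene="G4", name="T4", chrom="chr1", strand="+",
                        exons=((500, 900),))
        for f in derive_elements([tx]):
            assert f.start >= 0

    def test_no_exons_skipped_with_warning(self):
        tx = Transcript(gene="G5", name="T5", chrom="chr1", strand="+",
                        exons=())
        with pytest.warns(RuntimeWarning):
            assert derive_elements([tx]) == []

    def test_elements_disjoint_within_transcript(self):
        """Apart from the documented UTR/exon containment, derived elements
        of one transcript do not overlap."""
        feats = [f for f in derive_elements([self.tx_plus()])
                 if f.category not in ("5UTR", "3UTR")]
        ivs = sorted((f.start, f.end) for f in feats)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2


class TestAnnotateDmrs:
    def features(self):
        return [
            GenomicFeature("chr1", 800, 1200, "cgi1", "CGI"),
            GenomicFeature("chr1", 5000, 6000, "intr", "intron", gene="G1"),
            GenomicFeature("chr1", 9000, 10_000, "prom", "promoter", gene="G1"),
            GenomicFeature("chr2", 100, 500, "enh", "enhancer", gene="G9"),
        ]

    def test_one_bp_cgi_overlap(self):
        ann = annotate_dmrs([dmr_at("chr1", 100, 801)], self.features())
        assert ann[0].cgi_context == "CGI"
        ann = annotate_dmrs([dmr_at("chr1", 100, 800)], self.features())
        assert ann[0].cgi_context == "NoCGI"

    def test_intron_dmr_is_gene_body(self):
        ann = annotate_dmrs([dmr_at("chr1", 5200, 5400)], self.features())
        assert ann[0].region_groups == {"GB"}
        assert ann[0].genes == {"G1"}

    def test_promoter_dmr_is_reg(self):
        ann = annotate_dmrs([dmr_at("chr1", 9500, 9600)], self.features())
        assert ann[0].region_groups == {"Reg"}

    def test_no_overlap_is_intergenic(self):
        ann = annotate_dmrs([dmr_at("chr1", 100_000, 100_500)],
                            self.features())
        assert ann[0].region_groups == {"intergenic"}

    def test_unknown_chrom_features_warn(self):
        with pytest.warns(RuntimeWarning):
            annotate_dmrs([dmr_at("chr1", 0, 10)], self.features(),
                          known_chroms={"chr1"})

    def test_cgi_nocgi_partition(self):
        dmrs = [dmr_at("chr1", s, s + 300) for s in range(0, 20_000, 700)]
        ann = annotate_dmrs(dmrs, self.features())
        n_cgi = sum(a.cgi_context == "CGI" for a in ann)
        n_nocgi = sum(a.cgi_context == "NoCGI" for a in ann)
        assert n_cgi + n_nocgi == len(dmrs)
        frame = annotated_to_frame(ann)
        assert len(frame) == len(dmrs)

    def test_overlap_matches_quadratic_oracle(self, rng):
        """Tree-backed annotation equals an all-pairs brute-force scan."""
        feats = []
        cats = ["CGI", "promoter", "intron", "exon", "enhancer", "3UTR"]
        for i in range(300):
            s = int(rng.integers(0, 100_000))
            feats.append(GenomicFeature("chr1", s, s + int(rng.integers(1, 2000)),
                                        f"f{i}", cats[i % len(cats)],
                                        gene=f"g{i % 17}"))
        dmrs = []
        for i in range(150):
            s = int(rng.integers(0, 100_000))
            dmrs.append(dmr_at("chr1", s, s + int(rng.integers(50, 3000))))
        ann = annotate_dmrs(dmrs, feats)
        for d, a in zip(dmrs, ann):
            expected = {(f.category, f.gene) for f in feats
                        if f.start < d.end and d.start < f.end}
            got = {e for e in a.elements if e[0] != "intergenic"}
            assert got == expected
            assert (a.cgi_context == "CGI") == any(
                c == "CGI" for c, _ in expected)
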