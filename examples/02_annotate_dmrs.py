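"""Annotate called DMRs with CpG-island context and genic elements.

Uses the simulator's own island intervals as the CpG-island track and a toy
two-gene model, then reports each DMR's context (CGI vs NoCGI) and region
group (Reg = 5' regulatory, GB = gene body, enhancer, intergenic).
"""

from nanodmr import SimConfig, simulate_pair, call_pair
from nanodmr.annotate import (GenomicFeature, Transcript, derive_elements,
                              annotate_dmrs, annotated_to_frame)

pair = simulate_pair(SimConfig(seed=42, effect=0.5, coverage=20.0))
tracks, dmrs = call_pair(pair.test_freq, pair.control_freq)

features = [GenomicFeature("chr1", int(s), int(e), f"cgi_{i}", "CGI")
            for i, (s, e) in enumerate(pair.islands["chr1"])]
features += [GenomicFeature("chr2", int(s), int(e), f"cgi2_{i}", "CGI")
             for i, (s, e) in enumerate(pair.islands["chr2"])]
genes = [
    Transcript(gene="GENE1", name="tx1", chrom="chr1", strand="+",
               exons=((30_000, 31_000), (40_000, 41_500))),
    Transcript(gene="GENE2", name="tx2", chrom="chr2", strand="-",
               exons=((60_000, 62_000),)),
]
features += derive_elements(genes)

annotated = annotate_dmrs(dmrs, features)
print(annotated_to_frame(annotated).to_string(index=False))
n_cgi = sum(a.cgi_context == "CGI" for a in annotated)
print(f"\n{n_cgi}/{len(annotated)} DMRs overlap a CpG island")
# A DMR is in CGI context when it overlaps an island by >= 1 bp; DMRs
# touching a promoter/5'UTR/first-exon are 'Reg', intronic/exonic are 'GB'.
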