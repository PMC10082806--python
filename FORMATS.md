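# File formats

All coordinates are 0-based, half-open. All tables are tab-separated with a
header row unless noted. Column order never matters; names do.

## Per-read methylation calls (input to `entropy`, `io.calls_to_frame`)

The "call-methylation" dialect of nanopore methylation callers. Required
columns (extras ignored):

| column | meaning |
|---|---|
| `chromosome` | reference name |
| `strand` | `+`/`-` (groups are strand-collapsed) |
| `start`, `end` | CpG-group interval |
| `read_name` | read identifier |
| `log_lik_ratio` | methylated-vs-unmethylated log-likelihood ratio |
| `num_motifs` | CpG sites in the group |

A call is *methylated* when `log_lik_ratio > 2.5`, *unmethylated* when
`< −2.5`, otherwise *ambiguous* and excluded from counting (threshold
configurable, strict inequalities).

## Methylation frequency table (input to `call`; output of `simulate`)

The "methylation frequency" dialect. Required columns: `chromosome`,
`start`, `end`, `num_motifs_in_group`, `called_sites`,
`called_sites_methylated`, `methylated_frequency`. The optional
`group_sequence` column is written as `.`.

## Δβ track BED (`io.write_delta_track_bed`)

BED3+ without header: `chrom  start  end  delta_beta  beta_test
beta_control  called_sites_test  called_sites_control`.

## DMR table (output of `call`; input to `annotate`/`enrich`)

BED6+ with header: `chrom  start  end  dmr_id  mean_delta_beta  strand(.)
n_cpg_groups  p_value  direction(hyper|hypo)  cpg_density
resolution_class(<=2|<=3|>3)`. Sorted by coordinate. The companion
`*.summary.json` holds counts and total kb of hyper-/hypo-methylated DMRs.

## Feature BED (CpG islands, DHS, TFBS, enhancers)

BED4/BED6, no header, `#` comments allowed. For enhancer→gene maps, column
4 holds the target gene symbol.

## Gene model TSV (input to `annotate --genes`)

Header columns: `gene  transcript  chrom  strand  exon_starts  exon_ends`
(comma-separated block lists) and optional `cds_start  cds_end`. Without
CDS coordinates no UTRs are derived.

## Chromosome sizes (input to `enrich`)

Two columns, no header: chromosome name, length (UCSC `chrom.sizes`).

## Truth DMR BED (output of `simulate`)

No header: `chrom  start  end  direction  n_groups`.

## Benchmark score TSV (output of `benchmark`)

Header: `seed  cpg_precision  cpg_recall  cpg_f1  dmr_tp  dmr_fp  dmr_fn`.
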