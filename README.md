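# ribostall

Codon-resolution analysis of ribosome stalling from P-site-assigned
footprint count tables: multiplicative dwell-time estimation, positional
metrics (metagene, 5′/3′ ramp indices, polarity scores), stall-site peak
calling with codon-context and enrichment statistics, codon-usage
positional bias, a protein-turnover kinetic model, and polysome/qPCR assay
analytics — plus a seeded synthetic-data generator with planted ground
truth that exercises the whole pipeline.

## Layout

| module | what it does |
| --- | --- |
| `ribostall.core` | domain types (transcripts, samples, counts), FASTA/TSV/BED I/O, YAML config |
| `ribostall.simulate` | synthetic transcriptomes, footprint counts (7-site window model, attenuation, planted stalls), proteome log₂FC and qPCR Ct tables |
| `ribostall.dwell` | per-codon/per-site dwell factor estimation (cyclic Poisson updates), ±3-codon window summaries, per-codon ANOVA + Tukey HSD |
| `ribostall.metrics` | RPM/Norm_RPM layers, transcript filtering, metagene profiles, ramp indices, polarity scores and Δpolarity tests, codon-window enrichment, region codon-frequency shifts |
| `ribostall.stalls` | per-position stall calling vs control (fold-change + Welch-t conjunction), context profiles, hypergeometric overlaps, site metagenes, first-site distances, proteome enrichment |
| `ribostall.codons` | gene × codon count/fraction tables (isoform count-averaging), positional codon bias with bootstrap CIs |
| `ribostall.kinetics` | first-order turnover model `ratio = s + (1−s)·2^(−t/t½)`, protein classification, half-life group comparisons |
| `ribostall.assays` | polysome-profile smoothing/alignment/AUC + P/M ratios, spike-normalized tRNA charging, ΔΔCt fold changes |
| `ribostall.pipeline` | deterministic end-to-end driver (simulate → filter → dwell → metrics → stalls → context → enrichment) |

## CLI

```sh
ribostall simulate --n-genes 200 --conditions Ctrl,Val --seed 1 --out sim/
ribostall dwelltime --fasta sim/transcriptome.fa --counts sim/counts.tsv \
    --samples sim/samples.tsv --out dwell.tsv
ribostall metrics   --fasta sim/transcriptome.fa --counts sim/counts.tsv \
    --samples sim/samples.tsv --control Ctrl --out metrics/
ribostall callstalls --fasta sim/transcriptome.fa --counts sim/counts.tsv \
    --samples sim/samples.tsv --condition Val --control Ctrl --out sites.tsv
ribostall context   --fasta sim/transcriptome.fa --sites sites.tsv --out ctx.tsv
ribostall codontable --fasta sim/transcriptome.fa --out codons.tsv
ribostall kinetics  --proteins proteins.tsv --out classes.tsv
ribostall polysome  --trace trace.tsv --anchors anchors.tsv \
    --mono 1 4 --poly 4.5 8 --out pm.tsv
ribostall charging  --cts cts.tsv --control Ctrl --out charging.tsv
ribostall pipeline  --n-genes 120 --seed 1 --out run/
```

Count tables are long-format TSV (`transcript_id`, `codon_position`,
`sample_id`, `count`; 0-based codon positions, P-site-assigned), CDS
input is FASTA (`gene=` tag in the description links isoforms), stall
sites are emitted as TSV and BED6 in transcript nucleotide coordinates.
Analysis thresholds (filtering, peak criteria, polarity cuts, protein
thresholds) live in a YAML config; unset keys take the documented
defaults (`ribostall.core.load_config`).

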