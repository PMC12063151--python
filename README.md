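# lncpipe

A tested, reusable pipeline for identifying long non-coding RNAs (lncRNAs)
in compact (yeast-sized) genomes and generating functional hypotheses for
them: filter cascade, positional classification, RNA–DNA triplex
(TFO/TTS) prediction, genomic-context assignment, co-expression
correlation and soft clustering — plus a seeded synthetic-data generator
so every stage is verifiable without any downloads.

## Modules

| module | what it does |
| --- | --- |
| `lncpipe.genomics` | 0-based half-open interval model, transcript/annotation types, GTF/FASTA/BED I/O, overlaps, neighbour search |
| `lncpipe.filtering` | the candidate→lncRNA filter cascade (length ≥ 200 nt, same-strand exon overlap, coding-potential vote, known-RNA/domain hit filters, TPM > 1 expression filter) with per-filter bookkeeping |
| `lncpipe.coding` | transparent coding-potential scoring: longest ORF, Fickett TESTCODE, hexamer log-likelihood ratio, all-must-agree noncoding vote (external tool labels pluggable), confusion-matrix benchmarking |
| `lncpipe.positional` | category of each lncRNA vs its nearest coding gene: antisense-exonic, divergent, convergent, upstream/downstream sense |
| `lncpipe.triplex` | TFO tract search in lncRNAs (R/Y/M motifs), purine TTS search in duplex DNA, motif-rule matching, hierarchical genome context (promoter > exon > intron > intergenic), genome fractions, interaction pairs per scope |
| `lncpipe.expression` | gene-level aggregation, median-of-ratios + log2 normalization, z-scored Pearson correlations, exclusive pair labelling (Neighbouring / Interacting–Promoter / Independent), KS and bimodality summaries |
| `lncpipe.clustering` | replicate-median + z-score profiles, fuzzy c-means with membership cutoff, Dmin curve for choosing the cluster count |
| `lncpipe.simulate` | seeded synthetic genome/annotation/counts with recorded ground truth: planted lncRNAs of every positional class, per-filter decoys, planted promoter triplex sites, planted pair correlations and DE calls |
| `lncpipe.pipeline` | end-to-end orchestration of the above |

## CLI

```bash
# generate a synthetic dataset with ground truth
lncpipe simulate --seed 1 --out-prefix toy --triplex-sites 3

# run the filter cascade
lncpipe filter --candidates toy.candidates.gtf --reference toy.reference.gtf \
    --genome toy.genome.fa --counts toy.counts.tsv --hits toy.hits.tsv \
    --report-out report.tsv --retained-gtf lncrnas.gtf

# classify retained lncRNAs by position
lncpipe classify-position --lncs lncrnas.gtf --coding toy.reference.gtf \
    --out positions.tsv

# triplex prediction and genome-context fractions
lncpipe triplex scan --lncs lncrnas.gtf --genome toy.genome.fa --out interactions.tsv
lncpipe triplex context --annotation toy.reference.gtf --genome toy.genome.fa \
    --interactions interactions.tsv --out fractions.tsv

# coding-potential scores and benchmarking
lncpipe coding-potential --fasta transcripts.fa --out scores.tsv
lncpipe benchmark --predicted pred.tsv --truth truth.tsv

# fuzzy c-means clustering of expression profiles
lncpipe cluster --profiles transformed.tsv --design toy.design.tsv \
    --clusters 4 --dmin-range 2:10 --out-prefix clusters
```

## Notes on key defaults

- Triplex search: minimum tract length 20 nt, maximum error rate 5 %,
  at most 2 consecutive errors, minimum guanine fraction 20 %,
  overlapping sites merged. All configurable via `TriplexParams`.
- Genome context promoters are 1000 bp upstream / 250 bp downstream of
  every transcription start; interaction-pair promoter scope uses
  1500/250. Both configurable and independent.
- TPM expression filter is strictly greater than 1 in at least one
  sample; the threshold is configurable.
- Fuzzy c-means uses fuzzifier m = 2.0 and membership cutoff 0.7 by
  default; the cluster count is a user choice informed by the Dmin curve.
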