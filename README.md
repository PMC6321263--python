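# promusage

Quantifies **alternative promoter usage** of a multi-isoform gene from spliced
RNA-seq alignments, and provides the surrounding bulk-RNA-seq bookkeeping:
expression-level filtering, FPKM/TPM/median-of-ratios normalization, a simple
differential-expression caller with set algebra, and hypergeometric term
enrichment. It is aimed at transcriptomics analysts who have coordinate-level
alignments (SAM/BAM) and gene models (GTF) and want promoter-level activity
estimates for genes — such as porcine *PPARγ* — that are transcribed from
several alternative transcription start sites.

## The statistic

A gene with alternative promoters produces isoforms that differ in their
first exon but share downstream exons. Reads on the part of a first exon that
no other isoform touches are unambiguous evidence for one promoter. For
promoter *i* of a gene with first-exon read counts *c₁ … c_k* in one sample,

- **usage proportion**  π̂ᵢ = cᵢ / Σⱼ cⱼ  (a read-mass proxy for relative
  promoter activity),
- **RPM**  rᵢ = cᵢ · 10⁶ / (mapped reads in the library).

A read counts for promoter *i* when its aligned reference bases (CIGAR
M/=/X only) overlap that promoter's unique first-exon regions by at least
`min_overlap` bases (default 10), with MAPQ ≥ 20, primary alignments only.
Usage between sample groups is compared with a two-sided Welch *t*-test on
per-sample proportions.

Supporting stages: expressed-unit filter (size-factor-normalized count > 3 in
≥ 1 sample); DEG criterion |log₂FC| > 1 with Welch *p* < 0.05 on
log₂(normalized + 1); term enrichment p = P(X ≥ k), X ~
Hypergeometric(N, K, n), BH-adjusted, with richness factor k/K.

## Worked example

Everything is runnable without external data through the built-in simulator,
which emulates a three-promoter gene (150-nt paired-end reads, three
replicates per group, group-specific isoform mixtures):

```
promusage all --output-dir demo --seed 7 --reads-per-sample 20000
```

This writes, among other artifacts, `demo/usage.tsv`:

```
sample_id  group_id  promoter_id  count  rpm     proportion
min1       min       P1           3132   78300   0.3379005286
min1       min       P2           1588   39700   0.1713237674
min1       min       P3           4549   113725  0.490775704
```

and `demo/comparisons.tsv` (group `min` vs `dl`):

```
promoter_id  group_a  group_b  mean_a        mean_b        t_stat         p_value          n_a  n_b
P1           dl       min      0.1824072372  0.3416063375  74.04163737    2.982289744e-06  3    3
P2           dl       min      0.1684249458  0.1638734632  -0.8950064248  0.4216883523     3    3
P3           dl       min      0.649167817   0.4945201994  -43.58857855   7.112749429e-06  3    3
```

Reading: in the `min`-group samples ~34.2% of the gene's transcripts start at
promoter 1, versus ~18.2% in `dl`; the difference is highly significant
(Welch p ≈ 3·10⁻⁶), whereas promoter 2 usage does not differ. The simulator
records per-read truth labels, and with `min_overlap=1` the counter
reproduces them exactly.

Library use mirrors the CLI: `parse_gtf` → `derive_first_exons` →
`count_first_exon_reads` → `usage_proportions` → `compare_usage`, and
`size_factors_median_of_ratios` / `normalize_expression` / `call_degs` /
`enrich` for the expression side.

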