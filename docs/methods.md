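# Methods

## Model and estimand

A gene transcribed from *k* alternative promoters produces isoforms whose
first exons differ while downstream exons are shared. Reads falling on the
bases of a first exon that belong to no other isoform's exons identify one
promoter unambiguously; reads on shared exons are uninformative and ignored.
The package estimates, per sample, the vector of **usage proportions**
πᵢ = cᵢ/Σⱼcⱼ over the gene's usable promoters, where cᵢ is the number of
alignment records overlapping promoter *i*'s unique first-exon regions by at
least `min_overlap` bases.

Two caveats define what πᵢ estimates. First, it is a *read-mass* proportion:
isoforms with longer unique first-exon regions (relative to transcript
length) attract proportionally more reads, so πᵢ equals the molar isoform
proportion only when unique lengths and transcript lengths are balanced
across isoforms. The simulator records both truths so this bias is
measurable; the estimator is validated against read-mass truth. Second,
promoters whose first exon is entirely covered by other isoforms' exons are
unobservable by this method; they are excluded (with a warning), never
silently merged.

## First-exon derivation

Unique regions are computed by interval subtraction: each distinct first
exon minus the union of every exon of every other isoform of the gene.
Isoforms with byte-identical first exons collapse onto one promoter.
Residual pieces shorter than `min_unique_length` (default 25 b — shorter
pieces cannot reliably anchor a 150-nt read) are dropped; a promoter with no
remaining piece is excluded, and fewer than two usable promoters is an
error. Whether to count on whole first exons or on unique portions is a
genuine design choice — quantifying on unique portions is this package's
decision, because it makes each counted read attributable to exactly one
promoter at the cost of discarding shared first-exon bases.

Coordinates are 1-based inclusive (GTF convention) everywhere inside the
package; the BED6 exporter converts to 0-based half-open at the boundary.

## Counting policy

A record counts when it is mapped, primary, non-supplementary, passes MAPQ
(default ≥ 20), and its M/=/X reference bases overlap one promoter's regions
by ≥ `min_overlap` (default 10; N, D, S, I ops contribute nothing). Reads
bridging two promoters' regions go to the larger overlap; exact ties are
discarded and tallied. Duplicates are included by default (the upstream
protocol is unknown; configurable). In fragment mode a pair counts once,
and mates voting for different promoters are discarded. The RPM denominator
is the whole-file count of mapped units passing those filters — "reads per
million mapped reads" — not the first-exon total; both conventions exist,
and proportions are unaffected by the choice.

## Group comparison

Per-sample proportions are compared between groups with a two-sided Welch
(unequal-variance) *t*-test, computed on raw proportions by default; an
arcsine-square-root option exists for variance stabilization. Proportions
are computed per sample and then averaged per group (never pooled counts),
matching the per-replicate error structure of small-n designs. Degenerate
zero-variance cases are handled explicitly (equal means → p = 1). With
three replicates per group, the null calibration test shows mild
conservatism (rejection ≈ 0.034 at α = 0.05), which is expected Welch
small-sample behaviour. No multiple-testing correction is applied across
promoters (there are typically three).

## Expression stages

**Size factors** are the literal median-of-ratios: s_j = median over genes
of count[g,j]/geomean_g(count[g,·]), the median taken over genes with a
positive geometric mean. Note two properties often glossed over: factors are
defined only up to a common scale (scaling a column by *k* scales its
factor *ratio* to other samples by *k*, not the absolute factor), and when
the number of usable genes is even, a ratio-space median (arithmetic
midpoint) differs slightly from a log-space median (geometric midpoint);
this package uses ratio space, and the cross-check against a log-space
reference implementation agrees exactly for odd counts and to a few percent
at even-count midpoints.

**FPKM/TPM** follow the standard definitions; TPM columns sum to 10⁶ by
construction and equal column-renormalized FPKM. The **expressed-unit
filter** keeps genes with normalized count > 3 (default) in at least one
sample.

**DEG calling** is deliberately simple and is labelled as such: fold-change
from group means of size-factor-normalized counts with pseudocount 1, and a
two-sided Welch *t* on log₂(normalized + 1); a gene is a DEG when
|log₂FC| > 1 and p < 0.05. This is not a negative-binomial GLM — no
dispersion shrinkage, no independent filtering — and it trades power at low
counts for transparency. Note the pseudocount compresses fold-changes near
the detection floor: true group means of 8 vs 2 give log₂(9/3) ≈ 1.58, not
2. Set algebra over named DEG lists reports shared counts with *both*
shared/union and shared/total percentages, because the denominator
convention is ambiguous in common usage.

## Enrichment

Over-representation only: p = P(X ≥ k), X ~ Hypergeometric(N, K, n), summed
in log space (lgamma-based log-pmf terms combined by a max-shifted
exponential sum) so extreme tails keep full relative precision — verified
exhaustively against exact rational enumeration for every parameterization
with N ≤ 60 and spot-checked at N = 2000. Benjamini–Hochberg is the plain
step-up, cross-checked against statsmodels. Terms smaller than
`min_term_size` (default 5, a conventional stability floor) are not tested;
q-values are computed over tested terms only. Each term gets a richness
factor k/K. No ontology-graph propagation is performed — annotation maps
must be pre-propagated if parent-term inheritance is wanted.

## Synthetic data

The simulator generates the design the pipeline targets: one gene, three
isoforms with distinct 300-b first exons and identical shared downstream
exons (300/250/450 b, 700-b introns), 150-nt paired-end fragments
(truncated-normal length, mean 250, sd 30), three replicates per group,
emitted as coordinate-sorted spliced SAM with `N` CIGAR ops across introns.
Default group mixtures are (0.3403, 0.1615, 0.4982) and (0.1869, 0.1694,
0.6437) — an obese-type group favouring promoter 1 versus a lean-type group
favouring promoter 3, the pattern reported for the porcine *PPARγ* locus.
Reads are emitted already aligned (no FASTQ/aligner step): the pipeline's
scope starts at alignments, and this keeps tests hermetic. Default depth is
20,000 fragments per sample at this locus, a plausible per-gene depth for a
highly expressed gene in a several-hundred-million-read study; validation
tests that quantify estimator error use 10⁵ fragments per sample.

Per-read truth labels are assigned in transcript coordinates (read interval
versus the unique-first-exon segments), a code path independent of the
genomic interval intersection used by the counter, so exact-recovery tests
are a genuine cross-validation. The recorded expected read-mass shares are
computed exactly under the sampling scheme (uniform fragment start,
discretized truncated-normal length, both mates counted); with the default
equal lengths they reduce to the molar mixture. A counts-level shortcut
(`simulate_usage_counts`, multinomial draws from the read-mass shares — the
exact conditional distribution of first-exon counts given their total) is
used for replicate-heavy calibration studies, e.g. the 2,000-replicate
Welch null.

Count matrices are negative-binomial (variance μ + αμ², α = 0 giving the
Poisson limit) with log-normal gene means (median 150, log-sd 1), mild
log-normal sample-depth variation (log-sd 0.1), and a planted fraction of
genes (default 10%) whose group-B means are shifted by ±2 log₂ units with
random sign. Annotation maps are random term–gene assignments with one
deliberately over-represented term (30% of the query set drawn from it).

What the simulator does *not* model — sequencing errors and base qualities,
PCR duplicates, GC and positional bias, intron retention, multi-gene
overlapping loci, mapping ambiguity — bounds what passing tests show:
correctness of the counting/estimation machinery given correct alignments,
not robustness to alignment artifacts of real libraries.

## Numerical and interface choices

- Welch statistics via scipy; degenerate variance cases patched explicitly
  so p ∈ (0, 1] always holds.
- BH step-up and the hypergeometric tail are implemented directly (they are
  the tested contracts); scipy/statsmodels serve as independent
  cross-checks in the test suite, not as the implementation.
- Determinism: every stochastic routine takes a seed; per-sample streams
  are keyed by (seed, CRC32(sample id)), so sample files are independent
  yet reproducible, and repeated runs are byte-identical.
- CLI exit codes: 0 success, 1 usage error, 2 runtime error; partial
  outputs of a failed stage are removed.
- Problem sizes in the validation suite: 50 random SAM files for the
  counting oracle, 3 × 10⁵ fragments for proportion recovery, 2,000 null
  replicates for calibration, N ≤ 60 exhaustive enumeration for the
  hypergeometric tail, 100 replicates for enrichment ranking, 2,000 genes
  for DEG recovery, and a twice-run end-to-end pipeline (5,000 fragments,
  1,000 genes) for byte-level determinism.

## Known limitations

- Proportions are read-mass, not molar (see above); no deconvolution from
  shared exons is attempted.
- The DEG caller is a transparent stand-in, not a dispersion-modelling GLM;
  its operating characteristics are only validated on the simulator's NB
  conditions.
- Exact published promoter-usage p-values from any particular study are not
  reproduction targets: they depend on grouping choices and raw data not
  shipped here.
- GFF3 is not parsed (GTF only); BAM random access requires an index, and
  counting streams sequentially.
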