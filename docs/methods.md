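# Methods

This note records what each stage of `cistrokit` computes, the conventions
and tunable parameters behind it, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer would want written
down. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and containers

All internal coordinates are 0-based half-open (BED convention). Printed
1-based inclusive ranges are converted on ingest by `to_zero_based`, so a
range printed as `chr9:33,437,258–33,437,811` has length
`end − start = 554` internally. The peak center of `[start, end)` is
`floor((start + end)/2)`. Chromosome names match by exact string equality —
no `chr` aliasing — so fixture mismatches fail loudly.

Coverage is a dense, uniformly binned array per chromosome
(`CoverageTrack`); the terminal bin may be short. The per-base value at a
position is the value of its bin, and interval queries are width-weighted
bin sums computed from cached cumulative sums. bedGraph is the exchange
format; the reader infers the bin width as the GCD of all interval
boundaries and rejects overlapping lines.

Two window conventions coexist deliberately:

- **Ranking** (`rank_by_signal`) clips the ±250-bp averaging window at
  chromosome ends and shrinks the denominator, so terminal peaks are not
  zero-penalized in bottom-k / top-k cuts.
- **Reference-point matrices** (`signal_matrix`) zero-fill beyond
  chromosome ends with a full-width denominator, matching the behavior of
  the standard heatmap tooling they emulate.

## Cistrome categorization

Overlap is ≥ 1 bp, with no fraction-of-overlap option. Reproducible peaks
keep the first replicate's coordinates; shared peaks keep factor A's
coordinates (the first-file asymmetry of set intersection is inherent to
the procedure, so it is made explicit — which factor is "A" is the
caller's choice). `categorize` re-asserts on every call that no
factor-specific peak overlaps the other factor's set and that shared plus
A-specific partition the A peaks. Exclusion filtering drops peaks on
`chrM`, on contigs whose name starts with `chrUn`, and anything overlapping
a user-supplied blacklist by ≥ 1 bp.

Accessibility stratification ranks peaks by mean basal ATAC signal over
±250 bp of the center (descending; exact ties break deterministically by
(chrom, start)). The low cut takes the bottom *k* and then removes peaks
overlapping accessible-chromatin peak calls, so the returned set can be
smaller than *k*; the high cut takes the top *k* unfiltered. At full study
scale the cut sizes are the `PipelineConfig` defaults (17,125 / 3,296 /
6,593); on synthetic data the caller passes cut sizes scaled to the
simulated cistrome.

## Gene regulation linkage

Gene categories from two DE tables (outer-joined; a missing side is
non-significant; missing adjusted p never satisfies any criterion):

| category | rule |
|---|---|
| shared | padj < 0.05 and log2FC > 1.5 for both factors |
| A_specific / B_specific | the same, for exactly one factor |
| non_regulated | padj < 0.5 and 0 < log2FC < 0.5 — jointly for both factors by default (`joint_nonregulated=False` accepts either) |
| other | everything else, including significant down-regulation |

"Other" genes are excluded from fractions and tests; the analysis concerns
upregulation, and down-regulation is out of scope.

Peak-to-gene assignment intersects each labeled peak set with a symmetric
60-kb window centered on every TSS (strand ignored; ≥ 1-bp overlap;
half-open boundaries). A peak assigned to genes of more than one category
is re-assigned to the gene minimizing |peak center − TSS|, ties broken by
lexicographically smallest gene id; peaks whose genes all share one
category are untouched. The nearest-gene metric is center-to-TSS distance —
the simplest defensible choice where the upstream tooling convention is
unspecified.

Stacked-bar fractions map each gene to one display class by precedence
(default shared > A_specific > B_specific > no_peaks; configurable — the
display convention is not derivable from first principles, so it is a
documented option). The Fisher tests are precedence-free: for each
(regulated category, peak label) the 2×2 table compares genes in the
category against non-regulated genes, counting a gene as "has" when it
carries ≥ 1 disambiguated peak of that label, possibly for several labels
at once. Headline p-values are raw (uncorrected) Fisher two-sided
p-values; a Benjamini–Hochberg column is emitted alongside for users who
want it. The two-sided p sums hypergeometric probabilities of margin-fixed
tables at most `(1 + 1e-7)×` as probable as the observed table; the odds
ratio is the sample odds ratio `n11·n22 / (n12·n21)` (∞ when only the
denominator is zero, 1 when both are).

## Sequence environment

GC tracks bin the genome (default 50 bp), counting N in the denominator;
the terminal bin uses its actual width. Group comparisons use per-region
mean GC over ±5 kb of the peak center (per-region means rather than
per-bin values — the least granular statistic consistent with a
region-level claim) in a two-sided Mann–Whitney test.

`mann_whitney` enumerates the full permutation distribution of U
(midranks for ties) when `n_x + n_y ≤ 20` and otherwise uses the normal
approximation with tie and continuity corrections. The two-sided exact p
counts labelings with |U − μ| at least the observed distance, which equals
twice the smaller tail for the symmetric permutation distribution.

PWM scanning: counts → log2-odds with a pseudocount of 0.8 distributed by
the background (uniform by default), the convention of classical TFBS
libraries. Relative score is (raw − min)/(max − min) over the matrix's
score range; the default hit threshold is 0.8. N scores as the column
minimum, so N-rich windows fall below relative thresholds naturally.
Minus-strand hits are reported at plus-strand window coordinates.

Motif enrichment is AME-style but deliberately simplified to an exactly
testable statistic: per sequence the best raw score over both strands, a
one-sided Mann–Whitney (foreground > background), and a Bonferroni
E-value = p × number of motifs tested, flagged below 1e-30. Backgrounds
are either dinucleotide-preserving shuffles (Altschul–Erikson Euler-path
shuffle, deterministic per seed) or the other factor's peak sequences —
the reciprocal design that makes factor-differential motifs visible in
both directions. The built-in catalog holds consensus-derived stand-ins —
the inverted-repeat steroid element (AGAACAnnnTGTTCT), the DR3 direct
repeat (AGAACAnnnAGAACA), and two unrelated decoys (AP-1, GC-box) — not
empirical JASPAR frequencies; real JASPAR text files can be supplied
anywhere a catalog is accepted.

## STARR quantification

Reads are deduplicated within a sample per identical
(chrom, start, end, strand) by the directional UMI network: edges
u → v where Hamming(u, v) = 1 and count(u) ≥ 2·count(v) − 1, components
peeled by BFS from unvisited nodes in decreasing count order. An
exact-match-only mode (`method="unique"`) is available. Counts per region
(≥ 1-bp overlap; a fragment spanning two regions counts in both) are
RPKM-normalized by the full deduplicated library of the sample. Activation
is log2((RPKM_h + pc_h)/(RPKM_v + pc_v)) with a pseudocount equal to the
RPKM of one fragment in that region under the corresponding library — a
scale-free stabilizer for empty regions. Per category the summary reports
mean and median log2 fold change and a paired Wilcoxon signed-rank test
(normal approximation); a single-region category gets NaN, identical
conditions get p = 1.

Because RPKM divides by the per-sample library, global activation shifts
the normalizer (a composition effect intrinsic to RPKM, not a pipeline
defect). With a background-dominated library the combined bias of
composition shift plus pseudocount is ≤ ~0.35 log2 units under the default
synthetic conditions; the recovery tests budget for it.

## The synthetic-data generator

`SimulationConfig` defaults are the study conditions of every recovery
test: 3 chromosomes × 40 Mb; 300 shared / 200 A-specific / 400 B-specific
peaks (width ~ Normal(400, 80) bp), rejection-sampled with a 1-kb
exclusion buffer so no two peaks overlap and category recovery is
well-defined. The genome size gives ~1 peak per 130 kb — the density scale
of a real two-factor steroid-receptor cistrome — which matters: at
desk-scale density (Mb-scale chromosomes) the 60-kb TSS windows saturate
and planting positive linkage for one category mechanically depletes the
others, poisoning the null pairs of the Fisher recovery tests.

Planted structure:

- **GC landscape**: baseline GC 0.41; +0.14 within ±10 kb of B-specific
  centers, −0.06 around A-specific centers (A windows written first, B
  last, so the headline B elevation is exact even when environments
  occasionally abut). Shared-peak environments stay at baseline and serve
  as the measurement reference for delta recovery.
- **Replicates**: per factor and replicate, each true peak is dropped with
  probability 0.05 and its edges jittered by Normal(0, 25 bp).
- **Closed chromatin**: half of the B-specific peaks are flagged closed;
  their basal ATAC amplitude is attenuated 10×. Accessible-chromatin calls
  are the open truth peaks. Coverage tracks are Gaussian bumps over
  Poisson bin noise; hormone-response and H3K27ac tracks (gain only for
  factor B by default, a configurable asymmetry toggle) are emitted for
  completeness.
- **Expression**: 800 genes; 10–15% per regulated category get a TSS
  within 15 kb of a distinct peak of that category and a planted effect
  log2FC ~ Normal(2.5, 0.5) in the corresponding factor(s). Null genes
  carry small true changes ~ Normal(0, 0.15) shared between factors plus
  Normal(0, 0.03) factor wobble, tested against a standard error of 0.05
  (z-test, BH-adjusted across genes). Separating biological spread from
  standard error is what populates the non-regulated reference class
  (~150 genes) the Fisher tests need; a pure-noise null (spread = SE)
  leaves almost nothing below the BH-adjusted 0.5 cutoff. The DE layer is
  a generative shortcut — the pipeline consumes only (log2FC, padj), so no
  count model is simulated.
- **Motifs**: the DR3 consensus is written into 90% of A-specific peaks
  and the inverted repeat into 90% of shared and B-specific peaks, at a
  uniform offset within ±100 bp of the center on a random strand; every
  plant is ledgered.
- **STARR**: per sample, each region emits Poisson(50 × multiplier) true
  fragments (multipliers: 4× for the factor's own bound categories, 1×
  otherwise) plus 400,000 uniform background fragments; every read gets a
  random 8-mer UMI, and duplicates re-emit existing reads at an expected
  50% rate. Duplication is exact re-emission, so deduplication can be
  scored for exact recovery of true fragment counts.

All randomness flows from one seed through named substreams (peaks,
genome, replicates, coverage, expression, starr, motifs), so a bundle is
byte-reproducible and components can be regenerated independently (the
expression and STARR layers do not require the genome).

**Recovery metrics.** Category recall is conditional on replicate
detection: a truth peak dropped from a factor's replicates cannot be
categorized at all, so it is excluded from the denominator — the metric
isolates the categorization step from detection loss, which is a property
of the simulated dropout, not of the algebra. The closed-peak cut size
equals the number of truth-closed peaks among detected B-specific peaks
(the scaled analog of a bottom-17,125 cut chosen from a real signal
distribution).

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: read-level sequencing noise and mapping
artifacts (fragments and peaks are emitted directly), fragment GC bias,
nucleosome positioning, peak-width/signal correlations, distance-decay of
enhancer–promoter regulation beyond the hard 60-kb window, count-model DE
dispersion, and motif occurrences in background sequence beyond what the
base composition produces by chance.

## Numerical choices and degenerate inputs

- Fisher p-values come from `scipy.stats.fisher_exact` (which implements
  the same `(1 + 1e-7)` tie tolerance the contract states); the test suite
  checks it against an exact rational enumeration over all margins up to
  total 48.
- The exact Mann–Whitney enumeration is authored here because the standard
  library routine's exact mode does not handle ties; the asymptotic branch
  delegates to it. Exhaustive permutation oracles in the tests cover both.
- A degenerate PWM whose max and min scores coincide scores every window
  with relative score 1 rather than dividing by zero.
- Empty peak sets propagate as empty results; an empty signal matrix
  refuses to produce a mean profile; an empty group is an error for every
  rank test.
- Motifs wider than every input sequence are skipped with a warning rather
  than failing the whole enrichment run.
- `random_sample`, `shuffle_background` and the generator take explicit
  seeds; identical seeds give identical output.

## Problem sizes

The default synthetic conditions (120-Mb genome, 900 peaks, 800 genes,
~2 M true STARR fragments before duplication) run the full pipeline in
under a minute on one CPU within ~2 GiB; the test suite holds most
module-level fixtures at a 2-chromosome, 4-Mb scale and reserves the
default conditions for the end-to-end recovery tests.

## Known limitations

- BAM/SAM and bigWig are not read or written; alignment-level processing
  (mapping-quality filters, duplicate marking) has no home here because
  the pipeline starts from peak/track/fragment files.
- The AME-style enrichment is a rank-sum simplification; it preserves the
  reciprocal-background design but does not reproduce any particular
  external tool's E-values.
- Liftover, fraction-of-overlap intersection modes, repressed-gene
  analysis, and Hi-C-informed peak-gene linkage are out of scope.
- The built-in motif catalog is consensus-derived; analyses of real data
  should supply empirical JASPAR matrices.
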