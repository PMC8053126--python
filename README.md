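# cistrokit

Comparative analysis of the cistromes of two paralogous transcription
factors — the kind of question posed by the androgen and glucocorticoid
receptors, which share a nearly identical DNA-binding domain yet regulate
distinct gene sets. Given two factors' ChIP-seq peak sets (two replicates
each), accessibility and histone-mark coverage tracks, per-factor
differential-expression tables and STARR reporter fragments, `cistrokit`
answers, reproducibly and with explicit statistics:

- **Which binding sites are shared and which are factor-specific?**
  Reproducible peaks are the replicate-1 peaks overlapping replicate 2 by
  ≥ 1 bp (BEDtools `intersect -u` semantics), minus blacklisted regions and
  excluded contigs; categories come from cross-factor ≥ 1-bp overlap.
- **Which specific sites sit in closed chromatin?** Peaks are ranked by
  mean basal ATAC signal over ±250 bp of the peak center; the bottom-*k* cut,
  cleaned of anything overlapping an accessible-chromatin peak call, is the
  pioneer-like ("closed") subset; the top-*k* cut is the high-accessibility
  subset.
- **Does binding near a gene predict its regulation?** Genes are classed as
  factor-specific / shared upregulated (adjusted *p* < 0.05 and
  log2FC > 1.5), non-regulated (adjusted *p* < 0.5 and 0 < log2FC < 0.5 for
  both factors) or other; each peak set is intersected with a 60-kb window
  centered on every TSS, peaks touching windows of more than one gene
  category are re-assigned to the nearest gene, and each category is tested
  against the non-regulated reference with Fisher's exact test on 2×2
  tables (gene has ≥ 1 peak of the label vs none).
- **Do the sequence environments differ?** Per-bin GC content (50-bp bins,
  `bedtools nuc` convention for N), ±5-kb GC profiles around peak centers,
  and a Mann–Whitney *U* comparison of per-region mean GC between peak
  groups; PWM scanning (log2-odds with a background-distributed
  pseudocount of 0.8) reports hits above an 80% relative score
  (raw − min)/(max − min), and AME-style enrichment ranks motifs by a
  one-sided rank-sum on per-sequence best scores with a Bonferroni E-value
  over the catalog, against shuffled-input or reciprocal-factor
  backgrounds.
- **Which bound regions are hormone-activated enhancers?** STARR reads are
  deduplicated per genomic position by the directional UMI rule
  (count(u) ≥ 2·count(v) − 1 at Hamming distance 1), counted per region,
  RPKM-normalized, and summarized per peak category as
  log2((RPKM_hormone + pc)/(RPKM_vehicle + pc)) with a paired Wilcoxon
  signed-rank test.

Because the deposited sequencing data of any particular study are not
needed to exercise the method, the package ships a seeded synthetic-data
generator (`cistrokit.simulate`) that emits a genome, jittered replicate
peak sets, coverage tracks, DE tables, planted motifs and duplicated STARR
reads together with a ground-truth ledger, so every pipeline stage can be
scored on parameter recovery.

## Worked example

```python
from cistrokit.simulate import SimulationConfig, generate
from cistrokit import evaluate as ev

ds = generate(SimulationConfig(), seed=1)     # synthetic study conditions
cats = ev.build_cistrome(ds)                  # replicate overlap + categories
print(f"shared={len(cats.shared)}  A-specific={len(cats.a_specific)}  "
      f"B-specific={len(cats.b_specific)}")
gc = ev.gc_recovery(ds, cats)
print(f"GC contrast: {gc['direction']}, p = {gc['pvalue']:.2e}; "
      f"B-specific GC elevation = {gc['delta_b_recovered']:+.3f}")
row = ev.linkage_analysis(ds, cats)["enrichment"].set_index(
    ["gene_category", "peak_label"]).loc[("A_specific", "A_specific")]
print(f"A-specific genes x A-specific peaks: OR = {row['odds_ratio']:.1f}, "
      f"p = {row['pvalue']:.2e}")
```

prints

```
shared=248  A-specific=203  B-specific=392
GC contrast: B > A, p = 1.76e-84; B-specific GC elevation = +0.135
A-specific genes x A-specific peaks: OR = 96.3, p = 1.43e-43
```

The generator planted 300 shared, 200 A-specific and 400 B-specific peaks;
after 5% per-replicate dropout the pipeline recovers the categories of the
detected peaks, finds the planted +0.14 GC elevation around B-specific
sites (the analog of the higher GC content of glucocorticoid-receptor-
specific sites), and the Fisher linkage recovers the planted gene–peak
association for A-specific genes.

## Command-line interface

Every stage is also a `cistrokit` subcommand operating on plain
BED/bedGraph/FASTA/TSV files:

```sh
cistrokit simulate --seed 1 --outdir bundle/
cistrokit peaks --a-rep1 bundle/peaks_A_rep1.bed --a-rep2 bundle/peaks_A_rep2.bed \
    --b-rep1 bundle/peaks_B_rep1.bed --b-rep2 bundle/peaks_B_rep2.bed \
    --atac-basal bundle/atac_basal.bedgraph --accessible-calls bundle/accessible_calls.bed \
    --chrom-lengths lengths.tsv --outdir peaks_out/
cistrokit link --de-a bundle/de_A.tsv --de-b bundle/de_B.tsv --tss bundle/tss.tsv \
    --peaks shared=peaks_out/shared.bed --peaks A_specific=peaks_out/a_specific.bed \
    --peaks B_specific=peaks_out/b_specific.bed --outdir link_out/
```

See `cistrokit --help` for `profile`, `gc`, `motifs` and `starr`.

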