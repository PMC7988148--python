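# recat — regulatory-element catalogs and comparative epigenomics

`recat` is a Python toolkit for the post-processing side of tissue-atlas
functional-annotation studies: it turns per-tissue chromatin-state
segmentations into a species-level catalog of regulatory elements (REs),
predicts topologically associating domains (TADs) from CTCF motif
orientation, links enhancers to target genes by correlation inside TADs,
calls cross-species RE conservation over whole-genome alignment blocks,
computes ChIP-seq library QC metrics, and tests GWAS-SNP enrichment in
REs.  It is aimed at groups working with multi-tissue ChIP-seq/ATAC-seq
panels in species where Hi-C and large RE compendia are not available.

A seeded synthetic-data generator (`recat.simulate`) produces every input
the pipeline consumes together with planted ground truth, so each stage is
validated end to end against known answers.

## The methods in brief

* **RE catalog.** Within each tissue, consecutive segments whose chromatin
  state is in the active set {1–6, 8, 9, 11} of a 14-state model are merged
  into maximal runs; runs are then union-merged across tissues (bookended,
  BEDTools semantics).  Each combined RE keeps the set of contributing
  tissues (`tissue_specific` ⇔ exactly one) and is classified by
  precedence: *TSS-proximal* if within 2 kb of a protein-coding TSS, else
  *excluded* if within 2 kb of a non-coding/unannotated TSS, else *genic*
  if overlapping a gene body by ≥ 1 bp, else *intergenic*.
* **TADs.** CTCF peaks pooled across tissues are scanned with a PWM
  (log-odds vs uniform background; the p-value→score threshold is computed
  by exact dynamic programming over the discretized null score
  distribution).  Each peak keeps its best hit; a forward site pairs with
  the nearest downstream reverse site within 1 Mb (convergent
  loop-extrusion logic) and overlapping/nested loops merge into TADs.
* **Enhancer–gene links.** RE H3K27ac counts and gene expression counts
  are TMM-normalized to CPM (trimmed mean of M-values: 30%/5% two-sided
  trims on M/A, precision-weighted, factors scaled to geometric mean 1).
  Rows whose max/min CPM ratio is ≤ 6 are dropped.  Every (RE, gene) pair
  sharing a TAD (RE midpoint, 5′-most coding TSS) is tested by Spearman
  correlation across all 16 samples; p-values (t-approximation on n−2 df)
  are Benjamini–Hochberg adjusted once genome-wide and pairs with q < 0.05
  and ρ > 0 are reported, alongside a naive overlapping/nearest-gene
  baseline.
* **Conservation.** Source REs are mapped through gapless alignment
  blocks (strand-aware, majority-chromosome rule, min–max span); a mapped
  RE is *conserved* when its image overlaps a target-species RE by ≥ 1 bp.
  Lineage-level conservation is set intersection over per-target results.
* **QC.** NRF, PBC1 = N1/Nd, PBC2 = N1/N2 on (chrom, start, end, strand)
  locations; FRiP; Jensen–Shannon distance (log2, square root) between
  binned read-start distributions of ChIP and input.
* **GWAS overlap.** Per-SNP in-RE flags (half-open containment), in/out
  p-value densities, and per-category Fisher exact enrichment against
  uncategorized SNPs.

## Worked example

```python
from recat import (
    Simulation, small_config, NormalizedMatrix, predict_links,
    variance_filter, predict_tads, build_catalog,
)

sim = Simulation(small_config(seed=1))   # 2 x 2 Mb genome, 120 REs, 12 TADs

catalog = build_catalog(sim.segmentations(), sim.truth.genes, sim.truth.extra_tss)
print(f"catalog: {len(catalog)} REs, "
      f"{sum(r.tissue_specific for r in catalog)} tissue-specific")

genome, peaks, pwm = sim.ctcf_architecture()
tads, sites = predict_tads(genome, peaks, pwm)
print(f"TADs: {len(tads)} predicted from {len(sites)} oriented CTCF sites")

genes_df, res_df = sim.expression_and_signal()
signal = NormalizedMatrix(res_df)
expr = NormalizedMatrix(genes_df)
signal = NormalizedMatrix(signal.counts.loc[variance_filter(signal.cpm)])
expr = NormalizedMatrix(expr.counts.loc[variance_filter(expr.cpm)])
links, summary = predict_links(signal, expr, tads, sim.truth.res,
                               sim.truth.genes, re_ids=sim.truth.re_ids)
recovered = set(zip(links.re_id, links.gene_id)) & sim.truth.links
print(f"links: {len(links)} pairs at q < 0.05 "
      f"({summary['n_tests']} tests); {len(recovered)}/{len(sim.truth.links)} "
      f"planted links recovered")
```

Output:

```
catalog: 120 REs, 23 tissue-specific
TADs: 12 predicted from 24 oriented CTCF sites
links: 12 pairs at q < 0.05 (669 tests); 12/12 planted links recovered
```

The catalog recovers the planted REs exactly (the generator writes REs as
runs of active states); the 12 TADs equal the planted domains
interval-for-interval because their boundaries are exact convergent
consensus embeddings; and all 12 planted RE→gene links clear BH q < 0.05
at the default association strength (Spearman ≈ 0.9 across 16 samples).

Every stage is also exposed on the command line:

```bash
recat simulate --outdir sim --seed 1
recat annotate --segmentation-dir sim/segmentations --gff sim/genes.gff3 \
      --extra-tss sim/ground_truth/extra_tss.tsv --out catalog.bed
recat tads --fasta sim/genome.fa --peaks sim/ctcf_peaks.bed \
      --motif sim/ctcf_motif.meme --out tads.bed
recat link --catalog catalog.bed --tads tads.bed --gff sim/genes.gff3 \
      --signal sim/re_counts.tsv --expr sim/gene_counts.tsv --out links.tsv
recat conserve --map sim/alignment_blocks.tsv --src-catalog catalog.bed \
      --tgt-catalog sim/target_catalog.bed --out cons.tsv
recat gwas-overlap --snps sim/snps.tsv --catalog catalog.bed --out gwas/
recat qc --reads chip.bed --input input.bed --peaks peaks.bed --out report.tsv
```

## Layout

```
src/recat/
  intervals.py     coordinate types and interval algebra (0-based half-open)
  io.py            BED / GFF3 / FASTA / MEME / TSV readers and writers
  simulate.py      seeded synthetic-data generator with ground truth
  annotate.py      RE catalog construction and classification
  motif.py         PWM scanning with exact DP score thresholds
  tads.py          CTCF-orientation TAD prediction
  linking.py       TMM/CPM, filters, within-TAD Spearman link prediction
  conservation.py  alignment-block interval mapping and conservation calls
  gwas.py          SNP-in-RE overlap and Fisher category enrichment
  qc.py            NRF / PBC1 / PBC2 / FRiP / JSD
  stats.py         Spearman, BH step-up, Fisher exact (shared primitives)
  cli.py           `recat` command-line interface
```

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
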