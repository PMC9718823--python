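# chromlink

Integrative chromatin analysis for dissecting how a histone mark laid down
in two genomic compartments — gene bodies and distal regulatory elements —
controls gene expression. The package was built around the DOT1L/H3K79me2
problem in cardiomyocytes: when the only H3K79 methyltransferase is ablated,
which expression changes are explained by loss of gene-body methylation,
which by loss of methylated regulatory elements (K79-REs), and which
elements act as activators versus silencers?

`chromlink` provides the full analysis chain as a tested, reusable library
plus CLI:

* **Gene annotation model** — GENCODE-dialect GTF parsing, strand-aware
  most-5' TSS, 400 bp promoters, and an exclusive per-base feature map
  (promoter/TSS > UTR > exon > intron > intergenic) for peak distribution
  pie-chart style summaries.
* **Gene-body methylation** — per-gene read counts and covered fraction;
  a gene is gene-body methylated when coverage ≥ 50 reads and covered
  fraction ≥ 0.2 (inclusive); scaled metagene profiles (TSS→TTS, ±2 kb
  flanks).
* **Hi-C contacts** — plain-text triplet dumps at 5 kb resolution,
  Knight–Ruiz matrix balancing (Sinkhorn–Knopp fallback), masked-bin
  handling, symmetric contact lookups.
* **Adapted Activity-by-Contact scoring** — for a gene *g* and enhancer
  *e* (an H3K27ac peak with signal *A<sub>e</sub>*):

  &nbsp;&nbsp;&nbsp;&nbsp;*A<sub>e,g</sub>* = *A<sub>e</sub>* ·
  *C<sub>e,g</sub>* / Σ<sub>*j*∈*G<sub>e</sub>*</sub> *C<sub>e,j</sub>*

  &nbsp;&nbsp;&nbsp;&nbsp;score(*e*,*g*) = *A<sub>e,g</sub>* ·
  *C<sub>e,g</sub>* / Σ<sub>*i*∈*E<sub>g</sub>*</sub> *A<sub>i,g</sub>* ·
  *C<sub>i,g</sub>*

  with *C* the KR-balanced contact between the enhancer-midpoint bin and
  the TSS bin, *E<sub>g</sub>* the enhancers within a 5 Mb window centered
  on the TSS, and *G<sub>e</sub>* the genes whose windows contain *e*.
  Scores are relative contributions (they sum to 1 per gene); pairs with
  score ≥ 0.02 form the regulatory map. Sex chromosomes are excluded.
* **Regulatory-element integration** — an RE is differential for a mark
  when ≥ 10% of its length is covered by differential peaks; K79-REs and
  differential-H3K27ac REs are mapped to genes through the control-map
  links (cKO-only REs through the cKO map); genes are categorized into
  UpSet classes (DE direction × gene-body methylation × K79-RE linkage ×
  differential-acetylation linkage); cumulative log2FC distributions are
  compared between strata with two-tailed Kolmogorov–Smirnov tests.
* **Motif enrichment** — TRAP biophysical affinities (λ = 0.7,
  ln R₀ = 0.584·W − 5.66) of expressed TFs over activating versus
  silencing K79-RE sequences, one-tailed Mann–Whitney in both directions,
  Benjamini–Hochberg adjustment.
* **Synthetic-data generator** — a compact two-autosome + chrX genome
  with planted gene classes, condition-specific peaks and reads, a
  distance-decaying Hi-C matrix with planted enhancer–promoter loops,
  a generator-side differential-expression table, and motif-seeded RE
  sequences, all deterministic given a seed — the ground truth every
  stage is validated against.

## Worked example

Generate a synthetic dataset with planted truth, run the whole pipeline on
it, and score how well the planted structure is recovered:

```bash
chromlink simulate-run --out demo --seed 1 --n-genes 120
```

prints

```json
{
  "category_accuracy": 0.9666666666666667,
  "n_genes": 120,
  "planted_motif_rank": 1,
  "ks_p_many_re": 8.70817722936145e-06,
  "ks_D_many_re": 0.8285714285714285
}
```

meaning: 96.7% of the 120 genes were recovered in their planted category
(DE direction × gene-body methylation × K79-RE linkage); the motif planted
into silencing K79-REs ranked first by adjusted p in the enrichment screen;
and genes linked to ≥ 6 K79-REs showed a cumulative-log2FC shift against
the 1–5 stratum detected at KS D = 0.83, p ≈ 9 × 10⁻⁶. The stage outputs
land in `demo/report/` — for example the UpSet category table:

```
direction  category  n_genes  percent
down       GB+RE+    14       77.78
down       GB+RE-    4        22.22
up         GB-RE+    10       100
```

(the planted structure mirrors the biology: most downregulated genes carry
both gene-body methylation and K79-REs, upregulated genes carry silencing
K79-REs without gene-body methylation).

The same pipeline runs on real inputs through a YAML config
(`chromlink run-all --config config.yaml --out report/`) naming the GTF,
chrom.sizes, narrowPeak files per mark and condition, differential-peak
BEDs, per-chromosome Hi-C triplet dumps, the differential-expression
table, JASPAR PFMs and RE FASTA; `chromlink simulate --out dir --seed N`
writes a synthetic dataset without running the analysis.

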