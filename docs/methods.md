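# Methods

This note documents the models and procedures implemented in `chromlink`,
the parameters that matter, the numerical choices, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
the design was genuinely open.

## Coordinate and annotation conventions

All internal coordinates are 0-based half-open (BED convention); GTF
coordinates (1-based inclusive) are converted at the I/O boundary, which
confines off-by-one risk to one reader/writer pair (round-tripping is
tested exactly). Genes are modelled at gene level only: the gene body is
the span from the most-5' to the most-3' annotated coordinate, the TSS is
the most 5' position in gene orientation, and the promoter is a single
400 bp window centered on that TSS (±200 bp). One promoter definition is
used everywhere — in the feature map and in the promoter-overlap flags of
the regulatory map.

The feature map assigns every base exactly one label with precedence
promoter/TSS > UTR > exon > intron, evaluated jointly over all genes, so
any gene's promoter beats any other gene's exon and the result is
independent of gene order. The precedence order itself is a convention: promoters get priority
because they are added on top of the split annotation and reported as
their own category, and UTRs beat exons because a UTR is the more
specific annotation of the two. Bases inside a gene body
covered by nothing else are introns; everything else is intergenic. The
map is stored as one uint8 array per chromosome (1 byte/bp) — the right
trade-off for the compact genomes this package targets; a chromosome-scale
mammalian genome would need ~250 MB, acceptable but worth knowing.

## Gene-body methylation

Per gene we count read intervals overlapping the gene body by ≥ 1 bp and
the fraction of gene-body bases with non-zero coverage. A gene is
gene-body methylated when count ≥ 50 **and** fraction ≥ 0.2, both
inclusive, computed on control-condition reads. Replicates: fractions are
averaged, read counts summed (the alternative, averaging counts, halves
the effective threshold — summing treats the replicates as one library,
which is what a fixed absolute read cutoff implicitly assumes). The 50-read cutoff is an absolute count, without library-size
normalization.

Metagene profiles rescale each gene body linearly to 5,000 bp, attach
unscaled 2,000 bp flanks, orient 5'→3' (minus-strand genes reversed),
average in 20 bp bins across genes, and skip genes with zero total signal.
An input track, when provided, normalizes by per-bin ratio of ChIP to
input means.

## Expression

RPKM = count / (merged-exon kb) / (mapped reads in millions). A gene is
expressed when RPKM ≥ 1 in at least one condition; expressed genes are
down/up when FDR ≤ 0.05 and log2FC ≤ −0.5 / ≥ +0.5 (all boundaries
inclusive). Quartiles rank expressed genes by
control-condition RPKM (the reference state; a pooled ranking would be
an equally defensible convention — the control ranking is fixed here)
with stable gene-id tie-breaks and group sizes differing by at most one. Differential testing
itself is upstream: the module consumes a table.

## Hi-C balancing

Contacts are loaded from per-chromosome "pos1 pos2 count" triplet dumps
with positions at bin starts (5 kb default), summed over duplicates, and
stored dense and symmetric. Balancing finds x > 0 with
B = diag(x)·M·diag(x) having equal (unit) row sums over unmasked bins;
all-zero bins are masked out of the solve and report zero contact.

The solver is the Knight–Ruiz inner–outer Newton-CG iteration (the
standard Hi-C normalization); if it fails to reach a row-sum coefficient
of variation below `tol` (default 1e-6), a damped symmetric
Sinkhorn–Knopp fixed point (x ← sqrt(x / Mx), which avoids the
2-cycling of the undamped map) is run from scratch; failure of both
raises with the residual. Balanced values are used as-is — the adapted
ABC score is scale-invariant, so the overall normalization constant is
irrelevant. No distance pseudocount is added for zero-contact pairs: the
adapted score as defined has no contact imputation, so zero contact means
zero score. A `prenormalized` flag lets already-balanced dumps pass
through untouched. Only intra-chromosomal contacts are modelled.

## Adapted Activity-by-Contact scoring

Candidates for gene g are H3K27ac peaks whose midpoint lies in
[TSS − 2.5 Mb, TSS + 2.5 Mb) — the representative points (peak midpoint,
most-5' TSS) follow the reference ABC convention, and the half-open
boundary makes membership deterministic. Promoter peaks are candidates
like any other (promoters can act as distal regulatory elements for other
genes); surviving elements carry a promoter-overlap flag. Chromosomes X
and Y are excluded. The enhancer's activity is shared across its own
candidate target genes G_e in proportion to contact (gene-specific
activity), and the score of a pair is its share of the gene's total
activity-times-contact mass — so unthresholded scores sum to exactly 1
for every gene with any positive-contact candidate, and the score is
invariant to rescaling all activities or all contacts. G_e contains *all*
annotated autosomal genes whose window covers the enhancer, with no
expression filter (the narrower alternative is not stated anywhere and
would couple the regulatory map to the expression table). Pairs with
score ≥ 0.02 (inclusive) are kept. Interactions are computed per
condition from that condition's peak set against the same Hi-C matrix.

## Regulatory-element integration

An RE (an ABC-surviving H3K27ac peak) is differential for a mark when
≥ 10% (inclusive) of its length is covered by the union of that mark's
differential peaks — union, not sum, so fragmented differential calls do
not double-count. An RE reaching 10% for both acetylation directions is
labelled by the larger covered fraction, ties to "down" — a corner case
that needs a deterministic rule; down is preferred so a tie errs toward
the loss-of-signal reading.

Differential-acetylation REs are attributed to the genes they were linked
to in the **control** regulatory map; REs with no control links at all
are attributed to their cKO-map genes ("present only in cKO" is defined
as absence of any control ABC interaction for that element; peak-call
presence alone does not count, link presence does). An RE linked in both maps contributes nothing to
genes linked only in cKO. K79-RE counts per gene (`n_k79_res`) use
control-map links only: gene categories describe the control regulatory
state that was lost.

Gene categories combine DE direction, gene-body methylation, K79-RE
linkage (> 0) and, when requested, differential-acetylation linkage;
every DE gene lands in exactly one category and percentages sum to 100
per direction.

Stratified effect-size analysis compares cumulative log2FC distributions
between strata with the two-tailed two-sample KS test. Default strata:
gene-body covered fraction in thirds (half-open on the right, so a
fraction of exactly 1/3 is in the middle stratum), K79-RE counts
{0, 1–5, ≥6} (the ≥6 boundary inclusive), and
gene-body-methylated genes split by K79-RE presence. Strata with fewer
than two genes are skipped with a warning. The KS p-value is scipy's
`ks_2samp(method="asymp")`, which
evaluates the KS survival function at effective size nm/(n+m); the D
statistic is checked in the tests against an exhaustive ECDF-grid oracle,
exactly.

## Motif enrichment

TRAP models a PWM as a biophysical binding energy: for each window the
mismatch energy is E = (1/λ)·Σ ln(p_max/p_base) and the occupancy is
R₀e^(−E)/(1 + R₀e^(−E)), summed over all windows on both strands
(N-containing windows contribute 0). λ = 0.7 and ln R₀ = 0.584·W − 5.66
are the published TRAP defaults; with these defaults a perfect consensus site contributes
R₀/(1+R₀) ≈ 0.1 for W = 8 — affinities are expected occupancy, not site
counts. PWMs come from JASPAR count matrices with a +1 pseudocount and a
uniform background; TFs are kept only when their gene has RPKM ≥ 1 in
either condition.

The two compared groups are the K79-REs linked (control map) to
downregulated gene-body-methylated genes ("activating") and to
upregulated non-methylated genes ("silencing"). Each TF is tested with a
one-tailed Mann–Whitney U in both directions — exact p by distribution
enumeration when pooled n ≤ 12 without ties, otherwise the normal
approximation with tie and continuity corrections; two identical constant
samples give p = 1 — and **all** resulting p-values (both directions) are
adjusted as one Benjamini–Hochberg family — adjusting each direction
separately would run two 5% families and double the family-wise error of
the screen. Significance is adjusted p ≤ 0.05 (inclusive).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with planted truth for closed-loop validation. Defaults define the study
conditions: 300 genes on two 10 Mb autosomes plus a 5 Mb chrX (all chrX
genes neutral, to exercise the autosome-only rule), lognormal gene
lengths (median 20 kb), 1–10 exons, mixed strands.

Planted classes over autosomal genes — 15% gene-body-methylated with
activating K79-REs and log2FC −1.5 ± 0.3 (half of them "many-RE": 7–9
elements and an extra −0.5); 5% gene-body-only, −0.7 ± 0.3; 15% silencing
K79-REs without gene-body signal, +1.0 ± 0.3; 65% neutral, 0 ± 0.15 (5%
of them not expressed). Baseline expression places downregulated classes
high (lognormal, median 40 RPKM) and silenced-gene targets low (median
1.8), mirroring the quartile structure of the real data. Counts are
negative binomial (dispersion 0.02 — the low end of what a count-model
fit reports for homogeneous sorted-cell replicates), 3 vs 3 replicates,
the knockout mean shifted by the planted log2FC; the generator runs its
own naive test (t-test on log2 counts, BH) so the pipeline's expression
module stays a consumer of an upstream DE table.

Hi-C counts at bin distance d are Poisson(μ·(d+1)^(−α)) with μ = 100,
α = 1, within 5 Mb of the diagonal; each planted RE–gene pair receives an
independent extra Poisson((boost−1)·μ_d) with boost = 5, so its mean is
exactly 5× the distance-matched background. Gene-body-methylated genes
get two replicates of tiled control reads over a contiguous 5'-anchored
region of the planted covered fraction (≥ 60 reads each) and a trace in
the knockout; K79-REs are overlapped 30–80% by differential-H3K79me2
intervals; configurable subsets of activating/silencing REs get
differential acetylation (down/up), plus a few cKO-only elements.
Silencing-RE sequences carry 5 planted consensus sites on random strands;
all other REs are GC-matched random sequence; the PWM set is the planted
motif plus 19 random sharp decoys, each mapped to an expressed gene.

Identifiability is a design requirement of the generator, not an
afterthought: the relative ABC score guarantees that *every* gene passes
its top few candidates at 0.02, so planted structure must out-compete
geometry. Three choices follow. Background acetylation peaks (21/Mb,
anchored to the real dataset's ~52k peaks over ~2.5 Gb) may sit anywhere
except differential-H3K79me2 territory and the immediate TSS vicinity —
placing them only intergenically would starve unplanted genes of proximal
candidates and hand their score mass to neighbors' K79-REs. Planted REs
sit 15–60 kb from their gene's TSS: with the multiplicative loop boost
the relative score falls roughly with the square of contact, so elements
much beyond ~60 kb would lose the 0.02 cut to their nearer siblings.
Many-RE genes are planted at 7–9 elements so that one lost link cannot
flip them across the ≥6-stratum boundary. Gene-body-only genes (planted
RE-negative) are confined to the first fifth of each autosome with a
600 kb buffer before K79-RE territory, so no planted K79-RE can reach
them with appreciable contact.

What the generator does **not** emulate: read-level sequence content
(reads are intervals), isoform structure, inter-chromosomal contacts,
fragment-level Hi-C noise, peak-calling and differential-binding
uncertainty (peak files are taken as exact), promoter-overlapping
regulatory elements, and realistic motif co-occurrence or dinucleotide
background. Passing closed-loop tests therefore demonstrates that the
pipeline's logic recovers planted structure through the full file-format
chain under realistic decay/noise — not that the thresholds themselves
are optimal for real chromatin data.

## Null behavior

With all planted effect sizes and motif sites set to zero, the pipeline
finds (almost) no DE genes, the motif comparison groups are empty, and no
significant motif can be reported — verified over 20 full closed-loop
runs. The sharper module-level null — activating vs silencing RE groups
with zero planted sites, compared directly — is exercised over 60 seeds:
a significant TF appears in ~5% of seeds, matching the BH family-wise
guarantee under the global null (the affinity ranks of exchangeable
random sequences are distribution-free).

## Numerical notes

* KR tolerance is a row-sum coefficient of variation < 1e-6 (checked
  post-hoc; Sinkhorn fallback polishes or replaces a non-converged Newton
  run). Balancing of a matrix with a positive diagonal band converges for
  every case exercised here.
* Per-gene ABC score sums are exact to ~1e-15 in double precision; the
  acceptance check allows 1e-9.
* Exact Mann–Whitney enumeration is limited to pooled n ≤ 12 without
  ties; strata and RE groups in practice are far larger, so the normal
  approximation with tie correction is the operative path.
* Degenerate inputs: empty peak lists, empty samples, zero-length
  elements, genes without exons, and sub-bin genes all raise or warn
  explicitly rather than propagating NaNs.

## Known limitations

* The feature map's dense per-base representation trades memory for
  simplicity (see above).
* `n_k79_res` counts distinct control-map links; an RE shared by several
  genes counts once per gene, which matches the category definitions but
  means category percentages are not additive across genes.
* The truth tables written to TSV contain the class label `null`; when
  reading them with pandas, pass `keep_default_na=False` or the label is
  parsed as missing data (the package itself only consumes the in-memory
  tables).
* The KS p-value is asymptotic; for strata below ~10 genes it is only
  indicative (such strata are skipped below 2).
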