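# Methods

## Setting and scope

The package compares one chromosome arm present in two ploidy contexts: a
diploid progenitor genome ("diploid", modelled on *Ae. tauschii* 3L) and the
homologous arm inside a hexaploid derivative ("hexaploid", modelled on
bread-wheat 3DL). Inputs are the *outputs* of standard upstream tools —
TPM matrices, Bismark-style cytosine reports, called peak BEDs, fragment
BEDs, GFF3 annotation, a syntenic 1:1 pair table. Read alignment, peak
calling, synteny detection and TPM quantification are upstream and out of
scope; organelle read removal is therefore implemented as contig-name
filtering, not alignment.

All coordinates are internally 0-based half-open (BED convention); GFF3 is
converted at the boundary and back on write. Strandedness is explicit: a
"−" gene's TSS is its larger genomic coordinate and every upstream/downstream
window is strand-aware.

## Expression classification

A syntenic pair is expressed when either gene reaches the TPM threshold
(default 1, inclusive) in at least one tissue. The "either genome" reading
follows the study design, which counted genes expressed "from the hexaploid
and/or the diploid".

Cross-ploidy normalization uses a median-of-ratios factor pooled across
tissues over expressed pairs, with a pseudocount ε = 0.01 TPM in numerator
and denominator to keep zero TPMs finite. Pooling (rather than per-tissue
factors) is the default because the published factor was a single constant;
a fixed-factor mode (default 1.7604) reproduces that exactly. The median of
per-pair ratios, not the ratio of medians, is used for robustness.
Classification is per tissue at an inclusive 4-fold threshold after
rescaling; a pair is a DEG overall if any tissue crosses the threshold.
Classification is invariant to rescaling either genome's TPMs when the
median-ratio factor is recomputed (exactly so at ε = 0).

Replicates are aggregated by arithmetic mean: TPM is already within-sample
normalized, so no reweighting is justified. NaNs are rejected, never
propagated.

Conserved DEGs across diploid accessions are the intersection of pairs DEG
in the same direction versus every accession; a direction flip disqualifies.

## Methylation

Levels are always *weighted* methylation (Σ methylated reads / Σ total
reads), which is invariant to splitting a site's reads and weights deep
sites more than shallow ones.

Region aggregates follow the study's filter: a gene body or promoter is
analysed per context only if it contains ≥ 5 *methylated* cytosines
(≥ 1 methylated read each) at the per-genome coverage floor (5× diploid,
10× hexaploid — the hexaploid data were deeper). We read "5 methylated
cytosines" literally (each must carry a methylated read); the alternative
"any covered cytosine" is one flag away (`min_sites` semantics are
documented on the function). Promoters for methylation are 2 kb upstream of
the TSS; the accessibility module anchors its promoter class at the ATG
instead (its source protocol was ATG-anchored); both anchors are arguments.

DMR calling uses a two-sided two-proportion z-test with continuity
correction on the pooled read counts of the matched regions, BH-adjusted
within each context, and requires |Δ| ≥ 50/25/10 percentage points for
CpG/CHG/CHH (Δ = hexaploid − diploid throughout). The underlying published
analysis names only "q < 0.05"; the pooled-count z-test matches the
region-level aggregation and is exact enough at the coverage the filters
guarantee. The CHH threshold is applied at region level, like the others,
for symmetry.

Metaprofiles use fixed-width bins over 3-kb flanks and normalized-length
gene-body bins (default 50/40/50 — the bin counts are free choices); a site
exactly at the TSS falls in the first gene-body bin, and the binning is
exactly mirror-symmetric under strand flips. The TSS ± 20 bp test builds
per-position group means (expressed vs non-expressed genes) and runs a
pooled two-sample t-test across the 41 positions; df = 80 at full coverage,
shrinking when positions are uncovered in either group. Note the test
treats positions as independent samples (as in the source analysis), so
gene-level sampling noise can produce large |t| under the null; it is a
descriptive contrast, not a calibrated test.

## ATAC post-processing

Tn5 offsets: +4 bp forward, −5 bp reverse, applied to the whole read so
lengths are preserved (starts clip at 0 with a warning). Reproducible peaks
are the per-base AND of replicate coverage — the strictest reading of
"peaks present in all three replicates"; an any-overlap mode was considered
and rejected as the default because it admits single-replicate boundaries.
Intersection runs before the < 10 bp merge (exclusive threshold: a 10-bp
gap stays), since merging first would let near-misses in one replicate
manufacture reproducibility.

Peak classes partition each peak by precedence promoter+5'UTR > CDS+introns
> 3'UTR+downstream, intergenic otherwise; multi-gene overlaps resolve to
the nearest TSS from the peak midpoint. TSS distances are midpoint-based
(stable under merging) and strand-signed. The differential-accessibility
rule — flag a gene in a class when peak presence/absence differs or total
peak bp differs by ≥ 2-fold and ≥ 50 bp — is this package's own surrogate
definition: the source analysis never defined "differential ATAC peaks"
quantitatively. Both thresholds are exposed.

Fragment periodicity: the integer length histogram is detrended by a
centred moving average (~2× the band maximum), Fourier-transformed, and the
dominant band-limited frequency refined by parabolic interpolation on log
power. The amplitude statistic (peak power / median band power, threshold 8)
flags flat histograms as non-significant; < 1000 fragments flags the result
low-confidence.

## The synthetic generators

Every generator is a pure function of (config, seed) with NumPy's seeded
Generator streams; truth labels (class, DMR, accessibility loss) are emitted
as sidecars and never consumed by analysis code.

* **Gene models** — collinear 1:1 pairs, one per 20-kb slot, lengths
  1.5–4 kb, two exons, 5% pseudogenes (flag mirrored across genomes, as for
  syntenic pseudogenes). Homologs share geometry (length, strand, UTR), as
  expected at ~99% coding identity.
* **Expression** — diploid base TPM log-normal (log-mean 2, log-sd 1),
  tissue effects log-sd 0.3, replicate noise log-sd 0.1 (the replicate
  dispersion is a free choice; the source reports none). 70% of expressed
  pairs are balanced at ratio 0.40 × LogNormal(0, 0.2); 30% are DEGs with
  folds log-uniform in [4, 16] (spread past the threshold so boundary
  behaviour is testable), direction random, planted relative to the implied
  normalization.
* **Methylation** — per-site probability = per-genome per-context rate
  (hexaploid 89.9/59.4/3.8%, diploid 87.1/53.4/3.4% for CpG/CHG/CHH) with
  gene-level Beta overdispersion (concentration 20), pseudogene CpG/CHG
  elevation (+13.2/+12.6 points, clipped into [0,1] with a warning),
  Poisson(10) coverage and Binomial reads. A TSS methylation dip coupled to
  expression exists but defaults OFF so the marginal context rates equal the
  configured rates exactly. The paired generator shares the latent region
  level between genomes for non-DMR regions — otherwise gene-level
  overdispersion alone would create true CHH differences above threshold
  and an empirical-FDR check would be meaningless — and plants DMRs at the
  context threshold + 10 points at coverage 50.
* **ATAC** — latent true peaks around TSSs, exponential distance scale
  (diploid 25 kb, hexaploid 4.33 kb — the hexaploid value puts half the
  peaks within 3 kb; the diploid value is scaled to desk-size chromosomes
  where nearest-TSS distance saturates at half the gene spacing), widths
  log-normal (medians 500 vs 300 bp), 3 replicates as jittered copies
  (sd 15 bp) plus 15% replicate-specific noise peaks. The paired generator
  carries diploid peaks to the hexaploid at the same TSS offset with widths
  × 0.62 (below the differential threshold) and plants promoter losses in
  15% of pairs. Fragment lengths mix a sub-nucleosomal exponential with
  mono-/di-nucleosome Gaussians, modulated by a multiplicative cosine comb
  (period 10.5 bp, amplitude 0.35).

What the generators do **not** emulate: sequence-dependent site spacing
(cytosines are placed uniformly, not from a genome sequence), linkage
between methylation/accessibility and expression class (the layers are
planted independently unless explicitly coupled), repeat structure,
coverage biases, and between-replicate batch effects. Passing recovery
tests therefore demonstrates estimator correctness under the declared
generative laws, not robustness to real-data artefacts.

## Problem sizes and determinism

Desk-scale defaults (200 genes, 20-kb slots) run the full pipeline in a few
seconds; recovery checks use 5,000 pairs for classification, ≥ 100,000
cytosines per context for rate estimation, 250 genes (~1,500 regions) for
DMR recall/FDR, and 100,000 fragments for periodicity — sizes at which
Monte-Carlo error is far below the assertion margins. Reruns with the same
config are bit-identical; all randomness flows from the single seed through
named substreams.

## Known limitations

* The TSS-window t-test inherits the pseudo-replication of its published
  design (positions, not genes, are the samples).
* The differential-ATAC rule is a declared surrogate; the published gene
  counts under that heading are not recoverable from any definition given
  in the source.
* `pairwise_identity` scores one optimal global alignment
  (match 1 / mismatch −1 / gap −2); ties between co-optimal alignments may
  report different identities than other tools' tie-breaks.
* Region matching across genomes requires the syntenic pair table; unpaired
  genes are silently absent from DMR and differential-accessibility output
  (logged, not raised).
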