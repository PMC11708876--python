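# Methods

## Scope

`riboscreen` implements the computational arc of a translatome study in
intestinal organoids comparing stem-cell-enriched (SCe) and
stem-cell-depleted (SCd) cultures: quantification of ribosome occupancy
from footprint profiles, differential testing of five per-gene metrics,
gene-set enrichment over a capped ranking, rule-based design of a CRISPR
dropout library from the hit tables, and scoring of the resulting screen.
Everything upstream of transcript-coordinate footprint positions (read
trimming, rRNA removal, alignment) and everything wet-lab is out of scope.

## Occupancy metrics

A transcript is a 5'UTR / CDS / 3'UTR triple in 0-based transcript
coordinates; GTF input (1-based closed) is converted once at the boundary.
Footprints of 19–32 nt are kept; the P-site of a footprint is its 5' end
plus a single fixed offset (default 12 nt) for all lengths. The offset is
deliberately simple: the statistics below integrate over a 90-nt window,
which is wide relative to any per-length offset refinement.

Per gene (one APPRIS-style primary transcript, chosen by explicit map,
flag, longest CDS, then lexicographic tie-break):

* **RO** — P-site count over the CDS.
* **uORF RO** — P-site count over the 5'UTR, a proxy for upstream-ORF
  translation (upstream ORFs are represented as 5'UTR occupancy, not as
  annotated ORFs).
* **s2b** — (counts in the first 30 codons = 90 nt of CDS) / (counts in
  the rest of the CDS) × (CDS length − 90). Under uniform coverage the
  two density terms cancel and s2b = 90 for any CDS length, which is the
  point of the multiplier; elevated values flag initiation-proximal
  ribosome accumulation. Genes with CDS < 100 nt are excluded
  (`SHORT_CDS`; reported before any other reason), as are genes with
  fewer than `s2b_min_rpf` CDS footprints (`LOW_RPF`; the source
  analysis leaves "low" unquantified, so this is a config key, default
  32). A zero body with a nonzero start yields an infinite sentinel that
  never enters differential testing; a zero start with nonzero body is a
  valid s2b of 0. A config switch `s2b_multiplier="length_ratio"`
  provides the (L−90)/90 variant; the literal multiplier is the default.
* **TPM** — length-normalized abundance for point estimates; differential
  testing always runs on raw counts with size-factor offsets.

## Differential testing

All thresholds quoted below are config keys with the published defaults.

**Counts (RNA, RO, uORF RO).** Per-gene negative-binomial GLM with log
link and log size-factor offset (median-of-ratios factors), two
conditions, Wald test on the condition contrast. Both this design and the
TE design are saturated in their group structure, so each group's
log-mean is fitted by a one-dimensional Newton iteration vectorized
across genes; contrasts and their variances come from the Fisher
information. Genes below a mean normalized count of 5 (config) are
skipped as low-abundance.

**Dispersion.** A mean–dispersion trend α(μ) = a₀ + a₁/μ is fitted by
Cox–Reid-adjusted profile maximum likelihood over all genes, then each
gene takes the maximum-a-posteriori dispersion under a log-normal prior
centred on the trend (sd 0.5 on the natural-log scale, config
`dispersion_prior_sd`), evaluated on a 33-point log grid spanning 8-fold
either side. We originally tried per-gene method-of-moments estimates
blended with the trend; at three replicates the moment estimator is
skewed enough that every simple average of it left the Wald tests off
their nominal level, so the adjusted-likelihood route — the same device
the dedicated count-model packages use — was adopted. This package does
not replicate any external tool's shrinkage exactly; exact replication is
a non-goal.

**TE.** One NB GLM per gene over paired RNA and footprint-CDS counts with
assay, condition and assay×condition terms; the interaction coefficient
is the TE log2 fold change and carries the Wald test. Size factors are
per assay. Dispersion is estimated per gene *per assay*: an RNA count and
a footprint CDS count (itself a sum of two sub-region counts) have
genuinely different quadratic dispersions, and forcing one shared value
mis-weights the interaction variance.

**s2b.** log2(s2b) modelled by condition with empirical-Bayes variance
moderation: per-gene pooled variances are squeezed toward a prior
(s₀², d₀) fitted by matching moments of log s², and the moderated t uses
d + d₀ degrees of freedom, capped at the pooled residual df. With a
degenerate prior the ordinary t is used (warned). Excluded or infinite
s2b values are missing; a gene needs two finite values per condition.
Identical values in both conditions give p = 1 rather than an exclusion.
The implementation is cross-checked against the limma reference in the
test suite.

**Multiple testing.** Benjamini–Hochberg within each metric. The source
analysis says only "adj. P"; BH is the field default and the choice is
config-visible in the sense that raw p is always carried alongside.

## GSEA

Genes are ranked by log2FC × min(−log₁₀ p, 3) — adjusted p for every
metric except s2b, which uses raw p (its own convention throughout the
design rules as well). p = 0 is treated as hitting the cap, never as an
infinite score; ties are broken by gene id for determinism. The
enrichment score is the standard weighted Kolmogorov–Smirnov running sum
(hit increments |score|^w normalized by the in-set total, miss decrements
1/(N − n)); significance comes from gene-label permutations of set
membership, because the pipeline hands GSEA a precomputed ranking and
sample labels are no longer available at this stage — a documented
deviation from sample-permutation GSEA. NES is ES over the mean same-sign
null magnitude; FDR q is the standard pooled-NES ratio.

## Library design

Three selection rules over the five differential tables, union,
deduplicated, with per-rule provenance: (1) TE adj P < 0.1 or s2b raw
P < 0.1 → CDS; (2) RO adj P < 0.05 and RNA adj P > 0.05 → CDS; (3) uORF
RO adj P < 0.05 → CDS + UTR5 + UP (the region upstream of the uORF; UP is
a region label only — genomic coordinates for its guides are upstream of
this artifact, and pools arrive per region, pre-ranked, since guide
efficiency scoring is out of scope). A gene untested in a rule's table
makes that rule abstain. The s2b branch of rule 1 uses raw p, mirroring
the s2b exception in the ranking measure; a config switch flips it to
adjusted p.

Five guides per (gene, region) are taken in pool priority order after
rejecting any protospacer that contains an Esp3I site (CGTCTC or its
reverse complement) or would create one at an adapter junction; deficits
are logged. Nontargeting guides are seeded random 20-mers screened the
same way (and against supplied transcript sequences). Oligos are
5'flank + protospacer + 3'flank; the default flanks carry one forward and
one reverse Esp3I site, and an in-silico digest (cut 7 nt after a forward
site start, 5 nt before a reverse site end, top strand) must yield
exactly three fragments with the protospacer in the middle one.

## Screen scoring

Counts plus a pseudocount are scaled by median-of-ratios size factors;
guide log2 fold changes are end/T0 per replicate pair; a gene's score is
the mean of its guides' replicate-averaged LFCs. The null is the
distribution of means of size-matched draws (with replacement) from the
nontargeting guide LFC pool; empirical p = (1 + #{null ≤ score}) /
(n_resamples + 1), depletion-sided because this is a dropout screen, BH
across genes, and a DROPOUT call requires adj P below the FDR threshold
*and* a negative mean LFC. This resampling procedure is a fully specified
stand-in for pipeline-style screen callers (α-RRA internals are a
non-goal), so the original study's absolute dropout count is expressly
not a number this package tries to reproduce.

## Synthetic data

The generator emulates the study's design — two conditions × three
replicates of paired RiboSeq/RNA-seq — at per-nucleotide resolution, so
s2b is a genuine positional statistic rather than a two-number shortcut.
Since the source reports no accession, depths or dispersions, the
defaults are one-time choices of realistic conditions: per-gene expression
log-normal with median 300 CDS footprints per sample (a deeply sequenced
footprint library), NB dispersion 0.02 (tight biological replicates of
clonal organoid cultures), a 1.5× basal density excess over the first
90 nt of CDS, 5'UTR occupancy ~8% of CDS counts, library sizes varying
±20% so size-factor estimation is non-trivial, 2% of CDSs shorter than
100 nt to exercise the exclusion path, and footprint lengths 19–32 nt
peaked at 28–29.

Counts are Poisson-gamma: one gamma multiplier per (gene, sample) is
shared by all regions of a transcript, giving every region an NB marginal
with the configured dispersion while positional ratios such as s2b cancel
the shared replicate noise — the reason a start-to-body statistic is
informative at n = 3 at all. Spiked effects are disjoint gene classes
with random signs: RNA log2FC ±1 (5% of genes), TE log2FC ±1 (5%), s2b
shift ×4 or ×¼ (2.5%), uORF shift ×4 or ×¼ (2.5%). An s2b spike
*redistributes* density between start window and body without changing
total CDS occupancy, modelling a pure initiation-pausing change that is
visible to s2b but not to RO — the phenotype class the statistic exists
to detect. P-sites are only placed where an in-bounds 19–32-nt read can
represent them (offsets ≥ 12 and ≥ 7 nt from the 3' end), so written
alignment fixtures reproduce profiles exactly.

The screen generator draws T0 counts multinomially at 600-fold coverage
(±20% per replicate) over log-normal guide representation, depletes
essential genes' guides by 3 log2 units (guide-level sd 0.5) and leaves
all others, nontargeting included, on a tight null (sd 0.15).

What the generator does **not** model: sequence-level reads and alignment
error, GC and ligation bias, codon-level pausing structure, multi-isoform
genes, gene-specific dispersion heterogeneity beyond the fitted trend,
screen copy-number effects and infection (MOI) stochastics, intermediate
screen time points. Passing tests therefore demonstrate correctness of
the statistics and calibration under the stated noise model, not
robustness to every artefact of real libraries.

## Numerical choices and degenerate inputs

* Group log-means: Newton with step clamp ±5, 60 iterations, tolerance
  1e-10; an all-zero group has no finite MLE and the gene is skipped with
  reason CONVERGENCE.
* Wald p clipped to the smallest positive float; empirical screen p
  bounded below by 1/(n_resamples+1); GSEA needs ≥ 100 permutations.
* Ties in rankings and candidate ordering are always broken by
  identifier, so every stage is deterministic for a fixed seed; the CLI
  accepts `--threads` but results are independent of it (stages are
  vectorized, not thread-parallel).
* Size-factor estimation falls back to total-count ratios (with a
  warning) when no gene is positive in all samples.

## Problem sizes used in the checks

Calibration and recovery checks run on 2000-gene transcriptomes (the
smallest size at which KS uniformity tests and BH behave like the real
analysis); power and recovery pool ~200 spiked genes across independent
simulations; screen checks use a 720-guide library at 600-fold coverage
with 10,000 resamples. The acceptance script reports the same quantities
at the same sizes from a fresh seed.

## Known limitations

The Wald tests inherit mild small-sample optimism at two replicates per
group; with the adjusted-likelihood dispersions the residual excess at
nominal 5% is below half a percentage point in our checks, but exact
finite-sample calibration is not claimed. The TE model assumes
independence between paired RNA and footprint libraries of the same
biological sample. The moderated-t treats log2 s2b as Gaussian, which is
approximate for genes near the footprint-count floor. FDR q-values from
pooled-NES GSEA are known to be conservative for small set collections.
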