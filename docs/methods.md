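# Methods

`myosplice` reimplements, as a tested pipeline, an integrative analysis of
pre-mRNA alternative splicing (AS) and N6-methyladenosine (m6A)
methylation across two skeletal-muscle types — an oxidative, soleus-like
condition ("SOL") and a glycolytic, extensor-digitorum-longus-like
condition ("EDL") — with three biological replicates each and paired
MeRIP-seq IP/input libraries. All effect directions are reported as
condition 2 minus condition 1 (SOL minus EDL). Because the original
tissue data are not bundled, every stage is exercised against a
synthetic-data generator with planted, machine-readable ground truth.

## AS event classification

A gene model is a set of transcripts, each an ordered list of
non-overlapping exon intervals (internally 0-based half-open; GTF's
1-based closed convention is converted only at the I/O boundary). The
five classic event types are detected by evaluating their definitions
over all pairwise transcript comparisons:

- **SE** (skipped exon): an internal exon of one transcript absent from
  a second transcript that splices directly between the same flanking
  junctions.
- **A5SS / A3SS**: two exons sharing one boundary but differing at the
  donor (5') or acceptor (3') splice site, with a shared flanking
  junction. Labels are strand-aware: the genomically right-hand varying
  boundary is a donor on the plus strand but an acceptor on the minus
  strand.
- **MXE**: two non-overlapping internal exons with shared flanking
  junctions that never co-occur in any transcript of the gene.
- **RI**: a single exon of one transcript spanning two exons plus the
  intervening intron of another.

Duplicate events are suppressed on the key (type, ordered coordinates,
strand), and output order is deterministic. Detection is
annotation-only: novel junctions supported solely by reads are out of
scope. Catalogue percentages are reported to two decimals with
round-half-to-even (the published SE+RI share, 84.32%, fixes that
precision).

## Quantification

FPKM = count / (length/10^3) / (library/10^6), with library size taken
as total counted fragments (configurable). Genes with FPKM >= 0.5 in at
least one library count as expressed; the boundary is inclusive.

PSI for an event with inclusion/skipping junction counts (I, S) and
effective lengths (l_I, l_S) is

    psi = (I/l_I) / (I/l_I + S/l_S),

missing when I + S < 10 (the coverage floor is configurable; effective
lengths are data supplied with the event table, not constants, because
read length is a property of the study). PSI is invariant to common
scaling of the two lengths.

## Differential tests

**Expression.** Counts are normalised by median-of-ratios size factors.
Per-gene dispersion is estimated by method of moments from the pooled
within-condition variance, shrunk *upwards* to a fitted mean-dispersion
trend (alpha(mu) = a0 + a1/mu); taking the maximum of the per-gene and
trend estimates is deliberately conservative at n = 3. A Wald test on
the log of normalised condition means (variance (1/mu + alpha)/n per
condition, pseudocount 0.5) gives p-values, BH-adjusted across genes. A
gene is differentially expressed when |log2FC| >= 1 and FDR < 0.05.
This is a documented, simpler substitute for a full NB GLM: the
downstream contract is only the decision rule, and the synthetic null
and power suites calibrate it.

**Splicing.** Junction counts are pooled across replicates within a
condition and a likelihood-ratio test compares one shared binomial
inclusion proportion against condition-specific proportions
(chi-square, 1 df). Events lacking a defined PSI in at least two
samples per condition are reported untested and excluded from the BH
family (family size changes FDR, so this is explicit). An event is
differentially spliced (DAS) when FDR < 0.05; an optional |delta-PSI|
floor exists but defaults to off. The pooled test carries no
overdispersion term: at very high junction depth it will treat
biological replicate-to-replicate PSI variation as signal. This is a
known, documented limitation (see the generator notes below).

## MeRIP-seq enrichment

IP and input libraries are summarised over fixed-width bins (default
50 bp) tiling gene bodies. Per condition, replicate-pooled bin counts
are tested one-sided for IP enrichment with the Fisher exact test
(computed as the hypergeometric tail, vectorised); bins with BH-adjusted
p < 0.05 and fold enrichment >= 2 are merged when adjacent and the
per-condition peak sets are unioned so differential testing runs on a
single family. This window caller replaces a GC-corrected GLM peak
caller; downstream logic needs only peak intervals and enrichment.

MFPKM = FPKM_IP / FPKM_INPUT per replicate (region length cancels),
averaged over the condition's replicates as an arithmetic mean of
per-replicate ratios — not a ratio of means; the two differ and the
choice is fixed here. Zero-input replicates are excluded with a logged
flag; a region undefined in every replicate is reported missing.
Differential methylation uses log2FC = log2(MFPKM_2/MFPKM_1) with a
two-sided Fisher test on pooled (IP, input) counts per condition,
BH-adjusted; "hyper" means higher enrichment in condition 2.

Peak-feature overlap follows BED semantics (half-open): intervals
touching only at a boundary do not overlap and fall under the
flanking rule (gap <= 1 kb by default, matching the published
upstream-1kb/downstream-1kb window around skipped exons).

## Integration

- "m6A-modified gene" = gene containing at least one called peak in
  either condition (the source analysis never defines it; this is the
  natural reading).
- AS-count grouping of modified genes uses linear-interpolation
  quartiles (numpy default, type 7): high (count >= Q3), low (count <=
  Q1), medium strictly between; on degenerate quartiles (Q1 = Q3) high
  takes precedence, logged, and the partition remains total. Group
  comparisons of m6A change use one-sided Mann-Whitney tests (the
  original figure states no test; this choice is logged).
- **SE-DMAS**: SE events with DAS FDR < 0.05 joined to differential
  peaks (padj < 0.05) overlapping the cassette exon by >= 1 bp. When
  several peaks qualify, the largest overlap wins, ties broken by
  leftmost peak start, giving one deterministic record per event.
  Records are classified into the four (PSI direction x m6A direction)
  quadrants; quadrant assignment is peak-level, not exon-summed.
- Knockdown intersection matches events by (gene, cassette exon
  coordinates, strand); zero matches that would become matches under a
  one-base shift trigger a loud coordinate-convention warning.
- The RRACH scan counts overlapping matches of [AG][AG]AC[ACU] (N never
  matches; DNA and RNA alphabets accepted; reverse-complement scanning
  optional). Motif discovery beyond this consensus scan is out of scope.
- RT-PCR inclusion = upper band / (upper + lower band), mirroring the
  gel-quantification formula used for wet-lab validation.

## Splicing-factor network

Every splicing factor is Spearman-correlated against the PSI profile of
every DAS event; BH runs over all tested pairs as one family and an
edge is retained when |rho| >= 0.9 and adjusted p < 0.05. Both signs
are retained by default (repressive and activating factors alike; a
positive-only toggle exists). Mid-ranks handle ties — with n = 6
samples tie handling materially affects rho, so the convention is fixed
here. p-values use the t-approximation by default; an exact permutation
p is available for n <= 8. Pairs with a constant vector or fewer than
three complete samples are skipped with a log entry. The splicing-factor
list is an input file: the GO:0000380 membership is not bundled
(license and version drift), and the generator writes its own.

## Synthetic data generator

The generator emulates the study design at the level the statistics
consume (event/bin counts, not reads or alignments):

- **Gene models**: each gene carries a known planted event type by
  construction (including a two-cassette-exon form so multi-event genes
  exist); the classifier provably recovers exactly the constructed
  truth.
- **Junction counts**: per sample, event depth ~ Poisson(default 100);
  inclusion reads ~ Binomial with the planted PSI converted to a
  read-level proportion through the effective lengths, so the PSI
  estimator is unbiased. A planted delta-PSI (default 0.3, the regime
  the power suite targets) is applied to a subset of skipped exons with
  random sign; per-sample biological jitter (sd 0.02) keeps replicates
  from being identical.
- **Expression**: negative-binomial counts, mean = baseline x
  (length/1kb) x library factor x 2^(log2FC x condition), dispersion a
  config knob with Poisson as the zero limit; planted DE genes get
  log2FC +/-2 by default.
- **MeRIP**: input counts expression-proportional per bin; IP means
  multiply the paired input mean by 2^(2) = 4x inside planted peaks
  (background 1.0), plus 2^(+/-2) condition effects on the differential
  subset. Planted differential peaks on DAS cassette exons define the
  SE-DMAS truth; background peaks are restricted to constitutive exons
  so the planted set is the unique source of DAS/peak co-occurrence
  (the pooled tests, having no overdispersion terms, would otherwise
  convert replicate-level drift on deeply covered incidental peaks into
  spurious records).
- **Splicing factors**: log-expression = a + b x PSI_sample + noise,
  alternating slope sign; with zero noise planted pairs have Spearman
  rho exactly +/-1. SF rows are appended to the count matrix so they
  flow through FPKM like ordinary genes.

One global seed feeds a per-stream splittable RNG
(`SeedSequence.spawn`), so adding a stage never perturbs earlier
streams, and identical configs give byte-identical outputs. Defaults
(2 x 3 design, depth 100/event, 50 bp bins, 100 input reads per bin in
the recovery runs) are chosen for test power at desk scale, not
fidelity to the original sequencing depth, which the source never
states per event.

What the generator does **not** model: read-level artefacts (mapping
bias, GC effects, positional coverage), correlated splicing programs,
isoform-level expression coupling, and sequence-content realism beyond
the RRACH consensus in motif fixtures. Passing recovery suites
therefore demonstrate statistical correctness of the implementations
under the stated noise model, not performance on real tissue libraries.

## Numerical choices and degenerate inputs

- BH adjustment delegates to `scipy.stats.false_discovery_control`; a
  naive quadratic step-up oracle verifies it in the test suite.
- The one-sided Fisher bin test is evaluated as a vectorised
  hypergeometric tail and cross-checked against `fisher_exact`.
- Zero-depth events yield I = S = 0 and are flagged missing; 0/0 PSI is
  missing; all-zero catalogues make percentages undefined and raise.
- log2FC of expression uses a 0.5 pseudocount on normalised means.
- Percentages: two decimals (catalogue) / one decimal (knockdown
  share), round half to even.
- The run report is validated against a pydantic schema and serialised
  with sorted keys, making rerun identity a byte-level check.

## Problem sizes

The shipped test and acceptance runs use 40-200 genes, 2 x 3 samples,
depth 100-1000 junction reads per event and ~100 input reads per bin —
sizes chosen so the full suite completes in well under a minute on one
CPU while every recovery criterion retains adequate power (>= 300
planted events across 50 seeds for the power estimate; >= 1000 null
features for the false-flag rates).

## Known limitations

- The pooled binomial LRT and pooled Fisher tests are anticonservative
  under biological overdispersion at high depth (see above); on real
  data a replicate-aware hierarchical model would be preferable.
- Annotation-only event detection misses junctions absent from the GTF.
- The NB Wald test does not shrink fold changes; low-count genes rely
  on the pseudocount for stability.
- With n = 6 samples the |rho| >= 0.9 cut sits on a coarse lattice of
  achievable rank correlations; edge retention is correspondingly
  quantised.
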