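# Methods

This note documents the statistical model behind each stage of the
pipeline, the conventions adopted where several defensible choices exist,
what the synthetic-data generator does and does not emulate, and the
limitations a user should keep in mind.

## Coordinates and file formats

All coordinates are 0-based half-open internally. GFF3 (1-based closed,
CDS with strand and phase) is converted at the reader boundary; the VCF
dialect consumed and produced is VCFv4.2 with one ALT per record, unphased
diploid GT, per-sample DP and INFO/MQ. The ρ track is BED-like (scaffold,
start, end, ρ), 0-based half-open.

## Site classification

Every CDS site is labeled with its codon position using strand-aware codon
extraction (reverse complement on minus-strand genes, phase trimming of
leading bases). Four-fold degeneracy is determined from the standard
genetic code; the degeneracy of a position is the number of nucleotides
there that preserve the encoded amino acid. Conventions:

- **Overlapping gene models**: a site claimed by two genes with conflicting
  codon structure is masked for coding analyses and both codons are
  invalidated. Masking avoids arbitrary codon assignment.
- **Multiple transcripts**: the longest CDS isoform represents the gene.
- **Terminal stop codons** carry no degeneracy or substitution semantics
  and are masked; internal stops (annotation errors) likewise, with a QC
  count.
- **UTRs** (exonic non-CDS, when exon features are present) are classed as
  genic noncoding and enter neither the coding nor the intergenic bucket,
  so neither GC nor diversity contrast is contaminated.
- **CDS length not a multiple of three** after phase trimming: the gene is
  skipped with a warning and a QC count.

Gene density is coding nucleotides divided by nucleotides with sequence
information (non-N, repeats included) per window. GC is (G+C)/(A+C+G+T)
over the selected sites. Window ρ is the length-weighted mean of track
intervals intersected with the window; windows without data are missing.

## SNP inclusion and callability

Filters are pure predicates over VCF records, so their outcome is
order-independent:

- **depth**: a site is retained for a population iff every individual of
  that population has DP ≥ 2. The rule is applied per population — an
  individual outside the population cannot veto the site for it.
- **quality**: a record is dropped when QUAL < 15 *or* MQ < 20. The
  source rule is grammatically ambiguous between AND and OR; OR is the
  conservative reading and the conjunction is a switch
  (`qual_mq_combine`).
- **biallelic / call rate**: only biallelic SNPs with genotyping rate
  strictly greater than 0.9 across samples.

Every filtered-out variant position is also removed from the population's
callability mask; monomorphic callable sites enter diversity denominators
through that mask. Missing genotypes at retained sites reduce the per-site
haplotype count n rather than being imputed. Because a VCF carries depth
information only at variant sites, coverage dropouts thin segregating
sites but not monomorphic ones; with the default artifact rates this
depresses realized θπ by roughly the per-population joint dropout
probability (about 10 % at the defaults). The estimator-accuracy tests
therefore run with artifact rates of zero, and the artifact rates exist to
exercise the filter logic, not to model a specific sequencing error
process.

## Diversity

Per-site π is the unbiased mean pairwise difference `2k(n−k)/(n(n−1))`
with per-site n from the callability mask. Class and window θπ divide the
summed per-SNP π by callable-site counts of that class/window; a class
with callable sites and no SNPs is 0, a class with no callable sites is
missing. The GC-conservative variant keeps only {A,T} and {G,C} allele
pairs and shares denominators with the full estimate, so it is bounded by
it.

Windows (100 kb default, tiled from scaffold start) are retained when they
hold ≥ 1,000 coding positions and ≥ 50 % callable sites (both inclusive);
the terminal short window of each scaffold is computed but excluded from
comparison/regression stages by default, because unequal window sizes bias
per-window statistics. Standardization uses the sample SD (n−1) of
retained-window θπ per population — windows are the sampling unit — and
the z = 0 tie goes to "low" (configurable; the boundary case has measure
zero). Window inclusion is evaluated per population; cross-population
analyses join on window coordinates.

## Selection statistics

Site totals follow Nei–Gojobori (1986) fractional counting without
transition/transversion weighting: it is the minimal standard scheme and
fully checkable by enumerating all nine single-nucleotide mutations per
codon (LN + LS = 3 exactly per sense codon). Mutations to stop codons
count as nonsynonymous; stop-involving changes are excluded from pN/pS.
Codons with two or more segregating sites are classified per variant
against the reference codon (other positions held at reference) and
flagged multi-hit; pathway averaging is underdetermined for polymorphism
data.

A substitution for a population is a callable site where all sampled
haplotypes carry one allele that differs from the (non-N) outgroup base;
polymorphic sites are never substitutions. Sites fixed in the sample but
polymorphic in reality are accepted as sampling error, as in any MK-style
framework. No multiple-hit correction is applied by default (the intended
divergence regime is shallow); a JC69 toggle exists for sensitivity
analysis. Per-window LN/LS sum over valid codons whose three sites are all
callable, with each codon assigned to the window of its first base.

α is the McDonald–Kreitman form `1 − (dS·pN)/(dN·pS)` on the site-class
scheme: 4D sites are the neutral class, 2nd codon positions the selected
class, with counts of segregating sites and fixed differences at those
sites. Confidence intervals come from a percentile bootstrap over genes
(200 resamples, seeded), preserving within-gene correlation; windows are
an alternative resampling unit. An optional derived-allele-frequency floor
excludes low-frequency polymorphisms to mitigate segregating deleterious
variants. This is deliberately *not* a DFE-based likelihood estimator: no
correction for the segregation of slightly deleterious nonsynonymous
variants is applied, so on real data α will be biased downward when such
variants are common. On the generator's output (which has no deleterious
segregating class) the estimator is unbiased, which is what the recovery
tests verify.

## Regional statistics

Mann–Whitney U contrasts use exact enumeration of all group assignments
(midranks, ties handled exactly) for pooled sizes ≤ 20 and the
normal approximation with tie and continuity corrections otherwise.
Pearson correlations use pairwise deletion. The regression of π4D on GC,
ρ, gene density and dS is ordinary least squares on complete cases;
predictors are left on their raw scale by default (coefficient signs and
p-values, not magnitudes, are the scientific surface; a z-scoring option
is recorded in the result). Interaction analyses fit the main-effects
model plus one pairwise interaction at a time, reported side by side,
rather than a single saturated model — this avoids collinearity blow-up.
VIF_j = 1/(1 − R²_j) from regressing predictor j on the others; perfect
collinearity reports an infinite VIF with a diagnostic rather than an
exception. Raw p-values are reported; a Benjamini–Hochberg column is
available but off by default. Pooling is per population (no per-scaffold
blocks).

## The synthetic-data generator

The generator is deliberately site-independent — no coalescent trees, no
linkage — because every estimator downstream operates site-by-site and
window-by-window:

- **Reference**: random scaffolds at the noncoding GC target; genes placed
  without overlap on random strands, with exon/intron sizes drawn from
  configurable normals, CDS always a codon multiple, no internal stops, a
  terminal stop appended. Coding sequence is drawn at a per-base GC
  adjusted so that the sense-codon distribution hits the coding GC target
  (rejecting AT-rich stop codons would otherwise push realized GC above
  it).
- **Polymorphism**: each eligible site segregates in population p with
  probability θ_local · H(n−1), where H is the harmonic number and
  θ_local = class factor × window mutation multiplier × linked-selection
  multiplier. The derived count follows the neutral 1/i spectrum, under
  which the expected per-site θπ equals θ_local exactly; derived alleles
  go to a uniform random haplotype subset, haplotypes pair into diploids.
- **Class factors**: 1 for 4D/intron/intergenic, f (default 0.3) for
  1st/2nd positions, (1+f)/2 for non-4D third positions. A window-level
  selection-efficiency coupling makes f_w = f·L_w^(−κ) (κ default 0.5),
  so low-diversity windows show elevated pN/pS — the qualitative pattern
  the comparison stage is designed to detect.
- **Window structure**: a log-normal mutation multiplier (mean-normalized)
  shared between polymorphism and divergence; a linked-selection diversity
  multiplier exp(b_ρ·z(ρ) + b_gd·z(gene density)), also mean-normalized,
  applied to polymorphism only.
- **Divergence**: placed on the outgroup branch with probability linear in
  divergence_rate × class factor × mutation multiplier (at most one hit
  per site, so counts stay exactly proportional to the configured rates —
  the regime the MK estimator assumes). Nonsynonymous classes get the
  extra adaptive factor 1/(1−α), making the true α exact by construction.
  Ancestral state equals the outgroup allele; a mispolarization rate knob
  (default 0) flips the outgroup base to the derived allele at a fraction
  of polymorphic sites.
- **Coverage artifacts**: independent per-genotype missingness (GT → ./.)
  and low-depth (DP → 1) fractions at variant sites.
- **ρ track**: one interval per window, exactly tiling each scaffold.
- **Truth record**: per-window multipliers, ρ, gene density and selected
  factors, plus global parameters, written next to the outputs.

Default study design: populations LsSwe/LsKaz/LsSpa (θ = 0.0031), LrSpa
(0.0024), LjKaz/LjIre (0.0016), ten diploids each — values chosen to span
the per-site diversity range typical of the butterfly resequencing setting
this pipeline targets, without claiming to match any population's history.
Divergence 0.02/site, adaptive fraction 0.12, coding/noncoding GC
0.45/0.32, ρ ~ N(0.04, 0.02) truncated at 0, multiplier SD 0.3, couplings
(+0.15, −0.15), artifact rates 2 %/1 %.

What passing tests on this generator do **not** show: behavior under
linkage disequilibrium and coalescent variance (window estimates on real
data have much larger sampling variance than the Poisson noise here),
demography (bottlenecks, migration, skewed spectra), GC-biased gene
conversion, segregating deleterious variation (and hence the downward MK
α bias on real data), alignment and calling artifacts beyond simple
missingness.

## Problem sizes and numerics

Validation experiments are sized for a single-CPU desk run: per-class
diversity recovery on a 2 Mb six-population genome plus ten 0.6 Mb
replicates for the suppression-factor ratio; α recovery on 0.9 Mb
gene-dense genomes at divergence 0.05 (chosen to give hundreds of
substitutions per class); regression recovery on 2,000 directly simulated
windows with Poisson counting noise at realistic per-window site totals.
Estimator-accuracy experiments disable the window-level couplings and
coverage artifacts: those features deliberately shift class-weighted
means, and their effects are validated by their own tests (divergence–
multiplier correlation, low/high contrast direction, regression signs).

Numerical conventions: ratios with zero denominators are missing, never
infinite; zero-SD z-standardization aborts with a diagnostic; bootstrap
and simulation randomness use numpy Generators seeded from explicit
integers, and all output tables are written with fixed float formatting so
a fixed seed reproduces byte-identical files.

## Known limitations

- The callability mask treats non-variant sites as covered; real all-sites
  depth information would be needed to make coverage thinning unbiased.
- Lineage-specific dS is approximated by total reference–outgroup
  divergence (no third taxon for polarization of the divergence branch).
- The MK α omits the DFE-based correction for segregating deleterious
  variants; on real data it is a lower-bound-style approximation.
- Codons are assigned to the window of their first base, so window
  boundaries can split codons (negligible at 100 kb windows).
- The Mann–Whitney exact path enumerates all assignments and is meant for
  small groups only (pooled n ≤ 20 by default).
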