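# Methods

## Scope and model

`tecensus` quantifies transposable-element (TE) abundance per genotype
from short-read depth over family consensus sequences, and summarizes
within-family sequence variation across a panel. The underlying model of
the data is deliberately simple and matches the standard protocol for
inbred resequencing panels:

- Each genotype is a single haploid genome equivalent (inbred,
  essentially homozygous lines; wild-collected individuals are treated
  the same way, which is an approximation).
- Reads are mapped against the host genome concatenated with the TE
  consensus library, so every copy of a family, wherever it sits in the
  genome, contributes depth to the same consensus coordinate system.
- After removing duplicate-flagged records and alignments with mapping
  quality < 15 (which discards reads mapping equally well to several
  locations), mean per-base depth over a consensus is proportional to
  the number of copies present, and dividing by mean depth over a
  single-copy chromosome region cancels the genotype's sequencing
  effort: the ratio is the copy-number estimate.

"Mean per-base depth" (total aligned bases / reference length) is used
for both numerator and denominator rather than a raw read count divided
by length: the two panels this style of analysis targets mix 90-bp and
100-bp reads, and a count-based average shifts with read length while a
base-based average does not. A count-based statistic (`read_rate`)
remains available.

Copy numbers are reported as raw ratios (copies per haploid genome
equivalent), with no ploidy doubling. Families absent from a sample's
alignment header are reported as 0 copies, not missing; the distinction
between "absent from this sample" and "absent from the species" is left
to the reporting layer.

### Known biases of the depth ratio

Reads straddling the junction between a TE copy and its flanking
sequence do not map cleanly to either reference and are removed by the
MAPQ filter. Depth therefore ramps down linearly within one read length
of each copy end, deflating the estimate by roughly (L − r + 1)/L for a
full-length copy of consensus length L and read length r (~1.5% at
L = 6.5 kb, r = 100; ~13% at L = 750). The same effect deflates the
normalization chromosome negligibly (it is orders of magnitude longer
than a read). The estimator does not correct for this: it reproduces
the plain depth-ratio protocol, and the bias is small for the multi-kb
consensi where copy number matters most. Internal deletions likewise
reduce depth in proportion to the deleted fraction, which is exactly
what the covered-fraction classifier exploits.

## Coverage classification

- `covered_fraction(profile, norm, c=0.25, full_length_fraction=0.8)`:
  the share of consensus positions with normalized depth ≥ `c` copies.
  A family is classed full-length when the fraction reaches 0.8. No
  exact published criterion exists for the qualitative full-length /
  degraded distinction; `c = 0.25` sits well below one copy (so a
  single full-length copy passes everywhere except the edge ramps) and
  well above noise at ≥ 10× depth, and 0.8 tolerates the edge ramps and
  moderate internal deletions. Both are configurable.
- `coverage_concentration(profile, window=140)`: the largest share of
  all aligned bases in any contiguous window (leftmost argmax on ties;
  defined as 0 over [0, window) for an empty profile). The 140-bp
  default matches the scale of the short internal remnant this statistic
  is meant to flag — a value near 1 means virtually all of a family's
  signal is one short segment, not dispersed full copies.

## SNPs and the site-frequency spectrum

VCF input is the production path; filters follow the panel protocol:
indels and sites with more than two alleles are dropped, per-genotype
calls with depth < 4 become missing, and sites are *not* filtered for
missing calls, because genotypes lacking an element cannot carry calls
on it. Calls are treated as haploid (0 or 1 alt); heterozygous calls in
external VCFs count 0.5 toward the site frequency, a graceful
degradation for residual heterozygosity.

Site frequency: p = alt calls / non-missing calls. Fixed (p = 1,
within 1e-9) means divergence from the consensus; polymorphic
(0 < p < 1) means segregating variation. The per-family average SFS is
the arithmetic mean of polymorphic frequencies and is undefined
(rendered "-") when none exist — a family with only fixed differences
has divergence but no polymorphism, and reporting 0 or 1 would both be
wrong. Per-population averages recompute frequencies within each
population's genotypes; the joint estimate is reported alongside.

Tajima's D follows the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁,
e₂ as functions of sample size n): D = (π − S/a₁)/√(e₁S + e₂S(S−1)).
Two choices matter with missing calls:

- n for the constants is the number of genotypes with at least one
  non-missing call in the window (window-specific) — a panel-wide n
  would be wrong when sites are unfiltered for missingness.
- π uses each site's own called count m: per segregating site,
  2k(m−k)/(m(m−1)).

Windows are 1 kb, non-overlapping. Windows with S = 0, or fewer than
two called genotypes, report D as missing, never 0. D is also
mathematically undefined at n ≤ 3 (the variance term vanishes); such
windows likewise report missing.

The built-in pileup caller (`call_snps_pileup`) is a labelled test
substitute for a real haplotype caller, used on simulated reads only:
per genotype and position it calls alt when depth ≥ 4 and the alt-base
fraction ≥ 0.8, ref symmetrically, missing otherwise. It performs no
realignment and no likelihood modelling.

## Population comparison

Per family: Welch's t test for means (default) and the variance-ratio F
test, two-sided (p_F = 2·min(P(F≤f), P(F≥f)), capped at 1; a zero
sample variance makes the F test undefined and is reported as NaN, not
0). Bonferroni correction is strict (p < α/m) and applied separately to
the mean-test and variance-test families of hypotheses, with m
defaulting to the number of families tested.

Welch is the default because panel variances differ strongly between
populations and group sizes are very unbalanced; the pooled (Student)
test is available via `method="student"`. One calibration caveat,
measured in this package's verification runs: at group sizes 16 vs 169
the Satterthwaite degrees-of-freedom approximation is ~10% liberal at
the extreme quantiles a Bonferroni threshold of 0.05/128 ≈ 4×10⁻⁴
probes, so the family-wise error of Welch-based corrected tests lands
near 0.054 rather than ≤ 0.05. The pooled test, exact under the
identical-distribution null, keeps FWER ≤ α; the calibration tests
measure FWER on that route and power on the Welch default.

Outlier genotypes are flagged per (genotype, family) when the
leave-one-out z-score — (copy − mean of the population excluding the
genotype) / sd excluding it — reaches 4 *and* the absolute excess
reaches 5 copies. The z floor alone would fire on low-variance families
at biologically trivial excesses; the absolute floor alone would fire
on high-variance families for ordinary draws. A leave-one-out sd of 0
with positive excess reports an infinite z (flagged if the absolute
floor is met). Both thresholds are configurable; the defaults are this
package's own operational rule for a qualitative observation, and at
z ≥ 4 an i.i.d. normal panel of 169 genotypes is flagged in < 1% of
simulated panels.

Wild-vs-inbred contrasts run the same per-family Welch test between
origin classes within a population, Bonferroni-corrected, skipping
families where either class has fewer than two genotypes.

## The simulator

The generator emulates single-end resequencing of homozygous inbred
genotypes (the 90-bp paired-end regime is emulated read-1-only, i.e. as
single-end reads):

- **Library**: random ACGT consensi, unique family names, rejected and
  regenerated until no two families share any exact k-mer of read
  length, so error-free reads map uniquely. Real consensus libraries
  (FASTA) can be loaded instead.
- **Genotype genome**: a random backbone of configurable length with
  non-overlapping TE insertions at uniform positions. Two divergence
  layers: *shared* SNPs planted once per (genotype, family) and carried
  by all its copies (the genotype's source-copy haplotype — these
  become confident per-genotype variant calls), and *per-copy* SNPs
  (private mutations of individual copies). Copies may carry one
  internal deletion (probability and span distribution configurable, or
  a caller-supplied sampler for exact constructions). Each copy's
  recorded SNP list is its exact base-level difference from the
  consensus.
- **Reads**: uniform starts, Poisson (or fixed) count at
  depth·G/read_length, random strand, substitution errors at a per-base
  rate; optional exact-duplicate reads carrying the SAM duplicate flag.
  No indel errors, no quality modelling, no insert-size modelling.
- **Truth alignments**: each read's correct alignment is derived from
  its provenance. Reads wholly inside one contiguous mapping segment
  (backbone stretch, or a consensus segment of a copy) are reported
  there at MAPQ 60; reads straddling an insertion junction or deletion
  breakpoint get MAPQ 0 with the overhang soft-clipped — reproducing
  the *effect* of the MAPQ filter on ambiguous reads without modelling
  an aligner. Output is valid SAM that round-trips through pysam; an
  aligner can be run on the exported FASTQ instead if desired.
- **Truth variants**: per (family, consensus position), a genotype's
  call is the strict-majority base across its copies covering the
  position (ties resolve to the consensus base); genotypes whose copies
  all delete or lack the position are missing. DP is overlapping copies
  × a nominal per-copy depth (default 20). Output is VCF (v4.2) that
  round-trips through cyvcf2.

What passing simulated tests does **not** show about real data: the
simulator has no repeat structure in the backbone, no homology between
families, no mapping ambiguity beyond junctions, no GC or
library-preparation bias, no indels and no reference/consensus
divergence gradients along elements. Copy-number recovery on this
generator validates the estimator's arithmetic and filtering chain, not
robustness to cross-mapping between related TE families — on real data
that robustness is delegated to the aligner's MAPQ, exactly as in the
protocol being reproduced.

### Default study conditions

The pipeline's simulation defaults describe a small but structured
panel: two populations, 6 genotypes each, 6 families of 1.5–3 kb, 250-kb
backbone, 10× depth, 100-bp reads, 0.5% sequencing error, per-family
copy rates uniform on [0.5, 6] with a 1.3× multiplier in one population,
shared divergence 1% and per-copy divergence 0.2%. The verification
experiments use deeper, more extreme settings where the property under
test demands it: copy-number recovery uses 5–8-kb consensi (the scale of
LTR retrotransposons, where the junction-read bias is ~1.5%), true
counts spanning 0–120, 20× depth on a 3.2-Mb backbone; calibration uses
the full panel geometry (128 families, 16 vs 169 genotypes, 1,000
replicates). Problem sizes were chosen so the whole suite verifies the
statistical properties at panel scale while remaining a desk-scale
computation.

## Numerical and degenerate-input conventions

- Coordinates are 0-based half-open internally; SAM POS converts on
  read/write, VCF positions are 1-based in `SnpTable`.
- MAPQ filtering retains records at exactly the threshold (mapq ≥ 15).
- A zero normalization depth is an error (sample unusable), never a
  silent 0 or inf.
- Copy number for a family with no mapped reads is 0.0.
- Ties in the concentration argmax resolve leftmost; ties in the
  majority-base rule resolve to the consensus base.
- Fixed-site classification uses a 1e-9 tolerance on p = 1.
- TSV output uses %.6g floats and "-" for undefined values; manifests
  carry no timestamps, so identical config + seed reproduce every output
  byte for byte.

## Limitations

- The depth-ratio estimator cannot separate tandem local amplification
  from dispersed insertions, and inherits the junction-read bias above.
- The truth-alignment route bypasses real mapping ambiguity; conclusions
  about closely related families on real data depend on the upstream
  aligner.
- Insertion-site detection (split-read/discordant-pair evidence) and
  per-locus insertion frequencies are out of scope.
- Wild-collected samples are treated as haploid genotypes; for truly
  outbred individuals the copy-number ratio remains interpretable but
  per-genotype SNP calls conflate the two haplotypes.
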