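# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `popld`, and what the synthetic-data generator
does and does not emulate.

## Coordinates, genotypes, annotations

Internally every interval is 0-based half-open; VCF positions and
report tables are 1-based (BED input stays 0-based, per that format).
Genotypes are treated as unphased throughout; `/` and `|` separators
read identically.  A genotype with any missing allele is treated as a
missing call.  Site annotations (QUAL, QD, MQ, FS, HaplotypeScore,
MQRankSum, ReadPosRankSum, DP) are carried as floats keyed by tag; an
absent tag is absent, not zero, and never fails a filter — GATK omits
rank-sum tags at sites without heterozygotes, and treating absence as
failure would silently discard those.  VCF Float fields are stored by
htslib at IEEE single precision; the generator quantizes annotation
values to one decimal at that precision so files round-trip
bit-for-bit.

## Filter cascade

Hard-filter inequalities are strict, exactly as printed in the GATK
hard-filter recommendations: QD < 2.0, MQ < 40, FS > 60,
HaplotypeScore > 13, MQRankSum < −12.5, ReadPosRankSum < −8.0 fail;
the boundary values pass.  The high-confidence tier additionally
requires QUAL > 30 and combined DP > 30 (strict, so QUAL = 30 is
excluded) on biallelic single-base alleles.  The low-coverage tier
reduces the QUAL bound to 4 and drops the depth filter.

The four exclusion rules run in a fixed order (missing call,
high-confidence membership, minor-allele carriers, multiallelic), and
a site failing several is charged to the first.  Two interpretation
choices are deliberate and configurable:

* "minor allele detected in at least five individuals" counts
  *individuals carrying at least one copy* of the per-site minor
  allele (the less frequent allele among called genotypes), not allele
  copies.  At an exact 0.5/0.5 frequency tie the site passes only if
  both alleles meet the carrier floor.
* High-confidence membership requires the full (chrom, pos, ref, alt)
  identity, not position alone, so an allele swap cannot leak through.

Multiallelic records (more than one ALT, which covers sites biallelic
for two non-reference alleles) pass through rules 2–3 — identity and
carrier tests are biallelic concepts — and are excluded at rule 4.
Non-SNP alleles (indels) are excluded in a ledger stage of their own
before the hard filters.  The ledger enforces conservation
(input = retained + Σ excluded) and refuses to print otherwise.

## Estimators

**π.** Per site, π = 2j(n−j)/(n(n−1)) with n called alleles and j
alternate copies; sites with fewer than two called alleles are
skipped.  Windowed π divides by the full window length, the convention
of windowed-diversity tools run on SNP-only VCFs: monomorphic and
unascertained bases contribute zero to the numerator.  A
callable-length denominator can be substituted by passing explicit
windows, but the default matches the all-bases convention.

**F_ST.** Weir & Cockerham (1984) variance components for diploid
biallelic data, computed per site from per-population sample sizes
(recomputed per site under missingness, complete-case), allele
frequencies and observed heterozygote frequencies.  The multi-site
estimate is the ratio of sums Σa/Σ(a+b+c) over sites with positive
total variance; per-site values are never truncated at zero, since
truncation biases the ratio upward.  Sites where any population has no
called genotype, or where the mean sample size is ≤ 1, are skipped.
The estimator choice (rather than Nei-style G_ST or Hudson's) follows
the behaviour of the standard VCF toolchain for this analysis.

**r².** Squared Pearson correlation of dosage vectors over the
complete-case sample intersection; pairs where either restricted
vector is constant are skipped, not counted as zero, because an
undefined correlation carries no linkage information.  The decay curve
uses 10 bp distance bins to 5 kb by default — the binning must resolve
decay on a ~200 bp scale — and reports binned means (no decay-model
fit).  The windowed scan assigns each 1–10 kb pair to windows by pair
midpoint (left-anchor selectable), and excludes windows with fewer
than 100 contributing pairs, mirroring the figure-caption rule.

**Windows.** Windows anchor at coordinate 0, advance by the step, and
generation stops with the first window reaching the chromosome end
(truncated there), so every base is covered and no fully redundant
trailing window is emitted.  Diversity uses non-overlapping 100 kb
windows; F_ST, LD and coverage use 100 kb windows stepped by 50 kb.

**SNP classes.** A positional four-class scheme with precedence
coding > intronic > flank > intergenic.  "Flank" is within 5 kb of a
gene span (transcript extent, not CDS), symmetric in strand.  Exonic
non-CDS (UTR) positions fold into the within-gene non-coding bucket
reported as "intronic"; codon-level consequences are out of scope.
Percentages on real data depend on annotator precedence rules and are
not comparable across tools.

## The generator

Each simulated haplotype is a mosaic over a founder panel: the founder
identity switches in the gap before a site with probability
1 − exp(−switch_rate · effective gap length), producing r² that decays
with distance at scale ~1/switch_rate.  The effective length
integrates a piecewise-constant suppression profile: inside an
inversion the factor applies only to haplotypes of heterokaryotypous
individuals (karyotypes drawn per individual at the configured
inverted-arrangement frequency); inside the centromeric interval it
applies to everyone; overlapping intervals multiply.

Ancestral derived-allele counts follow the neutral SFS, P(i) ∝ 1/i
over founder alleles, with positions uniform on the arm.  Population
divergence follows Balding–Nichols: per-population frequencies are
Beta(p(1−θ')/θ', (1−p)(1−θ')/θ') around ancestral p.  Because each
population's descendants copy from a finite panel of n_f founder
haplotypes redrawn at those frequencies, panel sampling adds drift
variance (1−θ')p(1−p)/n_f; the Beta concentration is therefore
calibrated as θ' = (θ·n_f − 1)/(n_f − 1) so the realized divergence
equals the requested θ.  This requires θ ≥ 1/n_f (validated at
configuration time); θ = 0 shares the ancestral panel across
populations, giving F_ST ≈ 0 exactly as the no-divergence limit.
The calibration was derived analytically and checked by simulation
before being frozen; with θ = 0.05, n_f = 100, 10,000 sites and 20+20
diploids the weighted estimate recovers θ within ±0.01 across seeds.

Defaults mirror the study design the pipeline targets: one chromosome
arm of 1 Mb carrying 4,000 SNPs (one per 250 bp, matching the
high-density autosomal arms of such data), 20 + 4 diploids in two
populations with θ = 0.057 (the between-region divergence scale),
switch rate 10⁻³/bp (sub-kilobase LD decay), one 250 kb polymorphic
inversion with suppression factor 0 for heterokaryotypes at
inverted-arrangement frequency 0.5, and a 100 kb centromeric interval
with factor 0.1.  Desk-scale sizes keep the full chain and its tests
in seconds while leaving every windowed analysis enough data;
they are set in one place (`SimulationConfig`) and scale up freely.

Annotation values are drawn uniformly from passing ranges; engineered
failure modes overwrite disjoint site subsets with values that violate
exactly one filter (or inject a missing call, drop the site from the
high-confidence companion file, rewrite genotypes to a known carrier
count, or add a second ALT), and a truth table records the stage each
such site must be charged to.  When engineering is active, all
remaining sites are adjusted to pass the whole cascade (carrier floor
enforced), so stage counts are exactly predictable.

Randomness flows from one mandatory seed through named substreams
(founders, populations, annotations, depth) in a fixed documented
order; identical configurations produce byte-identical output files.

### What the generator does not emulate

* No coalescent genealogy: LD decays geometrically with distance and
  the SFS is imposed, not emergent; estimator variances on real data
  will differ.
* Divergence is drawn independently per site, so inversions do not
  show elevated F_ST — in real data that signal comes from selection
  and restricted gene flux between arrangements, which are not
  modelled.  The inversion affects LD only, through recombination
  suppression in heterokaryotypes.  The magnitude of the within-
  inversion LD elevation therefore scales with the realized number of
  heterokaryotypes and the founder-panel LD (≈1/(n_f−1)); it is
  positive in expectation but modest under the defaults.
* Arrangements carry no diverged haplotype pools; gene flux toward
  inversion centres is representable only through the suppression
  profile.
* Sequencing error, mapping bias and genotype-likelihood uncertainty
  are not simulated; annotations are draws from simple laws, so
  filter tests verify accounting logic, not error-model calibration.

Passing tests on this generator therefore demonstrate that the
estimators and the cascade are implemented correctly and behave as
theory predicts under a controlled model — not that the pipeline's
numerical output on any particular real data set is reproduced.

## Numerical conventions and degenerate inputs

Empty windows report 0 for sums (and for π, which is defined over all
bases) and NA for means; windows under the value floor are flagged
excluded and printed NA.  Aggregate F_ST returns NaN when no site has
positive total variance; SNP density reports NA for zero SNPs and
rejects zero-length spans.  The LD fast path (no missing genotypes)
uses centred dot products; with missingness it falls back to pairwise
complete-case computation — both paths are tested against an
exhaustive double loop.  Ties in the minor-allele definition and the
stage order of the cascade are fixed as described above.  Pipeline
TSVs print floats with `%.6g` so reruns are byte-comparable.

## Problem sizes used in tests and acceptance runs

Unit and property tests run on matrices of up to a few thousand sites;
the acceptance checks use the default 4,000-site arm, a 10,000-site
parameter-recovery configuration (20 + 20 diploids), and a 2,000-site
LD configuration (20 diploids, 200 kb), sizes at which every check
completes in seconds on one CPU while estimator standard errors stay
well inside the asserted tolerances.
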