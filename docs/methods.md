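# Methods

This note records the statistical models, estimator conventions, default
parameters, and numerical choices used throughout `haploscan`, together with
the reasoning behind the non-obvious design decisions.

## Scope and data model

`haploscan` analyzes panels of haploid genomes: biallelic SNPs with 0/1
alleles per sample (missing = `.`), two (or three) predefined or inferred
sample groups, and optionally a matrix of read counts in non-overlapping
1-kbp bins for copy-number work. All genomic coordinates are 1-based
inclusive; BED exports convert to 0-based half-open.

Heterozygous calls in a haploid panel are treated as errors: by default the
VCF reader rejects them (`het_policy="reject"`), or they can be masked to
missing (`het_policy="missing"`). Only biallelic SNPs are read.

## Variant filtering

Hard filters follow standard GATK-style annotation thresholds:

    QD < 2.0, FS > 80.0, MQ < 20.0, SOR > 3.0,
    MQRankSum < -12.5, ReadPosRankSum < -8.0, QUAL < 40.0

A site fails if **any** clause is strictly true; a missing annotation never
fails a clause (NaN passes). Singleton removal drops sites whose minor
allele count over non-missing calls is ≤ 1; such sites are uninformative
for frequency-based statistics and enriched for sequencing error.

## Diversity statistics

Windows are 10 kbp sliding by 1 kbp by default. Per site with `c` alternate
alleles among `n` non-missing calls, the pairwise-diversity contribution is
`2 c (n - c) / (n (n - 1))`. θπ and θw are reported both absolute (per
window) and per bp using the full window length as denominator. Tajima's D
uses the standard constants (a1…e2) evaluated at the window's modal number
of called samples; windows with S = 0 or n < 4 are NaN. Site-frequency
spectra are computed either at the modal n (restriction) or by
hypergeometric projection to a chosen n.

## Divergence

The primary Fst estimator is Hudson's, computed as a ratio of averages
(sums of per-site numerators and denominators over the window), which is
robust to rare variants; a Weir–Cockerham haploid ANOVA variant is
available as an option. Dxy is the mean per-bp inter-group difference
`p1 (1 - p2) + p2 (1 - p1)` summed over window sites. ZFst standardizes
windowed Fst and flags the top 5% / 1%. SNP sharing classifies each
biallelic site as polymorphic in both groups, fixed (different allele) in
both, or fixed in one and polymorphic in the other.

## Linkage disequilibrium

r² and D′ come from the explicit 2×2 haplotype table over
pairwise-complete samples (≥ 4 required). Decay curves are mean r² in
100-bp distance bins up to 10 kbp, smoothed with lowess (tricube local
linear, via statsmodels). LD50 is the start of the bin whose mean r² is
closest to half the maximum from above; if no bin falls to half-max the
curve is flagged "not decayed within range". Equal-S comparisons between
groups use a seeded random subsample of sites.

## Selection scan

**Permutation-calibrated Tajima's D.** Pseudo-windows with S* sites (S*
drawn from the observed per-window S distribution) are resampled with
replacement from genome-wide segregating sites; this preserves the SFS
while destroying spatial clustering. A window is a candidate only when its
D lies below the 5th percentile of **both** the permutation null and the
observed genomic distribution.

**CLR sweep scan.** At grid points every 2 kbp, the composite likelihood
of the surrounding 10-kbp window's allele-count classes is maximized over
a log-spaced sweep-strength grid α ∈ [1e-5, 1e-2] per bp and compared to
the genomic background spectrum: each lineage escapes the sweep with
probability `1 - exp(-α d)`; escaped lineages draw from the background SFS
(projected by hypergeometric sampling); non-escaped lineages coalesce into
one uniformly chosen ancestor's allele. Folded spectra are the default (no
outgroup polarization is assumed; a folded background is unfolded
symmetrically). The background model is the α → ∞ limit and is always
included as a candidate, so CLR = 2(maxα ℓ_sweep − ℓ_bg) ≥ 0.

*Invariant-site density term.* Conditioning every site on polymorphism
discards the sweep's strongest local signature — the deficit of
segregating sites. Usable sites are therefore modeled as a Poisson process
with intensity ρ·r(d), where ρ is the genome-wide usable-site density and
r(d) = P(site still polymorphic | α, d) under the same escape model.
Relative to the background this adds `Σ_i log r(d_i) + ρ ∫ (1 - r(d)) dd`
(64-point trapezoid over the window) to the sweep likelihood; both terms
vanish as α → ∞, preserving the nesting. Established sweep scanners use
invariant sites for the same reason. In testing this term raised
localization of injected 20-kbp sweeps from roughly half of replicates to
~95% within ±10 kbp.

**Genomic islands.** Windows flagged by ZFst (top 5%) *and* the combined
Tajima's D rule are merged when their starts lie within a configurable
number of window steps; a CLR top-1% requirement can be added.

## Copy number

Per sample, read counts are anchored to the genome-wide median bin count
(the haploid CN = 1 baseline). Classes 0..8 have negative-binomial
emissions with mean `median × max(c, 0.05)` and variance `μ + 0.1 μ²`
(dispersion matches typical short-read bin counts; the 0.05 floor gives
the CN = 0 "absence" class a residual rate for mismapped reads). Calls are
the Viterbi path of a sticky per-contig HMM (switch probability 0.01,
initial mass 0.9 on CN = 1).

Earlier prototypes using per-bin mixtures with a free baseline rate failed
on cohort-shared CNVs: the free rate absorbed the shifted depth and the
shared gain disappeared. Fixing the baseline at the per-sample median and
pooling evidence along the contig resolved this. The switch probability
was set from an operating-characteristic analysis of the emission model at
30× / dispersion 0.1: a single bin essentially never clears the switch
penalty by chance (~1e-8 per bin), while detection of a true 10-bin
doubling improves markedly as the penalty drops. Doublings of that length
are information-limited at this noise level (even the optimal whole-segment
detector reaches only ~93% at near-zero false-positive rate); absences and
≥ 3× gains are detected with near-certainty. Segment-level evaluation
therefore distinguishes *detection* (a correct-direction non-baseline
call over the segment) from *genotyping* (the exact integer copy number),
and population statistics at segments use the per-sample modal call —
segment-edge bins reflect breakpoint imprecision, a detection property.

CN = 0 is reported as an "absence", not a deletion: a locus missing from
an analyzed genome may equally reflect an insertion private to the
reference.

Vst = (V_T − V_S)/V_T with the sample-size-weighted mean of unbiased
within-group variances; V_T = 0 gives NaN. PIC is reported in the
gene-diversity form `1 - Σ p²` with Botstein's full form available.
Differential copy number uses Welch's t per gene (mean CN over member
bins) with Benjamini–Hochberg control at FDR < 0.01; a gene invariant in
both groups is untestable (NaN) unless the group means differ, which is a
fixed difference (p = 0).

## Synthetic data

The simulator is the package's validation instrument; its defaults are the
study conditions and are not adjusted to make tests pass.

**SNP panel.** Each candidate site (density 0.02/bp) draws an ancestral
frequency from the density ∝ 1/x on [1e-3, 1 − 1e-3] — integrating this
against binomial sampling yields the neutral 1/j sample SFS — and each
group g draws its frequency from the Balding–Nichols distribution
`Beta(p(1-F_g)/F_g, (1-p)(1-F_g)/F_g)`. With both groups at F the expected
Hudson Fst is ≈ F, and within-group heterozygosity shrinks by (1 − F_g),
so the defaults F₁ = 0.3, F₂ = 0.75 reproduce a strongly diverged pair
with asymmetric diversity. Sites monomorphic after sampling are dropped
(retention falls with F), so quoted SNP counts refer to emitted
segregating sites. Short-range LD is phenomenological: within 400-bp
blocks a site copies the previous site's sample pattern with probability
0.9, giving LD50 of a few hundred bp. This emulates the *pattern* of LD
decay, not a coalescent with recombination; analyses that need i.i.d.
sites (estimator-recovery and calibration runs) set the copy probability
to 0.

**Sweeps.** A sweep is injected at the pattern level in one group: sites
in the interval are homogenized to the group's majority allele with
probability 1 − 1/reduction (default 10× thinning), and 80% of the sites
left polymorphic become singletons. This produces the low-π, negative-D,
site-deficit signature a hard sweep leaves, sufficient to exercise the
scan; it is not a forward simulation of selection.

**CNV depth.** Per-sample coverage is the nominal 30× jittered uniformly
by ±20%; counts are negative binomial around coverage × CN with
dispersion 0.1; CN = 0 bins draw at a 5% residual rate.

## Determinism and numerics

All stochastic components take explicit integer seeds (numpy
`default_rng`); pipeline outputs carry a header with the package version,
seed, and config hash, and reruns are byte-identical. Log-space
computation is used for all likelihoods (gammaln-based binomial and NB
coefficients); escape probabilities are clipped to [1e-12, 1 − 1e-12] and
site probabilities floored at 1e-300 before logs. Tajima constants are
cached per n.

## Limitations

- The LD model is phenomenological; r² decay shape beyond the block scale
  is not coalescent-accurate.
- Sweep injection does not model hitchhiking's effect on nearby *between*
  group divergence, so ZFst at injected sweeps arises mainly from the
  diversity reduction.
- The CLR scan assumes a single panmictic background spectrum per group;
  strong internal structure within a group would miscalibrate it.
- Copy-number genotyping beyond ~3× is limited by the NB noise at 30×
  (CN 3 vs 4 confusion), and 10-bin doublings sit near the detection
  boundary by information content.
- The third "minor" group (n = 2) is carried through I/O and structure
  analyses but is too small for within-group statistics.
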