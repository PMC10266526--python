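# Methods

This note documents the statistical models implemented in `archintro`,
the choices made where the design was genuinely open, what the bundled
simulator does and does not emulate, and the numerical conventions.

## Meta-analysis

Per-study effects are ln odds ratios with standard errors.  The combined
estimate is inverse-variance-weighted fixed effects: weights wᵢ = 1/seᵢ²,
β̂ = Σwᵢβᵢ/Σwᵢ, se = (Σwᵢ)^(−1/2).  Cochran's Q and I² are computed and
reported as diagnostics but never used to filter or reweight — the
common-effect model is assumed throughout.

p-values are represented exclusively as −log₁₀ values.  `log10_tail_p`
evaluates −log₁₀(2Φ(−|z|)) through `scipy.special.log_ndtr`, which is
accurate over the whole double range; the inverse (`z_from_neg_log10_p`)
is a bracketed root solve on the same function, so p ↔ z round-trips to
better than 10⁻⁸ for z up to ~40 (p down to ~10⁻³⁵⁰).  This matters
because the strongest association handled here sits near p = 6.4 × 10⁻¹³²,
far below linear-scale underflow when combined across studies.

Harmonization across studies matches variants exactly on
(chrom, pos, ref, alt); ref/alt-swapped records are flipped (β → −β,
f → 1−f); strand-ambiguous A/T and C/G flip candidates are dropped and
counted, since their orientation cannot be verified from summary data.

Loci are defined by greedy clumping: the most significant remaining
variant passing P < 5 × 10⁻⁸ leads a locus that absorbs every variant
within ±500 kb (window configurable).  The upstream analysis used an
interactive locus browser without a printed algorithm; greedy distance
clumping is the standard reproducible stand-in, so locus *counts* are a
convention, not a replicated quantity.

## Archaic tract detection

For each diploid modern sample, each biallelic site receives a log₁₀
likelihood ratio comparing two emission models given the archaic
reference genotype and the panel alt-allele frequency p:

* **IBD**: one haplotype copies a uniformly chosen archaic allele, flipped
  with the modern genotype error ε_m (default 0.002); the other haplotype
  is an independent population draw at frequency p.  A heterozygous
  archaic call averages over the two alleles.  The archaic call itself is
  taken at face value; the `archaic_error` knob (default 0.01) exists for
  sensitivity analyses that perturb archaic genotypes upstream rather
  than entering the emission directly.
* **Null**: Hardy–Weinberg at p.

Missing archaic calls, panel-fixed sites, and sites below
`min_minor_count` contribute exactly 0.  All maximal-scoring runs of site
LODs are extracted with the Ruzzo–Tompa algorithm (verified against
exhaustive subsegment enumeration for short inputs) and runs with total
LOD ≥ 4 become tracts — the conservative threshold recommended for
reference-anchored IBD detection.  A tract's physical span runs from its
first to last contributing site, which slightly *under*-covers the true
recombination breakpoints; its genetic length comes from the
recombination map.

Zygosity of a tract uses a counting rule standing in for an HMM-based
runs-of-homozygosity caller: a region is homozygous iff it contains ≥ 10
genotyped sites of which ≥ 99% are homozygous.  The named upstream tool's
parameters are unpublished; the rule here is explicit and testable.

## The incomplete-lineage-sorting length test

A haplotype shared between a modern genome and an archaic genome either
entered by admixture (t_admix ≈ 2,000 generations ago) or descends from
the common ancestral population (divergence ≈ 21,500 generations).  In
the ancestral case the tract must survive recombination along both
branches, a total branch length of 2·t_div − t_admix = 41,000 generations,
so its expected genetic length is L = 100/41,000 = 1/410 cM and —
conditional on observation on both branches — its length is
Gamma(shape 2, rate 1/L): the sum of two exponential branch contributions.

The significance threshold m solves the survival equation
(1 + m/L)·e^(−m/L) = α/n_tests (α = 0.05, Bonferroni over the 61 tested
loci), implemented through the exact inverse upper-tail of Gamma(2,·)
(`scipy.special.gammainccinv`) and unit-tested against a pure-bisection
oracle on the survival equation itself: m = 0.023 cM.  Where the
recombination map runs out, a 1 cM/Mb end rate converts this to a 23 kb
physical cutoff.  Tracts must be strictly longer than m to count as gene
flow.

## Cosegregation and locus classification

Archaic carriage at a position is a per-sample dosage: 0 (no significant
tract covering the site), 1 (heterozygous tract) or 2 (homozygous);
overlapping tracts of one sample are merged first.  Cosegregation is the
squared Pearson correlation between variant dosage and carriage dosage —
the unphased genotype r² convention of standard LD software.  Dosage mode
is the default; carriage can be collapsed to presence/absence by callers
that prefer it.  Classification: r² ≤ 0.2 "none", 0.2 < r² ≤ 0.5
"candidate", r² > 0.5 "cosegregating"; boundaries fall to the lower class.

## Fine-mapping

Under a single causal variant, each variant's evidence is Wakefield's
approximate Bayes factor,
ln ABF = ½·ln(se²/(se² + W)) + z²W/(2(se² + W)), with prior variance
W = 0.04 (prior SD 0.2 on ln OR) — the conventional default for binary
traits; credible-set replication of the nine-variant chromosome 7 locus
is robust to W across [0.01, 0.1].  PIPs are normalized Bayes factors
computed via log-sum-exp (stable at ln ABF ≈ 300), and the 95% credible
set is the shortest PIP-descending prefix reaching 0.95, ties broken by
position.  Published tables print OR and p only; `se_from_or_p`
reconstructs (β, se) as β = ln OR, se = |β|/z(p), which reproduces the
published credible set exactly and the lead PIP to within rounding of the
printed inputs (±0.02).  Normalization runs over the supplied variant
list only — there is no "no causal variant" model, matching the
assumption of exactly one causal variant in-region.  Regions can be
delimited by recombination hotspots: maximal runs of map intervals whose
local rate exceeds 10 cM/Mb (configurable; the upstream hotspot
definition is unpublished).

## Heritability and polygenic risk scores

For case-control hits a linear transformation gives per-variant
h² ≈ k·f·(1−f)·β with k constant across variants.  The published formula
is linear in β; the standard explained-variance form is 2f(1−f)β².  Both
conventions are implemented (`as_printed` is the default and every report
labels its mode); every ratio the package reports cancels k exactly, and
the expected-share calculation is additionally mode-invariant because
equal βs cancel.  The expected archaic share under p = 2% of loci at
f = 0.04 versus f = 0.266 elsewhere is ~0.4%, robust to substituting the
0.246 non-archaic frequency alternative (0.42% vs 0.40%).

Combined odds ratios assume additivity on the log-odds scale: Σβ with
standard errors combined in quadrature; per-variant se can be recovered
from printed CIs symmetrically on the log scale, which reproduces the
published point estimate exactly and its CI to ±0.01.  PRS is Σ dosage·β
per individual or Σ 2f·β per group (the HWE expectation, an analytic
identity verified by simulation).  The prevalence comparison is a pooled
two-proportion z-test with Wilson 95% intervals — counts, not per-subject
values, are what summary data provide.

## The synthetic-data generator

`archintro.synthetic_data` generates exactly the structure the analyses
assume, with no coalescent machinery:

* **Haplotype mosaic.**  Each haplotype receives introgressed tracts whose
  genetic lengths are Exponential with mean 100/t_admix = 0.05 cM and
  whose expected total occupies `admix_fraction` (default 0.02) of the
  haplotype, plus ILS tracts drawn directly from the Gamma(2, rate 410)
  null (mean count 5 per haplotype by default) — so the ILS filter has an
  exact null to be calibrated against.  Tracts are placed uniformly in
  genetic coordinates and truncated at chromosome ends.
* **Sites.**  Archaic-diagnostic markers (0.3/kb) carry the archaic allele
  on archaic-origin sequence and segregate at 0.002 off-tract; neutral
  background sites (0.5/kb) have Uniform(0.05, 0.95) frequencies drawn
  independently of tract status.  The real density of diagnostic alleles
  on Neandertal haplotypes is not a published constant; the defaults make
  a 0.05 cM tract carry ~15 markers (summed LOD far above 4) while ILS
  tracts (mean 0.005 cM) usually carry too few to call.
* **Archaic reference.**  Homozygous archaic at markers, Hardy–Weinberg
  draws elsewhere, masked missing at rate 0.5 — emulating the roughly
  half-mapped archaic genomes.
* **Phenotypes.**  Logistic disease model on causal dosages with the
  intercept solved by bisection so the population prevalence is exact;
  per-allele odds ratios are therefore recovered directly.  The default
  study plants the published trio (1.79, 1/0.72, 1.14) on
  archaic-haplotype markers plus two ordinary variants (1.35, 1.25).
* **Summary statistics.**  Per-study allelic 2×2 Wald ln OR with Haldane
  0.5 correction on zero cells; p-values via the log-space tail.  A
  per-study logistic regression is unnecessary for unconfounded synthetic
  data.
* **Scale.**  The default fixture uses a 10 Mb chromosome at 1 cM/Mb, a
  150-sample introgression panel, and a 60,000-individual association
  cohort (5% prevalence) sampled into three disjoint studies of 900 cases
  and 9,000 controls — mirroring the real design's split between a large
  association cohort and a small haplotype panel while staying desk-scale.
  Every stochastic step is a pure function of (inputs, seed); one master
  seed fans out to stage seeds through a fixed `SeedSequence` derivation.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: linkage disequilibrium among background
variants (cohort genotypes are drawn independently per site), population
structure and other confounding (λ calibration holds by construction),
genotyping error in modern panels, internal haplotype structure of
archaic segments at non-marker sites (which depresses detected-tract
homozygosity calls), X chromosomes, and realistic site-frequency spectra.

## Numerical conventions and degenerate inputs

Coordinates are 1-based inclusive in memory and in VCF; BED output is
0-based half-open.  Recombination maps interpolate piecewise-linearly
between anchors and extrapolate at 1 cM/Mb beyond them; a missing
cumulative column is reconstructed by integrating the rate column.
Monomorphic variants yield β = 0 with infinite se and are excluded from
meta-analysis by their weight of zero; zero-variance dosage vectors make
r² undefined and flagged, never 0.  Multiallelic and indel records are
skipped with a logged count, never split.  Root solves (`ils_length_threshold`,
`z_from_neg_log10_p`) are bracketed and converge to relative tolerance
better than 10⁻⁹.

## Known limitations

* The locus count of a genome-wide scan depends on the clumping
  convention; only threshold-based quantities are reproducible.
* The per-site emission model is a fully specified reconstruction of a
  reference-anchored IBD caller whose exact defaults are unpublished;
  parameters are explicit configuration, not claims of equivalence.
* Detected tract spans shrink to the outermost informative sites, so
  genetic lengths are slightly conservative near the ILS threshold.
* Denisovan-optimized detection, reference-free (S*-type) scans,
  multi-causal fine-mapping and LD-score–based genome-wide heritability
  are out of scope.
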