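# Methods

This note records the models, parameter choices and numerical conventions
behind `impute-eval`, and what the synthetic evaluation does and does not
show about real data.

## The synthetic population

The generator produces the statistical structure that a sequence-level
imputation study depends on, without claiming population-genetic realism.

**Site-frequency spectrum.** Ancestral allele frequencies are drawn per
site from a symmetric Beta(α, α) law with α = `sfs_shape` (default 0.25)
and realized in a pool of `n_ancestors` (default 40) ancestral haplotypes.
The pair (0.25, 40) was calibrated once, by simulation, so that the
realized fraction of sites with MAF ≤ 0.03 in the bred cohort is close to
13.5% — the rare-variant load typical of an indicine sequence panel — and
stays within ±2 percentage points of it across seeds at the default scale.
Sites monomorphic across the founders are dropped, so a chromosome carries
slightly fewer than `n_sites_per_chrom` sites.

**Linkage disequilibrium.** Founder haplotypes are mosaics of the ancestor
pool, switching ancestor with probability `mosaic_switch_rate` (5e-4 per
site) at each site. This creates block-wise haplotype sharing — the
resource both imputation engines exploit — without a coalescent simulator
and with exact reproducibility.

**Recent mutations.** Sites whose realized founder MAF is at or below
`recent_mutation_maf` (0.05) are re-realized as *recent* mutations: the
carrier haplotypes are redrawn uniformly, so the minor allele sits in weak
LD with the mosaic background that the array sites tag. Without this step
rare alleles ride on old, array-taggable ancestor segments and impute as
easily as common ones, which inverts the rare/common accuracy contrast
that real sequence data show. Carriers still transmit the allele through
the pedigree, so imputation from close relatives remains possible — rare
variants become *harder*, not impossible.

**Breeding.** A pool of `n_sires` (12) founder males is mated to random
dams; each gamete recombines the parental haplotypes with a
Poisson(`recomb_rate` × chromosome length) crossover count (default
1 cM/Mb, one Morgan per 100-Mb chromosome). Offspring are therefore
enriched for half-sib relationships, like a sire-dominated cattle cohort.
The pedigree, with simulated progeny counts, is retained for reference
selection.

**Array ascertainment.** Array membership is sampled without replacement
with probability proportional to MAF (`array_fraction` default 0.019,
the array-to-sequence density ratio of a ~777k chip against ~30M sequence
sites). Commercial chips are ascertained for common variants; the chip's
exact SFS is not modelled.

**Functional annotation.** Impact classes (high / moderate / low /
modifier) are drawn with configurable marginal proportions (defaults
0.01 / 0.04 / 0.05 / 0.90 — high and moderate are deliberately more
frequent than in real VEP annotation so that class-level statistics are
testable at desk scale). Class probabilities are tilted by rarity so the
share of rare sites inside high+moderate matches
`rare_enrichment_high_moderate` (0.15).

**Sequencing artifacts.** Called genotypes flip to one of the other two
codes with probability `genotype_error_rate` (0.004, chosen so that
sequence-vs-truth concordance is ~99.6%, the level reported for ~15×
bovine calls validated against array genotypes). GQ is a rounded
N(45, 15²) clipped to [0, 99]; with the default GQ < 15 rule this sets
~2% of genotypes missing. Site filter statistics are drawn from ranges
that straddle the standard hard-filter thresholds, with a configurable
fraction of sites (default 1% per statistic) violating each rule.

All randomness flows from a single integer seed through named
`numpy.random.Generator` streams (stream names hashed with crc32); a fixed
seed reproduces byte-identical output.

## Quality control

Rules use strict inequalities exactly as conventionally printed: a site at
QD = 2.0 survives. Removal order is fixed and logged — site-statistic
rules (in the order QD, FS, MQ, ReadPosRankSum, MQRankSum, SOR; a site
violating several is counted under the first), biallelic restriction,
genotype-level filtering (GQ → missing, then the missingness cap), and
finally the MAF floor computed on the post-missingness calls. A site with
an absent (NaN) statistic is not tested by that rule, so imported VCFs
lacking some INFO keys still pass through. The missingness cap is an
absolute count (40) for the canonical 151-animal cohort and rescales by
the companion fraction (26.5%) otherwise. The report reconciles exactly:
`n_out = n_in − Σ removals`, and filtering is idempotent.

## Reference selection

The GRM is VanRaden method 1, G = ZZ′ / (2Σpⱼ(1−pⱼ)), with missing
genotypes mean-imputed per site for this computation only. k-means runs on
the leading `n_components` (20) eigenvectors scaled by √eigenvalue —
clustering raw GRM rows would conflate self-relationship with relationship
pattern. k-means++ with 10 restarts and a fixed seed makes the assignment
deterministic; ties in progeny count break toward the lexicographically
smallest sample id.

## Phasing

Targets are pre-phased at array sites by a two-stage heuristic: first an
IBD pair pass — half-overlapping windows (whole chromosome, then 48, 24,
12 array sites) are phased outright whenever a reference haplotype pair is
genotype-compatible at (almost) every observed site, tolerating a 2%
mismatch allowance for call errors, with each window oriented by majority
vote over the hets it overlaps; then a greedy left-to-right scan that, at
each heterozygote, keeps the allele arrangement extending the longest
running exact match to any reference haplotype. This is a deliberately
simple stand-in for a production phaser; at array density with a related
reference it achieves < 5% switch error for offspring of reference
animals, which suffices for the copying-model engine.

## The copying-HMM engine (`lshmm`)

Per target haplotype, hidden states are reference haplotypes; transitions
between consecutive array sites use the uniform-jump kernel (stay with
probability exp(−`recomb_scale`·Δd), otherwise land uniformly, including
on the current state), and emissions flip with miscopy probability
`mutation_rate`. The forward–backward recursion is run with per-step row
normalisation — exact posteriors without log arithmetic — and raises on
any non-finite mass. Posteriors at the array sites are linearly
interpolated on the genetic map (default 1 cM/Mb when none is supplied)
at the unobserved sites between them, flat beyond the terminal array
sites; the hidden-site haplotype dosage is the interpolated
posterior-weighted reference allele. Observed array alleles pass through
unchanged. With more reference haplotypes than `n_states_cap` (512) an
evenly spaced deterministic subset is used.

Defaults: `mutation_rate` 0.01 — the allele-level mismatch noise between
a target haplotype and its best template, absorbing the genotype-call
error (~0.004), residual phasing switch error and young alleles absent
from the copied background; `recomb_scale` 10 per Morgan — a small
closely-related panel needs few switches.

**Model Rsq.** The per-site quality statistic is the population variance
of the per-haplotype alt-allele probability divided by p(1−p) with p the
mean haplotype dosage (0 when p ∈ {0,1}, clamped to [0,1]); perfect
allele recovery gives exactly 1. The statistic is computed on the *full*
allele probability, which includes the miscopy layer on top of the
template posterior: P(allele) = (1−2μ)·P(template) + μ. This affine
damping does not change the correlation structure of the dosages (so
empirical R² is untouched) but makes Rsq a conservative estimate of
realized accuracy, most visibly at low MAF where p(1−p) reacts fastest —
the behaviour expected of this family of quality statistics. For imported
VCFs without haplotype-level dosages the diploid fallback
Var(d)/(2p(1−p)) is used.

**Hard calls.** best_guess rounds the dosage; an exact .5 rounds toward
the reference-panel major genotype (deterministic, logged).

## The sliding-window engine (`osw`)

Windows of `initial_window_sites` (64) array sites slide with 50% overlap;
per window and target, all reference haplotype pairs are scored for
genotype compatibility at the observed sites (an outer-product
formulation scores all K² pairs with three matrix products). The best
pair with agreement ≥ `min_match_fraction` (0.9) donates its alleles at
the still-unfilled sites the window spans. The window shrinks by
`shrink_factor` (0.5) per sweep down to `min_window_sites` (4); earlier
(longer-window, closer-relative) fills are never overwritten. Sites never
filled take the reference expected allele dosage p per haplotype. Matched
fills are integral genotypes; only fallback fills are fractional. The
exact window schedule and thresholds of production tools of this family
are proprietary; these defaults are calibration choices.

## Evaluation

Folds are a seeded balanced partition (151 animals in 5 folds → sizes
31, 30, 30, 30, 30). Masking hides every non-array genotype of the fold's
animals; all other animals form the phased reference. Only non-array
sites are scored. Per-SNP R² correlates observed genotype codes with
imputed dosages across fold animals (hard calls optionally, switchable);
PERC compares hard calls. Sites where either vector is constant — or
fewer than two truth genotypes remain — carry an undefined-R² reason code
(`constant_observed` / `constant_imputed` / `too_few_observations`); PERC
is still reported there, and undefined sites are excluded from R²
averages and from cross-engine comparisons (which use the jointly defined
site set). Variance below 1e-12 counts as constant.

Stratification MAF is the full pre-masking cohort MAF (switchable to
reference-only); windows are half-open 1-Mb intervals, window k covering
positions [k·10⁶+1, (k+1)·10⁶]; quartiles use the linear-interpolation
convention. The Rsq calibration replaces a LOESS-style smoother with
fixed-width (0.01) binned means of empirical R² and model Rsq by MAF —
deterministic and testable, visually equivalent at desk scale — plus the
overall correlation and mean signed difference of the two statistics.

## Problem sizes

The default study configuration is 200 animals, 2 chromosomes × 10,000
sequence sites (~17k polymorphic after founder realization, ~11k after
QC), 1.9% of sites on the array, fivefold masking CV. The directional
study runs one fold per seed (the fold index rotates with the seed) over
10 seeds; a single study takes a few seconds on one CPU. These sizes were
chosen so the full statistical structure — rare/common contrast, Rsq
calibration, engine ranking — is measurable while the whole suite runs in
well under a minute per component.

## What passing tests do and do not show

The generator reproduces the *structure* the evaluation design assumes —
rare-skewed SFS, decaying LD, array ascertainment, related targets,
call-quality artifacts — not any real population. Accuracy magnitudes on
synthetic data (per-animal R² ≈ 0.93, per-SNP R² ≈ 0.78) land near the
range reported for real cattle panels, but only the *directional*
statements (rare < common; window matcher > copying HMM on rare variants
with a small close reference and the reverse on common ones; model Rsq a
slight underestimate of empirical R²; per-animal > per-SNP accuracy) are
claimed and tested, as trends over seeds. Absolute accuracies on any real
population depend on its LD, relatedness and panel density and must be
measured there. No indels, no multi-allelic sites, no X chromosome, no
pedigree-based imputation, and no claim about wall-clock performance of
the engines relative to production tools.
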