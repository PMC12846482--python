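# Methods

This note documents the models, defaults and design choices behind
`growmark`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Quality control (`varfilter`)

Loci are retained when **all** of the following hold, with strict
inequalities: minor allele frequency > `maf_min` (default 0.1), per-locus
missing rate < `max_missing` (default 0.10), Hardy–Weinberg exact-test
p > `hwe_p_min` (default 1e-6). Allele frequencies exclude missing calls.
The HWE test is the exact conditional test on genotype counts: given the
allele counts, heterozygote counts of matching parity are enumerated via
the standard ratio recurrence from the modal count, and the two-sided
p-value is the total probability of counts no more likely than the
observed one. Monomorphic loci return p = 1 by convention. The test is
verified against an independent closed-form enumeration for every count
triple up to 30 individuals.

The HWE test pools all samples. In a structured sample the Wahlund effect
depresses heterozygosity, so strongly diverged loci can fail the pooled
test even when each population is internally in equilibrium. This is a
property of pooled filtering itself, kept deliberately; it matters for the
end-to-end scenario below. Multiallelic sites and indels are rejected at
VCF read time; genotypes come from the GT field only, with phased and
unphased separators treated identically.

## Diversity and trees (`popgen`)

Per-locus statistics use within-population allele frequencies. With alt
frequency p, q = 1−p, m non-missing alleles of which j are alternate:
Ho = observed heterozygote fraction, He = 2pq, Pi = 2j(m−j)/(m(m−1)),
PIC = 1−(p²+q²)−2p²q². Population means include monomorphic-within-
population loci (contributing 0), matching whole-panel averaging; a
`polymorphic_only` flag excludes them. PIC ≤ He always, with equality only
at fixation.

Individual distances are allele-sharing distances Σ|dᵢ−dⱼ|/(2L) over
pairwise-complete loci; population-level Nei (1972) standard distance is
provided as a companion. Neighbor joining is the classic Saitou–Nei
agglomeration. Two determinism/robustness rules are pinned: Q-matrix ties
resolve to the lowest-index pair, and a negative branch length is clamped
to zero with the deficit transferred to its sibling edge. On exactly
additive inputs the recovered tree's patristic distances equal the input
matrix, which the tests verify against scikit-bio tree traversal over
random 5–8 taxon trees.

## Mixed model and GWAS (`mixedmodel`)

The GRM is VanRaden method 1 on mean-imputed, 2p-centred dosages,
G = WWᵀ/(2Σp(1−p)). The phenotype model y = Xb + Za + e (Z = I at the
individual level) is fitted by REML, profiling the likelihood over the
variance ratio λ = σ²ₐ/σ²ₑ on the eigenbasis of G; each evaluation is a
weighted least-squares fit, and a 41-point grid over log λ ∈ [−12, 12]
seeds a bounded scalar refinement (xatol 1e-10). A ratio pinned at the
lower bound is reported as σ²ₐ = 0. With a group-block G this matches
statsmodels' MixedLM REML to ≲1e-4 relative (tested); with G = I the
*ratio* is unidentifiable (V ∝ I for any split), which is harmless for
GLS-based tests and is why the oracle comparison uses a block design.

Without pedigree records, "single-step" GBLUP reduces to GBLUP on the
GRM; that is what is implemented.

**Adjustment modes.** `fixed_only` (default) returns y − Xb̂: systematic
population/age/location/season effects are removed while additive genetic
signal is retained for the scan. `full_residual` returns
ê = y − Xb̂ − Zâ, a literal residual; because the BLUP â absorbs additive
signal, association on these residuals is attenuated (demonstrated in the
tests), so this mode is behind a flag rather than the default. This is the
most consequential modelling choice in the package and the reason the
default exists.

The fixed-effect builder dummy-codes categorical covariates and drops
columns that do not increase the design rank, greedily in input order,
logging what it dropped — with one population per location/season the
latter are fully aliased and removed.

**Scan.** EMMAX approximation: variance components estimated once under
the null, every locus then tested by GLS under V ∝ λ̂G + I. Computation
whitens y and the dosage matrix by (λ̂D+1)^(−1/2) on the eigenbasis,
residualizes the null covariates, and applies a two-sided t test
(n − p − 1 df) per locus. Monomorphic loci are skipped and logged. The
Bonferroni threshold is α/m with α = 0.05 and m the loci actually tested.
With G = I the scan reduces exactly to OLS simple regression, which the
acceptance suite checks to 1e-6 on 200 × 500 data.

`merge_model_results` unions per-model significant-locus lists by
`chrom_pos_ref_alt` identifier, concatenating contributing model labels
alphabetically and sorting by chromosome then position. It is commutative
and idempotent. FarmCPU and BLINK are established external algorithms and
are not re-implemented; their result files are merge inputs, and the
bundled published marker table reproduces the 29-hits → 26-loci collapse.

## LD expansion (`linkmap`)

Tags are annotated to genes whose 1-based closed interval intersects
[pos−50 kb, pos+50 kb]; strand is ignored. All SNPs with
start ≤ pos ≤ end belong to a gene (a SNP under overlapping genes counts
for each). LD is composite r²: squared Pearson correlation of unphased
dosages over pairwise-complete individuals — the convention of
genotype-based LD tools, chosen because the data are unphased; haplotype
(EM) r² would differ slightly at loci far from HWE. Each tag is compared
against the SNPs of its own genes by default (`pooled_gene_snps=True`
compares against all annotated genes' SNPs); loci with r² > 0.5 on the
same chromosome are linked. A SNP linked to several tags appears once in
the combined candidate list with its best tag and r²; tags without gene
annotation are excluded from expansion and logged. LD is computed on all
samples pooled, which population structure inflates; a caveat to keep in
mind when interpreting linked sets, and the reason r² thresholds should
not be pushed lower.

## Genotype-class association (`assoc`)

One-way fixed-effects ANOVA of adjusted weight across genotype classes
(scipy's F test), followed by Fisher's LSD: unadjusted pairwise t tests on
the pooled within-class MSE with N−k df. Classes below `min_class_n`
(default 3) are dropped from the ANOVA — the behaviour for rare classes
has to be pinned somewhere — but still appear in the per-population
frequency tables, where they matter for uniqueness. Fewer than two
eligible classes → "not testable", not an error.

A candidate is growth-related when ANOVA p < 0.05; no multiplicity
correction is applied across candidates by default, matching plain
marker-screening practice (the per-test level is verified to be ~0.05
under a global null); `bh_correct=True` applies Benjamini–Hochberg for a
stricter screen. The superior genotype is the highest-mean eligible class
(heterozygotes eligible), ties broken by larger n then lexicographically,
logged. The full LSD matrix is reported so stricter superior-genotype
definitions can be applied downstream. A growth-related marker is
population-unique iff its superior genotype has nonzero observed frequency
in exactly one population — an observed-data criterion, deliberately, not
a statement about true population frequencies.

Whether the class ANOVA should use raw or adjusted weights is genuinely
ambiguous in this kind of design; adjusted is the default (raw weights are
dominated by the ~35-fold between-cohort differences), and the CLI accepts
a raw-weight table if the user wants the literal alternative.

## Synthetic data (`simdata`)

The generator emulates a four-population resequencing design: unequal
sample sizes (default 20/20/20/30), population body-weight means and SDs
(17.4±3.5, 18.7±4.1, 30.6±5.5, 625.2±44.3 g) mirroring cohorts sampled at
different growth stages, per-population age/season/location covariates
that are fully confounded with population, and 2 % uniform missingness.

* **Divergence**: Balding–Nichols — population frequencies are
  Beta(p(1−F)/F, q(1−F)/F) around a Uniform(0.05, 0.95) ancestral
  frequency, so Var = F·p(1−p); default F = 0.08, single parameter,
  analytically checkable (Monte-Carlo verified in tests; empirical Hudson
  FST is monotone in configured F).
* **LD**: first-order Markov haplotype chains — a latent uniform is copied
  from the previous locus with probability `ld_rho` (default 0.3) and
  redrawn otherwise, then thresholded at the locus frequency. Marginal
  frequencies are exact; adjacent allelic correlation equals ρ when
  neighbouring frequencies are equal (genotype r² ≈ ρ², verified), and is
  attenuated otherwise, as for any binary chain. Chosen over coalescent
  simulation because it is desk-scale and its r² is analytically
  predictable; it does not reproduce coalescent allele-frequency spectra,
  recombination hotspots, or long-range LD decay.
* **Planted structure**: causal loci (effects in within-population SD
  units), LD partners (haplotype copy probability ρ ⇒ genotype r² ≈ ρ²),
  and population-restricted loci whose alternate allele exists only in one
  population.
* **Phenotypes**: population mean + covariate effects + Σβ·dosage +
  polygenic term (built from genome-wide standardized dosages, i.e.
  GRM-correlated) + residual, partitioned so the within-population
  variance has heritability h² (default 0.3) on each population's own SD
  scale.

Passing tests on these data show the machinery is correct under the
assumed structure (Beta-distributed divergence, Markovian LD, additive
effects, Gaussian residuals); they do not certify behaviour under real
resequencing artefacts such as batch-correlated missingness, allelic
dropout, or reference bias.

## The planted-marker scenario

`planted_marker_config` is the end-to-end stress test: n = 400 across
populations of 200/66/66/68, 10 chromosomes × 500 loci, one causal tag
(0.8 SD per allele) restricted to the first population at within-population
alt frequency 0.25, two partners at genotype r² ≈ 0.8. Two constraints
shaped it:

* A population-restricted allele must clear pooled MAF > 0.1 **and** the
  pooled HWE exact test. The Wahlund heterozygote deficit grows with
  sample size, so at n = 400 the carrier population must hold a large
  sample share: with 200 carriers at p = 0.25, pooled F_IT ≈ 0.14 and the
  exact test sits near p ≈ 4e-3 — comfortably above the 1e-6 floor —
  while pooled MAF ≈ 0.125.
* The restricted population is also the highest-variance cohort, so the
  genotype-class ANOVA (which pools residual variance across cohorts) has
  the allelic effect on the same scale as the dominant noise source;
  planting in a low-variance cohort would bury a within-cohort effect
  under the large cohort's residual spread.

Both points are consequences of the pooled-filtering and pooled-ANOVA
conventions documented above, derived analytically from the model.

## Numerical conventions

* Coordinates are 1-based inclusive everywhere (VCF/GFF convention).
* Dosage is the alternate-allele count {0, 1, 2}, NaN for missing;
  missing dosages are mean-imputed only where a complete matrix is
  required (GRM, GWAS, polygenic simulation), never in stored tables.
* Locus identifiers are normalized to `chrom_pos_ref_alt`; chromosome
  sort order is by embedded number.
* Seeded runs are byte-identical; the phenotype RNG stream is offset from
  the genotype stream so the two are independent under a shared seed.
* REML boundary: log-ratio bounds ±12 (ratios ~6e-6 to 1.6e5); residual
  variance floored at 1e-300 so an exact fixed-effect fit stays finite.

## Known limitations

* The pooled HWE filter and pooled LD are structure-sensitive by design
  (documented above); per-population alternatives exist only for LD.
* The REML fit models a single homogeneous residual variance; strongly
  heteroskedastic cohorts (e.g. a 44 g-SD cohort alongside 3.5 g-SD
  cohorts) are handled through the fixed effects and kinship only.
* ANOVA-based superior-genotype calls on observed data cannot distinguish
  "absent" from "unsampled" rare classes; population-uniqueness should be
  read as a sampling statement.
* Ancestry-proportion estimation (ADMIXTURE-style), GO/KEGG enrichment,
  FarmCPU/BLINK internals, genomic prediction and plot rendering are out
  of scope.
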