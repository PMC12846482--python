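# growmark pipeline configuration template
#
# Supply EXACTLY ONE of:
#   - real inputs: vcf + phenotypes + gff3 (+ optional populations,
#     external_results)
#   - a `simulation:` block (SimulationConfig fields)

out_dir: runs/example        # all stage outputs + manifest.json land here
seed: 1                      # drives every random draw (simulation only)

# --- real inputs (comment out when simulating) ------------------------------
# vcf: data/genotypes.vcf            # multi-sample VCF 4.2, biallelic SNPs
# phenotypes: data/phenotypes.tsv    # columns: id, population, weight_g,
#                                    #          age, location, season
# gff3: data/genes.gff3              # gene features define annotation windows
# populations: data/populations.tsv  # optional id -> population map
# external_results:                  # per-model significant-locus TSVs
#   - data/farmcpu_hits.tsv          # (columns: snp, method) merged with the
#   - data/blink_hits.tsv            # package's own MLM scan

# --- synthetic inputs -------------------------------------------------------
simulation:
  n_populations: 4
  n_per_population: [20, 20, 20, 30]
  n_chromosomes: 5
  loci_per_chromosome: 200
  fst: 0.08                  # Balding-Nichols divergence per population
  ld_rho: 0.3                # adjacent-locus haplotype copy probability
  heritability: 0.3          # within-population h2
  missing_rate: 0.02
  # causal_spec: [[525, 0.8]]        # [locus index, effect in SD units]
  # restricted_spec: [[525, 0]]      # [locus index, population index]
  # linked_spec: [[525, 526, 0.894]] # [tag, partner, copy probability]

# --- stage parameters (defaults shown) --------------------------------------
filter:
  maf_min: 0.1               # retain MAF > 0.1 (strict)
  max_missing: 0.10          # retain missing rate < 10 %
  hwe_p_min: 1.0e-6          # retain HWE exact p > 1e-6
covariates: [population, age, location, season]   # aliased columns dropped
adjust_mode: fixed_only      # or full_residual (attenuates genetic signal)
alpha: 0.05                  # Bonferroni family level and ANOVA gate
window: 50000                # gene-annotation window around tags, bp
r2_min: 0.5                  # composite-LD linkage threshold
min_class_n: 3               # smallest genotype class entering the ANOVA
run_popgen: true             # diversity stats, distances, NJ tree
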