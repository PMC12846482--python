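"""Synthetic genotypes, phenotypes and gene annotations for structured populations.

The generator emulates the statistical structure of a multi-population
resequencing study of a farmed fish: several diverged populations with
unequal sample sizes, linkage-disequilibrium-blocked genotypes, planted
causal loci with LD partners, population-restricted alternate alleles, and
body-weight phenotypes strongly confounded with population / growth-stage
effects.

Model choices
-------------
* Population allele frequencies follow the Balding–Nichols model: at each
  locus the frequency in population *k* is drawn from
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the ancestral frequency *p*, so
  that ``Var = F·p(1-p)``; ``F = 0`` returns *p* exactly.
* Haplotypes are first-order Markov chains over loci: a latent uniform is
  copied from the previous locus with probability ``ld_rho`` and redrawn
  otherwise, then thresholded at the locus frequency.  When adjacent loci
  share a frequency the adjacent allelic correlation equals ``ld_rho``
  exactly (hence adjacent genotype r² ≈ ``ld_rho²``); with unequal
  frequencies the achievable correlation is attenuated, as for any binary
  chain.  Marginal frequencies are preserved exactly.
* Phenotypes follow a mixed-model structure: population mean + covariate
  effects + Σ(causal dosage × effect) + polygenic term + residual, with the
  within-population variance partitioned by the configured heritability.
  Effect sizes are expressed in within-population phenotype SD units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import VariantTable, write_vcf

# Defaults mirror the study design this generator emulates: four populations
# of juvenile/adult Mandarin fish sampled at different growth stages, with
# body weight ~35-fold higher in the oldest cohort.
DEFAULT_POP_NAMES = ("HLJ", "AH", "HN", "HB")
DEFAULT_N_PER_POP = (20, 20, 20, 30)
DEFAULT_POP_MEANS = (17.4, 18.7, 30.6, 625.2)  # grams
DEFAULT_POP_SDS = (3.5, 4.1, 5.5, 44.3)  # grams
DEFAULT_POP_AGES = (6, 7, 7, 10)  # months at sampling
DEFAULT_POP_SEASONS = ("summer", "summer", "summer", "autumn")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``causal_spec`` maps flat locus indices to additive effects in
    within-population phenotype SD units.  ``restricted_spec`` lists
    ``(locus index, population index)`` pairs whose alternate allele is
    carried only by the designated population.  ``linked_spec`` plants LD
    partners: ``(tag index, partner index, rho)`` makes the partner's
    haplotype alleles copies of the tag's with probability ``rho``
    (genotype r² ≈ rho²).
    """

    n_populations: int = 4
    n_per_population: tuple[int, ...] = DEFAULT_N_PER_POP
    n_chromosomes: int = 5
    loci_per_chromosome: int = 200
    fst: float | tuple[float, ...] = 0.08
    ld_rho: float = 0.3
    causal_spec: tuple[tuple[int, float], ...] = ()
    restricted_spec: tuple[tuple[int, int], ...] = ()
    linked_spec: tuple[tuple[int, int, float], ...] = ()
    restricted_freq: float = 0.3
    heritability: float = 0.3
    population_means: tuple[float, ...] = DEFAULT_POP_MEANS
    population_sds: tuple[float, ...] = DEFAULT_POP_SDS
    population_names: tuple[str, ...] = DEFAULT_POP_NAMES
    population_ages: tuple[int, ...] = DEFAULT_POP_AGES
    population_seasons: tuple[str, ...] = DEFAULT_POP_SEASONS
    covariate_effects: dict = field(default_factory=lambda: {"age": 0.0})
    missing_rate: float = 0.02
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    locus_spacing: int = 2000  # bp between adjacent loci
    genes_per_chromosome: int = 10
    gene_length: int = 30000  # bp
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_population) != self.n_populations:
            raise ValueError("n_per_population length must equal n_populations")
        fsts = self.fst_per_population()
        if any(not (0 <= f < 1) for f in fsts):
            raise ValueError("fst must lie in [0, 1) for every population")
        if not (0 <= self.heritability <= 1):
            raise ValueError("heritability must lie in [0, 1]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        m = self.n_loci
        special = [i for i, _ in self.causal_spec]
        special += [i for i, _ in self.restricted_spec]
        special += [j for _, j, _ in self.linked_spec]
        if any(i < 0 or i >= m for i in special):
            raise ValueError("causal/restricted/linked locus index out of range")
        for _, pop in self.restricted_spec:
            if pop < 0 or pop >= self.n_populations:
                raise ValueError("restricted_spec population index out of range")
        if self.heritability == 1 and not self.causal_spec:
            # nothing to carry the genetic variance
            raise ValueError(
                "heritability 1 requires causal loci or must be lowered"
            )

    @property
    def n_individuals(self) -> int:
        return int(sum(self.n_per_population))

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    def fst_per_population(self) -> tuple[float, ...]:
        if np.isscalar(self.fst):
            return (float(self.fst),) * self.n_populations
        return tuple(float(f) for f in self.fst)

    def population_index(self) -> np.ndarray:
        """Population index per individual, in sample order."""
        return np.repeat(
            np.arange(self.n_populations), self.n_per_population
        )


def draw_population_freqs(
    ancestral_freq: float,
    fst: float | np.ndarray,
    rng: np.random.Generator,
    n_populations: int = 1,
) -> np.ndarray:
    """Balding–Nichols draw of per-population allele frequencies.

    Each population frequency is Beta-distributed with mean
    ``ancestral_freq`` and variance ``fst · p(1-p)``; ``fst = 0`` returns
    the ancestral frequency exactly.
    """
    p = float(ancestral_freq)
    if not (0.0 < p < 1.0):
        raise ValueError(f"degenerate locus: ancestral frequency {p} not in (0,1)")
    fst = np.broadcast_to(np.asarray(fst, dtype=float), (n_populations,))
    out = np.empty(n_populations)
    for k, f in enumerate(fst):
        if f == 0.0:
            out[k] = p
        else:
            a = p * (1.0 - f) / f
            b = (1.0 - p) * (1.0 - f) / f
            out[k] = rng.beta(a, b)
    return out


def _markov_haplotypes(
    freqs: np.ndarray, n_hap: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Haplotypes (n_hap × L) from a copy-or-redraw latent-uniform chain.

    The latent uniform at locus l is the previous locus's uniform with
    probability rho, a fresh uniform otherwise; the allele is
    ``1{u < freq_l}``, so marginal frequencies are exact.
    """
    L = len(freqs)
    u = np.empty((n_hap, L))
    u[:, 0] = rng.random(n_hap)
    if L > 1:
        fresh = rng.random((n_hap, L - 1))
        copy = rng.random((n_hap, L - 1)) < rho
        for l in range(1, L):
            u[:, l] = np.where(copy[:, l - 1], u[:, l - 1], fresh[:, l - 1])
    return (u < freqs[None, :]).astype(np.int8)


def simulate_genotypes(config: SimulationConfig) -> VariantTable:
    """Generate a :class:`VariantTable` under the configured structure.

    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_pops = config.n_populations
    fsts = np.asarray(config.fst_per_population())
    m = config.n_loci
    lo, hi = config.ancestral_freq_range
    anc = rng.uniform(lo, hi, size=m)

    # per-population frequencies (Balding–Nichols), vectorized over loci
    pop_freqs = np.empty((n_pops, m))
    for k in range(n_pops):
        f = fsts[k]
        if f == 0.0:
            pop_freqs[k] = anc
        else:
            a = anc * (1.0 - f) / f
            b = (1.0 - anc) * (1.0 - f) / f
            pop_freqs[k] = rng.beta(a, b)
    # keep background loci clear of fixation so they stay usable
    pop_freqs = np.clip(pop_freqs, 1e-4, 1 - 1e-4)

    restricted = {idx: pop for idx, pop in config.restricted_spec}
    for idx, pop in restricted.items():
        pop_freqs[:, idx] = 0.0
        pop_freqs[pop, idx] = config.restricted_freq
    # planted LD partners share their tag's per-population frequencies
    for tag, partner, _rho in config.linked_spec:
        pop_freqs[:, partner] = pop_freqs[:, tag]

    lpc = config.loci_per_chromosome
    hap_pairs = []
    for k in range(n_pops):
        n_hap = 2 * config.n_per_population[k]
        chrom_haps = []
        for c in range(config.n_chromosomes):
            sl = slice(c * lpc, (c + 1) * lpc)
            chrom_haps.append(
                _markov_haplotypes(pop_freqs[k, sl], n_hap, config.ld_rho, rng)
            )
        hap_pairs.append(np.hstack(chrom_haps))
    haps = np.vstack(hap_pairs)  # (2N, m)

    # planted special loci: regenerate independently of the background chain
    for idx, pop in restricted.items():
        col = np.zeros(haps.shape[0], dtype=np.int8)
        pidx = config.population_index()
        carrier_rows = np.flatnonzero(np.repeat(pidx == pop, 2))
        col[carrier_rows] = (
            rng.random(carrier_rows.size) < config.restricted_freq
        ).astype(np.int8)
        haps[:, idx] = col
    for tag, partner, rho in config.linked_spec:
        pidx2 = np.repeat(config.population_index(), 2)
        fresh = np.zeros(haps.shape[0], dtype=np.int8)
        for k in range(n_pops):
            rows = np.flatnonzero(pidx2 == k)
            fresh[rows] = (rng.random(rows.size) < pop_freqs[k, tag]).astype(
                np.int8
            )
        copy = rng.random(haps.shape[0]) < rho
        haps[:, partner] = np.where(copy, haps[:, tag], fresh)

    dosage = (haps[0::2, :] + haps[1::2, :]).astype(float)

    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    chroms = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    loci = pd.DataFrame(
        {
            "chrom": np.repeat(chroms, lpc),
            "pos": np.tile(
                (np.arange(lpc) + 1) * config.locus_spacing, config.n_chromosomes
            ),
            "ref": "A",
            "alt": "G",
        }
    )
    # vary substitution classes deterministically so Ts/Tv summaries have
    # something to count
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]
    choice = rng.integers(0, len(pairs), size=m)
    loci["ref"] = [pairs[c][0] for c in choice]
    loci["alt"] = [pairs[c][1] for c in choice]

    pidx = config.population_index()
    samples = [
        f"{config.population_names[p]}_{i + 1:03d}"
        for i, p in enumerate(pidx)
    ]
    populations = [config.population_names[p] for p in pidx]
    return VariantTable(
        loci=loci, dosage=dosage, samples=samples, populations=populations
    )


def simulate_phenotypes(
    genotypes: VariantTable, config: SimulationConfig
) -> pd.DataFrame:
    """Body-weight phenotypes with population, age, location, season covariates.

    Within each population the phenotypic variance is partitioned as
    ``h² = heritability`` genetic (planted causal effects plus a polygenic
    term built from the genome-wide standardized dosages) and ``1 - h²``
    residual, on the population's own SD scale.  Deterministic under
    ``config.seed`` (offset so genotype and phenotype noise are independent).
    """
    for idx, _ in config.causal_spec:
        if idx >= genotypes.n_loci:
            raise ValueError("causal locus missing from genotype table")
    rng = np.random.default_rng((config.seed + 0x9E3779B9) % 2**31)
    n = genotypes.n_samples
    pidx = config.population_index()
    if n != config.n_individuals:
        raise ValueError("genotype table does not match configured sample sizes")

    means = np.asarray(config.population_means, dtype=float)[pidx]
    sds = np.asarray(config.population_sds, dtype=float)[pidx]
    ages = np.asarray(config.population_ages, dtype=float)[pidx]

    dos = genotypes.dosage.copy()
    col_mean = np.nanmean(dos, axis=0)
    nan_mask = np.isnan(dos)
    dos[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    h2 = config.heritability
    causal_sd_units = np.zeros(n)
    v_causal = 0.0
    for idx, beta in config.causal_spec:
        x = dos[:, idx]
        causal_sd_units += beta * x
        p = col_mean[idx] / 2.0
        v_causal += beta**2 * 2.0 * p * (1.0 - p)
    v_poly = max(h2 - v_causal, 0.0)
    v_resid = max(1.0 - h2, 0.0)

    poly = np.zeros(n)
    if v_poly > 0:
        sd_col = np.nanstd(dos, axis=0)
        ok = sd_col > 0
        z = (dos[:, ok] - col_mean[ok]) / sd_col[ok]
        raw = z @ rng.standard_normal(int(ok.sum())) / np.sqrt(ok.sum())
        raw_sd = raw.std()
        if raw_sd > 0:
            poly = raw / raw_sd * np.sqrt(v_poly)

    resid = rng.standard_normal(n) * np.sqrt(v_resid)
    age_coef = float(config.covariate_effects.get("age", 0.0))
    y = means + age_coef * ages + sds * (causal_sd_units + poly + resid)

    return pd.DataFrame(
        {
            "id": genotypes.samples,
            "population": genotypes.populations,
            "weight_g": y,
            "age": ages.astype(int),
            "location": [config.population_names[p] for p in pidx],
            "season": [config.population_seasons[p] for p in pidx],
        }
    )


def write_gff3(config: SimulationConfig, path: str) -> int:
    """Write a synthetic GFF3 tiling each chromosome with gene features.

    Genes are evenly spaced so that ±50 kb window annotation and
    SNP-in-gene collection are exercised; returns the gene count.
    """
    chrom_len = config.loci_per_chromosome * config.locus_spacing + config.locus_spacing
    spacing = max(chrom_len // max(config.genes_per_chromosome, 1), 1)
    n_genes = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in range(config.n_chromosomes):
            chrom = f"chr{c + 1}"
            fh.write(f"##sequence-region {chrom} 1 {chrom_len}\n")
            for g in range(config.genes_per_chromosome):
                start = g * spacing + 1
                end = min(start + config.gene_length - 1, chrom_len)
                gid = f"gene_{chrom}_{g + 1}"
                strand = "+" if g % 2 == 0 else "-"
                fh.write(
                    f"{chrom}\tgrowmark\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={gid};Name={gid}\n"
                )
                n_genes += 1
    return n_genes


def write_outputs(
    genotypes: VariantTable,
    phenotypes: pd.DataFrame,
    config: SimulationConfig,
    out_dir: str,
) -> dict[str, str]:
    """Write VCF, phenotype TSV, population TSV and GFF3 to ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "phenotypes": os.path.join(out_dir, "phenotypes.tsv"),
        "populations": os.path.join(out_dir, "populations.tsv"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
    }
    write_vcf(genotypes, paths["vcf"])
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    pd.DataFrame(
        {"id": genotypes.samples, "population": genotypes.populations}
    ).to_csv(paths["populations"], sep="\t", index=False)
    write_gff3(config, paths["gff3"])
    return paths


def planted_marker_config(
    seed: int,
    n_per_population: tuple[int, ...] = (200, 66, 66, 68),
    n_chromosomes: int = 10,
    loci_per_chromosome: int = 500,
    effect_sd: float = 0.8,
    partner_rho: float = 0.894,
    null: bool = False,
) -> SimulationConfig:
    """Stress-test scenario: one causal tag with LD partners and a
    population-restricted superior genotype.

    The causal tag's alternate allele is restricted to the first (largest,
    highest-variance) population at within-population frequency 0.25, so the
    alt-homozygote "superior" class occurs in exactly one population while
    the locus still clears a pooled MAF > 0.1 filter and the pooled
    Hardy–Weinberg exact test (the Wahlund heterozygote deficit grows with
    both divergence and sample size, so the carrier population must hold a
    large sample share).  Two LD partners are planted at haplotype copy
    probability ``partner_rho`` (genotype r² ≈ 0.8).  With ``null=True`` no
    effects are planted (for false-positive-rate studies) but the same locus
    structure is kept.
    """
    m = n_chromosomes * loci_per_chromosome
    tag = loci_per_chromosome * (n_chromosomes // 2) + loci_per_chromosome // 2
    assert tag + 2 < m
    causal = () if null else ((tag, effect_sd),)
    return SimulationConfig(
        n_populations=4,
        n_per_population=tuple(n_per_population),
        n_chromosomes=n_chromosomes,
        loci_per_chromosome=loci_per_chromosome,
        fst=0.08,
        ld_rho=0.3,
        causal_spec=causal,
        restricted_spec=((tag, 0),),
        linked_spec=((tag, tag + 1, partner_rho), (tag, tag + 2, partner_rho)),
        restricted_freq=0.25,
        heritability=0.3,
        population_means=(625.2, 17.4, 18.7, 30.6),
        population_sds=(44.3, 3.5, 4.1, 5.5),
        population_names=("HB", "HLJ", "AH", "HN"),
        population_ages=(10, 6, 7, 7),
        population_seasons=("autumn", "summer", "summer", "summer"),
        seed=seed,
    )
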