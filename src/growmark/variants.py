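"""Genotype container and VCF input/output.

The central in-memory object is :class:`VariantTable`: locus metadata
(chromosome, 1-based position, ref/alt alleles) alongside an
individuals × loci additive-dosage matrix (0/1/2 copies of the alternate
allele, NaN for missing calls).  Only biallelic SNPs are represented;
multiallelic sites and indels are rejected at read time with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

MISSING = np.nan


def locus_ids(loci: pd.DataFrame) -> pd.Series:
    """Canonical locus identifiers ``<chrom>_<pos>_<ref>_<alt>``."""
    return (
        loci["chrom"].astype(str)
        + "_"
        + loci["pos"].astype(str)
        + "_"
        + loci["ref"]
        + "_"
        + loci["alt"]
    )


@dataclass
class VariantTable:
    """Biallelic SNP genotypes for a set of individuals.

    Parameters
    ----------
    loci :
        DataFrame with columns ``chrom``, ``pos`` (1-based bp), ``ref``,
        ``alt``; one row per locus, positions strictly increasing within a
        chromosome.
    dosage :
        Float array of shape ``(n_individuals, n_loci)`` with entries in
        {0, 1, 2, NaN}; NaN marks a missing genotype call.
    samples :
        Individual identifiers, one per dosage row.
    populations :
        Optional population label per individual (aligned with ``samples``).
    """

    loci: pd.DataFrame
    dosage: np.ndarray
    samples: list[str]
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D individuals × loci matrix")
        n, m = self.dosage.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} samples but {n} dosage rows")
        if m != len(self.loci):
            raise ValueError(f"{len(self.loci)} loci but {m} dosage columns")
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("populations must align with samples")
        self._validate_loci()
        self._validate_dosage()

    def _validate_loci(self) -> None:
        bad = ~(
            self.loci["ref"].isin(NUCLEOTIDES)
            & self.loci["alt"].isin(NUCLEOTIDES)
        ) | (self.loci["ref"] == self.loci["alt"])
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} loci are not biallelic SNPs with distinct "
                "single-nucleotide alleles"
            )
        for chrom, grp in self.loci.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on {chrom}"
                )

    def _validate_dosage(self) -> None:
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage entries must be 0, 1, 2 or NaN")

    # -- basic queries ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ids(self) -> pd.Series:
        return locus_ids(self.loci)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """Per-locus (hom-ref, het, hom-alt) counts, shape (n_loci, 3)."""
        out = np.empty((self.n_loci, 3), dtype=int)
        for k, g in enumerate((0.0, 1.0, 2.0)):
            out[:, k] = np.nansum(self.dosage == g, axis=0)
        return out

    def subset_loci(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return VariantTable(
            loci=self.loci.iloc[idx],
            dosage=self.dosage[:, idx],
            samples=list(self.samples),
            populations=list(self.populations) if self.populations else None,
        )

    def subset_samples(self, mask: np.ndarray) -> "VariantTable":
        idx = np.flatnonzero(np.asarray(mask)) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return VariantTable(
            loci=self.loci,
            dosage=self.dosage[idx, :],
            samples=[self.samples[i] for i in idx],
            populations=[self.populations[i] for i in idx] if self.populations else None,
        )


def read_vcf(path: str, populations: dict[str, str] | None = None) -> VariantTable:
    """Read biallelic SNPs from a VCF (plain or bgzipped) into a VariantTable.

    Genotypes come from the GT field only; phased and unphased separators are
    treated identically.  Multiallelic sites and indels are skipped with a
    logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dosages = [], []
    n_skipped = 0
    for var in vcf:
        if (
            len(var.ALT) != 1
            or var.REF not in NUCLEOTIDES
            or var.ALT[0] not in NUCLEOTIDES
        ):
            n_skipped += 1
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        gt = var.gt_types.astype(float)  # 0/1/2 dosage, 3 = unknown
        gt[gt == 3] = MISSING
        dosages.append(gt)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records", n_skipped)
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = (
        np.vstack(dosages).T if dosages else np.empty((len(samples), 0))
    )
    pops = [populations[s] for s in samples] if populations else None
    return VariantTable(loci=loci, dosage=dosage, samples=samples, populations=pops)


def write_vcf(table: VariantTable, path: str) -> None:
    """Write a VariantTable as a minimal standards-conformant VCF 4.2."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=growmark\n")
        for chrom, grp in table.loci.groupby("chrom", sort=False):
            fh.write(
                f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 100000}>\n"
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        ids = table.ids
        for j in range(table.n_loci):
            row = table.loci.iloc[j]
            gts = [
                gt_map.get(table.dosage[i, j], "./.")
                for i in range(table.n_samples)
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{ids.iloc[j]}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_populations(path: str) -> dict[str, str]:
    """Read a two-column (id, population) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = df.columns[0]
    pop_col = "population" if "population" in df.columns else df.columns[1]
    return dict(zip(df[id_col], df[pop_col]))
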