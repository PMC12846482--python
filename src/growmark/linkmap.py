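"""Gene-window annotation of tag SNPs and LD-based recovery of linked loci.

Genome-wide scans are usually run on tag SNPs retained from LD blocks, so a
trait-associated variant inside a gene can be masked when a correlated
intergenic tag was kept instead.  This module recovers such loci: each
significant (tag) SNP is annotated to genes within a ±window (default
50 kb), every SNP inside those genes is collected, and loci with dosage
r² > a threshold (default 0.5) to the tag are flagged as potentially
linked.  The combined candidate list is the union of annotated tags and
newly linked loci.

LD is the composite (genotypic) r²: the squared Pearson correlation of
allele dosages over pairwise-complete individuals, requiring no phasing.
Coordinates are 1-based inclusive throughout (VCF/GFF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import VariantTable

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 50_000
DEFAULT_R2_MIN = 0.5


@dataclass(frozen=True)
class GeneModel:
    """One gene feature: 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_gff3_genes(path: str) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file (substructure ignored)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or "+",
            )
        )
    return genes


def genes_near_snp(
    chrom: str,
    pos: int,
    genes: list[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> list[str]:
    """Gene ids whose interval intersects [pos-window, pos+window].

    Closed-interval overlap on 1-based coordinates; strand ignored.  A
    chromosome absent from the annotation yields an empty list (logged).
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    lo, hi = pos - window, pos + window
    hits = [
        g.gene_id
        for g in genes
        if g.chrom == chrom and g.start <= hi and g.end >= lo
    ]
    if not hits and not any(g.chrom == chrom for g in genes):
        logger.info("chromosome %s absent from gene annotation", chrom)
    return hits


def snps_in_genes(
    table: VariantTable, genes: list[GeneModel]
) -> dict[str, list[str]]:
    """SNP ids per gene id, for SNPs with ``start ≤ pos ≤ end``.

    A SNP inside overlapping genes is reported under each of them.
    """
    ids = table.ids
    out: dict[str, list[str]] = {}
    for gene in genes:
        mask = (
            (table.loci["chrom"] == gene.chrom)
            & (table.loci["pos"] >= gene.start)
            & (table.loci["pos"] <= gene.end)
        )
        out[gene.gene_id] = list(ids[mask])
    return out


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Composite LD r²: squared dosage correlation over complete pairs."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need at least 2 pairwise-complete individuals")
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        raise ValueError("zero dosage variance: LD undefined")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def expand_tags(
    tags: pd.DataFrame,
    table: VariantTable,
    genes: list[GeneModel],
    window: int = DEFAULT_WINDOW,
    r2_min: float = DEFAULT_R2_MIN,
    pooled_gene_snps: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LD-expand tag SNPs to linked loci within their gene windows.

    Parameters
    ----------
    tags :
        DataFrame with ``snp``/``chrom``/``pos`` columns (merged GWAS
        output); tags without gene annotation are excluded from expansion
        and reported in the annotation table.
    pooled_gene_snps :
        If True, every tag is compared against the pooled SNP set of all
        annotated genes (same chromosome) rather than only its own genes'.

    Returns
    -------
    (candidates, annotation) :
        ``candidates`` has one row per unique candidate SNP: snp, chrom,
        pos, source ("tag" or "linked"), best_tag, r2 (to best tag).  A SNP
        linked to several tags appears once with the highest r².
        ``annotation`` maps each tag to its gene ids (empty string when
        unannotated).
    """
    gene_snps = snps_in_genes(table, genes)
    ids = table.ids
    id_to_col = {s: j for j, s in enumerate(ids)}
    loci_by_id = table.loci.set_index(ids)

    annotation_rows = []
    candidates: dict[str, dict] = {}
    pooled_ids = sorted({s for members in gene_snps.values() for s in members})

    for _, tag in tags.iterrows():
        tag_id = tag["snp"]
        tag_genes = genes_near_snp(tag["chrom"], int(tag["pos"]), genes, window)
        annotation_rows.append(
            {"snp": tag_id, "chrom": tag["chrom"], "pos": int(tag["pos"]),
             "genes": ";".join(tag_genes), "n_genes": len(tag_genes)}
        )
        if not tag_genes:
            logger.info("tag %s has no gene annotation; excluded from expansion", tag_id)
            continue
        prev = candidates.get(tag_id)
        if prev is None or prev["source"] != "tag":
            candidates[tag_id] = {
                "snp": tag_id, "chrom": tag["chrom"], "pos": int(tag["pos"]),
                "source": "tag", "best_tag": tag_id, "r2": 1.0,
            }
        if tag_id not in id_to_col:
            logger.warning("tag %s not present in genotype table; no LD pool", tag_id)
            continue
        tag_dos = table.dosage[:, id_to_col[tag_id]]
        if pooled_gene_snps:
            pool = pooled_ids
        else:
            pool = sorted({s for g in tag_genes for s in gene_snps[g]})
        for snp_id in pool:
            if snp_id == tag_id or snp_id not in id_to_col:
                continue
            row = loci_by_id.loc[snp_id]
            if row["chrom"] != tag["chrom"]:
                continue
            try:
                r2 = ld_r2(tag_dos, table.dosage[:, id_to_col[snp_id]])
            except ValueError:
                continue
            if r2 > r2_min:
                prev = candidates.get(snp_id)
                if prev is None or (prev["source"] == "linked" and r2 > prev["r2"]):
                    candidates[snp_id] = {
                        "snp": snp_id, "chrom": row["chrom"], "pos": int(row["pos"]),
                        "source": "linked", "best_tag": tag_id, "r2": float(r2),
                    }
    cand = pd.DataFrame(
        list(candidates.values()),
        columns=["snp", "chrom", "pos", "source", "best_tag", "r2"],
    )
    if len(cand):
        cand["_ck"] = cand["chrom"].astype(str).str.extract(r"(\d+)", expand=False).astype(float)
        cand = (
            cand.sort_values(["_ck", "chrom", "pos"], kind="mergesort")
            .drop(columns="_ck")
            .reset_index(drop=True)
        )
    annotation = pd.DataFrame(
        annotation_rows, columns=["snp", "chrom", "pos", "genes", "n_genes"]
    )
    return cand, annotation
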