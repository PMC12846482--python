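"""SNP quality-control filters and substitution-class summaries.

Filters follow the convention of standard VCF-filtering tools applied to a
pooled multi-population call set: minor allele frequency strictly greater
than a floor, per-locus missing rate strictly below a ceiling, and a
Hardy–Weinberg exact-test p-value strictly above a floor.  The HWE test is
the exact conditional test on genotype counts (Wigginton-style): the
two-sided p-value sums the conditional probabilities, given the allele
counts, of every heterozygote count whose probability does not exceed that
of the observed count.

The HWE test is computed on all samples pooled.  In a structured sample the
Wahlund effect depresses heterozygosity, so strongly diverged loci can fail
a pooled test even when each population is itself in equilibrium; this
structure sensitivity is inherent to pooled filtering and is documented
rather than corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import NUCLEOTIDES, VariantTable

logger = logging.getLogger(__name__)

TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})
#: canonical display order of the six unordered substitution classes
SUBSTITUTION_CLASSES = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")


@dataclass
class FilterConfig:
    """Retention thresholds; all inequalities are strict."""

    maf_min: float = 0.1
    max_missing: float = 0.10
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_missing", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency at one locus; missing entries excluded."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all genotypes missing: MAF undefined")
    alt = d.sum() / (2.0 * d.size)
    return float(min(alt, 1.0 - alt))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy–Weinberg test p-value on genotype counts.

    Conditional on the observed allele counts, heterozygote counts with the
    same parity as the rare-allele count are enumerated via the standard
    ratio recurrence from the modal count; the p-value is the probability
    mass of all counts no more likely than the observed one.  Monomorphic
    loci return 1.0 by convention.
    """
    a, b, c = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(a, b, c) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = a + b + c
    if n < 1:
        raise ValueError("at least one individual required")
    rare = min(2 * a + b, 2 * c + b)
    if rare == 0:
        return 1.0
    probs = _hwe_het_distribution(n, rare)
    obs = probs[b // 2] if b % 2 == rare % 2 else 0.0
    if obs == 0.0:
        # observed parity inconsistent with allele counts: cannot happen for
        # genuine genotype data
        raise ValueError("heterozygote count parity inconsistent with allele counts")
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hwe_het_distribution(n: int, rare: int) -> np.ndarray:
    """P(het count) conditional on ``rare`` minor alleles among ``2n``.

    Index k corresponds to heterozygote count ``2k + rare % 2``.
    """
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    # start at the modal heterozygote count and apply the ratio recurrence
    # outwards in both directions
    mode_target = rare * (2 * n - rare) / (2.0 * n)
    start = int(np.argmin(np.abs(hets - mode_target)))
    logp = np.empty(len(hets))
    logp[start] = 0.0
    for i in range(start, len(hets) - 1):
        h = hets[i]
        # ratio P(h+2)/P(h) = (rare-h)(2n-rare-h) / ((h+2)(h+1))
        num = (rare - h) * (2 * n - rare - h)
        den = (h + 2.0) * (h + 1.0)
        logp[i + 1] = logp[i] + np.log(num) - np.log(den)
    for i in range(start, 0, -1):
        h = hets[i]
        num = h * (h - 1.0)
        den = (rare - h + 2.0) * (2 * n - rare - h + 2.0)
        logp[i - 1] = logp[i] + np.log(num) - np.log(den)
    p = np.exp(logp - logp.max())
    return p / p.sum()


def apply_filters(
    table: VariantTable, config: FilterConfig | None = None
) -> tuple[VariantTable, pd.DataFrame]:
    """Retain loci passing all filters; return (filtered table, audit log).

    The audit log has one row per input locus with its MAF, missing rate and
    HWE p, a ``retained`` flag, and a comma-separated ``failed`` column
    naming every rule a dropped locus violated (filter order is immaterial:
    all rules are evaluated for every locus).
    """
    config = config or FilterConfig()
    miss = table.missing_rate()
    counts = table.genotype_counts()
    m = table.n_loci
    maf = np.full(m, np.nan)
    hwe = np.full(m, np.nan)
    for j in range(m):
        a, b, c = counts[j]
        tot = a + b + c
        if tot == 0:
            continue
        alt = (b + 2 * c) / (2.0 * tot)
        maf[j] = min(alt, 1.0 - alt)
        hwe[j] = hwe_exact_test(a, b, c)

    ok_called = ~np.isnan(maf)
    pass_maf = ok_called & (maf > config.maf_min)
    pass_miss = miss < config.max_missing
    pass_hwe = ok_called & (hwe > config.hwe_p_min)
    retained = pass_maf & pass_miss & pass_hwe

    failed = []
    for j in range(m):
        reasons = []
        if not pass_maf[j]:
            reasons.append("maf")
        if not pass_miss[j]:
            reasons.append("missing")
        if not pass_hwe[j]:
            reasons.append("hwe")
        failed.append(",".join(reasons))
    audit = pd.DataFrame(
        {
            "snp": table.ids,
            "chrom": table.loci["chrom"],
            "pos": table.loci["pos"],
            "maf": maf,
            "missing_rate": miss,
            "hwe_p": hwe,
            "retained": retained,
            "failed": failed,
        }
    )
    if not retained.any():
        logger.warning("no loci passed the filters")
    return table.subset_loci(retained), audit


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Classify one substitution as transition/transversion with its
    unordered class label (e.g. ``("transition", "A/G")``)."""
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise ValueError(f"alleles must be A/C/G/T, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    pair = frozenset((ref, alt))
    kind = "transition" if pair in TRANSITIONS else "transversion"
    label = "/".join(sorted(pair))
    return kind, label


def summarize_substitution_classes(class_counts: dict[str, int]) -> pd.DataFrame:
    """Per-class counts and percentages plus transition/transversion totals.

    Percentages are of the grand total, rounded to two decimals.  Returns a
    DataFrame indexed by class label with ``count``, ``percent`` and
    ``kind`` columns, plus summary rows ``transition`` and ``transversion``.
    """
    total = sum(class_counts.values())
    if total <= 0:
        raise ValueError("zero total substitution count")
    rows = []
    kind_totals = {"transition": 0, "transversion": 0}
    for label in sorted(class_counts, key=lambda x: (SUBSTITUTION_CLASSES.index(x) if x in SUBSTITUTION_CLASSES else 99)):
        count = class_counts[label]
        if count < 0:
            raise ValueError("negative substitution count")
        ref, alt = label.split("/")
        kind, _ = classify_substitution(ref, alt)
        kind_totals[kind] += count
        rows.append((label, kind, count, round(100.0 * count / total, 2)))
    for kind in ("transition", "transversion"):
        rows.append(
            (kind, kind, kind_totals[kind], round(100.0 * kind_totals[kind] / total, 2))
        )
    rows.append(("total", "", total, 100.0))
    return pd.DataFrame(
        rows, columns=["class", "kind", "count", "percent"]
    ).set_index("class")


def count_substitution_classes(table: VariantTable) -> dict[str, int]:
    """Tally unordered substitution classes over a table's loci."""
    labels = [
        classify_substitution(r, a)[1]
        for r, a in zip(table.loci["ref"], table.loci["alt"])
    ]
    return dict(pd.Series(labels).value_counts())


def per_chromosome_counts(table: VariantTable) -> pd.Series:
    """Locus count per chromosome, ordered by chromosome id."""
    if table.n_loci == 0:
        return pd.Series(dtype=int)
    return table.loci.groupby("chrom", sort=True).size()
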