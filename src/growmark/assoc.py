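"""Genotype-class association, superior-genotype calling, population uniqueness.

Each candidate SNP is tested by one-way fixed-effects ANOVA of (adjusted)
body weight across its genotype classes, followed by Fisher's LSD —
unadjusted pairwise t tests using the pooled within-class mean square with
N - k degrees of freedom.  A SNP is growth-related when the ANOVA p-value
is below alpha (0.05 by default; no multiplicity correction is applied at
this stage, matching common marker-screening practice — a
Benjamini–Hochberg option is available).  The superior genotype of a
growth-related SNP is the eligible class with the highest mean weight
(heterozygotes are eligible); a marker is population-unique when its
superior genotype is observed in exactly one population.

Genotype classes with fewer than ``min_class_n`` individuals (default 3)
are dropped from the ANOVA but still appear in the per-population
frequency tables, where they matter for uniqueness.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variants import VariantTable

logger = logging.getLogger(__name__)


@dataclass
class MarkerCall:
    """Association result for one candidate SNP."""

    snp: str
    chrom: str
    pos: int
    classes: dict[str, int]  # class label -> n (all observed classes)
    class_means: dict[str, float]  # classes entering the ANOVA
    anova_f: float
    anova_p: float
    lsd_p: pd.DataFrame | None
    testable: bool
    growth_related: bool
    superior_genotype: str | None
    population_freqs: pd.DataFrame  # population × class frequencies
    population_unique: bool = False
    unique_population: str | None = None


def genotype_label(ref: str, alt: str, dosage: float) -> str:
    """Render a dosage as a genotype-class label (0→ref/ref, 1→ref alt, 2→alt/alt)."""
    if dosage == 0:
        return ref + ref
    if dosage == 1:
        return ref + alt
    if dosage == 2:
        return alt + alt
    raise ValueError(f"dosage {dosage} has no genotype label")


def anova_lsd(
    weights: np.ndarray,
    classes: np.ndarray,
    min_class_n: int = 3,
) -> tuple[float, float, pd.DataFrame | None, dict[str, float], bool]:
    """One-way ANOVA and Fisher's LSD across genotype classes.

    Classes with fewer than ``min_class_n`` members are dropped.  Returns
    ``(F, p, lsd_p_matrix, class_means, testable)``; with fewer than two
    eligible classes the SNP is not testable (no exception).
    """
    weights = np.asarray(weights, dtype=float)
    classes = np.asarray(classes)
    ok = ~np.isnan(weights)
    weights, classes = weights[ok], classes[ok]
    labels, counts = np.unique(classes, return_counts=True)
    eligible = [l for l, c in zip(labels, counts) if c >= min_class_n]
    if len(eligible) < 2:
        return np.nan, np.nan, None, {}, False
    groups = [weights[classes == l] for l in eligible]
    means = {l: float(g.mean()) for l, g in zip(eligible, groups)}
    f_stat, p_val = stats.f_oneway(*groups)

    # Fisher's LSD: pairwise t tests on the pooled within-class MSE
    N = sum(len(g) for g in groups)
    k = len(groups)
    df_within = N - k
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    mse = sse / df_within
    lsd = pd.DataFrame(np.nan, index=eligible, columns=eligible, dtype=float)
    for (la, ga), (lb, gb) in itertools.combinations(zip(eligible, groups), 2):
        if mse == 0:
            p_ab = 0.0 if ga.mean() != gb.mean() else 1.0
        else:
            t = (ga.mean() - gb.mean()) / np.sqrt(mse * (1 / len(ga) + 1 / len(gb)))
            p_ab = 2.0 * stats.t.sf(abs(t), df_within)
        lsd.loc[la, lb] = lsd.loc[lb, la] = p_ab
    np.fill_diagonal(lsd.values, 1.0)
    return float(f_stat), float(p_val), lsd, means, True


def call_superior_genotype(
    class_means: dict[str, float],
    class_n: dict[str, int],
    anova_p: float,
    alpha: float = 0.05,
) -> str | None:
    """Highest-mean eligible class, gated by ANOVA significance.

    Ties break by larger class size, then lexicographic order (logged).
    Returns None when the ANOVA is not significant.
    """
    if not class_means or not (anova_p < alpha):
        return None
    best = max(
        class_means,
        key=lambda l: (class_means[l], class_n.get(l, 0), _revlex(l)),
    )
    top = [l for l, m in class_means.items() if m == class_means[best]]
    if len(top) > 1:
        logger.info("superior-genotype tie among %s; chose %s", sorted(top), best)
    return best


def _revlex(label: str) -> tuple:
    # max() prefers larger keys; invert character order so ties resolve to
    # the lexicographically smallest label
    return tuple(-ord(c) for c in label)


def genotype_freqs_by_population(
    dosages: np.ndarray,
    populations: list[str],
    ref: str,
    alt: str,
) -> pd.DataFrame:
    """Population × genotype-class frequency table over non-missing calls.

    Rows are populations; columns are observed class labels.  Frequencies
    within a population sum to 1 over its observed classes; a population
    with no calls yields an all-zero row (logged).
    """
    dosages = np.asarray(dosages, dtype=float)
    pops = pd.Series(list(populations))
    all_labels = [genotype_label(ref, alt, d) for d in (0, 1, 2)]
    rows = {}
    for pop in pops.unique():
        idx = np.flatnonzero((pops == pop).to_numpy())
        d = dosages[idx]
        d = d[~np.isnan(d)]
        if d.size == 0:
            logger.info("population %s has no called genotypes at this SNP", pop)
            rows[pop] = {l: 0.0 for l in all_labels}
            continue
        counts = {l: float((d == g).sum()) for g, l in zip((0, 1, 2), all_labels)}
        total = sum(counts.values())
        rows[pop] = {l: c / total for l, c in counts.items()}
    return pd.DataFrame(rows).T[all_labels].rename_axis("population")


def classify_population_unique(call: MarkerCall) -> MarkerCall:
    """Flag a growth-related marker whose superior genotype is observed in
    exactly one population; record that population."""
    if not call.growth_related or call.superior_genotype is None:
        call.population_unique = False
        call.unique_population = None
        return call
    freqs = call.population_freqs[call.superior_genotype]
    present = freqs[freqs > 0]
    if present.empty:
        raise ValueError(
            f"superior genotype {call.superior_genotype} of {call.snp} absent "
            "from every population (inconsistent call)"
        )
    call.population_unique = len(present) == 1
    call.unique_population = present.index[0] if call.population_unique else None
    return call


def associate_candidates(
    candidates: pd.DataFrame,
    table: VariantTable,
    adjusted_weights: np.ndarray,
    populations: list[str] | None = None,
    alpha: float = 0.05,
    min_class_n: int = 3,
    bh_correct: bool = False,
) -> list[MarkerCall]:
    """Run the full genotype-class association over a candidate SNP list.

    ``candidates`` needs a ``snp`` column of ``chrom_pos_ref_alt`` ids
    matching loci in ``table``.  ``bh_correct=True`` applies a
    Benjamini–Hochberg adjustment across candidates before the
    growth-related gate.
    """
    pops = populations if populations is not None else table.populations
    if pops is None:
        raise ValueError("population labels required")
    ids = table.ids
    id_to_col = {s: j for j, s in enumerate(ids)}
    calls: list[MarkerCall] = []
    for _, row in candidates.iterrows():
        snp_id = row["snp"]
        j = id_to_col.get(snp_id)
        if j is None:
            logger.warning("candidate %s absent from genotype table; skipped", snp_id)
            continue
        locus = table.loci.iloc[j]
        dos = table.dosage[:, j]
        labels = np.array(
            [
                genotype_label(locus["ref"], locus["alt"], d) if not np.isnan(d) else ""
                for d in dos
            ]
        )
        observed = labels[labels != ""]
        class_n = dict(zip(*np.unique(observed, return_counts=True)))
        class_n = {l: int(c) for l, c in class_n.items()}
        w = np.where(labels == "", np.nan, adjusted_weights)
        f, p, lsd, means, testable = anova_lsd(w, labels, min_class_n=min_class_n)
        freqs = genotype_freqs_by_population(dos, pops, locus["ref"], locus["alt"])
        calls.append(
            MarkerCall(
                snp=snp_id,
                chrom=locus["chrom"],
                pos=int(locus["pos"]),
                classes=class_n,
                class_means=means,
                anova_f=f,
                anova_p=p,
                lsd_p=lsd,
                testable=testable,
                growth_related=False,
                superior_genotype=None,
                population_freqs=freqs,
            )
        )
    pvals = np.array([c.anova_p for c in calls])
    gate = pvals.copy()
    if bh_correct:
        ok = ~np.isnan(pvals)
        gate[ok] = stats.false_discovery_control(pvals[ok], method="bh")
    for call, g in zip(calls, gate):
        call.growth_related = bool(call.testable and g < alpha)
        if call.growth_related:
            call.superior_genotype = call_superior_genotype(
                call.class_means, call.classes, call.anova_p, alpha=1.1
            )
        classify_population_unique(call)
    return calls


def report_markers(calls: list[MarkerCall], out_dir: str) -> dict[str, str]:
    """Write candidate / growth-related / population-unique marker TSVs.

    Files are deterministically ordered by (chromosome, position) and are
    valid (header-only) even when empty.  Returns the file paths.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for c in sorted(calls, key=lambda c: (_chrom_key(c.chrom), c.pos)):
        pop_freq_str = ";".join(
            f"{pop}:" + ",".join(f"{g}={c.population_freqs.loc[pop, g]:.4g}"
                                 for g in c.population_freqs.columns)
            for pop in c.population_freqs.index
        )
        lsd_str = ""
        if c.lsd_p is not None:
            lsd_str = ";".join(
                f"{a}|{b}={c.lsd_p.loc[a, b]:.4g}"
                for a, b in itertools.combinations(c.lsd_p.index, 2)
            )
        rows.append(
            {
                "snp": c.snp,
                "chrom": c.chrom,
                "pos": c.pos,
                "classes": ";".join(f"{l}={n}" for l, n in sorted(c.classes.items())),
                "class_means": ";".join(
                    f"{l}={m:.6g}" for l, m in sorted(c.class_means.items())
                ),
                "anova_f": c.anova_f,
                "anova_p": c.anova_p,
                "lsd_p": lsd_str,
                "testable": c.testable,
                "growth_related": c.growth_related,
                "superior_genotype": c.superior_genotype or "",
                "population_freqs": pop_freq_str,
                "population_unique": c.population_unique,
                "unique_population": c.unique_population or "",
            }
        )
    cols = [
        "snp", "chrom", "pos", "classes", "class_means", "anova_f", "anova_p",
        "lsd_p", "testable", "growth_related", "superior_genotype",
        "population_freqs", "population_unique", "unique_population",
    ]
    full = pd.DataFrame(rows, columns=cols)
    paths = {
        "candidates": os.path.join(out_dir, "candidate_markers.tsv"),
        "growth_related": os.path.join(out_dir, "growth_related_markers.tsv"),
        "population_unique": os.path.join(out_dir, "population_unique_markers.tsv"),
    }
    full.to_csv(paths["candidates"], sep="\t", index=False)
    full[full["growth_related"] == True].to_csv(  # noqa: E712
        paths["growth_related"], sep="\t", index=False
    )
    full[full["population_unique"] == True].to_csv(  # noqa: E712
        paths["population_unique"], sep="\t", index=False
    )
    return paths


def _chrom_key(chrom: str) -> tuple:
    import re

    m = re.search(r"(\d+)", str(chrom))
    return (int(m.group(1)) if m else 10**9, str(chrom))
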