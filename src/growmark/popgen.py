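"""Per-population diversity statistics, genetic distances, neighbor-joining.

Per-locus statistics use within-population allele frequencies.  With alt
frequency p, q = 1 - p, m non-missing alleles of which j are alternate:

* Ho — observed heterozygote fraction among non-missing individuals
* He — expected heterozygosity 2pq
* Pi — per-site nucleotide diversity 2·j·(m-j) / (m·(m-1))
* PIC — polymorphism information content 1 - (p² + q²) - 2p²q²

Individual-pair distances are allele-sharing (1 - IBS) distances:
Σ|d_i - d_j| / (2·L) over pairwise-complete loci.  Population-level Nei
standard distance (-ln of normalized identity) is provided as a companion.
The neighbor-joining implementation is the classic Saitou–Nei agglomeration
with a documented lowest-index tie-break and clamping of negative branch
lengths (the deficit is transferred to the sibling edge).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .variants import VariantTable

DIVERSITY_COLUMNS = ("Ho", "He", "Pi", "PIC")


def _per_locus_stats(dosage: np.ndarray) -> pd.DataFrame:
    """Ho/He/Pi/PIC per locus for one population's dosage block."""
    n_called = (~np.isnan(dosage)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        j = np.nansum(dosage, axis=0)  # alt allele count
        m = 2.0 * n_called  # called alleles
        p = np.where(m > 0, j / np.maximum(m, 1), np.nan)
        q = 1.0 - p
        ho = np.where(
            n_called > 0, np.nansum(dosage == 1.0, axis=0) / np.maximum(n_called, 1), np.nan
        )
        he = 2.0 * p * q
        pi = np.where(m > 1, 2.0 * j * (m - j) / (m * np.maximum(m - 1.0, 1)), np.nan)
        pic = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return pd.DataFrame({"Ho": ho, "He": he, "Pi": pi, "PIC": pic, "p": p})


def diversity_stats(
    table: VariantTable,
    populations: list[str] | None = None,
    polymorphic_only: bool = False,
) -> pd.DataFrame:
    """Mean Ho/He/Pi/PIC per population.

    Monomorphic-within-population loci contribute zero to the means by
    default (whole-set averaging); ``polymorphic_only=True`` restricts the
    means to loci segregating within the population.
    """
    pops = populations if populations is not None else table.populations
    if pops is None:
        raise ValueError("population labels required")
    pops = pd.Series(list(pops))
    rows = {}
    for pop in pops.unique():
        idx = np.flatnonzero((pops == pop).to_numpy())
        if idx.size < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        stats = _per_locus_stats(table.dosage[idx, :])
        usable = stats["p"].notna()
        if polymorphic_only:
            usable &= (stats["p"] > 0) & (stats["p"] < 1)
        rows[pop] = stats.loc[usable, list(DIVERSITY_COLUMNS)].mean()
    return pd.DataFrame(rows).T.rename_axis("population")


def ibs_distance(table: VariantTable) -> pd.DataFrame:
    """Pairwise allele-sharing distance matrix between individuals.

    ``d(i, j) = Σ|dosage_i - dosage_j| / (2·L_ij)`` over the ``L_ij``
    pairwise-complete loci; zero diagonal.  Raises if any pair shares no
    non-missing loci.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 individuals")
    D = table.dosage
    called = ~np.isnan(D)
    # |a-b| over {0,1,2} decomposes onto genotype-indicator cross-products
    ind = [np.where(called & (D == g), 1.0, 0.0) for g in (0.0, 1.0, 2.0)]
    cross = [[ind[a] @ ind[b].T for b in range(3)] for a in range(3)]
    absdiff = (
        2.0 * (cross[0][2] + cross[2][0])
        + cross[0][1]
        + cross[1][0]
        + cross[1][2]
        + cross[2][1]
    )
    shared = called.astype(float) @ called.astype(float).T
    if np.any(shared[~np.eye(table.n_samples, dtype=bool)] == 0):
        i, j = np.argwhere((shared == 0) & ~np.eye(table.n_samples, dtype=bool))[0]
        raise ValueError(
            f"no shared non-missing loci between {table.samples[i]} and {table.samples[j]}"
        )
    dist = absdiff / (2.0 * shared)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # symmetrize away float noise
    return pd.DataFrame(dist, index=table.samples, columns=table.samples)


def nei_standard_distance(
    table: VariantTable, populations: list[str] | None = None
) -> pd.DataFrame:
    """Nei (1972) standard genetic distance between populations.

    ``D = -ln( Σ_l Σ_a x_a y_a / sqrt(Σ_l Σ_a x_a² · Σ_l Σ_a y_a²) )`` over
    biallelic frequencies per locus.
    """
    pops = populations if populations is not None else table.populations
    if pops is None:
        raise ValueError("population labels required")
    pops = pd.Series(list(pops))
    names = list(pops.unique())
    freqs = {}
    for pop in names:
        idx = np.flatnonzero((pops == pop).to_numpy())
        with np.errstate(invalid="ignore"):
            p = np.nanmean(table.dosage[idx, :], axis=0) / 2.0
        freqs[pop] = p
    out = np.zeros((len(names), len(names)))
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            x, y = freqs[names[a]], freqs[names[b]]
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            jxy = np.sum(x * y + (1 - x) * (1 - y))
            jx = np.sum(x**2 + (1 - x) ** 2)
            jy = np.sum(y**2 + (1 - y) ** 2)
            out[a, b] = out[b, a] = -np.log(jxy / np.sqrt(jx * jy))
    return pd.DataFrame(out, index=names, columns=names)


# -- neighbor joining -----------------------------------------------------


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{child.newick()}:{length:.10g}" for child, length in self.children
        )
        return f"({inner})"


def neighbor_joining(distances, labels: list[str] | None = None) -> str:
    """Neighbor-joining tree (Newick, unrooted trifurcation at the root).

    Classic Saitou–Nei agglomeration: at each step join the pair minimizing
    ``Q(i,j) = (n-2)·d(i,j) - r_i - r_j``; ties resolve to the
    lowest-index pair (row-major order), so output is deterministic.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling edge.
    """
    if isinstance(distances, pd.DataFrame):
        if labels is None:
            labels = list(distances.columns)
        D = distances.to_numpy(dtype=float).copy()
    else:
        D = np.asarray(distances, dtype=float).copy()
        if labels is None:
            labels = [f"t{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")

    nodes = [_Node(label=str(l)) for l in labels]
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index pair on ties: row-major argmin is deterministic
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, k)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining taxa
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [D.shape[0] - 1]

    # resolve the final three taxa with the three-point formulas
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    lengths = [la, lb, lc]
    for x in range(3):
        if lengths[x] < 0:
            deficit = lengths[x]
            lengths[x] = 0.0
            others = [y for y in range(3) if y != x]
            lengths[others[0]] += deficit / 2.0
            lengths[others[1]] += deficit / 2.0
    root = _Node(
        children=[
            (nodes[a], lengths[0]),
            (nodes[b], lengths[1]),
            (nodes[c], lengths[2]),
        ]
    )
    return root.newick() + ";"
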