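"""Genomic relationship matrix, REML mixed model, EMMAX-style GWAS, merging.

The phenotype model is ``y = Xb + Za + e`` with ``a ~ N(0, σ²_a G)`` for a
marker-based genomic relationship matrix G (VanRaden method 1) and
``e ~ N(0, σ²_e I)``; with individual-level records Z is the identity.
Variance components are estimated by REML with the likelihood profiled over
the variance ratio on the eigenbasis of G (EMMA-style), which turns each
evaluation into a weighted least-squares fit.

Without pedigree records a "single-step" GBLUP reduces to plain GBLUP on
the genomic relationship matrix; that is what is implemented here.

Phenotype adjustment offers two modes.  ``fixed_only`` (default) removes
only the estimated fixed effects ``Xb̂`` — population, age, location,
season — leaving additive genetic signal in place for the downstream GWAS.
``full_residual`` returns ``ê = y - Xb̂ - Zâ``; because the BLUP ``â``
absorbs additive genetic signal, association tests on these residuals are
attenuated, so this literal mode is kept behind a flag rather than used as
the default.

The association scan is single-marker GLS (EMMAX approximation): variance
components are estimated once under the null and each locus is then tested
with a Wald/t test under fixed covariance ``V = σ̂²_a G + σ̂²_e I``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .variants import VariantTable

logger = logging.getLogger(__name__)


def compute_grm(table: VariantTable) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    Dosages are mean-imputed per locus, centred by twice the allele
    frequency, and ``G = WWᵀ / (2 Σ p(1-p))``.  Monomorphic loci are
    skipped.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 individuals")
    D = table.dosage.copy()
    p = np.nanmean(D, axis=0) / 2.0
    nan_mask = np.isnan(D)
    D[nan_mask] = np.take(2.0 * p, np.nonzero(nan_mask)[1])
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all loci monomorphic: GRM undefined")
    W = D[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return (W @ W.T) / denom


def build_design_matrix(
    phenotypes: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Fixed-effect design matrix with intercept; aliased columns dropped.

    Categorical covariates are dummy-coded (first level as reference);
    numeric covariates enter as-is.  Columns that do not increase the
    matrix rank (e.g. location and season fully confounded with population)
    are dropped greedily in input order and reported.

    Returns (X, kept column names, dropped column names).
    """
    n = len(phenotypes)
    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(n))]
    for cov in covariates:
        series = phenotypes[cov]
        if pd.api.types.is_numeric_dtype(series):
            cols.append((cov, series.to_numpy(dtype=float)))
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols.append((name, dummies[name].to_numpy(dtype=float)))
    kept, dropped = [], []
    X = np.empty((n, 0))
    rank = 0
    for name, col in cols:
        cand = np.hstack([X, col[:, None]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            X, rank = cand, r
            kept.append(name)
        else:
            dropped.append(name)
    if dropped:
        logger.info("dropped aliased fixed-effect columns: %s", dropped)
    return X, kept, dropped


@dataclass
class MixedModelFit:
    """REML fit of ``y = Xb + a + e`` with ``a ~ N(0, σ²_a G)``."""

    beta: np.ndarray
    column_names: list[str]
    sigma2_a: float
    sigma2_e: float
    breeding_values: np.ndarray
    residuals: np.ndarray
    y: np.ndarray
    X: np.ndarray
    reml_loglik: float
    ratio: float  # σ²_a / σ²_e at the optimum

    @property
    def heritability(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0

    def fitted(self) -> np.ndarray:
        return self.X @ self.beta + self.breeding_values


_LOG_RATIO_BOUNDS = (-12.0, 12.0)


def _profiled_reml(
    log_ratio: float, eigvals: np.ndarray, yt: np.ndarray, Xt: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """REML log-likelihood profiled over σ²_e for V0 = λG + I.

    Works on the eigenbasis of G (yt = Uᵀy, Xt = UᵀX).  Returns
    (loglik, β̂, σ̂²_e).
    """
    lam = np.exp(log_ratio)
    w = 1.0 / (lam * eigvals + 1.0)
    n, p = Xt.shape
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    beta = np.linalg.solve(A, XtW.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.sum(w * r * r))
    # floor keeps the profiled likelihood finite when y sits exactly in the
    # column space of X
    sigma2e = max(rss / (n - p), 1e-300)
    sign_A, logdet_A = np.linalg.slogdet(A)
    sign_X, logdet_XX = np.linalg.slogdet(Xt.T @ Xt)
    loglik = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2e) + 1.0)
        - np.sum(np.log(w))
        + logdet_A
        - logdet_XX
    )
    return loglik, beta, sigma2e


def fit_lmm_reml(
    y: np.ndarray,
    X: np.ndarray,
    G: np.ndarray,
    column_names: list[str] | None = None,
) -> MixedModelFit:
    """REML fit by single-parameter optimization over the variance ratio.

    The likelihood is profiled on the spectral decomposition of G; a coarse
    grid over log-ratio seeds a bounded scalar refinement, guarding against
    flat or boundary likelihoods.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if len(y) != n or G.shape != (n, n):
        raise ValueError("dimension mismatch between y, X and G")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        aliased = _aliased_columns(X, column_names)
        raise ValueError(f"fixed-effect design is rank deficient; aliased columns: {aliased}")
    eigvals, U = np.linalg.eigh((G + G.T) / 2.0)
    eigvals = np.clip(eigvals, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    grid = np.linspace(*_LOG_RATIO_BOUNDS, 41)
    ll_grid = [_profiled_reml(g, eigvals, yt, Xt)[0] for g in grid]
    best = int(np.argmax(ll_grid))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_profiled_reml(g, eigvals, yt, Xt)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(
            f"REML optimization failed: {res.message}; "
            f"grid log-likelihoods {np.round(ll_grid, 3).tolist()}"
        )
    log_ratio = float(res.x)
    loglik, beta, sigma2e = _profiled_reml(log_ratio, eigvals, yt, Xt)
    lam = np.exp(log_ratio)
    # boundary handling: a ratio pinned at the lower bound means no
    # detectable genetic variance
    if log_ratio <= _LOG_RATIO_BOUNDS[0] + 1e-6:
        lam = 0.0
    sigma2a = lam * sigma2e
    # BLUP on the eigenbasis: â = λG(λG+I)⁻¹ (y - Xβ̂)
    r = yt - Xt @ beta
    shrink = lam * eigvals / (lam * eigvals + 1.0)
    a_hat = U @ (shrink * r)
    resid = y - X @ beta - a_hat
    return MixedModelFit(
        beta=beta,
        column_names=column_names or [f"x{i}" for i in range(p)],
        sigma2_a=float(sigma2a),
        sigma2_e=float(sigma2e),
        breeding_values=a_hat,
        residuals=resid,
        y=y,
        X=X,
        reml_loglik=float(loglik),
        ratio=float(lam),
    )


def _aliased_columns(X: np.ndarray, names: list[str] | None) -> list[str]:
    names = names or [f"x{i}" for i in range(X.shape[1])]
    kept_idx: list[int] = []
    aliased = []
    for i in range(X.shape[1]):
        cand = X[:, kept_idx + [i]]
        if np.linalg.matrix_rank(cand) > len(kept_idx):
            kept_idx.append(i)
        else:
            aliased.append(names[i])
    return aliased


def adjust_phenotypes(fit: MixedModelFit, mode: str = "fixed_only") -> np.ndarray:
    """Adjusted phenotypes: ``fixed_only`` (y - Xb̂) or ``full_residual`` (ê)."""
    if mode == "fixed_only":
        return fit.y - fit.X @ fit.beta
    if mode == "full_residual":
        return fit.residuals
    raise ValueError(f"unknown adjustment mode {mode!r}")


def gwas_mlm(
    y: np.ndarray,
    table: VariantTable,
    G: np.ndarray,
    alpha: float = 0.05,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-marker mixed-linear-model scan with Bonferroni control.

    Variance components are estimated once on the null model (EMMAX
    approximation); each locus is then tested by GLS under
    ``V ∝ λ̂G + I`` with a two-sided t test on the dosage effect.
    Monomorphic loci are skipped with a log entry.  The Bonferroni
    threshold is ``alpha / m`` with ``m`` the number of loci actually
    tested.

    Returns a DataFrame with columns snp, chrom, pos, ref, alt, beta, se,
    p, method, significant (NaN rows for skipped loci).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if table.n_samples != n:
        raise ValueError("phenotype/genotype sample mismatch")
    X0 = np.ones((n, 1)) if covariates is None else np.atleast_2d(covariates)
    null_fit = fit_lmm_reml(y, X0, G)
    lam = null_fit.ratio
    eigvals, U = np.linalg.eigh((G + G.T) / 2.0)
    eigvals = np.clip(eigvals, 0.0, None)
    w_half = 1.0 / np.sqrt(lam * eigvals + 1.0)
    # whitened responses/designs: rows of the model premultiplied by V^(-1/2)
    yw = w_half * (U.T @ y)
    Xw = w_half[:, None] * (U.T @ X0)

    D = table.dosage.copy()
    p_freq = np.nanmean(D, axis=0) / 2.0
    nan_mask = np.isnan(D)
    D[nan_mask] = np.take(2.0 * p_freq, np.nonzero(nan_mask)[1])
    poly = (p_freq > 0.0) & (p_freq < 1.0)
    n_skip = int((~poly).sum())
    if n_skip:
        logger.info("skipped %d monomorphic loci in GWAS", n_skip)
    Gw = w_half[:, None] * (U.T @ D[:, poly])

    # residualize the null covariates out of the whitened response/markers
    Q, _ = np.linalg.qr(Xw)
    y_res = yw - Q @ (Q.T @ yw)
    G_res = Gw - Q @ (Q.T @ Gw)

    xx = np.einsum("ij,ij->j", G_res, G_res)
    xy = G_res.T @ y_res
    ok = xx > 1e-12
    beta = np.full(ok.shape, np.nan)
    se = np.full(ok.shape, np.nan)
    beta[ok] = xy[ok] / xx[ok]
    df = n - X0.shape[1] - 1
    rss = np.sum(y_res**2) - beta[ok] ** 2 * xx[ok]
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2 / xx[ok])
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)

    m_tested = int(ok.sum())
    threshold = alpha / m_tested if m_tested else np.nan
    out = pd.DataFrame(
        {
            "snp": table.ids,
            "chrom": table.loci["chrom"],
            "pos": table.loci["pos"],
            "ref": table.loci["ref"],
            "alt": table.loci["alt"],
            "beta": np.nan,
            "se": np.nan,
            "p": np.nan,
            "method": "MLM",
            "significant": False,
        }
    )
    out.loc[poly, "beta"] = beta
    out.loc[poly, "se"] = se
    out.loc[poly, "p"] = pvals
    out.loc[poly, "significant"] = pvals < threshold
    out.attrs["n_tested"] = m_tested
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["sigma2_a"] = null_fit.sigma2_a
    out.attrs["sigma2_e"] = null_fit.sigma2_e
    return out


def merge_model_results(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of per-model significant-locus lists, deduplicated by locus.

    Each input needs either a ``snp`` column with
    ``<chrom>_<pos>_<ref>_<alt>`` identifiers or explicit
    chrom/pos/ref/alt columns, plus a ``method`` label.  The merged table
    concatenates contributing methods alphabetically (e.g. "BLINK,
    FarmCPU, MLM") and is sorted by chromosome then position.
    """
    rows = []
    for res in results:
        df = res.copy()
        if "snp" not in df.columns:
            if not {"chrom", "pos", "ref", "alt"}.issubset(df.columns):
                raise ValueError("result list lacks snp or chrom/pos/ref/alt columns")
            df["snp"] = (
                df["chrom"].astype(str)
                + "_"
                + df["pos"].astype(str)
                + "_"
                + df["ref"]
                + "_"
                + df["alt"]
            )
        if "method" not in df.columns:
            raise ValueError("result list lacks a method column")
        for _, row in df.iterrows():
            parts = str(row["snp"]).split("_")
            if len(parts) != 4 or not parts[1].isdigit():
                raise ValueError(f"malformed locus identifier: {row['snp']!r}")
            for meth in str(row["method"]).split(","):
                rows.append((row["snp"], parts[0], int(parts[1]), parts[2], parts[3], meth.strip()))
    if not rows:
        return pd.DataFrame(columns=["snp", "chrom", "pos", "ref", "alt", "method"])
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "ref", "alt", "method"])
    merged = (
        df.groupby(["snp", "chrom", "pos", "ref", "alt"], as_index=False)
        .agg(method=("method", lambda s: ", ".join(sorted(set(s)))))
    )
    merged["_chrom_key"] = merged["chrom"].str.extract(r"(\d+)", expand=False).astype(float)
    merged = (
        merged.sort_values(["_chrom_key", "chrom", "pos"], kind="mergesort")
        .drop(columns="_chrom_key")
        .reset_index(drop=True)
    )
    return merged
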