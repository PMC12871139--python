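"""Trait normalisation, per-SNP association scan, permutation thresholds,
peak calling, peak-to-gene reporting and candidate-locus genotyping.

The scan is a covariate-adjusted per-SNP ordinary linear model (batched
normal equations); population structure is absorbed by supplying the hybrid
index as a covariate, and residual miscalibration is absorbed by the
permutation-derived genome-wide threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import MISSING, GenotypeMatrix


@dataclass
class TraitVector:
    """A trait with its recorded normalising transformation."""

    name: str
    values: pd.Series                  # indexed by sample id
    transformation: str = "none"       # none | log | sqrt | boxcox(lambda)
    shapiro_p: float = np.nan


def normalize_trait(values: pd.Series, name: str = "trait",
                    alpha: float = 0.05) -> TraitVector:
    """Shapiro-Wilk-guided normalisation.

    A trait with Shapiro-Wilk p > alpha is kept untransformed.  Otherwise
    the admissible transformations (log for strictly positive values, sqrt
    for non-negative, Box-Cox with MLE lambda for strictly positive) are
    each re-tested and the one with the highest p is kept, provided it beats
    the untransformed p; ties go to the untransformed trait.
    """
    values = pd.Series(values).astype(float)
    x = values.dropna().to_numpy()
    if len(x) < 3:
        raise ValueError("need at least 3 non-missing values")
    p0 = stats.shapiro(x).pvalue
    if p0 > alpha:
        return TraitVector(name, values, "none", p0)
    candidates = {}
    if np.all(x > 0):
        candidates["log"] = (np.log(values), None)
        lam = stats.boxcox(x)[1]
        candidates[f"boxcox({lam:.4g})"] = (
            pd.Series(stats.boxcox(values.dropna().to_numpy(), lmbda=lam),
                      index=values.dropna().index).reindex(values.index), None)
    if np.all(x >= 0):
        candidates["sqrt"] = (np.sqrt(values), None)
    best = ("none", values, p0)
    for label, (tv, _) in candidates.items():
        p = stats.shapiro(pd.Series(tv).dropna().to_numpy()).pvalue
        if p > best[2]:
            best = (label, pd.Series(tv, index=values.index), p)
    return TraitVector(name, best[1], best[0], best[2])


def _batched_ols(y: np.ndarray, G: np.ndarray, W: np.ndarray,
                 C: np.ndarray):
    """Per-SNP OLS of y on [1, C, g] with per-SNP missingness masks.

    y : (n,) phenotype; G : (n, L) dosages with missing as 0;
    W : (n, L) 0/1 genotype-called mask; C : (n, k) covariates.
    Returns beta, se, t, p, df arrays of length L.
    """
    n, L = G.shape
    k = C.shape[1]
    p_dim = k + 2
    X0 = np.column_stack([np.ones(n), C])  # (n, k+1)
    # normal-equation blocks, per SNP
    A = np.empty((L, p_dim, p_dim))
    b = np.empty((L, p_dim))
    WX = W[:, :, None] * X0[:, None, :]            # broadcast masks
    A[:, :p_dim - 1, :p_dim - 1] = np.einsum("nj,nlk->ljk", X0, WX)
    Ag = np.einsum("nl,nlk->lk", G, WX)            # X0' g per SNP
    A[:, :p_dim - 1, p_dim - 1] = Ag
    A[:, p_dim - 1, :p_dim - 1] = Ag
    A[:, p_dim - 1, p_dim - 1] = np.einsum("nl,nl->l", G * W, G)
    Wy = W * y[:, None]
    b[:, :p_dim - 1] = np.einsum("nl,nk->lk", Wy, X0)
    b[:, p_dim - 1] = np.einsum("nl,nl->l", G, Wy)

    n_used = W.sum(axis=0)
    df = n_used - p_dim
    # guard against singular normal matrices from monomorphic SNPs
    with np.errstate(invalid="ignore", divide="ignore"):
        gmean = np.where(n_used > 0, G.sum(axis=0) / np.maximum(n_used, 1), 0)
        gvar = ((G - gmean[None, :]) ** 2 * W).sum(axis=0)
    ok = (df > 0) & (gvar > 0)
    beta = np.full((L, p_dim), np.nan)
    se_b = np.full(L, np.nan)
    yy = np.einsum("nl,n->l", W, y ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        try:
            sol = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
        except np.linalg.LinAlgError:  # singular SNPs handled one by one
            sol = np.stack([np.linalg.lstsq(Ai, bi, rcond=None)[0]
                            for Ai, bi in zip(A[ok], b[ok])])
        beta[ok] = sol
        rss = yy[ok] - np.einsum("lk,lk->l", sol, b[ok])
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / np.maximum(df[ok], 1)
        try:
            Ainv = np.linalg.inv(A[ok])
            last = Ainv[:, p_dim - 1, p_dim - 1]
        except np.linalg.LinAlgError:
            last = np.full(ok.sum(), np.nan)
        se_b[ok] = np.sqrt(sigma2 * last)
    bcol = beta[:, p_dim - 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = bcol / se_b
    p = np.full(L, np.nan)
    valid = ok & np.isfinite(t)
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df[valid])
    # a perfect fit (zero residual) gives t = +-inf: p underflows to 0
    p[ok & np.isinf(t)] = 0.0
    return bcol, se_b, t, p, df


def association_scan(gm: GenotypeMatrix, trait: TraitVector,
                     covariates: pd.DataFrame | None = None,
                     min_pairs: int = 10) -> pd.DataFrame:
    """Per-SNP slope, SE and two-sided p from the t statistic.

    Monomorphic SNPs (among phenotyped, genotyped samples) and SNPs with
    fewer than ``min_pairs`` complete pairs are skipped (NaN p).
    """
    y_full = trait.values.reindex(gm.samples)
    have_y = y_full.notna().to_numpy()
    idx = np.flatnonzero(have_y)
    y = y_full.to_numpy(dtype=float)[idx]
    if covariates is not None:
        C = covariates.reindex(np.array(gm.samples)[idx]).to_numpy(dtype=float)
        if np.isnan(C).any():
            raise ValueError("missing covariate values for phenotyped samples")
    else:
        C = np.empty((len(idx), 0))
    D = gm.dosage[idx].astype(float)
    W = (D != MISSING).astype(float)
    D[D == MISSING] = 0.0

    n_pairs = W.sum(axis=0)
    mono = np.zeros(gm.n_variants, dtype=bool)
    with np.errstate(invalid="ignore"):
        mean_d = np.where(n_pairs > 0, (D * W).sum(axis=0) / np.maximum(n_pairs, 1), 0)
        var_d = ((D - mean_d[None, :]) ** 2 * W).sum(axis=0)
    mono = var_d <= 0
    beta, se, t, p, df = _batched_ols(y, D, W, C)
    skip = mono | (n_pairs < min_pairs)
    for arr in (beta, se, t, p):
        arr[skip] = np.nan
    out = gm.variants[["chrom", "pos"]].copy()
    return out.assign(beta=beta, se=se, t=t, p=p,
                      n=n_pairs.astype(int))


def permutation_threshold(gm: GenotypeMatrix, trait: TraitVector,
                          covariates: pd.DataFrame | None = None,
                          n_perm: int = 100, pool_fraction: float = 0.01,
                          quantile: float = 1e-6, seed: int = 0) -> float:
    """Empirical genome-wide threshold from permuted-trait scans.

    The trait is shuffled ``n_perm`` times, the scan re-run each time, the
    lowest ``pool_fraction`` of p-values pooled across permutations, and the
    ``quantile`` (default 1e-6, i.e. "0.0001%") of the pooled values
    returned (type-7 interpolation).  If the pooled set is smaller than
    1/quantile a warning is issued and the pooled minimum returned.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pooled = []
    obs = trait.values.dropna()
    for _ in range(n_perm):
        shuffled = pd.Series(rng.permutation(obs.to_numpy()), index=obs.index)
        tv = TraitVector(trait.name, shuffled, trait.transformation)
        p = association_scan(gm, tv, covariates)["p"].dropna().to_numpy()
        k = max(1, int(np.ceil(pool_fraction * len(p))))
        pooled.append(np.sort(p)[:k])
    pooled = np.concatenate(pooled)
    return pooled_quantile_threshold(pooled, quantile)


def pooled_quantile_threshold(pooled_p: np.ndarray, quantile: float = 1e-6
                              ) -> float:
    """The stated quantile of a pooled low-p set (type-7 interpolation)."""
    pooled_p = np.asarray(pooled_p, dtype=float)
    if len(pooled_p) == 0:
        raise ValueError("empty pooled p-value set")
    if len(pooled_p) < 1.0 / quantile:
        import warnings
        warnings.warn(f"pooled set of {len(pooled_p)} p-values is smaller "
                      f"than 1/quantile; returning the pooled minimum",
                      stacklevel=2)
        return float(pooled_p.min())
    return float(np.quantile(pooled_p, quantile))


def bonferroni_threshold(n_snps: int, alpha: float = 0.05) -> float:
    return alpha / n_snps


def call_peaks(scan: pd.DataFrame, threshold: float, min_cluster: int = 5,
               afd: np.ndarray | None = None, trait: str = "trait"
               ) -> pd.DataFrame:
    """Association peaks: per chromosome, the set of SNPs below the threshold
    forms one peak if its size >= ``min_cluster``; the interval spans the
    significant SNPs.  With ``afd`` supplied, reports the percentage of
    significant SNPs that are fixed differences (AFD = 1)."""
    sig = scan["p"].to_numpy() < threshold
    peaks = []
    for ch in pd.unique(scan["chrom"]):
        on = (scan["chrom"] == ch).to_numpy() & sig
        n_sig = int(on.sum())
        if n_sig < min_cluster:
            continue
        pos = scan.loc[on, "pos"]
        pct_fixed = np.nan
        if afd is not None:
            a = np.asarray(afd, dtype=float)[np.flatnonzero(on)]
            pct_fixed = 100.0 * np.mean(a >= 1.0 - 1e-12)
        peaks.append((trait, ch, int(pos.min()), int(pos.max()), n_sig,
                      pct_fixed))
    return pd.DataFrame(peaks, columns=["trait", "chrom", "min_bp", "max_bp",
                                        "n_sig_snps", "pct_fixed"])


def genes_near_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                     flank_bp: int = 20_000) -> pd.DataFrame:
    """Genes overlapping [min_bp - flank, max_bp + flank] per peak (flank
    inclusive at exactly ``flank_bp``), listed in coordinate order."""
    out = peaks.copy()
    lists = []
    for _, pk in peaks.iterrows():
        lo, hi = pk["min_bp"] - flank_bp, pk["max_bp"] + flank_bp
        hit = genes[(genes["chrom"] == pk["chrom"])
                    & (genes["end"] >= lo) & (genes["start"] <= hi)]
        lists.append(list(hit.sort_values("start")["gene"]))
    out["genes"] = lists
    return out


def genotype_candidate_locus(gm: GenotypeMatrix, snp_indices,
                             freqs, samples=None) -> pd.Series:
    """Consensus ancestry genotype over a SNP set for each sample.

    SNP-level calls are oriented to parental ancestry via the parental
    allele-frequency difference; the locus call is heterozygous if >= 50% of
    non-missing SNP calls are heterozygous, else a parent class if its
    fraction exceeds 50%, else missing.
    """
    snp_indices = np.asarray(snp_indices, dtype=int)
    flip = freqs.p1[snp_indices] < freqs.p2[snp_indices]
    ids = samples if samples is not None else gm.samples
    idx = gm.sample_indices(ids)
    d = gm.dosage[np.ix_(idx, snp_indices)].astype(float)
    d[d == MISSING] = np.nan
    anc = np.where(flip[None, :], 2.0 - d, d)
    calls = []
    for row in anc:
        ok = ~np.isnan(row)
        n = ok.sum()
        if n == 0:
            calls.append("missing")
            continue
        f_het = np.sum(row[ok] == 1) / n
        f_p1 = np.sum(row[ok] == 2) / n
        f_p2 = np.sum(row[ok] == 0) / n
        if f_het >= 0.5:
            calls.append("het")
        elif f_p1 > 0.5:
            calls.append("parent1")
        elif f_p2 > 0.5:
            calls.append("parent2")
        else:
            calls.append("missing")
    return pd.Series(calls, index=list(ids), name="genotype")
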