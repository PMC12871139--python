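"""Hierarchical Bayesian genomic cline inference.

The cline function is the logit-logistic form

    phi(h; v, u) = h^v / (h^v + (1 - h)^v * exp(u)),

the probability that a gene copy at a locus in a hybrid with genome-wide
hybrid index ``h`` derives from parent1.  ``v`` is the cline slope relative
to the genome-wide average (v = 1) and ``u`` locates the cline through the
center ``c`` with ``logit(c) = u / v``, the hybrid index at which phi = 0.5.
Equivalently ``logit(phi) = v * logit(h) - u`` for h in (0, 1).

Estimation is two-stage, with hybrid indexes fixed at point estimates:

1. :meth:`GenomicClineModel.fit_sds` runs a joint MCMC over per-locus
   ``(log v, logit c)`` with hierarchical priors ``log v ~ N(0, sd_logv)``,
   ``logit c ~ N(0, sd_logitc)`` and half-Normal(0, 1) hyperpriors on both
   SDs, on a subset of loci; the posterior-median SDs become plug-in point
   estimates.
2. :meth:`GenomicClineModel.fit` runs per-locus MCMC (vectorised across
   loci) at those fixed SDs and classifies each locus steep / shallow /
   neutral by whether the 95% equal-tail interval of v sits above / below 1.

The sampler is an adaptive random-walk Metropolis on ``(log v, logit c)``
(componentwise-per-locus joint proposals, target acceptance 0.3-0.45),
deterministic under a seed.  Genotypes enter through the allele-frequency
mixture ``g ~ Binomial(2, q)`` with ``q = phi * p1 + (1 - phi) * p2``, which
handles non-fixed loci; loci with parental AFD below a configurable floor
are excluded as uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import mannwhitneyu

from .dataio import MISSING, GenotypeMatrix
from .popstats import ParentalAlleleFreqs, rolling_smooth

log = logging.getLogger(__name__)

_EPS = 1e-12


def cline_phi(h, v, u):
    """Logit-logistic genomic cline function, phi in [0, 1].

    phi(0) = 0 and phi(1) = 1 for all v > 0, u; computed in the numerically
    stable logit form for interior h.
    """
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(v <= 0):
        raise ValueError("cline slope v must be > 0")
    if np.any((h < 0) | (h > 1)):
        raise ValueError("hybrid index h must lie in [0, 1]")
    interior = np.where((h > 0) & (h < 1), h, 0.5)  # placeholder at bounds
    phi = expit(v * logit(interior) - u)
    phi = np.where(h <= 0, 0.0, np.where(h >= 1, 1.0, phi))
    return phi if phi.ndim else float(phi)


def cline_center(v, u):
    """The hybrid index c at which phi = 0.5: c = inverse-logit(u / v)."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("cline slope v must be > 0")
    out = expit(np.asarray(u, dtype=float) / v)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ClineParams:
    """One locus' cline parameters; logit(c) = u / v by construction."""

    v: float
    u: float

    def __post_init__(self):
        if self.v <= 0:
            raise ValueError("v must be > 0")

    @property
    def c(self) -> float:
        return float(expit(self.u / self.v))


@dataclass(frozen=True)
class MCMCConfig:
    iterations: int = 4000
    burnin: int = 2000
    chains: int = 2
    seed: int = 0
    init_scale: float = 0.3
    target_accept: float = 0.37
    adapt_interval: int = 50


@dataclass
class HierarchicalSDs:
    """Point estimates (posterior medians) of the cline SD hyperparameters."""

    sd_logv: float
    sd_logitc: float
    summary_frame: pd.DataFrame | None = None
    converged: bool = True

    def __post_init__(self):
        if self.sd_logv <= 0 or self.sd_logitc <= 0:
            raise ValueError("hierarchical SDs must be > 0")


# ---------------------------------------------------------------------------
# MCMC internals (batched over loci)


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split R-hat per locus; draws shape (chains, draws, L)."""
    m, n, L = draws.shape
    half = n // 2
    x = np.concatenate([draws[:, :half], draws[:, half: 2 * half]], axis=0)
    k, nn = x.shape[0], half
    means = x.mean(axis=1)                      # (k, L)
    w = x.var(axis=1, ddof=1).mean(axis=0)      # (L,)
    b = nn * means.var(axis=0, ddof=1)          # (L,)
    var_plus = (nn - 1) / nn * w + b / nn
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(np.where(w > 0, var_plus / np.where(w > 0, w, 1), 1.0))


def _ess(draws: np.ndarray) -> np.ndarray:
    """Bulk effective sample size per locus via FFT autocorrelation
    (Geyer initial-positive-sequence truncation); draws (chains, draws, L)."""
    m, n, L = draws.shape
    xc = draws - draws.mean(axis=1, keepdims=True)
    f = np.fft.rfft(xc, n=2 * n, axis=1)
    acov = np.fft.irfft(f * f.conj(), axis=1)[:, :n].real / n  # (m, n, L)
    var0 = acov[:, 0, :].mean(axis=0)  # (L,)
    var0 = np.where(var0 > 0, var0, 1.0)
    rho = acov.mean(axis=0) / var0      # (n, L)
    n_pairs = n // 2
    paired = rho[: 2 * n_pairs].reshape(n_pairs, 2, L).sum(axis=1)  # (n_pairs, L)
    positive = np.cumprod(paired > 0, axis=0).astype(bool)
    tau = 2.0 * np.where(positive, paired, 0.0).sum(axis=0) - 1.0
    tau = np.maximum(tau, 1.0 / (m * n))
    return np.minimum(m * n / tau, m * n * 1.0)


class _ClineLikelihood:
    """Batched log-likelihood of (log v, logit c) arrays over loci."""

    def __init__(self, G, W, lh, p1, p2):
        self.G = G          # (n, L) dosages, missing as 0
        self.W = W          # (n, L) 0/1 weights
        self.lh = lh[:, None]  # (n, 1) logit hybrid index
        self.p1 = p1[None, :]
        self.p2 = p2[None, :]
        self.G2 = 2.0 - G

    def __call__(self, lv, lc):
        v = np.exp(lv)[None, :]
        u = (np.exp(lv) * lc)[None, :]
        phi = expit(v * self.lh - u)
        q = np.clip(phi * self.p1 + (1.0 - phi) * self.p2, _EPS, 1 - _EPS)
        return (self.W * (self.G * np.log(q) + self.G2 * np.log1p(-q))).sum(axis=0)


def _run_chain(like, sd_logv, sd_logitc, cfg: MCMCConfig, rng,
               sample_sds: bool):
    """One chain; returns draws dict.  With ``sample_sds`` the SDs get
    half-Normal(0,1) hyperpriors and random-walk updates on the log scale."""
    L = like.p1.shape[1]
    lv = rng.normal(0.0, 0.1, size=L)
    lc = rng.normal(0.0, 0.1, size=L)
    sv, sc = float(sd_logv), float(sd_logitc)
    scale = np.full(L, cfg.init_scale)
    ll = like(lv, lc)

    def lprior(lv, lc, sv, sc):
        return (-0.5 * (lv / sv) ** 2 - np.log(sv)
                - 0.5 * (lc / sc) ** 2 - np.log(sc))

    lp = ll + lprior(lv, lc, sv, sc)
    n_keep = cfg.iterations - cfg.burnin
    out_lv = np.empty((n_keep, L))
    out_lc = np.empty((n_keep, L))
    out_sd = np.empty((n_keep, 2)) if sample_sds else None
    acc = np.zeros(L)
    for it in range(cfg.iterations):
        plv = lv + rng.normal(0.0, scale, size=L)
        plc = lc + rng.normal(0.0, scale, size=L)
        pll = like(plv, plc)
        plp = pll + lprior(plv, plc, sv, sc)
        accept = np.log(rng.random(L)) < (plp - lp)
        lv = np.where(accept, plv, lv)
        lc = np.where(accept, plc, lc)
        ll = np.where(accept, pll, ll)
        lp = np.where(accept, plp, lp)
        acc += accept

        if sample_sds:
            # Independence Metropolis from the scale-family conditional:
            # propose sd^2 ~ Inv-Gamma(L/2, S/2), which matches the
            # likelihood of the locus effects; the acceptance ratio then
            # reduces to the half-Normal(0,1) prior x Jacobian factor
            # exp(log sd - sd^2/2), so mixing stays good even as sd -> 0.
            for which in (0, 1):
                cur = sv if which == 0 else sc
                vals = lv if which == 0 else lc
                s_sq = float(np.sum(vals ** 2))
                prop = np.sqrt(s_sq / rng.chisquare(L)) if s_sq > 0 else cur
                lr = (np.log(prop) - 0.5 * prop ** 2) - \
                     (np.log(cur) - 0.5 * cur ** 2)
                if np.log(rng.random()) < lr:
                    if which == 0:
                        sv = prop
                    else:
                        sc = prop
            lp = ll + lprior(lv, lc, sv, sc)

        if it < cfg.burnin and (it + 1) % cfg.adapt_interval == 0:
            rate = acc / cfg.adapt_interval
            scale *= np.exp(np.clip(rate - cfg.target_accept, -0.5, 0.5))
            scale = np.clip(scale, 1e-3, 10.0)
            acc[:] = 0.0
        if it >= cfg.burnin:
            j = it - cfg.burnin
            out_lv[j] = lv
            out_lc[j] = lc
            if sample_sds:
                out_sd[j] = (sv, sc)
    return out_lv, out_lc, out_sd


# ---------------------------------------------------------------------------
# Model / Results


class GenomicClineModel:
    """Genomic cline model for a set of loci in a hybrid zone.

    Parameters
    ----------
    gm : GenotypeMatrix
    freqs : ParentalAlleleFreqs
        Parental ALT frequencies at the matrix's variants.
    hybrid_index : mapping or pandas.Series
        Point-estimate hybrid index per sample (proportion parent1 ancestry).
        Samples with boundary values (0 or 1) contribute no cline information
        and are excluded with a log entry.
    samples : sequence of str, optional
        Which samples to use (default: every sample present in
        ``hybrid_index`` with an interior value).
    afd_floor : float
        Loci with parental AFD below this are excluded as uninformative.
    """

    def __init__(self, gm: GenotypeMatrix, freqs: ParentalAlleleFreqs,
                 hybrid_index, samples=None, afd_floor: float = 0.3):
        self.gm = gm
        self.freqs = freqs
        h = pd.Series(hybrid_index)
        if samples is not None:
            h = h.loc[list(samples)]
        interior = (h > 0) & (h < 1)
        if (~interior).any():
            log.info("excluding %d boundary-hybrid-index individuals from "
                     "cline likelihoods", int((~interior).sum()))
        self.h = h[interior]
        if len(self.h) == 0:
            raise ValueError("no individuals with interior hybrid index")
        self.afd_floor = afd_floor
        self.eligible = freqs.defined & (freqs.afd >= afd_floor)

    def _prepare(self, loci):
        if loci is None:
            loci = np.flatnonzero(self.eligible)
        else:
            loci = np.asarray(loci, dtype=int)
            loci = loci[self.eligible[loci]]
        idx = self.gm.sample_indices(self.h.index)
        G = self.gm.dosage[np.ix_(idx, loci)].astype(float)
        W = (G != MISSING).astype(float)
        G[G == MISSING] = 0.0
        informative = W.sum(axis=0) > 0
        if (~informative).any():
            log.info("dropping %d loci with all-missing genotypes",
                     int((~informative).sum()))
            loci = loci[informative]
            G = G[:, informative]
            W = W[:, informative]
        if len(loci) == 0:
            raise ValueError("no usable loci for cline fitting")
        lh = logit(self.h.to_numpy(dtype=float))
        like = _ClineLikelihood(G, W, lh, self.freqs.p1[loci],
                                self.freqs.p2[loci])
        return loci, like

    def fit_sds(self, loci=None, n_snps: int | None = None,
                mcmc: MCMCConfig = MCMCConfig()) -> HierarchicalSDs:
        """Estimate the hierarchical SDs of log(v) and logit(c) by joint MCMC.

        Returns posterior-median SDs as plug-in point estimates; a
        non-convergence (R-hat > 1.1) sets ``converged=False`` with a
        warning, never an exception.
        """
        loci, like = self._prepare(loci)
        if n_snps is not None and n_snps < len(loci):
            rng = np.random.default_rng(mcmc.seed)
            keep = np.sort(rng.choice(len(loci), size=n_snps, replace=False))
            like = _ClineLikelihood(like.G[:, keep], like.W[:, keep],
                                    like.lh[:, 0], like.p1[0, keep],
                                    like.p2[0, keep])
        if like.p1.shape[1] < 100:
            log.warning("fit_sds on only %d loci; SD estimates may be poor",
                        like.p1.shape[1])
        seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
        sd_draws = []
        for s in seeds:
            _, _, out_sd = _run_chain(like, 1.0, 1.0, mcmc,
                                      np.random.default_rng(s), sample_sds=True)
            sd_draws.append(out_sd)
        sd_draws = np.stack(sd_draws)  # (chains, keep, 2)
        rhat = _split_rhat(sd_draws)
        converged = bool(np.all(rhat < 1.1))
        if not converged:
            log.warning("hierarchical SD MCMC not converged (R-hat %s)", rhat)
        med = np.median(sd_draws.reshape(-1, 2), axis=0)
        q = np.quantile(sd_draws.reshape(-1, 2), [0.025, 0.975], axis=0)
        frame = pd.DataFrame(
            {"median": med, "ci_low": q[0], "ci_high": q[1], "rhat": rhat},
            index=["sd_logv", "sd_logitc"])
        return HierarchicalSDs(sd_logv=float(med[0]), sd_logitc=float(med[1]),
                               summary_frame=frame, converged=converged)

    def fit(self, sds: HierarchicalSDs, loci=None,
            mcmc: MCMCConfig = MCMCConfig()) -> "GenomicClineResults":
        """Per-locus cline MCMC at fixed hierarchical SDs (two-stage design)."""
        loci, like = self._prepare(loci)
        seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
        lv_chains, lc_chains = [], []
        for s in seeds:
            out_lv, out_lc, _ = _run_chain(like, sds.sd_logv, sds.sd_logitc,
                                           mcmc, np.random.default_rng(s),
                                           sample_sds=False)
            lv_chains.append(out_lv)
            lc_chains.append(out_lc)
        lv = np.stack(lv_chains)  # (chains, keep, L)
        lc = np.stack(lc_chains)
        v = np.exp(lv)
        c = expit(lc)
        flat_v = v.reshape(-1, v.shape[-1])
        flat_c = c.reshape(-1, c.shape[-1])
        v_lo, v_hi = np.quantile(flat_v, [0.025, 0.975], axis=0)
        c_lo, c_hi = np.quantile(flat_c, [0.025, 0.975], axis=0)
        category = np.where(v_lo > 1.0, "steep",
                            np.where(v_hi < 1.0, "shallow", "neutral"))
        table = self.gm.variants.iloc[loci][["chrom", "pos"]].reset_index(drop=True)
        table = table.assign(
            v_mean=flat_v.mean(axis=0), v_median=np.median(flat_v, axis=0),
            v_lo=v_lo, v_hi=v_hi,
            c_mean=flat_c.mean(axis=0), c_median=np.median(flat_c, axis=0),
            c_lo=c_lo, c_hi=c_hi, category=category,
            ess_v=_ess(lv), rhat_v=_split_rhat(lv),
            ess_c=_ess(lc), rhat_c=_split_rhat(lc),
        )
        table["converged"] = ((table["rhat_v"] < 1.1) & (table["rhat_c"] < 1.1)
                              & (table["ess_v"] >= 100) & (table["ess_c"] >= 100))
        return GenomicClineResults(self, table, sds, loci)


@dataclass
class GenomicClineResults:
    """Per-locus posterior summaries, outlier categories and diagnostics."""

    model: GenomicClineModel | None
    table: pd.DataFrame
    sds: HierarchicalSDs
    loci: np.ndarray | None = None

    def summary(self) -> str:
        t = self.table
        counts = t["category"].value_counts()
        total = len(t)
        lines = [
            "Genomic cline fit (two-stage hierarchical Bayesian model)",
            f"  loci fitted: {total}",
            f"  hierarchical SDs: sd_logv={self.sds.sd_logv:.3f}  "
            f"sd_logitc={self.sds.sd_logitc:.3f}",
        ]
        for cat in ("steep", "shallow", "neutral"):
            n = int(counts.get(cat, 0))
            lines.append(f"  {cat:8s}: {n:6d}  ({percent_of(n, total):.4g}%)")
        lines.append(f"  converged loci: {int(t['converged'].sum())} / {total}")
        return "\n".join(lines)

    def category_percentages(self) -> dict:
        counts = self.table["category"].value_counts()
        total = len(self.table)
        return {cat: percent_of(int(counts.get(cat, 0)), total)
                for cat in ("steep", "shallow", "neutral")}

    def window_category_proportions(self, window_bp: int = 500_000,
                                    smooth_k: int = 5) -> pd.DataFrame:
        return window_category_proportions(self.table, window_bp, smooth_k)

    def chromosome_enrichment(self, n_perm: int = 1000, seed: int = 0
                              ) -> pd.DataFrame:
        return chromosome_enrichment(self.table, n_perm=n_perm, seed=seed)

    def region_vs_background(self, chrom, start, end) -> pd.DataFrame:
        return region_vs_background(self.table, chrom, start, end)


def percent_of(count: int, total: int, sig: int = 3) -> float:
    """Percentage rounded to ``sig`` significant figures (reporting path)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(f"%.{sig}g" % (100.0 * count / total))


def window_category_proportions(table: pd.DataFrame, window_bp: int = 500_000,
                                smooth_k: int = 5) -> pd.DataFrame:
    """Per-window fraction of loci in each cline category, rolling-smoothed."""
    start = ((table["pos"].to_numpy() - 1) // window_bp) * window_bp + 1
    df = pd.DataFrame({"chrom": table["chrom"].to_numpy(), "start": start})
    for cat in ("steep", "shallow", "neutral"):
        df[cat] = (table["category"] == cat).to_numpy(dtype=float)
    agg = df.groupby(["chrom", "start"], sort=True).agg(
        n_loci=("steep", "size"), steep=("steep", "mean"),
        shallow=("shallow", "mean"), neutral=("neutral", "mean")).reset_index()
    agg["end"] = agg["start"] + window_bp - 1
    agg = agg[["chrom", "start", "end", "n_loci", "steep", "shallow", "neutral"]]
    if smooth_k > 1:
        agg = rolling_smooth(agg, smooth_k,
                             value_cols=["steep", "shallow", "neutral"])
    return agg


def chromosome_enrichment(table: pd.DataFrame, n_perm: int = 1000,
                          seed: int = 0, low_power_min: int = 10
                          ) -> pd.DataFrame:
    """Per-chromosome permutation test for steep/shallow excess.

    Category labels are permuted across all loci (chromosome sizes
    preserved); empirical p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    chroms, codes = np.unique(table["chrom"].to_numpy(), return_inverse=True)
    K = len(chroms)
    rows = []
    for cat in ("steep", "shallow"):
        is_cat = (table["category"] == cat).to_numpy()
        obs = np.bincount(codes, weights=is_cat, minlength=K)
        ge = np.zeros(K)
        for _ in range(n_perm):
            perm = rng.permutation(is_cat)
            cnt = np.bincount(codes, weights=perm, minlength=K)
            ge += cnt >= obs
        p = (1.0 + ge) / (n_perm + 1.0)
        sizes = np.bincount(codes, minlength=K)
        for k in range(K):
            rows.append((chroms[k], cat, int(sizes[k]), int(obs[k]),
                         p[k], sizes[k] < low_power_min))
    return pd.DataFrame(rows, columns=["chrom", "category", "n_loci",
                                       "n_observed", "p_value", "low_power"])


def region_vs_background(table: pd.DataFrame, chrom, start, end
                         ) -> pd.DataFrame:
    """Two-sided Mann-Whitney U comparing posterior-median v and c inside a
    region against the genomic background (normal approximation with tie
    correction)."""
    inside = ((table["chrom"] == chrom) & (table["pos"] >= start)
              & (table["pos"] <= end)).to_numpy()
    if inside.sum() == 0:
        raise ValueError("region contains no fitted loci")
    if (~inside).sum() == 0:
        raise ValueError("background contains no fitted loci")
    rows = []
    for param in ("v_median", "c_median"):
        a = table.loc[inside, param].to_numpy()
        b = table.loc[~inside, param].to_numpy()
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        rows.append((param.split("_")[0], len(a), len(b),
                     float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["parameter", "n_region",
                                       "n_background", "U", "p_value"])


def select_cline_snps(variants: pd.DataFrame, maf: np.ndarray,
                      peaks: pd.DataFrame | None,
                      sig_snps: pd.DataFrame | None = None,
                      gene_intervals: pd.DataFrame | None = None,
                      maf_floor: float = 0.1, peak_subsample: float = 0.1,
                      dense_chroms=(), background_rate: float = 0.02,
                      bg_distance: int = 20_000, seed: int = 0) -> np.ndarray:
    """SNP selection scheme for cline fitting (peak + background union).

    Peak SNPs: inside any association-peak interval with MAF strictly above
    ``maf_floor``; on chromosomes listed in ``dense_chroms`` they are
    subsampled at ``peak_subsample``.  Background SNPs: MAF >= ``maf_floor``
    (inclusive), more than ``bg_distance`` bp from any significant SNP and
    outside every gene interval, sampled at ``background_rate`` per
    chromosome.  Sampled counts are floor(rate x count).  Returns sorted
    variant indices, deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    maf = np.asarray(maf, dtype=float)
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()

    in_peak = np.zeros(len(variants), dtype=bool)
    if peaks is not None and len(peaks):
        for _, pk in peaks.iterrows():
            in_peak |= ((chrom == pk["chrom"]) & (pos >= pk["min_bp"])
                        & (pos <= pk["max_bp"]))
    peak_sel = np.flatnonzero(in_peak & (maf > maf_floor))
    keep_peak = []
    for ch in np.unique(chrom[peak_sel]) if len(peak_sel) else []:
        idx = peak_sel[chrom[peak_sel] == ch]
        if ch in dense_chroms:
            k = int(np.floor(peak_subsample * len(idx)))
            idx = np.sort(rng.choice(idx, size=k, replace=False)) if k else idx[:0]
        keep_peak.append(idx)
    keep_peak = np.concatenate(keep_peak) if keep_peak else np.array([], int)

    near_sig = np.zeros(len(variants), dtype=bool)
    if sig_snps is not None and len(sig_snps):
        for ch in np.unique(sig_snps["chrom"]):
            sp = np.sort(sig_snps.loc[sig_snps["chrom"] == ch, "pos"].to_numpy())
            on = chrom == ch
            d_lo = pos[on] - sp[np.clip(np.searchsorted(sp, pos[on]) - 1,
                                        0, len(sp) - 1)]
            d_hi = sp[np.clip(np.searchsorted(sp, pos[on]), 0, len(sp) - 1)] - pos[on]
            near = np.minimum(np.abs(d_lo), np.abs(d_hi)) <= bg_distance
            near_sig[np.flatnonzero(on)[near]] = True
    in_gene = np.zeros(len(variants), dtype=bool)
    if gene_intervals is not None and len(gene_intervals):
        for _, g in gene_intervals.iterrows():
            in_gene |= ((chrom == g["chrom"]) & (pos >= g["start"])
                        & (pos <= g["end"]))

    bg_elig = np.flatnonzero((maf >= maf_floor) & ~near_sig & ~in_gene
                             & ~in_peak)
    keep_bg = []
    for ch in np.unique(chrom[bg_elig]) if len(bg_elig) else []:
        idx = bg_elig[chrom[bg_elig] == ch]
        k = int(np.floor(background_rate * len(idx)))
        if k:
            keep_bg.append(np.sort(rng.choice(idx, size=k, replace=False)))
    keep_bg = np.concatenate(keep_bg) if keep_bg else np.array([], int)

    union = np.unique(np.concatenate([keep_peak, keep_bg]))
    if len(union) == 0:
        raise ValueError("SNP selection produced an empty set")
    return union
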