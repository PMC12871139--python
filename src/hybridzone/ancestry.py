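"""Genome-wide hybrid index and diagnostic-marker ancestry summaries.

The hybrid index ``h`` is the proportion of an individual's genome inherited
from parent1.  Under the genome-average cline (v=1, u=0) each gene copy at
locus *i* carries the ALT allele with probability ``q_i(h) = h p1_i +
(1-h) p2_i`` and the genotype is Binomial(2, q_i(h)).  The per-sample
likelihood is one-dimensional and smooth, so the posterior under a flat prior
is summarised on a fine grid (deterministic; no MCMC needed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, xlogy

from .dataio import MISSING, GenotypeMatrix
from .popstats import ParentalAlleleFreqs


class HybridIndexModel:
    """Grid-posterior hybrid-index model.

    Parameters
    ----------
    gm : GenotypeMatrix
    freqs : ParentalAlleleFreqs
        Parental ALT frequencies at the same variants.
    afd_floor : float
        Loci with AFD below this are excluded as uninformative.
    grid_points : int
        Number of grid points on [0, 1] (default 1001).
    """

    def __init__(self, gm: GenotypeMatrix, freqs: ParentalAlleleFreqs,
                 afd_floor: float = 0.3, grid_points: int = 1001):
        self.gm = gm
        self.freqs = freqs
        self.afd_floor = afd_floor
        self.grid = np.linspace(0.0, 1.0, grid_points)
        self.informative = freqs.defined & (freqs.afd >= afd_floor)

    def fit(self, n_snps: int | None = 1000, seed: int = 0,
            samples=None, loci=None) -> "HybridIndexResults":
        """Maximum-likelihood h with a 95% equal-tail grid-posterior interval.

        ``n_snps`` informative loci are sampled without replacement with a
        fixed seed (None = use all); an explicit ``loci`` index array
        restricts the candidate set first (useful for keeping the
        hybrid-index loci disjoint from cline-fitting loci).  Missing
        genotypes are skipped.
        """
        if loci is None:
            loci = np.flatnonzero(self.informative)
        else:
            loci = np.asarray(loci, dtype=int)
            loci = loci[self.informative[loci]]
        if len(loci) == 0:
            raise ValueError("no informative loci above the AFD floor")
        if n_snps is not None and n_snps < len(loci):
            rng = np.random.default_rng(seed)
            loci = np.sort(rng.choice(loci, size=n_snps, replace=False))
        p1 = self.freqs.p1[loci]
        p2 = self.freqs.p2[loci]
        h = self.grid[:, None]
        q = np.clip(h * p1[None, :] + (1 - h) * p2[None, :], 0.0, 1.0)

        ids = samples if samples is not None else self.gm.samples
        idx = self.gm.sample_indices(ids)
        rows = []
        for sid, i in zip(ids, idx):
            g = self.gm.dosage[i, loci].astype(float)
            ok = g != MISSING
            if not ok.any():
                raise ValueError(f"sample {sid}: zero informative non-missing loci")
            gg = g[ok]
            # xlogy(0, 0) -> 0, so boundary h values are handled exactly
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = (xlogy(gg, q[:, ok])
                      + xlogy(2 - gg, 1.0 - q[:, ok])).sum(axis=1)
            post = ll - logsumexp(ll)
            cdf = np.cumsum(np.exp(post))
            cdf /= cdf[-1]
            h_hat = self.grid[int(np.argmax(ll))]
            lo = self.grid[int(np.searchsorted(cdf, 0.025))]
            hi = self.grid[int(np.searchsorted(cdf, 0.975))]
            rows.append((sid, h_hat, min(lo, h_hat), max(hi, h_hat),
                         int(ok.sum())))
        df = pd.DataFrame(rows, columns=["sample", "h_hat", "ci_low",
                                         "ci_high", "n_loci"])
        return HybridIndexResults(self, df, loci)


@dataclass
class HybridIndexResults:
    """Per-individual hybrid-index estimates with 95% credible intervals."""

    model: HybridIndexModel
    estimates: pd.DataFrame  # sample, h_hat, ci_low, ci_high, n_loci
    loci_used: np.ndarray

    def summary(self) -> str:
        df = self.estimates
        lines = ["Hybrid index estimates (grid posterior, flat prior)",
                 f"  samples: {len(df)}   loci used: {len(self.loci_used)}",
                 f"  mean h_hat: {df['h_hat'].mean():.3f}   "
                 f"median CI width: {(df['ci_high'] - df['ci_low']).median():.3f}"]
        return "\n".join(lines)

    def h_series(self) -> pd.Series:
        return self.estimates.set_index("sample")["h_hat"]

    def designate_parents(self, threshold: float = 0.99999) -> pd.DataFrame:
        return designate_parents(self.h_series(), threshold)


def designate_parents(admixture: pd.Series, threshold: float = 0.99999
                      ) -> pd.DataFrame:
    """Label samples parent1/parent2/hybrid from admixture proportions.

    ``h > threshold`` -> parent1 (the parent whose ancestry h measures),
    ``h < 1 - threshold`` -> parent2, otherwise hybrid.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    h = pd.Series(admixture)
    group = np.where(h > threshold, "parent1",
                     np.where(h < 1.0 - threshold, "parent2", "hybrid"))
    return pd.DataFrame({"sample": h.index, "group": group,
                         "admixture": h.to_numpy()})


def ancestry_triangle(gm: GenotypeMatrix, freqs: ParentalAlleleFreqs,
                      afd_threshold: float = 1.0, samples=None) -> pd.DataFrame:
    """Diagnostic-marker ancestry-class proportions per sample.

    At loci with AFD >= threshold, alleles are oriented to the parent in
    which they are at higher frequency; each genotype maps to homozygous-
    parent1 / heterozygous / homozygous-parent2 and proportions are taken
    over non-missing loci.
    """
    mask = freqs.defined & (freqs.afd >= afd_threshold - 1e-12)
    if not mask.any():
        raise ValueError("no loci pass the AFD threshold")
    cols = np.flatnonzero(mask)
    flip = freqs.p1[cols] < freqs.p2[cols]  # ALT is the parent2 allele
    ids = samples if samples is not None else gm.samples
    idx = gm.sample_indices(ids)
    d = gm.dosage[np.ix_(idx, cols)].astype(float)
    d[d == MISSING] = np.nan
    anc = np.where(flip[None, :], 2.0 - d, d)  # parent1-allele count
    n = np.sum(~np.isnan(anc), axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        hom1 = np.nansum(anc == 2, axis=1) / np.maximum(n, 1)
        het = np.nansum(anc == 1, axis=1) / np.maximum(n, 1)
        hom2 = np.nansum(anc == 0, axis=1) / np.maximum(n, 1)
    return pd.DataFrame({"sample": ids, "prop_hom_p1": hom1, "prop_het": het,
                         "prop_hom_p2": hom2, "n_loci": n.astype(int)})
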