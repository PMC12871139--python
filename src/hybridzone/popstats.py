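"""Allele-frequency summaries, windowed divergence landscape and the
heterozygosity-excess scan.

All windowed statistics are ratio-of-sums within non-overlapping, tiling
windows (pixy-style): per-site numerators are summed and divided by the count
of sites genotyped in the relevant group(s), so genotyped invariant sites
contribute 0 to the numerator and 1 to the denominator.  FST is the Hudson
estimator with the sample-size-corrected numerator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeMatrix


@dataclass
class ParentalAlleleFreqs:
    """Per-variant parental ALT frequencies and allele-frequency differences.

    ``p1``/``p2`` are NaN where a group has zero genotyped alleles (flagged,
    never silently 0); ``afd = |p1 - p2|``.
    """

    p1: np.ndarray
    p2: np.ndarray
    n1: np.ndarray  # genotyped allele counts (2 x individuals)
    n2: np.ndarray

    @property
    def afd(self) -> np.ndarray:
        return np.abs(self.p1 - self.p2)

    @property
    def defined(self) -> np.ndarray:
        return (self.n1 > 0) & (self.n2 > 0)


def _group_counts(gm: GenotypeMatrix, idx: np.ndarray):
    """ALT-allele count and genotyped-allele count per variant for a sample set."""
    d = gm.dosage[idx]
    called = d != MISSING
    alt = np.where(called, d, 0).sum(axis=0).astype(float)
    n = 2.0 * called.sum(axis=0)
    return alt, n


def allele_freqs(gm: GenotypeMatrix, groups: pd.DataFrame,
                 labels=("parent1", "parent2")) -> ParentalAlleleFreqs:
    """ALT frequency per group: (ALT dosage sum) / (2 x genotyped individuals)."""
    out = []
    for lab in labels:
        ids = groups.loc[groups["group"] == lab, "sample"]
        if len(ids) == 0:
            raise ValueError(f"group {lab!r} absent from sample table")
        alt, n = _group_counts(gm, gm.sample_indices(ids))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        out.append((p, n))
    (p1, n1), (p2, n2) = out
    return ParentalAlleleFreqs(p1=p1, p2=p2, n1=n1, n2=n2)


def _pairwise_within(alt, n):
    """Per-site mean pairwise difference among allele copies within a group."""
    with np.errstate(invalid="ignore", divide="ignore"):
        num = 2.0 * alt * (n - alt)
        den = n * (n - 1.0)
        return np.where(n >= 2, num / np.maximum(den, 1), np.nan)


def _pairwise_between(alt1, n1, alt2, n2):
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / np.maximum(n1, 1)
        p2 = alt2 / np.maximum(n2, 1)
        ok = (n1 >= 1) & (n2 >= 1)
        return np.where(ok, p1 * (1 - p2) + p2 * (1 - p1), np.nan)


def _hudson_components(alt1, n1, alt2, n2):
    """Hudson FST per-site numerator/denominator with sample-size correction."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / np.maximum(n1, 1)
        p2 = alt2 / np.maximum(n2, 1)
        ok = (n1 >= 2) & (n2 >= 2)
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
               - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return np.where(ok, num, np.nan), np.where(ok, den, np.nan)


def _window_index(variants: pd.DataFrame, window_bp: int):
    """(chrom, window start) per variant; windows are 1-based [start, start+W-1]."""
    start = ((variants["pos"].to_numpy() - 1) // window_bp) * window_bp + 1
    return variants["chrom"].to_numpy(), start


def windowed_stats(gm: GenotypeMatrix, groups: pd.DataFrame, window_bp: int,
                   labels=("parent1", "parent2"), warn_not_allsites=True
                   ) -> pd.DataFrame:
    """Windowed pi (per group), dxy and Hudson FST, ratio-of-sums.

    Returns a wide table with columns ``chrom, start, end, n_sites, pi_p1,
    pi_p2, dxy, fst``.  Windows with zero valid sites for a statistic carry
    NaN for it.
    """
    if warn_not_allsites and not gm.all_sites:
        import warnings
        warnings.warn("variant-only matrix: pi/dxy denominators lack invariant "
                      "sites and will be upwardly biased", stacklevel=2)
    idx = [gm.sample_indices(groups.loc[groups["group"] == lab, "sample"])
           for lab in labels]
    for lab, i in zip(labels, idx):
        if len(i) == 0:
            raise ValueError(f"group {lab!r} absent from sample table")
    alt1, n1 = _group_counts(gm, idx[0])
    alt2, n2 = _group_counts(gm, idx[1])

    pi1 = _pairwise_within(alt1, n1)
    pi2 = _pairwise_within(alt2, n2)
    dxy = _pairwise_between(alt1, n1, alt2, n2)
    fnum, fden = _hudson_components(alt1, n1, alt2, n2)

    chrom, start = _window_index(gm.variants, window_bp)
    df = pd.DataFrame({
        "chrom": chrom, "start": start,
        "pi1_num": pi1, "pi1_den": (~np.isnan(pi1)).astype(float),
        "pi2_num": pi2, "pi2_den": (~np.isnan(pi2)).astype(float),
        "dxy_num": dxy, "dxy_den": (~np.isnan(dxy)).astype(float),
        "fst_num": fnum, "fst_den": fden,
        "valid": (~np.isnan(dxy)).astype(float),
    })
    agg = df.groupby(["chrom", "start"], sort=True).sum(min_count=1).reset_index()

    def ratio(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)

    out = pd.DataFrame({
        "chrom": agg["chrom"],
        "start": agg["start"].astype(np.int64),
        "end": (agg["start"] + window_bp - 1).astype(np.int64),
        "n_sites": agg["valid"].fillna(0).astype(np.int64),
        "pi_p1": ratio(agg["pi1_num"].to_numpy(), agg["pi1_den"].to_numpy()),
        "pi_p2": ratio(agg["pi2_num"].to_numpy(), agg["pi2_den"].to_numpy()),
        "dxy": ratio(agg["dxy_num"].to_numpy(), agg["dxy_den"].to_numpy()),
        "fst": ratio(agg["fst_num"].to_numpy(), agg["fst_den"].to_numpy()),
    })
    return out


def rolling_smooth(stats: pd.DataFrame, k: int, value_cols=None) -> pd.DataFrame:
    """Centered rolling mean over k consecutive windows within a chromosome.

    Missing windows are excluded from the local mean; edge windows use the
    available neighbours (shrink-to-available).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if value_cols is None:
        value_cols = [c for c in stats.columns
                      if c not in ("chrom", "start", "end", "n_sites")]
    out = stats.copy()
    for col in value_cols:
        out[col] = (stats.groupby("chrom", sort=False)[col]
                    .transform(lambda s: s.rolling(k, center=True,
                                                   min_periods=1).mean()))
    return out


def het_excess_scan(gm: GenotypeMatrix, groups: pd.DataFrame,
                    admix: pd.Series | dict, admix_range=(0.25, 0.75),
                    afd_threshold: float = 1.0,
                    freqs: ParentalAlleleFreqs | None = None) -> pd.DataFrame:
    """Heterozygosity excess H_excess = P(Ho) - P(He) at near-diagnostic SNPs.

    Retains hybrids with admixture proportion inside ``admix_range``
    (bounds inclusive) and SNPs with parental AFD >= ``afd_threshold``
    (default 1.0 = fixed differences).  P(He) = 2q(1-q) with q the ALT
    frequency in the retained hybrid subset.
    """
    if freqs is None:
        freqs = allele_freqs(gm, groups)
    admix = pd.Series(admix)
    hybrids = groups.loc[groups["group"] == "hybrid", "sample"]
    keep = [s for s in hybrids
            if s in admix.index and admix_range[0] <= admix[s] <= admix_range[1]]
    if not keep:
        raise ValueError(
            f"no hybrid passes the admixture filter {admix_range}")
    snp_mask = freqs.defined & (freqs.afd >= afd_threshold - 1e-12)
    idx = gm.sample_indices(keep)
    d = gm.dosage[np.ix_(idx, np.flatnonzero(snp_mask))]
    called = d != MISSING
    n_called = called.sum(axis=0).astype(float)
    het = (d == 1).sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_obs = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
        q = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan)
    p_exp = 2.0 * q * (1.0 - q)
    var = gm.variants.loc[snp_mask, ["chrom", "pos"]].reset_index(drop=True)
    return var.assign(n_hybrids=n_called.astype(int), p_obs_het=p_obs,
                      p_exp_het=p_exp, h_excess=p_obs - p_exp)
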