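"""Synthetic hybrid-zone generator with known truth.

Emulates a two-species contact zone sampled along an elevational gradient:
two parental gene pools with a spectrum of allele-frequency differences
(including fixed differences), hybrids whose genome-wide ancestry follows a
logistic function of elevation, per-locus introgression controlled by known
logit-logistic cline parameters (v, c), a major-effect floral-hue locus plus
polygenic trait background, and hue-parameterised reflectance spectra.

Conventions
-----------
* ``h`` is the proportion of ancestry from parent1 (the high-elevation
  species); parent1 individuals have ``h = 1``.
* The probability a gene copy at locus *i* in hybrid *j* derives from parent1
  is the cline function ``phi(h_j; v_i, u_i)`` with ``logit(c) = u/v``.
* The two copies at a locus are conditionally independent given ``h``
  (no linkage); admixture LD is deliberately not simulated.
* All randomness flows through a single ``numpy`` generator seeded once; the
  draw order is: parental frequencies, positions, elevations, hybrid indices,
  hybrid ancestry copies, hybrid alleles, parent alleles, missingness,
  phenotypes.  A fixed seed therefore reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dataio import MISSING, GenotypeMatrix


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ClineBlock:
    """A contiguous run of loci sharing true cline parameters.

    Block loci are simulated as fixed differences (AFD = 1) so their cline
    behaviour is directly visible in genotypes.  ``force_het`` builds each
    hybrid's two gene copies from opposite parents (one parent1-derived, one
    parent2-derived), the construction used for the heterozygosity-excess
    block.
    """

    name: str
    chrom: int
    start_locus: int
    n_loci: int
    v: float
    c: float = 0.5
    force_het: bool = False

    @property
    def u(self) -> float:
        return self.v * logit(self.c)


def default_architecture() -> list[ClineBlock]:
    return [
        ClineBlock("steep_block", chrom=1, start_locus=40, n_loci=40, v=3.0),
        ClineBlock("shallow_block", chrom=2, start_locus=40, n_loci=40, v=0.3),
        ClineBlock("het_excess_block", chrom=2, start_locus=90, n_loci=5,
                   v=0.3, force_het=True),
        ClineBlock("hue_locus", chrom=0, start_locus=100, n_loci=1,
                   v=0.3, c=0.35),
    ]


@dataclass(frozen=True)
class SpectraParams:
    """Reflectance = baseline + amplitude * hue-weighted mixture of Gaussian bands.

    The two default bands sit in the blue (450 nm) and red (650 nm); their
    relative weights vary smoothly with the floral hue in degrees so that
    bluer flowers (hue near 360) reflect mostly in the blue band.
    """

    band_centers: tuple = (450.0, 650.0)
    band_widths: tuple = (35.0, 45.0)
    band_weights: tuple = (1.0, 1.0)
    amplitude: float = 0.6
    baseline: float = 0.02
    hue_low: float = 270.0   # reddest simulated hue -> all weight on band 2
    hue_high: float = 360.0  # bluest -> all weight on band 1
    wl_min: float = 300.0
    wl_max: float = 800.0
    wl_step: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    n_parent1: int = 40
    n_parent2: int = 30
    n_hybrids: int = 200
    n_chromosomes: int = 5
    loci_per_chromosome: int = 200
    chromosome_length_bp: int = 20_000_000
    fraction_fixed_diff: float = 0.5
    fraction_high_afd: float = 0.2
    cline_architecture: tuple = field(default_factory=lambda: tuple(default_architecture()))
    elevation_range: tuple = (2600.0, 3400.0)
    elevation_midpoint: float = 3000.0
    elevation_slope: float = 8.0  # logistic slope on elevation scaled to [0,1]
    h_concentration: float = 30.0  # Beta jitter concentration around the logistic mean
    hue_genotype_means: tuple = (300.0, 320.0, 340.0)  # by parent1-allele count
    hue_sd: float = 4.0
    polygenic_trait_specs: dict = field(default_factory=lambda: {
        "tube_length_mm": (18.0, 6.0, 0.8),     # (intercept, slope on h, sd)
        "stamen_exsertion_mm": (4.0, -3.5, 0.5),
        "nectary_area_mm2": (1.2, 0.8, 0.15),
    })
    spectra_params: SpectraParams = field(default_factory=SpectraParams)
    missing_rate: float = 0.01
    seed: int = 20260920

    def validate(self) -> None:
        for name in ("n_parent1", "n_parent2", "n_hybrids", "n_chromosomes",
                     "loci_per_chromosome", "chromosome_length_bp"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("fraction_fixed_diff", "fraction_high_afd", "missing_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must lie in [0,1]")
        if self.fraction_fixed_diff + self.fraction_high_afd > 1.0 + 1e-12:
            raise ConfigError("fraction_fixed_diff + fraction_high_afd > 1")
        if self.elevation_range[0] >= self.elevation_range[1]:
            raise ConfigError("elevation_range must be (min, max) with min < max")
        n_loci = self.n_chromosomes * self.loci_per_chromosome
        for b in self.cline_architecture:
            if b.v <= 0 or not 0 < b.c < 1:
                raise ConfigError(f"block {b.name}: need v > 0 and c in (0,1)")
            if b.chrom >= self.n_chromosomes or \
                    b.start_locus + b.n_loci > self.loci_per_chromosome:
                raise ConfigError(f"block {b.name} outside the simulated genome")
        n_fixed = int(round(self.fraction_fixed_diff * n_loci))
        if n_fixed < sum(b.n_loci for b in self.cline_architecture):
            raise ConfigError("fixed-difference budget smaller than architecture blocks")

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    def block_loci(self, block: ClineBlock) -> np.ndarray:
        start = block.chrom * self.loci_per_chromosome + block.start_locus
        return np.arange(start, start + block.n_loci)


@dataclass
class SimTruth:
    """Generative parameters of a simulated zone, for recovery tests."""

    loci: pd.DataFrame        # chrom, pos, p1, p2, v_true, u_true, c_true, force_het
    individuals: pd.DataFrame  # sample, group, elevation_m, h_true
    trait_specs: dict
    hue_genotype_means: tuple
    hue_sd: float


def simulate_parental_frequencies(config: SimConfig, rng=None):
    """Per-locus parental ALT frequencies (p1, p2) with exact AFD-class counts.

    ``round(fraction_fixed_diff * n_loci)`` loci are fixed differences
    (AFD = 1), ``round(fraction_high_afd * n_loci)`` are diagnostic
    (AFD uniform on [0.75, 1)), and the remainder low-AFD (AFD uniform on
    [0, 0.5)); REF/ALT orientation is randomised.  Architecture-block loci
    always fall in the fixed class.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.n_loci
    n_fixed = int(round(config.fraction_fixed_diff * L))
    n_high = int(round(config.fraction_high_afd * L))
    block_idx = np.unique(np.concatenate(
        [config.block_loci(b) for b in config.cline_architecture]
    )) if config.cline_architecture else np.array([], dtype=int)

    classes = np.zeros(L, dtype=int)  # 0 low, 1 high, 2 fixed
    classes[block_idx] = 2
    free = np.setdiff1d(np.arange(L), block_idx)
    free = rng.permutation(free)
    n_fixed_left = n_fixed - len(block_idx)
    classes[free[:n_fixed_left]] = 2
    classes[free[n_fixed_left:n_fixed_left + n_high]] = 1

    afd = np.empty(L)
    afd[classes == 2] = 1.0
    afd[classes == 1] = rng.uniform(0.75, 1.0, size=(classes == 1).sum())
    afd[classes == 0] = rng.uniform(0.0, 0.5, size=(classes == 0).sum())
    lo = afd / 2.0
    mid = rng.uniform(lo, 1.0 - lo)
    p1 = mid + afd / 2.0
    p2 = mid - afd / 2.0
    flip = rng.random(L) < 0.5  # orient ALT to parent2 at random loci
    p1[flip], p2[flip] = p2[flip], p1[flip]
    return np.clip(p1, 0, 1), np.clip(p2, 0, 1)


def _positions(config: SimConfig, rng) -> pd.DataFrame:
    chroms, poss = [], []
    for k in range(config.n_chromosomes):
        name = f"chr{k + 1:02d}"
        pos = np.array([], dtype=np.int64)
        while len(pos) < config.loci_per_chromosome:  # reject duplicates
            extra = rng.integers(1, config.chromosome_length_bp + 1,
                                 size=config.loci_per_chromosome - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.extend([name] * config.loci_per_chromosome)
        poss.append(np.sort(pos)[: config.loci_per_chromosome])
    return pd.DataFrame({"chrom": chroms, "pos": np.concatenate(poss)})


def cline_params_per_locus(config: SimConfig):
    """(v_true, c_true, force_het) arrays; background loci have v=1, c=0.5."""
    v = np.ones(config.n_loci)
    c = np.full(config.n_loci, 0.5)
    fh = np.zeros(config.n_loci, dtype=bool)
    for b in config.cline_architecture:
        idx = config.block_loci(b)
        v[idx] = b.v
        c[idx] = b.c
        fh[idx] = b.force_het
    return v, c, fh


def simulate_hybrid_zone(config: SimConfig):
    """Simulate genotypes, truth and metadata for a full zone.

    Returns ``(GenotypeMatrix, SimTruth, metadata DataFrame)``.  The returned
    truth also carries the pre-missingness genotype matrix used for phenotype
    generation (attribute ``_true_dosage``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p1, p2 = simulate_parental_frequencies(config, rng)
    loci = _positions(config, rng)
    v_true, c_true, force_het = cline_params_per_locus(config)
    u_true = v_true * logit(c_true)
    loci = loci.assign(p1=p1, p2=p2, v_true=v_true, u_true=u_true,
                       c_true=c_true, force_het=force_het)

    elo, ehi = config.elevation_range
    span = ehi - elo
    n1, n2, nh = config.n_parent1, config.n_parent2, config.n_hybrids
    elev_p1 = rng.uniform(ehi - 0.1 * span, ehi, size=n1)
    elev_p2 = rng.uniform(elo, elo + 0.1 * span, size=n2)
    elev_h = rng.uniform(elo, ehi, size=nh)
    mu = expit(config.elevation_slope * (elev_h - config.elevation_midpoint) / span)
    kappa = config.h_concentration
    h_hyb = rng.beta(np.clip(mu * kappa, 1e-3, None),
                     np.clip((1 - mu) * kappa, 1e-3, None))
    h_hyb = np.clip(h_hyb, 1e-6, 1 - 1e-6)

    samples = ([f"P1_{i:03d}" for i in range(n1)]
               + [f"P2_{i:03d}" for i in range(n2)]
               + [f"HYB_{i:03d}" for i in range(nh)])
    group = ["parent1"] * n1 + ["parent2"] * n2 + ["hybrid"] * nh
    elevation = np.concatenate([elev_p1, elev_p2, elev_h])
    h_true = np.concatenate([np.ones(n1), np.zeros(n2), h_hyb])

    L = config.n_loci
    # hybrid copies: parent-1 ancestry with probability phi(h; v, u)
    lh = logit(h_hyb)[:, None]  # (nh, 1)
    phi = expit(v_true[None, :] * lh - u_true[None, :])  # (nh, L)
    anc1 = rng.random((nh, L)) < phi
    anc2 = rng.random((nh, L)) < phi
    if force_het.any():
        anc1[:, force_het] = True
        anc2[:, force_het] = False
    freq1 = np.where(anc1, p1[None, :], p2[None, :])
    freq2 = np.where(anc2, p1[None, :], p2[None, :])
    g_hyb = ((rng.random((nh, L)) < freq1).astype(np.int8)
             + (rng.random((nh, L)) < freq2).astype(np.int8))
    g_p1 = ((rng.random((n1, L)) < p1).astype(np.int8)
            + (rng.random((n1, L)) < p1).astype(np.int8))
    g_p2 = ((rng.random((n2, L)) < p2).astype(np.int8)
            + (rng.random((n2, L)) < p2).astype(np.int8))
    dosage_true = np.vstack([g_p1, g_p2, g_hyb])

    dosage = dosage_true.copy()
    if config.missing_rate > 0:
        dosage[rng.random(dosage.shape) < config.missing_rate] = MISSING

    ref = np.full(L, "A")
    alt = np.full(L, "G")
    variants = loci[["chrom", "pos"]].assign(ref=ref, alt=alt)
    gm = GenotypeMatrix(samples, variants.reset_index(drop=True), dosage)
    meta = pd.DataFrame({"sample": samples, "group": group,
                         "elevation_m": np.round(elevation, 1)})
    truth = SimTruth(loci=loci,
                     individuals=meta.assign(h_true=h_true),
                     trait_specs=dict(config.polygenic_trait_specs),
                     hue_genotype_means=config.hue_genotype_means,
                     hue_sd=config.hue_sd)
    truth._true_dosage = dosage_true  # pre-missingness, for phenotype generation
    truth._rng = rng  # continue the documented draw order for phenotypes
    return gm, truth, meta


def hue_locus_index(config: SimConfig) -> int:
    for b in config.cline_architecture:
        if b.name == "hue_locus":
            return int(config.block_loci(b)[0])
    raise ConfigError("no 'hue_locus' block in the architecture")


def simulate_phenotypes(truth: SimTruth, genotypes: np.ndarray,
                        hue_locus: int, rng=None) -> pd.DataFrame:
    """Trait table: major-locus hue plus polygenic traits linear in h_true.

    ``genotypes`` is a (samples x loci) dosage array (no missingness expected at
    the hue locus); the hue genotype class is the parent1-allele count at the
    major locus, obtained by orienting the ALT dosage to parent1.
    """
    if rng is None:
        rng = getattr(truth, "_rng", None) or np.random.default_rng(0)
    loci = truth.loci
    dose = np.asarray(genotypes[:, hue_locus], dtype=float)
    if loci["p1"].iloc[hue_locus] < loci["p2"].iloc[hue_locus]:
        dose = 2.0 - dose  # orient to parent1 allele
    means = np.asarray(truth.hue_genotype_means)
    hue = means[dose.astype(int)] + rng.normal(0.0, truth.hue_sd, size=len(dose))
    h = truth.individuals["h_true"].to_numpy()
    out = {"sample": truth.individuals["sample"].to_numpy(),
           "floral_hue_deg": hue}
    for name, (a, b, sd) in truth.trait_specs.items():
        out[name] = a + b * h + rng.normal(0.0, sd, size=len(h))
    return pd.DataFrame(out)


def simulate_reflectance(hue_deg: float, params: SpectraParams = SpectraParams()):
    """Reflectance on the configured wavelength grid for one floral hue.

    A mixture of Gaussian bands whose relative weights vary smoothly
    (linearly) with hue: at ``hue_low`` all weight sits on the last (red)
    band, at ``hue_high`` on the first (blue) band.  Values are clipped to
    [0, 1].  Deterministic: identical inputs give identical arrays.
    """
    wl = np.arange(params.wl_min, params.wl_max + params.wl_step / 2,
                   params.wl_step)
    t = np.clip((hue_deg - params.hue_low) / (params.hue_high - params.hue_low),
                0.0, 1.0)
    mix = np.array([t, 1.0 - t]) if len(params.band_centers) == 2 else \
        np.full(len(params.band_centers), 1.0 / len(params.band_centers))
    refl = np.full_like(wl, float(params.baseline))
    for w_hue, w_cfg, c, s in zip(mix, params.band_weights,
                                  params.band_centers, params.band_widths):
        refl = refl + params.amplitude * w_hue * w_cfg * np.exp(-((wl - c) / s) ** 2)
    return wl, np.clip(refl, 0.0, 1.0)


def simulate_spectra(traits: pd.DataFrame, params: SpectraParams) -> pd.DataFrame:
    """Spectra table (wavelength column + one column per sample) from hues."""
    cols = {}
    wl = None
    for _, row in traits.iterrows():
        wl, refl = simulate_reflectance(row["floral_hue_deg"], params)
        cols[row["sample"]] = refl
    return pd.DataFrame({"wavelength": wl, **cols})


@dataclass
class SimBundle:
    config: SimConfig
    genotypes: GenotypeMatrix
    truth: SimTruth
    metadata: pd.DataFrame
    traits: pd.DataFrame
    spectra: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Full bundle: genotypes + metadata + traits + spectra, one seed."""
    gm, truth, meta = simulate_hybrid_zone(config)
    traits = simulate_phenotypes(truth, truth._true_dosage,
                                 hue_locus_index(config))
    spectra = simulate_spectra(traits, config.spectra_params)
    return SimBundle(config, gm, truth, meta, traits, spectra)


def write_bundle(bundle: SimBundle, outdir) -> list[str]:
    """Write VCF, metadata TSV, traits CSV, spectra CSV and truth TSVs."""
    import os

    from .dataio import write_vcf

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    paths["genotypes.vcf"] = os.path.join(outdir, "genotypes.vcf")
    write_vcf(bundle.genotypes, paths["genotypes.vcf"])
    paths["samples.tsv"] = os.path.join(outdir, "samples.tsv")
    bundle.metadata.to_csv(paths["samples.tsv"], sep="\t", index=False)
    paths["traits.csv"] = os.path.join(outdir, "traits.csv")
    bundle.traits.to_csv(paths["traits.csv"], index=False, float_format="%.6g")
    paths["spectra.csv"] = os.path.join(outdir, "spectra.csv")
    bundle.spectra.to_csv(paths["spectra.csv"], index=False, float_format="%.6g")
    paths["truth_loci.tsv"] = os.path.join(outdir, "truth_loci.tsv")
    bundle.truth.loci.to_csv(paths["truth_loci.tsv"], sep="\t", index=False,
                             float_format="%.10g")
    paths["truth_individuals.tsv"] = os.path.join(outdir, "truth_individuals.tsv")
    bundle.truth.individuals.to_csv(paths["truth_individuals.tsv"], sep="\t",
                                    index=False, float_format="%.10g")
    return sorted(paths.values())
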