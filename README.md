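# hybridzone

Genomic analysis of hybrid zones: who is admixed, which loci resist
introgression, and whether the loci that build a conspicuous phenotype are
the same loci that act as barriers to gene flow.

The package was built around the analysis of a long-standing elevational
hybrid zone between two wildflowers with divergent pollination syndromes
(a bee-pollinated, blue-flowered high-elevation species and a
hummingbird-pollinated, magenta-flowered low-elevation species).  It
provides, as one coherent toolkit:

- a **synthetic hybrid-zone generator** with known truth (parental allele
  frequencies, per-locus cline parameters, elevation-structured hybrid
  indices, a major-effect floral-hue locus, hue-parameterised reflectance
  spectra),
- **hybrid-index estimation** from ancestry-informative SNPs,
- **hierarchical Bayesian genomic cline inference** with steep / shallow /
  neutral outlier classification, window summaries, per-chromosome
  permutation enrichment and region-vs-background rank tests,
- **divergence landscapes** (windowed π, d<sub>xy</sub>, Hudson F<sub>ST</sub>,
  pixy-style ratio-of-sums) and a **heterozygosity-excess scan**,
- a **trait-association scan** with permutation-derived genome-wide
  significance thresholds, peak calling and peak-to-gene reporting,
- **pollinator visual models** (quantum catches, receptor-noise JNDs for
  trichromatic bee and tetrachromatic bird viewers, the bee colour hexagon)
  and segment-classification colour metrics.

## The model at the core

Let *h<sub>j</sub>* ∈ [0, 1] be the hybrid index of individual *j* — the
proportion of its genome inherited from parent 1.  The probability that a
gene copy at locus *i* derives from parent-1 ancestry follows the
logit-logistic genomic cline

&nbsp;&nbsp;&nbsp;&nbsp;φ<sub>ij</sub> = h<sub>j</sub><sup>v<sub>i</sub></sup> / ( h<sub>j</sub><sup>v<sub>i</sub></sup> + (1 − h<sub>j</sub>)<sup>v<sub>i</sub></sup> e<sup>u<sub>i</sub></sup> ),
&nbsp;&nbsp;equivalently&nbsp;&nbsp;logit(φ) = v·logit(h) − u,

where *v<sub>i</sub>* > 0 is the cline slope relative to the genome-wide
average (*v* = 1) and the center *c<sub>i</sub>* — the hybrid index at which
φ = 0.5 — satisfies logit(*c*) = *u*/*v*.  Loci with credibly *v* > 1
("steep" clines) resist introgression and are candidate barrier loci; loci
with credibly *v* < 1 ("shallow") are unusually permissive.  Genotypes enter
through *g<sub>ij</sub>* ~ Binomial(2, q) with
q = φ<sub>ij</sub>·p1<sub>i</sub> + (1 − φ<sub>ij</sub>)·p2<sub>i</sub>, the
parental allele-frequency mixture, so non-fixed loci are handled without
ancestry calls.  Estimation is two-stage, as in hierarchical Bayesian cline
practice: per-locus (log *v*, logit *c*) receive Normal(0, σ) priors whose
SDs are first estimated jointly (half-Normal(0, 1) hyperpriors) and then
plugged in as point estimates for per-locus MCMC; hybrid indices are
likewise plugged in as point estimates.

## Worked example

```python
from hybridzone import (SimConfig, simulate_dataset, allele_freqs,
                        HybridIndexModel, GenomicClineModel, MCMCConfig)

cfg = SimConfig(seed=7)          # default hybrid zone: 270 samples, 1,000 loci
bundle = simulate_dataset(cfg)
gm, meta = bundle.genotypes, bundle.metadata

freqs = allele_freqs(gm, meta)
hyb = meta.loc[meta.group == "hybrid", "sample"]
hi = HybridIndexModel(gm, freqs).fit(n_snps=1000, seed=7, samples=list(hyb))
print(hi.summary())

model = GenomicClineModel(gm, freqs, hi.h_series())
mcmc = MCMCConfig(iterations=4000, burnin=2000, chains=2, seed=7)
sds = model.fit_sds(n_snps=300, mcmc=mcmc)
results = model.fit(sds, mcmc=mcmc)
print(results.summary())
enr = results.chromosome_enrichment(n_perm=999, seed=7)
print(enr[enr.p_value < 0.05].to_string(index=False))
```

prints

```
Hybrid index estimates (grid posterior, flat prior)
  samples: 200   loci used: 810
  mean h_hat: 0.451   median CI width: 0.039
Genomic cline fit (two-stage hierarchical Bayesian model)
  loci fitted: 810
  hierarchical SDs: sd_logv=0.422  sd_logitc=0.037
  steep   :    109  (13.5%)
  shallow :     59  (7.28%)
  neutral :    642  (79.3%)
  converged loci: 698 / 810
chrom category  n_loci  n_observed  p_value  low_power
chr02    steep     169          51    0.001      False
chr03  shallow     167          48    0.001      False
```

Reading the output: the 200 hybrids span the full ancestry range with tight
(~0.04-wide) credible intervals; 13.5% of loci have credibly steep clines
and 7.3% credibly shallow ones; and the permutation test flags exactly the
two chromosomes the generator built that way — chr02 carries the simulated
barrier ("steep") block and chr03 the permissive ("shallow") block, each
enriched at the smallest possible empirical p (0.001 with 999 permutations).

A shell pipeline over the same stages (plus divergence windows,
heterozygosity excess, GWAS-style association and colour metrics) is
available as a console script:

```bash
hybridzone simulate --seed 7 --out zone/
hybridzone pipeline --config pipeline.yaml --out results/
```

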