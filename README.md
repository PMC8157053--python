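# mtgibbs

Bayesian multi-trait pedigree animal models via Gibbs sampling, for
quantitative geneticists estimating genetic parameters of livestock traits.
The motivating application is Korean beef cattle (Hanwoo), where carcass
traits — backfat thickness (BFT), carcass weight (CW), eye-muscle area
(EMA) and marbling score (MS) — can only be measured at slaughter, while
live-animal ultrasound measurements (UBFT, UEMA, UIMF) and yearling weight
(YW) are available on selection candidates.  Whether ultrasound data are
useful selection criteria is a question about heritabilities and genetic
correlations, which this package estimates.

## Model

The multi-trait animal model is

```
y = Xb + Zu + e,    Var(u) = G ⊗ A,    Var(e) = R ⊗ I
```

with trait-specific fixed effects `b` (contemporary groups, age
covariates), additive-genetic effects `u` for every pedigree animal,
the numerator relationship matrix `A` built from the pedigree, and
unstructured k×k covariance matrices `G` (genetic) and `R` (residual).
A Gibbs sampler (single-site fixed effects, per-animal trait blocks for
`u`, missing-trait data augmentation, inverse-Wishart updates for `G` and
`R`) yields posterior draws, from which the package reports

- σa², σe², σp² = σa² + σe² and h² = σa²/σp² per trait,
- genetic correlations r_g = G_ij/√(G_ii G_jj) and phenotypic correlations
  r_p = (G_ij + R_ij)/√(σp²_i σp²_j) per trait pair,

each as posterior mean (SD), computed per retained sample and then
averaged.  See `docs/methods.md` for algorithms, priors and caveats.

The package includes a synthetic-data generator whose default parameters
are the published Hanwoo posterior estimates, so the whole pipeline is
testable end to end without access to the original station data: pedigrees
with discrete generations, breeding values generated by the pedigree
recursion (exactly `G ⊗ A`), class-based missingness (carcass traits on
steers only, ultrasound on a scanned subset), and yearling weight emitted
as two raw weighings for the day-365 projection formula
`YW = (W_t − W_{t−1})/(t − t_{−1}) × (365 − t_{−1}) + W_{t−1}`.

## Worked example

Simulate the 3-trait carcass design (CW/EMA/MS, ~2,000 animals, steers
recorded only — about a third of the pedigree), fit it with a reduced
chain, and score recovery of the known truth:

```
$ mtgibbs recover --n-animals 2000 --seed 7 --out out/
  parameter    truth  posterior_mean  posterior_sd  covered_2sd
     h2[CW] 0.418579        0.529426      0.078192         True
    h2[EMA] 0.501449        0.393249      0.086728         True
     h2[MS] 0.595833        0.536794      0.086472         True
r_g[CW,EMA] 0.560000        0.552973      0.107045         True
 r_g[CW,MS] 0.170000       -0.012819      0.148374         True
r_g[EMA,MS] 0.350000        0.280090      0.162739         True
```

Each row compares the generator's true parameter with the posterior mean
and SD from the fitted chain (25,000 iterations, 5,000 burn-in, thinning
10); `covered_2sd` flags whether the truth lies within two posterior SDs —
here all six parameters are recovered.  (The r_g[CW,MS] mean of −0.01
against a truth of 0.17 illustrates how wide the posterior for a weak
correlation is at ~700 records.)

The library API mirrors the pipeline:

```python
from mtgibbs import (load_pedigree, load_phenotypes, build_design,
                     build_A_inverse, ChainConfig, run_chain, summarize)

ped = load_pedigree("pedigree.csv")
table = load_phenotypes("phenotypes.csv", trait_defs, pedigree=ped)
design = build_design(table, ped)
result = run_chain(ChainConfig(seed=1), design, build_A_inverse(ped))
print(summarize(result.G, result.R, result.trait_names).components)
```

`mtgibbs simulate` writes synthetic datasets (plus a truth file),
`mtgibbs fit run.yaml` fits a model described by a YAML config (pedigree
and phenotype paths, per-trait factors/covariates, chain schedule, prior),
and `mtgibbs summarize samples.tsv` re-summarizes a stored samples file.
Every run writes a provenance log; fits also emit descriptive statistics,
posterior report tables (variance components + h²; a correlation matrix
with genetic above and phenotypic below the diagonal), ESS/Geweke
diagnostics and trace plots.

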