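# patchscape

Landscape history and multi-facet diversity analysis of habitat-patch
networks.

## What it is for

Semi-natural grassland patches in fragmented agricultural landscapes differ
not only in their present-day configuration (size, isolation) but in their
history: some have persisted for centuries, others arose recently on
abandoned fields. Community ecologists studying such systems want to know
which filters — abiotic conditions, present-day landscape configuration, or
historical landscape configuration — shaped the plant communities now
occupying each patch, and whether the answer differs between old and newly
established patches.

`patchscape` implements that analysis end to end for presence/absence
survey data:

* **Landscape metrics** — patch isolation
  `I_j = −log₁₀ Σ_k (A_k / d_jk²)` over neighbours `k` within 0.5 km
  (edge-to-edge distances `d_jk`, neighbour areas `A_k`; higher = more
  isolated), historical area fractions `A_era` (share of a patch footprint
  covered by potential grassland habitat on an era map, after filtering
  habitat units to the abiotic envelope of the old patches, range limit
  ± SE), patch age by the between-map midpoint rule, and the topographic
  wetness index `TWI = ln(As / tan b)`.
* **Diversity metrics** — per patch: species richness SD; functional
  diversity FD as the mean pairwise dissimilarity (MPD) on a combined
  mixed-type Gower distance over three trait blocks (vegetative, phenology,
  seed; ordinal traits via the Podani rank formula with tie correction);
  phylogenetic diversity PD as MPD on cophenetic distances; and community
  means CM of each trait over the species present.
* **Inference** — collinearity screening (|r| threshold), Welch t-tests with
  Benjamini–Hochberg FDR for old-vs-new contrasts, per-block two-axis PCA,
  Poisson (SD) / Gaussian (FD, PD) GLMs, AIC ranking, and adjusted variance
  partitioning: deviance-based `D² = (D₀ − D)/D₀` with the Ezekiel
  adjustment `D²adj = 1 − [(n−1)/(n−p−1)](1−D²)`, decomposed by
  inclusion–exclusion over the seven block-combination models into three
  unique, three pairwise-shared and one triple-shared fraction that sum
  exactly to the total explained variation (TVE).
* **A synthetic-study generator** — seeded landscapes (spatially
  autocorrelated abiotic fields, log-normal patch areas, backward era
  persistence), pure-birth phylogenies with Brownian trait evolution, and a
  logistic occupancy model with known coefficients for environmental
  filtering, patch area, isolation and age — so the whole inferential chain
  can be validated against known truth.

## Worked example

`examples/04_variance_partitioning.py` generates a 272-patch, 99-species
study whose occupancy is dominated by present-day configuration
(`b_area = 0.8`, `b_iso = −0.5`) and runs the full pipeline:

```
adjusted variance partitioning (%, rows = age class x response):
        unique_abi  unique_pre  unique_his  shared_abi_pre  shared_abi_his  shared_pre_his  shared_all    TVE
old_SD        0.66       82.09        0.75           -0.20            0.04            3.35       -0.40  86.29
old_FD        0.13       -0.99       -0.82            0.02            0.02           -0.01       -0.00  -1.64
...
old-vs-new comparison of the diversity metrics:
          mean_old   sd_old  mean_new   sd_new   p_raw   p_fdr
SD         32.6652  19.4171   27.5490  18.2497  0.0785  0.4554
FD          0.3571   0.0127    0.3573   0.0186  0.9467  0.9789
PD          0.8607   0.0272    0.8639   0.0293  0.4709  0.9789
```

As generated, the present-day block carries by far the largest unique
fraction of richness variation (82% in the old class), while FD and PD —
driven only weakly here — show small, partly negative adjusted fractions.
Negative adjusted fractions are legitimate and never truncated in tables.

The other examples cover the generator (`01`), hand-checkable landscape
metrics (`02`) and the diversity indices on a five-species pool (`03`).

A thin CLI wraps the same functions:

```bash
patchscape simulate --seed 1 --out study/
patchscape analyze --dir study/ --out results/
```

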