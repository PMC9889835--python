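# strawcue

Analysis toolkit for ¹³C-labeled straw soil-incubation experiments: from raw
isotope and amplicon tables to the **microbial use efficiency of straw-C**
and the community analyses that explain it.

## The scientific problem

When crop straw is returned to soil, microbes split the straw carbon they
process between new biomass (which feeds soil organic carbon) and respired
CO₂. The efficiency of that split — the *microbial use efficiency of
straw-C*, a form of carbon use efficiency (CUE) — depends on the chemistry
of the organic amendments applied alongside the straw and on the microbial
community they recruit. Experiments probe this with ¹³C-enriched straw:
replicate soils receive labeled straw, parallel replicates receive unlabeled
straw, and every measured carbon pool is partitioned into straw-derived and
native fractions from its δ¹³C.

This package implements that computational chain for anyone running or
re-analysing such incubations:

1. **Isotope partitioning.** The straw-derived fraction of a pool follows
   the two-pool mixing model

   $$f = \frac{\delta - \delta_{soil}}{\delta_{straw} - \delta_{soil}}$$

   with the native endmember δ_soil estimated from the unlabeled replicates.
   The δ¹³C of microbial biomass comes from the chloroform
   fumigation–extraction mass balance

   $$\delta^{13}C_{MBC} = \frac{\delta C_{fum}\,C_{fum} - \delta C_{nfum}\,C_{nfum}}{C_{fum} - C_{nfum}},$$

   biomass carbon from MBC = (C_fum − C_nfum)/k_EC (k_EC = 0.45 by default),
   and the headline statistic is

   $$\mathrm{CUE} = \frac{^{13}\mathrm{C\text{-}MBC}}{^{13}\mathrm{C\text{-}MBC} + {}^{13}\mathrm{C\text{-}CO_2}}$$

   with replicate-level uncertainty and one-way ANOVA + Tukey compact-letter
   comparison of treatments.
2. **Community structure.** Relative abundances, richness, fungal:bacterial
   (ITS/16S) and cbhI:GH48 cellulolytic-gene ratios, Bray–Curtis PCoA and
   PERMANOVA (pseudo-F, R², permutation p).
3. **Co-occurrence network.** Dominant phylotypes (mean relative abundance
   > 0.1% and prevalence > half of samples), Spearman edges with |r| > 0.6
   and Benjamini–Hochberg-adjusted p < 0.01, modularity modules, top-3
   module summaries and per-sample subnetworks.
4. **Predictor importance.** Random-forest regression of CUE on community
   indicators with out-of-bag %IncMSE permutation importance and
   response-permutation (rfPermute-style) p-values.
5. **Amendment chemistry.** Aggregation of pyrolysis-GC/MS compound tables
   into eight chemical groups and four C-skeleton classes (Alic_C, Alip_C,
   Arom_C, Hete_C), correlated against CUE and community indices.
6. **Synthetic experiment.** A generator that emulates the full incubation
   with known ground truth (true f, true CUE, planted community shifts and
   co-occurrence modules), so every stage is covered by parameter-recovery
   tests.

## Worked example

```bash
python examples/01_partition_cue.py
```

prints (seed 1, default noise of 1‰ on δ values and 5% CV on pools):

```
Per-treatment straw-C use efficiency (mean over n=3, 95% t-interval):
treatment  timepoint_days  f_co2  f_mbc   cue  ci_low  ci_high
     Ctrl               7  0.631  0.308 0.305   0.279    0.330
       LM               7  0.469  0.286 0.362   0.319    0.405
       MM               7  0.464  0.332 0.419   0.392    0.446
       CM               7  0.424  0.422 0.546   0.518    0.575
...
Day-7 ANOVA: F = 194.1, p = 8.3e-08
    CM: CUE = 0.546  a
  Ctrl: CUE = 0.305  d
    LM: CUE = 0.362  c
    MM: CUE = 0.419  b
Generator ground truth for CM at day 7: 0.550
```

`f_co2`/`f_mbc` are the straw-derived fractions of the cumulative CO₂ and
biomass pools; `cue` is the biomass share of straw-derived C. The
cellulose-dominant, heterocyclic-rich amendment (CM) retains the most
straw-C in biomass at day 7 and carries a distinct ANOVA letter — and the
estimate sits within 1% of the generator's ground truth. The other examples
(`02`–`04`) walk through ordination/PERMANOVA, the co-occurrence network,
and the random-forest importance + chemistry correlations.

The same chain runs from a shell:

```bash
strawcue simulate --seed 1 --out data/
strawcue partition data/isotope_samples.csv --out cue.csv
strawcue run-all config.yaml          # full pipeline from one YAML config
```

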