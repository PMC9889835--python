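# Methods

This note documents the models implemented in `strawcue`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
generator does and does not emulate.

## Isotope partitioning

**Two-pool mixing.** Every measured pool (trapped CO₂-C, microbial biomass
C) is treated as a linear mixture of native soil C and labeled straw C.
The straw-derived fraction is f = (δ − δ_soil)/(δ_straw − δ_soil). The
native endmember δ_soil is estimated, per treatment × pool × timepoint, as
the mean of the replicates that received unlabeled straw — that is what
those replicates are for. Fractions outside [0, 1] can arise from
measurement noise; they are *returned as computed* with a warning, because
silently clamping negative f to zero would bias CUE upward. An explicit
`clamp_negative_f` flag exists for users who want the clamped behaviour.

**Biomass δ¹³C and pool size.** The biomass δ comes from the chloroform
fumigation–extraction mass balance
δ_MBC = (δC_fum·C_fum − δC_nfum·C_nfum)/(C_fum − C_nfum), which requires
C_fum > C_nfum (a fumigation flush no larger than background is a data
error, raised as such). This balance is always applied, at both timepoints.
Biomass C is MBC = (C_fum − C_nfum)/k_EC with k_EC = 0.45, the conventional
extraction-efficiency factor; k_EC is configuration-exposed and cancels out
of the δ ratio, so it affects pool sizes but not f.

**CUE.** CUE = ¹³C-MBC/(¹³C-MBC + ¹³C-CO₂), where ¹³C-CO₂ uses the
*cumulative* CO₂-C up to the sampling day. With non-negative inputs CUE is
in [0, 1] and strictly increasing in the biomass term.

**Uncertainty.** Per treatment × timepoint, CUE is computed per labeled
replicate and summarized by mean, SD, and a 95% interval. The default
interval is a Student-t interval over replicate CUEs. A percentile
bootstrap over replicates is also available (`ci_method="bootstrap"`,
seeded, default 1999 resamples), but it is *not* the default: with the
typical n = 3 replicates any percentile bootstrap interval is contained in
the replicate range, whose coverage of the mean is bounded by
1 − 2·(1/2)³ = 75%, far below nominal. The t-interval's coverage on the
generator's noise model is ≈ 93–95% (verified by the Monte-Carlo coverage
test in the suite).

**Treatment comparison.** One-way ANOVA (α = 0.05) with a compact letter
display derived from all pairwise Tukey HSD tests: letters are the maximal
cliques of the "not significantly different" graph, ordered so the
highest-mean group gets `a`. Identical data across all groups raise a
zero-variance error rather than returning an undefined F.

## Community structure

Relative abundances are per-sample count proportions; richness is the
observed-ASV count, optionally after seeded rarefaction without replacement
(multivariate hypergeometric). Rarefaction is off by default. The F:B
operation is a plain quotient applied identically to ITS/16S gene copies
and to cbhI/GH48 copies; the pipeline default uses qPCR gene copies, with
read-count totals available to the caller.

Bray–Curtis distances come from `scipy.spatial.distance.pdist`. PCoA is
classical metric scaling: Gower double-centering of −D²/2, symmetric
eigendecomposition, coordinates from the non-negative eigenvalues only, and
explained fractions over the sum of positive eigenvalues. Bray–Curtis
matrices are generally non-Euclidean, so small negative eigenvalues are
expected; dropping them is the simplest defensible convention. The
implementation is cross-checked against scikit-bio's PCoA in the tests.

PERMANOVA partitions the squared-distance sums: R² = SS_between/SS_total,
pseudo-F = (SS_B/(a−1))/(SS_W/(N−a)), p by seeded label permutation with
add-one correction (999 permutations by default). R² is reported because it
is the quantity of interest for "how strongly does the amendment structure
the community"; the pseudo-F statistic is cross-checked against scikit-bio's
PERMANOVA. Under perfect group separation SS_W = 0 and F is +infinite; only
permutations reproducing the same partition tie with it, which gives the
correct smallest-attainable p.

## Co-occurrence network

Dominant phylotypes are ASVs with mean relative abundance strictly above
0.1% *and* prevalence strictly above half of all samples, both criteria
evaluated across all samples. Bacterial and fungal tables are normalized
*within domain* before concatenation, so the arbitrary sequencing-depth
difference between the 16S and ITS assays cannot induce cross-domain
correlation artifacts.

Edges are Spearman correlations by default (robust to monotone distortions
of compositional data; Pearson by flag) computed over all pairs;
Benjamini–Hochberg adjustment is applied across the *full* family of
pairwise p-values before thresholding — adjusting only pre-selected
p-values would invalidate FDR control. An edge is retained iff |r| > 0.6
(strict) and adjusted p < 0.01 (strict). Constant-abundance ASVs have no
defined correlation and are excluded with a warning.

Modules are communities maximizing modularity on the unsigned graph:
deterministic greedy agglomeration by default, seeded Louvain by option.
Isolated nodes become singleton modules excluded from ranking. "Top"
modules are the largest by node count (ties broken by smallest member id),
renumbered so module 1 is the largest. Module summaries report member
counts by domain and, per treatment, the mean ± SD across samples of the
summed within-domain relative abundance of members. Per-sample subnetworks
are induced subgraphs on the ASVs with non-zero count in that sample.

The network pools all samples by default; a `treatments` argument restricts
construction to chosen groups for per-amendment networks.

## Predictor importance

The regression forest is bagged sklearn decision trees (default 500 trees,
mtry = ⌈p/3⌉ — the regression convention) with an explicit bootstrap loop
so each tree's out-of-bag (OOB) sample is available. %IncMSE for predictor
j is the mean over trees of (OOB MSE with column j permuted − OOB MSE),
expressed as a percentage of the forest's baseline OOB MSE — the raw,
unscaled variant. Significance follows the response-permutation scheme:
the response is permuted `n_null` times (default 100), the whole forest is
refitted each time, and p = (1 + #{null ≥ observed})/(1 + n_null).

Two properties worth knowing: (i) permutation p-values are calibrated —
under a fully null response the rejection rate at α = 0.05 is close to
nominal (verified over 200 seeded runs); (ii) the %IncMSE of a pure-noise
predictor does *not* converge to zero as the forest grows — trees partially
fit noise, so its expectation is a small positive constant; more trees only
shrink the Monte-Carlo spread of the estimate (the suite asserts exactly
that).

The experimental unit is the sample (replicate-level rows); where CUE is
measured on fewer replicates than the community (3 labeled vs 6 community
replicates), the cell-mean CUE is broadcast to the community samples.

## Amendment chemistry

Pyrolysate compound tables (compound, chemical group, C-skeleton class,
peak proportion — peak-area convention) are summed by group and by class
and renormalized; the group vocabulary is the eight-class set (lignin,
phenol, carbohydrate, saturated/unsaturated hydrocarbon, N-containing,
aromatic, poly-aromatic hydrocarbon) and the skeleton vocabulary is
{Alic_C, Alip_C, Arom_C, Hete_C}. Both vocabularies are closed; unknown
labels raise. A default compound → (group, class) mapping ships as
`data/synthetic_pyrolysate_classes.csv`; it is a package convention
assembled from general pyrolysis-GC/MS practice, not a measured reference,
and real analyses should supply their own assignments. Class–metric
correlations reuse the same correlation engine as the indicator panel
(Pearson default).

## Synthetic experiment

The generator encodes the study conditions: treatments Ctrl/LM/MM/CM
(control, lignin-dominant, mixed, cellulose-dominant amendment), sampling
at days 7 and 28, 3 labeled + 3 unlabeled replicates for isotope
measurements, 6 replicates for community profiling, straw at
δ¹³C = 99‰ and 1 mg straw-C g⁻¹ soil, amendments at 5 mg C g⁻¹ soil,
native soil baseline −20‰ (typical C3 soil, configurable). The 99‰ label
is taken verbatim as a δ value; an atom-fraction input mode is provided for
users whose tracer is specified in atom %.

Ground truth is expressed as straw-derived and native amounts per pool and
cell, so `true_cue = mbc13/(mbc13 + co2_13)` holds by construction. The
default truth makes CM decompose straw fastest and retain the most
straw-C at day 7 (true CUE 0.55 vs 0.30–0.42), with convergence by day 28,
and gives amended soils larger native pools. Measurement noise is Gaussian
on the ‰ scale for δ values (default SD 1‰) and mean-preserving log-normal
on pool sizes (default CV 5%) — the simplest models consistent with
replicate scatter reported as error bars in this kind of experiment. The
fumigated extract is constructed by inverting the mass balance from the
intended biomass δ, so the full analysis chain recovers the truth exactly
at zero noise (to ~1e-16 relative, tested).

ASV tables follow a log-normal relative-abundance model with multinomial
sampling: per-ASV baselines, per-phylum additive log effects per treatment
(default: Ascomycota enriched under CM and MM, Basidiomycota depleted under
CM), a shared latent factor per planted module (3 cross-domain modules of
7 bacterial + 3 fungal ASVs, loading 0.8 by default) and idiosyncratic
noise. Gene-copy tables use configured treatment multipliers on the fungal
markers and day-28/day-7 growth factors with bacterial markers growing
faster, so F:B and cbhI:GH48 are highest under CM and decline over time.
Amendment compositions are fixed presets (CM heterocyclic-rich, LM
aromatic-rich, MM balanced).

All randomness derives from the design seed through named `SeedSequence`
substreams, and the pipeline splits its global seed into per-stage child
seeds the same way (`SeedSequence([seed, stage_id])`), so identical
configs give bit-identical outputs and toggling one stage never shifts
another's draws.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: sequencing error, chimeras and
compositional zero-inflation; phylogenetic correlation between ASVs beyond
the planted modules; isotopic fractionation during respiration; temporal
autocorrelation between day 7 and day 28 (cells are drawn independently);
priming effects on native SOC mineralization; and any coupling between the
community tables and the isotope truth beyond shared treatment labels.
Parameter-recovery results show the *estimators* are correct under the
stated noise models, not that those models exhaust real measurement error.

## Problem sizes in the test suite

The heavy suite components use deliberately scaled designs: the CUE
recovery/coverage experiment runs 1,000 single-cell experiments (the
estimator is cell-wise, so one cell per experiment suffices); planted-module
recovery uses 50 seeds of a 24-sample, 90-ASV community; PERMANOVA null
calibration uses 200 runs of 999 permutations on 16-sample communities; and
the random-forest calibration uses 200 null runs at 100 trees and 30
response permutations (p-value resolution 1/31) on 24 × 5 data. These sizes
were chosen as the smallest that make the respective statistical assertions
stable.

## Known limitations

- The compact letter display uses maximal cliques of the non-significance
  graph; with many groups and borderline p-values the letter sets are not
  unique (any valid CLD is).
- PERMANOVA assumes exchangeability under the null; no strata/blocking.
- The forest does not handle missing predictor values; alignment errors
  are raised instead.
- Network inference is correlation-based by design (the convention being
  implemented); it does not correct for compositionality the way
  SparCC-type methods do.
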