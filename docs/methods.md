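# Methods

This note documents the models implemented in `clsmeta`, the defaults that
matter, the numerical choices, and what the synthetic-data generators do and
do not emulate.

## Harmonization and ranking

Screens report lifespan on incommensurable scales (outgrowth kinetics,
barcode microarray intensities, barcode sequencing counts, fluorescence
ratios), so all cross-screen statistics are rank-based.  Each screen is
oriented so that larger values mean longer-lived (a `lower_is_longer` flag
negates the column on load), genes are matched case-insensitively on
systematic ORF names, rows with missing or non-finite values are dropped per
dataset (treated as not measured, never imputed), and ranks use the
average-tie convention so that downstream Spearman statistics are exact.

## Inter-screen concordance

Pairwise agreement is tie-aware Spearman correlation over the genes shared
by all screens, with two-sided p-values from the t-approximation.  Tail
overlap between two screens is the Jaccard index of their top (or bottom)
`floor(f·n)` genes, re-ranked within the pairwise-shared universe (overlap
is undefined on unequal universes); minimum tail size is one gene.

The shared-variable model regresses raw pairwise ρ (no Fisher transform) on
one indicator per experimental variable, set to 1 when both screens have the
identical level.  Multi-level variables still contribute one share/not-share
indicator.  Constant indicators are non-estimable and excluded with a
warning rather than silently dropped.  With D screens the model has C(D,2)
observations; it requires at least two more observations than indicators.

## Dataset evaluation and weights

Each screen is scored as a binary classifier of a curated catalog of
long/short phenotypes validated by colony-forming-unit counting or
live/dead staining in small-scale studies.  The positive class defaults to
long-lived (a flag flips it); a gene's classifier score is minus its rank.
Catalog genes not measured by a screen are skipped; genes whose validation
came from the same study as the screen can be excluded to avoid
common-source bias.  The AUC equals the Mann–Whitney win fraction, which is
kept in the package as an independent oracle for the trapezoidal ROC area.
Integration weights are equal (1/D), AUC-proportional, or a normalized
priority vector; weights are stored at full precision and reported rounded
to four decimals.

## PROMETHEE II consensus

The usual preference function is strict: any positive difference on a
criterion yields full preference, ties yield none.  Net flows use the
1/(n−1) normalizer with n the total number of alternatives, regardless of
missingness.

Missing data policy is the one genuinely open design choice: screens cover
different deletion subsets and the handling of genes absent from some
criteria is undocumented in upstream tools.  The default, `renormalize`,
rescales weights to sum to one over the criteria observed for both genes of
a pair, which keeps φ on the [−1, 1] scale and avoids biasing low-coverage
genes toward zero; `zero_preference` (unshared criteria contribute nothing,
no rescaling) is provided for sensitivity analysis.  A pair sharing no
criterion contributes zero preference in both directions and is logged,
never an exception.

The production path groups genes by their pattern of observed criteria (at
most 2<sup>J</sup> groups); within a fixed ordered group pair the effective
weights are constant and, for the usual function, the summed preference of a
gene over a group on one criterion is a strictly-smaller count obtained by
binary search.  The quadratic transcription of the definition
(`net_flows_brute`) stays in the package as the reference; the two are
compared to 1e-12 in the tests.  Exact φ ties are broken lexicographically
by gene identifier, making the ordinal ranking deterministic.

## Rank-distribution statistics

Wilcoxon rank-sum shift tests use exact enumeration when both groups have at
most eight members *and* the ranking has no ties (the exact distribution is
not tie-corrected); otherwise the tie-corrected normal approximation.  Tail
enrichment is the one-sided hypergeometric upper tail with tail size
`floor(f·N)`, minimum one.  Decile trends report per-bin means with
t-intervals over contiguous rank bins.  Over-representation across a family
of gene sets applies Benjamini–Hochberg within that family only — never
across analysis families.

## Preranked GSEA

The running sum increments at set genes by |φ|<sup>p</sup> (p = 1 by
default) normalized by the in-set total and decrements at misses by
1/(N−|S|); ES is the signed maximum deviation.  If every in-set weight is
zero the hit weights fall back to uniform; if the whole statistic is
constant the input carries no ordering information and every set reports
ES = 0, p = 1.  When the maximum positive and negative deviations tie
exactly, the positive one is taken.

The null permutes gene labels of the statistic (phenotype permutation is
impossible without sample-level data).  One permutation relabels all genes
at once and is scored against every set — the batched scheme used by
fgsea — which leaves each set's marginal null exact while amortizing cost;
p = (1 + #{|ES'| ≥ |ES|, same sign}) / (1 + #same-sign permutations), and
NES divides ES by the mean |ES'| of the same sign.  Default n_perm is
10,000 and a seed is mandatory.  The 10–100 size filter applies to the
effective set size after intersection with the ranked universe.  BH-FDR is
computed across the retained sets.

Enriched terms are linked by Jaccard index of their (universe-restricted)
gene content; edges require Ji strictly above 0.1.  Functional clusters
come from average-linkage hierarchical clustering on 1 − Ji cut at height
0.9 (the complement of the edge threshold, so terms chained by Ji > 0.1
tend to cluster); each cluster is named after its member term with the most
genes.

## Regulator association

The displayed quantity is the fraction of a cluster's leading-edge genes
documented as targets of a TF; relevance is the one-sided hypergeometric
over-representation of the TF's targets in the leading edge drawn from the
ranked gene universe, at α = 0.01.  Breadth defaults: global = significant
in at least ⌈2/3⌉ of the clusters, local = at most 2, meso otherwise; with
three or fewer clusters these bands touch and the global rule wins, so
breadth labels are most meaningful with four or more clusters.  This
fraction+hypergeometric association replaces a web-service graph-ranking
algorithm that is not reproducible offline; it preserves the displayed
fraction-regulated quantity but is not the same score.

## Competitive-aging model

Background per channel and sampling point is the mean signal of the
opposite-color single-strain reference wells (a CFP-only well measures RFP
background), subtracted everywhere and floored at 1 fluorescence unit
before the log; a missing reference timepoint falls back to the nearest
with a warning.  Only readings with OD in [0.05, 1.0] (detection floor to
saturation ceiling — the fitted outgrowth window is not otherwise
specified) enter the fit; both bounds are configuration.

One least-squares fit per plate: per-well intercepts A<sub>w</sub>; aging-day and
outgrowth-hour slopes S<sub>w</sub>, G<sub>w</sub> for every competition well except WT/WT
wells, whose slope columns are omitted (enforcing S = G = 0 exactly); and a
shared plate effect C per sampling point, effect-coded to sum to zero for
identifiability (the constraint is a package choice; only the term itself
is given upstream).  Rank deficiency raises an error naming the
unidentifiable columns.  Standard errors are the usual OLS covariance;
intervals use the t quantile at the residual degrees of freedom.  Relative
lifespan is L = 1 + S by definition, so L inherits S's uncertainty.

## Synthetic generators

The stated world: five screens over 2000 genes with loading β = 1 on a
standard-normal latent longevity effect, Gaussian noise σ = 0.5, full
coverage; optional monotone distortions (rank, logistic) and uniform or
block missingness emulate scale heterogeneity and partial deletion-library
coverage.  The curated catalog labels the latent extremes (81 long + 81
short by default — the real catalog has 162 usable entries whose long/short
split is not published, so a balanced split was chosen once) with a 5%
label-flip rate standing in for small-scale validation error.  Planted gene
sets sample genes with weights ∝ exp(±2·λ), i.e. from the latent
distribution tilted to N(±2, 1); null sets sample uniformly.  Planted
shifts are applied before screens are drawn, so downstream enrichment is
real signal, not construction artifact.

Planted "local" TFs target a cluster's *exclusive* genes (members of no
other cluster): realized functional clusters share leading-edge genes, and
a TF targeting shared genes is genuinely significant in several clusters,
which would contradict a "local" truth label.  Global TFs target 80% of
every cluster; background TFs target uniform random genes.

Competition plates are generated from the forward model: y = A + S·T + G·t
+ C + N(0, sd²) split over a logistic outgrowth curve into RFP/CFP channel
pairs with constant added background, plus single-color reference wells.
A ~ N(ln 2, 0.3²) reflects the 2:1 RFP:CFP mixing ratio; S ~ N(0, 0.15²)
per day, G ~ N(0, 0.02²) per hour, C ~ N(0, 0.05²) centered to sum zero,
noise sd 0.1 by default.

What a green test does *not* establish: the generators are linear-Gaussian
in a single latent factor and do not emulate correlated screen errors,
batch structure within a screen, gene sets with realistic GO nesting,
plate-reader optics (gain nonlinearity, spectral bleed-through), or
biologically mechanistic aging.  Recovery results certify the statistical
machinery under the stated world, not performance on any particular real
compendium.

## Known limitations

- PROMETHEE II does not model statistical uncertainty of the input screens;
  rank-reversal sensitivity to the chosen weights is exposed only through
  the alternative weight schemes.
- Exact reproduction of published consensus ranks depends on the upstream
  tool's undocumented missing-data handling; both policies here are
  documented and tested, but neither is guaranteed to match it tie-for-tie.
- The GSEA permutation scheme and NES normalization are stated conventions;
  other implementations' enrichment lists need not reproduce term-for-term.
- Breadth classification of regulators is qualitative; the default
  thresholds are configuration, not biology.
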