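# Methods

`divergescan` implements a comparative transcriptome / DNA-methylome analysis
between two plant genotypes (an upland ecotype, HAL2, and a lowland ecotype,
FIL2) across an inflorescence developmental series, exercised end-to-end on
synthetic data with planted ground truth. This note records the models, the
tunable parameters, the numerical choices, and what the synthetic experiments
do and do not demonstrate.

## Synthetic study design

One `SimulationConfig` (a single integer seed plus explicit parameters)
deterministically generates every input. Named sub-streams are spawned from
the seed per component (genomes, counts, methylomes, CDS pairs, chloroplast),
so components can be regenerated independently and all outputs are
byte-identical across runs.

**Genomes and annotation.** Each genotype receives its own genome: genes laid
out left-to-right with intergenic gaps (0.8–2.5 kb) round-robin across
chromosomes, 1–4 exons per gene, UTRs at ~15% of the transcript on each end,
random strand, and i.i.d. random nucleotide sequence. The two genotypes share
gene order and ids up to a prefix; the one-to-one ortholog map is that
bijection. Chromosome sequences determine the cytosine positions and their
CG/CHG/CHH contexts on both strands.

**Methylomes.** A cytosine's true methylation level in one replicate is

    level = clip(baseline[context] + planted_delta + N(0, site_noise_sd), 0, 1)

with per-context baselines (0.66, 0.49, 0.031) for (CG, CHG, CHH) matching
typical grass inflorescence tissue, site noise sd 0.05 drawn independently
per site *per replicate* (so replicate variation is biological plus
binomial, and unplanted ortholog features are exchangeable between
genotypes — the null calibration of the downstream t-tests depends on
this). Coverage is negative-binomial per site per sample (mean 20,
dispersion 0.3 — the paper states neither; 0.3 is moderate WGBS-like
variation) and the methylated read count is binomial at the true level.
Planted differences select a fraction of (ortholog pair × feature-kind)
combinations, one random context each, one random hypermethylated genotype,
and add `dmr_delta` (default 0.3) to that genotype's sites in the feature.
The truth table records the pair, feature, context, and signed delta in the
FIL2 − HAL2 convention.

Clamping at 0 lifts the realized CHH mean above its 0.031 baseline (the
expectation of the clamped Gaussian is ≈ 0.043 at sd 0.05); tests compare
against the analytic truncated-Gaussian expectation, not the nominal
baseline. A Beta site-level model would avoid this and can replace the
clamped-Gaussian jitter without touching any downstream code.

**Counts.** The expression design is 2 genotypes × 4 stages × 3 replicates.
Gene baselines are log-normal (median ≈ 200 counts); library sizes are
uniform in the configured range and enter as true size factors. Counts are
gamma-Poisson (negative binomial) with gene dispersion `nb_dispersion`
(default 0.05). Planted effects are mutually exclusive per gene:

- *genotype*: a constant FIL2 − HAL2 log2 fold change at every stage;
- *development*: a linear expression ramp over stages, identical in both
  genotypes;
- *interaction*: a heterochronic rank change — the sign of the FIL2 − HAL2
  difference flips at a random changepoint along the series. This is the
  biologically motivated pattern (timing shifts between ecotypes) and is
  what gives the 3-df interaction LRT its intended power at |log2FC| = 1;
  a same-magnitude difference confined to a single stage is statistically
  invisible at q < 0.01 with three replicates.

**CDS pairs.** Ancestor sequences are random sense codons (no stops). A
configured number of synonymous and non-synonymous single-nucleotide
substitutions is applied, each at a distinct codon, rejecting changes that
create stops. For a configurable fraction of pairs (default 10%) the
non-synonymous count is calibrated through the ancestor's NG86 site counts
to land at ω ≈ 1.6–2.4 (positive selection); the rest target ω ≈ 0.25–0.55.
Truth stores realized counts.

**Chloroplast control.** All-unmethylated sites observed through the same
coverage model with methylated reads arising only from conversion failure
(rate 0.025, i.e. a 97.5% conversion rate).

**Feature-level generator.** For calibration studies that do not need genome
plumbing, `simulate_feature_table` simulates the same observation model
directly at the feature level (n sites per feature, NB coverage, binomial
reads, unweighted-mean summaries). The recovery study plants differences in
30% of features — differential methylation at this scale is what the
underlying study reports (roughly half of orthologs differentially
methylated in at least one feature), and at a 10% planted fraction the
3-vs-3 t-test (4 df) cannot push 80% of true features past the q < 0.01
cutoff regardless of implementation.

## Feature derivation

Internal coordinates are 0-based half-open; GFF3 I/O converts at the
boundary. The representative transcript is the longest mRNA (summed exon
length, ties by span then id). Six region classes: promoter (500 bp
strand-aware upstream of the TSS, clipped at chromosome edges), 5′UTR, CDS,
intron (gaps between exons), 3′UTR, and intergenic (per-chromosome
complement of gene spans and promoters, with stable region ids). A cytosine
falling in overlapping features (e.g. one gene's promoter over a neighbour's
3′UTR) counts toward all of them. Promoter windows are not trimmed against
upstream genes.

## Methylation quantification

Only sites with ≥ 5 reads enter the analysis (inclusive bound,
configurable). The regional level is the **unweighted mean of per-site
proportions** `n_meth / (n_meth + n_unmeth)`; a pooled-count estimator is
available behind a flag and off by default. Symmetric CG sites on opposite
strands stay separate. Global summaries report both the mean site level
(primary) and the fraction of sites with any methylated read. Site-level
histograms use bins [0, 0.2), [0.2, 0.8], (0.8, 1]. Window profiles tile
chromosomes, average site proportions per window, count genes by span
midpoint, and report a per-context Pearson r over windows with ≥ 1 site
(missing under zero variance or a single window). Metagene profiles scale
the gene body to 20 bins with 20 fixed-width bins per 2-kb flank, oriented
5′→3′ in transcript direction; group values are means over genes of
within-gene bin means. Expression rank groups put zero-count genes in
rank 1 and split the rest into equal-size quantile groups of mean
normalized count, ties broken by gene id.

## Differential methylation

Each (ortholog pair, feature, context) with replicate levels on both sides
is contrasted with a two-sided equal-variance Student t-test;
Δ = mean(FIL2) − mean(HAL2) (group B − group A in general). Degenerate
features — zero methylation in every replicate of exactly one group — skip
the t-test and are called on |Δ| > 0.1 alone. The zero-pooled-variance,
unequal-means case is treated as the limiting t (p = 0). Storey q-values
(smoother-based π0, cubic-polynomial smoother on a λ grid, fallback to
π0 = 1 below 100 tests) are computed within each context × feature-kind
family by default (pooling available), and significance requires q < 0.01
and |Δ| > 0.1. A gene is a DMG when ≥ 1 feature × context contrast is
significant. Genotype contrasts quantify each genotype against its own
annotation and join through the ortholog map; intergenic regions join on
their shared region ids; stage contrasts within a genotype need no join.

## Expression divergence

Nested NB log-linear models per gene (offset = log size factor,
median-of-ratios normalization rescaled to mean 1):

- genotype LRT: (genotype + stage) vs (stage), 1 df;
- development LRT: (genotype + stage) vs (genotype), 3 df;
- interaction LRT: (genotype × stage) vs (genotype + stage), 3 df.

Deviance differences are referred to χ². The gene dispersion is estimated
once under the full model by maximizing the **Cox–Reid adjusted** profile
likelihood (ll − ½ log det X′WX), then **moderated**: log dispersions are
winsorized at their 5th/95th percentiles, shrunk toward a log-linear
mean–dispersion trend with weight prior_df/(prior_df + residual_df)
(prior_df = 100), and finally rescaled by a single multiplier maximizing
the summed Cox–Reid likelihood over a deterministic gene subsample. The
moderation is essential, not cosmetic: with ~two dozen samples the
unmoderated per-gene estimate is noisy enough that genes in its low tail
get strongly inflated LRT statistics, and the null p-value distribution
fails a KS uniformity check at 2,000 genes. With moderation the three null
LRTs are uniform and the null divergent rate at q < 0.01 is ~0.

Multiple testing uses the q-value transform per test family; a gene is
*divergent* when q_genotype < 0.01 and/or q_interaction < 0.01, and
categories (interaction, genotype_only, development_only, both_additive,
none) partition the tested genes. Stage-specific FIL2-vs-HAL2 effects are
Wald tests on full-model coefficients (contrast = genotype main effect plus
the stage's interaction dummy), BH-adjusted within stage; log2FC is
FIL2 − HAL2, matching the methylation sign convention. Predominance over
significant stages (adjusted p < 0.01): all positive → FIL2-predominant,
all negative → HAL2-predominant, mixed → rank-changing, none significant →
none; only the sign rule is implemented (a "remarkable magnitude change"
variant is not). The stringent DEG set requires adjusted p < 0.01 and
|FC| > 1.5 per stage. The normalization for clustering and profiles is the
shifted log `log2(count/size_factor + 1)`; it is a surrogate for a
variance-stabilizing transform and is never used for testing.

## Divergence-pattern clustering

Profiles are the 8 genotype × stage cell means of normalized expression,
z-scored per gene (constant genes dropped). Fuzzy c-means uses Euclidean
distance, the Mfuzz-style data-driven fuzzifier m(n, d), and 5 restarts
keeping the best objective (a single random start can place two initial
centroids in one true group and stay there). The cluster number is read
from the minimum-centroid-distance curve: once c exceeds the number of real
groups, two centroids coincide and Dmin collapses by an order of magnitude;
the default rule picks the c just before the first consecutive drop of
Dmin below ⅓ of its previous value. An absolute-floor rule (first drop
below 0.1× the c = 2 value) is kept as an option but is sensitive to where
the post-collapse plateau sits and mis-selects on well-separated planted
mixtures. Hard assignments use k-means with 10 restarts. All clustering is
bit-reproducible under a fixed seed.

## GO enrichment

One-sided hypergeometric upper-tail p per term against the tested-gene
background, annotations intersected with the background first, terms with
fewer than 2 background genes skipped, BH FDR across tested terms,
significance at FDR < 0.05. No GO-graph propagation is applied.

## Ka/Ks (NG86)

Per codon, the synonymous site count is the fraction of the nine possible
single-nucleotide changes that preserve the amino acid (changes producing a
stop count as non-synonymous sites, so S + N = 3 per codon); site counts
are averaged over the two sequences. Difference counts average over all
orderings of the differing positions with equal weight, excluding orderings
that pass through a stop codon (retaining all orderings only if every one
does). pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − (4/3)p), undefined at p ≥ 3/4; ω = Ka/Ks is undefined at
Ks = 0, and undefined values stay missing rather than propagating NaN.
Codons with gaps or ambiguity characters are skipped with a count; internal
stops are an error naming the codon index. ω > 1 is classified positive,
ω < 1 purifying, ω = 1 neutral. Distributions are compared with a
two-sample KS test; the mode is the argmax of a Gaussian KDE (Silverman
bandwidth) over ω truncated to [0, 5].

## Integration

Stringent stage DEGs join significant methylation contrasts at the matched
stage (D1↔D1, D4↔D4) on the ortholog pair id. Each record keeps its
feature-level detail; per-context tallies count a gene once per context.
Quadrants combine the sign of log2FC with the sign of Δ (hyper/hypo ×
up/down, both in the FIL2-relative convention). The Ka/Ks overlay is a left
join; the positive-selection fraction is computed over distinct pairs with
a defined ω.

## Problem sizes and runtime

The validation experiments run at desk scale by design: 2,000 features for
t-test calibration and recovery, 2,000 null and 600 planted genes for the
factorial LRTs, 400 profiles × 10 seeds for cluster-number recovery, 100
30-codon pairs for the NG86 oracle, and a 150-gene two-chromosome genome
for the end-to-end run. The full test suite finishes in about two minutes
on one CPU; `scripts/acceptance.py` in about one.

## What passing tests do and do not show

The generator plants effects under the same distributional families the
methods assume (Gaussian site jitter, NB counts and coverage). Passing
recovery tests therefore demonstrates correctness of the implementations
and internal consistency of thresholds, not robustness to real-data
violations: there is no positional autocorrelation of methylation, no
TE/pericentromere structure (the window-level methylation–gene-density
correlation is near zero here by construction, unlike the strong negative
correlation of real pericentromeres), no beta-like site-level bimodality,
no mapping artifacts, and dispersion is homogeneous across genes.
Calibration results (uniform null p-values) do transfer in so far as the
real data meet the replicate-exchangeability assumption.

## Known limitations

- The DESeq2-style machinery is reimplemented (nested-deviance LRTs with
  moderated Cox–Reid dispersions); exact numerical agreement with DESeq2
  (shrinkage, Cook's filtering, independent filtering) is out of scope.
- The vst surrogate is a shifted log, not the reference variance-stabilizing
  transform.
- The NG86 reading of the "simple" Ka/Ks calculator (unweighted pathway
  averaging, JC correction) is an interpretation; tools differ in their
  treatment of stop-codon pathways.
- Minimum sites per feature defaults to 1; stricter filters are reproducible
  from the emitted `n_sites`.
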