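# Methods

## Function prediction

The imputation pathway assumes each OTU stands for a taxon whose gene
content is known up to gene-family copy numbers. Counts are first divided
by the OTU's 16S rRNA operon copy number `c_o` (operon counts vary
roughly 1–15 across gut bacteria, so raw reads over-represent
multi-operon taxa); OTUs without an annotated copy number default to 1
with a warning rather than being dropped, since losing sample mass
silently would bias every downstream ratio. The predicted profile is the
linear map `F = (X / c) · G`. No phylogenetic reconstruction is
performed: the gene-content matrix is an input, matching the workflow in
which precalculated reference content is consumed directly.

Pathway collapse is hierarchical. Gene families sum into level-3
pathways; a family annotated to *m* level-3 pathways contributes its full
value to each (the standard categorize-by-function convention — pathway
mass is therefore ≥ gene mass, and only a strict partition conserves
totals). Level-2 and level-1 tiers are sums of the tier below, and an
"Unclassified" level-1 category is retained as a first-class category.
Presence/absence set analysis across strata ("Venn" accounting) calls a
function present in a stratum when any sample there has a nonzero value;
the rule is configurable because detection thresholds are a free choice.

## Attribution

Linearity makes attribution exact: `contribution[t, c, s] =
Σ_{o∈t} Σ_{k∈c} (X[s,o]/c_o)·G[o,k]`, with the function→category weight
counting (function, level-3) mappings per category so that the tensor's
taxon-marginal reproduces the hierarchical level-1 collapse to rounding.
Summaries average *per-sample proportions* (unweighted over samples):
AAF is the mean share of a category's mass, AAT the mean share of the
grand total. This is the only convention under which per-taxon totals
equal their category sums, which is what the packaged reference
attribution table exhibits. Samples with zero grand total are excluded
with a warning; a category empty in one sample contributes no term to
that category's mean.

## Organism-level traits

Trait shares are abundance-weighted means of per-OTU trait memberships in
[0, 1] over copy-number-normalized abundances (consistent with the
imputation pathway). Binary annotations are the synthetic default, but
continuous memberships are accepted because trait-inference tools emit
coverage-thresholded continua. Being ratios, shares are invariant to
per-sample rescaling. The per-phylum breakdown partitions each trait's
trait-bearing mass by phylum (shares sum to 1 where the mass is positive;
degenerate cells are NaN). Both within-trait and per-sample views can be
derived from the returned tensor, since the axis normalization of such
figures is a presentation choice.

## Signature discovery

**Discriminant route.** Profiles are rescaled per sample to relative
abundance × 10⁶. The screen is a midrank Kruskal–Wallis test at
α = 0.05; constant features get p = 1 and are never candidates. Pairwise
consistency uses two-sided Wilcoxon rank-sum tests at α = 0.05 against
the class with maximal mean: *strict* requires every such comparison
significant with the top class's mean strictly larger, *less-strict* at
least one (the all-against-all vs one-against-all distinction for
multi-class designs). Effect sizes are bootstrapped: 30 rounds, each
retaining two-thirds of every class (selected through a single global
permutation per round, so relabeling classes cannot change the retained
set — this makes label-swap symmetry exact), fitting a linear
discriminant, and scoring each feature as half the sum of its largest
absolute between-class mean difference and that difference scaled by the
feature's unit-normalized first-axis coefficient; the reported score is
log₁₀(1 + mean round score) and the emission threshold is 2.0. Rounds in
which the discriminant cannot be fitted are skipped and logged. Note the
route applies no multiplicity correction — its realized false-discovery
proportion depends on the fraction of features that are truly enriched.

**ANOVA route.** One-way fixed-effects ANOVA per feature with
η² = SS_between/SS_total, Tukey–Kramer studentized-range pairwise
comparisons (valid for unequal group sizes), and Benjamini–Hochberg
step-up q-values computed across the features of one level at a time
(levels are analyzed separately, so correction is within-level).
Features with zero within-group variance but positive between-group
variance are floored at p = 10⁻³⁰⁰ rather than reported as 0.

**Importance route.** A low-count filter (value ≥ 2 in ≥ 20% of
samples), an inter-quartile-range drop of the least-variable
`floor(0.10·m)` surviving features (deterministic floor rule,
lexicographic tie-breaks), then cumulative sum scaling: per sample the
scaling factor is the sum of counts at or below the median of the
sample's nonzero counts, and values are scaled by 1000/factor (zeros stay
zero; all-zero samples are an error). Importance is Breiman-style mean
decrease in out-of-bag accuracy over a bagged ensemble of 500 decision
trees (bootstrap resampling and OOB bookkeeping are explicit; the tree
inducer is scikit-learn's): per tree, each feature used by the tree has
its OOB column permuted and the accuracy drop recorded, averaging drops
over all trees. The running OOB error curve is reported alongside the
ranking; ranking is a stable sort on score with lexicographic ties.

## Co-occurrence networks

Within one group × gender stratum (≥ 3 samples), pairwise Pearson
correlations are tested against a permutation null: each iteration
shuffles every feature column across samples independently once, and the
same shuffled matrix serves all pairs (O(B·m·n + B·m²) rather than
per-pair shuffles, and exchangeability is preserved). The two-sided
p-value uses add-one smoothing, `p = (#{|r_b| ≥ |r_obs|} + 1)/(B + 1)`,
so p is never 0; B defaults to 10,000. Zero-variance features get p = 1
everywhere and self-pairs are never tested. Edges are pairs with
p < 0.01; both correlation signs are kept with the sign stored on the
edge; isolated features are dropped.

Reported edge and degree figures use ordered-pair (doubled) counts, the
convention under which density is exactly `E/(N(N−1))` — equal to
standard undirected density and the identity the packaged reference
network table satisfies to all printed decimals in its male strata.
Diameter is computed on the largest connected component (finite by
construction); centralization is Freeman's `Σ(d_max − d_i)/((n−1)(n−2))`
on simple degrees (reported as 0 below 3 nodes); the clustering
coefficient is global transitivity, 3 × triangles / connected triples.
Hubs are the top-k nodes by ordered-pair degree, ties lexicographic.

## Synthetic cohorts

The generator emulates a two-gender, three-group study: 63 female
(29 Vata, 11 Pitta, 23 Kapha) and 50 male (13 Vata, 18 Pitta, 19 Kapha)
samples. Counts follow a Dirichlet-multinomial: per-sample OTU
proportions are drawn from a Dirichlet whose mean encodes phylum
structure (default mix 55% Firmicutes, 32% Bacteroidetes, 6%
Proteobacteria, 4% Actinobacteria, 2% Fusobacteria, 1% Tenericutes —
a Firmicutes/Bacteroidetes-dominated gut composition) and whose
concentration (`dispersion`, default 200) sets overdispersion; read
depths are Poisson around `sequencing_depth` (default 50,000). Within a
phylum, OTU base means are lognormal (σ = 1), giving the skewed
abundance distributions real surveys show. Gene content is a sparse
Poisson draw with phylum-specific rate profiles (presence probability
0.4), so phylum dominance of function mass emerges from abundance.
Hierarchy: 200 gene families under 40 level-3 and 12 level-2 pathways
and the five level-1 categories, with 15% of families multi-mapped to
two pathways. Traits are binary draws with per-phylum probabilities
(e.g. anaerobes dominate Firmicutes/Bacteroidetes; gram-negative for
Bacteroidetes/Proteobacteria/Fusobacteria; Tenericutes mostly
unannotated for gram stain, having no cell wall).

Planted effects are realized through dedicated low-abundance "driver"
OTUs (three per effect, base share 0.2% each) that *exclusively* carry
the effect's five gene families, which in turn feed one dedicated
level-3 pathway; the drivers' expected abundance is multiplied by the
fold-change (default 8) in the target group × gender stratum. The
default plants three pathways per stratum — 9 of 40 level-3 pathways per
gender (~22%), matching the signature density the emulated study reports
at level 3. Two details keep non-planted functions exactly exchangeable
(null) across groups: every stratum carries equal planted mass, so the
compositional renormalization that boosting induces is identical in all
groups; and all drivers share one fixed 16S copy number and base share,
since unequal values would give each stratum's boosted drivers a
different normalized mass and leak a systematic shift into every null
function's relative abundance. Optional *trait effects* multiply
trait-bearing OTUs' expected abundance in one stratum (used to emulate
the reported pathogen/stress-tolerance enrichments); they are off by
default because they deliberately break that null. Realized
function-level fold changes are echoed in the bundle's `truth` table.
All draws come from a single seeded generator stream, so a (config,
seed) pair is exactly reproducible.

What the generator does *not* emulate: phylogenetic correlation of gene
content beyond the phylum level, copy-number estimation error,
compositional correlation structure between background functions,
sequencing artifacts (chimeras, contamination), or covariates such as
age and diet. Passing recovery tests therefore demonstrates the
statistical machinery under the declared model, not robustness to the
full messiness of real 16S data.

Depth and dispersion defaults are chosen for test power; the emulated
study reports neither.

## Numerical and procedural choices

- Floats serialize at 6 significant digits; writers are deterministic,
  so identical configurations give identical checksums end to end.
- The classic OTU-table dialect (OTUs as rows) is auto-detected against
  metadata sample ids; internally everything is samples-as-rows.
- Ties everywhere break lexicographically after the primary key
  (descending score or degree), making rankings reproducible.
- Problem sizes in the test suite and acceptance script (e.g. 30
  features × 40 samples × B = 1000 × 20 replicates for the permutation
  calibration; three cohort replicates for planted-pathway recovery) are
  the package's chosen simulation scales; they give the calibration
  estimates sub-half-percent standard errors while keeping the default
  runs short.
- Genders are always analyzed as separate strata, mirroring the
  per-gender design of the emulated study.

## Known limitations

- The BIOM reader covers the v1 JSON dialect only (no HDF5).
- The discriminant route's effect-size formula is one published
  convention among several reference-implementation variants; scores are
  reproducible under this package's pinned contract but not guaranteed
  to match other tools digit-for-digit.
- Pearson correlations on compositional profiles carry the usual
  compositionality caveats; no compositionality-aware correlation
  (SparCC-style) is provided by design.
- Permutation p-values are granular at 1/(B+1); at B = 10,000 the
  smallest attainable p is ~10⁻⁴.
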