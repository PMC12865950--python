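# Methods

This note documents the statistical machinery in `paircore`: what each
stage computes, the defaults and why, what the synthetic cohorts do and
do not emulate, and the numerical choices a maintainer would want
written down.

## Study design being modelled

The pipeline targets a paired case–control oral-microbiome design:
patients recruited together with their healthy life partners from the
same households, two sampled niches (saliva, supragingival plaque), and
three sequencing views of the same physical samples — long-read shotgun
metagenomics (WGS), full-length 16S (FL) and short-read 16S V3/V4 (SR);
supragingival samples carry only the two amplicon views.  The pairing
exploits the co-housing effect (partners share a more similar
microbiota than unrelated people), which both motivates the intra-pair
similarity test and dictates restricted permutation schemes downstream.

## Synthetic cohort generator

A hierarchical log-normal–multinomial model, the simplest generator
exhibiting the three structures the analysis assumes: compositionality,
co-housing, and systematic platform bias.

On the log2 scale, the abundance of taxon *t* in subject *i* of
household *j* is

```
a[t,i] = m[t] + H[j,t] + S[i,t] + delta[t] * 1{i is a patient}
```

with global means `m[t] ~ N(0, base_log2_sd²)`, household effects
`H ~ N(0, household_sd²)` shared by both partners, subject effects
`S ~ N(0, subject_sd²)`, and `delta[t] = ±effect_log2` on the
designated disease-/health-enriched taxa (zero elsewhere).  A fixed
per-(platform, taxon) bias `B ~ N(0, platform_bias_sd²)` is added
before softmax — fixed, not noise, because amplification bias is
systematic.  Counts are multinomial at a per-sample drawn depth, so
column sums equal depths exactly.

Defaults (the study conditions): 25 pairs, 120 taxa with 8 + 8
designated, `effect_log2 = 2` (4-fold), `household_sd = 1.0`,
`subject_sd = 0.5` (log2), `platform_bias_sd = 0.5`,
`base_log2_sd = 2`.  Depth regimes: WGS log-normal with mean 35,000
and parameters solved so that 24% of samples fall below 1,000 reads
(the bacterial-read depth profile of host-dominated shotgun samples:
a 12-of-50 low-coverage tail); FL mean 100,000 and SR mean 2,000,000
with σ = 0.35 on the log scale.  Where the emulated design states no
value (effect sizes, variance components), the defaults are calibration
choices a field practitioner would call a strong but realistic
dysbiosis, chosen once.

RNG streams are split (community / depths / counts / metadata) from a
single `SeedSequence`, so dropping samples never perturbs other draws.

What the generator does **not** emulate: taxonomic misclassification,
16S copy-number variation, read-level error, zero inflation beyond
multinomial sampling, and correlations between taxa beyond
compositional closure.  A test passing on these cohorts therefore shows
the statistics behave as designed, not that real data would satisfy
their assumptions.

The test and acceptance suites run reduced conditions — 40–60 taxa,
depths of tens of thousands, 6–25 pairs depending on what the check
needs — chosen as the smallest sizes at which the statistical
behaviours under test are unambiguous.

## Pair similarity

Per pair, similarity of the partners' relative abundance vectors over
the union of taxa (zeros included): Pearson or Spearman correlation, or
Bray-Curtis distance.  The null draws uniform random *perfect
matchings* between the patient and control sets — not arbitrary sample
pairs — preserving the group structure; this is the conservative
reading of "random pairings".  The test is one-sided in the co-housing
direction (higher correlation, lower distance), with the add-one
estimator `p = (1 + #extreme)/(1 + n_perm)`; a two-sided variant is
available by flag.  Correlations are computed on untransformed relative
abundances.  A top-k filter (default 100 taxa by mean relative
abundance, ties broken by taxon name, no renormalisation) reproduces
the filtered variant of the analysis.

## Alpha diversity

SRS (scaling with ranked subsampling) normalises each counts column to
a target depth Cmin: scale by `Cmin/depth`, keep integer parts, then
hand the remaining reads one each to the taxa with the largest
fractional parts; fractional-part ties are broken uniformly at random
from the module seed.  Columns below Cmin are dropped and reported.
Cmin policies: `fixed` (e.g. 1,000 reads for sparse shotgun data) or
`lowest_sample`.

Indices: Shannon `−Σ p ln p` (natural log) and **Gini-Simpson**
`1 − Σ p²`.  The Simpson family has two conventions with opposite
directions; this package reports the Gini-Simpson complement —
anything comparing against `Σ p²` directly must negate.

Group tests are gated: Shapiro-Wilk (threshold 0.05) on the pair
differences selects between the paired t test (with a 95% CI on the
mean difference) and the Wilcoxon signed-rank test; unpaired mode gates
on per-group Shapiro plus Levene across groups, selecting the pooled
two-sample t or the rank-sum test.  Applying the normality gate to pair
differences (rather than raw values) is the statistically coherent
target for a paired test; the gate's type-I behaviour is verified by
simulation under Normal and Cauchy nulls.
`paired_on_complete_pairs` first drops pairs broken by depth
exclusion, emulating re-analysis of depth-filtered data (the companion
`unpaired` mode covers the same samples without their pairing).

## Beta diversity

Bray-Curtis `d(x,y) = 1 − 2Σmin(x,y)/(Σx+Σy)`; classical PCoA by
eigendecomposition of the Gower-centred squared-distance matrix
(negative eigenvalues reported, their axes dropped).

**PERMANOVA** partitions the Gower-centred matrix sequentially
(Type I) with the group term entered last after the covariates, so the
group pseudo-F is covariate-adjusted; sequential SS is exactly additive
(total = terms + residual).  The paired design demands a restricted
null: permutations swap the patient/control labels independently within
each pair — the exchangeable scheme under pairing.  The 2^n_pairs swap
space is enumerated exhaustively whenever it is no larger than the
requested permutation count (giving exact, granular p values; the
identity is included, which preserves the add-one guarantee), and
sampled otherwise.  Unpaired samples are excluded under this scheme.  A
`free` scheme (full sample permutations) matches a standard PERMANOVA
and is cross-checked against scikit-bio's implementation in the tests.

**Beta-dispersion**: samples embedded by full-rank PCoA; squared
distances to the *group centroid* subtract the imaginary-axis
(negative-eigenvalue) contribution, clamped at zero — the standard
correction.  The one-way F on centroid distances is tested by freely
permuting labels, recomputing centroids per permutation.  Centroids,
not spatial medians.

**Mantel**: correlation (Pearson or Spearman) over strictly-lower-
triangle entries, null by relabelling one matrix, one-sided for
positive association — platform concordance is directional.  The panel
runs all platform pairs × {no filter, mean relative abundance ≥ 0.1%,
prevalence ≥ 30%} × both correlations, BH-adjusted across the whole
panel; for the filtered variants removed taxa are summed into an
`Others` row so compositions stay closed.  Taxon overlap reports every
Venn region (region counts sum to the union) and the fraction of the
union detected by all platforms; `Others` rows never enter the sets.

## Differential-abundance engines

Three engines, deliberately *simplified stand-ins* whose fidelity
target is the statistical role — compositional paired testing,
covariate linear modelling, bias-corrected modelling — not numerical
parity with any published package.  All use Benjamini-Hochberg with the
adjusted-p threshold 0.1 (a deliberately lenient per-engine cut-off;
the consensus step supplies the real stringency), and the convention
that positive effects mean higher in patients.

**clr_paired** — per Monte-Carlo instance (default 128): draw each
sample's proportions from Dirichlet(counts + 0.5); CLR-transform
against either all retained taxa or the `lvha` denominator (taxa with
below-median CLR variance *and* above-median mean relative abundance,
recomputed per instance; falls back to all taxa if empty); Wilcoxon
signed-rank on within-pair CLR differences per taxon; BH per instance.
Reported p and adjusted p are means across instances; the effect
("diff.btw") is the across-instance median of the per-instance median
pair difference, and the standardised effect divides by 1.4826 × the
median MAD of the pair differences.  The signed-rank test is a
vectorised normal approximation with tie and continuity corrections
(validated against `scipy.stats.wilcoxon` in the tests) so that 128
instances × all taxa stay fast.  Only complete pairs enter.  The
engine pre-filters with the low-count rule (below).

**linear_covariate** — low-count filter: drop taxa with fewer than 10
reads in more than 70% of samples (strict inequalities on both sides).
TMM normalisation factors (reference column by upper-quartile
proximity; 30% trim on M, 5% on A; factor 1 fallback when a column
shares no positive taxa with the reference — the singleton-pairing
case), response `log2 CPM` with a 0.5 offset.  Per-taxon OLS on
`group + covariates + pair` with the pair as *fixed* blocking effects —
a documented simplification of estimating an intra-block correlation —
and uniform observation weights rather than mean-variance precision
weights, compensated by empirical-Bayes variance shrinkage: residual
variances are shrunk toward their mean with a method-of-moments prior
df, and the group coefficient is tested with a moderated t.  CIs come
from `effect ± t(0.975, df_residual) × se`.  A rank-deficient design
(covariate collinear with group) yields NA records for every taxon.

**bias_corrected** — prevalence filter 0.1 first ("present" = strictly
positive, matching common usage).  Structural zeros — taxa absent from
one whole group — are flagged, reported with the direction of the group
that carries them, and excluded from modelling *and* from the
consensus, since such taxa are usually carried by a handful of
subjects.  Zeros are missing on the log scale; per-sample offsets
(median over taxa of log count minus the taxon's grand mean) absorb
depth and sample-specific bias; each taxon's offset-adjusted log counts
are regressed on group + covariates over its observed samples.  The
sensitivity sweep refits with zeros replaced by each pseudo-count in
0.01…0.5 (ascending); `sensitivity_passed` requires the significance
verdict to be identical across the whole grid.  Pairing is not
modelled, mirroring the bias-corrected method family's lack of paired
testing.

## Consensus ("core dysbiosis")

Evidence rows are identifications: (taxon, material, platform, engine,
direction) plus optional robustness flags.  A taxon is called when

1. it has **≥ 3 evidence rows** — rows, not distinct engines: three
   identifications by a single engine on two platforms qualify, a
   reading forced by published core sets containing such patterns;
2. the direction is **unanimous** (a strict-majority rule exists but is
   off by default; the published tables are unanimous per taxon, so the
   default cannot distinguish the two readings); and
3. **≥ 2 sequencing platforms** contributed.

Robustness fractions (external rank-based identification, pseudo-count
sensitivity, covariate-rerun agreement) are averaged over rows with
non-null flags.  `call_core` is order-invariant and idempotent.  The
packaged evidence tables transcribe the published species and genus
identification tables; both are fixed points of the rules (20 species,
12 genera).  The published text summarising the genus direction split
disagrees with the genus table as printed; the per-direction genus
count is therefore reported from the table, not asserted against the
text.

**Re-pairing cross-validation** wraps any analysis that consumes a pair
map: each permutation replaces the pairing with a uniform random
perfect matching (which may coincide with the true pairing — leaving it
in keeps the null unbiased), reruns the analysis, and reports observed
vs permuted mean and the observed value's empirical quantile.  Failed
permutations are dropped and counted.

**Batch integration** concatenates the platform count tables of one
material (each physical sample appears once per platform), applies the
low-count filter, and refits the linear-covariate and bias-corrected
models with platform dummies added.  The group threshold tightens to
adjusted p ≤ 0.01 (compensating the artificially tripled sample
count); a taxon is *robust* in an engine when its group term passes
while its platform block shows no batch effect — a joint F test on the
platform dummies, BH-adjusted, above 0.05 (the platform-term threshold
is this package's choice).  The robust set is monotone non-increasing
in the group threshold.  The joint fit replaces zeros with the smallest
grid pseudo-count so one shared design serves all taxa.

## Numerical choices and degenerate inputs

- Add-one permutation p values everywhere a null is sampled; exact
  enumeration counts the identity instead.
- BH is implemented directly (step-up, monotone, capped at 1, original
  order restored) and property-tested against statsmodels.
- SRS ties in fractional parts are broken uniformly at random; the
  allocation is validated against a brute-force enumeration oracle on
  small columns.
- Relative tables derived by non-renormalising filters (top-k,
  mean-abundance without collapse) live on a sub-simplex and are marked
  non-strict; freshly read or normalised tables must have unit column
  sums to 1e-9.
- All-zero columns: rejected when converting to relative mode; two
  all-zero samples make Bray-Curtis undefined and raise.
- Degenerate dispersion (all samples identical) returns p = 1 with zero
  centroid distances.
- t quantiles come from `scipy.stats.t.ppf`; the test suite checks them
  against an independent inversion of the t CDF by root finding
  (df = 42 → 2.0181).

## Known limitations

- The engines trade fidelity for transparency: no REML/mixed models, no
  precision weights, no iterative bias estimation.  They are suitable
  for studying the consensus machinery and for cohorts of this size,
  not as drop-in replacements for the published tools.
- The generator's platform bias is taxon-fixed and multiplicative;
  real amplicon bias can be abundance-dependent.
- Covariates are handled complete-case with a warning; no imputation.
- PERMANOVA reports covariate p values under the same within-pair swap
  null used for the group term; only the group term's null is the
  design-exact one, and covariate p values should be read descriptively.
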