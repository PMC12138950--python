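# Methods

`metaregnet` implements a multi-cohort procedure for discovering
transcriptional regulators of a target gene and validating them end to end
on synthetic data with planted ground truth.  This note documents the models,
the estimators, the synthetic study conditions, and the numerical choices
that were genuinely open.

## The discovery chain

Given expression cohorts measured on heterogeneous platforms, the pipeline

1. normalizes each cohort (counts: median-of-ratios size factors + a
   variance-stabilizing transform; intensities: quantile normalization +
   empirical-Bayes batch adjustment),
2. intersects gene lists into a common gene space and stratifies each cohort
   by tumor subtype,
3. infers one signed mutual-information network per cohort x subtype
   (permutation significance, bootstrap support, DPI pruning, Pearson sign),
4. intersects all networks into a consensus (edge present everywhere, same
   sign everywhere; weight = mean MI),
5. extracts the consensus regulators of the focal gene and keeps those whose
   pooled correlation passes |r| > 0.4 with p < 0.05 in *both* subtypes
   (Fisher-z random-effects meta-analysis across cohorts),
6. keeps regulators with at least one canonical binding site in the focal
   gene's 3-kb promoter or first intron (PWM scan at 85% relative score,
   exact-consensus string filter), and
7. attaches supporting evidence: cross-species site conservation, regulon
   over-representation, and RT-/ChIP-qPCR quantification.

## Mutual information and its null

MI is the plug-in estimator on rank-based equal-frequency binnings
(B x B contingency table, bits).  Rank binning makes the statistic exactly
symmetric and invariant to strictly monotone transforms, and gives every
profile the *identical* marginal bin multiset.

Significance uses an empirical permutation null: `n_perm` (default 1000)
permutations of the TF profile, each scored against all targets.  Under rank
binning the null distribution of MI(perm(tf), target) depends only on the
two marginal multisets, which are the same for every profile, so the null is
exactly exchangeable across TFs; by default the per-TF nulls are pooled into
one reference pool of size `n_perm x n_targets x n_tfs` (empirical floor
~1.1e-7 at desk scale).  Without this second pooling level the BH-adjusted
floor is `3.3e-6 * m / k` where k is the number of pairs at the exact
per-TF floor, which makes any adjusted cutoff at or below 1e-3 a cliff that
depends on how many strong edges the data happen to contain.  Set
`pool_across_tfs=False` for strictly per-TF pools.

Benjamini-Hochberg adjustment runs over the full TF x target family.  The
default cutoff in `TrnParams` is the cohort-scale value 3.28e-7; at desk
scale (hundreds of targets) the pooled-null resolution cannot reach it, so
the pipeline's operating default is 1e-3.

**Bin count.**  `TrnParams(mi_bins="auto")` uses floor(sqrt(n)).  At
n = 100 that is B = 10, which concentrates (B-1)^2 = 81 degrees of freedom
of plug-in bias in the null tail while adding almost no signal for strong
edges, so genuine edges sit at the detection cliff (measured: the same
planted edge scores adjusted p ~1.6e-3 at B = 10 and ~2e-5 at B = 6).  The
pipeline therefore operates at B = 6; the power loss from coarser binning is
negligible relative to the null-tail gain for n of order 100.

**Bootstrap support.**  An edge's support is the fraction of
sample-with-replacement resamples in which its MI strictly exceeds that
resample's significance floor — the (1 - `boot_floor_alpha`) quantile
(default 1e-3, i.e. near the max) of a permutation null recomputed on the
resample (`n_perm_boot` = 30 permutations x candidate targets).  The null
permutes the *original* profile and then applies the same bootstrap column
indices: duplicated samples inflate plug-in MI even between independent
profiles, so a valid null must preserve the resample's duplication
structure.  `TrnParams` retains edges with support >= 0.95; the pipeline
operates at 0.8, because each resample carries only ~63% of the samples and
the floor sits near the max of the per-resample null, so demanding 95%
re-detection is far stricter than the permutation gate itself — measured
supports are ~0.92-1.0 for genuine planted edges and ~0.05 for null edges,
so 0.8 separates them cleanly.

**DPI.**  For every connected triplet the strictly weakest edge is removed
when its MI < min(other two) - epsilon, decisions taken on the input graph
and applied simultaneously; exact ties are kept, and the operation is
idempotent.  `TrnParams` defaults to the strict epsilon = 0; the pipeline
operates at epsilon = 0.15 bits because a tightly co-activated regulator
module produces TF-TF MI nearly as large as TF-target MI, and strict DPI
then deletes genuine direct edges — the standard failure mode that ARACne
practice answers with a tolerance of ~0.1-0.15.

**Sign.**  The sign of the Pearson correlation between the two profiles;
r = 0 or a constant profile leaves the edge unsigned, and unsigned edges are
dropped by the sign-consistent consensus.

## Consensus, regulons and topology

The consensus keeps edges present in every source network with an identical
sign (a flag relaxes this to presence only) and averages their MI.  Regulons
are classified as *reliable* with more than 15 targets and *balanced* with
at least 15 positive and 15 negative targets — the two quoted conventions
are preserved exactly (> 15 vs >= 15).  Degree distributions are summarized
(median, max, histogram) and tested for power-law adequacy with a
Clauset-style discrete MLE: the exponent maximizes the zeta likelihood on
the tail x >= x_min, x_min minimizes the KS distance (scan capped at 20
candidates for tractable bootstraps), and the adequacy p-value is a
semiparametric bootstrap (tail from the fitted model via the standard
continuous-inversion approximation, body resampled, full refit per
replicate; 500 replicates by default).

## Correlation meta-analysis

Cohort-level Pearson correlations enter as z = atanh(r) with variance
1/(n-3).  Between-study variance uses the DerSimonian-Laird moment
estimator; the pooled estimate, normal-theory CI and two-sided p are
back-transformed with tanh.  With zero heterogeneity the estimate reduces
exactly to the fixed-effect inverse-variance mean (tested), and the
implementation is cross-checked against `metafor::rma(method = "DL")`
through Rscript in the test suite.  REML/HKSJ variants are out of scope.
The regulator filter applies |pooled r| > 0.4 (strict, on the
back-transformed value) and p < 0.05 in every required subtype.

## Binding sites and conservation

PWMs are parsed from JASPAR PFM text (via Biopython) and converted to
log-odds with pseudocount kappa = 0.8 distributed by the background
composition (uniform 0.25 by default).  A window scores
rel = (S - S_min)/(S_max - S_min); both strands are scanned and hits with
rel >= 0.85 are reported with 1-based forward-strand starts (promoter
positions also map to TSS-relative coordinates -3000..-1).  Windows
containing N score 0; overlapping hits are all reported.  The canonical
filter keeps hits whose forward-strand match equals the motif's literature
consensus (forward or reverse-complement form); motifs without an
established consensus pass through on score alone.

Conservation is exact base identity with the human row of a multiple
alignment, per species and per human-base position; a gap on either side is
non-conserved, and a site is *fully conserved* iff every cell matches.  Real
alignments are ingested pre-aligned; synthetic panels are gap-free.  A small
Needleman-Wunsch global aligner (match +2 / mismatch -1 / gap -2,
deterministic diagonal > up > left tie-break) supports pairwise desk-scale
work; progressive multiple alignment is deliberately out of scope.

## Enrichment and qPCR

Over-representation uses the hypergeometric upper tail with the harmonized
cross-cohort gene space as the universe (not the whole genome; configurable)
and BH adjustment across the collection; enrichment only, no depletion test.

RT-qPCR folds use 2^-ddCt with the arithmetic mean of the reference-gene Cts
(equivalent to a geometric mean of linear quantities); the calibrator's fold
is exactly 1 by construction.  ChIP enrichment is
% input = 100 * 2^((Ct_input - log2(1/f)) - Ct_IP) with input fraction
f = 0.04 by default; the matched IgG % input is subtracted per cell line and
site, and negative nets are kept (flagged) so rank tests stay unbiased.
Cell lines are compared per site by Kruskal-Wallis and, when p <= 0.05, by
pairwise Mann-Whitney U (exact for group sizes <= 8) with BH correction.
Note the resolution limit this implies: with triplicates the exact two-sided
Mann-Whitney cannot go below p = 2/C(6,3) = 0.1, so triplicate pairwise
calls can never reach p < 0.05 under the exact test; the package reports the
exact p-values as they are.

## Synthetic study conditions

The generator's defaults are the package's study design, not tuning knobs:

- 300 genes, 30 TFs, three cohorts (counts, intensity, intensity), two
  subtypes x 100 samples each; TF out-degrees ~ discrete power law
  (exponent 2.5), background edge strengths U(0.4, 0.9), target noise
  sd 0.3.
- The focal target is regulated by 6 TFs with strengths U(0.85, 0.95) whose
  activities share a program factor with equicorrelation rho = 0.8,
  sign-aligned with each edge (a_i = sigma_i (sqrt(rho) f + sqrt(1-rho) e_i)).
  The co-activation is essential, not cosmetic: with independent activities
  the marginal correlation of each of six additive regulators is bounded by
  1/sqrt(6) ~ 0.41 even at zero noise, so no design with i.i.d. activities
  can pass the dual-subtype |r| > 0.4 filter robustly.  Biologically this
  mirrors a coordinated program (e.g. EMT) whose member TFs rise and fall
  together.
- Counts platform: mu = s_j exp(m_g + 0.7 * latent) with lognormal size
  factors (sd 0.2), negative-binomial dispersion alpha(mu) = 3/mu + 0.05
  (chosen so the dispersion-trend fit is well-posed).  Intensity platform:
  8 + N(0,1) gene baselines + 0.6 * latent + per-(batch, gene) offsets
  (sd 0.2, two batches) + measurement noise sd 0.12.
- Promoters: uniform base composition, 3-kb promoter + 2186-bp first
  intron, planted consensus sites written verbatim (minus-strand sites as
  reverse complements), no overlaps.  Synthetic per-TF PWMs put 85/100
  counts on the consensus base per column, so planted sites score a
  relative score of exactly 1.
- Ortholog panels: 11 non-human species, i.i.d. substitutions at 12% per
  site outside planted sites and 0% inside by default; substitutions always
  change the base.
- qPCR plates invert the quantification formulas exactly, so zero-noise
  recovery is exact; default Ct noise in the pipeline is sd 0.05.

What the generator does *not* emulate: read-level sequencing artifacts,
probe-level microarray structure, gene-gene correlation beyond the planted
network, alignment gaps, or amplification-efficiency drift.  Passing the
end-to-end test therefore demonstrates that the estimators and filters
compose correctly and recover a planted signal at realistic sizes — not
that the pipeline is robust to every artifact of real cohorts.

## Degenerate inputs and tie rules

Constant profiles: MI returns 0 and sign assignment flags the edge
unsigned.  Quartile classification assigns a value satisfying both boundary
conditions (degenerate spread) to `mid`.  Quantile normalization gives tied
values the mean of their would-be quantiles.  All-zero moment dispersions
return the trend (0, 1e-8) with a warning.  A single batch is an identity
adjustment; a single sample is an identity quantile normalization (with a
warning).  Empty gene-space intersections, singleton batches, missing
subtype labels, missing references/IgG controls, and out-of-range
probabilities all raise typed errors naming the offenders.

## Problem sizes

The shipped study conditions are desk-scale by design: 300-gene cohorts,
1000 permutations and 1000 bootstraps per network, 500-replicate power-law
bootstraps, 1000-replicate coverage checks.  The full pipeline runs in
about three minutes on one CPU; `scripts/acceptance.py` reruns it from
scratch together with the worked examples and property checks.

## Known limitations

- The plug-in MI bias is not subtracted; all comparisons are against
  empirical nulls with the same bias, which is why the bin count matters.
- DerSimonian-Laird is the only heterogeneity estimator; k = 3 cohorts give
  noisy tau^2.
- The consensus demands sign agreement in all sources; a regulator whose
  mode of action flips between subtypes is excluded by design.
- Bootstrap support and the permutation filter share the expression matrix,
  so support is conditional on candidacy, not an independent replication.
- The power-law p-value uses the standard continuous-inversion sampler for
  the discrete tail, which is approximate for small x_min.
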