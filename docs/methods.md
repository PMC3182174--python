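# Methods

This note documents the statistical procedures implemented in `fatbody`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Spectral-count quantification

Spectral counts are non-negative integers; a missing protein/sample cell is
a count of zero (spectral counting observes absence as zero), never NA.
Counts are corrected by dividing by the sample's total spectral count, so
each corrected column sums to 1 over the pre-filter protein set; this
normalizes for differences in total protein load. log2 values are defined
only for strictly positive corrected counts — no pseudocount is added, and
zeros become missing at the log stage, handled downstream (pairwise-complete
correlations in clustering, complete-case rows in PCA).

Two quantifiability rules screen proteins before testing: a spectral count
of at least `min_count` (default 3) in at least `min_count_reps` (3) of the
replicates of one group, and at least `min_peptides` (2) distinct peptides
in at least `min_pep_reps` (4) replicates of one group. The two rules may
be satisfied by *different* groups by default — the weaker reading of a
criterion that names "one group" separately for each clause — with
`same_group_required=True` available for the stricter reading.

Proteins sharing identical peptide sets are indistinguishable to spectral
counting. They are tracked as redundancy groups; per-protein test output
keeps all members, while multivariate summaries and the non-redundant
count collapse each group to its lexicographically smallest accession.

## Exact rank tests

The two-group test assigns mid-ranks over the pooled data. Without ties
the two-sided p-value is exact: the tie-free null distribution of the
first group's rank sum W is obtained by a subset-sum dynamic program that
enumerates all C(n₁+n₂, n₁) equally likely rank assignments, and
p = 2·min(P(W ≤ w), P(W ≥ w)) capped at 1 — the convention that reproduces
printed small-sample rank-test tables (at n₁ = n₂ = 5 the achievable
two-sided p-values are 2k/252). With ties the enumeration is invalid and
the same statistic is referred to a seeded Monte-Carlo permutation null
(20 000 label shuffles by default, with add-one smoothing); corrected
spectral counts rarely tie in practice. Group sizes below 2 are rejected.

Kruskal–Wallis H carries the standard tie correction. Its p-value is exact
by full enumeration of group assignments when the total n ≤ 12, a shared
seeded permutation null on request, and the χ²(k−1) approximation
otherwise. The multi-protein battery ranks each protein row once and
re-uses those ranks across label permutations, since ranks do not depend
on the grouping.

### Cutoff verification

The nominal α = 0.1 cutoff is verified by permutation: group labels are
reassigned across samples uniformly at random (sampling without
replacement — i.e. a permutation of the observed label multiset, which
preserves the marginal distribution exactly), the whole per-protein battery
is re-run, and the fraction of proteins with p ≤ α is recorded per
iteration (1000 by default). The cutoff is reported as verified when the
mean resampled fraction — the permutation estimate of the per-protein
false-positive rate — does not exceed α. The procedure is seeded and
invariant to protein and sample order.

### Effect classification

Each protein's three contrast p-values (CL/KL, CH/KH, CL/CH) map to one
class at the verified α: G when only the control-group genotype contrast
CL/CH is significant, T when CL/CH is not but at least one knockdown
contrast is, G&T when CL/CH and at least one knockdown contrast are, and
none otherwise. In the full pipeline the classification is applied to
proteins passing the Kruskal–Wallis screen at the same α, mirroring the
screen-then-post-hoc structure of the original analysis.

## Label-ratio processing

Peptides with an absolute calibrated mass error above 5 ppm are discarded
(strictly above: a record at exactly 5 ppm is kept). Proteins identified by
a single distinct peptide across the experiment are eliminated. Protein
log2 ratios are the arithmetic mean of their peptide log2 ratios per
comparison (the averaging step of the upstream quantification software is
described only as "averaged"; the mean is implemented), with the peptide
count kept as a precision weight.

### Reference bridging

Each labeled run measures 2–3 samples; within a triplex only the two
ratios against the lowest channel enter the system, because the third
pairwise ratio is their arithmetic consequence and would double-count
evidence. Per protein, the observed edges form a subgraph of the
comparison graph and the sample values solve the weighted least-squares
system value(a) − value(b) = ratio(a, b) with reference nodes fixed at 0;
weights are the contributing peptide counts (unit weights by option).
On a tree this is exactly chain summation in log space; with redundant
day-7 bridge runs (three duplexes plus two triplexes in the canonical
layout) the least squares reconciles inconsistencies, and on consistent
data any spanning tree yields identical values. Components without a
reference node are reported as unbridged rather than erroring. The
reference is realized per run: each replicate's day-7 CL aliquot is pinned
at 0, which is how reference-normalized labeled designs are structured.
The day-7 labels follow the collection-age convention (CL7); sources that
index the same samples by injection-relative day 6 refer to the same
design point.

### z-transform, presence and the dual replacement rule

For the rank-based age contrasts, values are z-transformed per protein over
the present contrast samples ((x − mean)/SD, n−1 denominator); proteins
with fewer than two present values or zero variance are flagged constant
and excluded. A protein is eligible for a contrast when present in at
least 3 of the 4 replicates of *at least one* of the two cells — the
criterion names "one group", and the eligibility gate inside the dual
replacement test follows the same one-group reading so the two stages
cannot disagree. Missing z-values are then replaced first with +0.5 and
next with −0.5 (±0.5 SD on the z scale, where SD = 1); the exact rank test
runs for both variants, the protein is retained only if both reach
p ≤ α, and the reported p comes from the +0.5 variant.

## Factorial models

The full-factorial response per protein is the bridged log2 value with
fixed treatment, genotype and age effects, all their interactions, and a
random per-sample intercept. Every fixed effect is a between-sample
contrast, so under the containment convention its F-test denominator is
sample-level variation: the model is fitted on per-sample means, which for
balanced designs equals the classical expected-mean-squares mixed-model
F-test. With a single measurement per biological sample — the default
synthetic design — the random intercept is absorbed into the residual and
the fit reduces *exactly* to the fixed-effects three-way ANOVA (verified to
1e-6 in the tests). Only the containment denominator is implemented;
Satterthwaite approximations are out of scope because no design handled
here has within-sample fixed effects that would make them differ.
Proteins enter the factorial only when present in all 4 replicates of at
least one group × age cell; rows with missing values are dropped
per protein (complete-case). P-values are adjusted per effect across
proteins by Benjamini–Hochberg step-up FDR.

Metabolite (and expression-summary) values are log2-transformed and
analyzed with a two-way factorial ANOVA. Type II sums of squares are the
default for unbalanced data — the conventional choice when the interaction
is not significant, which matches the reported outcome — with Types I/III
selectable (Type III via sum-to-zero contrasts). Levene's check uses the
classic mean-centered absolute deviations (Brown–Forsythe median centering
by flag). The Dixon ratio test uses the classical statistics (r10 for
n ≤ 7, r11 for 8–10, r21 for 11–13, r22 for 14–30) against the standard
two-sided critical tables at α ∈ {0.05, 0.01}; it reports the ratio and a
reject/retain decision rather than a continuous p-value, since software
floors like "p < 2.2e-16" are not Dixon p-values. A rejected extreme is
excluded once before modeling.

## Multivariate summaries

Sample clustering uses distance 1 − Pearson r between sample columns
(pairwise-complete observations, minimum overlap 3; constant columns are
excluded with a warning) and complete linkage, whose merge heights are
monotone. Ties in the agglomeration follow the deterministic smallest-index
order of the linkage implementation. Dendrograms serialize to Newick.
PCA centers each protein (no scaling by default, matching analysis of the
normalized matrix directly; scaling by flag) and decomposes the
sample × protein matrix by SVD; variance fractions sum to 1.

## Synthetic data

The generators plant known effects so recovery is checkable end to end.

* **Counts**: gamma-Poisson (negative-binomial) with
  var = μ(1 + dispersion·μ); per-protein baselines lognormal around
  `count_mean` (default 50, dispersion 0.05, i.e. CV ≈ 0.26 at the mean —
  typical overdispersion for spectral counts); planted group shifts of
  ±`effect_log2fc` (default 1.0) on the log2 mean for a fraction of
  proteins (default 0.1 each for genotype and treatment). Distinct-peptide
  counts are drawn from a per-protein peptide pool (2 + Poisson(3)) as a
  saturating monotone function of the realized count, so the peptide filter
  has realistic bite; a protein observed at all has ≥ 1 peptide.
* **Ratios**: the canonical layout mirrors the labeled experiments — per
  replicate, one triplex per group across the three ages plus the day-7
  bridge runs (duplexes KH/CL, CL/CH, CH/KL; triplexes KL/KH/CL, KH/CH/CL).
  Observed edge ratios are true log2 differences plus N(0, `ratio_sd`)
  (default 0.3); a protein is dropped from a whole comparison with
  probability `missing_rate` (default 0.1), missing completely at random —
  the real missingness mechanism is uncharacterized, and MCAR is the
  neutral assumption. Four replicates per group mirror the labeled design.
* **Metabolites**: log2-scale values with additive genotype/treatment
  shifts and N(0, `ratio_sd`) noise; group sizes default to
  `n_replicates` and are set per group when mirroring the unbalanced
  field collections (e.g. 16/15/15/17 bees).

One root seed sequence spawns independent sub-streams per generator, so
outputs are byte-identical under a fixed seed regardless of which
generators run. Sample pooling (three carcasses per sample) is not modeled
explicitly; the noise SDs are the net, post-pooling variabilities.

What passing tests show: the filters, exact tests, bridging algebra,
classifier and models behave correctly on data with the assumed structure,
at the designed sizes (hundreds of proteins, 4–5 replicates). What they do
not show: robustness to structured missingness (abundance-dependent
dropout), peptide-level interference or ratio compression, correlated
proteins, or batch effects — none of which the generators emulate.

## Problem sizes and numerics

Tests and acceptance checks run at 150–300 proteins with the study's
replicate counts: large enough for binomial bands (null calibration is
required within 3·√(α(1−α)/n) of α; power checks at ≥ 80–90% recovery) and
small enough to keep the suite fast. Monte-Carlo p-values use add-one
smoothing; least-squares bridging uses `lstsq` with default rcond;
equality of the degenerate mixed fit with the fixed ANOVA is asserted at
1e-6; exact enumerations are compared at 1e-14. The Kruskal–Wallis χ²
approximation at 4 groups of 5 is mildly conservative (permutation size
≈ 0.09 at α = 0.10), which the cutoff-verification machinery makes visible
rather than hiding.

## Known limitations

* The effect classifier follows the printed contrast p-values; published
  text and table disagree by one protein on the G&T count (15 vs 14 rows),
  and the package reproduces the table.
* Exact Kruskal–Wallis enumeration is limited to total n ≤ 12; beyond
  that, permutation or χ² approximations apply.
* Dixon decisions are table-driven at α = 0.05/0.01 only.
* The mixed model supports a single random per-sample intercept — no
  longitudinal covariance structures.
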