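# Methods

## Scope and model

`ctmeth` implements the statistical core of a cell type-specific WGBS
case/control differential-methylation study: two FANS-sorted nuclei
populations (NeuN+ neurons, OLIG2+ oligodendrocytes) from schizophrenia
cases and matched controls, with per-CpG methylated/total read counts as
the primitive observation. The pipeline stages are (1) per-CpG
covariate-adjusted differential methylation, (2) DMR calling, (3)
matched-null region enrichment, (4) permutation and directionality
statistics, (5) two EWAS power simulations, and (6) GWAS co-localization —
plus a synthetic-data generator with a planted-truth table that makes every
stage testable without any external download.

## Per-CpG tests (`diffmeth`)

**Arcsine weighted regression ("DSS-style").** Per site and sample,
`Y_i = arcsin(2 (X_i + 0.5)/(N_i + 1) − 1)`. Under binomial sampling at
depth `N_i` the delta method gives `Var(Y_i) ≈ 1/N_i` independent of the
methylation level, so the coefficient of the target term in a weighted
least-squares fit with weights `N_i` has the known-variance covariance
`(D'WD)^{-1}`, and the Wald statistic `coef/SE` is referred to the standard
normal. The pseudocounts (an Anscombe-type correction) keep the transform's
argument inside (−1, 1). This is a deliberate approximation of a
beta-binomial WGBS model: no dispersion shrinkage and no smoothing.
Statistic values are comparable in sign and ranking to a full
beta-binomial fit, not numerically identical.

A consequence worth knowing: the weighted test assumes read-level binomial
noise only. When biological replicate variance is present (as in real data
and in the generator's default, per-individual SD 0.05), the test is
anticonservative at deep sites and — because the 1/N binomial term then
dominates only at shallow sites — systematically *depleted* of small P at
low coverage relative to high coverage. We measured, on null data with
replicate noise, rejection at α=0.05 of ~0.015 for sites at 3× against
~0.077 at 30×, while the linear model is flat across coverage. This is the
coverage correction the method is used for; absolute calibration holds
under its assumed sampling model (measured 0.047 at α=0.05,
Kolmogorov–Smirnov uniformity P = 0.55 on ~24k null sites with binomial
noise only).

**Linear model.** Per-site OLS of raw fractions `X/N` (missing where
`N = 0`) on the same design, t reference with `n − p` degrees of freedom.
Its coefficient is directly interpretable as a methylation-fraction
difference, and for a two-group design it reduces exactly to the pooled
two-sample t-test (asserted against scipy to 1e-12). Sites with zero
residual variance are skipped and counted, never assigned P = 0.

**Conventions.** Reference levels are NeuN+ and control; a positive
coefficient means higher methylation in OLIG2+ (resp. schizophrenia);
`direction = sign(mean_g2 − mean_g1)` on the raw fraction scale. CpGs whose
dyad (position or position+1) hits a SNP are removed before testing; the
coverage filter keeps sites with ≥ `min_depth` (default 20×) in ≥
`min_fraction` (default 80%) of samples in *every* group. Multiple-testing
adjustment is Benjamini–Hochberg (via statsmodels) or Bonferroni.

## DMR calling (`dmr`)

Significant DMPs (default Bonferroni P < 0.05) on one chromosome are
chained greedily while consecutive significant DMPs are ≤ 50 bp apart;
maximal chains with ≥ 5 significant members become DMRs. Non-significant
CpGs inside a chain neither break it nor count toward the minimum. The
"50-bp region" reading as a gap rule (rather than a span minimum) is a
design choice: it is deterministic, order-independent, and reproduces
"≥5 DMPs within 50 bp" on dense clusters; a `min_span` option exposes the
alternative reading. Region coordinates are 0-based half-open
`[first_pos − 1, last_pos)`, so five DMPs at positions 100..140 span 41 bp.
`area_stat` is the exact sum of member statistics; `mean_diff` the mean
signed group difference over significant members. Output equals a
brute-force enumeration of maximal qualifying chains (property-tested).

## Matched-null enrichment (`enrichment`)

For each observed region, null regions are drawn uniformly on the same
chromosome with identical length until GC content matches within 1%
(ambiguous bases excluded from both numerator and denominator); k = 100
such sets form the empirical null. Draws overlapping any observed region
are rejected; after `max_tries` (default 10,000) the closest-GC candidate
is used and logged. Per-region 1:1 matching implies the set-level
length/chromosome matching automatically. The enrichment ratio is
observed/mean(null); the empirical P counts null sets *at least as
extreme* (ties count against significance — conservative). A zero count is
reported as an upper bound "< 1/k", never as 0. Fisher enrichment reports
the sample odds ratio `ad/bc` (∞ when `bc = 0`) with the exact
hypergeometric two-sided P. Genic annotation uses promoter = within 3 kb
of a TSS, distal intergenic = further than 1.5 kb from any gene boundary,
with precedence promoter > exon > intron > flank.

## Permutation and directionality statistics (`cc_stats`)

Diagnosis labels are permuted within cell type only, preserving group
sizes and the covariate rows exactly; the chosen site test is re-run per
permutation (default 100) and the summaries needed downstream are stored
(top-quantile |stat|, per-site directions and P at tracked sites,
directional-bias fraction). The directionality test is a two-sided exact
binomial test against 0.5, using the minimum-likelihood rule (sum of
probabilities of outcomes no more likely than observed) — this reproduces
the 13/14 → P = 0.0018 and 63/83 → P = 2.4e-6 anchors; the doubled-tail
rule is available by flag. Cross-study concordance joins sites with an
external direction table, bins by the external P on a −log10 scale
(default edges 0,1,2,3,4,∞ — the external study's own binning is not
knowable, so the edges are configurable), and tests each bin's
same-direction fraction against 0.5; permutation runs attach the per-bin
null concordance distribution. The QQ summary reports sorted observed vs
expected −log10 P and `lambda = median(chi2)/chi2_0.5`.

## Power simulations (`power`)

**Simulation 1 (per-CpG power).** Per CpG: control mean ~ truncated
normal(0.7, 0.05) on [0.1, 0.9]; SD ~ uniform(1e-7, 0.2); effect ~
uniform(0, 0.20); 25 control and 28 case individuals drawn from truncated
normals on [0, 1] (the per-individual truncation interval deliberately
differs from the per-CpG mean's [0.1, 0.9], following the generative
recipe literally); fraction regressed on the diagnosis indicator. The
regression is computed in its algebraically identical pooled-t form,
vectorized. Truncated normals are sampled by exact inverse-CDF (no
rejection), with underflow guarded by collapsing onto the nearest bound.
At 100,000 CpGs: ~9.5–9.9% of effects in [0.01, 0.04] reach P < 1e-5
(under the "less than 20%" headline) and ~51.5% of effects > 0.08 do
(the "about half" headline).

**Simulation 2 (top-k FDR).** 5000 causal CpGs receive effects from
Beta(p1, p2); their P values come from the simulation-1 cohort model
(the only generative model defined — causal P had to come from
somewhere, and this is the natural choice); 9,995,000 null CpGs receive
uniform P. All 10 million are ranked ascending (stable ties) and
FDR = 1 − (#causal in top 1000)/1000. The default case size is 28 (the
neuronal case count). A 5×5 grid over [0.1, 1.5] × [20, 51] brackets
FDR from ~0.001 to ~0.95 and always contains cells near 0.5; band cells
also report the effect/P distributions of true positives inside the top k
(which are strongly selected upward relative to the Beta mean). The
top-k computation uses argpartition, so the full-scale run costs ~1 s per
grid cell; a scaled-down instance at matched `n_causal/n_total` and
`k/n_total` ratios gives the same FDR within replicate noise
(property-tested).

## GWAS co-localization (`gwas`)

SNPs are binned by empirical OR quantiles of the full table (ties to the
lower bin). For each query CpG, SNPs within a 1-kb window (read as a
1-kb-wide window centered on the CpG, i.e. ±500 bp; a flank mode gives
±1 kb) are counted per quantile. k = 100 background sets of equal size are
drawn from the background pool (conventionally CpGs with case/control
P > 0.1, with the query set excluded), and the empirical P per quantile is
the fraction of background sets with a *strictly greater* count — note the
deliberate contrast with the region-enrichment "≥" rule; both follow their
respective conventions and are documented at the call sites.

## Synthetic data (`simulate`)

The generator's defaults are the study conditions, not tuning knobs:
cohort sizes 25/28/20/22; planted cell type DMPs with |Δ| ~ normal(0.326,
0.10) truncated symmetrically at ±0.25 (so the planted mean is exactly
0.326), 64% NeuN-hypermethylated; per cell type 50 szDMPs with |β| ~
normal(0.06, 0.03) truncated at ±0.04, 93% hypomethylated in cases at
NeuN+ sites and 75.9% hypermethylated at OLIG2+ sites, half placed inside
cell type DMPs; read depth ~ negative binomial(mean 25, dispersion 5) —
the depth distribution's shape is our choice, motivated by the >25× mean
coverage of the emulated study; per-individual fractions ~ truncated
normal(group mean, 0.05) on [0, 1], matching the power-simulation model;
covariate nuisance effects default to zero so acceptance-style checks
isolate the planted signal.

Two numerical choices matter. First, group means are placed symmetrically
around the per-CpG baseline and the *pair is shifted* into [0.1, 0.9]
rather than clipped, so the realized cell type difference equals the
planted delta exactly and the per-individual truncation on [0, 1] stays
essentially unbiased — naive clipping would shrink realized differences
and bias the recovered mean below 0.326. Disease betas are clipped only if
a group mean would leave [0.02, 0.98], with the realized beta recorded in
the truth table. Second, the genome generator removes accidental CG
dinucleotides from the background sequence and plants CGs at the requested
density plus occasional dense clusters (5–8 CpGs spaced 6–10 bp), so that
DMR-scale clusters exist; CpG positions are then re-derived by scanning
for "CG", making "every CpG sits at a CG" true by construction.

What the generator does *not* emulate: read-level bisulfite sequences and
conversion failure, alignment artifacts, spatial correlation of
methylation beyond the planted clusters, linkage structure among GWAS
SNPs, and realistic covariate–methylation confounding (unless nuisance
effects are switched on). Passing tests therefore demonstrate the
statistical machinery on data satisfying the model's assumptions, not
robustness to everything real WGBS data can do.

## Problem sizes used in the shipped tests

The test suite runs the genome-scale stages at desk scale as its own
design choice: a 500-kb single-chromosome genome (~6,000 CpGs) for unit
and property tests, a two-chromosome 4-Mb genome (~49,000 CpGs) for the
end-to-end recovery checks, 100,000 simulated CpGs for power simulation 1,
and the full 10-million-CpG, 5×5-grid run for power simulation 2 (cheap
once vectorized). Permutation tests use 20 permutations on 1,500-site
subsets; the library default remains 100.

## Known limitations

* The arcsine test is an approximation of a beta-binomial model; see the
  calibration discussion above.
* DMR chaining is greedy-maximal by gap; methods that smooth first can
  merge or split differently.
* The matched-null sampler can fall back to the closest-GC candidate on
  extremely GC-skewed chromosomes (always logged and counted).
* The concordance bins and the external-study site universe are
  configurable because no canonical values exist.
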