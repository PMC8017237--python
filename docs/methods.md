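# Methods

## Study design and data model

The pipeline assumes a 4 × 2 factorial design: ages 1, 20, 65 dph and
adult crossed with sex, three pooled replicates per cell (24 samples).
Pooling is modelled implicitly — each sample is one negative-binomial
draw, with the variance reduction from pooling absorbed into the
dispersion. Internally all genomic coordinates are 0-based half-open;
GTF input (1-based inclusive) is converted exactly once on read, and
bedGraph output is written natively 0-based.

## Differential expression

Counts are normalised by trimmed-mean-of-M-values (TMM): the reference
sample is the one whose library-scaled upper quartile is closest to the
mean upper quartile; gene-wise log2 ratios against the reference are
trimmed 30% from each tail (5% on average log-abundance) and averaged
with inverse delta-method-variance weights; factors are rescaled to
geometric mean 1. log-cpm uses a prior count of 2 scaled by effective
library size. Both match edgeR's implementation to machine precision
(verified in the test suite against `calcNormFactors` and `cpm`).

Each gene is fitted by an NB2 GLM (log link, offset = log effective
library size) on the 8 group means. Dispersion: per-gene adjusted
profile likelihood MLEs (Cox–Reid correction), a lowess trend of log
dispersion on average log-cpm, and log-scale shrinkage of each gene
toward the trend with a prior weight of 10 degrees of freedom against
the 16 residual df. As the prior weight goes to infinity the estimates
collapse to the trend; at zero they equal the raw MLEs (tested).
On synthetic data with true dispersion 0.05 the estimator is unbiased
to within a few percent.

Stagewise testing: stage 1 is a 5-df likelihood-ratio test of the five
contrasts jointly (the reduced model is fitted on the null-space basis
of the contrast matrix), BH-adjusted across genes at FDR 0.05; stage 2
reports per-contrast Wald tests Holm-adjusted within each screened
gene. Holm was chosen for the within-gene family because it is
uniformly valid with no independence assumptions. Genes never receive
stage-2 results without passing the screen.

The finite-sample chi-squared approximation of the LRT at n = 3 per
group is mildly liberal at the raw-p level (≈ 9% below 0.05 under the
null); the BH-FDR-controlled screen, which is what the pipeline reports,
shows ~0.1–0.2% positives under a 2,000-gene global null.

## Pattern classification

The per-gene noise scale is the pooled within-group SD of log-cpm over
all 8 groups (16 df). This measures replicate noise without being
inflated by real age effects, which per-age SDs would conflate; the
choice is configurable. Sexes are pooled for the age means. The 1.65
SD threshold corresponds to a one-sided standard-normal tail of 4.95%.
Constant genes (zero SD) are labelled EEE and flagged rather than
producing divisions by zero.

## Differential methylation

β and M values use the offset transform M = log2((β + 0.01)/(1 − β +
0.01)); no further normalisation is applied, since the transform is
self-normalising per site. Filters are applied on raw counts: mean
coverage ≥ 5× per sample and ≥ 6 methylated reads summed over samples,
both boundaries inclusive (tested at the exact boundary).

The moderated linear model is fitted per cytosine on M-values with the
same 8-group design and 5 contrasts as expression. Residual variances
are shrunk toward a scaled inverse-chi-square prior whose parameters
are moment-fitted on log variances (trigamma inversion by Newton's
method); moderated t and the omnibus moderated F gain the prior df.
The implementation reproduces limma's `eBayes` p-values, prior df and
prior variance exactly (atol 1e-10 in the R cross-check). BH q-values
can be recomputed on any site subset; on the full set they equal the
originals.

Complete-case handling: by default a site must be covered in all 24
samples; with a lower `min_samples`, incomplete sites are fitted on
their covered samples provided every group remains represented, with
per-site residual df entering the moderation.

Hydroxymethylation is computed on the β scale (ĥ = β_RRBS − β_oxRRBS)
rather than by raw count subtraction because coverage differs between
assays; negative values (sampling noise) are clipped to 0 and flagged.
Clipping makes the mean ĥ over low-coverage sites biased upward (by
E[max(−noise, 0)]); the bias vanishes as coverage grows. 5hmC is
reported descriptively only — no locus-wise test — because subtraction
noise at realistic coverage does not support per-site inference.

## TFBS scanning and enrichment

PWMs are built from count matrices with background-weighted
pseudocounts (default 0.1). The scan scores log2(P_pwm/P_bg) summed
over the window, both strands, against a 0-order background estimated
from the scanned sequence set (configurable to uniform) and symmetrised
with its reverse complement so both strands share one null
distribution — this makes the scan exactly strand-symmetric (tested).
Exact p-values come from dynamic programming over scores discretised at
1e-3 log2-odds units; the DP distribution matches brute-force
enumeration over all 4^L words for L ≤ 8 to 1e-9, and its total mass is
1 ± 1e-6. Matches are retained at p < 1e-4. Windows containing N are
skipped.

Enrichment uses the binary per-sequence unit (sequence with ≥ 1 match)
so the chi-squared's independence assumption holds at the sequence
level; total-match-count mode is available. Pearson chi-squared
without continuity correction, BH across motifs; a zero margin is
reported as missing with a reason rather than silently as 0. Fold
changes use Haldane-corrected proportions to stay finite.

## Expression–methylation integration

The association model is y_gs = a + b·m_gs + u_g + v_s + e_gs with
log-cpm response, the per-(gene, sample) mean M-value over the gene's
uniquely annotated cytosines in one region class as covariate, and
crossed random intercepts for gene and sample. REML is maximised over
the two variance ratios with a profiled criterion; the marginal
covariance is inverted through the Woodbury identity on the
(genes + samples)-dimensional random-effect space, so the fit scales
with the number of levels (about 9 s at 500 genes × 24 samples).
Convergence tolerance 1e-8 on the criterion; variance components at
the boundary flag the fit as singular rather than being hidden. Wald
p-values are reported for the slope. The fit matches `lme4::lmer`
(slope and SE to 1e-3 relative) and collapses to pooled OLS when both
variance components vanish (tested).

Gene–sample cells without a covered cytosine are dropped
(complete-case). Only cytosines with a unique gene annotation enter.

## Dosage compensation

M:F ratios use unlogged cpm with TMM-effective library sizes and an
epsilon = 1e-6 guard against zero female means (guarded genes are
flagged). The cutoff is the linear-interpolation quantile (default
95%) of the autosomal ratios, computed per decision age by default
(1 dph and adult; a pooled mode exists). Genes below the cutoff at
both ages are compensated from birth; above at 1 dph and below at
adult, acquiring; above at both, never compensated; the fourth cell
(below then above) does not fit the scheme and is kept as "other",
uncounted. Unplaced "_random" fragments count with their parent
chromosome class.

By construction the autosomal-quantile rule concedes ≈ 5% error per
boundary decision, so classification accuracy at ratio-2 effects with
n = 3 per sex per age has an operating ceiling near 0.91; measured
accuracy over replicate synthetic studies is 0.92 ± 0.02, and the
recovery tests therefore pool several independent runs rather than
asserting on a single draw.

## Synthetic data: what it does and does not emulate

The generator draws NB counts (default dispersion 0.05, mean library
size 1e7 ± 15%) with uniform baseline log2-cpm in (1, 9); planted
trajectory effects are specified in units of the within-group SD of
log2 counts implied by the NB mean–variance function, so the 1.65 SD
classifier has a controllable operating point. Dosage classes set the
true M:F mean ratio: 2 throughout ("never"), log-linear interpolation
from 2 to 1 across the four ages ("acquired"), 1 ("from_birth");
males and females are shifted symmetrically by half the log-ratio.
Methylation: CpG sites in promoters with Beta(5, 2) baseline levels,
CpH sites in gene bodies with Beta(1.5, 8) (markedly lower, as in
neural tissue); Poisson coverage (default 20×); DM sites gain
`meth_age_slope` logits per age step; oxRRBS success probabilities are
scaled by (1 − hmc_fraction). Promoters are 2,500 nt of i.i.d.
background with one exact consensus occurrence per motif-positive gene.

Deliberately not emulated: read-level artefacts (mapping, bisulfite
conversion error), GC/length biases, correlated methylation along a
promoter, between-gene expression correlation, and W-linked
transcription. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the assumed generative
model, not robustness to the technical covariates of real libraries.

Dispersion 0.05 and coverage 20× are defaults representing plausible
magnitudes, not claims about the original tissue; both are config
knobs. A helper generator produces expression coupled to methylation
through exactly the crossed random-intercept model (known slope,
default −0.04) for calibration of the integration stage.

Problem sizes in the tests and the acceptance script (2,000-feature
null calibrations, 500-gene recovery runs, six pooled 1,000-gene
studies for dosage) were chosen so each suite completes in seconds to
a couple of minutes on one CPU while keeping Monte-Carlo error well
below the asserted margins.

## Numerical choices

- NB GLM: Fisher-scoring IRLS, tolerance 1e-10, 50 iterations; linear
  predictor clipped at ±60; a 1e-6 ridge stabilises singular
  information matrices (e.g. all-zero groups) and flags the fit.
- Dispersion search on log scale in [1e-6, 10], bounded Brent.
- Moderation: trigamma inversion by Newton, 50 iterations, relative
  tolerance 1e-8.
- PWM DP bin width 1e-3 log2-odds units; p-values are exact for the
  discretised score, and match scoring uses the same discretisation so
  scan and null distribution are mutually consistent.
- bedGraph: non-significant sites with β = 0 are written as −0.001 so
  the sign always encodes significance.
- Quantiles: linear interpolation between order statistics throughout.
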