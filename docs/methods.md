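# Methods

This note documents the statistical model behind each module, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions at the edges.

## Antigen funnel

The funnel consumes per-gene *summary* statistics — log2 fold change and FDR
versus normal tissue in two tumor-grade strata — not raw expression data.
Upstream normalization, batch correction and model fitting are deliberately
out of scope: curated outputs of those standard tools are the input contract.

Upregulation is log2FC > 1 and FDR < 0.05, with both inequalities strict, and
(by default) required in both the Gleason ≤ 6 and Gleason ≥ 8 strata. The
dual-stratum requirement operationalizes "upregulated regardless of grade" as
passing the same rule in each stratum; `require_both_strata=False` exposes
the weaker reading in which only the low-grade stratum is tested. PIN
evidence and tumor-line expression are curated boolean annotations supplied
with the table (literature review, Western blot); a gene whose tumor-line
status was never assayed survives the filter but is flagged in the report,
because absence of evidence is not evidence of absence. Force-included genes
bypass the expression and PIN filters but not the tumor-line filter: an
antigen the target line does not express cannot be tested in vivo no matter
why it was added. Duplicate gene symbols are an input error — the funnel is
set-valued.

## ELISPOT response calling

Each donor × epitope × cytokine unit is nominally 4 experimental and 4
no-antigen control wells. CSPW = mean(experimental) − mean(control), with no
clamping: negative values are preserved (they carry information about assay
drift) but can never contribute to magnitude.

The replicate comparison defaults to the unpaired two-tailed pooled-variance
Student's t-test. At 4 replicates per group this choice matters: Welch's
unequal-variance correction (available as `test="welch"`) loses enough
degrees of freedom through the Satterthwaite approximation to become
conservative — its measured two-sided rejection rate on matched-mean Poisson
counts is about 0.042 at a nominal α = 0.05, versus about 0.052 for the
pooled test — and the response-calling chain is calibrated around the
nominal α. An exhaustive permutation test (70 relabelings at 4-vs-4) is
available as `test="permutation"` and is also the automatic fallback whenever
the t statistic degenerates (both groups constant), which integer spot counts
make common. All wells identical on both sides gives p = 1 by convention.

A *positive* call additionally requires CSPW > 0: a response cannot be a
deficit of spots. Under the null this direction requirement halves the
positive-call rate to about α/2, while the two-sided rejection rate of the
underlying test stays at α; both rates are reported by the acceptance script.

Cohort summaries: incidence = 100 × #positive/n; magnitude defaults to the
mean CSPW over responders. Averaging over all donors instead
(`magnitude_over="all"`) would shrink magnitude toward zero as incidence
falls, double-counting incidence in the downstream incidence × magnitude
product — but both conventions are exposed since the choice is a modelling
judgement. Donors missing either cytokine for an epitope are excluded
pairwise from that epitope's summaries (and logged) so the two cytokines'
denominators agree.

## Th1/Th2 selectivity

ratio = (IFN-γ incidence × magnitude)/(IL-10 incidence × magnitude). The
units of incidence cancel provided both cytokines use the same convention;
the package stores percent. Boundary conventions follow the definition
exactly: strictly > 4 (with IL-10 incidence ≤ 10%, inclusive) for
Th1-selective, strictly < 1 for Th2-selective, mixed between. Two edge
conventions are the package's own: a zero IL-10 product with a positive
IFN-γ product yields an infinite ratio and is classified Th1-selective when
the incidence cap holds (it is the ideal Th1 pattern); both products zero is
a fourth label, NON_REACTIVE, rather than mixed, because an epitope that
elicited no significant response in either cytokine is not evidence of a
mixed response. An infinite ratio with IL-10 incidence above the cap (only
possible under the all-donor magnitude convention) is mixed.

## Tumor efficacy

Volume is the ellipsoid approximation length × width × height × 0.5236
(π/6), symmetric and cubic in its arguments. Percent inhibition compares
group mean volumes at a common day.

Growth curves are compared with a two-way ANOVA on per-measurement volumes
with arm and day as categorical factors plus interaction — the plain
fixed-effects procedure, with repeated-measures correlation deliberately
ignored to match the simple named design. Terminated mice drop out of later
time points; no last-observation carry-forward is applied, and per-day
means ± SEM use the mice actually measured that day. Because dropout is
informative (the largest tumors leave first), the ANOVA and the arm
contrasts are restricted to the fully observed window — days up to the
earliest mouse's last measurement — so every mouse contributes to every
analyzed day; without this window, curves truncated at the termination
volume make whole-study averages nearly identical across arms. Contrasts
take each mouse's mean volume over that window as the experimental unit and
are adjusted with Dunnett's many-to-one procedure (multivariate-t, evaluated
with a fixed internal quadrature seed for reproducibility; a Bonferroni
fallback is available). With a single treated arm the Dunnett contrast
reduces to the unadjusted pooled-t contrast. Degenerate noise-free inputs
(zero within-group variance) short-circuit to p = 1 for equal means and
p = 0 otherwise.

Survival conversion: the event time is the first day the volume reaches
2000 mm³ — "reached" is inclusive, and crossings between caliper days are
linearly interpolated in volume, a deterministic, low-impact choice at 2–3
day measurement intervals. Mice never reaching the threshold by day 115 are
administratively censored at the horizon. Kaplan–Meier estimation uses the
product-limit estimator; Fisher's exact test (two-sided, by summing
hypergeometric probabilities no larger than the observed table's) serves for
horizon-proportion comparisons. The survival test used for the original
in-vivo p-value is not reproduced: the procedure behind it is not
identifiable from the reported quantities, and the reported survival
percentages do not correspond to integer fractions of the stated group size,
so no attempt is made to guess an exclusion rule.

`group_size` inverts the noncentral-t power function of the two-sided
two-sample t-test for the smallest per-group n. The standardized effect size
is a required user input: the planning difference and variance behind the
original "10 or 15 mice per group" statement are not recoverable, so the
calculator cannot (and does not pretend to) reproduce those specific counts.

## Synthetic-data generators

All generators are bit-reproducible given (seed, parameters).

*Gene tables* plant `n_true_candidates` genes that pass every funnel stage
among nulls each constructed to fail at least one differential-expression
criterion (weak effect or non-significance, in either stratum). FDR values
are drawn directly rather than computed from simulated tests, because the
funnel consumes summaries — simulating upstream inference would add nothing
the funnel can see.

*ELISPOT cohorts* model donor heterogeneity as a Bernoulli responder state
per donor × epitope × cytokine: response probability p, responder wells
Poisson with mean λ_resp, background/control wells Poisson with mean λ_bg.
Defaults for the canonical profiles are 10 donors and 4 replicates (the
study cohort structure), λ_bg = 5 spots, and for strong profiles p = 0.6,
λ_resp = 40 — a clearly supra-background signal of the size seen in potent
recall responses. Negative-binomial overdispersion is available via a
dispersion parameter; Poisson is the default to keep the distributional
assumptions minimal and the oracles simple. The generator does not emulate
plate effects, counting error in the reader, or correlation between
cytokines beyond the shared background level — so passing recovery tests
shows the chain's statistics behave as designed under the assumed count
model, not that real plates meet those assumptions.

*Tumor studies* use V(t) = V0·exp(arm_effect·r·t) with multiplicative
lognormal measurement noise (mean 1, CV default 0.3 — the mid-range spread
visible in individual-mouse caliper curves), sampled on an alternating
2/3-day grid from day 0 and truncated after the first measurement at or
above 2000 mm³. Defaults V0 = 5 mm³ and r ≈ 0.116/day are calibrated so the
control arm's expected mean is 1650 mm³ at day 50, and the default treated
arm_effect ≈ 0.661 puts the treated mean at 231 mm³ — the published
therapeutic-setting group means, giving an expected 86% inhibition. The
model is monotone and unimodal-noise by construction; it does not emulate
regressions, dormancy, or measurement floors.

## Problem sizes

The test suite and acceptance script use the study-scale conditions
throughout: 10-donor cohorts with 4 replicates, 200 simulation seeds for
label-recovery rates, 10⁴ assays for the type-I check, 10–15 mice per arm
for growth comparisons, and exhaustive enumeration for the Fisher (all 2×2
tables with row margins ≤ 12) and permutation (all 70 4-vs-4 relabelings)
oracles.

## Known limitations

- The ANOVA ignores within-mouse correlation; a mixed-effects model would be
  more efficient but is not the named procedure.
- The response-calling t-test treats counts as approximately normal; at very
  low spot counts the permutation test is the safer option.
- The original study's gene-funnel counts and per-antigen epitope
  classifications depend on raw data that are not machine-readable here;
  the package verifies the machinery on planted-truth synthetic data
  instead.
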