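# Methods

This note documents the statistical model, the numerical choices, and what
the synthetic-cohort generator does and does not emulate. It is the
package's own account of its science; every number quoted here is computed
by the test suite or by `scripts/acceptance.py`.

## Study design representation

The design is five visits (T1 pre-radiotherapy baseline, T2 end of
radiotherapy, T3/T4/T5 at 3, 6, 12 months) crossed with one between-patient
factor of ≥2 levels (five treatment groups, local vs locoregional
radiotherapy, or survivor vs non-survivor). Time is always reference coded
to T1, so time coefficients are changes from baseline. The group factor is
sum coded when the question is "which group deviates from the average
response" (treatment groups) and reference coded when a natural control
exists (local radiotherapy; survivors). Sum coding drops the *last* level,
which codes as −1 on every group column; which level is dropped is
statistically immaterial because both codings span the same column space —
a property the suite verifies by projecting random responses onto both
designs and comparing fitted values to 1e-10. The full visit × level
design-cell grid is always materialised so score trajectories span T1–T5
for every group even when a cell is unobserved.

## The mixed model and its estimation

Per variable, y = Xβ + Zu + ε with one random intercept per patient:
u_i ~ N(0, σ_u²), ε ~ N(0, σ_e²). Estimation is REML. For this covariance
structure the marginal covariance is blockwise V_i = σ_e²(I + λ J) with
λ = σ_u²/σ_e², so everything reduces to patient-level sums: the restricted
likelihood is profiled over σ_e² and β, leaving a smooth one-dimensional
criterion in log λ that is minimised by bounded Brent search on
log λ ∈ [−12, 12] with tolerance 1e-8. A solution at the lower bound is
reported as σ_u = 0; one at the upper bound is flagged unconverged. Fixed
effects and their standard errors come from the GLS solve at the optimum.
The fitter is cross-checked in the test suite against statsmodels MixedLM
(coefficients to 1e-5, restricted log-likelihood to 1e-6) and, with
variance components fixed at truth, against a dense GLS oracle (1e-6); the
fast profiled form exists because the bootstrap re-fits the whole panel
hundreds of times.

Wald tests use the normal reference distribution rather than a
degrees-of-freedom approximation: with cohorts of ~50–250 independent
patients the difference is negligible, and the suite confirms the T5
baseline contrast rejects at 4–7% under the global null (500 replicates,
95% binomial band around 0.05). Benjamini–Hochberg correction is applied
across variables within one coefficient at a time — families are never
pooled across coefficients, matching a correction "for the number of
variables tested". Variables are screened on their original scale; a
monotone transform of units does not change t or p, and any substantive
transformation is the caller's choice.

## RM-ASCA+

The multivariate step decomposes the fitted fixed-effect predictor into
additive effect matrices on the design-cell grid: the time matrix holds the
reference-coded visit effects (identical rows across groups), the group
matrix the group contrasts (constant across visits), the interaction matrix
their products; the intercept is always excluded. Combinations are
elementwise sums: `time + group + time:group` shows every group's
trajectory; `group + time:group` shows baseline differences plus their
development, with the reference group exactly at zero (the "flat line"
contract, which holds to machine precision by construction and is asserted
exactly in the tests).

PCA of an effect matrix is computed by SVD without re-centering (effect
matrices are already contrasts). Design cells are weighted by the square
root of their observation share, which makes the decomposition equal to
PCA of the per-observation effect matrix under unbalanced attendance.
Loadings are unit-norm rows; scores are the unweighted cell projections
E·Lᵀ. Determinism across runs and bootstrap replicates is imposed by a sign
convention: the largest-magnitude loading entry of each component is made
positive. Two components are retained by default (score/loading figures in
this literature show PC1/PC2); the count is configurable.

Pre-processing default is per-variable centering and unit-variance scaling:
lipoprotein parameters (mg/dL) and metabolites (mM) differ by orders of
magnitude and PCA is scale-sensitive. Scaling can be disabled; analyses
whose planted truth is defined on the raw scale (e.g. the recovery and
coverage checks) run with `scale=False`.

## Bootstrap

Confidence envelopes are nonparametric cluster bootstrap: patients are
drawn with replacement until the original patient count is reached, each
drawn patient contributing all visits (duplicates get fresh ids); the
*entire* pipeline including the replicate's own centering/scaling is
re-fitted; replicate components are sign-aligned to the point estimate by
the dot-product rule; and elementwise 2.5th/97.5th percentiles form the 95%
envelope. The default replicate count is 1000. Resampling is unstratified
by default (the literal reading of resampling "until the original sample
size is achieved"); stratified-by-group resampling is available as a flag.
With noiseless full-attendance data and stratified resampling every
replicate has identical cell composition, so the envelope collapses onto
the point estimate exactly — the degenerate contract asserted in the
tests. Replicates whose fit fails are skipped and counted; more than 10%
failures rejects the envelope.

Coverage is verified by simulation: a rank-one time effect with known
direction is planted (26-peak panel, 2 groups, 200 patients, unit noise
components), and elementwise coverage of the true PC1 loading by 200-replicate
percentile envelopes is pooled over 50 simulated cohorts; the suite
requires the pooled rate to sit in the 95% binomial band around 0.95.
Because a PCA axis has no intrinsic sign, the envelope is aligned to the
true loading's sign before assessing coverage.

## Synthetic cohort generator

The generator emulates the *statistical design* of the study cohort, not
its physiology. Defaults: 250 patients split evenly over five treatment
groups; attendance at each visit is an independent Bernoulli draw with
probabilities 229/250, 211/250, 198/250, 195/250, 146/250, calibrated so
expected per-visit attendance matches the study's printed counts (the
published per-visit totals at T4 exceed T3, so dropout must be
non-monotone; independent attendance is the simplest mechanism matching the
marginals). Attendance probabilities apply to T1 as well — matching the
printed T1 count of 229 of 250 — so a patient is only guaranteed at least
one visit, not necessarily a baseline record; the mixed models handle
either. Values are generated on an additive, unit-free scale
(effects in residual-SD units) as cell mean + random intercept + residual.
Residuals are equicorrelated within lipoprotein main-class blocks
(default ρ = 0.3) to mimic the strong co-variation of subfraction
parameters; metabolite residuals are independent. Random intercepts are
independent across variables. σ_u = σ_e = 1 by default (ICC 0.5, a typical
value for repeated serum biochemistry).

The default planted effect library mirrors the directions reported for
this kind of cohort: free cholesterol rising in HDL and HDL1–4 while
esterified cholesterol falls; LDL2–4 lipids and apo-B rising while LDL5–6
fall; lysine, glutamate and formate rising while glutamine and lactate
fall. The temporal profile is a ramp (0, 0.6, 0.8, 1.0)×0.8 over T2–T5 —
no systematic shift immediately after radiotherapy, then progressive
change — and unmentioned variables get exactly zero effect. Group sizes,
effect magnitudes, noise components and the retention vector are all
configurable.

What passing tests on this generator do **not** show about real data:
absolute concentration ranges and units are not realistic (no positivity
constraint; the machinery is location-scale invariant); the true
covariance of 100 lipoprotein parameters is far richer than equicorrelated
main-class blocks; real dropout is likely informative rather than
independent of outcome; and the 12 metabolites beyond those reported by
name are placeholder identities flagged `canonical=False` in the registry.

## Baseline statistics

Categorical baseline variables use Pearson chi-square without continuity
correction; `Unknown` categories and lost-to-follow-up patients are
excluded before testing. These two choices were validated against the
published survivor/non-survivor table: lymphatic involvement p = 0.021,
comorbidity p = 0.018, chemotherapy p = 0.390, endocrine treatment
p = 0.029, estrogen receptor p = 0.270 and HER-2 p = 0.829 all reproduce at
the printed 3 decimals from the printed counts. Two published rows do not
reproduce under any plain Pearson variant (trastuzumab prints 0.766,
Pearson gives 0.757; radiation prints 0.087 vs 0.088); the original test
variant for those rows is not recoverable from the counts, so they are
reported by the battery but not asserted. Continuous variables use
two-sample t-tests, pooled-variance by default with Welch as an option
(the published table does not state which; its continuous p-values are not
exactly recomputable from rounded summary statistics either way), and
tumor size is log transformed before testing.

## Problem sizes

The suite and the acceptance script scale the expensive simulations to
what one CPU handles comfortably: the coverage study uses the 26-peak
panel with 50 cohorts × 200 bootstrap replicates in the tests and
12 × 100 in the acceptance script; null calibration uses 500 replicates of
50-patient cohorts; everything else runs at the study's own sizes (250
patients, 100 variables, 1000 default bootstrap replicates for production
use).
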