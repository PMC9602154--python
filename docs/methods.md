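# Methods

## Study design being modelled

Endurance-trained male athletes complete three standardized 60-minute
exercise-heat trials: at baseline, after a summer of outdoor training in
natural heat (heat acclimatization, HAz), and after a subsequent five-day
laboratory heat-acclimation block (HA). The endpoints per trial are peak
heart rate (HR, bpm), peak thermal sensation (TS, 0–8 scale in 0.5 steps),
whole-trial sweat rate (SR, L·h⁻¹), and end-of-trial rectal temperature
(T_rec, °C). Three induction contrasts are formed per participant and pooled
into one observation set: HAz = post-HAz − baseline, HA = post-HA − post-HAz,
DHE = post-HA − baseline. Pooling the three contrasts treats them as
exchangeable observations of the predictor→outcome relationship; the within-
participant dependence this induces is deliberately not modelled, because the
analysis being reproduced pools them the same way. Improvement is
ΔT_rec < −tolerance with tolerance 0 by default (a tie is not improved); the
tolerance parameter makes the implicit margin explicit and testable.

## Synthetic cohort generator

Real per-athlete data are not redistributable, so every downstream stage is
exercised on synthetic cohorts. The generator is first-class, tested code,
not a test shim. Per participant *i*, one latent responsiveness factor
u_i ~ N(0,1) couples all four variables:

    baseline_v ~ N(μ_v0, σ_v0)
    ΔHAz_v = μ_v,HAz − s_v β_v u_i + ε,    ε  ~ N(0, τ_v)
    ΔHA_v  = μ_v,HA  − s_v β_v u_i + ε′,   ε′ ~ N(0, τ_v)

with s_v = +1 for HR/T_rec/TS and −1 for SR. Phase values accumulate
(post-HAz = baseline + ΔHAz, post-HA = post-HAz + ΔHA) and are then clipped
to physiologic bounds and quantized to instrument resolution; deltas are
always recomputed from the quantized stored values, so synthetic and real
data follow one code path and ΔDHE = ΔHAz + ΔHA holds exactly.

Defaults (per variable: baseline mean ± SD; HAz/HA delta means; β; τ; step;
bounds):

| variable | baseline      | Δ means        | β    | τ    | step | bounds       |
|----------|---------------|----------------|------|------|------|--------------|
| HR (bpm) | 143 ± 12      | −5, −4         | 8    | 5    | 1    | [90, 210]    |
| T_rec °C | 38.29 ± 0.37  | −0.04, −0.22   | 0.30 | 0.15 | 0.01 | [36.5, 41.0] |
| TS       | 5.6 ± 0.6     | −0.1, −0.4     | 0.4  | 0.3  | 0.5  | [0, 8]       |
| SR L·h⁻¹ | 1.70 ± 0.40   | +0.06, +0.17   | 0.20 | 0.10 | 0.01 | [0.1, 4.0]   |

Stage-delta means are differences of the reported (rounded) phase means.
The baseline SR distribution is not reported anywhere; 1.70 ± 0.40 L·h⁻¹ is
a typical endurance-athlete value chosen so that post-HAz ≈ 1.76 with a
small positive HAz delta. The coupling and residual scales place the
counting classifier in the reported accuracy regime; they are validated only
by the calibration property below, not asserted to be unique. A single
global seed drives one RNG stream (u first, then per-variable draws in a
fixed order); determinism is a whole-cohort contract.

What the generator does *not* emulate: between-variable correlation structure
beyond the single latent factor (no published estimates exist; this is an
assumption, not a reproduced fact), within-trial time courses, environmental
covariates, female or less-trained populations, and measurement drift.
Passing simulation tests therefore shows the pipeline recovers the structure
this model plants — not that the model is the true physiology.

## Cut-point search

Depth-1 splits only: the procedure being reproduced reports "after one
split" probabilities and never grows a deeper tree. Entropy is base 2; the
base does not affect the argmin. The favorable side per variable is fixed a
priori from the sign convention (HR/TS down, SR up), not searched. Candidate
thresholds are midpoints between consecutive distinct sorted values (every
distinct bipartition appears exactly once) or, with `grid_step` set, a
regular grid spanning the observed range. An empty split side contributes
zero weighted entropy, giving gain 0 rather than an error, so grid sweeps do
not abort.

Selection is a two-policy system making the published probability-vs-support
"balance" explicit. `max_ppv_min_support` (default): among candidates whose
favorable side holds ≥ ceil(0.25 · n) observations, maximize the favorable-
side improvement probability; ties break to larger support, then to the
threshold nearest zero (a smaller claimed adaptation is the more conservative
rule). The 0.25 floor approximates the accepted 22-of-75 support of the
published HR cut-point. `max_info_gain` is the plain entropy criterion.
Boundary strictness follows the published rules (strict for HR and SR,
non-strict for TS). The sources are internally inconsistent on the TS
boundary (≤ −0.5 in the headline statements, < −0.5 in the conclusions);
the non-strict form is the default and the flag is exposed per rule.

## Classifier and logistic screening

`count_criteria` evaluates the three rules with their own side/strictness
and predicts improvement at count ≥ k (default 2). The univariate logistic
screens regress improvement on the binary indicator of one rule, fitted by
Newton iterations (gradient tolerance 1e−8, ≤ 100 iterations) via
statsmodels. Complete separation is reported as `converged=False` with NaN
coefficients instead of an exception. Both Cox–Snell and Nagelkerke
pseudo-R² are reported side by side because a bare "r²" from a statistics
package could be either.

## Diagnostics

All 2×2 statistics are exact functions of the per-category counts:
sensitivity tp/(tp+fn), specificity tn/(fp+tn), LR⁺ = sens/(1−spec)
(reported as an explicit infinity marker at specificity 1 so ROC sweeps do
not abort), LR⁻ = (1−sens)/spec, PPV tp/(tp+fp). The ROC is the four-point
empirical curve over k = 3, 2, 1, 0 plus the trivial (0,0) endpoint; no AUC
beyond it is estimated. Group comparisons of ΔT_rec across count categories
(0, 1, 2–3) use the classical one-way ANOVA F (scipy) guarded against
all-constant groups, and Fisher's LSD: unadjusted pairwise t contrasts on
the pooled ANOVA error term with N−g degrees of freedom, 95% CIs from the
same standard error. Hedges' g uses pooled SD and the small-sample
correction J = 1 − 3/(4·df − 1), df = n_a + n_b − 2. The printed magnitude
bands (0.2–0.49, 0.5–0.79, >0.8) leave gaps, closed here as half-open
intervals [0.2, 0.5), [0.5, 0.8), [0.8, ∞), with |g| < 0.2 labelled
"negligible".

Two documented inconsistencies in the source results are left unreconciled:
the "at least one criterion" row (specificity 0.60, LR⁺ 2.2, LR⁻ 0.2) is
self-consistent but contradicts the printed per-category counts, which imply
specificity 0.40 at that rule (sensitivity 0.88 is consistent both ways);
and the printed effect sizes (1.42, 1.67) are not exactly recoverable from
the rounded group summaries (recomputation gives ≈ 1.38–1.40 for the first
contrast). The package always reports count-derived values.

## Reference fixture

`make_fixture_observations` deterministically builds 75 observations whose
criteria-count categories (23 at 2–3, of which 12 meet all three rules; 36
at 1; 16 at 0) and improvement tallies (22, 22, 6) match the published
contingency structure, with predictor deltas placed clearly on the intended
side of each rule and ΔT_rec values on the 0.01 °C grid whose category sums
are exact, so the group means are −0.71, −0.13, +0.03 °C to machine
precision. Within-category spreads are symmetric integer-cent offsets chosen
for plausible SDs; SDs are not asserted anywhere. The fixture drives the
exact-arithmetic acceptance checks of the diagnostics layer.

## Problem sizes and numerical choices

Simulation-based checks use: 2000 participants for phase-mean calibration
(Monte-Carlo SE of the post-HA HR mean ≈ 0.5 bpm, tolerance ±1 bpm); 100
cohorts of 200 participants for planted cut-point recovery; 50 cohorts of
200 for PPV calibration (pass when ≥ 90% of cohorts reach PPV ≥ 0.85 at
k ≥ 2). The recovery check uses a strong-coupling configuration (β_HR = 16,
τ_HR = 0.25, β_Trec = 0.50, τ_Trec = 0.005, T_rec delta means +0.10/+0.15)
in which the improvement boundary in the dual-exposure HR delta is analytic:
u* = (μ_T,HAz + μ_T,HA)/(2 β_T), h* = (μ_HR,HAz + μ_HR,HA) − 2 β_HR u* =
−17 bpm; recovery means the selected grid threshold lies within one 1-bpm
step of h*. Floating-point dust is controlled by quantizing stored values to
10 decimals and clamping provably non-negative information gains at zero.

## Known limitations

Single-latent-factor coupling is an assumption of convenience; pooled
contrasts are treated as independent; cut-points are not cross-validated
(matching the reproduced procedure); the logistic screen uses the binary
rule indicator, not the continuous delta; no exact binomial CIs on
sensitivity/specificity. Cut-points derived from 25 endurance-trained men
in one trial protocol should not be assumed portable to other populations
or protocols.
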