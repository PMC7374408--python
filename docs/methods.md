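# Methods

## Data model

A cohort is a set of subjects, each labelled NP (non-pathological) or OA
(osteoarthritic), carrying per-visit waveforms: one curve of exactly 101
samples (0–100% of the gait cycle, inclusive) per registered variable. The
default registry holds 24 variables — hip/knee/ankle × sagittal/frontal/
transverse × {angle, moment} (18), three ground-reaction-force components,
and three pelvis angles; the registry is configuration-driven, so any set of
channels can be declared. Inputs at other sampling resolutions are rejected
rather than resampled: silent resampling would change the PCA decomposition.

PROM instruments are mapped linearly to a 0–100% scale with 100% = healthy.
The Oxford Knee Score uses the classic orientation (0/48 is the perfect
score) by default, with a config switch for the modern 48-best scoring; the
KOS activities-of-daily-living scale is taken as 0–70 (70 best) and PACS as
0–110 (0 best). Only the percent scale feeds the analysis, so the native
ranges matter only for validation of raw inputs. Missing scores are never
imputed; every downstream statistic reports its own pairwise-complete n.

## Feature reduction

PCA is fitted per variable on the pooled NP+OA training curves (the features
of variation between and within cohorts), retaining 3 components per variable
(72 candidate features for the default registry). Curves are mean-centred but
not variance-standardised: per-variable PCA cannot mix scales across
variables, and scale normalisation happens later inside the classifier's
transfer function, which standardises each feature by its group spread.
Eigenvector sign ambiguity is removed by forcing each component's
largest-magnitude loading positive, so serialised models reproduce scores
bit-for-bit across platforms. Follow-up visits are always projected with the
trained mean and basis, never refitted.

## Classification

Each retained feature is turned into a body of evidence over the frame
{OA, NP} via a sigmoid confidence factor cf = 1/(1+e^(−k(v−θ))) and the
linear mass map

    m({OA}) = max(0, B/(1−A)·cf − A·B/(1−A)),
    m({NP}) = max(0, −B/(1−A)·cf + B),   m(Θ) = 1 − m({OA}) − m({NP}),

so a single feature can never commit more than B of its mass (default 0.9)
and confidence factors below the ignorance margin A (default 0.2) assign no
mass to {OA}. Control parameters are *explicit*, not optimised:
θ = (mean_NP + mean_OA)/2, k = sign(mean_OA − mean_NP)·2g/(sd_NP + sd_OA)
with gain g = 2 by default. The exact explicit recipe used in the original
clinical work is not published; this rule is the package's declared
reconstruction, with g, A and B exposed in the config. Features with zero
group separation or zero pooled spread are excluded at fit time (rather than
given an infinite slope); a group reduced to a single subject contributes a
point estimate with zero spread, which keeps leave-one-out folds of minimal
cohorts well defined.

Evidence is combined by Dempster's rule. All three combined masses are
computed explicitly and renormalised by their sum rather than obtaining m(Θ)
as 1 minus the others, so the uncertainty never cancels to exactly zero when
a singleton belief saturates. Confidence factors are clamped to
[1e-15, 1−1e-15] before mass assignment. Exact belief ties are reported as
unclassified and counted as incorrect in accuracy — a conservative reading of
the B(OA) > B(NP) decision rule. The simplex plot places B(NP)=1 at (0,0),
B(OA)=1 at (1,0) and U=1 at (0.5, √3/2), which makes the decision boundary
the vertical line x = 0.5.

## Feature ranking

The training cohort is split into two cohort-stratified halves (proportions
preserved within one subject; the split is seeded and depends on subject
positions, not identifiers). Within each half, every candidate feature is
scored by its single-feature leave-one-out accuracy, refitting θ and k on the
remaining subjects of the half for each fold; ties are broken by the mean
belief margin |B(OA) − B(NP)|, then registry order. The retained set is the
intersection of the two top-K lists at the smallest K whose intersection
reaches the target size (default 18). The ranking criterion is a
reconstruction — the original description says only that the classifier
ranked the variables on two half-splits — and the target size is a tunable
because the published count of 18 emerged from that study's data. The
per-fold statistics are computed with closed-form leave-one-out moment
identities; the test suite cross-checks them against the explicit
refit-and-classify path.

## Validation

Leave-one-out validation refits only the classifier control parameters on the
n−1 remaining subjects; the PCA models and the retained feature set are
fitted once on the full training cohort and held fixed. This mirrors a
calibration-only cross-validation and is a known source of optimistic bias;
`refit_pca_in_loo` enables full PCA refitting per fold for comparison.
Post-operative projection uses the fully trained classifier with no refit, so
follow-up data cannot leak into training (property-tested by poisoning the
held-out subject's features).

## Outcome analysis

Change summaries report per-visit means and SDs on the values available at
each visit, the difference of those means, a paired test on complete pairs
(t-test when the paired differences pass a Shapiro–Wilk gate at α = 0.05,
Wilcoxon signed-rank otherwise), and the effect size
(mean_post − mean_pre)/pooled SD, where the pooled SD is the square root of
the average of the two visit variances at equal n and the (n−1)-weighted
pooling otherwise. Correlations are Pearson when both margins pass the same
normality gate and Spearman otherwise; the method can be forced per the
published tables' per-cell choices. No multiple-testing correction is
applied, matching the presentation style of the tables this mirrors. Note
that published effect sizes are generally not exactly recoverable from
rounded printed means/SDs (the value implied by printed B(OA) moments is
−0.839 where −0.848 was printed from unrounded data); the package documents
its formula and does not chase printed values. The arrow ordering sorts
subjects by ΔB(OA) ascending (rank 1 = greatest recovery), flagging
worsening (ΔB(OA) > 0) subjects at the tail.

## Synthetic cohorts

The generator emulates the study conditions: 31 NP and 41 OA subjects, 22 OA
subjects with a post-operative visit, 24 variables with 3 latent variation
modes each. Waveforms are template + Σ_m score·mode_m + iid Gaussian noise,
with smooth orthonormal mode shapes (a QR-orthonormalised low-order cosine
basis, so PCA can recover the subspace up to sign). Mode scores are Gaussian
with per-mode SDs (3, 2, 1), giving a well-ordered eigenstructure; OA
subjects are shifted by d·SD on 6 planted (variable, mode-1) pairs
(d = 2 by default). Within-curve noise defaults to SD 0.05, calibrated so the
retained components recover the generating modes to within a few degrees of
principal angle at the default cohort size.

Post-operative mode scores move a latent per-subject fraction ρ of the way
from baseline toward the NP mean, with ρ drawn from a normal(0.6, 0.3)
truncated to [−0.1, 1.1] — the lower bound deliberately allows the small
worsening seen in real follow-up cohorts. PROM percent changes are built from
ρ by the standard bivariate-normal construction
change = μ_c + σ_c(r·z_ρ + √(1−r²)·ε), so their correlation with ρ is the
configured `prom_r` (default 0.8) in expectation; raw scores are quantised to
the instrument's native integer scale, which adds negligible noise. One
master seed spawns per-component substreams, so adding a variable does not
perturb earlier draws.

What the generator does **not** emulate: realistic gait waveform morphology
(templates are arbitrary smooth curves), demographic confounding (age/BMI
differences between cohorts), between-variable correlation of mode scores,
instrument-specific PROM response distributions, or missingness mechanisms.
Passing tests therefore demonstrate that the pipeline recovers the structure
it assumes — planted separations, latent recovery, calibrated correlations —
not that it would achieve any particular accuracy on real gait data.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's own scale (72 training
subjects, 72 candidate features, 22 follow-ups); Monte-Carlo checks use 20
seeds for ranking-recovery properties, 50 label permutations for the chance
baseline, 100 seeds for generator effect-size calibration, and n = 200–500
cohorts for correlation recovery. In the strong-separation runs (d = 3) the
ranking target is set to 6, matching the number of planted discriminatory
modes: retaining the default 18 would force 12 features carrying no group
signal into the classifier, a condition the clinical study — whose 18
retained features were all highly ranked — did not present. Belief
conservation is enforced to 1e-12, PCA orthonormality to 1e-8, and the fold
combination is validated against brute-force focal-element enumeration to
1e-10.

## Known limitations

- The explicit transfer-parameter recipe and the ranking criterion are
  reconstructions of unpublished details; both are config-overridable.
- Calibration-only LOO is optimistically biased relative to full-pipeline
  refitting (both modes are provided, only the former is the default).
- The generator's recovery model moves every mode score by the same subject
  fraction ρ, so synthetic recovery is more one-dimensional than real
  post-operative change.
- Ternary-frame extensions (more than two primary hypotheses) and alternative
  combination rules are out of scope.
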