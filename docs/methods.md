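# Methods

This note documents the models, parameter choices and numerical decisions
behind `braakstager`, and what the synthetic-data tests do and do not show
about real data.

## Staging model

Tau neurofibrillary pathology is assumed to invade six nested cortical
territories in order (transentorhinal → medial temporal → temporal neocortex
→ association cortices → primary sensory cortices).  Regional tau-PET SUVRs
(Desikan–Killiany–Tourville naming, hemispheres pre-averaged) are collapsed
into one composite per stage by a weighted mean; the default is unweighted
because stage-level composites are conventionally reported without a stated
within-stage rule, and optional per-region weights (e.g. volumes) are
accepted.

Abnormality cutoffs are `mean + k·sd` (k = 2.5, sample s.d. with n−1
denominator) over a calibration sample of cognitively unimpaired young
adults, one cutoff per stage composite.  Comparisons are strict (`>`): a
composite exactly at its cutoff is negative, consistent with the strict
amyloid rule (SUVR > 1.55).  The assigned stage is the latest positive
composite, 0 when none; non-conformant (skip) patterns keep the
latest-positive stage and are flagged rather than reassigned, so conformance
is an observable property of the data, not an assumption of the assignment.
Missing composites are an error — staging never imputes.  Calibration sorts
each composite column before reduction so the thresholds are bit-identical
under any permutation of calibration records.

Two thresholds are deliberately not bundled with defaults: the temporal
meta-ROI positivity cutoff (tracer-specific; the user must supply a
validated value via `meta_roi_threshold`) and Gaussian-mixture-based cutoff
derivation (out of scope; only the mean + k·sd rule is implemented).

Amyloid-β status uses SUVR > 1.55 (amyloid PET) and CSF Aβ42/Aβ40 < 0.068;
a missing modality yields a missing flag, and classification with both
modalities missing is an error.

## Longitudinal model

Each follow-up scan contributes one baseline → follow-up stage path per
interval (1y, 2y); subjects with both follow-ups contribute to both
intervals independently.  Outcomes partition into stability, one-step
progression, multi-step progression (≥ +2) and regression (any decrease,
interpreted as misclassification under a hierarchical model).  Progression
rates are stratified by **baseline** amyloid status only (no time-varying
status); a stratum with an empty denominator reports a missing rate, never
zero.  The gating report counts amyloid-negative progressions from the gate
stage (III) onward.  No dwell-time or Markov modeling is attempted — the
analysis is a tabulation.

## Statistical engine

*Omnibus*: Brown–Forsythe F\* on group means,
F\* = Σ nᵢ(m̄ᵢ − m̄)² / Σ (1 − nᵢ/N)sᵢ², with Satterthwaite denominator
degrees of freedom — chosen because stage groups have grossly unequal
spreads.  Anderson–Darling (normality) and Bartlett (equal s.d.) checks are
provided as diagnostics only and never gate the analysis.

*Many-to-one contrasts*: each stage versus stage 0 with a Welch t statistic
and Satterthwaite df per contrast.  The familywise adjustment evaluates the
null distribution of max |T| over the correlated contrast vector (product
correlation λᵢλⱼ with λᵢ = √(v₀/(v₀+vᵢ)) induced by the shared stage-0
group) by seeded Monte Carlo, 50,000 draws by default; adjusted p values are
clipped to be at least the unadjusted p.  With a single contrast there is no
multiplicity and the analytic Welch p is returned exactly.  Empirical
familywise error under the global null (5 groups × n = 20) is ≈ 0.05
(see the acceptance tests).

*Proportions*: Pearson χ² (uncorrected) on 2×2 stage-pair tables; a zero
margin is an error pointing at exact tests rather than a silent fallback.

*Years-to-onset*: EYO = participant age − parental symptom-onset age for
mutation carriers.  The stage association is a Spearman correlation with a
seeded permutation p value — the underlying test used for the reported
association is not fixed by convention, so a rank/permutation test is
provided without claiming equivalence to any particular parametric choice.

## Trajectory pipeline

Biomarkers are z-scored against the cognitively unimpaired older adults
(irrespective of their stage), n−1 s.d.; missing values propagate and
analyses drop them pairwise (no imputation).  Cognitive domain composites
are means of available within-domain standardized tests (memory: logical
memory immediate/delayed, RAVLT immediate/delayed; language: category
fluency, Boston naming; visuospatial: Birmingham object recognition;
executive: trail-making B time — sign-flipped so higher is better — digit
span backward, letter fluency).

LOESS is degree-1 local regression with tricube weights over the
`ceil(span·n)` nearest points, span 0.75 by default (configurable; the
smoothing choice is conventional, only the method is fixed).  It is written
in-package because the curves must be evaluated on the stage grid 0–6 with a
pointwise variance band: the band is `fit ± 1.96·σ̂·‖l(x₀)‖` with the
equivalent kernel l and residual variance σ̂² from the smoother at the data
points (df = n−2) — an approximate, not exact, 95% band.  Heavily tied
stage covariates are handled by falling back to a local weighted mean when
the local design is singular.  At span 1.0 on exactly linear data the fit
reproduces the OLS line to numerical precision.

The 0–10 abnormality scale orients each biomarker so larger = more abnormal
(the orientation registry ships in the config: Aβ42/Aβ40, Aβ42, hippocampal
volume, MMSE, MOCA and all cognitive composites flip; pTau species, amyloid
SUVR, NfL, neurogranin, SNAP-25 do not), then min–max maps onto [0, 10]
using the observed cohort extremes — "10 = maximum observed abnormality" is
anchored to the cohort because no other anchoring is defined; winsorization
is not applied by default.  Scaled curves are clipped to [0, 10] after
smoothing.  z-scoring followed by scaling is invariant to affine transforms
of the raw assay units.  The stage axis is an ordered severity index, not
time; no temporal ordering between biomarkers is inferred.

## Synthetic cohort generator

The generator defines the study conditions for all tests.  Defaults mirror
the published study design where it is stated: group sizes 179 CU / 80 MCI /
65 dementia-stage subjects; 140 one-year and 84 two-year follow-up scans
with 65 subjects contributing both (159 unique); hippocampal volume
3.54 ± 0.41 cm³ in CU; MMSE ≈ 29 in CU declining to ≈ 20 in dementia;
per-year transition kernel with stay probability 0.92.  Everything the
source material reports only qualitatively is encoded as explicit
stage-conditional means chosen once to reproduce the orderings: composite
SUVRs switch from a baseline regime (mean 1.0) to an abnormal regime (mean
1.6, rising 0.08 per stage after onset) exactly at the subject's true stage;
amyloid positivity mixes at stages 0–II and saturates from III, with the
amyloid-PET mean plateauing from stage IV; CSF pTau231/217 onset earliest
(stage II) and pTau181 rises most at late stages, CSF species plateau at V–VI
while plasma pTau231 keeps rising; memory declines from stage II and global
cognition (MMSE/MOCA) from stage IV; CDR is 0 at stages 0–II, predominantly
0.5 at III–IV and ≥1 at V–VI; amyloid-negative subjects at or beyond stage
III never advance.

Noise is lognormal for SUVRs and fluid concentrations
(positivity-preserving, parameterized to match the requested mean and s.d.
exactly), truncated normal for cognitive scores and categorical for CDR.
Baseline composite noise defaults to s.d. 0.035 with a 200-subject
calibration sample: because the cutoff is mean + 2.5·s.d. of the same
distribution, the per-composite false-positive mass is an irreducible
≈ 0.7–1% whatever the s.d., and these defaults put exact-stage recovery at
≈ 97%, comfortably above the ≥ 95% recovery the acceptance tests assert.  A
single global seed drives
independent named substreams (CRC-keyed `SeedSequence`), so adding a channel
never perturbs existing ones and identical configs export byte-identical
tables.

What passing tests show — and do not.  The generator encodes hierarchical
tau accumulation by construction, conditionally independent channels given
true stage, no demographic confounding (age/sex/APOE), no assay batch
effects, no informative missingness and no partial-volume or off-target
binding artifacts.  Tests against it validate the arithmetic and the
statistical machinery, not the biological claims; performance on real
cohorts depends on properties the generator does not emulate.

## Problem sizes

The test suite and acceptance script run: exhaustive 64-pattern staging
enumeration; randomized calibration tables (n ≤ 40); recovery at n = 1000;
gating and kernel-recovery cohorts at n = 2000 paths (kernel recovery pooled
over ten replicates, 20,000 paths); type-I-error simulation with 10,000
datasets of 5 × 20 observations (5,000–10,000 Monte-Carlo draws per Dunnett
adjustment); trajectory orderings at n = 1000.  These sizes were chosen so
Monte-Carlo error is small relative to every asserted margin while the whole
suite stays fast on one CPU.

## Known limitations

- The pointwise LOESS band ignores smoothing bias and uses a global residual
  variance; it is adequate for display, not for formal inference.
- The Dunnett adjustment conditions on estimated variances (plug-in λ and
  df); its familywise error is nominal only approximately, as verified by
  simulation.
- The permutation p value for the EYO association is exchangeability-based
  and does not model repeated scans per carrier.
- Min–max 0–10 scaling is sensitive to single extreme observations;
  winsorization is available in principle through pre-processing but not
  applied by default.
- The generator's transition kernel is stage-homogeneous per year; real
  progression hazards need not be.
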