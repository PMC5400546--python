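# Methods

## Scientific setting

Serum prostate-specific antigen (PSA) is the standard screening measure for
prostate cancer, but its concentration confounds three things: how much PSA
the prostate produces (benign tissue plus tumor), how large the gland is,
and how much plasma the PSA is diluted into.  Two derivatives address the
last two confounders:

* **PSA density (PSAD)** = PSA / prostate weight (PW, grams, measured
  without the seminal vesicles), in ng/mL per gram;
* **PSA mass (PSAM)** = PSA x plasma volume — the total circulating PSA,
  insensitive to hemodilution in larger men;
* **PSA mass density (PSAMD)** = PSAM / PW, adjusting for gland size and
  body size simultaneously.

The package's question is whether these derivatives predict *significant*
low-grade tumor volume (Gleason 3+3=6 / Grade Group 1, TV >= 0.5 cm^3 at
radical prostatectomy) equally well across race/ethnicity groups
(Non-Hispanic White, Non-Hispanic Black, Hispanic/Latino, other), and where
the group-specific optimal screening cutoffs sit.  Group-specific cutoffs
matter clinically because active-surveillance criteria use fixed PSAD
thresholds: if NHB or Hispanic/Latino tumors produce less PSA per unit
volume, a fixed threshold under-detects significant disease in those groups.

## Derivative conventions

* BMI categories use the WHO bins with half-open intervals [18.5, 25),
  [25, 30), [30, inf); 25 is overweight and 30 obese.
* Body surface area is computed as ``0.007184 * weight_kg^0.425 *
  height^0.72`` with height **in meters** — the convention under which the
  literature PSAM scale (medians about 0.5 ug) and the published PSAMD
  cutoffs (about 0.012 ug/g) arise.  The classic Du Bois formula (height in
  cm, exponent 0.725) gives values roughly 27x larger; it is available as
  ``bsa_mode="dubois-cm"`` but published mass-density cutoffs do not apply
  on that scale.  Intermediates are never rounded; reports round at the end
  (PSAD/PSAMD 3 dp, PSAM 2 dp).
* Plasma volume = 1.67 x BSA.
* Tumor volume from histologic grid counts: ``mm^2 x 3 mm (section
  thickness) x 1.12 (fixation shrinkage) / 1000`` cm^3.  The significance
  threshold 0.5 cm^3 is inclusive; 149 mm^2 is the smallest integer grid
  count that crosses it.

## ROC analysis and cutoff selection

A positive screening call is **score >= cutoff**, so a man whose PSAD equals
a published cutoff screens positive.  Curves are built with one operating
point per distinct observed score plus the all-negative point; thresholds
are never interpolated to midpoints, which keeps results exactly
reproducible on discrete data.  AUC is the trapezoidal area, which on this
construction equals the pair-counting concordance statistic (asserted
against brute-force enumeration in the tests).

The *optimal* cutoff is the upper-left criterion: minimize the Euclidean
distance from the operating point (FPR, TPR) to the ideal corner (0, 1).
Ties break toward higher specificity, then the higher threshold
(conservative: fewer men called positive).  Youden's J is available as an
alternative criterion.  Sensitivity "at fixed specificity" uses the least
achievable specificity at or above the target, i.e. the most sensitive
attaining point; the comparison of two derivatives at fixed specificity
uses a paired percentile bootstrap (records resampled with replacement,
default 2000 resamples, seeded) because no analytic test is assumed.

PPV and NPV are reported from the same 2x2 table and are therefore
prevalence-dependent; rates with a zero denominator are reported as absent,
never as zero.

## Inferential statistics

Group comparisons use the pooled-variance Student t-test (two groups) or a
one-way ANOVA F-test as the omnibus across the four race/ethnicity groups;
categorical variables use the Pearson chi-square without continuity
correction.  Correlations of tumor volume with each derivative use
Pearson's r, with a first-order partial correlation removing age
(algebraically identical to correlating the age-residualized variables; the
tests assert this identity and cross-check against an independent
implementation).  Linear association uses OLS, univariable or age-adjusted.
p <= 0.05 is flagged significant and no multiple-testing correction is
applied, matching the analysis conventions the pipeline reproduces.  Where a
single p-value is reported across four groups the omnibus ANOVA is used,
since a pairwise t-test cannot produce one number for four groups; the
pairwise t remains available.

## Surname-based ethnicity assignment

The NAACCR-style Hispanic identification procedure: normalize the surname
(uppercase, accents stripped, compound names matched whole), look it up in a
five-tier surname table, code Hispanic only for the *heavily Hispanic* tier,
then override to Non-Hispanic when the race code is Asian, American Indian,
Aleutian, Eskimo, Filipino, Pacific Islander, or Hawaiian.  Records without
a surname are coded Non-Hispanic with a logged warning — the conservative,
auditable choice.  The 1990 U.S. Census Spanish Surname List is not
redistributable, so the package ships a small synthetic table spanning all
five tiers for testing; any user-supplied two-column list can be loaded
instead.

## Synthetic cohort generator

No patient-level data are available, so the generator emulates the published
cohort's structure: group sizes 390/87/78/34 (66.2/14.8/13.2/5.8%),
institution counts 136/453 with the Hispanic/Latino group entirely from one
institution, and per-group marginals for age (truncated normal), prostate
weight and tumor volume (truncated lognormal), BMI (category mixture with
uniform within-category spread) and height (truncated normal).  Lognormal
forms were chosen because the published means exceed the medians (right
skew); each log-sd is solved from the printed mean/median pair
(mean = median * exp(sd^2/2)) and truncation bounds are the printed
min/max.  Weight is back-solved from BMI and height.  Inter-variable
correlations are not published; weak positive Gaussian-copula correlations
(PW~BMI and TV~age, both 0.2) are a documented assumption.

PSA follows the mechanism the analyses probe:

    PSA = (alpha * PW + beta_g * TV) * (PV_ref / PV)^gamma * eps

with equal benign production `alpha` across groups, a group tumor rate
`beta_g` carrying the reported 25% NHB production deficit (the
Hispanic/Latino deficit, 15%, is a free parameter with no published value),
multiplicative hemodilution through plasma volume (gamma = 1, anchored at a
reference man of BMI 27 and height 1.75 m), and lognormal noise.  PSA is
kept inside the observed 0.3-13 ng/mL envelope by resampling the noise
within the feasible range (inverse-CDF truncation, so seeds reproduce
exactly).

**Calibration (performed once, then frozen).**  With the marginals fixed as
above, the free parameters (alpha, beta_NHW, noise level) were scanned once
against three constraints: every per-group PSA median within 15% of the
printed medians, the NHB-below-NHW PSAD cutoff ordering resolvable at the
published group sizes, and the recovered NHB/NHW tumor-rate ratio near its
true 0.75.  The frozen defaults are alpha = 0.0675 ng/mL per gram,
beta_NHW = 2.4 ng/mL per cm^3 (NHB 1.8, Hispanic/Latino 2.04), noise log-sd
0.25.  The constraint set is tight: because the model forces equal benign
production while the published NHB and NHW PSA medians are equal despite
very different prostate weights, the group medians cannot all be matched
exactly, and the noise level that stabilizes cutoff estimation at n = 87
leaves the synthetic PSAD discrimination (AUC about 0.79-0.84) sharper than
the published 0.71-0.75.  Passing tests therefore demonstrate correctness
of the pipeline under this idealized mechanism, not reproduction of the
original patients: real cohorts carry measurement error, grade
heterogeneity, and selection effects the generator does not model.

**Null preset.**  `null_no_race_effect` makes the groups exchangeable up to
size: every group uses the NHW marginals *and* the same tumor rate.
Equalizing the rates alone is not a null for cutoff ordering — with the
published marginals retained, NHB's larger prostates alone push its PSAD
cutoff below NHW's in about 70% of replicates — which is itself a
demonstration of the prostate-weight confounding the derivatives exist to
correct.  Under the exchangeable null the ordering fraction is ~0.5 (sign
test p > 0.05 across 100 seeds).

**Identifiability.**  `recover_parameters` regresses PSA on (PW, TV) per
group without intercept.  On noiseless, untruncated cohorts it recovers the
configured rates to 1e-8.  Under the defaults, multiplicative noise inflates
both rates by the same factor so the between-group ratio stays interpretable:
the mean recovered NHB/NHW ratio over 100 replicates of 5000 per group is
about 0.78 against the true 0.75 (a small upward bias from the PSA-range
truncation acting more on the higher-rate group).  Ignoring hemodilution
biases the recovered tumor rate downward in high-BMI strata, as expected.

**Replicate-to-replicate variability.**  At the published group sizes the
NHB-below-NHW PSAD cutoff ordering holds in roughly 88-98 of 100 replicates
depending on the replicate seed set; the n = 87 NHB group makes the
upper-left cutoff estimate the noisiest quantity in the pipeline.

## Pipeline and problem sizes

`run_pipeline` chains derive -> ethnicity annotation -> group summaries ->
associations -> ROC/cutoff reports -> screening classification at the
published thresholds (PSAD 0.15, PSAMD 0.012) and the fixed-specificity-80%
bootstrap comparison, writing CSVs plus a JSON manifest (config + seed +
version) that reproduces every output byte for byte; all randomness descends
from the single analysis seed via a spawned `SeedSequence` per stage.
Cutoff rows are emitted for *all* groups, including ones a report might
suppress, with single-class groups flagged not estimable rather than
dropped.

The validation suites use: 1000 random instances (n <= 10) for the ROC
brute-force equivalences; 10^4 null replicates per test for type-I error
calibration; 100 replicates of 5000 per group for rate recovery; and 100
seeded replicates at the published group sizes (589 records) for the
cutoff-ordering property and its null control.  These sizes give Monte Carlo
standard errors comfortably below the asserted tolerances while keeping the
full suite around a minute of compute.

## Known limitations

* The generator reproduces marginals and one production mechanism, not joint
  clinical reality; its AUCs are optimistic (see calibration note).
* The bootstrap comparison at fixed specificity is one defensible choice
  among several; no claim is made that it matches any specific published
  test.
* PPV/NPV depend on the synthetic prevalence and should not be transported.
* The shipped surname table is a synthetic test fixture; real ethnicity
  annotation requires supplying the actual census-derived list.
* Records missing height/weight are excluded from BMI-dependent analyses
  and counted in the logs, since no imputation is attempted.
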