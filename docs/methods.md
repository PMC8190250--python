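# Methods

## The score

Five analytes of the diagnostic immunology panel are each mapped to an
integer point value and summed. Per-analyte categories (see the README table)
are piecewise-constant in the measured value, with the convention that the
**lower bound of the better category is inclusive**: smB of exactly 6% scores
1 point, CD4 of exactly 700/µL scores 1 point, IgA of exactly 0.07 g/L scores
2 points, and a total of exactly 10 is high-risk. This follows the strict
"<" labels that delimit the worse categories in the published scoring table
and the inclusive "≥ 10" phrasing of the risk dichotomy.

Two categories are unreachable by design (IgA and antibody responses have no
3-point cell), so the attainable component sets are {1,2,3,4}, {1,2,4},
{1,4}, {1,2,4}, {1,2,3,4} and the attainable totals are exactly 5–20. IgM
**within or below** the normal range contributes the floor of 1 point; only
an elevation above the upper normal limit (2.3 g/L) scores, and it scores 4.
Any other convention would make the printed 5–20 range unattainable, since a
0-contribution from normal IgM would allow totals of 4.

Values above the reference range (smB > 29%, CD4 > 1500/µL) have no worse
category to fall into: they score 1 point and carry a warning flag, never an
error. Records missing any of the five analytes are **refused, not imputed**
— an imputed component would silently shift a 5-component sum across the
risk cutoff.

### Reference limits

All thresholds are configurable (`ReferenceConfig`, YAML-overridable). One
default is not fixed by any published number: the IgA "2 SD below normal"
limit separating the 1- and 2-point categories. We use 0.4 g/L — a
conventional adult lower-alarm value sitting between the 0.07 g/L
undetectability limit and the 0.7 g/L lower normal bound used by the
generator. The invariant `undetectable ≤ 2SD ≤ lower normal` is enforced.

The vaccine-response helper classifies a titre rise as adequate on a ≥ 4-fold
rise (protein/tetanus, or post-titre > 0.15 IU/mL) or ≥ 3-fold rise
(polysaccharide/pneumococcal, or post-titre > 11 mg/dL); the scoring
functions themselves consume pre-computed adequate/inadequate labels, since
raw titres are often unavailable.

## Clinical severity and clustering

Two complication catalogs ship as editable YAML: a mild/moderate/severe
system weighting items 1/5/10 and a 15-item system where the 0–3 grade is its
own weight. The published item lists live in the original severity-score
papers and are not reproduced in full anywhere we can transcribe from; the
bundled item sets are assembled from the complications enumerated in the
study cohort's description. The contract is the weight/cutoff arithmetic,
not the canonical item list — users can swap in their own catalog file.

Cluster assignment in the pipeline uses the fixed cutoffs (≥ 14 and ≥ 5
points ⇒ Cluster B, boundaries inclusive). Because "dichotomise by a
clustering algorithm" and "use the fixed cutoff" are conflated in the source
description, the pipeline also re-derives the data-driven boundary with
`two_means_1d` — the exact 1-D 2-means: the optimal
within-cluster-sum-of-squares 2-partition is contiguous in sorted order, so
scanning the n−1 sorted splits (skipping splits inside ties) is exhaustive
— and reports whether it agrees with the fixed cutoff, together with
silhouette widths (absolute-difference distance; singleton clusters get
s = 0 by convention).

## Diagnostic performance

Classification rule: `score ≥ t ⇒ predicted severe`, thresholds swept over
the distinct observed scores plus a +∞ sentinel. AUC is the trapezoidal
integral of the empirical ROC, which equals the tie-corrected Mann–Whitney
probability P(S⁺ > S⁻) + ½P(tie); the test suite asserts this equality to
1e−12 on random tied instances. The optimal cutpoint minimises the Euclidean
distance from (1−specificity, sensitivity) to (0, 1); ties break toward
higher sensitivity, then lower threshold. Undefined confusion ratios (zero
denominators) are returned as NaN with an explicit flag.

McNemar comparisons restrict to true positives (sensitivity) or true
negatives (specificity); the exact binomial two-sided p is used while the
discordant count b + c < 25, the continuity-corrected chi-square above —
the standard small-sample switch. Zero discordance returns p = 1 with a flag.

Bootstrap inference is **patient-level percentile resampling** (the simplest
method consistent with asymmetric intervals such as a sensitivity CI hitting
100% on small positive counts; BCa is deliberately not used). The paired AUC
comparison resamples subjects once per replicate and evaluates both scores on
the same resample; degenerate (single-class) resamples are redrawn with a
capped retry count; the two-sided p is 2·min(frac ≤ 0, frac ≥ 0), floored at
1/B. B defaults to 2000; every bootstrap is seeded and bitwise reproducible.
Measured operating characteristics (seeded simulations in the test suite):
percentile-CI coverage 0.954 for a binomial-mean toy (n = 20, 500 sims,
B = 500) and null ΔAUC rejection 0.062 at α = 0.05 (500 sims).

## Association

The per-point odds ratio comes from a univariable logistic regression fitted
by Newton/IRLS iterations (statsmodels backend; tolerance 1e−8, ≤ 100
iterations), with Wald 95% CI exp(β₁ ± 1.96·se). Complete separation is
detected up front and raised as an explicit error rather than returning a
divergent coefficient. The dichotomised association is the 2×2 at the
(inclusive) cutoff with the sample odds ratio ad/bc, a log-scale Wald CI, and
the two-sided Fisher exact p (sum of hypergeometric probabilities no larger
than the observed table's). A Haldane–Anscombe 0.5 correction is applied to
the OR/CI only when a cell is zero, and is always flagged; a zero margin
yields p = 1 with a degenerate flag. Wald rather than profile-likelihood
intervals are reported, matching the symmetric style of the printed CIs.

## Survival

Kaplan–Meier product-limit estimates of progression to Cluster B use **age**
as the time axis (the published curves plot age, not time since diagnosis);
non-progressors are censored at age at last follow-up. Ties are handled
events-before-censoring. The two risk groups (total ≥ 10 vs < 10) are
compared with the Mantel–Cox log-rank test (observed − expected with
hypergeometric variance, chi-square with 1 df). **Limitation:** no left
truncation is applied for delayed entry at the diagnosis age, matching the
source analysis; with age as the time scale this overstates early-age risk
sets, so absolute survival levels should be read qualitatively.

## Synthetic cohort generator

The generator's defaults are the study conditions: n = 50; per-analyte
category frequencies smB 24/36/14/26%, IgA 26/24/50% (points 1/2/4),
elevated IgM 6%, antibody-response patterns 58% both altered / 28%
polysaccharide-only / 14% protein-only / 0% normal, CD4 44/12/32/12%;
severity link slope ln 1.3 per point with the intercept solved analytically
so P(Cluster B) = 0.56 at the expected total; diagnosis ages from a scaled
Beta(2, 2.6) on (4, 70) years (median ≈ 32); follow-up durations uniform on
1–31 years (median ≈ 16); progression delays for Cluster-B patients are 0
with probability 0.5, otherwise exponential with mean 4 years (halved for
the high-risk group), reproducing a short diagnosis-to-progression gap with
median 0.

Continuous laboratory values are drawn uniformly **strictly inside** the
drawn category's interval (category-1 intervals are bounded by the reference
ranges: smB 6–29%, IgA 0.7–4.0 g/L, IgM 0.4–2.3 g/L, CD4 700–1500/µL; the
elevated-IgM interval starts at 2.4 g/L to stay clear of the 2.3 boundary),
so re-categorisation round-trips to the drawn category for 100% of rows —
`roundtrip_check` verifies this, and a `corrupt_intervals` hook deliberately
breaks it as a negative control. Values are stored at full precision:
rounding could push a draw across a category boundary.

Severity totals are drawn uniformly on (8, 13)/(14, 21) and (2, 4)/(5, 10)
for Cluster A/B of the two catalogs (the printed cohort ranges), then
decomposed greedily into per-item complication records so that re-scoring
the records reproduces the totals exactly. Both catalogs' clusters derive
from the **same** drawn severity flag, so on synthetic data the two cluster
definitions coincide patient-by-patient; real cohorts would not behave this
way.

What the generator does *not* emulate: correlations among analytes (only
marginals are published; a shared-latent-factor Gaussian-copula hook
`latent_severity_rho` exists but defaults off), measurement error, age
dependence of reference ranges, or informative censoring. Passing pipeline
tests on synthetic cohorts therefore demonstrates the statistical machinery
and the direction/magnitude of the encoded association — not clinical
validity on real patients.

### A structural consequence worth knowing

The published marginal frequencies fix the expected total at 11.62, so on
generator cohorts the score distribution centres near 11.5 and the
closest-to-(0,1) cutpoint concentrates at 12 (mode 12, range 10–14 over 60
seeds) rather than at the cutoff of 10 reported for the original cohort
(whose printed median total of 10 is not consistent with its own printed
marginals). Multi-seed checks therefore assert the AUC band (mean ≈ 0.67,
within 0.60–0.85), the VISUAL-vs-smB ordering (VISUAL AUC ≥ smB-alone AUC in
≈ 83% of seeds) and the cutpoint's concentration near the score centre.

## Problem sizes and numerical choices

Default test/validation sizes: structural checks enumerate all 288 component
combinations exactly; oracle-equivalence checks run on ~100 random instances
(n ≤ 200) plus every 2×2 table with grand total ≤ 30; parameter recovery
uses 20 cohorts of n = 2000 (recovered mean slope 0.263 vs ln 1.3 = 0.262);
null calibration 500 cohorts of n = 50 (Fisher rejection 2.2% at α = 5%);
pipeline fidelity 50 cohorts of n = 50. Two-means tie-breaks prefer the
smaller left cluster on exact WSS ties; the ROC threshold grid uses the
observed scores, so cutpoints are always attained values; all RNG streams
are `numpy.random.default_rng` seeded per analysis stage via an FNV-1a hash
of (run seed, stage label), keeping streams independent and below 2³¹.

## Known limitations

* The severity catalogs are reconstructions, not the canonical item lists.
* Independence of analytes in the generator understates the real joint
  alteration of immune compartments (smB and CD4 co-vary in practice).
* No left truncation in the age-scale KM (see above); no Cox regression or
  competing risks.
* Cohort-specific published statistics (e.g. the exact AUC 0.721 or the 8.94
  odds ratio) depend on unavailable patient-level data and are targets of
  direction/band checks only.
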