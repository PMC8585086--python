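# Methods

## The measurement model

The package assumes the standard common-factor model for the questionnaire
battery: each of the 23 retained items is a threshold-discretized Gaussian
indicator of two correlated latent traits, functional disability and
depression/anxiety, with pattern matrix Λ, factor correlation Φ (unit
diagonal, Φ₁₂ ≈ 0.54) and uniquenesses Ψ = 1 − diag(ΛΦΛ′). Pain intensity
(NPRS) and the intensity-weighted painted surface (PMI) are treated as
observed constructs correlated with the factors. All symptom scales are
coded so that higher = worse; reverse-keyed HADS items are assumed re-coded
at data entry.

Exploratory analysis uses principal-axis factoring (iterated communalities
starting from squared multiple correlations) on Pearson correlations of
pooled per-visit complete observations, followed by promax rotation
(varimax pre-rotation with Kaiser normalization, |x|⁴ target, oblique
least-squares fit, columns scaled to unit-diagonal Φ). Polychoric
correlations are deliberately out of scope; the ordinal attenuation this
induces is discussed below. Confirmatory fits are single-level maximum
likelihood with a marker-variable identification; χ² = (n−1)·F at the
optimum, RMSEA with a 90 % CI by inverting the noncentral χ² cdf, CFI
against the independence baseline. Multilevel (within/between-patient)
decompositions, robust standard errors and scaled test statistics are not
implemented.

## The composite

Bartlett weighted-least-squares factor scores are conditionally unbiased
given the model; their accuracy is bounded by the item communalities: with
the published loading pattern, diag((Λ′Ψ⁻¹Λ)⁻¹) ≈ 0.28/0.27, so on
unit-variance cross-sectional factors the correlation between estimated and
true factor cannot exceed ≈ 0.885. On pooled longitudinal data the
visit-level factor variance exceeds 1 (real between-visit change), which is
what carries the observed recovery correlations above 0.9.

The index is the first principal component of the correlation matrix of the
four constructs (the correlation metric is forced by the published
eigenvalue ≈ 2 being ≈ 50 % of four unit variances). The sign is chosen so
that all four symptom-burden constructs receive negative weights (higher
index = better health). Scaling to [0, 10] is min–max over the pooled
derivation sample; both the construct standardization statistics and the
scaling bounds are frozen into the serialized composite model so follow-up
scoring never refits. Scores outside the derivation range are clipped (with
a counter); the [0, 100] construct scaling exists only for reporting. The
anchor-derived minimal important change of 1.05 index points is carried as
metadata.

## Anchor-based evaluation

Changes are oriented so that positive always means improvement
(baseline − follow-up for ODI, NPRS, HADS and PMI; follow-up − baseline for
the index and EQ-5D); a responder is `change ≥ cutoff`. PGIC is the
standard 7-category scale with ≥ 6 dichotomized as satisfactory. AUC is the
tie-corrected Mann–Whitney probability (identical to trapezoidal ROC
integration); optimal cutoffs maximize sensitivity + specificity over
midpoints between adjacent distinct changes plus the extremes, ties broken
toward higher sensitivity then the smaller cutoff. The Jonckheere–Terpstra
statistic sums pairwise Mann–Whitney counts over ordered PGIC groups with
half credit for ties; the default p-value is the one-sided (increasing)
normal approximation with the tie-corrected variance, with exact
enumeration and Monte-Carlo permutation available for small samples. No
multiple-testing correction is applied anywhere. All statistics are
computed on complete cases for the variables involved; nothing is imputed.

### Factor-count diagnostics

Horn's parallel analysis compares observed correlation-matrix eigenvalues
against the mean (default) or a quantile of eigenvalues from replicate
standard-normal datasets; on pure noise the mean comparator necessarily
flags the leading eigenvalue about half the time, so noise-rejection checks
use the 0.95 quantile. The VSS criterion is computed at complexity 1 and 2.
With correlated factors the complexity-1 curve mathematically favors one
factor even at the population level (a general factor reproduces the
off-diagonals of an oblique two-factor structure better, in summed squared
error, than a one-loading-per-item simplification that discards real
cross-loadings), so the package's two-factor verdict reads the complexity-2
curve, which peaks sharply at two factors; both curves are reported.

## The synthetic cohort generator

The generator is the package's test bed and defines its study conditions:
193 patients, five visits, per-visit completion probabilities
0.964/0.803/0.777/0.679/0.679 (independent across visits, matching the
observed pattern of equal 9- and 12-month counts), plus item-level
missingness completely at random at 0.5 %.

Latent state per patient-visit is a 4-vector (disability, distress, pain
intensity, pain surface) with baseline correlation matrix built from
Φ₁₂ = 0.54 and construct correlations (NPRS: 0.55/0.38 with the factors,
PMI: 0.30/0.05, NPRS–PMI 0.32) — chosen once so that the pooled construct
correlations reproduce the published composite geometry, including the
|loading| ordering disability > NPRS > distress > PMI. Items are threshold
cuts of λ′F plus unique noise (unit-variance continua); thresholds are
fixed constants calibrated to the published baseline summaries (ODI ≈ 44 %,
NPRS ≈ 6.1, EQ-5D index ≈ 0.28, HADS-D ≈ 8.6). The EQ-5D index is a fixed
linear map of the level sum (no national value set is modelled). Pain
surfaces are lognormal areas split across the four intensity classes by a
Dirichlet(2,2,2,2) draw.

Improvement is heterogeneous and multidimensional: at visit t every latent
dimension l shifts by `d_t · (1 + 1.7·g_il)` where d = (0, 0.35, 0.50,
0.55, 0.60) latent-SD units and the per-dimension propensities g_il are
standard normal with cross-dimension correlation 0.25 — so most patients
improve, a substantial minority worsens, and improvement in one dimension
only partially implies improvement in another. An occasion-level
fluctuation (SD 0.6, correlated like the baseline state) models
visit-to-visit symptom variability. The PGIC anchor is an ordinal cut of
the *sustained* improvement (the mean of the d-driven shifts, excluding
occasion fluctuation) plus anchor noise (SD 0.25), with thresholds set so
that ≈ 25 % are satisfied at 12 months. These longitudinal parameters were
calibrated once against the published summaries (satisfied share, the
composite's AUC advantage over single instruments, the component-loading
ordering) and then frozen.

Two deliberate departures from the published loading table in the
*default* truth: the five retained items whose printed dominant loadings
sit at 0.30–0.34 (on the 0.3 pruning threshold) are floored at 0.42, and
the three items meant to be pruned load at most 0.18. At the printed
values the qualitative 29 → 26 → 23 selection would be a per-seed coin
flip; the floor makes the selection a structural property of the
conditions rather than a threshold coincidence. Recovery analyses use the
exact published values through an explicit config.

What the generator does **not** emulate: treatment assignment and center
effects, informative dropout, response styles, the discrete boundary
effects of real EQ-5D value sets, or polychoric-vs-Pearson differences in
the published estimates. Passing tests therefore show that the pipeline
recovers the structure it assumes from data that satisfy its model — not
that the published estimates are correct for real patients.

## Numerical choices and problem sizes

- Principal-axis iteration: tolerance 1e−6 on communalities, up to 1000
  iterations with 0.5 relaxation after 50 (the plain fixed point can
  cycle at high factor counts); Heywood communalities clip to 0.995 with a
  warning. The factor-count scan (VSS) uses a looser 1e−3 tolerance.
- Varimax stops when the rotation criterion improves by < 1e−5
  (the classical stopping rule); promax power is 4.
- CFA optimizes with analytic gradients (L-BFGS-B) over free loadings, a
  log/tanh-parameterized factor covariance and log uniquenesses.
- Ties in Spearman correlations use average ranks; confidence intervals
  are Fisher-z with SD 1/√(n−3) (for the repeated-measures correlation,
  with the ANCOVA degrees of freedom n − subjects − 1 playing the role of
  n − 3 + 1).
- Test and acceptance problem sizes: recovery suites pool ≈ 2000–3500
  records (520–900 generated patients); factor-count and anchor checks run
  10 seeds at the default 193 patients; composite-structure checks run 10
  seeds at 900 patients, where sampling noise no longer swamps the
  0.04-wide gap between the top component loadings.

## Known limitations

- Pearson-based EFA on 4–6-category items attenuates loadings by roughly
  5–13 %; pooled longitudinal variance inflation works in the opposite
  direction. Both effects are visible at the ±0.05 level in recovery runs.
- The Bartlett-score accuracy ceiling above means the construct scores are
  irreducibly noisy at these communalities; this is a property of the
  published instrument battery, not of the estimator.
- The published two-level CFA fit values are not reproducible by the
  single-level fit implemented here and are not targeted.
- Confusion-table reporting assumes the printed counts' layout; one
  published row (9-month pain-mapping) transposes its satisfied counts and
  is handled by the rates it prints.
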