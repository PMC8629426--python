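# Methods

## Model

The package models the normalized burden ρ′(t) of a solid tumor under
PD-1/PD-L1 checkpoint blockade as the solution of

dρ/dt = k ρ (1 − ρ/ρ∞),  ρ(0) = 1,

whose closed form is ρ′(t) = ρ∞ / (1 − (1 − ρ∞) e^(−kt)) with

- k = α − µ + µΛ — net exponential rate (d⁻¹),
- ρ∞ = 1 + (α − µ)/(µΛ) — long-term burden.

α is the intrinsic proliferation rate the tumor would have without immune
kill; Λ (dimensionless, ≥ 0) aggregates effector-cell abundance and per-cell
kill ability at treatment start; µ (d⁻¹) is the checkpoint-inhibitor-mediated
amplification of that kill. The sign of α − µ decides progression versus
regression; µΛ sets how sharply the trajectory saturates. Underlying
assumptions: exponential intrinsic growth; a single net effector compartment;
drug and immune influx equilibrate much faster than clinical response, so the
treatment enters as a constant rate modification; spatial structure is
negligible at the resolution of total indexed-lesion volume.

Modeled limits and edge cases:

- **Exponential limit.** When |µΛ| ≤ ε = 10⁻¹², ρ∞ is undefined and the
  trajectory is evaluated as its analytic limit e^(kt). We use e^(kt) rather
  than e^(αt): it is the true pointwise limit of the closed form along any
  path µΛ → 0 (and the two coincide in the relevant case µ → 0), so the
  trajectory is continuous across the ε switch.
- **Complete regression.** For k < 0 the analytic trajectory decays to 0.
  Reported/projected burdens are clamped at 0; the analytic value is never
  negative on the valid branch.
- **Finite-time singularity.** For some µ < 0 combinations the denominator
  1 − (1 − ρ∞)e^(−kt) has a positive root t* = ln(1 − ρ∞)/k (hyperbolic
  blow-up). Evaluation within 10⁻⁹ of the root raises a singularity error;
  `singularity_time` exposes t* for screening.
- ρ′(0) is pinned to exactly 1 in all regimes (the normalization point).

Doubling time is ln 2/α. Reported per-histology rates span α = 0.0034 d⁻¹
(renal cell, ≈204 d) to 0.0622 d⁻¹ (colorectal, ≈11 d); these constants ship
in `synthetic.HISTOLOGY_ALPHA`.

## Estimation

Fitting is two-step, mirroring how the model is used on trial data.

**Step 1 — α.** Either (a) *fastest progressor*: every patient's on-treatment
series is fit to e^(αt) by linear regression of ln ρ′ on t (exact and convex
for positive burdens; the loss is a package choice), and the maximal rate is
used cohort-wide — the approximation needed when no pretreatment imaging
exists; patients with a zero burden (complete responses) cannot be
exponential-fit and are skipped, which cannot change the maximum; or
(b) *per-patient pretreatment*: α = ln(ρ_pre)/t_pre from the scan immediately
preceding the first dose; negative α (tumor already shrinking) is allowed.

**Step 2 — (Λ, µ).** With α fixed, (Λ, µ) minimize the sum of squared burden
residuals over all on-treatment points (the baseline contributes exactly 0).
Identifiability at fixed α follows from the invertible map
µΛ = k/ρ∞, µ = α − k(ρ∞ − 1)/ρ∞ — *provided the data determine (k, ρ∞)*;
see "Limitations". The optimizer is bounded trust-region least squares
(`scipy.optimize.least_squares`, trf) with an analytic Jacobian, run from a
deterministic multi-start grid Λ ∈ {0.01, 0.1, 1, 5} × µ ∈ {−0.01, 0.001,
0.01, 0.05, 0.2}, plus one data-driven start obtained by inverting a crude
(k, ρ∞) estimate (k from the first positive post-baseline point, ρ∞ from the
last observation); the data-driven start is what reaches plateaus orders of
magnitude outside the grid. Best final SSR wins, ties to the earliest start;
no randomness anywhere, so refits are bitwise identical. We optimize directly
in (Λ, µ) rather than (k, ρ∞): the bounds Λ ∈ [0, 100], µ ∈ [−1, 1] d⁻¹
(spanning all reported cohort values with wide margin) are rectangular in
this space, and convergence with the analytic Jacobian is robust. Points past
a finite-time singularity (denominator sign flipped relative to ρ∞) receive a
large penalty residual, and starts that begin inside such a region are
skipped — a trajectory that blows up before the last scan cannot describe the
data. Tolerances: relative SSR change 10⁻¹⁰ (`ftol`), step 10⁻¹² (`xtol`),
at most 500 evaluations per start.

## Response classification and projection

Patients are condensed into favorable (partial/complete response) versus
unfavorable (stable/progressive disease) by comparing the last observed — or
model-projected — normalized burden against a threshold. Two conventions are
implemented because a "≥30 % reduction" can be read on volume directly
(threshold 0.70, the default) or on the RECIST diameter sum, which for
spherical lesions is a volume ratio of 0.7³ = 0.343. Projection evaluates the
fitted trajectory at a configurable horizon (default 700 d, beyond the last
follow-up), clamped at 0.

Truncation analysis refits each patient on data restricted to t < w for
w ∈ {30, 60, 120, 200} d (strict inequality; baseline always kept). A patient
is fittable in a window if at least one post-baseline point survives; excluded
counts are reported per window, mirroring the varying per-window n of real
cohorts. Stability is summarized by Spearman correlations of windowed versus
full-data Λ and µ, and by the fraction of patients whose projected-horizon
label changes relative to the full-data fit (the comparison convention is
recorded in the report metadata; comparing against observed last-point labels
is the other defensible reading).

Sensitivity analyses: (i) Λ and µ individually perturbed ±10 % (α
deliberately not perturbed), maximal |Δρ′| at t = 200 d reported; (ii) every
post-baseline burden perturbed by Uniform(−0.1, 0.1) — the baseline stays 1
because burden is defined relative to it — refit, and rank correlations with
the original parameters reported.

## Statistics

- **Wilcoxon rank sum**: mid-rank statistic; exact two-tailed p by full
  enumeration of all C(N, n_x) rank assignments for pooled N ≤ 12 (tie-aware;
  counts assignments with |W − E[W]| at least as large as observed); above
  that, tie-corrected normal approximation with continuity correction. The
  approximation's exhaustive worst-case error just past the crossover is
  ≈0.015–0.018 absolute p, so exact and approximate branches agree to 0.02
  (not better — a property of the normal approximation, verified by complete
  enumeration).
- **Spearman**: Pearson correlation of mid-ranks (scipy); zero rank variance
  raises rather than returning 0.
- **ROC/Youden**: thresholds at all distinct-score midpoints plus ±∞;
  orientation fixed as "higher score ⇒ predicted responder" (no automatic
  sign flipping); Youden J maximized with ties resolved toward the smallest
  threshold (favoring sensitivity); AUC integrated along the threshold path,
  which equals the tie-adjusted Mann–Whitney U/(n₊n₋). Confusion ratios with
  zero denominators are NaN with a warning, never silently 0.

## Biomarker mapping

Λ → intratumoral CD8+ T-cell density via Λ × 5558 cells/mm² (one kill per
cell on average; microenvironment density as measured in melanoma — both
config constants). µ → PD-L1 positivity as µ × 100 %; negative fitted µ keeps
its raw value in reports but clamps to 0 for stratification, since staining
percentages are nonnegative. ORR is computed per stratum at the 1 % and 5 %
cutoffs; pooled literature ORRs (15 %/28 % at 1 %; 21 %/38 % at 5 %) are
shipped only as report annotations.

## Virtual-cohort generator

The generator emulates the structure of the trial data the model is meant for:

- visit schedule: baseline at t = 0, follow-ups every 42 d with ±10 d uniform
  jitter up to a 700 d horizon (inter-scan gaps stay inside the reported
  17–91 d range), plus an optional pretreatment scan at −U(17, 91) d;
- α by histology (the six reported rates, uniformly assigned) or per patient
  ~ U(−0.0129, 0.0602) for validation-style cohorts;
- class-conditional (Λ, µ): a patient is a responder with probability 0.29
  (the calibration ORR; 0.39 fits validation-style runs). Only class means
  and SEMs are reported for the real cohorts, so the distribution families
  are a commitment of this package: lognormal matched to (mean, SEM·√n) for
  Λ and responder µ (positive support), normal for nonresponder µ (negative
  values occur in the validation cohort). Draws are clipped to the fitting
  bounds and rejection-sampled until (a) the trajectory has no singularity
  inside 1.05× the horizon and (b) its projected label matches the drawn
  class — keeping the recorded responder flag consistent with the trajectory
  it generates;
- noise: additive Uniform(−a, a) on post-baseline burdens (default a = 0.1,
  the reported perturbation bound), clamped at 0; baseline stays exactly 1.
  The pretreatment scan is left noiseless: additive noise of this magnitude
  can push the small pretreatment burden of a fast grower to zero, leaving
  the pretreatment α undefined;
- lesions (optional): per-patient count from a truncated geometric
  (range 1–12, median 3), per-scan totals split by fixed Dirichlet
  proportions, axes back-solved from sphere volumes with long/short ratio
  ∈ [1, 2.5] so aggregation round-trips exactly;
- reproducibility: patient i is generated from an independent substream keyed
  by (seed, i), so cohorts are bit-reproducible and stable under cohort
  growth.

What the generator does **not** emulate: pseudoprogression, new or
differentially responding lesions, dropout/censoring beyond the horizon,
inter-site measurement bias, or any correlation between α and (Λ, µ). Passing
recovery tests therefore demonstrates correctness of the estimation machinery
under the model's own data-generating process, not robustness to
model misspecification in real images.

## Numerical choices

- ε = 10⁻¹² for the exponential-limit switch; 10⁻⁹ denominator tolerance for
  the singularity error.
- CSVs are written with `%.17g` and read with round-trip float parsing, so
  write→read reproduces cohorts to the last bit.
- Exact baseline: predicted and stored burdens at t = 0 are exactly 1.
- Missing short axis in lesion tables falls back to short = long with a
  warning (conservative sphere estimate). Scans earlier than the scan
  immediately preceding t = 0 are ignored with a warning. Patients without a
  positive baseline volume are excluded (CLI: listed in `exclusions.csv`).
- Problem sizes used by the test suite and the acceptance script (120-patient
  noiseless and 200-patient noisy recovery cohorts; 40–60-patient truncation
  cohorts) were chosen so each analysis completes in minutes on one CPU while
  keeping binomial/median estimates stable.

## Limitations

- **Kinetic identifiability.** (Λ, µ) are recoverable only where the data
  determine both k and ρ∞. A patient whose |k| exceeds ~0.2 d⁻¹ equilibrates
  within days, so every ~6-week follow-up sits on the plateau: ρ∞ (or 0) is
  measured but k is not, and infinitely many (Λ, µ) fit the data to machine
  precision. A few percent of generated patients (heavy lognormal tails) fall
  in this regime; `remaining_dynamic_signal` quantifies the trajectory signal
  left at the first follow-up and is used to screen recovery claims.
- Λ near 0 with µ near 0 is likewise weakly identified (the exponential-limit
  boundary); µ is consistently the better-determined parameter, which is also
  why its early-truncation rank stability exceeds Λ's.
- The two-step procedure conditions on α; errors in α propagate into (Λ, µ)
  and are not accounted for in the reported RMSE.
- No per-patient uncertainty intervals beyond RMSE, and no hierarchical
  pooling across patients.
- The CD8 and PD-L1 conversions are linear calibrations anchored to reported
  constants, not mechanistic derivations; they should be re-calibrated per
  disease/assay before any clinical interpretation.
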