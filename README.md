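# icikinetics

Mechanistic modeling of solid-tumor response to PD-1/PD-L1 immune checkpoint
inhibition, for translational oncology groups who want to turn routine imaging
follow-up (RECIST-style lesion measurements) into early, per-patient response
predictions and biomarker estimates.

## The model

Normalized tumor burden ρ′(t) — total indexed-lesion volume divided by its
value at the first dose, so ρ′(0) = 1 — follows the closed-form solution of a
logistic-type ODE:

    ρ′(t) = ρ∞ / (1 − (1 − ρ∞) e^(−k t))

with three biologically interpretable parameters:

| parameter | meaning | units |
|---|---|---|
| α | intrinsic tumor proliferation rate (doubling time = ln 2 / α) | d⁻¹ |
| Λ | anti-tumor immune state (effector-cell abundance × per-cell kill ability) | — |
| µ | immunotherapy-mediated amplification of immune kill | d⁻¹ |

and the derived constants k = α − µ + µΛ (net exponential rate) and
ρ∞ = 1 + (α − µ)/(µΛ) (long-term burden: progressive disease when α > µ,
regression when α < µ). When |µΛ| is negligible the trajectory degenerates to
the pure exponential e^(kt).

Around this core the package implements the full inference pipeline:

- **cohort I/O** — lesion-level (long/short axes → geometric-mean sphere
  volumes, summed per scan) and burden-level CSV dialects, per-patient
  normalization, YAML metadata sidecars;
- **two-step fitting** — α from the fastest-progressing patient
  (cohort-level exponential fit) or from each patient's pretreatment scan;
  then (Λ, µ) per patient by bounded multi-start nonlinear least squares;
- **response analysis** — condensed RECIST v1.1 labels (favorable = PR/CR,
  ≥30 % burden reduction; volume-0.7 or diameter-equivalent-0.343
  conventions), 700-day projection, early-truncation refits (t < 30/60/120/200
  d) with Spearman stability and misclassification reports, ±10 % parameter
  and ±0.1 data perturbation analyses, (α, Λ, µ) response-surface sweeps;
- **statistics** — Wilcoxon rank-sum (exact enumeration for pooled n ≤ 12,
  tie-corrected normal approximation above), Spearman correlation, ROC with
  Youden-J threshold selection and confusion metrics;
- **biomarker mapping** — Λ × 5558 → intratumoral CD8+ T-cell density
  (cells/mm²), µ × 100 → PD-L1 positivity (%), ORR stratification at the 1 %
  and 5 % cutoffs;
- **virtual cohorts** — a seeded generator with known ground truth emulating
  the calibration/validation trial structure (pretreatment scan, ~6-week
  follow-ups to 700 d, 1–12 indexed lesions, class-conditional parameter
  distributions, bounded uniform noise), so the whole pipeline is testable
  without protected clinical data.

## Worked example

```python
import numpy as np
import icikinetics as ik

# a slow-growing tumor (melanoma-like alpha) with decent immune infiltration
m = ik.TrajectoryModel.from_values(alpha=0.0069, lam=0.8, mu=0.02)
print(f"k = {m.k:.5f} /day, rho_inf = {m.rho_inf:.3f}")
print(f"rho'(200 d) = {ik.predict_burden(m, 200.0):.3f}")

# virtual cohort -> per-patient fits -> response statistics
syn = ik.generate_cohort(ik.GeneratorConfig(n=30), seed=7)
alpha = ik.resolve_alpha(syn.cohort, "per-patient-pretreatment")
fits = ik.fit_cohort(syn.cohort, alpha)
labels = {p.patient_id: ik.classify_response(p).favorable for p in syn.cohort}

mu = np.array([f.mu for f in fits])
fav = np.array([labels[f.patient_id] for f in fits])
w, p = ik.wilcoxon_rank_sum(mu[fav], mu[~fav])
roc = ik.roc_with_youden(mu, fav)
print(f"responders: {fav.sum()}/{len(fav)}")
print(f"mu  favorable vs unfavorable: {mu[fav].mean():.4f} vs {mu[~fav].mean():.4f}  (p = {p:.2e})")
print(f"Youden threshold on mu: {roc.youden_threshold:.5f}  "
      f"(sens {roc.metrics.sensitivity:.2f}, spec {roc.metrics.specificity:.2f}, AUC {roc.auc:.3f})")

f0 = fits[0]
print(f"{f0.patient_id}: Lambda = {f0.lam:.3f} -> CD8 {ik.lambda_to_cd8(f0.lam):.0f} cells/mm^2; "
      f"mu = {f0.mu:.4f} -> PD-L1 {ik.mu_to_pdl1_percent(f0.mu):.2f}%")
print(f"projected burden at 700 d: {ik.project_burden(f0):.3f}")
```

prints

```
k = 0.00290 /day, rho_inf = 0.181
rho'(200 d) = 0.335
responders: 7/30
mu  favorable vs unfavorable: 0.0574 vs 0.0111  (p = 1.44e-03)
Youden threshold on mu: 0.01821  (sens 0.86, spec 0.87, AUC 0.907)
P0000: Lambda = 0.021 -> CD8 116 cells/mm^2; mu = 0.0072 -> PD-L1 0.72%
projected burden at 700 d: 0.792
```

Read: the example patient's tumor shrinks toward 18 % of baseline
(rho_inf = 0.181); across the cohort the fitted immunotherapy effect µ
separates responders from nonresponders (higher µ → response), and the
Youden-optimal µ cutoff classifies with ~86 % sensitivity. Patient P0000's
low Λ and sub-1 % PD-L1 equivalent predict an unfavorable outcome, though the
projected 700-day burden (0.79) sits just under the 30 %-reduction threshold.

## Command line

```sh
icikinetics simulate --outdir out --seed 7 --n 50        # cohort.csv, truth.csv
icikinetics fit     --input out/cohort.csv --outdir out  # fits.csv, exclusions.csv
icikinetics analyze --input out/cohort.csv --outdir out \
    --alpha-mode per-patient-pretreatment --windows 30,60,120,200
# -> stats.csv, roc.csv, truncation.csv, biomarkers.csv, orr.csv,
#    config_resolved.yaml
```

All randomness flows through `--seed`; identical inputs and configuration
produce byte-identical outputs. Column orders of every report CSV are fixed as
written by `icikinetics.fitting.fits_to_frame`, `response.truncation_analysis`
and `biomarkers.biomarker_table`.

## Documentation

`docs/methods.md` describes the model and its assumptions, the estimation
procedure, what the virtual-cohort generator does and does not emulate,
numerical choices, and known limitations.
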