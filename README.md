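# pedrisk

Pedigree-based genetic risk scores and their moderation of psychiatric and
substance-use disorder risk, on synthetic registry data.

## The problem

National-registry psychiatric genetics often works without molecular data: a
person's genetic liability for a disorder is summarised by a **family genetic
risk score (FGRS)** — a kinship-weighted aggregate of affection status among
their 1st–5th-degree relatives under a liability-threshold model. The same
construction applied to relatives' educational attainment yields a **genetic
aptitude for educational attainment (GAEA)**. Three questions follow for a
birth cohort followed from age 17:

1. How strongly do GAEA and the disorder-specific FGRS each predict disorder
   risk, jointly and separately?
2. In males with conscript measurements, how much of the GAEA effect on risk
   is mediated by IQ versus by resilience?
3. Do FGRS and GAEA **interact** on the additive hazard scale — is the slope
   of risk in genetic liability steeper at low GAEA (a fan-shaped pattern)?

The registry data behind such analyses are confidential, so `pedrisk` ships a
synthetic-registry generator with the relevant statistical structure
(multigenerational pedigrees, correlated disorder/EA genetic liabilities,
liability-threshold affection, censoring, conscript mediators) and runs the
full analysis pipeline end to end on it.

## Models

- **FGRS / GAEA** — for proband *i* with relatives *r*:
  `raw_i = s_i * Σ_r w_r z_r / Σ_r w_r`, with `w_r = 2φ(i,r)` the relatedness,
  `z_r` the relative's liability contribution (`φ(τ)/K` if affected,
  `−φ(τ)/(1−K)` if not, `τ = Φ⁻¹(1−K)`; the continuous EA z-score for GAEA),
  residualized on co-residence years within degree class, and shrinkage
  `s_i = Σw/(Σw+λ)`. Scores are z-standardized within birth-year × county.
- **Tetrachoric correlation** — the latent bivariate-normal correlation of
  two dichotomized scores, by maximum likelihood with margin-implied
  thresholds (product-moment correlation of the continuous scores is reported
  alongside).
- **Aalen additive hazards** — `λ(t|x) = β₀(t) + Σ_j β_j(t) x_j`, estimated by
  least-squares increments of the cumulative coefficients `B_j(t)` at each
  event time; covariate sets A1 `{yob, sex, FGRS}`, A2 `{yob, sex, GAEA}`,
  B `{… FGRS, GAEA}`, C = B + FGRS×GAEA. Effects are reported as
  `100·B_j(408 months)`: the %-unit increase in cases per 34 years per SD.
- **Mediation** — males only; `m₁ = a₁g`, `m₂ = a₂g` (least squares) and a
  probit outcome `y* = c′g + b₁m₁ + b₂m₂`, standardized on the latent-response
  scale; total = c′ + a₁b₁ + a₂b₂ exactly, with proportion-mediated summaries
  and a bootstrap IQ-vs-resilience difference test.

## Worked example

```python
from pedrisk import (SimulationConfig, simulate_population, relative_links,
                     attach_cohab_years, compute_all_scores, score_correlation,
                     build_design, fit_aalen, summarize_34y)

cfg = SimulationConfig(n_founder_couples=5800, seed=1)   # ~20k cohort
bundle = simulate_population(cfg)
cohort = bundle.persons.loc[bundle.cohort_mask((1973, 1995)), "id"].to_numpy()
links = attach_cohab_years(relative_links(bundle.pedigree, probands=cohort),
                           bundle.cohab)
scores = compute_all_scores(bundle, links, ["DUD"], probands=cohort)

print(round(score_correlation(scores["FGRS_DUD"], scores["GAEA"]).rho, 3))
# -0.27   <- the drug-use-disorder FGRS and GAEA are negatively correlated

design = build_design(bundle, scores, "DUD", model="C")
summary = summarize_34y(design, n_boot=50, seed=1)
print(dict(zip(summary.columns, summary.estimate.round(2))))
# {'intercept': 4.96, 'yob_c': 0.17, 'sex': 4.42, 'FGRS': 5.43,
#  'GAEA': -0.93, 'FGRSxGAEA': -0.44}
```

A 1-SD increase in FGRS_DUD raises the 34-year case rate by ~5.4 %-units,
high GAEA lowers it, and the negative interaction means the FGRS slope
steepens as GAEA falls — the fan shape visible in `prediction_grid`.

The same run is available from the shell:

```bash
pedrisk all --seed 1 --outdir out/        # table1-3.csv, grids.csv, manifest.json
```

## Layout

- `pedrisk.simulate` — synthetic registry bundle (persons / pedigree / events
  / cohabitation CSVs)
- `pedrisk.pedigree` — kinship coefficients, 1st–5th-degree relative
  enumeration (recursive and vectorised paths)
- `pedrisk.scoring` — liability contributions, cohabitation adjustment, FGRS
  and GAEA aggregation and stratified standardization
- `pedrisk.tetrachoric` — tetrachoric MLE and product-moment correlations
- `pedrisk.aalen` — additive-hazards fit, 34-year summaries, prediction grids
- `pedrisk.mediation` — three-path probit mediation decomposition
- `pedrisk.pipeline` / `pedrisk.cli` — orchestration and the `pedrisk` CLI

See `docs/methods.md` for the modelling assumptions, generator defaults and
numerical conventions.
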