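# Methods

## Scope

`pedrisk` implements a registry-style genetic-epidemiological analysis on
synthetic data: family genetic risk scores (FGRS) for ten psychiatric and
substance-use disorders and an analogous score for educational attainment
(GAEA), their correlation, Aalen additive-hazards models with an FGRS×GAEA
interaction, and a three-path mediation decomposition of the GAEA effect
through IQ and resilience in males. The synthetic generator stands in for
confidential national registers; every downstream estimator is agnostic to
the data's origin and reads the same four CSV tables (persons, pedigree,
events, cohabitation).

## Synthetic registry generator

The generator emulates the statistical structure the estimators assume, not
Swedish demography.

**Pedigree.** `n_generations` (default 4) discrete generations descend from
`n_founder_couples`. Children per couple are Poisson(`mean_children` = 2.4);
mates are drawn within a generation under the constraint that spouses share
no founder ancestor, which keeps the pedigree outbred (every ancestor is
reached along a single line). The final generation is the study cohort, with
birth years uniform on 1973–1995; earlier generations are shifted back by 28
years per generation and act as phenotyped relatives. Probands typically have
80–120 enumerable 1st–5th-degree relatives; real registers, with incomplete
ascertainment, report several-fold fewer, so the pedigree is an
information-rich stand-in rather than a demographic replica.

**Genetics.** Each person carries an 11-dimensional additive-genetic vector
(ten disorder liabilities + EA) drawn, for founders, from a multivariate
normal with variances equal to the trait heritabilities and the only
off-diagonal structure being the disorder–EA genetic correlations
(defaults from −0.29 for DUD to +0.01 for BN; the matrix is
checked for positive semi-definiteness). Offspring receive the midparent mean
plus Mendelian-segregation noise with half the additive covariance. Disorder
liability is genetic value + independent environmental noise scaled so the
total variance is 1, plus an optional liability-scale moderation term
`γ · ĝ_d · ĝ_EA` (standardized genetic values). Defaults: γ = −0.10 for DUD,
AUD, ADHD; −0.05 for MD, AD; +0.03 for AN, BN; 0 otherwise — chosen once to
emulate the qualitative pattern reported for these disorder groups (robust negative moderation for
externalizing/internalizing disorders, weakly positive for eating disorders).
Liability-threshold curvature produces same-signed hazard-scale interaction
even at γ = 0; the planted term sharpens it.

**Affection and onset.** A person is affected when liability exceeds the
sex-specific threshold `Φ⁻¹(1−K_s)`, where female/male prevalences `K_s` are
derived from the overall lifetime prevalence and a female:male ratio. Ages at
first registration are truncated-exponential waiting times from age 17
(mean 120 months) conditioned to land before the person's censoring month, so
essentially every affected person with follow-up registers once. No onset-age model
is available for this construction; the waiting-time mean is a
configurable stand-in.

**Censoring.** Death and emigration are exponential with per-year hazards
0.0005 and 0.002; administrative end is December 2018. Heritabilities
(0.30–0.75) and sex ratios per disorder are standard literature-range values;
none of prevalence thresholds, correlations or censoring were tuned after
seeing test outcomes.

**Mediators and EA phenotype.** The EA phenotype is genetic EA plus noise
(h² = 0.40), z-standardized within birth year. Cohort males additionally get
IQ and resilience as linear loadings (0.50, 0.35) on the standardized EA
genetic factor plus unique noise, z-standardized within birth year — the
conscript-register design in which mediators exist for men only.

**Cohabitation.** Recorded co-residence years exist for 1st-degree pairs
(parent–child and full siblings), N(15, 3²) truncated at 0; unrecorded pairs
count as 0 years. The table exists to exercise the adjustment, not to model
household structure.

**What passing tests do not show.** The generator has no assortative mating,
immigration, diagnostic drift, ascertainment bias or comorbidity structure;
recovery of planted parameters here demonstrates estimator correctness, not
that real registry coefficients would be reproduced.

## Kinship and relative enumeration

Kinship uses the classical recursion φ(i,i) = ½(1+φ(f,m)),
φ(i,j) = ½[φ(f_i,j)+φ(m_i,j)], memoized, valid for arbitrary (including
inbred) pedigrees. At registry scale a vectorised path-counting variant sums
`2^−(d_i+d_j+1)` over common ancestors where the two descent paths diverge
immediately below the ancestor; it requires an outbred pedigree and verifies
that assumption, falling back to the recursion otherwise. Relatives are kept
when relatedness 2φ ≥ 2^−5.5 and binned to degrees 1–5 by
`round(−log₂ 2φ)` — the nearest bin on the log scale, our convention for
double relationships.

## Scores

A relative's contribution is the truncated-normal tail mean `φ(τ)/K`
(affected) or `−φ(τ)/(1−K)` (unaffected); for GAEA it is the relative's
continuous EA z-score. K is either supplied or estimated per relative
birth-year stratum from the bundle (strata with <10 cases pool to the overall
rate). Contributions are residualized on cohabitation years within degree
class (classes with <10 relatives or zero variance pass through; the class
mean is preserved), weighted by 2φ, shrunk by `Σw/(Σw+λ)` with λ = 1 by
default, and z-standardized within birth-year × county strata (singleton or
degenerate strata score 0, with a warning). The proband's own phenotype never
enters. Relatives missing from the persons table, or with missing EA,
contribute nothing — missingness is not treated as health. The exact weighting
and shrinkage constants of production FGRS implementations are not public; ours follow the same family of estimators and are
fully configurable.

## Tetrachoric correlation

Thresholds are fixed at normal quantiles of the 2×2 margins; ρ maximizes the
bivariate-normal cell likelihood over (−0.9999, 0.9999) by bounded scalar
minimization (xatol 1e−8), with the SE from a finite-difference observed
information. Because there is no canonical dichotomization rule for correlating two
continuous scores, the pipeline reports both the product-moment correlation
of the continuous scores and the tetrachoric after median splits, labelled
separately. Zero margins raise an error suggesting the optional +0.5
continuity correction.

## Additive hazards

Time is months since the 17th birthday. All subjects enter at 0, so the risk
set at event time t is {exit ≥ t} and the Gram matrix accumulates by scanning
exits in decreasing order (O(np² + mp³)). Tied events are solved jointly in
one least-squares increment. Rank-deficient risk sets (condition number
> 1e10) are solved by minimum-norm least squares (pseudoinverse), which keeps
the identifiable part of the increment — necessary for the exact reduction to
group-specific Nelson–Aalen paths once a binary covariate's group is
exhausted. Effect summaries are `100·B_j` at the last event time ≤ 408 months
(34 years, the reference mean follow-up of the cohort design), i.e. the cumulative coefficient,
not a time-averaged slope; confidence intervals are subject-level bootstrap
percentiles (default 200 replicates, seeded). Predicted 34-year rates over
the FGRS grid (−3…3 by 0.25) at GAEA ∈ {−2,−1,0,1,2} are `xᵀB(T*)` with sex
at 0.5 and centred birth year at 0, clamped to [0, 1] (clamping logged) since
a linear hazard model can stray off the probability scale.

## Mediation

Analysis sample: males with conscript mediators, excluding anyone registered
for the disorder before age 19 (mediators are measured at ~18); outcome is
any later first registration. Mediator equations are least squares; the
outcome is a probit, with coefficients standardized by the model-implied
latent-response SD `√(var(η)+1)`. The decomposition is product-of-
coefficients, so total = direct + via-IQ + via-resilience holds to machine
precision, and the two mediator shares sum to exactly 100% of the indirect
effect. Registry analyses of this design have used weighted-least-squares SEM
estimators; our probit path estimator is a documented approximation expected
to agree with those in sign and rough magnitude, not digit for digit. The IQ-vs-resilience contrast
is a seeded percentile bootstrap (default 1000 replicates) of
Δ = a₁b₁ − a₂b₂ with a two-sided sign-proportion p-value, in the absence of a
canonical analytic test.

## Pipeline and problem sizes

`run_pipeline` funnels all randomness through named substreams of one master
seed; identical configurations give byte-identical CSVs, which the manifest
certifies with SHA-256 hashes. Stages log dropped-subject counts. The default
desk-scale cohort is 100,000 probands (~310,000 persons), which runs in
roughly three minutes and under 4 GiB; the test suite exercises the full
end-to-end path at that size and the acceptance script at 50,000, with
hazard/mediation bootstrap replicates of 20–200 at desk scale (all
configurable upward). Sex-stratified and 1973–1983/1984–1995 cohort-split
reruns are configuration flags.

## Known limitations

- FGRS weighting constants, the cohabitation-correction functional form, and
  the SEM estimator are reconstructions within the established method family,
  not replicas of non-public internals.
- The generator's onset and censoring models are stand-ins; absolute hazard
  levels in synthetic output are not calibrated to registry values.
- Tetrachoric values on median-split scores need not match reported registry values
  whose dichotomization is unknown.
- X-linked inheritance, polychoric (>2 level) correlation, time-varying
  covariates and formal supremum tests of the cumulative paths are out of
  scope.
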