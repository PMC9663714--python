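# Methods

This note records the models, defaults, and design choices behind
`glycorank`, and what the simulation-based tests do and do not establish.

## Data model and snapshotting

The pipeline consumes four flat tables — labs, prescriptions, diagnoses,
demographics — keyed by patient. Dates are integer day offsets from an
arbitrary epoch; no calendar arithmetic is used anywhere. Diagnoses are
abstract comorbidity-category codes (one per Charlson category plus the
exclusion conditions), not ICD codes: the analysis consumes only category
flags, so code-level mapping is deliberately out of scope.

A *snapshot* is a pair of consecutive HbA1c labs for one patient. It is
retained when (i) the observation period is 90–365 days inclusive on both
ends (the source rule names the window without endpoint language;
inclusive is the least surprising reading), (ii) the index value is
≥ 9.0%, and (iii) a non-empty regimen covers the terminal lab. Duplicate
same-day HbA1c values keep the last recorded, with a warning. Patients
are excluded entirely for type-1 diabetes, gestational diabetes,
ketoacidosis, cystic fibrosis, solid-organ transplant flags, or age < 18
at any HbA1c lab.

Treatment attribution: a drug class covers day *t* when
`fill_day ≤ t < fill_day + days_supply + 30`; the 30-day grace absorbs
imperfect adherence. The snapshot's regimen is attributed at the
*terminal* lab (a mid-snapshot switch is attributed to the new regimen);
the prior regimen and insulin status are attributed at the index lab.
Regimens are canonicalized as the sorted `+`-join of class names, so set
equality and string equality coincide.

Cohorts A–J partition (insulin status at index) × (age < 65 / ≥ 65) ×
(unweighted Charlson count: ≤ 2, 3–4, ≥ 5 under 65; < 5, ≥ 5 at 65+).
Age is `(index_day − birth_day)/365.25`. "Most recent" EGFR/creatinine
means the latest value dated ≤ index day with unbounded lookback (no
recency window is specified by the underlying design; a window is easy to
add but would discard data at desk scale).

Confounders: per-category comorbidity flags, most recent EGFR and
creatinine, age, sex, area-level income and race fractions, and the index
HbA1c. Missing numerics are imputed to the *within-cohort training-set*
mean, with a companion missingness indicator per imputed field; age, sex
and index HbA1c must never be missing. The train/test split (default
80/20) is snapshot-level to match the published design; a patient-level
option exists because snapshot-level splitting lets a patient span both
sets, which mildly flatters generalization estimates.

## The synthetic generator

`simulate_population` emulates the statistical structure the analysis
assumes, not claims data realism:

- Index HbA1c ~ N(10.3, 1.0) truncated to (7.5, 16); later index values
  are the previous terminal values, so trajectories drift downward under
  effective treatment and some later snapshots fall below the 9% gate —
  exercising the filters.
- Assignment is multinomial logistic over standardized covariates (age,
  sex, comorbidity count, EGFR, creatinine, log income, index HbA1c).
  The coefficient matrix is `confounding_strength × (0.8·intensity_r·s +
  0.4·noise_r)`, where `s` is a fixed clinical-severity axis (older, more
  comorbid, worse kidney function, poorer, higher HbA1c) and
  `intensity_r` is the standardized class count of regimen *r*: sicker
  patients preferentially receive more intensive combinations. The
  outcome model uses `beta = outcome_covariate_scale × s` — the same axis
  — so confounding is systematic rather than a lottery over random
  coefficient draws. The noise term gives each regimen idiosyncratic
  appeal so propensities vary within intensity tiers.
- ΔHbA1c = true regimen effect + covariate term + N(0, `outcome_noise_sd`).
  Default effects span −0.9 to −1.9 points for the ten-regimen default
  catalog (monotherapies through a five-class combination), in the range
  reported for add-on therapy in poorly controlled disease; default noise
  SD is 1.0 point, comparable to short-term within-patient HbA1c
  variability.
- Prescriptions are written so that attribution at the terminal lab
  recovers the assigned regimen exactly, the previous interval's regimen
  covers the index lab (defining insulin status), and supplies expire
  before the following terminal lab. A lead-in prescription (default
  probability 0.7) covers the first index lab.
- Missingness (default: 10% EGFR/creatinine, 5% income/race) removes the
  value from the emitted tables; the generator still uses the true value
  internally, so downstream mean-imputation faces genuine
  measured-with-gaps covariates.
- Everything derives from one `numpy` Generator seeded by `config.seed`;
  two runs are byte-identical.

The ground-truth sidecar stores per-snapshot assigned regimen, true
effect, and the full assignment-probability vector, plus the model
coefficients. Binary-study true propensities are obtained by conditioning:
`e = p_case / (p_case + p_comp)`.

What passing tests on this generator do **not** show about real data:
assignment here follows the same functional family the propensity model
can represent (no gross misspecification), covariates are measured
without error, there is no unobserved confounding, and effects are
additive without interactions or effect modification. Results establish
internal correctness of the machinery, not robustness to those failures.

## BCAUS propensity model

One hidden layer (default width 64, ReLU) with sigmoid output, trained
full-batch with Adam (lr 0.01, default 300 epochs) on
`L = L_BCE + ν·μ·L_BIAS`:

- `L_BIAS` is the mean over covariates of the squared IPTW-weighted
  standardized mean difference — differentiable, dimensionless, and zero
  exactly at balance. The weighted SMD uses Hájek-weighted means over the
  pooled *unweighted* per-arm SD, the convention under which the 0.1
  balance threshold is normally quoted; zero-variance covariates score 0.
- `μ` is the detached ratio `L_BCE/L_BIAS`, recomputed each epoch, so the
  two terms contribute at comparable magnitude and `ν` (default 1) is the
  single user-facing trade-off.
- Gradients are analytic, including the balance term's path through the
  weights `1/e` and `1/(1−e)`; the propensity clip (default
  [0.01, 0.99]) contributes zero gradient outside the clip interval.
- The returned model is the epoch checkpoint maximizing the number of
  balanced covariates (|weighted SMD| < threshold, default 0.1), ties
  broken by lower cross-entropy. The initial epoch is a candidate, so
  selection can never end worse-balanced than no training.
- Covariates are standardized internally; constant columns pass through.
  Arms with fewer than 2 snapshots are rejected; arms under 36 are
  flagged (`small_arm_`) but fit, since the node-size rule is enforced at
  the network stage.

On simulated confounded studies the model recovers true propensities with
Pearson r ≈ 0.95 and calibration slope within [0.8, 1.2], and drives
maximum weighted SMDs from ≈ 0.9 to ≈ 0.015.

## Effects and bootstrap

The ATE is the Hájek (normalized-weight) IPTW difference of weighted arm
means of ΔHbA1c; negative favors the case regimen. Hájek over
Horvitz–Thompson because it is bounded and standard for weighted means.
Uncertainty comes from a stratified (within-arm) bootstrap, default
B = 200, percentile 95% CIs, SE = SD of replicates.

Two bootstrap modes exist. The default reuses the fitted propensities and
only recomputes weights on the resampled rows — cheap, but it omits the
variance *reduction* from propensity re-estimation and measures about
30–40% conservative (over-covering) in our calibration experiments. The
`refit_per_replicate` mode refits the propensity model in every replicate
and is calibrated (93–95% empirical coverage at nominal 95%); it is used
wherever coverage itself is the claim and is recommended when runtime
allows. No correction is attempted for residual correlation between
studies sharing a cohort; the network-synthesized variances are therefore
optimistic, a known limitation of this design.

Within a cohort, every unordered pair of eligible regimens defines one
study restricted to snapshots on exactly one of the two; the
lexicographically smaller regimen is the case arm, making edge signs
deterministic, and swapping arms negates the ATE exactly.

## Network meta-analysis and SUCRA

Nodes are regimens with cohort count strictly greater than 35; edges are
studies with *all* covariates balanced. Disconnected components (after
trimming) are excluded, keeping the component containing the baseline.
The baseline is metformin monotherapy; when absent from the retained
nodes the largest-arm regimen substitutes and the substitution is
recorded.

Model: `ate_e ~ N(θ_e, se_e²)`, `θ_e ~ N(d_case − d_comp, τ²)`, with the
per-edge latent marginalized analytically to
`ate_e ~ N(d_case − d_comp, se_e² + τ²)` — the same posterior over
`(d, τ)`, better conditioned for sampling. Priors: `d_k ~ N(0, 10²)` %
HbA1c, `τ ~ HalfNormal(5)` — effectively flat for effects of order 1.
`τ` is sampled as `log τ` (Jacobian-corrected), which removes the zero
boundary and mixes well even on sparse networks where `τ` is weakly
identified. `tau_prior_scale = 0` fixes τ = 0 (the common-effect model),
which also makes single-edge networks exactly conjugate — used as a
closed-form oracle in the tests. Sampling uses an affine-invariant
ensemble (24 walkers, 3000 warmup + 3000 kept steps by default,
stretch/differential-evolution move mixture), with split-chain R-hat per
parameter across walkers; the posterior is flagged unconverged above 1.05
and the ranking stage refuses flagged posteriors unless forced.

SUCRA: per posterior draw, each non-baseline treatment gets a predictive
ATE `d_k + N(0, τ²)` (the baseline's ATE is identically 0); treatments
are ranked ascending (most negative = rank 1), ties receive average
ranks, and `SUCRA = (T − mean rank)/(T − 1)`. Including the
heterogeneity draw treats the ranking question as "in a new study, which
treatment would win" — the standard predictive reading; a
posterior-only mode (`include_tau=False`) ranks by the basic parameters
alone. Mean ranks sum to T(T+1)/2, so SUCRAs sum to T/2 identically.

## Validation

Concordance: a snapshot is concordant when its regimen equals one of the
top-3 ranked regimens for its cohort (regimens absent from the ranking —
too few arms — are non-concordant). Group means of ΔHbA1c are compared
with a Welch t-test (the unequal-variance form, since group sizes and
spreads differ); at p < 0.05 a confounder-adjusted BCAUS study with
concordance as the binary treatment estimates the adjusted effect with a
bootstrap CI. No multiplicity correction is applied across cohorts, by
design parity with the published analysis; a correction flag exists.
Rankings are always fit on training snapshots; test snapshots are scored
against the train-derived ranking.

The tier sensitivity analysis contrasts ranks 1–3 and 4–10 against 11+;
with fewer than 11 ranked treatments the affected comparisons are skipped
with a recorded reason. Rank-trajectory descriptives assign unranked
regimens position `len(ranking) + 1` so switch statistics remain total.

## Problem sizes and numerical choices

The test and acceptance workloads run simulated populations of roughly
250–4,000 patients (≈ 330–5,300 snapshots), 20-seed recovery sweeps,
200-replication bootstrap-coverage experiments at B = 60, and a
100-seed null calibration — sizes chosen so the complete suite runs on a
single CPU in minutes while leaving Monte-Carlo error comfortably inside
the asserted bands. The type-I-rate check uses a data-independent
(seeded, shuffled) ranking: under "no rank–outcome relationship" this is
the exact null for the concordance t-test and avoids re-fitting the whole
ranking stack per seed; the planted-signal check, by contrast, runs the
genuine end-to-end pipeline.

Ties in per-draw SUCRA ranking are measure-zero and handled by average
ranks. Propensities are clipped before weighting everywhere
([0.01, 0.99] default). All stage seeds derive from one global seed via
`SeedSequence.spawn`, so stages are independently rerunnable and whole
runs reproduce byte-for-byte.

## Known limitations

- Multi-arm propensity is decomposed into pairwise binary studies; no
  single multinomial model, no doubly-robust estimators, no matching.
- Cross-study correlation from shared cohort members is unmodelled;
  network variances are underestimated.
- The generator has no unobserved confounding, covariate measurement
  error, informative missingness, or treatment-effect heterogeneity;
  conclusions about those regimes require extending it.
- The NMA assumes evidence consistency; no node-splitting or
  inconsistency diagnostics are implemented.
- Effectiveness is ΔHbA1c only — no cardiovascular, renal, or safety
  endpoints.
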