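# Methods

`senclock` implements a three-axis CpG selection pipeline and the three
"senescence-enriched" epigenetic clocks trained on its output, together
with a synthetic methylome generator that provides planted ground truth
for every stage. This note records the models, the defaults, and the
design choices that were genuinely open.

## The selection pipeline

DNA methylation is summarized per CpG as a beta value in [0, 1]. The
pipeline asks which CpGs move **in the same direction** with three
phenotype axes — in-vitro cellular senescence, chronological age, and
mortality risk — and keeps only the triple-concordant set.

1. **Senescence associations.** Within each (dataset, cell line) stratum,
   each CpG's beta values are centered and divided by their sample SD, and
   a logistic regression of senescent status (1 = senescent with the
   inducer under analysis, 0 = control; other senescence types excluded)
   on the scaled beta gives a coefficient, Wald SE and p-value. The
   coefficient's sign is the direction of methylation change in
   senescence. The scaled mean difference (senescent minus control, SD
   units) is kept alongside as the display effect size. CpGs with
   (quasi-)complete separation are refit with a Firth/Jeffreys penalty and
   flagged; they still receive a finite effect and direction.
2. **Meta-analysis.** Where an inducer has several strata, per-stratum
   coefficients are pooled by fixed-effects inverse-variance weighting
   (w = 1/SE²; pooled SE = 1/√Σw), with a two-sided normal p-value.
3. **Direction calls.** p-values are Bonferroni-adjusted with m = the CpG
   universe size. A CpG is called hyper(hypo)methylated for an inducer
   when its pooled effect is positive (negative) and adjusted p < 0.05.
   We read the significance threshold as applying to the *adjusted* p;
   `SelectionParams(use_raw_p=True)` switches to the raw p.
4. **Inducer concordance.** A CpG enters the pan-senescence set for
   direction d when it is significantly d in at least 2 of the 3 inducers
   (replicative, DNA damage, oncogene) and its raw effect sign is also d
   in the remaining inducer. `min_significant=1` relaxes the rule to
   ≥ 1-of-3 for small CpG universes (e.g. cross-species arrays).
5. **Immortalization filter.** In an immortalized passaging series, the
   biweight midcorrelation (median/MAD-based weights (1−u²)² for |u| < 1,
   u = deviation/(9·MAD)) of each CpG with passage number is computed;
   CpGs with |r| strictly > 0.3 and BH-adjusted p < 0.05 are removed from
   the pan-senescence set — they track replication, not senescence.
   Zero-MAD CpGs are flagged, never removed.
6. **Age and mortality concordance.** For pan-senescence CpGs, the
   standardized age slope (regression of z-scored beta on z-scored age,
   i.e. the Pearson r) is computed in an aging cohort, and — for the CpGs
   whose slope sign matches their senescence direction — the age-adjusted
   Cox log hazard ratio per 1 SD of beta in a mortality cohort. The final
   set keeps CpGs with sign-concordance on all three axes (hyper ⇒ slope
   > 0 and log HR > 0; hypo ⇒ both negative). These two stages use the
   raw sign, not significance: the counts of same-direction plus
   opposite-direction CpGs partition the pan-senescence set, with flagged
   CpGs (constant, non-converged) reported separately in the
   `SelectionLedger`.

Per-CpG model fitting is vectorized (batched Newton/IRLS across all CpGs,
closed-form 2×2 solves) because the default scale needs ~10⁵ logistic and
~10³ Cox fits per run; the implementations are cross-checked against
statsmodels GLM and lifelines in the test suite.

## The clocks

Three elastic-net models are trained on the final CpG set, mirroring the
three axes: **SenCultureAge** (binomial: senescent vs. control, on pooled
in-vitro data after batch harmonization), **SenChronoAge** (gaussian:
chronological age), and **SenMortalityAge** (Cox: time to death on the
70% training split of the mortality cohort, stratified by event status).

The penalty is the glmnet parametrization λ[α‖w‖₁ + (1−α)‖w‖₂²/2] on
internally standardized features, with α = 0.5 for all three clocks by
default. α is a published choice only for the senescence predictor; we
apply it uniformly and expose it per clock. λ is chosen by 10-fold
cross-validation at the CV-minimum loss (deviance / MSE / negative test
partial likelihood); `lambda_rule="1se"` selects the largest λ within one
SE of the minimum. Fold assignment is a pure function of (seed, n),
stratified by outcome class (binomial) or event status (Cox). Weights are
reported back on the raw beta scale; the stored model carries only
nonzero-weight CpGs plus their training-mean betas, which are used to
impute missing CpGs at scoring time. Scores are the linear predictor
(intercept + Σwᵢβᵢ); the binomial clock also reports the inverse-logit
probability, but all downstream comparisons use the linear predictor
(scale-free choice).

During the CV search the solvers run at loosened tolerance (10⁻⁴) and the
λ path stops at λ_max/100 for the binomial fit, since the near-unpenalized
tail is never selected; the final fit at the chosen λ is tight (10⁻⁷ to
10⁻¹²). The default path has 25 λ values in the orchestrated pipeline.

## Batch harmonization

Pooled in-vitro training data are adjusted with a parametric
empirical-Bayes location/scale model (the ComBat algorithm): per-CpG
standardization against a design containing batch indicators and
biological covariates (condition, so balanced group effects are
preserved), per-batch location/scale estimates shrunk toward common
priors (normal for location, inverse-gamma for scale, method-of-moments
hyperparameters, iterative posterior-mode solve to 10⁻⁴), removal, and
restoration of the pooled location/scale. Output betas are clipped to
[10⁻⁶, 1−10⁻⁶]. A single batch is returned unchanged. The implementation
is cross-checked against Bioconductor `sva::ComBat` on a small fixture
(max deviation < 10⁻³). Harmonization is applied to the pooled training
data only, never to test sets.

## Evaluation readouts

Group differences are two-sample t-tests (Welch by default; the pooled
variance variant is available), computed within (dataset, cell line,
inducer) strata and never across batches, with significance tiers *** for
p < 0.0001, ** for p < 0.001, * for p < 0.05. Age correlation is Pearson
r of score with age. Clock mortality is the age-adjusted Cox HR per 1 SD
of score (lifelines). Senolytic changes are post-minus-pre differences,
paired whenever pair ids are present, two-sample otherwise; a
"significant decrease" is a negative difference with p < 0.05. In
replicated null trials each clock's decrease rate is calibrated at the
nominal level individually; the union over clocks is not a controlled
quantity, so the no-reversal validation is stated per clock. CpG-level
effect concordance compares scaled mean differences under senescence with
scaled post-pre differences under senolytics. No multiplicity correction
is applied across clocks/datasets in these tables (a BH-adjusted view can
be derived from the exported p columns).

## The synthetic methylome

The generator emulates the study designs the pipeline consumes. All
effects are additive on the logit(beta) scale (M-value convention), the
inverse logit is applied last, so betas stay strictly inside (0, 1), and
population-mixture arithmetic stays tractable. One global seed drives
everything; each dataset uses sub-seed `seed + dataset index` so datasets
can be regenerated independently, and per-CpG baseline means (Beta(2,2),
clipped to [0.05, 0.95]) are shared across datasets of a run.

Every CpG belongs to exactly one class, deterministically assigned by
largest-remainder apportionment of the configured fractions (so class
frequencies match the fractions exactly, independent of the seed):

| class | fraction | behavior |
|---|---|---|
| concordant_all | 0.04 | senescence shift in all inducers; matching age slope and marginal log HR |
| pan_senescence_hyper / hypo | 0.005 each | senescence shift in all inducers, no in-vivo coupling |
| inducer_specific | 0.03 | shift in exactly one inducer (rotating) |
| replication_tracking | 0.05 | shift in replicative+oncogene senescence and linear passage drift in immortalized cells |
| age_only | 0.05 | age slope only |
| mortality_only | 0.03 | mortality association only |
| discordant | 0.03 | senescence shift with *opposite* age slope and log HR |
| null | 0.76 | noise |

Defaults: 20,000 CpGs; logit effect 1.0; residual SD 0.5 logit; cell-line
offsets N(0, 0.1) per (cell line, CpG); per-batch shifts N(0, 0.4) per
CpG (first batch is the reference); training layout of one large
fibroblast experiment (113 control / 24 per inducer) plus a three-cell-
line experiment (4/4/8 per line, two inducers); an immortalized series of
20 passages × 3 replicates with drift 0.08 logit/passage (giving |bicor|
≈ 0.6–0.7 with passage, matching how strongly mitotic-clock CpGs track
passaging); an aging cohort of n = 656 with uniform ages 19–101 and
standardized slope ±0.3; a mortality cohort of n = 2000, ages 40–90, 30%
independent censoring (exponential censoring times with the rate solved
so the expected censored fraction matches), age log HR 0.5 per SD; paired
senolytic trials of 6 pairs with shared per-pair offsets (SD 0.3 logit).

Mortality-axis CpGs share a latent per-subject "senescence burden" factor
(correlation ρ = 0.4 with each CpG's logit-beta). The Cox linear
predictor is the literal sum of per-CpG coefficients times z-scored
betas, plus the age term, but the coefficients are scaled by
1/(1+ρ²(m−1)) so that the **implied marginal standardized log HR of each
mortality CpG equals the configured ±0.3** — the marginal per-CpG hazard
ratio is what the selection pipeline estimates, and with hundreds of
mutually correlated CpGs the unscaled sum would make that estimand
meaningless. With a single mortality CpG the construction reduces to a
direct planted effect, which is what the coverage tests exercise. The
nonlinearity of the hazard attenuates realized marginals slightly below
the nominal value; sign, which is all the intersection uses, is
unaffected.

Senolytic trials support three clearance models: `none` (post = pre state
+ fresh noise — the no-reversal null), `subtract_effect` (the planted
pan-senescence effect is deleted at post-treatment for a configurable
fraction of eligible CpGs), and `remix_population` (betas are a
senescent/control mixture whose senescent weight drops, linear on the
beta scale, so a 0.5 → 0.1 weight change shrinks effects fivefold).
`reversal_fraction` drives `subtract_effect` only; the remix weights are
explicit arguments.

**What the generator does not emulate:** Infinium probe chemistry (Type
I/II bias), detection p-values, cell-composition heterogeneity in blood,
non-uniform age distributions, correlated noise beyond the single burden
factor, and SASP expression. Passing tests therefore demonstrate that the
pipeline recovers the structure it targets under a clean additive
logit-normal model, not that it would achieve the same operating point on
array data.

## Problem sizes and numerical choices

The recovery experiments run the full default scale (20,000 CpGs)
averaged over 20 seeds; clock validation uses one full run with held-out
test layouts (small independent series for senescence, half-size aging
cohort, the 30% survival split); the senolytic null uses 100 replicate
trials. The batch-fidelity experiment uses a balanced two-batch design of
4,000 CpGs so the planted shift is identifiable per CpG. Degenerate
inputs are flagged, not dropped silently: constant CpGs are excluded
per-axis, zero-MAD CpGs cannot be removed by the immortalization filter,
effects of exactly 0 have direction "none" and can never satisfy a
concordance rule, and non-converged Cox fits are excluded from the
mortality axis with their count recorded in the ledger.

## Known limitations

- The pan-senescence classes without in-vivo coupling pass the sign-only
  age/mortality gates with probability ≈ ¼ by chance; the empirical FDR
  of the final set against planted truth is therefore bounded away from
  zero by design, exactly as a sign-based intersection is in real data.
- The per-CpG logistic "effect" and the scaled mean difference are
  different estimands; both are stored, and each readout uses the one the
  corresponding display calls for.
- Real preprocessed beta matrices can be analyzed by writing them to the
  TSV exchange formats; IDAT-level preprocessing, probe annotation, and
  enrichment analysis are out of scope.
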