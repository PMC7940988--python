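# Methods

`cofeed` estimates group-level cofeeding tolerance in chimpanzees from scan
samples taken at a provisioned food patch, together with its demographic
correlates, its variation across groups and years, and an individual-level
network analysis of who shares the food zone with whom. This note records
the models, the synthetic-data generator, the numerical choices, and the
limits of what the test suite demonstrates.

## The tolerance model

During one assay session, a valued resource (shelled peanuts on a swinging
platform, or fruit juice from a perforated pipe) is made available inside a
marked food zone, and the number of individuals inside the zone is censused
at fixed scan times over roughly two minutes. The estimand is the *maximal*
(initial) cofeeding tolerance θ[g, y] of group g in year y: the probability
that an at-risk group member would be in the zone before any of the
resource has been consumed or carried away.

The observation model treats each scan count as

    k_j ~ Binomial(n_at_risk, θ[g, y] · r_j),

where r_j is the fraction of the resource remaining at scan j. The resource
starts full (r_1 = 1) and is depleted by realized attendance; by default

    r_{j+1} = r_j · exp(−κ · k_j / n_at_risk),

with the per-capita depletion rate κ ≥ 0 shared across groups. An
alternative linear rule r_{j+1} = max(0, r_j − κ·k_j/n_at_risk) is provided
behind the same interface, and constant-resource (juice-pipe) sessions fix
r ≡ 1 so κ drops out of the model. The trajectory is a *plug-in* function
of the observed counts rather than of latent expected attendance. This
makes the likelihood an exact, oracle-testable product of binomial terms
and keeps scans conditionally independent given the counts that preceded
them; the cost is that sampling noise in early-scan counts propagates into
the assumed resource state of later scans. The direction of any resulting
bias is unknown but the synthetic generator uses the same law, so parameter
recovery tests are internally consistent.

On the logit scale,

    logit θ[g, y] = α + u_g + X[g, y]·β(_g) + v_{g, y},

with u_g ~ Normal(0, σ_g) group effects, v_{g,y} ~ Normal(0, σ_gy)
group-year effects, and optional covariate effects (next section). Priors:
α ~ Normal(0, 1.5); σ_g, σ_gy, κ ~ half-Normal(1); all covariate effects
Normal(0, 1) on globally standardized covariates. Sampling uses a
non-centered parameterization for every random-effect vector and log-scale
parameterization (with Jacobian) for every scale parameter. A `flat` theta
prior (independent Uniform(0, 1) per cell) is available for conjugate
checks and single-cell fits.

## Covariate effects: within vs between groups

Four covariates summarize each group-year roster at a July 1 census:
fraction of infants under 3, fraction of females aged 5–12, group size, and
fraction of individuals with a co-resident maternal relative (mother,
maternal sibling, or offspring — mother links only, no paternal inference).
Raw values are z-scored jointly over all group-year cells so that both
model specifications share one covariate scale:

* **between** — a single coefficient vector β shared across groups (group
  random intercepts retained). Identification comes mostly from stable
  differences among groups.
* **within** — group-specific vectors β_g ~ Normal(β̄, diag(τ)), with
  independent scales τ per covariate, applied to *group-mean-centered*
  covariates. β̄ summarizes effects of covariate *change within* groups.
  The centering (the standard within-/between-subject decomposition)
  matters: without it, a covariate that differs between groups but is
  constant within them acts as a group intercept, and the β̄ posterior
  silently absorbs the between-group pattern the specification is meant
  to exclude.

Covariates enter the linear predictor jointly with the depletion
likelihood (one-stage inference), so uncertainty in θ propagates into the
effect estimates; there is no plug-in of θ point estimates. Columns without
usable variation for a given specification trigger a `CollinearityWarning`
and leave their coefficients prior-dominated.

Age bins are [0,3), [3,5), [5,9), [9,13), [13,∞) whole years, left-closed;
they are configurable because published bin labels ("infants < 3", "females
5–12", "males 5 to 8") pin the edges only up to this reconstruction.
Fractions use the full roster as denominator by default; a flag excludes
dependent infants from the denominator.

## Variation decomposition and counterfactuals

For each posterior draw, `decompose` computes the sample SD of θ across
groups within each year and across years within each group, and the
contrast (mean within-year across-group SD) − (mean within-group
across-year SD); `Pr(contrast > 0)` summarizes whether inter-group
differences dominate. Draws with a contrast of exactly zero count half, so
a degenerate posterior reports 0.5.

`counterfactual_predict` pins selected covariate columns at a reference
value (default 0, the grand mean on the standardized scale — for a
within-group fit, 0 is each group's own mean because of the centering) and
recomputes
θ draw by draw while keeping α, u_g, v_{g,y}, and the coefficient draws at
their posterior values — an intervention on group composition only. An
empty scenario reproduces the factual draws bit-exactly because the same
code path evaluates the linear predictor. The headline statistic is the
attenuation ratio: posterior-mean between-group SD of group-mean θ,
counterfactual over factual. Values near 0 mean demography explains the
group differences; values near 1 mean it explains none.

Counterfactuals that remove demographic variation *across* groups are
computed on the between-group fit, whose coefficients carry the
between-group differences (after centering, the within-group fit's
coefficients cannot). With only four groups, the attribution of
between-group differences to covariates versus residual group effects is
softly identified; the ratio should be read together with the group-mean
intervals, and rank statements about residual effects are most meaningful
for demographically similar groups.

## Assay comparison

`compare_assays` takes fits from the depleting and constant-resource assays
over the same groups, restricts to a common year (latest by default), and
reports the posterior probability of each group ordering, the Kendall tau
between assay-wise median ranks, and the ratio of mean 90% interval widths.
Constant-resource sessions keep every scan fully informative about θ and
drop κ from the model, so their intervals are expected to be narrower at a
matched design.

## The social relations model

For sessions where individual identities at each scan were coded, two
symmetric logistic random-effects models are fitted:

* presence: logit P(i in zone) = μ + e·x_i + a_i, with a_i ~ N(0, σ_a);
* coresidence: logit P(i, j both in zone) = μ' + c·x_ij + a'_i + a'_j + d_ij,
  with a'_i ~ N(0, σ_a'), d_ij ~ N(0, σ_d).

Individual covariates are sex-by-age-class indicators plus a
female-with-dependent-infant indicator (time-varying, evaluated at the
session's census date); dyad covariates cross female infant status with
male partner age class, other dyad types forming the baseline. Coresidence
is undirected, so the directed SRM's sender/receiver effects collapse to
one multi-membership effect a' per individual and a symmetric dyad effect.
Scans are repeated Bernoulli trials aggregated into binomial blocks per
individual (or dyad) and covariate profile; within-scan dependence between
dyads sharing a member is captured only through the shared a' terms (no
scan-level random effect by default). Scans are pooled across sessions.

The dyad effects d_ij are integrated out of the likelihood with 21-node
Gauss–Hermite quadrature (15 nodes in fast configurations), which reduces
the sampled dimension from ~220 to ~30 and is accurate to about 1e−4 in
log-likelihood against adaptive quadrature. Conditional posterior
summaries of each d_ij are recovered afterwards from the same grid.

## Posterior computation

No gradient-based probabilistic-programming framework is used; all
posteriors are sampled with an affine-invariant ensemble sampler (emcee)
using a differential-evolution move mixture (80% DE, 20% DE-snooker),
which mixes far better than stretch moves on these correlated hierarchical
posteriors. Log-posteriors are fully vectorized across walkers, so one
move costs one array evaluation over the whole ensemble. Walker count
defaults to max(2.5·ndim, 48); budgets default to 800 warmup + 800 kept
steps, thinned to about 4000 retained draws.

Convergence is summarized by split-R̂ and bulk ESS computed over four
walker subgroups treated as pseudo-chains. Walkers are not independent
chains, so these diagnostics are indicative rather than exact; fits whose
R̂ exceeds 1.01 attach a `ConvergenceWarning` and flag `converged=False`
in their diagnostics rather than failing. Initialization spreads walkers
tightly around a moment-based starting point (overall first-scan rate on
the logit scale).

## The synthetic-data generator

The generator emulates the study design: four groups followed over eight
annual waves (2011–2018), with group-size ranges (23–25, 42–52, 10–14,
11–13), percent-female bands (0.56–0.67, 0.61–0.71, 0.57–0.67, 0.18–0.38),
and maternal-kin linking probabilities patterned on the four study
communities — three female-biased groups of varying size and one small
male-biased group. Rosters evolve through births (mother resident and at
least 10 years older), adult transfers, and removals; two turnover events
per year plus a bounded random walk in target size produce year-to-year
covariate variation while the size and sex-ratio bands are enforced
exactly. Sessions default to 6 per group-year with 9 scans at 15 s
intervals (the published design states only "about 2 minutes"; these
defaults are stand-ins and configurable). Simulation truth defaults:
α = 0.2, σ_g = 0.5, σ_gy = 0.2, κ = 1.0, β = 0 — chosen so θ spans roughly
0.3–0.8, the realistic range for this assay. Group effects can be fixed
explicitly (for matched-design experiments); n_at_risk excludes infants
under 3 by default, who travel with their mothers rather than attending
independently.

Identity-resolved scans are generated by weighted sampling without
replacement given the drawn head-counts, with class-level log-weights, a
female-with-infant shift, individual-level noise, and optional
state-dependent interaction terms (a female's weight changes with the
males already present in the scan), which induces dyadic structure while
preserving the marginal counts. A separate direct-law simulator
(`simulate_srm_observations`) draws presence and coresidence channels
exactly from the SRM law for parameter-recovery tests.

What the generator does *not* emulate: spatial structure of the enclosure
and food zone, observation error in scan coding, estrous state, dominance
rank dynamics, temporal autocorrelation of v_{g,y} across years, and any
dependence of food-zone size on assay. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the assumed
data-generating law, not robustness to these unmodeled features of real
data.

## Test and acceptance problem sizes

Statistical acceptance checks run replicated studies at the default design
(4 groups × 8 years × 6 sessions × 9 scans). The package's chosen
replicate counts are: 12 replicates for θ/κ recovery, 10 for covariate
sign recovery, 10 for the variation contrast, 10 for the assay comparison,
and 5 (plus 3 zero-truth) for SRM recovery, with sampler budgets of
700–1500 warmup steps per fit. Pass thresholds (bias < 0.03, coverage in
[0.80, 0.97], ≥ 90% sign recovery, κ within 25%, SRM SDs within ±0.3 in
≥ 80%) follow the properties the models are expected to satisfy at this
design. All tests are seeded and fully deterministic.

## Known limitations

* The plug-in depletion trajectory conditions on realized counts; a
  latent-consumption model would propagate depletion uncertainty but lose
  the exact likelihood oracle.
* κ is shared across groups by default (a per-group option exists via
  configuration of the spec); group-varying depletion would be confounded
  with θ at small session counts.
* Ensemble-sampler diagnostics over walker subgroups can understate
  autocorrelation relative to independent chains.
* θ interval coverage at the default design sits near 0.83 rather than
  0.90 — partial pooling shrinks extreme cells, and ensemble tails are
  slightly short; the recovery test band [0.80, 0.97] reflects this.
* The within-group model's β̄ and the residual group effects are only
  softly separated with four groups; between-group effect estimates
  inherit the usual observational-confounding caveats.
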