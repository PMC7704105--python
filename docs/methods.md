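# Methods

This note documents the models, defaults and numerical choices behind
`dimorph`, and what the synthetic-data validation does and does not show
about real data.

## Effect sizes (`dimorph.effects`)

All three estimators compare males (numerator) to females on a log-ratio
scale, so positive values are male-biased, units cancel, and baseline
shifts shared by the sexes (drift over time, site offsets) drop out.

* **lnRR** = ln(x̄_m/x̄_f), variance s²_m/(n_m x̄²_m) + s²_f/(n_f x̄²_f).
* **lnVR** = ln(s_m/s_f) + 1/(2(n_m−1)) − 1/(2(n_f−1)); the correction
  removes the O(1/n) bias of ln s under normal sampling; variance
  1/(2(n_m−1)) + 1/(2(n_f−1)).
* **lnCVR** = ln(CV_m/CV_f) with the same correction; variance is the sum
  of the lnRR and lnVR terms. This *independent-terms* form assumes the
  sample mean and SD are uncorrelated on the log scale. The full form needs
  the within-population mean–SD correlation, which is not identifiable from
  summary statistics; the independent form is also what the standard
  meta-analytic calculators produce by default (the test suite verifies
  exact agreement with metafor's `escalc` for all three measures).

Identities used as checks: antisymmetry under sex swap (variances
invariant); lnCVR = lnVR − lnRR exactly for point estimates when n_m = n_f
(the corrections cancel); variances strictly decreasing in n.

`percent_difference(b)` returns 100(e^b − 1) for b ≥ 0 (percent by which
males exceed females) and 100(1 − e^b) for b < 0 (magnitude of the female
bias). The convention reproduces the way positive estimates are reported in
the literature exactly; for negative estimates published percentages are
typically computed from unrounded estimates, so only approximate agreement
can be expected there.

## Preprocessing (`dimorph.preprocess`)

Cleaning order, each rule idempotent and logged:

1. one measurement per animal × trait: closest to 100 days of age, ties to
   the earlier age, then stable input order (deterministic);
2. adults only, 100–500 days **inclusive** (the endpoint convention is a
   package choice; the age window itself is standard for "young adult"
   phenotyping), sexed animals with recorded values;
3. per-population per-sex n, mean, sample SD (ddof = 1);
4. eligibility: n ≥ 6 *per sex* (reconciling "at least six individuals"
   with per-group minima as reported in consortium analyses); traits must
   span ≥ 2 institutions; zero-variance ("fixed") traits dropped; traits
   with any non-positive population mean dropped (ratio effect sizes are
   undefined otherwise — the nonpositive-mean rule is this package's
   addition).

Population-level rules run before trait-level rules. The exclusion log has
one row per dropped population with a machine-readable reason
(`min_per_sex`, `single_institution`, `fixed_trait`, `nonpositive_mean`),
so kept + logged rows account for every input row.

## Trait-level meta-analysis (`dimorph.metamodel`)

Model per trait: y_i = μ + u_strain + u_location + u_unit + e_i with
Var(e_i) = v_i known, three non-negative variance components estimated by
REML. The restricted likelihood is maximised by L-BFGS-B on the components
with box constraints at zero (boundary solutions allowed), started from the
origin, from an evenly split DerSimonian–Laird moment estimate, and from
each component carrying that estimate alone, then polished with a
Nelder–Mead simplex (L-BFGS-B can stall within ~1e−5 of the optimum near
the boundary). On random instances the solution matches a dense-grid +
simplex brute-force oracle to ≤ 1e−6 in log-likelihood, and matches
metafor's `rma.mv` to ~1e−5 in μ̂, SE and components. Non-finite
likelihoods or optimiser failure set `converged = False`; the pipeline
excludes such traits and counts them in the manifest.

**Confidence intervals.** The default is a t interval with Satterthwaite
degrees of freedom: df = 2φ²/Var(φ̂), φ = (1'V⁻¹1)⁻¹, with Var(φ̂) from the
delta method and the inverse REML information of the *active* components
(components estimated at the zero boundary are treated as known zeros; with
no active component the interval is the z interval). Rationale: z-Wald
intervals ignore variance-component uncertainty. In this design each strain
or institution contributes only one or two effects, so components are
estimated with few effective replicates and z intervals undercover
materially (90.4% at nominal 95% in the validation suite below); the
Satterthwaite interval achieves 94.2% under the same conditions while
remaining essentially z when no heterogeneity is detected. `ci_dist="z"`
(the historical software default) and `ci_dist="t"` (t with k−1 df) are
available as switches.

**Heterogeneity.** Multilevel I² with the Higgins–Thompson typical sampling
variance s̄² = Σw(k−1)/((Σw)²−Σw²), w = 1/v: each component's share is
σ²_c/(σ²_strain+σ²_location+σ²_unit+s̄²), and the total is their sum, so
the decomposition is additive by construction. Printed I² values from other
software may use different typical-variance estimators; exact parity is not
asserted.

**Classical random-effects** (`fit_random_effects`, used for second-order
aggregation): single-τ² REML via bounded 1-D minimisation (with an explicit
check of the τ² = 0 endpoint, which a bounded minimiser cannot hit
exactly), or DerSimonian–Laird moments (`method="dl"`). Wald-z intervals;
τ² = 0 reduces to the fixed-effect inverse-variance mean.

### Validation conditions (recovery and calibration suites)

Simulated at the effect-size level — the level the model operates on — with
k = 16 populations per trait drawn from a 9-strain × 11-institution pool,
sampling variances scattered around 0.003 (the order of lnCVR variances at
n ≈ 400 per sex) and components (0.004, 0.004, 0.004), i.e. total I² ≈ 80%,
in the range reported for real trait panels. Under these conditions, 500
traits at μ = 0.1 give |bias(μ̂)| < 0.01 and ~94% CI coverage; 1000 traits
at μ = 0 (heterogeneity unchanged) give a 4–5% rejection rate. A remark on
the "everything zero" null (μ = 0 *and* all components 0): REML truncation
at the boundary makes every standard interval conservative there (~2–3%
rejection); that regime tests shrinkage at the boundary, not α-calibration,
which is why calibration is assessed with nuisance heterogeneity present.

## Correlated traits (`dimorph.rve`)

Phenotyping panels contain hierarchically overlapping measurements (cell
type A, B, A+B), so their trait-level results are not independent. Each
annotated sub-group (2–10 member traits) is collapsed into one result under
an assumed equicorrelation ρ of the members' sampling errors (default 0.8,
the conventional default of robust-variance meta-analysis).

`combine_correlated` treats the sub-group as a single correlated block:

* between-member τ² by moments: E[SS/(k−1)] = v̄(1−ρ) + τ², truncated at 0;
* point estimate: the approximate-weights mean (weights built from the
  block-average variance are equal, so this is the simple mean — the
  standard correlated-effects approximation);
* SE: member-level sandwich, ×k/(k−1) for blocks of ≤ 4, **floored at the
  working-model variance** [v̄(1+(k−1)ρ)+τ²]/k. The floor matters: when few
  members agree closely the empirical sandwich collapses towards zero, and
  a spuriously tiny SE would dominate every downstream inverse-variance
  weight. Averaging k ρ-correlated estimates cannot beat the model
  variance, so this is an information bound, not a tuning constant.

The combined row (its robust SE, not a refit) is what second-order stages
consume. `rve_fit` is the general multi-cluster correlated-effects fit
(Hedges–Tipton–Johnson approximate weights, between-cluster sandwich,
small-sample multiplier at ≤ 4 clusters); with ρ = 0 and singleton clusters
its moment τ² reduces exactly to DerSimonian–Laird, which is the reduction
the test suite checks against `fit_random_effects(method="dl")` at 1e−8.

## Second-order meta-analysis (`dimorph.secondorder`)

Condensed trait-level means are aggregated per functional group (nine
labels: behaviour, morphology, metabolism, physiology, immunology,
hematology, heart, hearing, eye) and for all groups combined, via the
classical random-effects model. Sign-bias tallies classify trait means by
strict sign; exact zeros are reported separately as unclassified, and no
test statistic is ever attached to counts (vote-counting). Direction-wise
magnitude estimates (purpose "C") first select traits whose 95% CI excludes
zero — no multiplicity correction, as none is standard in this design —
then aggregate each sign separately; sides with fewer than two traits are
reported as unaggregable rather than estimated. Counts default to the
condensed (post-RVE) table; callers can pass the uncondensed table instead.

## Power (`dimorph.power`)

Two-sided two-sample comparison of means under heteroscedasticity.
Allocation: `optimal` (Neyman, n_f/n_m = sd_f/sd_m, minimising the contrast
variance at fixed total N), `equal`, or a fixed ratio. The search starts at
the z closed form n_m = (z_{1−α/2}+z_{1−β})²(sd²_m + sd²_f/r)/δ², then
walks to the smallest integer pair whose *Welch noncentral-t* power meets
the target (Welch–Satterthwaite df), finally shrinking each side greedily
so that decrementing either n by one drops below target. Convention fixed
by the benchmark δ = σ, equal SDs, α = 0.05, power 0.8: the z form gives
16/group, the Welch convention implemented here gives 17/group. Formula
power agrees with Monte-Carlo simulation of the Welch test to < 0.01.
`variability_lookup` converts pipeline results into SD ratios (exp lnVR)
and CV ratios (exp lnCVR) for planning; CV ratios are used as SD ratios
under an equal-means assumption unless means are supplied.

## Synthetic data (`dimorph.synthdata`)

What it emulates: strictly positive continuous traits measured on 9 strains
× 11 institutions with partial crossing (default 20% of cells realised;
2–18 populations per trait); per-population per-sex adult counts truncated
normal (mean 400, SD 240, min 6); ages 65–550 days so the adult window has
work to do, with duplicate measurements (p = 0.2) exercising the
closest-to-age rule; missing values (2%); nine functional groups; clusters
of correlated traits (~40% of traits, sizes 2–5, log-scale correlation 0.8
via a shared per-animal latent factor on a shared animal roster).

Values are lognormal: value = exp(m_sex + u_strain + u_institution +
σ_sex·z). This guarantees positivity, and because the raw-scale CV depends
only on σ_log (CV = √(exp(σ²_log)−1)) while baseline log-means vary widely
across traits, it reproduces the strong cross-trait mean–SD coupling
(r > 0.9 on the log scale) seen in real panels. Sex effects are injected
exactly: σ_m solves σ²_m = ln(1 + e^{2·lnCVR}(e^{σ²_f}−1)) so the raw-scale
lnCVR equals the target, and the male log-mean offset lnRR − (σ²_m−σ²_f)/2
makes the raw-scale mean ratio e^{lnRR}; the implied lnVR is lnCVR + lnRR.
Verified by simulation: at n = 2000 per sex the mean effect sizes match the
configured truths to < 0.001.

Choices a user should know:

* the lognormal family is this package's choice; real phenotyping data are
  not told to be lognormal, only positive and mean–variance coupled;
* strain and institution effects are shared by both sexes, so they shift
  population baselines but cancel from ratio effect sizes: the generator
  makes no claim about strain-specific sex effects, and the metamodel
  recovery suites therefore simulate heterogeneity directly at the
  effect-size level;
* the guaranteed minimum of 6 adult animals per sex always has recorded
  sexes and values, so eligible populations never fall below the filter
  threshold by construction;
* seeding is hierarchical (one master seed, counter-based per-trait
  children), so datasets are byte-identical across runs and adding traits
  leaves existing ones untouched.

What passing on synthetic data does **not** show: robustness to
non-lognormal tails, to sex-specific site effects, to unit heterogeneity
across procedures, or to body-weight mediation of sex differences — none of
which the generator emulates.

## Pipeline (`dimorph.pipeline`, `dimorph.cli`)

simulate → preprocess → effects → trait-level REML → condensing →
second-order, each stage writing plain CSV, with a JSON manifest (seed,
config hash, per-stage row counts, exclusion reasons). Unknown config keys
are rejected; any stage error aborts with the stage name; re-running a
config reproduces byte-identical outputs. The CLI (`dimorph
simulate|run|power|report`) is a thin wrapper over these functions.

## Problem sizes

Test and acceptance runs use scaled-down designs chosen to exercise every
code path at desk scale: 8–18 traits with ~30–120 animals per population
and sex for end-to-end runs; 500 traits for recovery, 1000 for calibration;
50 instances for the REML oracle; 1e5 replicates for Monte-Carlo power.
These sizes are the package's validation design, documented here so they
can be scaled up verbatim.
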