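# Methods

## Problem and scope

The package selects, from d dichotomized clinicopathologic covariates, the
subset whose Cox proportional-hazards model best discriminates overall
survival as measured by the in-sample Harrell C-statistic, using binary
biogeography-based optimization (BBO); it benchmarks the selected model
against the fully adjusted model and stepwise selection at entry levels
0.05/0.1/0.2. The motivating registry (a single-center breast-cancer cohort,
n = 1896, 66 deaths, followed 2005–2017) is not public; only its per-covariate
two-way margins, risk codings and the selected model's hazard-ratio estimates
are. Those published summaries are packaged in `bbocox.reference` and serve
two purposes: deterministic arithmetic checks (cross-tabulation percentages,
chi-squared p-values recomputed from counts), and the default parameters of
the synthetic-cohort generator that stands in for the withheld data.

## Synthetic-cohort generator

One patient row is (time, event, x_1..x_d) with x_j ∈ {0,1}, 1 = high-risk
level.

- **Covariates.** Marginal Bernoulli(p_j) with p_j the published prevalence
  of the high-risk level (e.g. tumor > 2 cm: 735/1896 = 0.388). Optionally a
  latent-Gaussian copula with a user correlation matrix; a documented default
  block correlates the tumor-burden covariates (tumor size, node, LVI,
  perineural, dermal; latent ρ = 0.3), since the variables are known to be
  interrelated but no joint structure was published. The copula preserves the
  Bernoulli margins exactly in distribution.
- **Event times.** T = −ln(U) / (h₀ e^η), η = Σ β_j x_j: exponential
  (constant) baseline hazard. Cox estimation is baseline-agnostic, and the
  exponential gives a closed form for calibration. Planted β defaults are the
  ln hazard ratios of the published selected model (8 nonzero effects,
  0.21–0.86); the other 7 covariates carry β = 0.
- **Censoring.** C ~ Uniform(0, H], H = 144 months: rolling accrual over a
  12-year window with administrative cut-off, without patient-level dates.
  Observed time = min(T, C), event = 1{T ≤ C}.
- **Calibration.** Given a target event fraction π (default 66/1896 =
  0.0348), `calibrate_baseline` solves E[1{T ≤ C}] = π for h₀. For a rate r =
  h₀e^η the event probability against uniform censoring is
  1 − (1 − e^{−rH})/(rH); the expectation over η is computed exactly by
  enumerating the (at most 2^16) active-covariate combinations when
  covariates are independent, or from a fixed-seed latent Monte-Carlo sample
  under a copula, and the monotone 1-D root is bracketed by Brent's method on
  log₁₀ h₀. Targets are reachable for any π ∈ (0,1); the solver raises a
  calibration error with diagnostics if the bracket fails.
- **Ties.** Generated times are continuous (ties have probability zero); a
  `tie_rounding` option rounds times up to a grid to exercise the tie
  handling of the fitter.
- **Determinism.** All randomness flows through one `numpy` Generator seeded
  from the config; identical (config, seed) gives bit-identical tables.

What the generator does *not* emulate: patient-level calendar dates,
competing risks, time-varying covariates or effects, missing data, and the
registry's true joint covariate distribution (only margins, optionally a
synthetic correlation block). Tests passing on these cohorts therefore
validate the machinery and its statistical calibration, not any clinical
conclusion about the original registry.

## Survival statistics core

- **Cox fitting.** Newton–Raphson on the Breslow partial likelihood
  (default; Efron available). Risk sets are prefixes of the cohort sorted by
  descending time, with an explicit tail boundary so subjects censored below
  the smallest event time never enter a risk set; repeated subset fits on one
  cohort share the sorted arrays. Convergence: score max-norm < 1e-8, at most
  25 iterations, step-halving on any likelihood decrease. Monotone
  likelihood is reported, not raised: if any |β| exceeds 15 the fit is
  flagged `diverged` with the capped coefficients. Constant or collinear
  columns raise a degenerate-design error naming the offending covariates
  (collinearity located by pivoted QR). Variances come from the inverse
  observed information; Wald CIs use z = 1.959964. Breslow is the default
  because the reference analyses were run in a system whose Cox procedure
  defaults to Breslow; with continuous times the two tie methods coincide.
- **Concordance.** A pair (i, j) is usable iff the observed times differ and
  the earlier member died; concordant iff the earlier member has the higher
  risk score. Default Harrell mode credits risk ties 0.5; a strict mode
  credits them 0. The risk score is the Cox linear predictor (larger =
  worse); equivalently the negated predicted survival. Pairs with tied
  observed times are never usable — this is where the implementation can
  differ from other packages at the 1e-4 level on tied data, and why the
  cross-check against the reference implementation is run on tie-free
  cohorts.
- **Kaplan–Meier, log-rank, chi-squared.** Product-limit estimator over
  distinct event times; k-group log-rank with the hypergeometric variance and
  df = k−1; Pearson chi-squared without continuity correction (the convention
  that reproduces the published summary p-values from their own counts).

## BBO engine

- **Species counts** are rank-based: the fittest habitat hosts S_max species
  (S_max = population size), the next S_max−1, etc., ties broken by stable
  population order. The published description maps fitness to species
  richness only qualitatively; rank assignment is the canonical realization.
- **Stationary species-count distribution.** P_s ∝ Π_{i<s} λ_i / Π_{i=1..s}
  μ_i, normalized — the equilibrium of the birth–death chain; for E = I it is
  the symmetric binomial over 0..S_max. Computed once per parameter set.
- **Migration** tests each bit of each non-elite habitat independently with
  probability λ_i and copies the bit from an emigrant drawn by roulette over
  μ_j (j ≠ i, elites included — they carry the most emigration mass by
  design). Sources are read from a pre-migration snapshot, making the
  operator independent of population order. If all emigration mass vanishes
  the source is drawn uniformly and the event logged.
- **Mutation** redraws each selected bit uniformly from {0,1} (a redraw may
  keep the value), at rate m_max(1 − P_s/P_max).
- **Loop.** Evaluate → rank → copy elites → migrate → mutate → re-evaluate →
  reinsert elites over the worst. The per-generation best HSI is therefore
  non-decreasing. The modification probability p_mod defaults to 1 (the
  published configuration names the parameter without a value). Runs are
  reproducible from the seed; the memo cache bounds distinct Cox fits by
  min(2^d, population × (generations + 1)) and in practice a default run on
  the study-scale cohort performs ~500–700 distinct fits.
- **Diverged fits in the fitness function.** A monotone-likelihood fit still
  induces the limit risk ordering, so its (capped) linear predictor scores
  normally; only degenerate designs and true non-convergence score the
  chance value 0.5 (flagged). The all-zero habitat scores 0.5 by the
  chance-discrimination convention. All HSI values are in-sample: no
  resampling is part of the procedure being modelled, so BBO and benchmark C
  values are directly comparable (and equally optimistic).

## Model ladder

Univariate Cox per covariate; the fully adjusted model on all 15; stepwise
selection; the BBO model refitted on its selected subset. Stepwise uses
equal entry and stay thresholds (only inclusion levels were specified):
entry by likelihood-ratio test against the current model (Wald entry
available), stay by Wald. Because the two tests can disagree near the
threshold, selection stops when the variable just entered is immediately
removed (the classical termination rule), a visited-state guard ends longer
add/remove cycles, and a final pure-removal sweep guarantees the returned
model satisfies its own stay criterion. Selection is deterministic for a
given cohort.

## Benchmark designs and problem sizes

- **Search-vs-oracle**: d = 10, n = 400, four active covariates with
  ln HR = 1 at prevalence 0.5, event fraction 0.5 — a deliberately
  well-powered design in which the C-optimal subset is essentially unique,
  so "BBO finds the exhaustive optimum" is sharp. 100 seeds in the test
  suite; the acceptance script reports a 30-seed rate.
- **Coverage**: 200 replicates (100 in the script) of the default
  study-scale generator; 95% Wald CI coverage of the 8 planted log-hazards,
  pooled, fitted on the true active set. Expected range [0.90, 0.99].
- **Ranking replication**: 100 default-generator cohorts (30 in the
  script); the BBO model's C must be at least the best stepwise C − 0.01.
- **Type-I error**: 1000 null replicates at n = 200 (500 in the script) for
  the log-rank test (one exponential, two arbitrary groups, no censoring)
  and the univariate Wald test (null covariate, ~50% events); nominal 0.05,
  accepted range (0.03, 0.07).

## Numerical choices and edge cases

- exp overflow in the partial likelihood is prevented by subtracting the
  linear-predictor maximum (exact in all ratios).
- HSI ties in exhaustive search resolve to the lowest bit-pattern integer;
  population ranking ties resolve by stable order.
- Display rounding in exports is decimal half-up (0.4935 → 0.494), matching
  the publication style rather than float banker's rounding; full-precision
  files are always written alongside.
- Empty vital-status strata in the cohort summary are flagged and their
  percentages left missing rather than printed as 0/0.
- Two internal inconsistencies of the published summary table (a transposed
  treatment row, one misprinted percentage) are resolved in favor of the
  counts; the tumor-size cut is printed as both "2 cm" and "2.4 cm" in the
  source tables and is recorded verbatim as a label without adjudication
  (the covariate is binary either way).

## Known limitations

- In-sample C is optimistic; no bootstrap or cross-validated C is provided,
  by design (the procedure being modelled is in-sample).
- The Wald-based stay test inherits the usual small-event-count caveats; at
  ~66 events the fully adjusted 15-covariate model is near the events-per-
  variable rule of thumb.
- Exhaustive search is limited to d ≤ 20 by construction.
- No stratified/time-varying Cox, exact-ties likelihood, competing risks or
  missing-data handling.
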