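# bbocox

Covariate selection for Cox proportional-hazards survival models by binary
**biogeography-based optimization (BBO)**, with the in-sample Harrell
C-statistic as the fitness function, benchmarked against the classical model
ladder (fully adjusted Cox, stepwise selection at several entry levels).

The package is aimed at biostatisticians and epidemiologists studying which
dichotomized clinicopathologic variables (tumor size, nodal status, receptor
status, treatments, ...) jointly discriminate overall survival in a
follow-up cohort — here, a breast-cancer cohort of n = 1896 patients with a
3.48% death fraction over a 144-month window. Because the original
patient-level registry is not public, the package ships a synthetic-cohort
generator that reproduces the cohort's published marginal structure and
plants known log-hazard effects, so every claim about the method is testable
on data with known truth.

## The method

**Search space.** Each candidate model is a *habitat*: a binary vector
h = (SIV_1, ..., SIV_d), one suitability-index variable (bit) per covariate,
SIV_j ∈ {0, 1} meaning covariate j enters the Cox model.

**Fitness (HSI).** For the selected subset S, fit the Cox model
λ(t | x) = λ₀(t) exp(Σ_{j∈S} β_j x_j) by Newton–Raphson on the Breslow
partial likelihood, then score the habitat by Harrell's concordance of the
linear predictor η̂ = Σ β̂_j x_j on the same cohort:

C = (#concordant pairs + ½ #risk-tied pairs) / #usable pairs,

where a pair (i, j) is usable iff its observed times differ and the member
with the smaller time died; C = 0.5 is chance, 1 is perfect discrimination.
The empty model scores 0.5.

**Evolution.** With species count k assigned by fitness rank, habitats
immigrate at rate λ_k = I(1 − k/S_max) and emigrate at μ_k = E·k/S_max (so
λ_k + μ_k = E when E = I). Migration overwrites each bit of an
immigration-prone habitat, with probability λ, by the corresponding bit of
an emigrant drawn by roulette wheel over μ. Mutation redraws bits uniformly
at rate m = m_max (1 − P_s/P_max), with P_s the stationary species-count
distribution of the underlying birth–death chain. The best habitats
(elites, default 2) pass unchanged; HSI values are memoized by bit pattern.
Defaults: population 50, 100 generations, E = I = 1, m_max = 0.04.

An exhaustive-search oracle scores all 2^d subsets (guarded to d ≤ 20) and
is used in the test suite to verify the search actually finds the C-optimal
subset.

## Worked example

```sh
bbocox simulate --seed 7 --out cohort.csv
bbocox select-bbo --cohort cohort.csv --seed 7 --out run.json
bbocox compare --cohort cohort.csv --bbo-run run.json --out report.json
bbocox km --cohort cohort.csv --covariate tumor_gt2cm --out km_tumor.csv
```

prints

```
wrote 1896 patients (68 events) to cohort.csv
best subset ['age_gt50', 'her2_pos', 'pr_pos', 'tumor_gt2cm', 'node_pos',
 'lvi_pos', 'dermal_pos', 'perineural_pos', 'total_mastectomy', 'no_ct',
 'no_ht', 'no_tt'] (C = 0.7374); wrote run.json
C-statistics: {'full': 0.7369, 'stepwise_0.05': 0.7115, 'stepwise_0.1':
 0.7115, 'stepwise_0.2': 0.728, 'bbo': 0.7374}; wrote report.json
log-rank p = 1.201e-05; wrote km_tumor.csv
```

Reading the numbers: the simulated cohort reproduces the study scale (1896
patients, ~3.5% deaths). The BBO-selected model attains the highest
in-sample C (0.7374), above the fully adjusted 15-covariate model (0.7369)
and all three stepwise models (0.71–0.73) — the qualitative ranking the
method is designed to produce. The Kaplan–Meier log-rank p for tumor size
(1.2e-5) confirms the planted effect separates the survival curves. The
`simulate` / `table1` / `univariate` / `stepwise` / `exhaustive` / `run-all`
subcommands expose the remaining stages; `bbocox run-all --seed 7 --out dir/`
writes the full artifact bundle (cohort summary, univariate table,
comparison table, per-covariate KM curves) as stamped CSV/JSON.

Library use mirrors the CLI:

```python
from bbocox import GeneratorConfig, generate_cohort, run_bbo, compare_models, BBOParams

cohort = generate_cohort(GeneratorConfig(seed=7))
run = run_bbo(cohort, BBOParams(seed=7))
report = compare_models(cohort, run)
```

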