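# Methods

## The design and the model

`pnbayes` targets partially nested two-arm trials: subjects randomised to
the treatment arm are organised into `c` clusters of `m` (therapy groups,
classrooms), while the `n_C` control subjects are mutually independent.
The generative and fitted model for subject *i* is

    Y_ij = b0 + b1 X_ij + u_j Z_j + e_ij

with treatment indicator `X`, cluster effects `u_j ~ N(0, σ²_U)` present
only in the treatment arm, and heteroscedastic residuals: `Var(e) = σ²_eC`
under control, `σ²_eU` under treatment.  The treatment-arm intraclass
correlation is `ρ = σ²_U / (σ²_U + σ²_eU)`.  Estimating σ²_U ("the nesting
effect") with few clusters is the hard problem; the package exists to
compare how two variance-component prior regimes behave there.

Truth-model defaults: `b0 = 2`, `b1 = 0.5`, `σ²_eC = 0.27`, total
treatment-arm variance `0.46` split as `σ²_U = ρ·0.46`,
`σ²_eU = (1−ρ)·0.46`.  The canonical design grid crosses
`c ∈ {8, 12, 16}`, `m ∈ {5, 10, 15, 20}`, `ρ ∈ {0.05, 0.10, 0.15}` with
the two prior regimes — 72 conditions.  The control-arm size is not part
of the grid definition; we default to `n_C = c·m` (balanced total
allocation, the standard choice in the partially nested literature), and
expose it as a field on `SimulationCondition`.

## Prior regimes

* **uniform**: `σ²_U ~ U(0, 0.23)`, `σ²_eC ~ U(0, 0.69)`,
  `σ²_eU ~ U(0, 0.69)` — flat on the *variance* scale.
* **gamma**: `σ²_U ~ G(13, 0.03)`, `σ²_eC ~ G(13, 0.03)`,
  `σ²_eU ~ G(9, 0.03)`.

Fixed effects always get `b0 ~ N(3, 2.25)` and `b1 ~ N(0, 1)`.

The gamma hyperparameters are read as **shape–scale on the variance**, so
G(13, 0.03) has mean 0.39 and G(9, 0.03) has mean 0.27.  This is a genuine
interpretation decision: the G(a, b) notation fixes no convention, and no
reading we examined is consistent with every reference result at once.

* Shape–rate on the variance puts the prior means three orders of
  magnitude above any plausible variance.
* A gamma prior on the *precision* (the BUGS/JAGS idiom) concentrates
  σ²_U near 0.002, which would destroy nesting-effect coverage even in
  the weakest-data cells, where reference coverage is ~97%.
* Priors on standard deviations are ruled out for the uniform regime:
  U(0, 0.23) on σ_U would cap σ²_U at 0.053 < 0.069, the truth at
  ρ = 0.15, where reference coverage stays near 90%.

Under the adopted reading the residual-variance priors sit near the truth
values (0.27 and ≈0.39–0.44) — though assigned crosswise, G(13, 0.03) to
σ²_eC and G(9, 0.03) to σ²_eU; a `swap_gamma_residual_priors` switch
exchanges them for sensitivity analysis — while the σ²_U prior mean 0.39
lies an order of magnitude above the true nesting variance
(0.023–0.069).  A consequence users should understand: **under this
regime the gamma prior's 2.5% quantile for σ²_U is ≈ 0.21, so no
posterior interval can contain the true nesting variance**, nesting-effect
coverage under the gamma regime is ≈ 0 on the canonical grid, and the
gamma regime loses the nesting-effect RMSE comparison everywhere.  The
qualitative contrast "uniform is safer at low ICC" reproduces strongly;
published claims of good gamma performance near ρ = 0.15 do not reproduce
under any hyperparameter reading we could defend, and we deliberately do
not tune hyperparameters to manufacture them.

A sentence in our source material assigning a normal prior to "the total
error under treatment" maps to no model parameter (the three variance
priors above already cover all variance components) and is ignored.

## Sampler

`fit_model` runs Metropolis-within-Gibbs:

1. **Location block** — `b0`, `b1` and the `u_j` have exact normal full
   conditionals (the `u_j` conditional has precision `m/σ²_eU + 1/σ²_U`)
   and are drawn by Gibbs steps computed from sufficient statistics
   (control sums, per-cluster sums), so iteration cost does not grow with
   raw data size.
2. **Uniform-prior variances** — the full conditional is an inverse-gamma
   density, shape `n/2 − 1` and scale `SSE/2` (the flat-prior reading),
   truncated to `(0, upper)`; drawn exactly by inverse-CDF via the
   regularised upper incomplete gamma function.  If the CDF mass on the
   support underflows, the update falls back to one reflected random-walk
   Metropolis step (debug-logged).
3. **Gamma-prior variances** — non-conjugate; one random-walk Metropolis
   step on `λ = log σ²` whose target includes the Gaussian likelihood
   term, the gamma log-prior at `e^λ`, and the `+λ` Jacobian.

Protocol defaults: 3 chains × 50,000 iterations, 10,000 burn-in, thinning
10 → 4,000 retained draws per chain, 12,000 pooled.  Tests and desk-scale
studies use `scaled_settings()` (3 × 5,000, burn-in 1,000, thin 5), which
is *not* the full protocol; problem sizes used by each test are stated in
its docstring.

Numerical choices:

* Overdispersed starts: fixed effects drawn from their priors, variances
  from their priors (gamma draws retried into (0.001, 1)); chain *k* uses
  the sub-seed `SeedSequence(entropy=seed, spawn_key=(k,))`.
* Random-walk step default 0.5 on the log scale, with burn-in-only
  adaptation toward 30–45% acceptance, frozen at the end of burn-in so
  retained draws preserve detailed balance.
* Convergence: a fit "converges" iff the Gelman–Rubin PSRF
  `sqrt(((n−1)/n·W + B/n)/W)` over the retained draws is ≤ 1.1 for all
  five monitored parameters (threshold configurable).  Degenerate case:
  identical constant chains give 1, separated constant chains +inf.
* Point estimate: posterior mean of the pooled thinned draws; intervals
  are equal-tailed 2.5/97.5 percentiles.  ESS uses averaged per-chain
  FFT autocovariances with Geyer's paired-lag truncation.

## Evaluation and aggregation

Per design cell and prior family: convergence rate `100·r/R`; coverage =
percentage of **converged** replicates whose open interval strictly
contains the truth (`b1 = 0.5`; `σ²_U = ρ·0.46`); bias and RMSE of
(estimate − truth) over converged replicates.  Metrics are computed over
converged replicates only because non-converged fits have no trustworthy
summaries; the convergence rate reports them separately.  Grand
(mean/median/min/max) and marginal summaries aggregate the 36
condition-level values per family, never pooled replicates, so extrema
are attributable to single cells.  Bias/RMSE are stored raw; display
multipliers (e.g. 10³) exist only at formatting time.

## Study orchestration

`run_study` iterates cells × replicates, generating each dataset once and
fitting it under both regimes (common random numbers; configurable off).
Sub-seeds are `SeedSequence(entropy=master_seed, spawn_key=(cell, rep,
stream))` — pure functions of indices, so runs are reproducible,
order-independent and resumable from the `records.jsonl` checkpoint.
Replicate-level fit failures are logged and counted as non-converged.

`recommend_prior` adjudicates G vs U per cell.  No published rule exists
for this adjudication; the default — smaller nesting-effect RMSE wins,
ties broken by |coverage − 95| then |bias| — is an explicit, replaceable
choice (`rule=` accepts a callable).

## What the generator does and does not emulate

The generator reproduces the truth model exactly: normal effects and
residuals, equal cluster sizes, heteroscedastic arms, no covariates.
Real partially nested trials feature unequal cluster sizes, attrition,
non-normal outcomes and baseline covariates; passing tests here say
nothing about those.  Three-level nesting and inverse-gamma or half-t
priors are out of scope.

## Known limitations

* The gamma regime's behaviour is wholly determined by the hyperparameter
  reading discussed above; results under other readings can be explored
  via `gamma_parameterization="rate"` and `swap_gamma_residual_priors`
  but are not part of the canonical regimes.
* The exact truncated-inverse-gamma update requires conditional shape
  `n/2 − 1 > 0`, i.e. at least 3 clusters for σ²_U; smaller problems use
  the Metropolis fallback.
* Serial execution only; a full 72 × 1000 study at the long-chain
  protocol is a multi-day single-core computation and is intended to be
  run resumable, cell by cell.
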