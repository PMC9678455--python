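# pnbayes

Bayesian estimation of treatment and nesting effects in **partially
nested** trial designs, with a Monte-Carlo harness for comparing
variance-component prior regimes.

## The problem

In many behavioural and clinical trials, treated subjects are organised
into clusters (therapy groups, classrooms, wards) while control subjects
remain mutually independent — a *partially nested* design.  The model for
subject *i* is

    Y_ij = b0 + b1·X_ij + u_j·Z_j + e_ij

with treatment indicator `X_ij`, cluster effects `u_j ~ N(0, σ²_U)`
present only in the treatment arm, and residuals heteroscedastic across
arms (`σ²_eC` under control, `σ²_eU` under treatment).  The treatment-arm
intraclass correlation is `ρ = σ²_U / (σ²_U + σ²_eU)`.

With few clusters (8–16) and small groups, likelihood-based estimates of
the nesting variance σ²_U are unstable, and Bayesian inference becomes
acutely sensitive to the prior placed on the variance components.  This
package implements the full simulation pipeline for studying that
sensitivity: a generator for the truth model, a Metropolis-within-Gibbs
sampler under matched **gamma** or **uniform** prior regimes, the four
standard evaluation indices (convergence rate, 95% interval coverage,
bias, RMSE), and a study runner that crosses
`c ∈ {8,12,16} × m ∈ {5,10,15,20} × ρ ∈ {0.05,0.10,0.15}` with both
regimes (72 conditions) and emits per-cell prior recommendations.

It is aimed at methodologists evaluating priors for small-sample
multilevel models, and at trialists who want a defensible prior for a
concrete partially nested design before collecting data.

## Worked example

```python
from pnbayes import (SimulationCondition, TruthParameters, generate_dataset,
                     canonical_regime, fit_model, empirical_icc)
from pnbayes.runner import scaled_settings

cond = SimulationCondition(c=8, m=10, rho=0.15)      # 80 treated + 80 controls
data = generate_dataset(cond, TruthParameters(rho=0.15), seed=7)
print("subjects:", len(data.y), " clusters:", data.c,
      " empirical ICC:", round(empirical_icc(data), 3))

for fam in ("uniform", "gamma"):
    fit = fit_model(data, canonical_regime(fam), scaled_settings(seed=1))
    b1, s2u = fit.summary("b1"), fit.summary("sigma2_U")
    print(f"{fam:8s} b1 = {b1.mean:.3f} ({b1.ci_low:.3f}, {b1.ci_high:.3f})   "
          f"sigma2_U = {s2u.mean:.4f} ({s2u.ci_low:.4f}, {s2u.ci_high:.4f})   "
          f"converged = {fit.converged}")
```

prints

```
subjects: 160  clusters: 8  empirical ICC: -0.028
uniform  b1 = 0.407 (0.199, 0.626)   sigma2_U = 0.0385 (0.0007, 0.1572)   converged = True
gamma    b1 = 0.409 (0.004, 0.806)   sigma2_U = 0.3049 (0.1512, 0.5167)   converged = True
```

Both regimes recover the treatment effect (truth 0.5) with intervals
covering it.  For the nesting variance (truth `0.15 × 0.46 = 0.069`) the
flat U(0, 0.23) prior yields an interval containing the truth, while the
informative G(13, 0.03) prior — mean 0.39 under the shape–scale reading —
drags the posterior an order of magnitude upward: one dataset's view of
the prior sensitivity the Monte-Carlo study quantifies systematically.

A study over any sub-grid, with common random numbers across regimes,
checkpointing and tidy outputs:

```python
from pnbayes import StudyConfig, run_study, recommend_prior
from pnbayes.runner import scaled_settings

config = StudyConfig(grid=..., n_reps=200, chain_settings=scaled_settings(),
                     master_seed=11, output_dir="out/")
table, records = run_study(config)     # tidy per-cell metric table
recommend_prior(table)                 # per-cell G/U verdicts
```

The same operations are exposed as a CLI: `pnbayes simulate | fit | run |
summarize | recommend`.

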