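"""Metropolis-within-Gibbs sampler for the partially nested model.

The model fitted here is

    Y_ij = b0 + b1 * X_ij + u_j * Z_j + e_ij

with heteroscedastic residuals (variance ``sigma2_eC`` in the control arm,
``sigma2_eU`` in the treatment arm) and cluster effects
``u_j ~ N(0, sigma2_U)`` in the treatment arm only.  Sampling proceeds in
blocks:

* ``b0``, ``b1`` and the vector ``u`` have exact normal full conditionals
  (conjugate normal--normal updates) and are drawn by Gibbs steps.
* Under a **uniform** prior, each variance's full conditional is an
  inverse-gamma density truncated to ``(0, upper)`` and is drawn exactly by
  inverse-CDF sampling, with a reflected random-walk Metropolis fallback
  when the CDF mass on the support underflows.
* Under a **gamma** prior the variance conditional is non-conjugate; a
  random-walk Metropolis step on ``log sigma2`` is used (with the +lambda
  Jacobian term), optionally step-size-adapted during burn-in only so the
  retained draws preserve detailed balance.

Convergence is judged by the Gelman--Rubin potential scale reduction
factor computed over chains for each of the five monitored parameters
(b0, b1, sigma2_U, sigma2_eC, sigma2_eU); a fit "converges" when every
PSRF is at or below the threshold (default 1.1).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaincc, gammainccinv

from .priors import PriorRegime, VariancePrior
from .simulate import PartiallyNestedDataset

__all__ = [
    "ChainSettings",
    "ModelState",
    "PosteriorSummary",
    "FitResult",
    "gelman_rubin",
    "effective_sample_size",
    "update_location_block",
    "update_variance_uniform",
    "update_variance_gamma",
    "fit_model",
]

logger = logging.getLogger(__name__)

MONITORED = ("b0", "b1", "sigma2_U", "sigma2_eC", "sigma2_eU")


@dataclass(frozen=True)
class ChainSettings:
    """MCMC protocol settings.

    Defaults mirror a long-chain protocol for small-sample variance
    estimation: 50,000 iterations with a 10,000-iteration burn-in, three
    chains, thinning every 10th draw, hence 4,000 retained draws per chain
    (12,000 pooled).
    """

    n_iter: int = 50_000
    n_burn: int = 10_000
    thin: int = 10
    n_chains: int = 3
    rw_step: float = 0.5
    adapt_rw: bool = True
    rhat_threshold: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for the convergence diagnostic")
        if self.rw_step <= 0:
            raise ValueError("rw_step must be positive")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin

    @property
    def retained_total(self) -> int:
        return self.retained_per_chain * self.n_chains


@dataclass
class ModelState:
    """Current parameter values of one chain."""

    b0: float
    b1: float
    u: np.ndarray
    sigma2_U: float
    sigma2_eC: float
    sigma2_eU: float

    def check(self) -> None:
        if min(self.sigma2_U, self.sigma2_eC, self.sigma2_eU) <= 0:
            raise RuntimeError("sampler invariant violated: non-positive variance")


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean/sd, equal-tailed 95% interval, and diagnostics."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    rhat: float
    ess: float

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "rhat": self.rhat,
            "ess": self.ess,
        }


@dataclass
class FitResult:
    """Posterior summaries for the five monitored parameters plus the
    convergence verdict and M-H acceptance bookkeeping."""

    summaries: dict[str, PosteriorSummary]
    converged: bool
    acceptance_rates: dict[str, float]
    settings: ChainSettings
    draws: dict[str, np.ndarray] | None = None  # (n_chains, retained) each

    def summary(self, parameter: str) -> PosteriorSummary:
        return self.summaries[parameter]

    def dump_draws_csv(self, path) -> None:
        """Write retained draws as a (chain, iteration) x parameter CSV;
        requires the fit to have been run with ``keep_draws=True``."""
        if self.draws is None:
            raise ValueError("fit was run without keep_draws=True")
        import pandas as pd

        n_chains, retained = next(iter(self.draws.values())).shape
        frame = pd.DataFrame(
            {name: values.ravel() for name, values in self.draws.items()}
        )
        frame.insert(0, "chain", np.repeat(np.arange(n_chains), retained))
        frame.insert(1, "draw", np.tile(np.arange(retained), n_chains))
        frame.to_csv(path, index=False)

    def to_json(self) -> str:
        payload = {
            "summaries": {k: v.to_dict() for k, v in self.summaries.items()},
            "converged": self.converged,
            "acceptance_rates": self.acceptance_rates,
            "settings": {
                "n_iter": self.settings.n_iter,
                "n_burn": self.settings.n_burn,
                "thin": self.settings.thin,
                "n_chains": self.settings.n_chains,
                "rw_step": self.settings.rw_step,
                "adapt_rw": self.settings.adapt_rw,
                "rhat_threshold": self.settings.rhat_threshold,
                "seed": self.settings.seed,
            },
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# sufficient statistics


@dataclass(frozen=True)
class _SuffStats:
    """Fixed-data summaries; every full conditional depends on the data
    only through these."""

    n_c: int
    sum_c: float
    ss_c: float
    c: int
    m: int
    n_t: int
    cluster_sums: np.ndarray  # (c,) sums of y within each treatment cluster
    sum_t: float
    ss_t: float


def _suffstats(data: PartiallyNestedDataset) -> _SuffStats:
    ctrl = data.x == 0
    treat = ~ctrl
    if not ctrl.any() or not treat.any():
        raise ValueError(
            "model requires both arms: an independent control arm and a "
            "clustered treatment arm"
        )
    y_c = data.y[ctrl]
    y_t = data.y[treat]
    labels = data.group[treat]
    uniq, inv = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inv)
    if len(uniq) < 2:
        raise ValueError("need at least 2 treatment clusters")
    if len(set(sizes)) != 1:
        raise ValueError("treatment clusters must be equal-sized")
    cluster_sums = np.bincount(inv, weights=y_t)
    return _SuffStats(
        n_c=len(y_c),
        sum_c=float(y_c.sum()),
        ss_c=float(y_c @ y_c),
        c=len(uniq),
        m=int(sizes[0]),
        n_t=len(y_t),
        cluster_sums=cluster_sums,
        sum_t=float(y_t.sum()),
        ss_t=float(y_t @ y_t),
    )


def _sse_control(state: ModelState, ss: _SuffStats) -> float:
    return ss.ss_c - 2.0 * state.b0 * ss.sum_c + ss.n_c * state.b0 * state.b0


def _sse_treatment(state: ModelState, ss: _SuffStats) -> float:
    mu = state.b0 + state.b1 + state.u
    return float(ss.ss_t - 2.0 * (mu @ ss.cluster_sums) + ss.m * (mu @ mu))


# ---------------------------------------------------------------------------
# location block (exact Gibbs)


def _update_location(
    state: ModelState, ss: _SuffStats, regime: PriorRegime, rng: np.random.Generator
) -> None:
    fixed = regime.fixed
    s2c, s2u_res, s2u = state.sigma2_eC, state.sigma2_eU, state.sigma2_U

    # b0 | rest
    usum = float(state.u.sum())
    prec = ss.n_c / s2c + ss.n_t / s2u_res + 1.0 / fixed.b0_var
    num = (
        ss.sum_c / s2c
        + (ss.sum_t - ss.n_t * state.b1 - ss.m * usum) / s2u_res
        + fixed.b0_mean / fixed.b0_var
    )
    state.b0 = num / prec + rng.standard_normal() / math.sqrt(prec)

    # b1 | rest
    prec = ss.n_t / s2u_res + 1.0 / fixed.b1_var
    num = (
        ss.sum_t - ss.n_t * state.b0 - ss.m * usum
    ) / s2u_res + fixed.b1_mean / fixed.b1_var
    state.b1 = num / prec + rng.standard_normal() / math.sqrt(prec)

    # u_j | rest  (precision m/sigma2_eU + 1/sigma2_U)
    prec = ss.m / s2u_res + 1.0 / s2u
    mean = (ss.cluster_sums - ss.m * (state.b0 + state.b1)) / s2u_res / prec
    state.u = mean + rng.standard_normal(ss.c) / math.sqrt(prec)


def update_location_block(
    state: ModelState,
    data: PartiallyNestedDataset,
    priors: PriorRegime,
    rng: np.random.Generator,
) -> ModelState:
    """One exact Gibbs sweep over (b0, b1, u) given the variances."""
    state.check()
    _update_location(state, _suffstats(data), priors, rng)
    return state


# ---------------------------------------------------------------------------
# variance updates


def _draw_truncated_invgamma(
    a: float, b: float, upper: float, current: float, rng: np.random.Generator
) -> float:
    """Exact draw from an InvGamma(shape a, scale b) density truncated to
    (0, upper), via the inverse CDF; falls back to one reflected
    random-walk Metropolis step when the support mass underflows or the
    shape is non-positive."""
    if a > 0.0:
        # CDF of InvGamma(a, b) at x is Q(a, b/x) (upper incomplete ratio)
        f_up = float(gammaincc(a, b / upper))
        if f_up > 1e-290:
            v = rng.random() * f_up
            if v > 0.0:
                x = b / float(gammainccinv(a, v))
                if 0.0 < x < upper:
                    return x
            # v == 0 or numerical round-off out of support: fall through
    logger.debug(
        "truncated inverse-gamma draw fell back to reflected RW-MH "
        "(a=%g, b=%g, upper=%g)",
        a,
        b,
        upper,
    )
    # reflected random-walk M-H on the variance scale; the reflection at 0
    # and upper keeps the proposal symmetric
    prop = current + 0.1 * upper * rng.standard_normal()
    span = 2.0 * upper
    prop = prop % span
    if prop > upper:
        prop = span - prop
    if prop <= 0.0:
        return current

    def log_kernel(x: float) -> float:
        return -(a + 1.0) * math.log(x) - b / x

    if math.log(rng.random()) < log_kernel(prop) - log_kernel(current):
        return prop
    return current


_COMPONENT_ATTR = {"U": "sigma2_U", "eC": "sigma2_eC", "eU": "sigma2_eU"}


def _likelihood_stats(
    state: ModelState, component: str, ss: _SuffStats
) -> tuple[float, float]:
    """(n, sse) entering the variance conditional
    sigma2^{-n/2} exp(-sse / (2 sigma2))."""
    if component == "U":
        return ss.c, float(state.u @ state.u)
    if component == "eC":
        return ss.n_c, _sse_control(state, ss)
    if component == "eU":
        return ss.n_t, _sse_treatment(state, ss)
    raise ValueError(f"unknown variance component {component!r}")


def _update_variance_uniform(
    state: ModelState,
    component: str,
    ss: _SuffStats,
    prior: VariancePrior,
    rng: np.random.Generator,
) -> None:
    n, sse = _likelihood_stats(state, component, ss)
    # flat prior on the variance => truncated InvGamma(n/2 - 1, sse/2)
    a = n / 2.0 - 1.0
    b = sse / 2.0
    attr = _COMPONENT_ATTR[component]
    current = getattr(state, attr)
    setattr(
        state, attr, _draw_truncated_invgamma(a, b, prior.upper, current, rng)
    )


def update_variance_uniform(
    state: ModelState,
    component: str,
    data: PartiallyNestedDataset,
    prior: VariancePrior,
    rng: np.random.Generator,
) -> ModelState:
    """Exact truncated-inverse-gamma draw of one variance under its
    uniform prior."""
    if prior.family != "uniform":
        raise ValueError("update_variance_uniform requires a uniform prior")
    state.check()
    _update_variance_uniform(state, component, _suffstats(data), prior, rng)
    return state


def _update_variance_gamma(
    state: ModelState,
    component: str,
    ss: _SuffStats,
    prior: VariancePrior,
    step: float,
    rng: np.random.Generator,
) -> bool:
    """One random-walk Metropolis step on lambda = log sigma2; returns
    whether the proposal was accepted."""
    n, sse = _likelihood_stats(state, component, ss)
    k, theta = prior.shape, prior.scale
    attr = _COMPONENT_ATTR[component]
    current = getattr(state, attr)
    lam = math.log(current)
    lam_prop = lam + step * rng.standard_normal()
    x_prop = math.exp(lam_prop)

    # log posterior in lambda: likelihood - n/2*lam - sse/(2 e^lam),
    # gamma prior (k-1)*lam - e^lam/theta, Jacobian +lam
    def logpost(lam_: float, x_: float) -> float:
        return -0.5 * n * lam_ - 0.5 * sse / x_ + k * lam_ - x_ / theta

    if math.log(rng.random()) < logpost(lam_prop, x_prop) - logpost(lam, current):
        setattr(state, attr, x_prop)
        return True
    return False


def update_variance_gamma(
    state: ModelState,
    component: str,
    data: PartiallyNestedDataset,
    prior: VariancePrior,
    settings: ChainSettings,
    rng: np.random.Generator,
) -> ModelState:
    """One random-walk Metropolis update of one variance under its gamma
    prior."""
    if prior.family != "gamma":
        raise ValueError("update_variance_gamma requires a gamma prior")
    state.check()
    _update_variance_gamma(
        state, component, _suffstats(data), prior, settings.rw_step, rng
    )
    return state


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor sqrt([(n-1)/n W + B/n] / W).

    ``chains`` is (n_chains, n_draws).  With zero within-chain variance in
    every chain, returns 1.0 when the chains are one identical constant
    sequence and +inf otherwise.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise ValueError("need >= 2 chains with >= 10 draws each")
    n = chains.shape[1]
    means = chains.mean(axis=1)
    w = float(chains.var(axis=1, ddof=1).mean())
    b = n * float(means.var(ddof=1))
    if w == 0.0:
        return 1.0 if b == 0.0 else math.inf
    v_hat = (n - 1) / n * w + b / n
    return math.sqrt(v_hat / w)


def effective_sample_size(chains: np.ndarray) -> float:
    """Autocorrelation-based effective sample size of pooled chains.

    Averages per-chain autocovariances, then truncates the lag sum with
    Geyer's initial positive-sequence rule on paired lags.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be (n_chains, n_draws)")
    m, n = chains.shape
    if n < 4:
        return float(m * n)
    centered = chains - chains.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    fft = np.fft.rfft(centered, n=size, axis=1)
    acov = np.fft.irfft(fft * np.conj(fft), n=size, axis=1)[:, :n].real / n
    var_w = float(acov[:, 0].mean())
    if var_w == 0.0:
        return float(m * n)
    # combined autocorrelation using the between-chain variance, so that
    # non-mixing chains register as high autocorrelation
    mean_acov = acov.mean(axis=0)
    var_plus = var_w * (n - 1) / n
    if m > 1:
        var_plus += float(chains.mean(axis=1).var(ddof=1))
    rho = 1.0 - (var_w - mean_acov) / var_plus
    rho[0] = 1.0
    # pair consecutive lags (1,2), (3,4), ... keep while the pair sum > 0
    tail = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        tail += pair
        t += 2
    ess = m * n / (1.0 + 2.0 * tail)
    return float(min(ess, m * n))


# ---------------------------------------------------------------------------
# full fit


def _initial_state(
    regime: PriorRegime, c: int, rng: np.random.Generator
) -> ModelState:
    """Overdispersed start: fixed effects from their priors, variances
    from their priors (gamma draws truncated to (0.001, 1))."""
    fixed = regime.fixed
    b0 = fixed.b0_mean + math.sqrt(fixed.b0_var) * rng.standard_normal()
    b1 = fixed.b1_mean + math.sqrt(fixed.b1_var) * rng.standard_normal()

    def var_draw(prior: VariancePrior) -> float:
        if prior.family == "uniform":
            return float(rng.uniform(0.0, prior.upper))
        for _ in range(100):
            v = float(rng.gamma(prior.shape, prior.scale))
            if 0.001 < v < 1.0:
                return v
        return min(max(v, 0.001), 1.0)

    s2u = var_draw(regime.prior_U)
    state = ModelState(
        b0=b0,
        b1=b1,
        u=math.sqrt(s2u) * rng.standard_normal(c),
        sigma2_U=s2u,
        sigma2_eC=var_draw(regime.prior_eC),
        sigma2_eU=var_draw(regime.prior_eU),
    )
    return state


_ADAPT_INTERVAL = 50
_ADAPT_TARGET = (0.30, 0.45)


def fit_model(
    data: PartiallyNestedDataset,
    regime: PriorRegime,
    settings: ChainSettings,
    keep_draws: bool = False,
) -> FitResult:
    """Fit the partially nested model to one dataset by MCMC.

    Runs ``settings.n_chains`` chains from overdispersed starts; each
    iteration applies the location Gibbs block followed by the three
    variance updates dictated by each component's prior family.  Burn-in
    draws are discarded, the rest thinned; summaries pool the retained
    draws of all chains.  Fully reproducible from ``settings.seed``.
    """
    ss = _suffstats(data)
    is_gamma = {
        comp: getattr(regime, f"prior_{comp}").family == "gamma"
        for comp in ("U", "eC", "eU")
    }
    retained = settings.retained_per_chain
    draws = {p: np.empty((settings.n_chains, retained)) for p in MONITORED}
    accept_counts = {c: 0 for c in ("U", "eC", "eU")}

    for chain in range(settings.n_chains):
        # per-chain sub-seed derived from the master seed via a counter
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=settings.seed, spawn_key=(chain,)
        ))
        state = _initial_state(regime, ss.c, rng)
        steps = {c: settings.rw_step for c in ("U", "eC", "eU")}
        window = {c: [0, 0] for c in ("U", "eC", "eU")}  # [accepts, tries]
        kept = 0
        for it in range(settings.n_iter):
            in_burn = it < settings.n_burn
            _update_location(state, ss, regime, rng)
            for comp in ("U", "eC", "eU"):
                prior = getattr(regime, f"prior_{comp}")
                if is_gamma[comp]:
                    accepted = _update_variance_gamma(
                        state, comp, ss, prior, steps[comp], rng
                    )
                    if in_burn:
                        if settings.adapt_rw:
                            window[comp][0] += accepted
                            window[comp][1] += 1
                            if window[comp][1] == _ADAPT_INTERVAL:
                                rate = window[comp][0] / _ADAPT_INTERVAL
                                if rate < _ADAPT_TARGET[0]:
                                    steps[comp] *= 0.8
                                elif rate > _ADAPT_TARGET[1]:
                                    steps[comp] *= 1.25
                                window[comp] = [0, 0]
                    else:
                        accept_counts[comp] += accepted
                else:
                    _update_variance_uniform(state, comp, ss, prior, rng)
            if not in_burn:
                offset = it - settings.n_burn
                if offset % settings.thin == 0 and kept < retained:
                    draws["b0"][chain, kept] = state.b0
                    draws["b1"][chain, kept] = state.b1
                    draws["sigma2_U"][chain, kept] = state.sigma2_U
                    draws["sigma2_eC"][chain, kept] = state.sigma2_eC
                    draws["sigma2_eU"][chain, kept] = state.sigma2_eU
                    kept += 1
        if kept != retained:  # pragma: no cover - arithmetic guard
            raise RuntimeError("retained-draw bookkeeping error")

    post_burn_iters = settings.n_chains * (settings.n_iter - settings.n_burn)
    acceptance = {
        comp: (accept_counts[comp] / post_burn_iters if is_gamma[comp] else math.nan)
        for comp in ("U", "eC", "eU")
    }

    summaries: dict[str, PosteriorSummary] = {}
    for p in MONITORED:
        pooled = draws[p].ravel()
        lo, hi = np.quantile(pooled, [0.025, 0.975])
        summaries[p] = PosteriorSummary(
            mean=float(pooled.mean()),
            sd=float(pooled.std(ddof=1)),
            ci_low=float(lo),
            ci_high=float(hi),
            rhat=gelman_rubin(draws[p]),
            ess=effective_sample_size(draws[p]),
        )
    converged = all(
        summaries[p].rhat <= settings.rhat_threshold for p in MONITORED
    )
    return FitResult(
        summaries=summaries,
        converged=converged,
        acceptance_rates=acceptance,
        settings=settings,
        draws=draws if keep_draws else None,
    )
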