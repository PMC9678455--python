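"""Tests of the Metropolis-within-Gibbs sampler and its diagnostics."""

import dataclasses
import math

import numpy as np
import pytest

from pnbayes import (
    ChainSettings,
    ModelState,
    PartiallyNestedDataset,
    SimulationCondition,
    TruthParameters,
    VariancePrior,
    canonical_regime,
    effective_sample_size,
    fit_model,
    gelman_rubin,
    generate_dataset,
    update_location_block,
)
from pnbayes.mcmc import (
    _SuffStats,
    _update_location,
    _update_variance_gamma,
    _suffstats,
)
from pnbayes.priors import FixedEffectPriors, PriorRegime


def _state_for(data, sigma2_U=0.05, sigma2_eC=0.27, sigma2_eU=0.4):
    return ModelState(
        b0=2.0,
        b1=0.5,
        u=np.zeros(data.c),
        sigma2_U=sigma2_U,
        sigma2_eC=sigma2_eC,
        sigma2_eU=sigma2_eU,
    )


class TestChainSettings:
    def test_default_protocol_bookkeeping(self):
        settings = ChainSettings()
        assert settings.retained_per_chain == 4000
        assert settings.retained_total == 12000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_iter": 100, "n_burn": 100},
            {"thin": 0},
            {"n_chains": 1},
            {"rw_step": 0.0},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ChainSettings(**kwargs)


class TestLocationBlock:
    def test_no_shrinkage_limit(self, small_dataset, rng):
        # sigma2_U -> infinity: E[b0 + b1 + u_j] is the cluster mean of y
        state = _state_for(small_dataset, sigma2_U=1e12)
        ss = _suffstats(small_dataset)
        totals = np.zeros(small_dataset.c)
        n_draws = 4000
        for _ in range(n_draws):
            _update_location(state, ss, canonical_regime("uniform"), rng)
            totals += state.b0 + state.b1 + state.u
        cluster_means = ss.cluster_sums / ss.m
        assert np.allclose(totals / n_draws, cluster_means, atol=0.1)

    def test_complete_shrinkage_limit(self, small_dataset, rng):
        # sigma2_U -> 0: the u conditional collapses to a point mass at 0
        state = _state_for(small_dataset, sigma2_U=1e-12)
        update_location_block(
            state, small_dataset, canonical_regime("uniform"), rng
        )
        assert np.max(np.abs(state.u)) < 1e-4

    def test_rejects_nonpositive_variance(self, small_dataset, rng):
        state = _state_for(small_dataset, sigma2_U=-1.0)
        with pytest.raises(RuntimeError):
            update_location_block(
                state, small_dataset, canonical_regime("uniform"), rng
            )


class TestGammaVarianceStep:
    def test_degenerate_proposal_always_accepted(self, small_dataset, rng):
        # zero step proposes the current point; detailed balance makes the
        # acceptance probability exactly one
        state = _state_for(small_dataset)
        ss = _suffstats(small_dataset)
        prior = VariancePrior.gamma(13.0, 0.03)
        before = state.sigma2_U
        accepted = _update_variance_gamma(state, "U", ss, prior, 0.0, rng)
        assert accepted
        assert state.sigma2_U == pytest.approx(before, rel=1e-12)

    def test_acceptance_rate_tracked_in_fit(self, small_dataset, tiny_settings):
        fit = fit_model(small_dataset, canonical_regime("gamma"), tiny_settings)
        for comp in ("U", "eC", "eU"):
            assert 0.0 < fit.acceptance_rates[comp] <= 1.0


class TestGelmanRubin:
    def test_identical_constant_chains(self):
        chains = np.full((3, 50), 1.7)
        assert gelman_rubin(chains) == 1.0

    def test_distinct_constant_chains_diverge(self):
        chains = np.vstack([np.full(50, 0.0), np.full(50, 5.0)])
        assert gelman_rubin(chains) == math.inf

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(5)
        chains = rng.standard_normal((3, 20_000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(6)
        chains = rng.standard_normal((3, 500)) + np.array([[0.0], [10.0], [20.0]])
        assert gelman_rubin(chains) > 1.1

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((2, 5)))


class TestEffectiveSampleSize:
    def test_iid_chains_close_to_total(self):
        rng = np.random.default_rng(8)
        chains = rng.standard_normal((3, 4000))
        ess = effective_sample_size(chains)
        assert 0.7 * 12000 <= ess <= 12000

    def test_autocorrelated_chains_much_smaller(self):
        rng = np.random.default_rng(9)
        n = 4000
        chains = np.empty((2, n))
        for k in range(2):
            x = 0.0
            for i in range(n):
                x = 0.97 * x + rng.standard_normal()
                chains[k, i] = x
        assert effective_sample_size(chains) < 0.2 * 2 * n


class TestFitModel:
    def test_seed_determinism(self, small_dataset, tiny_settings):
        a = fit_model(small_dataset, canonical_regime("uniform"), tiny_settings)
        b = fit_model(small_dataset, canonical_regime("uniform"), tiny_settings)
        for p in a.summaries:
            assert a.summaries[p] == b.summaries[p]
        assert a.converged == b.converged

    def test_different_seeds_differ(self, small_dataset, tiny_settings):
        other = dataclasses.replace(tiny_settings, seed=8)
        a = fit_model(small_dataset, canonical_regime("uniform"), tiny_settings)
        b = fit_model(small_dataset, canonical_regime("uniform"), other)
        assert a.summary("b1").mean != b.summary("b1").mean

    def test_retained_draw_bookkeeping(self, small_dataset, tiny_settings):
        fit = fit_model(
            small_dataset, canonical_regime("uniform"), tiny_settings, keep_draws=True
        )
        expected = tiny_settings.retained_per_chain
        for p, draws in fit.draws.items():
            assert draws.shape == (tiny_settings.n_chains, expected)

    def test_uniform_support_respected(self, small_dataset, tiny_settings):
        regime = canonical_regime("uniform")
        fit = fit_model(small_dataset, regime, tiny_settings, keep_draws=True)
        for comp, prior in (
            ("sigma2_U", regime.prior_U),
            ("sigma2_eC", regime.prior_eC),
            ("sigma2_eU", regime.prior_eU),
        ):
            draws = fit.draws[comp]
            assert np.all(draws > 0.0)
            assert np.all(draws < prior.upper)

    def test_draws_csv_dump(self, small_dataset, tiny_settings, tmp_path):
        import pandas as pd

        fit = fit_model(
            small_dataset, canonical_regime("uniform"), tiny_settings, keep_draws=True
        )
        path = tmp_path / "draws.csv"
        fit.dump_draws_csv(path)
        frame = pd.read_csv(path)
        assert len(frame) == tiny_settings.retained_total
        assert "sigma2_U" in frame.columns
        bare = fit_model(small_dataset, canonical_regime("uniform"), tiny_settings)
        with pytest.raises(ValueError):
            bare.dump_draws_csv(path)

    def test_interval_ordering(self, small_dataset, tiny_settings):
        fit = fit_model(small_dataset, canonical_regime("gamma"), tiny_settings)
        for summary in fit.summaries.values():
            assert summary.ci_low <= summary.ci_high

    def test_single_arm_rejected(self, tiny_settings):
        data = PartiallyNestedDataset(
            y=np.arange(6, dtype=float),
            x=np.ones(6, dtype=int),
            group=np.array([1, 1, 1, 2, 2, 2]),
        )
        with pytest.raises(ValueError, match="arm"):
            fit_model(data, canonical_regime("uniform"), tiny_settings)

    def test_monotone_relabelling_and_row_order_invariance(
        self, small_dataset, tiny_settings
    ):
        # relabelling clusters 1..c -> 2,4,6,... (order-preserving) and
        # shuffling whole clusters' row positions leaves the sufficient
        # statistics, and hence the seeded fit, bit-identical
        relabelled = PartiallyNestedDataset(
            y=small_dataset.y,
            x=small_dataset.x,
            group=np.where(
                small_dataset.group > 0, small_dataset.group * 2, small_dataset.group
            ),
        )
        a = fit_model(small_dataset, canonical_regime("uniform"), tiny_settings)
        b = fit_model(relabelled, canonical_regime("uniform"), tiny_settings)
        assert a.summaries == b.summaries

    def test_interval_calibration_for_treatment_effect(self):
        # diffuse priors: the 95% interval for b1 should cover the truth
        # at roughly the nominal rate (99% binomial band at 60 replicates)
        n_reps, hits = 60, 0
        condition = SimulationCondition(c=8, m=5, rho=0.1)
        wide = PriorRegime(
            prior_U=VariancePrior.uniform(2.3),
            prior_eC=VariancePrior.uniform(6.9),
            prior_eU=VariancePrior.uniform(6.9),
            fixed=FixedEffectPriors(b0_var=100.0, b1_var=100.0),
        )
        settings = ChainSettings(
            n_iter=1200, n_burn=300, thin=3, n_chains=2, seed=0
        )
        for rep in range(n_reps):
            data = generate_dataset(condition, seed=1000 + rep)
            fit = fit_model(
                data, wide, dataclasses.replace(settings, seed=rep)
            )
            s = fit.summary("b1")
            hits += s.ci_low < 0.5 < s.ci_high
        rate = hits / n_reps
        band = 2.58 * math.sqrt(0.95 * 0.05 / n_reps)
        assert rate == pytest.approx(0.95, abs=band + 0.02)
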