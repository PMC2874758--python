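import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import qtlshrink as qs
from qtlshrink.model import ModelSpec
from qtlshrink.sampler import (MappingContext, McmcConfig,
                               gibbs_update_beta, mh_update_position,
                               mh_update_variance, propose_variance,
                               run_chain, _reflect)
from qtlshrink.simdata import Family, FamilyDataset


def _residual_only_context(y_fams, genome, spec, cfg):
    """A reduced model with no QTL component and beta pinned at zero."""
    M = genome.n_markers
    fams = []
    for yv in y_fams:
        s = len(yv)
        fams.append(Family(sire=np.tile([1, 2], (M, 1)),
                           dam=np.tile([1, 2], (M, 1)),
                           offspring=np.tile([1, 2], (s, M, 1)),
                           phenotypes=np.asarray(yv, dtype=float)))
    ds = FamilyDataset(families=fams, genome=genome)
    ctx = MappingContext(ds, spec, config=cfg)
    ctx.state.sigma2[:] = 0.0
    ctx.state.beta[:] = 0.0
    ctx.yc = ctx.y.copy()
    ctx.rebuild()
    return ctx


class TestProposeVariance:
    def test_mean_matching(self, rng):
        props = np.array([propose_variance(2.0, 10.0, rng)[0]
                          for _ in range(100_000)])
        assert np.all(props > 0)
        se = props.std() / np.sqrt(len(props))
        assert abs(props.mean() - 2.0) < 3 * se

    def test_hastings_ratio_antisymmetry(self, rng):
        from qtlshrink.sampler import _sichi2_logpdf
        for a, b, nu in ((0.5, 2.0, 5.0), (1.3, 0.01, 10.0)):
            hr_ab = (_sichi2_logpdf(a, nu, b * (nu - 2) / nu)
                     - _sichi2_logpdf(b, nu, a * (nu - 2) / nu))
            hr_ba = (_sichi2_logpdf(b, nu, a * (nu - 2) / nu)
                     - _sichi2_logpdf(a, nu, b * (nu - 2) / nu))
            assert hr_ab == pytest.approx(-hr_ba)

    def test_nu_must_exceed_two(self, rng):
        with pytest.raises(ValueError):
            propose_variance(1.0, 2.0, rng)


class TestGibbsBeta:
    def test_conditional_mean_is_gls(self, tiny_map, rng):
        y_fams = [rng.normal(1.5, 1.0, 5) for _ in range(6)]
        spec = ModelSpec(q=1, include_polygenic=True)
        ctx = _residual_only_context(y_fams, tiny_map, spec,
                                     McmcConfig(n_iter=10, burnin=1))
        # random positive variances -> non-trivial V; vague prior -> GLS
        ctx.state.sigma2_A = 0.8
        ctx.state.sigma2_e = 1.3
        ctx.rebuild()
        r = np.random.default_rng(5)
        draws = np.array([gibbs_update_beta(ctx, r)[0] for _ in range(4000)])
        import scipy.linalg as sla
        V = sla.block_diag(*[1.3 * np.eye(5) + 0.8 * (np.full((5, 5), .5)
                                                      + .5 * np.eye(5))
                             for _ in range(6)])
        Vi = np.linalg.inv(V)
        X = ctx.X
        gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ ctx.y)[0]
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - gls) < 4 * se

    def test_degenerate_prior_pins_beta(self, tiny_map, rng):
        y_fams = [rng.normal(3.0, 1.0, 4) for _ in range(4)]
        spec = ModelSpec(q=1, include_polygenic=False, beta0=np.array([9.0]),
                         V0=np.array([[1e-12]]))
        ctx = _residual_only_context(y_fams, tiny_map, spec,
                                     McmcConfig(n_iter=10, burnin=1))
        beta = gibbs_update_beta(ctx, np.random.default_rng(0))
        assert beta[0] == pytest.approx(9.0, abs=1e-4)


class TestVarianceUpdate:
    def test_conjugate_posterior_closed_form(self, tiny_map):
        """Residual-only model: M-H draws match the scaled-inv-chi2
        posterior (Kolmogorov-Smirnov)."""
        rng = np.random.default_rng(123)
        y_fams = [rng.normal(0, np.sqrt(1.7), 5) for _ in range(8)]
        spec = ModelSpec(q=1, include_polygenic=False, omega_e=3.0, s2_e=2.0)
        ctx = _residual_only_context(y_fams, tiny_map, spec,
                                     McmcConfig(n_iter=10, burnin=1,
                                                nu_e=10.0))
        y = ctx.y
        n = len(y)
        post_df = 3.0 + n
        post_scale = (3.0 * 2.0 + (y ** 2).sum()) / post_df
        r = np.random.default_rng(7)
        draws = []
        for it in range(42_000):
            mh_update_variance(ctx, "residual", r)
            if it >= 2_000 and it % 20 == 0:
                draws.append(ctx.state.sigma2_e)
        ks = scipy.stats.kstest(
            np.asarray(draws),
            lambda x: scipy.stats.invgamma.cdf(
                x, post_df / 2, scale=post_df * post_scale / 2))
        assert len(draws) == 2_000
        assert ks.pvalue > 0.01

    def test_floor_rejects_tiny_proposals(self, tiny_map, rng):
        y_fams = [rng.normal(0, 1, 4) for _ in range(3)]
        spec = ModelSpec(q=1, include_polygenic=False)
        cfg = McmcConfig(n_iter=10, burnin=1, variance_floor=1e-3, nu=10.0)
        ctx = _residual_only_context(y_fams, tiny_map, spec, cfg)
        ctx.state.sigma2[0] = 2e-3
        ctx.rebuild()
        r = np.random.default_rng(1)
        for _ in range(500):
            mh_update_variance(ctx, ("qtl", 0), r)
            assert ctx.state.sigma2[0] >= 1e-3


class TestPositionUpdate:
    def test_reflection_keeps_bounds(self):
        for x in (-3.0, 105.0, 250.0, 50.0):
            assert 0.0 <= _reflect(x, 0.0, 100.0) <= 100.0
        assert _reflect(-3.0, 0.0, 100.0) == 3.0
        assert _reflect(103.0, 0.0, 100.0) == 97.0

    @given(st.floats(-500.0, 500.0), st.floats(1.0, 300.0))
    @settings(max_examples=100, deadline=None)
    def test_reflection_bounds_property(self, x, hi):
        assert 0.0 <= _reflect(x, 0.0, hi) <= hi

    def test_flat_likelihood_samples_uniform(self, small_dataset):
        """With the QTL variance at zero the position chain must target the
        uniform prior over the chromosome."""
        genome, truth, ds, st = small_dataset
        spec = ModelSpec(q=1, include_polygenic=True)
        cfg = McmcConfig(n_iter=10, burnin=1, k_cm=20.0)
        ctx = MappingContext(ds, spec, config=cfg)
        ctx.state.sigma2[0] = 0.0
        ctx.rebuild()
        r = np.random.default_rng(11)
        draws = []
        for it in range(40_000):
            mh_update_position(ctx, 0, r)
            if it % 20 == 0:
                draws.append(ctx.state.pos[0])
        ks = scipy.stats.kstest(np.asarray(draws), "uniform",
                                args=(0.0, 100.0))
        assert ks.pvalue > 0.01

    def test_proposal_support(self, small_dataset):
        genome, truth, ds, st = small_dataset
        spec = ModelSpec(q=1)
        cfg = McmcConfig(n_iter=10, burnin=1, k_cm=2.0)
        ctx = MappingContext(ds, spec, config=cfg)
        ctx.state.pos[0] = 50.0
        ctx.Pi[0] = ctx.engine.blocks_at(50.0)
        r = np.random.default_rng(2)
        for _ in range(100):
            old = ctx.state.pos[0]
            mh_update_position(ctx, 0, r)
            assert abs(ctx.state.pos[0] - old) <= 2.0 + 1e-12


class TestRunChain:
    def test_sample_counts_match_schedule(self, tiny_map):
        truth = qs.TrueQtlConfig(qtl=[], sigma2_A=0.5, sigma2_e=1.0)
        ds, _ = qs.simulate_dataset(tiny_map, truth, 8, 3, 0)
        spec = ModelSpec(q=2)
        store = run_chain(ds, spec, McmcConfig(n_iter=21_000, burnin=1_000,
                                               thin=10, seed=0))
        assert store.n_samples == 2_000
        store = run_chain(ds, spec, McmcConfig(n_iter=51_000, burnin=1_000,
                                               thin=10, seed=0))
        assert store.n_samples == 5_000

    def test_same_seed_bit_identical(self, small_dataset):
        genome, truth, ds, st = small_dataset
        spec = ModelSpec(q=3)
        cfg = McmcConfig(n_iter=400, burnin=100, thin=10, seed=21)
        a = run_chain(ds, spec, cfg)
        b = run_chain(ds, spec, cfg)
        for field in ("beta", "sigma2", "pos", "sigma2_A", "sigma2_e"):
            np.testing.assert_array_equal(getattr(a, field),
                                          getattr(b, field))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burnin=100)
        with pytest.raises(ValueError):
            McmcConfig(nu=2.0)
        with pytest.raises(ValueError):
            McmcConfig(thin=0)
        with pytest.warns(UserWarning):
            McmcConfig(nu=250.0)
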