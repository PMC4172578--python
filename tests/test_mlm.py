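"""Spectral REML against a dense oracle, GLS marker tests, and scans."""

import numpy as np
import pytest
from scipy import stats

from supergwas import (
    ModelSpec,
    compute_kinship,
    estimate_variance_components,
    glm_scan,
    identity_context,
    make_p3d_context,
    mlm_scan,
)
from supergwas import test_marker_gls
from supergwas.errors import DegenerateFitError, ValidationError
from supergwas.kinship import _centered_columns
from supergwas.mlm import make_lowrank_context
from supergwas.mlm import test_markers_batch as markers_batch

# pytest would otherwise collect the library's test_* functions as tests
gls = test_marker_gls
del test_marker_gls

from _oracles import dense_reml_grid_max, ols_marker_f_test
from conftest import make_matrix, random_instance


class TestModelSpec:
    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValidationError, match="rank"):
            ModelSpec(X=X)

    def test_from_covariates(self):
        spec = ModelSpec.from_covariates(5, np.arange(5.0))
        assert spec.X.shape == (5, 2)
        assert spec.rank == 2


class TestRemlAgainstDenseOracle:
    @pytest.mark.parametrize("trial", range(8))
    def test_matches_dense_grid_small_instances(self, trial):
        rng = np.random.default_rng(7 + trial)
        n = int(rng.integers(10, 21))
        q = 1 if trial % 2 == 0 else 2
        y, spec, K, _ = random_instance(rng, n=n, m=30, h2=0.5, q=q)
        vc = estimate_variance_components(y, spec, K)
        oracle_ll, oracle_delta = dense_reml_grid_max(y, spec.X, K.values)
        assert vc.reml_loglik == pytest.approx(oracle_ll, abs=1e-6)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(42)
        y, spec, K, _ = random_instance(rng, n=15)
        vc1 = estimate_variance_components(y, spec, K)
        vc2 = estimate_variance_components(2.0 * y, spec, K)
        assert vc2.sigma_a2 == pytest.approx(4.0 * vc1.sigma_a2, rel=1e-5)
        assert vc2.sigma_e2 == pytest.approx(4.0 * vc1.sigma_e2, rel=1e-5)
        assert vc2.delta == pytest.approx(vc1.delta, rel=1e-5)

    def test_delta_consistency(self):
        rng = np.random.default_rng(9)
        y, spec, K, _ = random_instance(rng, n=14)
        vc = estimate_variance_components(y, spec, K)
        assert vc.delta == pytest.approx(vc.sigma_e2 / vc.sigma_a2, rel=1e-8)
        assert vc.sigma_a2 >= 0 and vc.sigma_e2 >= 0

    def test_perfectly_explained_trait_degenerate(self):
        rng = np.random.default_rng(3)
        _, spec, K, _ = random_instance(rng, n=12)
        y = 3.0 * spec.X[:, 0]
        with pytest.raises(DegenerateFitError):
            estimate_variance_components(y, spec, K)


class TestGlsMarkerTest:
    def test_identity_context_equals_ols_oracle(self):
        rng = np.random.default_rng(12)
        n = 10
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        w = rng.integers(0, 3, size=n).astype(float)
        ctx = identity_context(ModelSpec(X=X))
        t = gls(ctx, y, w)
        eff, f, p = ols_marker_f_test(y, X, w)
        assert t.effect == pytest.approx(eff, abs=1e-10)
        assert t.f_stat == pytest.approx(f, abs=1e-10)
        assert t.p_value == pytest.approx(p, abs=1e-10)
        assert t.df_den == n - X.shape[1] - 1

    def test_collinear_marker_yields_sentinel(self):
        n = 8
        X = np.ones((n, 1))
        ctx = identity_context(ModelSpec(X=X))
        t = gls(ctx, np.random.default_rng(0).normal(size=n),
                            np.full(n, 1.0))
        assert not t.testable
        assert t.p_value is None and t.f_stat is None
        assert "collinear" in t.reason

    def test_deterministic_for_duplicated_marker(self, small_panel,
                                                 small_trait, small_spec,
                                                 small_kinship):
        vc = estimate_variance_components(small_trait.y, small_spec,
                                          small_kinship)
        ctx = make_p3d_context(vc, small_kinship, small_spec)
        w = small_panel.dosages[:, 3]
        t1 = gls(ctx, small_trait.y, w)
        t2 = gls(ctx, small_trait.y, w)
        assert t1 == t2

    def test_context_reuse_matches_fresh_factorization(self, small_panel,
                                                       small_trait,
                                                       small_spec,
                                                       small_kinship):
        vc = estimate_variance_components(small_trait.y, small_spec,
                                          small_kinship)
        ctx = make_p3d_context(vc, small_kinship, small_spec)
        for j in range(0, 100, 10):
            fresh = make_p3d_context(vc, small_kinship, small_spec)
            t_reused = gls(ctx, small_trait.y,
                                       small_panel.dosages[:, j])
            t_fresh = gls(fresh, small_trait.y,
                                      small_panel.dosages[:, j])
            assert t_reused.f_stat == pytest.approx(t_fresh.f_stat, abs=1e-12)

    def test_lowrank_context_matches_spectral(self, small_panel, small_trait,
                                              small_spec):
        """Woodbury whitening and full eigendecomposition give equal tests."""
        pool = list(range(0, 40))
        K = compute_kinship(small_panel, pool)
        vc = estimate_variance_components(small_trait.y, small_spec, K)
        ctx_spec = make_p3d_context(vc, K, small_spec)
        M, terms = _centered_columns(small_panel, pool)
        ctx_low = make_lowrank_context(vc, M, float(terms.sum()), small_spec)
        W = small_panel.dosages[:, 200:260]
        ids = [f"x{j}" for j in range(W.shape[1])]
        ts = markers_batch(ctx_spec, small_trait.y, W, ids)
        tl = markers_batch(ctx_low, small_trait.y, W, ids)
        for a, b in zip(ts, tl):
            assert a.p_value == pytest.approx(b.p_value, abs=1e-10)
            assert a.f_stat == pytest.approx(b.f_stat, rel=1e-8)

    def test_batch_equals_single_calls(self, small_panel, small_trait,
                                       small_spec, small_kinship):
        vc = estimate_variance_components(small_trait.y, small_spec,
                                          small_kinship)
        ctx = make_p3d_context(vc, small_kinship, small_spec)
        W = small_panel.dosages[:, :25]
        batch = markers_batch(ctx, small_trait.y, W,
                                   small_panel.marker_ids[:25])
        for j, t in enumerate(batch):
            single = gls(ctx, small_trait.y, W[:, j])
            assert t.f_stat == pytest.approx(single.f_stat, abs=1e-10)

class TestScans:
    def test_glm_equals_mlm_with_zero_genetic_variance(self, small_panel,
                                                       small_trait,
                                                       small_spec,
                                                       small_kinship):
        from supergwas.mlm import VarianceComponents

        g = glm_scan(small_trait.y, small_spec, small_panel)
        vc0 = VarianceComponents(sigma_a2=0.0, sigma_e2=1.0, delta=np.inf,
                                 reml_loglik=0.0)
        ctx = make_p3d_context(vc0, small_kinship, small_spec)
        forced = markers_batch(ctx, small_trait.y, small_panel.dosages,
                                    small_panel.marker_ids)
        for a, b in zip(g.tests, forced):
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_single_marker_scan_equals_direct_test(self, small_panel,
                                                   small_trait, small_spec,
                                                   small_kinship):
        G1 = small_panel.subset_markers([7])
        scan = mlm_scan(small_trait.y, small_spec, G1, small_kinship)
        ctx = make_p3d_context(scan.variance_components, small_kinship,
                               small_spec)
        direct = gls(ctx, small_trait.y, G1.dosages[:, 0])
        assert scan.tests[0].p_value == pytest.approx(direct.p_value,
                                                      abs=1e-12)

    def test_scan_is_reproducible(self, small_panel, small_trait, small_spec,
                                  small_kinship):
        s1 = mlm_scan(small_trait.y, small_spec, small_panel, small_kinship)
        s2 = mlm_scan(small_trait.y, small_spec, small_panel, small_kinship)
        np.testing.assert_array_equal(s1.pvalues(), s2.pvalues())

    def test_p3d_tracks_per_marker_reestimation(self):
        """Fixing the variance ratio barely moves the evidence ranking."""
        from supergwas import PopulationModel, simulate_genotypes, \
            simulate_phenotype

        model = PopulationModel(
            chromosomes=[(str(c + 1), 30, 30_000_000) for c in range(5)]
        )
        G = simulate_genotypes(model, n_per_subpop=40, seed=77)
        trait = simulate_phenotype(G, n_qtn=5, h2=0.75, seed=78)
        spec = ModelSpec.from_covariates(G.n_samples)
        K = compute_kinship(G)
        fast = mlm_scan(trait.y, spec, G, K, p3d=True)
        slow = mlm_scan(trait.y, spec, G, K, p3d=False)
        pf, ps = fast.pvalues(), slow.pvalues()
        ok = np.isfinite(pf) & np.isfinite(ps)
        rho = stats.spearmanr(-np.log10(pf[ok]), -np.log10(ps[ok])).statistic
        assert rho >= 0.99
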