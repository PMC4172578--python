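"""Bin partitioning, pseudo-QTN selection, LD and the complementary-kinship scan."""

import numpy as np
import pytest

from supergwas import (
    ModelSpec,
    PseudoQTNSet,
    VariantInfo,
    assign_bins,
    choose_representatives,
    compute_kinship,
    estimate_variance_components,
    glm_scan,
    ld_r2,
    mlm_scan,
    optimize_pseudo_qtns,
    super_scan,
)
from supergwas.errors import ParameterError, SelectionError
from supergwas.mlm import MarkerTest, ScanResult

from conftest import make_matrix


def _variants(positions, chrom="1"):
    return [
        VariantInfo(id=f"v{i}", chromosome=chrom, position=p)
        for i, p in enumerate(positions)
    ]


class TestAssignBins:
    def test_floor_rule(self):
        bins = assign_bins(_variants([1, 999_999, 1_000_001]), b=1_000_000)
        assert bins == {("1", 0): [0, 1], ("1", 1): [2]}

    def test_huge_bin_is_one_per_chromosome(self):
        v = _variants([5, 500]) + _variants([7], chrom="2")
        bins = assign_bins(v, b=10**9)
        assert set(bins) == {("1", 0), ("2", 0)}

    def test_unit_bin_is_one_per_position(self):
        bins = assign_bins(_variants([3, 4, 4, 9]), b=1)
        assert bins[("1", 3)] == [1, 2]
        assert len(bins) == 3

    def test_invalid_bin_size(self):
        with pytest.raises(ParameterError):
            assign_bins(_variants([1]), b=0)


def _scan_with_p(pvalues):
    tests = [
        MarkerTest(marker_id=f"v{i}", effect=0.0, f_stat=1.0, df_num=1,
                   df_den=10, p_value=p)
        if p is not None
        else MarkerTest(marker_id=f"v{i}", effect=None, f_stat=None, df_num=1,
                        df_den=10, p_value=None, reason="untestable")
        for i, p in enumerate(pvalues)
    ]
    return ScanResult(tests=tests, method="glm")


class TestChooseRepresentatives:
    def test_ranked_by_representative_p(self):
        variants = _variants([100, 200, 1_000_100, 1_000_200])
        bins = assign_bins(variants, b=1_000_000)
        scan = _scan_with_p([1e-3, 1e-6, 1e-4, 0.5])
        pset = choose_representatives(bins, scan, s=1, variants=variants)
        assert pset.markers == (1,)  # the 1e-6 marker wins its bin and ranks 1st

    def test_saturation_returns_all_bins(self):
        variants = _variants([100, 1_000_100])
        bins = assign_bins(variants, b=1_000_000)
        pset = choose_representatives(bins, _scan_with_p([0.2, 0.1]), s=10,
                                      variants=variants)
        assert pset.s == 2

    def test_tie_breaks_to_smaller_position(self):
        variants = _variants([900, 500])
        # GenotypeMatrix would sort these; here positions arrive unsorted on purpose
        bins = assign_bins(variants, b=1_000_000)
        pset = choose_representatives(bins, _scan_with_p([0.05, 0.05]), s=1,
                                      variants=variants)
        assert pset.markers == (1,)  # position 500 < 900

    def test_untestable_markers_ineligible(self):
        variants = _variants([100, 200])
        bins = assign_bins(variants, b=1_000_000)
        pset = choose_representatives(bins, _scan_with_p([None, 0.9]), s=1,
                                      variants=variants)
        assert pset.markers == (1,)
        with pytest.raises(SelectionError):
            choose_representatives(bins, _scan_with_p([None, None]), s=1,
                                   variants=variants)


class TestLdR2:
    def test_perfect_correlation_either_sign(self):
        g = np.array([0.0, 1.0, 2.0, 1.0])
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2.0 - g) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        assert ld_r2(np.array([0.0, 0, 1, 2]),
                     np.array([0.0, 1, 1, 2])) == pytest.approx(4 / 5.5,
                                                                abs=1e-10)

    def test_constant_vector_convention(self):
        assert ld_r2(np.array([1.0, 1, 1]), np.array([0.0, 1, 2])) == 0.0


class TestOptimizePseudoQtns:
    def test_single_cell_grid_returned(self, small_panel, small_trait,
                                       small_spec):
        stage1 = glm_scan(small_trait.y, small_spec, small_panel)
        pset, log = optimize_pseudo_qtns(
            small_trait.y, small_spec, small_panel, stage1,
            s_grid=(8,), b_grid=(5_000_000,),
        )
        assert pset.s == 8 and pset.b == 5_000_000
        assert len(log) == 1
        assert np.isfinite(pset.reml_loglik)

    def test_s_capped_at_available_bins(self, small_panel, small_trait,
                                        small_spec):
        stage1 = glm_scan(small_trait.y, small_spec, small_panel)
        # one bin per chromosome -> only 5 bins exist
        pset, log = optimize_pseudo_qtns(
            small_trait.y, small_spec, small_panel, stage1,
            s_grid=(50,), b_grid=(10**9,),
        )
        assert pset.s == 5
        assert log.loc[0, "s_effective"] == 5

    def test_optimized_pool_beats_random_pool(self, small_panel, small_spec):
        """The likelihood-chosen pool explains the trait better than chance."""
        from supergwas import simulate_phenotype

        rng = np.random.default_rng(31)
        wins = 0
        reps = 6
        for rep in range(reps):
            trait = simulate_phenotype(small_panel, n_qtn=5, h2=0.9,
                                       seed=500 + rep)
            stage1 = glm_scan(trait.y, small_spec, small_panel)
            pset, _ = optimize_pseudo_qtns(
                trait.y, small_spec, small_panel, stage1,
                s_grid=(10,), b_grid=(5_000_000,),
            )
            rand = rng.choice(small_panel.n_markers, size=len(pset),
                              replace=False)
            K_rand = compute_kinship(small_panel, rand.tolist())
            ll_rand = estimate_variance_components(
                trait.y, small_spec, K_rand
            ).reml_loglik
            if pset.reml_loglik >= ll_rand:
                wins += 1
        assert wins >= reps - 1


class TestSuperScan:
    def test_never_exclude_limit_equals_mlm(self, small_panel, small_trait,
                                            small_spec):
        pool = tuple(int(j) for j in small_trait.qtn_indices)
        pseudo = PseudoQTNSet(markers=pool, s=len(pool), b=0)
        sup = super_scan(small_trait.y, small_spec, small_panel, pseudo,
                         t=1.01)
        K = compute_kinship(small_panel, list(pool))
        mlm = mlm_scan(small_trait.y, small_spec, small_panel, K)
        np.testing.assert_allclose(sup.pvalues(), mlm.pvalues(), atol=1e-10)
        assert all(t.n_excluded == 0 for t in sup.tests)

    def test_always_exclude_limit_equals_glm(self, small_panel, small_trait,
                                             small_spec):
        pool = tuple(int(j) for j in small_trait.qtn_indices)
        pseudo = PseudoQTNSet(markers=pool, s=len(pool), b=0)
        sup = super_scan(small_trait.y, small_spec, small_panel, pseudo, t=0.0)
        glm = glm_scan(small_trait.y, small_spec, small_panel)
        np.testing.assert_allclose(sup.pvalues(), glm.pvalues(), atol=1e-10)
        assert all(t.n_excluded == len(pool) for t in sup.tests)

    def test_pseudo_qtn_excludes_itself(self, small_panel, small_trait,
                                        small_spec):
        pool = tuple(int(j) for j in small_trait.qtn_indices)
        pseudo = PseudoQTNSet(markers=pool, s=len(pool), b=0)
        sup = super_scan(small_trait.y, small_spec, small_panel, pseudo, t=0.5)
        for j in pool:
            assert sup.tests[j].n_excluded >= 1  # r^2 with itself is 1 >= t

    def test_n_excluded_monotone_in_threshold(self, small_panel, small_trait,
                                              small_spec):
        pool = tuple(int(j) for j in small_trait.qtn_indices)
        pseudo = PseudoQTNSet(markers=pool, s=len(pool), b=0)
        counts = []
        for t in (0.05, 0.2, 0.5, 0.9):
            sup = super_scan(small_trait.y, small_spec, small_panel, pseudo,
                             t=t)
            counts.append(np.array([x.n_excluded for x in sup.tests]))
        for a, b in zip(counts, counts[1:]):
            assert np.all(b <= a)

    def test_scan_kinship_matches_from_scratch_per_marker(self, small_panel,
                                                          small_trait,
                                                          small_spec):
        """Spot-check: a marker's test equals an explicit rebuild of its
        complementary kinship and a fresh GLS test."""
        from supergwas.mlm import make_p3d_context, test_marker_gls
        from supergwas.superscan import _ld_r2_matrix

        pool = [int(j) for j in small_trait.qtn_indices]
        pseudo = PseudoQTNSet(markers=tuple(pool), s=len(pool), b=0)
        t = 0.10
        sup = super_scan(small_trait.y, small_spec, small_panel, pseudo, t=t)
        vc = sup.variance_components
        R2 = _ld_r2_matrix(small_panel.dosages, small_panel.dosages[:, pool])
        for j in [0, 57, 123, pool[0], pool[3]]:
            excl = [pool[i] for i in np.flatnonzero(R2[j] >= t)]
            retained = [q for q in pool if q not in set(excl)]
            if not retained:
                continue
            K_ref = compute_kinship(small_panel, retained)
            ctx = make_p3d_context(vc, K_ref, small_spec)
            ref = test_marker_gls(ctx, small_trait.y,
                                  small_panel.dosages[:, j])
            assert sup.tests[j].p_value == pytest.approx(ref.p_value,
                                                         abs=1e-10)

    def test_empty_pool_rejected(self, small_panel, small_trait, small_spec):
        with pytest.raises(ParameterError):
            super_scan(small_trait.y, small_spec, small_panel,
                       PseudoQTNSet(markers=(), s=0, b=0), t=0.1)
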