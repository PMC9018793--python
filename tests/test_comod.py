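"""Module detection (WGCNA-lite): adjacency, TOM, clustering, eigengenes,
merging, and trait correlation."""

import numpy as np
import pandas as pd
import pytest

from oracles import tom_direct

from epidmr.comod import (GREY, ModuleAssignment, adjacency, corr_pvalue_student,
                          detect_modules, eigengene_matrix, merge_close_modules,
                          module_eigengene, module_trait_correlation,
                          select_top_windows, tom_similarity)
from epidmr.genome import InvalidParameterError


def planted_blocks(n_per_block=50, n_noise=20, n_samples=20, within_r=0.9,
                   seed=13):
    """Two latent-factor blocks plus independent noise windows.

    Returns (profiles, true_labels, factor of block 0). Block windows are
    sqrt(r)*factor + sqrt(1-r)*noise, giving within-block correlation ~ r.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((2, n_samples))
    rows, labels = [], []
    for b in range(2):
        for _ in range(n_per_block):
            rows.append(np.sqrt(within_r) * z[b]
                        + np.sqrt(1 - within_r) * rng.standard_normal(n_samples))
            labels.append(f"block{b}")
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
        labels.append("noise")
    return np.array(rows), np.array(labels), z[0]


class TestSelectTopWindows:
    def test_all_windows_identity(self):
        x = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(select_top_windows(x, 4), [0, 1, 2, 3])

    def test_top_by_mean(self):
        x = np.array([[5.0], [3.0], [9.0]])
        np.testing.assert_array_equal(select_top_windows(x, 2), [0, 2])

    def test_tie_breaks_to_lower_ordinal(self):
        x = np.array([[2.0], [2.0], [1.0]])
        np.testing.assert_array_equal(select_top_windows(x, 1), [0])

    def test_total_depth_mode(self):
        x = np.array([[1.0, 9.0], [4.0, 4.0]])
        np.testing.assert_array_equal(select_top_windows(x, 1, "total_depth"), [0])

    def test_bad_n_top_rejected(self):
        with pytest.raises(InvalidParameterError):
            select_top_windows(np.ones((3, 2)), 0)


class TestAdjacency:
    def test_power_transform_of_known_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 30))
        a = adjacency(x, power=4)
        r = np.corrcoef(x)
        np.testing.assert_allclose(a, np.abs(r) ** 4 + np.eye(6) * (1 - np.abs(np.diag(r)) ** 4),
                                   atol=1e-10)

    def test_identical_and_anticorrelated_profiles_hit_one(self):
        base = np.arange(10.0)
        x = np.vstack([base, base, -base])
        a = adjacency(x, power=4)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(1.0)   # unsigned network

    def test_zero_variance_window_correlates_zero(self):
        x = np.vstack([np.arange(10.0), np.full(10, 3.0)])
        a = adjacency(np.vstack([x, np.arange(10.0) ** 2]), power=4)
        assert a[1, 0] == 0.0 and a[1, 2] == 0.0 and a[1, 1] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            adjacency(np.ones((3, 2)), power=4)


class TestTom:
    def test_two_node_closed_form(self):
        for a12 in (0.0, 0.3, 0.8, 1.0):
            a = np.array([[1.0, a12], [a12, 1.0]])
            assert tom_similarity(a)[0, 1] == pytest.approx(a12, abs=1e-12)

    def test_complete_graph_all_one(self):
        a = np.ones((5, 5))
        np.testing.assert_allclose(tom_similarity(a), 1.0)

    def test_identity_adjacency_maps_to_identity(self):
        np.testing.assert_array_equal(tom_similarity(np.eye(4)), np.eye(4))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.random((10, 10))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(tom_similarity(a), tom_direct(a), atol=1e-12)

    def test_entries_in_unit_interval(self):
        rng = np.random.default_rng(9)
        r = rng.random((30, 30))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        t = tom_similarity(a)
        assert np.all((t >= 0) & (t <= 1 + 1e-12))

    def test_asymmetric_rejected(self):
        a = np.array([[1.0, 0.2], [0.6, 1.0]])
        with pytest.raises(InvalidParameterError):
            tom_similarity(a)


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        profiles, truth, _ = planted_blocks()
        tom = tom_similarity(adjacency(profiles, 4))
        assign = detect_modules(1.0 - tom, min_module_size=30)
        mods = assign.modules()
        assert len(mods) == 2
        # each block maps onto one module with >= 95% agreement
        for b in ("block0", "block1"):
            labs = assign.labels[truth == b]
            top = pd.Series(labs).value_counts()
            assert top.index[0] != GREY
            assert top.iloc[0] / len(labs) >= 0.95

    def test_independent_noise_mostly_grey(self):
        rng = np.random.default_rng(4)
        profiles = rng.standard_normal((100, 20))
        tom = tom_similarity(adjacency(profiles, 4))
        assign = detect_modules(1.0 - tom, min_module_size=30)
        assert (assign.labels == GREY).mean() >= 0.8

    def test_min_size_above_n_gives_all_grey(self):
        rng = np.random.default_rng(1)
        profiles = rng.standard_normal((10, 12))
        tom = tom_similarity(adjacency(profiles, 4))
        assign = detect_modules(1.0 - tom, min_module_size=30)
        assert (assign.labels == GREY).all()

    def test_deterministic(self):
        profiles, _, _ = planted_blocks(seed=3)
        tom = tom_similarity(adjacency(profiles, 4))
        a1 = detect_modules(1.0 - tom, 30)
        a2 = detect_modules(1.0 - tom, 30)
        np.testing.assert_array_equal(a1.labels, a2.labels)


class TestModuleEigengene:
    def test_shared_profile_recovered(self):
        profile = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        x = np.tile(profile, (6, 1))
        eig = module_eigengene(x, np.arange(6))
        expected = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig, expected, atol=1e-10)

    def test_orientation_invariant_to_sign_flips(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((10, 15)) + np.linspace(-1, 1, 15)
        e1 = module_eigengene(x, np.arange(10))
        e2 = module_eigengene(-x, np.arange(10))
        for e, mat in ((e1, x), (e2, -x)):
            z = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
            assert np.corrcoef(e, z.mean(axis=0))[0, 1] >= 0

    def test_two_window_module_is_standardized_average(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal(20)
        x = np.vstack([base + 0.05 * rng.standard_normal(20),
                       base + 0.05 * rng.standard_normal(20)])
        eig = module_eigengene(x, np.arange(2))
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        avg = z.mean(axis=0)
        avg = (avg - avg.mean()) / avg.std()
        assert abs(np.corrcoef(eig, avg)[0, 1]) > 0.999

    def test_unit_variance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((5, 12))
        assert module_eigengene(x, np.arange(5)).std() == pytest.approx(1.0)

    def test_single_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            module_eigengene(np.ones((3, 1)), np.arange(3))


class TestMergeCloseModules:
    def _assignment_with_two_modules(self, r_between, seed=0):
        rng = np.random.default_rng(seed)
        shared = rng.standard_normal(24)
        rows, labels = [], []
        for m, mix in (("turquoise", r_between), ("blue", 1.0)):
            factor = np.sqrt(mix) * shared + np.sqrt(1 - mix) * rng.standard_normal(24)
            for _ in range(40):
                rows.append(factor + 0.05 * rng.standard_normal(24))
                labels.append(m)
        return np.array(rows), ModuleAssignment(np.array(labels, dtype=object))

    def test_highly_correlated_modules_merge(self):
        profiles, assign = self._assignment_with_two_modules(r_between=0.95)
        merged = merge_close_modules(profiles, assign, 0.25)
        assert len(merged.modules()) == 1

    def test_distinct_modules_stay(self):
        profiles, assign = self._assignment_with_two_modules(r_between=0.25)
        merged = merge_close_modules(profiles, assign, 0.25)
        assert len(merged.modules()) == 2

    def test_idempotent_at_fixed_point(self):
        profiles, assign = self._assignment_with_two_modules(r_between=0.25)
        m1 = merge_close_modules(profiles, assign, 0.25)
        m2 = merge_close_modules(profiles, m1, 0.25)
        np.testing.assert_array_equal(m1.labels, m2.labels)


class TestModuleTraitCorrelation:
    def test_corr_pvalue_student_reference_value(self):
        # n=5, r=0.9: t = 0.9*sqrt(3)/sqrt(0.19) = 3.576, p ~ 0.0374
        assert corr_pvalue_student(0.9, 5) == pytest.approx(0.0374, abs=1e-3)

    def test_perfect_correlation_p_zero(self):
        assert corr_pvalue_student(1.0, 10) == 0.0
        assert corr_pvalue_student(-1.0, 10) == 0.0

    def test_zero_correlation_p_one(self):
        assert corr_pvalue_student(0.0, 10) == pytest.approx(1.0)

    def test_table_against_direct_formula(self):
        rng = np.random.default_rng(11)
        eg = pd.DataFrame({"turquoise": rng.standard_normal(20)})
        traits = pd.DataFrame({"exposed": rng.integers(0, 2, 20).astype(float),
                               "flat": np.ones(20)})
        out = module_trait_correlation(eg, traits)
        row = out[out["trait"] == "exposed"].iloc[0]
        r_direct = np.corrcoef(eg["turquoise"], traits["exposed"])[0, 1]
        assert row["r"] == pytest.approx(r_direct, abs=1e-12)
        assert row["p"] == pytest.approx(corr_pvalue_student(r_direct, 20), abs=1e-12)
        assert np.isnan(out[out["trait"] == "flat"].iloc[0]["r"])

    def test_planted_trait_linked_block_recovered(self):
        profiles, truth, factor = planted_blocks(n_samples=20, seed=21)
        trait = (factor > np.median(factor)).astype(float)
        tom = tom_similarity(adjacency(profiles, 4))
        assign = detect_modules(1.0 - tom, 30)
        eg = eigengene_matrix(profiles, assign)
        out = module_trait_correlation(eg, pd.DataFrame({"trait": trait}))
        best = out.loc[out["r"].abs().idxmax()]
        assert abs(best["r"]) >= 0.8 and best["p"] < 0.01
        # and the best module is the block-0 module
        block0_mod = pd.Series(assign.labels[truth == "block0"]).value_counts().index[0]
        assert best["module"] == block0_mod
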