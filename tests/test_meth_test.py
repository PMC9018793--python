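"""NB exact test, dispersion estimation, log fold change, and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from oracles import bh_hand, binomial_exact_p

from epidmr.genome import InvalidParameterError
from epidmr.meth_test import (bh_fdr, equalize_libraries, estimate_dispersion,
                              exact_test_window, logfc)
from epidmr.meth_test import test_all_windows as run_window_tests
from epidmr.synthdata import StudyDesign, simulate_counts
from epidmr.windows import CountMatrix, make_windows
from epidmr.genome import GenomeDef


def _null_counts(n_windows, n_per_group, phi, mu, seed):
    genome = GenomeDef(["c"], [n_windows * 1000])
    grid = make_windows(genome, 1000)
    ga = [f"a{i}" for i in range(n_per_group)]
    gb = [f"b{i}" for i in range(n_per_group)]
    samples = pd.DataFrame({"sample_id": ga + gb, "exposure": "x"})
    d = StudyDesign(samples=samples, groups={"cmp": (ga, gb)},
                    library_size_targets={s: mu * n_windows for s in ga + gb},
                    dispersion=phi, baseline_mu=float(mu), seed=seed)
    return simulate_counts(d, grid), ga, gb


class TestExactTest:
    def test_symmetric_mode_is_p_one(self):
        assert exact_test_window(3, 3, 1, 1, 0.0) == 1.0

    def test_six_zero_binomial_tail(self):
        # Binomial(6, 1/2): P(0) + P(6) = 2/64
        assert exact_test_window(6, 0, 1, 1, 0.0) == pytest.approx(0.03125, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 1.0])
    def test_equal_sums_equal_groups_p_one(self, phi):
        assert exact_test_window(7, 7, 3, 3, phi) == pytest.approx(1.0)

    def test_zero_total_p_one_by_convention(self):
        assert exact_test_window(0, 0, 2, 2, 0.5) == 1.0

    @pytest.mark.parametrize("na,nb", [(1, 1), (2, 3), (6, 6)])
    def test_phi_zero_matches_binomial_oracle(self, na, nb):
        for T in range(0, 26):
            for a in range(T + 1):
                got = exact_test_window(a, T - a, na, nb, 0.0)
                want = binomial_exact_p(a, T - a, na, nb)
                assert got == pytest.approx(want, abs=1e-12), (a, T - a)

    def test_group_swap_symmetry(self):
        for phi in (0.0, 0.2):
            for (a, b) in [(10, 3), (0, 7), (25, 11)]:
                assert exact_test_window(a, b, 4, 4, phi) == \
                    pytest.approx(exact_test_window(b, a, 4, 4, phi), abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            exact_test_window(-1, 3, 1, 1, 0.0)

    def test_overdispersion_widens_the_null(self):
        # same split, larger phi => less surprising
        p0 = exact_test_window(30, 10, 3, 3, 0.0)
        p1 = exact_test_window(30, 10, 3, 3, 0.5)
        assert p1 > p0


class TestLogfc:
    @pytest.mark.parametrize("args,expected", [
        ((20, 10, 100, 100, 0.0), 1.0),
        ((15, 15, 100, 100, 0.0), 0.0),
        ((0, 15, 100, 100, 0.5), np.log2(0.5 / 15.5)),
    ])
    def test_values(self, args, expected):
        assert logfc(*args) == pytest.approx(expected, abs=1e-9)

    def test_undefined_when_all_zero(self):
        with pytest.raises(InvalidParameterError):
            logfc(0, 0, 100, 100, 0.0)

    def test_library_normalization(self):
        # same raw sums, A library twice as deep => logFC -1
        assert logfc(10, 10, 200, 100, 0.0) == pytest.approx(-1.0)


class TestBhFdr:
    def test_hand_example(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.8])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.8 / 30, 0.8], atol=1e-12)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_hand_step_up_and_dominates_p(self, p):
        q = bh_fdr(p)
        np.testing.assert_allclose(q, bh_hand(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)   # monotone in p order


class TestDispersionEstimation:
    def test_zero_variance_moments_floor(self):
        cm = CountMatrix(np.tile([[10, 10, 10, 10, 10, 10]], (50, 1)),
                         [f"s{i}" for i in range(6)], np.full(6, 500))
        est = estimate_dispersion(cm, ["s0", "s1", "s2"], ["s3", "s4", "s5"], "moments")
        assert est.phi == 0.0

    def test_poisson_data_moments_near_zero(self):
        cm, ga, gb = _null_counts(5000, 5, phi=0.0, mu=20.0, seed=8)
        est = estimate_dispersion(cm, ga, gb, "moments")
        assert est.phi <= 0.02

    def test_grid_cml_recovers_planted_dispersion(self):
        cm, ga, gb = _null_counts(5000, 6, phi=0.2, mu=50.0, seed=15)
        est = estimate_dispersion(cm, ga, gb, "grid_cml")
        assert 0.1 <= est.phi <= 0.4

    def test_grid_cml_without_replication_rejected(self):
        cm = CountMatrix(np.array([[5, 6]]), ["a", "b"], np.array([5, 6]))
        with pytest.raises(InvalidParameterError):
            estimate_dispersion(cm, ["a"], ["b"], "grid_cml")


class TestEqualizeLibraries:
    def test_scales_to_geometric_mean(self):
        counts = np.array([[100, 100], [50, 50]])
        eq, geo = equalize_libraries(counts, np.array([1000, 4000]))
        assert geo == pytest.approx(2000.0)
        np.testing.assert_array_equal(eq[:, 0], [200, 100])
        np.testing.assert_array_equal(eq[:, 1], [50, 25])


class TestTestAllWindows:
    def test_null_type_one_error(self):
        cm, ga, gb = _null_counts(2000, 6, phi=0.1, mu=10.0, seed=21)
        stats = run_window_tests(cm, ga, gb, dispersion="grid_cml")
        frac = float((stats["pvalue"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_label_permutation_leaves_null_p_distribution(self):
        cm, ga, gb = _null_counts(2000, 6, phi=0.1, mu=10.0, seed=22)
        p1 = run_window_tests(cm, ga, gb, dispersion=0.1)["pvalue"]
        mixed_a, mixed_b = ga[:3] + gb[:3], ga[3:] + gb[3:]
        p2 = run_window_tests(cm, mixed_a, mixed_b, dispersion=0.1)["pvalue"]
        assert ks_2samp(p1, p2).pvalue > 0.001

    def test_planted_effect_detected_with_power(self):
        genome = GenomeDef(["c"], [500 * 1000])
        grid = make_windows(genome, 1000)
        ga = [f"a{i}" for i in range(6)]
        gb = [f"b{i}" for i in range(6)]
        samples = pd.DataFrame({"sample_id": ga + gb, "exposure": "x"})
        from epidmr.synthdata import PlantedDMR
        d = StudyDesign(samples=samples, groups={"cmp": (ga, gb)},
                        library_size_targets={s: 100.0 * 500 for s in ga + gb},
                        planted_dmrs=[PlantedDMR(100, 150, 2.0, "cmp")],
                        dispersion=0.05, baseline_mu=100.0, seed=30)
        cm = simulate_counts(d, grid)
        stats = run_window_tests(cm, ga, gb, dispersion="grid_cml")
        planted_p = stats["pvalue"].to_numpy()[100:150]
        assert (planted_p < 1e-4).mean() >= 0.9

    def test_overlapping_groups_rejected(self):
        cm, ga, gb = _null_counts(10, 2, phi=0.0, mu=5.0, seed=1)
        with pytest.raises(InvalidParameterError):
            run_window_tests(cm, ga, ga)

    def test_deterministic(self):
        cm, ga, gb = _null_counts(200, 3, phi=0.1, mu=10.0, seed=5)
        s1 = run_window_tests(cm, ga, gb, dispersion="moments")
        s2 = run_window_tests(cm, ga, gb, dispersion="moments")
        pd.testing.assert_frame_equal(s1, s2)
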