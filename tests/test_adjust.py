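"""Six-method FDR estimation, adjusted p-values, and step rejection."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from fdrkit import (
    RawPValueSet,
    adjusted_pvalues,
    c_by,
    fdr_estimates,
    p_fdr,
    step_rejection_set,
)
from fdrkit.adjust import canonical_method

from conftest import TABLE1_ADJ, TABLE1_FDR, TABLE1_P

ALL_METHODS = ["BH", "BY", "Bonferroni", "Sidak", "Holm", "Hochberg"]
STEP_METHODS = ["BH", "BY", "Holm", "Hochberg"]

# statsmodels tokens for the same six procedures — the independent cross-check
SM_TOKENS = {
    "BH": "fdr_bh",
    "BY": "fdr_by",
    "Bonferroni": "bonferroni",
    "Sidak": "sidak",
    "Holm": "holm",
    "Hochberg": "simes-hochberg",
}


def random_pvector(rng, max_m=50):
    m = int(rng.integers(1, max_m + 1))
    return rng.uniform(size=m)


class TestCBy:
    @pytest.mark.parametrize("m, expected", [(1, 1.0), (2, 1.5), (5, 1 + 1 / 2 + 1 / 3 + 1 / 4 + 1 / 5)])
    def test_harmonic_sum(self, m, expected):
        assert c_by(m) == pytest.approx(expected, rel=1e-12)

    def test_negative_corr_uses_same_harmonic_sum(self):
        assert c_by(10, "negative") == c_by(10, "positive")

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            c_by(0)


class TestFdrEstimates:
    def test_table1_bh_column(self, table1_pset):
        est = fdr_estimates(table1_pset, "BH", pi0=1.0)
        np.testing.assert_allclose(np.round(est, 3), TABLE1_FDR)

    def test_bh_closed_form_no_ties(self, rng):
        p = rng.uniform(size=30)
        pset = RawPValueSet(p)
        ranks = pset.ranks()
        np.testing.assert_allclose(fdr_estimates(pset, "BH"), np.minimum(p * 30 / ranks, 1))

    def test_single_pvalue_identity(self):
        for method in ALL_METHODS:
            np.testing.assert_allclose(fdr_estimates([0.3], method), [0.3])

    def test_by_scales_bh_by_harmonic_sum(self, table1_pset):
        bh = fdr_estimates(table1_pset, "BH")
        by = fdr_estimates(table1_pset, "BY")
        np.testing.assert_allclose(by, np.minimum(bh * c_by(5), 1.0))
        assert by[0] == pytest.approx(0.025 * c_by(5), abs=1e-10)

    def test_fdr_column_is_non_monotone(self, table1_pset):
        # the step-free estimates dip and rise: 0.122 > 0.083 > 0.064 < 0.700
        est = fdr_estimates(table1_pset, "BH")
        assert est[1] > est[2] > est[3] < est[4]

    def test_pi0_scales_estimates(self, table1_pset):
        full = fdr_estimates(table1_pset, "BH", pi0=1.0)
        half = fdr_estimates(table1_pset, "BH", pi0=0.5)
        np.testing.assert_allclose(half, np.minimum(full * 0.5, 1.0))

    def test_outputs_capped_in_unit_interval(self, rng):
        for method in ALL_METHODS:
            for _ in range(20):
                est = fdr_estimates(random_pvector(rng), method)
                assert np.all((0 <= est) & (est <= 1))

    def test_invalid_pi0(self, table1_pset):
        with pytest.raises(ValueError, match="pi0"):
            fdr_estimates(table1_pset, "BH", pi0=1.5)


class TestAdjustedPValues:
    def test_table1_bh_column(self, table1_pset):
        adj = adjusted_pvalues(table1_pset, "BH")
        np.testing.assert_allclose(np.round(adj, 3), TABLE1_ADJ)

    def test_hochberg_brute_force(self, table1_pset):
        # min over j >= i of p_(j) * (m + 1 - j), frozen from direct enumeration
        adj = adjusted_pvalues(table1_pset, "Hochberg")
        np.testing.assert_allclose(np.round(adj, 3), [0.025, 0.102, 0.102, 0.102, 0.700])

    def test_holm_brute_force(self, table1_pset):
        # max over j <= i of p_(j) * (m + 1 - j), frozen from direct enumeration
        adj = adjusted_pvalues(table1_pset, "Holm")
        np.testing.assert_allclose(np.round(adj, 3), [0.025, 0.196, 0.196, 0.196, 0.700])

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_matches_statsmodels(self, method, rng):
        for _ in range(25):
            p = random_pvector(rng)
            ours = adjusted_pvalues(p, method)
            theirs = multipletests(p, alpha=0.05, method=SM_TOKENS[method])[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_monotone_in_rank_for_step_methods(self, rng):
        for method in STEP_METHODS:
            for _ in range(10):
                p = random_pvector(rng)
                adj = adjusted_pvalues(p, method)
                assert np.all(np.diff(adj[np.argsort(p, kind="stable")]) >= -1e-12)

    def test_power_orderings(self, rng):
        # Holm <= Bonferroni (uniformly more powerful); Hochberg <= Holm
        for _ in range(50):
            p = random_pvector(rng)
            bon = adjusted_pvalues(p, "Bonferroni")
            holm = adjusted_pvalues(p, "Holm")
            hoch = adjusted_pvalues(p, "Hochberg")
            assert np.all(holm <= bon + 1e-12)
            assert np.all(hoch <= holm + 1e-12)

    def test_by_with_unit_cm_equals_bh(self):
        # c(1) = 1 trivially; more usefully, BY/BH ratio is exactly c(m) before capping
        p = np.array([0.001, 0.002, 0.003])
        bh = adjusted_pvalues(p, "BH")
        by = adjusted_pvalues(p, "BY")
        np.testing.assert_allclose(by, np.minimum(bh * c_by(3), 1.0))

    def test_ties_share_adjusted_value(self):
        p = np.array([0.02, 0.02, 0.02, 0.8])
        for method in STEP_METHODS:
            adj = adjusted_pvalues(p, method)
            assert adj[0] == adj[1] == adj[2]


class TestStepRejection:
    def test_table1_gamma_005_selects_first_only(self, table1_pset):
        k, flags = step_rejection_set(table1_pset, 0.05, "BH")
        assert k == 1
        np.testing.assert_array_equal(flags, [True, False, False, False, False])

    def test_table1_gamma_007_selects_first_four(self, table1_pset):
        k, flags = step_rejection_set(table1_pset, 0.07, "BH")
        assert k == 4
        np.testing.assert_array_equal(flags, [True, True, True, True, False])

    @pytest.mark.parametrize("method", STEP_METHODS + ["Bonferroni", "Sidak"])
    def test_equivalence_with_adjusted_pvalues(self, method, rng):
        for _ in range(100):
            p = random_pvector(rng)
            gamma = float(rng.uniform(0.01, 0.3))
            _, flags = step_rejection_set(p, gamma, method)
            np.testing.assert_array_equal(flags, adjusted_pvalues(p, method) <= gamma)

    def test_invalid_gamma(self, table1_pset):
        with pytest.raises(ValueError, match="gamma"):
            step_rejection_set(table1_pset, 0.0, "BH")


class TestPFdr:
    def test_table1_full_result(self, table1_pset):
        res = p_fdr(table1_pset, method="BH", threshold=0.05)
        np.testing.assert_allclose(np.round(res.fdrs, 3), TABLE1_FDR)
        np.testing.assert_allclose(np.round(res.adjusted_p, 3), TABLE1_ADJ)
        np.testing.assert_allclose(res.raw_p, TABLE1_P)
        np.testing.assert_array_equal(
            res.reject, ["Reject.H0", "FTR.H0", "FTR.H0", "FTR.H0", "FTR.H0"]
        )
        assert res.pi0 == 1.0 and res.threshold == 0.05 and res.method == "BH"

    def test_single_pvalue_all_methods_identity(self):
        for method in ALL_METHODS:
            res = p_fdr([0.04], method=method, threshold=0.05)
            np.testing.assert_allclose(res.fdrs, [0.04])
            np.testing.assert_allclose(res.adjusted_p, [0.04])
            np.testing.assert_array_equal(res.reject, ["Reject.H0"])

    def test_bonferroni_fdr_equals_adjusted(self, table1_pset):
        res = p_fdr(table1_pset, method="Bon")
        np.testing.assert_allclose(res.fdrs, res.adjusted_p)

    def test_sidak_fdr_equals_adjusted(self, table1_pset):
        res = p_fdr(table1_pset, method="Sidak")
        np.testing.assert_allclose(res.fdrs, res.adjusted_p)

    def test_reject_matches_adjusted_threshold(self, rng):
        p = rng.uniform(size=60)
        res = p_fdr(p, method="Hoch", threshold=0.1)
        np.testing.assert_array_equal(
            res.reject == "Reject.H0", res.adjusted_p <= 0.1
        )

    def test_lower_bound_column_optional(self, table1_pset):
        res = p_fdr(table1_pset, include_lower_bound=True)
        assert res.lower_bound is not None
        np.testing.assert_allclose(np.round(res.lower_bound, 3), [0.019, 0.126, 0.128, 0.130, 0.481])

    def test_to_frame_sorting_orders_by_fdr(self, table1_pset):
        df = p_fdr(table1_pset).to_frame(sort_results=True)
        assert np.all(np.diff(df["fdr"].to_numpy()) >= 0)

    def test_to_frame_just_fdr_single_column(self, table1_pset):
        df = p_fdr(table1_pset).to_frame(just_fdr=True)
        assert list(df.columns) == ["fdr"]

    def test_method_aliases(self):
        assert canonical_method("Bon") == "Bonferroni"
        assert canonical_method("Hoch") == "Hochberg"
        with pytest.raises(ValueError, match="unknown adjustment method"):
            canonical_method("qvalue")
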