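"""Modified Wilcoxon test: rank sums, Z values, p-values, sign accounting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ecdselect import (
    classify_cds,
    corrected_z,
    fold_change,
    misclassification,
    mwt_pvalue,
    mwt_table,
    signed_rank_sums,
    z_value,
)
from ecdselect.mwt import score_differences


class TestSignedRankSums:
    def test_all_positive_hand_example(self):
        assert signed_rank_sums([0.75, 1.50, 2.25]) == (6.0, 0.0)

    def test_mixed_signs(self):
        assert signed_rank_sums([-1, 2]) == (2.0, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = rng.normal(size=10)
            r_plus, r_minus = signed_rank_sums(d)
            # independent oracle: sort |d|, walk the order, sum positions
            order = np.argsort(np.abs(d))
            oracle_plus = sum(
                rank for rank, idx in enumerate(order, start=1) if d[idx] > 0
            )
            assert r_plus == oracle_plus
            assert r_plus + r_minus == 10 * 11 / 2

    def test_ties_get_average_ranks(self):
        # |d| = (1, 1, 2): tied pair shares rank 1.5
        r_plus, r_minus = signed_rank_sums([1.0, -1.0, 2.0])
        assert r_plus == pytest.approx(1.5 + 3)
        assert r_minus == pytest.approx(1.5)

    def test_zeros_dropped_before_ranking(self):
        assert signed_rank_sums([0.0, 1.0, -2.0]) == (1.0, 2.0)

    def test_all_zero_is_degenerate(self):
        assert signed_rank_sums([0.0, 0.0, 0.0]) == (0.0, 0.0)


class TestZValue:
    def test_n10_rmin0(self):
        assert z_value(0, 10) == pytest.approx(-27.5 / np.sqrt(96.25), abs=1e-4)
        assert z_value(0, 10) == pytest.approx(-2.8031, abs=1e-4)

    def test_zero_at_the_mean(self):
        assert z_value(10 * 11 / 4, 10) == 0.0

    def test_n27_rmin0(self):
        assert z_value(0, 27) == pytest.approx(-4.5407, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            z_value(0, 1)


class TestCorrectedZ:
    def test_none_is_identity(self):
        z = z_value(3, 10)
        assert corrected_z(z, 10, "none") == z

    def test_continuity_n10(self):
        z = corrected_z(z_value(0, 10), 10, "continuity", r_min=0)
        assert z == pytest.approx(-27.0 / 9.8107, abs=1e-4)
        assert z == pytest.approx(-2.7521, abs=1e-4)

    def test_shrink_n28(self):
        z = corrected_z(z_value(0, 28), 28, "shrink:3")
        assert z_value(0, 28) == pytest.approx(-4.6226, abs=1e-3)
        assert z == pytest.approx(-4.6226 * np.sqrt(25 / 28), abs=1e-3)
        assert z == pytest.approx(-4.368, abs=1e-3)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="unknown z-correction"):
            corrected_z(-1.0, 10, "bogus")


class TestPValue:
    def test_z_zero_gives_one(self):
        assert mwt_pvalue(0.0) == 1.0

    def test_normal_tail(self):
        assert mwt_pvalue(-2.8031) == pytest.approx(0.00506, abs=1e-4)

    @given(st.floats(min_value=-8, max_value=-0.01),
           st.floats(min_value=-8, max_value=-0.01))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_z(self, z1, z2):
        lo, hi = sorted([z1, z2])
        assert mwt_pvalue(lo) <= mwt_pvalue(hi)


class TestSignAccounting:
    def test_misclassification_counts_minority(self):
        assert misclassification(5, 1, 6) == (1, pytest.approx(1 / 6))
        assert misclassification(6, 0, 6) == (0, 0.0)

    def test_two_errors_in_27_is_about_seven_percent(self):
        count, rate = misclassification(25, 2, 27)
        assert count == 2
        assert rate * 100 == pytest.approx(7.4, abs=0.05)
        assert round(rate * 100) == 7

    def test_cds_requires_unanimous_strict_signs(self):
        assert classify_cds(3, 0, 0, 3) == "CDS"
        assert classify_cds(0, 27, 0, 27) == "CDS"
        assert classify_cds(26, 1, 0, 27) == "IDS"
        assert classify_cds(26, 0, 1, 27) == "IDS"  # a zero breaks CDS

    def test_misclassification_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        d = rng.normal(size=(20, 9))
        base = score_differences(d)["misclassification_count"]
        transformed = score_differences(np.expm1(d) * 3.0)  # strictly increasing
        np.testing.assert_array_equal(
            base, transformed["misclassification_count"]
        )


class TestFoldChange:
    def test_hand_example(self):
        fc, direction = fold_change([1, 2, 3], [2, 4, 6])
        assert fc == pytest.approx(2.0)
        assert direction == "up"

    def test_identical_classes(self):
        fc, _ = fold_change([1, 2, 3], [1, 2, 3])
        assert fc == pytest.approx(1.0)

    def test_swap_inverts_direction_only(self):
        fc_up, d_up = fold_change([1, 2, 3], [2, 4, 6])
        fc_dn, d_dn = fold_change([2, 4, 6], [1, 2, 3])
        assert fc_up == pytest.approx(fc_dn)
        assert (d_up, d_dn) == ("up", "down")


class TestScoredTable:
    def test_rank_sum_conservation(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=(200, 13))
        table = score_differences(d)
        n_eff = 13 - table["n_zero_diffs"]
        np.testing.assert_allclose(
            table["r_plus"] + table["r_minus"], n_eff * (n_eff + 1) / 2
        )

    def test_cds_pvalue_depends_only_on_n(self):
        # any zero-misclassification, tie-free feature at fixed N shares one p
        rng = np.random.default_rng(2)
        d = np.abs(rng.normal(size=(50, 11))) + 1e-6
        d[25:] *= -1  # half all-negative
        table = score_differences(d)
        assert (table["misclassification_count"] == 0).all()
        assert table["p_mwt"].nunique() == 1

    def test_degenerate_all_zero_feature(self):
        table = score_differences(np.zeros((1, 5)))
        assert table.loc[0, "p_mwt"] == 1.0
        assert np.isnan(table.loc[0, "z_value"])
        assert bool(table.loc[0, "degenerate"])
        assert table.loc[0, "cds_flag"] == "IDS"

    def test_full_table_on_small_matrix(self, small_pem):
        table = mwt_table(small_pem)
        ga = table.set_index("feature_id").loc["gA"]
        assert ga["cds_flag"] == "CDS"
        assert ga["fold_change"] == pytest.approx(2.0)
        assert ga["direction"] == "up"
        gb = table.set_index("feature_id").loc["gB"]
        assert gb["cds_flag"] == "IDS"


def _exact_two_sided_p(d: np.ndarray) -> float:
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    a = np.abs(d)
    ranks = stats.rankdata(a)
    n = len(d)
    observed = min(signed_rank_sums(d))
    count = 0
    total = 0
    for signs in itertools.product([1, -1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s > 0)
        w_min = min(w, n * (n + 1) / 2 - w)
        total += 1
        if w_min <= observed:
            count += 1
    return count / total


@pytest.mark.parametrize("n", [6, 8, 10, 12])
def test_normal_approximation_matches_exact_enumeration_at_rmin0(n):
    """Uncorrected normal p at complete separation vs the exact permutation
    law; the approximation is adequate (within 0.01) from n = 6 up, while at
    n <= 5 the discrete law is too coarse for any normal tail to track."""
    d = np.arange(1.0, n + 1)  # all positive, tie-free: r_min = 0
    table = score_differences(d[None, :], z_correction="none")
    p_normal = float(table.loc[0, "p_mwt"])
    p_exact = _exact_two_sided_p(d)
    assert p_exact == pytest.approx(2 / 2**n)
    assert abs(p_normal - p_exact) < 0.01


def test_agrees_with_scipy_wilcoxon_normal_approximation():
    """Independent cross-check of the signed-rank machinery against scipy."""
    rng = np.random.default_rng(19)
    for _ in range(10):
        d = rng.normal(0.3, 1.0, size=30)
        table = score_differences(d[None, :], z_correction="none")
        res = stats.wilcoxon(d, correction=False, method="approx")
        assert table.loc[0, "p_mwt"] == pytest.approx(res.pvalue, rel=1e-6)
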