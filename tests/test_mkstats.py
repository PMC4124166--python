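"""MK statistic family: printed-value reproduction, identities, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineagemk import (
    GenePolymorphism,
    MKCounts,
    alpha_adaptive,
    bh_fdr,
    direction_of_selection,
    fixation_index,
    mk_gtest_williams,
    mk_test,
    neutrality_index,
    neutrality_index_tg,
    pool_counts,
    stratum_summary,
)

from _oracles import mutual_information_g


class TestRatioStatistics:
    def test_fixation_index_worked_examples(self):
        assert fixation_index(MKCounts(13, 1, 5, 4)) == pytest.approx(10.4)
        assert fixation_index(MKCounts(7, 1, 2, 4)) == pytest.approx(14.0)
        assert fixation_index(MKCounts(1, 1, 1, 1)) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "c", [MKCounts(0, 1, 1, 1), MKCounts(1, 0, 1, 1), MKCounts(1, 1, 0, 1), MKCounts(1, 1, 1, 0)]
    )
    def test_fixation_index_undefined_on_any_zero(self, c):
        assert fixation_index(c) is None
        assert mk_test(c).undefined_reason.startswith("zero_")

    def test_direction_of_selection(self):
        assert direction_of_selection(MKCounts(1, 1, 1, 1)) == pytest.approx(0.0)
        assert direction_of_selection(MKCounts(1, 0, 0, 1)) == pytest.approx(1.0)
        assert direction_of_selection(MKCounts(13, 1, 5, 4)) == pytest.approx(
            13 / 14 - 5 / 9
        )
        assert direction_of_selection(MKCounts(0, 0, 1, 1)) is None

    def test_alpha(self):
        assert alpha_adaptive(MKCounts(1, 1, 1, 1)) == pytest.approx(0.0)
        assert alpha_adaptive(MKCounts(13, 1, 5, 4)) == pytest.approx(1 - 5 / 52)
        assert alpha_adaptive(MKCounts(3, 2, 0, 4)) == pytest.approx(1.0)
        assert alpha_adaptive(MKCounts(0, 1, 1, 1)) is None

    def test_counts_must_be_non_negative(self):
        with pytest.raises(ValueError):
            MKCounts(-1, 1, 1, 1)


positive_counts = st.tuples(
    st.integers(1, 200), st.integers(1, 200), st.integers(1, 200), st.integers(1, 200)
)


class TestIdentities:
    @settings(derandomize=True, max_examples=200)
    @given(positive_counts)
    def test_ni_alpha_dos_identities(self, t):
        c = MKCounts(*t)
        fi = fixation_index(c)
        assert neutrality_index(c) == pytest.approx(1.0 / fi)
        assert alpha_adaptive(c) == pytest.approx(1.0 - 1.0 / fi)
        dos = direction_of_selection(c)
        if fi != pytest.approx(1.0):
            assert np.sign(dos) == np.sign(fi - 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(positive_counts)
    def test_gtest_swap_invariance_and_williams_shrinkage(self, t):
        c = MKCounts(*t)
        g, p = mk_gtest_williams(c)
        # simultaneous row and column swap leaves the table's association
        swapped = MKCounts(c.Ps, c.Pn, c.Ds, c.Dn)
        g2, p2 = mk_gtest_williams(swapped)
        assert g == pytest.approx(g2) and p == pytest.approx(p2)
        # Williams q >= 1 so the corrected statistic never exceeds raw G
        assert g <= mutual_information_g(c.Dn, c.Ds, c.Pn, c.Ps) + 1e-9


class TestGTest:
    def test_zero_margin_undefined(self):
        assert mk_gtest_williams(MKCounts(0, 0, 1, 1)) == (None, None)
        assert mk_gtest_williams(MKCounts(1, 0, 1, 0)) == (None, None)

    def test_perfect_independence(self):
        g, p = mk_gtest_williams(MKCounts(5, 5, 5, 5))
        assert g == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_uncorrected_g_matches_mutual_information_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(1, 60, size=4))
            table = MKCounts(a, b, c, d)
            g_adj, _ = mk_gtest_williams(table)
            n = a + b + c + d
            q = 1 + (n / (a + b) + n / (c + d) - 1) * (
                n / (a + c) + n / (b + d) - 1
            ) / (6 * n)
            assert g_adj * q == pytest.approx(
                mutual_information_g(a, b, c, d), abs=1e-9
            )


class TestPoolingAndNITG:
    def test_pool_counts(self):
        assert pool_counts([MKCounts(1, 1, 1, 1), MKCounts(2, 2, 2, 2)]) == MKCounts(
            3, 3, 3, 3
        )
        assert pool_counts([]) == MKCounts(0, 0, 0, 0)

    def test_pooling_copies_preserves_fi(self):
        c = MKCounts(6, 2, 3, 4)
        pooled = pool_counts([c] * 5)
        assert fixation_index(pooled) == pytest.approx(fixation_index(c))

    def test_ni_tg_single_gene_and_degenerate_cases(self):
        assert neutrality_index_tg([MKCounts(1, 1, 1, 1)]) == pytest.approx(1.0)
        assert neutrality_index_tg([MKCounts(2, 3, 0, 4), MKCounts(1, 1, 0, 2)]) == 0.0
        assert neutrality_index_tg([MKCounts(1, 1, 2, 0)]) is None

    def test_ni_tg_three_gene_hand_computation(self):
        genes = [MKCounts(4, 2, 1, 3), MKCounts(1, 5, 2, 2), MKCounts(3, 1, 1, 1)]
        # spreadsheet-style evaluation of sum(Ds*Pn/(Ps+Ds)) / sum(Dn*Ps/(Ps+Ds))
        num = 2 * 1 / 5 + 5 * 2 / 7 + 1 * 1 / 2
        den = 4 * 3 / 5 + 1 * 2 / 7 + 3 * 1 / 2
        assert neutrality_index_tg(genes) == pytest.approx(num / den)


class TestStratumSummary:
    def test_single_gene_set_equals_gene_stats(self):
        polys = [GenePolymorphism("a", "s", 2, 3)]
        (summary,) = stratum_summary(
            {"a": (4.0, 2.0)}, polys, strata=["s"], set_labels={"solo": ["a"]}
        )
        assert summary.n_genes == 1
        assert summary.pooled == MKCounts(4, 2, 2, 3)
        assert summary.stats.FI == pytest.approx((4 / 2) / (2 / 3))

    def test_nonpolymorphic_genes_excluded_from_pool(self):
        polys = [
            GenePolymorphism("a", "s", 1, 1),
            GenePolymorphism("b", "s", 0, 0),
        ]
        (summary,) = stratum_summary(
            {"a": (1.0, 1.0), "b": (50.0, 1.0)}, polys, ["s"], {"all": ["a", "b"]}
        )
        assert summary.n_genes == 1 and summary.pooled.Dn == 1.0

    def test_empty_set_row(self):
        (summary,) = stratum_summary({}, [], ["s"], {"empty": []})
        assert summary.n_genes == 0 and summary.stats.FI is None


def test_bh_fdr_is_monotone_and_bounded():
    p = [0.001, 0.01, 0.02, 0.5, 0.9]
    adj = bh_fdr(p)
    assert np.all(adj >= p) and np.all(adj <= 1.0)
    assert list(adj) == sorted(adj)
    assert bh_fdr([]).size == 0
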