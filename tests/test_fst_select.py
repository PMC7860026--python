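import numpy as np
import pytest
from hypothesis import given, strategies as st

from aimpanel.errors import ParameterError, ShortfallError
from aimpanel.fst_select import (LOOSE, STRINGENT, FstSettings, pairwise_fst,
                                 select_fst_panel, site_filter, summed_fst,
                                 summed_fst_all)
from aimpanel.io_formats import PoolFreqTable, SnpKey

freqs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def table_from_freqs(P, depth=100):
    """Exact-frequency table: ref depth = round(p * depth)."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    ref = np.rint(P * depth).astype(int)
    snps = [SnpKey("chr1", i + 1, "A", "C") for i in range(P.shape[0])]
    pools = [f"p{j + 1}" for j in range(P.shape[1])]
    return PoolFreqTable(snps, pools, ref, depth - ref)


class TestPairwiseFst:
    @pytest.mark.parametrize("p1,p2,expected", [
        (1.0, 0.0, 1.0),
        (0.0, 1.0, 1.0),
        (0.3, 0.3, 0.0),
        (0.8, 0.2, 0.36),   # H_T = 0.5, H_S = 0.32
        (0.0, 0.0, 0.0),    # jointly fixed: H_T = 0 convention
    ])
    def test_known_values(self, p1, p2, expected):
        assert pairwise_fst(p1, p2) == pytest.approx(expected, abs=1e-12)

    @given(p1=freqs, p2=freqs)
    def test_symmetric_bounded_and_identities(self, p1, p2):
        f = pairwise_fst(p1, p2)
        assert 0.0 <= f <= 1.0
        assert f == pytest.approx(pairwise_fst(p2, p1), abs=1e-12)
        if {p1, p2} == {0.0, 1.0}:
            assert f == pytest.approx(1.0)
        elif p1 == p2:
            assert f == pytest.approx(0.0, abs=1e-12)
        else:
            assert f < 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            pairwise_fst(1.2, 0.5)

    def test_matches_heterozygosity_oracle(self):
        rng = np.random.default_rng(0)
        p1, p2 = rng.random(200), rng.random(200)
        pbar = (p1 + p2) / 2
        ht = 2 * pbar * (1 - pbar)
        hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
        expected = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1), 0.0)
        np.testing.assert_allclose(pairwise_fst(p1, p2), expected, atol=1e-12)


class TestSiteFilter:
    def test_zero_depth_pool_never_eligible(self):
        t = PoolFreqTable([SnpKey("chr1", 1, "A", "C")], ["a", "b"],
                          np.array([[0, 50]]), np.array([[0, 50]]))
        assert not site_filter(t, FstSettings("loose", 1, 0))[0, 0, 1]

    def test_loose_passes_where_stringent_rejects(self):
        # depth 15 in both pools, minor count 6
        t = PoolFreqTable([SnpKey("chr1", 1, "A", "C")], ["a", "b"],
                          np.array([[12, 12]]), np.array([[3, 3]]))
        loose = FstSettings("loose", 10, 2)
        stringent = FstSettings("stringent", 30, 4)
        assert site_filter(t, loose)[0, 0, 1]
        assert not site_filter(t, stringent)[0, 0, 1]

    def test_loose_eligibility_contains_stringent(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(0, 40, size=(50, 4))
        alt = rng.integers(0, 40, size=(50, 4))
        snps = [SnpKey("chr1", i + 1, "A", "C") for i in range(50)]
        t = PoolFreqTable(snps, list("abcd"), ref, alt)
        e_loose = site_filter(t, LOOSE)
        e_str = site_filter(t, STRINGENT)
        assert not (e_str & ~e_loose).any()


class TestSummedFst:
    def test_fixed_unique_snp_saturates_bound_at_21(self):
        P = [[1.0] + [0.0] * 21]
        t = table_from_freqs(P)
        ranked = summed_fst(t, "p1", LOOSE)
        assert ranked.iloc[0]["summed_fst"] == pytest.approx(21.0)

    def test_identical_pools_sum_to_zero(self):
        t = table_from_freqs([[0.4] * 5, [0.7] * 5])
        S = summed_fst_all(t, LOOSE)
        np.testing.assert_allclose(S, 0.0, atol=1e-12)

    def test_three_pools_two_fixed_pairs(self):
        t = table_from_freqs([[1.0, 0.0, 0.0]])
        ranked = summed_fst(t, "p1", FstSettings("loose", 1, 0))
        assert ranked.iloc[0]["summed_fst"] == pytest.approx(2.0)

    def test_bound_never_exceeded(self):
        rng = np.random.default_rng(9)
        t = table_from_freqs(rng.random((100, 6)))
        S = summed_fst_all(t, LOOSE)
        assert (S <= 5.0 + 1e-9).all()

    def test_unknown_pool_rejected(self):
        t = table_from_freqs([[0.5, 0.5]])
        with pytest.raises(KeyError):
            summed_fst(t, "nope", LOOSE)

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(17)
        ref = rng.integers(0, 60, size=(100, 5))
        alt = rng.integers(0, 60, size=(100, 5))
        snps = [SnpKey("chr1", i + 1, "A", "C") for i in range(100)]
        t = PoolFreqTable(snps, list("abcde"), ref, alt)
        for settings in (LOOSE, STRINGENT):
            S = summed_fst_all(t, settings)
            f = t.freq
            d = t.depth
            for i in range(t.n_snps):
                for j in range(t.n_pools):
                    expected = 0.0
                    for k in range(t.n_pools):
                        if k == j:
                            continue
                        if d[i, j] < settings.min_depth or d[i, k] < settings.min_depth:
                            continue
                        minor = min(ref[i, j] + ref[i, k], alt[i, j] + alt[i, k])
                        if minor < settings.min_minor_count:
                            continue
                        expected += pairwise_fst(f[i, j], f[i, k])
                    assert S[i, j] == pytest.approx(expected, abs=1e-10)


class TestSelectFstPanel:
    def test_single_pool_small_quotas(self):
        t = table_from_freqs([[0.9], [0.2]])
        panel = select_fst_panel(t, k_loose=1, k_stringent=1,
                                 loose=FstSettings("loose", 1, 0),
                                 stringent=FstSettings("stringent", 1, 0))
        assert len(panel) == 2
        assert len(set(panel.snps)) == 2

    def test_two_pools_full_quotas(self):
        t = table_from_freqs([[0.9, 0.1], [0.2, 0.8], [0.5, 0.4], [0.3, 0.7]])
        panel = select_fst_panel(t, k_loose=1, k_stringent=1,
                                 loose=FstSettings("loose", 1, 0),
                                 stringent=FstSettings("stringent", 1, 0))
        assert len(panel) == 4  # 2 pools x (1 + 1), all unique
        assert len(set(panel.snps)) == 4

    def test_contested_top_snp_goes_to_first_pool(self):
        # SNP 1 is the top scorer for both pools; pool 2 must take its next
        P = np.array([
            [1.0, 0.0],   # strongest for both
            [0.9, 0.1],
            [0.2, 0.8],
            [0.5, 0.5],
            [0.45, 0.55],
        ])
        t = table_from_freqs(P)
        panel = select_fst_panel(t, k_loose=0, k_stringent=1,
                                 stringent=FstSettings("stringent", 1, 0),
                                 loose=FstSettings("loose", 1, 0))
        by_pool = {e.focal_unit: e.snp.pos for e in panel.entries}
        assert by_pool["p1"] == 1
        assert by_pool["p2"] != 1
        assert len(set(panel.snps)) == 2

    def test_shortfall_names_the_pool(self):
        t = table_from_freqs([[0.9, 0.1]])
        with pytest.raises(ShortfallError, match="pool 'p1'"):
            select_fst_panel(t, k_loose=1, k_stringent=1,
                             loose=FstSettings("loose", 1, 0),
                             stringent=FstSettings("stringent", 1, 0))

    def test_deterministic_manifest(self):
        rng = np.random.default_rng(2)
        t = table_from_freqs(rng.random((200, 4)))
        kw = dict(k_loose=3, k_stringent=5,
                  loose=FstSettings("loose", 1, 0),
                  stringent=FstSettings("stringent", 1, 0))
        assert select_fst_panel(t, **kw).entries == select_fst_panel(t, **kw).entries

    def test_stringent_thresholds_must_dominate_loose(self):
        t = table_from_freqs([[0.5, 0.5]])
        from aimpanel.errors import ValidationError
        with pytest.raises(ValidationError):
            select_fst_panel(t, loose=FstSettings("loose", 30, 4),
                             stringent=FstSettings("stringent", 10, 2))
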