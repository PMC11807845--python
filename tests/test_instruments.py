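"""Instrument selection, LD clumping, and strength formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrscreen.instruments import (
    LDMatrix,
    f_statistic,
    filter_weak_instruments,
    instrument_strength,
    ld_clump,
    select_by_pvalue,
    variance_explained,
)
from mrscreen.sumstats import InputError
from tests.conftest import make_sumstats, variant


def _stats_with_pvalues(pvals, chrom="1", spacing=1000):
    return make_sumstats(
        [variant(f"rs{i}", chrom=chrom, pos=(i + 1) * spacing, pvalue=p)
         for i, p in enumerate(pvals)])


class TestSelectByPvalue:
    def test_threshold_screen(self):
        stats = _stats_with_pvalues([1e-7, 4e-6, 2e-5])
        assert select_by_pvalue(stats, 5e-6) == ["rs0", "rs1"]

    def test_threshold_one_keeps_all_ordered_by_p(self):
        stats = _stats_with_pvalues([2e-5, 1e-7, 4e-6])
        assert select_by_pvalue(stats, 1.0) == ["rs1", "rs2", "rs0"]

    def test_below_minimum_gives_empty(self):
        stats = _stats_with_pvalues([1e-7, 4e-6])
        assert select_by_pvalue(stats, 1e-9) == []

    def test_ties_broken_by_position(self):
        stats = make_sumstats([
            variant("rsB", pos=2000, pvalue=1e-8),
            variant("rsA", pos=1000, pvalue=1e-8),
        ])
        assert select_by_pvalue(stats, 1.0) == ["rsA", "rsB"]


def _ld(ids, r2, positions=None):
    return LDMatrix(variant_ids=ids, r2=np.asarray(r2, dtype=float),
                    positions=positions)


def brute_force_clump(candidates, ld, stats, window_kb, r2_max):
    """Independent re-statement of the greedy rule, kept deliberately naive."""
    tab = stats.table.set_index("variant_id")
    ordered = sorted(candidates, key=lambda v: (tab.loc[v, "pvalue"],
                                                tab.loc[v, "chromosome"],
                                                tab.loc[v, "position"], v))
    kept = []
    for v in ordered:
        conflict = False
        for k in kept:
            same_chrom = tab.loc[v, "chromosome"] == tab.loc[k, "chromosome"]
            close = abs(tab.loc[v, "position"] - tab.loc[k, "position"]) <= window_kb * 1000
            if same_chrom and close and ld.pair_r2(v, k) > r2_max:
                conflict = True
                break
        if not conflict:
            kept.append(v)
    return kept


class TestLdClump:
    def test_single_candidate_kept(self):
        stats = _stats_with_pvalues([1e-8])
        ld = _ld(["rs0"], [[1.0]])
        assert ld_clump(["rs0"], ld, stats) == ["rs0"]

    def test_correlated_trio_keeps_most_significant(self):
        stats = _stats_with_pvalues([1e-9, 1e-8, 1e-7], spacing=300)
        r2 = [[1.0, 0.9, 0.9], [0.9, 1.0, 0.9], [0.9, 0.9, 1.0]]
        ld = _ld(["rs0", "rs1", "rs2"], r2)
        assert ld_clump(["rs0", "rs1", "rs2"], ld, stats) == ["rs0"]

    def test_pair_outside_window_both_kept(self):
        stats = make_sumstats([
            variant("rs0", pos=1_000_000, pvalue=1e-9),
            variant("rs1", pos=1_000_000 + 20_000_000 + 1, pvalue=1e-8),
        ])
        ld = _ld(["rs0", "rs1"], [[1.0, 0.9], [0.9, 1.0]])
        assert ld_clump(["rs0", "rs1"], ld, stats, window_kb=10_000) == ["rs0", "rs1"]

    def test_cross_chromosome_never_clumped(self):
        stats = make_sumstats([
            variant("rs0", chrom="1", pos=1000, pvalue=1e-9),
            variant("rs1", chrom="2", pos=1000, pvalue=1e-8),
        ])
        ld = _ld(["rs0", "rs1"], [[1.0, 0.99], [0.99, 1.0]])
        assert ld_clump(["rs0", "rs1"], ld, stats) == ["rs0", "rs1"]

    def test_missing_candidate_is_error_naming_id(self):
        stats = _stats_with_pvalues([1e-8])
        ld = _ld(["rs0"], [[1.0]])
        with pytest.raises(InputError, match="rs9"):
            ld_clump(["rs9"], ld, stats)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = 12
        pos = np.sort(rng.integers(1, 5_000_000, size=m))
        stats = make_sumstats([
            variant(f"rs{i}", pos=int(pos[i]), pvalue=float(rng.uniform(1e-12, 1e-4)))
            for i in range(m)])
        a = rng.uniform(0, 1, size=(m, m))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = _ld([f"rs{i}" for i in range(m)], r2)
        cands = [f"rs{i}" for i in range(m)]
        got = ld_clump(cands, ld, stats, window_kb=1000, r2_max=0.3)
        expected = brute_force_clump(cands, ld, stats, 1000, 0.3)
        assert got == expected
        # post-condition: no kept same-chromosome pair within window exceeds r2_max
        tab = stats.table.set_index("variant_id")
        for i, vi in enumerate(got):
            for vj in got[i + 1:]:
                if abs(tab.loc[vi, "position"] - tab.loc[vj, "position"]) <= 1e6:
                    assert ld.pair_r2(vi, vj) <= 0.3

    def test_output_independent_of_candidate_order(self, rng):
        stats = _stats_with_pvalues(list(rng.uniform(1e-10, 1e-5, size=8)), spacing=2000)
        a = rng.uniform(0, 1, size=(8, 8))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = _ld([f"rs{i}" for i in range(8)], r2)
        cands = [f"rs{i}" for i in range(8)]
        shuffled = list(cands)
        rng.shuffle(shuffled)
        assert ld_clump(cands, ld, stats) == ld_clump(shuffled, ld, stats)


class TestStrength:
    def test_variance_explained_closed_form(self):
        # beta=0.05, se=0.008, n=26333: R^2 = 0.0025 / (0.0025 + 0.000064*26333)
        assert variance_explained(0.05, 0.008, 26333) == pytest.approx(
            0.0025 / (0.0025 + 0.008**2 * 26333), rel=1e-12)
        assert variance_explained(0.05, 0.008, 26333) == pytest.approx(0.0014815, rel=1e-3)

    def test_zero_beta_gives_zero(self):
        assert variance_explained(0.0, 0.01, 1000) == 0.0

    def test_monotone_decreasing_in_se(self):
        r2 = [variance_explained(0.05, s, 26333) for s in (0.004, 0.008, 0.016)]
        assert r2[0] > r2[1] > r2[2]

    def test_missing_n_is_error(self):
        with pytest.raises(InputError):
            variance_explained(0.05, 0.008, np.nan)

    def test_f_statistic_value(self):
        r2 = variance_explained(0.05, 0.008, 26333)
        assert f_statistic(r2, 26333, k=1) == pytest.approx(39.06, rel=1e-3)

    def test_f_zero_when_r2_zero(self):
        assert f_statistic(0.0, 1000, k=5) == 0.0

    def test_f_requires_n_above_k_plus_1(self):
        with pytest.raises(InputError):
            f_statistic(0.01, 3, k=2)

    @given(r2=st.floats(1e-6, 0.5), n=st.integers(100, 10**6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_f_monotone_in_r2_and_n(self, r2, n):
        assert f_statistic(min(r2 * 1.5, 0.9), n, 1) > f_statistic(r2, n, 1)
        assert f_statistic(r2, n + 1000, 1) > f_statistic(r2, n, 1)

    def test_weak_instrument_flag_and_filter(self):
        # F = (n-2) * r2/(1-r2); choose betas straddling F=10 at n=10000
        strong = variant("rs_strong", beta=0.05, se=0.008, n=26333)
        weak = variant("rs_weak", pos=2000, beta=0.01, se=0.008, n=26333)  # F ~ 1.5
        stats = make_sumstats([strong, weak])
        table = instrument_strength(stats, ["rs_strong", "rs_weak"])
        assert list(table["weak"]) == [False, True]
        kept, _ = filter_weak_instruments(stats, ["rs_strong", "rs_weak"])
        assert kept == ["rs_strong"]

    def test_aggregate_f_uses_instrument_count(self):
        stats = make_sumstats([variant("rs1"), variant("rs2", pos=2000)])
        table = instrument_strength(stats, ["rs1", "rs2"])
        assert table.attrs["aggregate_k"] == 2
        r2_sum = float(table["r_squared"].sum())
        assert table.attrs["aggregate_f"] == pytest.approx(
            (26333 - 3) / 2 * r2_sum / (1 - r2_sum))


class TestLDMatrix:
    def test_square_table_roundtrip(self, tmp_path):
        ld = _ld(["a", "b"], [[1.0, 0.25], [0.25, 1.0]])
        ld.to_square_table(tmp_path / "ld.tsv")
        back = LDMatrix.from_square_table(tmp_path / "ld.tsv")
        assert back.variant_ids == ["a", "b"]
        np.testing.assert_allclose(back.r2, ld.r2)

    def test_from_panel_squared_pearson(self, rng):
        panel = pd.DataFrame(rng.integers(0, 3, size=(200, 3)).astype(float),
                             columns=["a", "b", "c"])
        panel["b"] = panel["a"] * 0.9 + rng.normal(0, 0.3, 200)  # strong LD
        ld = LDMatrix.from_panel(panel)
        expected = np.corrcoef(panel["a"], panel["b"])[0, 1] ** 2
        assert ld.pair_r2("a", "b") == pytest.approx(expected, rel=1e-10)
        assert ld.pair_r2("a", "b") > 0.5

    def test_asymmetric_rejected(self):
        with pytest.raises(InputError):
            _ld(["a", "b"], [[1.0, 0.2], [0.5, 1.0]])
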