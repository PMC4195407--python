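import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rhm import (MarkerMap, ScanResult, call_qtl, compute_thresholds,
                 make_windows, run_scan)
from rhm.scan import lrt_pvalue


def even_map(n_chrom=5, m=2000, spacing=50_000, start=0):
    ids, chroms, pos = [], [], []
    for c in range(1, n_chrom + 1):
        for j in range(m):
            ids.append(f"c{c}s{j + 1}")
            chroms.append(str(c))
            pos.append(start + j * spacing)
    return MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                     np.array(pos, dtype=np.int64))


class TestWindows:
    def test_benchmark_window_counts(self):
        wins = make_windows(even_map(), w=20, s=10)
        per_chrom = sum(1 for w in wins if w.chromosome == "1")
        assert per_chrom == 199
        assert len(wins) == 995

    def test_window_equal_to_chromosome(self):
        wins = make_windows(even_map(n_chrom=1, m=50), w=50, s=10)
        assert len(wins) == 1
        assert wins[0].snp_start == 1 and wins[0].snp_end == 50

    def test_published_region_coordinates(self):
        # 50-kb spacing starting at 0: region 30 spans 14,500-15,450 kb and
        # region 117 spans 58,000-58,950 kb
        wins = make_windows(even_map(), w=20, s=10)
        by_key = {(w.chromosome, w.region_index): w for w in wins}
        r30 = by_key[("1", 30)]
        assert (r30.bp_start, r30.bp_end) == (14_500_000, 15_450_000)
        r117 = by_key[("1", 117)]
        assert (r117.bp_start, r117.bp_end) == (58_000_000, 58_950_000)

    def test_short_chromosome_skipped(self):
        mm = even_map(n_chrom=2, m=15)
        wins = make_windows(mm, w=20, s=10)
        assert wins == []

    @settings(max_examples=50, deadline=None)
    @given(m=st.integers(20, 400), w=st.integers(2, 50), s=st.integers(1, 50))
    def test_window_count_and_coverage_formula(self, m, w, s):
        s = min(s, w)
        if m < w:
            return
        mm = even_map(n_chrom=1, m=m, spacing=1000, start=1000)
        wins = make_windows(mm, w=w, s=s)
        assert len(wins) == (m - w) // s + 1
        covered = set()
        for win in wins:
            assert win.size == w
            covered.update(range(win.snp_start, win.snp_end + 1))
        # every SNP before the trailing tail is covered when s <= w
        tail_start = wins[-1].snp_end + 1
        assert covered == set(range(1, tail_start))


class TestThresholds:
    @pytest.mark.parametrize("w,gw,sugg,l10gw,l10sugg", [
        (100, 10.83, 6.64, 3.30, 2.00),
        (50, 12.12, 7.88, 3.60, 2.30),
        (20, 13.83, 9.55, 4.00, 2.70),
    ])
    def test_printed_threshold_set(self, w, gw, sugg, l10gw, l10sugg):
        t = compute_thresholds(10_000, w, alpha=0.05)
        assert t.n_effective_tests == 10_000 // w
        assert abs(t.lrt_genomewide - gw) < 0.0055
        assert abs(t.lrt_suggestive - sugg) < 0.0055
        assert t.minus_log10_p_genomewide == pytest.approx(l10gw, abs=0.005)
        assert t.minus_log10_p_suggestive == pytest.approx(l10sugg, abs=0.005)

    def test_monotone_in_window_size(self):
        ts = [compute_thresholds(10_000, w) for w in (100, 50, 20)]
        gw = [t.lrt_genomewide for t in ts]
        sugg = [t.lrt_suggestive for t in ts]
        assert gw == sorted(gw) and sugg == sorted(sugg)

    def test_uniform_conventions_differ_coherently(self):
        mixed = compute_thresholds(10_000, 20, null_dist="mixed")
        mix = compute_thresholds(10_000, 20, null_dist="mixture")
        plain = compute_thresholds(10_000, 20, null_dist="chi2_1")
        assert mix.lrt_genomewide == mixed.lrt_genomewide
        assert plain.lrt_suggestive == mixed.lrt_suggestive
        assert plain.lrt_genomewide > mixed.lrt_genomewide
        assert mix.lrt_suggestive < mixed.lrt_suggestive

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            compute_thresholds(10, 20)


def test_lrt_zero_gives_p_one():
    assert lrt_pvalue(0.0) == 1.0
    assert lrt_pvalue(-1e-9) == 1.0
    assert 0 < lrt_pvalue(10.0) < 0.001


@pytest.fixture(scope="module")
def scan_result(small_dataset):
    return run_scan(small_dataset["genotypes"], small_dataset["map"],
                    small_dataset["phenotypes"], "trait1", w=20, s=10)


class TestRunScan:
    def test_table_is_complete_and_consistent(self, scan_result, small_dataset):
        t = scan_result.table
        assert len(t) == len(make_windows(small_dataset["map"], 20, 10))
        assert (t["lrt"] >= 0).all()
        assert ((t["p"] > 0) & (t["p"] <= 1)).all()
        zero = t["lrt"] == 0
        assert (t.loc[zero, "p"] == 1).all()
        th = scan_result.thresholds
        gw = t["lrt"] >= th.lrt_genomewide
        sugg = (t["lrt"] >= th.lrt_suggestive) & ~gw
        assert (t.loc[gw, "level"] == "genomewide").all()
        assert (t.loc[sugg, "level"] == "suggestive").all()
        assert (t.loc[t["lrt"] < th.lrt_suggestive, "level"] == "none").all()

    def test_detects_planted_qtl_region(self, scan_result, small_dataset):
        truth = small_dataset["truth"]
        qtl_bp = truth.qtl[0].position_bp
        top = scan_result.table.sort_values("lrt", ascending=False).iloc[0]
        assert top["chromosome"] == "1"
        assert top["bp_start"] - 10_000_000 <= qtl_bp <= top["bp_end"] + 10_000_000

    def test_invariant_to_individual_ordering(self, scan_result, small_dataset):
        gm = small_dataset["genotypes"]
        pheno = small_dataset["phenotypes"]
        rng = np.random.default_rng(3)
        perm = rng.permutation(gm.n_individuals)
        from rhm import GenotypeMatrix
        gm_p = GenotypeMatrix(gm.individual_ids[perm], gm.snp_ids, gm.codes[perm])
        res_p = run_scan(gm_p, small_dataset["map"], pheno, "trait1", w=20, s=10)
        np.testing.assert_allclose(res_p.table["lrt"].to_numpy(),
                                   scan_result.table["lrt"].to_numpy(),
                                   atol=1e-4)


class TestCallQtl:
    def make_result(self, rows):
        cols = ["chromosome", "region_index", "snp_start", "snp_end",
                "bp_start", "bp_end", "h2_reg", "h2_background",
                "lrt", "p", "minus_log10_p", "level", "converged"]
        df = pd.DataFrame(rows, columns=cols)
        th = compute_thresholds(1000, 20)
        return ScanResult(df, th)

    def row(self, chrom, idx, start, lrt, level, conv=True):
        return [chrom, idx, start, start + 19, start * 1000, (start + 19) * 1000,
                0.05, 0.2, lrt, 0.01, 2.0, level, conv]

    def test_overlapping_windows_merge_to_one_call(self):
        res = self.make_result([self.row("1", 1, 1, 12.0, "genomewide"),
                                self.row("1", 2, 11, 15.0, "genomewide"),
                                self.row("1", 3, 21, 10.5, "suggestive")])
        calls = call_qtl(res)
        assert len(calls) == 1
        c = calls[0]
        assert c.level == "genomewide"
        assert c.peak_region_index == 2
        assert (c.bp_start, c.bp_end) == (1000, 40_000)

    def test_separated_windows_give_two_calls(self):
        res = self.make_result([self.row("1", 1, 1, 12.0, "genomewide"),
                                self.row("1", 9, 81, 11.0, "suggestive")])
        calls = call_qtl(res)
        assert len(calls) == 2
        assert [c.level for c in calls] == ["genomewide", "suggestive"]

    def test_peak_tie_breaks_to_smaller_bp(self):
        res = self.make_result([self.row("1", 1, 1, 12.0, "genomewide"),
                                self.row("1", 2, 11, 12.0, "genomewide")])
        calls = call_qtl(res)
        assert calls[0].peak_region_index == 1

    def test_nonconverged_windows_excluded(self):
        res = self.make_result([self.row("1", 1, 1, 12.0, "genomewide", conv=False)])
        assert call_qtl(res) == []
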