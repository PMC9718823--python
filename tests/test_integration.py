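"""Differential-RE flags, gene mapping rules, categories, and KS tests."""

import numpy as np
import pandas as pd
import pytest

from chromlink.integration import (categorize_genes,
                                   differential_overlap_fraction, flag_res,
                                   ks_two_sample, map_diff_k27_to_genes,
                                   stratified_cdf_analysis)
from chromlink.intervals import GenomicInterval


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestOverlapFraction:
    def test_boundary_ten_percent(self):
        assert differential_overlap_fraction(
            iv(0, 1000), [iv(100, 200)]
        ) == pytest.approx(0.10)

    def test_overlapping_diff_peaks_use_union(self):
        re = iv(0, 1000)
        frac = differential_overlap_fraction(re, [iv(0, 300), iv(200, 400)])
        assert frac == pytest.approx(0.4)

    def test_no_peaks_zero(self):
        assert differential_overlap_fraction(iv(0, 1000), []) == 0.0

    def test_invariant_to_peak_fragmentation(self):
        re = iv(500, 1500)
        peaks = [iv(600, 900), iv(1200, 1400)]
        split = [iv(600, 750), iv(750, 900), iv(1200, 1300), iv(1300, 1400)]
        assert differential_overlap_fraction(re, peaks) == \
            differential_overlap_fraction(re, split)

    def test_other_chromosome_ignored(self):
        assert differential_overlap_fraction(
            iv(0, 1000), [iv(0, 1000, "chr2")]
        ) == 0.0


class TestFlagRes:
    def test_k79_flag_and_k27_direction(self):
        res = {"a": iv(0, 1000), "b": iv(2000, 3000), "c": iv(4000, 5000)}
        flagged = {
            r.name: r for r in flag_res(
                res,
                diff_k79=[iv(0, 500)],                # 50% of a
                diff_k27_up=[iv(2000, 2100)],          # 10% of b
                diff_k27_down=[],
            )
        }
        assert flagged["a"].is_k79_re and flagged["a"].k27_diff == "none"
        assert not flagged["b"].is_k79_re and flagged["b"].k27_diff == "up"
        assert not flagged["c"].is_k79_re and flagged["c"].k27_diff == "none"

    def test_both_directions_larger_fraction_wins_tie_goes_down(self):
        flagged = {
            r.name: r for r in flag_res(
                {"t": iv(0, 1000)}, [],
                diff_k27_up=[iv(0, 300)], diff_k27_down=[iv(500, 650)],
            )
        }
        assert flagged["t"].k27_diff == "up"  # 30% up vs 15% down
        tie = flag_res({"u": iv(0, 1000)}, [],
                       diff_k27_up=[iv(0, 200)], diff_k27_down=[iv(500, 700)])
        assert tie[0].k27_diff == "down"


def _inter(pairs, condition):
    return pd.DataFrame(
        [{"enhancer": e, "gene_id": g, "condition": condition}
         for e, g in pairs]
    )


class TestDiffK27Mapping:
    def test_three_rules_by_enumeration(self):
        """Ctrl-linked REs map via ctrl; ctrl-absent REs via ko; an RE
        linked in both maps only to its ctrl genes."""
        from chromlink.integration import RegulatoryElement
        res = [
            RegulatoryElement("r1", iv(0, 100), k27_diff="up"),
            RegulatoryElement("r2", iv(200, 300), k27_diff="up"),
            RegulatoryElement("r3", iv(400, 500), k27_diff="down"),
            RegulatoryElement("r4", iv(600, 700), k27_diff="none"),
        ]
        ctrl = _inter([("r1", "A"), ("r1", "B"), ("r3", "D0")], "ctrl")
        ko = _inter([("r2", "C"), ("r3", "D0"), ("r3", "D"),
                     ("r4", "E")], "ko")
        mapping = map_diff_k27_to_genes(res, ctrl, ko)
        assert mapping == {"A": {"r1"}, "B": {"r1"}, "C": {"r2"},
                           "D0": {"r3"}}
        # r3 linked to D only in ko while present in ctrl: not counted
        assert "D" not in mapping
        # non-differential r4 never counted
        assert "E" not in mapping


def _profiles(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "de_status", "gb_k79", "n_k79_res",
                 "n_diff_k27_res", "category", "log2fc",
                 "fraction_covered"],
    )


class TestCategorize:
    def test_categories_and_percentages(self):
        rows = [
            ("a", "down", True, 3, 0, "GB+RE+", -1.0, 0.8),
            ("b", "down", True, 0, 0, "GB+RE-", -0.8, 0.5),
            ("c", "up", False, 2, 1, "GB-RE+diffK27+", 1.2, 0.0),
            ("d", "up", False, 2, 0, "GB-RE+", 0.9, 0.0),
            ("e", "unchanged", False, 0, 0, "unchanged", 0.0, 0.0),
        ]
        table = categorize_genes(_profiles(rows))
        down = table[table["direction"] == "down"]
        up = table[table["direction"] == "up"]
        assert down["n_genes"].sum() == 2 and up["n_genes"].sum() == 2
        assert down["percent"].sum() == pytest.approx(100)
        assert up["percent"].sum() == pytest.approx(100)
        merged = categorize_genes(_profiles(rows))
        assert set(merged.loc[merged["direction"] == "up", "category"]) == \
            {"GB-RE+"}

    def test_diff_k27_split_kept_when_requested(self):
        rows = [
            ("c", "up", False, 2, 1, "GB-RE+diffK27+", 1.2, 0.0),
            ("d", "up", False, 2, 0, "GB-RE+", 0.9, 0.0),
        ]
        table = categorize_genes(_profiles(rows), include_diff_k27=True)
        assert set(table["category"]) == {"GB-RE+diffK27+", "GB-RE+"}


def ks_d_oracle(x, y):
    """Brute-force sup |ECDF_x - ECDF_y| on the pooled grid."""
    grid = np.concatenate([x, y])
    fx = np.array([(np.asarray(x) <= g).mean() for g in grid])
    fy = np.array([(np.asarray(y) <= g).mean() for g in grid])
    return np.abs(fx - fy).max()


class TestKs:
    def test_identical_samples_d_zero(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports_d_one(self):
        d, _ = ks_two_sample([1, 2], [3, 4])
        assert d == 1.0

    def test_interleaved_half(self):
        d, _ = ks_two_sample([1, 3], [2, 4])
        assert d == 0.5

    def test_d_matches_grid_oracle_exhaustively(self):
        """All pair sizes with total n <= 8, values drawn from {1..6}."""
        rng = np.random.default_rng(8)
        for na in range(1, 8):
            for nb in range(1, 9 - na):
                for _ in range(25):
                    x = rng.integers(1, 7, na).astype(float)
                    y = rng.integers(1, 7, nb).astype(float)
                    d, _ = ks_two_sample(x, y)
                    assert d == pytest.approx(ks_d_oracle(x, y), abs=1e-12)

    def test_d_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(0.5, 1, 15)
        d0, _ = ks_two_sample(x, y)
        d1, _ = ks_two_sample(np.exp(x), np.exp(y))
        assert d0 == pytest.approx(d1)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestStratified:
    def _make(self, rng, n, shift, n_res, frac, gb):
        return [
            (f"g{rng.integers(1e9)}", "unchanged", gb, n_res, 0, "x",
             float(rng.normal(shift, 0.3)), frac)
            for _ in range(n)
        ]

    def test_planted_shift_in_many_re_stratum_detected(self):
        rng = np.random.default_rng(0)
        rows = (
            self._make(rng, 200, 0.0, 0, 0.0, False)
            + self._make(rng, 200, 0.0, 3, 0.0, False)
            + self._make(rng, 200, -0.5, 7, 0.0, False)
        )
        _, ks = stratified_cdf_analysis(_profiles(rows))
        row = ks[(ks["stratification"] == "k79_re_count")
                 & (ks["stratum_b"] == ">=6 K79-REs")
                 & (ks["stratum_a"] == "1-5 K79-REs")]
        assert row["ks_p"].iloc[0] < 0.01

    def test_null_strata_not_significant_on_average(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(20):
            rows = (
                self._make(rng, 40, 0.0, 0, 0.0, False)
                + self._make(rng, 40, 0.0, 3, 0.0, False)
            )
            _, ks = stratified_cdf_analysis(_profiles(rows))
            sub = ks[ks["stratification"] == "k79_re_count"]
            pvals.append(sub["ks_p"].iloc[0])
        assert np.mean(np.array(pvals) < 0.05) < 0.3

    def test_fraction_boundary_one_third_in_middle_stratum(self):
        rng = np.random.default_rng(2)
        rows = (
            self._make(rng, 5, 0, 0, 1 / 3, True)
            + self._make(rng, 5, 0, 0, 0.2, True)
            + self._make(rng, 5, 0, 0, 0.8, True)
        )
        cdfs, _ = stratified_cdf_analysis(_profiles(rows))
        sizes = {c.stratum: c.values.size for c in cdfs
                 if c.stratification == "gb_fraction"}
        assert sizes["GB fraction 1/3-2/3"] == 5
        assert sizes["GB fraction < 1/3"] == 5

    def test_small_stratum_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        rows = self._make(rng, 10, 0, 0, 0.0, False) + \
            self._make(rng, 1, 0, 7, 0.0, False)
        with pytest.warns(UserWarning, match="KS test skipped"):
            _, ks = stratified_cdf_analysis(_profiles(rows))
        sub = ks[(ks["stratification"] == "k79_re_count")
                 & (ks["stratum_b"] == ">=6 K79-REs")]
        assert len(sub) == 0
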