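"""Allele-count-weighted differentiation statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import nei_gst_oracle
from ploidyscan import (count_alleles, genetic_diff, read_popmap,
                        simulate_populations, weighted_diff_stats)


def _variants(n):
    return pd.DataFrame({"CHROM": ["chr1"] * n,
                         "POS": np.arange(1, n + 1, dtype=np.int64)})


class TestCountAlleles:
    def test_diploid_population_count(self):
        gt = pd.DataFrame({f"a{i}": ["0/1"] for i in range(10)})
        pops = {s: "a" for s in gt.columns}
        pops["b0"] = "b"
        gt["b0"] = ["0/0"]
        counts, n = count_alleles(gt, pops)
        assert n["a"].iloc[0] == 20
        assert n["b"].iloc[0] == 2

    def test_mixed_ploidy_counting(self):
        gt = pd.DataFrame({"s1": ["0/1/1"], "s2": ["0/0"], "x": ["0/1"]})
        pops = {"s1": "a", "s2": "a", "x": "b"}
        counts, n = count_alleles(gt, pops)
        assert n["a"].iloc[0] == 5
        assert counts["a"][0, 0] == 3 and counts["a"][0, 1] == 2
        freq1 = counts["a"][0, 1] / n["a"].iloc[0]
        assert freq1 == pytest.approx(0.4)

    def test_missing_contributes_nothing(self):
        gt = pd.DataFrame({"s1": ["./."], "s2": ["0/1"]})
        counts, n = count_alleles(gt, {"s1": "a", "s2": "b"})
        assert n["a"].iloc[0] == 0

    def test_unassigned_sample_rejected(self):
        gt = pd.DataFrame({"s1": ["0/1"], "s2": ["0/1"]})
        with pytest.raises(KeyError, match="s2"):
            count_alleles(gt, {"s1": "a"})


class TestWeightedDiffStats:
    # Frozen expected values computed by hand from the weighting formulas
    # (weights n_k/sum n; Htmax = 1 - sum w_k^2 (1 - Hs_k)).
    @pytest.mark.parametrize("hs,n,ht,expected", [
        ((0.42, 0.42), (20, 20), 0.4650,
         dict(Htmax=0.710, Gstmax=0.408, Gst=0.0968, Gprimest=0.2369)),
        ((0.42, 0.42), (20, 30), 0.4632,
         dict(Htmax=0.698, Gstmax=0.399, Gst=0.0933, Gprimest=0.234)),
        ((0.42, 0.42), (20, 40), 0.4600,
         dict(Htmax=0.678, Gstmax=0.380, Gst=0.0870, Gprimest=0.229)),
    ])
    def test_weighted_rows(self, hs, n, ht, expected):
        out = weighted_diff_stats(np.array(hs), np.array(n), ht)
        for key, val in expected.items():
            assert out[key] == pytest.approx(val, abs=5e-4)

    def test_equal_weights_reduce_to_hedrick_htmax(self):
        """With k equal populations Htmax collapses to (k-1+Hs)/k."""
        for k in (2, 3, 4):
            hs = np.full(k, 0.3)
            out = weighted_diff_stats(hs, np.full(k, 10), ht=None)
            assert out["Htmax"] == pytest.approx((k - 1 + 0.3) / k)

    def test_zero_alleles_all_missing(self):
        out = weighted_diff_stats(np.array([0.1, 0.2]), np.array([0, 0]))
        assert all(np.isnan(v) for v in out.values())


class TestGeneticDiff:
    def test_fixed_difference_is_maximal(self):
        gt = pd.DataFrame({
            "a1": ["0/0"], "a2": ["0/0"],
            "b1": ["1/1"], "b2": ["1/1"],
        })
        pops = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        out = genetic_diff(gt, _variants(1), pops)
        assert out["Hs_a"].iloc[0] == 0.0
        assert out["Ht"].iloc[0] == pytest.approx(0.5)
        assert out["Gst"].iloc[0] == pytest.approx(1.0)
        assert out["Gprimest"].iloc[0] == pytest.approx(1.0)

    def test_monomorphic_yields_missing_gst(self):
        gt = pd.DataFrame({"a1": ["0/0"], "b1": ["0/0"]})
        out = genetic_diff(gt, _variants(1), {"a1": "a", "b1": "b"})
        assert out["Ht"].iloc[0] == 0.0
        assert np.isnan(out["Gst"].iloc[0])

    def test_column_layout(self):
        gt = pd.DataFrame({"a1": ["0/1"], "b1": ["0/1"]})
        out = genetic_diff(gt, _variants(1), {"a1": "a", "b1": "b"})
        assert list(out.columns) == [
            "CHROM", "POS", "Hs_a", "Hs_b", "Ht", "n_a", "n_b",
            "Gst", "Htmax", "Gstmax", "Gprimest"]

    def test_single_population_rejected(self):
        gt = pd.DataFrame({"a1": ["0/1"]})
        with pytest.raises(ValueError, match="populations"):
            genetic_diff(gt, _variants(1), {"a1": "a"})

    @pytest.mark.parametrize("seed", range(5))
    def test_equal_ploidy_equal_n_matches_nei_oracle(self, seed):
        """On balanced diploid data the weighted Gst collapses to the
        textbook Nei Gst, computed by an independent closed form."""
        rng = np.random.default_rng(seed)
        n_samples = 8
        gt_cols = {}
        pops = {}
        counts_a: dict = {}
        counts_b: dict = {}
        for j in range(n_samples):
            for pop, counts in (("a", counts_a), ("b", counts_b)):
                name = f"{pop}{j}"
                alleles = rng.integers(0, 3, size=2)
                gt_cols[name] = ["/".join(map(str, sorted(alleles)))]
                pops[name] = pop
                for a in alleles:
                    counts[int(a)] = counts.get(int(a), 0) + 1
        out = genetic_diff(pd.DataFrame(gt_cols), _variants(1), pops)
        expected = nei_gst_oracle(counts_a, counts_b)
        if np.isnan(expected):
            assert np.isnan(out["Gst"].iloc[0])
        else:
            assert out["Gst"].iloc[0] == pytest.approx(expected)

    def test_sample_order_invariance(self):
        gt, pops, _ = simulate_populations(
            {"a": [0.7, 0.3], "b": [0.2, 0.8]},
            {"a": 6, "b": 6}, {"a": 2, "b": 4}, n_variants=5, seed=9)
        variants = _variants(5)
        out1 = genetic_diff(gt, variants, pops)
        cols = list(gt.columns)[::-1]
        out2 = genetic_diff(gt[cols], variants, pops)
        for col in ("Ht", "Gst", "Htmax", "Gstmax", "Gprimest"):
            np.testing.assert_allclose(out1[col], out2[col])

    @pytest.mark.parametrize("seed", range(5))
    def test_jensen_and_htmax_bounds(self, seed):
        """Ht >= weighted Hs (convexity) and Htmax >= Ht on random
        mixed-ploidy data."""
        rng = np.random.default_rng(100 + seed)
        pa, pb = rng.random(2)
        gt, pops, _ = simulate_populations(
            {"a": [pa, 1 - pa], "b": [pb, 1 - pb]},
            {"a": 5, "b": 7}, {"a": 2, "b": 3},
            n_variants=20, seed=seed)
        out = genetic_diff(gt, _variants(20), pops)
        hs_w = (out["Hs_a"] * out["n_a"] + out["Hs_b"] * out["n_b"]) / \
            (out["n_a"] + out["n_b"])
        assert (out["Ht"] + 1e-12 >= hs_w).all()
        assert (out["Htmax"] + 1e-12 >= out["Ht"]).all()


class TestPopmap:
    def test_read_whitespace_and_comma(self, tmp_path):
        p = tmp_path / "pops.txt"
        p.write_text("s1 a\ns2,b\n# comment\n\ns3\tb\n")
        assert read_popmap(str(p)) == {"s1": "a", "s2": "b", "s3": "b"}

    def test_malformed_line(self, tmp_path):
        p = tmp_path / "pops.txt"
        p.write_text("loner\n")
        with pytest.raises(ValueError, match="pops.txt:1"):
            read_popmap(str(p))
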