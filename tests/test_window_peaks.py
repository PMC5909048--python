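"""Window assignment, modal-bin peak calling and coordinate flattening."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_peak
from ploidyscan import assign_windows, freq_peak, repos
from ploidyscan.window_peaks import bin_counts, bin_edges


class TestAssignWindows:
    def test_boundary_positions(self):
        idx, coords = assign_windows([1, 40000, 40001], 40000)
        assert list(idx) == [0, 0, 1]
        assert coords.iloc[0]["START"] == 1
        assert coords.iloc[0]["END"] == 40000

    def test_single_variant_in_second_window(self):
        idx, coords = assign_windows([200001], 200000)
        assert list(idx) == [1]
        assert coords.iloc[1]["START"] == 200001
        assert coords.iloc[1]["END"] == 400000

    def test_empty_windows_present(self):
        idx, coords = assign_windows([150, 250, 3250], 1000)
        # brute-force: 150,250 -> window 0; 3250 -> window 3
        assert list(idx) == [0, 0, 3]
        assert len(coords) == 4
        counts = np.bincount(idx, minlength=4)
        assert list(counts) == [2, 0, 0, 1]
        assert list(coords["START"]) == [1, 1001, 2001, 3001]
        assert list(coords["END"]) == [1000, 2000, 3000, 4000]

    def test_unsorted_positions_error_names_index(self):
        with pytest.raises(ValueError, match="index 2"):
            assign_windows([10, 20, 15], 1000)


class TestFreqPeak:
    def test_single_occupied_bin(self):
        vals = [0.665, 0.67, 0.675, 0.68]
        wt = freq_peak(pd.DataFrame({"s": vals}), [10, 20, 30, 40],
                       window_size=1000, bin_width=0.02, min_count=1)
        assert wt.peaks["s"].iloc[0] == pytest.approx(0.67)

    def test_clear_mode(self):
        vals = [0.49] * 4 + [0.65] * 9
        pos = list(range(10, 10 + 10 * len(vals), 10))
        wt = freq_peak(pd.DataFrame({"s": vals}), pos,
                       window_size=1000, bin_width=0.02, min_count=1)
        assert wt.peaks["s"].iloc[0] == pytest.approx(0.65)

    def test_min_count_censors_peak_not_count(self):
        vals = [0.5] * 5
        wt = freq_peak(pd.DataFrame({"s": vals}), [1, 2, 3, 4, 5],
                       window_size=100, bin_width=0.02, min_count=20)
        assert wt.counts["s"].iloc[0] == 5
        assert np.isnan(wt.peaks["s"].iloc[0])

    def test_seeded_triploid_peak_near_two_thirds(self):
        rng = np.random.default_rng(11)
        vals = rng.binomial(100, 2 / 3, size=500) / 100.0
        pos = np.arange(1, 501)
        wt = freq_peak(pd.DataFrame({"s": vals}), pos,
                       window_size=1000, bin_width=0.02, min_count=20)
        peak = wt.peaks["s"].iloc[0]
        oracle_peak, _ = brute_force_peak(list(vals), 0.02)
        assert peak == pytest.approx(oracle_peak)
        assert abs(peak - 2 / 3) <= 0.01

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError, match="bin_width"):
            freq_peak(pd.DataFrame({"s": [0.5]}), [1], bin_width=0.7)

    def test_multi_chromosome_windows_restart(self):
        vals = [0.5, 0.5, 0.75, 0.75]
        wt = freq_peak(pd.DataFrame({"s": vals}), [10, 20, 10, 20],
                       window_size=1000, bin_width=0.02, min_count=1,
                       chrom=["c1", "c1", "c2", "c2"])
        assert list(wt.coords["CHROM"]) == ["c1", "c2"]
        assert list(wt.coords["START"]) == [1, 1]
        assert wt.peaks["s"].to_numpy() == pytest.approx([0.49, 0.75])

    def test_conservation_counts_equal_occupancy(self):
        rng = np.random.default_rng(3)
        vals = rng.random(200)
        pos = np.sort(rng.choice(np.arange(1, 5001), 200, replace=False))
        wt = freq_peak(pd.DataFrame({"s": vals}), pos,
                       window_size=1000, bin_width=0.1, min_count=1)
        idx = (pos - 1) // 1000
        for k in range(len(wt.coords)):
            in_win = vals[idx == k]
            occ = bin_counts(in_win, 0.1)
            assert occ.sum() == wt.counts["s"].iloc[k]

    def test_within_window_permutation_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.binomial(60, 0.5, 50) / 60.0
        pos = np.arange(1, 51)
        base = freq_peak(pd.DataFrame({"s": vals}), pos,
                         window_size=1000, bin_width=0.02, min_count=1)
        perm = rng.permutation(50)
        shuf = freq_peak(pd.DataFrame({"s": vals[perm]}), pos,
                         window_size=1000, bin_width=0.02, min_count=1)
        assert base.peaks["s"].iloc[0] == shuf.peaks["s"].iloc[0]

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_instances(self, seed):
        """freq_peak equals the explicit-loop oracle on random data
        (10 parametrised seeds x 10 windows each)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 1000))
        pos = np.sort(rng.choice(np.arange(1, 20_001), n, replace=False))
        vals = rng.random(n)
        vals[rng.random(n) < 0.1] = np.nan
        bin_width = float(rng.choice([0.02, 0.05, 0.1, 0.3]))
        wt = freq_peak(pd.DataFrame({"s": vals}), pos,
                       window_size=2000, bin_width=bin_width, min_count=1)
        idx = (pos - 1) // 2000
        for k in range(len(wt.coords)):
            exp_peak, exp_count = brute_force_peak(list(vals[idx == k]),
                                                   bin_width)
            assert wt.counts["s"].iloc[k] == exp_count
            got = wt.peaks["s"].iloc[k]
            if np.isnan(exp_peak):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(exp_peak)

    def test_zero_variant_window_has_no_peak(self):
        wt = freq_peak(pd.DataFrame({"s": [0.5]}), [2500],
                       window_size=1000, bin_width=0.02, min_count=1)
        assert np.isnan(wt.peaks["s"].iloc[0])
        assert wt.counts["s"].iloc[0] == 0
        assert wt.coords["START_ROW"].iloc[0] == -1

    def test_matches_vcfR_reference_on_untied_windows(self):
        """Dual-route check against the vcfR R implementation on seeded
        data; windows with tied modal bins are excluded (the two
        implementations break ties differently, by design)."""
        rng = np.random.default_rng(7)
        n = 400
        pos = np.sort(rng.choice(np.arange(1, 100_001), n, replace=False))
        vals = np.where(pos < 50_000,
                        rng.binomial(100, 0.5, n) / 100.0,
                        rng.binomial(90, 2 / 3, n) / 90.0)
        vals = np.clip(vals, 0.01, 0.99)
        wt = freq_peak(pd.DataFrame({"s": vals}), pos,
                       window_size=20_000, bin_width=0.02, min_count=1)
        script = textwrap.dedent("""
            suppressMessages(library(vcfR))
            args <- commandArgs(trailingOnly=TRUE)
            v <- matrix(scan(args[1], quiet=TRUE), ncol=1)
            p <- scan(args[2], quiet=TRUE)
            fp <- freq_peak(v, p, winsize=20000, bin_width=0.02)
            cat(fp$peaks, sep="\\n")
        """)
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            np.savetxt(os.path.join(d, "v.txt"), vals)
            np.savetxt(os.path.join(d, "p.txt"), pos, fmt="%d")
            sp = os.path.join(d, "cmp.R")
            with open(sp, "w") as fh:
                fh.write(script)
            out = subprocess.run(
                ["Rscript", sp, os.path.join(d, "v.txt"),
                 os.path.join(d, "p.txt")],
                capture_output=True, text=True, check=True)
        ref = np.array([float(x) for x in out.stdout.split()])
        idx = (pos - 1) // 20_000
        for k in range(len(wt.coords)):
            occ = bin_counts(vals[idx == k], 0.02)
            if occ.max() > 0 and np.sum(occ == occ.max()) == 1:
                assert wt.peaks["s"].iloc[k] == pytest.approx(ref[k])


class TestRepos:
    def test_observed_max_offsets(self):
        chrom = ["A", "A", "B"]
        pos = [50, 100, 5]
        assert list(repos(chrom, pos, buffer=0)) == [50, 100, 105]
        assert list(repos(chrom, pos, buffer=10)) == [50, 100, 115]

    def test_declared_lengths_cumulative(self):
        chrom = ["A", "B", "C"]
        pos = [1, 1, 1]
        lengths = {"A": 1000, "B": 500, "C": 800}
        # cumulative-sum oracle: offsets 0, 1000, 1500
        assert list(repos(chrom, pos, chrom_lengths=lengths)) == [1, 1001, 1501]

    @given(st.integers(0, 1000))
    @settings(max_examples=50, derandomize=True)
    def test_within_chromosome_order_preserved(self, buffer):
        chrom = ["A"] * 3 + ["B"] * 3
        pos = [5, 10, 20, 3, 8, 13]
        out = repos(chrom, pos, buffer=buffer)
        assert list(np.diff(out[:3]) > 0) == [True, True]
        assert list(np.diff(out[3:]) > 0) == [True, True]


def test_bin_edges_cover_unit_interval():
    for w in (0.02, 0.05, 0.3, 0.5):
        e = bin_edges(w)
        assert e[0] == 0.0 and e[-1] == 1.0
        assert len(e) - 1 == int(np.ceil(1.0 / w))
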