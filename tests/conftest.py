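"""Shared fixtures: small in-memory VCF texts and brute-force oracles.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##contig=<ID=chr2,length=50000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB
"""

# 3 records x 2 samples; third record carries GT only.
VCF_BODY = """\
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:AD\t0/1:12,7\t0/0:20,0
chr1\t40000\t.\tC\tG,T\t.\tPASS\t.\tGT:AD\t1/2:3,9,5\t0/1:10,10
chr2\t5\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t./.
"""


@pytest.fixture
def small_vcf(tmp_path):
    p = tmp_path / "small.vcf"
    p.write_text(VCF_HEADER + VCF_BODY)
    return str(p)


@pytest.fixture
def empty_vcf(tmp_path):
    p = tmp_path / "empty.vcf"
    p.write_text(VCF_HEADER)
    return str(p)


def brute_force_peak(values, bin_width):
    """Independent modal-bin oracle: explicit per-value loop over
    half-open (lo, hi] bins; ties to the bin midpoint nearest 1/2, then
    the lower bin.  Returns (peak_midpoint_or_nan, count)."""
    n_bins = math.ceil(1.0 / bin_width)
    counts = [0] * n_bins
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if not 0.0 < v <= 1.0:
            continue
        for b in range(n_bins):
            lo = b * bin_width
            hi = min((b + 1) * bin_width, 1.0)
            if lo < v <= hi:
                counts[b] += 1
                break
    total = sum(counts)
    if total == 0 or max(counts) == 0:
        return float("nan"), total
    best = max(counts)
    candidates = [b for b, c in enumerate(counts) if c == best]
    mids = [(b * bin_width + min((b + 1) * bin_width, 1.0)) / 2.0
            for b in candidates]
    order = sorted(range(len(candidates)),
                   key=lambda i: (abs(mids[i] - 0.5), candidates[i]))
    return mids[order[0]], total


def nei_gst_oracle(genotype_counts_a, genotype_counts_b):
    """Textbook Nei Gst for two equal-sized diploid populations given
    per-allele count dicts; closed-form, no weighting shortcuts."""
    def freqs(counts):
        tot = sum(counts.values())
        return {a: c / tot for a, c in counts.items()}

    fa, fb = freqs(genotype_counts_a), freqs(genotype_counts_b)
    hs_a = 1.0 - sum(p * p for p in fa.values())
    hs_b = 1.0 - sum(p * p for p in fb.values())
    hs = (hs_a + hs_b) / 2.0
    alleles = set(fa) | set(fb)
    pooled = {a: (fa.get(a, 0.0) + fb.get(a, 0.0)) / 2.0 for a in alleles}
    ht = 1.0 - sum(p * p for p in pooled.values())
    return (ht - hs) / ht if ht > 0 else float("nan")
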