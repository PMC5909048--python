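"""Allele balance at heterozygous sites.

At a heterozygous position the sequencer samples reads from each allele
roughly in proportion to its copy number, so the fraction of reads carrying
the most abundant allele — the allele balance — concentrates near simple
dosage ratios: 1/2 in a diploid, 2/3 in a triploid carrying two copies of
one allele, 3/4 in a tetraploid with a 3:1 dosage, and so on.  This module
turns the AD depth strings into ordered depth pairs (masking everything
that is not a heterozygous call), converts them to balance matrices, and
offers per-sample depth-quantile censoring as a quality-control step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vcf_io import is_het

logger = logging.getLogger(__name__)

__all__ = ["AlleleDepthMatrix", "ad_to_depths", "depths_to_balance",
           "censor_by_depth"]


@dataclass
class AlleleDepthMatrix:
    """Ordered read depths of the two most abundant alleles at heterozygous
    genotypes.

    ``d1`` and ``d2`` are variants x samples float frames with
    ``d1 >= d2 >= 0``; cells at non-heterozygous or missing genotypes are
    ``nan``.  ``variants`` carries CHROM and POS (1-based) aligned to the
    rows.  Zero depth is data; ``nan`` is absence.
    """

    variants: pd.DataFrame
    d1: pd.DataFrame
    d2: pd.DataFrame

    def __post_init__(self) -> None:
        if self.d1.shape != self.d2.shape:
            raise ValueError("d1 and d2 shapes differ")
        if len(self.variants) != len(self.d1):
            raise ValueError("variant table does not align with depth matrix")

    @property
    def samples(self) -> list[str]:
        return list(self.d1.columns)

    def total(self) -> pd.DataFrame:
        """Per-cell total depth d1 + d2 (nan where missing)."""
        return self.d1 + self.d2

    def copy(self) -> "AlleleDepthMatrix":
        return AlleleDepthMatrix(self.variants.copy(), self.d1.copy(),
                                 self.d2.copy())

    def to_tsv(self, path: str) -> None:
        """Export as TSV with CHROM/POS leading columns; cells are
        ``d1,d2`` pairs (positions 1-based)."""
        out = self.variants[["CHROM", "POS"]].copy()
        for s in self.samples:
            a, b = self.d1[s], self.d2[s]
            out[s] = [
                "" if np.isnan(x) else f"{x:g},{y:g}" for x, y in zip(a, b)
            ]
        out.to_csv(path, sep="\t", index=False)


def _parse_ad_pair(cell: object) -> tuple[float, float]:
    """Two largest AD entries, descending; (nan, nan) if unusable."""
    if cell is None or cell is pd.NA or (isinstance(cell, float) and np.isnan(cell)):
        return (np.nan, np.nan)
    vals = []
    for p in str(cell).split(","):
        p = p.strip()
        if p in (".", ""):
            continue
        try:
            vals.append(float(p))
        except ValueError:
            pass
    if len(vals) < 2:
        return (np.nan, np.nan)
    vals.sort(reverse=True)
    return (vals[0], vals[1])


def ad_to_depths(
    ad_matrix: pd.DataFrame,
    gt_matrix: pd.DataFrame,
    variants: pd.DataFrame | None = None,
) -> AlleleDepthMatrix:
    """Mask non-heterozygous genotypes and order each AD cell's two largest
    depths.

    Only cells whose genotype is heterozygous (two or more distinct alleles
    observed) contribute; at multiallelic records the two most abundant
    alleles are kept.  Homozygous, half-missing and missing genotypes give
    missing cells.
    """
    if ad_matrix.shape != gt_matrix.shape:
        raise ValueError(
            f"AD matrix {ad_matrix.shape} and GT matrix {gt_matrix.shape} "
            "dimensions differ"
        )
    if variants is None:
        variants = pd.DataFrame({
            "CHROM": ["."] * len(ad_matrix),
            "POS": np.arange(1, len(ad_matrix) + 1, dtype=np.int64),
        })
    n, _ = ad_matrix.shape
    d1 = {}
    d2 = {}
    for col in ad_matrix.columns:
        a = np.full(n, np.nan)
        b = np.full(n, np.nan)
        ad_col = ad_matrix[col].to_numpy(dtype=object)
        gt_col = gt_matrix[col].to_numpy(dtype=object)
        for i in range(n):
            if is_het(gt_col[i]) is True:
                a[i], b[i] = _parse_ad_pair(ad_col[i])
        d1[col] = a
        d2[col] = b
    return AlleleDepthMatrix(
        variants.reset_index(drop=True),
        pd.DataFrame(d1, columns=ad_matrix.columns),
        pd.DataFrame(d2, columns=ad_matrix.columns),
    )


def depths_to_balance(
    depths: AlleleDepthMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert ordered depths to allele-balance frequencies.

    Returns ``(dominant, secondary)`` frames: dominant = d1/(d1+d2) in
    [1/2, 1], secondary = d2/(d1+d2) in [0, 1/2]; the two sum to one
    wherever defined.  Cells with zero total depth are missing.
    """
    total = depths.total()
    with np.errstate(invalid="ignore", divide="ignore"):
        dom = depths.d1 / total
        sec = depths.d2 / total
    zero = total == 0
    dom = dom.mask(zero)
    sec = sec.mask(zero)
    return dom, sec


def censor_by_depth(
    depths: AlleleDepthMatrix,
    lower_q: float = 0.05,
    upper_q: float = 0.95,
) -> AlleleDepthMatrix:
    """Censor cells of unusual total coverage, per sample.

    For each sample, the empirical ``lower_q`` and ``upper_q`` quantiles of
    its non-missing total depths are computed (linear interpolation); cells
    whose total lies strictly outside ``[lo, hi]`` are set missing.  Trims
    the long high- and low-coverage tails typical of high-throughput
    sequencing.  Samples with no non-missing cells are left unchanged.
    """
    if not 0.0 <= lower_q < upper_q <= 1.0:
        raise ValueError("require 0 <= lower_q < upper_q <= 1")
    out = depths.copy()
    total = depths.total()
    n_censored = 0
    for s in depths.samples:
        t = total[s].to_numpy(dtype=float)
        finite = t[~np.isnan(t)]
        if finite.size == 0:
            logger.warning("sample %s has no usable depths; not censored", s)
            continue
        lo, hi = np.quantile(finite, [lower_q, upper_q])
        bad = (~np.isnan(t)) & ((t < lo) | (t > hi))
        out.d1.loc[bad, s] = np.nan
        out.d2.loc[bad, s] = np.nan
        n_censored += int(bad.sum())
    logger.info("depth censoring (q=%.3g..%.3g) removed %d cells",
                lower_q, upper_q, n_censored)
    return out
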