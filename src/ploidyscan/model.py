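"""Model-style front end: build a scan from data, ``fit()``, inspect results.

Two entry points:

``PloidyScan``
    Holds the dominant/secondary allele-balance matrices derived from a
    VCF (or supplied directly); ``fit()`` runs the windowing, peak calling
    and copy-number assignment and returns a :class:`PloidyScanResults`
    with the per-window estimates, their distance-from-expectation
    confidences and a ``summary()`` table.

``PopulationDifferentiation``
    Holds a GT matrix plus a sample-to-population map; ``fit()`` computes
    the per-variant allele-count-weighted differentiation table.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import allele_balance, ploidy_call, pop_diff, vcf_io, window_peaks
from .allele_balance import AlleleDepthMatrix
from .ploidy_call import PloidyCalls
from .window_peaks import (DEFAULT_BIN_WIDTH, DEFAULT_MIN_COUNT,
                           DEFAULT_WINDOW_SIZE, WindowTable)

logger = logging.getLogger(__name__)

__all__ = ["PloidyScan", "PloidyScanResults",
           "PopulationDifferentiation", "DifferentiationResults"]


class PloidyScan:
    """Allele-balance copy-number scan over one or more samples.

    Parameters
    ----------
    dominant, secondary
        Variants x samples balance matrices (dominant in [1/2, 1],
        secondary in [0, 1/2], nan missing).
    variants
        Aligned table with CHROM and POS (1-based).
    """

    def __init__(self, dominant: pd.DataFrame, secondary: pd.DataFrame,
                 variants: pd.DataFrame,
                 depths: AlleleDepthMatrix | None = None) -> None:
        if dominant.shape != secondary.shape:
            raise ValueError("dominant/secondary shapes differ")
        if len(variants) != len(dominant):
            raise ValueError("variant table does not align with balances")
        self.dominant = dominant
        self.secondary = secondary
        self.variants = variants.reset_index(drop=True)
        self.depths = depths

    @classmethod
    def from_vcf(cls, path: str, samples: Sequence[str] | None = None,
                 depth_quantiles: tuple[float, float] | None = None,
                 ) -> "PloidyScan":
        """Build a scan from a VCF with GT and AD FORMAT fields.

        ``depth_quantiles`` (lower, upper) optionally censors cells of
        unusual total depth per sample before computing balances.
        """
        variants, mats = vcf_io.read_vcf(path, samples=samples,
                                         format_fields=("GT", "AD"))
        if mats["AD"].isna().all().all():
            raise ValueError(
                f"VCF {path!r} carries no AD FORMAT data; allele balance "
                "needs per-allele read depths")
        depths = allele_balance.ad_to_depths(mats["AD"], mats["GT"], variants)
        if depth_quantiles is not None:
            depths = allele_balance.censor_by_depth(depths, *depth_quantiles)
        dom, sec = allele_balance.depths_to_balance(depths)
        return cls(dom, sec, variants, depths=depths)

    @property
    def samples(self) -> list[str]:
        return list(self.dominant.columns)

    def fit(self, window_size: int = DEFAULT_WINDOW_SIZE,
            bin_width: float = DEFAULT_BIN_WIDTH,
            min_count: int = DEFAULT_MIN_COUNT,
            max_dfe: float | None = None) -> "PloidyScanResults":
        """Run the windowed peak calling and copy-number assignment.

        The dominant-allele matrix drives the copy-number calls; the
        secondary matrix is windowed too as a diagnostic (its peaks should
        mirror the dominant ones about 1/2).  ``max_dfe`` optionally
        removes border cases after assignment.
        """
        chrom = self.variants["CHROM"].to_numpy()
        pos = self.variants["POS"].to_numpy()
        windows = window_peaks.freq_peak(
            self.dominant, pos, window_size=window_size,
            bin_width=bin_width, min_count=min_count, chrom=chrom)
        windows_secondary = window_peaks.freq_peak(
            self.secondary, pos, window_size=window_size,
            bin_width=bin_width, min_count=min_count, chrom=chrom)
        calls = {s: ploidy_call.peak_to_ploid(windows.peaks[s].to_numpy())
                 for s in self.samples}
        if max_dfe is not None:
            calls = {s: ploidy_call.filter_calls(c, max_dfe)
                     for s, c in calls.items()}
        params = {"window_size": window_size, "bin_width": bin_width,
                  "min_count": min_count, "max_dfe": max_dfe}
        return PloidyScanResults(self, windows, windows_secondary, calls,
                                 params)


@dataclass
class PloidyScanResults:
    """Fitted scan: window peaks plus per-window copy-number calls."""

    model: PloidyScan
    windows: WindowTable
    windows_secondary: WindowTable
    calls: Mapping[str, PloidyCalls]
    params: dict

    @property
    def samples(self) -> list[str]:
        return self.model.samples

    def call_table(self) -> pd.DataFrame:
        """Window coordinates plus per-sample PEAK, COPY_NUMBER and DFE
        columns (positions 1-based, inclusive)."""
        out = self.windows.coords.copy()
        for s in self.samples:
            out[f"PEAK_{s}"] = self.windows.peaks[s].to_numpy()
            out[f"COUNT_{s}"] = self.windows.counts[s].to_numpy()
            out[f"COPY_NUMBER_{s}"] = self.calls[s].copy_number
            out[f"DFE_{s}"] = self.calls[s].dfe
        return out

    def summary(self) -> str:
        """Human-readable per-sample summary of the scan."""
        lines = ["Allele-balance copy-number scan",
                 "=" * 47,
                 "windows: {} (size {} bp, bin width {}, min count {})".format(
                     len(self.windows.coords), self.params["window_size"],
                     self.params["bin_width"], self.params["min_count"]),
                 "positions 1-based; dfe: 0 = at expectation, "
                 "1 = between expectations", ""]
        header = (f"{'sample':<16}{'called':>8}{'censored':>10}"
                  f"{'modal CN':>10}{'mean dfe':>10}")
        lines.append(header)
        lines.append("-" * len(header))
        for s in self.samples:
            cn = self.calls[s].copy_number
            dfe = self.calls[s].dfe
            called = int(np.sum(~np.isnan(cn)))
            censored = int(len(cn) - called)
            modal = (int(pd.Series(cn[~np.isnan(cn)]).mode().iloc[0])
                     if called else "-")
            mean_dfe = (f"{np.nanmean(dfe):.3f}" if called else "-")
            lines.append(f"{s:<16}{called:>8}{censored:>10}"
                         f"{modal!s:>10}{mean_dfe:>10}")
        return "\n".join(lines)

    def to_tsv(self, directory: str, prefix: str = "ploidyscan") -> dict:
        """Write windows.tsv (peak engine output) and calls.tsv
        (copy-number calls); returns the paths."""
        os.makedirs(directory, exist_ok=True)
        paths = {
            "windows": os.path.join(directory, f"{prefix}_windows.tsv"),
            "calls": os.path.join(directory, f"{prefix}_calls.tsv"),
        }
        self.windows.to_tsv(paths["windows"])
        self.call_table().to_csv(paths["calls"], sep="\t", index=False,
                                 na_rep="NA")
        return paths

    def plot(self, chrom: str, sample: str, ax=None):
        """Balance-along-chromosome plot with window-peak bars and a
        marginal histogram (see :mod:`ploidyscan.plotting`)."""
        from . import plotting
        return plotting.freq_peak_plot(self, chrom, sample, ax=ax)


class PopulationDifferentiation:
    """Per-variant differentiation model for mixed-ploidy populations."""

    def __init__(self, gt_matrix: pd.DataFrame, variants: pd.DataFrame,
                 pops: Mapping[str, str]) -> None:
        self.gt_matrix = gt_matrix
        self.variants = variants.reset_index(drop=True)
        self.pops = dict(pops)

    @classmethod
    def from_vcf(cls, path: str, popmap: str | Mapping[str, str],
                 samples: Sequence[str] | None = None,
                 ) -> "PopulationDifferentiation":
        pops = (pop_diff.read_popmap(popmap) if isinstance(popmap, str)
                else dict(popmap))
        if samples is None:
            samples = [s for s in pops]
        variants, mats = vcf_io.read_vcf(path, samples=samples,
                                         format_fields=("GT",))
        return cls(mats["GT"], variants, pops)

    def fit(self) -> "DifferentiationResults":
        table = pop_diff.genetic_diff(self.gt_matrix, self.variants,
                                      self.pops)
        return DifferentiationResults(self, table)


@dataclass
class DifferentiationResults:
    """Fitted differentiation table with summary statistics."""

    model: PopulationDifferentiation
    table: pd.DataFrame

    def summary(self) -> str:
        t = self.table
        pops = [c[3:] for c in t.columns if c.startswith("Hs_")]
        lines = ["Allele-count-weighted differentiation",
                 "=" * 47,
                 f"variants: {len(t)}   populations: {', '.join(pops)}", ""]
        for col in ["Ht", "Gst", "Gstmax", "Gprimest"]:
            v = t[col].to_numpy(dtype=float)
            ok = v[~np.isnan(v)]
            lines.append(
                f"{col:>9}: mean {np.mean(ok):.4f}  median "
                f"{np.median(ok):.4f}  (defined at {ok.size}/{len(t)})"
                if ok.size else f"{col:>9}: undefined everywhere")
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")
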