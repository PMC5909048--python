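"""Per-variant genetic differentiation for mixed-ploidy populations.

Classical Nei G_ST and Hedrick G'_ST are ratios of heterozygosities
(gene diversities, Hs = 1 - sum_i p_i^2).  When populations mix copy
numbers — or are simply unbalanced — a tetraploid population contributes
twice the allelic information of a diploid one of the same size, so the
within-population diversities are weighted by the number of alleles
actually observed in each population at each variant, w_k = n_k / sum(n):

    Hs    = sum_k w_k Hs_k
    p_bar = sum_k w_k p_k              (pooled allele frequencies)
    Ht    = 1 - sum_i p_bar_i^2
    Gst   = (Ht - Hs) / Ht
    Htmax = 1 - sum_k w_k^2 (1 - Hs_k)   (total diversity were no allele
                                          shared between populations)
    Gstmax  = (Htmax - Hs) / Htmax
    G'st    = Gst / Gstmax             (Hedrick's standardization)

With equal weights across k populations, Htmax reduces to Hedrick's
HT(max) = 1 - (1 - Hs)/k = (k - 1 + Hs)/k.  Genotypes of any ploidy
(and mixtures across samples) are supported: every non-missing allele in
every call contributes one count.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_popmap", "count_alleles", "weighted_diff_stats",
           "genetic_diff"]

_ALLELE_SPLIT = re.compile(r"[/|]")


def read_popmap(path: str) -> dict[str, str]:
    """Read a two-column headerless sample-to-population file
    (whitespace- or comma-delimited)."""
    pops: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'sample population', got {line!r}"
                )
            pops[parts[0]] = parts[1]
    return pops


def count_alleles(
    gt_matrix: pd.DataFrame,
    pops: Mapping[str, str],
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Count alleles per variant and population from GT strings.

    Genotypes may have any ploidy (``0/1``, ``0/1/1``, ...) and ploidy may
    differ across samples.  Every non-missing allele index contributes one
    count to its sample's population.

    Returns
    -------
    counts : dict population -> (variants x alleles) count matrix, allele
        columns indexed 0..max allele index seen anywhere.
    n : DataFrame (variants x populations) of total observed alleles n_k.
    """
    unassigned = [s for s in gt_matrix.columns if s not in pops]
    if unassigned:
        raise KeyError(
            f"sample(s) without population assignment: {', '.join(unassigned)}"
        )
    pop_labels = list(dict.fromkeys(pops[s] for s in gt_matrix.columns))
    n_var = len(gt_matrix)

    # First pass over parsed alleles to size the count matrices.
    parsed: dict[str, list[list[int]]] = {}
    max_allele = 0
    for s in gt_matrix.columns:
        col = []
        for cell in gt_matrix[s]:
            if cell is None or cell is pd.NA or (
                    isinstance(cell, float) and np.isnan(cell)):
                col.append([])
                continue
            alleles = [int(a) for a in _ALLELE_SPLIT.split(str(cell))
                       if a not in (".", "")]
            if alleles:
                max_allele = max(max_allele, max(alleles))
            col.append(alleles)
        parsed[s] = col

    counts = {p: np.zeros((n_var, max_allele + 1), dtype=np.int64)
              for p in pop_labels}
    for s in gt_matrix.columns:
        mat = counts[pops[s]]
        for i, alleles in enumerate(parsed[s]):
            for a in alleles:
                mat[i, a] += 1
    n = pd.DataFrame({p: counts[p].sum(axis=1) for p in pop_labels})
    return counts, n


def weighted_diff_stats(
    hs: np.ndarray,
    n: np.ndarray,
    ht: float | None = None,
) -> dict[str, float]:
    """Allele-count-weighted differentiation statistics for one variant.

    Parameters
    ----------
    hs
        Within-population gene diversities Hs_k.
    n
        Observed allele counts n_k (the weights are n_k / sum(n)).
    ht
        Total gene diversity of the pooled populations.  When omitted only
        the quantities that do not need it (Hs, Htmax, Gstmax) are finite.

    Returns
    -------
    dict with keys Hs, Ht, Gst, Htmax, Gstmax, Gprimest.  Ratios with a
    zero denominator are nan.
    """
    hs = np.asarray(hs, dtype=float)
    n = np.asarray(n, dtype=float)
    if hs.shape != n.shape:
        raise ValueError("hs and n must align")
    total = n.sum()
    if total <= 0:
        return {k: np.nan for k in
                ("Hs", "Ht", "Gst", "Htmax", "Gstmax", "Gprimest")}
    w = n / total
    hs_bar = float(np.sum(w * hs))
    htmax = float(1.0 - np.sum(w ** 2 * (1.0 - hs)))
    ht_val = np.nan if ht is None else float(ht)
    gst = (ht_val - hs_bar) / ht_val if ht_val and not np.isnan(ht_val) \
        else np.nan
    gstmax = (htmax - hs_bar) / htmax if htmax != 0 else np.nan
    gprimest = gst / gstmax if gstmax not in (0,) and not np.isnan(gstmax) \
        and not np.isnan(gst) else np.nan
    return {"Hs": hs_bar, "Ht": ht_val, "Gst": gst, "Htmax": htmax,
            "Gstmax": gstmax, "Gprimest": gprimest}


def genetic_diff(
    gt_matrix: pd.DataFrame,
    variants: pd.DataFrame,
    pops: Mapping[str, str],
) -> pd.DataFrame:
    """Per-variant differentiation table for two or more populations.

    Returns a DataFrame with columns CHROM, POS, Hs_<pop> for each
    population, Ht, n_<pop>, Gst, Htmax, Gstmax, Gprimest.  Monomorphic
    variants (Ht = 0) yield nan Gst rather than 0.
    """
    pop_labels = list(dict.fromkeys(pops[s] for s in gt_matrix.columns
                                    if s in pops))
    if len(pop_labels) < 2:
        raise ValueError("need >= 2 populations with samples")
    counts, n = count_alleles(gt_matrix, pops)
    n_var = len(gt_matrix)

    hs_pop = {}
    freq = {}
    for p in pop_labels:
        cnt = counts[p].astype(float)
        tot = cnt.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = cnt / tot
        freq[p] = f
        hs_pop[p] = 1.0 - np.nansum(f ** 2, axis=1)
        hs_pop[p][tot[:, 0] == 0] = np.nan

    n_mat = n.to_numpy(dtype=float)
    total = n_mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = n_mat / total[:, None]
    hs_bar = np.nansum(
        np.column_stack([hs_pop[p] for p in pop_labels]) * w, axis=1)
    hs_bar[total == 0] = np.nan

    pooled = np.zeros_like(freq[pop_labels[0]])
    for j, p in enumerate(pop_labels):
        pooled += np.where(np.isnan(freq[p]), 0.0, freq[p]) * \
            np.where(np.isnan(w[:, j:j + 1]), 0.0, w[:, j:j + 1])
    ht = 1.0 - np.sum(pooled ** 2, axis=1)
    ht[total == 0] = np.nan

    one_minus_hs = np.column_stack(
        [1.0 - hs_pop[p] for p in pop_labels])
    htmax = 1.0 - np.nansum(w ** 2 * one_minus_hs, axis=1)
    htmax[total == 0] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        gst = np.where(ht != 0, (ht - hs_bar) / ht, np.nan)
        gstmax = np.where(htmax != 0, (htmax - hs_bar) / htmax, np.nan)
        gprimest = np.where((gstmax != 0) & ~np.isnan(gstmax),
                            gst / gstmax, np.nan)

    out = pd.DataFrame({
        "CHROM": variants["CHROM"].to_numpy(),
        "POS": variants["POS"].to_numpy(),
    })
    for p in pop_labels:
        out[f"Hs_{p}"] = hs_pop[p]
    out["Ht"] = ht
    for p in pop_labels:
        out[f"n_{p}"] = n[p].to_numpy()
    out["Gst"] = gst
    out["Htmax"] = htmax
    out["Gstmax"] = gstmax
    out["Gprimest"] = gprimest
    n_mono = int(np.sum((ht == 0) & ~np.isnan(ht)))
    if n_mono:
        logger.info("genetic_diff: %d monomorphic variants -> Gst missing",
                    n_mono)
    return out
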