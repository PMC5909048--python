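"""Read VCF records into per-sample genotype-field matrices.

VCF genotype (FORMAT) fields arrive as delimited strings — ``GT`` as
``"0/1"``, allele depth ``AD`` as ``"12,7"``.  This module materialises them
as variants x samples :class:`pandas.DataFrame` objects of strings, the
layout every downstream step consumes.  Missing data is the pandas missing
sentinel (``pd.NA``), never the literal string ``"."``: a cell is missing
when the FORMAT key is absent from a record (or the value is the VCF null),
while ``"./."`` remains an ordinary genotype string whose alleles happen to
be missing.

Positions are 1-based and intervals inclusive throughout, as in the VCF
specification.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = ["read_vcf", "write_vcf", "is_het", "masplit", "masplit_matrix"]

_GT_SEPARATORS = ("/", "|")


def _format_gt(sample_rec) -> object:
    """Reconstitute the GT string for one sample record, ``pd.NA`` if absent."""
    alleles = sample_rec.get("GT")
    if alleles is None or len(alleles) == 0:
        return pd.NA
    sep = "|" if sample_rec.phased else "/"
    return sep.join("." if a is None else str(a) for a in alleles)


def _format_numeric_field(value) -> object:
    """Render a parsed FORMAT value (tuple of ints/floats) back to its
    comma-delimited string form; fully-null values are missing."""
    if value is None:
        return pd.NA
    if isinstance(value, (tuple, list)):
        if all(v is None for v in value):
            return pd.NA
        return ",".join("." if v is None else str(v) for v in value)
    return str(value)


def read_vcf(
    path: str,
    samples: Sequence[str] | None = None,
    format_fields: Sequence[str] = ("GT", "AD"),
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Read a VCF (plain or bgzipped) into a variant table plus one string
    matrix per requested FORMAT key.

    Parameters
    ----------
    path
        VCF v4.x file with a FORMAT column.
    samples
        Optional subset of sample names; order is preserved.  Unknown names
        raise ``KeyError``.
    format_fields
        FORMAT keys to extract (default GT and AD).

    Returns
    -------
    variants : DataFrame with columns CHROM, POS (1-based), REF, ALT — one
        row per record, in file order.
    matrices : dict mapping each requested key to a variants x samples
        DataFrame of raw field strings (``pd.NA`` where the record does not
        carry the key).
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc

    header_samples = list(vf.header.samples)
    if samples is None:
        use_samples = header_samples
    else:
        missing = [s for s in samples if s not in header_samples]
        if missing:
            raise KeyError(
                f"sample(s) not in VCF header: {', '.join(missing)}"
            )
        use_samples = list(samples)

    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    cells: dict[str, list[list[object]]] = {k: [] for k in format_fields}

    record_no = 0
    try:
        for rec in vf:
            record_no += 1
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref or ".")
            alt.append(",".join(rec.alts) if rec.alts else ".")
            for key in format_fields:
                key_present = key in rec.format
                row: list[object] = []
                for s in use_samples:
                    if not key_present:
                        row.append(pd.NA)
                    elif key == "GT":
                        row.append(_format_gt(rec.samples[s]))
                    else:
                        row.append(_format_numeric_field(rec.samples[s].get(key)))
                cells[key].append(row)
    except (ValueError, OSError) as exc:
        raise ValueError(
            f"malformed VCF record at data line {record_no + 1} of {path!r}: {exc}"
        ) from exc

    variants = pd.DataFrame(
        {"CHROM": chrom, "POS": np.asarray(pos, dtype=np.int64),
         "REF": ref, "ALT": alt}
    )
    matrices = {
        key: pd.DataFrame(cells[key], columns=use_samples, dtype=object)
        for key in format_fields
    }
    logger.info("read %d variants x %d samples from %s",
                len(variants), len(use_samples), path)
    return variants, matrices


def write_vcf(
    variants: pd.DataFrame,
    matrices: Mapping[str, pd.DataFrame],
    path: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a variant table and its FORMAT-field string matrices back to a
    plain-text VCF v4.2 file.

    The inverse of :func:`read_vcf` for the fields it carries: re-reading
    the written file reproduces the same matrices (missing cells are
    serialised as the VCF null ``"."``).
    """
    keys = list(matrices)
    samples = list(next(iter(matrices.values())).columns) if keys else []
    lines = ["##fileformat=VCFv4.2"]
    contigs = dict.fromkeys(variants["CHROM"].astype(str))
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    if "GT" in keys:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if "AD" in keys:
        lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                      'Description="Allelic depths for the ref and alt alleles">')
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        header += "\tFORMAT\t" + "\t".join(samples)
    lines.append(header)

    fmt = ":".join(keys)
    for i in range(len(variants)):
        row = variants.iloc[i]
        fields = [str(row["CHROM"]), str(int(row["POS"])), ".",
                  str(row.get("REF", "A")), str(row.get("ALT", "T")),
                  ".", ".", "."]
        if samples:
            fields.append(fmt)
            for s in samples:
                parts = []
                for key in keys:
                    v = matrices[key].iloc[i][s]
                    parts.append("." if pd.isna(v) else str(v))
                fields.append(":".join(parts))
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def is_het(gt: object) -> object:
    """Classify a genotype string as heterozygous.

    Returns ``True`` iff at least two distinct non-missing allele indices
    appear, ``False`` if all non-missing alleles are identical (including
    half-missing calls like ``"./1"``), and ``pd.NA`` when every allele is
    missing or the string cannot be parsed.  Phase separators ``/`` and
    ``|`` are treated identically.
    """
    if gt is None or (isinstance(gt, float) and np.isnan(gt)) or gt is pd.NA:
        return pd.NA
    s = str(gt)
    for sep in _GT_SEPARATORS[1:]:
        s = s.replace(sep, _GT_SEPARATORS[0])
    alleles = s.split(_GT_SEPARATORS[0])
    observed = set()
    for a in alleles:
        a = a.strip()
        if a in (".", ""):
            continue
        if not a.isdigit():
            logger.debug("unparseable genotype %r -> missing", gt)
            return pd.NA
        observed.add(a)
    if not observed:
        return pd.NA
    return len(observed) >= 2


def masplit(
    cell: object,
    delimiter: str = ",",
    record: int = 1,
    sort_desc: bool = False,
) -> float:
    """Isolate one element from a delimited numeric string.

    With ``sort_desc`` the ``record``-th largest element is returned (so
    ``record=1`` is the maximum); otherwise the ``record``-th element in
    written order.  ``record`` is 1-based.  Missing cells, out-of-range
    records and non-numeric elements give ``nan``.
    """
    if cell is None or cell is pd.NA or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    parts = str(cell).split(delimiter)
    values = []
    for p in parts:
        p = p.strip()
        if p in (".", ""):
            continue
        try:
            values.append(float(p))
        except ValueError:
            logger.debug("non-numeric element %r in cell %r", p, cell)
    if record < 1 or record > len(values):
        logger.debug("record %d out of range for cell %r", record, cell)
        return np.nan
    if sort_desc:
        values.sort(reverse=True)
    return values[record - 1]


def masplit_matrix(
    matrix: pd.DataFrame,
    delimiter: str = ",",
    record: int = 1,
    sort_desc: bool = False,
) -> pd.DataFrame:
    """Apply :func:`masplit` to every cell of a string matrix, returning a
    float matrix with ``nan`` for missing."""
    out = {
        col: [masplit(v, delimiter, record, sort_desc) for v in matrix[col]]
        for col in matrix.columns
    }
    return pd.DataFrame(out, index=matrix.index, dtype=float)
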