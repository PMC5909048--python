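"""Copy-number assignment from allele-balance peaks.

A dominant-allele peak is matched to the nearest expected dosage ratio —
1/5, 1/4, 1/3, 1/2, 2/3, 3/4, 4/5, corresponding to copy numbers
5, 4, 3, 2, 3, 4, 5 — using critical values half way between adjacent
expectations.  Confidence is expressed as the distance from expectation
(dfe): the absolute gap between the observed peak and its assigned
expectation, divided by the gap from that expectation to the critical
value on the side where the peak lies.  dfe is 0 exactly at an expectation
and 1 half way between two expectations, so border cases can be filtered
with a single threshold.

Peaks closer to homozygosity than to any supported ratio — below 7/40 =
0.175 or above 33/40 = 0.825, a half-gap beyond the extreme expectations —
receive no call.  Note one ambiguity inherent to a single modal bin: a
peak at 1/2 is called copy number 2, although 1/2 is also the central
tetraploid expectation; a tetraploid reveals itself through the flanking
1/4 / 3/4 peaks, not the central one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["EXPECTATIONS", "COPY_NUMBERS", "CRITICAL_VALUES",
           "LOWER_BOUND", "UPPER_BOUND", "PloidyCalls", "peak_to_ploid",
           "filter_calls"]

#: Expected dominant/secondary allele-balance ratios, ascending.
EXPECTATIONS = np.array([1 / 5, 1 / 4, 1 / 3, 1 / 2, 2 / 3, 3 / 4, 4 / 5])
#: Copy number implied by each expectation.
COPY_NUMBERS = np.array([5, 4, 3, 2, 3, 4, 5])
#: Midpoints between adjacent expectations.
CRITICAL_VALUES = np.array([9 / 40, 7 / 24, 5 / 12, 7 / 12, 17 / 24, 31 / 40])
#: Outermost callable peaks: a half-gap (1/40) beyond 1/5 and 4/5.
LOWER_BOUND = 7 / 40
UPPER_BOUND = 33 / 40

# Interval edges per expectation; at a critical value the interval nearer
# 1/2 owns the point, so the 1/2 interval is closed on both sides and the
# assignment stays symmetric about 1/2.
_LO = np.concatenate(([LOWER_BOUND], CRITICAL_VALUES))
_HI = np.concatenate((CRITICAL_VALUES, [UPPER_BOUND]))
_LO_CLOSED = np.array([True, True, True, True, False, False, False])
_HI_CLOSED = np.array([False, False, False, True, True, True, True])


@dataclass
class PloidyCalls:
    """Per-peak copy-number calls (arrays aligned with the input peaks).

    ``expectation`` is the assigned dosage ratio, ``copy_number`` the
    implied integer copies (as float, nan where uncallable) and ``dfe``
    the distance from expectation in [0, 1].
    """

    expectation: np.ndarray
    copy_number: np.ndarray
    dfe: np.ndarray

    def __len__(self) -> int:
        return self.expectation.size

    def copy(self) -> "PloidyCalls":
        return PloidyCalls(self.expectation.copy(), self.copy_number.copy(),
                           self.dfe.copy())


def peak_to_ploid(peaks) -> PloidyCalls:
    """Assign peaks to expected dosage ratios and score their confidence.

    Parameters
    ----------
    peaks
        Scalar, array or DataFrame of peak locations in the open interval
        (0, 1), nan for missing.  Values at 0 or 1 are homozygous
        artifacts that must be excluded upstream and raise ``ValueError``.

    Returns
    -------
    PloidyCalls with the same shape as the input.  Peaks outside
    [0.175, 0.825] get a missing call (nan throughout).
    """
    arr = np.asarray(peaks, dtype=float)
    finite = ~np.isnan(arr)
    if np.any(finite & ((arr <= 0) | (arr >= 1))):
        bad = arr[finite & ((arr <= 0) | (arr >= 1))].flat[0]
        raise ValueError(
            f"peak {bad!r} outside (0, 1): values at 0 or 1 are expected to "
            "be homozygous calls and must be excluded upstream"
        )

    expectation = np.full(arr.shape, np.nan)
    copy_number = np.full(arr.shape, np.nan)
    dfe = np.full(arr.shape, np.nan)
    for i in range(EXPECTATIONS.size):
        lo_ok = arr >= _LO[i] if _LO_CLOSED[i] else arr > _LO[i]
        hi_ok = arr <= _HI[i] if _HI_CLOSED[i] else arr < _HI[i]
        sel = finite & lo_ok & hi_ok
        if not np.any(sel):
            continue
        e = EXPECTATIONS[i]
        expectation[sel] = e
        copy_number[sel] = COPY_NUMBERS[i]
        gap_below = e - _LO[i]
        gap_above = _HI[i] - e
        dev = arr[sel] - e
        dfe[sel] = np.abs(dev) / np.where(dev >= 0, gap_above, gap_below)
    return PloidyCalls(expectation, copy_number, dfe)


def filter_calls(calls: PloidyCalls, max_dfe: float) -> PloidyCalls:
    """Remove border cases: calls with dfe > ``max_dfe`` become missing.

    The input is untouched; a new collection is returned and the number of
    removed calls is logged.
    """
    if not 0.0 <= max_dfe <= 1.0:
        raise ValueError("max_dfe must be in [0, 1]")
    out = calls.copy()
    bad = ~np.isnan(out.dfe) & (out.dfe > max_dfe)
    out.expectation[bad] = np.nan
    out.copy_number[bad] = np.nan
    out.dfe[bad] = np.nan
    logger.info("filter_calls: removed %d of %d calls (dfe > %g)",
                int(bad.sum()), int(np.sum(~np.isnan(calls.dfe))), max_dfe)
    return out
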