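"""Age-band definitions and assignment.

Two band systems are used throughout the package:

* ``ANALYSIS_BANDS`` — the bands used for sepsis tabulation and the decision
  model: 0-4, 5-14, then 10-year bands up to an open-ended 85+ band.
* ``FIVE_YEAR_BANDS`` — 5-year bands up to 104 years, used by the stratified
  sampling design for consultation-rate estimation.

A band is a ``(low, high)`` pair of integer ages in completed years, with
``high=None`` meaning open-ended. Band labels are strings such as ``"0-4"``
or ``"85+"``.
"""
from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

Band = Tuple[int, Optional[int]]

ANALYSIS_BANDS: Sequence[Band] = (
    (0, 4), (5, 14), (15, 24), (25, 34), (35, 44),
    (45, 54), (55, 64), (65, 74), (75, 84), (85, None),
)

FIVE_YEAR_BANDS: Sequence[Band] = tuple(
    (lo, lo + 4) for lo in range(0, 105, 5)
)


class BandError(ValueError):
    """Raised for overlapping or non-exhaustive band definitions."""


def band_label(band: Band) -> str:
    lo, hi = band
    return f"{lo}+" if hi is None else f"{lo}-{hi}"


def band_labels(bands: Sequence[Band]) -> list[str]:
    return [band_label(b) for b in bands]


def validate_bands(bands: Sequence[Band]) -> None:
    """Check that bands are sorted, non-overlapping and exhaustive from 0.

    Raises :class:`BandError` otherwise. Bands with a finite top edge must
    abut (``next.lo == prev.hi + 1``); only the last band may be open-ended.
    """
    if not bands:
        raise BandError("empty band list")
    if bands[0][0] != 0:
        raise BandError(f"bands must start at age 0, got {bands[0][0]}")
    for i, (lo, hi) in enumerate(bands):
        last = i == len(bands) - 1
        if hi is None:
            if not last:
                raise BandError(f"open-ended band {band_label((lo, hi))} must be last")
            continue
        if hi < lo:
            raise BandError(f"band {band_label((lo, hi))} has high < low")
        if not last:
            nxt = bands[i + 1][0]
            if nxt <= hi:
                raise BandError(
                    f"bands {band_label((lo, hi))} and starting at {nxt} overlap"
                )
            if nxt != hi + 1:
                raise BandError(f"gap between age {hi} and {nxt}")


def assign_band(ages, bands: Sequence[Band] = ANALYSIS_BANDS):
    """Vectorised band assignment: integer ages -> band labels.

    Ages beyond the last finite band edge fall into the final band (which is
    normally open-ended). Negative ages raise.
    """
    validate_bands(bands)
    ages = np.asarray(ages)
    if ages.size and ages.min() < 0:
        raise BandError("negative age")
    edges = [b[0] for b in bands[1:]]
    idx = np.searchsorted(edges, ages, side="right")
    labels = np.asarray(band_labels(bands), dtype=object)
    return labels[idx]
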