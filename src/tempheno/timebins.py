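"""Anchor-relative six-month time bins.

All windows count backward from a per-patient anchor date (AMI onset for
cases, last encounter for controls).  The five-year observation span is cut
into ten 183-day bins; bin 9 is the most recent, covering
``(anchor - 183 d, anchor]``.  Bins are half-open ``(older, newer]`` so an
event exactly 183 days before the anchor falls in bin 8.
"""

import numpy as np

N_BINS = 10
BIN_DAYS = 183
SPAN_DAYS = N_BINS * BIN_DAYS  # 1830


def bin_of_days(days_before_anchor):
    """Map days-before-anchor to a bin index in ``0..9`` (9 = most recent).

    Days beyond the observation span (> 1830) map to -1 (outside).
    ``days == 1830`` is clipped into bin 0 so the span endpoint is usable.
    """
    d = np.asarray(days_before_anchor, dtype=float)
    idx = (N_BINS - 1) - np.floor(d / BIN_DAYS).astype(int)
    idx = np.where(d == SPAN_DAYS, 0, idx)
    idx = np.where((d < 0) | (d > SPAN_DAYS), -1, idx)
    if np.isscalar(days_before_anchor):
        return int(idx)
    return idx
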