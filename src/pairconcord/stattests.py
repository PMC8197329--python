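"""Shared low-level statistical tests."""

from __future__ import annotations

from typing import Sequence

from statsmodels.stats.proportion import proportions_ztest


def two_proportion_ztest(counts: Sequence[int], nobs: Sequence[int]) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample proportion z-test.

    Returns (z, p).  Equal sample proportions give z = 0, p = 1 exactly,
    which also covers the degenerate pooled-variance corner where both
    proportions are 0 or 1.
    """
    if len(counts) != 2 or len(nobs) != 2:
        raise ValueError("exactly two samples required")
    if min(nobs) <= 0:
        raise ValueError("sample sizes must be positive")
    if counts[0] * nobs[1] == counts[1] * nobs[0]:
        return 0.0, 1.0
    z, p = proportions_ztest(list(counts), list(nobs), alternative="two-sided")
    return float(z), float(p)
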