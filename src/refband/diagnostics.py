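"""Pre-checks for the reference band's homogeneity assumption.

The band's width is derived assuming the two measurements share a common
variance.  Two diagnostics are provided:

* :func:`pitman_morgan_test` — the paired-sample test of variance equality,
  based on the fact that for a bivariate normal pair, ``sigma_1 = sigma_2``
  iff the sums ``x1 + x2`` and differences ``x1 - x2`` are uncorrelated.
  An unpaired F-test would be invalid here because the columns are
  correlated by design.
* :func:`difference_trend` — the least-squares line of the differences on
  the averages in the Bland-Altman plane.  Its slope has the sign of
  ``sigma_2 - sigma_1`` in expectation, so a visible tilt flags variance
  heterogeneity, while a vertical shift flags a mean difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .core import InvalidInputError, PairedSample

__all__ = [
    "VarianceConclusion",
    "VarianceTestResult",
    "TrendFit",
    "pitman_morgan_test",
    "difference_trend",
]


class VarianceConclusion(str, Enum):
    NOT_REJECTED = "homogeneous-not-rejected"
    REJECTED = "rejected"


@dataclass(frozen=True)
class VarianceTestResult:
    """Pitman-Morgan paired test of ``sigma_1 = sigma_2``.

    ``statistic`` is ``r sqrt(n-2) / sqrt(1 - r^2)`` where ``r`` is the
    sample correlation between sums and differences; it follows Student's t
    with ``n - 2`` degrees of freedom under the null.  ``degenerate`` marks
    the |r| = 1 case, where the statistic is infinite and p is reported 0.
    """

    statistic: float
    df: int
    p_value: float
    conclusion: VarianceConclusion
    degenerate: bool = False


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of differences on averages: ``d = slope * a + intercept``."""

    slope: float
    intercept: float


def pitman_morgan_test(
    sample: PairedSample, level: float = 0.05
) -> VarianceTestResult:
    """Test equality of the two paired variances.

    Parameters
    ----------
    sample
        Paired measurements; requires ``n >= 4``.
    level
        Two-sided significance level used to phrase the conclusion.
    """
    n = sample.n
    if n < 4:
        raise InvalidInputError("Pitman-Morgan test requires at least 4 pairs")
    if not 0.0 < level < 1.0:
        raise InvalidInputError("level must lie in (0, 1)")
    s = sample.x1 + sample.x2
    d = sample.x1 - sample.x2
    if s.var() == 0.0 or d.var() == 0.0:
        raise InvalidInputError(
            "degenerate input: constant sums or constant differences"
        )
    r = float(np.corrcoef(s, d)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if 1.0 - r * r < 1e-15:
        stat = math.copysign(math.inf, r)
        p = 0.0
        degenerate = True
    else:
        stat = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(stats.t.sf(abs(stat), df))
        degenerate = False
    conclusion = (
        VarianceConclusion.REJECTED
        if p < level
        else VarianceConclusion.NOT_REJECTED
    )
    return VarianceTestResult(
        statistic=stat, df=df, p_value=p, conclusion=conclusion,
        degenerate=degenerate,
    )


def difference_trend(sample: PairedSample) -> TrendFit:
    """Least-squares line of the differences against the averages."""
    a = sample.averages
    d = sample.differences
    if a.var() == 0.0:
        raise InvalidInputError("degenerate input: constant averages")
    slope, intercept = np.polyfit(a, d, 1)
    return TrendFit(slope=float(slope), intercept=float(intercept))
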