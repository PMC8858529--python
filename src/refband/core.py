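"""Agreement estimators and the CCC-anchored reference band.

The central objects are a :class:`PairedSample` of two same-unit continuous
measurements on the same subjects, and the statistics computed from it:

* sample moments and Pearson correlation;
* Lin's concordance correlation coefficient (CCC) and its bias-correction
  factor C_b, which penalises mean shift and scale mismatch;
* the Bland-Altman limits of agreement (LoA), ``dbar +/- t_{n-1,alpha/2} S_d``;
* a reference band (RB) of half-width
  ``omega_RB = t_{nu,alpha/2} S_d sqrt((1 - rho_L) / (1 - rho_hat))``,
  symmetric about zero in the mean-difference plane, where ``rho_L`` is the
  chosen lower bound of excellent concordance (default 0.75);
* an outlier rule flagging pairs whose absolute difference strictly exceeds
  the RB half-width.

The RB is derived under the homogeneity assumption ``sigma_1 = sigma_2``
(i.e. C_b = 1); :mod:`refband.diagnostics` provides the recommended
pre-check for that assumption.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "InvalidInputError",
    "UndefinedStatisticError",
    "PairedSample",
    "PopulationParams",
    "AgreementEstimates",
    "LimitsOfAgreement",
    "ReferenceBand",
    "OutlierReport",
    "summarize_pairs",
    "pearson_correlation",
    "sample_ccc",
    "population_ccc",
    "limits_of_agreement",
    "sigma_hat",
    "reference_band",
    "detect_outliers",
    "t_quantile",
]

# below this value of 1 - rho_hat the ratio S_d / sqrt(2 (1 - rho_hat)) is
# numerically unstable and the pooled-variance fallback is used instead
DEGENERATE_RHO_EPS = 1e-8


class InvalidInputError(ValueError):
    """Raised when inputs violate a precondition (sizes, ranges, signs)."""


class UndefinedStatisticError(InvalidInputError):
    """Raised when a statistic is undefined for the data (e.g. zero variance)."""


@dataclass(frozen=True)
class PairedSample:
    """``n`` paired continuous measurements of the same quantity.

    ``x1`` and ``x2`` must be the same length and share units.  Differences
    are oriented as ``d_i = x2_i - x1_i`` and averages as
    ``a_i = (x1_i + x2_i) / 2``, i.e. the Bland-Altman plane coordinates.
    """

    x1: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        x1 = np.asarray(self.x1, dtype=float)
        x2 = np.asarray(self.x2, dtype=float)
        if x1.ndim != 1 or x2.ndim != 1:
            raise InvalidInputError("x1 and x2 must be one-dimensional")
        if x1.shape != x2.shape:
            raise InvalidInputError(
                f"length mismatch: {x1.size} vs {x2.size} measurements"
            )
        if x1.size < 2:
            raise InvalidInputError("at least 2 pairs are required")
        if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
            raise InvalidInputError("measurements must be finite (no NaN/inf)")
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)

    @property
    def n(self) -> int:
        return self.x1.size

    @property
    def differences(self) -> np.ndarray:
        """Pairwise differences ``d_i = x2_i - x1_i``."""
        return self.x2 - self.x1

    @property
    def averages(self) -> np.ndarray:
        """Pairwise averages ``(x1_i + x2_i) / 2``."""
        return 0.5 * (self.x1 + self.x2)

    @classmethod
    def from_arrays(
        cls, x1: Sequence[float], x2: Sequence[float]
    ) -> "PairedSample":
        return cls(np.asarray(x1, dtype=float), np.asarray(x2, dtype=float))


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of a bivariate normal measurement-pair population."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    rho: float

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise InvalidInputError("standard deviations must be positive")
        if not -1.0 < self.rho < 1.0:
            raise InvalidInputError("rho must lie strictly inside (-1, 1)")


@dataclass(frozen=True)
class AgreementEstimates:
    """Sample moments and agreement indices for one paired sample.

    ``cb_hat`` is ``None`` when the Pearson correlation is exactly zero, in
    which case the bias-correction factor is undefined (the CCC itself is 0).
    ``sd_diff`` always uses the ``1/(n-1)`` denominator, matching the LoA
    definition; the moments honour the requested denominator.
    """

    n: int
    mean1: float
    mean2: float
    s1: float
    s2: float
    s12: float
    rho_hat: float
    ccc_hat: float
    cb_hat: float | None
    dbar: float
    sd_diff: float
    sigma_hat: float
    denominator: Literal["n", "n-1"] = "n"


@dataclass(frozen=True)
class LimitsOfAgreement:
    """Bland-Altman limits ``dbar +/- t_{n-1,alpha/2} S_d``."""

    dbar: float
    half_width: float
    alpha: float
    df: int

    @property
    def lower(self) -> float:
        return self.dbar - self.half_width

    @property
    def upper(self) -> float:
        return self.dbar + self.half_width


@dataclass(frozen=True)
class ReferenceBand:
    """The CCC-anchored band ``|d| <= omega_RB``, symmetric about zero.

    Unlike the LoA the band is centred on 0, not on the mean difference:
    under excellent concordance the differences should scatter around zero.
    """

    half_width: float
    rho_L: float
    alpha: float
    df: int
    center: float = field(default=0.0, init=False)

    @property
    def lower(self) -> float:
        return -self.half_width

    @property
    def upper(self) -> float:
        return self.half_width


@dataclass(frozen=True)
class OutlierReport:
    """Pairs whose absolute difference strictly exceeds the RB half-width."""

    n: int
    outlier_indices: tuple[int, ...]

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_indices)

    @property
    def pct_outliers(self) -> float:
        return 100.0 * self.n_outliers / self.n


def _moments(
    sample: PairedSample, ddof: int
) -> tuple[float, float, float, float, float]:
    x1, x2 = sample.x1, sample.x2
    mean1, mean2 = float(x1.mean()), float(x2.mean())
    s1 = float(x1.std(ddof=ddof))
    s2 = float(x2.std(ddof=ddof))
    s12 = float(((x1 - mean1) * (x2 - mean2)).sum() / (sample.n - ddof))
    return mean1, mean2, s1, s2, s12


def summarize_pairs(
    sample: PairedSample, denominator: Literal["n", "n-1"] = "n"
) -> AgreementEstimates:
    """Compute all sample moments and agreement indices in one pass.

    Parameters
    ----------
    sample
        The paired measurements.
    denominator
        Divisor convention for variances and covariance: ``"n"`` (maximum
        likelihood, the convention of Lin's CCC estimator and the default)
        or ``"n-1"`` (unbiased).  The SD of the differences ``sd_diff`` is
        always computed with ``1/(n-1)``, as the LoA definition requires,
        and the CCC always uses ``1/n`` moments regardless of this setting.
    """
    if denominator not in ("n", "n-1"):
        raise InvalidInputError(f"unknown denominator convention {denominator!r}")
    if sample.n < 2:
        raise InvalidInputError("at least 2 pairs are required")
    ddof = 0 if denominator == "n" else 1
    mean1, mean2, s1, s2, s12 = _moments(sample, ddof)

    d = sample.differences
    dbar = float(d.mean())
    sd_diff = float(d.std(ddof=1))

    # correlation is denominator-invariant; CCC is defined on 1/n moments.
    # With a constant column or only 2 pairs the scaled indices are
    # undefined; the moment layer reports NaN rather than refusing.
    if sample.n < 3 or s1 == 0.0 or s2 == 0.0:
        rho_hat = math.nan
        ccc_hat = math.nan
        cb_hat = None
        sig = math.nan
    else:
        rho_hat = pearson_correlation(sample)
        ccc_hat, _, cb_hat = sample_ccc(sample)
        sig = sigma_hat(sd_diff, rho_hat, s1, s2)

    return AgreementEstimates(
        n=sample.n,
        mean1=mean1,
        mean2=mean2,
        s1=s1,
        s2=s2,
        s12=s12,
        rho_hat=rho_hat,
        ccc_hat=ccc_hat,
        cb_hat=cb_hat,
        dbar=dbar,
        sd_diff=sd_diff,
        sigma_hat=sig,
        denominator=denominator,
    )


def pearson_correlation(sample: PairedSample) -> float:
    """Product-moment correlation of the two measurement columns."""
    if sample.n < 3:
        raise InvalidInputError("correlation requires at least 3 pairs")
    x1, x2 = sample.x1, sample.x2
    v1 = float(x1.var())
    v2 = float(x2.var())
    if v1 == 0.0 or v2 == 0.0:
        raise UndefinedStatisticError(
            "correlation undefined: a measurement column has zero variance"
        )
    c = float(((x1 - x1.mean()) * (x2 - x2.mean())).mean())
    r = c / math.sqrt(v1 * v2)
    return max(-1.0, min(1.0, r))


def sample_ccc(sample: PairedSample) -> tuple[float, float, float | None]:
    """Lin's sample concordance correlation coefficient.

    Returns ``(ccc_hat, rho_hat, cb_hat)`` where

    ``ccc_hat = 2 s12 / (s1^2 + s2^2 + (mean1 - mean2)^2)``

    with maximum-likelihood (``1/n``) variances and covariance, and
    ``cb_hat = ccc_hat / rho_hat`` (``None`` when ``rho_hat`` is zero).
    """
    if sample.n < 3:
        raise InvalidInputError("CCC requires at least 3 pairs")
    mean1, mean2, s1, s2, s12 = _moments(sample, ddof=0)
    if s1 == 0.0 or s2 == 0.0:
        raise UndefinedStatisticError(
            "CCC undefined: a measurement column has zero variance"
        )
    ccc = 2.0 * s12 / (s1 * s1 + s2 * s2 + (mean1 - mean2) ** 2)
    rho = pearson_correlation(sample)
    cb = ccc / rho if rho != 0.0 else None
    return ccc, rho, cb


def population_ccc(params: PopulationParams) -> tuple[float, float]:
    """Population CCC ``rho_c = rho * C_b`` with the closed-form C_b.

    ``C_b = 2 / (sigma1/sigma2 + sigma2/sigma1 + (mu1 - mu2)^2/(sigma1 sigma2))``
    lies in (0, 1] and equals 1 iff the means and variances both match.
    """
    s1, s2 = params.sigma1, params.sigma2
    cb = 2.0 / (s1 / s2 + s2 / s1 + (params.mu1 - params.mu2) ** 2 / (s1 * s2))
    return params.rho * cb, cb


def t_quantile(df: int, alpha: float) -> float:
    """Upper ``alpha/2`` quantile of Student's t with ``df`` degrees of freedom."""
    if df < 1:
        raise InvalidInputError("degrees of freedom must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must lie in (0, 1)")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def limits_of_agreement(
    sample: PairedSample, alpha: float = 0.05
) -> LimitsOfAgreement:
    """Bland-Altman limits of agreement ``dbar +/- t_{n-1,alpha/2} S_d``."""
    if sample.n < 3:
        raise InvalidInputError("limits of agreement require at least 3 pairs")
    d = sample.differences
    dbar = float(d.mean())
    sd = float(d.std(ddof=1))
    df = sample.n - 1
    return LimitsOfAgreement(
        dbar=dbar,
        half_width=t_quantile(df, alpha) * sd,
        alpha=alpha,
        df=df,
    )


def sigma_hat(sd_diff: float, rho_hat: float, s1: float, s2: float) -> float:
    """Common-SD estimate ``S_d / sqrt(2 (1 - rho_hat))``.

    Valid under the band's homogeneity assumption ``sigma_1 = sigma_2``.
    When ``rho_hat`` is within ``1e-8`` of 1 the ratio is numerically
    unstable and the pooled form ``sqrt((s1^2 + s2^2)/2)`` — algebraically
    equal under the assumption — is returned instead.
    """
    if sd_diff < 0:
        raise InvalidInputError("sd_diff must be nonnegative")
    if not -1.0 <= rho_hat <= 1.0:
        raise InvalidInputError("rho_hat must lie in [-1, 1]")
    if 1.0 - rho_hat < DEGENERATE_RHO_EPS:
        return math.sqrt(0.5 * (s1 * s1 + s2 * s2))
    return sd_diff / math.sqrt(2.0 * (1.0 - rho_hat))


def reference_band(
    sample: PairedSample, alpha: float = 0.05, rho_L: float = 0.75
) -> ReferenceBand:
    """The 100(1-alpha)% reference band at concordance threshold ``rho_L``.

    The half-width is ``t_{nu,alpha/2} S_d sqrt((1 - rho_L)/(1 - rho_hat))``
    with ``nu = n - 1``; equivalently ``t_{nu,alpha/2} sigma_hat
    sqrt(2 (1 - rho_L))``.  Both forms are evaluated and cross-checked except
    in the degenerate ``rho_hat -> 1`` case, where only the pooled-variance
    ``sigma_hat`` form is defined.

    Points farther than the half-width from zero signal concordance below
    ``rho_L``; when ``rho_hat`` equals ``rho_L`` the band coincides with a
    zero-centred copy of the LoA.
    """
    if sample.n < 3:
        raise InvalidInputError("reference band requires at least 3 pairs")
    if not 0.0 <= rho_L < 1.0:
        raise InvalidInputError("rho_L must lie in [0, 1)")
    df = sample.n - 1
    tq = t_quantile(df, alpha)
    d = sample.differences
    sd = float(d.std(ddof=1))
    rho = pearson_correlation(sample)
    if rho < 0.0:
        warnings.warn(
            "negative correlation between measurements: the reference band "
            "shrinks accordingly but agreement is implausible",
            stacklevel=2,
        )
    ests = _moments(sample, ddof=0)
    sig = sigma_hat(sd, rho, ests[2], ests[3])
    hw_sigma = tq * sig * math.sqrt(2.0 * (1.0 - rho_L))
    if 1.0 - rho >= DEGENERATE_RHO_EPS:
        hw_direct = tq * sd * math.sqrt((1.0 - rho_L) / (1.0 - rho))
        if not math.isclose(hw_direct, hw_sigma, rel_tol=1e-10, abs_tol=1e-300):
            raise AssertionError(
                "reference-band forms disagree: "
                f"{hw_direct!r} vs {hw_sigma!r}"
            )
        half_width = hw_direct
    else:
        half_width = hw_sigma
    return ReferenceBand(half_width=half_width, rho_L=rho_L, alpha=alpha, df=df)


def detect_outliers(sample: PairedSample, band: ReferenceBand) -> OutlierReport:
    """Flag pairs with ``|d_i|`` strictly exceeding the RB half-width.

    A difference exactly on the boundary counts as inside the band.
    """
    d = np.abs(sample.differences)
    idx = np.flatnonzero(d > band.half_width)
    return OutlierReport(n=sample.n, outlier_indices=tuple(int(i) for i in idx))
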