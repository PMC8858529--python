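"""Mean-difference plots with the reference band, and run-association plots.

Figures are built on matplotlib with a headless-safe backend.  Every band
layer carries a stable ``gid`` (``"rb-upper"``, ``"loa-lower"``, ...), so
tests and downstream tooling can read band positions back off the figure's
data layers instead of comparing rasters.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

# deterministic element ids so identical figures serialize identically
matplotlib.rcParams["svg.hashsalt"] = "refband"

from .core import (
    InvalidInputError,
    LimitsOfAgreement,
    PairedSample,
    ReferenceBand,
    detect_outliers,
)
from .diagnostics import difference_trend
from .simulation import RunRecord

__all__ = ["PlotOptions", "mean_difference_plot", "association_plot"]


@dataclass(frozen=True)
class PlotOptions:
    """Layer toggles and labelling for the agreement figures."""

    show_rb: bool = True
    show_loa: bool = True
    show_trend: bool = False
    units: str = ""
    title: str = ""
    fmt: str = "png"

    def __post_init__(self) -> None:
        if not (self.show_rb or self.show_loa):
            raise InvalidInputError("enable at least one band layer")
        if self.fmt not in ("png", "svg", "pdf"):
            raise InvalidInputError(f"unsupported output format {self.fmt!r}")


def _unit_suffix(units: str) -> str:
    return f" ({units})" if units else ""


def _savefig(fig, path, fmt: str) -> None:
    metadata = {"Date": None} if fmt == "svg" else (
        {"CreationDate": None} if fmt == "pdf" else None
    )
    fig.savefig(path, format=fmt, dpi=150, metadata=metadata)


def mean_difference_plot(
    sample: PairedSample,
    band: ReferenceBand | None = None,
    loa: LimitsOfAgreement | None = None,
    options: PlotOptions = PlotOptions(),
    path: str | None = None,
):
    """Differences against averages with the RB and/or LoA overlaid.

    The reference band is drawn as horizontal lines at ``+/- omega_RB``
    around zero; the limits of agreement at ``dbar +/- omega``.  Points
    outside the RB are drawn as open red markers.  Returns the figure;
    if ``path`` is given the figure is also written there.
    """
    if options.show_rb and band is None:
        raise InvalidInputError("show_rb requires a computed ReferenceBand")
    if options.show_loa and loa is None:
        raise InvalidInputError("show_loa requires computed LimitsOfAgreement")
    a = sample.averages
    d = sample.differences
    fig, ax = plt.subplots(figsize=(6.0, 4.5))
    inside = np.ones(sample.n, dtype=bool)
    if options.show_rb:
        report = detect_outliers(sample, band)
        inside[list(report.outlier_indices)] = False
    ax.plot(
        a[inside], d[inside], "o", color="C0", mfc="none", ms=5, gid="points"
    )
    if (~inside).any():
        ax.plot(
            a[~inside], d[~inside], "o", color="red", mfc="none", ms=6,
            gid="outliers",
        )
    ax.axhline(0.0, color="0.6", lw=0.8, gid="zero")
    if options.show_rb:
        ax.axhline(band.upper, color="C3", ls="-", lw=1.4, gid="rb-upper",
                   label=f"RB (rho_L={band.rho_L:g})")
        ax.axhline(band.lower, color="C3", ls="-", lw=1.4, gid="rb-lower")
    if options.show_loa:
        ax.axhline(loa.upper, color="C2", ls="--", lw=1.2, gid="loa-upper",
                   label="LoA")
        ax.axhline(loa.lower, color="C2", ls="--", lw=1.2, gid="loa-lower")
        ax.axhline(loa.dbar, color="C2", ls=":", lw=1.0, gid="loa-center")
    if options.show_trend:
        fit = difference_trend(sample)
        xs = np.array([a.min(), a.max()])
        ax.plot(xs, fit.slope * xs + fit.intercept, color="C1", lw=1.2,
                gid="trend", label="trend")
    suffix = _unit_suffix(options.units)
    ax.set_xlabel(f"average of the two measurements{suffix}")
    ax.set_ylabel(f"difference X2 - X1{suffix}")
    if options.title:
        ax.set_title(options.title)
    ax.legend(loc="best", frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        _savefig(fig, path, options.fmt)
    return fig


def association_plot(
    records: list[RunRecord],
    options: PlotOptions = PlotOptions(),
    path: str | None = None,
):
    """Scatter of per-run % outliers against per-run CCC."""
    clean = [r for r in records if not r.flagged]
    if len(clean) < 2:
        raise InvalidInputError("association plot requires >= 2 run records")
    ccc = np.array([r.ccc for r in clean])
    pct = np.array([r.pct_outliers for r in clean])
    fig, ax = plt.subplots(figsize=(6.0, 4.5))
    ax.plot(ccc, pct, "o", color="C0", ms=3, alpha=0.5, mew=0, gid="runs")
    ax.set_xlabel("sample CCC")
    ax.set_ylabel("% of data outside the reference band")
    if options.title:
        ax.set_title(options.title)
    fig.tight_layout()
    if path is not None:
        _savefig(fig, path, options.fmt)
    return fig
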