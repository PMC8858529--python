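"""CSV ingestion, the bundled PEFR example data, and report serialization.

The analysis report is a versioned nested mapping carrying all estimates,
both bands and the diagnostics; it serializes to JSON without precision
loss (``repr``-roundtrip floats) and to a flat one-row CSV.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import (
    InvalidInputError,
    PairedSample,
    detect_outliers,
    limits_of_agreement,
    reference_band,
    summarize_pairs,
)
from .diagnostics import difference_trend, pitman_morgan_test

__all__ = [
    "SchemaError",
    "DomainError",
    "read_paired_csv",
    "pefr_fixture",
    "build_report",
    "write_report_json",
    "write_report_csv",
    "read_report_json",
]

logger = logging.getLogger("refband")

REPORT_SCHEMA_VERSION = 1


class SchemaError(InvalidInputError):
    """Input file does not have the expected columns or types."""


class DomainError(InvalidInputError):
    """A value is outside the mathematical domain of a requested transform."""


def read_paired_csv(
    path: str | Path,
    col1: str,
    col2: str,
    log_transform: bool = False,
) -> PairedSample:
    """Read two numeric measurement columns from a delimited text file.

    Rows with a missing value in either column are dropped (the count is
    logged).  With ``log_transform`` the natural log is applied to both
    columns, which must then be strictly positive.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in (col1, col2):
        if col not in df.columns:
            raise SchemaError(
                f"column {col!r} not found in {path.name}; "
                f"available: {', '.join(map(str, df.columns))}"
            )
    sub = df[[col1, col2]].apply(pd.to_numeric, errors="coerce")
    keep = sub.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d row(s) with missing values", dropped)
    sub = sub[keep]
    if log_transform:
        bad = sub[(sub[col1] <= 0) | (sub[col2] <= 0)]
        if len(bad):
            row = int(bad.index[0])
            raise DomainError(
                f"log transform requires strictly positive values; "
                f"row {row} violates this"
            )
        sub = np.log(sub)
    return PairedSample(sub[col1].to_numpy(float), sub[col2].to_numpy(float))


def pefr_fixture() -> PairedSample:
    """The classic two-meter peak expiratory flow rate comparison (n=17).

    PEFR (l/min) for 17 subjects measured with a large Wright peak flow
    meter and a mini Wright meter, two readings per meter.  Only the first
    reading of each meter enters the default comparison, with the mini
    meter as X1 and the large meter as X2 so the differences are
    large-minus-mini (mean difference about -2.12 l/min).
    """
    with resources.files("refband.data").joinpath("pefr.csv").open() as fh:
        df = pd.read_csv(fh)
    return PairedSample(
        df["wright_mini_1"].to_numpy(float),
        df["wright_large_1"].to_numpy(float),
    )


def build_report(
    sample: PairedSample,
    alpha: float = 0.05,
    rho_L: float = 0.75,
) -> dict[str, Any]:
    """Run the full analysis and assemble the machine-readable report."""
    est = summarize_pairs(sample)
    loa = limits_of_agreement(sample, alpha=alpha)
    band = reference_band(sample, alpha=alpha, rho_L=rho_L)
    outliers = detect_outliers(sample, band)
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n": sample.n,
        "alpha": alpha,
        "rho_L": rho_L,
        "estimates": {
            "mean1": est.mean1,
            "mean2": est.mean2,
            "s1": est.s1,
            "s2": est.s2,
            "s12": est.s12,
            "rho_hat": est.rho_hat,
            "ccc_hat": est.ccc_hat,
            "cb_hat": est.cb_hat,
            "dbar": est.dbar,
            "sd_diff": est.sd_diff,
            "sigma_hat": est.sigma_hat,
        },
        "limits_of_agreement": {
            "center": loa.dbar,
            "half_width": loa.half_width,
            "lower": loa.lower,
            "upper": loa.upper,
            "df": loa.df,
        },
        "reference_band": {
            "center": 0.0,
            "half_width": band.half_width,
            "lower": band.lower,
            "upper": band.upper,
            "df": band.df,
        },
        "outliers": {
            "n_outliers": outliers.n_outliers,
            "pct_outliers": outliers.pct_outliers,
            "indices": list(outliers.outlier_indices),
        },
    }
    try:
        trend = difference_trend(sample)
        report["trend"] = {"slope": trend.slope, "intercept": trend.intercept}
    except InvalidInputError:
        report["trend"] = None
    if sample.n >= 4:
        try:
            vt = pitman_morgan_test(sample)
        except InvalidInputError:
            report["variance_homogeneity"] = None
        else:
            report["variance_homogeneity"] = {
                "test": "pitman-morgan",
                "statistic": vt.statistic,
                "df": vt.df,
                "p_value": vt.p_value,
                "conclusion": vt.conclusion.value,
            }
            if vt.conclusion.value == "rejected":
                logger.warning(
                    "variance homogeneity rejected (p=%.4g): the reference "
                    "band width may not be reliable",
                    vt.p_value,
                )
    else:
        report["variance_homogeneity"] = None
    return report


def _flatten(prefix: str, obj: Any, out: dict[str, Any]) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}{k}." if prefix else f"{k}.", v, out)
    else:
        key = prefix.rstrip(".")
        out[key] = obj


def write_report_json(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report_csv(report: dict[str, Any], path: str | Path) -> None:
    """Single-row flat CSV variant with dotted column names."""
    flat: dict[str, Any] = {}
    _flatten("", _jsonable(report), flat)
    flat = {
        k: (json.dumps(v) if isinstance(v, list) else v)
        for k, v in flat.items()
    }
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(flat))
        writer.writeheader()
        writer.writerow({k: ("" if v is None else repr(v) if isinstance(v, float) else v) for k, v in flat.items()})


def read_report_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
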