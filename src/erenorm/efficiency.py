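"""Standard-curve fitting and the assay-retention gate.

An assay's amplification efficiency is estimated from a dilution series by
ordinary least squares of Cq on log10 template input:

    efficiency (%) = (10 ** (-1/slope) - 1) * 100

A perfect doubling assay has slope -1/log10(2) = -3.3219. Assays are retained
when efficiency lies in [90, 110]% and the curve's r^2 exceeds 0.98.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "StandardCurve",
    "GateVerdict",
    "fit_standard_curve",
    "gate_assay",
    "read_dilution_table",
    "write_gate_table",
]


class DilutionError(ValueError):
    pass


@dataclass(frozen=True)
class DilutionSeries:
    """One assay's dilution series: (log10 input, Cq) points.

    Input amounts are log10 of template mass (conventionally µg); only their
    relative spacing matters to the fitted slope.
    """

    target_id: str
    log10_input: tuple[float, ...]
    cq: tuple[float, ...]
    n_points: int | None = None
    dilution_factor: float | None = None

    def __post_init__(self) -> None:
        if len(self.log10_input) != len(self.cq):
            raise DilutionError("log10_input and cq lengths differ")
        if len(set(self.log10_input)) < 3:
            raise DilutionError("need >= 3 distinct input amounts")
        if any(not math.isfinite(v) for v in self.cq):
            raise DilutionError("Cq missing or non-finite in dilution series")
        if self.dilution_factor is not None and self.dilution_factor <= 1:
            raise DilutionError("dilution_factor must exceed 1")


@dataclass(frozen=True)
class StandardCurve:
    target_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float  # NaN when slope is non-negative
    efficiency_defined: bool = True

    @property
    def amplification_factor(self) -> float:
        return 1.0 + self.efficiency_percent / 100.0


def efficiency_from_slope(slope: float) -> float:
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(series: DilutionSeries) -> StandardCurve:
    """OLS fit of Cq on log10 input; r^2 is the squared Pearson correlation.

    A non-negative slope (no dilution response) yields a curve whose
    efficiency is flagged undefined rather than an exception, so the gate can
    report it as a failure with reasons.
    """
    x = np.asarray(series.log10_input, dtype=float)
    y = np.asarray(series.cq, dtype=float)
    if np.ptp(x) == 0:
        raise DilutionError("zero variance in log10_input")
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    r2 = float(fit.rvalue) ** 2
    if slope < 0:
        return StandardCurve(series.target_id, slope, float(fit.intercept), r2,
                             efficiency_from_slope(slope))
    return StandardCurve(series.target_id, slope, float(fit.intercept), r2,
                         math.nan, efficiency_defined=False)


@dataclass(frozen=True)
class GateVerdict:
    target_id: str
    passed: bool
    reasons: tuple[str, ...]


def gate_assay(
    curve: StandardCurve,
    e_low: float = 90.0,
    e_high: float = 110.0,
    r2_min: float = 0.98,
) -> GateVerdict:
    """Retention gate: e_low <= efficiency <= e_high and r^2 strictly > r2_min.

    Efficiency bounds are inclusive; the r^2 bound is exclusive. Every
    violated criterion is listed in the verdict.
    """
    reasons: list[str] = []
    if not curve.efficiency_defined:
        reasons.append("efficiency undefined (non-negative slope)")
    else:
        if curve.efficiency_percent < e_low:
            reasons.append(f"efficiency below {e_low:g}%")
        if curve.efficiency_percent > e_high:
            reasons.append(f"efficiency above {e_high:g}%")
    if not curve.r_squared > r2_min:
        reasons.append(f"r^2 not above {r2_min:g}")
    return GateVerdict(curve.target_id, not reasons, tuple(reasons))


def read_dilution_table(path: str | Path) -> list[DilutionSeries]:
    """Read a TSV with columns target, log10_input, cq into per-assay series."""
    df = pd.read_csv(path, sep="\t")
    required = {"target", "log10_input", "cq"}
    if not required.issubset(df.columns):
        raise DilutionError(f"dilution table needs columns {sorted(required)}")
    out = []
    for target, grp in df.groupby("target", sort=False):
        out.append(
            DilutionSeries(
                str(target),
                tuple(float(v) for v in grp["log10_input"]),
                tuple(float(v) for v in grp["cq"]),
            )
        )
    return out


def write_gate_table(
    curves: Sequence[StandardCurve],
    verdicts: Sequence[GateVerdict],
    path: str | Path,
) -> None:
    rows = [
        {
            "target": c.target_id,
            "slope": c.slope,
            "efficiency_percent": c.efficiency_percent,
            "r_squared": c.r_squared,
            "pass": v.passed,
            "reasons": "; ".join(v.reasons),
        }
        for c, v in zip(curves, verdicts, strict=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
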