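"""Calibration-curve quantification of identified constituents.

Peak areas are converted to solution concentrations through per-standard
ordinary-least-squares calibration lines and then to contents in mg per g
of lyophilized extract powder (or, optionally, per g of dried leaves via
the extraction yield). Triplicate contents are summarized as mean +/- SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


class QuantWarning(UserWarning):
    """Non-fatal quantification notice (e.g. negative concentration clamp)."""


@dataclass(frozen=True)
class CalibrationCurve:
    standard_id: int
    slope: float  # area per (ug/mL)
    intercept: float  # area
    r: float  # Pearson correlation of the calibration points
    n_points: int

    @property
    def usable(self) -> bool:
        return self.slope > 0 and self.n_points >= 2


@dataclass(frozen=True)
class ContentEstimate:
    standard_id: int
    mean: float  # mg/g
    sd: float  # mg/g
    n: int
    single_replicate: bool = False


@dataclass(frozen=True)
class ExtractionFactors:
    """Unit-conversion constants of the extraction protocol.

    ``solution_conc``: mg of lyophilized powder per mL of analyzed solution
    (30 mg/mL). ``powder_yield``: g of lyophilized powder per g of dried
    leaves (0.3 g from 10.0 g).
    """

    solution_conc: float = 30.0  # mg powder / mL
    powder_yield: float = 0.3 / 10.0  # g powder / g leaves

    def __post_init__(self) -> None:
        if self.solution_conc <= 0 or self.powder_yield <= 0:
            raise ValueError("extraction factors must be positive")


def fit_calibration(points, standard_id: int = 0) -> CalibrationCurve:
    """Ordinary least squares on (concentration ug/mL, peak area) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two calibration points")
    conc, area = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("calibration concentrations have zero variance")
    res = stats.linregress(conc, area)
    return CalibrationCurve(standard_id, float(res.slope), float(res.intercept),
                            float(res.rvalue), len(pts))


def quantify(area: float, curve: CalibrationCurve,
             factors: ExtractionFactors = ExtractionFactors(),
             basis: str = "powder") -> float:
    """Convert a peak area to a content in mg/g.

    conc = (area - intercept) / slope gives ug/mL of analyte; dividing by
    the solution concentration (mg powder/mL) yields mg analyte per g of
    powder. ``basis="leaves"`` further multiplies by the extraction yield.
    A negative back-calculated concentration (intercept noise near the
    detection limit) is clamped to 0 with a :class:`QuantWarning`.
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    if basis not in ("powder", "leaves"):
        raise ValueError(f"unknown content basis {basis!r}")
    conc = (area - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(f"standard {curve.standard_id}: negative back-calculated "
                      "concentration clamped to 0", QuantWarning, stacklevel=2)
        conc = 0.0
    content = conc / factors.solution_conc  # mg analyte / g powder
    if basis == "leaves":
        content *= factors.powder_yield
    return content


def replicate_stats(values, standard_id: int = 0) -> ContentEstimate:
    """Mean and sample SD (n-1 denominator) over replicate contents.

    A single replicate is reported with sd 0 and flagged.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate values")
    single = vals.size == 1
    # identical replicates report exactly 0, not float-roundoff noise
    sd = 0.0 if single or np.ptp(vals) == 0 else float(np.std(vals, ddof=1))
    return ContentEstimate(standard_id, float(np.mean(vals)), sd,
                           int(vals.size), single_replicate=single)
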