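"""Stable-isotope-dilution quantification conventions.

Implements the data-evaluation layer of an LC–MS/MS isotope-dilution
method, downstream of peak integration:

* **ISTD cross-talk correction.** A 13C2-labelled internal standard sits
  only 2 Da above its native analyte, so the native isotope pattern bleeds
  into the ISTD's MRM trace.  The observed ISTD area is corrected
  subtractively, ``A_corr = A_obs - r * A_native``, with the interference
  factor ``r`` taken from configuration or computed from the molecular
  formula's natural M+2 abundance (:func:`m_plus_2_fraction`).
* **Response-ratio calibration.** Linear fit of response ratio
  (native area / corrected ISTD area) versus amount ratio, with the
  method's minimum of six calibration points enforced.
* **Quantification.** ``amount = (ratio - intercept) / slope * istd_amount``
  and mass fraction = amount / sample mass (ng/g = µg/kg).
* **Linear/branched isomer convention.** Some analytes occur as linear plus
  branched isomers while the calibrant's certified content covers only the
  linear part (e.g. an L-fraction of 0.788).  The convention reports the
  L+br sum against the L-only calibration, which raises the result by
  1 / L_fraction relative to naive quantification; equivalently the
  calibration amount axis is rescaled from certified-L to total amounts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import StatisticalError, ValidationError

__all__ = [
    "MrmOverlapCorrection",
    "CalCurve",
    "IsomerConvention",
    "QuantResult",
    "correct_istd_area",
    "fit_calibration",
    "rescale_amounts_to_total",
    "quantify",
    "m_plus_2_fraction",
]

MIN_CAL_POINTS = 6

# natural isotopic abundances of the heavy (+1 / +2) isotopes per element
_ISO = {
    "C": {1: 0.0107},
    "H": {1: 0.000115},
    "N": {1: 0.00364},
    "O": {1: 0.00038, 2: 0.00205},
    "S": {1: 0.0075, 2: 0.0421},
    "F": {},
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MrmOverlapCorrection:
    """Isotopic cross-talk of a native analyte into its ISTD MRM trace."""

    istd: str
    native: str
    r: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r < 1.0):
            raise ValidationError(f"interference factor r must be in [0, 1), got {self.r}")


@dataclass(frozen=True)
class CalCurve:
    """Linear response-ratio calibration."""

    analyte: str
    slope: float
    intercept: float
    n_points: int
    residual_sd: float

    def __post_init__(self) -> None:
        if self.n_points < MIN_CAL_POINTS:
            raise ValidationError(
                f"calibration needs >= {MIN_CAL_POINTS} points (method minimum), got {self.n_points}"
            )
        if self.slope <= 0:
            raise StatisticalError(f"calibration slope must be > 0 for a usable curve, got {self.slope}")


@dataclass(frozen=True)
class IsomerConvention:
    """Linear/branched summation convention for one analyte."""

    analyte: str
    L_fraction: float
    sum_L_br: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.L_fraction <= 1.0):
            raise ValidationError(f"L_fraction must be in (0, 1], got {self.L_fraction}")


@dataclass(frozen=True)
class QuantResult:
    """Quantified mass fraction with a below-calibration-range flag."""

    analyte: str
    mass_fraction: float
    below_range: bool = False


def correct_istd_area(A_istd_obs: float, A_native: float, corr: MrmOverlapCorrection) -> float:
    """Subtract the native bleed-through from the observed ISTD area.

    Floors at zero (with a warning) when the correction exceeds the
    observed area.
    """
    if A_istd_obs < 0 or A_native < 0:
        raise ValidationError("peak areas must be >= 0")
    corrected = A_istd_obs - corr.r * A_native
    if corrected < 0:
        warnings.warn(
            f"{corr.istd}: MRM overlap correction exceeds the observed area "
            f"({A_istd_obs:.4g} - {corr.r:g} x {A_native:.4g}); floored at 0",
            stacklevel=2,
        )
        return 0.0
    return corrected


def fit_calibration(
    points: Sequence[tuple[float, float]], analyte: str = "", weighting: str | None = None
) -> CalCurve:
    """Fit response ratio vs amount ratio by least squares.

    *points* are (amount_ratio, response_ratio) pairs with strictly
    increasing amount ratios; ``weighting='1/x'`` applies inverse-amount
    weights, the default is unweighted OLS.
    """
    if len(points) < MIN_CAL_POINTS:
        raise ValidationError(
            f"calibration needs >= {MIN_CAL_POINTS} points (method minimum), got {len(points)}"
        )
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if not np.all(np.diff(x) > 0):
        raise ValidationError("amount ratios must be strictly increasing")
    if weighting is None:
        w = np.ones_like(x)
    elif weighting == "1/x":
        if np.any(x <= 0):
            raise ValidationError("1/x weighting requires positive amount ratios")
        w = 1.0 / x
    else:
        raise ValidationError(f"unknown weighting {weighting!r}; use None or '1/x'")
    W = w.sum()
    xbar = (w * x).sum() / W
    ybar = (w * y).sum() / W
    sxx = (w * (x - xbar) ** 2).sum()
    slope = float((w * (x - xbar) * (y - ybar)).sum() / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - (intercept + slope * x)
    dof = len(x) - 2
    residual_sd = float(np.sqrt((w * resid**2).sum() / dof))
    return CalCurve(analyte=analyte, slope=slope, intercept=intercept,
                    n_points=len(x), residual_sd=residual_sd)


def rescale_amounts_to_total(
    points: Sequence[tuple[float, float]], conv: IsomerConvention
) -> list[tuple[float, float]]:
    """Rescale certified-L amount ratios to total (L+br) amounts.

    The calibrant's nominal amounts cover only the certified linear
    fraction; dividing by ``L_fraction`` recovers the total amounts the
    measured response corresponds to.  Quantifying against the rescaled
    curve equals dividing the naive result by ``L_fraction``.
    """
    if not conv.sum_L_br:
        return list(points)
    return [(a / conv.L_fraction, r) for a, r in points]


def quantify(
    sample_response_ratio: float,
    curve: CalCurve,
    istd_amount_ng: float,
    sample_mass_g: float,
    conv: IsomerConvention | None = None,
) -> QuantResult:
    """Quantify a sample by stable isotope dilution.

    The response ratio maps through the inverse calibration to an amount
    ratio, scales by the spiked ISTD amount (ng) and divides by the sample
    intake (g), giving µg/kg.  A response below the calibration intercept is
    reported as a flagged below-range result of 0, not an exception.  When
    the isomer convention applies, the result is raised by ``1/L_fraction``
    (L+br sum against an L-only calibration).
    """
    if sample_mass_g <= 0:
        raise ValidationError(f"sample mass must be > 0 g, got {sample_mass_g}")
    if istd_amount_ng <= 0:
        raise ValidationError(f"ISTD amount must be > 0 ng, got {istd_amount_ng}")
    amount_ratio = (sample_response_ratio - curve.intercept) / curve.slope
    if amount_ratio < 0:
        return QuantResult(curve.analyte, 0.0, below_range=True)
    amount_ng = amount_ratio * istd_amount_ng
    mass_fraction = amount_ng / sample_mass_g  # ng/g == µg/kg
    if conv is not None and conv.sum_L_br:
        mass_fraction /= conv.L_fraction
    return QuantResult(curve.analyte, float(mass_fraction), below_range=False)


def _parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos or not m.group(1):
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValidationError(f"cannot parse molecular formula {formula!r}")
    return counts


def m_plus_2_fraction(formula: str) -> float:
    """Natural M+2 isotopologue abundance relative to the monoisotopic peak.

    Polynomial expansion over natural isotope abundances: the M+2 peak
    collects one +2 isotope (18O, 34S) or two +1 isotopes (13C, 2H, ...).
    Useful as a theoretical default for the MRM overlap factor ``r`` of a
    2-Da-spaced labelled/native pair.
    """
    counts = _parse_formula(formula)
    unknown = [e for e in counts if e not in _ISO]
    if unknown:
        raise ValidationError(f"no isotope data for element(s) {unknown}")
    p1 = 0.0  # expected number of +1 isotopes
    p2 = 0.0  # expected number of +2 isotopes
    pairs1 = 0.0  # sum over elements of C(n,2)-style same-element double +1
    for elem, n in counts.items():
        a1 = _ISO[elem].get(1, 0.0)
        a2 = _ISO[elem].get(2, 0.0)
        p1 += n * a1
        p2 += n * a2
        pairs1 += 0.5 * n * (n - 1) * a1**2
    # cross-element double +1 terms: (sum n_i a_i)^2/2 - same-element diagonal
    cross = 0.5 * p1**2 - sum(
        0.5 * (n * _ISO[e].get(1, 0.0)) ** 2 for e, n in counts.items()
    )
    return p2 + pairs1 + cross
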