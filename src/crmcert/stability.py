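"""Isochronous stability evaluation with a linear degradation model.

Units aged at several temperatures for up to a year are all measured in one
analytical run (isochronous design), so run-to-run bias cancels and the
value-vs-time series at each temperature can be fitted by ordinary least
squares.  The long-term (in)stability contribution for a shelf life of
``t_sl`` months is the slope's standard error projected over the horizon,

    u_stab = se(b1) * t_sl,        u_stab_r = u_stab / reference value,

the standard linear-model contribution for reference-material shelf-life
assessment.  The regression at the storage temperature (default -20 °C)
feeds the budget; hotter series are fitted for screening only.  A
significant slope (two-sided t test, P < alpha) does not veto
certification — it flags the analyte for post-certification monitoring
(PCM), where the mean of freshly measured units is compared against the
certified reference within the combined uncertainty window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import StatisticalError, ValidationError
from .io import validate_measurements

__all__ = [
    "StabilityFit",
    "MonitoringCheck",
    "fit_degradation",
    "u_stab_from_fit",
    "screen_slopes",
    "pcm_check",
    "StabilityModel",
    "StabilityResults",
]

# residual variance below this fraction of the response mean square is
# treated as an exact fit (keeps se/P exact on noise-free inputs)
_EXACT_FIT_REL = 1e-20


@dataclass(frozen=True)
class StabilityFit:
    """Per-analyte, per-temperature degradation regression."""

    analyte: str
    temperature: float
    b0: float
    b1: float
    se_b1: float
    P_slope: float
    k_points: int
    t_sl: float | None = None
    u_stab: float | None = None
    u_stab_r: float | None = None


@dataclass(frozen=True)
class MonitoringCheck:
    """Post-certification monitoring comparison for one analyte."""

    analyte: str
    reference_mean: float
    monitoring_mean: float
    window: float

    @property
    def passed(self) -> bool:
        return abs(self.monitoring_mean - self.reference_mean) <= self.window


def fit_degradation(table: pd.DataFrame, analyte: str, temperature: float) -> StabilityFit:
    """OLS fit of mass fraction vs time (months) at one storage temperature.

    Slope standard error from the residual variance with k - 2 degrees of
    freedom (k = number of measurements); two-sided t test of slope = 0.
    """
    table = validate_measurements(table, "stability")
    sub = table[(table["analyte"] == analyte) & (table["temperature_C"] == temperature)]
    if len(sub) == 0:
        raise StatisticalError(f"no data for {analyte!r} at {temperature} °C")
    t = sub["time_months"].to_numpy(dtype=float)
    y = sub["value"].to_numpy(dtype=float)
    if len(np.unique(t)) < 3:
        raise StatisticalError(
            f"{analyte} at {temperature} °C: need >= 3 distinct time points, got {len(np.unique(t))}"
        )
    sxx = float(((t - t.mean()) ** 2).sum())
    if sxx == 0.0:
        raise StatisticalError(f"{analyte} at {temperature} °C: zero time spread")
    b1 = float(((t - t.mean()) * (y - y.mean())).sum() / sxx)
    b0 = float(y.mean() - b1 * t.mean())
    resid = y - (b0 + b1 * t)
    k = len(y)
    rss = float((resid**2).sum())
    scale = float((y**2).mean()) or 1.0
    if rss <= _EXACT_FIT_REL * scale * k:
        se = 0.0
        P = 1.0 if b1 == 0.0 else 0.0
    else:
        s2 = rss / (k - 2)
        se = math.sqrt(s2 / sxx)
        tstat = b1 / se
        P = 2.0 * float(stats.t.sf(abs(tstat), k - 2))
    return StabilityFit(analyte=analyte, temperature=float(temperature),
                        b0=b0, b1=b1, se_b1=se, P_slope=P, k_points=k)


def u_stab_from_fit(fit: StabilityFit, t_sl: float, reference_value: float) -> StabilityFit:
    """Attach the shelf-life instability contribution to a fitted line."""
    if t_sl <= 0:
        raise ValidationError(f"shelf life must be > 0 months, got {t_sl}")
    if reference_value <= 0:
        raise ValidationError(f"reference value must be > 0, got {reference_value}")
    u = fit.se_b1 * t_sl
    return replace(fit, t_sl=float(t_sl), u_stab=u, u_stab_r=u / reference_value)


def screen_slopes(fits: list[StabilityFit], alpha: float = 0.05) -> list[StabilityFit]:
    """Analytes/temperatures with a statistically significant trend.

    Flagged series trigger a warning and mandatory PCM scheduling, not
    rejection.
    """
    if not fits:
        raise ValidationError("no fits supplied to screen")
    return [f for f in fits if f.P_slope < alpha]


def pcm_check(
    reference: pd.DataFrame, monitoring: pd.DataFrame, analyte: str, certificate_U: float
) -> MonitoringCheck:
    """Compare a monitoring mean against the certified reference.

    Passes when |difference of means| <= sqrt(U^2 + (k * sem)^2) with the
    monitoring mean's standard error expanded with k = 2.
    """
    ref = reference[reference["analyte"] == analyte]["value"]
    mon = monitoring[monitoring["analyte"] == analyte]["value"]
    if len(ref) == 0 or len(mon) == 0:
        raise StatisticalError(f"analyte {analyte!r} missing from reference or monitoring table")
    sem = float(mon.std(ddof=1) / math.sqrt(len(mon))) if len(mon) > 1 else 0.0
    window = math.sqrt(certificate_U**2 + (2.0 * sem) ** 2)
    return MonitoringCheck(analyte, float(ref.mean()), float(mon.mean()), window)


class StabilityModel:
    """Stability study model over a long-format isochronous table.

    Parameters
    ----------
    data : DataFrame
        Columns ``analyte, temperature_C, time_months, unit, value``.
    t_sl : float
        Shelf-life horizon in months (default 36, a three-year initial
        shelf life).
    ref_temp : float
        Storage temperature whose regression feeds the budget.
    reference_values : mapping, optional
        Per-analyte reference mass fraction used to relativise u_stab
        (typically the assigned value); defaults to the fitted intercept.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        t_sl: float = 36.0,
        ref_temp: float = -20.0,
        alpha: float = 0.05,
        reference_values: dict[str, float] | None = None,
    ):
        self.data = validate_measurements(data, "stability")
        if t_sl <= 0:
            raise ValidationError(f"t_sl must be > 0, got {t_sl}")
        self.t_sl = t_sl
        self.ref_temp = ref_temp
        self.alpha = alpha
        self.reference_values = reference_values or {}

    @classmethod
    def from_csv(cls, path, **kwargs) -> "StabilityModel":
        from .io import read_measurements

        return cls(read_measurements(path, "stability"), **kwargs)

    def fit(self) -> "StabilityResults":
        fits = []
        for analyte in dict.fromkeys(self.data["analyte"]):
            temps = sorted(self.data.loc[self.data["analyte"] == analyte, "temperature_C"].unique())
            if self.ref_temp not in temps:
                raise StatisticalError(
                    f"{analyte}: no data at the reference storage temperature {self.ref_temp} °C"
                )
            for temp in temps:
                f = fit_degradation(self.data, analyte, temp)
                if temp == self.ref_temp:
                    ref = self.reference_values.get(analyte, f.b0)
                    f = u_stab_from_fit(f, self.t_sl, ref)
                fits.append(f)
        return StabilityResults(self, fits)


class StabilityResults:
    def __init__(self, model: StabilityModel, fits: list[StabilityFit]):
        self.model = model
        self.fits = fits

    def __iter__(self):
        return iter(self.fits)

    def at(self, analyte: str, temperature: float | None = None) -> StabilityFit:
        temperature = self.model.ref_temp if temperature is None else temperature
        for f in self.fits:
            if f.analyte == analyte and f.temperature == temperature:
                return f
        raise KeyError((analyte, temperature))

    @property
    def flagged(self) -> list[StabilityFit]:
        """Series with a significant trend (re-test in PCM, do not reject)."""
        return screen_slopes(self.fits, self.model.alpha)

    def u_stab_r(self) -> dict[str, float]:
        """Relative instability contribution per analyte (storage temp)."""
        return {
            f.analyte: f.u_stab_r
            for f in self.fits
            if f.temperature == self.model.ref_temp and f.u_stab_r is not None
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "analyte": [f.analyte for f in self.fits],
                "temperature_C": [f.temperature for f in self.fits],
                "b0": [f.b0 for f in self.fits],
                "b1": [f.b1 for f in self.fits],
                "se_b1": [f.se_b1 for f in self.fits],
                "P_slope": [f.P_slope for f in self.fits],
                "u_stab_r": [f.u_stab_r for f in self.fits],
            }
        )

    def summary(self) -> str:
        df = self.to_frame().copy()
        for col in ("b0", "b1", "se_b1"):
            df[col] = df[col].map(lambda v: f"{v:.5g}")
        df["P_slope"] = df["P_slope"].map(lambda v: f"{v:.4f}")
        df["u_stab_r"] = df["u_stab_r"].map(lambda v: "" if v is None else f"{v:.4f}")
        lines = [
            f"Stability assessment (linear degradation model, t_sl = {self.model.t_sl} months, "
            f"storage {self.model.ref_temp} °C)",
            df.to_string(index=False),
        ]
        for f in self.flagged:
            lines.append(
                f"WARNING: {f.analyte} at {f.temperature} °C shows a significant trend "
                f"(P = {f.P_slope:.4f}); schedule post-certification monitoring"
            )
        return "\n".join(lines)

    def plot_trend(self, analyte: str, temperature: float | None = None, ax=None):
        """Measured values and fitted degradation line at one temperature."""
        import matplotlib.pyplot as plt

        temperature = self.model.ref_temp if temperature is None else temperature
        f = self.at(analyte, temperature)
        sub = self.model.data[
            (self.model.data["analyte"] == analyte)
            & (self.model.data["temperature_C"] == temperature)
        ]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(sub["time_months"], sub["value"], "o", alpha=0.7)
        ts = np.linspace(0, sub["time_months"].max(), 50)
        ax.plot(ts, f.b0 + f.b1 * ts, "-")
        ax.set_xlabel("time (months)")
        ax.set_ylabel("mass fraction (µg/kg)")
        ax.set_title(f"{analyte} at {temperature} °C (slope {f.b1:.3g} ± {f.se_b1:.3g})")
        return ax
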