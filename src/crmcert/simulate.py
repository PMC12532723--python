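"""Synthetic study generators with the variance structure the pipeline assumes.

Each generator draws from the random-effects model that the corresponding
assessment stage estimates, so every downstream estimator can be tested by
parameter recovery:

* homogeneity — bottled batch: ``value(b, r) = mu + B_b + e_br`` with
  ``B_b ~ N(0, sigma_bb^2)`` (between-bottle) and ``e_br ~ N(0, sigma_wb^2)``
  (within-bottle repeatability),
* stability — isochronous grid: ``value(T, t, u) = y0 + slope(T) * t + e``
  with ``e ~ N(0, sigma_meas^2)``; every (temperature, time) cell carries the
  same number of units, mirroring a design where all units are measured
  together in one analytical run,
* characterisation — three-level nesting: ``value(w, u, r) = mu + L_w + B_u
  + e`` with between-workplace, between-unit and repeatability components.

Noise is additive Gaussian on the mass-fraction scale and simulated values
may be negative (no truncation) so estimator properties stay unbiased; pass
``strict_positive=True`` to redraw negative values for display realism.

Randomness contract: each spec carries one root seed; the actual stream is a
``numpy`` :class:`~numpy.random.Generator` spawned from ``(seed, analyte)``
so multi-analyte batches are independent of generation order and two calls
with the same spec are bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import validate_measurements

_MAX_REDRAW = 100


def _rng_for(seed: int, analyte: str) -> np.random.Generator:
    """Deterministic per-analyte substream of the root seed."""
    key = zlib.crc32(analyte.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _require(cond: bool, invariant: str) -> None:
    if not cond:
        raise ValidationError(f"invariant violated: {invariant}")


@dataclass(frozen=True)
class HomogeneitySimSpec:
    """True parameters of a simulated between-bottle homogeneity study."""

    analyte: str
    mu: float
    sigma_bb: float
    sigma_wb: float
    N: int = 14
    n: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.mu > 0, f"mu > 0 (got {self.mu})")
        _require(self.sigma_bb >= 0, f"sigma_bb >= 0 (got {self.sigma_bb})")
        _require(self.sigma_wb > 0 or (self.sigma_wb == 0 and self.sigma_bb == 0),
                 f"sigma_wb > 0 (got {self.sigma_wb})")
        _require(self.N >= 2, f"N >= 2 bottles (got {self.N})")
        _require(self.n >= 2, f"n >= 2 replicates per bottle (got {self.n})")


@dataclass(frozen=True)
class StabilitySimSpec:
    """True degradation lines of a simulated isochronous stability study."""

    analyte: str
    y0: float
    slopes: Mapping[float, float]
    times: Sequence[float]
    units_per_point: int = 2
    sigma_meas: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        times = list(self.times)
        _require(len(times) > 0, "times must be non-empty")
        _require(all(t >= 0 for t in times), "times must be non-negative")
        _require(all(b > a for a, b in zip(times, times[1:])), "times must be strictly increasing")
        _require(0.0 in [float(t) for t in times], "times must include 0")
        _require(self.units_per_point >= 1, f"units_per_point >= 1 (got {self.units_per_point})")
        _require(self.sigma_meas > 0, f"sigma_meas > 0 (got {self.sigma_meas})")
        _require(len(self.slopes) > 0, "slopes must map at least one temperature")


@dataclass(frozen=True)
class CharacterisationSimSpec:
    """True variance components of a simulated multi-workplace study.

    Defaults (W=3 workplaces, 10 units, 3 replicates) reproduce the in-house
    certification layout of 30 analyses per workplace, 90 results in total.
    """

    analyte: str
    mu: float
    sigma_lab: float
    sigma_unit: float
    sigma_rep: float
    W: int = 3
    U_n: int = 10
    R: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.mu > 0, f"mu > 0 (got {self.mu})")
        _require(self.W >= 2, f"W >= 2 workplaces (got {self.W}; a single workplace "
                              "cannot support a between-workplace SD)")
        _require(self.U_n >= 1, f"U_n >= 1 (got {self.U_n})")
        _require(self.R >= 1, f"R >= 1 (got {self.R})")
        for name in ("sigma_lab", "sigma_unit", "sigma_rep"):
            _require(getattr(self, name) >= 0, f"{name} >= 0 (got {getattr(self, name)})")


def _maybe_redraw(values: np.ndarray, draw, strict_positive: bool) -> np.ndarray:
    if not strict_positive:
        return values
    for _ in range(_MAX_REDRAW):
        neg = values <= 0
        if not neg.any():
            return values
        values = np.where(neg, draw(), values)
    raise ValidationError("strict_positive: could not draw positive values (noise SD >> mu?)")


def simulate_homogeneity(spec: HomogeneitySimSpec, strict_positive: bool = False) -> pd.DataFrame:
    """Simulate one homogeneity study table (``N * n`` rows).

    Bottle indices run 1..N in filling order.
    """
    rng = _rng_for(spec.seed, spec.analyte)
    bottle_effects = rng.normal(0.0, spec.sigma_bb, size=spec.N)
    noise = rng.normal(0.0, spec.sigma_wb, size=(spec.N, spec.n))
    values = spec.mu + bottle_effects[:, None] + noise
    values = _maybe_redraw(
        values, lambda: spec.mu + bottle_effects[:, None] + rng.normal(0.0, spec.sigma_wb, values.shape),
        strict_positive,
    )
    rows = pd.DataFrame(
        {
            "analyte": spec.analyte,
            "bottle": np.repeat(np.arange(1, spec.N + 1), spec.n),
            "replicate": np.tile(np.arange(1, spec.n + 1), spec.N),
            "value": values.ravel(),
        }
    )
    return validate_measurements(rows, "homogeneity")


def simulate_stability(spec: StabilitySimSpec, strict_positive: bool = False) -> pd.DataFrame:
    """Simulate one isochronous stability table.

    One row per (temperature, pull time, unit); all grid cells carry
    ``units_per_point`` units.
    """
    rng = _rng_for(spec.seed, spec.analyte)
    records = []
    for temp in sorted(spec.slopes):
        slope = spec.slopes[temp]
        for t in spec.times:
            truth = spec.y0 + slope * t
            vals = truth + rng.normal(0.0, spec.sigma_meas, size=spec.units_per_point)
            vals = _maybe_redraw(
                vals, lambda: truth + rng.normal(0.0, spec.sigma_meas, size=spec.units_per_point),
                strict_positive,
            )
            for u, v in enumerate(vals, start=1):
                records.append((spec.analyte, temp, t, u, v))
    rows = pd.DataFrame(records, columns=["analyte", "temperature_C", "time_months", "unit", "value"])
    return validate_measurements(rows, "stability")


def simulate_characterisation(spec: CharacterisationSimSpec, strict_positive: bool = False) -> pd.DataFrame:
    """Simulate one characterisation table (``W * U_n * R`` rows)."""
    rng = _rng_for(spec.seed, spec.analyte)
    lab = rng.normal(0.0, spec.sigma_lab, size=spec.W)
    unit = rng.normal(0.0, spec.sigma_unit, size=(spec.W, spec.U_n))
    rep = rng.normal(0.0, spec.sigma_rep, size=(spec.W, spec.U_n, spec.R))
    values = spec.mu + lab[:, None, None] + unit[:, :, None] + rep
    values = _maybe_redraw(
        values,
        lambda: spec.mu + lab[:, None, None] + unit[:, :, None]
        + rng.normal(0.0, spec.sigma_rep, values.shape),
        strict_positive,
    )
    w_idx, u_idx, r_idx = np.meshgrid(
        np.arange(1, spec.W + 1), np.arange(1, spec.U_n + 1), np.arange(1, spec.R + 1), indexing="ij"
    )
    rows = pd.DataFrame(
        {
            "analyte": spec.analyte,
            "workplace": [f"W{i}" for i in w_idx.ravel()],
            "unit": u_idx.ravel(),
            "replicate": r_idx.ravel(),
            "value": values.ravel(),
        }
    )
    return validate_measurements(rows, "characterisation")


def simulate_batch(specs: Sequence, kind: str, strict_positive: bool = False) -> pd.DataFrame:
    """Concatenate single-analyte simulations into one multi-analyte table.

    Because substreams are keyed by (seed, analyte), the result is
    independent of the order of *specs*.
    """
    dispatch = {
        "homogeneity": simulate_homogeneity,
        "stability": simulate_stability,
        "characterisation": simulate_characterisation,
    }
    if kind not in dispatch:
        raise ValidationError(f"unknown study kind {kind!r}")
    frames = [dispatch[kind](s, strict_positive=strict_positive) for s in specs]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Default multi-analyte study: a realistic 18-analyte batch


@dataclass(frozen=True)
class StudyScenario:
    """True values for one analyte across all three study kinds.

    ``u_pur_r`` rides along so a full synthetic certification can be run
    without an external calibrant-uncertainty table.
    """

    analyte: str
    mu: float
    sigma_bb_r: float = 0.01
    sigma_wb_r: float = 0.025
    sigma_lab_r: float = 0.015
    sigma_unit_r: float = 0.012
    sigma_rep_r: float = 0.025
    slope_r_per_month: float = 0.0
    sigma_meas_r: float = 0.02
    u_pur_r: float = 0.03

    def homogeneity_spec(self, seed: int) -> HomogeneitySimSpec:
        return HomogeneitySimSpec(
            analyte=self.analyte, mu=self.mu,
            sigma_bb=self.sigma_bb_r * self.mu, sigma_wb=self.sigma_wb_r * self.mu,
            N=14, n=3, seed=seed,
        )

    def stability_spec(self, seed: int,
                       temperatures: Sequence[float] = (-20.0, 4.0, 23.0, 40.0, 60.0),
                       times: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 12.0),
                       units_per_point: int = 3) -> StabilitySimSpec:
        slopes = {t: self.slope_r_per_month * self.mu for t in temperatures}
        return StabilitySimSpec(
            analyte=self.analyte, y0=self.mu, slopes=slopes, times=tuple(times),
            units_per_point=units_per_point, sigma_meas=self.sigma_meas_r * self.mu, seed=seed,
        )

    def characterisation_spec(self, seed: int) -> CharacterisationSimSpec:
        return CharacterisationSimSpec(
            analyte=self.analyte, mu=self.mu,
            sigma_lab=self.sigma_lab_r * self.mu, sigma_unit=self.sigma_unit_r * self.mu,
            sigma_rep=self.sigma_rep_r * self.mu, W=3, U_n=10, R=3, seed=seed,
        )


#: default scenario: one mid-range PFAS-like analyte per family
DEFAULT_SCENARIOS = (
    StudyScenario("PFHxA", mu=35.0, sigma_bb_r=0.012, sigma_wb_r=0.027),
    StudyScenario("PFOA", mu=71.0, sigma_bb_r=0.0, sigma_wb_r=0.031),
    StudyScenario("PFOS", mu=41.0, sigma_bb_r=0.014, sigma_wb_r=0.036),
    StudyScenario("6:2 FTSA", mu=4.5, sigma_bb_r=0.02, sigma_wb_r=0.033),
)
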