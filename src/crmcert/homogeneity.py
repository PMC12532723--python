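"""Between-bottle homogeneity assessment by one-factorial ANOVA.

A reference-material batch is homogeneous enough when the variation between
bottles is negligible against the variation of the method itself.  For each
analyte the study measures ``n`` replicates from each of ``N`` bottles; the
one-way ANOVA splits the variance into a between-bottle mean square
``M_between`` and a within-bottle (repeatability) mean square ``M_within``.
Two estimators feed the uncertainty budget:

* the between-bottle standard deviation
  ``s_bb = sqrt((M_between - M_within) / n)`` — applicable only when
  ``M_between > M_within``;
* the minimal detectable inhomogeneity
  ``s_bb_min = sqrt(M_within / n) * (2 / (N * (n - 1)))**0.25`` — the largest
  inhomogeneity that the repeatability of the method could still hide.

The budget takes the conservative maximum of the two relative values as the
inhomogeneity contribution ``u_bb_r``.  ANOVA P-values are screened per
analyte and, because a certified material carries many analytes, also after
a Bonferroni adjustment ``P_adj = min(1, m * P)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import StatisticalError, ValidationError
from .io import validate_measurements

__all__ = [
    "AnovaDecomposition",
    "HomogeneityAnalyteResult",
    "anova_oneway",
    "sbb",
    "sbb_min",
    "adjust_bonferroni",
    "assess_homogeneity",
    "HomogeneityModel",
    "HomogeneityResults",
]


@dataclass(frozen=True)
class AnovaDecomposition:
    """One-way ANOVA of replicate measurements grouped by bottle."""

    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    P: float
    group_means: pd.Series
    group_sizes: pd.Series
    grand_mean: float

    @property
    def M_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def M_within(self) -> float:
        return self.ss_within / self.df_within

    @property
    def mean_of_group_means(self) -> float:
        """Study mean: unweighted mean of bottle means (equals the grand
        mean only for balanced designs)."""
        return float(self.group_means.mean())

    @property
    def n_eff(self) -> float:
        """Effective replicates per bottle; equals n for balanced designs."""
        ni = self.group_sizes.to_numpy(dtype=float)
        total = ni.sum()
        return float((total - (ni**2).sum() / total) / (len(ni) - 1))


def anova_oneway(table: pd.DataFrame, analyte: str) -> AnovaDecomposition:
    """One-factorial ANOVA of *analyte* grouped by bottle.

    Requires at least two bottles with at least two replicates each; raises
    :class:`StatisticalError` when the within-bottle variance is zero (the
    F ratio is then undefined).
    """
    table = validate_measurements(table, "homogeneity")
    sub = table[table["analyte"] == analyte]
    if len(sub) == 0:
        raise StatisticalError(f"analyte {analyte!r} not present in homogeneity table")
    groups = sub.groupby("bottle")["value"]
    sizes = groups.size()
    if len(sizes) < 2:
        raise StatisticalError(f"{analyte}: need >= 2 bottles, got {len(sizes)}")
    if (sizes < 2).any():
        bad = sizes.index[sizes < 2].tolist()
        raise StatisticalError(f"{analyte}: bottles {bad} have fewer than 2 replicates")

    values = sub["value"].to_numpy(dtype=float)
    grand = float(values.mean())
    means = groups.mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((sub["value"] - sub["bottle"].map(means)) ** 2).sum())
    df_between = len(sizes) - 1
    df_within = int((sizes - 1).sum())
    if ss_within <= 0.0:
        raise StatisticalError(
            f"{analyte}: within-bottle sum of squares is zero; the F statistic is undefined"
        )
    M_b = ss_between / df_between
    M_w = ss_within / df_within
    F = M_b / M_w
    P = float(stats.f.sf(F, df_between, df_within))
    return AnovaDecomposition(
        ss_between=ss_between, ss_within=ss_within,
        df_between=df_between, df_within=df_within,
        F=F, P=P, group_means=means, group_sizes=sizes, grand_mean=grand,
    )


def sbb(M_between: float, M_within: float, n: float) -> float | None:
    """Between-bottle SD estimate from ANOVA mean squares (µg/kg).

    Returns ``None`` when ``M_between < M_within``, where the estimator is
    not applicable (the difference would be negative); the boundary
    ``M_between == M_within`` gives 0.
    """
    if n < 2:
        raise StatisticalError(f"sbb requires n >= 2 replicates, got {n}")
    if M_within < 0 or M_between < 0:
        raise ValidationError("mean squares must be non-negative")
    if M_between < M_within:
        return None
    return math.sqrt((M_between - M_within) / n)


def sbb_min(M_within: float, n: float, N: int) -> float:
    """Minimal detectable inhomogeneity (µg/kg): the largest between-bottle
    SD that could be hidden by the method repeatability for this study size.
    """
    if n < 2:
        raise StatisticalError(f"sbb_min requires n >= 2 replicates, got {n}")
    if N < 2:
        raise StatisticalError(f"sbb_min requires N >= 2 bottles, got {N}")
    if M_within <= 0:
        raise ValidationError(f"M_within must be > 0, got {M_within}")
    return math.sqrt(M_within / n) * (2.0 / (N * (n - 1.0))) ** 0.25


def adjust_bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``P_adj = min(1, m * P)``, order-preserving.

    *m* defaults to the number of P-values supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("P-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValidationError(f"number of tests m must be >= 1, got {m}")
    return np.minimum(1.0, m * p)


@dataclass(frozen=True)
class HomogeneityAnalyteResult:
    """Per-analyte homogeneity assessment (one row of the study table)."""

    analyte: str
    mean: float
    n: float
    N: int
    M_between: float
    M_within: float
    P: float
    P_adj: float
    s_bb: float | None
    s_bb_min: float
    model_A_applicable: bool

    @property
    def s_bb_r(self) -> float:
        """Relative between-bottle SD; 0 when the estimator is inapplicable
        (matching how such rows are displayed)."""
        return 0.0 if self.s_bb is None else self.s_bb / self.mean

    @property
    def s_bb_min_r(self) -> float:
        return self.s_bb_min / self.mean

    @property
    def u_bb_r(self) -> float:
        """Conservative inhomogeneity contribution: max of the two relative
        estimators."""
        return max(self.s_bb_r, self.s_bb_min_r)


def assess_homogeneity(
    table: pd.DataFrame, alpha: float = 0.05, m: int | None = None
) -> list[HomogeneityAnalyteResult]:
    """Assess every analyte in a homogeneity table.

    Returns one :class:`HomogeneityAnalyteResult` per analyte (input order).
    """
    table = validate_measurements(table, "homogeneity")
    analytes = list(dict.fromkeys(table["analyte"]))
    decomps = {a: anova_oneway(table, a) for a in analytes}
    p_adj = adjust_bonferroni([decomps[a].P for a in analytes], m)
    results = []
    for a, padj in zip(analytes, p_adj):
        d = decomps[a]
        n_eff = d.n_eff
        s_bb_val = sbb(d.M_between, d.M_within, n_eff)
        results.append(
            HomogeneityAnalyteResult(
                analyte=a,
                mean=d.mean_of_group_means,
                n=n_eff,
                N=len(d.group_means),
                M_between=d.M_between,
                M_within=d.M_within,
                P=d.P,
                P_adj=float(padj),
                s_bb=s_bb_val,
                s_bb_min=sbb_min(d.M_within, n_eff, len(d.group_means)),
                model_A_applicable=d.M_between > d.M_within,
            )
        )
    return results


class HomogeneityModel:
    """Between-bottle homogeneity model for a long-format study table.

    Parameters
    ----------
    data : DataFrame
        Columns ``analyte, bottle, replicate, value`` (µg/kg).
    alpha : float
        Significance level for the inhomogeneity warning flags.
    m_tests : int, optional
        Bonferroni multiplier; defaults to the number of analytes present.
    """

    def __init__(self, data: pd.DataFrame, alpha: float = 0.05, m_tests: int | None = None):
        if not (0 < alpha < 1):
            raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
        self.data = validate_measurements(data, "homogeneity")
        self.alpha = alpha
        self.m_tests = m_tests

    @classmethod
    def from_csv(cls, path, **kwargs) -> "HomogeneityModel":
        from .io import read_measurements

        return cls(read_measurements(path, "homogeneity"), **kwargs)

    def fit(self) -> "HomogeneityResults":
        results = assess_homogeneity(self.data, alpha=self.alpha, m=self.m_tests)
        return HomogeneityResults(self, results)


class HomogeneityResults:
    """Fitted homogeneity assessment; one row per analyte."""

    def __init__(self, model: HomogeneityModel, results: list[HomogeneityAnalyteResult]):
        self.model = model
        self.results = results

    def __iter__(self):
        return iter(self.results)

    def for_analyte(self, analyte: str) -> HomogeneityAnalyteResult:
        for r in self.results:
            if r.analyte == analyte:
                return r
        raise KeyError(analyte)

    @property
    def warnings(self) -> list[str]:
        """Analytes whose adjusted P-value falls below alpha."""
        return [r.analyte for r in self.results if r.P_adj < self.model.alpha]

    def u_bb_r(self) -> dict[str, float]:
        return {r.analyte: r.u_bb_r for r in self.results}

    def bottle_means(self, analyte: str) -> pd.Series:
        """Per-bottle means in filling order, for visual trend screening."""
        sub = self.model.data[self.model.data["analyte"] == analyte]
        if len(sub) == 0:
            raise KeyError(analyte)
        return sub.groupby("bottle")["value"].mean().sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "analyte": r.analyte,
                    "mean": r.mean,
                    "n": r.n,
                    "N": r.N,
                    "M_between": r.M_between,
                    "M_within": r.M_within,
                    "P": r.P,
                    "P_adj": r.P_adj,
                    "s_bb_r": r.s_bb_r,
                    "s_bb_min_r": r.s_bb_min_r,
                    "u_bb_r": r.u_bb_r,
                    "model_A_applicable": r.model_A_applicable,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame().copy()
        for col in ("s_bb_r", "s_bb_min_r", "u_bb_r"):
            df[col] = df[col].map(lambda v: f"{v:.4f}")
        for col in ("P", "P_adj"):
            df[col] = df[col].map(lambda v: f"{v:.4f}")
        for col in ("mean", "M_between", "M_within"):
            df[col] = df[col].map(lambda v: f"{v:.4g}")
        lines = ["Homogeneity assessment (one-factorial ANOVA)",
                 f"alpha = {self.model.alpha}, Bonferroni m = {self.model.m_tests or len(self.results)}",
                 df.to_string(index=False)]
        if self.warnings:
            lines.append("WARNING: adjusted P < alpha for: " + ", ".join(self.warnings))
        return "\n".join(lines)

    def plot_bottle_means(self, analyte: str, ax=None):
        """Bottle means vs filling order — the visual screen for trends."""
        import matplotlib.pyplot as plt

        means = self.bottle_means(analyte)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(means.index, means.values, "o-")
        ax.axhline(self.for_analyte(analyte).mean, color="grey", ls="--", lw=1)
        ax.set_xlabel("bottle (filling order)")
        ax.set_ylabel("mass fraction (µg/kg)")
        ax.set_title(f"{analyte}: bottle means")
        return ax
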