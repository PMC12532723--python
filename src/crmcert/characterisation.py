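"""Value assignment from a multi-workplace characterisation study.

Each workplace contributes a set of independent results (by default 10 units
x 3 replicates = 30 per workplace).  Workplace means are screened for
outliers (Grubbs, Dixon, Scheffé on means; Cochran on variances); the
assigned value is the unweighted mean of the accepted workplace means,

    x_char = mean(workplace means),    u_char = SD(workplace means) / sqrt(N),

where N is the number of accepted workplaces.  Variance outliers are flagged
but never excluded — with ~30 replicates per group one inflated variance
barely moves its group mean.  Mean outliers would exclude a workplace, but
with as few as three workplaces exclusion is statistically weak, so it must
be explicitly confirmed (``confirm_exclusion=True``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from .exceptions import StatisticalError
from .io import validate_measurements
from .outliers import OutlierTest, cochran_test, dixon_test, grubbs_test, scheffe_pairs

__all__ = [
    "WorkplaceSummary",
    "CharacterisationAnalyteResult",
    "summarize_workplaces",
    "outlier_tests",
    "assign_value",
    "CharacterisationModel",
    "CharacterisationResults",
]


@dataclass(frozen=True)
class WorkplaceSummary:
    workplace: str
    mean: float
    sd: float
    n_results: int
    mean_outlier: bool = False
    variance_outlier: bool = False


@dataclass(frozen=True)
class CharacterisationAnalyteResult:
    """Assigned value and its characterisation uncertainty for one analyte."""

    analyte: str
    N: int
    x_char: float
    SD: float
    workplaces: tuple[WorkplaceSummary, ...] = ()
    tests: tuple[OutlierTest, ...] = ()

    @property
    def u_char(self) -> float:
        return self.SD / math.sqrt(self.N)

    @property
    def u_char_r(self) -> float:
        return self.u_char / self.x_char


def summarize_workplaces(table: pd.DataFrame, analyte: str) -> list[WorkplaceSummary]:
    """Per-workplace mean, SD and result count over all unit x replicate
    results of *analyte*."""
    table = validate_measurements(table, "characterisation")
    sub = table[table["analyte"] == analyte]
    if len(sub) == 0:
        raise StatisticalError(f"analyte {analyte!r} not present in characterisation table")
    groups = sub.groupby("workplace")["value"]
    if len(groups) < 2:
        raise StatisticalError(f"{analyte}: need >= 2 workplaces, got {len(groups)}")
    out = []
    for wp, vals in groups:
        if len(vals) < 2:
            raise StatisticalError(f"{analyte}: workplace {wp!r} has fewer than 2 results")
        out.append(WorkplaceSummary(str(wp), float(vals.mean()), float(vals.std(ddof=1)), int(len(vals))))
    return out


def outlier_tests(
    summaries: list[WorkplaceSummary], alpha: float = 0.05
) -> tuple[list[WorkplaceSummary], list[OutlierTest]]:
    """Screen workplace means (Grubbs, Dixon, Scheffé) and variances
    (Cochran); returns summaries with flags set plus the test outcomes."""
    means = [s.mean for s in summaries]
    variances = [s.sd**2 for s in summaries]
    sizes = [s.n_results for s in summaries]
    df_within = sum(n - 1 for n in sizes)
    pooled_var = (
        sum((n - 1) * v for n, v in zip(sizes, variances)) / df_within if df_within > 0 else 0.0
    )
    tests = [
        grubbs_test(means, alpha),
        dixon_test(means, alpha),
        scheffe_pairs(means, sizes, pooled_var, df_within, alpha),
        cochran_test(variances, df=min(sizes) - 1, alpha=alpha),
    ]
    mean_flags: set[int] = set()
    var_flags: set[int] = set()
    for t in tests:
        if not t.applicable:
            continue
        (var_flags if t.name == "cochran" else mean_flags).update(t.outliers)
    annotated = [
        replace(s, mean_outlier=(i in mean_flags), variance_outlier=(i in var_flags))
        for i, s in enumerate(summaries)
    ]
    return annotated, tests


def assign_value(
    summaries: list[WorkplaceSummary], analyte: str = "", confirm_exclusion: bool = False
) -> CharacterisationAnalyteResult:
    """Unweighted mean of accepted workplace means and its standard
    uncertainty ``SD / sqrt(N)``.

    Mean-outlier workplaces are dropped only when *confirm_exclusion* is
    set; variance outliers are never dropped.
    """
    accepted = [s for s in summaries if not (confirm_exclusion and s.mean_outlier)]
    if len(accepted) < 2:
        raise StatisticalError(
            f"{analyte or 'analyte'}: need >= 2 accepted workplaces to form an SD, got {len(accepted)}"
        )
    means = pd.Series([s.mean for s in accepted])
    return CharacterisationAnalyteResult(
        analyte=analyte,
        N=len(accepted),
        x_char=float(means.mean()),
        SD=float(means.std(ddof=1)),
        workplaces=tuple(summaries),
    )


class CharacterisationModel:
    """Characterisation study model over a long-format table.

    Parameters
    ----------
    data : DataFrame
        Columns ``analyte, workplace, unit, replicate, value``.
    alpha : float
        Level for the outlier screens.
    confirm_exclusion : bool
        Actually drop mean-outlier workplaces (off by default: flags only).
    """

    def __init__(self, data: pd.DataFrame, alpha: float = 0.05, confirm_exclusion: bool = False):
        self.data = validate_measurements(data, "characterisation")
        self.alpha = alpha
        self.confirm_exclusion = confirm_exclusion

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CharacterisationModel":
        from .io import read_measurements

        return cls(read_measurements(path, "characterisation"), **kwargs)

    def fit(self) -> "CharacterisationResults":
        results = []
        for analyte in dict.fromkeys(self.data["analyte"]):
            summaries = summarize_workplaces(self.data, analyte)
            annotated, tests = outlier_tests(summaries, self.alpha)
            res = assign_value(annotated, analyte, confirm_exclusion=self.confirm_exclusion)
            results.append(replace(res, tests=tuple(tests)))
        return CharacterisationResults(self, results)


class CharacterisationResults:
    def __init__(self, model: CharacterisationModel, results: list[CharacterisationAnalyteResult]):
        self.model = model
        self.results = results

    def __iter__(self):
        return iter(self.results)

    def for_analyte(self, analyte: str) -> CharacterisationAnalyteResult:
        for r in self.results:
            if r.analyte == analyte:
                return r
        raise KeyError(analyte)

    @property
    def warnings(self) -> list[str]:
        out = []
        for r in self.results:
            for s in r.workplaces:
                if s.mean_outlier:
                    out.append(f"{r.analyte}: workplace {s.workplace} flagged as mean outlier")
                if s.variance_outlier:
                    out.append(f"{r.analyte}: workplace {s.workplace} flagged as variance outlier (not excluded)")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "analyte": [r.analyte for r in self.results],
                "N": [r.N for r in self.results],
                "x_char": [r.x_char for r in self.results],
                "SD": [r.SD for r in self.results],
                "u_char": [r.u_char for r in self.results],
                "u_char_r": [r.u_char_r for r in self.results],
            }
        )

    def summary(self) -> str:
        df = self.to_frame().copy()
        df["x_char"] = df["x_char"].map(lambda v: f"{v:.3f}")
        df["SD"] = df["SD"].map(lambda v: f"{v:.3f}")
        df["u_char"] = df["u_char"].map(lambda v: f"{v:.4f}")
        df["u_char_r"] = df["u_char_r"].map(lambda v: f"{v:.4f}")
        lines = ["Characterisation study (unweighted mean of workplace means)", df.to_string(index=False)]
        lines += self.warnings
        return "\n".join(lines)
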