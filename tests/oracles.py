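"""Brute-force definitional oracles, independent of the library's code paths.

Everything here is written with explicit loops and textbook definitions
(two-pass variances, normal equations, max-deviation ratios) so the main
implementations can be checked against a genuinely separate route.
"""

from __future__ import annotations

import math


def anova_twopass(groups: list[list[float]]) -> dict:
    """One-way ANOVA by explicit loops and two-pass variance sums."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ss_between = 0.0
    ss_within = 0.0
    for g in groups:
        m = sum(g) / len(g)
        ss_between += len(g) * (m - grand) ** 2
        for v in g:
            ss_within += (v - m) ** 2
    df_between = len(groups) - 1
    df_within = sum(len(g) - 1 for g in groups)
    return {
        "ss_between": ss_between,
        "ss_within": ss_within,
        "M_between": ss_between / df_between,
        "M_within": ss_within / df_within,
        "df": (df_between, df_within),
    }


def ols_normal_equations(x: list[float], y: list[float]) -> dict:
    """Simple linear regression via the raw normal equations."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    det = n * sxx - sx * sx
    b1 = (n * sxy - sx * sy) / det
    b0 = (sy - b1 * sx) / n
    rss = sum((yi - b0 - b1 * xi) ** 2 for xi, yi in zip(x, y))
    s2 = rss / (n - 2)
    se_b1 = math.sqrt(s2 * n / det)
    return {"b0": b0, "b1": b1, "se_b1": se_b1, "rss": rss}


def grubbs_statistic(values: list[float]) -> float:
    """Max absolute deviation over the sample SD."""
    n = len(values)
    m = sum(values) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))
    return max(abs(v - m) for v in values) / sd


def dixon_r10(values: list[float]) -> float:
    """Larger of the two end gap/range ratios."""
    s = sorted(values)
    rng = s[-1] - s[0]
    return max((s[1] - s[0]) / rng, (s[-1] - s[-2]) / rng)


def cochran_c(variances: list[float]) -> float:
    return max(variances) / sum(variances)
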