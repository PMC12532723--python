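"""Outlier screening tests for interlaboratory group means and variances.

The characterisation stage screens workplace summaries before value
assignment: the group *means* with the Grubbs, Dixon and Scheffé tests and
the group *variances* with the Cochran test.  All tests are two-sided at the
caller's significance level (default 0.05).

Critical values come from the standard closed forms: Grubbs from the t
distribution (two-sided single-outlier form), Cochran from the
F-distribution relation ``C_crit = 1 / (1 + (k - 1) / F)`` with
``F = F(alpha / k; df, (k - 1) df)``, Scheffé from the F distribution for
all-pairs contrasts.  The Dixon r10 ratio has no closed form; its two-sided
5% and 1% critical values for 3 <= n <= 7 are the tabulated values of
Rorabacher (1991).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import StatisticalError, ValidationError

__all__ = [
    "OutlierTest",
    "grubbs_test",
    "dixon_test",
    "cochran_test",
    "scheffe_pairs",
    "grubbs_critical",
    "dixon_critical",
    "cochran_critical",
]


@dataclass(frozen=True)
class OutlierTest:
    """Outcome of one screening test.

    ``outliers`` holds indices into the input sequence; ``applicable`` is
    False when the group count is below the test's minimum (too few groups
    is reported as a status, never raised).
    """

    name: str
    statistic: float | None
    critical: float | None
    outliers: tuple[int, ...]
    applicable: bool

    @property
    def flagged(self) -> bool:
        return len(self.outliers) > 0


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-Grubbs critical value for sample size *n*."""
    if n < 3:
        raise StatisticalError(f"Grubbs test needs n >= 3, got {n}")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values, alpha: float = 0.05) -> OutlierTest:
    """Two-sided single-outlier Grubbs test on group means."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        return OutlierTest("grubbs", None, None, (), applicable=False)
    sd = x.std(ddof=1)
    if sd == 0.0:
        return OutlierTest("grubbs", 0.0, grubbs_critical(len(x), alpha), (), applicable=True)
    dev = np.abs(x - x.mean())
    idx = int(dev.argmax())
    G = float(dev[idx] / sd)
    crit = grubbs_critical(len(x), alpha)
    return OutlierTest("grubbs", G, crit, (idx,) if G > crit else (), applicable=True)


# Two-sided Dixon r10 critical values (Rorabacher 1991, Table 1).
_DIXON_R10 = {
    0.05: {3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568},
    0.01: {3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680},
}


def dixon_critical(n: int, alpha: float = 0.05) -> float:
    if alpha not in _DIXON_R10:
        raise ValidationError(f"Dixon critical values tabulated for alpha in {sorted(_DIXON_R10)} only")
    table = _DIXON_R10[alpha]
    if n not in table:
        raise StatisticalError(f"Dixon r10 applies to 3 <= n <= 7, got {n}")
    return table[n]


def dixon_test(values, alpha: float = 0.05) -> OutlierTest:
    """Dixon r10 ratio test (gap over range) on group means, both ends."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3 or n > 7:
        return OutlierTest("dixon", None, None, (), applicable=False)
    order = np.argsort(x)
    s = x[order]
    rng = s[-1] - s[0]
    if rng == 0.0:
        return OutlierTest("dixon", 0.0, dixon_critical(n, alpha), (), applicable=True)
    r_low = (s[1] - s[0]) / rng
    r_high = (s[-1] - s[-2]) / rng
    if r_high >= r_low:
        Q, idx = float(r_high), int(order[-1])
    else:
        Q, idx = float(r_low), int(order[0])
    crit = dixon_critical(n, alpha)
    return OutlierTest("dixon", Q, crit, (idx,) if Q > crit else (), applicable=True)


def cochran_critical(k: int, df: int, alpha: float = 0.05) -> float:
    """Cochran C critical value for *k* groups of *df* degrees of freedom."""
    if k < 2:
        raise StatisticalError(f"Cochran test needs k >= 2 groups, got {k}")
    if df < 1:
        raise StatisticalError(f"Cochran test needs df >= 1 per group, got {df}")
    F = stats.f.ppf(1.0 - alpha / k, df, (k - 1) * df)
    return 1.0 / (1.0 + (k - 1) / F)


def cochran_test(variances, df: int, alpha: float = 0.05) -> OutlierTest:
    """Cochran test for a single excessive group variance.

    ``C = max(s_i^2) / sum(s_i^2)`` with *df* degrees of freedom per group
    (replicate count minus one).
    """
    v = np.asarray(variances, dtype=float)
    if (v < 0).any():
        raise ValidationError("variances must be non-negative")
    if len(v) < 2:
        return OutlierTest("cochran", None, None, (), applicable=False)
    total = v.sum()
    if total == 0.0:
        return OutlierTest("cochran", 0.0, cochran_critical(len(v), df, alpha), (), applicable=True)
    idx = int(v.argmax())
    C = float(v[idx] / total)
    crit = cochran_critical(len(v), df, alpha)
    return OutlierTest("cochran", C, crit, (idx,) if C > crit else (), applicable=True)


def scheffe_pairs(means, sizes, pooled_var: float, df_within: int, alpha: float = 0.05) -> OutlierTest:
    """Scheffé all-pairs comparison of group means.

    A pair (i, j) is significant when
    ``(m_i - m_j)^2 / (s2 (1/n_i + 1/n_j)) > (k - 1) F(alpha; k - 1, df)``
    with the pooled within-group variance ``s2``.  Of each significant pair
    the member lying further from the centre of the group means is flagged
    (the screen looks for the discrepant group, not for both sides of a
    discrepant difference).
    """
    m = np.asarray(means, dtype=float)
    ns = np.asarray(sizes, dtype=float)
    k = len(m)
    if k < 3:
        return OutlierTest("scheffe", None, None, (), applicable=False)
    if pooled_var < 0 or df_within < 1:
        raise ValidationError("pooled variance must be >= 0 and df_within >= 1")
    crit = (k - 1) * stats.f.ppf(1.0 - alpha, k - 1, df_within)
    centre = m.mean()
    flagged: set[int] = set()
    worst = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            denom = pooled_var * (1.0 / ns[i] + 1.0 / ns[j])
            if denom == 0.0:
                stat = math.inf if m[i] != m[j] else 0.0
            else:
                stat = (m[i] - m[j]) ** 2 / denom
            worst = max(worst, stat)
            if stat > crit:
                flagged.add(i if abs(m[i] - centre) >= abs(m[j] - centre) else j)
    return OutlierTest("scheffe", float(worst), float(crit), tuple(sorted(flagged)), applicable=True)
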