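"""Uncertainty budget and certificate assembly.

The four relative contributions — between-bottle inhomogeneity ``u_bb_r``,
long-term instability ``u_stab_r``, characterisation ``u_char_r`` and
calibrant purity ``u_pur_r`` — combine by root sum of squares into the
relative combined uncertainty ``u_com_r``; the expanded uncertainty is
``U = x_cert * u_com_r * k`` with coverage factor ``k = 2`` (about 95 %
confidence).

Certificate presentation: the certified value is rounded half-up at its
display precision, while the expanded uncertainty is rounded *up* (ceiling)
at the same precision so the displayed interval always covers the computed
one.  Display precision per analyte is an explicit input (defaulting to two
significant figures of the certified value) because certificates routinely
choose precision analyte by analyte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_CEILING, ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .characterisation import CharacterisationAnalyteResult
from .exceptions import ValidationError

__all__ = [
    "UncertaintyContributions",
    "CertificateEntry",
    "Certificate",
    "combine",
    "expand",
    "round_certificate",
    "default_precision",
    "build_certificate",
]

#: analytes certified as the sum of linear and branched isomers
ISOMER_SUM_DEFAULT = ("PFOA", "PFHxS", "PFOS")


@dataclass(frozen=True)
class UncertaintyContributions:
    """Relative uncertainty contributions for one analyte."""

    analyte: str
    u_bb_r: float
    u_stab_r: float
    u_char_r: float
    u_pur_r: float

    def __post_init__(self) -> None:
        for name in ("u_bb_r", "u_stab_r", "u_char_r", "u_pur_r"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{self.analyte}: {name} must be >= 0, got {v}")


def combine(contribs: UncertaintyContributions) -> float:
    """Relative combined uncertainty: root sum of squares of the four
    contributions."""
    return math.sqrt(
        contribs.u_bb_r**2 + contribs.u_stab_r**2 + contribs.u_char_r**2 + contribs.u_pur_r**2
    )


def expand(x_cert: float, u_com_r: float, k: float = 2.0) -> float:
    """Expanded uncertainty ``U = x_cert * u_com_r * k`` (µg/kg, full
    precision)."""
    if x_cert <= 0:
        raise ValidationError(f"certified value must be > 0, got {x_cert}")
    if u_com_r < 0:
        raise ValidationError(f"u_com_r must be >= 0, got {u_com_r}")
    if k <= 0:
        raise ValidationError(f"coverage factor must be > 0, got {k}")
    return x_cert * u_com_r * k


def _decimal(x: float) -> Decimal:
    # str() keeps the shortest repr, avoiding binary-float ceiling artifacts
    return Decimal(str(float(x)))


def round_certificate(x_cert: float, U: float, precision: int) -> tuple[float, float]:
    """Certificate display rounding at *precision* decimal places.

    The certified value rounds half-up; the expanded uncertainty rounds up
    (ceiling) so the displayed interval never understates the computed one.
    """
    if precision not in (0, 1, 2):
        raise ValidationError(f"display precision must be 0, 1 or 2 decimals, got {precision}")
    q = Decimal(1).scaleb(-precision)
    x_disp = float(_decimal(x_cert).quantize(q, rounding=ROUND_HALF_UP))
    U_disp = float(_decimal(U).quantize(q, rounding=ROUND_CEILING))
    return x_disp, U_disp


def default_precision(x_cert: float) -> int:
    """Decimals giving two significant figures of the certified value,
    clipped to the 0-2 range a certificate uses."""
    if x_cert <= 0:
        raise ValidationError(f"certified value must be > 0, got {x_cert}")
    return int(min(2, max(0, 1 - math.floor(math.log10(x_cert)))))


@dataclass(frozen=True)
class CertificateEntry:
    """One certificate row: certified value with expanded uncertainty."""

    analyte: str
    full_name: str
    x_cert: float
    u_com_r: float
    k: float
    U: float
    x_display: float
    U_display: float
    precision: int
    isomer_note: bool
    contributions: UncertaintyContributions | None = None


class Certificate:
    """Certified values for a batch of analytes, with display rounding."""

    def __init__(self, entries: list[CertificateEntry], k: float):
        self.entries = entries
        self.k = k

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def for_analyte(self, analyte: str) -> CertificateEntry:
        for e in self.entries:
            if e.analyte == analyte:
                return e
        raise KeyError(analyte)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "analyte": [e.analyte for e in self.entries],
                "full_name": [e.full_name for e in self.entries],
                "x_cert": [e.x_cert for e in self.entries],
                "u_com_r": [e.u_com_r for e in self.entries],
                "k": [e.k for e in self.entries],
                "U": [e.U for e in self.entries],
                "x_display": [e.x_display for e in self.entries],
                "U_display": [e.U_display for e in self.entries],
                "isomer_note": [e.isomer_note for e in self.entries],
            }
        )

    def summary(self) -> str:
        lines = [
            "Certified mass fractions and expanded uncertainties",
            f"(coverage factor k = {self.k:g}, ~95 % confidence)",
            f"{'analyte':<12}{'certified (µg/kg)':>20}{'U (µg/kg)':>14}",
        ]
        for e in self.entries:
            star = "*" if e.isomer_note else ""
            lines.append(
                f"{e.analyte + star:<12}{e.x_display:>20.{e.precision}f}{e.U_display:>14.{e.precision}f}"
            )
        if any(e.isomer_note for e in self.entries):
            lines.append("*) sum of linear (L-) and branched (br-) isomers")
        return "\n".join(lines)


def build_certificate(
    char_results: Iterable[CharacterisationAnalyteResult] | Mapping[str, float],
    contribs: Mapping[str, UncertaintyContributions],
    k: float = 2.0,
    precision_map: Mapping[str, int] | None = None,
    isomer_sum_analytes: Iterable[str] = ISOMER_SUM_DEFAULT,
    full_names: Mapping[str, str] | None = None,
) -> Certificate:
    """Assemble certificate rows from assigned values and contributions.

    *char_results* may be characterisation results or a plain
    ``{analyte: x_cert}`` mapping.  Raises when any analyte lacks its
    uncertainty contributions.
    """
    if k <= 0:
        raise ValidationError(f"coverage factor must be > 0, got {k}")
    if isinstance(char_results, Mapping):
        assigned = dict(char_results)
    else:
        assigned = {r.analyte: r.x_char for r in char_results}
    precision_map = dict(precision_map or {})
    full_names = dict(full_names or {})
    isomer = set(isomer_sum_analytes)
    entries = []
    for analyte, x_cert in assigned.items():
        if analyte not in contribs:
            raise ValidationError(f"missing uncertainty contributions for analyte {analyte!r}")
        c = contribs[analyte]
        u_com_r = combine(c)
        U = expand(x_cert, u_com_r, k)
        precision = precision_map.get(analyte, default_precision(x_cert))
        x_disp, U_disp = round_certificate(x_cert, U, precision)
        entries.append(
            CertificateEntry(
                analyte=analyte,
                full_name=full_names.get(analyte, analyte),
                x_cert=float(x_cert),
                u_com_r=u_com_r,
                k=k,
                U=U,
                x_display=x_disp,
                U_display=U_disp,
                precision=precision,
                isomer_note=analyte in isomer,
                contributions=c,
            )
        )
    return Certificate(entries, k)
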