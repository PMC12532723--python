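"""Published certification summary statistics of CRM BAM-B003.

BAM-B003 is a certified reference material for 18 per- and polyfluoroalkyl
substances (PFAS) in an outdoor-textile matrix.  Its public certification
report prints the stage summaries — the homogeneity ANOVA table (14 bottles
x 3 replicates per analyte), the characterisation summary (unweighted mean
of three workplace means with 90 results per analyte) and the certificate
(certified values with expanded uncertainties, k = 2).  Those summary
numbers are bundled here as worked-example inputs for the statistics in
this package: the formulas can be re-run directly on the printed mean
squares and assigned values and compared against the printed uncertainty
columns and certificate entries.

All mass fractions are µg/kg; mean squares are µg²/kg².  ``precision`` in
the certificate table is the number of display decimals of the printed
certified value; ``isomer_sum`` marks values certified as the sum of linear
and branched isomers.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "homogeneity_summary",
    "characterisation_summary",
    "certificate_published",
    "ANALYTE_FULL_NAMES",
]

# analyte, mean, n, N, M_between, M_within, P_printed, s_bb_r, s_bb_min_r
_HOMOGENEITY = [
    ("PFBA", 2.22, 3, 14, 0.2211, 0.2590, 0.6053, 0.0000, 0.0685),
    ("PFPeA", 3.67, 3, 14, 0.0430, 0.0302, 0.2098, 0.0178, 0.0141),
    ("PFHxA", 35.3, 3, 14, 1.4356, 0.8936, 0.1425, 0.0121, 0.0080),
    ("PFHpA", 19.3, 3, 14, 0.2580, 0.2237, 0.3601, 0.0056, 0.0073),
    ("PFOA", 71.2, 3, 14, 4.2473, 4.7555, 0.5695, 0.0000, 0.0091),
    ("PFNA", 14.7, 3, 14, 0.1345, 0.1944, 0.7548, 0.0000, 0.0089),
    ("PFDA", 22.1, 3, 14, 1.2937, 1.3498, 0.5119, 0.0000, 0.0157),
    ("PFUnDA", 6.02, 3, 14, 0.2202, 0.2271, 0.5022, 0.0000, 0.0236),
    ("PFDoDA", 12.7, 3, 14, 2.0364, 1.1036, 0.0851, 0.0439, 0.0247),
    ("PFTrDA", 1.35, 3, 14, 0.1566, 0.2019, 0.6778, 0.0000, 0.0994),
    ("PFTeDA", 8.18, 3, 14, 1.7670, 0.6585, 0.0139, 0.0743, 0.0296),
    ("PFBS", 0.697, 3, 14, 0.0017, 0.0025, 0.7593, 0.0000, 0.0216),
    ("PFHxS", 2.55, 3, 14, 0.0122, 0.0132, 0.5411, 0.0000, 0.0134),
    ("PFHpS", 0.510, 3, 14, 0.0061, 0.0118, 0.8947, 0.0000, 0.0636),
    ("PFOS", 40.8, 3, 14, 7.8332, 6.4807, 0.3239, 0.0164, 0.0186),
    ("PFDS", 5.45, 3, 14, 2.0975, 2.1743, 0.5065, 0.0000, 0.0808),
    ("6:2 FTSA", 4.51, 3, 14, 0.0911, 0.0645, 0.2145, 0.0209, 0.0168),
    ("8:2 FTSA", 4.53, 3, 14, 0.0815, 0.0576, 0.2129, 0.0197, 0.0158),
]

# analyte, N_workplaces, x_char (= x_cert), SD, u_char_r, u_com_r
_CHARACTERISATION = [
    ("PFBA", 3, 2.498, 0.231, 0.0533, 0.1442),
    ("PFPeA", 3, 3.719, 0.320, 0.0493, 0.1274),
    ("PFHxA", 3, 34.999, 0.231, 0.0215, 0.0868),
    ("PFHpA", 3, 19.359, 0.318, 0.0335, 0.0938),
    ("PFOA", 3, 68.949, 1.899, 0.0195, 0.0792),
    ("PFNA", 3, 14.771, 0.656, 0.0257, 0.0895),
    ("PFDA", 3, 21.371, 2.329, 0.0259, 0.1017),
    ("PFUnDA", 3, 6.143, 0.657, 0.0515, 0.1286),
    ("PFDoDA", 3, 12.744, 0.960, 0.0396, 0.1333),
    ("PFTrDA", 3, 1.335, 0.548, 0.0474, 0.2138),
    ("PFTeDA", 3, 7.597, 0.875, 0.0683, 0.1484),
    ("PFBS", 3, 0.842, 0.110, 0.1152, 0.1620),
    ("PFHxS", 3, 2.534, 0.251, 0.0867, 0.1304),
    ("PFHpS", 3, 0.470, 0.132, 0.0917, 0.2670),
    ("PFOS", 3, 41.096, 0.972, 0.0132, 0.1041),
    ("PFDS", 3, 6.444, 0.128, 0.0509, 0.1990),
    ("6:2 FTSA", 3, 0.464, 0.940, 0.0721, 0.1148),
    ("8:2 FTSA", 3, 3.253, 0.568, 0.0047, 0.1053),
]

ANALYTE_FULL_NAMES = {
    "PFBA": "Perfluorobutanoic acid",
    "PFPeA": "Perfluoropentanoic acid",
    "PFHxA": "Perfluorohexanoic acid",
    "PFHpA": "Perfluoroheptanoic acid",
    "PFOA": "Perfluorooctanoic acid",
    "PFNA": "Perfluorononanoic acid",
    "PFDA": "Perfluorodecanoic acid",
    "PFUnDA": "Perfluoroundecanoic acid",
    "PFDoDA": "Perfluorododecanoic acid",
    "PFTrDA": "Perfluorotridecanoic acid",
    "PFTeDA": "Perfluorotetradecanoic acid",
    "PFBS": "Perfluorobutanesulfonic acid",
    "PFHxS": "Perfluorohexanesulfonic acid",
    "PFHpS": "Perfluoroheptanesulfonic acid",
    "PFOS": "Perfluorooctanesulfonic acid",
    "PFDS": "Perfluorodecanesulfonic acid",
    "6:2 FTSA": "6:2 Fluorotelomersulfonic acid",
    "8:2 FTSA": "8:2 Fluorotelomersulfonic acid",
}

# analyte, certified display value, U display, display decimals, isomer sum
_CERTIFICATE = [
    ("PFBA", 2.5, 0.8, 1, False),
    ("PFPeA", 3.7, 1.0, 1, False),
    ("PFHxA", 35, 7, 0, False),
    ("PFHpA", 19, 4, 0, False),
    ("PFOA", 69, 11, 0, True),
    ("PFNA", 14.8, 2.7, 1, False),
    ("PFDA", 21, 5, 0, False),
    ("PFUnDA", 6.1, 1.6, 1, False),
    ("PFDoDA", 13, 4, 0, False),
    ("PFTrDA", 1.3, 0.6, 1, False),
    ("PFTeDA", 7.6, 2.3, 1, False),
    ("PFBS", 0.84, 0.28, 2, False),
    ("PFHxS", 2.5, 0.7, 1, True),
    ("PFHpS", 0.47, 0.26, 2, False),
    ("PFOS", 41, 9, 0, True),
    ("PFDS", 6.4, 2.6, 1, False),
    ("6:2 FTSA", 0.46, 0.11, 2, False),
    ("8:2 FTSA", 3.3, 0.7, 1, False),
]


def homogeneity_summary() -> pd.DataFrame:
    """Printed homogeneity ANOVA summary (one row per analyte).

    ``s_bb_r`` of 0.0000 marks rows where ``M_between < M_within`` and the
    between-bottle estimator is not applicable.  The printed ``P`` column of
    the source shows 0.0000 for those same rows (a typesetting artifact, as
    F < 1 implies P > 0.3); recompute P from the mean squares when needed.
    """
    return pd.DataFrame(
        _HOMOGENEITY,
        columns=["analyte", "mean", "n", "N", "M_between", "M_within", "P_printed",
                 "s_bb_r", "s_bb_min_r"],
    )


def characterisation_summary() -> pd.DataFrame:
    """Printed characterisation summary (assigned values, per-analyte).

    Note: the 6:2 FTSA row's SD (0.940) exceeds its mean (0.464) and is
    inconsistent with its printed u_char_r under SD/(sqrt(N) x); kept
    verbatim — x_char and u_com_r, the certificate inputs, are consistent.
    """
    return pd.DataFrame(
        _CHARACTERISATION,
        columns=["analyte", "N", "x_char", "SD", "u_char_r", "u_com_r"],
    )


def certificate_published() -> pd.DataFrame:
    """Printed certificate: display values, expanded uncertainties (k = 2)."""
    df = pd.DataFrame(
        _CERTIFICATE, columns=["analyte", "x_display", "U_display", "precision", "isomer_sum"]
    )
    df["full_name"] = df["analyte"].map(ANALYTE_FULL_NAMES)
    return df
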