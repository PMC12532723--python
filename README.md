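# crmcert

Statistics for certifying reference materials, built around the workflow
used to certify PFAS mass fractions in a bottled textile matrix: a
**homogeneity** study across bottles, an **isochronous stability** study
across storage temperatures, a **multi-workplace characterisation** study
that assigns the certified value, and an **uncertainty budget** that turns
the three study outcomes plus the calibrant-purity uncertainty into an
expanded uncertainty printed on a certificate. A synthetic-study generator
with the same variance structure makes the whole pipeline runnable and
testable without any measurement data, and a small module implements the
data-evaluation conventions of stable-isotope-dilution (SIDA) LC–MS/MS
quantification (internal-standard MRM cross-talk correction and the
linear/branched isomer summation convention).

Intended users: reference-material producers and QA/metrology labs who
need the certification statistics of ISO Guide 35-style procedures as
reusable, tested code rather than a spreadsheet.

## The statistics

For each analyte, with `N` bottles measured in `n` replicates, a one-way
ANOVA yields mean squares `M_between` and `M_within`, and

    s_bb      = sqrt((M_between − M_within) / n)            (between-bottle SD)
    s_bb,min  = sqrt(M_within / n) · (2 / (N(n−1)))^(1/4)   (smallest detectable inhomogeneity)

The inhomogeneity contribution is the conservative maximum
`u_bb,r = max(s_bb,r, s_bb,min,r)` of the two relative values (`s_bb,r` is 0
when `M_between < M_within`). ANOVA P-values are also screened after a
Bonferroni adjustment `P_adj = min(1, m·P)` across the `m` analytes.

Stability: per temperature, OLS of value vs time (months); the contribution
for a shelf life `t_sl` is `u_stab = se(b₁)·t_sl`, relativised by the
assigned value; the −20 °C storage series feeds the budget.

Characterisation: with workplace means screened for outliers (Grubbs,
Dixon, Scheffé on means; Cochran on variances),

    x_char = mean(workplace means),   u_char = SD(workplace means)/√N.

Budget and certificate:

    u_com,r = sqrt(u_bb,r² + u_stab,r² + u_char,r² + u_pur,r²)
    U       = x_cert · u_com,r · k          (k = 2, ≈95 % confidence)

with the certified value rounded half-up and `U` rounded **up** at the
display precision.

## Worked example

```python
from crmcert import sbb, sbb_min, UncertaintyContributions, combine, expand, round_certificate

# homogeneity study of an analyte: 14 bottles x 3 replicates,
# ANOVA mean squares 0.0430 / 0.0302 (µg²/kg²), study mean 3.67 µg/kg
s_bb_r = sbb(0.0430, 0.0302, 3) / 3.67
s_bb_min_r = sbb_min(0.0302, 3, 14) / 3.67
print(f"s_bb,r = {s_bb_r:.4f}  s_bb,min,r = {s_bb_min_r:.4f}")

# budget for an analyte assigned x_char = 0.470 µg/kg with u_com,r = 0.2670
U = expand(0.470, 0.2670, k=2)
print(f"U = {U:.5f} µg/kg ->", round_certificate(0.470, U, precision=2))
```

prints

```
s_bb,r = 0.0178  s_bb,min,r = 0.0141
U = 0.25098 µg/kg -> (0.47, 0.26)
```

i.e. the between-bottle SD for this analyte is 1.78 % of the study mean
(larger than the 1.41 % the repeatability could hide, so 0.0178 enters the
budget), and the certificate for the second analyte reads
(0.47 ± 0.26) µg/kg after ceiling-rounding the expanded uncertainty.

A fully synthetic certification (studies simulated, fitted, budgeted and
rounded) is one call chain away:

```python
from crmcert import PipelineConfig, run_pipeline_frames
from crmcert.simulate import DEFAULT_SCENARIOS, simulate_batch

hom  = simulate_batch([s.homogeneity_spec(1) for s in DEFAULT_SCENARIOS], "homogeneity")
stab = simulate_batch([s.stability_spec(2) for s in DEFAULT_SCENARIOS], "stability")
char = simulate_batch([s.characterisation_spec(3) for s in DEFAULT_SCENARIOS], "characterisation")
result = run_pipeline_frames(hom, stab, char, PipelineConfig(u_pur_r=0.03))
print(result.certificate.summary())
```

The same stages are available from a shell via the `crmcert` CLI
(`simulate`, `homogeneity`, `stability`, `characterise`, `quantify`,
`certify`, `report`).

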