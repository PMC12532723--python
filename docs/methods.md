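# Methods

This note documents the statistical models behind `crmcert`, the defaults
and numerical choices, what the synthetic-study generator does and does not
emulate, and the known limitations.

## Homogeneity model

The between-bottle study is a balanced one-way random-effects layout:
`y_br = µ + B_b + e_br`, `B_b ~ N(0, σ_bb²)`, `e_br ~ N(0, σ_wb²)`, with
`N` bottles and `n` replicates. The one-way ANOVA mean squares estimate
`E[M_within] = σ_wb²` and `E[M_between] = σ_wb² + n·σ_bb²`, giving the
moment estimator `s_bb = sqrt((M_between − M_within)/n)`. When
`M_between < M_within` the moment estimator has no real solution; the
result object then reports `s_bb` as not-applicable (displayed 0.0000) and
the budget falls back to the minimal detectable inhomogeneity
`s_bb,min = sqrt(M_within/n)·(2/(N(n−1)))^(1/4)`, the largest between-bottle
SD that the repeatability could mask at this study size. The contribution
entering the budget is always `u_bb,r = max(s_bb,r, s_bb,min,r)` — the
deliberately conservative choice, so a "perfectly homogeneous-looking"
study still contributes its detection floor.

The study mean that relativises both estimators is the unweighted mean of
bottle means, which differs from the grand mean only in unbalanced data.
For unbalanced group sizes the `n` in both formulas becomes the effective
replicate count `n_eff = (Σnᵢ − Σnᵢ²/Σnᵢ)/(N−1)`, which reduces to `n`
when balanced.

Screening is two-layered: raw ANOVA P-values per analyte, and
Bonferroni-adjusted values `P_adj = min(1, m·P)` across the `m` analytes
of a multi-analyte material. `m` defaults to the number of analytes in the
table and is overridable, because the appropriate multiplier depends on how
many analytes were originally screened, not only on how many are reported.
Pre-ANOVA screening for trends with filling order is deliberately visual
(the results object exposes per-bottle means in filling order); no
automatic exclusion is performed.

## Stability model

Isochronous design: units aged at each temperature are measured together in
one run, so no between-run correction is applied and reference units enter
at t = 0. Per temperature, an OLS line `y = b0 + b1·t` (t in months) is
fitted over all units; `se(b1)` uses the residual variance with k−2 degrees
of freedom and the slope is tested two-sided against zero. The shelf-life
contribution is `u_stab = se(b1)·t_sl` with a default horizon of
`t_sl = 36` months (a three-year initial shelf life) — the standard
linear-degradation-model contribution: even an insignificant slope leaves
uncertainty about degradation over the claimed lifetime proportional to how
precisely the slope is known. The slope's standard error, not the slope
estimate, is used uniformly, including for flagged analytes.

Only the storage-temperature series (default −20 °C) feeds the budget;
elevated-temperature series are fitted for screening. A significant slope
does not veto certification — the procedure's response is re-testing under
post-certification monitoring (PCM), so the package flags the analyte and
provides `pcm_check`, which passes when the monitoring mean lies within
`sqrt(U² + (2·sem)²)` of the reference mean.

The reference value that relativises `u_stab` is the assigned value
`x_char` when the pipeline supplies it, else the fitted intercept; this is
configurable because either convention appears in practice.

Numerical choice: when the residual sum of squares is below 1e−20 of the
response mean square, the fit is treated as exact (`se = 0`, `P = 0` for a
nonzero slope, `P = 1` for a zero slope). This keeps the degenerate
noise-free cases exact instead of leaking ~1e−17 floating-point residuals
into standard errors.

## Characterisation model

Workplaces are treated as the exchangeable units: `x_char` is the
unweighted mean of accepted workplace means and `u_char = SD/√N` their
standard uncertainty. Unit-level nesting within a workplace is collapsed
for value assignment (it is part of what makes a workplace mean
uncertain) and retained only diagnostically. No variance-weighted or
consensus estimators (DerSimonian–Laird, Mandel–Paule) are offered: with
two or three workplaces they are not meaningfully estimable, and the
certification convention is the unweighted mean.

Outlier screening before assignment: Grubbs (two-sided, single outlier,
t-based critical value), Dixon r10 (gap/range, two-sided tabulated critical
values for 3–7 groups), and Scheffé all-pairs contrasts against the pooled
within-workplace variance for the means; Cochran `C = max s² / Σs²` for the
variances. Of a significant Scheffé pair, the member further from the
centre of the means is flagged (the screen looks for the discrepant group,
not for both sides of a difference). Variance outliers are flagged but
never excluded — with ~30 results per group an inflated variance barely
moves the group mean. Mean outliers are excluded only when the caller
confirms (`confirm_exclusion=True` / `--confirm-exclusion`): with N = 3
workplaces an automatic exclusion on a 3-point outlier test would be
statistically reckless.

## Budget and certificate

`u_com,r = sqrt(u_bb,r² + u_stab,r² + u_char,r² + u_pur,r²)` and
`U = x_cert·u_com,r·k` with `k = 2`. The calibrant-purity contribution
`u_pur,r` is a configuration input keyed by analyte (it comes from the
calibrant's own certificate, not from the studies); the synthetic default
is 0.03 relative, a typical low-to-mid-level value for a certified
multi-component calibration standard.

Display rounding: the certified value is rounded half-up at its display
precision; the expanded uncertainty is rounded **up** (ceiling) at the same
precision, so the printed interval always covers the computed one.
Rounding is done in decimal arithmetic on the shortest float representation
to avoid binary-float ceiling artifacts (e.g. `0.28*100 = 28.000…004`).
Display precision is an explicit per-analyte input because certificates
choose precision irregularly; the default is two significant figures of the
certified value, capped at two decimals.

## SIDA quantification conventions

The quantification layer starts from integrated peak areas. The ISTD
cross-talk correction is subtractive: `A_corr = A_obs − r·A_native`,
floored at zero with a warning. An iterative mutual correction (native and
ISTD each correcting the other) would matter only if the labelled compound
also bled into the native trace; the subtractive form is the implemented
reading, and `r` is a per-pair configuration input. A helper computes a
theoretical default for `r` as the natural M+2 isotopologue abundance from
the molecular formula (polynomial expansion over ¹³C/²H/¹⁸O/³⁴S
abundances), appropriate for a 2-Da-spaced ¹³C₂ label.

Calibration is unweighted OLS of response ratio vs amount ratio (1/x
weighting available), with a hard floor of six calibration points.
Quantification inverts the curve and scales by ISTD amount over sample
intake (ng/g = µg/kg); a response below the calibration intercept returns a
flagged below-range zero rather than raising.

Isomer convention: where an analyte occurs as linear + branched isomers but
the calibrant certifies only its linear content (L-fraction, e.g. 0.788),
the convention reports the L+br sum against the L-only calibration, i.e.
the naive result divided by the L-fraction. Equivalently the calibration
amount axis can be rescaled from certified-L amounts to the total amounts
the measured response represents (divide by the L-fraction); both routes
are implemented and agree to 1e−12, and L-fraction = 1 reduces to plain
quantification.

## Synthetic-study generator

The generator draws from exactly the random-effects structures the
estimators assume: additive Gaussian noise on the mass-fraction scale,
independent levels, equal cell counts on the stability grid (all units
measured in one isochronous run). Defaults mirror the study design the
pipeline certifies: 14 bottles × 3 replicates for homogeneity; 5
temperatures (−20…60 °C) × pull times 0–12 months for stability; 3
workplaces × 10 units × 3 replicates (90 results) for characterisation.
Each spec carries one root seed, and the actual stream is a per-analyte
substream of `(seed, crc32(analyte))`, so multi-analyte batches are
bit-reproducible and order-independent. Negative values are not truncated
(keeping estimator checks unbiased); `strict_positive` redraws them when
realism matters.

What it does **not** emulate — and therefore what passing tests do not
show about real data: non-Gaussian and proportional (log-normal) error,
drift with measurement sequence or filling order, calibration bias shared
within a workplace, chromatographic integration artifacts, and any
systematic extraction bias. Parameter-recovery results validate the
estimators under their own assumptions, not the assumptions themselves.

## Problem sizes used in the checks

Simulation-based checks use 300–1000 replicate studies per property (e.g.
1000 null-slope fits for the type-I error of the trend screen, 500
homogeneity studies for variance-component recovery, 200 full pipeline runs
for interval coverage); these sizes put the Monte-Carlo error comfortably
inside the asserted tolerances while keeping the suite fast.

## Known limitations

- The homogeneity P-value recomputation assumes a correct F reference
  distribution, i.e. Gaussian within-bottle error; heavy tails inflate the
  false-positive rate of the screen.
- Arrhenius extrapolation across stability temperatures and nonlinear
  kinetics are out of scope; the linear model is a local approximation over
  the studied horizon.
- Dixon critical values are tabulated only for 3–7 groups (the test is
  reported not-applicable outside that range).
- One row of the bundled published summary (the 6:2 FTSA characterisation
  SD) is internally inconsistent with its printed relative uncertainty and
  is carried verbatim; the certificate-level quantities derived from that
  row (assigned value, combined uncertainty) are consistent and are the
  ones used downstream.
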