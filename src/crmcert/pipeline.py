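"""End-to-end certification pipeline: studies in, certificate out.

Orchestrates the four statistical stages over a common analyte set:

1. homogeneity ANOVA  -> ``u_bb_r`` (conservative max rule),
2. stability regression at the storage temperature -> ``u_stab_r``
   (relativised by the assigned value),
3. characterisation -> ``x_char`` and ``u_char_r``,
4. budget -> ``u_com_r``, expanded uncertainty and display rounding.

All artifacts are deterministic functions of the input tables and
configuration; the rendered report carries every intermediate table so each
certificate number is traceable to a stage output.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .budget import Certificate, UncertaintyContributions, build_certificate
from .characterisation import CharacterisationModel, CharacterisationResults
from .exceptions import CrmCertError, ValidationError
from .homogeneity import HomogeneityModel, HomogeneityResults
from .io import PipelineConfig, read_measurements
from .stability import StabilityModel, StabilityResults

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_frames"]


@dataclass
class PipelineResult:
    homogeneity: HomogeneityResults
    stability: StabilityResults
    characterisation: CharacterisationResults
    certificate: Certificate
    warnings: list[str]

    def report(self) -> str:
        """Human-readable report over all stages (deterministic text)."""
        sections = [
            "CERTIFICATION REPORT",
            "=" * 60,
            self.homogeneity.summary(),
            "-" * 60,
            self.stability.summary(),
            "-" * 60,
            self.characterisation.summary(),
            "-" * 60,
            self.certificate.summary(),
        ]
        if self.warnings:
            sections += ["-" * 60, "Warnings:"] + [f"  - {w}" for w in self.warnings]
        return "\n".join(sections)


def _stage(name: str, analyte: str | None = None):
    ctx = f"stage {name}" + (f", analyte {analyte!r}" if analyte else "")

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, CrmCertError):
                raise type(exc)(f"[{ctx}] {exc}") from None
            return False

    return _Ctx()


def run_pipeline_frames(
    homogeneity: pd.DataFrame,
    stability: pd.DataFrame,
    characterisation: pd.DataFrame,
    config: PipelineConfig,
) -> PipelineResult:
    """Run the full certification given in-memory study tables."""
    analytes = list(dict.fromkeys(characterisation["analyte"]))
    for name, table in (("homogeneity", homogeneity), ("stability", stability)):
        present = set(table["analyte"])
        missing = [a for a in analytes if a not in present]
        if missing:
            raise ValidationError(f"[stage {name}] analyte(s) {missing} missing from the {name} study")

    with _stage("characterisation"):
        char = CharacterisationModel(characterisation, alpha=config.alpha).fit()
    with _stage("homogeneity"):
        hom = HomogeneityModel(homogeneity, alpha=config.alpha, m_tests=config.m_tests).fit()
    with _stage("stability"):
        stab = StabilityModel(
            stability,
            t_sl=config.t_sl,
            ref_temp=config.ref_temp,
            alpha=config.alpha,
            reference_values={r.analyte: r.x_char for r in char},
        ).fit()

    u_bb = hom.u_bb_r()
    u_stab = stab.u_stab_r()
    contribs = {}
    for a in analytes:
        with _stage("budget", a):
            if a not in u_bb:
                raise ValidationError(f"analyte {a!r} missing from the homogeneity results")
            if a not in u_stab:
                raise ValidationError(f"analyte {a!r} missing from the stability results")
            contribs[a] = UncertaintyContributions(
                analyte=a,
                u_bb_r=u_bb[a],
                u_stab_r=u_stab[a],
                u_char_r=char.for_analyte(a).u_char_r,
                u_pur_r=config.u_pur_for(a),
            )
    with _stage("budget"):
        cert = build_certificate(
            list(char),
            contribs,
            k=config.k,
            precision_map=config.precision_map,
            isomer_sum_analytes=config.isomer_sum_analytes,
        )
    warnings = []
    warnings += [f"homogeneity: adjusted P < alpha for {a}" for a in hom.warnings]
    warnings += [
        f"stability: significant trend for {f.analyte} at {f.temperature} °C "
        f"(P = {f.P_slope:.4f}); PCM scheduled"
        for f in stab.flagged
    ]
    warnings += [f"characterisation: {w}" for w in char.warnings]
    return PipelineResult(hom, stab, char, cert, warnings)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full certification from the CSV paths in *config*."""
    for attr in ("homogeneity_path", "stability_path", "characterisation_path"):
        if getattr(config, attr) is None:
            raise ValidationError(f"config is missing {attr}")
    hom = read_measurements(config.homogeneity_path, "homogeneity")
    stab = read_measurements(config.stability_path, "stability")
    char = read_measurements(config.characterisation_path, "characterisation")
    return run_pipeline_frames(hom, stab, char, config)
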