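"""Permeabilized-cell three-stage summaries and ETC-complex assignment.

The assay feeds complex-I substrates, then succinate+rotenone (complex-II
entry with CI blocked), then ascorbate/TMPD+antimycin A (complex-IV entry
with CIII blocked). The second OCR measurement of each stage, as percent
of the pre-compound baseline, summarizes the stage; the pattern of
inhibition and rescue across stages localizes the block:

* no stage inhibited            -> no ETC inhibition
* stage 1 inhibited, rescued 2  -> CI
* stage 1 spared, 2 inhibited,
  rescued 3                     -> CII
* stages 1+2 inhibited,
  rescued 3                     -> CIII (partial rescue -> CIII_partial)
* stage 3 inhibited             -> downstream of CIII (CIV/CV pooled; the
  assay cannot separate the two)

"Inhibited" and "rescued" are fractional thresholds against the plate's
vehicle stage levels; the qualitative case logic carries no scale, so any
common positive rescaling of stage and vehicle values leaves calls
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegeneratePlateError, ScheduleError, ValidationError
from .normalize import baseline_mean
from .simulate import COMPLEX_STAGES, KineticWellTrace

CALLS = (
    "no_inhibition",
    "CI",
    "CII",
    "CIII",
    "CIII_partial",
    "CIV_CV_downstream",
    "ambiguous",
)


@dataclass(frozen=True)
class ComplexStageSummary:
    """Second-measurement OCR of each stage, % of pre-compound baseline."""

    m1_pct: float
    m2_pct: float
    m3_pct: float
    vehicle_m1_pct: float
    vehicle_m2_pct: float
    vehicle_m3_pct: float
    conc: float

    def __post_init__(self) -> None:
        for name in ("m1_pct", "m2_pct", "m3_pct",
                     "vehicle_m1_pct", "vehicle_m2_pct", "vehicle_m3_pct"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ComplexCall:
    call: str
    thresholds_used: dict

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValidationError(f"unknown complex call {self.call!r}")


def stage_measurements(trace: KineticWellTrace) -> tuple[float, float, float]:
    """Second OCR measurement of each stage as % of the pre-compound baseline."""
    b = baseline_mean(trace, "ocr")
    if b <= 0:
        raise ValidationError(f"non-positive baseline in well {trace.well}")
    out = []
    for stage in COMPLEX_STAGES:
        vals = trace.phase_values(stage, "ocr")
        if len(vals) < 2:
            raise ScheduleError(
                f"stage {stage!r} in well {trace.well} has fewer than two measurements"
            )
        out.append(float(vals[1]) / b * 100.0)
    return tuple(out)


def summarize_stages(
    trace: KineticWellTrace,
    vehicle_reference: tuple[float, float, float],
) -> ComplexStageSummary:
    m1, m2, m3 = stage_measurements(trace)
    v1, v2, v3 = vehicle_reference
    return ComplexStageSummary(
        m1_pct=m1, m2_pct=m2, m3_pct=m3,
        vehicle_m1_pct=v1, vehicle_m2_pct=v2, vehicle_m3_pct=v3,
        conc=float(trace.conc),
    )


def vehicle_stage_reference(vehicle_traces: list[KineticWellTrace]) -> tuple[float, float, float]:
    if not vehicle_traces:
        raise DegeneratePlateError("no vehicle wells on the complex-assay plate")
    ms = np.asarray([stage_measurements(t) for t in vehicle_traces], dtype=float)
    return tuple(float(v) for v in ms.mean(axis=0))


def classify_complex(
    s: ComplexStageSummary,
    inhibition_frac: float = 0.7,
    rescue_frac: float = 0.7,
    partial_band: tuple[float, float] = (0.4, 0.7),
) -> ComplexCall:
    """Assign the inhibited-complex case from one stage summary.

    A stage is *inhibited* when its OCR falls below ``inhibition_frac`` of
    the vehicle level, *rescued* when it recovers to at least
    ``rescue_frac`` of vehicle. The partial band catches compounds whose
    terminal-stage recovery is real but incomplete.
    """
    if min(s.vehicle_m1_pct, s.vehicle_m2_pct, s.vehicle_m3_pct) <= 0:
        raise ValidationError("vehicle stage references must be positive")
    thresholds = {
        "inhibition_frac": inhibition_frac,
        "rescue_frac": rescue_frac,
        "partial_band": partial_band,
    }
    r1 = s.m1_pct / s.vehicle_m1_pct
    r2 = s.m2_pct / s.vehicle_m2_pct
    r3 = s.m3_pct / s.vehicle_m3_pct
    inhibited = [r < inhibition_frac for r in (r1, r2, r3)]
    rescued = [r >= rescue_frac for r in (r1, r2, r3)]

    if not any(inhibited):
        call = "no_inhibition"
    elif inhibited[0] and rescued[1]:
        call = "CI"
    elif not inhibited[0] and inhibited[1] and rescued[2]:
        call = "CII"
    elif inhibited[0] and inhibited[1] and rescued[2]:
        call = "CIII"
    elif inhibited[0] and inhibited[1] and partial_band[0] <= r3 < partial_band[1]:
        call = "CIII_partial"
    elif inhibited[2]:
        call = "CIV_CV_downstream"
    else:
        call = "ambiguous"
    return ComplexCall(call=call, thresholds_used=thresholds)


def classify_plate(
    traces: list[KineticWellTrace],
    inhibition_frac: float = 0.7,
    rescue_frac: float = 0.7,
    partial_band: tuple[float, float] = (0.4, 0.7),
):
    """Per-compound complex calls from a whole plate.

    The headline call is made at the lowest concentration at which any
    stage is inhibited (most-specific-dose principle); the full
    per-concentration table is returned alongside.
    """
    vehicles = [t for t in traces if t.compound == "vehicle"]
    reference = vehicle_stage_reference(vehicles)
    per_conc: dict[str, list[tuple[float, ComplexStageSummary, ComplexCall]]] = {}
    for t in traces:
        if t.compound == "vehicle":
            continue
        s = summarize_stages(t, reference)
        c = classify_complex(s, inhibition_frac, rescue_frac, partial_band)
        per_conc.setdefault(t.compound, []).append((float(t.conc), s, c))

    headline: dict[str, ComplexCall] = {}
    for compound, rows in per_conc.items():
        rows.sort(key=lambda r: r[0])
        chosen = None
        for _conc, s, call in rows:
            if call.call != "no_inhibition":
                chosen = call
                break
        headline[compound] = chosen or rows[-1][2]
    return headline, per_conc


def complex_potency(
    summaries: list[ComplexStageSummary],
    top_tested: float,
    flat_effect_pct: float = 20.0,
):
    """Stage-wise censored potencies from a concentration ladder of summaries.

    Each stage's OCR (as % of its vehicle level) is fit with a decreasing
    Hill curve; stages whose total response stays below ``flat_effect_pct``
    report NR, crossings beyond the ladder report the "> top" censor.
    Stage 1 reflects CI(-CIII-CIV) flux, stage 2 CII/CIII flux, stage 3
    CIV flux.
    """
    from .doseresponse import fit_hill4, ic50_from_fit

    if len(summaries) < 4:
        raise ValidationError("need at least four concentrations for stage potencies")
    rows = sorted(summaries, key=lambda s: s.conc)
    conc = np.asarray([s.conc for s in rows], dtype=float)
    out = {}
    for stage, get_m, get_v in (
        ("stage1", lambda s: s.m1_pct, lambda s: s.vehicle_m1_pct),
        ("stage2", lambda s: s.m2_pct, lambda s: s.vehicle_m2_pct),
        ("stage3", lambda s: s.m3_pct, lambda s: s.vehicle_m3_pct),
    ):
        resp = np.asarray([get_m(s) / get_v(s) * 100.0 for s in rows], dtype=float)
        fit = fit_hill4(conc, resp, direction="decreasing")
        out[stage] = ic50_from_fit(fit, top_tested, flat_policy="nr",
                                   flat_effect_pct=flat_effect_pct)
    return out
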