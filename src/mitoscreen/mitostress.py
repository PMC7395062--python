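"""Decompose intact-cell mitostress traces into respiration parameters.

From a baseline-normalized trace the sequential injections yield six
quantities (all in % of the well's own basal OCR): basal (100 by
construction), the post-compound basal, ATP-linked respiration (drop on
oligomycin), maximal (uncoupled) respiration on FCCP, non-mitochondrial
respiration after rotenone/antimycin A, and proton leak (oligomycin
level minus non-mitochondrial). A protonophore is flagged when the test
compound itself raises basal OCR and oligomycin fails to suppress it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegeneratePlateError, ScheduleError, ValidationError
from .normalize import (
    NormalizedCurve,
    normalize_ecar_range,
    normalize_maximal_to_control,
    normalize_to_baseline,
    vehicle_oligo_ecar_relative,
)
from .simulate import MITOSTRESS_PHASES, KineticWellTrace


@dataclass(frozen=True)
class MitoStressParams:
    """The six mitostress quantities plus the uncoupling flag (% of basal)."""

    basal_pct: float  # 100 by construction
    compound_basal_pct: float  # mean of the last two post-compound cycles
    atp_linked_pct: float  # compound basal minus oligomycin level
    maximal_pct: float  # FCCP maximum
    maximal_vs_control_pct: float | None  # FCCP max as % of vehicle FCCP max
    nonmito_pct: float  # rotenone/antimycin A mean
    proton_leak_pct: float  # oligomycin level minus non-mitochondrial
    uncoupling: bool
    ecar_compound_pct_range: float | None  # compound-phase ECAR, % of glycolytic range

    @property
    def oligomycin_pct(self) -> float:
        return self.nonmito_pct + self.proton_leak_pct


def decompose_mitostress(
    trace: KineticWellTrace,
    vehicle_maximal_pct: float | None = None,
    ecar_range_ref: float | None = None,
    rise_threshold: float = 115.0,
    oligo_resistance: float = 100.0,
) -> MitoStressParams:
    """Summarize one baseline-normalized trace into MitoStressParams.

    Phase summaries: compound = mean of the last 2 of its cycles (the
    equilibrated inhibition), oligomycin = minimum, FCCP = maximum,
    rotenone/antimycin A = mean.
    """
    for phase in MITOSTRESS_PHASES:
        if phase not in trace.phase_labels:
            raise ScheduleError(f"trace in well {trace.well} is missing phase {phase!r}")

    compound = trace.phase_values("compound")
    compound_basal = float(np.mean(compound[-2:]))
    oligo = float(np.min(trace.phase_values("oligomycin")))
    maximal = float(np.max(trace.phase_values("fccp")))
    nonmito = float(np.mean(trace.phase_values("rot_aa")))
    if nonmito < 0:
        raise ValidationError(f"negative non-mitochondrial OCR in well {trace.well}")

    maximal_vs_control = (
        normalize_maximal_to_control(maximal, vehicle_maximal_pct)
        if vehicle_maximal_pct is not None
        else None
    )
    ecar_range = None
    if ecar_range_ref is not None:
        vals = normalize_ecar_range(trace, ecar_range_ref)
        mask = np.asarray([p == "compound" for p in trace.phase_labels])
        ecar_range = float(np.mean(vals[mask][-2:]))

    params = MitoStressParams(
        basal_pct=100.0,
        compound_basal_pct=compound_basal,
        atp_linked_pct=compound_basal - oligo,
        maximal_pct=maximal,
        maximal_vs_control_pct=maximal_vs_control,
        nonmito_pct=nonmito,
        proton_leak_pct=oligo - nonmito,
        uncoupling=False,
        ecar_compound_pct_range=ecar_range,
    )
    return replace(
        params,
        uncoupling=detect_uncoupling(params, rise_threshold, oligo_resistance),
    )


def detect_uncoupling(
    params: MitoStressParams,
    rise_threshold: float = 115.0,
    oligo_resistance: float = 100.0,
) -> bool:
    """Protonophore signature: the compound itself raises basal OCR above
    ``rise_threshold`` % AND the oligomycin-phase OCR stays at or above
    ``oligo_resistance`` % of basal (ATP-synthase blockade cannot suppress
    uncoupled respiration)."""
    return (
        params.compound_basal_pct >= rise_threshold
        and params.oligomycin_pct >= oligo_resistance
    )


def _group_wells(traces: list[KineticWellTrace]):
    vehicles = [t for t in traces if t.compound == "vehicle"]
    treated: dict[str, dict[float, list[KineticWellTrace]]] = {}
    for t in traces:
        if t.compound == "vehicle":
            continue
        treated.setdefault(t.compound, {}).setdefault(float(t.conc), []).append(t)
    return vehicles, treated


def decompose_plate(
    traces: list[KineticWellTrace],
    rise_threshold: float = 115.0,
    oligo_resistance: float = 100.0,
):
    """Baseline-normalize and decompose every well of a mitostress plate.

    Returns ``(params_by_well, vehicle_maximal_pct, ecar_range_ref)`` with
    plate references taken from vehicle wells only, so treated-well scaling
    stays independent of each compound's own oligomycin response.
    """
    vehicles, _ = _group_wells(traces)
    if not vehicles:
        raise DegeneratePlateError("plate has no vehicle wells")
    norm_vehicles = [normalize_to_baseline(t) for t in vehicles]
    vehicle_maximal = float(np.mean([np.max(t.phase_values("fccp")) for t in norm_vehicles]))
    ecar_ref = vehicle_oligo_ecar_relative(vehicles)

    params_by_well = {}
    for t in traces:
        norm = normalize_to_baseline(t)
        params_by_well[(t.plate_id, t.well)] = (
            t.compound,
            float(t.conc),
            decompose_mitostress(norm, vehicle_maximal, ecar_ref,
                                 rise_threshold, oligo_resistance),
        )
    return params_by_well, vehicle_maximal, ecar_ref


def potency_curves_from_plate(
    traces: list[KineticWellTrace],
    rise_threshold: float = 115.0,
    oligo_resistance: float = 100.0,
) -> dict[str, dict[str, NormalizedCurve]]:
    """Per-compound dose-response curves ready for potency fitting.

    Three curves per compound: basal OCR after compound injection (% of
    the well's own baseline), maximal OCR as % of the vehicle maximal,
    and compound-phase ECAR as % of the plate's glycolytic range.
    """
    params_by_well, _vmax, _eref = decompose_plate(traces, rise_threshold, oligo_resistance)
    per_compound: dict[str, dict[float, list[MitoStressParams]]] = {}
    for _well, (compound, conc, params) in params_by_well.items():
        if compound == "vehicle":
            continue
        per_compound.setdefault(compound, {}).setdefault(conc, []).append(params)

    curves: dict[str, dict[str, NormalizedCurve]] = {}
    for compound, by_conc in per_compound.items():
        concs = np.asarray(sorted(by_conc), dtype=float)
        if len(concs) < 2:
            raise ValidationError(f"compound {compound}: need at least two concentrations")

        def curve(getter, anchor, info):
            means, sds, ns = [], [], []
            for c in concs:
                vals = np.asarray([getter(p) for p in by_conc[c]], dtype=float)
                means.append(float(np.mean(vals)))
                sds.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
                ns.append(len(vals))
            return NormalizedCurve(
                conc=concs,
                response=np.asarray(means),
                sd=np.asarray(sds),
                n=np.asarray(ns),
                anchor=anchor,
                anchor_info=info,
            )

        curves[compound] = {
            "ocr_basal": curve(lambda p: p.compound_basal_pct, "baseline",
                               "post-compound OCR, % of own baseline"),
            "ocr_maximal": curve(lambda p: p.maximal_vs_control_pct, "vehicle",
                                 "FCCP maximum, % of vehicle maximal"),
            "ecar_range": curve(lambda p: p.ecar_compound_pct_range, "glycolytic_range",
                                "compound-phase ECAR, % of oligomycin range"),
        }
    return curves


def uncoupling_flags(
    traces: list[KineticWellTrace],
    rise_threshold: float = 115.0,
    oligo_resistance: float = 100.0,
) -> dict[str, bool]:
    """True for a compound if any concentration on the plate shows the
    protonophore signature."""
    params_by_well, _v, _e = decompose_plate(traces, rise_threshold, oligo_resistance)
    flags: dict[str, bool] = {}
    for _well, (compound, _conc, params) in params_by_well.items():
        if compound == "vehicle":
            continue
        flags[compound] = flags.get(compound, False) or params.uncoupling
    return flags
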