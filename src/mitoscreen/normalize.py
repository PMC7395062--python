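"""The normalization ledger for kinetic and endpoint responses.

Every transform here is affine and order-preserving, and each normalized
curve records which anchor defined its 100% (vehicle mean, the mean of
non-effective low concentrations, a well's own pre-injection baseline,
or the plate's glycolytic ECAR range).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegeneratePlateError, DegenerateWellError, MitoscreenError
from .simulate import KineticWellTrace

ANCHORS = ("vehicle", "non_effective_mean", "baseline", "glycolytic_range")


@dataclass(frozen=True, eq=False)
class NormalizedCurve:
    """A per-compound concentration-response curve on a % scale."""

    conc: np.ndarray  # molar, ascending
    response: np.ndarray  # %
    sd: np.ndarray  # %
    n: np.ndarray  # replicate counts
    anchor: str
    anchor_info: str = ""
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (len(self.conc) == len(self.response) == len(self.sd) == len(self.n)):
            raise MitoscreenError("curve arrays must have equal length")
        if self.anchor not in ANCHORS:
            raise MitoscreenError(f"unknown anchor {self.anchor!r}")
        if np.any(np.diff(self.conc) <= 0):
            raise MitoscreenError("concentrations must be strictly ascending")


def baseline_mean(trace: KineticWellTrace, channel: str = "ocr",
                  baseline_phase: str = "baseline") -> float:
    """Arithmetic mean of the pre-injection cycles of one channel."""
    return float(np.mean(trace.phase_values(baseline_phase, channel)))


def normalize_to_baseline(trace: KineticWellTrace, baseline_phase: str = "baseline") -> KineticWellTrace:
    """Rescale OCR and ECAR so each channel's own baseline mean maps to 100%."""
    b_ocr = baseline_mean(trace, "ocr", baseline_phase)
    b_ecar = baseline_mean(trace, "ecar", baseline_phase)
    if b_ocr <= 0 or b_ecar <= 0:
        raise DegenerateWellError(
            f"well {trace.well}: non-positive baseline (OCR {b_ocr}, ECAR {b_ecar})"
        )
    return KineticWellTrace(
        plate_id=trace.plate_id,
        well=trace.well,
        compound=trace.compound,
        conc=trace.conc,
        phase_labels=trace.phase_labels,
        times=trace.times,
        ocr=trace.ocr / b_ocr * 100.0,
        ecar=trace.ecar / b_ecar * 100.0,
    )


def normalize_to_vehicle(values, vehicle_values) -> np.ndarray:
    """Express values as percent of the vehicle-well mean."""
    vehicle_values = np.asarray(vehicle_values, dtype=float)
    if vehicle_values.size == 0:
        raise DegeneratePlateError("no vehicle values to normalize against")
    mean = float(np.mean(vehicle_values))
    if mean <= 0:
        raise DegeneratePlateError(f"non-positive vehicle mean {mean}")
    return np.asarray(values, dtype=float) / mean * 100.0


def renormalize_to_noneffective(
    curve: NormalizedCurve,
    k_min: int = 2,
    delta: float = 10.0,
    signif=None,
    direction: str = "decreasing",
) -> NormalizedCurve:
    """Re-anchor a %-of-vehicle curve to its non-effective low-dose prefix.

    The maximal low-concentration prefix whose points are non-significant
    and within +/- ``delta`` of 100% is taken as the plateau; if it holds at
    least ``k_min`` points, its mean is rescaled to 100% (the upper asymptote
    of an inhibition curve, the lower asymptote of an activation curve).
    Otherwise the curve is returned unchanged with a fallback flag. The
    operation is idempotent.
    """
    resp = np.asarray(curve.response, dtype=float)
    if signif is None:
        signif = np.zeros(len(resp), dtype=bool)
    signif = np.asarray(signif, dtype=bool)

    prefix = 0
    for i in range(len(resp)):
        if signif[i] or abs(resp[i] - 100.0) > delta:
            break
        prefix = i + 1
    if prefix < k_min:
        if "no_noneffective_prefix" in curve.flags:
            return curve
        return replace(curve, flags=curve.flags + ("no_noneffective_prefix",))
    factor = 100.0 / float(np.mean(resp[:prefix]))
    return NormalizedCurve(
        conc=curve.conc,
        response=resp * factor,
        sd=np.asarray(curve.sd, dtype=float) * factor,
        n=curve.n,
        anchor="non_effective_mean",
        anchor_info=f"prefix of {prefix} non-effective concentrations ({direction})",
        flags=curve.flags,
    )


def vehicle_oligo_ecar_relative(vehicle_traces: list[KineticWellTrace]) -> float:
    """Plate reference: mean over vehicle wells of max oligomycin-phase ECAR,
    each expressed relative to that well's own baseline ECAR."""
    if not vehicle_traces:
        raise DegeneratePlateError("no vehicle wells for the ECAR range reference")
    ratios = []
    for t in vehicle_traces:
        b = baseline_mean(t, "ecar")
        if b <= 0:
            raise DegenerateWellError(f"well {t.well}: non-positive baseline ECAR")
        ratios.append(float(np.max(t.phase_values("oligomycin", "ecar"))) / b)
    ref = float(np.mean(ratios))
    if ref <= 1.0:
        raise DegeneratePlateError(
            f"vehicle oligomycin ECAR ({ref:.3f}x basal) does not exceed basal"
        )
    return ref


def normalize_ecar_range(trace: KineticWellTrace, vehicle_oligo_rel: float) -> np.ndarray:
    """Map ECAR onto the glycolytic range: own basal -> 0%, vehicle oligomycin max -> 100%.

    The basal acidification (100% of the pre-injection scale) is by
    construction the 0% of this range scale; both scales are affine images
    of each other, and the pre-injection scale stays available on the
    baseline-normalized trace.
    """
    if vehicle_oligo_rel <= 1.0:
        raise DegeneratePlateError("oligomycin ECAR reference must exceed basal")
    b = baseline_mean(trace, "ecar")
    if b <= 0:
        raise DegenerateWellError(f"well {trace.well}: non-positive baseline ECAR")
    rel = trace.ecar / b
    return (rel - 1.0) / (vehicle_oligo_rel - 1.0) * 100.0


def normalize_maximal_to_control(fccp_ocr_pct: float, vehicle_fccp_ocr_pct: float) -> float:
    """FCCP-phase (maximal) OCR as percent of the vehicle maximal OCR."""
    if vehicle_fccp_ocr_pct <= 0:
        raise DegeneratePlateError("vehicle maximal OCR must be positive")
    return fccp_ocr_pct / vehicle_fccp_ocr_pct * 100.0
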