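"""Read/write plate-map, kinetic-trace and endpoint tables (CSV, optionally gzip).

Column contracts
----------------
traces:   plate_id, well, compound, conc_M, phase, time_min, ocr, ecar
platemap: well, compound, conc_M, role            (role: vehicle|treatment|blank)
endpoints: compound, conc_M, endpoint, then either aggregated columns
          (mean_pct, sd_pct, n) or per-replicate rows (value_pct).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ScheduleError, ValidationError
from .simulate import InjectionSchedule, KineticWellTrace

TRACE_COLUMNS = ("plate_id", "well", "compound", "conc_M", "phase", "time_min", "ocr", "ecar")
PLATEMAP_COLUMNS = ("well", "compound", "conc_M", "role")
ROLES = ("vehicle", "treatment", "blank")

_WELL_RE = re.compile(r"^[A-P](?:[1-9]|1[0-9]|2[0-4])$")


@dataclass(frozen=True)
class PlateMap:
    """well -> (compound, molar concentration, role)."""

    entries: dict[str, tuple[str, float, str]]

    def __post_init__(self) -> None:
        for well, (compound, conc, role) in self.entries.items():
            if role not in ROLES:
                raise ValidationError(f"unknown role {role!r} for well {well}")
            if role == "vehicle" and conc != 0:
                raise ValidationError(f"vehicle well {well} must carry conc 0, got {conc}")
            if not _WELL_RE.match(well):
                raise ValidationError(f"malformed well name {well!r}")


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        # round_trip float parsing keeps write -> read the identity on
        # repr-shortest serialized values
        return pd.read_csv(path, compression="infer", float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def _require(df: pd.DataFrame, columns: tuple[str, ...], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table missing columns: {', '.join(missing)}")


def write_traces(traces: list[KineticWellTrace], path: str | Path) -> None:
    rows = []
    for t in traces:
        for phase, time, ocr, ecar in zip(t.phase_labels, t.times, t.ocr, t.ecar):
            rows.append((t.plate_id, t.well, t.compound, repr(float(t.conc)),
                         phase, repr(float(time)), repr(float(ocr)), repr(float(ecar))))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_traces(path: str | Path, schedule: InjectionSchedule | None = None) -> list[KineticWellTrace]:
    """One trace per (plate_id, well); rows time-sorted; phases validated if a schedule is given."""
    df = _read_csv(path)
    _require(df, TRACE_COLUMNS, "trace")
    if schedule is not None:
        unknown = set(df["phase"].unique()) - set(schedule.labels)
        if unknown:
            raise FormatError(f"unknown phase labels: {', '.join(sorted(map(str, unknown)))}")
    traces = []
    for (plate_id, well), grp in df.groupby(["plate_id", "well"], sort=True):
        grp = grp.sort_values("time_min", kind="stable")
        times = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise FormatError(f"non-monotone measurement times in well {well} of {plate_id}")
        compounds = grp["compound"].unique()
        concs = grp["conc_M"].unique()
        if len(compounds) != 1 or len(concs) != 1:
            raise ValidationError(f"well {well} of {plate_id} mixes conditions")
        traces.append(
            KineticWellTrace(
                plate_id=str(plate_id),
                well=str(well),
                compound=str(compounds[0]),
                conc=float(concs[0]),
                phase_labels=tuple(grp["phase"].astype(str)),
                times=times,
                ocr=grp["ocr"].to_numpy(dtype=float),
                ecar=grp["ecar"].to_numpy(dtype=float),
            )
        )
    return traces


def write_platemap(pm: PlateMap, path: str | Path) -> None:
    rows = [(w, c, repr(float(conc)), role) for w, (c, conc, role) in sorted(pm.entries.items())]
    pd.DataFrame(rows, columns=PLATEMAP_COLUMNS).to_csv(path, index=False)


def read_platemap(path: str | Path) -> PlateMap:
    df = _read_csv(path)
    _require(df, PLATEMAP_COLUMNS, "plate map")
    dupes = df["well"][df["well"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate wells in plate map: {', '.join(map(str, dupes))}")
    entries = {
        str(r.well): (str(r.compound), float(r.conc_M), str(r.role))
        for r in df.itertuples(index=False)
    }
    return PlateMap(entries=entries)


def platemap_from_traces(traces: list[KineticWellTrace]) -> PlateMap:
    entries = {}
    for t in traces:
        role = "vehicle" if t.compound == "vehicle" else "treatment"
        entries[t.well] = (t.compound, float(t.conc), role)
    return PlateMap(entries=entries)


def read_endpoints(path: str | Path) -> pd.DataFrame:
    """Endpoint table aggregated to (compound, conc_M, endpoint) means/SDs.

    Accepts either pre-aggregated rows (mean_pct [, sd_pct, n]) or
    per-replicate rows (value_pct), which are averaged here.
    """
    df = _read_csv(path)
    _require(df, ("compound", "conc_M", "endpoint"), "endpoint")
    if "mean_pct" in df.columns:
        out = df.copy()
        if "sd_pct" not in out.columns:
            out["sd_pct"] = 0.0
        if "n" not in out.columns:
            out["n"] = 1
    elif "value_pct" in df.columns:
        grouped = df.groupby(["compound", "conc_M", "endpoint"], sort=True)["value_pct"]
        out = grouped.agg(mean_pct="mean", sd_pct=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
                          n="count").reset_index()
    else:
        raise FormatError("endpoint table needs a mean_pct or value_pct column")
    return out[["compound", "conc_M", "endpoint", "mean_pct", "sd_pct", "n"]]
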