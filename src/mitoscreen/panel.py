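"""Compound panel metadata and concentration-ladder arithmetic.

The packaged panel covers 21 agrochemical/natural-product inhibitors of
the mitochondrial electron transport chain (ETC): 8 complex-I (CI,
NADH:ubiquinone oxidoreductase), 5 complex-II (CII, succinate
dehydrogenase) and 8 complex-III (CIII, cytochrome bc1) compounds.
Simulator ground-truth columns (``sim_*``) are optional and are never
consulted by any analysis stage; they exist only so the synthetic-data
generator can produce traces with a known mechanism and potency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DomainError, FormatError, ValidationError

TARGET_COMPLEXES = ("CI", "CII", "CIII")
MECHANISMS = ("inhibitor", "uncoupler", "downstream_inhibitor", "inactive")

_REQUIRED_COLUMNS = ("name", "target_complex", "cas", "mol_weight", "clogp", "subset_flag")


@dataclass(frozen=True)
class CompoundRecord:
    """One panel compound with physicochemical and (optional) simulator fields."""

    name: str
    target_complex: str
    cas: str
    mol_weight: float
    clogp: float
    subset_flag: bool
    sim_mechanism: str | None = None
    sim_potency_log10M: float | None = None
    sim_hill_slope: float = 2.0

    def __post_init__(self) -> None:
        if self.target_complex not in TARGET_COMPLEXES:
            raise ValidationError(
                f"unknown target complex {self.target_complex!r} for {self.name}"
            )
        if not self.mol_weight > 0:
            raise ValidationError(f"molecular weight must be positive for {self.name}")
        if self.sim_mechanism is not None and self.sim_mechanism not in MECHANISMS:
            raise ValidationError(
                f"unknown simulator mechanism {self.sim_mechanism!r} for {self.name}"
            )
        if self.sim_potency_log10M is not None and not -12 <= self.sim_potency_log10M <= -2:
            raise ValidationError(
                f"simulator potency {self.sim_potency_log10M} outside [-12, -2] "
                f"log10[M] for {self.name}"
            )


@dataclass(frozen=True)
class ConcentrationSeries:
    """Geometric dilution ladder, stored ascending in molar units."""

    top: float
    fold: float
    n_points: int
    values: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.values:
            object.__setattr__(self, "values", _ladder_values(self.top, self.fold, self.n_points))
        vals = self.values
        if len(vals) != self.n_points:
            raise ValidationError("series length does not match n_points")
        if abs(max(vals) - self.top) > 1e-9 * self.top:
            raise ValidationError("series maximum does not equal top")
        for lo, hi in zip(vals, vals[1:]):
            if abs(hi / lo - self.fold) > 1e-9 * self.fold:
                raise ValidationError("series is not a constant-fold ladder")

    def log10_values(self) -> tuple[float, ...]:
        return tuple(math.log10(v) for v in self.values)


def _ladder_values(top: float, fold: float, n_points: int) -> tuple[float, ...]:
    return tuple(top / fold ** (n_points - 1 - k) for k in range(n_points))


def make_dilution_series(top: float, fold: float, n_points: int) -> ConcentrationSeries:
    """Build an ascending 1-in-``fold`` dilution ladder topping out at ``top`` molar.

    ``values[k] = top / fold**(n_points - 1 - k)``.
    """
    if top <= 0:
        raise DomainError("top concentration must be positive")
    if fold <= 1:
        raise DomainError("dilution fold must exceed 1")
    if n_points < 1:
        raise DomainError("need at least one concentration")
    return ConcentrationSeries(top=top, fold=fold, n_points=n_points)


#: Ladder used for intact-cell work: 8 points, 1-in-5 from 10 uM.
#: Ladder used for permeabilized-cell work: wider, reaching 500 uM.
LADDER_PRESETS = {
    "intact_default": (1.00e-5, 5.0, 8),
    "permeabilized_extended": (5.00e-4, 10.0, 8),
}


def ladder_preset(name: str) -> ConcentrationSeries:
    try:
        top, fold, n = LADDER_PRESETS[name]
    except KeyError:
        raise ValidationError(f"unknown ladder preset {name!r}") from None
    return make_dilution_series(top, fold, n)


def _coerce_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in ("true", "1", "yes")


def load_panel(table_path: str | Path | None = None) -> list[CompoundRecord]:
    """Read a compound panel CSV into validated records.

    With no argument the packaged 21-compound panel is loaded. Required
    columns: name, target_complex, cas, mol_weight, clogp, subset_flag;
    simulator columns are optional.
    """
    if table_path is None:
        ref = resources.files("mitoscreen.data") / "compound_panel.csv"
        with resources.as_file(ref) as p:
            return load_panel(p)
    try:
        df = pd.read_csv(table_path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse panel table {table_path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"panel table missing columns: {', '.join(missing)}")
    dupes = df["name"][df["name"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate compound names: {', '.join(map(str, dupes))}")

    records = []
    for row in df.itertuples(index=False):
        mech = getattr(row, "sim_mechanism", None)
        pot = getattr(row, "sim_potency_log10M", None)
        slope = getattr(row, "sim_hill_slope", 2.0)
        records.append(
            CompoundRecord(
                name=str(row.name),
                target_complex=str(row.target_complex),
                cas=str(row.cas),
                mol_weight=float(row.mol_weight),
                clogp=float(row.clogp),
                subset_flag=_coerce_bool(row.subset_flag),
                sim_mechanism=None if mech is None or pd.isna(mech) else str(mech),
                sim_potency_log10M=None if pot is None or pd.isna(pot) else float(pot),
                sim_hill_slope=2.0 if slope is None or pd.isna(slope) else float(slope),
            )
        )
    return records


def display_log10_molar(value: float) -> str:
    """Render a log10-molar potency the way summary tables print it."""
    return f"{value:.2f}"
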