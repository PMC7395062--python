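"""Synthetic kinetic plate data for intact-cell and permeabilized-cell assays.

The generator is phenomenological, not mechanistic: it translates a
compound's occupancy (a Hill sigmoid in concentration) into expected
oxygen-consumption (OCR) and extracellular-acidification (ECAR) levels
per injection phase, then applies multiplicative lognormal measurement
noise plus a per-well lognormal scale factor. All expected values are
expressed in percent of a well's own pre-injection baseline, so the
analysis-side baseline normalization recovers them exactly at zero noise.

Flux model for the intact-cell mitostress sequence (baseline -> test
compound -> oligomycin -> FCCP -> rotenone/antimycin A), in % of basal:

* occupancy ``a`` = Hill fraction at the well's concentration;
* ETC capacity ``1 - a`` for CI/CIII inhibitors and downstream
  inhibitors; ``1`` for CII inhibitors (intact-cell masking: CII is
  dispensable for the CI->CIII electron path) and for inactive
  compounds; a protonophore adds uncoupling drive ``u = a``;
* compound phase: ``nonmito + (100 - nonmito) * capacity`` for
  inhibitors; ``min(maximal, 100 + (maximal - 100) * u)`` for
  uncouplers;
* oligomycin: ``nonmito + leak * capacity`` (+ ``(maximal - 100) * u``
  for uncouplers — oligomycin cannot suppress uncoupled respiration);
* FCCP: ``nonmito + (maximal - nonmito) * capacity``;
* rotenone/antimycin A: ``nonmito``.

ECAR rises with the fraction of ATP demand displaced onto glycolysis,
scaled by the cell line's glycolytic reserve, saturating at the
oligomycin response; an optional further FCCP increment reproduces the
high-spare-capacity (oxidative) cell-line behaviour.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ScheduleError, ValidationError
from .panel import CompoundRecord, ConcentrationSeries

MITOSTRESS_PHASES = ("baseline", "compound", "oligomycin", "fccp", "rot_aa")
COMPLEX_STAGES = ("stage1", "stage2", "stage3")


@dataclass(frozen=True)
class CellLineProfile:
    """Respiratory phenotype of a cell line, in % of its basal OCR."""

    name: str
    maximal_ocr_pct: float  # uncoupled (FCCP) capacity, >= 100
    nonmito_pct: float  # OCR remaining after rotenone/antimycin A
    leak_pct: float  # proton-leak share of basal OCR
    glycolytic_reserve: float  # max fold-increase of ECAR over basal
    fccp_ecar_boost: bool  # does ECAR rise further after FCCP?
    glucose_rescue: float  # fraction of ATP demand glycolysis covers in glucose
    culture_modifier_3d: float  # scaling of glucose_rescue in spheroid culture

    def __post_init__(self) -> None:
        if self.maximal_ocr_pct < 100:
            raise ValidationError("maximal OCR must be at least basal (100%)")
        if self.nonmito_pct + self.leak_pct >= 100:
            raise ValidationError("non-mitochondrial plus leak OCR must be below basal")
        if not 0 <= self.glucose_rescue <= 1 or not 0 <= self.culture_modifier_3d <= 1:
            raise ValidationError("glucose_rescue and culture_modifier_3d must lie in [0, 1]")


# Default phenotypes: a glycolytic hepatoma-like line with low spare
# respiratory capacity, and an oxidative renal-epithelium-like line with
# high spare capacity. Maximal OCR defaults (159.4 / 337.4 % of basal)
# are the two lines' uncoupled-capacity means.
HEPG2 = CellLineProfile(
    name="HepG2",
    maximal_ocr_pct=159.4,
    nonmito_pct=10.0,
    leak_pct=15.0,
    glycolytic_reserve=2.0,
    fccp_ecar_boost=False,
    glucose_rescue=1.0,
    culture_modifier_3d=0.3,
)
RPTEC = CellLineProfile(
    name="RPTEC/TERT1",
    maximal_ocr_pct=337.4,
    nonmito_pct=10.0,
    leak_pct=15.0,
    glycolytic_reserve=1.0,
    fccp_ecar_boost=True,
    glucose_rescue=0.2,
    culture_modifier_3d=1.0,
)
CELL_LINE_PROFILES = {"HepG2": HEPG2, "RPTEC/TERT1": RPTEC}

#: Extra ECAR reserve fraction recruited by FCCP when the profile boosts.
FCCP_ECAR_BOOST_FRAC = 0.25


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered injection phases: (label, agent, n_cycles, cycle_minutes)."""

    phases: tuple[tuple[str, str, int, float], ...]

    def __post_init__(self) -> None:
        labels = [p[0] for p in self.phases]
        if len(set(labels)) != len(labels):
            raise ScheduleError("phase labels must be unique")
        if any(p[2] < 1 for p in self.phases):
            raise ScheduleError("each phase needs at least one measurement cycle")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.phases)

    def expand(self) -> tuple[list[str], np.ndarray]:
        """Per-measurement phase labels and cycle-midpoint times in minutes."""
        labels: list[str] = []
        times: list[float] = []
        t = 0.0
        for label, _agent, n_cycles, cycle_minutes in self.phases:
            for _ in range(n_cycles):
                labels.append(label)
                times.append(t + cycle_minutes / 2.0)
                t += cycle_minutes
        return labels, np.asarray(times)


def default_mitostress_schedule() -> InjectionSchedule:
    """Five-phase mitostress schedule: 3/5/3/3/3 cycles of 6 min each."""
    return InjectionSchedule(
        phases=(
            ("baseline", "none", 3, 6.0),
            ("compound", "test compound", 5, 6.0),
            ("oligomycin", "oligomycin 2 uM", 3, 6.0),
            ("fccp", "FCCP 2 uM", 3, 6.0),
            ("rot_aa", "rotenone/antimycin A 0.5 uM", 3, 6.0),
        )
    )


def default_complex_schedule() -> InjectionSchedule:
    """Permeabilized-cell schedule: baseline then three 2-measurement stages."""
    return InjectionSchedule(
        phases=(
            ("baseline", "CI substrates (pyruvate/malate/ADP)", 3, 2.5),
            ("stage1", "test compound", 2, 2.5),
            ("stage2", "succinate 10 mM + rotenone 2 uM", 2, 2.5),
            ("stage3", "ascorbate/TMPD + antimycin A 2 uM", 2, 2.5),
        )
    )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise per measurement plus per-well scale."""

    cv: float = 0.03
    well_scale_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.well_scale_sd < 0:
            raise ValidationError("noise parameters must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True, eq=False)
class KineticWellTrace:
    """One well's OCR/ECAR time series with per-measurement phase labels."""

    plate_id: str
    well: str
    compound: str
    conc: float  # molar; 0 for vehicle
    phase_labels: tuple[str, ...]
    times: np.ndarray  # minutes, strictly increasing
    ocr: np.ndarray
    ecar: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.phase_labels)
        if not (len(self.times) == len(self.ocr) == len(self.ecar) == n):
            raise ValidationError("trace arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"times must be strictly increasing in well {self.well}")

    def phase_values(self, phase: str, channel: str = "ocr") -> np.ndarray:
        mask = np.asarray([p == phase for p in self.phase_labels])
        if not mask.any():
            raise ScheduleError(f"phase {phase!r} absent from well {self.well}")
        return getattr(self, channel)[mask]


def hill_fraction(conc: float, ic50: float, slope: float) -> float:
    """Fractional occupancy ``conc^s / (ic50^s + conc^s)``."""
    if conc < 0:
        raise DomainError("concentration must be non-negative")
    if ic50 <= 0 or slope <= 0:
        raise DomainError("ic50 and slope must be positive")
    if conc == 0:
        return 0.0
    r = (conc / ic50) ** slope
    return r / (1.0 + r)


def _well_names(n: int) -> list[str]:
    rows = string.ascii_uppercase[:16]
    names = [f"{r}{c}" for r in rows for c in range(1, 25)]
    if n > len(names):
        raise ValidationError(f"cannot place {n} wells on a 384-well plate")
    return names[:n]


def _occupancy(record: CompoundRecord, conc: float) -> float:
    if record.sim_mechanism is None or record.sim_potency_log10M is None:
        raise ValidationError(
            f"compound {record.name} lacks simulator ground-truth fields"
        )
    return hill_fraction(conc, 10.0 ** record.sim_potency_log10M, record.sim_hill_slope)


def mitostress_expected(
    mechanism: str,
    occupancy: float,
    profile: CellLineProfile,
    target: str | None = None,
    cii_masking: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Noise-free (OCR % of basal, ECAR fraction of glycolytic reserve) per phase.

    ``cii_masking`` is the fraction of a CII inhibitor's occupancy hidden
    from intact-cell respiration (1 = total masking, the default: CII is
    bypassed by the CI->CIII electron path); lower it for sensitivity
    analyses of partial masking.
    """
    nm, leak, mx = profile.nonmito_pct, profile.leak_pct, profile.maximal_ocr_pct
    a = occupancy
    if mechanism == "inhibitor" and target == "CII":
        a = a * (1.0 - cii_masking)
    if mechanism in ("inhibitor", "downstream_inhibitor", "inactive"):
        capacity = 1.0 - a if mechanism != "inactive" else 1.0
        u = 0.0
    elif mechanism == "uncoupler":
        capacity = 1.0
        u = a
    else:
        raise ValidationError(f"unknown mechanism {mechanism!r}")

    if u > 0:
        compound_ocr = min(mx, 100.0 + (mx - 100.0) * u)
    else:
        compound_ocr = nm + (100.0 - nm) * capacity
    oligo_ocr = nm + leak * capacity + (mx - 100.0) * u
    fccp_ocr = nm + (mx - nm) * capacity
    rot_ocr = nm

    shift = a if (u > 0 or capacity < 1.0) else 0.0  # ATP demand moved to glycolysis
    boost = FCCP_ECAR_BOOST_FRAC if profile.fccp_ecar_boost else 0.0
    return {
        "baseline": (100.0, 0.0),
        "compound": (compound_ocr, min(1.0, shift)),
        "oligomycin": (oligo_ocr, 1.0),
        "fccp": (fccp_ocr, 1.0 + boost),
        "rot_aa": (rot_ocr, 1.0),
    }


def _apply_capacity(mechanism: str, target: str, occupancy: float) -> dict[str, float]:
    """Per-complex transmission factors g(X) for the permeabilized assay."""
    g = {"CI": 1.0, "CII": 1.0, "CIII": 1.0, "CIV": 1.0}
    if mechanism == "inhibitor":
        g[target] = 1.0 - occupancy
    elif mechanism == "downstream_inhibitor":
        g["CIV"] = 1.0 - occupancy
    elif mechanism in ("uncoupler", "inactive"):
        pass  # no ETC block; ADP-stimulated flux is unchanged
    else:
        raise ValidationError(f"unknown mechanism {mechanism!r}")
    return g


def complex_assay_expected(
    mechanism: str,
    target: str,
    occupancy: float,
    stage_capacities: dict[str, float] | None = None,
) -> dict[str, float]:
    """Noise-free stage OCR in % of the pre-compound (CI-substrate) baseline.

    stage1 runs CI->CIII->CIV, stage2 (succinate+rotenone) CII->CIII->CIV,
    stage3 (ascorbate/TMPD+antimycin A) CIV only.
    """
    caps = dict(DEFAULT_STAGE_CAPACITIES)
    if stage_capacities:
        caps.update(stage_capacities)
    g = _apply_capacity(mechanism, target, occupancy)
    return {
        "baseline": 100.0,
        "stage1": 100.0 * caps["CI"] * g["CI"] * g["CIII"] * g["CIV"],
        "stage2": 100.0 * caps["CII"] * g["CII"] * g["CIII"] * g["CIV"],
        "stage3": 100.0 * caps["CIV"] * g["CIV"],
    }


#: Relative flux each substrate pathway supports in vehicle wells
#: (CI-substrate path defines 100%; TMPD-driven CIV flux runs higher).
DEFAULT_STAGE_CAPACITIES = {"CI": 1.0, "CII": 0.9, "CIV": 1.4}


def _noisy(expected: np.ndarray, rng: np.random.Generator, cv: float, well_scale: float) -> np.ndarray:
    if cv == 0:
        return expected * well_scale
    sigma = np.sqrt(np.log1p(cv * cv))
    return expected * well_scale * np.exp(rng.normal(0.0, sigma, size=expected.shape))


def _well_scale(rng: np.random.Generator, sd: float) -> float:
    return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0


def simulate_mitostress_plate(
    panel: list[CompoundRecord],
    series: ConcentrationSeries,
    profile: CellLineProfile,
    schedule: InjectionSchedule | None = None,
    noise: NoiseModel | None = None,
    n_vehicle: int = 6,
    n_replicates: int = 1,
    basal_ocr: float = 60.0,
    basal_ecar: float = 20.0,
    plate_id: str | None = None,
) -> list[KineticWellTrace]:
    """Simulate one mitostress plate: every compound at every ladder point plus vehicle wells."""
    schedule = schedule or default_mitostress_schedule()
    noise = noise or NoiseModel()
    missing = [p for p in MITOSTRESS_PHASES if p not in schedule.labels]
    if missing:
        raise ScheduleError(f"mitostress schedule missing phases: {', '.join(missing)}")
    labels, times = schedule.expand()
    rng = noise.rng()
    plate_id = plate_id or f"mitostress_{profile.name}"

    conditions: list[tuple[str, float]] = [("vehicle", 0.0)] * n_vehicle
    for rec in panel:
        for conc in series.values:
            conditions.extend([(rec.name, conc)] * n_replicates)
    wells = _well_names(len(conditions))
    by_name = {r.name: r for r in panel}

    traces = []
    for well, (cname, conc) in zip(wells, conditions):
        if cname == "vehicle":
            expected = mitostress_expected("inactive", 0.0, profile)
        else:
            rec = by_name[cname]
            expected = mitostress_expected(rec.sim_mechanism, _occupancy(rec, conc),
                                           profile, target=rec.target_complex)
        ocr_pct = np.asarray([expected[p][0] for p in labels])
        ecar_frac = np.asarray([expected[p][1] for p in labels])
        scale = _well_scale(rng, noise.well_scale_sd)
        ocr = _noisy(basal_ocr * ocr_pct / 100.0, rng, noise.cv, scale)
        ecar = _noisy(basal_ecar * (1.0 + profile.glycolytic_reserve * ecar_frac), rng, noise.cv, scale)
        traces.append(
            KineticWellTrace(
                plate_id=plate_id,
                well=well,
                compound=cname,
                conc=conc,
                phase_labels=tuple(labels),
                times=times.copy(),
                ocr=ocr,
                ecar=ecar,
            )
        )
    return traces


def simulate_complex_assay_plate(
    panel: list[CompoundRecord],
    series: ConcentrationSeries,
    noise: NoiseModel | None = None,
    stage_capacities: dict[str, float] | None = None,
    schedule: InjectionSchedule | None = None,
    n_vehicle: int = 6,
    n_replicates: int = 1,
    basal_ocr: float = 120.0,
    plate_id: str = "complex_assay",
) -> list[KineticWellTrace]:
    """Simulate a permeabilized-cell three-stage complex-specificity plate."""
    schedule = schedule or default_complex_schedule()
    noise = noise or NoiseModel()
    missing = [p for p in ("baseline",) + COMPLEX_STAGES if p not in schedule.labels]
    if missing:
        raise ScheduleError(f"complex-assay schedule missing phases: {', '.join(missing)}")
    labels, times = schedule.expand()
    rng = noise.rng()

    conditions: list[tuple[str, float]] = [("vehicle", 0.0)] * n_vehicle
    for rec in panel:
        for conc in series.values:
            conditions.extend([(rec.name, conc)] * n_replicates)
    wells = _well_names(len(conditions))
    by_name = {r.name: r for r in panel}

    traces = []
    for well, (cname, conc) in zip(wells, conditions):
        if cname == "vehicle":
            expected = complex_assay_expected("inactive", "CI", 0.0, stage_capacities)
        else:
            rec = by_name[cname]
            expected = complex_assay_expected(
                rec.sim_mechanism, rec.target_complex, _occupancy(rec, conc), stage_capacities
            )
        ocr_pct = np.asarray([expected[p] for p in labels])
        scale = _well_scale(rng, noise.well_scale_sd)
        ocr = _noisy(basal_ocr * ocr_pct / 100.0, rng, noise.cv, scale)
        # Permeabilized wells are run in mitochondrial assay buffer; the
        # acidification channel is not interpreted, keep a flat placeholder.
        ecar = np.full_like(ocr, 1.0)
        traces.append(
            KineticWellTrace(
                plate_id=plate_id,
                well=well,
                compound=cname,
                conc=conc,
                phase_labels=tuple(labels),
                times=times.copy(),
                ocr=ocr,
                ecar=ecar,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# Endpoint panel (24 h assays: viability, lactate, membrane potential, PI)

#: Half-maximal energy deficit for viability loss and PI gain, and shared
#: Hill steepness of the viability coupling.
VIABILITY_DEFICIT_D50 = 0.4
VIABILITY_DEFICIT_HILL = 3.0
PI_MAX_FRACTION = 0.9
LACTATE_GAIN = 1.5
#: Potency fold-change conferred by a full repeated-exposure course
#: (applied geometrically per extra 24 h administration, 4 extra = full).
SENSITISATION_FOLD_PER_COURSE = 2.0

ENDPOINTS = ("resazurin", "lactate", "mmp", "pi")


def _endpoint_expected(
    record: CompoundRecord,
    conc: float,
    profile: CellLineProfile,
    medium: str,
    culture: str,
    exposures: int,
) -> dict[str, float]:
    mech = record.sim_mechanism
    sens = SENSITISATION_FOLD_PER_COURSE ** ((exposures - 1) / 4.0)
    ic50_eff = 10.0 ** record.sim_potency_log10M / sens
    a = hill_fraction(conc, ic50_eff, record.sim_hill_slope)

    etc_block = a if mech in ("inhibitor", "downstream_inhibitor") else 0.0
    if mech == "inhibitor" and record.target_complex == "CII":
        etc_block = 0.0  # masked in intact cells
    coupling_loss = a if mech == "uncoupler" else etc_block

    rescue = profile.glucose_rescue if medium == "glucose" else 0.0
    if culture == "spheroid_3d":
        rescue *= profile.culture_modifier_3d
    deficit = coupling_loss * (1.0 - rescue)

    d, d50, h = deficit, VIABILITY_DEFICIT_D50, VIABILITY_DEFICIT_HILL
    hit = d**h / (d**h + d50**h) if d > 0 else 0.0
    glyc = coupling_loss
    mmp_drop = a if (etc_block > 0 and record.target_complex in ("CI", "CIII")) else 0.0
    if mech == "downstream_inhibitor" or mech == "uncoupler":
        mmp_drop = a
    return {
        "resazurin": 100.0 * (1.0 - hit),
        "lactate": 100.0 * (1.0 + LACTATE_GAIN * glyc),
        "mmp": 100.0 * (1.0 - mmp_drop),
        "pi": 100.0 * PI_MAX_FRACTION * hit,
    }


def simulate_endpoint_panel(
    panel: list[CompoundRecord],
    series: ConcentrationSeries,
    profile: CellLineProfile,
    medium: str = "glucose",
    culture: str = "monolayer_2d",
    exposures: int = 1,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
):
    """Per compound x concentration endpoint means/SDs as a long-format table.

    Endpoints: resazurin viability (% of control), supernatant lactate
    (% of control), mitochondrial membrane potential (% of control) and
    PI-positive cells (%). The PI endpoint stands for a pre-quantified
    image-analysis readout (nuclei counted PI-positive by overlap with
    the nuclear mask); segmentation itself is outside this package.
    """
    import pandas as pd

    if medium not in ("glucose", "galactose"):
        raise ValidationError(f"unknown medium {medium!r}")
    if culture not in ("monolayer_2d", "spheroid_3d"):
        raise ValidationError(f"unknown culture mode {culture!r}")
    if exposures < 1:
        raise DomainError("exposures must be at least 1")
    noise = noise or NoiseModel()
    rng = noise.rng()

    rows = []
    for rec in panel:
        for conc in series.values:
            expected = _endpoint_expected(rec, conc, profile, medium, culture, exposures)
            for endpoint in ENDPOINTS:
                mu = expected[endpoint]
                if noise.cv > 0:
                    sigma = np.sqrt(np.log1p(noise.cv**2))
                    reps = mu * np.exp(rng.normal(0.0, sigma, size=n_replicates))
                else:
                    reps = np.full(n_replicates, mu)
                rows.append(
                    {
                        "compound": rec.name,
                        "conc_M": conc,
                        "endpoint": endpoint,
                        "mean_pct": float(np.mean(reps)),
                        "sd_pct": float(np.std(reps, ddof=1)) if n_replicates > 1 else 0.0,
                        "n": n_replicates,
                    }
                )
    return pd.DataFrame(rows)
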