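"""Single-document YAML configuration for the simulator and analysis thresholds."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import FormatError, ValidationError
from .panel import LADDER_PRESETS
from .simulate import CELL_LINE_PROFILES, CellLineProfile, NoiseModel


@dataclass(frozen=True)
class AnalysisThresholds:
    """Every named analysis threshold with its default."""

    noneffective_k_min: int = 2
    noneffective_delta_pct: float = 10.0
    uncoupling_rise_pct: float = 115.0
    uncoupling_oligo_resistance_pct: float = 100.0
    complex_inhibition_frac: float = 0.7
    complex_rescue_frac: float = 0.7
    complex_partial_band: tuple[float, float] = (0.4, 0.7)
    flat_effect_pct: float = 20.0
    alpha: float = 0.05
    annotate_top_dose_only_calls: bool = True


@dataclass(frozen=True)
class SimConfig:
    profile: str = "HepG2"
    ladder: str = "intact_default"
    cv: float = 0.03
    well_scale_sd: float = 0.05
    seed: int = 0
    sensitisation_fold_per_course: float = 2.0


@dataclass(frozen=True)
class Config:
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)

    def hash(self) -> str:
        """Stable short hash recorded on emitted tables for provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def profile_obj(self) -> CellLineProfile:
        try:
            return CELL_LINE_PROFILES[self.sim.profile]
        except KeyError:
            raise ValidationError(f"unknown cell-line profile {self.sim.profile!r}") from None

    def noise(self) -> NoiseModel:
        return NoiseModel(cv=self.sim.cv, well_scale_sd=self.sim.well_scale_sd,
                          seed=self.sim.seed)


def load_config(path: str | Path | None) -> Config:
    if path is None:
        return Config()
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError("config document must be a mapping")
    try:
        sim = SimConfig(**raw.get("sim", {}))
        thr_raw = dict(raw.get("thresholds", {}))
        if "complex_partial_band" in thr_raw:
            thr_raw["complex_partial_band"] = tuple(thr_raw["complex_partial_band"])
        thresholds = AnalysisThresholds(**thr_raw)
    except TypeError as exc:
        raise FormatError(f"unknown config key: {exc}") from exc
    if sim.ladder not in LADDER_PRESETS:
        raise ValidationError(f"unknown ladder preset {sim.ladder!r}")
    return Config(sim=sim, thresholds=thresholds)


def dump_default_config(path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(Config()), fh, sort_keys=False)
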