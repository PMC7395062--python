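"""Cross-assay integration: summary tables, correlations and mechanism calls.

The mechanism-of-action (MoA) call synthesizes all endpoints with a fixed
precedence — uncoupler > complex-specific inhibitor > downstream
inhibitor > inactive:

1. a protonophore signature in the intact-cell assay (basal OCR rise
   that oligomycin cannot suppress) dominates every other pattern;
2. otherwise the permeabilized-cell complex call names the inhibited
   complex. A CII call is reported as *masked* CII inhibition, because
   CII blockade is invisible in intact cells (the CI->CIII electron path
   bypasses it); CI/CIII calls stand even when the intact-cell assay was
   silent, which simply means the compound's potency lies beyond the
   intact ladder;
3. a stage-3 (downstream-of-CIII) pattern maps to a pooled CIV/CV call;
4. with no complex evidence and no intact activity the compound is
   inactive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .complexassay import ComplexCall, classify_plate, complex_potency, summarize_stages, vehicle_stage_reference
from .doseresponse import PotencyResult, ec50_pointwise, fit_hill4, ic50_from_fit, not_tested
from .errors import ValidationError
from .mitostress import potency_curves_from_plate, uncoupling_flags
from .normalize import NormalizedCurve
from .panel import CompoundRecord, ladder_preset, load_panel
from .simulate import (
    HEPG2,
    RPTEC,
    NoiseModel,
    simulate_complex_assay_plate,
    simulate_endpoint_panel,
    simulate_mitostress_plate,
)

MOA_CALLS = (
    "etc_inhibitor_CI",
    "etc_inhibitor_CII_masked",
    "etc_inhibitor_CIII",
    "etc_inhibitor_CIII_partial",
    "uncoupler",
    "downstream_inhibitor",
    "inactive",
)


@dataclass(frozen=True)
class CorrelationResult:
    endpoint_x: str
    endpoint_y: str
    slope: float
    intercept: float
    r2: float
    n: int


@dataclass(frozen=True)
class MoACall:
    compound: str
    call: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.call not in MOA_CALLS:
            raise ValidationError(f"unknown MoA call {self.call!r}")


def build_summary_matrix(
    potencies: dict[tuple[str, str], PotencyResult],
    compounds: list[str],
    endpoints: list[str],
) -> pd.DataFrame:
    """Compound x endpoint table of display strings, in fixed panel order.

    Missing cells render as NT; conflicting duplicate keys are an error
    upstream (dict keys are unique by construction here, so only the
    caller can introduce conflicts — see ``collect_potencies``).
    """
    data = {}
    for endpoint in endpoints:
        col = []
        for compound in compounds:
            res = potencies.get((compound, endpoint))
            col.append(res.display if res is not None else "NT")
        data[endpoint] = col
    return pd.DataFrame(data, index=pd.Index(compounds, name="compound"))


def collect_potencies(records: list[tuple[str, str, PotencyResult]]) -> dict:
    """Key potency records by (compound, endpoint); conflicting duplicates error."""
    out: dict[tuple[str, str], PotencyResult] = {}
    for compound, endpoint, res in records:
        key = (compound, endpoint)
        if key in out and out[key] != res:
            raise ValidationError(f"conflicting potency entries for {key}")
        out[key] = res
    return out


def correlate_endpoints(x: dict, y: dict, endpoint_x: str = "x", endpoint_y: str = "y") -> CorrelationResult:
    """OLS of matched per-(compound, concentration) means; r2 = squared Pearson r."""
    keys = sorted(set(x) & set(y))
    if len(keys) < 3:
        raise ValidationError("need at least three matched pairs to correlate")
    xv = np.asarray([x[k] for k in keys], dtype=float)
    yv = np.asarray([y[k] for k in keys], dtype=float)
    res = stats.linregress(xv, yv)
    return CorrelationResult(
        endpoint_x=endpoint_x,
        endpoint_y=endpoint_y,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        n=len(keys),
    )


def call_moa(
    compound: str,
    uncoupling: bool,
    intact_basal: PotencyResult | None,
    intact_ecar: PotencyResult | None,
    complex_call: ComplexCall | None,
    mmp_potency: PotencyResult | None = None,
    lactate_potency: PotencyResult | None = None,
) -> MoACall:
    """Synthesize one compound's mechanism call from all available evidence."""
    evidence = {
        "uncoupling": uncoupling,
        "intact_basal": intact_basal.display if intact_basal else "NT",
        "intact_ecar": intact_ecar.display if intact_ecar else "NT",
        "complex_call": complex_call.call if complex_call else "NT",
        "mmp": mmp_potency.display if mmp_potency else "NT",
        "lactate": lactate_potency.display if lactate_potency else "NT",
    }
    intact_active = intact_basal is not None and intact_basal.censored == "none"
    cc = complex_call.call if complex_call is not None else "no_inhibition"

    if uncoupling:
        if cc in ("CI", "CIII", "CIV_CV_downstream"):
            evidence["contradiction"] = "uncoupling signature alongside a full ETC block"
        call = "uncoupler"
    elif cc == "CI":
        call = "etc_inhibitor_CI"
    elif cc == "CII":
        call = "etc_inhibitor_CII_masked"
    elif cc == "CIII":
        call = "etc_inhibitor_CIII"
    elif cc == "CIII_partial":
        call = "etc_inhibitor_CIII_partial"
    elif cc == "CIV_CV_downstream":
        call = "downstream_inhibitor"
    else:
        call = "inactive"
    evidence["intact_silent"] = not intact_active
    return MoACall(compound=compound, call=call, evidence=evidence)


# ---------------------------------------------------------------------------
# End-to-end pipeline on simulated plates


def intact_potencies_from_curves(
    curves: dict[str, NormalizedCurve], top_tested: float
) -> dict[str, PotencyResult]:
    """Fit the three intact-cell curves of one compound.

    Basal and maximal OCR are inhibition endpoints (Hill fit, censored
    IC50); a basal-OCR curve that rises instead of falling (protonophore
    pattern) is routed to the activation branch and reported as a
    point-to-point EC50 on its own 0-100 rise scale. The ECAR range curve
    is an activation endpoint by construction.
    """
    out: dict[str, PotencyResult] = {}
    basal = curves["ocr_basal"]
    top_resp = float(np.mean(basal.response[-2:]))
    if top_resp >= 115.0:  # rising basal OCR: uncoupler-type activation
        rise = basal.response - 100.0
        peak = float(np.max(rise))
        act = rise / peak * 100.0 if peak > 0 else rise
        out["ocr_basal"] = ec50_pointwise(basal.conc, act)
    else:
        fit = fit_hill4(basal.conc, basal.response, direction="decreasing")
        out["ocr_basal"] = ic50_from_fit(fit, top_tested)
    maximal = curves["ocr_maximal"]
    fit = fit_hill4(maximal.conc, maximal.response, direction="decreasing")
    out["ocr_maximal"] = ic50_from_fit(fit, top_tested)
    out["ecar_range"] = ec50_pointwise(curves["ecar_range"].conc, curves["ecar_range"].response)
    return out


def endpoint_potency(table: pd.DataFrame, compound: str, endpoint: str, top_tested: float) -> PotencyResult:
    """Potency of one 24 h endpoint from an aggregated endpoint table."""
    sub = table[(table["compound"] == compound) & (table["endpoint"] == endpoint)]
    sub = sub.sort_values("conc_M")
    if sub.empty:
        return not_tested()
    conc = sub["conc_M"].to_numpy(dtype=float)
    resp = sub["mean_pct"].to_numpy(dtype=float)
    if endpoint in ("resazurin", "mmp"):  # falling endpoints
        fit = fit_hill4(conc, resp, direction="decreasing")
        return ic50_from_fit(fit, top_tested)
    if endpoint == "pi":  # % positive, already a 0-100 activation scale
        return ec50_pointwise(conc, resp)
    # lactate: % of control rising above 100; rescale its own rise to 0-100
    rise = resp - 100.0
    peak = float(np.max(rise))
    if peak < 20.0:
        return ec50_pointwise(conc, np.zeros_like(rise))  # NR
    return ec50_pointwise(conc, rise / peak * 100.0)


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    moa: dict[str, MoACall]
    correlations: list[CorrelationResult]
    complex_calls: dict[str, ComplexCall]
    uncoupling: dict[str, bool]
    intact: dict[str, dict[str, dict[str, PotencyResult]]]  # cell line -> compound -> endpoint
    curves: dict[str, dict[str, dict[str, NormalizedCurve]]]  # cell line -> compound -> curve


def run_pipeline(
    panel: list[CompoundRecord] | None = None,
    seed: int = 0,
    cv: float = 0.03,
    well_scale_sd: float = 0.05,
    n_replicates: int = 1,
) -> PipelineResult:
    """Simulate the full study design and analyse it end to end.

    One intact-cell mitostress plate per cell line on the 8-point 1-in-5
    ladder from 10 uM, one permeabilized complex-assay plate on the
    extended ladder, and 24 h endpoint panels; then normalization,
    decomposition, classification, potency fitting, mechanism calls and
    the basal-OCR-vs-ECAR correlation.
    """
    panel = panel or load_panel()
    intact = ladder_preset("intact_default")
    extended = ladder_preset("permeabilized_extended")
    compounds = [r.name for r in panel]

    plates = {}
    for i, profile in enumerate((RPTEC, HEPG2)):
        noise = NoiseModel(cv=cv, well_scale_sd=well_scale_sd, seed=seed * 31 + i)
        plates[profile.name] = simulate_mitostress_plate(
            panel, intact, profile, noise=noise, n_replicates=n_replicates
        )
    complex_plate = simulate_complex_assay_plate(
        panel, extended, noise=NoiseModel(cv=cv, well_scale_sd=well_scale_sd, seed=seed * 31 + 2),
        n_replicates=n_replicates,
    )
    endpoint_tables = {
        ("RPTEC/TERT1", "glucose"): simulate_endpoint_panel(
            panel, intact, RPTEC, "glucose",
            noise=NoiseModel(cv=cv, seed=seed * 31 + 3)),
        ("HepG2", "glucose"): simulate_endpoint_panel(
            panel, intact, HEPG2, "glucose",
            noise=NoiseModel(cv=cv, seed=seed * 31 + 4)),
        ("HepG2", "galactose"): simulate_endpoint_panel(
            panel, intact, HEPG2, "galactose",
            noise=NoiseModel(cv=cv, seed=seed * 31 + 5)),
    }

    top = max(intact.values)
    intact_results: dict[str, dict[str, dict[str, PotencyResult]]] = {}
    flags_by_line = {}
    curves_by_line = {}
    for line, traces in plates.items():
        curves = potency_curves_from_plate(traces)
        curves_by_line[line] = curves
        intact_results[line] = {
            c: intact_potencies_from_curves(curves[c], top) for c in curves
        }
        flags_by_line[line] = uncoupling_flags(traces)
    uncoupling = {
        c: any(flags_by_line[line].get(c, False) for line in flags_by_line)
        for c in compounds
    }

    complex_calls, per_conc = classify_plate(complex_plate)
    vehicle_ref = vehicle_stage_reference([t for t in complex_plate if t.compound == "vehicle"])
    stage_potencies = {}
    for compound in compounds:
        rows = [summarize_stages(t, vehicle_ref) for t in complex_plate
                if t.compound == compound]
        stage_potencies[compound] = complex_potency(rows, max(extended.values))

    records: list[tuple[str, str, PotencyResult]] = []
    for line in intact_results:
        tag = "RPTEC" if "RPTEC" in line else "HepG2"
        for compound, res in intact_results[line].items():
            records.append((compound, f"ocr_basal_{tag}", res["ocr_basal"]))
            records.append((compound, f"ocr_maximal_{tag}", res["ocr_maximal"]))
            records.append((compound, f"ecar_{tag}", res["ecar_range"]))
    for (line, medium), table in endpoint_tables.items():
        tag = ("RPTEC" if "RPTEC" in line else "HepG2") + ("_gal" if medium == "galactose" else "")
        for compound in compounds:
            records.append((compound, f"viability_{tag}",
                            endpoint_potency(table, compound, "resazurin", top)))
            records.append((compound, f"lactate_{tag}",
                            endpoint_potency(table, compound, "lactate", top)))
            records.append((compound, f"mmp_{tag}",
                            endpoint_potency(table, compound, "mmp", top)))
    for compound, stages in stage_potencies.items():
        records.append((compound, "perm_CI", stages["stage1"]))
        records.append((compound, "perm_CII_CIII", stages["stage2"]))
        records.append((compound, "perm_CIV", stages["stage3"]))
    potencies = collect_potencies(records)

    endpoint_order = [
        "viability_RPTEC", "viability_HepG2", "viability_HepG2_gal",
        "mmp_RPTEC", "mmp_HepG2", "lactate_RPTEC", "lactate_HepG2",
        "ecar_RPTEC", "ecar_HepG2",
        "ocr_basal_RPTEC", "ocr_basal_HepG2",
        "ocr_maximal_RPTEC", "ocr_maximal_HepG2",
        "perm_CI", "perm_CII_CIII", "perm_CIV",
    ]
    summary = build_summary_matrix(potencies, compounds, endpoint_order)

    moa = {}
    for compound in compounds:
        hepg2 = intact_results.get("HepG2", {}).get(compound, {})
        moa[compound] = call_moa(
            compound,
            uncoupling=uncoupling.get(compound, False),
            intact_basal=hepg2.get("ocr_basal"),
            intact_ecar=hepg2.get("ecar_range"),
            complex_call=complex_calls.get(compound),
            mmp_potency=potencies.get((compound, "mmp_HepG2")),
            lactate_potency=potencies.get((compound, "lactate_HepG2")),
        )

    correlations = []
    for line in curves_by_line:
        tag = "RPTEC" if "RPTEC" in line else "HepG2"
        xs, ys = {}, {}
        for compound, curves in curves_by_line[line].items():
            for conc, ocr, ecar in zip(curves["ocr_basal"].conc,
                                       curves["ocr_basal"].response,
                                       curves["ecar_range"].response):
                xs[(compound, conc)] = ocr
                ys[(compound, conc)] = ecar
        correlations.append(
            correlate_endpoints(xs, ys, f"ocr_basal_{tag}", f"ecar_{tag}")
        )

    return PipelineResult(
        summary=summary,
        moa=moa,
        correlations=correlations,
        complex_calls=complex_calls,
        uncoupling=uncoupling,
        intact=intact_results,
        curves=curves_by_line,
    )


def expected_moa(record: CompoundRecord) -> str:
    """The mechanism call a perfect analysis would assign to a simulated compound."""
    if record.sim_mechanism == "uncoupler":
        return "uncoupler"
    if record.sim_mechanism == "downstream_inhibitor":
        return "downstream_inhibitor"
    if record.sim_mechanism == "inactive":
        return "inactive"
    if record.target_complex == "CI":
        return "etc_inhibitor_CI"
    if record.target_complex == "CII":
        return "etc_inhibitor_CII_masked"
    return "etc_inhibitor_CIII"


def plot_correlation(result: CorrelationResult, x: dict, y: dict, path: str) -> None:
    """Scatter of matched points with the fitted line (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = sorted(set(x) & set(y))
    xv = np.asarray([x[k] for k in keys], dtype=float)
    yv = np.asarray([y[k] for k in keys], dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(xv, yv, s=12, alpha=0.7)
    grid = np.linspace(xv.min(), xv.max(), 50)
    ax.plot(grid, result.intercept + result.slope * grid, color="crimson")
    ax.set_xlabel(result.endpoint_x)
    ax.set_ylabel(result.endpoint_y)
    ax.set_title(f"slope {result.slope:.2f}, r2 {result.r2:.3f} (n={result.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
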