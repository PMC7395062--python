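"""Four-parameter Hill fits, censored potencies, point-to-point EC50s and Dunnett LOECs.

Potency conventions
-------------------
* Inhibition endpoints are fit with the 4-parameter Hill (log-logistic)
  model ``y = bottom + (top - bottom) / (1 + 10**((x - logIC50) * slope))``
  in ``x = log10(conc)`` and solved for y = 50%.
* Activation endpoints use a model-free point-to-point (piecewise-linear)
  curve evaluated on a 1000-point log-concentration grid; the EC50 is the
  first grid point whose interpolated response reaches 50%.
* Potencies beyond the tested range are censored and displayed as
  ``"> <log10 top>"``; flat activation curves display ``"NR"`` (no
  response); untested cells display ``"NT"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, MitoscreenError, ValidationError

SLOPE_BOUNDS = (0.1, 10.0)
BOTTOM_BOUNDS = (-10.0, 110.0)


@dataclass(frozen=True)
class HillFit:
    bottom: float
    top: float
    log_ic50: float
    hill_slope: float
    rss: float
    converged: bool
    direction: str = "decreasing"

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _hill(np.asarray(x, dtype=float), self.bottom, self.top,
                     self.log_ic50, self.hill_slope, self.direction)


@dataclass(frozen=True)
class PotencyResult:
    """A log10-molar potency, possibly censored."""

    value: float | None
    censored: str  # none | above_top_tested | not_tested | no_response
    kind: str  # IC50 | EC50

    @property
    def display(self) -> str:
        if self.censored == "not_tested":
            return "NT"
        if self.censored == "no_response":
            return "NR"
        if self.censored == "above_top_tested":
            return f"> {self.value:.2f}"
        return f"{self.value:.2f}"


def not_tested(kind: str = "IC50") -> PotencyResult:
    return PotencyResult(value=None, censored="not_tested", kind=kind)


def no_response(kind: str = "EC50") -> PotencyResult:
    return PotencyResult(value=None, censored="no_response", kind=kind)


@dataclass(frozen=True)
class StatConfig:
    alpha: float = 0.05
    comparison: str = "dunnett_vs_control"
    n_mc: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")


def _hill(x, bottom, top, log_ic50, slope, direction):
    expo = (x - log_ic50) * slope if direction == "decreasing" else (log_ic50 - x) * slope
    return bottom + (top - bottom) / (1.0 + 10.0 ** np.clip(expo, -300.0, 300.0))


def _clean_xy(conc, response):
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    mask = conc > 0
    return np.log10(conc[mask]), response[mask]


def fit_hill4(conc, response, direction: str = "decreasing") -> HillFit:
    """Least-squares 4-parameter Hill fit in log10-concentration space.

    Zero-concentration (vehicle) points anchor the normalization upstream
    and are excluded here because their abscissa is undefined.
    """
    if direction not in ("decreasing", "increasing"):
        raise DomainError(f"unknown direction {direction!r}")
    x, y = _clean_xy(conc, response)
    if len(np.unique(x)) < 4:
        raise ValidationError("need at least four distinct positive concentrations")

    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.ptp(y) < 1e-9:
        level = float(np.mean(y))
        return HillFit(bottom=level, top=level, log_ic50=float("nan"),
                       hill_slope=1.0, rss=0.0, converged=True, direction=direction)

    if direction == "decreasing":
        top0 = float(np.mean(y[:2]))
        bottom0 = float(np.min(y))
    else:
        bottom0 = float(np.mean(y[:2]))
        top0 = float(np.max(y))
    half = (top0 + bottom0) / 2.0
    crossing = y <= half if direction == "decreasing" else y >= half
    log_ic50_0 = float(x[np.argmax(crossing)]) if crossing.any() else float(x[-1])

    lo = [BOTTOM_BOUNDS[0], BOTTOM_BOUNDS[0], x[0] - 6.0, SLOPE_BOUNDS[0]]
    hi = [BOTTOM_BOUNDS[1], max(400.0, top0 * 2), x[-1] + 6.0, SLOPE_BOUNDS[1]]
    p0 = np.clip([bottom0, top0, log_ic50_0, 1.0], lo, hi)

    def residuals(p):
        return _hill(x, p[0], p[1], p[2], p[3], direction) - y

    sign = 1.0 if direction == "decreasing" else -1.0

    def jac(p):
        bottom, top, log_ic50, slope = p
        expo = np.clip(sign * (x - log_ic50) * slope, -300.0, 300.0)
        pw = 10.0**expo
        d = 1.0 + pw
        core = (top - bottom) * pw / d**2 * np.log(10.0)
        return np.column_stack([
            1.0 - 1.0 / d,
            1.0 / d,
            sign * slope * core,
            -sign * (x - log_ic50) * core,
        ])

    try:
        sol = optimize.least_squares(residuals, p0, jac=jac, bounds=(lo, hi),
                                     method="trf", xtol=1e-13, ftol=1e-13,
                                     gtol=1e-13, max_nfev=2000)
        bottom, top, log_ic50, slope = sol.x
        converged = bool(sol.success)
        rss = float(np.sum(sol.fun**2))
    except Exception:
        bottom, top, log_ic50, slope = p0
        converged = False
        rss = float(np.sum(residuals(p0) ** 2))
    if top < bottom:
        bottom, top = top, bottom
    return HillFit(bottom=float(bottom), top=float(top), log_ic50=float(log_ic50),
                   hill_slope=float(slope), rss=rss, converged=converged, direction=direction)


def ic50_from_fit(
    fit: HillFit,
    top_tested: float,
    min_effect: float = 50.0,
    flat_policy: str = "censor",
    flat_effect_pct: float = 20.0,
) -> PotencyResult:
    """Solve the fitted curve for response = ``min_effect`` % with censoring.

    A curve that never reaches the 50% level within the ladder, or whose
    crossing lies above the top tested concentration, is censored as
    ``"> log10(top_tested)"``. With ``flat_policy="nr"`` a fit whose total
    dynamic range is below ``flat_effect_pct`` is instead reported as NR
    (no response), matching the reporting split used for the permeabilized
    stage potencies.
    """
    top_log = float(np.log10(top_tested))
    censored = PotencyResult(value=top_log, censored="above_top_tested", kind="IC50")
    if flat_policy == "nr" and (fit.top - fit.bottom) < flat_effect_pct:
        return no_response(kind="IC50")
    if not np.isfinite(fit.log_ic50):
        return censored
    if not (fit.bottom < min_effect < fit.top):
        return censored
    q = (fit.top - fit.bottom) / (min_effect - fit.bottom) - 1.0
    if q <= 0:
        return censored
    if fit.direction == "decreasing":
        x50 = fit.log_ic50 + np.log10(q) / fit.hill_slope
    else:
        x50 = fit.log_ic50 - np.log10(q) / fit.hill_slope
    if x50 > top_log:
        return censored
    return PotencyResult(value=float(x50), censored="none", kind="IC50")


def ec50_pointwise(conc, response, n_grid: int = 1000, threshold: float = 50.0) -> PotencyResult:
    """Model-free EC50: first of ``n_grid`` log-spaced points whose
    piecewise-linear interpolated response reaches ``threshold`` %."""
    x, y = _clean_xy(conc, response)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if len(x) < 2:
        raise ValidationError("need at least two positive concentrations")
    grid = np.linspace(x[0], x[-1], n_grid)
    interp = np.interp(grid, x, y)
    above = interp >= threshold
    if not above.any():
        return no_response(kind="EC50")
    return PotencyResult(value=float(grid[np.argmax(above)]), censored="none", kind="EC50")


def dunnett_loec(groups, vehicle, concentrations, cfg: StatConfig | None = None):
    """Dunnett many-to-one comparisons against the vehicle and the LOEC.

    ``groups`` are per-concentration replicate arrays (ascending
    concentration order), compared against the ``vehicle`` replicates.
    The one-way ANOVA omnibus p-value is computed and returned for
    reporting, but the per-concentration flags come from the Dunnett
    adjustment alone, which controls the familywise error rate at
    ``alpha`` exactly (an ANOVA pre-gate would deflate it).
    Pooled-variance contract: the Dunnett statistic uses the pooled
    within-group variance; unequal spread is tolerated, not modelled.
    Returns ``(flags, loec, pvalues, anova_p)`` where ``loec`` is the
    lowest significant concentration (None if none).
    """
    cfg = cfg or StatConfig()
    groups = [np.asarray(g, dtype=float) for g in groups]
    vehicle = np.asarray(vehicle, dtype=float)
    concentrations = np.asarray(concentrations, dtype=float)
    if len(groups) != len(concentrations):
        raise ValidationError("one replicate group per concentration required")
    if len(vehicle) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("at least two replicates per group required")

    anova_p = float(stats.f_oneway(vehicle, *groups).pvalue)
    res = stats.dunnett(*groups, control=vehicle, rng=np.random.default_rng(cfg.seed))
    pvalues = np.asarray(res.pvalue, dtype=float)
    flags = pvalues < cfg.alpha
    loec = float(concentrations[flags][0]) if flags.any() else None
    return flags, loec, pvalues, anova_p
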