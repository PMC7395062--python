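import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mitoscreen.doseresponse import (
    StatConfig,
    dunnett_loec,
    ec50_pointwise,
    fit_hill4,
    ic50_from_fit,
    no_response,
    not_tested,
)
from mitoscreen.errors import ValidationError

LADDER = 1e-5 / 5.0 ** np.arange(7, -1, -1)
X = np.log10(LADDER)


def hill_curve(bottom, top, log_ic50, slope, x=X):
    return bottom + (top - bottom) / (1 + 10 ** ((x - log_ic50) * slope))


def grid_search_log_ic50(x, y, direction="decreasing"):
    """Independent oracle: profile the (log_ic50, slope) grid, solving the
    linear (bottom, top) sub-problem exactly at each node, then zoom."""
    lo, hi = x[0] - 1.0, x[-1] + 1.0
    best = None
    slopes = np.geomspace(0.1, 10.0, 80)
    for _ in range(5):
        ls = np.linspace(lo, hi, 81)
        for l in ls:
            for s in slopes:
                f = 1.0 / (1 + 10 ** ((x - l) * s))
                if direction == "increasing":
                    f = 1.0 - f
                basis = np.column_stack([1.0 - f, f])
                coef, rss, *_ = np.linalg.lstsq(basis, y, rcond=None)
                resid = y - basis @ coef
                r = float(resid @ resid)
                if best is None or r < best[0]:
                    best = (r, l, s)
        width = (hi - lo) / 10
        lo, hi = best[1] - width, best[1] + width
        slopes = np.geomspace(max(0.1, best[2] / 2), min(10, best[2] * 2), 40)
    return best[1]


class TestHillFit:
    def test_noise_free_self_consistency_and_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            bottom = rng.uniform(0, 30)
            top = rng.uniform(70, 110)
            logi = rng.uniform(-8.5, -6.0)
            slope = rng.uniform(0.5, 3.0)
            y = hill_curve(bottom, top, logi, slope)
            fit = fit_hill4(LADDER, y)
            assert abs(fit.log_ic50 - logi) < 1e-6
            oracle = grid_search_log_ic50(X, y)
            assert abs(fit.log_ic50 - oracle) < 5e-3  # oracle grid resolution

    def test_constant_response_gives_degenerate_converged_fit(self):
        fit = fit_hill4(LADDER, np.full(8, 100.0))
        assert fit.converged
        assert fit.top == fit.bottom == pytest.approx(100.0)
        res = ic50_from_fit(fit, LADDER.max())
        assert res.censored == "above_top_tested"

    def test_noisy_median_recovery(self):
        rng = np.random.default_rng(3)
        recovered = []
        for _ in range(100):
            y = hill_curve(0, 100, -6.5, 1.5) * rng.normal(1.0, 0.03, size=8)
            recovered.append(fit_hill4(LADDER, y).log_ic50)
        assert abs(np.median(recovered) - (-6.5)) < 0.1

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            fit_hill4(LADDER[:3], np.ones(3) * 50)


class TestIC50:
    def test_symmetric_curve_midpoint(self):
        fit = fit_hill4(LADDER, hill_curve(0, 100, -6.0, 1.0))
        res = ic50_from_fit(fit, LADDER.max())
        assert res.value == pytest.approx(-6.0, abs=1e-6)
        assert res.display == "-6.00"

    def test_asymmetric_curve_crossing_differs_from_log_ic50(self):
        # bottom 20, top 100: the 50% crossing sits below the inflection
        fit = fit_hill4(LADDER, hill_curve(20, 100, -6.0, 1.0))
        res = ic50_from_fit(fit, LADDER.max())
        expected = -6.0 + np.log10(80 / 30 - 1)
        assert res.value == pytest.approx(expected, abs=1e-6)

    def test_flat_curve_censors_above_top(self):
        fit = fit_hill4(LADDER, np.full(8, 99.0) + np.linspace(0, 0.5, 8))
        res = ic50_from_fit(fit, 1e-5)
        assert res.display == "> -5.00"

    def test_flat_policy_nr_for_stage_reporting(self):
        fit = fit_hill4(LADDER, np.full(8, 100.0))
        assert ic50_from_fit(fit, 1e-5, flat_policy="nr").display == "NR"

    @settings(max_examples=30, deadline=None)
    @given(logi=st.floats(min_value=-4.5, max_value=-2.0))
    def test_censoring_monotonic_beyond_ladder(self, logi):
        """Any true potency beyond the ladder renders the same censored display."""
        y = hill_curve(0, 100, logi, 2.0)
        res = ic50_from_fit(fit_hill4(LADDER, y), LADDER.max())
        assert res.censored == "above_top_tested"
        assert res.display == "> -5.00"

    def test_display_conventions(self):
        assert not_tested().display == "NT"
        assert no_response().display == "NR"


class TestPointwiseEC50:
    def test_linear_midpoint(self):
        res = ec50_pointwise([1e-7, 1e-5], [0.0, 100.0])
        assert res.value == pytest.approx(-6.0, abs=0.01)

    def test_collinear_interior_points_do_not_move_it(self):
        base = ec50_pointwise([1e-7, 1e-5], [0.0, 100.0])
        dense = ec50_pointwise([1e-7, 1e-6, 1e-5], [0.0, 50.0, 100.0])
        assert dense.value == pytest.approx(base.value, abs=0.01)

    def test_monotone_curve_recovery_within_grid_step(self):
        conc = LADDER
        true = -6.3
        resp = 100 / (1 + 10 ** ((true - np.log10(conc)) * 2.0))
        res = ec50_pointwise(conc, resp)
        # piecewise-linear interpolation error is bounded by the ladder
        # spacing (0.7 log units between points), not the fine grid step
        assert abs(res.value - true) <= 0.1

    def test_all_zero_response_is_nr(self):
        res = ec50_pointwise(LADDER, np.zeros(8))
        assert res.display == "NR"


class TestDunnett:
    def test_effect_only_at_top_concentration(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(100, 5, 4) for _ in range(7)] + [rng.normal(75, 5, 4)]
        vehicle = rng.normal(100, 5, 6)
        flags, loec, pvals, anova_p = dunnett_loec(groups, vehicle, LADDER,
                                                   StatConfig(seed=1))
        assert flags[-1]
        assert loec == pytest.approx(LADDER[-1])
        assert anova_p < 0.05

    def test_single_replicate_groups_rejected(self):
        with pytest.raises(ValidationError):
            dunnett_loec([[1.0]] * 8, [100.0, 101.0], LADDER)

    def test_adjustment_never_creates_significance(self):
        """Dunnett-significant concentrations are a subset of unadjusted t-test hits."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            groups = [rng.normal(100, 10, 3) for _ in range(6)]
            vehicle = rng.normal(100, 10, 6)
            flags, _loec, pvals, _ = dunnett_loec(groups, vehicle, LADDER[:6],
                                                  StatConfig(seed=2))
            for g, flag in zip(groups, flags):
                if flag:
                    assert stats.ttest_ind(g, vehicle).pvalue < 0.05
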