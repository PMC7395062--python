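import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_compound
from mitoscreen.errors import DomainError, ScheduleError, ValidationError
from mitoscreen.simulate import (
    HEPG2,
    RPTEC,
    InjectionSchedule,
    NoiseModel,
    complex_assay_expected,
    hill_fraction,
    mitostress_expected,
    simulate_complex_assay_plate,
    simulate_endpoint_panel,
    simulate_mitostress_plate,
)

NOISELESS = NoiseModel(cv=0.0, well_scale_sd=0.0, seed=0)


class TestHillFraction:
    def test_midpoint(self):
        assert hill_fraction(1e-6, 1e-6, 1.7) == pytest.approx(0.5)

    def test_zero_dose(self):
        assert hill_fraction(0.0, 1e-6, 2.0) == 0.0

    def test_25x_ic50_unit_slope(self):
        assert hill_fraction(25e-6, 1e-6, 1.0) == pytest.approx(25 / 26, abs=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            hill_fraction(-1e-9, 1e-6, 1.0)


class TestMitostressFluxModel:
    def test_vehicle_fccp_reaches_configured_maximal(self, panel, intact_series):
        traces = simulate_mitostress_plate(panel, intact_series, HEPG2, noise=NOISELESS)
        vehicle = next(t for t in traces if t.compound == "vehicle")
        basal = np.mean(vehicle.phase_values("baseline"))
        fccp = np.max(vehicle.phase_values("fccp")) / basal * 100
        assert fccp == pytest.approx(159.4)

    def test_saturating_ci_inhibitor_hits_nonmito_floor(self):
        exp = mitostress_expected("inhibitor", 1.0, HEPG2)
        ocr, ecar = exp["compound"]
        assert ocr == pytest.approx(HEPG2.nonmito_pct)
        assert ecar == pytest.approx(1.0)  # glycolytic ceiling

    def test_uncoupler_raises_basal_and_resists_oligomycin(self):
        exp = mitostress_expected("uncoupler", 1.0, RPTEC)
        assert exp["compound"][0] == pytest.approx(RPTEC.maximal_ocr_pct)
        # oligomycin cannot suppress uncoupled respiration below basal
        assert exp["oligomycin"][0] > 100.0

    def test_vehicle_decomposition_identity(self):
        exp = mitostress_expected("inactive", 0.0, HEPG2)
        atp_linked = exp["compound"][0] - exp["oligomycin"][0]
        leak = exp["oligomycin"][0] - exp["rot_aa"][0]
        assert atp_linked + leak + exp["rot_aa"][0] == pytest.approx(100.0)

    @settings(max_examples=40, deadline=None)
    @given(occ=st.floats(min_value=0.0, max_value=1.0))
    def test_inhibitor_phase_ordering(self, occ):
        exp = mitostress_expected("inhibitor", occ, HEPG2)
        assert exp["compound"][0] >= exp["oligomycin"][0] - 1e-9
        assert exp["fccp"][0] >= exp["oligomycin"][0] - 1e-9

    @settings(max_examples=20, deadline=None)
    @given(data=st.data())
    def test_dose_monotonicity(self, data):
        lo = data.draw(st.floats(min_value=1e-9, max_value=1e-6))
        hi = data.draw(st.floats(min_value=1e-6, max_value=1e-4))
        a_lo = hill_fraction(lo, 1e-6, 2.0)
        a_hi = hill_fraction(max(lo, hi), 1e-6, 2.0)
        inh_lo = mitostress_expected("inhibitor", a_lo, HEPG2)["compound"][0]
        inh_hi = mitostress_expected("inhibitor", a_hi, HEPG2)["compound"][0]
        assert inh_hi <= inh_lo + 1e-9
        unc_lo = mitostress_expected("uncoupler", a_lo, HEPG2)["compound"][0]
        unc_hi = mitostress_expected("uncoupler", a_hi, HEPG2)["compound"][0]
        assert unc_hi >= unc_lo - 1e-9

    def test_schedule_missing_phase_rejected(self, panel, intact_series):
        bad = InjectionSchedule(phases=(("baseline", "none", 3, 6.0),))
        with pytest.raises(ScheduleError):
            simulate_mitostress_plate(panel, intact_series, HEPG2, schedule=bad)

    def test_determinism(self, panel, intact_series):
        noise = NoiseModel(cv=0.05, well_scale_sd=0.05, seed=42)
        a = simulate_mitostress_plate(panel, intact_series, HEPG2, noise=noise)
        b = simulate_mitostress_plate(panel, intact_series, HEPG2, noise=noise)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.ocr, tb.ocr) and np.array_equal(ta.ecar, tb.ecar)


class TestComplexAssayModel:
    # saturating stage patterns, oracle: direct evaluation of the g-products
    @pytest.mark.parametrize(
        "mechanism,target,expected_pattern",
        [
            ("inhibitor", "CI", (0.0, 1.0, 1.0)),
            ("inhibitor", "CII", (1.0, 0.0, 1.0)),
            ("inhibitor", "CIII", (0.0, 0.0, 1.0)),
            ("downstream_inhibitor", "CI", (0.0, 0.0, 0.0)),
            ("uncoupler", "CIII", (1.0, 1.0, 1.0)),
            ("inactive", "CI", (1.0, 1.0, 1.0)),
        ],
    )
    def test_saturating_stage_patterns(self, mechanism, target, expected_pattern):
        exp = complex_assay_expected(mechanism, target, 1.0)
        vehicle = complex_assay_expected("inactive", target, 0.0)
        got = tuple(exp[s] / vehicle[s] for s in ("stage1", "stage2", "stage3"))
        assert got == pytest.approx(expected_pattern, abs=1e-12)

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValidationError):
            complex_assay_expected("osmotic", "CI", 0.5)

    def test_plate_contains_vehicle_and_all_ladder_points(self, panel, extended_series):
        traces = simulate_complex_assay_plate(panel, extended_series, noise=NOISELESS)
        vehicles = [t for t in traces if t.compound == "vehicle"]
        assert len(vehicles) == 6
        concs = {t.conc for t in traces if t.compound == panel[0].name}
        assert concs == set(extended_series.values)


class TestEndpointPanel:
    def test_glucose_rescue_keeps_hepg2_viability_flat(self, intact_series):
        ci = make_compound(potency=-6.5)
        table = simulate_endpoint_panel([ci], intact_series, HEPG2, "glucose",
                                        noise=NOISELESS)
        res = table[table.endpoint == "resazurin"]["mean_pct"]
        assert (res > 99.0).all()

    def test_galactose_unmasks_hepg2_viability(self, intact_series):
        ci = make_compound(potency=-6.5)
        table = simulate_endpoint_panel([ci], intact_series, HEPG2, "galactose",
                                        noise=NOISELESS)
        res = table[table.endpoint == "resazurin"].sort_values("conc_M")["mean_pct"]
        assert res.iloc[-1] < 10.0  # near-complete kill at the top dose

    def test_inactive_compound_leaves_all_endpoints_at_control(self, intact_series):
        null = make_compound(mechanism="inactive", potency=-6.0)
        table = simulate_endpoint_panel([null], intact_series, HEPG2, noise=NOISELESS)
        assert (table[table.endpoint == "resazurin"].mean_pct == 100).all()
        assert (table[table.endpoint == "lactate"].mean_pct == 100).all()
        assert (table[table.endpoint == "mmp"].mean_pct == 100).all()
        assert (table[table.endpoint == "pi"].mean_pct == 0).all()

    def test_cii_inhibitor_is_masked_in_intact_endpoints(self, intact_series):
        cii = make_compound(target="CII", potency=-5.5)
        table = simulate_endpoint_panel([cii], intact_series, HEPG2, "galactose",
                                        noise=NOISELESS)
        assert (table[table.endpoint == "resazurin"].mean_pct == 100).all()
        assert (table[table.endpoint == "mmp"].mean_pct == 100).all()

    def test_repeated_exposure_increases_potency(self, intact_series):
        ci = make_compound(potency=-5.2)
        one = simulate_endpoint_panel([ci], intact_series, HEPG2, "galactose",
                                      exposures=1, noise=NOISELESS)
        five = simulate_endpoint_panel([ci], intact_series, HEPG2, "galactose",
                                       exposures=5, noise=NOISELESS)
        pi_one = one[one.endpoint == "pi"].sort_values("conc_M")["mean_pct"].to_numpy()
        pi_five = five[five.endpoint == "pi"].sort_values("conc_M")["mean_pct"].to_numpy()
        assert (pi_five >= pi_one).all() and pi_five.sum() > pi_one.sum()

    def test_bad_exposures_rejected(self, panel, intact_series):
        with pytest.raises(DomainError):
            simulate_endpoint_panel(panel, intact_series, HEPG2, exposures=0)
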