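import numpy as np
import pytest
from dataclasses import replace

from tofasim import (
    DosingRegimen,
    IR_TABLET,
    bateman_concentration,
    elimination_breakdown,
    fluconazole,
    interaction_state,
    ketoconazole,
    perpetrator_exposure,
    rifampicin,
    run_ddi,
    simulate,
)
from tofasim.ddi import InteractionState, PerpetratorModel, _induction_trace


class TestPerpetratorExposure:
    def test_zero_dose_gives_zero_trace(self):
        model = replace(fluconazole(), daily_doses_mg=(0.0,), loading_dose_mg=None)
        _, cu = perpetrator_exposure(model, 48.0)
        assert np.all(cu == 0.0)

    def test_single_dose_matches_bateman(self):
        model = replace(ketoconazole(), daily_doses_mg=(400.0,))
        t, cu = perpetrator_exposure(model, 20.0)  # one dose only within 20 h
        ref = bateman_concentration(t, 400.0, model.ka, model.v_l, model.cl_l_h)
        ref_u = ref * 1000.0 / model.mw * model.fu
        assert np.allclose(cu, ref_u, rtol=1e-12, atol=1e-15)

    def test_daily_troughs_accumulate_to_plateau(self):
        model = fluconazole()
        t, cu = perpetrator_exposure(model, 24.0 * 10)
        troughs = [cu[np.searchsorted(t, 24.0 * d) - 1] for d in range(2, 10)]
        assert all(b >= a - 1e-9 for a, b in zip(troughs, troughs[1:]))


class TestInteractionState:
    def test_no_exposure_means_unit_activity(self):
        t = np.linspace(0, 48, 100)
        st = interaction_state(t, np.zeros_like(t), fluconazole())
        a3, a2 = st(10.0)
        assert a3 == 1.0 and a2 == 1.0

    def test_competitive_inhibition_at_ki_halves_activity(self):
        model = fluconazole()
        t = np.linspace(0, 10, 50)
        cu = np.full_like(t, model.ki["CYP3A4"])
        st = interaction_state(t, cu, model)
        a3, _ = st(5.0)
        assert a3 == pytest.approx(0.5, rel=1e-9)

    def test_induction_saturates_at_one_plus_emax(self):
        model = rifampicin()
        emax, ec50 = model.induction["CYP3A4"]
        t = np.linspace(0, 2000.0, 4000)  # many enzyme turnover half-lives
        cu = np.full_like(t, ec50 * 1e6)  # far above EC50
        e = _induction_trace(t, cu, emax, ec50, model.enzyme_turnover_kdeg)
        assert e[-1] == pytest.approx(1.0 + emax, rel=1e-3)

    def test_inhibition_bounded_and_induction_above_one(self):
        t, cu = perpetrator_exposure(rifampicin(), 24.0 * 10)
        st = interaction_state(t, cu, rifampicin())
        assert np.all(st.activities["CYP3A4"] >= 1.0 - 1e-12)
        t2, cu2 = perpetrator_exposure(fluconazole(), 24.0 * 5)
        st2 = interaction_state(t2, cu2, fluconazole())
        for enz in ("CYP3A4", "CYP2C19"):
            assert np.all(st2.activities[enz] <= 1.0)
            assert np.all(st2.activities[enz] > 0.0)

    def test_missing_enzyme_trace_rejected(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(KeyError):
            InteractionState(t, {"CYP3A4": np.ones_like(t)})


class TestRunDDI:
    def test_zero_perpetrator_dose_gives_unit_ratios(self):
        model = replace(fluconazole(), daily_doses_mg=(0.0,), loading_dose_mg=None)
        r = run_ddi(model, victim_dose_mg=5.0, pretreatment_days=2)
        assert r.aucr == pytest.approx(1.0, abs=1e-9)
        assert r.cmaxr == pytest.approx(1.0, abs=1e-9)

    def test_inhibitor_aucr_monotone_in_dose(self):
        base = ketoconazole()
        ratios = []
        for dose in (100.0, 400.0):
            model = replace(base, daily_doses_mg=(dose,))
            ratios.append(run_ddi(model, victim_dose_mg=5.0, pretreatment_days=3).aucr)
        assert ratios[0] < ratios[1]

    def test_inducer_aucr_monotone_in_dose(self):
        base = rifampicin()
        ratios = []
        for dose in (150.0, 600.0):
            model = replace(base, daily_doses_mg=(dose,))
            ratios.append(run_ddi(model, victim_dose_mg=5.0, pretreatment_days=6).aucr)
        assert ratios[0] > ratios[1]

    def test_pure_cyp3a4_inhibitor_bounded_by_complete_inhibition(
        self, single_dose_5mg
    ):
        bd = elimination_breakdown(single_dose_5mg)
        r = run_ddi(ketoconazole(), victim_dose_mg=5.0, pretreatment_days=5)
        assert 1.0 < r.aucr <= 1.0 / (1.0 - bd.f_cyp3a4) + 0.05

    def test_dynamic_aucr_close_to_static_well_stirred_estimate(
        self, ref_adult, compound, single_dose_5mg
    ):
        """The dynamic co-simulation should sit near the static estimate
        AUCR ~ 1 / (sum_p f_p / IF_p) using interaction factors averaged over
        the victim exposure window."""
        model = fluconazole()
        days = 5
        t, cu = perpetrator_exposure(model, days * 24.0 + 48.0)
        st = interaction_state(t, cu, model)
        window = (t >= days * 24.0) & (t <= days * 24.0 + 24.0)
        if3 = float(np.mean(st.activities["CYP3A4"][window]))
        if2 = float(np.mean(st.activities["CYP2C19"][window]))
        bd = elimination_breakdown(single_dose_5mg)
        static = 1.0 / (bd.f_cyp3a4 * if3 + bd.f_cyp2c19 * if2 + bd.f_renal)
        dynamic = run_ddi(model, victim_dose_mg=5.0, pretreatment_days=days).aucr
        assert dynamic == pytest.approx(static, rel=0.25)


class TestPerpetratorValidation:
    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            PerpetratorModel("x", mw=300.0, ka=1.0, v_l=50.0, cl_l_h=5.0, fu=0.5,
                             ki={"CYP3A4": -1.0})
        with pytest.raises(ValueError):
            PerpetratorModel("x", mw=300.0, ka=1.0, v_l=50.0, cl_l_h=5.0, fu=0.5,
                             induction={"CYP3A4": (2.0, 0.0)})
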