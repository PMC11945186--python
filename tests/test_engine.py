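import numpy as np
import pytest

from tofasim import (
    DosingRegimen,
    FAST_SOLVER,
    FED_TABLET,
    IR_TABLET,
    ORAL_SOLUTION,
    XR_TABLET,
    bateman_concentration,
    elimination_breakdown,
    oral_bioavailability,
    simulate,
    simulate_reduced,
    steady_state_profile,
)
from tofasim.engine import SolverSettings


def auc(res):
    return float(np.trapezoid(res.plasma_conc, res.time))


class TestMassBalanceAndBasics:
    def test_mass_balance_within_tenth_of_percent(self, single_dose_5mg):
        assert single_dose_5mg.mass_balance_residual() < 1e-3

    def test_mass_balance_multidose_xr(self, ref_adult, compound):
        reg = DosingRegimen(11.0, XR_TABLET, schedule="QD", n_doses=3)
        res = simulate(ref_adult, compound, reg, 96.0)
        assert res.mass_balance_residual() < 1e-3

    def test_zero_dose_gives_zero_profile(self, ref_adult, compound):
        res = simulate(ref_adult, compound, DosingRegimen(0.0, IR_TABLET), 24.0)
        assert np.all(res.plasma_conc == 0.0)

    def test_trajectories_non_negative(self, single_dose_5mg):
        res = single_dose_5mg
        assert np.all(res.plasma_conc >= 0)
        for series in res.organ_amounts.values():
            assert np.all(series >= -1e-9)

    def test_duration_must_cover_doses(self, ref_adult, compound):
        reg = DosingRegimen(5.0, IR_TABLET, schedule="BID", n_doses=4)
        with pytest.raises(ValueError):
            simulate(ref_adult, compound, reg, 20.0)


class TestReducedModeOracle:
    def test_matches_bateman_closed_form(self):
        ka, v, cl = 1.2, 90.0, 20.0
        t, c = simulate_reduced(10.0, ka, v, cl, 48.0)
        ref = bateman_concentration(t, 10.0, ka, v, cl)
        mask = ref > ref.max() * 1e-6
        rel = np.abs(c[mask] - ref[mask]) / ref[mask]
        assert rel.max() < 0.005

    def test_equal_rate_constants_limit(self):
        t, c = simulate_reduced(10.0, 0.5, 100.0, 50.0, 24.0)
        ref = bateman_concentration(t, 10.0, 0.5, 100.0, 50.0)
        assert np.allclose(c, ref, rtol=0.005, atol=1e-9)


class TestDisposition:
    def test_oral_bioavailability_near_three_quarters(self, ref_adult, compound):
        f = oral_bioavailability(ref_adult, compound)
        assert f == pytest.approx(0.74, abs=0.05)

    def test_pathway_fractions(self, single_dose_5mg):
        bd = elimination_breakdown(single_dose_5mg)
        assert bd.f_cyp3a4 + bd.f_cyp2c19 + bd.f_renal == pytest.approx(1.0, abs=1e-6)
        assert bd.f_cyp3a4 == pytest.approx(0.53, abs=0.02)
        assert bd.f_cyp2c19 == pytest.approx(0.16, abs=0.02)
        assert bd.f_renal == pytest.approx(0.29, abs=0.02)

    def test_no_metabolism_means_all_renal(self, ref_adult, compound):
        c = compound.with_params(kcat_cyp3a4=0.0, clspec_cyp2c19=0.0)
        res = simulate(ref_adult, c, DosingRegimen(5.0, IR_TABLET), 240.0)
        bd = elimination_breakdown(res)
        assert bd.f_renal == pytest.approx(1.0, abs=1e-9)

    def test_doubling_secretion_raises_renal_fraction(
        self, ref_adult, compound, single_dose_5mg
    ):
        base = elimination_breakdown(single_dose_5mg)
        c = compound.with_params(ts_spec=2 * compound.ts_spec)
        res = simulate(ref_adult, c, DosingRegimen(5.0, IR_TABLET), 120.0)
        assert elimination_breakdown(res).f_renal > base.f_renal

    def test_incomplete_elimination_raises(self, ref_adult, compound):
        res = simulate(ref_adult, compound, DosingRegimen(5.0, IR_TABLET), 6.0)
        with pytest.raises(ValueError, match="residual"):
            elimination_breakdown(res)

    def test_dose_normalized_auc_flat_over_clinical_range(self, ref_adult, compound):
        norm = []
        for dose in (0.3, 5.0, 30.0, 100.0):
            res = simulate(
                ref_adult, compound, DosingRegimen(dose, IR_TABLET), 120.0,
                solver=FAST_SOLVER,
            )
            norm.append(auc(res) / dose)
        spread = (max(norm) - min(norm)) / min(norm)
        assert spread < 0.10


class TestFormulationsAndSchedules:
    def test_tmax_ordering_across_formulations(self, ref_adult, compound):
        tmax = {}
        for name, form in (("sol", ORAL_SOLUTION), ("IR", IR_TABLET), ("XR", XR_TABLET)):
            res = simulate(ref_adult, compound, DosingRegimen(5.0, form), 48.0)
            tmax[name] = res.time[int(np.argmax(res.plasma_conc))]
        assert tmax["sol"] <= tmax["IR"] < tmax["XR"]

    def test_steady_state_matches_superposition(self, ref_adult, compound, single_dose_5mg):
        reg = DosingRegimen(5.0, IR_TABLET, schedule="BID", n_doses=6)
        ss = steady_state_profile(ref_adult, compound, reg)
        assert auc(ss) == pytest.approx(auc(single_dose_5mg), rel=0.01)

    def test_accumulation_ratio_exceeds_one(self, ref_adult, compound):
        reg = DosingRegimen(5.0, IR_TABLET, schedule="BID", n_doses=6)
        res = simulate(ref_adult, compound, reg, 72.0, solver=FAST_SOLVER)
        first = res.time <= 12.0
        last = res.time >= 60.0
        auc_first = np.trapezoid(res.plasma_conc[first], res.time[first])
        auc_last = np.trapezoid(res.plasma_conc[last], res.time[last])
        assert auc_last / auc_first > 1.0

    def test_dose_doubling_doubles_steady_state_auc(self, ref_adult, compound):
        def ss_auc(dose):
            reg = DosingRegimen(dose, IR_TABLET, schedule="BID", n_doses=6)
            return auc(steady_state_profile(ref_adult, compound, reg, solver=FAST_SOLVER))

        assert ss_auc(10.0) / ss_auc(5.0) == pytest.approx(2.0, rel=0.02)


class TestSolverRobustness:
    def test_tolerance_tightening_leaves_auc_unchanged(self, ref_adult, compound):
        reg = DosingRegimen(5.0, IR_TABLET)
        a = auc(simulate(ref_adult, compound, reg, 96.0))
        tight = SolverSettings(rtol=1e-9, atol=1e-11)
        b = auc(simulate(ref_adult, compound, reg, 96.0, solver=tight))
        assert abs(a / b - 1.0) < 1e-3

    def test_runtime_is_interactive(self, ref_adult, compound):
        import time

        start = time.perf_counter()
        simulate(ref_adult, compound, DosingRegimen(5.0, IR_TABLET), 120.0)
        assert time.perf_counter() - start < 5.0
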