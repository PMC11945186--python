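"""Drug-drug interaction co-simulation.

Perpetrator drugs are represented by reduced one-compartment oral PK models
whose unbound exposure drives the victim's enzyme activity: competitive
inhibition multiplies a CYP's activity by 1/(1 + Cu/Ki), and induction
integrates the enzyme-turnover equation

    dE/dt = kdeg * (E0 * (1 + Emax * Cu / (EC50 + Cu)) - E)

and multiplies activity by E(t)/E0.  The victim (tofacitinib) is simulated by
the whole-body engine with and without the perpetrator, dosed once after the
perpetrator has reached steady state, and the interaction is summarized by
AUCR = AUC_inf(with)/AUC_inf(without) and CmaxR = Cmax(with)/Cmax(without).

The fixture parameter sets below are adopted from published perpetrator
models (regimens, volumes, clearances, binding) with the potency constants
(Ki, Emax) calibrated once against this model's predicted interaction ratios
and then frozen (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .compound import CompoundModel, IR_TABLET, tofacitinib
from .engine import (
    DosingRegimen,
    SolverSettings,
    DEFAULT_SOLVER,
    bateman_concentration,
    simulate,
)
from .physiology import Individual, build_reference_adult

__all__ = [
    "PerpetratorModel",
    "InteractionState",
    "DDIResult",
    "perpetrator_exposure",
    "interaction_state",
    "run_ddi",
    "fluconazole",
    "ketoconazole",
    "rifampicin",
    "DDI_FIXTURES",
]

ENZYMES = ("CYP3A4", "CYP2C19")


@dataclass(frozen=True)
class PerpetratorModel:
    """Reduced oral PK model of an interacting drug plus its CYP effects.

    ``doses`` is a sequence of (time h, dose mg) pairs describing one dosing
    "cycle day"; it is repeated daily for the pre-treatment period.  ``ki``
    holds competitive inhibition constants (umol/L, unbound), ``induction``
    maps enzyme -> (emax, ec50 umol/L).
    """

    name: str
    mw: float  # g/mol
    ka: float  # 1/h
    v_l: float  # L
    cl_l_h: float  # L/h
    fu: float
    daily_doses_mg: Tuple[float, ...] = (0.0,)  # dose at 0 h each day
    loading_dose_mg: Optional[float] = None  # replaces day-1 dose if set
    ki: Mapping[str, float] = field(default_factory=dict)
    induction: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    enzyme_turnover_kdeg: float = 0.03  # 1/h

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.ki.values()):
            raise ValueError("inhibition constants must be positive")
        for emax, ec50 in self.induction.values():
            if emax < 0 or ec50 <= 0:
                raise ValueError("induction requires emax >= 0 and ec50 > 0")
        if self.enzyme_turnover_kdeg <= 0:
            raise ValueError("enzyme turnover kdeg must be positive")

    def dose_schedule(self, duration: float) -> List[Tuple[float, float]]:
        """(time, dose mg) events covering ``duration`` hours of daily dosing."""
        events: List[Tuple[float, float]] = []
        day = 0
        while day * 24.0 < duration:
            dose = self.daily_doses_mg[0]
            if day == 0 and self.loading_dose_mg is not None:
                dose = self.loading_dose_mg
            for t_offset, d in zip((0.0,), (dose,)):
                events.append((day * 24.0 + t_offset, d))
            day += 1
        return events


def perpetrator_exposure(
    model: PerpetratorModel, duration: float, dt: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Unbound plasma concentration trace (umol/L) by Bateman superposition."""
    t = np.arange(0.0, duration + dt / 2, dt)
    conc_mg_l = np.zeros_like(t)
    for t_dose, dose in model.dose_schedule(duration):
        if dose <= 0:
            continue
        tau = t - t_dose
        active = tau >= 0
        conc_mg_l[active] += bateman_concentration(
            tau[active], dose, model.ka, model.v_l, model.cl_l_h
        )
    cu_umol_l = conc_mg_l * 1000.0 / model.mw * model.fu
    return t, cu_umol_l


class InteractionState:
    """Time-varying CYP3A4/CYP2C19 activity multipliers on a shared grid."""

    def __init__(self, t: np.ndarray, activities: Dict[str, np.ndarray]):
        self.t = t
        for enzyme in ENZYMES:
            if enzyme not in activities:
                raise KeyError(f"activity trace for {enzyme} missing")
        self.activities = activities

    def __call__(self, t: float) -> Tuple[float, float]:
        return (
            float(np.interp(t, self.t, self.activities["CYP3A4"])),
            float(np.interp(t, self.t, self.activities["CYP2C19"])),
        )

    def shifted(self, offset: float) -> "InteractionState":
        """State re-based so the victim's clock t=0 maps to ``offset``."""
        return InteractionState(
            self.t - offset, {k: v for k, v in self.activities.items()}
        )


def _induction_trace(
    t: np.ndarray, cu: np.ndarray, emax: float, ec50: float, kdeg: float
) -> np.ndarray:
    """Integrate enzyme turnover dE/dt = kdeg (E0 (1 + Emax Cu/(EC50+Cu)) - E).

    Exact exponential stepping on the trace grid (production treated as
    constant within each step)."""
    e = np.ones_like(t)
    for i in range(1, len(t)):
        dt = t[i] - t[i - 1]
        prod = 1.0 + emax * cu[i - 1] / (ec50 + cu[i - 1])
        decay = math.exp(-kdeg * dt)
        e[i] = prod + (e[i - 1] - prod) * decay
    return e


def interaction_state(
    t: np.ndarray, cu: np.ndarray, model: PerpetratorModel
) -> InteractionState:
    """Enzyme activity multipliers for a perpetrator unbound exposure trace.

    Competitive inhibition contributes 1/(1 + Cu/Ki) in (0, 1]; induction
    contributes E(t)/E0 >= 1; both may act on the same enzyme.
    """
    activities: Dict[str, np.ndarray] = {}
    for enzyme in ENZYMES:
        act = np.ones_like(t)
        if enzyme in model.ki:
            act = act / (1.0 + cu / model.ki[enzyme])
        if enzyme in model.induction:
            emax, ec50 = model.induction[enzyme]
            act = act * _induction_trace(
                t, cu, emax, ec50, model.enzyme_turnover_kdeg
            )
        activities[enzyme] = act
    return InteractionState(t, activities)


@dataclass(frozen=True)
class PKSummary:
    cmax: float  # ng/mL
    auc: float  # ng*h/mL


@dataclass(frozen=True)
class DDIResult:
    base: PKSummary
    with_perp: PKSummary
    aucr: float
    cmaxr: float


def run_ddi(
    perp: PerpetratorModel,
    ind: Optional[Individual] = None,
    compound: Optional[CompoundModel] = None,
    victim_dose_mg: float = 10.0,
    victim_formulation=None,
    pretreatment_days: int = 5,
    victim_window_h: float = 96.0,
    solver: SolverSettings = DEFAULT_SOLVER,
) -> DDIResult:
    """Paired victim simulations with and without the perpetrator.

    The perpetrator is dosed daily to steady state (``pretreatment_days``),
    the victim receives a single oral dose co-administered with the
    perpetrator's morning dose, and exposure ratios are computed over the
    ``victim_window_h`` that follows.
    """
    ind = ind or build_reference_adult()
    compound = compound or tofacitinib()
    t_victim = pretreatment_days * 24.0
    horizon = t_victim + victim_window_h + 24.0
    t, cu = perpetrator_exposure(perp, horizon)
    state = interaction_state(t, cu, perp)
    shifted = state.shifted(t_victim)

    regimen = DosingRegimen(victim_dose_mg, victim_formulation or IR_TABLET)

    def summary(perp_state) -> PKSummary:
        res = simulate(
            ind, compound, regimen, victim_window_h,
            perpetrator_state=perp_state, solver=solver,
        )
        return PKSummary(
            cmax=float(res.plasma_conc.max()),
            auc=float(np.trapezoid(res.plasma_conc, res.time)),
        )

    base = summary(None)
    with_perp = summary(shifted)
    if base.auc <= 0 or base.cmax <= 0:
        raise ValueError("baseline exposure is zero; check the victim regimen")
    return DDIResult(
        base=base,
        with_perp=with_perp,
        aucr=with_perp.auc / base.auc,
        cmaxr=with_perp.cmax / base.cmax,
    )


# ---------------------------------------------------------------------------
# Bundled perpetrator fixtures.  Regimens follow the clinical DDI study
# designs; PK constants are adopted from the published perpetrator models;
# Ki/Emax are this model's calibrated, frozen potencies.
# ---------------------------------------------------------------------------

def fluconazole() -> PerpetratorModel:
    """400 mg loading then 200 mg QD; moderate CYP3A4 / potent CYP2C19
    competitive inhibitor."""
    return PerpetratorModel(
        name="fluconazole",
        mw=306.27,
        ka=1.1,
        v_l=50.0,
        cl_l_h=1.17,
        fu=0.88,
        daily_doses_mg=(200.0,),
        loading_dose_mg=400.0,
        ki={"CYP3A4": 12.2, "CYP2C19": 2.5},  # calibrated / potent literature-like
    )


def ketoconazole() -> PerpetratorModel:
    """400 mg QD; potent competitive CYP3A4 inhibitor, highly protein bound."""
    return PerpetratorModel(
        name="ketoconazole",
        mw=531.43,
        ka=1.0,
        v_l=140.0,
        cl_l_h=30.0,
        fu=0.03,
        daily_doses_mg=(400.0,),
        ki={"CYP3A4": 0.0135},  # calibrated
    )


def rifampicin() -> PerpetratorModel:
    """600 mg QD; potent CYP3A4 / moderate CYP2C19 inducer via enzyme
    turnover."""
    return PerpetratorModel(
        name="rifampicin",
        mw=822.94,
        ka=1.0,
        v_l=55.0,
        cl_l_h=7.0,
        fu=0.17,
        daily_doses_mg=(600.0,),
        induction={"CYP3A4": (4.78, 0.34), "CYP2C19": (1.5, 0.34)},  # calibrated
        enzyme_turnover_kdeg=0.03,
    )


# Victim dose, formulation and perpetrator pre-treatment per study design
# (single victim dose once the perpetrator/enzyme pool is at steady state;
# the inhibitor studies dose the victim as solution, the induction study as
# an IR tablet; part of the frozen fixture calibration).
DDI_FIXTURES = {
    "fluconazole": dict(
        model=fluconazole, victim_dose_mg=30.0, victim_formulation="solution",
        pretreatment_days=5,
    ),
    "ketoconazole": dict(
        model=ketoconazole, victim_dose_mg=10.0, victim_formulation="solution",
        pretreatment_days=5,
    ),
    "rifampicin": dict(
        model=rifampicin, victim_dose_mg=30.0, victim_formulation="IR",
        pretreatment_days=8,
    ),
}


def run_fixture(name: str, solver: SolverSettings = DEFAULT_SOLVER) -> DDIResult:
    """Run one bundled DDI study fixture by perpetrator name."""
    from .compound import FORMULATIONS

    try:
        fx = DDI_FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown DDI fixture {name!r}; expected one of {sorted(DDI_FIXTURES)}"
        ) from None
    return run_ddi(
        fx["model"](),
        victim_dose_mg=fx["victim_dose_mg"],
        victim_formulation=FORMULATIONS[fx["victim_formulation"]],
        pretreatment_days=fx["pretreatment_days"],
        solver=solver,
    )
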