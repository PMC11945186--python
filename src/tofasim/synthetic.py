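"""Synthetic observed-data generation and bundled study fixtures.

Real model evaluation used concentration-time tables digitized from
published figures; this module generates equivalent pseudo-observed tables
entirely from the model so the full pipeline (fitting, validation metrics,
population comparisons) can run without any external data.  Profiles are
simulated, sampled at nominal times, multiplied by log-normal proportional
noise exp(N(0, sigma)) with sigma = sqrt(ln(1 + cv^2)), perturbed by
truncated Gaussian additive assay noise, and censored below the lower limit
of quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .compound import CompoundModel, FORMULATIONS, tofacitinib
from .ddi import DDI_FIXTURES, interaction_state, perpetrator_exposure
from .engine import DosingRegimen, FAST_SOLVER, SolverSettings, simulate
from .physiology import (
    HepaticStatus,
    Individual,
    PopulationSpec,
    RenalStatus,
    apply_hepatic_impairment,
    apply_pediatric_scaling,
    apply_renal_impairment,
    build_reference_adult,
    sample_population,
)

__all__ = [
    "NoiseModel",
    "StudyArm",
    "StudyFixture",
    "generate_observed",
    "population_band",
    "bundled_fixtures",
]

DEFAULT_SAMPLING_TIMES = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class NoiseModel:
    """Residual-error model of the pseudo-observed data."""

    proportional_cv: float = 0.15
    additive_sd: float = 0.05  # ng/mL
    lloq: float = 0.1  # ng/mL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass(frozen=True)
class StudyArm:
    """One simulated arm: a subject, a regimen and nominal sampling times.

    ``age``/``sex`` select a pediatric subject, ``hepatic``/``renal`` apply
    an organ-impairment state to the reference adult, and ``perpetrator``
    names a bundled DDI fixture whose steady-state interaction acts on the
    victim simulation.
    """

    name: str
    regimen: DosingRegimen
    sampling_times: Tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    age: Optional[float] = None  # pediatric subject when set
    sex: str = "male"
    hepatic: Optional[str] = None  # Child-Pugh class
    renal: Optional[str] = None  # renal category
    perpetrator: Optional[str] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.sampling_times)
        if np.any(np.diff(times) <= 0) or np.any(times < 0):
            raise ValueError("sampling times must be non-negative, strictly increasing")

    def subject(self) -> Individual:
        if self.age is not None and self.age < 18:
            ind = apply_pediatric_scaling(self.age, self.sex)
        else:
            ind = build_reference_adult()
        if self.hepatic:
            ind = apply_hepatic_impairment(ind, HepaticStatus(self.hepatic))
        if self.renal:
            ind = apply_renal_impairment(ind, RenalStatus(self.renal))
        return ind

    def duration(self) -> float:
        horizon = max(self.sampling_times)
        last_dose = self.regimen.start_times[-1]
        return max(horizon, last_dose + 1.0) + 1e-6


@dataclass(frozen=True)
class StudyFixture:
    """A study design: arms (median-subject profiles for pseudo-observed
    tables) plus the virtual population the study's population analysis
    uses."""

    study_id: str
    arms: Tuple[StudyArm, ...]
    noise: NoiseModel = NoiseModel()
    population: Optional[PopulationSpec] = None


def _arm_profile(
    arm: StudyArm, compound: CompoundModel, solver: SolverSettings
) -> np.ndarray:
    perp_state = None
    if arm.perpetrator:
        fx = DDI_FIXTURES[arm.perpetrator]
        days = fx["pretreatment_days"]
        model = fx["model"]()
        t, cu = perpetrator_exposure(model, days * 24.0 + arm.duration() + 24.0)
        perp_state = interaction_state(t, cu, model).shifted(days * 24.0)
    res = simulate(
        arm.subject(), compound, arm.regimen, arm.duration(),
        perpetrator_state=perp_state, solver=solver,
    )
    return np.interp(arm.sampling_times, res.time, res.plasma_conc)


def apply_noise(
    pred: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """One noisy realization of a noise-free prediction vector: log-normal
    proportional error times the prediction, plus zero-truncated Gaussian
    additive error (censoring is applied by the caller)."""
    out = np.asarray(pred, dtype=float).copy()
    cv = noise.proportional_cv
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        out = out * np.exp(rng.normal(0.0, sigma, size=out.shape))
    if noise.additive_sd > 0:
        out = np.maximum(out + rng.normal(0.0, noise.additive_sd, size=out.shape), 0.0)
    return out


def generate_observed(
    fixture: StudyFixture,
    compound: Optional[CompoundModel] = None,
    solver: SolverSettings = FAST_SOLVER,
) -> pd.DataFrame:
    """Pseudo-observed concentration table for a study fixture.

    Returns a frame with columns ``study_id, arm, time_h, conc_ng_ml``;
    concentrations below the LLOQ carry the string ``"BLQ"``.  Seeded and
    reproducible: the same fixture always yields the identical table.
    """
    compound = compound or tofacitinib()
    rng = np.random.default_rng(fixture.noise.seed)
    rows: List[Dict] = []
    for arm in fixture.arms:
        pred = _arm_profile(arm, compound, solver)
        noisy = apply_noise(pred, fixture.noise, rng)
        for t, c in zip(arm.sampling_times, noisy):
            rows.append(
                {
                    "study_id": fixture.study_id,
                    "arm": arm.name,
                    "time_h": float(t),
                    "conc_ng_ml": "BLQ" if c < fixture.noise.lloq else float(c),
                }
            )
    return pd.DataFrame(rows, columns=["study_id", "arm", "time_h", "conc_ng_ml"])


def population_band(
    population: Sequence[Individual],
    compound: CompoundModel,
    regimen: DosingRegimen,
    duration: float,
    quantiles: Tuple[float, float, float] = (0.05, 0.5, 0.95),
    solver: SolverSettings = FAST_SOLVER,
) -> pd.DataFrame:
    """Population concentration band: per-time quantiles across subjects."""
    profiles = []
    t_ref = None
    for ind in population:
        res = simulate(ind, compound, regimen, duration, solver=solver)
        t_ref = res.time
        profiles.append(res.plasma_conc)
    q = np.quantile(np.vstack(profiles), quantiles, axis=0)
    return pd.DataFrame(
        {
            "time_h": t_ref,
            "q_low": q[0],
            "median": q[1],
            "q_high": q[2],
        }
    )


def bundled_fixtures() -> Dict[str, StudyFixture]:
    """The packaged study designs, covering every simulated study family:
    adult single/multiple dosing across formulations, the three pediatric
    cohorts, hepatic impairment (fed state), the renal-function classes at
    10 mg, and the three DDI designs."""

    def reg(dose, form, schedule="single", n=1):
        return DosingRegimen(dose, FORMULATIONS[form], schedule=schedule, n_doses=n)

    long_times = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 36.0, 48.0)
    multi_times = (48.0, 48.5, 49.0, 50.0, 51.0, 52.0, 54.0, 56.0, 60.0)

    # study-family virtual populations
    adults = PopulationSpec(n=200, age_range=(18.0, 60.0), female_fraction=0.5, seed=20)
    def pediatric_pop(lo, hi, seed):
        return PopulationSpec(n=100, age_range=(lo, hi), female_fraction=0.7, seed=seed)
    hepatic_pop = PopulationSpec(n=1000, age_range=(18.0, 60.0), female_fraction=0.25, seed=30)
    renal_pop = PopulationSpec(n=1000, age_range=(18.0, 60.0), female_fraction=0.5, seed=40)

    fixtures = {
        # --- adult single/multiple dose, plain / IR / XR -------------------
        "adult_single_0p3mg_plain": StudyFixture(
            "adult_single_0p3mg_plain",
            (StudyArm("0.3 mg plain", reg(0.3, "plain")),),
            NoiseModel(seed=101),
            population=adults,
        ),
        "adult_single_5mg_IR": StudyFixture(
            "adult_single_5mg_IR",
            (StudyArm("5 mg IR", reg(5.0, "IR")),),
            NoiseModel(seed=102),
            population=adults,
        ),
        "adult_single_30mg_IR": StudyFixture(
            "adult_single_30mg_IR",
            (StudyArm("30 mg IR", reg(30.0, "IR"), long_times),),
            NoiseModel(seed=103),
            population=adults,
        ),
        "adult_single_100mg_plain": StudyFixture(
            "adult_single_100mg_plain",
            (StudyArm("100 mg plain", reg(100.0, "plain"), long_times),),
            NoiseModel(seed=104),
            population=adults,
        ),
        "adult_multiple_5mg_BID_IR": StudyFixture(
            "adult_multiple_5mg_BID_IR",
            (StudyArm("5 mg BID IR", reg(5.0, "IR", "BID", 5), multi_times),),
            NoiseModel(seed=105),
            population=adults,
        ),
        "adult_multiple_11mg_QD_XR": StudyFixture(
            "adult_multiple_11mg_QD_XR",
            (StudyArm("11 mg QD XR", reg(11.0, "XR", "QD", 3), multi_times),),
            NoiseModel(seed=106),
            population=adults,
        ),
        # --- pediatric cohorts --------------------------------------------
        "pediatric_cohort1_12to18": StudyFixture(
            "pediatric_cohort1_12to18",
            (StudyArm("cohort 1", reg(5.0, "IR"), age=15.0, sex="female"),),
            NoiseModel(seed=201),
            population=pediatric_pop(12.0, 17.99, 21),
        ),
        "pediatric_cohort2_6to12": StudyFixture(
            "pediatric_cohort2_6to12",
            (StudyArm("cohort 2", reg(2.5, "solution"), age=9.0, sex="female"),),
            NoiseModel(seed=202),
            population=pediatric_pop(6.0, 11.99, 22),
        ),
        "pediatric_cohort3_2to6": StudyFixture(
            "pediatric_cohort3_2to6",
            (StudyArm("cohort 3", reg(2.0, "solution"), age=4.0, sex="female"),),
            NoiseModel(seed=203),
            population=pediatric_pop(2.0, 5.99, 23),
        ),
        # --- hepatic impairment, fed state --------------------------------
        "hepatic_fed_10mg": StudyFixture(
            "hepatic_fed_10mg",
            (
                StudyArm("healthy fed", reg(10.0, "fed"), long_times),
                StudyArm("Child-Pugh A", reg(10.0, "fed"), long_times, hepatic="A"),
                StudyArm("Child-Pugh B", reg(10.0, "fed"), long_times, hepatic="B"),
            ),
            NoiseModel(seed=301),
            population=hepatic_pop,
        ),
        # --- renal impairment, 10 mg single -------------------------------
        "renal_10mg": StudyFixture(
            "renal_10mg",
            (
                StudyArm("normal", reg(10.0, "IR"), long_times),
                StudyArm("mild RI", reg(10.0, "IR"), long_times, renal="mild"),
                StudyArm("moderate RI", reg(10.0, "IR"), long_times, renal="moderate"),
                StudyArm("severe RI", reg(10.0, "IR"), long_times, renal="severe"),
            ),
            NoiseModel(seed=401),
            population=renal_pop,
        ),
        # --- DDI designs ---------------------------------------------------
        "ddi_fluconazole": StudyFixture(
            "ddi_fluconazole",
            (
                StudyArm("tofacitinib alone", reg(30.0, "solution"), long_times),
                StudyArm(
                    "with fluconazole", reg(30.0, "solution"), long_times,
                    perpetrator="fluconazole",
                ),
            ),
            NoiseModel(seed=501),
            population=adults,
        ),
        "ddi_ketoconazole": StudyFixture(
            "ddi_ketoconazole",
            (
                StudyArm("tofacitinib alone", reg(10.0, "solution"), long_times),
                StudyArm(
                    "with ketoconazole", reg(10.0, "solution"), long_times,
                    perpetrator="ketoconazole",
                ),
            ),
            NoiseModel(seed=502),
            population=adults,
        ),
        "ddi_rifampicin": StudyFixture(
            "ddi_rifampicin",
            (
                StudyArm("tofacitinib alone", reg(30.0, "IR"), long_times),
                StudyArm(
                    "with rifampicin", reg(30.0, "IR"), long_times,
                    perpetrator="rifampicin",
                ),
            ),
            NoiseModel(seed=503),
            population=adults,
        ),
    }
    return fixtures
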