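"""Virtual individuals: reference adults, sampled populations, and the
pediatric / hepatic-impairment / renal-impairment transforms.

The physiology carried here is a minimal 14-compartment whole-body set
(11 perfused tissues, lung, arterial and venous blood) with ICRP-style
reference organ volumes and regional blood flows for an adult male and
female.  Pediatric anatomy is obtained from embedded age lookup tables
(ages 2-17 y) with linear interpolation in age; organ-impairment states
are expressed as multiplicative scalers on the relevant parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Individual",
    "PopulationSpec",
    "HepaticStatus",
    "RenalStatus",
    "ORGANS",
    "TISSUES",
    "build_reference_adult",
    "sample_population",
    "apply_pediatric_scaling",
    "apply_hepatic_impairment",
    "apply_renal_impairment",
    "CHILD_PUGH_SCALERS",
    "RENAL_CLASSES",
    "REFERENCE_EGFR",
    "DEFAULT_VARIABILITY",
]

# Perfused tissue compartments (besides lung and the two blood pools).
TISSUES: Tuple[str, ...] = (
    "adipose", "bone", "brain", "gut", "heart", "kidney",
    "liver", "muscle", "skin", "spleen", "rest",
)
ORGANS: Tuple[str, ...] = TISSUES + ("lung", "arterial_blood", "venous_blood")

# ---------------------------------------------------------------------------
# Reference adult physiology (ICRP-style reference male / female).
# Volumes in L, blood flows as fractions of cardiac output, CO in L/h,
# GFR in mL/min.
# ---------------------------------------------------------------------------
_REFERENCE_ADULT = {
    "male": {
        "body_weight": 73.0,
        "height": 176.0,
        "cardiac_output": 390.0,
        "hematocrit": 0.45,
        "gfr": 110.0,
        "volumes": {
            "lung": 0.50, "adipose": 14.5, "bone": 10.5, "brain": 1.45,
            "gut": 1.10, "heart": 0.33, "kidney": 0.31, "liver": 1.80,
            "muscle": 29.0, "skin": 3.30, "spleen": 0.15, "rest": 3.00,
            "arterial_blood": 1.70, "venous_blood": 3.90,
        },
        "flow_fractions": {
            "adipose": 0.050, "bone": 0.050, "brain": 0.120, "gut": 0.150,
            "heart": 0.040, "kidney": 0.190, "liver": 0.065, "muscle": 0.170,
            "skin": 0.050, "spleen": 0.030, "rest": 0.085,
        },
    },
    "female": {
        "body_weight": 60.0,
        "height": 163.0,
        "cardiac_output": 350.0,
        "hematocrit": 0.40,
        "gfr": 100.0,
        "volumes": {
            "lung": 0.42, "adipose": 17.0, "bone": 7.80, "brain": 1.30,
            "gut": 1.00, "heart": 0.25, "kidney": 0.275, "liver": 1.55,
            "muscle": 17.5, "skin": 2.30, "spleen": 0.13, "rest": 2.60,
            "arterial_blood": 1.25, "venous_blood": 2.85,
        },
        "flow_fractions": {
            "adipose": 0.085, "bone": 0.050, "brain": 0.120, "gut": 0.150,
            "heart": 0.040, "kidney": 0.170, "liver": 0.065, "muscle": 0.120,
            "skin": 0.050, "spleen": 0.030, "rest": 0.120,
        },
    },
}

# Pediatric growth tables (reference size at the 50th percentile).
# Columns: body weight kg, height cm, liver L, kidney L, brain L, GFR mL/min.
# The final row (age 20) carries the adult male reference so interpolation is
# continuous up to adulthood.
_PED_AGES = np.array([2.0, 4.0, 6.0, 9.0, 12.0, 15.0, 17.0, 20.0])
_PED_TABLE = {
    "body_weight": np.array([12.6, 16.5, 21.0, 29.0, 41.0, 55.0, 62.0, 73.0]),
    "height": np.array([87.0, 102.0, 115.0, 134.0, 149.0, 163.0, 169.0, 176.0]),
    "liver": np.array([0.40, 0.53, 0.65, 0.85, 1.12, 1.45, 1.60, 1.80]),
    "kidney": np.array([0.065, 0.080, 0.095, 0.120, 0.160, 0.210, 0.240, 0.310]),
    "brain": np.array([1.10, 1.25, 1.32, 1.38, 1.40, 1.43, 1.44, 1.45]),
    "gfr": np.array([35.0, 45.0, 58.0, 72.0, 88.0, 100.0, 105.0, 110.0]),
}
# Female body-size multiplier, interpolated in age (sex differences in size
# emerge through adolescence).
_PED_FEMALE_AGES = np.array([2.0, 11.0, 15.0, 17.0, 20.0])
_PED_FEMALE_WEIGHT = np.array([1.00, 1.00, 0.88, 0.85, 60.0 / 73.0])

DEFAULT_VARIABILITY: Dict[str, float] = {
    "volumes": 0.16,
    "flows": 0.20,
    "enzymes": 0.25,
    "permeability": 0.30,
    "gfr": 0.16,
}

REFERENCE_EGFR = 100.0  # mL/min/1.73 m^2, healthy-adult representative value

# Child-Pugh physiology scalers (calibrated once against the exposure anchors:
# class-A AUC ratio inside [1.0, 1.25], class-B AUC ratio ~2.0; see
# docs/methods.md) and frozen here.
CHILD_PUGH_SCALERS: Dict[str, Dict[str, float]] = {
    "healthy": {
        "cyp3a4_abundance": 1.0, "functional_liver_fraction": 1.0,
        "hepatic_blood_flow": 1.0, "albumin_fu": 1.0, "gfr": 1.0,
    },
    "A": {
        "cyp3a4_abundance": 0.80, "functional_liver_fraction": 0.90,
        "hepatic_blood_flow": 0.90, "albumin_fu": 1.05, "gfr": 0.95,
    },
    "B": {
        "cyp3a4_abundance": 0.29, "functional_liver_fraction": 0.50,
        "hepatic_blood_flow": 0.65, "albumin_fu": 1.15, "gfr": 0.90,
    },
}

# Representative eGFR per KDOQI-style renal-function class (mL/min/1.73 m^2):
# band midpoints for mild/moderate/severe chronic kidney disease.
RENAL_CLASSES: Dict[str, Tuple[float, float, float]] = {
    # category: (band low, band high, representative value)
    "normal": (90.0, 130.0, 100.0),
    "mild": (60.0, 90.0, 75.0),
    "moderate": (30.0, 60.0, 45.0),
    "severe": (15.0, 30.0, 22.5),
}


@dataclass
class Individual:
    """One virtual subject's anatomy and physiology."""

    age: float
    sex: str
    body_weight: float  # kg
    height: float  # cm
    organ_volumes: Dict[str, float]  # L, keys = ORGANS
    blood_flows: Dict[str, float]  # L/h, keys = TISSUES (liver = arterial supply)
    hematocrit: float
    gfr: float  # mL/min
    enzyme_abundance: Dict[str, float] = field(
        default_factory=lambda: {"CYP3A4": 1.0, "CYP2C19": 1.0}
    )
    fu_scaler: float = 1.0
    functional_liver_fraction: float = 1.0
    permeability_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        for organ in ORGANS:
            if self.organ_volumes.get(organ, 0.0) <= 0:
                raise ValueError(f"volume of {organ} must be positive")
        for tissue in TISSUES:
            if self.blood_flows.get(tissue, 0.0) <= 0:
                raise ValueError(f"blood flow of {tissue} must be positive")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.gfr < 0:
            raise ValueError("gfr must be non-negative")
        if any(v < 0 for v in self.enzyme_abundance.values()):
            raise ValueError("enzyme abundance must be non-negative")

    @property
    def cardiac_output(self) -> float:
        """Total perfusion (L/h); venous return equals this by construction."""
        return float(sum(self.blood_flows[t] for t in TISSUES))

    def copy(self) -> "Individual":
        return replace(
            self,
            organ_volumes=dict(self.organ_volumes),
            blood_flows=dict(self.blood_flows),
            enzyme_abundance=dict(self.enzyme_abundance),
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a virtual cohort."""

    n: int
    age_range: Tuple[float, float] = (18.0, 60.0)
    female_fraction: float = 0.5
    seed: int = 0
    variability: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIABILITY)
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        lo, hi = self.age_range
        if not (lo <= hi) or lo < 2:
            raise ValueError("malformed age range")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class HepaticStatus:
    """Child-Pugh hepatic-function class with its physiology scalers."""

    child_pugh_class: str
    scalers: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.child_pugh_class not in CHILD_PUGH_SCALERS:
            raise ValueError(
                f"unknown Child-Pugh class {self.child_pugh_class!r}; "
                f"expected one of {sorted(CHILD_PUGH_SCALERS)}"
            )
        if self.scalers is not None and any(v <= 0 for v in self.scalers.values()):
            raise ValueError("all hepatic scalers must be positive")

    @property
    def effective_scalers(self) -> Dict[str, float]:
        base = dict(CHILD_PUGH_SCALERS[self.child_pugh_class])
        if self.scalers:
            base.update(self.scalers)
        return base


@dataclass(frozen=True)
class RenalStatus:
    """Renal-function category with its representative eGFR."""

    category: str
    egfr: float | None = None  # mL/min/1.73 m^2

    def __post_init__(self) -> None:
        if self.category not in RENAL_CLASSES:
            raise ValueError(
                f"unknown renal category {self.category!r}; "
                f"expected one of {sorted(RENAL_CLASSES)}"
            )
        if self.egfr is not None:
            if self.egfr <= 0:
                raise ValueError("eGFR must be positive")
            lo, hi = RENAL_CLASSES[self.category][:2]
            if not (lo <= self.egfr <= hi):
                raise ValueError(
                    f"eGFR {self.egfr} outside the {self.category} band [{lo}, {hi}]"
                )

    @property
    def effective_egfr(self) -> float:
        return self.egfr if self.egfr is not None else RENAL_CLASSES[self.category][2]


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _adult_from_reference(sex: str, age: float = 30.0) -> Individual:
    ref = _REFERENCE_ADULT[sex]
    co = ref["cardiac_output"]
    flows = {t: co * f for t, f in ref["flow_fractions"].items()}
    return Individual(
        age=age,
        sex=sex,
        body_weight=ref["body_weight"],
        height=ref["height"],
        organ_volumes=dict(ref["volumes"]),
        blood_flows=flows,
        hematocrit=ref["hematocrit"],
        gfr=ref["gfr"],
    )


def build_reference_adult() -> Individual:
    """The deterministic reference individual: a 30-year-old male adult with
    the packaged organ volumes, regional flows and GFR."""
    return _adult_from_reference("male")


def _ped_interp(column: str, age: float) -> float:
    return float(np.interp(age, _PED_AGES, _PED_TABLE[column]))


def apply_pediatric_scaling(
    age: float, sex: str = "male", size_percentile: float = 0.5
) -> Individual:
    """Construct a pediatric individual by age-dependent scaling.

    Organ volumes are taken from the embedded growth tables where organ-
    specific data are carried (liver, kidney, brain) and scale with the
    body-weight ratio otherwise; flows scale allometrically (weight^0.75);
    GFR comes from its own maturation table.  CYP3A4/CYP2C19 ontogeny is
    treated as complete for age >= 2 y (both pathways near-mature after
    infancy), and plasma protein levels as adult, so ``fu_scaler`` stays 1.
    ``size_percentile`` shifts body size on a log-normal weight-for-age
    distribution (sigma 0.13).
    """
    if not 2.0 <= age < 18.0:
        raise ValueError("pediatric scaling supports ages 2 <= age < 18 years")
    if not 0 < size_percentile < 1:
        raise ValueError("size_percentile must lie strictly in (0, 1)")

    from scipy.stats import norm

    ref = _REFERENCE_ADULT["male"]
    weight = _ped_interp("body_weight", age)
    height = _ped_interp("height", age)
    sex_factor = 1.0
    if sex == "female":
        sex_factor = float(np.interp(age, _PED_FEMALE_AGES, _PED_FEMALE_WEIGHT))
        weight *= sex_factor
        height *= sex_factor ** (1.0 / 2.5)
    size_shift = math.exp(norm.ppf(size_percentile) * 0.13)
    weight *= size_shift
    organ_shift = size_shift * sex_factor  # organ-level size scaling

    w_ratio = weight / ref["body_weight"]
    volumes: Dict[str, float] = {}
    for organ in ORGANS:
        if organ == "liver":
            volumes[organ] = _ped_interp("liver", age) * organ_shift
        elif organ == "kidney":
            volumes[organ] = _ped_interp("kidney", age) * organ_shift
        elif organ == "brain":
            volumes[organ] = _ped_interp("brain", age)
        else:
            volumes[organ] = ref["volumes"][organ] * w_ratio
    co = ref["cardiac_output"] * w_ratio ** 0.75
    flows = {t: co * f for t, f in ref["flow_fractions"].items()}
    gfr = _ped_interp("gfr", age) * organ_shift ** 0.75

    return Individual(
        age=age,
        sex=sex,
        body_weight=weight,
        height=height,
        organ_volumes=volumes,
        blood_flows=flows,
        hematocrit=ref["hematocrit"] * (0.95 if age < 6 else 1.0),
        gfr=gfr,
    )


def _base_individual(age: float, sex: str) -> Individual:
    if age < 18.0:
        return apply_pediatric_scaling(age, sex)
    return _adult_from_reference(sex, age=age)


def sample_population(spec: PopulationSpec) -> List[Individual]:
    """Sample a virtual cohort.

    Ages are uniform over ``age_range`` and sex is an independent Bernoulli
    draw at ``female_fraction``.  Anatomical parameters are sampled
    log-normally around the age/sex-consistent reference with the
    coefficient-of-variation map in ``spec.variability``.  The same spec
    (including seed) always yields the identical population.
    """
    rng = np.random.default_rng(spec.seed)
    cv = {**DEFAULT_VARIABILITY, **dict(spec.variability)}
    sigmas = {k: math.sqrt(math.log(1.0 + c * c)) for k, c in cv.items()}

    out: List[Individual] = []
    for _ in range(spec.n):
        age = float(rng.uniform(*spec.age_range))
        sex = "female" if rng.random() < spec.female_fraction else "male"
        ind = _base_individual(age, sex)
        sv, sf = sigmas["volumes"], sigmas["flows"]
        volumes = {
            o: v * math.exp(rng.normal(0.0, sv)) if sv > 0 else v
            for o, v in ind.organ_volumes.items()
        }
        flows = {
            t: q * math.exp(rng.normal(0.0, sf)) if sf > 0 else q
            for t, q in ind.blood_flows.items()
        }
        se = sigmas["enzymes"]
        enzymes = {
            e: math.exp(rng.normal(0.0, se)) if se > 0 else 1.0
            for e in ("CYP3A4", "CYP2C19")
        }
        sp = sigmas["permeability"]
        perm = math.exp(rng.normal(0.0, sp)) if sp > 0 else 1.0
        sg = sigmas["gfr"]
        gfr = ind.gfr * (math.exp(rng.normal(0.0, sg)) if sg > 0 else 1.0)
        out.append(
            replace(
                ind,
                organ_volumes=volumes,
                blood_flows=flows,
                enzyme_abundance=enzymes,
                permeability_factor=perm,
                gfr=gfr,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Impairment transforms
# ---------------------------------------------------------------------------

def apply_hepatic_impairment(ind: Individual, status: HepaticStatus) -> Individual:
    """Return a modified copy with the Child-Pugh class scalers applied.

    CYP3A4 abundance, functional liver fraction, hepatic (arterial + portal)
    blood flow, the plasma unbound-fraction scaler and GFR are each multiplied
    by the class scaler; everything else is untouched.
    """
    s = status.effective_scalers
    out = ind.copy()
    out.enzyme_abundance["CYP3A4"] *= s["cyp3a4_abundance"]
    out.functional_liver_fraction *= s["functional_liver_fraction"]
    for vessel in ("liver", "gut", "spleen"):  # arterial supply + portal inflow
        out.blood_flows[vessel] *= s["hepatic_blood_flow"]
    out.fu_scaler *= s["albumin_fu"]
    out.gfr *= s["gfr"]
    return out


def apply_renal_impairment(ind: Individual, status: RenalStatus) -> Individual:
    """Return a modified copy with GFR (and with it the engine's tubular-
    secretion capacity, which scales with the individual's GFR ratio)
    reduced by eGFR relative to the healthy reference; hepatic parameters
    are untouched."""
    factor = status.effective_egfr / REFERENCE_EGFR
    out = ind.copy()
    out.gfr *= factor
    return out
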