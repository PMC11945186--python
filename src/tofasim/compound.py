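"""Tofacitinib compound model: physicochemistry, dissolution, tissue partitioning.

The compound is parameterized the way whole-body PBPK platforms parameterize a
small molecule: measured physicochemical constants (MW, logP, pKa, fu, solubility),
permeability, and per-pathway intrinsic clearance scalers.  Tofacitinib is a
monoprotic base (pKa 5.07) that is >99% un-ionized at physiological pH, is mainly
cleared by hepatic CYP3A4 (Michaelis-Menten) and CYP2C19 (first order), with the
remainder excreted unchanged in urine by glomerular filtration plus tubular
secretion.

The three clearance scalers and the absorption area factor are *calibrated*
quantities: they were fitted once (see ``mc_fit.calibration_recipe`` and
``docs/methods.md``) so that the reference adult reproduces the compound's known
disposition anchors -- pathway fractions 53% / 16% / 29% (CYP3A4 / CYP2C19 /
renal) and oral bioavailability 0.74 -- and then frozen here as defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping

import numpy as np

__all__ = [
    "Formulation",
    "CompoundModel",
    "PartitionSet",
    "TISSUE_COMPOSITION",
    "weibull_dissolved_fraction",
    "rodgers_rowland_partition",
    "tofacitinib",
    "IR_TABLET",
    "XR_TABLET",
    "FED_TABLET",
    "ORAL_SOLUTION",
    "PLAIN_TABLET",
]

LN2 = math.log(2.0)

WEIBULL_KINDS = ("IR", "XR", "fed")
IMMEDIATE_KINDS = ("solution", "plain")


@dataclass(frozen=True)
class Formulation:
    """Oral dosage form with empirical Weibull dissolution kinetics.

    ``t50`` is the 50% dissolution time in hours and ``shape`` the Weibull
    exponent.  ``solution`` and ``plain`` (conventional tablet, assumed
    immediately dissolved) bypass dissolution entirely.
    """

    kind: str
    t50: float | None = None
    shape: float | None = None

    def __post_init__(self) -> None:
        if self.kind in IMMEDIATE_KINDS:
            if self.t50 is not None or self.shape is not None:
                raise ValueError(f"{self.kind} formulation takes no Weibull parameters")
        elif self.kind in WEIBULL_KINDS:
            if self.t50 is None or self.shape is None:
                raise ValueError(f"{self.kind} formulation requires t50 and shape")
            if self.t50 <= 0 or self.shape <= 0:
                raise ValueError("t50 and shape must be positive")
        else:
            raise ValueError(f"unknown formulation kind {self.kind!r}")

    @property
    def immediate(self) -> bool:
        return self.kind in IMMEDIATE_KINDS


# Marketed forms; Weibull parameters optimized against clinical profiles
# (IR/XR fasted, 'fed' for post-prandial administration).
ORAL_SOLUTION = Formulation("solution")
PLAIN_TABLET = Formulation("plain")
IR_TABLET = Formulation("IR", t50=0.29, shape=0.59)
XR_TABLET = Formulation("XR", t50=3.22, shape=2.42)
FED_TABLET = Formulation("fed", t50=1.25, shape=1.01)

FORMULATIONS: Dict[str, Formulation] = {
    "solution": ORAL_SOLUTION,
    "plain": PLAIN_TABLET,
    "IR": IR_TABLET,
    "XR": XR_TABLET,
    "fed": FED_TABLET,
}


def weibull_dissolved_fraction(t, form: Formulation):
    """Cumulative dissolved fraction F(t) = 1 - exp(-ln2 * (t/t50)^shape).

    By construction F(t50) = 0.5 for every shape.  Immediate forms return 1
    for any t > 0.  Accepts scalars or arrays; negative times are an error.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("dissolution time must be non-negative")
    if form.immediate:
        out = np.where(arr > 0, 1.0, 0.0)
    else:
        with np.errstate(divide="ignore"):
            out = 1.0 - np.exp(-LN2 * (arr / form.t50) ** form.shape)
    if np.isscalar(t) or arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class CompoundModel:
    """All tofacitinib-specific model inputs.

    Clearance scalers (reference adult, scaled in the engine by enzyme
    abundance, functional liver mass and kidney function):

    - ``kcat_cyp3a4``: CYP3A4 Vmax of the reference liver, umol/h.
    - ``clspec_cyp2c19``: CYP2C19 unbound intrinsic clearance, L/h.
    - ``ts_spec``: tubular-secretion unbound intrinsic clearance, L/h.
    """

    name: str = "tofacitinib"
    mw: float = 312.40  # g/mol
    logp: float = 1.15
    fu_plasma: float = 0.61
    pka: float = 5.07  # monoprotic base
    pka_type: str = "base"
    solubility_mg_ml: float = 2.9
    specific_intestinal_permeability: float = 7.24e-6  # cm/min
    cellular_permeability: float = 4.37e-4  # cm/min
    km_cyp3a4: float = 10.61  # umol/L
    # --- calibrated clearance scalers (frozen; see module docstring) ---
    kcat_cyp3a4: float = 187.043  # umol/h, reference-liver Vmax
    clspec_cyp2c19: float = 5.4617  # L/h, unbound intrinsic
    ts_spec: float = 4.7321  # L/h, unbound intrinsic
    # effective absorptive area per lumen volume converting the specific
    # intestinal permeability into a segment absorption rate constant;
    # calibrated jointly with the clearance scalers.
    absorption_area_factor: float = 2517.12  # cm^-1
    gfr_fraction: float = 1.0
    fm_cyp3a4_target: float = 0.53
    fm_cyp2c19_target: float = 0.17
    f_urine_target: float = 0.30
    blood_plasma_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")
        total = self.fm_cyp3a4_target + self.fm_cyp2c19_target + self.f_urine_target
        if abs(total - 1.0) > 0.01:
            raise ValueError("pathway fraction targets must sum to 1 within 0.01")
        for attr in ("kcat_cyp3a4", "clspec_cyp2c19", "ts_spec"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")

    def with_params(self, **kwargs) -> "CompoundModel":
        return replace(self, **kwargs)


def tofacitinib() -> CompoundModel:
    """The packaged tofacitinib parameter set."""
    return CompoundModel()


@dataclass(frozen=True)
class PartitionSet:
    """Tissue-to-plasma partition coefficients (total concentration basis)."""

    kp: Mapping[str, float]

    def __post_init__(self) -> None:
        for organ, value in self.kp.items():
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"Kp[{organ}] must be positive and finite")

    def __getitem__(self, organ: str) -> float:
        return self.kp[organ]


# Fractional tissue composition used by the tissue-partitioning equations:
# extracellular water, intracellular water, neutral lipids, neutral
# phospholipids (all v/v) and the tissue-to-plasma albumin ratio governing
# residual protein binding of neutrals / very weak bases.  Values are the
# published composition constants commonly used with this method; the 'rest'
# compartment reuses muscle composition.
TISSUE_COMPOSITION: Dict[str, Dict[str, float]] = {
    #            f_ew    f_iw    f_nl     f_np     alb_ratio
    "adipose": {"f_ew": 0.135, "f_iw": 0.017, "f_nl": 0.853, "f_np": 0.0016, "alb_ratio": 0.049},
    "bone":    {"f_ew": 0.100, "f_iw": 0.346, "f_nl": 0.017, "f_np": 0.0017, "alb_ratio": 0.100},
    "brain":   {"f_ew": 0.162, "f_iw": 0.620, "f_nl": 0.039, "f_np": 0.0015, "alb_ratio": 0.048},
    "gut":     {"f_ew": 0.282, "f_iw": 0.475, "f_nl": 0.038, "f_np": 0.0125, "alb_ratio": 0.158},
    "heart":   {"f_ew": 0.320, "f_iw": 0.456, "f_nl": 0.014, "f_np": 0.0111, "alb_ratio": 0.157},
    "kidney":  {"f_ew": 0.273, "f_iw": 0.483, "f_nl": 0.012, "f_np": 0.0242, "alb_ratio": 0.130},
    "liver":   {"f_ew": 0.161, "f_iw": 0.573, "f_nl": 0.014, "f_np": 0.0240, "alb_ratio": 0.086},
    "lung":    {"f_ew": 0.336, "f_iw": 0.446, "f_nl": 0.022, "f_np": 0.0128, "alb_ratio": 0.212},
    "muscle":  {"f_ew": 0.118, "f_iw": 0.630, "f_nl": 0.010, "f_np": 0.0072, "alb_ratio": 0.064},
    "skin":    {"f_ew": 0.382, "f_iw": 0.291, "f_nl": 0.060, "f_np": 0.0044, "alb_ratio": 0.277},
    "spleen":  {"f_ew": 0.207, "f_iw": 0.579, "f_nl": 0.0077, "f_np": 0.0113, "alb_ratio": 0.097},
    "rest":    {"f_ew": 0.118, "f_iw": 0.630, "f_nl": 0.010, "f_np": 0.0072, "alb_ratio": 0.064},
}

# Plasma neutral-lipid / phospholipid content and compartment pH values.
PLASMA_F_NL = 0.0023
PLASMA_F_NP = 0.0013
PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0


def _lipid_term(p: float, f_nl: float, f_np: float) -> float:
    """Neutral-lipid / neutral-phospholipid partition contribution."""
    return p * f_nl + (0.3 * p + 0.7) * f_np


def rodgers_rowland_partition(
    compound: CompoundModel,
    tissue_composition: Mapping[str, Mapping[str, float]] = TISSUE_COMPOSITION,
) -> PartitionSet:
    """Mechanistic tissue-to-plasma partition coefficients for a weak base.

    Implements the tissue-composition partitioning equations for a monoprotic
    base whose pKa lies below intracellular pH (tofacitinib, pKa 5.07): the
    un-ionized species partitions into neutral lipid and neutral phospholipid
    according to logP, water partitioning accounts for the (small) ionized
    fraction via the intracellular/plasma pH difference, and residual binding
    to tissue interstitial albumin is back-calculated from the plasma unbound
    fraction.  Returns total tissue:plasma coefficients (Kpu * fu).
    """
    if compound.pka_type != "base":
        raise ValueError("only monoprotic bases are supported")
    p = 10.0 ** compound.logp
    fu = compound.fu_plasma
    # ionization: base, fraction ionized = 1/(1+10^(pH-pKa)); X = 1 + 10^(pKa-pH)
    x_iw = 1.0 + 10.0 ** (compound.pka - PH_INTRACELLULAR)
    y_p = 1.0 + 10.0 ** (compound.pka - PH_PLASMA)
    # residual protein (albumin) association from plasma binding:
    # 1/fu = 1 + lipid_term_plasma/Y + Ka_PR*[PR]_plasma
    ka_pr_prp = 1.0 / fu - 1.0 - _lipid_term(p, PLASMA_F_NL, PLASMA_F_NP) / y_p
    ka_pr_prp = max(ka_pr_prp, 0.0)  # highly lipophilic edge case

    kp: Dict[str, float] = {}
    for organ, comp in tissue_composition.items():
        try:
            kpu = (
                comp["f_ew"]
                + (x_iw / y_p) * comp["f_iw"]
                + _lipid_term(p, comp["f_nl"], comp["f_np"]) / y_p
                + ka_pr_prp * comp["alb_ratio"]
            )
        except KeyError as exc:  # pragma: no cover - config guard
            raise KeyError(f"tissue composition for {organ!r} missing {exc}") from exc
        kp[organ] = kpu * fu
    return PartitionSet(kp=kp)
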