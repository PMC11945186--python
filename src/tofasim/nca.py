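"""Non-compartmental analysis, validation statistics and local sensitivity.

NCA metrics (Cmax, Tmax, AUC by linear-up/log-down trapezoid, terminal
half-life from a log-linear regression) are computed model-free from any
concentration-time profile.  Model validation uses the fold error
FE = predicted/observed and its geometric mean

    GMFE = 10 ^ ( sum |log10 FE_i| / n ),

with the absolute-log convention so over- and under-prediction cannot
cancel (GMFE >= 1, and = 1 only for perfect agreement), plus the standard
2-fold / 1.25-fold goodness-of-fit fractions.  Local sensitivity of exposure
to a model parameter is the normalized derivative

    S = (dAUC / AUC) * (p / dp)

from a +10% forward perturbation; S = +1 means a 10% parameter increase
raises AUC by 10%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PKMetrics",
    "ValidationRecord",
    "ValidationSummary",
    "SensitivityResult",
    "nca",
    "fold_error",
    "gmfe",
    "gof_fractions",
    "local_sensitivity",
]

SPARSE_LINEAR_THRESHOLD = 8  # <= this many points: plain linear trapezoid


@dataclass(frozen=True)
class PKMetrics:
    """Non-compartmental exposure metrics of one profile."""

    cmax: float  # ng/mL
    tmax: float  # h
    auc_last: float  # ng*h/mL
    auc_inf: Optional[float]  # ng*h/mL; None when no terminal phase fits
    auc_tau: Optional[float]  # ng*h/mL over the final dosing interval
    t_half: Optional[float]  # h
    lambda_z: Optional[float]  # 1/h


@dataclass(frozen=True)
class ValidationRecord:
    parameter_name: str
    predicted: float
    observed: float

    @property
    def fe(self) -> float:
        return fold_error(self.predicted, self.observed)


@dataclass(frozen=True)
class ValidationSummary:
    records: Tuple[ValidationRecord, ...]
    gmfe: float
    n: int
    frac_within_2fold: float
    frac_within_1p25fold: float


@dataclass(frozen=True)
class SensitivityResult:
    parameter_name: str
    p: float
    delta_p: float
    delta_auc: float
    s: float


def _auc_trapezoid(t: np.ndarray, c: np.ndarray, linear_only: bool) -> float:
    """Linear-up/log-down trapezoid (log interpolation on declining segments
    with both endpoints positive); plain linear when ``linear_only``."""
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    linear = (c1 + c2) / 2.0 * dt
    if linear_only:
        return float(linear.sum())
    down = (c2 < c1) & (c2 > 0) & (c1 > 0)
    seg = linear.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = (c1 - c2) * dt / np.log(c1 / c2)
    seg[down] = log_seg[down]
    return float(seg.sum())


def _terminal_fit(t: np.ndarray, c: np.ndarray, i_tmax: int):
    """lambda_z from the best adjusted-R^2 window among the last 3-6 points
    strictly after Tmax; ties favor the longer window."""
    positive = c > 0
    candidates: List[Tuple[float, int, float]] = []
    n = len(t)
    for width in range(3, 7):
        idx = np.arange(n - width, n)
        if idx[0] <= i_tmax or np.any(~positive[idx]):
            continue
        x, y = t[idx], np.log(c[idx])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (width - 1) / (width - 2)
        candidates.append((adj, width, -slope))
    if not candidates:
        return None
    # max adjusted R^2; ties (within 1e-12) -> longer window
    candidates.sort(key=lambda c: (round(c[0], 12), c[1]))
    return candidates[-1][2]


def nca(
    time_h: Sequence[float],
    conc_ng_ml: Sequence[float],
    tau: Optional[float] = None,
) -> PKMetrics:
    """Non-compartmental metrics of a concentration-time profile.

    ``tau`` (h), when given, additionally reports the AUC over the final
    dosing interval.  Requires at least three positive concentrations on a
    strictly increasing time grid.  When no valid terminal phase can be
    fitted, AUC_inf, lambda_z and t_half are reported as None with a warning.
    """
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(conc_ng_ml, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("time and concentration must be 1-D and equally long")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if len(t) < 3 or int((c > 0).sum()) < 2:
        raise ValueError("need at least three points with two positive concentrations")

    i_tmax = int(np.argmax(c))  # first index of the maximum (tie-break: earliest)
    cmax = float(c[i_tmax])
    tmax = float(t[i_tmax])
    linear_only = len(t) <= SPARSE_LINEAR_THRESHOLD
    auc_last = _auc_trapezoid(t, c, linear_only)

    lam = _terminal_fit(t, c, i_tmax)
    if lam is None:
        warnings.warn("no valid terminal phase; AUC_inf not estimable", stacklevel=2)
        auc_inf = t_half = None
    else:
        auc_inf = auc_last + float(c[-1]) / lam
        t_half = math.log(2.0) / lam

    auc_tau = None
    if tau is not None:
        t0 = t[-1] - tau
        mask = t >= t0 - 1e-9
        if mask.sum() >= 2:
            auc_tau = _auc_trapezoid(t[mask], c[mask], linear_only)
    return PKMetrics(
        cmax=cmax, tmax=tmax, auc_last=auc_last, auc_inf=auc_inf,
        auc_tau=auc_tau, t_half=t_half, lambda_z=lam,
    )


def fold_error(predicted: float, observed: float) -> float:
    """FE = predicted / observed (requires observed > 0)."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    if predicted <= 0:
        raise ValueError("predicted value must be positive")
    return predicted / observed


def gmfe(records: Iterable[ValidationRecord | float]) -> float:
    """Geometric mean fold error, 10^(mean |log10 FE|).

    Accepts ValidationRecords or raw FE values.  The absolute-value
    convention is used so GMFE >= 1 with equality only when every FE = 1.
    """
    fes = [r.fe if isinstance(r, ValidationRecord) else float(r) for r in records]
    if not fes:
        raise ValueError("at least one record is required")
    if any(f <= 0 for f in fes):
        raise ValueError("fold errors must be positive")
    return 10.0 ** (np.mean([abs(math.log10(f)) for f in fes]))


def gof_fractions(
    predicted: Sequence[float], observed: Sequence[float]
) -> Tuple[float, float]:
    """Fractions of prediction/observation pairs within 2-fold and 1.25-fold."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or len(p) == 0:
        raise ValueError("predicted and observed must be equal-length 1-D arrays")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("pairs must be positive")
    ratio = p / o
    within2 = float(np.mean((ratio >= 0.5) & (ratio <= 2.0)))
    within125 = float(np.mean((ratio >= 0.8) & (ratio <= 1.25)))
    return within2, within125


def summarize_validation(
    records: Sequence[ValidationRecord],
) -> ValidationSummary:
    """GMFE plus goodness-of-fit fractions over a set of validation records."""
    if not records:
        raise ValueError("at least one record is required")
    w2, w125 = gof_fractions(
        [r.predicted for r in records], [r.observed for r in records]
    )
    return ValidationSummary(
        records=tuple(records),
        gmfe=gmfe(records),
        n=len(records),
        frac_within_2fold=w2,
        frac_within_1p25fold=w125,
    )


# ---------------------------------------------------------------------------
# Local sensitivity analysis
# ---------------------------------------------------------------------------

def _resolve_and_perturb(ind, compound, regimen, path: str, new_value: float):
    """Return (ind, compound, regimen) with the dotted parameter replaced."""
    block, _, name = path.partition(".")
    if block == "compound":
        return ind, compound.with_params(**{name: new_value}), regimen
    if block == "regimen":
        return ind, compound, replace(regimen, **{name: new_value})
    if block == "individual":
        out = ind.copy()
        if name in out.enzyme_abundance:
            out.enzyme_abundance[name] = new_value
        elif hasattr(out, name):
            setattr(out, name, new_value)
        else:
            raise KeyError(f"unknown individual parameter {name!r}")
        return out, compound, regimen
    raise KeyError(f"parameter path must start with compound/regimen/individual: {path!r}")


def _baseline_value(ind, compound, regimen, path: str) -> float:
    block, _, name = path.partition(".")
    if block == "compound":
        return float(getattr(compound, name))
    if block == "regimen":
        return float(getattr(regimen, name))
    if name in ind.enzyme_abundance:
        return float(ind.enzyme_abundance[name])
    return float(getattr(ind, name))


def local_sensitivity(
    ind,
    compound,
    regimen,
    parameter_path: str,
    metric: str = "auc_inf",
    rel_step: float = 0.10,
    duration: float = 96.0,
    solver=None,
) -> SensitivityResult:
    """Normalized AUC sensitivity to one model parameter.

    ``parameter_path`` is dotted (``compound.fu_plasma``, ``regimen.dose_mg``,
    ``individual.CYP3A4``); ``metric`` is ``auc_inf`` for single dosing or
    ``auc_tau`` for multiple dosing.  Uses a forward +10% perturbation.
    """
    from .engine import DEFAULT_SOLVER, simulate, steady_state_profile

    solver = solver or DEFAULT_SOLVER

    def metric_value(i, c, r) -> float:
        if metric == "auc_tau":
            res = steady_state_profile(i, c, r, solver=solver)
            return float(np.trapezoid(res.plasma_conc, res.time))
        res = simulate(i, c, r, duration, solver=solver)
        return float(np.trapezoid(res.plasma_conc, res.time))

    p0 = _baseline_value(ind, compound, regimen, parameter_path)
    base = metric_value(ind, compound, regimen)
    if base <= 0:
        raise ValueError("baseline AUC must be positive")
    if p0 == 0:
        warnings.warn(
            "zero baseline parameter; using an absolute perturbation", stacklevel=2
        )
        delta_p = rel_step
        s_norm = 1.0  # report dAUC/AUC per absolute unit of the parameter
    else:
        delta_p = p0 * rel_step
        s_norm = rel_step
    i2, c2, r2 = _resolve_and_perturb(
        ind, compound, regimen, parameter_path, p0 + delta_p
    )
    pert = metric_value(i2, c2, r2)
    delta_auc = pert - base
    s = (delta_auc / base) / s_norm
    return SensitivityResult(
        parameter_name=parameter_path, p=p0, delta_p=delta_p,
        delta_auc=delta_auc, s=s,
    )
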