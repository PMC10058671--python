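"""Local sensitivity analysis and predictive-performance metrics.

Normalized sensitivity coefficient (NSC): perturb one parameter by a
fraction ``delta`` (default 1%, forward one-sided), recompute a blood
exposure metric, and report the fractional metric change per fractional
parameter change, ((A - B)/B) / ((C - D)/D).  A coefficient of 1 means a
1% parameter change moves the metric by 1%; magnitudes above 1 amplify
input error.

Fold error FE = P_pred / P_obs; average fold error AFE = 10^(mean log10
FE), the geometric mean.  Predictions within the closed interval
[0.5, 2] count as within two-fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import ConfigurationError, ModelSpec
from .simulate import DoseRegimen, simulate_regimen

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityResult",
    "FoldErrorReport",
    "blood_metric",
    "normalized_sensitivity",
    "sensitivity_scan",
    "fold_error",
    "average_fold_error",
    "fold_error_report",
    "METRICS",
]

METRICS = ("Cmax_blood", "AUC_blood")


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    metric: str
    normalized_coefficient: float
    perturbation: float
    amplifies_input_error: bool = False


@dataclass
class FoldErrorReport:
    fold_errors: dict  # label -> FE
    afe: float
    fraction_within_twofold: float


def blood_metric(spec: ModelSpec, regimen: DoseRegimen, metric: str,
                 analyte: str = "parent",
                 t_end: Optional[float] = None, **solver) -> float:
    """Compute a blood exposure metric (C_max or AUC from zero to the last
    simulated time) from a simulation of ``regimen``."""
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; "
                                 f"choose from {METRICS}")
    res = simulate_regimen(spec, regimen, t_end=t_end, **solver)
    c = res.concentration("blood", analyte)
    if metric == "Cmax_blood":
        return float(np.max(c))
    return float(np.trapezoid(c, res.times))


def normalized_sensitivity(spec: ModelSpec, regimen: DoseRegimen,
                           parameter: str, metric: str = "AUC_blood",
                           delta: float = 0.01, analyte: str = "parent",
                           t_end: Optional[float] = None,
                           **solver) -> SensitivityResult:
    """Forward one-sided NSC of ``metric`` with respect to ``parameter``.

    ``parameter`` may name any disposition parameter of the model (parent
    or metabolite) or ``dose_per_kg`` on the regimen; the original value
    must be strictly positive so a relative perturbation is defined.
    """
    if not delta > 0:
        raise ConfigurationError("perturbation delta must be > 0")
    if parameter == "dose_per_kg":
        original = regimen.dose_per_kg
    else:
        spec.with_parameters(**{parameter: 1.0})  # raises if unknown
        owner = (spec.parent if parameter
                 in type(spec.parent).__dataclass_fields__
                 else spec.metabolite)
        original = getattr(owner, parameter)
    if not original > 0:
        raise ConfigurationError(
            f"{parameter} must be > 0 for a relative perturbation "
            f"(got {original!r})")
    B = blood_metric(spec, regimen, metric, analyte, t_end, **solver)
    if B == 0:
        raise ZeroDivisionError(
            f"baseline {metric} is zero; NSC undefined")
    if parameter == "dose_per_kg":
        spec2, regimen2 = spec, replace(regimen,
                                        dose_per_kg=original * (1 + delta))
    else:
        spec2 = spec.with_parameters(**{parameter: original * (1 + delta)})
        regimen2 = regimen
    A = blood_metric(spec2, regimen2, metric, analyte, t_end, **solver)
    coef = ((A - B) / B) / delta
    return SensitivityResult(parameter=parameter, metric=metric,
                             normalized_coefficient=float(coef),
                             perturbation=delta,
                             amplifies_input_error=abs(coef) > 1.0)


def sensitivity_scan(spec: ModelSpec, regimen: DoseRegimen,
                     parameters: list[str],
                     metrics: list[str] = list(METRICS),
                     delta: float = 0.01, analyte: str = "parent",
                     t_end: Optional[float] = None,
                     **solver) -> list[SensitivityResult]:
    """NSC for every parameter x metric pair, sorted by |coefficient|
    descending."""
    if not parameters or not metrics:
        raise ConfigurationError("parameters and metrics must be nonempty")
    out = [normalized_sensitivity(spec, regimen, p, m, delta, analyte,
                                  t_end, **solver)
           for p in parameters for m in metrics]
    out.sort(key=lambda r: abs(r.normalized_coefficient), reverse=True)
    for r in out:
        if r.amplifies_input_error:
            logger.warning("|NSC| > 1 for %s on %s: %.3f (amplifies input "
                           "error)", r.parameter, r.metric,
                           r.normalized_coefficient)
    return out


def fold_error(p_pred: float, p_obs: float) -> float:
    """FE = predicted / observed; both must be strictly positive."""
    if not (p_pred > 0 and p_obs > 0):
        raise ValueError(
            f"fold error requires positive inputs, got pred={p_pred!r}, "
            f"obs={p_obs!r}")
    return p_pred / p_obs


def average_fold_error(fe_values) -> float:
    """Geometric mean of fold errors, 10^(mean log10 FE)."""
    fe = np.asarray(list(fe_values), dtype=float)
    if fe.size == 0:
        raise ValueError("empty fold-error list")
    if np.any(fe <= 0):
        raise ValueError("fold errors must be strictly positive")
    return float(10.0 ** np.mean(np.log10(fe)))


def fold_error_report(predicted: dict, observed: dict) -> FoldErrorReport:
    """FE per shared key, their AFE, and the fraction within the closed
    two-fold band [0.5, 2]."""
    keys = [k for k in predicted if k in observed]
    if not keys:
        raise ValueError("no shared keys between predictions and "
                         "observations")
    fes = {k: fold_error(predicted[k], observed[k]) for k in keys}
    vals = np.array(list(fes.values()))
    within = float(np.mean((vals >= 0.5) & (vals <= 2.0)))
    return FoldErrorReport(fold_errors=fes, afe=average_fold_error(vals),
                           fraction_within_twofold=within)
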