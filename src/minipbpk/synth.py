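"""Synthetic study-like datasets.

Emulates the hamster study design: two dose groups dosed orally once a day
for three days, a 22-point blood sampling grid spanning 0-72 h, a 13-point
lung/trachea grid, and four animals per time point with destructive tissue
sampling (each tissue animal contributes lung and trachea at one time
point only).  Residual variability is proportional lognormal by default,
mean-corrected so the expected observation equals the model prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import ConfigurationError, ModelSpec
from .simulate import DoseRegimen, simulate_regimen

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "ErrorModel",
    "default_design",
    "generate_dataset",
    "replicate_study",
    "BLOOD_TIMES",
    "TISSUE_TIMES",
]

#: Blood sampling grid (h): predose plus 21 post-dose points over 3 daily
#: doses (0-72 h).
BLOOD_TIMES = (0.0, 0.08, 0.25, 0.5, 0.75, 1, 2, 4, 8, 12, 24, 47,
               48.08, 48.25, 48.5, 48.75, 49, 50, 52, 56, 60, 72)

#: Lung/trachea sampling grid (h), destructive.
TISSUE_TIMES = (0.08, 0.25, 0.5, 0.75, 1, 4, 8, 24, 48.08, 48.25, 48.75,
                52, 72)

_HAMSTER_BW_KG = 0.10201  # mean study body weight


@dataclass(frozen=True)
class StudyDesign:
    dose_groups: dict  # group label -> DoseRegimen
    blood_times: tuple = BLOOD_TIMES
    tissue_times: tuple = TISSUE_TIMES
    n_per_timepoint: int = 4
    matrices: tuple = ("blood", "lung", "trachea")
    destructive_tissues: bool = True
    lloq: dict = field(default_factory=dict)  # (analyte, matrix) -> conc

    def __post_init__(self) -> None:
        for name in ("blood_times", "tissue_times"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
                raise ConfigurationError(
                    f"{name} must be nonnegative and strictly increasing")
        if self.n_per_timepoint < 1:
            raise ConfigurationError("n_per_timepoint must be >= 1")
        bad = set(self.matrices) - {"blood", "plasma", "lung", "trachea"}
        if bad:
            raise ConfigurationError(f"unknown matrices: {sorted(bad)}")


@dataclass(frozen=True)
class ErrorModel:
    """Residual error drawn per record.

    ``proportional_lognormal``: observation = prediction * exp(s*Z - s^2/2)
    with s^2 = ln(1 + cv^2), so E[observation] = prediction exactly.
    ``additive_normal`` adds N(0, sd_additive) and clips at zero;
    ``combined`` applies both.
    """

    kind: str = "proportional_lognormal"
    cv: float = 0.20
    sd_additive: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("proportional_lognormal", "additive_normal",
                             "combined"):
            raise ConfigurationError(f"unknown error kind {self.kind!r}")
        if self.cv < 0 or self.sd_additive < 0:
            raise ConfigurationError("cv and sd_additive must be >= 0")

    def draw(self, predictions: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
        obs = np.asarray(predictions, dtype=float).copy()
        if self.kind in ("proportional_lognormal", "combined") \
                and self.cv > 0:
            s = np.sqrt(np.log1p(self.cv ** 2))
            z = rng.standard_normal(obs.shape)
            obs = obs * np.exp(s * z - 0.5 * s * s)
        if self.kind in ("additive_normal", "combined") \
                and self.sd_additive > 0:
            obs = obs + rng.normal(0.0, self.sd_additive, obs.shape)
        return np.clip(obs, 0.0, None)


def default_design(drug: str = "pyronaridine",
                   n_doses: int = 3) -> StudyDesign:
    """The two-group daily-oral-dosing study design with the standard
    sampling grids and n = 4 animals per time point.

    Doses are 180/360 mg/kg for pyronaridine and 60/120 mg/kg for
    artesunate (the two components of the combination), at the mean study
    body weight.
    """
    if drug == "pyronaridine":
        low, high = 180.0, 360.0
    elif drug == "artesunate":
        low, high = 60.0, 120.0
    else:
        raise ConfigurationError(f"unknown drug {drug!r}")
    groups = {
        "low": DoseRegimen(dose_per_kg=low, body_weight=_HAMSTER_BW_KG,
                           n_doses=n_doses, interval_tau=24.0),
        "high": DoseRegimen(dose_per_kg=high, body_weight=_HAMSTER_BW_KG,
                            n_doses=n_doses, interval_tau=24.0),
    }
    return StudyDesign(dose_groups=groups)


def _predict(spec: ModelSpec, regimen: DoseRegimen, times: np.ndarray,
             **solver) -> dict:
    t_end = max(float(times.max()),
                regimen.start_time + regimen.n_doses * regimen.interval_tau)
    res = simulate_regimen(spec, regimen, t_end=t_end, times=times,
                           **solver)
    out = {}
    for analyte in res.analytes():
        for matrix in ("blood", "plasma", "lung", "trachea"):
            out[(analyte, matrix)] = res.concentrations[analyte][matrix]
    return out


def generate_dataset(spec: ModelSpec, design: StudyDesign,
                     error: ErrorModel, **solver) -> pd.DataFrame:
    """One synthetic observed dataset in the long record format
    (animal_id, dose_group, analyte, matrix, time_h, concentration, units,
    bql).

    Predose (t = 0) records are exact zeros.  Records below the configured
    LLOQ are flagged ``bql`` with the concentration withheld (NaN).
    Destructive tissue sampling shares one animal id across the lung and
    trachea records drawn at the same time point.
    """
    rng = np.random.default_rng(error.seed)
    units = "ng/mL" if spec.unit_mode == "mass_ng" else "nmol/L"
    blood_like = [m for m in design.matrices if m in ("blood", "plasma")]
    tissue = [m for m in design.matrices if m in ("lung", "trachea")]
    rows = []
    for group, regimen in design.dose_groups.items():
        all_times = np.unique(np.concatenate(
            [np.asarray(design.blood_times, dtype=float),
             np.asarray(design.tissue_times, dtype=float)]))
        pred = _predict(spec, regimen, all_times, **solver)
        t_index = {t: i for i, t in enumerate(all_times)}

        def emit(analyte: str, matrix: str, times, animal_fmt: str) -> None:
            for t in times:
                p = pred[(analyte, matrix)][t_index[t]]
                for rep in range(design.n_per_timepoint):
                    if t == 0.0 and regimen.start_time == 0.0:
                        value = 0.0
                    else:
                        value = float(error.draw(np.array([p]), rng)[0])
                    lloq = design.lloq.get((analyte, matrix))
                    bql = bool(lloq is not None and value < lloq)
                    rows.append({
                        "animal_id": animal_fmt.format(group=group,
                                                       t=t, rep=rep + 1),
                        "dose_group": group, "analyte": analyte,
                        "matrix": matrix, "time_h": float(t),
                        "concentration": (np.nan if bql else value),
                        "units": units, "bql": bql})

        analyte_names = [spec.parent_name]
        if spec.kind == "parent_metabolite":
            analyte_names.append(spec.metabolite_name)
        for analyte in analyte_names:
            for matrix in blood_like:
                emit(analyte, matrix, design.blood_times,
                     "B-{group}-t{t:g}-{rep}")
            for matrix in tissue:
                # destructive sampling: the same four animals supply lung
                # and trachea at each tissue time point
                fmt = ("T-{group}-t{t:g}-{rep}" if design.destructive_tissues
                       else "T-{group}-" + matrix + "-t{t:g}-{rep}")
                emit(analyte, matrix, design.tissue_times, fmt)
    df = pd.DataFrame(rows)
    logger.info("generated %d synthetic records (%d groups, n=%d per "
                "time point)", len(df), len(design.dose_groups),
                design.n_per_timepoint)
    return df


def replicate_study(spec: ModelSpec, design: StudyDesign, error: ErrorModel,
                    n_replicates: int, **solver) -> list[pd.DataFrame]:
    """Independent replicate datasets with seeds ``seed + 0 .. n-1``."""
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    from dataclasses import replace
    return [generate_dataset(spec, design,
                             replace(error, seed=error.seed + i), **solver)
            for i in range(n_replicates)]
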