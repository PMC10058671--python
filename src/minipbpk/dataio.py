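"""File formats, configuration loading, and the end-to-end pipeline.

Concentration datasets are long-format CSV with the columns
``animal_id, dose_group, analyte, matrix, time_h, concentration, units,
bql``.  Model and run configuration is TOML with sections
``[physiology]``, ``[parent]``, ``[metabolite]``, ``[options]``,
``[[regimen]]`` and ``[run]``; parsing is strict — any unknown key fails
loudly so a typo like ``K_lung`` vs ``K_lung_m`` cannot silently fall back
to a default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .model import (ConfigurationError, DispositionParameters,
                    MetaboliteDispositionParameters, ModelSpec,
                    MOLAR_MASSES, PhysiologicalParameters)
from .simulate import DoseRegimen

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetError",
    "PipelineError",
    "RunConfig",
    "DATASET_COLUMNS",
    "ANALYTES",
    "MATRICES",
    "read_dataset",
    "write_dataset",
    "load_config",
    "builtin_config_path",
    "run_pipeline",
]

DATASET_COLUMNS = ("animal_id", "dose_group", "analyte", "matrix",
                   "time_h", "concentration", "units", "bql")
ANALYTES = ("pyronaridine", "artesunate", "dihydroartemisinin")
MATRICES = ("blood", "plasma", "lung", "trachea")


class DatasetError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "minipbpk_out"
    log_level: str = "INFO"
    rtol: float = 1e-8
    atol: Optional[float] = None
    grid_step: Optional[float] = None
    cv: float = 0.20
    per_group_fit: bool = True
    n_starts: int = 4
    free_parameters: Optional[dict] = None


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def read_dataset(path) -> pd.DataFrame:
    """Read and validate a long-format concentration dataset CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DatasetError(f"{path}: empty file (no header)") from exc
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing column(s) {missing}")
    for col in ("time_h", "concentration"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()
                       & ~df[col].astype(str).str.lower().isin(["nan", ""])]
        if len(bad):
            raise DatasetError(
                f"{path}: unparseable {col} at row(s) "
                f"{(bad + 2).tolist()[:5]}")
        df[col] = vals
    df["bql"] = df["bql"].astype(bool)
    for i, row in df.iterrows():
        where = f"{path}: row {i + 2}"
        if row["analyte"] not in ANALYTES:
            raise DatasetError(f"{where}: unknown analyte "
                               f"{row['analyte']!r}")
        if row["matrix"] not in MATRICES:
            raise DatasetError(f"{where}: unknown matrix "
                               f"{row['matrix']!r}")
        if not row["time_h"] >= 0:
            raise DatasetError(f"{where}: negative time {row['time_h']!r}")
        if not row["bql"] and not row["concentration"] >= 0:
            raise DatasetError(
                f"{where}: concentration must be >= 0 or bql set")
    units = df.groupby("analyte")["units"].nunique()
    mixed = units[units > 1]
    if len(mixed):
        raise DatasetError(
            f"{path}: inconsistent units for analyte(s) "
            f"{mixed.index.tolist()}")
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a dataset CSV at full (round-tripping) precision."""
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"refusing to write dataset missing {missing}")
    df.loc[:, DATASET_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_PHYS_KEYS = {"V_total", "V_blood", "V_lung", "V_trachea", "V_rest",
              "Q_co", "Q_trachea", "Q_rest", "trachea_co_fraction"}
_OPTION_KEYS = {"kind", "unit_mode", "metabolite_trachea_form",
                "parent_name", "metabolite_name", "molar_mass",
                "salt_factor"}
_REGIMEN_KEYS = {"dose_per_kg", "body_weight", "n_doses", "interval_tau",
                 "start_time", "label"}
_RUN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}
_TOP_KEYS = {"physiology", "parent", "metabolite", "options", "regimen",
             "run"}


def _strict(section: dict, allowed: set, where: str,
            problems: list) -> None:
    unknown = set(section) - allowed
    if unknown:
        problems.append(f"unknown key(s) in [{where}]: {sorted(unknown)}")


def builtin_config_path(name: str):
    """Path to a bundled model configuration (``pyronaridine`` or
    ``artesunate``)."""
    ref = resources.files("minipbpk") / "configs" / f"{name}.toml"
    if not ref.is_file():
        raise ConfigurationError(f"no bundled config named {name!r}")
    return ref


def load_config(path) -> tuple[ModelSpec, list[DoseRegimen], RunConfig]:
    """Load and validate a TOML model/run configuration.

    ``V_rest``, ``Q_rest`` (and ``Q_trachea`` from ``trachea_co_fraction``)
    are derived when omitted and echoed to the log.  All validation
    failures are collected and reported together.
    """
    data = tomllib.loads(Path(path).read_text())
    problems: list[str] = []
    _strict(data, _TOP_KEYS, "top level", problems)
    phys_sec = data.get("physiology", {})
    parent_sec = data.get("parent", {})
    met_sec = data.get("metabolite")
    opt_sec = data.get("options", {})
    run_sec = data.get("run", {})
    _strict(phys_sec, _PHYS_KEYS, "physiology", problems)
    _strict(parent_sec,
            set(DispositionParameters.__dataclass_fields__), "parent",
            problems)
    if met_sec is not None:
        _strict(met_sec,
                set(MetaboliteDispositionParameters.__dataclass_fields__),
                "metabolite", problems)
    _strict(opt_sec, _OPTION_KEYS, "options", problems)
    _strict(run_sec, _RUN_KEYS, "run", problems)
    for i, reg in enumerate(data.get("regimen", [])):
        _strict(reg, _REGIMEN_KEYS, f"regimen #{i + 1}", problems)
    if problems:
        raise ConfigurationError("; ".join(problems))

    try:
        phys_kwargs = dict(phys_sec)
        if "V_rest" in phys_kwargs and "Q_rest" in phys_kwargs \
                and "Q_trachea" in phys_kwargs:
            phys = PhysiologicalParameters(**phys_kwargs)
        else:
            phys_kwargs.pop("V_rest", None)
            phys_kwargs.pop("Q_rest", None)
            phys = PhysiologicalParameters.from_totals(**phys_kwargs)
        logger.info("physiology: V_rest=%.4g mL, Q_trachea=%.4g mL/h, "
                    "Q_rest=%.4g mL/h", phys.V_rest, phys.Q_trachea,
                    phys.Q_rest)
        parent = DispositionParameters(**parent_sec)
        metabolite = (MetaboliteDispositionParameters(**met_sec)
                      if met_sec is not None else None)
        opt = dict(opt_sec)
        kind = opt.pop("kind",
                       "parent_metabolite" if metabolite else "single")
        parent_name = opt.pop("parent_name", "parent")
        molar_mass = opt.pop("molar_mass",
                             MOLAR_MASSES.get(parent_name))
        spec = ModelSpec(kind=kind, phys=phys, parent=parent,
                         metabolite=metabolite, parent_name=parent_name,
                         molar_mass=molar_mass, **opt)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc

    regimens = []
    for reg in data.get("regimen", []):
        reg = dict(reg)
        reg.pop("label", None)
        regimens.append(DoseRegimen(**reg))
    run = RunConfig(**run_sec)
    return spec, regimens, run


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config_path, out_dir: Optional[str] = None,
                 seed: Optional[int] = None) -> dict:
    """generate -> fit -> nca -> sensitivity -> validate, writing all
    artifacts (CSV/JSON plus run metadata) under the output directory.

    Returns a mapping of stage name to the artifact path(s) written.  A
    stage failure raises :class:`PipelineError` naming the stage; partial
    outputs are preserved.
    """
    from . import evaluation, fitting, nca, synth  # local: avoid cycles
    from .simulate import simulate_regimen

    spec, regimens, run = load_config(config_path)
    if out_dir is not None:
        run.out_dir = out_dir
    if seed is not None:
        run.seed = seed
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=run.log_level)
    logger.info("run options in effect: metabolite_trachea_form=%s, "
                "terminal window = last dose + %g h",
                spec.metabolite_trachea_form, nca.TERMINAL_WINDOW_LAG)
    artifacts: dict[str, str] = {}
    if not regimens:
        raise PipelineError("stage 'generate': config defines no "
                            "[[regimen]] entries")
    groups = {f"group{i + 1}": r for i, r in enumerate(regimens)}
    solver = {"rtol": run.rtol}

    stage = "generate"
    try:
        design = synth.StudyDesign(dose_groups=groups)
        error = synth.ErrorModel(cv=run.cv, seed=run.seed)
        dataset = synth.generate_dataset(spec, design, error, **solver)
        data_path = out / "synthetic_data.csv"
        write_dataset(dataset, data_path)
        artifacts[stage] = str(data_path)

        stage = "fit"
        free = run.free_parameters or {
            "k_a": (spec.parent.k_a, spec.parent.k_a / 100,
                    spec.parent.k_a * 100),
            "CL_F": (spec.parent.CL_F, spec.parent.CL_F / 100,
                     spec.parent.CL_F * 100),
            "K_lung": (spec.parent.K_lung, spec.parent.K_lung / 100,
                       spec.parent.K_lung * 100),
            "K_trachea": (spec.parent.K_trachea,
                          spec.parent.K_trachea / 100,
                          spec.parent.K_trachea * 100),
        }
        fit_report: dict = {"weighting": "one_over_pred_sq", "groups": {}}
        fit_groups = ([(g, dataset[dataset["dose_group"] == g], {g: r})
                       for g, r in groups.items()]
                      if run.per_group_fit
                      else [("joint", dataset, groups)])
        for label, subset, regs in fit_groups:
            problem = fitting.FitProblem(spec=spec, data=subset,
                                         free_parameters=free,
                                         regimens=regs)
            result = fitting.fit_model(problem, n_starts=run.n_starts,
                                       seed=run.seed)
            fit_report["groups"][label] = {
                "estimates": result.estimates,
                "objective": result.objective_value,
                "n_obs": result.n_obs,
                "converged": result.converged,
                "poorly_identifiable": result.poorly_identifiable,
            }
        fit_path = out / "fit.json"
        fit_path.write_text(json.dumps(fit_report, indent=2))
        artifacts[stage] = str(fit_path)

        stage = "nca"
        rows = []
        for g, regimen in groups.items():
            last_dose = regimen.start_time \
                + (regimen.n_doses - 1) * regimen.interval_tau
            for analyte in ([spec.parent_name, spec.metabolite_name]
                            if spec.kind == "parent_metabolite"
                            else [spec.parent_name]):
                for matrix in ("blood", "lung", "trachea"):
                    series = nca.pooled_series(dataset, analyte, matrix, g)
                    report = nca.nca_report(series, regimen.interval_tau,
                                            last_dose_time=last_dose)
                    rows.extend(report.to_records())
        nca_path = out / "nca.csv"
        pd.DataFrame(rows).to_csv(nca_path, index=False)
        artifacts[stage] = str(nca_path)

        stage = "sensitivity"
        params = ["k_a", "CL_F", "K_lung", "K_trachea", "K_rest", "k_tl",
                  "k_lt"]
        scan = evaluation.sensitivity_scan(spec, regimens[0], params,
                                           **solver)
        sens_path = out / "sensitivity.csv"
        pd.DataFrame([dataclasses.asdict(s) for s in scan]).to_csv(
            sens_path, index=False)
        artifacts[stage] = str(sens_path)

        stage = "validate"
        fe_rows = []
        for g, regimen in groups.items():
            t_end = regimen.start_time \
                + regimen.n_doses * regimen.interval_tau
            sim = simulate_regimen(spec, regimen, t_end=t_end, **solver)
            for analyte in sim.analytes():
                for matrix in ("blood", "lung", "trachea"):
                    series = nca.pooled_series(dataset, analyte, matrix, g)
                    obs_cmax, _ = nca.cmax_tmax(series)
                    obs_auc = nca.auc_trapezoid(series)
                    pred_c = sim.concentrations[analyte][matrix]
                    lo, hi = series.times[0], series.times[-1]
                    m = (sim.times >= lo) & (sim.times <= hi)
                    pred_cmax = float(np.max(pred_c[m]))
                    pred_auc = float(np.trapezoid(pred_c[m], sim.times[m]))
                    for name, p, o in (("C_max", pred_cmax, obs_cmax),
                                       ("AUC_t", pred_auc, obs_auc)):
                        if o > 0:
                            fe_rows.append({
                                "dose_group": g, "analyte": analyte,
                                "matrix": matrix, "parameter": name,
                                "FE": evaluation.fold_error(p, o)})
        fe_df = pd.DataFrame(fe_rows)
        fe_df["within_twofold"] = (fe_df["FE"] >= 0.5) & (fe_df["FE"] <= 2)
        fe_path = out / "fold_errors.csv"
        fe_df.to_csv(fe_path, index=False)
        artifacts[stage] = str(fe_path)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    meta = {
        "package_version": __version__,
        "seed": run.seed,
        "config": str(config_path),
        "solver": {"rtol": run.rtol, "method": "LSODA"},
        "options": {
            "metabolite_trachea_form": spec.metabolite_trachea_form,
            "unit_mode": spec.unit_mode,
            "terminal_window_lag_h": nca.TERMINAL_WINDOW_LAG,
            "error_model": {"kind": "proportional_lognormal",
                            "cv": run.cv},
            "per_group_fit": run.per_group_fit,
        },
        "versions": {"numpy": np.__version__,
                     "pandas": pd.__version__},
        "artifacts": artifacts,
    }
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    artifacts["metadata"] = str(meta_path)
    return artifacts
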