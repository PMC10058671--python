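"""Noncompartmental analysis of concentration-time series.

Model-independent PK parameter estimation: C_max/T_max by direct
observation, AUC by the linear trapezoidal rule, terminal elimination rate
by log-linear ordinary least squares, C_avg = AUC_tau / tau, and the
accumulation ratio AUC_tau(steady state) / AUC_0-24(day 1).

Sparse destructive sampling gives each animal only a few observations, so
observed-style datasets are reduced to one pooled profile per
analyte/matrix/dose group by arithmetic averaging across animals at each
time point (naive pooling) before any of the estimators run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConcentrationSeries",
    "HalfLifeFit",
    "NCAReport",
    "auc_trapezoid",
    "terminal_halflife",
    "cmax_tmax",
    "cavg",
    "accumulation_ratio",
    "tissue_to_blood_ratio",
    "pooled_series",
    "nca_report",
    "TERMINAL_WINDOW_LAG",
]

#: Default terminal-regression window start: this many hours after the
#: final dose (the regression window materially affects the half-life, so
#: it is always recorded in the result).
TERMINAL_WINDOW_LAG = 4.0


@dataclass(frozen=True)
class ConcentrationSeries:
    times: np.ndarray
    concentrations: np.ndarray
    matrix: str = ""
    analyte: str = ""
    dose_group: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be matching "
                             "1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class HalfLifeFit:
    """Terminal log-linear regression result.  ``flagged`` is set (and the
    half-life left as nan) when the fitted slope is nonnegative."""

    k_e: float
    t_half: float
    n_points: int
    r_squared: float
    window: tuple[float, float]
    flagged: bool = False


def auc_trapezoid(series: ConcentrationSeries, t0: Optional[float] = None,
                  t1: Optional[float] = None) -> float:
    """Linear trapezoidal AUC over ``[t0, t1]``; window endpoints not on
    the sampling grid are linearly interpolated."""
    t, c = series.times, series.concentrations
    if t.size < 2:
        raise ValueError("at least two points are required for an AUC")
    if t0 is None:
        t0 = float(t[0])
    if t1 is None:
        t1 = float(t[-1])
    if t1 <= t0:
        raise ValueError(f"t1={t1} must exceed t0={t0}")
    if t0 < t[0] or t1 > t[-1]:
        raise ValueError("AUC window extends beyond the sampled span")
    inside = (t > t0) & (t < t1)
    if inside.sum() + 2 < 2:  # pragma: no cover - arithmetic guard
        raise ValueError("fewer than two points in the window")
    tw = np.concatenate([[t0], t[inside], [t1]])
    cw = np.concatenate([[np.interp(t0, t, c)], c[inside],
                         [np.interp(t1, t, c)]])
    return float(np.trapezoid(cw, tw))


def terminal_halflife(series: ConcentrationSeries,
                      window: Optional[tuple[float, float]] = None,
                      last_dose_time: Optional[float] = None,
                      ) -> HalfLifeFit:
    """Terminal elimination rate by OLS on ln(C) vs t; t_half = ln2 / k_e.

    The regression window is ``window`` if given; otherwise all samples
    strictly after ``last_dose_time + TERMINAL_WINDOW_LAG`` (or, with no
    dose information, strictly after T_max).  BLQ/zero concentrations are
    excluded; at least three positive points are required.
    """
    t, c = series.times, series.concentrations
    if window is None:
        if last_dose_time is not None:
            lo = last_dose_time + TERMINAL_WINDOW_LAG
        else:
            lo = float(t[int(np.argmax(c))])
        window = (lo, float(t[-1]))
    lo, hi = window
    mask = (t > lo) & (t <= hi) & (c > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"terminal regression needs >=3 positive points in ({lo}, {hi}]"
            f"; found {int(mask.sum())}")
    res = stats.linregress(t[mask], np.log(c[mask]))
    k_e = -res.slope
    if k_e <= 0:
        logger.warning("nonnegative terminal slope in window %s; no "
                       "half-life reported", window)
        return HalfLifeFit(k_e=float(k_e), t_half=float("nan"),
                           n_points=int(mask.sum()),
                           r_squared=float(res.rvalue**2),
                           window=(float(lo), float(hi)), flagged=True)
    return HalfLifeFit(k_e=float(k_e), t_half=float(np.log(2) / k_e),
                       n_points=int(mask.sum()),
                       r_squared=float(res.rvalue**2),
                       window=(float(lo), float(hi)))


def cmax_tmax(series: ConcentrationSeries) -> tuple[float, float]:
    """Maximum observed concentration and its earliest time."""
    if len(series) == 0:
        raise ValueError("empty series")
    i = int(np.argmax(series.concentrations))  # argmax returns first max
    return float(series.concentrations[i]), float(series.times[i])


def cavg(auc_tau: float, tau: float) -> float:
    """Interval-average concentration AUC_tau / tau."""
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau!r}")
    return auc_tau / tau


def accumulation_ratio(auc_tau_ss: float, auc_day1: float) -> float:
    """AUC over one dosing interval at steady state divided by the day-1
    AUC over the same interval length."""
    if not auc_day1 > 0:
        raise ValueError(f"day-1 AUC must be > 0, got {auc_day1!r}")
    return auc_tau_ss / auc_day1


def tissue_to_blood_ratio(blood, tissue, t0: Optional[float] = None,
                          t1: Optional[float] = None) -> float:
    """AUC_tissue / AUC_blood over a common window.

    Accepts two :class:`ConcentrationSeries` (windows must be coverable by
    both) or two precomputed AUC values.
    """
    if isinstance(blood, ConcentrationSeries):
        if not isinstance(tissue, ConcentrationSeries):
            raise ValueError("blood and tissue must both be series or both "
                             "be AUC values")
        lo = t0 if t0 is not None else max(blood.times[0], tissue.times[0])
        hi = t1 if t1 is not None else min(blood.times[-1], tissue.times[-1])
        if hi <= lo:
            raise ValueError("blood and tissue windows do not overlap")
        auc_b = auc_trapezoid(blood, lo, hi)
        auc_t = auc_trapezoid(tissue, lo, hi)
    else:
        auc_b, auc_t = float(blood), float(tissue)
    if not auc_b > 0:
        raise ValueError("blood AUC must be > 0")
    return auc_t / auc_b


def pooled_series(dataset: pd.DataFrame, analyte: str, matrix: str,
                  dose_group: Optional[str] = None,
                  bql_as_zero: bool = True) -> ConcentrationSeries:
    """Naive-pooled profile: arithmetic mean concentration across animals
    at each sampling time.  BLQ records enter the mean as zero when
    ``bql_as_zero`` (the default), otherwise they are dropped."""
    df = dataset[(dataset["analyte"] == analyte)
                 & (dataset["matrix"] == matrix)]
    if dose_group is not None:
        df = df[df["dose_group"] == dose_group]
    if df.empty:
        raise ValueError(
            f"no records for analyte={analyte!r}, matrix={matrix!r}, "
            f"dose_group={dose_group!r}")
    df = df.copy()
    if "bql" in df.columns:
        if bql_as_zero:
            df.loc[df["bql"].astype(bool), "concentration"] = 0.0
        else:
            df = df[~df["bql"].astype(bool)]
    mean = df.groupby("time_h")["concentration"].mean().sort_index()
    return ConcentrationSeries(times=mean.index.to_numpy(dtype=float),
                               concentrations=mean.to_numpy(dtype=float),
                               matrix=matrix, analyte=analyte,
                               dose_group=dose_group or "")


@dataclass
class NCAReport:
    analyte: str
    matrix: str
    dose_group: str
    C_max: float
    T_max: float
    auc: dict = field(default_factory=dict)  # window label -> AUC
    half_life: Optional[HalfLifeFit] = None
    C_avg: dict = field(default_factory=dict)  # window label -> C_avg
    accumulation: Optional[float] = None

    def to_records(self) -> list[dict]:
        rows = [
            {"parameter": "C_max", "window": "", "value": self.C_max},
            {"parameter": "T_max", "window": "", "value": self.T_max},
        ]
        for label, v in self.auc.items():
            rows.append({"parameter": "AUC", "window": label, "value": v})
        for label, v in self.C_avg.items():
            rows.append({"parameter": "C_avg", "window": label, "value": v})
        if self.half_life is not None and not self.half_life.flagged:
            w = self.half_life.window
            rows.append({"parameter": "t_half",
                         "window": f"{w[0]:g}-{w[1]:g}",
                         "value": self.half_life.t_half})
            rows.append({"parameter": "k_e",
                         "window": f"{w[0]:g}-{w[1]:g}",
                         "value": self.half_life.k_e})
        if self.accumulation is not None:
            rows.append({"parameter": "accumulation_ratio", "window": "",
                         "value": self.accumulation})
        for r in rows:
            r.update(analyte=self.analyte, matrix=self.matrix,
                     dose_group=self.dose_group)
        return rows


def nca_report(series: ConcentrationSeries, tau: float,
               windows: Optional[dict[str, tuple[float, float]]] = None,
               last_dose_time: Optional[float] = None) -> NCAReport:
    """Full NCA of one pooled series.

    ``windows`` maps labels to (t0, t1) AUC windows; defaults to day 1
    ``(0, tau)`` and, when the span allows, the final whole interval
    (labelled ``ss``).  The accumulation ratio is reported when both the
    day-1 and ``ss`` windows are present.
    """
    t_start = float(series.times[0])
    t_end = float(series.times[-1])
    if windows is None:
        # default windows are clipped to the sampled span (tissue grids
        # start just after dosing, not at 0)
        windows = {"day1": (max(0.0, t_start), min(tau, t_end))}
        n_complete = int(np.floor(t_end / tau + 1e-9))
        if n_complete >= 2:
            windows["ss"] = (max((n_complete - 1) * tau, t_start),
                             n_complete * tau)
        windows = {k: (lo, hi) for k, (lo, hi) in windows.items()
                   if hi > lo}
    C_max, T_max = cmax_tmax(series)
    aucs = {label: auc_trapezoid(series, lo, hi)
            for label, (lo, hi) in windows.items()}
    cavgs = {label: cavg(aucs[label], hi - lo)
             for label, (lo, hi) in windows.items()}
    try:
        hl = terminal_halflife(series, last_dose_time=last_dose_time)
    except ValueError as exc:
        logger.info("no terminal half-life for %s/%s: %s",
                    series.analyte, series.matrix, exc)
        hl = None
    acc = None
    if "day1" in aucs and "ss" in aucs and aucs["day1"] > 0:
        acc = accumulation_ratio(aucs["ss"], aucs["day1"])
    return NCAReport(analyte=series.analyte, matrix=series.matrix,
                     dose_group=series.dose_group, C_max=C_max,
                     T_max=T_max, auc=aucs, half_life=hl, C_avg=cavgs,
                     accumulation=acc)
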