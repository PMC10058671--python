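"""Minimal PBPK model core: parameter types, ODE right-hand sides, and
closed-form linear-balance oracles.

The model lumps a hamster into five compartments — an oral absorption
depot, blood, lung, trachea, and the rest of the body — connected by blood
flows under perfusion rate-limited kinetics: each tissue equilibrates
instantaneously with its local blood, governed by a tissue-to-blood
partition coefficient ``K_tissue``.  Lung and trachea additionally exchange
drug directly through first-order transfer rate constants (``k_lt``,
``k_tl``), reflecting the mucociliary/airway connection between the two
target tissues.  Elimination is a single apparent oral clearance ``CL/F``
acting on blood.  For a prodrug/metabolite pair (artesunate →
dihydroartemisinin) the parent clearance term feeds the metabolite blood
compartment mole-for-mole, and the metabolite has its own partition
coefficients, exchange constants, and clearance.

Canonical internal units: amounts in ng (``mass_ng`` mode) or nmol
(``molar_nmol`` mode), volumes in mL, time in h, flows in mL/h.  Clearances
are supplied in L/h (as tabulated) and converted to mL/h internally, so
internal concentrations are amount/mL.  Reported concentrations are ng/mL
(mass mode) or nmol/L (molar mode, i.e. internal value x 1000).

The system is linear and time-invariant between dose events, so the
right-hand side is ``dA/dt = M @ A`` for a constant matrix ``M`` built by
:func:`system_matrix`; the same matrix serves as the analytic Jacobian for
the stiff integrator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterError",
    "ConfigurationError",
    "MOLAR_MASSES",
    "PhysiologicalParameters",
    "DispositionParameters",
    "MetaboliteDispositionParameters",
    "ModelSpec",
    "SINGLE_COMPARTMENTS",
    "PARENT_METABOLITE_COMPARTMENTS",
    "system_matrix",
    "derivatives_single",
    "derivatives_parent_metabolite",
    "steady_state_ratio_oracle",
    "integrated_auc_ratio_oracle",
    "blood_plasma_convert",
]


class ParameterError(ValueError):
    """A physiological or disposition parameter violates its constraints."""


class ConfigurationError(ValueError):
    """A model/run configuration is internally inconsistent."""


#: Molar masses in g/mol, used only for mg -> nmol dose conversion in the
#: molar unit mode.  Standard reference values (free base for pyronaridine);
#: overridable through the ``molar_mass`` config option.
MOLAR_MASSES: dict[str, float] = {
    "pyronaridine": 518.05,
    "artesunate": 384.42,
    "dihydroartemisinin": 284.35,
}

#: State ordering for the single-analyte model.
SINGLE_COMPARTMENTS = ("absorption", "blood", "lung", "trachea", "rest")

#: State ordering for the parent-metabolite model (parent first).
PARENT_METABOLITE_COMPARTMENTS = SINGLE_COMPARTMENTS + (
    "blood_m",
    "lung_m",
    "trachea_m",
    "rest_m",
)

_REL_TOL = 1e-9


@dataclass(frozen=True)
class PhysiologicalParameters:
    """Fixed hamster physiology: compartment volumes (mL) and blood flows
    (mL/h).

    ``V_rest`` must equal ``V_total - (V_blood + V_lung + V_trachea)`` and
    ``Q_rest`` must equal ``Q_co - Q_trachea``; both are checked to 1e-9
    relative tolerance so a hand-edited config cannot silently break mass
    balance.
    """

    V_total: float
    V_blood: float
    V_lung: float
    V_trachea: float
    V_rest: float
    Q_co: float
    Q_trachea: float
    Q_rest: float

    def __post_init__(self) -> None:
        problems = []
        for name in ("V_total", "V_blood", "V_lung", "V_trachea", "V_rest",
                     "Q_co", "Q_trachea", "Q_rest"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be strictly positive, got "
                                f"{getattr(self, name)!r}")
        v_rest = self.V_total - (self.V_blood + self.V_lung + self.V_trachea)
        if abs(self.V_rest - v_rest) > _REL_TOL * max(abs(v_rest), 1.0):
            problems.append(
                f"V_rest={self.V_rest} inconsistent with "
                f"V_total - (V_blood + V_lung + V_trachea) = {v_rest}")
        q_rest = self.Q_co - self.Q_trachea
        if abs(self.Q_rest - q_rest) > _REL_TOL * max(abs(q_rest), 1.0):
            problems.append(
                f"Q_rest={self.Q_rest} inconsistent with "
                f"Q_co - Q_trachea = {q_rest}")
        if problems:
            raise ParameterError("; ".join(problems))

    @classmethod
    def from_totals(cls, V_total: float, V_blood: float, V_lung: float,
                    V_trachea: float, Q_co: float,
                    Q_trachea: Optional[float] = None,
                    trachea_co_fraction: Optional[float] = None,
                    ) -> "PhysiologicalParameters":
        """Build a consistent set, deriving ``V_rest``/``Q_rest`` (and
        ``Q_trachea`` from a cardiac-output fraction if given)."""
        if Q_trachea is None:
            if trachea_co_fraction is None:
                raise ParameterError(
                    "either Q_trachea or trachea_co_fraction is required")
            Q_trachea = Q_co * trachea_co_fraction
        elif trachea_co_fraction is not None:
            raise ParameterError(
                "give Q_trachea or trachea_co_fraction, not both")
        return cls(
            V_total=V_total, V_blood=V_blood, V_lung=V_lung,
            V_trachea=V_trachea,
            V_rest=V_total - (V_blood + V_lung + V_trachea),
            Q_co=Q_co, Q_trachea=Q_trachea, Q_rest=Q_co - Q_trachea)


@dataclass(frozen=True)
class DispositionParameters:
    """Fitted biochemical parameters of one analyte.

    ``CL_F`` is the apparent oral clearance in L/h (clearance over
    bioavailability); partition coefficients are unitless tissue-to-blood
    ratios; ``k_tl``/``k_lt`` are the trachea->lung and lung->trachea
    first-order exchange constants in 1/h.  ``K_bp`` is the blood-to-plasma
    concentration ratio used only to report plasma concentrations.
    """

    k_a: float
    CL_F: float
    K_lung: float
    K_trachea: float
    K_rest: float
    k_tl: float
    k_lt: float
    K_bp: float = 1.0

    def __post_init__(self) -> None:
        problems = []
        for name in ("k_a", "CL_F", "K_lung", "K_trachea", "K_rest",
                     "k_tl", "k_lt"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0, got "
                                f"{getattr(self, name)!r}")
        if not self.K_bp > 0:
            problems.append(f"K_bp must be > 0, got {self.K_bp!r}")
        if problems:
            raise ParameterError("; ".join(problems))


@dataclass(frozen=True)
class MetaboliteDispositionParameters:
    """Disposition parameters of the metabolite (no absorption: it is
    formed in blood from the parent clearance term)."""

    CLm_F: float
    K_lung_m: float
    K_trachea_m: float
    K_rest_m: float
    k_tl_m: float
    k_lt_m: float
    K_bp_m: float = 1.0

    def __post_init__(self) -> None:
        problems = []
        for name in ("CLm_F", "K_lung_m", "K_trachea_m", "K_rest_m",
                     "k_tl_m", "k_lt_m"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0, got "
                                f"{getattr(self, name)!r}")
        if not self.K_bp_m > 0:
            problems.append(f"K_bp_m must be > 0, got {self.K_bp_m!r}")
        if problems:
            raise ParameterError("; ".join(problems))


@dataclass(frozen=True)
class ModelSpec:
    """A fully-specified minimal PBPK model.

    ``metabolite_trachea_form`` selects the return term of the metabolite
    trachea equation: ``as_printed`` uses the lung partition coefficient in
    the trachea outflow (C_lung,m * Q_trachea / K_lung,m), which is the
    form the source model was fitted with; ``mass_balanced`` uses the
    trachea's own coefficient (C_trachea,m * Q_trachea / K_trachea,m) so
    inter-compartment terms cancel pairwise.  Only the mass_balanced form
    conserves metabolite moles exactly; see the methods note.
    """

    kind: str  # "single" | "parent_metabolite"
    phys: PhysiologicalParameters
    parent: DispositionParameters
    metabolite: Optional[MetaboliteDispositionParameters] = None
    unit_mode: str = "mass_ng"  # "mass_ng" | "molar_nmol"
    metabolite_trachea_form: str = "as_printed"
    parent_name: str = "parent"
    metabolite_name: str = "metabolite"
    molar_mass: Optional[float] = None  # g/mol of the dosed parent
    salt_factor: float = 1.0  # dose multiplier (salt -> active moiety)

    def __post_init__(self) -> None:
        if self.kind not in ("single", "parent_metabolite"):
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        if self.unit_mode not in ("mass_ng", "molar_nmol"):
            raise ConfigurationError(f"unknown unit_mode {self.unit_mode!r}")
        if self.metabolite_trachea_form not in ("as_printed", "mass_balanced"):
            raise ConfigurationError(
                f"unknown metabolite_trachea_form "
                f"{self.metabolite_trachea_form!r}")
        if (self.kind == "parent_metabolite") != (self.metabolite is not None):
            raise ConfigurationError(
                "metabolite parameters must be present iff "
                "kind='parent_metabolite'")
        if self.kind == "parent_metabolite" and self.unit_mode != "molar_nmol":
            raise ConfigurationError(
                "parent_metabolite models require unit_mode='molar_nmol'; "
                "mole-conserving conversion is undefined in mass units")
        if not self.salt_factor > 0:
            raise ConfigurationError("salt_factor must be > 0")

    @property
    def n_states(self) -> int:
        return 5 if self.kind == "single" else 9

    @property
    def compartments(self) -> tuple:
        return (SINGLE_COMPARTMENTS if self.kind == "single"
                else PARENT_METABOLITE_COMPARTMENTS)

    def analyte_label(self, which: str) -> str:
        """Map 'parent'/'metabolite' (or an explicit name) to the analyte
        name used in datasets and results."""
        if which == "parent" or which == self.parent_name:
            return self.parent_name
        if which == "metabolite" or which == self.metabolite_name:
            if self.kind != "parent_metabolite":
                raise ConfigurationError(
                    "single-analyte model has no metabolite")
            return self.metabolite_name
        raise ConfigurationError(f"unknown analyte {which!r}")

    def with_parameters(self, **values: float) -> "ModelSpec":
        """Return a copy with the named disposition parameters replaced.

        Names are resolved against the parent and metabolite parameter
        fields (they do not overlap)."""
        parent_fields = {f for f in DispositionParameters.__dataclass_fields__}
        met_fields = {
            f for f in MetaboliteDispositionParameters.__dataclass_fields__}
        p_updates = {k: v for k, v in values.items() if k in parent_fields}
        m_updates = {k: v for k, v in values.items() if k in met_fields}
        unknown = set(values) - parent_fields - met_fields
        if unknown:
            raise ConfigurationError(
                f"unknown parameter name(s): {sorted(unknown)}")
        if m_updates and self.metabolite is None:
            raise ConfigurationError(
                "metabolite parameters given for a single-analyte model")
        new_parent = replace(self.parent, **p_updates) if p_updates \
            else self.parent
        new_met = (replace(self.metabolite, **m_updates)
                   if m_updates else self.metabolite)
        return replace(self, parent=new_parent, metabolite=new_met)


# ---------------------------------------------------------------------------
# ODE right-hand sides (as the constant system matrix of the linear model)
# ---------------------------------------------------------------------------

def _check_partitions(spec: ModelSpec) -> None:
    p, ph = spec.parent, spec.phys
    bad = []
    if p.K_lung == 0 and ph.Q_co != 0:
        bad.append("K_lung")
    if p.K_trachea == 0 and ph.Q_trachea != 0:
        bad.append("K_trachea")
    if p.K_rest == 0 and ph.Q_rest != 0:
        bad.append("K_rest")
    if spec.metabolite is not None:
        m = spec.metabolite
        if m.K_lung_m == 0 and ph.Q_co != 0:
            bad.append("K_lung_m")
        if m.K_trachea_m == 0 and ph.Q_trachea != 0 \
                and spec.metabolite_trachea_form == "mass_balanced":
            bad.append("K_trachea_m")
        if m.K_rest_m == 0 and ph.Q_rest != 0:
            bad.append("K_rest_m")
    if bad:
        raise ParameterError(
            f"zero partition coefficient(s) with nonzero flow: {bad} "
            "(division by zero in tissue return term)")


def system_matrix(spec: ModelSpec) -> np.ndarray:
    """Constant matrix ``M`` with ``dA/dt = M @ A`` for the linear minimal
    PBPK system; also the exact Jacobian for implicit integrators.

    Clearances are converted L/h -> mL/h here; all other quantities are
    already in canonical units.
    """
    _check_partitions(spec)
    ph, p = spec.phys, spec.parent
    Vb, Vl, Vt, Vr = ph.V_blood, ph.V_lung, ph.V_trachea, ph.V_rest
    Qco, Qtr, Qr = ph.Q_co, ph.Q_trachea, ph.Q_rest
    CL = p.CL_F * 1000.0  # L/h -> mL/h

    n = spec.n_states
    M = np.zeros((n, n))
    # absorption depot
    M[0, 0] = -p.k_a
    # blood: absorption input, tissue returns, outflows + clearance.
    # The outflow coefficient Q_co + Q_trachea + Q_rest is taken exactly as
    # the model defines it (it exceeds cardiac output; the system is still
    # mass-conserving because every outflow has a matching tissue gain).
    M[1, 0] = p.k_a
    M[1, 1] = -(Qco + Qtr + Qr + CL) / Vb
    M[1, 2] = Qco / (p.K_lung * Vl)
    M[1, 3] = Qtr / (p.K_trachea * Vt)
    M[1, 4] = Qr / (p.K_rest * Vr)
    # lung
    M[2, 1] = Qco / Vb
    M[2, 2] = -(Qco / (p.K_lung * Vl) + p.k_lt)
    M[2, 3] = p.k_tl
    # trachea
    M[3, 1] = Qtr / Vb
    M[3, 2] = p.k_lt
    M[3, 3] = -(Qtr / (p.K_trachea * Vt) + p.k_tl)
    # rest of body
    M[4, 1] = Qr / Vb
    M[4, 4] = -Qr / (p.K_rest * Vr)

    if spec.kind == "parent_metabolite":
        m = spec.metabolite
        CLm = m.CLm_F * 1000.0
        # metabolite blood: formed from parent blood clearance (mole-for-
        # mole, hence the molar unit requirement), plus its own circulation.
        M[5, 1] = CL / Vb
        M[5, 5] = -(Qco + Qtr + Qr + CLm) / Vb
        M[5, 6] = Qco / (m.K_lung_m * Vl)
        M[5, 7] = Qtr / (m.K_trachea_m * Vt)
        M[5, 8] = Qr / (m.K_rest_m * Vr)
        # metabolite lung
        M[6, 5] = Qco / Vb
        M[6, 6] = -(Qco / (m.K_lung_m * Vl) + m.k_lt_m)
        M[6, 7] = m.k_tl_m
        # metabolite trachea: the return term depends on the configured
        # form (see ModelSpec docstring).  Metabolite trachea concentration
        # is A_trachea_m / V_trachea in both forms.
        M[7, 5] = Qtr / Vb
        if spec.metabolite_trachea_form == "as_printed":
            M[7, 6] = m.k_lt_m - Qtr / (m.K_lung_m * Vl)
            M[7, 7] = -m.k_tl_m
        else:  # mass_balanced
            M[7, 6] = m.k_lt_m
            M[7, 7] = -(Qtr / (m.K_trachea_m * Vt) + m.k_tl_m)
        # metabolite rest of body
        M[8, 5] = Qr / Vb
        M[8, 8] = -Qr / (m.K_rest_m * Vr)
    return M


def derivatives_single(state: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Time derivatives (amount/h) of the single-analyte model at ``state``
    ordered as :data:`SINGLE_COMPARTMENTS`."""
    if spec.kind != "single":
        raise ConfigurationError("derivatives_single requires kind='single'")
    state = np.asarray(state, dtype=float)
    if state.shape != (5,):
        raise ConfigurationError(f"expected 5 states, got {state.shape}")
    return system_matrix(spec) @ state


def derivatives_parent_metabolite(state: np.ndarray,
                                  spec: ModelSpec) -> np.ndarray:
    """Time derivatives (amount/h) of the parent-metabolite model at
    ``state`` ordered as :data:`PARENT_METABOLITE_COMPARTMENTS`."""
    if spec.kind != "parent_metabolite":
        raise ConfigurationError(
            "derivatives_parent_metabolite requires kind='parent_metabolite'")
    state = np.asarray(state, dtype=float)
    if state.shape != (9,):
        raise ConfigurationError(f"expected 9 states, got {state.shape}")
    return system_matrix(spec) @ state


# ---------------------------------------------------------------------------
# Linear-balance oracles
# ---------------------------------------------------------------------------
#
# At periodic steady state under repeated dosing (or integrated 0->inf after
# a single dose, when all compartments start and end empty), the net change
# of each tissue amount over the window is zero.  Integrating the lung and
# trachea equations over the window therefore yields a 2x2 linear system in
# the interval-average (or AUC) tissue-to-blood concentration ratios, which
# these oracles solve directly.  They are independent of the ODE integrator
# and serve as its cross-check.

def _solve_ratio_system(Qco: float, Qtr: float, Vl: float, Vt: float,
                        K_lung: float, K_trachea: float,
                        k_tl: float, k_lt: float,
                        printed_trachea_form: bool) -> tuple[float, float]:
    # lung balance (r_b = 1):
    #   Qco - (Qco/K_lung + k_lt*Vl) r_l + k_tl*Vt r_t = 0
    # trachea balance, mass-balanced return term:
    #   Qtr + k_lt*Vl r_l - (Qtr/K_trachea + k_tl*Vt) r_t = 0
    # trachea balance, printed form (return term uses C_lung/K_lung):
    #   Qtr + (k_lt*Vl - Qtr/K_lung) r_l - k_tl*Vt r_t = 0
    A = np.empty((2, 2))
    A[0, 0] = -(Qco / K_lung + k_lt * Vl)
    A[0, 1] = k_tl * Vt
    if printed_trachea_form:
        A[1, 0] = k_lt * Vl - Qtr / K_lung
        A[1, 1] = -k_tl * Vt
    else:
        A[1, 0] = k_lt * Vl
        A[1, 1] = -(Qtr / K_trachea + k_tl * Vt)
    b = np.array([-Qco, -Qtr])
    try:
        r = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ParameterError(
            f"degenerate tissue-balance system (K_lung={K_lung}, "
            f"K_trachea={K_trachea}, k_tl={k_tl}, k_lt={k_lt}): {exc}"
        ) from exc
    return float(r[0]), float(r[1])


def steady_state_ratio_oracle(spec: ModelSpec) -> tuple[float, float]:
    """Interval-average lung-to-blood and trachea-to-blood concentration
    ratios at periodic steady state of a single-analyte model.

    Exact for the linear system; when ``k_tl = k_lt = 0`` the system
    decouples and the ratios are exactly ``(K_lung, K_trachea)``.
    """
    if spec.kind != "single":
        raise ConfigurationError(
            "steady_state_ratio_oracle requires kind='single'")
    p, ph = spec.parent, spec.phys
    if not (p.K_lung > 0 and p.K_trachea > 0):
        raise ParameterError("K_lung and K_trachea must be > 0")
    return _solve_ratio_system(ph.Q_co, ph.Q_trachea, ph.V_lung,
                               ph.V_trachea, p.K_lung, p.K_trachea,
                               p.k_tl, p.k_lt, printed_trachea_form=False)


def integrated_auc_ratio_oracle(spec: ModelSpec,
                                analyte: str = "parent",
                                ) -> tuple[float, float]:
    """Lung-to-blood and trachea-to-blood AUC(0->inf) ratios after a single
    dose, for the parent or the metabolite.

    The metabolite result honours ``spec.metabolite_trachea_form``; with
    the printed form the lung ratio collapses to exactly ``K_lung_m``
    (summing the lung and trachea balances cancels every exchange term).
    """
    ph = spec.phys
    if analyte == "parent":
        p = spec.parent
        if not (p.K_lung > 0 and p.K_trachea > 0):
            raise ParameterError("K_lung and K_trachea must be > 0")
        return _solve_ratio_system(ph.Q_co, ph.Q_trachea, ph.V_lung,
                                   ph.V_trachea, p.K_lung, p.K_trachea,
                                   p.k_tl, p.k_lt,
                                   printed_trachea_form=False)
    if analyte == "metabolite":
        if spec.kind != "parent_metabolite":
            raise ConfigurationError(
                "metabolite ratios require kind='parent_metabolite'")
        m = spec.metabolite
        if not (m.K_lung_m > 0 and m.K_trachea_m > 0):
            raise ParameterError("K_lung_m and K_trachea_m must be > 0")
        return _solve_ratio_system(
            ph.Q_co, ph.Q_trachea, ph.V_lung, ph.V_trachea,
            m.K_lung_m, m.K_trachea_m, m.k_tl_m, m.k_lt_m,
            printed_trachea_form=(
                spec.metabolite_trachea_form == "as_printed"))
    raise ConfigurationError(f"unknown analyte {analyte!r}")


def blood_plasma_convert(value: float, K_bp: float,
                         direction: str = "plasma_to_blood") -> float:
    """Convert between plasma and whole-blood concentration through the
    blood-to-plasma ratio ``K_bp`` (blood = plasma * K_bp)."""
    if not K_bp > 0:
        raise ParameterError(f"K_bp must be > 0, got {K_bp!r}")
    if direction == "plasma_to_blood":
        return value * K_bp
    if direction == "blood_to_plasma":
        return value / K_bp
    raise ConfigurationError(f"unknown direction {direction!r}")
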