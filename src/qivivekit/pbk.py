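"""Two-compound physiologically based kinetic model (parent + metabolite).

Compartments: gut lumen (parent, oral route), liver, kidney, fat, richly
perfused tissue, slowly perfused tissue and blood, for both compounds.  All
tissues are flow-limited: dA_T/dt = Q_T * (C_art - C_T/P_T).  The liver adds
oral absorption inflow, a saturable conversion of parent to metabolite,
parallel saturable conjugation pathways (losses), first-order biliary loss
of parent and linear intrinsic clearance of the metabolite.  Renal excretion
of each compound is glomerular filtration of the unbound plasma
concentration, taken from the kidney's arterial supply.

Units: amounts umol, volumes L, flows L/h, concentrations uM, time h.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "TISSUES",
    "SpeciesPhysiology",
    "CompoundParams",
    "DoseRegimen",
    "PBKModel",
    "SimulationOutput",
    "build_pbk",
    "simulate",
    "extract_cmax",
    "local_sensitivity",
]

TISSUES = ("liver", "kidney", "fat", "richly", "slowly")


@dataclass
class SpeciesPhysiology:
    """Body weight, tissue volumes and blood flows for one species.

    ``volume_fractions`` are fractions of body weight (1 kg ~ 1 L) for the
    five perfused tissues plus blood; any remainder is unperfused.
    ``flow_fractions`` are fractions of cardiac output over the five perfused
    tissues and must sum to 1.  ``gfr`` is in mL/min/kg body weight.
    """

    species: str
    body_weight: float  # kg
    volume_fractions: dict
    flow_fractions: dict
    cardiac_output: float  # L/h
    gfr: float  # mL/min/kg BW

    def __post_init__(self) -> None:
        if self.body_weight <= 0 or self.cardiac_output <= 0 or self.gfr < 0:
            raise ValueError("body weight and cardiac output must be positive, gfr non-negative")
        missing = [t for t in TISSUES + ("blood",) if t not in self.volume_fractions]
        if missing:
            raise ValueError(f"missing volume fractions: {missing}")
        missing = [t for t in TISSUES if t not in self.flow_fractions]
        if missing:
            raise ValueError(f"missing flow fractions: {missing}")
        if any(v <= 0 for v in self.volume_fractions.values()):
            raise ValueError("volume fractions must be positive")
        if any(q <= 0 for q in self.flow_fractions.values()):
            raise ValueError("flow fractions must be positive")
        vsum = sum(self.volume_fractions.values())
        if vsum > 1.0 + 1e-9:
            raise ValueError(f"volume fractions sum to {vsum:.3f} > 1")
        qsum = sum(self.flow_fractions[t] for t in TISSUES)
        if abs(qsum - 1.0) > 1e-6:
            raise ValueError(f"flow fractions must sum to 1 (got {qsum:.6f})")

    def volumes(self) -> dict:
        """Tissue volumes in L (density ~1 kg/L)."""
        return {t: f * self.body_weight for t, f in self.volume_fractions.items()}

    def flows(self) -> dict:
        """Tissue blood flows in L/h."""
        return {t: f * self.cardiac_output for t, f in self.flow_fractions.items()}

    @property
    def gfr_total(self) -> float:
        """Total glomerular filtration in L/h."""
        return self.gfr * self.body_weight * 60.0 / 1000.0

    @property
    def liver_mass_g(self) -> float:
        return self.volume_fractions["liver"] * self.body_weight * 1000.0


@dataclass
class CompoundParams:
    """Compound-specific model parameters.

    ``partition`` maps each perfused tissue to its tissue:blood partition
    coefficient.  ``pathways`` holds scaled saturable metabolic pathways
    (umol/h, uM); the one named ``conversion_pathway`` in :func:`build_pbk`
    produces the metabolite, the rest are terminal losses.  ``clint`` is a
    linear whole-liver intrinsic clearance in L/h.  ``ka``/``fa``/``kb``
    apply to the orally dosed parent only.
    """

    name: str
    molar_mass: float  # g/mol
    partition: dict
    bpr: float  # blood/plasma concentration ratio
    fup: float  # unbound fraction in plasma
    ka: float = 0.0  # 1/h
    fa: float = 0.0
    kb: float = 0.0  # 1/h biliary loss from liver
    pathways: list = field(default_factory=list)
    clint: float = 0.0  # L/h

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")
        if not (0.0 < self.fup <= 1.0):
            raise ValueError("fup must be in (0, 1]")
        if not (0.0 < self.bpr <= 1.5):
            raise ValueError("bpr must be in (0, 1.5]")
        missing = [t for t in TISSUES if t not in self.partition]
        if missing:
            raise ValueError(f"{self.name}: missing partition coefficients for {missing}")
        if any(p <= 0 for p in self.partition.values()):
            raise ValueError("partition coefficients must be positive")
        if self.ka < 0 or self.kb < 0 or self.clint < 0:
            raise ValueError("rate constants must be non-negative")
        if not (0.0 <= self.fa <= 1.0):
            raise ValueError("fa must be in [0, 1]")


@dataclass
class DoseRegimen:
    """Single administration at t = 0."""

    route: str  # "oral" | "iv"
    dose: float  # mg/kg body weight

    def __post_init__(self) -> None:
        if self.route not in ("oral", "iv"):
            raise ValueError("route must be 'oral' or 'iv'")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


# state vector layout
_IDX_GUT = 0
_P_OFF = 1  # parent tissues start (liver..slowly), then parent blood
_IDX_P_BLOOD = _P_OFF + len(TISSUES)
_M_OFF = _IDX_P_BLOOD + 1
_IDX_M_BLOOD = _M_OFF + len(TISSUES)
_IDX_BILE = _IDX_M_BLOOD + 1
_IDX_URINE_P = _IDX_BILE + 1
_IDX_CONJ = _IDX_URINE_P + 1  # parent lost to conjugation pathways (umol parent)
_IDX_FORMED = _IDX_CONJ + 1  # cumulative metabolite formed (umol)
_IDX_URINE_M = _IDX_FORMED + 1
_IDX_CLEARED_M = _IDX_URINE_M + 1
N_STATE = _IDX_CLEARED_M + 1


class PBKModel:
    """Assembled ODE right-hand side for one species and compound pair."""

    def __init__(
        self,
        physiology: SpeciesPhysiology,
        parent: CompoundParams,
        metabolite: CompoundParams,
        conversion_pathway: str = "rhein_formation",
    ):
        # re-run dataclass validation: parameter objects may have been
        # mutated (e.g. by sensitivity perturbation) since construction
        physiology.__post_init__()
        parent.__post_init__()
        metabolite.__post_init__()
        self.physiology = physiology
        self.parent = parent
        self.metabolite = metabolite
        self.conversion_pathway = conversion_pathway

        conv = [p for p in parent.pathways if p.pathway == conversion_pathway]
        if len(conv) != 1:
            raise ValueError(
                f"metabolite must be linked to exactly one parent pathway named "
                f"{conversion_pathway!r}; found {len(conv)}"
            )
        self._conv = conv[0]
        self._losses = [p for p in parent.pathways if p.pathway != conversion_pathway]
        for p in parent.pathways:
            if p.vmax_scaled is None:
                raise ValueError(f"pathway {p.pathway!r} has no scaled Vmax")

        vols = physiology.volumes()
        flows = physiology.flows()
        self._V = np.array([vols[t] for t in TISSUES])
        self._Vb = vols["blood"]
        self._Q = np.array([flows[t] for t in TISSUES])
        self._Pp = np.array([parent.partition[t] for t in TISSUES])
        self._Pm = np.array([metabolite.partition[t] for t in TISSUES])
        self._cl_ren_p = physiology.gfr_total * parent.fup / parent.bpr
        self._cl_ren_m = physiology.gfr_total * metabolite.fup / metabolite.bpr
        self._i_liver = TISSUES.index("liver")
        self._i_kidney = TISSUES.index("kidney")
        self._vmax = np.array([p.vmax_scaled for p in parent.pathways])
        self._km = np.array([p.km for p in parent.pathways])
        self._is_conv = np.array([p.pathway == conversion_pathway for p in parent.pathways])

    def dose_to_umol(self, dose_mg_per_kg: float) -> float:
        return dose_mg_per_kg * self.physiology.body_weight / self.parent.molar_mass * 1000.0

    def initial_state(self, regimen: DoseRegimen) -> tuple[np.ndarray, float]:
        """Initial state vector and the unabsorbed amount (umol)."""
        y0 = np.zeros(N_STATE)
        dose_umol = self.dose_to_umol(regimen.dose)
        if regimen.route == "oral":
            y0[_IDX_GUT] = self.parent.fa * dose_umol
            unabsorbed = (1.0 - self.parent.fa) * dose_umol
        else:
            y0[_IDX_P_BLOOD] = dose_umol
            unabsorbed = 0.0
        return y0, unabsorbed

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(N_STATE)
        # --- parent ---
        a_t = y[_P_OFF:_IDX_P_BLOOD]
        c_b = y[_IDX_P_BLOOD] / self._Vb
        c_ven = a_t / self._V / self._Pp  # venous-equilibrated concentrations
        flux = self._Q * (c_b - c_ven)
        dy[_P_OFF:_IDX_P_BLOOD] = flux
        dy[_IDX_P_BLOOD] = -np.sum(flux)

        absorbed = self.parent.ka * y[_IDX_GUT]
        dy[_IDX_GUT] = -absorbed
        dy[_P_OFF + self._i_liver] += absorbed

        c_vl = c_ven[self._i_liver]
        v_met = self._vmax * c_vl / (self._km + c_vl)
        dy[_P_OFF + self._i_liver] -= np.sum(v_met)
        v_conv = float(np.sum(v_met[self._is_conv]))
        dy[_IDX_CONJ] = float(np.sum(v_met[~self._is_conv]))
        dy[_IDX_FORMED] = v_conv

        bile = self.parent.kb * y[_P_OFF + self._i_liver]
        dy[_P_OFF + self._i_liver] -= bile
        dy[_IDX_BILE] = bile

        renal_p = self._cl_ren_p * c_b
        dy[_P_OFF + self._i_kidney] -= renal_p
        dy[_IDX_URINE_P] = renal_p

        # --- metabolite ---
        a_tm = y[_M_OFF:_IDX_M_BLOOD]
        c_bm = y[_IDX_M_BLOOD] / self._Vb
        c_venm = a_tm / self._V / self._Pm
        fluxm = self._Q * (c_bm - c_venm)
        dy[_M_OFF:_IDX_M_BLOOD] = fluxm
        dy[_IDX_M_BLOOD] = -np.sum(fluxm)

        dy[_M_OFF + self._i_liver] += v_conv
        cleared = self.metabolite.clint * c_venm[self._i_liver]
        dy[_M_OFF + self._i_liver] -= cleared
        dy[_IDX_CLEARED_M] = cleared

        renal_m = self._cl_ren_m * c_bm
        dy[_M_OFF + self._i_kidney] -= renal_m
        dy[_IDX_URINE_M] = renal_m
        return dy


@dataclass
class SimulationOutput:
    """Dense simulation result with per-compartment amounts in umol."""

    time: np.ndarray
    states: np.ndarray  # (N_STATE, n_time)
    model: PBKModel
    regimen: DoseRegimen
    dose_umol: float
    unabsorbed_umol: float
    sol: object = None  # scipy OdeResult with dense output

    def _compound_indices(self, compound: str):
        if compound in ("parent", self.model.parent.name):
            return _P_OFF, _IDX_P_BLOOD, self.model._Pp, self.model.parent
        if compound in ("metabolite", self.model.metabolite.name):
            return _M_OFF, _IDX_M_BLOOD, self.model._Pm, self.model.metabolite
        raise ValueError(f"unknown compound {compound!r}")

    def blood_conc(self, compound: str, units: str = "uM") -> np.ndarray:
        _, i_blood, _, params = self._compound_indices(compound)
        c = self.states[i_blood] / self.model._Vb
        if units == "uM":
            return c
        if units == "ug_per_mL":
            return c * params.molar_mass / 1000.0
        raise ValueError("units must be 'uM' or 'ug_per_mL'")

    def tissue_venous_conc(self, compound: str, tissue: str) -> np.ndarray:
        off, _, part, _ = self._compound_indices(compound)
        i = TISSUES.index(tissue)
        vols = self.model._V
        return self.states[off + i] / vols[i] / part[i]

    def amount(self, key: str) -> np.ndarray:
        """Accumulator or compartment series by name.

        Keys: ``gut``, ``bile``, ``urine_parent``, ``conjugated``,
        ``metabolite_formed``, ``urine_metabolite``, ``metabolite_cleared``.
        """
        idx = {
            "gut": _IDX_GUT,
            "bile": _IDX_BILE,
            "urine_parent": _IDX_URINE_P,
            "conjugated": _IDX_CONJ,
            "metabolite_formed": _IDX_FORMED,
            "urine_metabolite": _IDX_URINE_M,
            "metabolite_cleared": _IDX_CLEARED_M,
        }[key]
        return self.states[idx]

    def mass_balance_residual(self) -> tuple[float, float]:
        """Max relative residual over time for (parent, metabolite) balances.

        Parent: gut + body + bile + urine + conjugated + converted +
        unabsorbed = dose.  Metabolite: body + urine + cleared = formed.
        """
        y = self.states
        parent_total = (
            y[_IDX_GUT]
            + np.sum(y[_P_OFF : _IDX_P_BLOOD + 1], axis=0)
            + y[_IDX_BILE]
            + y[_IDX_URINE_P]
            + y[_IDX_CONJ]
            + y[_IDX_FORMED]
            + self.unabsorbed_umol
        )
        if self.dose_umol > 0:
            parent_res = float(np.max(np.abs(parent_total - self.dose_umol)) / self.dose_umol)
        else:
            parent_res = float(np.max(np.abs(parent_total)))
        met_total = np.sum(y[_M_OFF : _IDX_M_BLOOD + 1], axis=0) + y[_IDX_URINE_M] + y[_IDX_CLEARED_M]
        formed = y[_IDX_FORMED]
        scale = max(float(np.max(formed)), 1e-300)
        met_res = float(np.max(np.abs(met_total - formed)) / scale) if np.max(formed) > 0 else 0.0
        return parent_res, met_res


def build_pbk(
    physiology: SpeciesPhysiology,
    parent: CompoundParams,
    metabolite: CompoundParams,
    conversion_pathway: str = "rhein_formation",
) -> PBKModel:
    """Assemble the ODE system; validates parameter sets."""
    return PBKModel(physiology, parent, metabolite, conversion_pathway)


def simulate(
    model: PBKModel,
    regimen: DoseRegimen,
    duration: float = 24.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_out: int = 600,
    method: str = "LSODA",
) -> SimulationOutput:
    """Integrate the model with a stiff-capable adaptive solver.

    Dense output is kept on the result so that Cmax can be refined beyond the
    output grid.  Negative states beyond solver tolerance abort.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    y0, unabsorbed = model.initial_state(regimen)
    dose_umol = model.dose_to_umol(regimen.dose)
    if dose_umol == 0.0:
        t = np.linspace(0.0, duration, n_out)
        return SimulationOutput(
            time=t,
            states=np.zeros((N_STATE, n_out)),
            model=model,
            regimen=regimen,
            dose_umol=0.0,
            unabsorbed_umol=0.0,
        )
    sol = integrate.solve_ivp(
        model.rhs,
        (0.0, duration),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    t = np.linspace(0.0, duration, n_out)
    states = sol.sol(t)
    floor = -max(atol * 1e4, rtol * dose_umol * 10.0)
    if np.min(states) < floor:
        raise RuntimeError(
            f"negative state beyond solver tolerance: min={np.min(states):.3g} umol"
        )
    return SimulationOutput(
        time=t,
        states=states,
        model=model,
        regimen=regimen,
        dose_umol=dose_umol,
        unabsorbed_umol=unabsorbed,
        sol=sol,
    )


def _series_for_matrix(out: SimulationOutput, compound: str, matrix: str):
    if matrix == "blood":
        off, i_blood, part, params = out._compound_indices(compound)

        def conc_at(tq):
            y = out.sol.sol(np.atleast_1d(tq)) if out.sol is not None else None
            return y[i_blood] / out.model._Vb

        series = out.blood_conc(compound)
        return series, conc_at
    if matrix in TISSUES:
        off, _, part, _ = out._compound_indices(compound)
        i = TISSUES.index(matrix)
        vol = out.model._V[i]
        p = part[i]

        def conc_at(tq):
            y = out.sol.sol(np.atleast_1d(tq))
            return y[off + i] / vol / p

        series = out.tissue_venous_conc(compound, matrix)
        return series, conc_at
    raise ValueError(f"unknown matrix {matrix!r}")


def extract_cmax(out: SimulationOutput, compound: str = "parent", matrix: str = "blood") -> float:
    """Maximum concentration (uM) over the dense solution.

    Tissue matrices report the venous-equilibrated concentration
    C_tissue/P_tissue.  The grid maximum is refined with a bounded scalar
    optimization on the dense output; a peak at the end of the window is
    flagged with a warning.
    """
    series, conc_at = _series_for_matrix(out, compound, matrix)
    if out.dose_umol == 0.0:
        return 0.0
    i = int(np.argmax(series))
    if i == len(series) - 1:
        import warnings

        warnings.warn("concentration peak at end of simulation window; extend duration", stacklevel=2)
    if out.sol is None or i == 0 or i == len(series) - 1:
        return float(series[i])
    lo, hi = out.time[i - 1], out.time[i + 1]
    res = optimize.minimize_scalar(
        lambda tq: -float(conc_at(tq)[0]), bounds=(lo, hi), method="bounded",
        options={"xatol": (hi - lo) * 1e-6},
    )
    return float(max(series[i], -res.fun))


def _resolve_parameter(objs: dict, path: str):
    """Resolve a dotted parameter path into (getter, setter).

    Paths: ``parent.fup``, ``physiology.cardiac_output``,
    ``parent.partition.liver``, ``physiology.volume_fractions.fat``,
    ``parent.pathways.rhein_formation.vmax_scaled``.
    """
    parts = path.split(".")
    obj = objs[parts[0]]
    for j, name in enumerate(parts[1:-1], start=1):
        if isinstance(obj, dict):
            obj = obj[name]
        elif isinstance(obj, list):
            matches = [p for p in obj if getattr(p, "pathway", None) == name]
            if len(matches) != 1:
                raise KeyError(f"pathway {name!r} not found in {path!r}")
            obj = matches[0]
        else:
            obj = getattr(obj, name)
    leaf = parts[-1]

    def get():
        return obj[leaf] if isinstance(obj, dict) else getattr(obj, leaf)

    def set_(value):
        if isinstance(obj, dict):
            obj[leaf] = value
        else:
            object.__setattr__(obj, leaf, value)

    return get, set_


def local_sensitivity(
    model: PBKModel,
    regimen: DoseRegimen,
    parameter: str,
    delta: float = 0.05,
    compound: str = "parent",
    matrix: str = "blood",
    duration: float = 24.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Normalized forward-difference sensitivity of Cmax to one parameter.

    SC = ((Cmax(p*(1+delta)) - Cmax(p)) / Cmax(p)) / delta.
    """
    if parameter == "dose":
        base = extract_cmax(
            simulate(model, regimen, duration, rtol=rtol, atol=atol), compound, matrix
        )
        if regimen.dose == 0:
            raise ValueError("cannot perturb a zero dose multiplicatively")
        pert_reg = DoseRegimen(regimen.route, regimen.dose * (1.0 + delta))
        pert = extract_cmax(
            simulate(model, pert_reg, duration, rtol=rtol, atol=atol), compound, matrix
        )
        return (pert - base) / base / delta

    physiology = copy.deepcopy(model.physiology)
    parent = copy.deepcopy(model.parent)
    metabolite = copy.deepcopy(model.metabolite)
    objs = {"physiology": physiology, "parent": parent, "metabolite": metabolite}
    get, set_ = _resolve_parameter(objs, parameter)
    value = get()
    if not isinstance(value, (int, float)):
        raise ValueError(f"{parameter!r} is not a scalar parameter")
    if value == 0:
        raise ValueError(f"{parameter!r} is zero and cannot be perturbed multiplicatively")

    base_out = simulate(model, regimen, duration, rtol=rtol, atol=atol)
    base = extract_cmax(base_out, compound, matrix)
    if base == 0:
        raise ValueError("baseline Cmax is zero; sensitivity undefined")

    set_(value * (1.0 + delta))
    pert_model = build_pbk(physiology, parent, metabolite, model.conversion_pathway)
    pert = extract_cmax(
        simulate(pert_model, regimen, duration, rtol=rtol, atol=atol), compound, matrix
    )
    return (pert - base) / base / delta
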