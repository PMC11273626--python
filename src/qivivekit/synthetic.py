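"""Synthetic dataset generators with known ground truth.

Every dataset shape consumed by the pipeline can be generated here with
explicit true parameters, an explicit experimental design and an explicit
seed, so the downstream fitting, simulation and BMD stages are testable
without any external data.

Noise is multiplicative by default: lognormal factors with unit mean and the
requested coefficient of variation (assay-like heteroscedasticity).  A
multiplicative normal model is available as an option.  ``noise_cv = 0``
reproduces the noise-free functional form exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from qivivekit.datasets import DepletionDataset, DoseResponseCurve, KineticDataset

__all__ = [
    "SyntheticSpec",
    "gen_mm_velocities",
    "gen_depletion_course",
    "gen_dose_response",
    "gen_pk_profile",
    "sigmoid_response",
    "analytic_bmc",
]

_KINDS = ("mm_velocity", "depletion", "dose_response", "pk_profile")
_NOISE_MODELS = ("lognormal", "normal")


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Parameters
    ----------
    kind : str
        One of ``mm_velocity``, ``depletion``, ``dose_response``,
        ``pk_profile``.
    true_params : dict
        Ground-truth parameters for the chosen kind.
    design : sequence of float
        Substrate concentrations (uM), time points (min) or doses, depending
        on ``kind``.
    replicates : int
        Replicates per design point (incubations in the emulated experiments
        are run in triplicate; the default follows that).
    noise_cv : float
        Coefficient of variation of the multiplicative noise; 0 disables it.
    noise_model : str
        ``"lognormal"`` (default) or ``"normal"``, both multiplicative with
        unit mean.
    seed : int
        Seed for the generator; identical spec + seed gives identical data.
    """

    kind: str
    true_params: dict = field(default_factory=dict)
    design: tuple = ()
    replicates: int = 3
    noise_cv: float = 0.0
    noise_model: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {_KINDS}")
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {_NOISE_MODELS}")
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        self.design = tuple(float(x) for x in self.design)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noise_factors(rng: np.random.Generator, n: int, cv: float, model: str) -> np.ndarray:
    """Unit-mean multiplicative noise factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    if model == "lognormal":
        sigma = np.sqrt(np.log1p(cv * cv))
        return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)
    return 1.0 + rng.normal(0.0, cv, size=n)


def _tiled_design(design: tuple, replicates: int):
    x = np.repeat(np.asarray(design, dtype=float), replicates)
    rep = np.tile(np.arange(replicates), len(design))
    return x, rep


def gen_mm_velocities(spec: SyntheticSpec) -> KineticDataset:
    """Michaelis-Menten velocities at the design concentrations.

    The noise-free mean at substrate concentration S is
    ``Vmax * S / (Km + S)``.  A no-cofactor control series with zero velocity
    is emitted alongside the assay series so that control filtering in the
    fitting stage can be exercised.
    """
    if spec.kind != "mm_velocity":
        raise ValueError("spec.kind must be 'mm_velocity'")
    vmax = float(spec.true_params["vmax"])
    km = float(spec.true_params["km"])
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be positive")
    if any(s < 0 for s in spec.design):
        raise ValueError("substrate concentrations must be non-negative")

    rng = spec.rng()
    conc, rep = _tiled_design(spec.design, spec.replicates)
    mean = vmax * conc / (km + conc)
    v = mean * _noise_factors(rng, conc.size, spec.noise_cv, spec.noise_model)

    # no-cofactor control: no product formation at any concentration
    ctrl_conc, ctrl_rep = _tiled_design(spec.design, 1)
    all_conc = np.concatenate([conc, ctrl_conc])
    all_v = np.concatenate([v, np.zeros_like(ctrl_conc)])
    all_rep = np.concatenate([rep, ctrl_rep])
    series = np.concatenate(
        [np.full(conc.size, "assay", dtype=object), np.full(ctrl_conc.size, "no_cofactor", dtype=object)]
    )
    return KineticDataset(
        concentrations=all_conc,
        velocities=all_v,
        replicate=all_rep,
        series=series,
        protein_source=spec.true_params.get("protein_source", "microsomes"),
        species=spec.true_params.get("species", "rat"),
        pathway=spec.true_params.get("pathway", "rhein_formation"),
    )


def gen_depletion_course(spec: SyntheticSpec) -> DepletionDataset:
    """First-order substrate depletion course plus a constant no-cell control.

    Noise-free cell series: ``C(t) = C0 * exp(-k t)``; control series constant
    at C0.
    """
    if spec.kind != "depletion":
        raise ValueError("spec.kind must be 'depletion'")
    k = float(spec.true_params["k"])
    c0 = float(spec.true_params["c0"])
    density = float(spec.true_params.get("cell_density", 0.5))
    if k < 0:
        raise ValueError("first-order rate k must be >= 0")
    if c0 <= 0 or density <= 0:
        raise ValueError("c0 and cell density must be positive")
    if any(t < 0 for t in spec.design):
        raise ValueError("time points must be non-negative")

    rng = spec.rng()
    t, rep = _tiled_design(spec.design, spec.replicates)
    mean = c0 * np.exp(-k * t)
    c = mean * _noise_factors(rng, t.size, spec.noise_cv, spec.noise_model)

    ctrl_t, ctrl_rep = _tiled_design(spec.design, spec.replicates)
    ctrl_mean = np.full(ctrl_t.size, c0)
    ctrl_c = ctrl_mean * _noise_factors(rng, ctrl_t.size, spec.noise_cv, spec.noise_model)

    return DepletionDataset(
        times=np.concatenate([t, ctrl_t]),
        concentrations=np.concatenate([c, ctrl_c]),
        cell_density=density,
        replicate=np.concatenate([rep, ctrl_rep]),
        series=np.concatenate(
            [np.full(t.size, "cells", dtype=object), np.full(ctrl_t.size, "control", dtype=object)]
        ),
        species=spec.true_params.get("species", "rat"),
    )


def sigmoid_response(dose, background: float, plateau: float, midpoint: float, steepness: float):
    """Four-parameter sigmoid: background + (plateau-background) * d^h / (m^h + d^h)."""
    dose = np.asarray(dose, dtype=float)
    if midpoint <= 0:
        raise ValueError("midpoint must be positive")
    u = np.zeros_like(dose)
    nz = dose > 0
    u[nz] = dose[nz] ** steepness / (midpoint**steepness + dose[nz] ** steepness)
    return background + (plateau - background) * u


def analytic_bmc(params: dict, bmr: float = 0.10) -> float:
    """Closed-form dose at which the noise-free sigmoid changes by ``bmr``
    relative to background (the ground-truth benchmark concentration)."""
    background = float(params["background"])
    plateau = float(params["plateau"])
    m = float(params["midpoint"])
    h = float(params["steepness"])
    delta = plateau - background
    if delta == 0:
        raise ValueError("flat curve has no benchmark concentration")
    u = bmr * background / abs(delta)
    if u >= 1:
        raise ValueError("requested response change exceeds the curve range")
    return m * (u / (1.0 - u)) ** (1.0 / h)


def gen_dose_response(spec: SyntheticSpec) -> DoseResponseCurve:
    """Replicate responses on a monotone sigmoid at the design doses."""
    if spec.kind != "dose_response":
        raise ValueError("spec.kind must be 'dose_response'")
    p = spec.true_params
    background = float(p["background"])
    plateau = float(p["plateau"])
    midpoint = float(p["midpoint"])
    steepness = float(p.get("steepness", 1.0))
    if midpoint <= 0:
        raise ValueError("midpoint must be positive")
    if any(d < 0 for d in spec.design):
        raise ValueError("doses must be non-negative")

    rng = spec.rng()
    dose, rep = _tiled_design(spec.design, spec.replicates)
    mean = sigmoid_response(dose, background, plateau, midpoint, steepness)
    resp = mean * _noise_factors(rng, dose.size, spec.noise_cv, spec.noise_model)
    direction = "decreasing" if plateau < background else "increasing"
    return DoseResponseCurve(
        doses=dose,
        responses=resp,
        replicate=rep,
        direction=direction,
        dose_units=p.get("dose_units", "uM"),
        response_units=p.get("response_units", "percent"),
    )


def gen_pk_profile(spec: SyntheticSpec):
    """One-compartment oral concentration profile (Bateman form) with noise.

    Returns (times, concentrations) arrays; used as a lightweight stand-in
    for digitized blood concentration-time courses.
    """
    if spec.kind != "pk_profile":
        raise ValueError("spec.kind must be 'pk_profile'")
    p = spec.true_params
    ka = float(p["ka"])
    ke = float(p["ke"])
    f_dose_over_v = float(p.get("f_dose_over_v", 1.0))
    if ka <= 0 or ke <= 0 or ka == ke:
        raise ValueError("require ka > 0, ke > 0 and ka != ke")
    t = np.asarray(spec.design, dtype=float)
    if np.any(t < 0):
        raise ValueError("time points must be non-negative")
    mean = f_dose_over_v * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    rng = spec.rng()
    conc = mean * _noise_factors(rng, t.size, spec.noise_cv, spec.noise_model)
    return t, conc
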