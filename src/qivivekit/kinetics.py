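"""Michaelis-Menten fitting, depletion clearance and whole-organ scaling.

Units convention
----------------
unscaled Vmax   nmol/min/mg protein
Km              uM
unscaled CE     mL/min/mg protein  (= Vmax/Km)
scaled Vmax     umol/h whole liver
scaled CE       L/h                (= scaled Vmax/Km)
CLint in vitro  mL/min/10^6 cells
CLint in vivo   L/h
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from qivivekit.datasets import DepletionDataset, KineticDataset

__all__ = [
    "EnzymeKinetics",
    "ScalingFactors",
    "ClearanceEstimate",
    "FitError",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "scale_vmax",
    "clint_from_depletion",
    "scale_clint",
]

log = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Raised when a kinetic fit cannot be obtained."""


@dataclass
class EnzymeKinetics:
    """Vmax/Km for one saturable metabolic pathway in one species.

    Catalytic efficiencies are properties computed from Vmax/Km so the
    identity CE = Vmax/Km holds by construction.
    """

    vmax_unscaled: float  # nmol/min/mg protein
    km: float  # uM
    pathway: str = "rhein_formation"
    species: str = "rat"
    vmax_scaled: float | None = None  # umol/h whole liver
    vmax_se: float | None = None
    km_se: float | None = None
    km_extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.vmax_unscaled <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be strictly positive")
        if self.vmax_scaled is not None and self.vmax_scaled <= 0:
            raise ValueError("scaled vmax must be strictly positive")

    @property
    def ce_unscaled(self) -> float:
        """mL/min/mg protein."""
        return catalytic_efficiency(self.vmax_unscaled, self.km)

    @property
    def ce_scaled(self) -> float:
        """L/h; requires a scaled Vmax."""
        if self.vmax_scaled is None:
            raise ValueError("vmax_scaled has not been set; call .scaled() first")
        return catalytic_efficiency(self.vmax_scaled, self.km)

    def scaled(self, protein_per_g_liver: float, liver_mass_g: float) -> "EnzymeKinetics":
        """Return a copy with the whole-liver Vmax populated."""
        return EnzymeKinetics(
            vmax_unscaled=self.vmax_unscaled,
            km=self.km,
            pathway=self.pathway,
            species=self.species,
            vmax_scaled=scale_vmax(self.vmax_unscaled, protein_per_g_liver, liver_mass_g),
            vmax_se=self.vmax_se,
            km_se=self.km_se,
            km_extrapolated=self.km_extrapolated,
        )


#: protein contents and hepatocellularity per gram/kilogram of liver.
_SCALING_DEFAULTS = {
    "rat": dict(microsomal_protein=46.0, s9_protein=165.0, hepatocellularity=135_000.0, liver_mass_g=8.5),
    "human": dict(microsomal_protein=40.0, s9_protein=120.7, hepatocellularity=135_000.0, liver_mass_g=1560.0),
}


@dataclass
class ScalingFactors:
    """Liver scaling factors for one species.

    microsomal_protein / s9_protein in mg/g liver, hepatocellularity in
    10^6 cells/kg liver, liver mass in g.  Liver masses default to the values
    that make the shipped scaled/unscaled Vmax pairs mutually consistent
    (8.5 g for a 0.25 kg rat, 1560 g for a 60 kg human).
    """

    species: str
    microsomal_protein: float
    s9_protein: float
    hepatocellularity: float
    liver_mass_g: float

    def __post_init__(self) -> None:
        for name in ("microsomal_protein", "s9_protein", "hepatocellularity", "liver_mass_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_species(cls, species: str, liver_mass_g: float | None = None) -> "ScalingFactors":
        try:
            d = dict(_SCALING_DEFAULTS[species])
        except KeyError:
            raise ValueError(f"no scaling defaults for species {species!r}") from None
        if liver_mass_g is not None:
            d["liver_mass_g"] = liver_mass_g
        return cls(species=species, **d)

    def protein_content(self, protein_source: str) -> float:
        if protein_source == "microsomes":
            return self.microsomal_protein
        if protein_source == "s9":
            return self.s9_protein
        raise ValueError(f"no protein scaling factor for source {protein_source!r}")


@dataclass
class ClearanceEstimate:
    """Intrinsic clearance from a substrate-depletion incubation."""

    clint_invitro: float  # mL/min/10^6 cells
    depletion_rate: float  # 1/min
    half_life: float  # min (inf when no depletion)
    clint_invivo: float | None = None  # L/h
    n_dropped: int = 0
    flagged_nonpositive_rate: bool = False

    def __post_init__(self) -> None:
        if self.clint_invitro < 0:
            raise ValueError("clint must be non-negative")


def catalytic_efficiency(vmax: float, km: float) -> float:
    """vmax/km in consistent units.

    (nmol/min/mg, uM) -> mL/min/mg protein; (umol/h, uM) -> L/h.
    """
    if km <= 0:
        raise ValueError("km must be strictly positive")
    return vmax / km


def scale_vmax(vmax_unscaled: float, protein_per_g_liver: float, liver_mass_g: float) -> float:
    """Scale an in-vitro Vmax (nmol/min/mg protein) to the whole liver (umol/h)."""
    if vmax_unscaled < 0:
        raise ValueError("vmax must be non-negative")
    if protein_per_g_liver <= 0 or liver_mass_g <= 0:
        raise ValueError("protein content and liver mass must be positive")
    return vmax_unscaled * protein_per_g_liver * liver_mass_g * 60.0 / 1000.0


def scale_clint(clint_invitro: float, hepatocellularity: float, liver_mass_kg: float) -> float:
    """Scale an in-vitro intrinsic clearance (mL/min/10^6 cells) to L/h.

    ``hepatocellularity`` in 10^6 cells/kg liver; ``liver_mass_kg`` in kg.
    """
    if clint_invitro < 0 or hepatocellularity < 0 or liver_mass_kg < 0:
        raise ValueError("inputs must be non-negative")
    return clint_invitro * hepatocellularity * liver_mass_kg * 60.0 / 1000.0


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(data: KineticDataset) -> EnzymeKinetics:
    """Nonlinear least-squares fit of v = Vmax*S/(Km+S) on untransformed data.

    All replicate observations in the ``assay`` series are used with uniform
    weights.  Standard errors come from the covariance of the fit.  A Km
    above 10x the highest tested concentration is flagged as extrapolated.
    """
    mask = data.assay_mask
    s = data.concentrations[mask]
    v = data.velocities[mask]
    if np.any(v < 0):
        raise ValueError("velocities must be non-negative")
    if np.unique(s[s > 0]).size < 4:
        raise ValueError("need at least 4 distinct non-zero substrate concentrations")
    if np.ptp(v) == 0:
        raise FitError("flat velocity data: Vmax/Km not identifiable")

    vmax0 = float(np.max(v)) * 1.2
    half = 0.5 * np.max(v)
    above = s[v >= half]
    km0 = float(np.min(above[above > 0])) if np.any(above > 0) else float(np.median(s[s > 0]))
    try:
        popt, pcov = optimize.curve_fit(
            _mm, s, v, p0=[vmax0, km0], bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = popt
    if vmax <= 0 or km <= 0:
        raise FitError(f"degenerate fit: vmax={vmax:.3g}, km={km:.3g}")
    perr = np.sqrt(np.diag(pcov))
    extrapolated = km > 10.0 * np.max(s)
    if extrapolated:
        warnings.warn(
            f"fitted Km ({km:.3g} uM) exceeds 10x the highest tested concentration; "
            "estimate is an extrapolation",
            stacklevel=2,
        )
    return EnzymeKinetics(
        vmax_unscaled=float(vmax),
        km=float(km),
        pathway=data.pathway,
        species=data.species,
        vmax_se=float(perr[0]),
        km_se=float(perr[1]),
        km_extrapolated=bool(extrapolated),
    )


def clint_from_depletion(data: DepletionDataset, cell_density: float | None = None) -> ClearanceEstimate:
    """First-order depletion rate by log-linear regression, scaled to CLint.

    Zero or negative concentrations cannot enter the log fit and are dropped
    with a logged count.  A non-positive fitted rate yields CLint = 0 with a
    flag rather than an error.
    """
    density = float(cell_density) if cell_density is not None else data.cell_density
    if density <= 0:
        raise ValueError("cell density must be positive")
    mask = data.cells_mask
    t = data.times[mask]
    c = data.concentrations[mask]
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct time points")
    pos = c > 0
    n_dropped = int(np.sum(~pos))
    if n_dropped:
        log.info("dropped %d non-positive concentrations from log-linear depletion fit", n_dropped)
    t, c = t[pos], c[pos]
    if np.unique(t).size < 2:
        raise ValueError("not enough positive concentrations for a depletion fit")

    res = stats.linregress(t, np.log(c))
    k = -float(res.slope)
    if k > 0 and res.slope > 0:  # pragma: no cover - defensive
        raise AssertionError
    if res.slope > 0:
        warnings.warn("concentration series increases with time; depletion rate is negative", stacklevel=2)
    if k <= 0:
        return ClearanceEstimate(
            clint_invitro=0.0,
            depletion_rate=k,
            half_life=np.inf,
            n_dropped=n_dropped,
            flagged_nonpositive_rate=True,
        )
    return ClearanceEstimate(
        clint_invitro=k / density,
        depletion_rate=k,
        half_life=float(np.log(2.0) / k),
        n_dropped=n_dropped,
    )
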