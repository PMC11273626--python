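"""Reverse dosimetry: in-vitro concentrations to in-vivo doses.

The in-vitro effective concentration (corrected to its unbound value with
the albumin-based unbound-fraction relation) is set equal to the unbound
maximum venous blood concentration in the target organ, expressed in
parent-compound equivalents by weighting the metabolite with its relative
potency factor (RPF).  The oral dose producing that internal concentration
is found by inverting the monotone dose -> Cmax map of the PBK model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from qivivekit.datasets import DoseResponseCurve
from qivivekit.pbk import DoseRegimen, PBKModel, extract_cmax, simulate

__all__ = [
    "ALBUMIN_PLASMA_G_L",
    "ALBUMIN_PER_FBS_PERCENT",
    "ENDPOINT_ORGANS",
    "RPFTable",
    "DoseCapExceeded",
    "albumin_from_fbs",
    "fu_invitro",
    "compute_rpf",
    "equivalent_unbound_blood",
    "ReverseDosimetry",
    "reverse_dosimetry",
    "convert_curve",
]

ALBUMIN_PLASMA_G_L = 42.5
#: g/L fetal bovine albumin contributed per % (v/v) FBS in the medium.
ALBUMIN_PER_FBS_PERCENT = 0.23

#: default target organs per endpoint.
ENDPOINT_ORGANS = {
    "hepatotoxicity": ("liver",),
    "nephrotoxicity": ("kidney",),
    "ros": ("liver", "kidney"),
    "nrf2": ("liver", "kidney"),
}


class DoseCapExceeded(RuntimeError):
    """Target concentration not reachable below the configured dose cap."""


def albumin_from_fbs(fbs_percent: float) -> float:
    """Albumin concentration (g/L) contributed by % (v/v) FBS in the medium."""
    if not (0.0 <= fbs_percent <= 100.0):
        raise ValueError("FBS percentage must be in [0, 100]")
    return ALBUMIN_PER_FBS_PERCENT * fbs_percent


def fu_invitro(albumin_invitro: float, albumin_plasma: float, fup: float) -> float:
    """Unbound fraction in the assay medium from albumin concentrations.

    fu = 1 / (1 + (Calb,vitro/Calb,plasma) * (1/fup - 1)); reduces to fup
    when the albumin concentrations are equal.
    """
    if albumin_plasma <= 0:
        raise ValueError("plasma albumin must be positive")
    if not (0.0 < fup <= 1.0):
        raise ValueError("fup must be in (0, 1]")
    if albumin_invitro < 0:
        raise ValueError("in-vitro albumin must be non-negative")
    return 1.0 / (1.0 + (albumin_invitro / albumin_plasma) * (1.0 / fup - 1.0))


def compute_rpf(bmcl_parent: float, bmcl_other: float) -> float:
    """Relative potency factor: BMCL10(parent) / BMCL10(other)."""
    if bmcl_parent <= 0 or bmcl_other <= 0:
        raise ValueError("BMCL values must be strictly positive")
    return bmcl_parent / bmcl_other


@dataclass
class RPFTable:
    """Endpoint -> in-vitro BMCL10 pairs and the derived relative potencies.

    The parent compound's RPF is 1 for every endpoint by definition; the
    metabolite's is the ratio of BMCL10 values.  A reported RPF (as printed
    in a source table, possibly from unrounded BMCLs) can be stored
    alongside and used on request.
    """

    entries: dict = field(default_factory=dict)
    # entries[endpoint] = {"bmcl_parent": uM, "bmcl_metabolite": uM,
    #                      "bmcu_parent": uM, "bmcu_metabolite": uM,
    #                      "rpf_reported": float | None}

    def endpoints(self):
        return tuple(self.entries)

    def rpf(self, endpoint: str, compound: str = "metabolite", use_reported: bool = False) -> float:
        if compound == "parent":
            return 1.0
        try:
            e = self.entries[endpoint]
        except KeyError:
            raise KeyError(
                f"no relative potency factor available for endpoint {endpoint!r}"
            ) from None
        if use_reported and e.get("rpf_reported") is not None:
            return float(e["rpf_reported"])
        return compute_rpf(e["bmcl_parent"], e["bmcl_metabolite"])


def equivalent_unbound_blood(
    cmax_parent: float,
    cmax_metabolite: float,
    parent,
    metabolite,
    rpf_metabolite: float,
    rpf_parent: float = 1.0,
) -> float:
    """Parent-equivalent unbound concentration (uM) from blood Cmax values.

    Sum over compounds of (C_blood / BPR) * fup * RPF.
    """
    if rpf_metabolite < 0 or rpf_parent < 0:
        raise ValueError("RPFs must be non-negative")
    return (
        cmax_parent / parent.bpr * parent.fup * rpf_parent
        + cmax_metabolite / metabolite.bpr * metabolite.fup * rpf_metabolite
    )


class ReverseDosimetry:
    """Invert the monotone dose -> organ-venous equivalent Cmax map.

    Simulations are memoized by dose, so converting a whole curve reuses the
    bracketing evaluations.
    """

    def __init__(
        self,
        model: PBKModel,
        rpf_table: RPFTable,
        endpoint: str,
        organ: str = "liver",
        route: str = "oral",
        duration: float = 72.0,
        dose_cap: float = 10_000.0,
        rtol: float = 1e-7,
        atol: float = 1e-9,
        conc_tol: float = 1e-3,
    ):
        if organ not in ("liver", "kidney"):
            raise ValueError("organ must be 'liver' or 'kidney'")
        self.model = model
        self.endpoint = endpoint
        self.organ = organ
        self.route = route
        self.duration = duration
        self.dose_cap = dose_cap
        self.rtol = rtol
        self.atol = atol
        self.conc_tol = conc_tol
        self.rpf_metabolite = rpf_table.rpf(endpoint, "metabolite")
        self._cache: dict[float, float] = {}

    def equivalent_cmax(self, dose: float) -> float:
        """Parent-equivalent unbound organ-venous Cmax (uM) at an oral/iv dose."""
        if dose == 0.0:
            return 0.0
        key = float(dose)
        if key in self._cache:
            return self._cache[key]
        out = simulate(
            self.model,
            DoseRegimen(self.route, dose),
            duration=self.duration,
            rtol=self.rtol,
            atol=self.atol,
        )
        cp = extract_cmax(out, "parent", self.organ)
        cm = extract_cmax(out, "metabolite", self.organ)
        value = equivalent_unbound_blood(
            cp, cm, self.model.parent, self.model.metabolite, self.rpf_metabolite
        )
        self._cache[key] = value
        return value

    def invert(self, target: float) -> float:
        """Oral dose (mg/kg) whose equivalent Cmax equals ``target`` (uM)."""
        if target < 0:
            raise ValueError("target concentration must be non-negative")
        if target == 0.0:
            return 0.0
        at_cap = self.equivalent_cmax(self.dose_cap)
        if at_cap < target:
            raise DoseCapExceeded(
                f"target {target:.4g} uM exceeds the concentration reachable at the "
                f"dose cap ({self.dose_cap:g} mg/kg -> {at_cap:.4g} uM)"
            )
        dose = optimize.brentq(
            lambda d: self.equivalent_cmax(d) - target,
            1e-9,
            self.dose_cap,
            rtol=1e-7,
        )
        achieved = self.equivalent_cmax(dose)
        if abs(achieved - target) > self.conc_tol * target:
            warnings.warn(
                f"reverse dosimetry converged to {achieved:.4g} uM for target "
                f"{target:.4g} uM (beyond {self.conc_tol:.0e} tolerance)",
                stacklevel=2,
            )
        return float(dose)


def reverse_dosimetry(
    model: PBKModel,
    target_conc: float,
    rpf_table: RPFTable,
    endpoint: str,
    organ: str = "liver",
    route: str = "oral",
    **kwargs,
) -> float:
    """One-shot reverse dosimetry; see :class:`ReverseDosimetry`."""
    rd = ReverseDosimetry(model, rpf_table, endpoint, organ, route, **kwargs)
    return rd.invert(target_conc)


def convert_curve(
    curve: DoseResponseCurve,
    assay_fbs_percent: float,
    rd: ReverseDosimetry,
    albumin_plasma: float = ALBUMIN_PLASMA_G_L,
) -> DoseResponseCurve:
    """Map an in-vitro concentration-response curve to an in-vivo dose-response.

    Each in-vitro concentration is reduced to its unbound value with the
    medium's albumin content, matched to the organ-venous equivalent unbound
    Cmax, and inverted through the PBK model.  Responses carry over
    unchanged; concentrations above the dose cap are censored at the cap.
    """
    fu = fu_invitro(albumin_from_fbs(assay_fbs_percent), albumin_plasma, rd.model.parent.fup)
    unique = np.unique(curve.doses)
    mapped: dict[float, tuple[float, bool]] = {}
    for conc in unique:
        if conc == 0.0:
            mapped[conc] = (0.0, False)
            continue
        target = conc * fu
        try:
            mapped[conc] = (rd.invert(target), False)
        except DoseCapExceeded:
            mapped[conc] = (rd.dose_cap, True)
    doses = np.array([mapped[c][0] for c in curve.doses])
    censored = np.array([mapped[c][1] for c in curve.doses])
    return DoseResponseCurve(
        doses=doses,
        responses=curve.responses.copy(),
        replicate=curve.replicate.copy(),
        direction=curve.direction,
        dose_units="mg/kg",
        response_units=curve.response_units,
        censored=censored,
        meta={
            "endpoint": rd.endpoint,
            "organ": rd.organ,
            "species": rd.model.physiology.species,
            "fu_invitro": fu,
            "assay_fbs_percent": assay_fbs_percent,
            "rpf_metabolite": rd.rpf_metabolite,
        },
    )
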