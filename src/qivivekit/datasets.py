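"""Dataset containers shared by the in-vitro fitting, BMD and I/O layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KineticDataset", "DepletionDataset", "DoseResponseCurve"]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must not be empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _series_array(series, n: int) -> np.ndarray:
    if series is None:
        return np.full(n, "assay", dtype=object)
    arr = np.asarray(series, dtype=object).ravel()
    if arr.size != n:
        raise ValueError("series labels do not match data length")
    return arr


@dataclass
class KineticDataset:
    """Substrate concentration / velocity pairs from an enzyme incubation.

    Velocities are in nmol/min/mg protein, concentrations in uM.  One row per
    (concentration, replicate); control incubations (e.g. without cofactor)
    carry a non-``"assay"`` series label and are excluded from fits.
    """

    concentrations: np.ndarray
    velocities: np.ndarray
    replicate: np.ndarray | None = None
    series: np.ndarray | None = None
    protein_source: str = "microsomes"
    species: str = "rat"
    pathway: str = "rhein_formation"

    def __post_init__(self) -> None:
        self.concentrations = _as_float_array(self.concentrations, "concentrations")
        self.velocities = _as_float_array(self.velocities, "velocities")
        n = self.concentrations.size
        if self.velocities.size != n:
            raise ValueError("concentrations and velocities differ in length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.replicate is None:
            self.replicate = np.zeros(n, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int).ravel()
            if self.replicate.size != n:
                raise ValueError("replicate index does not match data length")
        self.series = _series_array(self.series, n)

    @property
    def assay_mask(self) -> np.ndarray:
        return np.asarray(self.series == "assay")

    def distinct_nonzero_levels(self) -> int:
        conc = self.concentrations[self.assay_mask]
        return int(np.unique(conc[conc > 0]).size)


@dataclass
class DepletionDataset:
    """Time / concentration course of substrate depletion in a cell incubation.

    ``series`` distinguishes the cell incubation (``"cells"``) from the
    no-cell control (``"control"``).  ``cell_density`` is in 10^6 cells/mL.
    """

    times: np.ndarray
    concentrations: np.ndarray
    cell_density: float
    replicate: np.ndarray | None = None
    series: np.ndarray | None = None
    species: str = "rat"

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.concentrations = _as_float_array(self.concentrations, "concentrations")
        n = self.times.size
        if self.concentrations.size != n:
            raise ValueError("times and concentrations differ in length")
        if np.any(self.times < 0):
            raise ValueError("time points must be non-negative")
        if self.cell_density <= 0:
            raise ValueError("cell density must be positive")
        if self.replicate is None:
            self.replicate = np.zeros(n, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int).ravel()
            if self.replicate.size != n:
                raise ValueError("replicate index does not match data length")
        if self.series is None:
            self.series = np.full(n, "cells", dtype=object)
        else:
            self.series = _series_array(self.series, n)

    @property
    def cells_mask(self) -> np.ndarray:
        return np.asarray(self.series == "cells")


@dataclass
class DoseResponseCurve:
    """Continuous response versus dose (in vivo) or concentration (in vitro).

    ``direction`` is ``"decreasing"`` for viability-like endpoints and
    ``"increasing"`` for induction endpoints (ROS, Nrf2).  ``censored`` marks
    points whose dose could not be resolved (e.g. reverse dosimetry hit the
    dose cap).
    """

    doses: np.ndarray
    responses: np.ndarray
    replicate: np.ndarray | None = None
    direction: str = "decreasing"
    dose_units: str = "uM"
    response_units: str = "percent"
    censored: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = _as_float_array(self.doses, "doses")
        self.responses = _as_float_array(self.responses, "responses")
        n = self.doses.size
        if self.responses.size != n:
            raise ValueError("doses and responses differ in length")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        if self.direction not in ("decreasing", "increasing"):
            raise ValueError("direction must be 'decreasing' or 'increasing'")
        if self.replicate is None:
            self.replicate = np.zeros(n, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int).ravel()
            if self.replicate.size != n:
                raise ValueError("replicate index does not match data length")
        if self.censored is None:
            self.censored = np.zeros(n, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool).ravel()
            if self.censored.size != n:
                raise ValueError("censored flags do not match data length")

    @property
    def n_levels(self) -> int:
        return int(np.unique(self.doses[~self.censored]).size)

    @property
    def has_control(self) -> bool:
        return bool(np.any(self.doses[~self.censored] == 0))
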