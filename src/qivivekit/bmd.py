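"""Benchmark-dose analysis for continuous dose-response data.

Two continuous model families are implemented, both parameterized as
background ``a``, potency ``b``, maximal fold change ``c`` and steepness
``d``:

hill          y = a * (1 + (c - 1) * x^d / (b^d + x^d))
exponential   y = a * (c - (c - 1) * exp(-b * x^d))

The benchmark dose is the dose at which the fitted curve reaches a
``bmr``-sized relative change from the fitted background (10% by default).
Confidence bounds are 90% two-sided (5th/95th percentiles) from a
parametric bootstrap that resamples residuals; this is a simplified,
documented procedure, not a re-implementation of any particular BMD suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from qivivekit.datasets import DoseResponseCurve

__all__ = [
    "FAMILIES",
    "BMDError",
    "BmrOutOfRange",
    "FittedDoseResponse",
    "BMDResult",
    "fit_dose_response",
    "bmd_point",
    "bmd_bounds",
    "benchmark_dose",
]

FAMILIES = ("hill", "exponential")


class BMDError(RuntimeError):
    pass


class BmrOutOfRange(BMDError):
    """The fitted response range does not span the requested BMR."""


def _hill(x, a, b, c, d):
    x = np.asarray(x, dtype=float)
    u = np.zeros_like(x)
    nz = x > 0
    u[nz] = x[nz] ** d / (b**d + x[nz] ** d)
    return a * (1.0 + (c - 1.0) * u)


def _exponential(x, a, b, c, d):
    x = np.asarray(x, dtype=float)
    return a * (c - (c - 1.0) * np.exp(-b * np.power(x, d, where=x > 0, out=np.zeros_like(x))))


_MODEL_FUNCS = {"hill": _hill, "exponential": _exponential}


@dataclass
class FittedDoseResponse:
    family: str
    params: np.ndarray  # (a, b, c, d)
    direction: str
    sigma: float
    loglik: float
    aic: float
    converged: bool = True
    identifiable: bool = True
    fallback_from: str | None = None

    def predict(self, x):
        return _MODEL_FUNCS[self.family](x, *self.params)


@dataclass
class BMDResult:
    model_name: str
    params: list
    bmd: float
    bmdl: float
    bmdu: float
    bmr: float
    n_bootstrap: int
    seed: int
    converged: bool = True
    n_failed_boot: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.bmdl <= self.bmd <= self.bmdu):
            raise ValueError("require bmdl <= bmd <= bmdu")

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "params": [float(p) for p in self.params],
            "bmd": self.bmd,
            "bmdl": self.bmdl,
            "bmdu": self.bmdu,
            "bmr": self.bmr,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "converged": self.converged,
            "n_failed_boot": self.n_failed_boot,
            **self.meta,
        }


def _initial_guess(doses, responses, family, direction):
    ctrl = responses[doses == 0]
    a0 = float(np.mean(ctrl)) if ctrl.size else float(np.mean(responses[doses == np.min(doses)]))
    top = responses[doses == np.max(doses)]
    c0 = float(np.mean(top)) / a0 if a0 != 0 else (0.5 if direction == "decreasing" else 2.0)
    c0 = max(c0, 1e-3)
    pos = doses[doses > 0]
    b0 = float(np.median(pos))
    if family == "exponential":
        b0 = max(np.log(2.0) / b0, 1e-6)
    return [a0, b0, c0, 1.0]


def _fit_family(doses, responses, family, direction, p0=None):
    fn = _MODEL_FUNCS[family]
    if p0 is None:
        p0 = _initial_guess(doses, responses, family, direction)
    bounds = ([1e-12, 1e-12, 1e-9, 0.1], [np.inf, np.inf, np.inf, 20.0])
    p0 = np.clip(p0, bounds[0], bounds[1])
    popt, _ = optimize.curve_fit(fn, doses, responses, p0=p0, bounds=bounds, maxfev=20000)
    resid = responses - fn(doses, *popt)
    n = responses.size
    sigma2 = float(np.sum(resid**2) / n)
    sigma = float(np.sqrt(sigma2))
    if sigma2 > 0:
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    else:
        loglik = np.inf
    aic = 2 * 5 - 2 * loglik
    return popt, sigma, loglik, aic


def fit_dose_response(
    curve: DoseResponseCurve, family: str = "hill", p0=None
) -> FittedDoseResponse:
    """Least-squares (normal-residual MLE) fit of one model family.

    Non-convergence falls back to the other family with a warning.  A flat
    curve is returned with ``identifiable=False``; its potency parameter is
    meaningless and benchmark doses cannot be derived from it.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    mask = ~curve.censored
    doses = curve.doses[mask]
    responses = curve.responses[mask]
    if np.unique(doses).size < 4 or not np.any(doses == 0):
        raise ValueError("need >= 4 distinct dose levels including a control")

    # flat-curve guard: no systematic change across dose levels
    level_means = np.array([np.mean(responses[doses == u]) for u in np.unique(doses)])
    spread = np.ptp(level_means)
    scale = max(abs(np.mean(level_means)), 1e-12)
    if spread / scale < 1e-10:
        fit = FittedDoseResponse(
            family=family,
            params=np.array([float(np.mean(responses)), 1.0, 1.0, 1.0]),
            direction=curve.direction,
            sigma=float(np.std(responses)),
            loglik=np.nan,
            aic=np.nan,
            converged=True,
            identifiable=False,
        )
        return fit

    try:
        popt, sigma, loglik, aic = _fit_family(doses, responses, family, curve.direction, p0)
        fallback = None
    except (RuntimeError, ValueError):
        other = "exponential" if family == "hill" else "hill"
        warnings.warn(
            f"{family} fit did not converge; falling back to {other}", stacklevel=2
        )
        popt, sigma, loglik, aic = _fit_family(doses, responses, other, curve.direction, p0=None)
        family, fallback = other, family
    return FittedDoseResponse(
        family=family,
        params=np.asarray(popt, dtype=float),
        direction=curve.direction,
        sigma=sigma,
        loglik=loglik,
        aic=aic,
        fallback_from=fallback,
    )


def bmd_point(fit: FittedDoseResponse, bmr: float = 0.10, direction: str | None = None) -> float:
    """Dose at which the fitted curve changes by ``bmr`` relative to background.

    Solved in closed form for both families.  Raises :class:`BmrOutOfRange`
    when the fitted maximal change is smaller than the BMR.
    """
    if not fit.identifiable:
        raise BmrOutOfRange("flat fit: potency unidentifiable, no benchmark dose")
    if not (0.0 < bmr < 1.0):
        raise ValueError("bmr must be in (0, 1)")
    direction = direction or fit.direction
    a, b, c, d = fit.params
    q = -bmr if direction == "decreasing" else bmr
    cm1 = c - 1.0
    if cm1 == 0 or np.sign(cm1) != np.sign(q) or abs(cm1) <= abs(q):
        raise BmrOutOfRange(
            f"fitted maximal relative change {cm1:+.3g} does not span bmr {q:+.3g}"
        )
    if fit.family == "hill":
        xd = q * b**d / (cm1 - q)
        return float(xd ** (1.0 / d))
    r = (cm1 - q) / cm1  # exponential family
    return float((-np.log(r) / b) ** (1.0 / d))


def bmd_bounds(
    fit: FittedDoseResponse,
    curve: DoseResponseCurve,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.90,
    bmr: float = 0.10,
) -> tuple[float, float, int]:
    """Two-sided bootstrap confidence bounds on the benchmark dose.

    Parametric bootstrap: residuals from the fit are resampled with
    replacement onto the fitted means, the model is refit and the benchmark
    dose recomputed.  Returns (bmdl, bmdu, n_failed).  More than 20% failed
    refits widens the bounds to the min/max of the successes with a warning.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    mask = ~curve.censored
    doses = curve.doses[mask]
    responses = curve.responses[mask]
    fitted = fit.predict(doses)
    resid = responses - fitted
    if np.max(np.abs(resid)) == 0.0:
        point = bmd_point(fit, bmr=bmr)
        return point, point, 0
    # residuals of a p-parameter fit underestimate the noise scale by
    # (n-p)/n on average; inflate so the bootstrap noise is unbiased
    n_pts, n_par = resid.size, 4
    resid = resid * np.sqrt(n_pts / max(n_pts - n_par, 1))

    rng = np.random.default_rng(seed)
    bmds = []
    n_failed = 0
    for _ in range(n_boot):
        sample = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            popt, *_ = _fit_family(doses, sample, fit.family, fit.direction, p0=fit.params)
            boot_fit = FittedDoseResponse(
                family=fit.family, params=popt, direction=fit.direction,
                sigma=0.0, loglik=0.0, aic=0.0,
            )
            bmds.append(bmd_point(boot_fit, bmr=bmr))
        except (RuntimeError, ValueError, BMDError):
            n_failed += 1
    if not bmds:
        raise BMDError("all bootstrap refits failed")
    bmds = np.asarray(bmds)
    alpha = (1.0 - level) / 2.0
    if n_failed > 0.2 * n_boot:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap refits failed; widening bounds to the "
            "range of successful replicates",
            stacklevel=2,
        )
        return float(np.min(bmds)), float(np.max(bmds)), n_failed
    lo, hi = np.percentile(bmds, [100.0 * alpha, 100.0 * (1.0 - alpha)])
    return float(lo), float(hi), n_failed


def benchmark_dose(
    curve: DoseResponseCurve,
    family: str = "hill",
    bmr: float = 0.10,
    n_boot: int = 200,
    seed: int = 0,
) -> BMDResult:
    """Fit, benchmark-dose point and bootstrap bounds in one call."""
    fit = fit_dose_response(curve, family)
    bmd = bmd_point(fit, bmr=bmr)
    bmdl, bmdu, n_failed = bmd_bounds(fit, curve, n_boot=n_boot, seed=seed, bmr=bmr)
    # the point estimate is kept inside the interval (percentiles of a skewed
    # bootstrap can otherwise clip it by a hair)
    bmdl, bmdu = min(bmdl, bmd), max(bmdu, bmd)
    return BMDResult(
        model_name=fit.family,
        params=list(fit.params),
        bmd=float(bmd),
        bmdl=float(bmdl),
        bmdu=float(bmdu),
        bmr=bmr,
        n_bootstrap=n_boot,
        seed=seed,
        converged=fit.identifiable,
        n_failed_boot=n_failed,
        meta={"aic": float(fit.aic), "sigma": float(fit.sigma), "dose_units": curve.dose_units},
    )
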