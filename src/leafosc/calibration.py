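"""Fitting photosynthetic traits from A-ci response curves.

Nonlinear least squares of observed net assimilation against the two-branch
model evaluated point-wise as ``min(Ac, Aj)``, with fitted at-temperature
rates normalised back to 25 °C via the inverse peaked-Arrhenius response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .biochem import (
    GAS_CONSTANT,
    CELSIUS_TO_KELVIN,
    KineticsAtT,
    SpeciesParams,
    electron_transport,
    gamma_star,
    michaelis,
    peaked_arrhenius,
)

__all__ = ["AciCurve", "FittedParams", "FitError", "fit_aci", "normalize_to_25", "average_params"]

MIN_POINTS = 6


class FitError(RuntimeError):
    """Raised when an A-ci fit fails to converge or the input is degenerate.

    Carries the optimizer trace (one status line per start) in ``trace``.
    """

    def __init__(self, message: str, trace: Optional[list[str]] = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class AciCurve:
    """One A-ci response curve: ordered (ci, A) pairs at fixed leaf T and light.

    Duplicate ci steps are allowed (measurement ladders revisit the ambient
    set point).
    """

    points: tuple[tuple[float, float], ...]
    Tl: float              # leaf temperature, °C
    Q: float               # PPFD during the curve, μmol·m⁻²·s⁻¹
    curve_id: str = "curve"

    def __post_init__(self) -> None:
        pts = tuple((float(c), float(a)) for c, a in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < MIN_POINTS:
            raise ValueError(f"A-ci curve needs >= {MIN_POINTS} points, got {len(pts)}")
        if any(c <= 0 for c, _ in pts):
            raise ValueError("all ci values must be positive")

    @property
    def ci(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def A_obs(self) -> np.ndarray:
        return np.array([a for _, a in self.points])

    @property
    def Tk(self) -> float:
        return self.Tl + CELSIUS_TO_KELVIN


@dataclass(frozen=True)
class FittedParams:
    """Result of one curve fit, normalised to 25 °C."""

    Vcmax25: float
    Jmax25: float
    Rd25: float
    residual_sse: float
    mode: str                               # "constrained" | "free"
    Km_fit: Optional[float] = None          # at-temperature, free mode only
    gamma_star_fit: Optional[float] = None  # at-temperature, free mode only
    curve_id: str = "curve"

    def __post_init__(self) -> None:
        for name in ("Vcmax25", "Jmax25", "Rd25"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.residual_sse < 0:
            raise ValueError("residual_sse must be >= 0")


def normalize_to_25(value_at_T: float, Tk: float, Ea: float, dS: float, Hd: float,
                    R: float = GAS_CONSTANT) -> float:
    """Invert the peaked-Arrhenius response: the 25 °C rate whose response
    at ``Tk`` equals ``value_at_T``."""
    if not (math.isfinite(value_at_T) and value_at_T > 0):
        raise ValueError(f"value_at_T must be positive and finite, got {value_at_T!r}")
    return value_at_T / peaked_arrhenius(1.0, Tk, Ea, dS, Hd, R)


def _model_A(ci: np.ndarray, Vcmax: float, J: float, Rd: float,
             Km: float, gstar: float) -> np.ndarray:
    Ac = Vcmax * (ci - gstar) / (ci + Km) - Rd
    Aj = J * (ci - gstar) / (4.0 * ci + 8.0 * gstar) - Rd
    return np.minimum(Ac, Aj)


# At-temperature fitting bounds; 25 °C bounds from the module contract are
# enforced after back-conversion.
_BOUNDS_25 = {"Vcmax25": (1.0, 300.0), "Jmax25": (1.0, 500.0), "Rd25": (0.01, 10.0)}


def fit_aci(curve: AciCurve, params0: SpeciesParams | None = None,
            mode: str = "constrained", seed: int = 0) -> FittedParams:
    """Fit (Vcmax25, Jmax25, Rd25) — and per-curve (Km, Γ*) in free mode —
    to one A-ci curve.

    The objective evaluates ``min(Ac, Aj)`` point-wise at the curve's leaf
    temperature and light level; fitted at-temperature rates are converted
    to 25 °C with :func:`normalize_to_25`. Several widely jittered
    multi-starts (deterministic under ``seed``) guard against the kink of
    the min operator. Raises :class:`FitError` on degenerate input or
    non-convergence, with the per-start optimizer trace attached.
    """
    if mode not in ("constrained", "free"):
        raise ValueError(f"mode must be 'constrained' or 'free', got {mode!r}")
    params0 = params0 or SpeciesParams()
    ci = curve.ci
    A_obs = curve.A_obs
    Tk = curve.Tk

    if float(np.ptp(A_obs)) < 1e-9:
        raise FitError("degenerate curve: observed A is constant")

    n_free = 3 if mode == "constrained" else 5
    if len(ci) < n_free + 1:
        raise FitError(f"curve has {len(ci)} points; need more than {n_free} to fit {n_free} parameters")

    gstar_T = gamma_star(Tk, params0.R)
    _, _, Km_T = michaelis(Tk, params0.O, params0.R)

    # scale factors: at-temperature rate per unit 25 °C rate
    fv = peaked_arrhenius(1.0, Tk, params0.Ea_v, params0.dS_v, params0.Hd, params0.R)
    fj = peaked_arrhenius(1.0, Tk, params0.Ea_j, params0.dS_j, params0.Hd, params0.R)

    def unpack(theta):
        Vcmax_T, Jmax_T, Rd_T = theta[:3]
        if mode == "free":
            Km, gstar = theta[3], theta[4]
        else:
            Km, gstar = Km_T, gstar_T
        J = electron_transport(curve.Q, Jmax_T, params0.alpha)
        return Vcmax_T, J, Rd_T, Km, gstar

    def residuals(theta):
        Vcmax_T, J, Rd_T, Km, gstar = unpack(theta)
        return _model_A(ci, Vcmax_T, J, Rd_T, Km, gstar) - A_obs

    lo = [_BOUNDS_25["Vcmax25"][0] * fv, _BOUNDS_25["Jmax25"][0] * fj, _BOUNDS_25["Rd25"][0]]
    hi = [_BOUNDS_25["Vcmax25"][1] * fv, _BOUNDS_25["Jmax25"][1] * fj, _BOUNDS_25["Rd25"][1]]
    x0 = [params0.Vcmax25 * fv, params0.Jmax25 * fj, params0.Rd25]
    if mode == "free":
        lo += [50.0, 5.0]
        hi += [5000.0, 200.0]
        x0 += [Km_T, gstar_T]
    lo, hi, x0 = np.array(lo), np.array(hi), np.clip(x0, lo, hi)

    rng = np.random.default_rng(seed)
    best = None
    trace: list[str] = []
    # wide multiplicative jitter: the min() kink creates basins far apart
    for start in range(6):
        if start == 0:
            xs = x0
        else:
            xs = np.clip(x0 * rng.uniform(0.3, 3.0, size=x0.shape), lo, hi)
        try:
            sol = least_squares(residuals, xs, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as exc:  # pragma: no cover - scipy internal failure
            trace.append(f"start {start}: raised {exc!r}")
            continue
        sse = float(2.0 * sol.cost)
        trace.append(f"start {start}: status={sol.status} nfev={sol.nfev} sse={sse:.6g}")
        if sol.status > 0 and (best is None or sse < best[0]):
            best = (sse, sol)
    if best is None:
        raise FitError("A-ci fit did not converge from any start", trace)
    sse, sol = best

    # Degenerate fits park parameters on a bound with the data unexplained.
    sst = float(np.sum((A_obs - A_obs.mean()) ** 2))
    if sse > 0.999 * sst:
        raise FitError("A-ci fit explains no variance (boundary/degenerate solution)", trace)

    Vcmax_T, Jmax_T, Rd_T = sol.x[:3]
    out = dict(
        Vcmax25=normalize_to_25(Vcmax_T, Tk, params0.Ea_v, params0.dS_v, params0.Hd, params0.R),
        Jmax25=normalize_to_25(Jmax_T, Tk, params0.Ea_j, params0.dS_j, params0.Hd, params0.R),
        Rd25=float(Rd_T),
        residual_sse=sse,
        mode=mode,
        curve_id=curve.curve_id,
    )
    if mode == "free":
        out["Km_fit"] = float(sol.x[3])
        out["gamma_star_fit"] = float(sol.x[4])
    else:
        out["Km_fit"] = None
        out["gamma_star_fit"] = None
    return FittedParams(**out)


def average_params(fits: Sequence[FittedParams], base: SpeciesParams | None = None) -> SpeciesParams:
    """Arithmetic mean of (Vcmax25, Jmax25, Rd25) across curve fits,
    merged into a full species-parameter set."""
    if len(fits) == 0:
        raise ValueError("average_params requires at least one fit")
    base = base or SpeciesParams()
    return base.with_(
        Vcmax25=float(np.mean([f.Vcmax25 for f in fits])),
        Jmax25=float(np.mean([f.Jmax25 for f in fits])),
        Rd25=float(np.mean([f.Rd25 for f in fits])),
    )
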