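"""Model evaluation: agreement metrics, binned error surfaces and
one-factor-at-a-time perturbation sensitivity coefficients."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence, Union

import numpy as np

from .biochem import MeteoInputs, SpeciesParams
from .oscm import Form, as_form, forward

__all__ = [
    "EvalReport",
    "SensitivityResult",
    "PERTURBATION_LEVELS",
    "METEO_FACTORS",
    "PARAM_FACTORS",
    "score",
    "error_surface",
    "sensitivity",
]

logger = logging.getLogger(__name__)

#: relative perturbation levels applied one factor at a time
PERTURBATION_LEVELS = (-0.20, -0.15, -0.10, -0.05, 0.05, 0.10, 0.15, 0.20)

METEO_FACTORS = ("P", "D", "ca", "Q", "Ta")
PARAM_FACTORS = ("lambda", "Vcmax25", "Jmax25", "Rd25")


@dataclass(frozen=True)
class EvalReport:
    """Four agreement indicators between predictions and observations.

    ``r2`` is the squared Pearson correlation (not 1−SSE/SST — the two
    differ for biased predictions); ``mae`` is in the variable's own units;
    ``mbe`` and the per-point ``re`` entries are percentages.
    """

    r2: float
    mae: float
    mbe: float
    re: tuple[float, ...]
    n: int


@dataclass(frozen=True)
class SensitivityResult:
    """Mean and per-level sensitivity coefficients for one factor/output pair."""

    factor: str
    output: str
    sc_levels: tuple[float, ...]
    sc_mean: float
    levels: tuple[float, ...] = PERTURBATION_LEVELS


def score(pred: Sequence[float], obs: Sequence[float]) -> EvalReport:
    """Compute R², MAE, MBE(%) and per-point |RE|(%) of pred against obs.

    Observations equal to zero are skipped in the |RE| list (with a
    warning); they still count toward the other indicators.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-D arrays of equal length")
    n = pred.size
    if n < 2:
        raise ValueError("need at least 2 points")
    if float(np.ptp(obs)) == 0.0:
        raise ValueError("observations are all identical; R² undefined")

    if float(np.ptp(pred)) == 0.0:
        r2 = 0.0  # constant predictions carry no correlation
    else:
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    mae = float(np.mean(np.abs(pred - obs)))
    mbe = float(np.sum(pred - obs) / np.sum(obs) * 100.0)
    nonzero = obs != 0.0
    if not np.all(nonzero):
        logger.warning("score: skipping %d zero observations in |RE|", int(np.sum(~nonzero)))
    re = tuple(np.abs(pred[nonzero] - obs[nonzero]) / np.abs(obs[nonzero]) * 100.0)
    return EvalReport(r2=r2, mae=mae, mbe=mbe, re=re, n=n)


def error_surface(re: Sequence[float], x: Sequence[float], y: Sequence[float],
                  x_edges: Sequence[float], y_edges: Sequence[float],
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Mean |RE| and point count per 2-D meteorological bin.

    Bins are left-open/right-closed, ``(lo, hi]``, except the first which
    also includes its lower edge; a point exactly on an interior edge lands
    in the bin having that edge as its upper bound. Empty bins are NaN in
    the mean array (never zero). Returns ``(mean, count)`` arrays of shape
    ``(len(x_edges)-1, len(y_edges)-1)``.
    """
    re = np.asarray(re, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (re.shape == x.shape == y.shape):
        raise ValueError("re, x and y must be aligned 1-D arrays")
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    for name, e in (("x_edges", x_edges), ("y_edges", y_edges)):
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError(f"{name} must be strictly increasing with >= 2 entries")

    nx, ny = x_edges.size - 1, y_edges.size - 1
    ix = np.digitize(x, x_edges, right=True) - 1
    iy = np.digitize(y, y_edges, right=True) - 1
    ix[x == x_edges[0]] = 0
    iy[y == y_edges[0]] = 0
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)

    mean = np.full((nx, ny), np.nan)
    count = np.zeros((nx, ny), dtype=int)
    for i, j, v in zip(ix[inside], iy[inside], re[inside]):
        count[i, j] += 1
        mean[i, j] = v if math.isnan(mean[i, j]) else mean[i, j] + v
    nonempty = count > 0
    mean[nonempty] /= count[nonempty]
    return mean, count


def _saturation_vp(t_celsius: float) -> float:
    """Tetens saturation vapor pressure, kPa."""
    return 0.6108 * math.exp(17.27 * t_celsius / (t_celsius + 237.3))


def _perturb(meteo: MeteoInputs, params: SpeciesParams, lam: float,
             factor: str, rel: float, couple_ta_d: bool = False):
    if factor in METEO_FACTORS:
        value = getattr(meteo, factor) * (1.0 + rel)
        kwargs = {factor: value}
        if factor == "Ta":
            kwargs["Tl"] = None  # leaf temperature tracks the perturbed Ta
            if couple_ta_d:
                # hold actual vapor pressure fixed so D follows the
                # saturation curve at the perturbed temperature
                d_new = _saturation_vp(value) - (_saturation_vp(meteo.Ta) - meteo.D)
                kwargs["D"] = max(d_new, 0.05)
        return dc_replace(meteo, **kwargs), params, lam
    if factor == "lambda":
        return meteo, params, lam * (1.0 + rel)
    if factor in ("Vcmax25", "Jmax25", "Rd25"):
        return meteo, params.with_(**{factor: getattr(params, factor) * (1.0 + rel)}), lam
    raise ValueError(f"unknown factor {factor!r}; expected one of "
                     f"{METEO_FACTORS + PARAM_FACTORS}")


def sensitivity(meteo: MeteoInputs, params: SpeciesParams, lam: float,
                factor: str, output: str = "gs",
                form: Union[str, Form] = Form.COMBINED,
                couple_ta_d: bool = False) -> SensitivityResult:
    """Sensitivity coefficient of one model output to one input factor.

    Each of the eight relative perturbation levels yields
    ``SC_i = ((S_i−S)/S) / ((F_i−F)/F)`` where S is the reference forward
    solution's output and S_i the solution with only that factor perturbed;
    the reported coefficient is their arithmetic mean. Factors the chosen
    model form does not use give exactly zero.

    By default exactly one factor varies at a time. ``couple_ta_d=True``
    lets a temperature perturbation drag the vapor pressure deficit along
    the saturation curve (actual vapor pressure held fixed), which is how
    the two covary in the field.
    """
    form = as_form(form)
    if output not in ("ci", "A", "gs", "E"):
        raise ValueError(f"output must be one of ci/A/gs/E, got {output!r}")
    ref = forward(form, lam, meteo, params)
    if not ref.converged:
        raise RuntimeError("reference forward solution did not converge")
    S = getattr(ref, output)
    if S == 0.0:
        raise ValueError(f"reference output {output} is zero; SC undefined")
    scs = []
    for rel in PERTURBATION_LEVELS:
        m_i, p_i, lam_i = _perturb(meteo, params, lam, factor, rel, couple_ta_d)
        sol_i = forward(form, lam_i, m_i, p_i)
        scs.append(((getattr(sol_i, output) - S) / S) / rel)
    return SensitivityResult(factor=factor, output=output,
                             sc_levels=tuple(scs), sc_mean=float(np.mean(scs)))
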