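"""Coupled optimal stomatal conductance solvers.

Given meteorology, species traits and a prescribed marginal water cost λ,
solve the implicit system {Fick diffusion, two-branch assimilation,
constant-λ optimality} for intercellular CO2, assimilation, stomatal
conductance and transpiration.

Rather than the rearranged closed-form left/right sides (whose implicit
mole-fraction conversion is easy to get wrong), the optimality condition is
posed directly as ``λ(ci) = λ_target`` where λ(ci) closes the system with
``A = A_branch(ci)``, ``gs = 1.6·A/(ca−ci)``, ``E = gs·D/P`` and evaluates
λ exactly as :mod:`leafosc.marginal_cost` does. λ(ci) is strictly
increasing on its domain, so a bracketed Brent root is reliable, and the
λ round trip (solve forward, re-estimate λ from the solution) is exact by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence, Union

from scipy.optimize import brentq

from .biochem import (
    KineticsAtT,
    Limitation,
    MeteoInputs,
    SpeciesParams,
    assimilation,
    assimilation_slope,
    kinetics_at,
)

__all__ = [
    "Form",
    "OSCMSolution",
    "LambdaSchedule",
    "NoRoot",
    "lambda_of_ci",
    "ci_compensation",
    "solve_ci",
    "forward",
    "simulate_dataset",
]

#: factor converting (mmol/μmol) ratios to mol·mol⁻¹ (same as marginal_cost)
_UNIT_FACTOR = 1.0e3
#: mol → mmol for transpiration
_MOL_TO_MMOL = 1.0e3
#: relative bracket margin at both ends, as a fraction of ca
_EPS_REL = 1e-6
#: relative tolerance on the ci root
_CI_RTOL = 1e-12


class Form(str, Enum):
    """Model form: single-branch or combined limitation selection."""

    VC = "OSCvc"
    VJ = "OSCvj"
    COMBINED = "OSC"


_FORM_ALIASES = {
    "vc": Form.VC, "oscvc": Form.VC,
    "vj": Form.VJ, "oscvj": Form.VJ,
    "combined": Form.COMBINED, "osc": Form.COMBINED, "co": Form.COMBINED,
}


def as_form(form: Union[str, Form]) -> Form:
    if isinstance(form, Form):
        return form
    try:
        return Form(form)
    except ValueError:
        key = str(form).lower()
        if key in _FORM_ALIASES:
            return _FORM_ALIASES[key]
        raise ValueError(f"unknown model form {form!r}")


class NoRoot(Exception):
    """Internal sentinel: no positive-assimilation solution for this λ."""


@dataclass(frozen=True)
class OSCMSolution:
    """Output of one forward solve.

    ``floored`` marks solutions where the minimum-conductance rule engaged;
    unfloored converged solutions satisfy ``gs = 1.6·A/(ca−ci)`` and
    reproduce ``lambda_used`` when fed back to the λ estimator.
    """

    ci: float            # μmol·mol⁻¹
    A: float             # μmol·m⁻²·s⁻¹
    gs: float            # mol·m⁻²·s⁻¹
    E: float             # mmol·m⁻²·s⁻¹
    branch: Limitation
    form: Form
    converged: bool
    floored: bool
    lambda_used: float


@dataclass(frozen=True)
class LambdaSchedule:
    """λ input: a long-term scalar or a per-day map."""

    mode: str                                        # "long_term" | "daily"
    value: Union[float, Mapping[str, float]]

    def __post_init__(self) -> None:
        if self.mode == "long_term":
            if not (isinstance(self.value, (int, float)) and self.value > 0):
                raise ValueError("long_term schedule needs a positive scalar λ")
        elif self.mode == "daily":
            if not isinstance(self.value, Mapping) or not self.value:
                raise ValueError("daily schedule needs a non-empty day_id→λ map")
            if any(v <= 0 for v in self.value.values()):
                raise ValueError("all daily λ values must be positive")
        else:
            raise ValueError(f"mode must be 'long_term' or 'daily', got {self.mode!r}")

    def lam_for(self, day_id: Optional[str]) -> float:
        if self.mode == "long_term":
            return float(self.value)
        if day_id is None or str(day_id) not in self.value:
            raise KeyError(f"no λ scheduled for day {day_id!r}")
        return float(self.value[str(day_id)])


def ci_compensation(branch: Limitation, kin: KineticsAtT) -> Optional[float]:
    """ci at which the branch's net assimilation is zero.

    Returns None when the branch cannot reach positive assimilation at any
    ci (e.g. the electron-transport branch in darkness).
    """
    branch = Limitation(branch)
    g, Rd = kin.gamma_star, kin.Rd
    if branch is Limitation.VC:
        denom = kin.Vcmax - Rd
        if denom <= 0:
            return None
        return (kin.Vcmax * g + Rd * kin.Km) / denom
    denom = kin.J - 4.0 * Rd
    if denom <= 0:
        return None
    return g * (kin.J + 8.0 * Rd) / denom


def _branch_A(ci: float, kin: KineticsAtT, branch: Limitation) -> float:
    res = assimilation(ci, kin)
    return res.Ac if branch is Limitation.VC else res.Aj


def lambda_of_ci(ci: float, meteo: MeteoInputs, kin: KineticsAtT,
                 branch: Limitation) -> float:
    """λ implied by an optimal operating point at intercellular CO2 ``ci``.

    Valid on (ci_comp, ca) where the branch's assimilation is positive;
    strictly increasing there and divergent as ci → ca.
    """
    branch = Limitation(branch)
    comp = ci_compensation(branch, kin)
    if comp is None or not comp < ci < meteo.ca:
        raise ValueError(
            f"ci={ci!r} outside the solvable domain (compensation={comp!r}, ca={meteo.ca!r})")
    A = _branch_A(ci, kin, branch)
    gs = 1.6 * A / (meteo.ca - ci)
    E = _MOL_TO_MMOL * gs * meteo.D / meteo.P
    slope = assimilation_slope(ci, kin, branch)
    return (E / A) * (1.0 + gs / (1.6 * slope)) * _UNIT_FACTOR


def solve_ci(branch: Limitation, lam: float, meteo: MeteoInputs,
             kin: KineticsAtT) -> float:
    """ci at which λ(ci) equals ``lam``; raises :class:`NoRoot` when λ is
    below the attainable floor (no positive-assimilation solution)."""
    if not (math.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be positive and finite, got {lam!r}")
    branch = Limitation(branch)
    comp = ci_compensation(branch, kin)
    if comp is None or comp >= meteo.ca:
        raise NoRoot(f"branch {branch.value} has no positive assimilation below ca")
    eps = _EPS_REL * meteo.ca
    lo = comp + eps
    hi = meteo.ca - eps
    if lo >= hi:
        raise NoRoot("bracket collapsed: compensation point at ambient CO2")

    def f(ci: float) -> float:
        return lambda_of_ci(ci, meteo, kin, branch) - lam

    flo = f(lo)
    if flo >= 0.0:
        # λ at the smallest admissible ci already exceeds the target: the
        # target is unattainable with positive assimilation.
        raise NoRoot(f"λ={lam} below attainable floor {lam + flo:.6g}")
    fhi = f(hi)
    if fhi <= 0.0:
        # λ(ci) diverges as ci→ca so this indicates a broken objective.
        raise RuntimeError("λ(ci) non-monotone or bounded near ca; cannot bracket root")
    return brentq(f, lo, hi, xtol=eps * 1e-6, rtol=_CI_RTOL)


def _floored_solution(branch_A, meteo: MeteoInputs, kin: KineticsAtT,
                      params: SpeciesParams, form: Form, lam: float) -> OSCMSolution:
    """Minimum-conductance regime: gs pinned at gmin, ci from the fixed
    point A(ci) = gmin·(ca−ci)/1.6."""
    gmin = params.gmin

    def g(ci: float) -> float:
        return branch_A(ci) - gmin * (meteo.ca - ci) / 1.6

    lo = 1e-9
    # A >= −Rd everywhere, so at hi the diffusion term is below −(Rd+1)
    hi = meteo.ca + 1.6 * (kin.Rd + kin.Vcmax + 1.0) / gmin
    converged = True
    try:
        ci = brentq(g, lo, hi, xtol=1e-10, rtol=_CI_RTOL)
    except ValueError:
        ci, converged = meteo.ca, False
    A = branch_A(ci) if converged else 0.0
    E = _MOL_TO_MMOL * gmin * meteo.D / meteo.P
    branch = assimilation(ci, kin).limitation if converged else Limitation.VC
    return OSCMSolution(ci=ci, A=A, gs=gmin, E=E, branch=branch, form=form,
                        converged=converged, floored=True, lambda_used=lam)


def _single_branch(form: Form, branch: Limitation, lam: float,
                   meteo: MeteoInputs, kin: KineticsAtT,
                   params: SpeciesParams) -> OSCMSolution:
    try:
        ci = solve_ci(branch, lam, meteo, kin)
    except NoRoot:
        return _floored_solution(lambda c: _branch_A(c, kin, branch),
                                 meteo, kin, params, form, lam)
    A = _branch_A(ci, kin, branch)
    gs_raw = 1.6 * A / (meteo.ca - ci)
    floored = gs_raw < params.gmin
    gs = max(gs_raw, params.gmin)
    E = _MOL_TO_MMOL * gs * meteo.D / meteo.P
    return OSCMSolution(ci=ci, A=A, gs=gs, E=E, branch=branch, form=form,
                        converged=True, floored=floored, lambda_used=lam)


def forward(form: Union[str, Form], lam: float, meteo: MeteoInputs,
            params: SpeciesParams) -> OSCMSolution:
    """Solve one forward problem.

    Single-branch forms solve their branch only. The combined form solves
    both branches and accepts the self-consistent one — the branch that is
    also the binding limitation of the full two-branch model at its own
    solved ci; if both or neither qualify, the branch with the smaller
    assimilation wins. When no positive-assimilation root exists (e.g.
    darkness), the conductance floor engages and ci comes from the
    gs=gmin diffusion fixed point.
    """
    form = as_form(form)
    if not (math.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be positive and finite, got {lam!r}")
    kin = kinetics_at(meteo, params)

    if form is Form.VC:
        return _single_branch(form, Limitation.VC, lam, meteo, kin, params)
    if form is Form.VJ:
        return _single_branch(form, Limitation.VJ, lam, meteo, kin, params)

    # The combined model min(Ac, Aj) is positive only where BOTH branches
    # are: if either branch cannot reach positive assimilation below ca
    # (e.g. darkness), the combined model has no optimal interior solution.
    comps = [ci_compensation(b, kin) for b in (Limitation.VC, Limitation.VJ)]
    if any(c is None or c >= meteo.ca for c in comps):
        return _floored_solution(lambda c: assimilation(c, kin).A,
                                 meteo, kin, params, form, lam)

    candidates: list[OSCMSolution] = []
    for branch in (Limitation.VC, Limitation.VJ):
        try:
            ci = solve_ci(branch, lam, meteo, kin)
        except NoRoot:
            continue
        A = _branch_A(ci, kin, branch)
        gs_raw = 1.6 * A / (meteo.ca - ci)
        floored = gs_raw < params.gmin
        gs = max(gs_raw, params.gmin)
        E = _MOL_TO_MMOL * gs * meteo.D / meteo.P
        candidates.append(OSCMSolution(
            ci=ci, A=A, gs=gs, E=E, branch=branch, form=form,
            converged=True, floored=floored, lambda_used=lam))
    if not candidates:
        return _floored_solution(lambda c: assimilation(c, kin).A,
                                 meteo, kin, params, form, lam)
    self_consistent = [s for s in candidates
                       if assimilation(s.ci, kin).limitation is s.branch]
    if len(self_consistent) == 1:
        return self_consistent[0]
    return min(candidates, key=lambda s: s.A)


def simulate_dataset(records: Sequence[MeteoInputs],
                     schedule: LambdaSchedule,
                     form: Union[str, Form],
                     params: SpeciesParams) -> list[OSCMSolution]:
    """Forward-solve every record with its scheduled λ, order-preserving.

    Daily schedules are validated up front: a record whose ``day_id`` has
    no λ rejects the whole call before any computation.
    """
    form = as_form(form)
    if schedule.mode == "daily":
        missing = sorted({str(m.day_id) for m in records
                          if m.day_id is None or str(m.day_id) not in schedule.value})
        if missing:
            raise KeyError(f"no λ scheduled for day(s): {missing}")
    return [forward(form, schedule.lam_for(m.day_id), m, params) for m in records]
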