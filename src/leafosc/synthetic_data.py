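"""Synthetic fixture generators with known ground truth.

Meteorology is drawn uniformly within physically plausible ranges;
gas-exchange datasets are produced by the forward optimal-conductance model
at a known λ (optionally noised); A-ci curves come from the two-branch
assimilation model on a standard chamber CO2 ladder. Everything is a pure
function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .biochem import MeteoInputs, SpeciesParams, assimilation, kinetics_at
from .calibration import AciCurve
from .marginal_cost import GasExchangeRecord
from .oscm import Form, LambdaSchedule, OSCMSolution, as_form, simulate_dataset

__all__ = ["SynthConfig", "DEFAULT_CO2_LADDER", "gen_meteo", "gen_gas_exchange", "gen_aci"]

#: Standard chamber CO2 set-point sequence (μmol·mol⁻¹): down-ramp from
#: ambient, return-to-ambient checks, then an up-ramp.
DEFAULT_CO2_LADDER = (400, 300, 200, 150, 100, 50, 400, 400, 600, 800,
                      1000, 1200, 1500, 1800, 2000)

_PHYSICAL_BOUNDS = {
    "Q": (0.0, 2500.0),
    "Ta": (5.0, 50.0),
    "D": (1e-6, 6.0),
    "ca": (300.0, 2000.0),
    "P": (70.0, 105.0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for synthetic meteorology / gas-exchange generation."""

    n_days: int = 5
    points_per_day: Union[int, Sequence[int]] = 50
    Q_range: tuple[float, float] = (200.0, 2000.0)
    Ta_range: tuple[float, float] = (15.0, 40.0)
    D_range: tuple[float, float] = (0.5, 4.0)
    ca_range: tuple[float, float] = (380.0, 420.0)
    P_range: tuple[float, float] = (90.0, 100.0)
    lambda_truth: Union[float, Mapping[str, float]] = 1787.10
    noise_sd: float = 0.0          # multiplicative Gaussian sd on gs
    noise_target: str = "gs"       # "gs" (A re-derived via diffusion) | "gs_and_A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_target not in ("gs", "gs_and_A"):
            raise ValueError(f"noise_target must be 'gs' or 'gs_and_A', got {self.noise_target!r}")
        for name, (plo, phi) in _PHYSICAL_BOUNDS.items():
            lo, hi = getattr(self, f"{name}_range")
            if not (plo <= lo <= hi <= phi):
                raise ValueError(
                    f"{name}_range {(lo, hi)} outside physical bounds [{plo}, {phi}] or inverted")

    @property
    def counts(self) -> list[int]:
        if isinstance(self.points_per_day, int):
            return [self.points_per_day] * self.n_days
        counts = list(self.points_per_day)
        if len(counts) != self.n_days:
            raise ValueError("points_per_day sequence length must equal n_days")
        return counts


def gen_meteo(cfg: SynthConfig) -> list[MeteoInputs]:
    """Uniform meteorological draws within the configured ranges, tagged
    day-001 … day-N. Deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for day, n in enumerate(cfg.counts, start=1):
        day_id = f"day-{day:03d}"
        for _ in range(n):
            records.append(MeteoInputs(
                Q=float(rng.uniform(*cfg.Q_range)),
                Ta=float(rng.uniform(*cfg.Ta_range)),
                D=float(rng.uniform(*cfg.D_range)),
                ca=float(rng.uniform(*cfg.ca_range)),
                P=float(rng.uniform(*cfg.P_range)),
                day_id=day_id,
            ))
    return records


def _schedule_from(lambda_truth: Union[float, Mapping[str, float]]) -> LambdaSchedule:
    if isinstance(lambda_truth, Mapping):
        return LambdaSchedule(mode="daily", value=dict(lambda_truth))
    return LambdaSchedule(mode="long_term", value=float(lambda_truth))


def gen_gas_exchange(
    meteo: Sequence[MeteoInputs],
    params: SpeciesParams,
    lambda_truth: Union[float, Mapping[str, float]] = 1787.10,
    noise_sd: float = 0.0,
    seed: int = 0,
    form: Union[str, Form] = Form.COMBINED,
    noise_target: str = "gs",
) -> tuple[list[GasExchangeRecord], list[OSCMSolution]]:
    """Forward-simulate gas exchange at a known λ, then noise it.

    Multiplicative Gaussian noise hits gs; by default A is re-derived from
    the noised gs through the diffusion relation (keeping the record
    internally consistent), while ``noise_target='gs_and_A'`` noises A
    independently instead. Returns ``(records, clean_solutions)`` so
    callers can tell floored solutions apart (those should be excluded
    from λ-recovery truth sets).
    """
    sols = simulate_dataset(list(meteo), _schedule_from(lambda_truth), form, params)
    rng = np.random.default_rng(seed)
    records = []
    for m, s in zip(meteo, sols):
        gs = s.gs
        A, ci, E = s.A, s.ci, s.E
        if noise_sd > 0:
            gs = gs * float(rng.normal(1.0, noise_sd))
            if noise_target == "gs_and_A":
                A = A * float(rng.normal(1.0, noise_sd))
            else:
                # keep the diffusion relation exact under the noised gs
                A = gs * (m.ca - ci) / 1.6
            E = 1.0e3 * gs * m.D / m.P
        records.append(GasExchangeRecord(meteo=m, A=A, E=E, gs=gs, ci=ci))
    return records, sols


def gen_aci(
    params: SpeciesParams,
    Tl: float = 25.0,
    Q: float = 1000.0,
    ladder: Sequence[float] = DEFAULT_CO2_LADDER,
    noise_sd: float = 0.0,
    seed: int = 0,
    curve_id: str = "synthetic",
) -> AciCurve:
    """A-ci curve from the two-branch model on a chamber CO2 ladder.

    ci is taken equal to the chamber set point (fixture simplification —
    real instruments infer ci from conductance). Noise is multiplicative
    Gaussian on A.
    """
    if len(ladder) == 0:
        raise ValueError("ladder must be non-empty")
    meteo = MeteoInputs(Q=Q, Ta=Tl, D=1.0, ca=max(ladder), P=100.0)
    kin = kinetics_at(meteo, params)
    rng = np.random.default_rng(seed)
    pts = []
    for ci in ladder:
        A = assimilation(float(ci), kin).A
        if noise_sd > 0:
            A = A * float(rng.normal(1.0, noise_sd))
        pts.append((float(ci), A))
    return AciCurve(points=tuple(pts), Tl=Tl, Q=Q, curve_id=curve_id)
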