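"""Marginal water cost of carbon gain (λ) from gas-exchange observations.

λ = ∂E/∂A is evaluated analytically per observation from the observed
(A, E, gs, ci) and the branch-specific assimilation slope, then aggregated
to daily and long-term characteristic values with percentile trimming.

Unit bookkeeping (done once, here): with E in mmol·m⁻²·s⁻¹, A in
μmol·m⁻²·s⁻¹, gs in mol·m⁻²·s⁻¹ and ∂A/∂ci in mol·m⁻²·s⁻¹ (per mole
fraction), ``λ = (E/A)·(1 + gs/(1.6·∂A/∂ci))·10³`` is in mol H₂O per
mol CO₂.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .biochem import (
    Limitation,
    MeteoInputs,
    SpeciesParams,
    assimilation,
    assimilation_slope,
    kinetics_at,
)

__all__ = [
    "GasExchangeRecord",
    "LambdaEstimate",
    "LambdaCharacteristic",
    "lambda_point",
    "filter_valid",
    "characteristic_lambda",
    "CITRUS_LAMBDA_CO",
    "CITRUS_LAMBDA_VC",
    "CITRUS_LAMBDA_VJ",
]

logger = logging.getLogger(__name__)

# Characteristic long-term λ values for citrus (pooled medians over the
# whole measurement campaign): co-limited, carboxylation-limited and
# electron-transport-limited, mol·mol⁻¹.
CITRUS_LAMBDA_CO = 1787.10
CITRUS_LAMBDA_VC = 1478.51
CITRUS_LAMBDA_VJ = 2703.65

#: factor converting (mmol/μmol) ratios to mol·mol⁻¹
_UNIT_FACTOR = 1.0e3


@dataclass(frozen=True)
class GasExchangeRecord:
    """One leaf observation: meteorological drivers plus measured fluxes."""

    meteo: MeteoInputs
    A: float    # net assimilation, μmol·m⁻²·s⁻¹
    E: float    # transpiration, mmol·m⁻²·s⁻¹
    gs: float   # stomatal conductance to water, mol·m⁻²·s⁻¹
    ci: float   # intercellular CO2, μmol·mol⁻¹

    @property
    def day_id(self) -> Optional[str]:
        return self.meteo.day_id


@dataclass(frozen=True)
class LambdaEstimate:
    """Point-wise λ with its limitation tag and validity flag."""

    lam: float
    limitation: Optional[Limitation]
    day_id: Optional[str]
    valid: bool
    reason: str = ""


@dataclass(frozen=True)
class LambdaCharacteristic:
    """Trimmed-median λ for one aggregation scope."""

    scope: str                       # e.g. "long_term", "daily:2021-04-29"
    limitation: str                  # "co" | "Vc" | "Vj"
    median_lam: float
    n_points: int                    # before trimming
    n_trimmed: int                   # after trimming
    trim_bounds: tuple[float, float]


def lambda_point(rec: GasExchangeRecord, params: SpeciesParams,
                 branch: Optional[Limitation] = None) -> LambdaEstimate:
    """Analytic λ for one observation.

    The limitation branch is whichever of the two modelled assimilation
    rates is smaller at the observed ``ci``; its analytic slope enters
    ``λ = (E/A)·(1 + gs/(1.6·∂A/∂ci))·10³``. Passing ``branch`` overrides
    the selection — useful when the record came from a single-branch
    forward model whose assumed limitation should be honoured.

    Unusable observations (non-positive A, E or gs; ci not below ca)
    yield an invalid estimate carrying the reason — they are filtered
    downstream, never raised.
    """
    for name in ("A", "E", "gs", "ci"):
        if not math.isfinite(getattr(rec, name)):
            return LambdaEstimate(math.nan, None, rec.day_id, False, f"non-finite {name}")
    if rec.A <= 0:
        return LambdaEstimate(math.nan, None, rec.day_id, False, "non-positive assimilation")
    if rec.E <= 0:
        return LambdaEstimate(math.nan, None, rec.day_id, False, "non-positive transpiration")
    if rec.gs <= 0:
        return LambdaEstimate(math.nan, None, rec.day_id, False, "non-positive conductance")
    if rec.ci <= 0:
        return LambdaEstimate(math.nan, None, rec.day_id, False, "non-positive ci")
    if rec.ci >= rec.meteo.ca:
        return LambdaEstimate(math.nan, None, rec.day_id, False, "ci not below ca")

    kin = kinetics_at(rec.meteo, params)
    limitation = Limitation(branch) if branch is not None \
        else assimilation(rec.ci, kin).limitation
    slope = assimilation_slope(rec.ci, kin, limitation)
    if slope <= 0 or not math.isfinite(slope):
        return LambdaEstimate(math.nan, limitation, rec.day_id, False, "non-positive slope")
    lam = (rec.E / rec.A) * (1.0 + rec.gs / (1.6 * slope)) * _UNIT_FACTOR
    if not math.isfinite(lam) or lam <= 0:
        return LambdaEstimate(math.nan, limitation, rec.day_id, False, "non-positive lambda")
    return LambdaEstimate(lam, limitation, rec.day_id, True)


def filter_valid(estimates: Iterable[LambdaEstimate]) -> list[LambdaEstimate]:
    """Drop invalid estimates, preserving order; log rejection counts."""
    kept, reasons = [], Counter()
    for est in estimates:
        if est.valid:
            kept.append(est)
        else:
            reasons[est.reason] += 1
    if reasons:
        logger.info("filter_valid dropped %d estimates: %s",
                    sum(reasons.values()), dict(reasons))
    return kept


def _trimmed_median(values: np.ndarray, trim: tuple[float, float]) -> tuple[float, int]:
    """Median of the values inside the [lo, hi] percentile band.

    Percentiles use linear interpolation; points equal to a bound are kept.
    """
    lo, hi = np.percentile(values, trim)
    survivors = values[(values >= lo) & (values <= hi)]
    if survivors.size == 0:  # pathological trim bounds
        return math.nan, 0
    return float(np.median(survivors)), int(survivors.size)


def characteristic_lambda(
    estimates: Sequence[LambdaEstimate],
    scope: str = "long_term",
    limitation: str = "co",
    trim: tuple[float, float] = (10.0, 90.0),
) -> list[LambdaCharacteristic]:
    """Aggregate valid λ estimates to characteristic values.

    ``scope='long_term'`` pools every valid point into one group;
    ``scope='daily'`` groups by ``day_id``. ``limitation`` pre-filters by
    branch tag: ``'co'`` keeps all points, ``'Vc'``/``'Vj'`` keep only the
    matching branch. Within each group, points outside the
    ``[trim[0], trim[1]]`` percentile band of λ are discarded before taking
    the median. Groups left empty are omitted with a warning.
    """
    if scope not in ("long_term", "daily"):
        raise ValueError(f"scope must be 'long_term' or 'daily', got {scope!r}")
    if limitation not in ("co", "Vc", "Vj"):
        raise ValueError(f"limitation must be 'co', 'Vc' or 'Vj', got {limitation!r}")
    if not (0.0 <= trim[0] < trim[1] <= 100.0):
        raise ValueError(f"trim bounds must satisfy 0 <= lo < hi <= 100, got {trim!r}")

    valid = filter_valid(estimates)
    if limitation != "co":
        valid = [e for e in valid if e.limitation == Limitation(limitation)]
    if not valid:
        raise ValueError("no valid estimates in scope")

    if scope == "long_term":
        groups = {"long_term": valid}
    else:
        groups: dict[str, list[LambdaEstimate]] = {}
        for e in valid:
            groups.setdefault(str(e.day_id), []).append(e)

    out = []
    for key in groups:
        vals = np.array([e.lam for e in groups[key]])
        med, n_kept = _trimmed_median(vals, trim)
        if n_kept == 0:
            logger.warning("group %s empty after trimming; omitted", key)
            continue
        label = key if scope == "long_term" else f"daily:{key}"
        out.append(LambdaCharacteristic(
            scope=label, limitation=limitation, median_lam=med,
            n_points=vals.size, n_trimmed=n_kept, trim_bounds=(trim[0], trim[1]),
        ))
    return out
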