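"""Campaign-shaped synthetic fixtures built from the bundled reference tables.

The measurement-day table fixes the dates and per-day record counts; the
forward model at the daily characteristic λ supplies internally consistent
gas-exchange values.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .. import data
from ..biochem import MeteoInputs, SpeciesParams
from ..marginal_cost import CITRUS_LAMBDA_CO, GasExchangeRecord
from ..synthetic_data import gen_gas_exchange

__all__ = ["reference_campaign_records"]


def reference_campaign_records(seed: int = 0,
                               params: Optional[SpeciesParams] = None,
                               noise_sd: float = 0.0) -> list[GasExchangeRecord]:
    """Gas-exchange records shaped like the reference campaign.

    One record per measurement in the bundled day table (17 days), dated by
    that table, with meteorology drawn within mild field-like ranges and
    fluxes from the forward model at each day's characteristic λ (falling
    back to the overall value where a day has none).
    """
    params = params or SpeciesParams()
    days = data.measurement_days()
    lam_table = data.daily_lambda().set_index("date")["lam_co"]
    rng = np.random.default_rng(seed)

    meteo: list[MeteoInputs] = []
    lam_by_day: dict[str, float] = {}
    for row in days.itertuples(index=False):
        date = str(row.date)
        lam = float(lam_table.get(date, CITRUS_LAMBDA_CO))
        lam_by_day[date] = lam if np.isfinite(lam) else CITRUS_LAMBDA_CO
        for k in range(int(row.measure)):
            meteo.append(MeteoInputs(
                Q=float(rng.uniform(300.0, 1800.0)),
                Ta=float(rng.uniform(20.0, 38.0)),
                D=float(rng.uniform(0.8, 3.5)),
                ca=float(rng.uniform(390.0, 415.0)),
                P=float(rng.uniform(93.0, 97.0)),
                day_id=date,
                timestamp=f"{date}T{9 + (k % 8):02d}:00",
            ))
    records, _ = gen_gas_exchange(meteo, params, lambda_truth=lam_by_day,
                                  noise_sd=noise_sd, seed=seed)
    return records
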