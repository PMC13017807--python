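"""Bundled reference tables for the citrus campaign.

Three small CSVs ship with the package: the measurement-day summary
(dates and per-day record counts), the daily characteristic λ values per
limitation, and the per-curve calibrated photosynthesis traits.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["measurement_days", "daily_lambda", "calibrated_curves"]


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, thousands=",")


def measurement_days() -> pd.DataFrame:
    """Measurement-day summary: date, time window, record count, weather."""
    return _load("measurement_days.csv")


def daily_lambda() -> pd.DataFrame:
    """Daily median λ (mol·mol⁻¹) overall and per limitation branch."""
    return _load("daily_lambda.csv")


def calibrated_curves() -> pd.DataFrame:
    """Per-curve calibrated traits (Tl, Km, Γ*, Vcmax25, Jmax25, Rd25)."""
    return _load("calibrated_curves.csv")
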