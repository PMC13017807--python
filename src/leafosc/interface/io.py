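"""CSV readers and writers for gas-exchange and A-ci tables.

One canonical dialect: comma-separated, UTF-8, '.' decimal point, header
mandatory. Thousands separators inside quoted fields ("1,787.10") are
accepted on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from ..biochem import MeteoInputs
from ..calibration import AciCurve
from ..marginal_cost import GasExchangeRecord, LambdaCharacteristic, LambdaEstimate
from ..oscm import OSCMSolution

__all__ = [
    "GASEX_COLUMNS",
    "ACI_COLUMNS",
    "METEO_COLUMNS",
    "read_gas_exchange",
    "write_gas_exchange",
    "read_aci",
    "write_aci",
    "read_meteo",
    "write_meteo",
    "write_solutions",
    "write_lambda_table",
    "write_lambda_summary",
]

logger = logging.getLogger(__name__)

GASEX_COLUMNS = ["day_id", "timestamp", "Q", "Ta", "D", "ca", "P", "A", "E", "gs", "ci"]
METEO_COLUMNS = ["day_id", "timestamp", "Q", "Ta", "D", "ca", "P"]
ACI_COLUMNS = ["curve_id", "ci", "A", "Tl", "Q"]

_GASEX_REQUIRED = ["Q", "Ta", "D", "ca", "P", "A", "E", "gs", "ci"]
_METEO_REQUIRED = ["Q", "Ta", "D", "ca", "P"]


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, thousands=",")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _drop_incomplete(df: pd.DataFrame, required: Sequence[str], path) -> pd.DataFrame:
    bad = df[required].isna().any(axis=1)
    if bad.any():
        # +2: 1-based line numbers plus the header line
        lines = [int(i) + 2 for i in df.index[bad]]
        logger.warning("%s: skipped %d row(s) with missing required fields (lines %s)",
                       path, int(bad.sum()), lines)
    return df[~bad]


def _opt_str(row, col):
    value = getattr(row, col, None)
    if value is None or pd.isna(value):
        return None
    return str(value)


def read_meteo(path) -> list[MeteoInputs]:
    """Read a meteorology CSV into typed records (driver columns only)."""
    df = _drop_incomplete(_read_table(path, _METEO_REQUIRED), _METEO_REQUIRED, path)
    return [
        MeteoInputs(Q=float(r.Q), Ta=float(r.Ta), D=float(r.D), ca=float(r.ca),
                    P=float(r.P),
                    Tl=float(r.Tl) if "Tl" in df.columns and pd.notna(r.Tl) else None,
                    day_id=_opt_str(r, "day_id"), timestamp=_opt_str(r, "timestamp"))
        for r in df.itertuples(index=False)
    ]


def read_gas_exchange(path) -> list[GasExchangeRecord]:
    """Read a gas-exchange CSV; rows missing any required field are skipped
    with their line numbers logged, absent columns fail hard."""
    df = _drop_incomplete(_read_table(path, _GASEX_REQUIRED), _GASEX_REQUIRED, path)
    records = []
    for r in df.itertuples(index=False):
        meteo = MeteoInputs(Q=float(r.Q), Ta=float(r.Ta), D=float(r.D),
                            ca=float(r.ca), P=float(r.P),
                            Tl=float(r.Tl) if "Tl" in df.columns and pd.notna(r.Tl) else None,
                            day_id=_opt_str(r, "day_id"), timestamp=_opt_str(r, "timestamp"))
        records.append(GasExchangeRecord(meteo=meteo, A=float(r.A), E=float(r.E),
                                         gs=float(r.gs), ci=float(r.ci)))
    return records


def write_meteo(records: Sequence[MeteoInputs], path) -> None:
    pd.DataFrame([
        {"day_id": m.day_id, "timestamp": m.timestamp, "Q": m.Q, "Ta": m.Ta,
         "D": m.D, "ca": m.ca, "P": m.P}
        for m in records
    ], columns=METEO_COLUMNS).to_csv(path, index=False)


def write_gas_exchange(records: Sequence[GasExchangeRecord], path) -> None:
    pd.DataFrame([
        {"day_id": rec.meteo.day_id, "timestamp": rec.meteo.timestamp,
         "Q": rec.meteo.Q, "Ta": rec.meteo.Ta, "D": rec.meteo.D,
         "ca": rec.meteo.ca, "P": rec.meteo.P,
         "A": rec.A, "E": rec.E, "gs": rec.gs, "ci": rec.ci}
        for rec in records
    ], columns=GASEX_COLUMNS).to_csv(path, index=False)


def read_aci(path) -> list[AciCurve]:
    """Read an A-ci CSV grouped by curve_id, order preserved within each
    curve; an empty file yields an empty list with a warning."""
    df = _read_table(path, ["ci", "A", "Tl", "Q"])
    if df.empty:
        logger.warning("%s: no A-ci rows", path)
        return []
    if "curve_id" not in df.columns:
        raise ValueError(f"{path}: missing required column(s) ['curve_id']")
    df = _drop_incomplete(df, ["curve_id", "ci", "A", "Tl", "Q"], path)
    curves = []
    for cid in df["curve_id"].unique():
        sub = df[df["curve_id"] == cid]
        curves.append(AciCurve(
            points=tuple(zip(sub["ci"].astype(float), sub["A"].astype(float))),
            Tl=float(sub["Tl"].iloc[0]), Q=float(sub["Q"].iloc[0]), curve_id=str(cid)))
    return curves


def write_aci(curves: Sequence[AciCurve], path) -> None:
    rows = [
        {"curve_id": c.curve_id, "ci": ci, "A": a, "Tl": c.Tl, "Q": c.Q}
        for c in curves for ci, a in c.points
    ]
    pd.DataFrame(rows, columns=ACI_COLUMNS).to_csv(path, index=False)


def write_solutions(meteo: Sequence[MeteoInputs], sols: Sequence[OSCMSolution], path) -> None:
    """Prediction CSV: input drivers plus solved ci/A/gs/E and flags."""
    pd.DataFrame([
        {"day_id": m.day_id, "timestamp": m.timestamp, "Q": m.Q, "Ta": m.Ta,
         "D": m.D, "ca": m.ca, "P": m.P,
         "ci": s.ci, "A": s.A, "gs": s.gs, "E": s.E,
         "branch": s.branch.value, "form": s.form.value,
         "converged": s.converged, "floored": s.floored,
         "lambda_used": s.lambda_used}
        for m, s in zip(meteo, sols)
    ]).to_csv(path, index=False)


def write_lambda_table(estimates: Sequence[LambdaEstimate], path) -> None:
    pd.DataFrame([
        {"day_id": e.day_id, "lam": e.lam,
         "limitation": e.limitation.value if e.limitation else "",
         "valid": e.valid, "reason": e.reason}
        for e in estimates
    ]).to_csv(path, index=False)


def write_lambda_summary(chars: Sequence[LambdaCharacteristic], path) -> None:
    pd.DataFrame([
        {"scope": c.scope, "limitation": c.limitation, "median_lam": c.median_lam,
         "n_points": c.n_points, "n_trimmed": c.n_trimmed,
         "trim_lo": c.trim_bounds[0], "trim_hi": c.trim_bounds[1]}
        for c in chars
    ]).to_csv(path, index=False)
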