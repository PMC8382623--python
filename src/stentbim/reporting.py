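"""Display rounding and report rendering.

The engine is unrounded end to end; this module is the only place numbers are
rounded, using half-up (away from zero) rounding at display time.  Totals are
rounded from the unrounded sums, never from already-rounded cells — which is
why, e.g., a TLRs-avoided total can differ by one event from the sum of its
rounded per-year cells.  Rendering is a pure function of the result objects:
no model arithmetic happens here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .costing import BudgetImpactResult

__all__ = [
    "round_half_up",
    "format_range",
    "render_national_table",
    "render_state_table",
    "render_scenario_table",
    "write_table",
]

Number = Union[float, np.ndarray]


def round_half_up(x: Number, decimals: int = 0) -> Number:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1)."""
    scale = 10.0 ** decimals
    arr = np.asarray(x, dtype=float)
    rounded = np.sign(arr) * np.floor(np.abs(arr) * scale + 0.5) / scale
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(rounded)
    return rounded


def _ints(x: np.ndarray) -> np.ndarray:
    return round_half_up(x).astype(np.int64)


def _row(values: np.ndarray) -> list[int]:
    """Per-year cells plus the total, each rounded from unrounded values."""
    return [*_ints(values).tolist(), int(round_half_up(float(values.sum())))]


def render_national_table(result: BudgetImpactResult) -> pd.DataFrame:
    """National base-case report: per-year cohort, events, days and costs.

    One row per metric for the comparator arm, the intervention arm and
    their difference; columns are the model years plus an unrounded-sum
    total.  All cells are whole counts or whole AUD.
    """
    z, e = result.comparator, result.intervention
    columns = [
        f"Year {t} ({y})" for t, y in enumerate(np.asarray(result.year_labels).tolist())
    ] + ["Total"]
    rows = {"DES-treated population": _row(result.cohort)}
    for table in (z, e):
        p = table.projection
        name = table.arm_name
        rows[f"{name}: CD-TLRs"] = _row(p.tlr_total)
        rows[f"{name}: hospital days for AEs"] = _row(p.hospital_days)
        rows[f"{name}: healthcare system cost (AUD)"] = _row(table.healthcare_total)
        rows[f"{name}: hospital system cost (AUD)"] = _row(table.hospital_total)
    rows["Difference: CD-TLRs avoided"] = _row(result.tlr_avoided)
    rows["Difference: hospital days averted"] = _row(result.days_averted)
    rows["Difference: healthcare system savings (AUD)"] = _row(result.healthcare_savings)
    rows["Difference: hospital savings (AUD)"] = _row(result.hospital_savings)
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def _fmt(value: float, decimals: int) -> str:
    # thousands separators only from five digits up, matching the published style
    sep = "," if abs(value) >= 10_000 else ""
    return f"{value:{sep}.{decimals}f}"


def format_range(low: float, high: float, decimals: int = 0) -> str:
    """Published-style "low–high" range (en dash, separators from 5 digits)."""
    lo = round_half_up(low, decimals)
    hi = round_half_up(high, decimals)
    return f"{_fmt(lo, decimals)}–{_fmt(hi, decimals)}"


def render_state_table(
    low: Mapping[str, BudgetImpactResult], high: Mapping[str, BudgetImpactResult]
) -> pd.DataFrame:
    """State/territory report as "low–high" ranges across a usage-rate span.

    Counts and days are whole numbers; savings are AUD millions to three
    decimals, following the published layout.
    """
    if set(low) != set(high):
        raise ValueError("low and high results cover different states")
    metrics = {
        "Number of patients treated": ("patients", 0, 1.0),
        "Number of CD-TLRs avoided": ("tlr_avoided", 0, 1.0),
        "Hospital days for AE avoided": ("days_averted", 0, 1.0),
        "Total savings to healthcare system (AUD millions)": ("healthcare_savings", 3, 1e-6),
        "Total savings to hospital (AUD millions)": ("hospital_savings", 3, 1e-6),
    }
    data: dict[str, dict[str, str]] = {}
    for state in low:
        lo_t, hi_t = low[state].totals(), high[state].totals()
        col = {}
        for label, (key, decimals, unit) in metrics.items():
            col[label] = format_range(lo_t[key] * unit, hi_t[key] * unit, decimals)
        data[state] = col
    return pd.DataFrame(data, columns=list(low))


def render_scenario_table(sweep_table: pd.DataFrame) -> pd.DataFrame:
    """Display-round a scenario sweep: counts and AUD to whole units."""
    out = sweep_table.copy()
    for col in out.columns:
        if col != "scenario":
            out[col] = _ints(out[col].to_numpy(dtype=float))
    return out


def write_table(df: pd.DataFrame, path: str | Path, fmt: str = "csv") -> Path:
    """Write a rendered table as RFC-4180 CSV or JSON with identical numbers."""
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=True, lineterminator="\n")
    elif fmt == "json":
        payload = {
            "columns": [str(c) for c in df.columns],
            "index": [str(i) for i in df.index],
            "data": [
                [v.item() if isinstance(v, np.generic) else v for v in row]
                for row in df.itertuples(index=False, name=None)
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
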