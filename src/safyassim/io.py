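"""CSV readers and writers for weather, reflectance and plot observations.

All tables are plain UTF-8 CSV with a header row.  Dates are integer
day-of-season throughout.  Every writer's output is parsed back to equal
in-memory values by its paired reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from safyassim.assimilation import PlotObservations
from safyassim.safy_core import WeatherSeries

__all__ = [
    "read_weather",
    "write_weather",
    "read_reflectance",
    "write_reflectance",
    "read_plot_tables",
    "write_plot_tables",
]

logger = logging.getLogger(__name__)

VARIETY_CODES = {"P1", "P2"}
NITROGEN_CODES = {"N1", "N2", "N3", "N4"}
WATER_CODES = {"W1", "W2", "W3"}


class ParseError(ValueError):
    pass


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path)


def _require_columns(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")


def read_weather(path) -> WeatherSeries:
    """Read a daily weather CSV.

    Accepts either pre-averaged ``ta_c`` or ``tmin_c``/``tmax_c`` (the daily
    mean is their average).  Days must be contiguous integers.
    """
    df = _read_csv(path)
    _require_columns(df, {"day", "rg_mj_m2"}, path)
    has_ta = "ta_c" in df.columns
    if not has_ta:
        _require_columns(df, {"tmin_c", "tmax_c"}, path)

    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
    if df.isna().any().any():
        raise ParseError(f"{path}: missing values")

    day = df["day"].to_numpy(int)
    gaps = np.flatnonzero(np.diff(day) != 1)
    if gaps.size:
        raise ParseError(f"{path}: day gap after day {day[gaps[0]]} (missing day {day[gaps[0]] + 1})")
    if has_ta:
        return WeatherSeries(day=day, ta=df["ta_c"].to_numpy(float), rg=df["rg_mj_m2"].to_numpy(float))
    return WeatherSeries.from_min_max(
        day, df["tmin_c"].to_numpy(float), df["tmax_c"].to_numpy(float), df["rg_mj_m2"].to_numpy(float)
    )


def write_weather(weather: WeatherSeries, path) -> None:
    pd.DataFrame({"day": weather.day, "ta_c": weather.ta, "rg_mj_m2": weather.rg}).to_csv(
        path, index=False
    )


def read_reflectance(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, {"plot_id", "date", "b_blue", "b_green", "b_red", "b_nir"}, path)
    if df.duplicated(["plot_id", "date"]).any():
        dup = df[df.duplicated(["plot_id", "date"])].iloc[0]
        raise ParseError(f"{path}: duplicate row for plot {dup['plot_id']} date {dup['date']}")
    return df


def write_reflectance(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _obs_frame(path, value_col: str) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, {"plot_id", "date", value_col}, path)
    if df.duplicated(["plot_id", "date"]).any():
        dup = df[df.duplicated(["plot_id", "date"])].iloc[0]
        raise ParseError(f"{path}: duplicate row for plot {dup['plot_id']} date {dup['date']}")
    return df


def read_plot_tables(
    plots_path, lai_path, dam_path=None
) -> list[PlotObservations]:
    """Join the plot register with LAI (and optional biomass) observations.

    Plot ids appearing in observation tables but not in the register are
    excluded with a warning; unknown treatment codes are rejected.
    """
    plots = _read_csv(plots_path)
    _require_columns(plots, {"plot_id", "variety", "nitrogen", "water"}, plots_path)
    for col, codes in (("variety", VARIETY_CODES), ("nitrogen", NITROGEN_CODES), ("water", WATER_CODES)):
        bad = set(plots[col].astype(str)) - codes
        if bad:
            raise ParseError(f"{plots_path}: unknown {col} code(s) {sorted(bad)}")
    if plots["plot_id"].duplicated().any():
        raise ParseError(f"{plots_path}: duplicate plot ids")

    lai = _obs_frame(lai_path, "lai")
    dam = _obs_frame(dam_path, "dam_t_ha") if dam_path is not None else None

    known = set(plots["plot_id"])
    for name, df in (("lai", lai), ("dam", dam)):
        if df is None:
            continue
        orphans = set(df["plot_id"]) - known
        if orphans:
            logger.warning("excluding %s rows for unknown plot ids: %s", name, sorted(orphans))

    out = []
    for _, row in plots.iterrows():
        pid = row["plot_id"]
        sub = lai[lai["plot_id"] == pid].sort_values("date")
        dsub = (
            dam[dam["plot_id"] == pid].sort_values("date")
            if dam is not None
            else pd.DataFrame(columns=["date", "dam_t_ha"])
        )
        y = row["yield_t_ha"] if "yield_t_ha" in plots.columns and pd.notna(row.get("yield_t_ha")) else None
        out.append(
            PlotObservations(
                plot_id=pid,
                lai_days=sub["date"].to_numpy(int),
                lai_values=sub["lai"].to_numpy(float),
                dam_days=dsub["date"].to_numpy(int),
                dam_values=dsub["dam_t_ha"].to_numpy(float),
                yield_t_ha=None if y is None else float(y),
                variety=str(row["variety"]),
                nitrogen=str(row["nitrogen"]),
                water=str(row["water"]),
            )
        )
    return out


def write_plot_tables(plots: list[PlotObservations], out_dir) -> dict[str, Path]:
    """Write the plot register, LAI and biomass observation CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reg_rows, lai_rows, dam_rows = [], [], []
    for p in plots:
        reg_rows.append(
            {
                "plot_id": p.plot_id,
                "variety": p.variety,
                "nitrogen": p.nitrogen,
                "water": p.water,
                "yield_t_ha": p.yield_t_ha,
            }
        )
        for d, v in zip(p.lai_days, p.lai_values):
            lai_rows.append({"plot_id": p.plot_id, "date": int(d), "lai": v})
        for d, v in zip(p.dam_days, p.dam_values):
            dam_rows.append({"plot_id": p.plot_id, "date": int(d), "dam_t_ha": v})
    paths = {
        "plots": out_dir / "plots.csv",
        "lai": out_dir / "lai_obs.csv",
        "dam": out_dir / "dam_obs.csv",
    }
    pd.DataFrame(reg_rows).to_csv(paths["plots"], index=False)
    pd.DataFrame(lai_rows).to_csv(paths["lai"], index=False)
    pd.DataFrame(dam_rows).to_csv(paths["dam"], index=False)
    return paths
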