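"""Delimited-table readers and writers for every pipeline stage.

All tables are RFC-4180 comma-separated files with a header row, decimal
points, and ISO-8601 timestamps. Readers validate schemas and units and
report malformed rows with their line numbers; an empty file yields an
empty collection with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .carbon_costs import BranchRecord
from .errors import TableFormatError
from .lrc import GasExchangeCurve, LRCParams
from .starch import StarchDynamics

__all__ = [
    "read_table",
    "write_table",
    "light_frame_to_series",
    "light_series_to_frame",
    "temperature_frame_to_series",
    "gas_exchange_frame_to_curves",
    "curves_to_frame",
    "lrc_params_to_frame",
    "frame_to_lrc_params",
    "branch_frame_to_records",
    "records_to_frame",
    "starch_frame_to_dynamics",
]

#: Required columns per table kind (extra columns, e.g. provenance, are kept).
SCHEMAS = {
    "light": ["timestamp", "ppfd", "sensor_id", "species", "position"],
    "temperature": ["timestamp", "temp_c"],
    "gas_exchange": ["curve_id", "species", "position", "ppfd", "pn"],
    "lrc_params": ["curve_id", "species", "position", "pgmax", "rd", "phi0",
                   "rss", "converged"],
    "a_n": ["date", "species", "position", "a_n_g_m2_d"],
    "branch": ["tree_id", "species", "position", "leaf_area_m2", "leaf_mass_g",
               "twig_mass_g", "leaf_c_frac", "twig_c_frac", "budbreak",
               "discoloration", "habit", "lifespan_years"],
    "costs": ["tree_id", "species", "position", "c_f_g", "c_t_g",
              "leaf_amortisation_days", "total_amortisation_days",
              "leaf_rcc_pct", "twig_rcc_pct", "total_rcc_pct",
              "looped_years", "never_amortised", "c_negative"],
    "sensitivity": ["species", "factor", "rcc_initial", "rcc_replaced",
                    "rel_change"],
    "starch": ["species", "position", "basis", "amplitude_g_per_g",
               "window_start", "window_end", "tissue_mass_g"],
    "starch_costs": ["species", "position", "starch_c_g", "window_uptake_g",
                     "relative_cost_pct", "uptake_nonpositive"],
}

_TIMESTAMP_COLS = {"timestamp", "date", "budbreak", "discoloration",
                   "window_start", "window_end"}
_NONNEGATIVE_COLS = {"ppfd"}


def _parse_timestamps(df: pd.DataFrame, col: str, path) -> None:
    try:
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"{path}: column {col!r}: {exc}") from exc


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate one table; rows are numbered from 2 (after header)."""
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file, returning empty table", stacklevel=2)
        return pd.DataFrame(columns=SCHEMAS[kind])
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    for col in _TIMESTAMP_COLS & set(df.columns):
        _parse_timestamps(df, col, path)
    for col in _NONNEGATIVE_COLS & set(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0)]
        if len(bad):
            raise TableFormatError(
                f"{path}: column {col!r} must be nonnegative; "
                f"bad value at row {bad[0] + 2}"
            )
        df[col] = vals
    return df


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    """Write one table, checking its schema first."""
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise TableFormatError(f"refusing to write {kind}: missing {missing}")
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


# -- conversions between tables and domain objects ---------------------------


def light_series_to_frame(
    series: pd.Series, sensor_id: str, species: str, position: str
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": series.index,
            "ppfd": series.to_numpy(),
            "sensor_id": sensor_id,
            "species": species,
            "position": position,
        }
    )


def light_frame_to_series(df: pd.DataFrame) -> dict[str, pd.Series]:
    """Split a light table into one PPFD series per sensor id."""
    out = {}
    for sensor, grp in df.groupby("sensor_id", sort=False):
        s = pd.Series(
            grp["ppfd"].to_numpy(),
            index=pd.DatetimeIndex(grp["timestamp"].to_numpy()),
            name="ppfd",
        )
        s.attrs.update(
            species=grp["species"].iloc[0], position=grp["position"].iloc[0]
        )
        out[sensor] = s
    return out


def temperature_frame_to_series(df: pd.DataFrame) -> pd.Series:
    return pd.Series(
        df["temp_c"].to_numpy(),
        index=pd.DatetimeIndex(df["timestamp"].to_numpy()),
        name="temp_c",
    )


def temperature_series_to_frame(series: pd.Series) -> pd.DataFrame:
    return pd.DataFrame({"timestamp": series.index, "temp_c": series.to_numpy()})


def curves_to_frame(curves: list[GasExchangeCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for i, pn in zip(c.ppfd, c.pn):
            rows.append(
                {"curve_id": c.curve_id, "species": c.species,
                 "position": c.position, "ppfd": i, "pn": pn}
            )
    return pd.DataFrame(rows)


def gas_exchange_frame_to_curves(df: pd.DataFrame) -> list[GasExchangeCurve]:
    curves = []
    for curve_id, grp in df.groupby("curve_id", sort=False):
        curves.append(
            GasExchangeCurve(
                ppfd=grp["ppfd"].to_numpy(float),
                pn=grp["pn"].to_numpy(float),
                species=grp["species"].iloc[0],
                position=grp["position"].iloc[0],
                curve_id=str(curve_id),
            )
        )
    return curves


def lrc_params_to_frame(fits: dict[str, tuple[str, str, LRCParams]]) -> pd.DataFrame:
    rows = []
    for curve_id, (species, position, p) in fits.items():
        rows.append(
            {"curve_id": curve_id, "species": species, "position": position,
             "pgmax": p.pgmax, "rd": p.rd, "phi0": p.phi0, "rss": p.rss,
             "converged": p.converged}
        )
    return pd.DataFrame(rows)


def frame_to_lrc_params(df: pd.DataFrame) -> dict[str, tuple[str, str, LRCParams]]:
    out = {}
    for _, row in df.iterrows():
        out[row["curve_id"]] = (
            row["species"],
            row["position"],
            LRCParams(
                pgmax=float(row["pgmax"]), rd=float(row["rd"]),
                phi0=float(row["phi0"]), rss=float(row["rss"]),
                converged=bool(row["converged"]),
            ),
        )
    return out


def records_to_frame(records: list[BranchRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "tree_id": r.tree_id, "species": r.species, "position": r.position,
                "leaf_area_m2": r.leaf_area_m2, "leaf_mass_g": r.leaf_mass_g,
                "twig_mass_g": r.twig_mass_g, "leaf_c_frac": r.leaf_c_frac,
                "twig_c_frac": r.twig_c_frac,
                "budbreak": r.budbreak,
                "discoloration": r.discoloration if r.discoloration is not None else "",
                "habit": r.habit,
                "lifespan_years": r.lifespan_years if r.lifespan_years else "",
            }
        )
    return pd.DataFrame(rows)


def branch_frame_to_records(df: pd.DataFrame) -> list[BranchRecord]:
    records = []
    for _, row in df.iterrows():
        disc = row["discoloration"]
        disc = None if pd.isna(disc) else pd.Timestamp(disc)
        lifespan = row["lifespan_years"]
        lifespan = None if pd.isna(lifespan) else int(lifespan)
        records.append(
            BranchRecord(
                tree_id=str(row["tree_id"]), species=str(row["species"]),
                position=str(row["position"]),
                leaf_area_m2=float(row["leaf_area_m2"]),
                leaf_mass_g=float(row["leaf_mass_g"]),
                twig_mass_g=float(row["twig_mass_g"]),
                leaf_c_frac=float(row["leaf_c_frac"]),
                twig_c_frac=float(row["twig_c_frac"]),
                budbreak=pd.Timestamp(row["budbreak"]),
                discoloration=disc, habit=str(row["habit"]),
                lifespan_years=lifespan,
            ).validate()
        )
    return records


def starch_frame_to_dynamics(df: pd.DataFrame) -> dict[tuple, StarchDynamics]:
    out = {}
    for _, row in df.iterrows():
        out[(row["species"], row["position"])] = StarchDynamics(
            amplitude_g_per_g=float(row["amplitude_g_per_g"]),
            window_start=pd.Timestamp(row["window_start"]),
            window_end=pd.Timestamp(row["window_end"]),
            basis=str(row["basis"]),
            tissue_mass_g=float(row["tissue_mass_g"]),
        ).validate()
    return out
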