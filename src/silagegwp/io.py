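"""Readers and writers for profile and result tables.

Profile tables are comma-separated UTF-8 text with a mandatory header. The
column dictionary:

==========  =====================================================
column      meaning
==========  =====================================================
sample_id   free-text identifier (optional)
acetic      acetic acid concentration
ethanol     ethanol concentration (empty -> imputed for vcDML)
lactic      lactic acid concentration
ammonia     ammonia concentration (empty -> imputed for vcDML)
dml         oven dry matter loss (optional)
vcdml       volatile-corrected dry matter loss (optional)
units       "percent_dm" or "mg_per_kg" (per row; default mg_per_kg)
==========  =====================================================

All concentrations share the row's unit; values are converted to mg/kg on
read (1% of DM = 1e4 mg/kg). Missing values are empty fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import MG_PER_KG_PER_PERCENT

__all__ = ["read_profiles", "write_table"]

VALUE_COLUMNS = ("acetic", "ethanol", "lactic", "ammonia", "dml", "vcdml")
REQUIRED_COLUMNS = ("acetic", "lactic")


def read_profiles(path) -> pd.DataFrame:
    """Read a profile CSV and return an mg/kg frame.

    Rows tagged ``units=percent_dm`` are multiplied by 1e4. Output columns:
    sample_id plus the six value columns (NaN where absent).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile table is missing required columns: {missing}")
    out = pd.DataFrame(index=df.index)
    out["sample_id"] = df["sample_id"].astype(str) if "sample_id" in df else [
        f"row-{i}" for i in range(len(df))]
    units = df["units"] if "units" in df else pd.Series("mg_per_kg", index=df.index)
    bad_units = ~units.isin(["mg_per_kg", "percent_dm"])
    if bad_units.any():
        raise ValueError(f"unknown units values: {sorted(units[bad_units].unique())}")
    scale = np.where(units == "percent_dm", MG_PER_KG_PER_PERCENT, 1.0)
    for col in VALUE_COLUMNS:
        out[col] = pd.to_numeric(df[col], errors="raise") * scale if col in df else np.nan
    for col in ("acetic", "ethanol", "lactic", "ammonia"):
        neg = out[col] < 0
        if neg.any():
            raise ValueError(
                f"negative {col} in rows: {out.loc[neg, 'sample_id'].tolist()}")
    return out


def write_table(frame: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a result table as CSV (UTF-8, header, decimal point)."""
    frame.to_csv(path, index=False, float_format=float_format)
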