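"""Campaign table schemas, CSV loading/writing and validation.

A campaign directory holds up to six UTF-8 CSV tables keyed by ISO-8601
``date`` (and ``site`` where applicable):

* ``scrape.csv`` — hot-water extraction filtrate + blank concentrations,
  extraction volume and chl a mass on the extracted filter;
* ``core_melt.csv`` — FSW-diluted chl a / abundance / biovolume with the
  melt geometry needed to undo the dilution;
* ``bulk_melt.csv`` — bulk (no-FSW) melt nutrient concentrations and bulk
  salinity (optional: some campaigns measure no bulk nutrients);
* ``water_column.csv`` — 2-m nutrient concentrations and salinity;
* ``currents.csv`` — daily maximum under-ice current speed;
* ``truth.csv`` — simulator ground truth (optional, absent for real data).

Concentrations are umol/L, chl a in mg (mass) or mg/m^3 (volumetric),
volumes in L, speeds in m/s; decimal separator is ".".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["CampaignTables", "LoadError", "elapsed_days", "load_campaign",
           "write_campaign_tables"]


class LoadError(ValueError):
    """A campaign directory failed validation; the message lists offenders."""


REQUIRED_COLUMNS = {
    "scrape": [
        "date", "site", "filtrate_N_umol_l", "filtrate_Si_umol_l",
        "blank_N_umol_l", "blank_Si_umol_l", "extraction_volume_l",
        "scrape_chla_mg",
    ],
    "core_melt": [
        "date", "site", "chla_diluted_ug_l", "abundance_diluted_cells_l",
        "biovolume_diluted_um3_l", "fsw_volume_l", "melted_ice_volume_l",
        "core_section_length_m",
    ],
    "bulk_melt": ["date", "site", "bulk_salinity", "no3no2_umol_l",
                  "sioh4_umol_l"],
    "water_column": ["date", "salinity", "no3no2_umol_l", "sioh4_umol_l"],
    "currents": ["date", "max_speed_m_s"],
}

OPTIONAL_TABLES = ("bulk_melt", "truth")


@dataclass
class CampaignTables:
    """The validated in-memory campaign bundle."""

    scrape: pd.DataFrame
    core_melt: pd.DataFrame
    water_column: pd.DataFrame
    currents: pd.DataFrame
    bulk_melt: Optional[pd.DataFrame] = None
    truth: Optional[pd.DataFrame] = None
    notices: list = field(default_factory=list)

    @property
    def start_date(self) -> pd.Timestamp:
        return pd.to_datetime(self.scrape["date"]).min()


def elapsed_days(dates, start=None) -> np.ndarray:
    """Fractional days elapsed since the campaign start (or ``start``)."""
    d = pd.to_datetime(pd.Series(dates))
    if start is None:
        start = d.min()
    return ((d - pd.Timestamp(start)) / pd.Timedelta(days=1)).to_numpy()


def _validate(name: str, df: pd.DataFrame, problems: list):
    missing = [c for c in REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        problems.append(f"{name}.csv: missing column(s) {', '.join(missing)}")
        return
    try:
        pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError):
        problems.append(f"{name}.csv: 'date' must be ISO-8601 (YYYY-MM-DD)")
    keys = ["date", "site"] if "site" in REQUIRED_COLUMNS[name] else ["date"]
    dup = df.duplicated(subset=keys)
    if name != "scrape" and dup.any():  # scrape allows replicate rows
        problems.append(f"{name}.csv: duplicate {'x'.join(keys)} rows")
    numeric = [c for c in REQUIRED_COLUMNS[name] if c not in ("date", "site")]
    for c in numeric:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            problems.append(f"{name}.csv: non-numeric values in column '{c}'")


def load_campaign(path) -> CampaignTables:
    """Load and validate a campaign directory.

    Raises
    ------
    LoadError
        Listing every missing file, unknown/missing column and unparsable
        value found.  A missing ``bulk_melt.csv`` is allowed (downstream
        bulk stages are skipped with a notice), as is a missing truth table.
    """
    path = Path(path)
    if not path.is_dir():
        raise LoadError(f"campaign directory not found: {path}")
    problems, frames, notices = [], {}, []
    for name in REQUIRED_COLUMNS:
        f = path / f"{name}.csv"
        if not f.exists():
            if name in OPTIONAL_TABLES:
                frames[name] = None
                notices.append(f"optional table {name}.csv absent; "
                               "bulk-melt stages will be skipped")
                continue
            problems.append(f"missing required file {name}.csv")
            continue
        df = pd.read_csv(f)
        if df.empty and name in OPTIONAL_TABLES:
            frames[name] = None
            notices.append(f"{name}.csv is empty; bulk-melt stages skipped")
            continue
        _validate(name, df, problems)
        frames[name] = df
    truth_f = path / "truth.csv"
    truth = pd.read_csv(truth_f) if truth_f.exists() else None
    if problems:
        raise LoadError("campaign failed validation:\n  " + "\n  ".join(problems))
    return CampaignTables(
        scrape=frames["scrape"],
        core_melt=frames["core_melt"],
        water_column=frames["water_column"],
        currents=frames["currents"],
        bulk_melt=frames.get("bulk_melt"),
        truth=truth,
        notices=notices,
    )


def write_campaign_tables(tables: CampaignTables, outdir) -> None:
    """Write the bundle back to CSV (float format fixed for reproducibility)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mapping = {
        "scrape": tables.scrape,
        "core_melt": tables.core_melt,
        "bulk_melt": tables.bulk_melt,
        "water_column": tables.water_column,
        "currents": tables.currents,
        "truth": tables.truth,
    }
    for name, df in mapping.items():
        if df is None:
            continue
        try:
            df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
        except OSError as exc:
            raise OSError(f"failed writing {outdir / (name + '.csv')}: {exc}") from exc
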