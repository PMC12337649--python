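"""Campaign analysis models.

Each analysis is a model object built from campaign tables whose ``fit()``
returns a Results object carrying estimates, inference and a ``summary()``
table:

* :class:`DilutionModel` — classifies bulk-melt nutrient samples against
  the conservative dilution line from the 2-m water column and compares
  bulk vs water-column N:Si (Kruskal-Wallis);
* :class:`RetentionModel` — standardized major axis (SMA) regression of
  bulk-melt concentrations on the independently estimated bottom-ice
  intracellular concentrations; the slope estimates the fraction of the
  intracellular pool released on bulk melt (full release -> 1:1 line,
  ~1/11 for silicic acid -> 1:11 line);
* :class:`TidalTrendModel` — OLS time trends of the site-averaged bloom and
  chl-specific IC series, detrended-residual correlations against daily
  maximum under-ice currents at lags of 0 and 1 sampling cycles, and the
  log-linear decay of the intracellular N:Si ratio;
* :class:`CampaignAnalysis` — orchestrates the chain end-to-end from a
  campaign directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import nutrients, stats
from .biomass import MeltGeometry, fsw_dilution_correct
from .io import CampaignTables, elapsed_days, load_campaign
from .physics import DilutionLine, classify_vs_dilution_line, dilution_concentration

__all__ = [
    "CampaignAnalysis",
    "CampaignResults",
    "DilutionModel",
    "RetentionModel",
    "TidalTrendModel",
    "ic_profiles",
    "season_summary",
    "site_average",
    "water_column_line",
]

NUTRIENT_COLS = {"N": "no3no2_umol_l", "Si": "sioh4_umol_l"}


# ---------------------------------------------------------------------------
# intracellular estimation chain over the whole campaign


def ic_profiles(tables: CampaignTables) -> pd.DataFrame:
    """Per-(date, site) intracellular nutrient profiles.

    Scrape replicates are blank-corrected first and averaged before chl a
    normalisation; FSW-diluted core measurements are corrected to melted-ice
    volume before entering the chain.
    """
    sc = tables.scrape.copy()
    for nut in ("N", "Si"):
        corr = nutrients.blank_correct(
            sc[f"filtrate_{nut}_umol_l"].to_numpy(),
            sc[f"blank_{nut}_umol_l"].to_numpy(),
        )
        sc[f"corrected_{nut}"] = corr.value
        sc[f"clipped_{nut}"] = corr.clipped
    agg = sc.groupby(["date", "site"], as_index=False).agg(
        corrected_N=("corrected_N", "mean"),
        corrected_Si=("corrected_Si", "mean"),
        extraction_volume_l=("extraction_volume_l", "mean"),
        scrape_chla_mg=("scrape_chla_mg", "mean"),
        blank_clipped=("clipped_N", "any"),
    )

    cm = tables.core_melt.copy()
    factors = []
    for _, row in cm.iterrows():
        g = MeltGeometry(
            core_section_length=row["core_section_length_m"],
            fsw_volume=row["fsw_volume_l"],
            melted_ice_volume=row["melted_ice_volume_l"],
            n_cores_pooled=int(row.get("n_cores_pooled", 1)),
        )
        factors.append(fsw_dilution_correct(1.0, g))
    cm["dilution_factor"] = factors
    cm["chla_mg_m3"] = cm["chla_diluted_ug_l"] * cm["dilution_factor"]
    cm["abundance_cells_l"] = cm["abundance_diluted_cells_l"] * cm["dilution_factor"]
    cm["biovolume_um3_l"] = cm["biovolume_diluted_um3_l"] * cm["dilution_factor"]
    cm["chla_areal_mg_m2"] = cm["chla_mg_m3"] * cm["core_section_length_m"]

    df = agg.merge(
        cm[
            ["date", "site", "chla_mg_m3", "chla_areal_mg_m2",
             "abundance_cells_l", "biovolume_um3_l"]
        ],
        on=["date", "site"],
        how="inner",
    )
    df["ic_chl_N"] = df["corrected_N"] * df["extraction_volume_l"] / df["scrape_chla_mg"]
    df["ic_chl_Si"] = (
        df["corrected_Si"] * df["extraction_volume_l"] / df["scrape_chla_mg"]
    )
    for nut in ("N", "Si"):
        df[f"bottom_ice_ic_{nut}"] = nutrients.bottom_ice_ic(
            df[f"ic_chl_{nut}"].to_numpy(), df["chla_mg_m3"].to_numpy()
        )
        df[f"ic_per_cell_volume_{nut}"] = nutrients.ic_per_cell_volume(
            df[f"bottom_ice_ic_{nut}"].to_numpy(), df["biovolume_um3_l"].to_numpy()
        )
        df[f"ic_per_cell_{nut}"] = nutrients.ic_per_cell(
            df[f"bottom_ice_ic_{nut}"].to_numpy(), df["abundance_cells_l"].to_numpy()
        )
    df["n_si"] = nutrients.n_si_ratio(
        df["ic_chl_N"].to_numpy(), df["ic_chl_Si"].to_numpy()
    )
    return df.drop(columns=["corrected_N", "corrected_Si"])


_SUMMARY_COLS = [
    "chla_areal_mg_m2", "ic_chl_N", "ic_chl_Si", "bottom_ice_ic_N",
    "bottom_ice_ic_Si", "ic_per_cell_volume_N", "ic_per_cell_volume_Si",
    "ic_per_cell_N", "ic_per_cell_Si", "abundance_cells_l",
    "biovolume_um3_l", "n_si",
]


def season_summary(profiles: pd.DataFrame, order: str = "per_sample") -> pd.DataFrame:
    """Season mean +- SD of every profile quantity.

    ``order='per_sample'`` (default) averages per-sample derived quantities;
    ``'ratio_of_means'`` recomputes the ratio-type rows (per-cell and
    per-cell-volume quantities, N:Si) from season-mean numerators and
    denominators.  The two differ because a mean of ratios is not the ratio
    of the means.
    """
    if order not in ("per_sample", "ratio_of_means"):
        raise ValueError("order must be 'per_sample' or 'ratio_of_means'")
    rows = []
    for col in _SUMMARY_COLS:
        vals = profiles[col].dropna()
        rows.append({"quantity": col, "mean": vals.mean(),
                     "sd": vals.std(ddof=1), "n": len(vals)})
    out = pd.DataFrame(rows).set_index("quantity")
    if order == "ratio_of_means":
        for nut in ("N", "Si"):
            bi = profiles[f"bottom_ice_ic_{nut}"].mean()
            out.loc[f"ic_per_cell_volume_{nut}", "mean"] = nutrients.ic_per_cell_volume(
                bi, profiles["biovolume_um3_l"].mean()
            )
            out.loc[f"ic_per_cell_{nut}", "mean"] = nutrients.ic_per_cell(
                bi, profiles["abundance_cells_l"].mean()
            )
        out.loc["n_si", "mean"] = (
            profiles["ic_chl_N"].mean() / profiles["ic_chl_Si"].mean()
        )
    return out.reset_index()


def site_average(df: pd.DataFrame, value: str) -> pd.DataFrame:
    """Per-date mean +- SD across sites; SD is NaN (flagged) for single-site dates."""
    g = df.groupby("date")[value]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_sites="count").reset_index()
    out["single_site"] = out["n_sites"] == 1
    return out


def water_column_line(water: pd.DataFrame, nutrient: str) -> DilutionLine:
    """Dilution line anchored at the campaign-average 2-m concentration/salinity."""
    return DilutionLine(
        reference_concentration=float(water[NUTRIENT_COLS[nutrient]].mean()),
        reference_salinity=float(water["salinity"].mean()),
    )


# ---------------------------------------------------------------------------
# dilution-line classification + N:Si comparison


@dataclass
class DilutionResults:
    classifications: pd.DataFrame  # per sample x nutrient label
    lines: dict
    bulk_n_si: pd.Series
    water_n_si: pd.Series
    kw_h: float
    kw_p: float
    low_salinity_threshold: float
    low_salinity_fraction_on: dict

    @property
    def kw_significance(self) -> str:
        return stats.significance_label(self.kw_p)

    def summary(self) -> str:
        lines = ["Bulk-melt nutrients vs conservative dilution"]
        for nut in ("N", "Si"):
            counts = (
                self.classifications.query("nutrient == @nut")["label"]
                .value_counts()
                .to_dict()
            )
            lines.append(f"  {nut}: {counts}")
            lines.append(
                f"  {nut} fraction 'on' line at salinity <= "
                f"{self.low_salinity_threshold}: "
                f"{self.low_salinity_fraction_on[nut]:.2f}"
            )
        lines.append(
            f"  bulk N:Si mean {self.bulk_n_si.mean():.2f} vs water-column "
            f"{self.water_n_si.mean():.2f}; Kruskal-Wallis H = {self.kw_h:.2f}, "
            f"p = {self.kw_p:.3g} ({self.kw_significance})"
        )
        return "\n".join(lines)


class DilutionModel:
    """Classify bulk-melt samples against the water-column dilution line."""

    def __init__(self, bulk_melt: pd.DataFrame, water_column: pd.DataFrame):
        self.bulk_melt = bulk_melt
        self.water_column = water_column

    @classmethod
    def from_tables(cls, tables: CampaignTables) -> "DilutionModel":
        if tables.bulk_melt is None:
            raise ValueError("campaign has no bulk-melt table")
        return cls(tables.bulk_melt, tables.water_column)

    def fit(
        self,
        rel_tolerance: float = 0.15,
        abs_floor: float = 0.2,
        low_salinity_threshold: float = 6.2,
    ) -> DilutionResults:
        recs, lines, low_frac = [], {}, {}
        sal = self.bulk_melt["bulk_salinity"].to_numpy()
        for nut, col in NUTRIENT_COLS.items():
            line = water_column_line(self.water_column, nut)
            lines[nut] = line
            labels = classify_vs_dilution_line(
                sal, self.bulk_melt[col].to_numpy(), line,
                rel_tolerance=rel_tolerance, abs_floor=abs_floor,
            )
            for (_, row), lab in zip(self.bulk_melt.iterrows(), labels):
                recs.append(
                    {"date": row["date"], "site": row["site"], "nutrient": nut,
                     "salinity": row["bulk_salinity"], "concentration": row[col],
                     "expected": dilution_concentration(line, row["bulk_salinity"]),
                     "label": lab}
                )
            low = labels[sal <= low_salinity_threshold]
            low_frac[nut] = float(np.mean(low == "on")) if low.size else float("nan")
        bulk_ratio = nutrients.n_si_ratio(
            self.bulk_melt["no3no2_umol_l"].to_numpy(),
            self.bulk_melt["sioh4_umol_l"].to_numpy(),
        )
        water_ratio = nutrients.n_si_ratio(
            self.water_column["no3no2_umol_l"].to_numpy(),
            self.water_column["sioh4_umol_l"].to_numpy(),
        )
        h, p = stats.kruskal_wallis([bulk_ratio, water_ratio])
        return DilutionResults(
            classifications=pd.DataFrame(recs),
            lines=lines,
            bulk_n_si=pd.Series(bulk_ratio),
            water_n_si=pd.Series(water_ratio),
            kw_h=h,
            kw_p=p,
            low_salinity_threshold=low_salinity_threshold,
            low_salinity_fraction_on=low_frac,
        )


# ---------------------------------------------------------------------------
# bulk vs intracellular SMA (retention inference)


@dataclass
class RetentionResults:
    sma: dict  # nutrient -> RegressionResult or None
    retention: dict  # nutrient -> slope (fraction released)
    release_dilution: dict  # nutrient -> 1/slope
    n_joint: dict
    background_subtracted: bool
    notices: list = field(default_factory=list)

    def summary(self) -> str:
        out = ["Bulk-melt vs bottom-ice intracellular concentration (SMA)"]
        for nut, res in self.sma.items():
            if res is None:
                out.append(f"  {nut}: skipped ({self.n_joint[nut]} joint samples)")
                continue
            out.append(
                f"  {nut}: slope = {res.slope:.3f} (1/slope = "
                f"{self.release_dilution[nut]:.2f}), r^2 = {res.r_squared:.2f}, "
                f"p = {res.p_value:.3g} ({res.significance}), n = {res.n}"
            )
        out.append(
            "  brine background "
            + ("subtracted via water-column dilution line"
               if self.background_subtracted else "not subtracted")
        )
        return "\n".join(out)


class RetentionModel:
    """SMA regression of bulk-melt nutrients on estimated bottom-ice IC pools.

    Both axes are estimated with error from independent measurements, which
    is what motivates a symmetric (model II) line fit.  The slope estimates
    the melt-release (retention) fraction of the intracellular pool; its
    reciprocal is the apparent dilution of the pool in the bulk measurement.
    """

    def __init__(
        self,
        profiles: pd.DataFrame,
        bulk_melt: pd.DataFrame,
        water_column: Optional[pd.DataFrame] = None,
    ):
        self.profiles = profiles
        self.bulk_melt = bulk_melt
        self.water_column = water_column

    @classmethod
    def from_tables(cls, tables: CampaignTables,
                    profiles: Optional[pd.DataFrame] = None) -> "RetentionModel":
        if tables.bulk_melt is None:
            raise ValueError("campaign has no bulk-melt table")
        if profiles is None:
            profiles = ic_profiles(tables)
        return cls(profiles, tables.bulk_melt, tables.water_column)

    def fit(self, subtract_background: bool = True) -> RetentionResults:
        joint = self.profiles.merge(self.bulk_melt, on=["date", "site"], how="inner")
        sma, retention, recip, n_joint, notices = {}, {}, {}, {}, []
        for nut, col in NUTRIENT_COLS.items():
            x = joint[f"bottom_ice_ic_{nut}"].to_numpy()
            y = joint[col].to_numpy()
            if subtract_background and self.water_column is not None:
                line = water_column_line(self.water_column, nut)
                y = y - dilution_concentration(line, joint["bulk_salinity"].to_numpy())
            n_joint[nut] = x.size
            if x.size < 3:
                sma[nut] = retention[nut] = recip[nut] = None
                notices.append(f"{nut}: fewer than 3 joint samples; SMA skipped")
                continue
            res = stats.sma_fit(x, y)
            sma[nut] = res
            retention[nut] = res.slope
            recip[nut] = 1.0 / res.slope if res.slope != 0 else float("inf")
        return RetentionResults(
            sma=sma, retention=retention, release_dilution=recip, n_joint=n_joint,
            background_subtracted=subtract_background
            and self.water_column is not None,
            notices=notices,
        )


# ---------------------------------------------------------------------------
# time series: trends, tidal residual coupling, N:Si decay


@dataclass
class TidalTrendResults:
    trends: dict  # series name -> RegressionResult
    residual_correlations: dict  # (series, lag) -> CorrelationResult
    nsi_decay: stats.RegressionResult
    series: pd.DataFrame  # site-averaged series with matched forcing
    current_matching: str

    def summary(self) -> str:
        out = ["Seasonal trends (OLS on site-averaged series)"]
        for name, res in self.trends.items():
            out.append(
                f"  {name}: slope = {res.slope:.4g}/day, r^2 = {res.r_squared:.2f}, "
                f"p = {res.p_value:.3g} ({res.significance})"
            )
        out.append("Detrended residuals vs daily maximum currents "
                   f"({self.current_matching})")
        for (name, lag), res in self.residual_correlations.items():
            out.append(
                f"  {name} lag {lag}: r = {res.r:.2f}, p = {res.p_value:.3g} "
                f"({res.significance}), n = {res.n}"
            )
        d = self.nsi_decay
        out.append(
            f"ln(IC N:Si) decay: rate = {d.slope:.4g}/day, r^2 = "
            f"{d.r_squared:.2f}, p = {d.p_value:.3g} ({d.significance})"
        )
        return "\n".join(out)


class TidalTrendModel:
    """Trend + tidal-residual analysis of the site-averaged bloom series.

    ``current_matching='same_day'`` pairs each sampling date with that day's
    maximum current; ``'interpolated'`` linearly interpolates the daily
    series onto the sampling dates (identical when the grids align).
    """

    SERIES = ("chla_areal_mg_m2", "ic_chl_N", "ic_chl_Si")

    def __init__(self, profiles: pd.DataFrame, currents: pd.DataFrame,
                 current_matching: str = "same_day"):
        if current_matching not in ("same_day", "interpolated"):
            raise ValueError("current_matching must be 'same_day' or 'interpolated'")
        self.profiles = profiles
        self.currents = currents
        self.current_matching = current_matching

    @classmethod
    def from_tables(cls, tables: CampaignTables,
                    profiles: Optional[pd.DataFrame] = None,
                    current_matching: str = "same_day") -> "TidalTrendModel":
        if profiles is None:
            profiles = ic_profiles(tables)
        return cls(profiles, tables.currents, current_matching)

    def _matched_currents(self, dates) -> np.ndarray:
        cur = self.currents.copy()
        cur_days = elapsed_days(cur["date"], start=pd.to_datetime(dates).min())
        want = elapsed_days(dates, start=pd.to_datetime(dates).min())
        if self.current_matching == "same_day":
            lookup = dict(zip(cur_days, cur["max_speed_m_s"]))
            out = np.array([lookup.get(d, np.nan) for d in want])
            if np.isnan(out).any():  # fall back for missing days
                out = np.interp(want, cur_days, cur["max_speed_m_s"])
            return out
        return np.interp(want, cur_days, cur["max_speed_m_s"])

    def fit(self, lags=(0, 1)) -> TidalTrendResults:
        avg = {s: site_average(self.profiles, s) for s in self.SERIES}
        nsi = site_average(self.profiles, "n_si")
        dates = avg[self.SERIES[0]]["date"]
        t = elapsed_days(dates)
        forcing = self._matched_currents(dates)
        series = pd.DataFrame({"date": dates, "elapsed_days": t,
                               "daily_max_current": forcing})
        trends, resid_corr = {}, {}
        for name in self.SERIES:
            y = avg[name]["mean"].to_numpy()
            series[name] = y
            trends[name] = stats.ols_fit(t, y)
            resid = stats.detrend_linear(t, y)
            series[f"resid_{name}"] = resid
            for lag in lags:
                resid_corr[(name, lag)] = stats.lagged_residual_correlation(
                    resid, forcing, lag=lag
                )
        series["n_si"] = nsi["mean"].to_numpy()
        decay = stats.loglinear_decay_fit(t, nsi["mean"].to_numpy())
        return TidalTrendResults(
            trends=trends,
            residual_correlations=resid_corr,
            nsi_decay=decay,
            series=series,
            current_matching=self.current_matching,
        )


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class CampaignResults:
    profiles: pd.DataFrame
    summary_table: pd.DataFrame
    dilution: Optional[DilutionResults]
    retention: Optional[RetentionResults]
    tidal: TidalTrendResults
    notices: list

    def summary(self) -> str:
        parts = [
            "Campaign analysis",
            "=" * 17,
            f"samples: {len(self.profiles)} site-days, "
            f"{self.profiles['date'].nunique()} dates, "
            f"{self.profiles['site'].nunique()} sites",
            "",
            "Season means (+- SD)",
        ]
        for _, r in self.summary_table.iterrows():
            parts.append(f"  {r['quantity']}: {r['mean']:.4g} (+-{r['sd']:.3g})")
        for block in (self.dilution, self.retention):
            if block is not None:
                parts += ["", block.summary()]
        parts += ["", self.tidal.summary()]
        for n in self.notices:
            parts.append(f"note: {n}")
        parts.append("note: no multiple-testing correction is applied; "
                     "p-values are reported as computed")
        return "\n".join(parts)

    def save(self, outdir) -> Path:
        """Write the report CSVs (auditable intermediates) and summary text."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(outdir / "ic_profiles.csv", index=False,
                             float_format="%.10g")
        self.summary_table.to_csv(outdir / "season_summary.csv", index=False,
                                  float_format="%.10g")
        regs = []
        for name, res in self.tidal.trends.items():
            regs.append({"analysis": f"trend_{name}", **_reg_row(res)})
        regs.append({"analysis": "nsi_decay", **_reg_row(self.tidal.nsi_decay)})
        if self.retention is not None:
            for nut, res in self.retention.sma.items():
                if res is not None:
                    regs.append({"analysis": f"retention_{nut}", **_reg_row(res)})
        pd.DataFrame(regs).to_csv(outdir / "regressions.csv", index=False)
        corr = [
            {"series": name, "lag": lag, "r": c.r, "p_value": c.p_value,
             "n": c.n, "significance": c.significance}
            for (name, lag), c in self.tidal.residual_correlations.items()
        ]
        pd.DataFrame(corr).to_csv(outdir / "correlations.csv", index=False)
        self.tidal.series.to_csv(outdir / "site_averaged_series.csv", index=False,
                                 float_format="%.10g")
        if self.dilution is not None:
            self.dilution.classifications.to_csv(
                outdir / "dilution_classifications.csv", index=False
            )
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        return outdir


def _reg_row(res: stats.RegressionResult) -> dict:
    return {"method": res.method, "slope": res.slope, "intercept": res.intercept,
            "r_squared": res.r_squared, "p_value": res.p_value, "n": res.n,
            "significance": res.significance}


class CampaignAnalysis:
    """End-to-end analysis of one campaign (directory or in-memory tables)."""

    def __init__(self, tables: CampaignTables, current_matching: str = "same_day"):
        self.tables = tables
        self.current_matching = current_matching

    @classmethod
    def from_campaign(cls, path, **kw) -> "CampaignAnalysis":
        return cls(load_campaign(path), **kw)

    def fit(self, subtract_background: bool = True,
            summary_order: str = "per_sample") -> CampaignResults:
        notices = list(self.tables.notices)
        profiles = ic_profiles(self.tables)
        summary = season_summary(profiles, order=summary_order)
        dilution = retention = None
        if self.tables.bulk_melt is not None:
            dilution = DilutionModel.from_tables(self.tables).fit()
            retention = RetentionModel.from_tables(self.tables, profiles).fit(
                subtract_background=subtract_background
            )
            notices.extend(retention.notices)
        else:
            notices.append("no bulk-melt table: dilution and retention "
                           "stages skipped")
        tidal = TidalTrendModel.from_tables(
            self.tables, profiles, current_matching=self.current_matching
        ).fit()
        return CampaignResults(
            profiles=profiles, summary_table=summary, dilution=dilution,
            retention=retention, tidal=tidal, notices=notices,
        )
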