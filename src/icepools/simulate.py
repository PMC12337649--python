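"""Synthetic field-campaign generator.

Emulates a declining Arctic bottom-ice algal spring bloom sampled every 3-4
days at three snow-depth sites, together with the three observation
protocols used on it:

* **scrape** sampling of the soft skeletal bottom layer into filtered
  seawater (FSW), filtered and hot-water extracted for intracellular (IC)
  nutrients, with a daily extraction blank;
* **FSW-diluted core melt** for bottom-ice chl a, cell abundance and
  community biovolume (with the dilution geometry recorded);
* **bulk melt** of the bottom 3 cm without FSW, which dilutes brine along a
  conservative line and osmotically shocks cells so that a *retention
  fraction* of each IC pool is released into the meltwater (modelled as
  full release for nitrate+nitrite and ~1/11 for silicic acid).

The physical forcing is a semidiurnal tidal current built from the lunar
(M2, 12.42 h) and solar (S2, 12.00 h) constituents, whose beat produces the
~14.8-day spring-neap envelope; detrended IC residuals are coupled to the
standardized daily-maximum current with a configurable target correlation.

All stochasticity flows from a single seeded generator, so a fixed seed
reproduces a campaign exactly.  Noise is multiplicative lognormal (unit
mean) for concentration-type measurements and Poisson for cell counts;
setting ``noise_cv = 0`` switches every measurement perturbation off, which
makes the whole observe -> analyse chain exactly invertible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimConfig",
    "sampling_days",
    "simulate_bloom",
    "simulate_campaign",
    "simulate_currents",
    "observe_bulk_melt",
    "observe_core_melt",
    "observe_scrape",
    "write_campaign",
]

_M2_PERIOD_H = 12.42  # lunar semidiurnal
_S2_PERIOD_H = 12.00  # solar semidiurnal

SNOW_CLASSES = ("thin", "medium", "thick")


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """All generator parameters; defaults emulate the study conditions.

    Trends are linear per day (``trend_mode='linear'``); in
    ``'exponential'`` mode the IC trends are applied as relative rates
    ``trend/ic0`` per day so the true ln(N:Si) is linear in time.
    """

    seed: int = 0
    n_days: int = 42  # campaign length, days
    sampling_pattern: tuple = (3, 4)  # alternating 3-4 day intervals
    n_sites: int = 3  # thin / medium / thick snow
    site_chla_factor: tuple = (1.2, 1.0, 0.8)  # per snow class
    start_date: str = "2010-05-08"

    # tidal forcing, m/s
    a_m2: float = 0.12
    a_s2: float = 0.06
    current_noise_sd: float = 0.01

    # bloom: areal chl a over the bottom 3-cm section
    chla0: float = 90.0  # mg/m^2 at day 0 (before site factors)
    chla_decline_rate: float = -2.0  # mg/m^2 per day
    core_section_length: float = 0.03  # m

    # chl-specific IC pools, umol per mg chl a
    icN0: float = 16.0
    icN_trend: float = -0.15  # per day (declining)
    icSi0: float = 40.0
    icSi_trend: float = 0.9  # per day (rising)
    trend_mode: str = "linear"  # or "exponential"

    # tidal coupling of detrended IC residuals
    coupling_r: float = 0.5  # target residual-forcing correlation
    process_sd_N: float = 1.5  # biological variability, umol/mg
    process_sd_Si: float = 6.0

    # bulk-melt differential retention
    retention_N: float = 1.0
    retention_Si: float = 1.0 / 11.0
    bulk_salinity_range: tuple = (4.0, 12.0)

    # under-ice water column (2-m depth)
    water_column_N: float = 7.67  # umol/L
    water_column_Si: float = 14.7
    water_salinity: float = 32.0

    # community structure
    mean_cell_volume: float = 1890.0  # um^3/cell
    cells_per_mg_chla_m3: float = 1.72e5  # cells/L per (mg chl a / m^3)
    pennate_fraction: float = 0.82
    counted_cells: int = 400

    # measurement model
    noise_cv: float = 0.1
    blank_N: float = 0.3  # umol/L in the hot-water blank
    blank_Si: float = 0.5
    extraction_volume: float = 0.040  # L
    scrape_chla0: float = 0.025  # mg on the filter at peak bloom
    fsw_volume_range: tuple = (1.0, 3.0)  # L
    core_inner_diameter: float = 0.09  # m
    n_cores_pooled: int = 3

    def __post_init__(self):
        if not 0 <= self.retention_N <= 1 or not 0 <= self.retention_Si <= 1:
            raise ConfigError("retention fractions must lie in [0, 1]")
        if not 0 <= self.coupling_r < 1:
            raise ConfigError("coupling_r must lie in [0, 1)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.n_sites < 1 or self.n_sites > len(self.site_chla_factor):
            raise ConfigError("n_sites must be between 1 and the number of factors")
        if self.trend_mode not in ("linear", "exponential"):
            raise ConfigError("trend_mode must be 'linear' or 'exponential'")
        # means must stay positive over the whole season at every site
        t_end = self.n_days
        if self.trend_mode == "linear":
            chla_end = self.chla0 * min(self.site_chla_factor[: self.n_sites]) + (
                self.chla_decline_rate * t_end * min(self.site_chla_factor[: self.n_sites])
            )
            if chla_end <= 0:
                raise ConfigError("chl a trend reaches zero before the season ends")
            if self.icN0 + self.icN_trend * t_end <= 0:
                raise ConfigError("IC-N trend reaches zero before the season ends")
            if self.icSi0 + self.icSi_trend * t_end <= 0:
                raise ConfigError("IC-Si trend reaches zero before the season ends")

    @classmethod
    def grid_2010(cls, **overrides) -> "SimConfig":
        """The 12-date 3-4-day sampling grid of a 41-day season."""
        overrides.setdefault("n_days", 41)
        return cls(**overrides)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("sampling_pattern", "site_chla_factor", "bulk_salinity_range",
                    "fsw_volume_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def sampling_days(cfg: SimConfig) -> np.ndarray:
    """Day offsets of the sampling events (0, 3, 7, 10, ... within the season)."""
    days = [0]
    i = 0
    while True:
        nxt = days[-1] + cfg.sampling_pattern[i % len(cfg.sampling_pattern)]
        if nxt > cfg.n_days:
            break
        days.append(nxt)
        i += 1
    return np.asarray(days, dtype=int)


def _lognoise(rng, cv, size=None):
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_currents(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Daily maximum under-ice current speed (m/s) for every day of the season.

    Hourly speed u(t) = A_M2 sin(2 pi t / 12.42 h) + A_S2 sin(2 pi t / 12 h)
    + noise; the daily maximum of |u| carries the ~14.8-day spring-neap beat
    of the two constituents.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_days = cfg.n_days + 1
    hours = np.arange(n_days * 24, dtype=float)
    u = cfg.a_m2 * np.sin(2 * np.pi * hours / _M2_PERIOD_H) + cfg.a_s2 * np.sin(
        2 * np.pi * hours / _S2_PERIOD_H
    )
    if cfg.current_noise_sd > 0:
        u = u + rng.normal(0.0, cfg.current_noise_sd, size=u.size)
    daily_max = np.abs(u).reshape(n_days, 24).max(axis=1)
    return pd.DataFrame({"day": np.arange(n_days), "max_speed": daily_max})


def _trend(value0, trend, t, mode):
    if mode == "exponential":
        return value0 * np.exp(trend / value0 * t)
    return value0 + trend * t


def simulate_bloom(cfg: SimConfig, currents: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Ground-truth state per site and sampling day.

    Chl a declines linearly with a multiplicative site (snow-class) factor;
    IC-N^B declines and IC-Si^B rises; both IC series receive a component
    proportional to the standardized daily-maximum current, scaled so the
    detrended residual-forcing correlation targets ``coupling_r`` against
    the biological process noise, plus that process noise itself.
    Abundance is proportional to chl a and biovolume to abundance times the
    (site-jittered) mean cell volume.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    days = sampling_days(cfg)
    cmax = currents.set_index("day")["max_speed"]
    forcing = cmax.reindex(days).to_numpy()
    f_sd = forcing.std(ddof=0)
    f_std = (forcing - forcing.mean()) / f_sd if f_sd > 0 else np.zeros_like(forcing)

    if cfg.coupling_r > 0:
        gain = cfg.coupling_r / np.sqrt(1.0 - cfg.coupling_r**2)
    else:
        gain = 0.0
    amp_n = gain * cfg.process_sd_N
    amp_si = gain * cfg.process_sd_Si

    # site-level mean cell volume jitter (a community-composition effect)
    mcv_site = cfg.mean_cell_volume * _lognoise(rng, 0.05 * (cfg.noise_cv > 0),
                                                cfg.n_sites)

    rows = []
    start = date.fromisoformat(cfg.start_date)
    for si in range(cfg.n_sites):
        factor = cfg.site_chla_factor[si]
        chla_areal = np.maximum(
            _trend(cfg.chla0 * factor, cfg.chla_decline_rate * factor, days, "linear"),
            1e-6,
        )
        proc_n = (
            rng.normal(0.0, cfg.process_sd_N, days.size)
            if cfg.process_sd_N > 0
            else np.zeros(days.size)
        )
        proc_si = (
            rng.normal(0.0, cfg.process_sd_Si, days.size)
            if cfg.process_sd_Si > 0
            else np.zeros(days.size)
        )
        ic_n = np.maximum(
            _trend(cfg.icN0, cfg.icN_trend, days, cfg.trend_mode)
            + amp_n * f_std + proc_n,
            1e-6,
        )
        ic_si = np.maximum(
            _trend(cfg.icSi0, cfg.icSi_trend, days, cfg.trend_mode)
            + amp_si * f_std + proc_si,
            1e-6,
        )
        chla_vol = chla_areal / cfg.core_section_length  # mg/m^3 of melted ice
        abundance = chla_vol * cfg.cells_per_mg_chla_m3
        biovolume = abundance * mcv_site[si]
        for j, d in enumerate(days):
            rows.append(
                {
                    "date": (start + timedelta(days=int(d))).isoformat(),
                    "day": int(d),
                    "site": SNOW_CLASSES[si % len(SNOW_CLASSES)],
                    "chla_areal_mg_m2": chla_areal[j],
                    "chla_mg_m3": chla_vol[j],
                    "ic_chl_N": ic_n[j],
                    "ic_chl_Si": ic_si[j],
                    "abundance_cells_l": abundance[j],
                    "biovolume_um3_l": biovolume[j],
                    "daily_max_current": forcing[j],
                }
            )
    return pd.DataFrame(rows)


def observe_scrape(state: pd.DataFrame, cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Scrape-extraction observations: filtrate and blank concentrations.

    The hot-water filtrate concentration is the true chl-specific pool times
    the chl a mass on the filter over the extraction volume, on top of the
    daily blank, with multiplicative lognormal noise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    # one blank per sampling day, shared across sites
    uniq_days = state["day"].unique()
    blank_n = {d: cfg.blank_N * _lognoise(rng, cfg.noise_cv) for d in uniq_days}
    blank_si = {d: cfg.blank_Si * _lognoise(rng, cfg.noise_cv) for d in uniq_days}
    rows = []
    for _, s in state.iterrows():
        # scrape biomass scales with the bloom; it cancels in the chain
        mass_true = max(cfg.scrape_chla0 * s["chla_areal_mg_m2"] / cfg.chla0, 0.002)
        bn, bs = blank_n[s["day"]], blank_si[s["day"]]
        filtrate_n = bn + s["ic_chl_N"] * mass_true / cfg.extraction_volume * _lognoise(
            rng, cfg.noise_cv
        )
        filtrate_si = bs + s["ic_chl_Si"] * mass_true / cfg.extraction_volume * _lognoise(
            rng, cfg.noise_cv
        )
        rows.append(
            {
                "date": s["date"],
                "site": s["site"],
                "filtrate_N_umol_l": filtrate_n,
                "filtrate_Si_umol_l": filtrate_si,
                "blank_N_umol_l": bn,
                "blank_Si_umol_l": bs,
                "extraction_volume_l": cfg.extraction_volume,
                "scrape_chla_mg": mass_true * _lognoise(rng, cfg.noise_cv),
            }
        )
    return pd.DataFrame(rows)


def observe_core_melt(state: pd.DataFrame, cfg: SimConfig, rng=None) -> pd.DataFrame:
    """FSW-diluted core-melt observations with their melt geometry.

    Concentrations are diluted by melt/(melt+FSW) and perturbed; abundance
    carries Poisson counting error with ``counted_cells`` enumerated.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    area = np.pi * (cfg.core_inner_diameter / 2) ** 2
    melt_volume = cfg.core_section_length * area * cfg.n_cores_pooled * 1000.0  # L
    rows = []
    for _, s in state.iterrows():
        fsw = rng.uniform(*cfg.fsw_volume_range)
        dil = melt_volume / (melt_volume + fsw)
        chla_obs = s["chla_mg_m3"] * dil * _lognoise(rng, cfg.noise_cv)
        abund_diluted = s["abundance_cells_l"] * dil
        if cfg.noise_cv > 0:
            count = rng.poisson(cfg.counted_cells)
            abund_obs = abund_diluted * count / cfg.counted_cells
        else:
            abund_obs = abund_diluted
        mcv = s["biovolume_um3_l"] / s["abundance_cells_l"]
        biovol_obs = abund_obs * mcv * _lognoise(rng, 0.5 * cfg.noise_cv)
        rows.append(
            {
                "date": s["date"],
                "site": s["site"],
                "chla_diluted_ug_l": chla_obs,
                "abundance_diluted_cells_l": abund_obs,
                "biovolume_diluted_um3_l": biovol_obs,
                "pennate_abundance_diluted_cells_l": abund_obs * cfg.pennate_fraction,
                "pennate_biovolume_diluted_um3_l": biovol_obs * min(
                    1.0, cfg.pennate_fraction + 0.15
                ),
                "fsw_volume_l": fsw,
                "melted_ice_volume_l": melt_volume,
                "core_section_length_m": cfg.core_section_length,
                "core_inner_diameter_m": cfg.core_inner_diameter,
                "n_cores_pooled": cfg.n_cores_pooled,
            }
        )
    return pd.DataFrame(rows)


def observe_bulk_melt(state: pd.DataFrame, cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Bulk (no-FSW) melt nutrient observations.

    Concentration = conservative brine background at the sample's bulk
    salinity + retention_x times the true bottom-ice IC pool, with
    multiplicative measurement noise on the total.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows = []
    for _, s in state.iterrows():
        sal = rng.uniform(*cfg.bulk_salinity_range)
        bg_n = cfg.water_column_N * sal / cfg.water_salinity
        bg_si = cfg.water_column_Si * sal / cfg.water_salinity
        ic_bottom_n = s["ic_chl_N"] * s["chla_mg_m3"] / 1000.0
        ic_bottom_si = s["ic_chl_Si"] * s["chla_mg_m3"] / 1000.0
        rows.append(
            {
                "date": s["date"],
                "site": s["site"],
                "bulk_salinity": sal,
                "no3no2_umol_l": (bg_n + cfg.retention_N * ic_bottom_n)
                * _lognoise(rng, cfg.noise_cv),
                "sioh4_umol_l": (bg_si + cfg.retention_Si * ic_bottom_si)
                * _lognoise(rng, cfg.noise_cv),
            }
        )
    return pd.DataFrame(rows)


def _observe_water_column(state: pd.DataFrame, cfg: SimConfig, rng) -> pd.DataFrame:
    dates = state.drop_duplicates("date")["date"]
    return pd.DataFrame(
        {
            "date": dates.to_numpy(),
            "salinity": cfg.water_salinity,
            "no3no2_umol_l": cfg.water_column_N
            * _lognoise(rng, 0.3 * cfg.noise_cv, dates.size),
            "sioh4_umol_l": cfg.water_column_Si
            * _lognoise(rng, 0.3 * cfg.noise_cv, dates.size),
        }
    )


def simulate_campaign(cfg: SimConfig):
    """Run the full generator; returns a CampaignTables bundle (with truth)."""
    from .io import CampaignTables

    rng = np.random.default_rng(cfg.seed)
    currents = simulate_currents(cfg, rng)
    state = simulate_bloom(cfg, currents, rng)
    scrape = observe_scrape(state, cfg, rng)
    core = observe_core_melt(state, cfg, rng)
    bulk = observe_bulk_melt(state, cfg, rng)
    water = _observe_water_column(state, cfg, rng)
    start = date.fromisoformat(cfg.start_date)
    cur = currents.assign(
        date=[(start + timedelta(days=int(d))).isoformat() for d in currents["day"]]
    )[["date", "max_speed"]].rename(columns={"max_speed": "max_speed_m_s"})
    return CampaignTables(
        scrape=scrape,
        core_melt=core,
        bulk_melt=bulk,
        water_column=water,
        currents=cur,
        truth=state,
    )


def write_campaign(cfg: SimConfig, outdir) -> Path:
    """Write the campaign CSV bundle + ground truth + config to ``outdir``.

    Deterministic for a fixed seed: the same config yields byte-identical
    files.
    """
    from .io import write_campaign_tables

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = simulate_campaign(cfg)
    write_campaign_tables(tables, outdir)
    cfg.to_yaml(outdir / "config.yaml")
    return outdir
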