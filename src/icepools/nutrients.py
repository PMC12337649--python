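"""Intracellular (IC) nutrient estimation chain.

Bottom-ice algae (dominantly pennate diatoms) hold intracellular pools of
nitrate+nitrite (N) and silicic acid (Si) far above ambient seawater
concentrations.  The pools are sampled by scraping the soft skeletal
bottom-ice layer into near-freezing filtered seawater, concentrating cells
on a filter, and extracting with hot water; the filtrate concentration,
blank-corrected and normalised to the chl a mass on the filter, gives the
chl-a-specific pool

    IC^B = (C_filtrate - C_blank) * V_extraction / m_chla   [umol / mg chl a].

Multiplying IC^B by the bottom-ice chl a concentration (from FSW-diluted
cores, corrected to melted-ice volume) yields a melt-volume-corrected
bottom-ice IC concentration (umol/L of melted ice), which dividing by
community biovolume or abundance converts to a concentration per unit cell
volume (mmol/L) or a per-cell content (fmol/cell).

Unit conventions: concentrations in umol/L, chl a mass in mg, biovolume in
um^3/L, abundance in cells/L; 1 um^3 = 1e-15 L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ICProfile",
    "ScrapeExtraction",
    "blank_correct",
    "bottom_ice_ic",
    "chl_specific_ic",
    "ic_per_cell",
    "ic_per_cell_volume",
    "ic_profile",
    "implied_mean_cell_volume",
    "n_si_ratio",
]


class BlankCorrected(NamedTuple):
    value: float
    clipped: bool


def blank_correct(filtrate, blank) -> BlankCorrected:
    """Subtract the daily hot-water blank, clipping negatives to zero.

    A blank exceeding the filtrate is physically a below-detection sample;
    the result is clipped at zero and flagged rather than propagated as a
    negative concentration.
    """
    f = np.asarray(filtrate, dtype=float)
    b = np.asarray(blank, dtype=float)
    if np.any(f < 0) or np.any(b < 0):
        raise ValueError("filtrate and blank concentrations must be >= 0")
    corrected = np.maximum(f - b, 0.0)
    clipped = b > f
    if np.isscalar(filtrate) and np.isscalar(blank):
        return BlankCorrected(float(corrected), bool(clipped))
    return BlankCorrected(corrected, clipped)


@dataclass(frozen=True)
class ScrapeExtraction:
    """One scrape-sample hot-water extraction for both nutrients."""

    filtrate_concentration_N: float  # umol/L in the 40-mL extract
    filtrate_concentration_Si: float
    blank_N: float
    blank_Si: float
    extraction_volume: float = 0.040  # L of boiling reverse-osmosis water
    scrape_chla_mass: float = 0.015  # mg chl a on the extracted filter

    def __post_init__(self):
        vals = (
            self.filtrate_concentration_N,
            self.filtrate_concentration_Si,
            self.blank_N,
            self.blank_Si,
        )
        if any(v < 0 for v in vals):
            raise ValueError("concentrations must be >= 0")
        if self.extraction_volume <= 0:
            raise ValueError("extraction_volume must be > 0")


def chl_specific_ic(
    filtrate_concentration,
    blank,
    extraction_volume,
    scrape_chla_mass,
):
    """Chl-a-specific IC pool IC^B, umol per mg chl a.

    Blank-corrected amount in the extraction volume divided by the chl a
    mass on the extracted filter.  Linear in the filtrate concentration and
    inversely proportional to the chl a mass.
    """
    if np.any(np.asarray(scrape_chla_mass, dtype=float) <= 0):
        raise ValueError("scrape_chla_mass must be > 0")
    corrected, _ = blank_correct(filtrate_concentration, blank)
    return corrected * extraction_volume / scrape_chla_mass


def bottom_ice_ic(ic_chl_specific, bottom_chla_mg_m3):
    """Melt-volume-corrected bottom-ice IC concentration, umol/L of melted ice.

    ``IC^B [umol/mg] * chla [mg/m^3] / 1000`` (mg/m^3 == ug/L, so /1000
    converts to mg/L).
    """
    ic = np.asarray(ic_chl_specific, dtype=float)
    chla = np.asarray(bottom_chla_mg_m3, dtype=float)
    if np.any(ic < 0) or np.any(chla < 0):
        raise ValueError("inputs must be >= 0")
    out = ic * chla / 1000.0
    return float(out) if out.ndim == 0 else out


def ic_per_cell_volume(bottom_ic_umol_l, biovolume_um3_l):
    """IC concentration per unit cell volume, mmol/L of cell volume.

    umol/L of melt divided by um^3/L of melt; with 1 um^3 = 1e-15 L and
    umol -> mmol this is ``bottom_ic / biovolume * 1e12``.
    """
    if np.any(np.asarray(biovolume_um3_l, dtype=float) <= 0):
        raise ValueError("biovolume must be > 0")
    out = np.asarray(bottom_ic_umol_l, dtype=float) / np.asarray(
        biovolume_um3_l, dtype=float
    ) * 1e12
    return float(out) if out.ndim == 0 else out


def ic_per_cell(bottom_ic_umol_l, abundance_cells_l):
    """IC content per cell, fmol/cell (umol -> fmol is a factor 1e9)."""
    if np.any(np.asarray(abundance_cells_l, dtype=float) <= 0):
        raise ValueError("abundance must be > 0")
    out = np.asarray(bottom_ic_umol_l, dtype=float) / np.asarray(
        abundance_cells_l, dtype=float
    ) * 1e9
    return float(out) if out.ndim == 0 else out


def n_si_ratio(n, si):
    """Molar N:Si ratio; undefined (nan) where Si is zero."""
    n = np.asarray(n, dtype=float)
    si = np.asarray(si, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(si > 0, n / si, np.nan)
    return float(out) if out.ndim == 0 else out


def implied_mean_cell_volume(content_fmol_cell, concentration_mmol_l):
    """Mean cell volume (um^3) implied by a per-cell content and a per-cell-volume
    concentration.

    The two Table-style quantities share the same numerator, so their ratio
    is the community mean cell volume: ``content / concentration * 1000``
    (fmol = 1e-15 mol, mmol/L = 1e-3 mol/L, 1 L = 1e15 um^3).
    """
    if np.any(np.asarray(concentration_mmol_l, dtype=float) <= 0):
        raise ValueError("concentration must be > 0")
    out = np.asarray(content_fmol_cell, dtype=float) / np.asarray(
        concentration_mmol_l, dtype=float
    ) * 1000.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ICProfile:
    """Full per-sample IC nutrient profile for N and Si."""

    ic_chl_specific_N: float  # umol / mg chl a
    ic_chl_specific_Si: float
    bottom_ice_ic_N: float  # umol/L of melted ice
    bottom_ice_ic_Si: float
    ic_conc_per_cell_volume_N: float  # mmol/L of cell volume
    ic_conc_per_cell_volume_Si: float
    ic_content_per_cell_N: float  # fmol/cell
    ic_content_per_cell_Si: float
    n_si: float  # mol/mol
    blank_clipped: bool = False


def ic_profile(
    scrape: ScrapeExtraction,
    bottom_chla_mg_m3: float,
    abundance_cells_l: float,
    biovolume_um3_l: float,
) -> ICProfile:
    """Run the whole estimation chain for one sample.

    The chain is linear in the filtrate concentrations and in the bottom-ice
    chl a, and satisfies the exact identity
    ``ic_per_cell / ic_per_cell_volume == biovolume / abundance``.
    """
    corr_n = blank_correct(scrape.filtrate_concentration_N, scrape.blank_N)
    corr_si = blank_correct(scrape.filtrate_concentration_Si, scrape.blank_Si)
    ic_b_n = corr_n.value * scrape.extraction_volume / scrape.scrape_chla_mass
    ic_b_si = corr_si.value * scrape.extraction_volume / scrape.scrape_chla_mass
    bi_n = bottom_ice_ic(ic_b_n, bottom_chla_mg_m3)
    bi_si = bottom_ice_ic(ic_b_si, bottom_chla_mg_m3)
    return ICProfile(
        ic_chl_specific_N=ic_b_n,
        ic_chl_specific_Si=ic_b_si,
        bottom_ice_ic_N=bi_n,
        bottom_ice_ic_Si=bi_si,
        ic_conc_per_cell_volume_N=ic_per_cell_volume(bi_n, biovolume_um3_l),
        ic_conc_per_cell_volume_Si=ic_per_cell_volume(bi_si, biovolume_um3_l),
        ic_content_per_cell_N=ic_per_cell(bi_n, abundance_cells_l),
        ic_content_per_cell_Si=ic_per_cell(bi_si, abundance_cells_l),
        n_si=n_si_ratio(ic_b_n, ic_b_si),
        blank_clipped=bool(corr_n.clipped or corr_si.clipped),
    )
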