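"""Algal biomass measurements: fluorometric chl a and community metrics.

Chlorophyll a is measured by acidification fluorometry: the acetone extract
is read before (Fb) and after (Fa) acidification with dilute HCl, and the
acid-labile part of the signal is attributed to chl a using the instrument's
maximum acid ratio Fm,

    chl a = Fm/(Fm - 1) * (Fb - Fa) * K * V_extract / V_filtered,

where K is the calibration factor (ug/L per fluorescence unit).

Bottom-ice cores are melted into 0.2-um filtered seawater (FSW) to buffer
the melt against osmotic shock; every concentration measured on the diluted
solution must be scaled back to the melted-ice volume.  Areal chl a follows
from the volumetric concentration and the sampled core-section length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "CommunityFractions",
    "CommunitySample",
    "FluorometryReading",
    "MeltGeometry",
    "areal_chla",
    "chla_concentration",
    "community_fractions",
    "fsw_dilution_correct",
]


@dataclass(frozen=True)
class FluorometryReading:
    """One acidification-fluorometry measurement of an acetone extract."""

    f_before: float
    f_after: float
    acid_ratio_max: float = 2.2
    calibration: float = 1.0  # ug/L per fluorescence unit
    extract_volume: float = 0.010  # L of acetone extract
    filtered_volume: float = 0.100  # L of sample filtered

    def __post_init__(self):
        if self.f_after < 0 or self.f_before < 0:
            raise ValueError("fluorescence readings must be >= 0")
        if self.f_after > self.f_before:
            raise ValueError(
                "phaeopigment inversion: fluorescence increased on acidification"
            )
        if self.acid_ratio_max <= 1:
            raise ValueError("acid_ratio_max must exceed 1")
        if self.extract_volume <= 0 or self.filtered_volume <= 0:
            raise ValueError("volumes must be > 0")


def chla_concentration(reading: FluorometryReading) -> float:
    """Chl a concentration (ug/L) in the filtered solution.

    Linear in (f_before - f_after) and in the calibration factor.
    """
    r = reading
    return (
        r.acid_ratio_max
        / (r.acid_ratio_max - 1.0)
        * (r.f_before - r.f_after)
        * r.calibration
        * r.extract_volume
        / r.filtered_volume
    )


@dataclass(frozen=True)
class MeltGeometry:
    """Geometry of a pooled bottom-ice core melt in FSW."""

    core_section_length: float = 0.03  # m, bottommost section
    core_inner_diameter: float = 0.09  # m
    fsw_volume: float = 2.0  # L of filtered seawater added
    melted_ice_volume: float = 0.573  # L of melted ice
    n_cores_pooled: int = 3

    def __post_init__(self):
        if min(
            self.core_section_length,
            self.core_inner_diameter,
            self.melted_ice_volume,
        ) <= 0 or self.fsw_volume < 0:
            raise ValueError("geometry dimensions must be positive")
        if self.n_cores_pooled not in (1, 2, 3):
            raise ValueError("n_cores_pooled must be 1, 2 or 3")

    @property
    def core_area(self) -> float:
        """Cross-sectional area of one core, m^2."""
        return math.pi * (self.core_inner_diameter / 2.0) ** 2

    @property
    def nominal_melt_volume(self) -> float:
        """Melt volume (L) implied by section length x area x cores."""
        return self.core_section_length * self.core_area * self.n_cores_pooled * 1000.0


def fsw_dilution_correct(measured: float, geometry: MeltGeometry) -> float:
    """Scale a concentration in the FSW-diluted solution to per-L of melted ice.

    ``measured * (V_fsw + V_melt) / V_melt``; the exact inverse of diluting
    the melt with the recorded FSW volume.
    """
    if geometry.melted_ice_volume <= 0:
        raise ValueError("melted_ice_volume must be > 0")
    return (
        measured
        * (geometry.fsw_volume + geometry.melted_ice_volume)
        / geometry.melted_ice_volume
    )


def areal_chla(volumetric: float, geometry: MeltGeometry) -> float:
    """Areal chl a (mg/m^2) from a volumetric concentration (mg/m^3 of melt).

    The melted-ice column under unit area has height equal to the core
    section length, so areal = volumetric * length.  When the melt volume
    equals length x area x n_cores exactly, this agrees with dividing the
    chl a amount in the pooled melt by the pooled core cross-section.
    """
    return volumetric * geometry.core_section_length


@dataclass(frozen=True)
class CommunitySample:
    """Microscopy summary of the melt: abundance and biovolume, total and pennate."""

    total_abundance: float  # cells/L of melted ice
    total_biovolume: float  # um^3/L of melted ice
    pennate_abundance: float = 0.0
    pennate_biovolume: float = 0.0

    def __post_init__(self):
        vals = (
            self.total_abundance,
            self.total_biovolume,
            self.pennate_abundance,
            self.pennate_biovolume,
        )
        if any(v < 0 for v in vals):
            raise ValueError("abundance and biovolume must be >= 0")
        if self.pennate_abundance > self.total_abundance:
            raise ValueError("pennate abundance exceeds total")
        if self.pennate_biovolume > self.total_biovolume:
            raise ValueError("pennate biovolume exceeds total")


class CommunityFractions(NamedTuple):
    pennate_abundance_pct: float
    pennate_biovolume_pct: float
    mean_cell_volume: float  # um^3/cell


def community_fractions(sample: CommunitySample) -> CommunityFractions:
    """Pennate-diatom percentages and community mean cell volume."""
    if sample.total_abundance <= 0:
        if sample.total_biovolume > 0:
            raise ValueError("nonzero biovolume with zero abundance")
        raise ValueError("total_abundance must be > 0")
    pa = 100.0 * sample.pennate_abundance / sample.total_abundance
    pv = (
        100.0 * sample.pennate_biovolume / sample.total_biovolume
        if sample.total_biovolume > 0
        else 0.0
    )
    mcv = sample.total_biovolume / sample.total_abundance
    return CommunityFractions(pa, pv, mcv)
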