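"""Sea-ice brine and melt physics.

Brine trapped in sea-ice channels is in thermal equilibrium with the
surrounding ice, so its salinity is set by ice temperature alone: colder ice
means more concentrated brine.  The closed form used here,

    S_b(T) = 1000 / (1 - 54.11 / T),    T in degrees Celsius, T < 0,

reproduces the classic freezing-equilibrium brine salinities for first-year
sea ice over its customary validity range (-22.9 degC <= T < 0 degC); at the
bottom-ice extremes of -1.8 and -3.0 degC it gives practical salinities of
32.2 and 52.5.

The module also provides conservative-mixing "dilution lines": when an ice
core is melted without filtered-seawater buffering, dissolved nutrients are
diluted in proportion to salinity, so conservative samples fall on the
straight line from a reference (salinity, concentration) point through the
origin.  Samples above the line carry non-conservative additions, e.g.
intracellular pools released by osmotic shock of algal cells during melt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BRINE_TEMPERATURE_MIN",
    "DilutionLine",
    "brine_salinity",
    "classify_vs_dilution_line",
    "dilution_concentration",
]

#: Lower validity bound of the brine salinity-temperature relation (degC).
BRINE_TEMPERATURE_MIN = -22.9

_BRINE_COEFF = 54.11  # degC; empirical coefficient of the closed form


def brine_salinity(temperature):
    """Brine practical salinity from ice temperature (degC).

    Parameters
    ----------
    temperature : float or array_like
        Ice temperature in degrees Celsius.  Must satisfy
        ``BRINE_TEMPERATURE_MIN <= temperature < 0``.

    Returns
    -------
    float or ndarray
        Practical salinity (dimensionless), strictly decreasing in
        temperature on the valid range.

    Raises
    ------
    ValueError
        If any temperature is >= 0 (no brine) or below the validity bound.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t >= 0):
        raise ValueError(
            "brine_salinity requires temperatures below freezing (T < 0 degC)"
        )
    if np.any(t < BRINE_TEMPERATURE_MIN):
        raise ValueError(
            f"brine_salinity is only valid for T >= {BRINE_TEMPERATURE_MIN} degC"
        )
    s = 1000.0 / (1.0 - _BRINE_COEFF / t)
    return float(s) if np.isscalar(temperature) else s


@dataclass(frozen=True)
class DilutionLine:
    """Conservative-mixing line through the origin.

    Anchored at a reference water mass, typically the campaign-average 2-m
    water-column concentration and salinity.

    Attributes
    ----------
    reference_concentration : float
        Nutrient concentration at the reference salinity, umol/L.
    reference_salinity : float
        Practical salinity of the reference water (> 0).
    """

    reference_concentration: float
    reference_salinity: float

    def __post_init__(self):
        if self.reference_concentration < 0:
            raise ValueError("reference_concentration must be >= 0")
        if self.reference_salinity <= 0:
            raise ValueError("reference_salinity must be > 0")

    def concentration_at(self, salinity):
        """Expected conservative concentration (umol/L) at ``salinity``."""
        return dilution_concentration(self, salinity)


def dilution_concentration(line: DilutionLine, salinity):
    """Concentration predicted by conservative dilution at a given salinity.

    Linear and homogeneous: C(a*s) = a*C(s) for a >= 0, and C(0) = 0.
    """
    s = np.asarray(salinity, dtype=float)
    if np.any(s < 0):
        raise ValueError("salinity must be >= 0")
    c = line.reference_concentration * s / line.reference_salinity
    return float(c) if np.isscalar(salinity) else c


def classify_vs_dilution_line(
    salinities,
    concentrations,
    line: DilutionLine,
    rel_tolerance: float = 0.15,
    abs_floor: float = 0.2,
):
    """Label samples relative to a dilution line: ``above``, ``on`` or ``below``.

    A sample is "on" the line when its concentration is within
    ``rel_tolerance`` (fractional) of the line's prediction at its salinity,
    with an absolute floor of ``abs_floor`` umol/L so that near-origin samples
    are not classified by vanishing relative bands.

    Parameters
    ----------
    salinities, concentrations : array_like
        Paired sample salinity and nutrient concentration (umol/L).
    line : DilutionLine
    rel_tolerance : float
        Fractional half-width of the "on" band, in (0, 1).
    abs_floor : float
        Absolute minimum half-width of the band, umol/L.

    Returns
    -------
    ndarray of str
        One label per sample; empty input yields an empty array.
    """
    if not 0 < rel_tolerance < 1:
        raise ValueError("rel_tolerance must lie in (0, 1)")
    s = np.atleast_1d(np.asarray(salinities, dtype=float))
    c = np.atleast_1d(np.asarray(concentrations, dtype=float))
    if s.shape != c.shape:
        raise ValueError("salinities and concentrations must have equal length")
    if s.size == 0:
        return np.array([], dtype=object)
    c_line = dilution_concentration(line, s)
    band = np.maximum(rel_tolerance * c_line, abs_floor)
    labels = np.where(
        np.abs(c - c_line) <= band, "on", np.where(c > c_line, "above", "below")
    )
    return labels.astype(object)
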