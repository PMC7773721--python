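"""Hexagon color space for trichromatic bee vision.

A reflectance spectrum is mapped to a locus in the 2-D color hexagon:
each receptor's quantum catch is the integral of reflectance times
illuminant times sensitivity; von Kries adaptation divides by the catch
of the (leaf-green) background, and the hyperbolic transform
E = q / (q + 1) gives receptor excitations in [0, 1).  The three
excitations place the stimulus in a plane where the angle from the
center encodes hue and the radius encodes chromatic contrast against
the background.

Hexagon orientation used throughout: receptor vertices at
B = 90 deg, G = 330 deg, UV = 210 deg and blended vertices at
BG = 30, UB = 150, UG = 270 deg.  Sectors are the vertex-centered
60-degree wedges, half-open [vertex - 30, vertex + 30).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import Illuminant, ReflectanceSpectrum, SensitivityCurve

__all__ = [
    "ExcitationTriple",
    "ColorLocus",
    "excitations",
    "hexagon_locus",
    "spectrum_to_locus",
    "color_distance",
    "sector_frequency",
    "preference_fraction",
    "loci_table",
    "SECTOR_VERTICES",
]

#: Vertex angles (degrees) of the six hexagon sectors.
SECTOR_VERTICES = {"BG": 30.0, "B": 90.0, "UB": 150.0, "UV": 210.0, "UG": 270.0, "G": 330.0}

_SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class ExcitationTriple:
    """Receptor excitations (UV, blue, green), each in [0, 1)."""

    e_uv: float
    e_b: float
    e_g: float


@dataclass(frozen=True)
class ColorLocus:
    """A species' position in hexagon color space.

    theta is the hue angle in degrees, counterclockwise from the
    positive x-axis, in [0, 360); r is the chromatic contrast (distance
    from the achromatic center).  An achromatic locus (r = 0) reports
    theta = 0 by convention and carries sector ``None``.
    """

    species_id: str
    x: float
    y: float
    theta: float
    r: float
    sector: str | None


def _quantum_catch(
    reflectance: np.ndarray, sens: SensitivityCurve, ill: Illuminant, grid: np.ndarray
) -> float:
    return float(np.trapezoid(reflectance * sens.sensitivity * ill.photon_flux, grid))


def excitations(
    flower: ReflectanceSpectrum,
    background: ReflectanceSpectrum,
    sensitivities: tuple[SensitivityCurve, SensitivityCurve, SensitivityCurve],
    illuminant: Illuminant,
) -> ExcitationTriple:
    """Receptor excitations of a flower against an adapting background.

    For each receptor i the quantum catch is
    ``P_i = integral R(lambda) S_i(lambda) I(lambda) dlambda``
    (trapezoidal rule on the common grid); the relative catch
    ``q_i = P_i / P_i(background)`` implements von Kries adaptation, and
    the excitation is ``E_i = q_i / (q_i + 1)``.  The background itself
    therefore maps to E = 0.5 in every receptor.
    """
    grid = flower.wavelengths
    if not np.array_equal(grid, background.wavelengths):
        raise ValueError("flower and background must share the wavelength grid")
    es = []
    for sens in sensitivities:
        if not np.array_equal(sens.grid, grid) or not np.array_equal(illuminant.grid, grid):
            raise ValueError("sensitivities and illuminant must share the spectrum grid")
        p_bg = _quantum_catch(background.reflectance, sens, illuminant, grid)
        if p_bg <= 0.0:
            raise ValueError(
                f"background catch is zero for receptor at {sens.lambda_max:g} nm; "
                "adaptation is degenerate"
            )
        q = _quantum_catch(flower.reflectance, sens, illuminant, grid) / p_bg
        es.append(q / (q + 1.0))
    return ExcitationTriple(*es)


def hexagon_locus(e: ExcitationTriple, species_id: str = "") -> ColorLocus:
    """Place an excitation triple in the hexagon plane.

    x = (sqrt(3)/2) (E_g - E_uv);  y = E_b - (E_uv + E_g) / 2.
    """
    x = _SQRT3_2 * (e.e_g - e.e_uv)
    y = e.e_b - (e.e_uv + e.e_g) / 2.0
    r = math.hypot(x, y)
    if r == 0.0:
        return ColorLocus(species_id, x, y, 0.0, 0.0, None)
    theta = math.degrees(math.atan2(y, x)) % 360.0
    return ColorLocus(species_id, x, y, theta, r, sector_of(theta))


def sector_of(theta: float) -> str:
    """Sector label for a hue angle; 60-degree vertex-centered wedges."""
    for name, vertex in SECTOR_VERTICES.items():
        lo = (vertex - 30.0) % 360.0
        if lo <= theta % 360.0 < lo + 60.0:
            return name
    # G wedge wraps through 360
    return "G"


def spectrum_to_locus(
    flower: ReflectanceSpectrum,
    background: ReflectanceSpectrum,
    sensitivities: tuple[SensitivityCurve, SensitivityCurve, SensitivityCurve],
    illuminant: Illuminant,
) -> ColorLocus:
    """Full pipeline for one spectrum: excitations then hexagon locus."""
    return hexagon_locus(
        excitations(flower, background, sensitivities, illuminant), flower.species_id
    )


def color_distance(a: ColorLocus, b: ColorLocus) -> float:
    """Euclidean distance between two loci in hexagon units."""
    return math.hypot(a.x - b.x, a.y - b.y)


def sector_frequency(
    loci: list[ColorLocus], bin_width: float = 10.0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of hue angles in fixed angular bins.

    Returns ``(bin_edges_low, counts, n_achromatic)``.  Bins are
    [0, bw), [bw, 2 bw), ...; achromatic loci (r = 0) are excluded from
    the counts and reported separately.
    """
    if not (bin_width > 0 and math.isclose(360.0 / bin_width, round(360.0 / bin_width))):
        raise ValueError(f"bin_width {bin_width} does not divide 360")
    n_bins = int(round(360.0 / bin_width))
    edges = np.arange(n_bins) * bin_width
    counts = np.zeros(n_bins, dtype=int)
    n_achro = 0
    for locus in loci:
        if locus.r == 0.0:
            n_achro += 1
            continue
        counts[int(locus.theta // bin_width) % n_bins] += 1
    return edges, counts, n_achro


def preference_fraction(
    loci: list[ColorLocus], window: tuple[float, float] = (30.0, 90.0)
) -> float:
    """Fraction of chromatic loci with hue in the half-open window [lo, hi).

    The default window (30–90 degrees) covers the bee-blue and
    bee-blue-green region where bee innate color preferences peak.
    """
    lo, hi = window
    chromatic = [locus for locus in loci if locus.r > 0.0]
    if not chromatic:
        return 0.0
    hit = sum(1 for locus in chromatic if lo <= locus.theta < hi)
    return hit / len(chromatic)


def loci_table(loci: list[ColorLocus]) -> pd.DataFrame:
    """Loci as a tidy table (species_id, x, y, theta_deg, r, sector)."""
    return pd.DataFrame(
        {
            "species_id": [l.species_id for l in loci],
            "x": [l.x for l in loci],
            "y": [l.y for l in loci],
            "theta_deg": [l.theta for l in loci],
            "r": [l.r for l in loci],
            "sector": [l.sector if l.sector is not None else "achromatic" for l in loci],
        }
    )
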