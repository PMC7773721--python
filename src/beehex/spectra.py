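"""Reflectance spectra: I/O, resampling, receptor sensitivities, illuminant.

All downstream color computation happens on a common wavelength grid
(1-nm steps over 300–700 nm by default, the finest resolution common
spectrometer exports share).  This module reads spectrometer-style
tables, puts every spectrum on that grid, builds the trichromatic bee
receptor sensitivities from a visual-pigment template, and tabulates a
photon-flux-corrected standard daylight illuminant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GRID",
    "ReflectanceSpectrum",
    "SensitivityCurve",
    "Illuminant",
    "read_spectra",
    "resample",
    "mean_background",
    "receptor_template",
    "d65_photon_flux",
    "detect_marker_points",
]

#: Default integration grid: 1-nm steps, 300–700 nm inclusive (401 points).
DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)

#: Maximum tolerated gap (nm) when a spectrum does not quite cover the
#: requested grid (edge extrapolation) or has holes from dropped readings.
EDGE_MARGIN_NM = 5.0


class SpectrumError(ValueError):
    """Raised for malformed or insufficient spectral input."""


@dataclass
class ReflectanceSpectrum:
    """A single species' (or background) reflectance spectrum.

    Parameters
    ----------
    species_id : str
        Label; taken from the column header or file stem on read.
    wavelengths : ndarray
        Wavelengths in nm, strictly increasing.
    reflectance : ndarray
        Unitless reflectance fraction per wavelength.  Values above 1
        (specular glare) are retained with a warning; negative readings
        are clipped to 0 during resampling.
    """

    species_id: str
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.reflectance.ndim != 1:
            raise SpectrumError("wavelengths and reflectance must be 1-D")
        if self.wavelengths.size != self.reflectance.size:
            raise SpectrumError(
                f"{self.species_id}: wavelength/reflectance length mismatch "
                f"({self.wavelengths.size} vs {self.reflectance.size})"
            )
        if self.wavelengths.size < 2:
            raise SpectrumError(f"{self.species_id}: need at least 2 samples")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectrumError(
                f"{self.species_id}: wavelengths must be strictly increasing"
            )
        if np.nanmax(self.reflectance) > 1.0:
            warnings.warn(
                f"{self.species_id}: reflectance exceeds 1.0 "
                f"(max {np.nanmax(self.reflectance):.3f}); retained as glare",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass
class SensitivityCurve:
    """Peak-normalized spectral sensitivity of one photoreceptor class."""

    lambda_max: float
    grid: np.ndarray
    sensitivity: np.ndarray = field(repr=False)


@dataclass
class Illuminant:
    """Relative photon flux per nm on a wavelength grid."""

    grid: np.ndarray
    photon_flux: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# reading


def _sniff_table(path: Path) -> pd.DataFrame:
    """Read a delimited text table with delimiter auto-detection."""
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except pd.errors.EmptyDataError:
        raise SpectrumError(f"{path}: empty file") from None
    except Exception as exc:  # noqa: BLE001 - surface parse context
        raise SpectrumError(f"{path}: unparseable table ({exc})") from exc
    if df.empty:
        raise SpectrumError(f"{path}: no data rows")
    return df


def _to_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        raise SpectrumError(
            f"{path}: non-numeric reflectance value near data line {row + 2}"
        )
    return out


def _collapse_duplicates(wl: np.ndarray, refl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by wavelength and average readings at duplicated wavelengths."""
    order = np.argsort(wl, kind="stable")
    wl, refl = wl[order], refl[order]
    uniq, inverse = np.unique(wl, return_inverse=True)
    if uniq.size == wl.size:
        return wl, refl
    sums = np.bincount(inverse, weights=refl)
    counts = np.bincount(inverse)
    return uniq, sums / counts


def _average_shared_ids(spectra: list[ReflectanceSpectrum]) -> list[ReflectanceSpectrum]:
    """Average replicate spectra sharing a species_id (one locus per species).

    Replicates are first resampled to the default grid so spectrometer
    exports with slightly different wavelength vectors can be combined.
    """
    by_id: dict[str, list[ReflectanceSpectrum]] = {}
    for s in spectra:
        by_id.setdefault(s.species_id, []).append(s)
    out = []
    for sid, group in by_id.items():
        if len(group) == 1:
            out.append(group[0])
        else:
            rs = [resample(s, DEFAULT_GRID) for s in group]
            mean = np.mean([s.reflectance for s in rs], axis=0)
            out.append(ReflectanceSpectrum(sid, DEFAULT_GRID.copy(), mean))
    return out


def read_spectra(path: str | Path, dialect: str = "wide") -> list[ReflectanceSpectrum]:
    """Read reflectance spectra from disk.

    Parameters
    ----------
    path : path
        File (``wide``/``long``) or directory (``per_species_dir``).
    dialect : {"wide", "long", "per_species_dir"}
        * ``wide`` — first column wavelength (nm), one column per species.
        * ``long`` — columns species_id, wavelength, reflectance.
        * ``per_species_dir`` — one two-column file per species; the
          species_id is the file stem.

    Returns
    -------
    list of ReflectanceSpectrum
        Wavelengths sorted ascending, duplicate wavelengths averaged,
        replicate spectra sharing a species_id averaged on the default
        grid.
    """
    path = Path(path)
    spectra: list[ReflectanceSpectrum] = []
    if dialect == "wide":
        df = _sniff_table(path)
        if df.shape[1] < 2:
            raise SpectrumError(f"{path}: wide table needs >= 2 columns")
        ids = [str(c) for c in df.columns[1:]]
        num = _to_numeric(df, path)
        wl = num.iloc[:, 0].to_numpy(float)
        for j, sid in enumerate(ids, start=1):
            w, r = _collapse_duplicates(wl, num.iloc[:, j].to_numpy(float))
            spectra.append(ReflectanceSpectrum(sid, w, r))
    elif dialect == "long":
        df = _sniff_table(path)
        cols = {str(c).lower(): c for c in df.columns}
        try:
            sid_c = cols["species_id"]
            wl_c = cols["wavelength"]
            re_c = cols["reflectance"]
        except KeyError as exc:
            raise SpectrumError(
                f"{path}: long table needs species_id/wavelength/reflectance columns"
            ) from exc
        num = _to_numeric(df[[wl_c, re_c]], path)
        for sid, idx in df.groupby(sid_c, sort=True).groups.items():
            w, r = _collapse_duplicates(
                num.loc[idx, wl_c].to_numpy(float), num.loc[idx, re_c].to_numpy(float)
            )
            spectra.append(ReflectanceSpectrum(str(sid), w, r))
    elif dialect == "per_species_dir":
        if not path.is_dir():
            raise SpectrumError(f"{path}: not a directory")
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".csv", ".tsv", ".txt"}
        )
        if not files:
            raise SpectrumError(f"{path}: no spectrum files found")
        for f in files:
            df = _sniff_table(f)
            # headerless exports parse their first reading as the header
            first = list(df.columns[:2])
            try:
                head = [float(v) for v in first]
            except (TypeError, ValueError):
                head = None
            if df.shape[1] < 2:
                raise SpectrumError(f"{f}: expected two columns")
            num = _to_numeric(df.iloc[:, :2], f)
            wl = num.iloc[:, 0].to_numpy(float)
            r = num.iloc[:, 1].to_numpy(float)
            if head is not None:
                wl = np.concatenate([[head[0]], wl])
                r = np.concatenate([[head[1]], r])
            w, r = _collapse_duplicates(wl, r)
            spectra.append(ReflectanceSpectrum(f.stem, w, r))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _average_shared_ids(spectra)


# ---------------------------------------------------------------------------
# resampling and background


def resample(spectrum: ReflectanceSpectrum, grid: np.ndarray) -> ReflectanceSpectrum:
    """Linearly interpolate a spectrum onto ``grid``, clipping below at 0.

    Non-finite readings are dropped before interpolation.  The spectrum
    must cover the grid to within ``EDGE_MARGIN_NM`` at each edge, and
    dropped readings must not leave an internal hole wider than that
    margin; otherwise the offending gap is reported.
    """
    grid = np.asarray(grid, dtype=float)
    ok = np.isfinite(spectrum.reflectance) & np.isfinite(spectrum.wavelengths)
    wl = spectrum.wavelengths[ok]
    refl = spectrum.reflectance[ok]
    if wl.size < 2:
        raise SpectrumError(f"{spectrum.species_id}: fewer than 2 finite samples")
    lo_gap = wl[0] - grid[0]
    hi_gap = grid[-1] - wl[-1]
    if lo_gap > EDGE_MARGIN_NM or hi_gap > EDGE_MARGIN_NM:
        raise SpectrumError(
            f"{spectrum.species_id}: spectrum covers [{wl[0]:g}, {wl[-1]:g}] nm; "
            f"gap of {max(lo_gap, hi_gap):g} nm to grid "
            f"[{grid[0]:g}, {grid[-1]:g}] exceeds {EDGE_MARGIN_NM:g} nm"
        )
    if not ok.all():
        # only holes created by dropped readings count as internal gaps
        gaps = np.diff(wl)
        step = np.median(np.diff(spectrum.wavelengths))
        worst = np.argmax(gaps)
        if gaps[worst] > max(EDGE_MARGIN_NM, 2.0 * step):
            raise SpectrumError(
                f"{spectrum.species_id}: internal gap of {gaps[worst]:g} nm "
                f"near {wl[worst]:g} nm after dropping bad readings"
            )
    values = np.interp(grid, wl, refl)
    return ReflectanceSpectrum(spectrum.species_id, grid.copy(), np.maximum(values, 0.0))


def mean_background(spectra: list[ReflectanceSpectrum]) -> ReflectanceSpectrum:
    """Pointwise mean of resampled spectra; the adaptation background.

    The bee visual system is modeled as adapted to the average foliage
    ("leaf-green") reflectance, so the background spectrum is simply the
    arithmetic mean of all leaf spectra on the common grid.
    """
    if not spectra:
        raise SpectrumError("mean_background requires at least one spectrum")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != grid.shape or not np.array_equal(s.wavelengths, grid):
            raise SpectrumError(
                f"mismatched grids: {s.species_id} differs from {spectra[0].species_id}"
            )
    mean = np.mean([s.reflectance for s in spectra], axis=0)
    return ReflectanceSpectrum("background", grid.copy(), mean)


# ---------------------------------------------------------------------------
# receptor sensitivities (A1 visual-pigment template)

# alpha-band template constants (Govardovskii et al. 2000, A1 pigments)
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


def receptor_template(lambda_max: float, grid: np.ndarray | None = None) -> SensitivityCurve:
    """A1 visual-pigment nomogram sensitivity, peak-normalized to 1.

    The alpha band follows the standard A1 rhodopsin template with the
    lambda-max-dependent steepness parameter; the beta (cis) band is the
    template's Gaussian correction, which keeps sensitivity strictly
    positive in the near-UV for long-wavelength receptors.

    Parameters
    ----------
    lambda_max : float
        Peak wavelength (nm) of the receptor, within [300, 700].
        The trichromatic bee set used throughout is 350/440/540 nm.
    grid : ndarray, optional
        Evaluation grid; defaults to the 1-nm 300–700 nm grid.
    """
    if not 300.0 <= lambda_max <= 700.0:
        raise ValueError(f"lambda_max {lambda_max} nm outside [300, 700]")
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )
    # beta band
    lam_mb = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((grid - lam_mb) / b_beta) ** 2))
    sens = alpha + beta
    sens = sens / sens.max()
    return SensitivityCurve(lambda_max=float(lambda_max), grid=grid.copy(), sensitivity=sens)


def bee_sensitivities(
    peaks: tuple[float, float, float] = (350.0, 440.0, 540.0),
    grid: np.ndarray | None = None,
) -> tuple[SensitivityCurve, SensitivityCurve, SensitivityCurve]:
    """The UV/blue/green receptor triplet for a trichromatic bee."""
    uv, b, g = (receptor_template(p, grid) for p in peaks)
    return uv, b, g


# ---------------------------------------------------------------------------
# illuminant

# CIE standard illuminant D65, relative spectral power distribution,
# 300-700 nm at 5-nm tabulation (normalized to 100 at 560 nm).
_D65_WL = np.arange(300.0, 701.0, 5.0)
_D65_SPD = np.array([
    0.0341, 1.6643, 3.2945, 11.7652, 20.2360, 28.6447, 37.0535, 38.5011,
    39.9488, 42.4302, 44.9117, 45.7750, 46.6383, 49.3637, 52.0891, 51.0323,
    49.9755, 52.3118, 54.6482, 68.7015, 82.7549, 87.1204, 91.4860, 92.4589,
    93.4318, 90.0570, 86.6823, 95.7736, 104.8650, 110.9360, 117.0080,
    117.4100, 117.8120, 116.3360, 114.8610, 115.3920, 115.9230, 112.3670,
    108.8110, 109.0820, 109.3540, 108.5780, 107.8020, 106.2960, 104.7900,
    106.2390, 107.6890, 106.0470, 104.4050, 104.2250, 104.0460, 102.0230,
    100.0000, 98.1671, 96.3342, 96.0611, 95.7880, 92.2368, 88.6856, 89.3459,
    90.0062, 89.8026, 89.5991, 88.6489, 87.6987, 85.4936, 83.2886, 83.4939,
    83.6992, 81.8630, 80.0268, 80.1207, 80.2146, 81.2462, 82.2778, 80.2810,
    78.2842, 74.0027, 69.7213, 70.6652, 71.6091,
])


def d65_photon_flux(grid: np.ndarray | None = None) -> Illuminant:
    """Standard D65 daylight converted to relative photon flux.

    The tabulated D65 spectral power (energy units) is interpolated to
    the grid and multiplied by wavelength — photon energy scales as
    1/lambda, so photon flux scales as lambda times power — then
    normalized to a maximum of 1.  Any overall scale cancels in the von
    Kries adaptation step downstream.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if grid[0] < _D65_WL[0] or grid[-1] > _D65_WL[-1]:
        raise ValueError(f"grid must lie within [{_D65_WL[0]:g}, {_D65_WL[-1]:g}] nm")
    power = np.interp(grid, _D65_WL, _D65_SPD)
    photons = power * grid
    photons = photons / photons.max()
    return Illuminant(grid=grid.copy(), photon_flux=photons)


# ---------------------------------------------------------------------------
# marker points


def detect_marker_points(
    spectrum: ReflectanceSpectrum,
    smooth_window: float = 11.0,
    rel_threshold: float = 0.2,
) -> list[float]:
    """Wavelengths of the steepest spectral transitions (marker points).

    The spectrum is smoothed with a centered moving average of width
    ``smooth_window`` nm, then local maxima of the absolute first
    derivative are located; maxima whose slope falls below
    ``rel_threshold`` times the global maximum slope are suppressed.
    A constant spectrum yields an empty list.

    The spectrum must already be on a uniform grid.
    """
    from scipy.signal import find_peaks

    wl = spectrum.wavelengths
    step = np.diff(wl)
    if not np.allclose(step, step[0]):
        raise SpectrumError("detect_marker_points requires a uniform grid")
    step = step[0]
    n_win = max(1, int(round(smooth_window / step)))
    if n_win % 2 == 0:
        n_win += 1

    def _moving_average(values: np.ndarray) -> np.ndarray:
        kernel = np.ones(n_win) / n_win
        padded = np.pad(values, n_win // 2, mode="edge")
        return np.convolve(padded, kernel, mode="valid")

    smooth = _moving_average(spectrum.reflectance)
    # smoothing the slope as well suppresses sub-window noise wiggles
    slope = _moving_average(np.abs(np.gradient(smooth, wl)))
    peak = slope.max()
    if peak <= 0.0:
        return []
    floor = rel_threshold * peak
    idx, _ = find_peaks(slope, height=floor, prominence=floor)
    return [float(wl[i]) for i in idx]
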