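"""Spectral data containers and standard curves for fly-vision modeling.

This module owns the plumbing the colorimetric model consumes: a uniform
wavelength grid, validated spectra (reflectance, illuminant, or receptor
sensitivity), CSV input/output in a simple one-wavelength-column dialect,
linear resampling, the CIE D65 daylight illuminant (in photon or energy
units), and an A1 visual-pigment nomogram for receptor sensitivities when
tabulated curves are unavailable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
import pandas as pd

from ._d65 import D65_POWER, D65_WAVELENGTH_NM
from .errors import CoverageError, DomainError, SpectralFormatError

logger = logging.getLogger(__name__)

#: Reflectance values above this are treated as gross calibration errors.
REFLECTANCE_CEILING = 1.5

#: Allowed extrapolation (nm) at grid edges before a CoverageError is raised.
EDGE_TOLERANCE_NM = 5.0

SPECTRUM_KINDS = ("reflectance", "illuminant", "sensitivity")

#: Receptor names of the two opponent pairs (pale/yellow R7 against R8).
RECEPTOR_NAMES = ("R7p", "R7y", "R8p", "R8y")

#: Default nomogram peak wavelengths (nm) for the four receptors.  These are
#: documented stand-ins for tabulated hoverfly sensitivities: two UV-peaking
#: R7 classes and blue/green-peaking R8 classes.  Override via
#: :func:`nomogram_receptor_set` or tabulated CSVs.
DEFAULT_LAMBDA_MAX = {"R7p": 330.0, "R7y": 350.0, "R8p": 460.0, "R8y": 530.0}


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid: ``start, start+step, ..., stop`` in nm."""

    start_nm: float
    stop_nm: float
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start_nm < self.stop_nm):
            raise DomainError(
                f"grid start {self.start_nm} must be below stop {self.stop_nm}"
            )
        if self.step_nm <= 0:
            raise DomainError(f"grid step must be positive, got {self.step_nm}")
        n_steps = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise DomainError(
                f"grid span {self.start_nm}-{self.stop_nm} is not a whole "
                f"number of {self.step_nm} nm steps"
            )

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.start_nm, self.stop_nm, len(self))


#: Default modeling grid: spans the near-UV and visible bands of flower signals.
DEFAULT_GRID = WavelengthGrid(300.0, 700.0, 1.0)


@dataclass
class Spectrum:
    """Nonnegative values on a :class:`WavelengthGrid`.

    ``kind`` is one of ``reflectance`` (0-1 scale, ceiling 1.5 to allow
    calibration overshoot), ``illuminant`` or ``sensitivity``.
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "reflectance"
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SPECTRUM_KINDS:
            raise DomainError(f"unknown spectrum kind {self.kind!r}")
        if self.values.shape != (len(self.grid),):
            raise DomainError(
                f"spectrum has {self.values.size} values for a grid of "
                f"{len(self.grid)} points"
            )
        if not np.all(np.isfinite(self.values)):
            raise DomainError("spectrum values must be finite")
        if np.any(self.values < 0):
            raise DomainError("spectrum values must be nonnegative")
        if self.kind == "reflectance" and np.any(self.values > REFLECTANCE_CEILING):
            raise DomainError(
                f"reflectance exceeds {REFLECTANCE_CEILING}; check calibration"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths


@dataclass
class ReceptorSet:
    """The four fly photoreceptor sensitivity curves, max-normalized to 1."""

    sensitivities: Dict[str, Spectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(RECEPTOR_NAMES) - set(self.sensitivities)
        if missing:
            raise DomainError(f"missing receptor sensitivities: {sorted(missing)}")
        for name in RECEPTOR_NAMES:
            s = self.sensitivities[name]
            peak = float(s.values.max())
            if not np.isclose(peak, 1.0, atol=1e-6):
                raise DomainError(
                    f"receptor {name} sensitivity must be max-normalized to 1 "
                    f"(max = {peak:.6g})"
                )

    def __getitem__(self, name: str) -> Spectrum:
        return self.sensitivities[name]

    @property
    def grid(self) -> WavelengthGrid:
        return self.sensitivities[RECEPTOR_NAMES[0]].grid


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

def read_spectra_csv(path: str | Path, kind: str = "reflectance") -> Dict[str, Spectrum]:
    """Read labeled spectra from CSV.

    Dialect: first column ``wavelength_nm`` (strictly increasing, uniform
    spacing), one spectrum per subsequent column, labels from the header;
    ``#`` starts a comment line.  Negative values are clipped to zero with a
    logged warning (spectrometer noise near zero reflectance).
    """
    path = Path(path)
    try:
        # round_trip parsing + %.17g on write makes write/read lossless
        table = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise SpectralFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if table.shape[1] < 2:
        raise SpectralFormatError(f"{path}: need a wavelength column plus >=1 value column")
    if table.shape[0] < 2:
        raise SpectralFormatError(f"{path}: need at least 2 wavelength rows")

    for col in table.columns:
        bad = pd.to_numeric(table[col], errors="coerce").isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectralFormatError(
                f"{path}: non-numeric cell at row {row + 2}, column {col!r}"
            )
        if table[col].isna().any():
            row = int(np.flatnonzero(table[col].isna().to_numpy())[0])
            raise SpectralFormatError(
                f"{path}: missing value at row {row + 2}, column {col!r}"
            )

    wl = table.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise SpectralFormatError(f"{path}: wavelengths must be strictly increasing")
    steps = np.diff(wl)
    if not np.allclose(steps, steps[0], atol=1e-6):
        raise SpectralFormatError(f"{path}: wavelength spacing must be uniform")
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(steps[0]))

    spectra: Dict[str, Spectrum] = {}
    for col in table.columns[1:]:
        values = table[col].to_numpy(dtype=float)
        if np.any(values < 0):
            n_neg = int((values < 0).sum())
            logger.warning(
                "%s: column %r has %d negative value(s); clipped to 0", path, col, n_neg
            )
            values = np.clip(values, 0.0, None)
        spectra[str(col)] = Spectrum(grid, values, kind=kind, label=str(col))
    return spectra


def write_spectra_csv(path: str | Path, spectra: Mapping[str, Spectrum] | Iterable[Spectrum]) -> None:
    """Write spectra sharing one grid to the CSV dialect of :func:`read_spectra_csv`."""
    if isinstance(spectra, Mapping):
        items = [(label, s) for label, s in spectra.items()]
    else:
        items = [(s.label or f"spectrum_{i}", s) for i, s in enumerate(spectra)]
    if not items:
        raise SpectralFormatError("no spectra to write")
    grid = items[0][1].grid
    for label, s in items:
        if s.grid != grid:
            raise SpectralFormatError(f"spectrum {label!r} is on a different grid")
    frame = pd.DataFrame({"wavelength_nm": grid.wavelengths})
    for label, s in items:
        frame[label] = s.values
    # %.17g round-trips IEEE doubles exactly
    frame.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(
    spectrum: Spectrum,
    grid: WavelengthGrid,
    edge_tolerance_nm: float = EDGE_TOLERANCE_NM,
) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    The native range must cover the target grid; a shortfall of at most
    ``edge_tolerance_nm`` at either edge is filled with the terminal value,
    anything larger raises :class:`CoverageError`.
    """
    native = spectrum.wavelengths
    if grid.start_nm < native[0] - edge_tolerance_nm:
        raise CoverageError(
            f"spectrum starts at {native[0]} nm; cannot cover "
            f"[{grid.start_nm}, {native[0]}) nm"
        )
    if grid.stop_nm > native[-1] + edge_tolerance_nm:
        raise CoverageError(
            f"spectrum ends at {native[-1]} nm; cannot cover "
            f"({native[-1]}, {grid.stop_nm}] nm"
        )
    values = np.interp(grid.wavelengths, native, spectrum.values)
    return Spectrum(grid, values, kind=spectrum.kind, label=spectrum.label)


# ---------------------------------------------------------------------------
# Standard illuminants
# ---------------------------------------------------------------------------

def d65_illuminant(grid: WavelengthGrid = DEFAULT_GRID, photon_units: bool = True) -> Spectrum:
    """CIE D65 daylight illuminant on ``grid``, max-normalized to 1.

    Photoreceptors count photons, so by default the tabulated spectral power
    is converted to relative photon flux (power x wavelength) before
    normalization; pass ``photon_units=False`` to stay in energy units.
    """
    if grid.start_nm < D65_WAVELENGTH_NM[0] or grid.stop_nm > D65_WAVELENGTH_NM[-1]:
        raise CoverageError(
            f"D65 is tabulated on {D65_WAVELENGTH_NM[0]}-{D65_WAVELENGTH_NM[-1]} nm; "
            f"requested {grid.start_nm}-{grid.stop_nm} nm"
        )
    flux = D65_POWER * D65_WAVELENGTH_NM if photon_units else D65_POWER.copy()
    values = np.interp(grid.wavelengths, D65_WAVELENGTH_NM, flux)
    values = values / values.max()
    return Spectrum(grid, values, kind="illuminant", label="D65")


def equal_energy_illuminant(grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Flat (equal-energy) illuminant, all values 1."""
    return Spectrum(grid, np.ones(len(grid)), kind="illuminant", label="equal_energy")


# ---------------------------------------------------------------------------
# Visual pigment nomogram
# ---------------------------------------------------------------------------

# Govardovskii-style A1 rhodopsin alpha-band template constants.
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


def _alpha_band(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    x = lambda_max / np.asarray(wavelengths, dtype=float)
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )


def nomogram_sensitivity(lambda_max: float, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """A1 visual-pigment alpha-band template peaking at ``lambda_max`` (nm).

    Unimodal, max-normalized to 1 at the peak.  Serves as a stand-in
    sensitivity when tabulated receptor curves are not supplied.
    """
    if not (300.0 <= lambda_max <= 650.0):
        raise DomainError(f"lambda_max {lambda_max} nm outside [300, 650] nm")
    values = _alpha_band(grid.wavelengths, lambda_max)
    return Spectrum(grid, values / values.max(), kind="sensitivity",
                    label=f"nomogram_{lambda_max:g}nm")


def nomogram_receptor_set(
    lambda_max: Mapping[str, float] | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> ReceptorSet:
    """Build the four-receptor set from nomogram templates.

    Defaults to :data:`DEFAULT_LAMBDA_MAX`; pass a mapping to override any
    subset of the peak wavelengths.
    """
    peaks = dict(DEFAULT_LAMBDA_MAX)
    if lambda_max:
        unknown = set(lambda_max) - set(RECEPTOR_NAMES)
        if unknown:
            raise DomainError(f"unknown receptor names: {sorted(unknown)}")
        peaks.update(lambda_max)
    sens = {
        name: nomogram_sensitivity(peaks[name], grid) for name in RECEPTOR_NAMES
    }
    for name in RECEPTOR_NAMES:
        sens[name].label = name
    return ReceptorSet(sens)


def receptor_set_from_csv(path: str | Path, grid: WavelengthGrid = DEFAULT_GRID) -> ReceptorSet:
    """Load tabulated receptor sensitivities (columns R7p, R7y, R8p, R8y)."""
    raw = read_spectra_csv(path, kind="sensitivity")
    sens = {}
    for name in RECEPTOR_NAMES:
        if name not in raw:
            raise SpectralFormatError(f"{path}: missing receptor column {name!r}")
        s = resample(raw[name], grid)
        peak = s.values.max()
        if peak <= 0:
            raise SpectralFormatError(f"{path}: receptor {name} is identically zero")
        sens[name] = Spectrum(grid, s.values / peak, kind="sensitivity", label=name)
    return ReceptorSet(sens)
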