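"""Wavelength grids, spectra, molar fluorescences and the linear
intensity model.

A solution's fluorescence spectrum is modelled as the concentration-weighted
sum of per-species molar fluorescence profiles::

    If_j = sum_i C_i * Phi_{i,j}

which is linear in every species concentration.  Molar fluorescence matrices
are per acquisition mode; modes are never coupled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .equilibrium import EquilibriumModel, SpeciationResult
from .errors import DataWarning, IdentifiabilityError, ValidationError

__all__ = [
    "MODES",
    "WavelengthGrid",
    "Spectrum",
    "MolarFluorescenceMatrix",
    "compute_spectrum",
    "estimate_molar_fluorescence",
    "smooth_spectrum",
]

MODES = ("emission", "sync15", "sync60")

#: default scan ranges (nm) per acquisition mode
_DEFAULT_RANGES = {
    "emission": (295.0, 550.0),
    "sync15": (230.0, 400.0),
    "sync60": (230.0, 400.0),
}


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered wavelength axis of one acquisition mode.

    ``excitation`` is the excitation wavelength for emission scans and the
    fixed excitation-emission offset (delta-lambda) for synchronous scans.
    """

    mode: str
    wavelengths: np.ndarray
    excitation: float

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValidationError("wavelength grid must be 1-D with >= 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self):
        return self.wavelengths.size

    def __eq__(self, other):
        return (isinstance(other, WavelengthGrid) and self.mode == other.mode
                and self.excitation == other.excitation
                and np.array_equal(self.wavelengths, other.wavelengths))

    def __hash__(self):  # frozen dataclass with array field
        return hash((self.mode, self.excitation, self.wavelengths.tobytes()))

    @classmethod
    def default(cls, mode: str, step_nm: float = 1.0) -> "WavelengthGrid":
        lo, hi = _DEFAULT_RANGES[mode]
        n = int(round((hi - lo) / step_nm)) + 1
        wl = lo + step_nm * np.arange(n)
        exc = {"emission": 285.0, "sync15": 15.0, "sync60": 60.0}[mode]
        return cls(mode=mode, wavelengths=wl, excitation=exc)


@dataclass(frozen=True)
class Spectrum:
    grid: WavelengthGrid
    intensities: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (len(self.grid),):
            raise ValidationError("intensity length does not match grid")
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class MolarFluorescenceMatrix:
    """Per-species, per-wavelength molar fluorescence coefficients for one
    mode (intensity units per mol/L)."""

    grid: WavelengthGrid
    species_keys: tuple[tuple[int, int], ...]
    values: np.ndarray  # (n_species, n_wavelengths)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        expect = (len(self.species_keys), len(self.grid))
        if v.shape != expect:
            raise ValidationError(f"Phi matrix shape {v.shape} != {expect}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("Phi matrix must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "species_keys", tuple(tuple(k) for k in self.species_keys))

    def row(self, key: tuple[int, int]) -> np.ndarray:
        return self.values[self.species_keys.index(tuple(key))]


def _conc_matrix(model: EquilibriumModel,
                 speciations: Sequence[SpeciationResult],
                 keys: Sequence[tuple[int, int]]) -> np.ndarray:
    return np.array([[sp.concentration(k) for k in keys] for sp in speciations])


def compute_spectrum(speciation: SpeciationResult,
                     phi: MolarFluorescenceMatrix,
                     grid: WavelengthGrid | None = None) -> Spectrum:
    """Model spectrum of one solution: If_j = sum_i C_i * Phi_{i,j}."""
    if grid is not None and grid != phi.grid:
        raise ValidationError("grid does not match Phi matrix grid")
    try:
        c = np.array([speciation.concentration(k) for k in phi.species_keys])
    except KeyError as err:
        raise ValidationError(f"speciation lacks species {err}") from err
    return Spectrum(grid=phi.grid, intensities=c @ phi.values)


def estimate_molar_fluorescence(
    speciations: Sequence[SpeciationResult],
    observed: Sequence[Spectrum],
    model: EquilibriumModel,
    nonnegative: bool = False,
    rcond: float = 1e-10,
) -> tuple[MolarFluorescenceMatrix, np.ndarray]:
    """Least-squares estimate of the molar fluorescences of all fluorescent
    species from observed spectra.

    Solves, wavelength by wavelength, ``min_Phi ||Y - C Phi||^2`` with the
    species concentration matrix ``C`` as design matrix (all wavelengths
    share ``C``, so a single matrix least-squares call suffices).

    Returns the matrix and the residual matrix (solutions x wavelengths).

    Raises
    ------
    IdentifiabilityError
        If the concentration matrix is numerically rank deficient; the
        message names the species involved in the collinearity.
    """
    if len(speciations) != len(observed):
        raise ValidationError("speciations and spectra length mismatch")
    if len(observed) == 0:
        raise ValidationError("need at least one solution")
    grid = observed[0].grid
    for sp in observed[1:]:
        if sp.grid != grid:
            raise ValidationError("all observed spectra must share one grid")

    keys = [sp.key for sp in model.fluorescent_species]
    if len(speciations) < len(keys):
        raise IdentifiabilityError(
            f"{len(keys)} fluorescent species need >= {len(keys)} solutions")
    c = _conc_matrix(model, speciations, keys)
    y = np.array([sp.intensities for sp in observed])

    # rank test on the column-scaled design so absolute concentration scale
    # (uM free drug vs nM complex) does not masquerade as collinearity
    norms = np.linalg.norm(c, axis=0)
    if np.any(norms == 0):
        labels = [model.species[model.species_index(k)].label
                  for k, n in zip(keys, norms) if n == 0]
        raise IdentifiabilityError(
            "species never present in any solution: " + ", ".join(labels))
    cs = c / norms
    u, sing, vt = np.linalg.svd(cs, full_matrices=False)
    if sing[-1] < rcond * sing[0]:
        null = vt[-1]
        labels = [model.species[model.species_index(k)].label
                  for k, w in zip(keys, null) if abs(w) > 0.1]
        raise IdentifiabilityError(
            "concentration matrix is rank deficient; collinear species: "
            + ", ".join(labels))

    phi = (vt.T @ ((u.T @ y) / sing[:, None])) / norms[:, None]
    if nonnegative:
        from scipy.optimize import nnls
        phi = np.column_stack([nnls(c, y[:, j])[0] for j in range(y.shape[1])])
    elif np.any(phi < -1e-9 * max(np.abs(phi).max(), 1.0)):
        warnings.warn("negative molar fluorescence estimated", DataWarning,
                      stacklevel=2)
    residuals = y - c @ phi
    return (MolarFluorescenceMatrix(grid=grid, species_keys=tuple(keys), values=phi),
            residuals)


def smooth_spectrum(spec: Spectrum, window: int = 11, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing; the grid is unchanged."""
    if window % 2 == 0 or window < 3:
        raise ValidationError("window must be an odd integer >= 3")
    if not 0 <= polyorder < window:
        raise ValidationError("polyorder must satisfy 0 <= polyorder < window")
    if window > len(spec.grid):
        raise ValidationError("window exceeds spectrum length")
    y = savgol_filter(spec.intensities, window_length=window, polyorder=polyorder)
    return Spectrum(grid=spec.grid, intensities=y)
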