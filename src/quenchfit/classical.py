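"""Single-wavelength quenching analyses.

Implements the linear quench plot ``(F0-F)/F = Kq * tau * [Q]`` (regression
forced through the origin, since the relation has no intercept), the
double-logarithm plot ``log((F0-F)/F) = log Kb + nH * log[Q]`` (free
intercept: the intercept *is* the binding constant), the static-quenching
classification against the aqueous diffusion limit, and the drug-interference
wavelength-selection rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (DataWarning, InsufficientDataError, ValidationError)
from .spectra import Spectrum

__all__ = [
    "DIFFUSION_LIMIT",
    "QuenchingSeries",
    "SVFitResult",
    "DLSVFitResult",
    "WavelengthSelection",
    "sv_fit",
    "classify_quenching",
    "dlsv_fit",
    "interference_percent",
    "select_wavelength",
]

#: maximum bimolecular quenching constant for diffusion-limited quenching
#: in water (M^-1 s^-1); larger apparent values imply a ground-state complex
DIFFUSION_LIMIT = 1e10


@dataclass(frozen=True)
class QuenchingSeries:
    """Intensity at a single wavelength along a quencher titration.

    ``quencher`` holds total quencher concentrations in mol/L, strictly
    increasing; ``intensity`` the measured fluorescence at each point.
    ``f0`` is the intensity with no quencher present.
    """

    f0: float
    quencher: np.ndarray
    intensity: np.ndarray
    wavelength: float | None = None
    mode: str | None = None

    def __post_init__(self):
        q = np.asarray(self.quencher, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        if q.shape != f.shape or q.ndim != 1:
            raise ValidationError("quencher and intensity must be 1-D, same length")
        if not self.f0 > 0:
            raise ValidationError("F0 must be > 0")
        if np.any(f <= 0):
            raise ValidationError("all intensities must be > 0")
        if not np.all(np.diff(q) > 0):
            raise ValidationError("quencher concentrations must be strictly increasing")
        object.__setattr__(self, "quencher", q)
        object.__setattr__(self, "intensity", f)


@dataclass(frozen=True)
class SVFitResult:
    kq: float          # bimolecular quenching constant, M^-1 s^-1
    tau: float         # assumed fluorophore lifetime, s
    ksv: float         # Kq * tau, M^-1
    r2: float

    def __post_init__(self):
        if not (np.isfinite(self.ksv) and np.isfinite(self.kq)):
            raise ValidationError("non-finite SV fit")


@dataclass(frozen=True)
class DLSVFitResult:
    log_kb: float
    nh: float
    r2: float
    se_log_kb: float
    se_nh: float
    n_used: int


def sv_fit(series: QuenchingSeries, tau: float = 5e-9) -> SVFitResult:
    """Stern-Volmer fit: OLS slope of (F0-F)/F on [Q] through the origin."""
    if not (1e-12 < tau < 1e-6):
        raise ValidationError("tau must be a plausible lifetime in seconds")
    y = (series.f0 - series.intensity) / series.intensity
    x = series.quencher
    if x.size < 3 and not np.allclose(y, 0):
        raise InsufficientDataError("need >= 3 titration points for the SV fit")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValidationError("all quencher concentrations are zero")
    slope = float(np.dot(x, y)) / sxx
    sst = float(np.dot(y, y))  # through-origin convention
    sse = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
    return SVFitResult(kq=slope / tau, tau=tau, ksv=slope, r2=r2)


def classify_quenching(result: SVFitResult,
                       threshold: float = DIFFUSION_LIMIT) -> str:
    """'static' when apparent Kq exceeds the diffusion limit, else
    'dynamic-compatible'."""
    return "static" if result.kq > threshold else "dynamic-compatible"


def dlsv_fit(series: QuenchingSeries) -> DLSVFitResult:
    """Double-logarithm Stern-Volmer fit.

    Unweighted least-squares line of log10((F0-F)/F) on log10([Q]);
    slope = Hill coefficient, intercept = log10 Kb.  Points with F >= F0
    carry no quench information on the log scale and are dropped with a
    warning.
    """
    mask = (series.intensity < series.f0) & (series.quencher > 0)
    n_dropped = int(np.sum(~mask))
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} point(s) with F >= F0 or [Q] = 0",
                      DataWarning, stacklevel=2)
    q = series.quencher[mask]
    f = series.intensity[mask]
    if q.size < 3:
        raise InsufficientDataError(
            f"only {q.size} usable points (need >= 3) for the DLSV fit")
    x = np.log10(q)
    y = np.log10((series.f0 - f) / f)

    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym))) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sse = float(np.dot(resid, resid))
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    dof = max(n - 2, 1)
    s2 = sse / dof
    se_slope = np.sqrt(s2 / sxx)
    se_inter = np.sqrt(s2 * (1.0 / n + xm ** 2 / sxx))
    return DLSVFitResult(log_kb=intercept, nh=slope, r2=min(max(r2, 0.0), 1.0),
                         se_log_kb=se_inter, se_nh=se_slope, n_used=n)


def interference_percent(i_drug: float, i_total: float) -> float:
    """Drug spectral interference, 100 * I_drug / I_total."""
    if not i_total > 0:
        raise ValidationError("I_total must be > 0")
    if i_drug < 0 or i_drug > i_total:
        raise ValidationError("need 0 <= I_drug <= I_total")
    return 100.0 * i_drug / i_total


@dataclass(frozen=True)
class WavelengthSelection:
    wavelength: float | None     # None when no wavelength qualifies
    interference: float | None   # % at the selected wavelength
    protein_intensity: float | None
    usable_mask: np.ndarray      # per-wavelength, interference <= threshold


def select_wavelength(protein_spectrum: Spectrum, drug_spectrum: Spectrum,
                      threshold: float = 10.0) -> WavelengthSelection:
    """Pick the monitoring wavelength: maximum protein signal among
    wavelengths whose drug interference is at or below ``threshold`` percent.

    Interference at each wavelength is 100 * I_drug / (I_drug + I_protein).
    Returns a selection with ``wavelength=None`` when no wavelength
    qualifies (strongly fluorescent drugs).
    """
    if protein_spectrum.grid != drug_spectrum.grid:
        raise ValidationError("protein and drug spectra must share a grid")
    p = protein_spectrum.intensities
    d = drug_spectrum.intensities
    if np.any(p < 0) or np.any(d < 0):
        raise ValidationError("spectra must be non-negative for selection")
    total = p + d
    with np.errstate(invalid="ignore", divide="ignore"):
        interf = np.where(total > 0, 100.0 * d / total, 100.0)
    usable = interf <= threshold
    if not np.any(usable):
        return WavelengthSelection(None, None, None, usable)
    idx_candidates = np.flatnonzero(usable)
    best = idx_candidates[np.argmax(p[idx_candidates])]
    return WavelengthSelection(
        wavelength=float(protein_spectrum.grid.wavelengths[best]),
        interference=float(interf[best]),
        protein_intensity=float(p[best]),
        usable_mask=usable,
    )
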