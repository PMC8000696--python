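"""Synthetic fluorescence titrations with the structure the fitters assume.

Emulates the bench protocol: a fixed protein aliquot, sixteen consecutive
additions of a concentrated drug stock covering a drug:protein ratio range,
cumulative dilution tracked exactly, species spectra built from Gaussian
peaks, and seeded additive Gaussian noise.  Four drug-like presets span the
behaviours the analysis must cope with: no detectable quenching, a single
quenched site with a fluorescent drug, two sites with minor drug
interference, and two close sites with a strongly fluorescent drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .equilibrium import (EquilibriumModel, SolutionComposition, Species,
                          speciation_series)
from .errors import DataWarning, ProtocolError, ValidationError
from .io import TitrationDataset
from .spectra import MODES, MolarFluorescenceMatrix, WavelengthGrid

__all__ = ["Peak", "GroundTruth", "TitrationProtocol", "plan_additions",
           "simulate_titration", "drug_presets", "preset_protocol",
           "PRESET_NAMES"]

_UM = 1e-6

PRESET_NAMES = ("ibuprofen", "naproxen", "diflunisal", "flurbiprofen")


@dataclass(frozen=True)
class Peak:
    """One Gaussian band of a species spectrum.

    ``amplitude`` is the peak molar fluorescence (intensity per mol/L).
    """

    center_nm: float
    width_nm: float
    amplitude: float

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (wavelengths - self.center_nm) / self.width_nm
        return self.amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class GroundTruth:
    """True equilibrium model plus per-species, per-mode spectral shapes."""

    model: EquilibriumModel
    species_peaks: dict[tuple[int, int], dict[str, tuple[Peak, ...]]]
    noise_sd_fraction: float = 0.005
    high_intensity_modes: tuple[str, ...] = ()
    name: str = ""

    def phi_for_grid(self, grid: WavelengthGrid) -> MolarFluorescenceMatrix:
        keys = [sp.key for sp in self.model.fluorescent_species]
        values = np.zeros((len(keys), len(grid)))
        for i, key in enumerate(keys):
            for peak in self.species_peaks.get(key, {}).get(grid.mode, ()):
                values[i] += peak.profile(grid.wavelengths)
        return MolarFluorescenceMatrix(grid=grid, species_keys=tuple(keys),
                                       values=values)


@dataclass(frozen=True)
class TitrationProtocol:
    """Bench protocol for one titration (concentrations in uM, volumes uL)."""

    seed: int
    initial_volume_uL: float = 2700.0
    protein_uM: float = 4.5
    n_additions: int = 16
    ratio_range: tuple[float, float] = (0.4, 14.0)
    stock_uM: float = 1000.0
    temperature_C: float = 25.0
    modes: tuple[str, ...] = MODES
    spacing: str = "geometric"
    wavelength_step_nm: float = 1.0
    max_volume_increase: float = 0.2

    def __post_init__(self):
        if self.initial_volume_uL <= 0 or self.protein_uM <= 0 or self.stock_uM <= 0:
            raise ValidationError("volumes and concentrations must be positive")
        if self.n_additions < 0:
            raise ValidationError("n_additions must be >= 0")
        lo, hi = self.ratio_range
        if not (0 < lo <= hi):
            raise ValidationError("ratio_range must be increasing and positive")
        if self.spacing not in ("geometric", "linear"):
            raise ValidationError("spacing must be 'geometric' or 'linear'")
        for m in self.modes:
            if m not in MODES:
                raise ValidationError(f"unknown mode {m!r}")


def _target_ratios(protocol: TitrationProtocol) -> np.ndarray:
    lo, hi = protocol.ratio_range
    n = protocol.n_additions
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.array([hi])
    if protocol.spacing == "geometric":
        return np.geomspace(lo, hi, n)
    return np.linspace(lo, hi, n)


def plan_additions(protocol: TitrationProtocol
                   ) -> tuple[list[SolutionComposition], list[float]]:
    """Plan the titration: the protein-only point plus one point per drug
    addition, with exact cumulative-dilution bookkeeping.

    Target drug:protein ratios are spaced across ``ratio_range``
    (geometrically by default); the added stock volume at each step is
    whatever brings the total drug:protein *mole* ratio to the target, so
    the concentration ratio is hit exactly despite dilution.

    Returns (compositions in mol/L, cumulative volumes in uL).

    Raises
    ------
    ProtocolError
        If reaching the maximum ratio would grow the total volume by more
        than ``max_volume_increase`` (stock too dilute).
    """
    v0 = protocol.initial_volume_uL
    n_protein = protocol.protein_uM * v0  # uM * uL, proportional to moles
    ratios = _target_ratios(protocol)

    if ratios.size:
        needed = ratios[-1] * n_protein / protocol.stock_uM
        if needed > protocol.max_volume_increase * v0:
            min_stock = ratios[-1] * n_protein / (protocol.max_volume_increase * v0)
            raise ProtocolError(
                f"stock {protocol.stock_uM} uM cannot reach ratio "
                f"{ratios[-1]} within a {protocol.max_volume_increase:.0%} "
                f"volume increase; need >= {min_stock:.0f} uM")

    comps = [SolutionComposition(total_S=protocol.protein_uM * _UM,
                                 total_Q=0.0,
                                 temperature=protocol.temperature_C)]
    volumes = [v0]
    v = v0
    n_drug = 0.0
    for r in ratios:
        add = (r * n_protein - n_drug) / protocol.stock_uM
        if add < 0:
            raise ProtocolError("target ratios must be non-decreasing")
        v += add
        n_drug = r * n_protein
        comps.append(SolutionComposition(total_S=n_protein / v * _UM,
                                         total_Q=n_drug / v * _UM,
                                         temperature=protocol.temperature_C))
        volumes.append(v)
    return comps, volumes


def simulate_titration(protocol: TitrationProtocol, truth: GroundTruth,
                       full_scale: float | None = None) -> TitrationDataset:
    """Simulate one titration: plan, solve speciation, build clean spectra
    as concentration-weighted sums of the species profiles, add i.i.d.
    Gaussian noise with sd = ``noise_sd_fraction`` x the clean maximum of
    each mode.  Same seed, same dataset, bit for bit."""
    import warnings

    comps, volumes = plan_additions(protocol)
    specs = speciation_series(truth.model, comps)
    conc = np.array([s.vector(truth.model, fluorescent_only=True)
                     for s in specs])
    rng = np.random.default_rng(protocol.seed)

    grids: dict[str, WavelengthGrid] = {}
    spectra: dict[str, np.ndarray] = {}
    for mode in MODES:          # fixed order keeps noise draws reproducible
        if mode not in protocol.modes:
            continue
        grid = WavelengthGrid.default(mode, protocol.wavelength_step_nm)
        phi = truth.phi_for_grid(grid)
        clean = conc @ phi.values
        if full_scale is not None and clean.max() > full_scale:
            warnings.warn(f"mode {mode!r}: clean intensity {clean.max():.3g} "
                          f"exceeds detector full scale {full_scale:.3g}",
                          DataWarning, stacklevel=2)
        if truth.noise_sd_fraction > 0:
            sd = truth.noise_sd_fraction * clean.max()
            clean = clean + rng.normal(0.0, sd, size=clean.shape)
        grids[mode] = grid
        spectra[mode] = clean

    meta = {
        "generator": "quenchfit.synthetic",
        "preset": truth.name,
        "seed": protocol.seed,
        "temperature_C": protocol.temperature_C,
        "noise_sd_fraction": truth.noise_sd_fraction,
        "high_intensity_modes": list(truth.high_intensity_modes),
    }
    return TitrationDataset(grids=grids, spectra=spectra, compositions=comps,
                            volumes_uL=volumes, metadata=meta)


# ---------------------------------------------------------------------------
# presets

#: true stepwise log K values per preset and temperature (deg C)
_CONSTANTS = {
    "naproxen": {20.0: (4.88,), 25.0: (4.80,), 37.0: (4.66,)},
    "diflunisal": {20.0: (5.74, 4.57), 25.0: (5.86, 4.70), 37.0: (5.62, 4.49)},
    "flurbiprofen": {20.0: (4.91, 5.53), 25.0: (4.96, 5.52), 37.0: (4.98, 5.22)},
    "ibuprofen": {20.0: (4.5,), 25.0: (4.5,), 37.0: (4.5,)},  # nominal; not detectable
}

_PROTEIN_PEAKS = {
    "emission": (Peak(346.0, 30.0, 1.0e8),),
    "sync15": (Peak(286.0, 10.0, 6.0e7),),
    "sync60": (Peak(286.0, 12.0, 8.0e7),),
}


def _attenuated(factor: float, shift_nm: float = 0.0) -> dict[str, tuple[Peak, ...]]:
    """Complex spectrum: the protein spectrum quenched by ``factor`` and
    red-shifted by ``shift_nm`` (complexation perturbs the fluorophore
    microenvironment, so bound-state bands move as well as shrink)."""
    return {mode: tuple(Peak(p.center_nm + shift_nm, p.width_nm,
                             factor * p.amplitude)
                        for p in peaks)
            for mode, peaks in _PROTEIN_PEAKS.items()}


_DRUG_PEAKS = {
    # minor interference everywhere
    "ibuprofen": {
        "emission": (Peak(330.0, 22.0, 7.0e6),),
        "sync15": (Peak(282.0, 9.0, 7.0e5),),
        "sync60": (Peak(288.0, 12.0, 6.0e6),),
    },
    # strongly fluorescent in emission and sync60, minor in sync15
    "naproxen": {
        "emission": (Peak(356.0, 32.0, 1.0e9),),
        "sync15": (Peak(281.0, 9.0, 4.0e6),),
        "sync60": (Peak(290.0, 14.0, 8.0e8),),
    },
    # minor interference; a distinct red-shifted emission band
    "diflunisal": {
        "emission": (Peak(423.0, 24.0, 9.0e6),),
        "sync15": (Peak(292.0, 9.0, 1.3e6),),
        "sync60": (Peak(300.0, 14.0, 7.0e6),),
    },
    # interference above the 10% rule in all three modes; sync60 extremely
    # intense (orders of magnitude above the protein signal)
    "flurbiprofen": {
        "emission": (Peak(318.0, 26.0, 8.0e6),),
        "sync15": (Peak(285.0, 10.0, 1.0e7),),
        "sync60": (Peak(291.0, 13.0, 2.0e9),),
    },
}

# complex (retained fraction of protein spectrum, red shift nm) per species
_QUENCH = {
    "ibuprofen": ((1.0, 0.0),),   # Phi(complex) == Phi(protein): undetectable
    "naproxen": ((0.35, 8.0),),
    "diflunisal": ((0.6, 8.0), (0.1, 16.0)),
    "flurbiprofen": ((0.3, 12.0), (0.05, 24.0)),
}

#: recommended bench parameters per preset: (protein uM, stock uM); the
#: least-soluble drug gets the dilute stock and a protein level that keeps
#: the full ratio range reachable within the volume budget
_BENCH = {
    "ibuprofen": (3.0, 1000.0),
    "naproxen": (3.0, 1000.0),
    "diflunisal": (4.5, 1000.0),
    "flurbiprofen": (4.2, 300.0),
}


def preset_protocol(name: str, seed: int, temperature_C: float = 20.0,
                    **overrides) -> TitrationProtocol:
    """Protocol with the recommended protein/stock levels for a preset."""
    if name not in PRESET_NAMES:
        raise ValidationError(f"unknown preset {name!r}")
    protein, stock = _BENCH[name]
    kwargs = dict(seed=seed, protein_uM=protein, stock_uM=stock,
                  temperature_C=temperature_C)
    kwargs.update(overrides)
    return TitrationProtocol(**kwargs)


def _cumulative(stepwise: tuple[float, ...]) -> list[float]:
    out = []
    total = 0.0
    for k in stepwise:
        total += k
        out.append(total)
    return out


def drug_presets(temperature_C: float = 20.0,
                 noise_sd_fraction: float = 0.005) -> dict[str, GroundTruth]:
    """Named ground-truth templates at one of the measured temperatures
    (20, 25 or 37 deg C)."""
    temp = float(temperature_C)
    if temp not in (20.0, 25.0, 37.0):
        raise ValidationError("presets are defined at 20, 25 and 37 deg C")

    out: dict[str, GroundTruth] = {}
    for name in PRESET_NAMES:
        stepwise = _CONSTANTS[name][temp]
        betas = _cumulative(stepwise)
        species = tuple(Species(1, q + 1, log_kb=betas[q], fluorescent=True)
                        for q in range(len(betas)))
        # free drug is fluorescent in every preset (its interference may be
        # minor); Phi rows for it are near zero where it does not emit
        model = EquilibriumModel(species=tuple(
            [Species(0, 1, fluorescent=True)] + list(species)))

        peaks: dict[tuple[int, int], dict[str, tuple[Peak, ...]]] = {
            (1, 0): dict(_PROTEIN_PEAKS),
            (0, 1): dict(_DRUG_PEAKS[name]),
        }
        for q, (factor, shift) in enumerate(_QUENCH[name]):
            peaks[(1, q + 1)] = _attenuated(factor, shift)

        out[name] = GroundTruth(
            model=model,
            species_peaks=peaks,
            noise_sd_fraction=noise_sd_fraction,
            high_intensity_modes=("sync60",) if name == "flurbiprofen" else (),
            name=name,
        )
    return out
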