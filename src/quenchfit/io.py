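"""Titration dataset container, file formats, and fit-report rendering.

On disk a titration is a directory with two plain-text files:

``spectra.csv``
    Long format, header ``solution_id,mode,wavelength_nm,intensity``;
    every (solution, mode) pair must cover exactly the same wavelength
    grid as every other solution of that mode.

``meta.json``
    Per-solution totals and volumes (concentrations in **uM** in files;
    mol/L everywhere in memory) plus per-mode excitation / delta-lambda.

Numeric payloads are written with 17 significant digits so that
``write -> read`` is the identity on IEEE doubles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import SolutionComposition
from .errors import SchemaError, ValidationError
from .spectra import MODES, Spectrum, WavelengthGrid

__all__ = ["TitrationDataset", "read_titration", "write_titration", "report"]

_UM = 1e-6  # file concentrations are uM; memory is mol/L

SPECTRA_FILE = "spectra.csv"
META_FILE = "meta.json"


@dataclass
class TitrationDataset:
    """All spectra and compositions of one titration experiment.

    ``spectra[mode]`` is an (n_solutions x n_wavelengths) intensity matrix,
    rows ordered like ``compositions``.
    """

    grids: dict[str, WavelengthGrid]
    spectra: dict[str, np.ndarray]
    compositions: list[SolutionComposition]
    solution_ids: list[str] = field(default_factory=list)
    volumes_uL: list[float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ns = len(self.compositions)
        if ns == 0:
            raise ValidationError("dataset needs at least one solution")
        if not self.solution_ids:
            self.solution_ids = [f"s{i:02d}" for i in range(ns)]
        if len(self.solution_ids) != ns:
            raise ValidationError("solution_ids length mismatch")
        if not self.spectra:
            raise ValidationError("dataset needs at least one mode")
        for mode, mat in self.spectra.items():
            if mode not in self.grids:
                raise ValidationError(f"mode {mode!r} has no grid")
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (ns, len(self.grids[mode])):
                raise ValidationError(
                    f"mode {mode!r}: spectra shape {mat.shape} != "
                    f"({ns}, {len(self.grids[mode])})")
            self.spectra[mode] = mat

    @property
    def modes(self) -> tuple[str, ...]:
        return tuple(m for m in MODES if m in self.spectra)

    @property
    def n_solutions(self) -> int:
        return len(self.compositions)

    def spectrum(self, mode: str, index: int) -> Spectrum:
        return Spectrum(grid=self.grids[mode], intensities=self.spectra[mode][index])

    def quenching_series(self, mode: str, wavelength: float):
        """Single-wavelength view of this titration for the classical fits.

        The first solution must be quencher-free; it provides F0.
        """
        from .classical import QuenchingSeries

        grid = self.grids[mode]
        j = int(np.argmin(np.abs(grid.wavelengths - wavelength)))
        if abs(grid.wavelengths[j] - wavelength) > 0.5:
            raise ValidationError(f"wavelength {wavelength} nm not on grid")
        if self.compositions[0].total_Q != 0:
            raise ValidationError("first solution must have zero quencher (F0)")
        col = self.spectra[mode][:, j]
        return QuenchingSeries(
            f0=float(col[0]),
            quencher=np.array([c.total_Q for c in self.compositions[1:]]),
            intensity=col[1:].copy(),
            wavelength=float(grid.wavelengths[j]),
            mode=mode,
        )


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_titration(dataset: TitrationDataset, path: str | Path) -> Path:
    """Write ``spectra.csv`` + ``meta.json`` into directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for mode in dataset.modes:
        wl = dataset.grids[mode].wavelengths
        for i, sid in enumerate(dataset.solution_ids):
            for j in range(wl.size):
                rows.append((sid, mode, _fmt(wl[j]),
                             _fmt(dataset.spectra[mode][i, j])))
    with open(path / SPECTRA_FILE, "w") as fh:
        fh.write("solution_id,mode,wavelength_nm,intensity\n")
        for r in rows:
            fh.write(",".join(r) + "\n")

    meta = {
        "format_version": 1,
        "solutions": [
            {
                "solution_id": sid,
                "total_S_uM": comp.total_S / _UM,
                "total_Q_uM": comp.total_Q / _UM,
                "temperature_C": comp.temperature,
                **({"volume_uL": dataset.volumes_uL[i]}
                   if dataset.volumes_uL is not None else {}),
            }
            for i, (sid, comp) in enumerate(
                zip(dataset.solution_ids, dataset.compositions))
        ],
        "modes": {
            mode: {"excitation": dataset.grids[mode].excitation}
            for mode in dataset.modes
        },
        "metadata": dataset.metadata,
    }
    with open(path / META_FILE, "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_titration(path: str | Path) -> TitrationDataset:
    """Read a titration directory written by :func:`write_titration`.

    Raises :class:`SchemaError` naming the offending solution/mode when the
    layout is inconsistent (missing wavelengths, non-monotone grids, ...).
    """
    path = Path(path)
    csv_path = path / SPECTRA_FILE
    meta_path = path / META_FILE
    if not csv_path.exists():
        raise SchemaError(f"missing {csv_path}")
    if not meta_path.exists():
        raise SchemaError(f"missing {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)

    try:
        sols = meta["solutions"]
        solution_ids = [s["solution_id"] for s in sols]
        compositions = [
            SolutionComposition(
                total_S=s["total_S_uM"] * _UM,
                total_Q=s["total_Q_uM"] * _UM,
                temperature=s.get("temperature_C", 25.0),
            )
            for s in sols
        ]
    except (KeyError, TypeError) as err:
        raise SchemaError(f"malformed meta.json: {err}") from err
    volumes = [s["volume_uL"] for s in sols] if all(
        "volume_uL" in s for s in sols) else None

    df = pd.read_csv(csv_path, dtype={"solution_id": str},
                     float_precision="round_trip")
    expect_cols = ["solution_id", "mode", "wavelength_nm", "intensity"]
    if list(df.columns) != expect_cols:
        raise SchemaError(f"spectra.csv columns {list(df.columns)} != {expect_cols}")

    grids: dict[str, WavelengthGrid] = {}
    spectra: dict[str, np.ndarray] = {}
    for mode, sub in df.groupby("mode", sort=False):
        if mode not in MODES:
            raise SchemaError(f"unknown mode {mode!r} in spectra.csv")
        ref_wl = None
        mat = []
        for sid in solution_ids:
            block = sub[sub["solution_id"] == sid]
            if block.empty:
                raise SchemaError(f"mode {mode!r}: no rows for solution {sid!r}")
            wl = block["wavelength_nm"].to_numpy(dtype=float)
            if not np.all(np.diff(wl) > 0):
                raise SchemaError(
                    f"mode {mode!r}, solution {sid!r}: wavelengths not "
                    "strictly increasing")
            if ref_wl is None:
                ref_wl = wl
            elif wl.shape != ref_wl.shape or not np.array_equal(wl, ref_wl):
                raise SchemaError(
                    f"mode {mode!r}, solution {sid!r}: wavelength grid differs "
                    "from the first solution")
            mat.append(block["intensity"].to_numpy(dtype=float))
        extra = set(sub["solution_id"]) - set(solution_ids)
        if extra:
            raise SchemaError(f"mode {mode!r}: unknown solution ids {sorted(extra)}")
        exc = meta.get("modes", {}).get(mode, {}).get(
            "excitation", WavelengthGrid.default(mode).excitation)
        grids[mode] = WavelengthGrid(mode=mode, wavelengths=ref_wl, excitation=exc)
        spectra[mode] = np.array(mat)

    if not spectra:
        raise SchemaError("spectra.csv contains no data")
    return TitrationDataset(grids=grids, spectra=spectra,
                            compositions=compositions,
                            solution_ids=solution_ids, volumes_uL=volumes,
                            metadata=meta.get("metadata", {}))


# ---------------------------------------------------------------------------
# fit-report rendering

def _fmt_pm(value: float, err: float | None) -> str:
    """Render '5.74 (0.01)' style constants."""
    if err is None or not math.isfinite(err):
        return f"{value:.3f}"
    if err <= 0:
        return f"{value:.3f} (0)"
    digits = max(0, -int(math.floor(math.log10(err))))
    return f"{value:.{digits}f} ({err:.{digits}f})"


def report(result, format: str = "text") -> str:
    """Human- or machine-readable rendering of any fit result.

    Accepts :class:`~quenchfit.globalfit.GlobalFitResult`,
    :class:`~quenchfit.classical.DLSVFitResult` or
    :class:`~quenchfit.classical.SVFitResult`.
    """
    from .classical import DLSVFitResult, SVFitResult
    from .globalfit import GlobalFitResult

    if format not in ("text", "json"):
        raise ValidationError("format must be 'text' or 'json'")

    if isinstance(result, GlobalFitResult):
        payload = {
            "schema": "quenchfit.global_fit/1",
            "converged": result.converged,
            "iterations": result.iterations,
            "U": result.u,
            "sd_residual": result.sd_residual,
            "ns": result.ns,
            "nw": result.nw,
            "log_kb_stepwise": {
                f"{k[0]}:{k[1]}": {"value": v, "se": result.se_stepwise.get(k)}
                for k, v in result.log_kb_stepwise.items()},
            "log_beta_cumulative": {
                f"{k[0]}:{k[1]}": v for k, v in result.log_beta.items()},
        }
        if format == "json":
            return json.dumps(payload, indent=1)
        lines = []
        if not result.converged:
            lines.append("*** WARNING: fit did not converge ***")
        lines.append("Global multiwavelength fit")
        lines.append(f"  solutions: {result.ns}   wavelengths (all modes): {result.nw}")
        for k, v in sorted(result.log_kb_stepwise.items()):
            lines.append(
                f"  log Kb ({k[0]}:{k[1]}) = "
                f"{_fmt_pm(v, result.se_stepwise.get(k))}")
        lines.append(f"  U = {result.u:.6g}   sd(residual) = {result.sd_residual:.6g}")
        lines.append(f"  iterations = {result.iterations}")
        return "\n".join(lines)

    if isinstance(result, DLSVFitResult):
        payload = {
            "schema": "quenchfit.dlsv/1",
            "log_kb": result.log_kb, "se_log_kb": result.se_log_kb,
            "nh": result.nh, "se_nh": result.se_nh,
            "r2": result.r2, "n_used": result.n_used,
        }
        if format == "json":
            return json.dumps(payload, indent=1)
        return "\n".join([
            "Double-logarithm Stern-Volmer fit",
            f"  log Kb = {_fmt_pm(result.log_kb, result.se_log_kb)}",
            f"  nH     = {_fmt_pm(result.nh, result.se_nh)}",
            f"  R2 = {result.r2:.4f}   points used = {result.n_used}",
        ])

    if isinstance(result, SVFitResult):
        from .classical import classify_quenching
        payload = {
            "schema": "quenchfit.sv/1",
            "kq": result.kq, "tau_s": result.tau, "ksv": result.ksv,
            "r2": result.r2, "classification": classify_quenching(result),
        }
        if format == "json":
            return json.dumps(payload, indent=1)
        return "\n".join([
            "Stern-Volmer fit",
            f"  KSV = {result.ksv:.4g} 1/M   Kq = {result.kq:.4g} 1/(M s) "
            f"(tau = {result.tau * 1e9:.3g} ns)",
            f"  R2 = {result.r2:.4f}   classification: {classify_quenching(result)}",
        ])

    raise ValidationError(f"cannot report object of type {type(result).__name__}")
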