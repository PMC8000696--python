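"""Global multiwavelength refinement of binding constants.

The formation constants are refined by a Gauss-Newton iteration on the
sum of squared differences between experimental and calculated intensities

    U = sum_solutions sum_wavelengths (If_exp - If_calc)^2

accumulated over every acquisition mode used.  The problem is separable:
for fixed constants the speciation follows from the mass balances and the
molar fluorescences enter linearly, so each objective evaluation (i) solves
the speciation of every solution, (ii) estimates the per-mode molar
fluorescence matrices by linear least squares (unless supplied), and
(iii) forms the residuals.  The Gauss-Newton step on the log10 constants
uses a finite-difference Jacobian of that projected residual and is
safeguarded by step halving, so the accepted U sequence never increases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .equilibrium import (EquilibriumModel, SpeciationResult, stepwise_log_k,
                          speciation_series)
from .errors import (DataWarning, IdentifiabilityError, IdentifiabilityWarning,
                     ValidationError)
from .io import TitrationDataset
from .spectra import (MolarFluorescenceMatrix, Spectrum,
                      estimate_molar_fluorescence)

__all__ = ["FitSpec", "GlobalFitResult", "ModelRanking", "objective_U",
           "refine_constants", "staged_fit", "compare_models"]

logger = logging.getLogger(__name__)

#: capacity of the reference implementation this mirrors; exceeded sizes
#: only warn
MAX_SOLUTIONS = 300
MAX_POINTS_PER_SPECTRUM = 500


@dataclass(frozen=True)
class FitSpec:
    """What to refine, on which modes, and how."""

    model: EquilibriumModel
    free: tuple[tuple[int, int], ...] = ()      # complex keys whose log_kb is refined
    modes_used: tuple[str, ...] = ("emission", "sync15", "sync60")
    phi_supplied: dict[str, MolarFluorescenceMatrix] | None = None
    mode_weights: dict[str, float] | None = None
    max_iter: int = 200
    tol_u: float = 1e-8
    fd_step: float = 1e-4
    n_starts: int = 3
    start_spacing: float = 1.0

    def __post_init__(self):
        if len(self.modes_used) == 0:
            raise ValidationError("modes_used must be non-empty")
        keys = {sp.key for sp in self.model.complexes}
        for k in self.free:
            if tuple(k) not in keys:
                raise ValidationError(f"free species {k} not in model")
        object.__setattr__(self, "free", tuple(tuple(k) for k in self.free))
        object.__setattr__(self, "modes_used", tuple(self.modes_used))


@dataclass
class GlobalFitResult:
    log_beta: dict[tuple[int, int], float]          # cumulative, all complexes
    log_kb_stepwise: dict[tuple[int, int], float]   # ladder convention
    se_beta: dict[tuple[int, int], float | None]
    se_stepwise: dict[tuple[int, int], float | None]
    u: float
    sd_residual: float
    ns: int
    nw: int                       # wavelengths summed over modes
    n_refined: int
    n_phi: int
    iterations: int
    converged: bool
    identifiable: bool
    phi_hat: dict[str, MolarFluorescenceMatrix]
    residuals: dict[str, np.ndarray]
    u_history: list[float] = field(default_factory=list)
    modes_used: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    @property
    def model(self) -> EquilibriumModel:
        return self.provenance["model"]


def _check_capacity(data: TitrationDataset, modes):
    if data.n_solutions > MAX_SOLUTIONS:
        warnings.warn(f"{data.n_solutions} solutions exceeds the reference "
                      f"capacity of {MAX_SOLUTIONS}", DataWarning, stacklevel=3)
    for m in modes:
        if len(data.grids[m]) > MAX_POINTS_PER_SPECTRUM:
            warnings.warn(f"mode {m!r}: {len(data.grids[m])} wavelengths "
                          f"exceeds the reference capacity of "
                          f"{MAX_POINTS_PER_SPECTRUM}", DataWarning, stacklevel=3)


def _evaluate(model: EquilibriumModel, data: TitrationDataset, modes,
              phi_supplied, weights) -> tuple[np.ndarray, float, dict, dict]:
    """Projected residual at the current constants.

    Solves all mass balances, estimates (or applies) per-mode Phi, and
    returns (stacked weighted residual vector, U, phi per mode,
    residual matrices per mode).  U is always unweighted-by-default
    (weights of 1) times the supplied per-mode weights.
    """
    specs = speciation_series(model, data.compositions)
    parts = []
    phi_out: dict[str, MolarFluorescenceMatrix] = {}
    res_out: dict[str, np.ndarray] = {}
    for mode in modes:
        y = data.spectra[mode]
        w = weights.get(mode, 1.0)
        if phi_supplied and mode in phi_supplied:
            phi = phi_supplied[mode]
            c = np.array([s.vector(model, fluorescent_only=True) for s in specs])
            resid = y - c @ phi.values
        else:
            observed = [Spectrum(grid=data.grids[mode], intensities=row)
                        for row in y]
            with warnings.catch_warnings():
                # negative Phi estimates are routine while the constants are
                # still far from the optimum; only the converged Phi matters
                warnings.simplefilter("ignore", DataWarning)
                phi, resid = estimate_molar_fluorescence(specs, observed, model)
        phi_out[mode] = phi
        res_out[mode] = resid
        parts.append(np.sqrt(w) * resid.ravel())
    r = np.concatenate(parts)
    return r, float(np.dot(r, r)), phi_out, res_out


def objective_U(model: EquilibriumModel, data: TitrationDataset,
                phi: dict[str, MolarFluorescenceMatrix],
                modes: tuple[str, ...] | None = None,
                mode_weights: dict[str, float] | None = None) -> float:
    """Sum of squared intensity differences over all solutions, wavelengths
    and modes, at fixed constants and fixed molar fluorescences."""
    modes = tuple(modes) if modes else data.modes
    for m in modes:
        if m not in phi:
            raise ValidationError(f"phi missing for mode {m!r}")
    _, u, _, _ = _evaluate(model, data, modes, phi, mode_weights or {})
    return u


def _precheck(spec: FitSpec, data: TitrationDataset):
    for m in spec.modes_used:
        if m not in data.spectra:
            raise ValidationError(f"dataset lacks mode {m!r}")
    _check_capacity(data, spec.modes_used)
    tq = np.array([c.total_Q for c in data.compositions])
    if spec.free and np.all(tq == 0):
        raise IdentifiabilityError(
            "all solutions have zero quencher: no complex ever forms, the "
            "binding constants are unidentifiable")
    ratios = {round(c.total_Q / c.total_S, 9) for c in data.compositions
              if c.total_Q > 0}
    if spec.free and len(ratios) < 2 * len(spec.free):
        warnings.warn(
            f"only {len(ratios)} distinct quencher ratios for "
            f"{len(spec.free)} refined constant(s); fit may be ill-determined",
            IdentifiabilityWarning, stacklevel=3)


def _gauss_newton(spec: FitSpec, data: TitrationDataset, p0: np.ndarray):
    """One Gauss-Newton run from p0 (log10 cumulative constants of the
    refined species).  Returns (p, U, r, J, iters, converged, history)."""
    weights = spec.mode_weights or {}
    free = list(spec.free)

    def model_at(p):
        return spec.model.with_log_kb(dict(zip(free, p)))

    def resid(p):
        r, u, phi, res = _evaluate(model_at(p), data, spec.modes_used,
                                   spec.phi_supplied, weights)
        return r, u, phi, res

    p = p0.copy()
    r, u, phi, res = resid(p)
    history = [u]
    converged = False
    it = 0
    jac = None
    while it < spec.max_iter:
        it += 1
        if u == 0.0:
            converged = True
            break
        jac = np.empty((r.size, len(free)))
        for k in range(len(free)):
            pk = p.copy()
            pk[k] += spec.fd_step
            rk, _, _, _ = resid(pk)
            jac[:, k] = (rk - r) / spec.fd_step
        jtj = jac.T @ jac
        g = jac.T @ r
        try:
            step = np.linalg.solve(jtj, -g)
        except np.linalg.LinAlgError:
            raise IdentifiabilityError(
                "singular normal equations: constants are not jointly "
                "identifiable from these data") from None
        step = np.clip(step, -2.0, 2.0)
        accepted = False
        lam = 1.0
        for _ in range(10):
            r2v, u2, phi2, res2 = resid(p + lam * step)
            if u2 <= u:
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            # no descent possible along the Gauss-Newton direction:
            # we are at a minimum within finite-difference resolution
            converged = True
            break
        du = u - u2
        p = p + lam * step
        r, u, phi, res = r2v, u2, phi2, res2
        history.append(u)
        logger.debug("iter %d: U=%.8e params=%s", it, u, p)
        if du <= spec.tol_u * max(u, 1e-300):
            converged = True
            break
    return p, u, r, jac, phi, res, it, converged, history


def refine_constants(spec: FitSpec, data: TitrationDataset) -> GlobalFitResult:
    """Refine the flagged binding constants against a titration dataset.

    Alternates mass-balance solves, linear molar-fluorescence estimation and
    safeguarded Gauss-Newton steps on the log10 constants; optional
    multi-start (offsets of ``start_spacing`` log units) guards against
    local minima.  Standard errors come from the residual variance and the
    diagonal of (J^T J)^-1.
    """
    _precheck(spec, data)
    free = list(spec.free)
    weights = spec.mode_weights or {}

    if not free:
        # pure Phi estimation at fixed constants
        r, u, phi, res = _evaluate(spec.model, data, spec.modes_used,
                                   spec.phi_supplied, weights)
        return _package(spec, data, spec.model, np.empty(0), u, r, None, phi,
                        res, 0, True, [u])

    p0 = np.array([spec.model.species[spec.model.species_index(k)].log_kb
                   for k in free])
    offsets = [0.0]
    for i in range(1, spec.n_starts):
        offsets.append(spec.start_spacing * ((i + 1) // 2) * (1 if i % 2 else -1))
    best = None
    for off in offsets[: max(spec.n_starts, 1)]:
        out = _gauss_newton(spec, data, p0 + off)
        if best is None or out[1] < best[1]:
            best = out
    p, u, r, jac, phi, res, it, converged, history = best

    model = spec.model.with_log_kb(dict(zip(free, p)))
    if jac is None:  # converged at the initial point without a step
        jac = np.empty((r.size, len(free)))
        for k in range(len(free)):
            pk = p.copy()
            pk[k] += spec.fd_step
            rk, _, _, _ = _evaluate(model.with_log_kb({free[k]: pk[k]}), data,
                                    spec.modes_used, spec.phi_supplied, weights)
            jac[:, k] = (rk - r) / spec.fd_step
    return _package(spec, data, model, p, u, r, jac, phi, res, it, converged,
                    history)


def _package(spec, data, model, p, u, r, jac, phi, res, it, converged,
             history) -> GlobalFitResult:
    free = list(spec.free)
    ns = data.n_solutions
    nw = sum(len(data.grids[m]) for m in spec.modes_used)
    n_phi = 0
    if not spec.phi_supplied:
        n_phi = sum(len(phi[m].species_keys) * len(phi[m].grid)
                    for m in spec.modes_used)
    else:
        n_phi = sum(len(phi[m].species_keys) * len(phi[m].grid)
                    for m in spec.modes_used if m not in spec.phi_supplied)
    n_params = len(free) + n_phi
    dof = max(ns * nw - n_params, 1)
    sd = float(np.sqrt(u / dof))

    se_beta: dict[tuple[int, int], float | None] = {
        sp.key: None for sp in model.complexes}
    cov = None
    identifiable = True
    if free and jac is not None and r.size:
        jtj = jac.T @ jac
        cond = np.linalg.cond(jtj)
        if not np.isfinite(cond) or cond > 1e12:
            identifiable = False
            warnings.warn("near-singular normal equations: standard errors "
                          "unreliable", IdentifiabilityWarning, stacklevel=3)
        s2 = u / dof
        try:
            cov = s2 * np.linalg.inv(jtj)
            for k, key in enumerate(free):
                se_beta[key] = float(np.sqrt(max(cov[k, k], 0.0)))
        except np.linalg.LinAlgError:
            identifiable = False
            cov = None

    log_beta = {sp.key: sp.log_kb for sp in model.complexes}
    stepwise = stepwise_log_k(model)

    # propagate covariance through the cumulative -> stepwise map
    se_step: dict[tuple[int, int], float | None] = {}
    betas_all = {sp.key: sp.log_kb for sp in model.species}
    for key in stepwise:
        s_, q_ = key
        prev = (s_, q_ - 1)
        grad = {key: 1.0}
        if s_ == 1 and q_ >= 2 and prev in betas_all:
            grad[prev] = -1.0
        if cov is not None:
            gvec = np.array([grad.get(k, 0.0) for k in free])
            if np.any(gvec):
                se_step[key] = float(np.sqrt(max(gvec @ cov @ gvec, 0.0)))
            else:
                se_step[key] = None
        else:
            se_step[key] = se_beta.get(key)

    result = GlobalFitResult(
        log_beta=log_beta, log_kb_stepwise=stepwise,
        se_beta=se_beta, se_stepwise=se_step,
        u=u, sd_residual=sd, ns=ns, nw=nw,
        n_refined=len(free), n_phi=n_phi,
        iterations=it, converged=converged, identifiable=identifiable,
        phi_hat=phi, residuals=res, u_history=list(history),
        modes_used=spec.modes_used,
        provenance={"model": model, "free": tuple(free)},
    )
    big = [k for k in free if se_beta.get(k) is not None and se_beta[k] > 1.0]
    if big:
        warnings.warn(f"standard error exceeds 1 log unit for {big}: "
                      "constant effectively undetermined",
                      IdentifiabilityWarning, stacklevel=3)
        result.identifiable = False
    return result


def staged_fit(spec_stage1: FitSpec, spec_stage2: FitSpec,
               data: TitrationDataset) -> GlobalFitResult:
    """Two-stage refinement: fit stage 1 on its mode subset, transplant its
    refined constants into stage 2 (where they are held fixed), then refine
    stage 2 on its own mode set.  Returns the stage-2 result with both
    stages' values and provenance."""
    if not spec_stage1.free:
        raise ValidationError("stage 1 must refine at least one constant")
    r1 = refine_constants(spec_stage1, data)
    carried = {k: r1.log_beta[k] for k in spec_stage1.free
               if k in {sp.key for sp in spec_stage2.model.complexes}}
    model2 = spec_stage2.model.with_log_kb(carried)
    spec2 = replace(spec_stage2, model=model2)
    r2 = refine_constants(spec2, data)
    r2.provenance["stage1"] = r1
    r2.provenance["fixed_from_stage1"] = carried
    for k in carried:
        if k not in spec2.free:
            r2.se_beta[k] = r1.se_beta.get(k)
            if r2.se_stepwise.get(k) is None:
                r2.se_stepwise[k] = r1.se_stepwise.get(k)
    return r2


@dataclass(frozen=True)
class ModelRanking:
    order: tuple[int, ...]          # indices into the input list, best first
    sd_residuals: tuple[float, ...]
    notes: tuple[str, ...]

    @property
    def best(self) -> int:
        return self.order[0]


def compare_models(results: list[GlobalFitResult],
                   parsimony_factor: float = 0.05) -> ModelRanking:
    """Rank candidate equilibrium models fitted to the same dataset by
    residual standard deviation.

    Adds a parsimony note whenever a model with more refined constants beats
    a simpler one by less than ``parsimony_factor`` (relative sd_residual
    improvement); nothing is ever deleted automatically.
    """
    if not results:
        raise ValidationError("need at least one fit result")
    order = tuple(sorted(range(len(results)), key=lambda i: results[i].sd_residual))
    notes = []
    for i in order:
        for j in order:
            ri, rj = results[i], results[j]
            if (ri.n_refined > rj.n_refined
                    and ri.sd_residual <= rj.sd_residual
                    and rj.sd_residual > 0
                    and (rj.sd_residual - ri.sd_residual) / rj.sd_residual
                    < parsimony_factor):
                notes.append(
                    f"model {i} ({ri.n_refined} constants) improves on model "
                    f"{j} ({rj.n_refined}) by less than "
                    f"{parsimony_factor:.0%} in sd_residual; prefer the "
                    "simpler model")
    return ModelRanking(order=order,
                        sd_residuals=tuple(r.sd_residual for r in results),
                        notes=tuple(notes))
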