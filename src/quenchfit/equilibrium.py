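"""Two-component binding equilibria and mass-balance speciation.

A model is built from one macromolecule component ``S`` and one ligand
(quencher) component ``Q``.  Complex species ``SsQq`` are defined by their
integer stoichiometric coefficients and a *cumulative* formation constant
referenced to the free components::

    s S + q Q  <->  SsQq        beta = [SsQq] / ([S]^s [Q]^q)

``log_kb`` stores log10(beta) on the molar scale.  Stepwise constants along
the S(Q)q ladder (the values usually tabulated for 1:1 and 1:2 binding) are
obtained with :func:`stepwise_log_k`.

Given total (analytical) concentrations, :func:`solve_mass_balance` finds
the free and complex concentrations satisfying both component balances by a
damped Newton-Raphson iteration in log free-concentration space, which keeps
every concentration strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import SolverError, ValidationError

__all__ = [
    "Component",
    "Species",
    "EquilibriumModel",
    "SolutionComposition",
    "SpeciationResult",
    "solve_mass_balance",
    "speciation_series",
    "stepwise_log_k",
]

FREE_S = (1, 0)
FREE_Q = (0, 1)


@dataclass(frozen=True)
class Component:
    """A chemical component of the equilibrium system."""

    name: str
    role: str  # "macromolecule" | "ligand"

    def __post_init__(self):
        if self.role not in ("macromolecule", "ligand"):
            raise ValidationError(f"unknown component role {self.role!r}")


@dataclass(frozen=True)
class Species:
    """A solution species S_s Q_q with cumulative formation constant.

    Free components are represented as the degenerate species (1,0) and
    (0,1) with ``log_kb == 0``.
    """

    s: int
    q: int
    log_kb: float = 0.0
    fluorescent: bool = True

    def __post_init__(self):
        if self.s < 0 or self.q < 0 or self.s + self.q < 1:
            raise ValidationError(f"invalid stoichiometry ({self.s},{self.q})")
        if self.key in (FREE_S, FREE_Q) and self.log_kb != 0.0:
            raise ValidationError("free components must have log_kb = 0")

    @property
    def key(self) -> tuple[int, int]:
        return (self.s, self.q)

    @property
    def is_free(self) -> bool:
        return self.key in (FREE_S, FREE_Q)

    @property
    def label(self) -> str:
        if self.key == FREE_S:
            return "S"
        if self.key == FREE_Q:
            return "Q"
        out = ""
        if self.s:
            out += "S" + (str(self.s) if self.s > 1 else "")
        if self.q:
            out += "Q" + (str(self.q) if self.q > 1 else "")
        return out


def _default_components():
    return (
        Component("S", "macromolecule"),
        Component("Q", "ligand"),
    )


@dataclass(frozen=True)
class EquilibriumModel:
    """Components plus the full species list (free species auto-added)."""

    species: tuple[Species, ...]
    components: tuple[Component, ...] = field(default_factory=_default_components)

    def __post_init__(self):
        roles = [c.role for c in self.components]
        if roles.count("macromolecule") != 1 or roles.count("ligand") != 1:
            raise ValidationError(
                "model needs exactly one macromolecule and one ligand component"
            )
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValidationError("component names must be unique")
        full = list(self.species)
        keys = [sp.key for sp in full]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (s,q) species")
        for free_key in (FREE_S, FREE_Q):
            if free_key not in keys:
                full.append(Species(*free_key, log_kb=0.0, fluorescent=free_key == FREE_S))
        # free species first, complexes in (s,q) order: stable indexing
        full.sort(key=lambda sp: (not sp.is_free, sp.s, sp.q))
        object.__setattr__(self, "species", tuple(full))

    @property
    def complexes(self) -> tuple[Species, ...]:
        return tuple(sp for sp in self.species if not sp.is_free)

    @property
    def fluorescent_species(self) -> tuple[Species, ...]:
        return tuple(sp for sp in self.species if sp.fluorescent)

    def with_log_kb(self, updates: dict[tuple[int, int], float]) -> "EquilibriumModel":
        """Return a copy with the cumulative log_kb of some complexes replaced."""
        new = []
        for sp in self.species:
            if sp.key in updates:
                if sp.is_free:
                    raise ValidationError("cannot set log_kb of a free component")
                new.append(replace(sp, log_kb=float(updates[sp.key])))
            else:
                new.append(sp)
        return EquilibriumModel(species=tuple(new), components=self.components)

    def species_index(self, key: tuple[int, int]) -> int:
        for i, sp in enumerate(self.species):
            if sp.key == key:
                return i
        raise KeyError(key)


def stepwise_log_k(model: EquilibriumModel) -> dict[tuple[int, int], float]:
    """Stepwise formation constants along the (1,q) ladder.

    log K_q = log beta_(1,q) - log beta_(1,q-1), with beta_(1,0) = 1.
    Species off the ladder keep their cumulative value.
    """
    betas = {sp.key: sp.log_kb for sp in model.species}
    out: dict[tuple[int, int], float] = {}
    for sp in model.complexes:
        s, q = sp.key
        prev = (s, q - 1)
        if s == 1 and q >= 2 and prev in betas:
            out[sp.key] = sp.log_kb - betas[prev]
        else:
            out[sp.key] = sp.log_kb
    return out


@dataclass(frozen=True)
class SolutionComposition:
    """Analytical totals for one solution (mol/L)."""

    total_S: float
    total_Q: float
    temperature: float = 25.0

    def __post_init__(self):
        if not self.total_S > 0:
            raise ValidationError("total_S must be > 0")
        if self.total_Q < 0:
            raise ValidationError("total_Q must be >= 0")


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium concentrations (mol/L) for one solution."""

    free: dict[str, float]  # keyed "S", "Q"
    complexes: dict[tuple[int, int], float]
    residual: float
    iterations: int = 0

    def concentration(self, key: tuple[int, int]) -> float:
        if key == FREE_S:
            return self.free["S"]
        if key == FREE_Q:
            return self.free["Q"]
        return self.complexes[key]

    def vector(self, model: EquilibriumModel, fluorescent_only: bool = False) -> np.ndarray:
        sps = model.fluorescent_species if fluorescent_only else model.species
        return np.array([self.concentration(sp.key) for sp in sps])


def _arrays(model: EquilibriumModel):
    s = np.array([sp.s for sp in model.species], dtype=float)
    q = np.array([sp.q for sp in model.species], dtype=float)
    beta = np.array([10.0 ** sp.log_kb for sp in model.species])
    return s, q, beta


def _result(model, conc, residual, iterations):
    free = {
        "S": float(conc[model.species_index(FREE_S)]),
        "Q": float(conc[model.species_index(FREE_Q)]),
    }
    complexes = {
        sp.key: float(conc[model.species_index(sp.key)]) for sp in model.complexes
    }
    return SpeciationResult(free=free, complexes=complexes, residual=residual,
                            iterations=iterations)


def solve_mass_balance(
    model: EquilibriumModel,
    comp: SolutionComposition,
    tol: float = 1e-10,
    max_iter: int = 100,
    initial_free: tuple[float, float] | None = None,
) -> SpeciationResult:
    """Solve both component mass balances for the free concentrations.

    Newton-Raphson on (ln[S], ln[Q]) with step halving whenever a full
    step increases the balance residual.  Convergence is declared when both
    relative balance errors fall below ``tol``.

    Parameters
    ----------
    initial_free
        Optional warm start (free S, free Q) in mol/L; defaults to the
        analytical totals.

    Raises
    ------
    SolverError
        If the residual is still above ``tol`` after ``max_iter`` iterations.
    """
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    ts, tq = comp.total_S, comp.total_Q

    s, q, beta = _arrays(model)

    if tq == 0.0:
        # no ligand anywhere: only q == 0 species can exist.  With a single
        # macromolecule free species this is exact and avoids log(0).
        conc = np.zeros_like(beta)
        conc[model.species_index(FREE_S)] = ts
        only_free_s = all(sp.key == FREE_S for sp in model.species if sp.q == 0)
        if not only_free_s:  # pragma: no cover - S-only polymers unsupported
            raise ValidationError("q=0 complexes unsupported at total_Q = 0")
        return _result(model, conc, 0.0, 0)

    if initial_free is not None and min(initial_free) > 0:
        x = np.log(np.asarray(initial_free, dtype=float))
    else:
        x = np.log(np.array([ts, tq]))

    scale = np.array([ts, tq])

    def balances(x):
        conc = beta * np.exp(s * x[0] + q * x[1])
        f = np.array([np.dot(s, conc) - ts, np.dot(q, conc) - tq])
        return conc, f

    conc, f = balances(x)
    res = float(np.max(np.abs(f) / scale))
    it = 0
    while res > tol and it < max_iter:
        it += 1
        jac = np.array([
            [np.dot(s * s, conc), np.dot(s * q, conc)],
            [np.dot(q * s, conc), np.dot(q * q, conc)],
        ])
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            raise SolverError("singular Jacobian in mass-balance solve",
                              residual=res)
        # limit huge log steps, then damp until the residual decreases
        step = np.clip(step, -5.0, 5.0)
        lam = 1.0
        for _ in range(40):
            conc_new, f_new = balances(x + lam * step)
            res_new = float(np.max(np.abs(f_new) / scale))
            if res_new < res or res_new <= tol:
                break
            lam *= 0.5
        x = x + lam * step
        conc, f, res = conc_new, f_new, res_new

    if res > tol:
        raise SolverError(
            f"mass balance did not converge in {max_iter} iterations "
            f"(residual {res:.3e})", residual=res)
    return _result(model, conc, res, it)


def speciation_series(
    model: EquilibriumModel,
    compositions: Sequence[SolutionComposition],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> list[SpeciationResult]:
    """Solve an ordered titration series, warm-starting each point from the
    previous solution (speed only; results match point-by-point solves)."""
    if len(compositions) == 0:
        raise ValidationError("need at least one composition")
    out: list[SpeciationResult] = []
    warm: tuple[float, float] | None = None
    for i, comp in enumerate(compositions):
        try:
            r = solve_mass_balance(model, comp, tol=tol, max_iter=max_iter,
                                   initial_free=warm)
        except SolverError as err:
            raise SolverError(f"speciation failed at point {i}: {err}",
                              residual=err.residual, point_index=i) from err
        out.append(r)
        if r.free["Q"] > 0:
            warm = (r.free["S"], r.free["Q"])
        else:
            warm = None
    return out
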