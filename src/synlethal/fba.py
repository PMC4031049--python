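"""Linear-programming core: FBA, growth-fixed FVA, and biomass-unconstrained FVA.

Flux balance analysis maximises the biomass flux nu subject to the
steady-state balance S.v = 0 and flux bounds. Because the optimum is
usually degenerate, per-reaction activity calls ("does reaction r carry
flux at maximum growth?") are solver-dependent under plain FBA; the
default ``flux_minimized`` mode therefore performs a secondary
minimisation of total absolute flux at the fixed optimal biomass value
(parsimonious FBA), which yields deterministic, backend-independent
activity patterns. ``raw`` mode returns the primary LP solution as-is.

The LP backend is pluggable behind :class:`LPBackend`; the default uses
scipy's HiGHS interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError

#: absolute flux threshold below which a flux is treated as zero
FLUX_EPSILON = 1e-9
#: relative growth threshold (fraction of wild-type) below which a mutant
#: is called non-viable
GROWTH_EPSILON = 1e-6


class SolverError(RuntimeError):
    """The LP backend failed for a reason other than infeasibility."""


@dataclass(frozen=True)
class LPSolution:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    x: np.ndarray | None
    objective: float | None
    message: str = ""


class LPBackend:
    """Minimal LP backend contract: minimise c.x s.t. A_eq.x = 0, lb<=x<=ub."""

    name = "abstract"

    def solve(
        self,
        c: np.ndarray,
        A_eq: np.ndarray,
        b_eq: np.ndarray,
        lb: np.ndarray,
        ub: np.ndarray,
    ) -> LPSolution:
        raise NotImplementedError


class ScipyHighsBackend(LPBackend):
    """HiGHS via scipy.optimize.linprog; ``method`` selects the algorithm."""

    def __init__(self, method: str = "highs"):
        self.method = method
        self.name = f"scipy-{method}"

    def solve(self, c, A_eq, b_eq, lb, ub) -> LPSolution:
        bounds = np.column_stack([lb, ub])
        res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method=self.method)
        if res.status == 0:
            return LPSolution("optimal", res.x, float(res.fun), res.message)
        if res.status == 2:
            return LPSolution("infeasible", None, None, res.message)
        if res.status == 3:
            return LPSolution("unbounded", None, None, res.message)
        return LPSolution("error", None, None, res.message)


DEFAULT_BACKEND = ScipyHighsBackend()


@dataclass(frozen=True)
class FluxState:
    """One FBA solution: flux vector, biomass objective and solver status."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible"
    mode: str  # "raw" | "flux_minimized"

    def flux(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def is_active(self, rxn_id: str, epsilon: float = FLUX_EPSILON) -> bool:
        return abs(self.fluxes[rxn_id]) > epsilon

    def active_reactions(self, epsilon: float = FLUX_EPSILON) -> set[str]:
        return {r for r, v in self.fluxes.items() if abs(v) > epsilon}


@dataclass(frozen=True)
class FluxRange:
    """Per-reaction flux intervals from a variability analysis."""

    ranges: dict[str, tuple[float, float]]
    constraint_note: str = ""

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]

    def active_capable(self, epsilon: float = FLUX_EPSILON) -> set[str]:
        """Reactions whose range extends beyond +-epsilon of zero."""
        return {
            r
            for r, (lo, hi) in self.ranges.items()
            if abs(lo) > epsilon or abs(hi) > epsilon
        }


def _lp_ingredients(model: MetabolicModel):
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    if not np.all(np.isfinite(lb)) or not np.all(np.isfinite(ub)):
        # replace infinities with a large box so HiGHS never sees an
        # unbounded column; 1e6 dwarfs any realistic flux (bounds are O(10))
        lb = np.where(np.isfinite(lb), lb, -1e6)
        ub = np.where(np.isfinite(ub), ub, 1e6)
    return S, rxn_ids, lb, ub


def fba(
    model: MetabolicModel,
    mode: str = "flux_minimized",
    backend: LPBackend = DEFAULT_BACKEND,
) -> FluxState:
    """Maximise biomass flux; optionally minimise total flux at that optimum.

    Parameters
    ----------
    model
        Model with a medium already applied (exchange bounds set).
    mode
        ``"flux_minimized"`` (default) re-solves for the minimum total
        absolute flux at the fixed optimal growth; ``"raw"`` reports the
        primary LP solution directly.
    """
    if mode not in ("raw", "flux_minimized"):
        raise ValueError(f"unknown FBA mode {mode!r}")
    S, rxn_ids, lb, ub = _lp_ingredients(model)
    n = len(rxn_ids)
    bm = rxn_ids.index(model.biomass_reaction.id)
    c = np.zeros(n)
    c[bm] = -1.0  # maximise biomass
    sol = backend.solve(c, S, np.zeros(S.shape[0]), lb, ub)
    if sol.status == "unbounded":
        raise ModelError(
            f"unbounded biomass objective in model {model.id!r}: missing exchange bounds?"
        )
    if sol.status == "error":
        raise SolverError(f"LP backend {backend.name} failed: {sol.message}")
    if sol.status == "infeasible":
        return FluxState({}, 0.0, "infeasible", mode)
    nu_star = max(0.0, -sol.objective)
    x = sol.x
    objective = float(x[bm])
    if mode == "flux_minimized":
        # fluxes from the parsimonious solve, objective from the primary
        # LP (the parsimonious biomass sits a hair inside its pin)
        x = _minimize_total_flux(S, lb, ub, bm, nu_star, backend)
    fluxes = {rid: float(x[j]) for j, rid in enumerate(rxn_ids)}
    return FluxState(fluxes, objective, "optimal", mode)


def _minimize_total_flux(S, lb, ub, bm, nu_star, backend: LPBackend) -> np.ndarray:
    """Secondary LP: min sum|v| with biomass fixed at its optimum.

    Standard variable splitting v = p - q with p, q >= 0. The biomass
    flux is pinned with a tiny absolute slack so the second solve cannot
    fail on the feasibility tolerance of the first.
    """
    n = S.shape[1]
    lb2 = lb.copy()
    ub2 = ub.copy()
    slack = 1e-9 + 1e-9 * abs(nu_star)
    lb2[bm] = max(lb[bm], nu_star - slack)
    ub2[bm] = min(ub[bm], nu_star + slack)
    p_lb = np.maximum(lb2, 0.0)
    p_ub = np.maximum(ub2, 0.0)
    q_lb = np.maximum(-ub2, 0.0)
    q_ub = np.maximum(-lb2, 0.0)
    A = np.hstack([S, -S])
    c = np.ones(2 * n)
    sol = backend.solve(
        c,
        A,
        np.zeros(S.shape[0]),
        np.concatenate([p_lb, q_lb]),
        np.concatenate([p_ub, q_ub]),
    )
    if sol.status != "optimal":
        raise SolverError(f"flux-minimisation LP failed: {sol.status} {sol.message}")
    return sol.x[:n] - sol.x[n:]


def _variability(
    model: MetabolicModel,
    biomass_lb: float,
    note: str,
    backend: LPBackend,
    reactions: list[str] | None = None,
) -> FluxRange:
    S, rxn_ids, lb, ub = _lp_ingredients(model)
    bm = rxn_ids.index(model.biomass_reaction.id)
    lb = lb.copy()
    lb[bm] = max(lb[bm], biomass_lb)
    if lb[bm] > ub[bm] + 1e-12:
        raise ModelError(
            f"FVA infeasible: biomass lower bound {lb[bm]} exceeds upper bound {ub[bm]}"
        )
    targets = rxn_ids if reactions is None else reactions
    index = {rid: j for j, rid in enumerate(rxn_ids)}
    ranges: dict[str, tuple[float, float]] = {}
    b_eq = np.zeros(S.shape[0])
    for rid in targets:
        j = index[rid]
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        lo = backend.solve(c, S, b_eq, lb, ub)
        hi = backend.solve(-c, S, b_eq, lb, ub)
        if lo.status != "optimal" or hi.status != "optimal":
            raise ModelError(
                f"FVA infeasible for reaction {rid!r} under constraint: {note}"
            )
        ranges[rid] = (float(lo.objective), float(-hi.objective))
    return FluxRange(ranges, note)


def fva(
    model: MetabolicModel,
    growth_fraction: float = 1.0,
    backend: LPBackend = DEFAULT_BACKEND,
    reactions: list[str] | None = None,
) -> FluxRange:
    """Flux variability with growth held at ``growth_fraction`` of its optimum.

    Two LPs per reaction (min and max) subject to nu >= growth_fraction * nu*.
    """
    if not 0.0 <= growth_fraction <= 1.0:
        raise ValueError("growth_fraction must lie in [0, 1]")
    wt = fba(model, mode="raw", backend=backend)
    if wt.status != "optimal" or wt.objective_value <= 0:
        raise ModelError("FVA requires a viable model (positive optimal growth)")
    floor = growth_fraction * wt.objective_value
    # shave the floor by a hair so the growth-fraction-1.0 case is not
    # knocked infeasible by the primary solve's own tolerance
    floor = floor * (1.0 - 1e-9)
    return _variability(
        model,
        floor,
        f"nu >= {growth_fraction:g} * {wt.objective_value:.6g}",
        backend,
        reactions,
    )


def unconstrained_growth_fva(
    model: MetabolicModel,
    backend: LPBackend = DEFAULT_BACKEND,
    reactions: list[str] | None = None,
) -> FluxRange:
    """Flux variability requiring only nu >= 0 on the biomass reaction.

    This deliberately ignores the attainable growth level: the resulting
    "active-capable" set (ranges extending beyond zero) is the maximal
    set of reactions that can carry flux in the medium under any
    non-optimal or low-growth scenario, a superset of the reactions
    active at maximum growth.
    """
    return _variability(model, 0.0, "nu >= 0 (growth unconstrained)", backend, reactions)


def is_viable(
    state: FluxState,
    wild_type_growth: float,
    growth_epsilon: float = GROWTH_EPSILON,
) -> bool:
    """Whether a flux state represents growth, relative to the wild type."""
    if wild_type_growth <= 0:
        raise ValueError("wild_type_growth must be positive")
    return state.status == "optimal" and state.objective_value > growth_epsilon * wild_type_growth
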