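"""Candidate-space construction and exhaustive single/double deletion screening.

The knockout candidate space is the intersection of three filters:
reactions with genetic information (non-empty GPR), reactions that can
carry flux in the medium regardless of the attainable growth level
(biomass-unconstrained FVA), and reactions that are not individually
essential. All unordered pairs of candidates are then deleted one pair
at a time (both flux directions zeroed) and the pair is called synthetic
lethal when the double mutant shows a no-growth phenotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from . import fba as _fba
from .fba import DEFAULT_BACKEND, FLUX_EPSILON, GROWTH_EPSILON, LPBackend
from .model import MetabolicModel, filter_gene_associated

# wild-type growth cache keyed by model content hash
_WT_CACHE: dict[tuple[str, str], float] = {}


def wild_type_growth(
    model: MetabolicModel,
    backend: LPBackend = DEFAULT_BACKEND,
) -> float:
    """Optimal biomass flux of the intact model, cached by content hash."""
    key = (model.content_hash(), backend.name)
    if key not in _WT_CACHE:
        state = _fba.fba(model, mode="raw", backend=backend)
        _WT_CACHE[key] = state.objective_value if state.status == "optimal" else 0.0
    return _WT_CACHE[key]


@dataclass(frozen=True)
class CandidateSet:
    """Reactions eligible for pairing, with a per-reaction reason trail."""

    reaction_ids: frozenset[str]
    provenance: dict[str, dict[str, bool]]  # rxn -> {gene_associated, active_capable, nonessential}

    def __iter__(self):
        return iter(sorted(self.reaction_ids))

    def __len__(self) -> int:
        return len(self.reaction_ids)


@dataclass(frozen=True)
class DeletionResult:
    deleted: frozenset[str]
    growth: float
    viable: bool
    status: str = "optimal"


def essential_reactions(
    model: MetabolicModel,
    backend: LPBackend = DEFAULT_BACKEND,
    growth_epsilon: float = GROWTH_EPSILON,
) -> set[str]:
    """Reactions whose single deletion abolishes growth."""
    wt = wild_type_growth(model, backend)
    if wt <= 0:
        raise ValueError("wild-type model does not grow; check the medium")
    essential: set[str] = set()
    for r in model.reactions:
        state = _fba.fba(model.knock_out([r.id]), mode="raw", backend=backend)
        if not _fba.is_viable(state, wt, growth_epsilon):
            essential.add(r.id)
    return essential


def candidate_reactions(
    model: MetabolicModel,
    backend: LPBackend = DEFAULT_BACKEND,
    flux_epsilon: float = FLUX_EPSILON,
    growth_epsilon: float = GROWTH_EPSILON,
    exclude_gene_less: bool = True,
) -> CandidateSet:
    """Intersect the gene-association, active-capable and nonessential filters.

    ``exclude_gene_less=False`` reproduces the alternative reading in
    which spontaneous/orphan reactions stay in the candidate space.
    """
    _, gene_less = filter_gene_associated(model)
    gene_less_set = set(gene_less) if exclude_gene_less else set()
    ranges = _fba.unconstrained_growth_fva(model, backend=backend)
    capable = ranges.active_capable(flux_epsilon)
    essential = essential_reactions(model, backend, growth_epsilon)
    provenance: dict[str, dict[str, bool]] = {}
    eligible: set[str] = set()
    for r in model.reactions:
        if r.is_exchange or r.is_biomass:
            continue
        flags = {
            "gene_associated": r.has_gpr or not exclude_gene_less,
            "active_capable": r.id in capable,
            "nonessential": r.id not in essential,
        }
        provenance[r.id] = flags
        if all(flags.values()) and r.id not in gene_less_set:
            eligible.add(r.id)
    return CandidateSet(frozenset(eligible), provenance)


def double_deletion_screen(
    model: MetabolicModel,
    candidates: CandidateSet,
    backend: LPBackend = DEFAULT_BACKEND,
    growth_epsilon: float = GROWTH_EPSILON,
) -> list[DeletionResult]:
    """Exhaustive FBA over all unordered candidate pairs.

    Deterministic lexicographic order; solver failures on individual
    pairs are recorded (status ``"failed"``) and the screen continues.
    """
    wt = wild_type_growth(model, backend)
    ordered = sorted(candidates.reaction_ids)
    results: list[DeletionResult] = []
    for a, b in itertools.combinations(ordered, 2):
        try:
            state = _fba.fba(model.knock_out([a, b]), mode="raw", backend=backend)
        except _fba.SolverError:
            results.append(DeletionResult(frozenset({a, b}), float("nan"), False, "failed"))
            continue
        growth = state.objective_value if state.status == "optimal" else 0.0
        viable = _fba.is_viable(state, wt, growth_epsilon) if state.status == "optimal" else False
        results.append(DeletionResult(frozenset({a, b}), growth, viable, state.status))
    return results


def synthetic_lethal_pairs(results: list[DeletionResult]) -> list[frozenset[str]]:
    """The inviable pairs of a double-deletion screen, in screen order."""
    return [r.deleted for r in results if r.status != "failed" and not r.viable]
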