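"""In-memory representation of a constraint-based metabolic model.

A :class:`MetabolicModel` holds metabolites, reactions (stoichiometry,
flux bounds in mmol/(gDW.h), GPR rule, pathway/subsystem label), the gene
set, and exactly one biomass reaction whose flux is the growth rate.
Exchange reactions follow the standard sign convention: negative flux is
uptake, positive flux is secretion.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .gpr import GeneAssociation, parse_gpr


class ModelError(ValueError):
    """Structural problem with a metabolic model."""


class ConfigurationError(ValueError):
    """Invalid medium / annotation / run configuration."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    is_external: bool = False


@dataclass(frozen=True)
class Reaction:
    """One reaction column of the stoichiometric matrix.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed). ``reversible`` is derived from the lower bound.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: GeneAssociation = field(default_factory=GeneAssociation)
    subsystem: str = ""
    is_exchange: bool = False
    is_biomass: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def has_gpr(self) -> bool:
        return not self.gpr.is_empty


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    id: str = "model"

    def __post_init__(self) -> None:
        self._validate()

    # -- structure -----------------------------------------------------

    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
        n_biomass = sum(r.is_biomass for r in self.reactions)
        if n_biomass != 1:
            raise ModelError(
                f"model {self.id!r} must have exactly one biomass reaction, found {n_biomass}"
            )
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def biomass_reaction(self) -> Reaction:
        return next(r for r in self.reactions if r.is_biomass)

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for r in self.reactions:
            out |= r.gpr.genes
        return out

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def reactions_for_gene(self, gene: str) -> list[str]:
        """Ids of reactions whose GPR mentions ``gene``."""
        return [r.id for r in self.reactions if gene in r.gpr.genes]

    # -- numerics ------------------------------------------------------

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S over internal (non-external) metabolites.

        Returns ``(S, metabolite_ids, reaction_ids)`` with rows ordered as
        the internal metabolites and columns as the reactions. External
        (boundary) metabolites are excluded from the steady-state balance.
        """
        internal = [m for m in self.metabolites if not m.is_external]
        row = {m.id: i for i, m in enumerate(internal)}
        S = np.zeros((len(internal), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                if met in row:
                    S[row[met], j] = coef
        return S, [m.id for m in internal], [r.id for r in self.reactions]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    # -- copies with modified bounds -----------------------------------

    def with_bounds(self, new_bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy of the model with the listed reactions' bounds replaced."""
        unknown = set(new_bounds) - set(self._rxn_index)
        if unknown:
            raise KeyError(f"unknown reactions {sorted(unknown)} in bounds update")
        reactions = [
            replace(r, lower_bound=new_bounds[r.id][0], upper_bound=new_bounds[r.id][1])
            if r.id in new_bounds
            else r
            for r in self.reactions
        ]
        return MetabolicModel(self.metabolites, reactions, id=self.id)

    def knock_out(self, rxn_ids: set[str] | frozenset[str] | list[str]) -> "MetabolicModel":
        """Copy with the listed reactions' flux forced to zero in both directions."""
        return self.with_bounds({rid: (0.0, 0.0) for rid in rxn_ids})

    def content_hash(self) -> str:
        """Stable digest of stoichiometry + bounds, used for result caching."""
        h = hashlib.sha256()
        for r in sorted(self.reactions, key=lambda r: r.id):
            h.update(r.id.encode())
            for met in sorted(r.stoichiometry):
                h.update(f"{met}:{r.stoichiometry[met]:.12g}".encode())
            h.update(f"{r.lower_bound:.12g},{r.upper_bound:.12g}".encode())
        return h.hexdigest()


@dataclass(frozen=True)
class Medium:
    """Environment definition as exchange-reaction uptake bounds.

    ``uptake_bounds`` maps exchange reaction id to a lower bound (negative
    values allow uptake). Exchanges absent from the map are closed to
    uptake (lower bound 0); secretion stays allowed everywhere.
    """

    uptake_bounds: dict[str, float]
    label: str = "medium"

    def with_compounds(self, extra: dict[str, float]) -> "Medium":
        merged = dict(self.uptake_bounds)
        merged.update(extra)
        return Medium(merged, label=self.label)


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy of ``model`` with exchange lower bounds set by ``medium``.

    Every exchange reaction not named in the medium gets lower bound 0
    (no uptake); upper bounds and non-exchange reactions are untouched.
    """
    exchange_ids = {r.id for r in model.exchange_reactions}
    bad = set(medium.uptake_bounds) - exchange_ids
    if bad:
        raise ConfigurationError(
            f"medium {medium.label!r} names non-exchange reactions: {sorted(bad)}"
        )
    updates: dict[str, tuple[float, float]] = {}
    for r in model.exchange_reactions:
        lb = medium.uptake_bounds.get(r.id, 0.0)
        updates[r.id] = (lb, r.upper_bound)
    return model.with_bounds(updates)


@dataclass(frozen=True)
class EssentialityAnnotation:
    """Experimental gene essentiality calls.

    ``unknown_policy`` controls how genes absent from the table (or marked
    unknown) are treated: ``"nonessential"`` (default) or ``"strict"``
    (raise).
    """

    gene_essentiality: dict[str, str]
    source: str = ""
    unknown_policy: str = "nonessential"

    VALID = ("essential", "nonessential", "unknown")

    def __post_init__(self) -> None:
        bad = {v for v in self.gene_essentiality.values() if v not in self.VALID}
        if bad:
            raise ConfigurationError(f"invalid essentiality statuses: {sorted(bad)}")
        if self.unknown_policy not in ("nonessential", "strict"):
            raise ConfigurationError(f"invalid unknown_policy {self.unknown_policy!r}")

    def is_essential(self, gene: str) -> bool:
        status = self.gene_essentiality.get(gene, "unknown")
        if status == "unknown":
            if self.unknown_policy == "strict":
                raise ConfigurationError(
                    f"gene {gene!r} has no essentiality annotation (strict policy)"
                )
            return False
        return status == "essential"


def filter_gene_associated(model: MetabolicModel) -> tuple[MetabolicModel, list[str]]:
    """Identify internal reactions lacking any gene association.

    Returns the model unchanged (fluxes of spontaneous/orphan reactions
    must remain available to carry metabolism) together with the sorted
    ids of non-exchange, non-biomass reactions with an empty GPR; callers
    exclude those ids from the knockout candidate space.
    """
    removed = sorted(
        r.id
        for r in model.reactions
        if not r.is_exchange and not r.is_biomass and not r.has_gpr
    )
    return model, removed


def drop_reactions(model: MetabolicModel, rxn_ids: list[str]) -> MetabolicModel:
    """Copy of the model with the listed reactions deleted outright.

    Provided to reproduce the alternative reading in which gene-less
    reactions are removed from the network, not just from the candidate
    space.
    """
    drop = set(rxn_ids)
    reactions = [r for r in model.reactions if r.id not in drop]
    return MetabolicModel(model.metabolites, reactions, id=model.id)


def parse_gpr_string(text: str | None) -> GeneAssociation:
    """Re-export of :func:`synlethal.gpr.parse_gpr` for convenience."""
    return parse_gpr(text)
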