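"""High-level screen object and its results container.

:class:`SyntheticLethalityScreen` bundles a metabolic model with a
growth medium and runs the whole analysis when fitted: candidate-space
construction, exhaustive double-deletion screening, plasticity vs
redundancy classification, the RSL fitness comparison and (when an
essentiality annotation is supplied) inconsistency flagging. The
returned :class:`ScreenResults` carries the classified pairs, class
counts, a tidy pair table and a text ``summary()``; pathway
entanglement, network distances and cross-environment comparisons hang
off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import fba as _fba
from . import screen as _screen
from .classify import (
    SLPair,
    class_counts,
    classify_pair,
    count_genes_and_complexes,
    fitness_comparison,
    flag_inconsistencies,
)
from .environments import (
    MediaPanel,
    PairSetComparison,
    SensitivityProfile,
    compare_pair_sets,
    media_sensitivity,
)
from .fba import DEFAULT_BACKEND, FLUX_EPSILON, GROWTH_EPSILON, LPBackend
from .model import EssentialityAnnotation, MetabolicModel, Medium, apply_medium
from .topology import (
    build_bipartite_graph,
    entanglement_graph,
    intra_inter_counts,
    mean_pair_distance,
)


class SyntheticLethalityScreen:
    """Exhaustive reaction-pair synthetic lethality screen of one model.

    Parameters
    ----------
    model
        The metabolic model (medium not yet applied).
    medium
        Environment to screen in; ``None`` uses the bounds already on
        the model.
    mode
        FBA mode for the reference optimum: ``"flux_minimized"``
        (default, deterministic activity calls) or ``"raw"``.
    annotation
        Optional experimental gene essentiality; enables the
        inconsistency rules.
    """

    def __init__(
        self,
        model: MetabolicModel,
        medium: Medium | None = None,
        mode: str = "flux_minimized",
        annotation: EssentialityAnnotation | None = None,
        backend: LPBackend = DEFAULT_BACKEND,
        flux_epsilon: float = FLUX_EPSILON,
        growth_epsilon: float = GROWTH_EPSILON,
        exclude_gene_less: bool = True,
        explicit_enzyme_pairs: set[frozenset[str]] | None = None,
    ):
        self.model = apply_medium(model, medium) if medium is not None else model
        self.medium = medium
        self.mode = mode
        self.annotation = annotation
        self.backend = backend
        self.flux_epsilon = flux_epsilon
        self.growth_epsilon = growth_epsilon
        self.exclude_gene_less = exclude_gene_less
        self.explicit_enzyme_pairs = explicit_enzyme_pairs

    def fit(self) -> "ScreenResults":
        """Run candidates -> double-deletion screen -> classification."""
        wt = _fba.fba(self.model, mode=self.mode, backend=self.backend)
        if wt.status != "optimal" or wt.objective_value <= 0:
            raise ValueError(
                "wild type does not grow in the supplied medium; nothing to screen"
            )
        candidates = _screen.candidate_reactions(
            self.model,
            backend=self.backend,
            flux_epsilon=self.flux_epsilon,
            growth_epsilon=self.growth_epsilon,
            exclude_gene_less=self.exclude_gene_less,
        )
        deletions = _screen.double_deletion_screen(
            self.model, candidates, backend=self.backend,
            growth_epsilon=self.growth_epsilon,
        )
        lethal = _screen.synthetic_lethal_pairs(deletions)
        pairs = [
            fitness_comparison(
                classify_pair(
                    p, wt, self.model, backend=self.backend,
                    flux_epsilon=self.flux_epsilon,
                )
            )
            for p in lethal
        ]
        if self.annotation is not None:
            pairs = flag_inconsistencies(
                pairs, self.annotation, self.model,
                explicit_enzyme_pairs=self.explicit_enzyme_pairs,
            )
        return ScreenResults(
            screen=self,
            wild_type=wt,
            candidates=candidates,
            deletion_results=deletions,
            pairs=pairs,
        )


@dataclass
class ScreenResults:
    """Classified output of one synthetic lethality screen."""

    screen: SyntheticLethalityScreen
    wild_type: _fba.FluxState
    candidates: _screen.CandidateSet
    deletion_results: list[_screen.DeletionResult]
    pairs: list[SLPair]

    @property
    def model(self) -> MetabolicModel:
        return self.screen.model

    @property
    def wild_type_growth(self) -> float:
        return self.wild_type.objective_value

    @property
    def n_pairs_tested(self) -> int:
        return len(self.deletion_results)

    @property
    def class_counts(self) -> dict[str, int]:
        return class_counts(self.pairs)

    @property
    def sl_pairs(self) -> set[frozenset[str]]:
        return {p.members for p in self.pairs}

    # -- tables --------------------------------------------------------

    def pair_table(self) -> pd.DataFrame:
        """Tidy per-pair table (supplementary-table style)."""
        rows = [
            {
                "rxn_a": p.rxn_a,
                "rxn_b": p.rxn_b,
                "subtype": p.subtype,
                "active": p.active_reaction or "",
                "backup": p.backup_reaction or "",
                "fitness_increased": p.fitness_increased,
                "wt_flux_a": p.wt_flux_a,
                "wt_flux_b": p.wt_flux_b,
                "growth_wt": p.growth_wt,
                "growth_ko_a": p.growth_ko_a,
                "growth_ko_b": p.growth_ko_b,
                "genes_a": p.genes_a.to_string(),
                "genes_b": p.genes_b.to_string(),
                "pathway_a": p.pathway_a,
                "pathway_b": p.pathway_b,
                "inconsistency_reason": p.inconsistency_reason,
            }
            for p in sorted(self.pairs, key=lambda p: (p.rxn_a, p.rxn_b))
        ]
        return pd.DataFrame(rows)

    def candidate_table(self) -> pd.DataFrame:
        rows = [
            {"reaction": rid, **flags, "candidate": rid in self.candidates.reaction_ids}
            for rid, flags in sorted(self.candidates.provenance.items())
        ]
        return pd.DataFrame(rows)

    def screen_table(self) -> pd.DataFrame:
        rows = []
        for d in self.deletion_results:
            a, b = sorted(d.deleted)
            rows.append(
                {"rxn_a": a, "rxn_b": b, "growth_double": d.growth,
                 "viable": d.viable, "status": d.status}
            )
        return pd.DataFrame(rows)

    def gene_complex_counts(self) -> dict[str, tuple[int, int]]:
        return count_genes_and_complexes(self.pairs, self.model)

    # -- topology ------------------------------------------------------

    def bipartite_graph(self, exclude_metabolites: set[str] | None = None):
        return build_bipartite_graph(self.model, exclude_metabolites)

    def entanglement(self):
        return entanglement_graph(self.pairs)

    def distances(self, exclude_metabolites: set[str] | None = None):
        graph = self.bipartite_graph(exclude_metabolites)
        return mean_pair_distance(self.pairs, graph)

    def intra_inter(self) -> dict[str, dict[str, int]]:
        return intra_inter_counts(self.pairs)

    # -- environments --------------------------------------------------

    def media_sensitivity(self, panel: MediaPanel) -> SensitivityProfile:
        base = self.screen
        # each panel medium fully resets the exchange bounds, so the
        # screen medium on self.model is simply overwritten
        return media_sensitivity(
            base.model,
            self.pairs,
            panel,
            mode=base.mode,
            backend=base.backend,
            growth_epsilon=base.growth_epsilon,
        )

    def compare(self, other: "ScreenResults") -> PairSetComparison:
        return compare_pair_sets(self.pairs, other.pairs)

    # -- presentation --------------------------------------------------

    def summary(self) -> str:
        counts = self.class_counts
        ii = self.intra_inter()
        lines = [
            "Synthetic lethality screen",
            "==========================",
            f"model:               {self.model.id}",
            f"medium:              {self.screen.medium.label if self.screen.medium else '(model bounds)'}",
            f"FBA mode:            {self.screen.mode}",
            f"wild-type growth:    {self.wild_type_growth:.6g}",
            f"candidate reactions: {len(self.candidates)}",
            f"pairs tested:        {self.n_pairs_tested}",
            f"synthetic lethal:    {len(self.pairs)}",
            "",
            "class     pairs",
        ]
        for cls in ("RSL", "RSL_I", "PSL", "PSL_I"):
            lines.append(f"{cls:<9} {counts.get(cls, 0):>5}")
        lines.append("")
        lines.append("base class  intra  inter (pathway)")
        for base in ("RSL", "PSL"):
            intra = ii.get(base, {}).get("intra", 0)
            inter = ii.get(base, {}).get("inter", 0)
            lines.append(f"{base:<11} {intra:>5}  {inter:>5}")
        fit_up = sum(1 for p in self.pairs if p.fitness_increased)
        lines.append("")
        lines.append(f"RSL pairs with fitness gain from parallel use: {fit_up}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ScreenResults: {len(self.pairs)} SL pairs of "
            f"{self.n_pairs_tested} tested, wt growth {self.wild_type_growth:.4g}>"
        )
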