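"""Plasticity/redundancy classification of synthetic lethal pairs.

A synthetic lethal (SL) pair is *plasticity* (PSL) when exactly one
member carries flux in the reference optimum: the zero-flux member is a
dormant backup that switches on when its active partner is deleted. It
is *redundancy* (RSL) when both members carry flux in parallel; for most
RSL pairs the parallel use increases fitness (maximal biomass rate) over
either branch alone. Pairs contradicted by in-vivo gene essentiality are
flagged as inconsistencies (PSL_I / RSL_I) under a three-case rule:
essentiality of a gene that regulates several reactions may refer to the
other reactions it controls, so only single-reaction essential genes
make a pair inconsistent. PSL pairs whose two members are associated
through isoenzymes or a single multifunctional enzyme are additionally
flagged, since reaction-level lethality then collapses onto one genetic
unit in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import fba as _fba
from .fba import DEFAULT_BACKEND, FLUX_EPSILON, FluxState, LPBackend
from .gpr import GeneAssociation
from .model import EssentialityAnnotation, MetabolicModel


class ClassificationError(RuntimeError):
    """A pair could not be assigned a subtype (e.g. both members at zero flux)."""


@dataclass(frozen=True)
class SLPair:
    """One classified coessential reaction pair."""

    rxn_a: str
    rxn_b: str
    subtype: str  # "PSL" | "RSL" | "PSL_I" | "RSL_I"
    wt_flux_a: float
    wt_flux_b: float
    growth_wt: float
    growth_ko_a: float
    growth_ko_b: float
    active_reaction: str | None = None  # PSL only
    backup_reaction: str | None = None  # PSL only
    fitness_increased: bool | None = None  # RSL only
    genes_a: GeneAssociation = field(default_factory=GeneAssociation)
    genes_b: GeneAssociation = field(default_factory=GeneAssociation)
    pathway_a: str = ""
    pathway_b: str = ""
    inconsistency_reason: str = ""

    @property
    def members(self) -> frozenset[str]:
        return frozenset({self.rxn_a, self.rxn_b})

    @property
    def base_subtype(self) -> str:
        """Subtype with the inconsistency mark stripped: PSL or RSL."""
        return self.subtype.removesuffix("_I")

    @property
    def is_inconsistent(self) -> bool:
        return self.subtype.endswith("_I")

    @property
    def is_intra_pathway(self) -> bool:
        return self.pathway_a == self.pathway_b


def classify_pair(
    pair: frozenset[str] | tuple[str, str],
    wt: FluxState,
    model: MetabolicModel,
    backend: LPBackend = DEFAULT_BACKEND,
    flux_epsilon: float = FLUX_EPSILON,
) -> SLPair:
    """Assign PSL or RSL to one synthetic lethal pair.

    ``wt`` must be the reference FBA solution (``flux_minimized`` mode
    recommended: under raw FBA the activity pattern depends on which of
    the degenerate optima the solver happened to return).
    """
    a, b = sorted(pair)
    fa, fb = wt.flux(a), wt.flux(b)
    active_a = abs(fa) > flux_epsilon
    active_b = abs(fb) > flux_epsilon
    ga = _fba.fba(model.knock_out([a]), mode="raw", backend=backend)
    gb = _fba.fba(model.knock_out([b]), mode="raw", backend=backend)
    growth_a = ga.objective_value if ga.status == "optimal" else 0.0
    growth_b = gb.objective_value if gb.status == "optimal" else 0.0
    rxn_a, rxn_b = model.reaction(a), model.reaction(b)
    common = dict(
        rxn_a=a,
        rxn_b=b,
        wt_flux_a=fa,
        wt_flux_b=fb,
        growth_wt=wt.objective_value,
        growth_ko_a=growth_a,
        growth_ko_b=growth_b,
        genes_a=rxn_a.gpr,
        genes_b=rxn_b.gpr,
        pathway_a=rxn_a.subsystem,
        pathway_b=rxn_b.subsystem,
    )
    if active_a and active_b:
        return SLPair(subtype="RSL", **common)
    if active_a != active_b:
        active, backup = (a, b) if active_a else (b, a)
        return SLPair(
            subtype="PSL", active_reaction=active, backup_reaction=backup, **common
        )
    raise ClassificationError(
        f"pair ({a}, {b}) has zero flux on both members in the reference optimum; "
        "this contradicts candidacy -- review the FBA mode (raw optima are degenerate)"
    )


def backup_activation_check(
    pair: SLPair,
    model: MetabolicModel,
    backend: LPBackend = DEFAULT_BACKEND,
    mode: str = "flux_minimized",
) -> tuple[float, float]:
    """Verify the backup law for a PSL pair.

    Deleting the active member must leave a viable optimum in which the
    backup carries flux; returns ``(backup_flux_after_ko, growth_after_ko)``.
    """
    if pair.base_subtype != "PSL":
        raise ValueError("backup_activation_check applies to PSL pairs only")
    assert pair.active_reaction is not None and pair.backup_reaction is not None
    state = _fba.fba(model.knock_out([pair.active_reaction]), mode=mode, backend=backend)
    if state.status != "optimal":
        raise ClassificationError(
            f"single knockout of active member {pair.active_reaction!r} is infeasible"
        )
    return state.flux(pair.backup_reaction), state.objective_value


def fitness_comparison(
    pair: SLPair,
    tolerance: float = 1e-9,
) -> SLPair:
    """RSL fitness check: does parallel use beat either branch alone?

    Sets ``fitness_increased`` to True when wild-type growth strictly
    exceeds the best single-knockout growth; False means growth is
    unchanged when one branch is removed. PSL pairs are returned
    untouched (not applicable).
    """
    if pair.base_subtype != "RSL":
        return pair
    increased = pair.growth_wt > max(pair.growth_ko_a, pair.growth_ko_b) + tolerance
    return replace(pair, fitness_increased=increased)


# ---------------------------------------------------------------------------
# inconsistency rules
# ---------------------------------------------------------------------------


def _member_essential_single_reaction(
    gpr: GeneAssociation, ann: EssentialityAnnotation, model: MetabolicModel
) -> tuple[bool, bool]:
    """(has an essential gene, every essential gene maps to only one reaction)."""
    essentials = [g for g in gpr.genes if ann.is_essential(g)]
    if not essentials:
        return False, False
    single_only = all(len(model.reactions_for_gene(g)) <= 1 for g in essentials)
    return True, single_only


def _isoenzyme_or_multifunctional(pair: SLPair) -> str:
    """Detect shared enzymatic identity between the two members.

    multifunctional: both members carry the identical single-gene GPR
    (one enzyme catalyses both reactions). isoenzymes: both members'
    GPRs are the same OR-family of >= 2 gene units (the same set of
    isoenzymes catalyses both reactions). Returns a reason string or "".
    """
    ua = pair.genes_a.gene_units()
    ub = pair.genes_b.gene_units()
    if not ua or not ub:
        return ""
    if len(ua) == 1 and len(ub) == 1 and ua == ub and len(ua[0]) == 1:
        return "multifunctional_enzyme"
    if len(ua) >= 2 and set(ua) == set(ub):
        return "isoenzymes"
    return ""


def flag_inconsistencies(
    pairs: list[SLPair],
    ann: EssentialityAnnotation,
    model: MetabolicModel,
    explicit_enzyme_pairs: set[frozenset[str]] | None = None,
) -> list[SLPair]:
    """Promote subtypes to PSL_I / RSL_I per the gene-essentiality rules.

    Case 1: both members' genes nonessential -> subtype kept. Case 2:
    one member governed by an experimentally essential gene -> the pair
    is inconsistent iff every such gene regulates only that one reaction
    (otherwise the essentiality may refer to the other reactions the
    gene controls). Case 3: both members essential-gene-governed ->
    inconsistent unless both sides' essential genes all regulate more
    than one reaction. In addition, PSL pairs whose members share enzyme
    identity (isoenzymes or one multifunctional enzyme) are flagged;
    ``explicit_enzyme_pairs`` names pairs to flag on curated evidence,
    bypassing the structural heuristic.
    """
    explicit = explicit_enzyme_pairs or set()
    out: list[SLPair] = []
    for p in pairs:
        reason = ""
        has_a, single_a = _member_essential_single_reaction(p.genes_a, ann, model)
        has_b, single_b = _member_essential_single_reaction(p.genes_b, ann, model)
        if has_a and has_b:
            if single_a or single_b:
                reason = "both_members_essential_genes"
        elif has_a or has_b:
            if (has_a and single_a) or (has_b and single_b):
                reason = "single_reaction_essential_gene"
        if not reason and p.base_subtype == "PSL":
            if p.members in explicit:
                reason = "curated_enzyme_pair"
            else:
                reason = _isoenzyme_or_multifunctional(p)
        if reason:
            out.append(
                replace(p, subtype=p.base_subtype + "_I", inconsistency_reason=reason)
            )
        else:
            out.append(replace(p, subtype=p.base_subtype, inconsistency_reason=""))
    return out


def count_genes_and_complexes(
    pairs: list[SLPair], model: MetabolicModel
) -> dict[str, tuple[int, int]]:
    """Distinct reactions and gene units per base subtype.

    A gene unit is a maximal AND-subtree of a GPR: an enzyme complex
    counts once, OR-alternative isoenzymes count separately. Returns
    ``{subtype: (n_reactions, n_gene_units)}`` over base subtypes
    (inconsistent pairs counted with their base class).
    """
    by_subtype: dict[str, tuple[set[str], set[frozenset[str]]]] = {}
    for p in pairs:
        rxns, units = by_subtype.setdefault(p.base_subtype, (set(), set()))
        for rid in (p.rxn_a, p.rxn_b):
            rxns.add(rid)
            for unit in model.reaction(rid).gpr.gene_units():
                units.add(unit)
    return {k: (len(rxns), len(units)) for k, (rxns, units) in by_subtype.items()}


def class_counts(pairs: list[SLPair]) -> dict[str, int]:
    """Histogram over the four subtype classes (the Fig.-2-style summary)."""
    counts = {"RSL": 0, "RSL_I": 0, "PSL": 0, "PSL_I": 0}
    for p in pairs:
        counts[p.subtype] = counts.get(p.subtype, 0) + 1
    return counts
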