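"""Media panels, enriched/overconstrained media, and cross-environment analysis.

Minimal media are built combinatorially: a fixed set of mineral salts
plus one variable source each of carbon, nitrogen, phosphorus and
sulfur; one element is varied at a time over its candidate compounds
while the other three stay at the reference choice, and media in which
the wild type cannot grow are filtered out. Enriched media open extra
uptake exchanges (default -10 mmol/(gDW.h)). Overconstrained media
tighten uptake bounds so the maximal growth drops to a fraction of its
reference value, either through the mineral salts or through the four
basic element sources, using FVA-derived uptake limits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from . import fba as _fba
from .classify import SLPair, classify_pair, fitness_comparison
from .fba import DEFAULT_BACKEND, GROWTH_EPSILON, LPBackend
from .model import ConfigurationError, MetabolicModel, Medium, apply_medium


@dataclass
class MediaPanel:
    """Viable minimal media plus a construction log.

    ``construction_log`` records, per constructed medium, which element
    was varied and to which compound; ``viable_flags`` covers all
    constructed media, including those filtered out.
    """

    media: list[Medium]
    construction_log: list[dict]
    viable_flags: dict[str, bool]

    @property
    def n_constructed(self) -> int:
        return len(self.construction_log)

    @property
    def n_viable(self) -> int:
        return len(self.media)


def build_minimal_media_panel(
    salts: Medium,
    sources: dict[str, list[str]],
    reference: dict[str, str],
    model: MetabolicModel,
    uptake_bound: float = -10.0,
    backend: LPBackend = DEFAULT_BACKEND,
    growth_epsilon: float = GROWTH_EPSILON,
) -> MediaPanel:
    """One-medium-per-(element, candidate) panel, viability-filtered by FBA.

    ``sources`` maps each element (C/N/P/S) to its candidate exchange
    reactions; ``reference`` picks the fixed compound per element. The
    reference combination itself is included once and must be viable.
    """
    for element in reference:
        if element not in sources:
            raise ConfigurationError(f"reference element {element!r} not in sources")
    ref_bounds = dict(salts.uptake_bounds)
    for element, compound in reference.items():
        if compound in model:
            ref_bounds[compound] = uptake_bound
    ref_medium = Medium(ref_bounds, label="reference")
    wt = _fba.fba(apply_medium(model, ref_medium), mode="raw", backend=backend)
    if wt.status != "optimal" or wt.objective_value <= 0:
        raise ConfigurationError("reference medium is not viable")

    media: list[Medium] = [ref_medium]
    log: list[dict] = [
        {"medium_label": "reference", "varied_element": "", "compound": ""}
    ]
    viable = {"reference": True}
    for element in sorted(sources):
        for compound in sources[element]:
            if compound == reference.get(element):
                continue  # already covered by the reference medium
            label = f"{element}:{compound}"
            bounds = dict(salts.uptake_bounds)
            for other, ref_compound in reference.items():
                if other != element and ref_compound in model:
                    bounds[ref_compound] = uptake_bound
            log.append(
                {"medium_label": label, "varied_element": element, "compound": compound}
            )
            if compound not in model:
                viable[label] = False
                continue
            bounds[compound] = uptake_bound
            medium = Medium(bounds, label=label)
            state = _fba.fba(apply_medium(model, medium), mode="raw", backend=backend)
            ok = (
                state.status == "optimal"
                and state.objective_value > growth_epsilon * wt.objective_value
            )
            viable[label] = ok
            if ok:
                media.append(medium)
    return MediaPanel(media, log, viable)


def enrich_medium(
    base: Medium,
    compounds: list[str],
    model: MetabolicModel,
    uptake_bound: float = -10.0,
) -> Medium:
    """Open uptake of extra compounds on top of an existing medium.

    Compounds without a matching exchange reaction in the model are
    skipped with a warning (some rich-medium components simply cannot be
    taken up by a given reconstruction).
    """
    extra: dict[str, float] = {}
    for ex in compounds:
        if ex not in model or not model.reaction(ex).is_exchange:
            warnings.warn(
                f"compound exchange {ex!r} absent from model {model.id!r}; skipped",
                stacklevel=2,
            )
            continue
        extra[ex] = uptake_bound
    enriched = base.with_compounds(extra)
    return Medium(enriched.uptake_bounds, label=f"{base.label}+enriched")


def overconstrain_by_growth(
    model: MetabolicModel,
    reference: Medium,
    fraction: float,
    target: str,
    salt_exchanges: list[str] | None = None,
    source_exchanges: list[str] | None = None,
    backend: LPBackend = DEFAULT_BACKEND,
) -> Medium:
    """Tighten uptake bounds so maximal growth falls to ``fraction`` of reference.

    ``target="mineral_salts"``: FVA with biomass fixed at fraction * nu*
    yields each salt exchange's maximal uptake (most negative flux);
    those become the new lower bounds while other compounds keep their
    reference bounds. ``target="basic_sources"``: FVA at maximal growth
    gives the uptake limit of each of the four element sources; the new
    bounds are those limits scaled by ``fraction``, salts untouched.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if target not in ("mineral_salts", "basic_sources"):
        raise ValueError(f"unknown overconstrain target {target!r}")
    targets = salt_exchanges if target == "mineral_salts" else source_exchanges
    if not targets:
        raise ConfigurationError(f"no exchanges listed for target {target!r}")
    constrained = apply_medium(model, reference)
    wt = _fba.fba(constrained, mode="raw", backend=backend)
    if wt.status != "optimal" or wt.objective_value <= 0:
        raise ConfigurationError("reference medium is not viable")
    nu = wt.objective_value
    fix = fraction * nu if target == "mineral_salts" else nu
    # pin biomass at the target growth and read off uptake variability
    bm = constrained.biomass_reaction.id
    pinned = constrained.with_bounds({bm: (fix * (1 - 1e-9), fix)})
    ranges = _fba.fva(pinned, growth_fraction=1.0, backend=backend, reactions=list(targets))
    new_bounds = dict(reference.uptake_bounds)
    for ex in targets:
        max_uptake = ranges[ex][0]  # most negative feasible flux
        if target == "basic_sources":
            max_uptake *= fraction
        new_bounds[ex] = min(max_uptake, 0.0)
    return Medium(new_bounds, label=f"{reference.label}|{target}@{fraction:g}")


@dataclass
class SensitivityProfile:
    """Per-pair lethality/subtype bookkeeping across a media panel."""

    counts: dict[frozenset[str], dict[str, float]]

    def table(self) -> list[dict]:
        rows = []
        for pair, c in self.counts.items():
            a, b = sorted(pair)
            rows.append({"rxn_a": a, "rxn_b": b, **c})
        rows.sort(key=lambda r: (-r["fraction_lethal"], -r["fraction_psl"], r["rxn_a"], r["rxn_b"]))
        return rows


def media_sensitivity(
    model: MetabolicModel,
    pairs: list[SLPair],
    panel: MediaPanel,
    mode: str = "flux_minimized",
    backend: LPBackend = DEFAULT_BACKEND,
    growth_epsilon: float = GROWTH_EPSILON,
) -> SensitivityProfile:
    """Re-test and re-classify each SL pair in every viable panel medium.

    For each medium: the pair is re-screened for lethality against that
    medium's wild type; if lethal, it is re-classified (PSL vs RSL)
    using the medium's own reference optimum under the same FBA mode as
    the original screen. Media where the solver fails are excluded from
    that pair's denominators.
    """
    counts = {
        p.members: {
            "n_media_tested": 0.0,
            "n_media_lethal": 0.0,
            "n_media_psl": 0.0,
        }
        for p in pairs
    }
    for medium in panel.media:
        conditioned = apply_medium(model, medium)
        wt = _fba.fba(conditioned, mode=mode, backend=backend)
        if wt.status != "optimal" or wt.objective_value <= 0:
            continue  # panel media should be viable; skip defensively
        for p in pairs:
            try:
                ko = _fba.fba(
                    conditioned.knock_out(sorted(p.members)), mode="raw", backend=backend
                )
            except _fba.SolverError:
                continue
            c = counts[p.members]
            c["n_media_tested"] += 1
            lethal = not (
                ko.status == "optimal"
                and ko.objective_value > growth_epsilon * wt.objective_value
            )
            if not lethal:
                continue
            c["n_media_lethal"] += 1
            try:
                reclassified = classify_pair(p.members, wt, conditioned, backend=backend)
            except Exception:
                continue
            if reclassified.base_subtype == "PSL":
                c["n_media_psl"] += 1
    for c in counts.values():
        c["fraction_lethal"] = (
            c["n_media_lethal"] / c["n_media_tested"] if c["n_media_tested"] else math.nan
        )
        c["fraction_psl"] = (
            c["n_media_psl"] / c["n_media_lethal"] if c["n_media_lethal"] else math.nan
        )
    return SensitivityProfile(counts)


@dataclass
class PairSetComparison:
    """Reference-vs-alternative screen comparison.

    conserved: lethal in both; rescued: lethal in the reference only;
    novel: lethal in the alternative only. Subtype switches and PSL
    active/backup role swaps are evaluated on conserved pairs only.
    """

    conserved: list[frozenset[str]]
    rescued: list[frozenset[str]]
    novel: list[frozenset[str]]
    subtype_switches: list[tuple[frozenset[str], str, str]]
    activity_switches: list[frozenset[str]]

    @property
    def n_conserved(self) -> int:
        return len(self.conserved)

    @property
    def n_rescued(self) -> int:
        return len(self.rescued)


def compare_pair_sets(
    reference: list[SLPair], alternative: list[SLPair]
) -> PairSetComparison:
    """Partition two classified pair sets and detect subtype/role switches."""
    ref = {p.members: p for p in reference}
    alt = {p.members: p for p in alternative}
    conserved = sorted(ref.keys() & alt.keys(), key=sorted)
    rescued = sorted(ref.keys() - alt.keys(), key=sorted)
    novel = sorted(alt.keys() - ref.keys(), key=sorted)
    switches: list[tuple[frozenset[str], str, str]] = []
    activity: list[frozenset[str]] = []
    for key in conserved:
        pr, pa = ref[key], alt[key]
        if pr.base_subtype != pa.base_subtype:
            switches.append((key, pr.base_subtype, pa.base_subtype))
        elif pr.base_subtype == "PSL" and pr.active_reaction != pa.active_reaction:
            activity.append(key)
    return PairSetComparison(conserved, rescued, novel, switches, activity)
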