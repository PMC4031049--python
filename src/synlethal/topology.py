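"""Bipartite network representation, reaction distances, pathway entanglement.

Metabolism is modelled as a bipartite directed graph: metabolite nodes
and reaction nodes, with an edge metabolite->reaction when the reaction
consumes the metabolite and reaction->metabolite when it produces it
(reversible reactions contribute edges in both orientations). The
distance between two reactions is the minimal number of *intermediate
nodes* (metabolites and reactions, excluding the endpoints) visited on a
directed path, so two reactions coupled through one shared metabolite
are at distance 1. Pair distances are symmetrised by taking the minimum
over both orientations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .classify import SLPair
from .model import MetabolicModel

UNANNOTATED = "unannotated"


def build_bipartite_graph(
    model: MetabolicModel,
    exclude_metabolites: set[str] | None = None,
) -> nx.DiGraph:
    """Directed bipartite metabolite/reaction graph of a model.

    ``exclude_metabolites`` optionally drops currency hubs (ATP, H2O, ...)
    whose shared use would otherwise shortcut paths; none are excluded by
    default and any exclusion is recorded in the graph metadata.
    """
    excluded = exclude_metabolites or set()
    g = nx.DiGraph(model_id=model.id, excluded_metabolites=sorted(excluded))
    for m in model.metabolites:
        if m.id not in excluded:
            g.add_node(("M", m.id), kind="metabolite")
    for r in model.reactions:
        g.add_node(("R", r.id), kind="reaction")
        for met, coef in r.stoichiometry.items():
            if met in excluded:
                continue
            mn, rn = ("M", met), ("R", r.id)
            if coef < 0:  # consumed
                g.add_edge(mn, rn)
                if r.reversible:
                    g.add_edge(rn, mn)
            elif coef > 0:  # produced
                g.add_edge(rn, mn)
                if r.reversible:
                    g.add_edge(mn, rn)
    return g


def reaction_distance(graph: nx.DiGraph, r1: str, r2: str) -> float:
    """Symmetrised intermediate-node distance between two reactions.

    Reactions sharing any metabolite (substrate or product, in either
    role) are *directly connected* at distance 1. Otherwise the
    distance is the smaller, over both orientations, of the number of
    intermediate nodes on the shortest directed path (Dijkstra on the
    unweighted graph); 0 for a reaction with itself, ``inf`` when the
    reactions share nothing and neither orientation admits a path.
    """
    n1, n2 = ("R", r1), ("R", r2)
    for node, rid in ((n1, r1), (n2, r2)):
        if node not in graph:
            raise KeyError(f"reaction {rid!r} not in graph")
    if r1 == r2:
        return 0.0
    neighbours1 = set(graph.successors(n1)) | set(graph.predecessors(n1))
    neighbours2 = set(graph.successors(n2)) | set(graph.predecessors(n2))
    if neighbours1 & neighbours2:
        return 1.0
    best = math.inf
    for src, dst in ((n1, n2), (n2, n1)):
        try:
            hops = nx.dijkstra_path_length(graph, src, dst)
        except nx.NetworkXNoPath:
            continue
        best = min(best, hops - 1)  # intermediate nodes = edges - 1
    return best


def mean_pair_distance(
    pairs: list[SLPair], graph: nx.DiGraph
) -> dict[str, dict[str, float]]:
    """Average distance and direct-connection fraction per base subtype.

    Only finite distances enter the mean; the fraction of pairs at
    distance 1 (sharing a metabolite along the flux direction) is
    reported alongside. Subtypes with no finite distance report NaN.
    """
    acc: dict[str, list[float]] = {}
    for p in pairs:
        acc.setdefault(p.base_subtype, []).append(
            reaction_distance(graph, p.rxn_a, p.rxn_b)
        )
    out: dict[str, dict[str, float]] = {}
    for subtype, dists in acc.items():
        finite = [d for d in dists if math.isfinite(d)]
        out[subtype] = {
            "n_pairs": float(len(dists)),
            "n_finite": float(len(finite)),
            "mean_distance": sum(finite) / len(finite) if finite else math.nan,
            "fraction_direct": (
                sum(1 for d in finite if d == 1.0) / len(dists) if dists else math.nan
            ),
        }
    return out


@dataclass
class EntanglementGraph:
    """Pathway-level summary of SL interactions.

    ``psl`` is directed (backup pathway -> active pathway), ``rsl`` is
    undirected; edge weights count pairs and self-loops mark
    intra-pathway pairs.
    """

    psl: nx.DiGraph
    rsl: nx.Graph

    def total_weight(self, subtype: str) -> int:
        g = self.psl if subtype == "PSL" else self.rsl
        return sum(d["weight"] for _, _, d in g.edges(data=True))

    def edge_table(self) -> list[dict]:
        rows = []
        for u, v, d in self.psl.edges(data=True):
            rows.append(
                {"source_pathway": u, "target_pathway": v, "subtype": "PSL",
                 "weight": d["weight"], "directed": True}
            )
        for u, v, d in self.rsl.edges(data=True):
            a, b = sorted((u, v))
            rows.append(
                {"source_pathway": a, "target_pathway": b, "subtype": "RSL",
                 "weight": d["weight"], "directed": False}
            )
        rows.sort(key=lambda r: (r["subtype"], r["source_pathway"], r["target_pathway"]))
        return rows


def _pathway(label: str) -> str:
    return label if label else UNANNOTATED


def entanglement_graph(pairs: list[SLPair]) -> EntanglementGraph:
    """Aggregate classified pairs into the pathway entanglement graph.

    Each PSL pair adds weight 1 to the directed edge from its backup's
    pathway to its active member's pathway; each RSL pair adds weight 1
    to the undirected edge between its two pathways. Inconsistent pairs
    contribute with their base subtype.
    """
    psl = nx.DiGraph()
    rsl = nx.Graph()
    for p in pairs:
        if p.base_subtype == "PSL":
            backup_pw = _pathway(
                p.pathway_a if p.backup_reaction == p.rxn_a else p.pathway_b
            )
            active_pw = _pathway(
                p.pathway_a if p.active_reaction == p.rxn_a else p.pathway_b
            )
            w = psl.get_edge_data(backup_pw, active_pw, {"weight": 0})["weight"]
            psl.add_edge(backup_pw, active_pw, weight=w + 1)
        else:
            a, b = _pathway(p.pathway_a), _pathway(p.pathway_b)
            w = rsl.get_edge_data(a, b, {"weight": 0})["weight"]
            rsl.add_edge(a, b, weight=w + 1)
    return EntanglementGraph(psl, rsl)


def intra_inter_counts(pairs: list[SLPair]) -> dict[str, dict[str, int]]:
    """Pairs whose two pathway labels match (intra) vs differ (inter), per subtype."""
    out: dict[str, dict[str, int]] = {}
    for p in pairs:
        bucket = out.setdefault(p.base_subtype, {"intra": 0, "inter": 0})
        bucket["intra" if p.is_intra_pathway else "inter"] += 1
    return out
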