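"""Independent brute-force oracle for the test suite.

Everything here is deliberately coded apart from the package under
test: fixture files are parsed with the csv module (not synlethal.io),
the LP is formulated differently (growth pinned with an extra equality
row instead of variable bounds; flux minimisation over split variables
assembled here), and shortest paths use a hand-rolled BFS over an
adjacency map built straight from the stoichiometry dictionaries.
"""

from __future__ import annotations

import csv
import itertools
import math
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

BIG = 1e6
ZERO = 1e-9


# -- independent fixture parser ---------------------------------------------


def load_fixture(path: Path) -> dict:
    """Parse a tsv-triplet fixture directory into plain dicts."""
    rxns = {}
    order = []
    with open(Path(path) / "reactions.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            stoich = {}
            for term in row["stoichiometry"].split(";"):
                met, coef = term.rsplit(":", 1)
                stoich[met] = float(coef)
            rxns[row["id"]] = {
                "stoich": stoich,
                "lb": float(row["lower_bound"]),
                "ub": float(row["upper_bound"]),
                "gpr": row.get("gpr", ""),
                "exchange": row.get("is_exchange", "") == "true",
                "biomass": row.get("is_biomass", "") == "true",
            }
            order.append(row["id"])
    media = {}
    media_file = Path(path) / "media.tsv"
    if media_file.exists():
        with open(media_file) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                media.setdefault(row["medium_label"], {})[
                    row["exchange_reaction_id"]
                ] = float(row["lower_bound"])
    truth_pairs = {}
    tp = Path(path) / "truth_pairs.tsv"
    if tp.exists():
        with open(tp) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                truth_pairs[frozenset({row["rxn_a"], row["rxn_b"]})] = row
    truth_rxns = {}
    tr = Path(path) / "truth_reactions.tsv"
    if tr.exists():
        with open(tr) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                truth_rxns[row["reaction"]] = row
    return {"reactions": rxns, "order": order, "media": media,
            "truth_pairs": truth_pairs, "truth_reactions": truth_rxns}


# -- LP machinery ------------------------------------------------------------


def _matrices(raw, medium, deleted=()):
    order = raw["order"]
    mets = sorted({m for r in raw["reactions"].values() for m in r["stoich"]})
    mrow = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(order)))
    lb = np.zeros(len(order))
    ub = np.zeros(len(order))
    for j, rid in enumerate(order):
        r = raw["reactions"][rid]
        for met, coef in r["stoich"].items():
            S[mrow[met], j] = coef
        lo, hi = r["lb"], r["ub"]
        if r["exchange"]:
            lo = medium.get(rid, 0.0)
        if rid in deleted:
            lo = hi = 0.0
        lb[j] = max(lo, -BIG)
        ub[j] = min(hi, BIG)
    bm = next(j for j, rid in enumerate(order) if raw["reactions"][rid]["biomass"])
    return S, lb, ub, bm, order


def brute_growth(raw, medium, deleted=()) -> float:
    """Maximal biomass flux, one direct linprog call."""
    S, lb, ub, bm, _ = _matrices(raw, medium, deleted)
    c = np.zeros(S.shape[1])
    c[bm] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    if res.status != 0:
        return 0.0
    return float(-res.fun)


def brute_min_flux_solution(raw, medium) -> dict[str, float]:
    """Minimum-total-flux optimum, growth pinned by an extra equality row."""
    nu = brute_growth(raw, medium)
    S, lb, ub, bm, order = _matrices(raw, medium)
    n = S.shape[1]
    # v = p - q ; extra row pins v_bm = nu
    pin = np.zeros((1, n))
    pin[0, bm] = 1.0
    A = np.vstack([S, pin])
    b = np.concatenate([np.zeros(S.shape[0]), [nu * (1 - 1e-9)]])
    A_split = np.hstack([A, -A])
    bounds = np.concatenate(
        [np.column_stack([np.zeros(n), np.maximum(ub, 0.0)]),
         np.column_stack([np.zeros(n), np.maximum(-lb, 0.0)])]
    )
    res = linprog(np.ones(2 * n), A_eq=A_split, b_eq=b, bounds=bounds, method="highs")
    assert res.status == 0, res.message
    v = res.x[:n] - res.x[n:]
    return dict(zip(order, v))


def brute_flux_capable(raw, medium, rid) -> bool:
    """Can the reaction carry any flux with growth merely nonnegative?"""
    S, lb, ub, bm, order = _matrices(raw, medium)
    lb[bm] = max(lb[bm], 0.0)
    j = order.index(rid)
    for sign in (1.0, -1.0):
        c = np.zeros(S.shape[1])
        c[j] = sign
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=np.column_stack([lb, ub]), method="highs")
        if res.status == 0 and abs(res.fun) > ZERO:
            return True
    return False


def brute_essentials(raw, medium) -> set[str]:
    wt = brute_growth(raw, medium)
    return {
        rid
        for rid in raw["order"]
        if brute_growth(raw, medium, deleted={rid}) <= 1e-6 * wt
    }


def brute_candidates(raw, medium) -> set[str]:
    essential = brute_essentials(raw, medium)
    out = set()
    for rid, r in raw["reactions"].items():
        if r["exchange"] or r["biomass"] or not r["gpr"].strip():
            continue
        if rid in essential:
            continue
        if brute_flux_capable(raw, medium, rid):
            out.add(rid)
    return out


def brute_sl_pairs(raw, medium, candidates) -> set[frozenset[str]]:
    wt = brute_growth(raw, medium)
    pairs = set()
    for a, b in itertools.combinations(sorted(candidates), 2):
        if brute_growth(raw, medium, deleted={a, b}) <= 1e-6 * wt:
            pairs.add(frozenset({a, b}))
    return pairs


def brute_subtype(raw, medium, pair) -> tuple[str, str | None]:
    """(subtype, active member) from the independent min-flux optimum."""
    v = brute_min_flux_solution(raw, medium)
    a, b = sorted(pair)
    act_a, act_b = abs(v[a]) > ZERO, abs(v[b]) > ZERO
    if act_a and act_b:
        return "RSL", None
    if act_a or act_b:
        return "PSL", a if act_a else b
    return "NONE", None


# -- BFS distance oracle ------------------------------------------------------


def brute_reaction_distance(raw, r1, r2) -> float:
    """Symmetrised intermediate-node count by plain BFS.

    Shared-metabolite pairs are directly connected (distance 1); beyond
    that, the shorter directed path over both orientations counts its
    intermediate nodes.
    """
    if r1 == r2:
        return 0.0
    if set(raw["reactions"][r1]["stoich"]) & set(raw["reactions"][r2]["stoich"]):
        return 1.0
    adj: dict[tuple, set[tuple]] = {}

    def add(u, v):
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set())

    for rid, r in raw["reactions"].items():
        rev = r["lb"] < 0
        for met, coef in r["stoich"].items():
            if coef < 0:
                add(("M", met), ("R", rid))
                if rev:
                    add(("R", rid), ("M", met))
            elif coef > 0:
                add(("R", rid), ("M", met))
                if rev:
                    add(("M", met), ("R", rid))

    def bfs(src, dst):
        if src == dst:
            return 0
        seen = {src}
        frontier = [src]
        hops = 0
        while frontier:
            hops += 1
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if v == dst:
                        return hops
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        return math.inf

    if r1 == r2:
        return 0.0
    d = min(bfs(("R", r1), ("R", r2)), bfs(("R", r2), ("R", r1)))
    return d - 1 if math.isfinite(d) else math.inf
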