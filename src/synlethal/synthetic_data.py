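"""Small stoichiometric toy models with planted, closed-form ground truth.

Models are assembled from independent *motifs*, each hanging off the
biomass reaction through private metabolites so that truths compose:

* ``linear_chain`` -- an unbranched source->precursor chain; every step
  is essential.
* ``psl_backup`` -- two routes from a private source A to a precursor P:
  an efficient active route (A -> P) and a dormant backup consuming
  ``yield_ratio`` > 1 units of A per P. At maximum growth the backup is
  forced to zero flux, so the pair is plasticity synthetic lethal with
  known knockout growths (active KO: uptake/yield_ratio).
* ``rsl_parallel`` -- two parallel branches with per-branch capacities
  below the demand, so both must run at maximum growth: a redundancy
  pair whose single-knockout growth equals the surviving capacity.
* ``isoenzyme_pair`` -- a psl_backup topology in which both reactions
  share one OR rule over two genes (the same isoenzyme family), to
  exercise the enzyme-identity inconsistency rule.
* ``dead_branch`` -- a gene-associated reaction producing a metabolite
  with no sink; blocked in every medium, hence never a candidate.
* ``medium_dependent_backup`` -- a psl_backup motif plus a rescue route
  from a nutrient B whose exchange is closed in the reference medium;
  the pair is lethal only in media lacking B.

Each motif takes up to ``uptake`` mmol/(gDW.h) of its own source and
the biomass reaction consumes one unit of every feeding motif's
precursor, so wild-type growth equals ``uptake`` and knockout growths
follow the per-motif algebra above by a simple minimum.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gpr import GeneAssociation, parse_gpr
from .io import write_media_panel, write_model_tsv
from .model import Metabolite, MetabolicModel, Medium, Reaction, apply_medium

_INF = 1e6

MOTIFS = (
    "linear_chain",
    "psl_backup",
    "rsl_parallel",
    "isoenzyme_pair",
    "dead_branch",
    "medium_dependent_backup",
)

_PATHWAY_POOL = (
    "Glycolysis",
    "Pentose Phosphate Pathway",
    "Cell Envelope Biosynthesis",
    "Membrane Lipid Metabolism",
    "Nucleotide Metabolism",
    "Folate Metabolism",
    "Amino Acid Biosynthesis",
    "Cofactor and Prosthetic Group",
)


@dataclass(frozen=True)
class MotifSpec:
    """Composition of one synthetic toy model.

    ``counts`` gives the number of instances per motif; parameters apply
    to every instance of the motif unless randomisation is enabled, in
    which case they are drawn per instance within the documented safe
    ranges (yield_ratio > 1; each rsl capacity < uptake <= their sum)
    so the planted truth stays derivable.
    """

    counts: dict[str, int]
    seed: int = 0
    uptake: float = 10.0
    yield_ratio: float = 2.0
    rsl_capacities: tuple[float, float] = (6.0, 6.0)
    chain_length: int = 3
    randomize: bool = False

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(MOTIFS)
        if bad:
            raise ValueError(f"unknown motifs {sorted(bad)}")
        if self.yield_ratio <= 1:
            raise ValueError("yield_ratio must exceed 1 (the backup must be costlier)")
        c1, c2 = self.rsl_capacities
        if not (c1 < self.uptake and c2 < self.uptake and c1 + c2 >= self.uptake):
            raise ValueError(
                "rsl capacities must each be below the demand and sum to at least it"
            )
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")


@dataclass(frozen=True)
class PlantedPair:
    rxn_a: str
    rxn_b: str
    subtype: str  # "PSL" | "RSL"
    active: str | None
    backup: str | None
    growth_ko_active: float | None  # PSL: growth after deleting the active member
    fitness_increased: bool | None  # RSL
    enzyme_flag: str = ""  # "isoenzymes" when the pair shares an OR family

    @property
    def members(self) -> frozenset[str]:
        return frozenset({self.rxn_a, self.rxn_b})


@dataclass
class PlantedTruth:
    """Ground truth derivable from the motif algebra, no LP involved."""

    wild_type_growth: float
    essential: set[str]
    candidates: set[str]
    pairs: dict[frozenset[str], PlantedPair]
    single_ko_growth: dict[str, float]
    media: list[Medium]
    media_lethal: dict[frozenset[str], set[str]]

    @property
    def sl_pairs(self) -> set[frozenset[str]]:
        return set(self.pairs)


class _Builder:
    def __init__(self, uptake: float):
        self.uptake = uptake
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self.biomass_inputs: list[str] = []
        self.medium_bounds: dict[str, float] = {}
        self.alt_media: list[Medium] = []
        self.truth = PlantedTruth(uptake, set(), set(), {}, {}, [], {})

    def met(self, mid: str) -> str:
        self.metabolites.append(Metabolite(mid))
        return mid

    def rxn(
        self,
        rid: str,
        stoich: dict[str, float],
        lb: float = 0.0,
        ub: float = _INF,
        gpr: str | None = None,
        subsystem: str = "",
        exchange: bool = False,
    ) -> str:
        rule = gpr if gpr is not None else (None if exchange else f"g_{rid}")
        self.reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(rule),
                subsystem=subsystem,
                is_exchange=exchange,
            )
        )
        return rid

    def source(self, tag: str, open_in_medium: bool = True) -> str:
        mid = self.met(f"A_{tag}")
        ex = self.rxn(f"EX_A_{tag}", {mid: -1.0}, lb=0.0, exchange=True)
        if open_in_medium:
            self.medium_bounds[ex] = -self.uptake
            self.truth.essential.add(ex)
        return mid


def _add_linear_chain(b: _Builder, tag: str, length: int, pathway: str) -> None:
    src = b.source(tag)
    prev = src
    for step in range(1, length + 1):
        nxt = b.met(f"P_{tag}") if step == length else b.met(f"m{step}_{tag}")
        # one interior step reversible to exercise two-direction handling
        lb = -_INF if (step == 2 and length >= 2) else 0.0
        rid = b.rxn(f"R_{tag}_s{step}", {prev: -1.0, nxt: 1.0}, lb=lb, subsystem=pathway)
        b.truth.essential.add(rid)
        b.truth.single_ko_growth[rid] = 0.0
        prev = nxt
    b.biomass_inputs.append(prev)


def _add_psl_backup(
    b: _Builder,
    tag: str,
    yield_ratio: float,
    pathways: tuple[str, str],
    iso: bool = False,
    rescue_nutrient: bool = False,
) -> None:
    src = b.source(tag)
    pre = b.met(f"P_{tag}")
    gpr_hi = gpr_lo = None
    if iso:
        gpr_hi = gpr_lo = f"g_{tag}_x or g_{tag}_y"
    hi = b.rxn(f"R_{tag}_hi", {src: -1.0, pre: 1.0}, gpr=gpr_hi, subsystem=pathways[0])
    lo = b.rxn(
        f"R_{tag}_lo", {src: -yield_ratio, pre: 1.0}, gpr=gpr_lo, subsystem=pathways[1]
    )
    b.biomass_inputs.append(pre)
    pair = PlantedPair(
        *sorted((hi, lo)),
        subtype="PSL",
        active=hi,
        backup=lo,
        growth_ko_active=b.uptake / yield_ratio,
        fitness_increased=None,
        enzyme_flag="isoenzymes" if iso else "",
    )
    b.truth.pairs[pair.members] = pair
    b.truth.candidates.update({hi, lo})
    b.truth.single_ko_growth[hi] = b.uptake / yield_ratio
    b.truth.single_ko_growth[lo] = b.uptake
    if rescue_nutrient:
        nut = b.met(f"B_{tag}")
        ex = b.rxn(f"EX_B_{tag}", {nut: -1.0}, lb=0.0, exchange=True)
        b.rxn(f"R_{tag}_resc", {nut: -1.0, pre: 1.0}, subsystem=pathways[1])
        b.alt_media.append((f"with_rescue_{tag}", ex, pair.members))
    else:
        b.truth.media_lethal[pair.members] = None  # lethal everywhere; filled later


def _add_rsl_parallel(
    b: _Builder, tag: str, capacities: tuple[float, float], pathway: str
) -> None:
    src = b.source(tag)
    pre = b.met(f"P_{tag}")
    p1 = b.rxn(f"R_{tag}_p1", {src: -1.0, pre: 1.0}, ub=capacities[0], subsystem=pathway)
    p2 = b.rxn(f"R_{tag}_p2", {src: -1.0, pre: 1.0}, ub=capacities[1], subsystem=pathway)
    b.biomass_inputs.append(pre)
    pair = PlantedPair(
        *sorted((p1, p2)),
        subtype="RSL",
        active=None,
        backup=None,
        growth_ko_active=None,
        fitness_increased=True,  # guaranteed by capacity < demand
    )
    b.truth.pairs[pair.members] = pair
    b.truth.candidates.update({p1, p2})
    b.truth.single_ko_growth[p1] = capacities[1]
    b.truth.single_ko_growth[p2] = capacities[0]
    b.truth.media_lethal[pair.members] = None


def _add_dead_branch(b: _Builder, tag: str, pathway: str) -> None:
    src = b.met(f"D_{tag}")
    ex = b.rxn(f"EX_D_{tag}", {src: -1.0}, lb=0.0, exchange=True)
    b.medium_bounds[ex] = -b.uptake  # nutrient offered, but the branch is blocked
    sink_less = b.met(f"X_{tag}")
    rid = b.rxn(f"R_{tag}_dead", {src: -1.0, sink_less: 1.0}, subsystem=pathway)
    b.truth.single_ko_growth[rid] = b.uptake
    b.truth.single_ko_growth[ex] = b.uptake


def make_toy_model(spec: MotifSpec) -> tuple[MetabolicModel, Medium, PlantedTruth]:
    """Assemble a toy model, its reference medium, and the planted truth.

    The returned model does **not** have the medium applied; callers use
    :func:`synlethal.model.apply_medium`. ``truth.media`` holds the
    reference medium first, followed by any alternative media planted by
    ``medium_dependent_backup`` motifs.
    """
    rng = np.random.default_rng(spec.seed)
    b = _Builder(spec.uptake)

    def draw_pathways(n: int) -> list[str]:
        if spec.randomize:
            return list(rng.choice(_PATHWAY_POOL, size=n, replace=True))
        return list(_PATHWAY_POOL[:n])

    def token() -> str:
        if not spec.randomize:
            return ""
        letters = rng.choice(list(string.ascii_lowercase), size=4)
        return "_" + "".join(letters)

    for motif in MOTIFS:
        for i in range(spec.counts.get(motif, 0)):
            if motif == "linear_chain":
                _add_linear_chain(b, f"ch{i}{token()}", spec.chain_length, draw_pathways(1)[0])
            elif motif == "psl_backup":
                k = (
                    float(rng.choice([1.25, 1.5, 2.0, 2.5, 4.0]))
                    if spec.randomize
                    else spec.yield_ratio
                )
                _add_psl_backup(b, f"psl{i}{token()}", k, tuple(draw_pathways(2)))
            elif motif == "rsl_parallel":
                if spec.randomize:
                    c1 = float(rng.uniform(0.45, 0.95)) * spec.uptake
                    c2 = float(rng.uniform(max(0.0, 1 - c1 / spec.uptake) + 0.05, 0.95)) * spec.uptake
                    caps = (round(c1, 3), round(c2, 3))
                else:
                    caps = spec.rsl_capacities
                _add_rsl_parallel(b, f"rsl{i}{token()}", caps, draw_pathways(1)[0])
            elif motif == "isoenzyme_pair":
                _add_psl_backup(
                    b, f"iso{i}{token()}", spec.yield_ratio, tuple(draw_pathways(2)), iso=True
                )
            elif motif == "dead_branch":
                _add_dead_branch(b, f"dead{i}{token()}", draw_pathways(1)[0])
            elif motif == "medium_dependent_backup":
                _add_psl_backup(
                    b,
                    f"med{i}{token()}",
                    spec.yield_ratio,
                    tuple(draw_pathways(2)),
                    rescue_nutrient=True,
                )

    if not b.biomass_inputs:
        raise ValueError("spec plants no biomass-feeding motif; the model cannot grow")
    b.rxn("BM", {m: -1.0 for m in b.biomass_inputs}, gpr="", subsystem="Biomass")
    reactions = [
        r if r.id != "BM" else Reaction(
            id=r.id,
            stoichiometry=r.stoichiometry,
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            gpr=r.gpr,
            subsystem=r.subsystem,
            is_biomass=True,
        )
        for r in b.reactions
    ]
    model = MetabolicModel(b.metabolites, reactions, id=f"toy_seed{spec.seed}")
    b.truth.essential.add("BM")

    reference = Medium(dict(b.medium_bounds), label="reference")
    media = [reference]
    for label, rescue_ex, _pair in b.alt_media:
        bounds = dict(b.medium_bounds)
        bounds[rescue_ex] = -spec.uptake
        media.append(Medium(bounds, label=label))
    b.truth.media = media
    all_labels = {m.label for m in media}
    for key, lethal_in in list(b.truth.media_lethal.items()):
        if lethal_in is None:
            b.truth.media_lethal[key] = set(all_labels)
    for label, _ex, pair_members in b.alt_media:
        # a rescued pair is lethal everywhere except in its own rescue medium
        b.truth.media_lethal[pair_members] = all_labels - {label}
    return model, reference, b.truth


# ---------------------------------------------------------------------------
# canonical spec fixtures
# ---------------------------------------------------------------------------


def toy_rsl() -> tuple[MetabolicModel, Medium, PlantedTruth]:
    """The 4-reaction redundancy fixture: two capacity-6 branches, demand 10."""
    spec = MotifSpec({"rsl_parallel": 1}, rsl_capacities=(6.0, 6.0))
    return make_toy_model(spec)


def toy_psl(yield_ratio: float = 2.0) -> tuple[MetabolicModel, Medium, PlantedTruth]:
    """The plasticity fixture: efficient route vs yield-ratio-k backup."""
    spec = MotifSpec({"psl_backup": 1}, yield_ratio=yield_ratio)
    return make_toy_model(spec)


def kitchen_sink(seed: int = 0) -> tuple[MetabolicModel, Medium, PlantedTruth]:
    """One model combining every motif."""
    spec = MotifSpec({m: 1 for m in MOTIFS}, seed=seed)
    return make_toy_model(spec)


def entangled_psl_model(
    yield_ratio: float = 2.0, uptake: float = 20.0
) -> tuple[MetabolicModel, Medium, PlantedTruth]:
    """Two plasticity pairs sharing a single source metabolite.

    Both motifs draw on the same pool A (one exchange, uptake bound
    ``-uptake``), so the motifs are deliberately *not* independent:
    wild-type growth is uptake/2 and deleting one active route drops
    growth to uptake/(1 + yield_ratio). The screen must still find
    exactly the two planted pairs and no cross-motif pair.
    """
    k = yield_ratio
    mets = [Metabolite("A"), Metabolite("P1"), Metabolite("P2")]
    def r(rid, stoich, **kw):
        defaults = dict(lower_bound=0.0, upper_bound=_INF)
        defaults.update(kw)
        gpr = defaults.pop("gpr", f"g_{rid}")
        return Reaction(id=rid, stoichiometry=stoich, gpr=parse_gpr(gpr), **defaults)
    reactions = [
        r("EX_A", {"A": -1.0}, lower_bound=0.0, is_exchange=True, gpr=""),
        r("R_a_hi", {"A": -1.0, "P1": 1.0}, subsystem="Glycolysis"),
        r("R_a_lo", {"A": -k, "P1": 1.0}, subsystem="Pentose Phosphate Pathway"),
        r("R_b_hi", {"A": -1.0, "P2": 1.0}, subsystem="Membrane Lipid Metabolism"),
        r("R_b_lo", {"A": -k, "P2": 1.0}, subsystem="Cell Envelope Biosynthesis"),
        r("BM", {"P1": -1.0, "P2": -1.0}, is_biomass=True, gpr=""),
    ]
    model = MetabolicModel(mets, reactions, id="entangled_psl")
    medium = Medium({"EX_A": -uptake}, label="reference")
    wt = uptake / 2.0
    ko_active = uptake / (1.0 + k)
    truth = PlantedTruth(
        wild_type_growth=wt,
        essential={"EX_A", "BM"},
        candidates={"R_a_hi", "R_a_lo", "R_b_hi", "R_b_lo"},
        pairs={
            frozenset({"R_a_hi", "R_a_lo"}): PlantedPair(
                "R_a_hi", "R_a_lo", "PSL", "R_a_hi", "R_a_lo", ko_active, None
            ),
            frozenset({"R_b_hi", "R_b_lo"}): PlantedPair(
                "R_b_hi", "R_b_lo", "PSL", "R_b_hi", "R_b_lo", ko_active, None
            ),
        },
        single_ko_growth={
            "R_a_hi": ko_active,
            "R_a_lo": wt,
            "R_b_hi": ko_active,
            "R_b_lo": wt,
        },
        media=[medium],
        media_lethal={},
    )
    return model, medium, truth


# ---------------------------------------------------------------------------
# randomized fixture suite
# ---------------------------------------------------------------------------


def random_motif_spec(seed: int) -> MotifSpec:
    """A randomized but truth-preserving model composition."""
    rng = np.random.default_rng(seed)
    counts = {
        "psl_backup": int(rng.integers(1, 3)),
        "rsl_parallel": int(rng.integers(0, 3)),
        "linear_chain": int(rng.integers(0, 2)),
        "dead_branch": int(rng.integers(0, 2)),
        "isoenzyme_pair": int(rng.integers(0, 2)),
    }
    return MotifSpec(counts, seed=seed, randomize=True)


def fixture_suite(seed: int, n_models: int, out_dir: str | Path) -> list[Path]:
    """Write ``n_models`` randomized fixtures to disk, deterministically.

    Each fixture directory holds the tsv-triplet model, a media panel
    TSV, and two truth tables: ``truth_pairs.tsv`` (pair, subtype,
    active, backup, fitness_increased) and ``truth_reactions.tsv``
    (reaction, essential, candidate, single_ko_growth). The suite
    always includes one kitchen-sink model (index 0) and one
    medium-dependent model with a 2-medium panel (index 1).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(n_models):
        sub_seed = (seed * 100003 + i) % (2**31 - 1)
        if i == 0:
            model, medium, truth = kitchen_sink(seed=sub_seed)
        elif i == 1:
            spec = MotifSpec(
                {"psl_backup": 1, "medium_dependent_backup": 1}, seed=sub_seed
            )
            model, medium, truth = make_toy_model(spec)
        else:
            model, medium, truth = make_toy_model(random_motif_spec(sub_seed))
        fdir = out_dir / f"fixture_{i:03d}"
        write_model_tsv(model, fdir)
        write_media_panel(truth.media, fdir / "media.tsv")
        pd.DataFrame(
            [
                {
                    "rxn_a": p.rxn_a,
                    "rxn_b": p.rxn_b,
                    "subtype": p.subtype,
                    "active": p.active or "",
                    "backup": p.backup or "",
                    "fitness_increased": "" if p.fitness_increased is None else str(p.fitness_increased).lower(),
                    "lethal_in_media": ";".join(sorted(truth.media_lethal.get(p.members, set()))),
                }
                for p in sorted(truth.pairs.values(), key=lambda p: (p.rxn_a, p.rxn_b))
            ]
        ).to_csv(fdir / "truth_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "reaction": r.id,
                    "essential": str(r.id in truth.essential).lower(),
                    "candidate": str(r.id in truth.candidates).lower(),
                    "single_ko_growth": (
                        f"{truth.single_ko_growth[r.id]:.12g}"
                        if r.id in truth.single_ko_growth
                        else ""
                    ),
                }
                for r in model.reactions
            ]
        ).to_csv(fdir / "truth_reactions.tsv", sep="\t", index=False)
        paths.append(fdir)
    return paths
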