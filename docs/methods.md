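# Methods

## Constraint-based model and FBA core

A model is a stoichiometric matrix **S** over internal metabolites,
per-reaction flux bounds in mmol/(gDW·h), one biomass pseudo-reaction
whose flux ν is the growth rate, and exchange reactions written
`met ↔ ∅` with the standard sign convention (negative flux = uptake, so
a medium is a map of exchange lower bounds; exchanges absent from a
medium are closed to uptake while secretion stays open). Reversible
reactions are a single variable with a negative lower bound; a knockout
zeroes both bounds, removing both directions at once, and the bipartite
network representation gives reversible reactions edges in both
orientations.

FBA maximises ν subject to `S·v = 0` and the bounds. The LP is solved
with HiGHS through `scipy.optimize.linprog` behind a minimal pluggable
backend contract (matrix, bounds, objective in; status, solution,
objective out); the dual-simplex and interior-point algorithms are both
exposed and used to check backend independence. Infinite bounds are
boxed at ±10⁶, three orders of magnitude above any meaningful flux at
the O(10) bound scale used throughout.

### Alternate optima and the two FBA modes

Plain FBA optima are almost always degenerate, so "reaction r carries
flux at maximum growth" is solver-dependent. Because the
plasticity/redundancy split hinges exactly on that activity call, the
default mode `flux_minimized` re-solves a second LP at the fixed
optimal biomass, minimising total absolute flux over split variables
(parsimonious FBA). This yields a deterministic, backend-independent
reference optimum. `raw` mode returns the primary solution unmodified
for comparison with single-solver behaviour; activity-dependent counts
may legitimately differ between modes, which the results objects make
visible rather than hide. The biomass pin of the secondary LP carries
an absolute slack of 1e−9 (plus 1e−9 relative) so that the second solve
cannot go infeasible on the feasibility tolerance of the first; the
reported objective is the primary optimum.

### Tolerances

* `flux_epsilon = 1e−9` (absolute): below this a flux is "zero". Used
  for activity calls and active-capability. Appropriate because all
  shipped fixtures have bounds of order 10 and vertex solutions are
  exact rationals under HiGHS.
* `growth_epsilon = 1e−6` (relative to wild-type growth): below this a
  mutant is non-viable. Relative, so the call is invariant to rescaling
  the uptake bounds.

Both are keyword-configurable everywhere they matter.

## Candidate space

Candidates for pairing are the intersection of three filters:

1. **Gene-associated** — reactions with a non-empty GPR rule.
   Spontaneous/orphan reactions are excluded from the *candidate space
   only*; they remain in the network so their fluxes can carry
   metabolism. Deleting them outright would change growth phenotypes; a
   `drop_reactions` helper and an `exclude_gene_less` flag reproduce
   the alternative reading.
2. **Active-capable** — the reaction's flux range extends beyond
   ±`flux_epsilon` under flux variability analysis with biomass
   unconstrained (only ν ≥ 0). This deliberately ignores the attainable
   growth level: it captures reactions that are idle at maximum growth
   but available in low-growth scenarios — precisely the dormant
   backups the plasticity class is made of — while excluding blocked
   reactions.
3. **Nonessential** — single deletion leaves a viable optimum.

The filters commute (the set is an intersection), so their order is
irrelevant. Exchanges and the biomass reaction are never candidates.

## Classification and inconsistency rules

Against the parsimonious reference optimum, a lethal pair with exactly
one member below `flux_epsilon` is PSL (zero-flux member = backup,
other = active); two active members make it RSL. Both members at zero
flux contradicts active-capability and raises an error pointing at the
mode choice (it can occur under `raw` with degenerate optima). For PSL
pairs the backup law is checked directly: after deleting the active
member the backup must carry flux in a viable optimum, and deleting the
backup must leave growth unchanged. For RSL pairs `fitness_increased`
is true when wild-type growth strictly exceeds the best single-knockout
growth (tolerance 1e−9).

Experimental gene essentiality can contradict a computational SL call.
The three-case rule: both members' genes nonessential — subtype kept;
one member governed by an essential gene — inconsistent iff every such
gene regulates only that one reaction (a multi-reaction essential gene
may owe its essentiality to the other reactions it controls); both
members essential-gene-governed — inconsistent unless each side has an
essential gene regulating more than one reaction. Genes with no
annotation default to nonessential (a `strict` policy raises instead).

PSL pairs whose two members share enzymatic identity are additionally
flagged: *multifunctional* = identical single-gene GPR on both members;
*isoenzymes* = both members' GPRs are the same OR-family of ≥ 2 gene
units. This structural heuristic was a genuinely open design point — no
detection algorithm exists for it beyond curation — so an explicit
curated pair list is accepted as the faithful fallback and takes
precedence in the reason trail. A *gene unit* throughout is a maximal
AND-subtree of the GPR: an enzyme complex counts once, OR-alternative
isoenzymes count separately; gene/complex counts per subtype use these
units.

## Network distances and entanglement

Metabolism is a bipartite directed graph (metabolite→reaction when
consumed, reaction→metabolite when produced). The distance between two
reactions counts *intermediate nodes*, not edges. Two reactions sharing
any metabolite — substrate or product, in either role — are treated as
directly connected at distance 1; beyond that, the distance is the
smaller over both orientations of the intermediate-node count of the
shortest directed path (Dijkstra). The shared-metabolite rule is a
deliberate convention choice: under a strictly directed reading, two
parallel branches consuming and producing the same metabolites would be
mutually unreachable (distance ∞), which contradicts the natural
reading of redundant branches as directly coupled; the strictly
directed variant remains available by inspecting the graph directly.
Currency metabolites are not pruned by default; an exclusion list can
be supplied and is recorded in the graph metadata, since hub
metabolites otherwise shortcut paths.

The entanglement graph aggregates pairs at the pathway level: each PSL
pair adds weight 1 to the directed edge backup-pathway → active-pathway,
each RSL pair adds weight 1 to the undirected edge between its two
pathways; intra-pathway pairs become self-loops, unlabeled pathways
fall into an `unannotated` bucket, and per-subtype edge weights sum to
the number of pairs by construction.

## Environments

Minimal-media panels are built combinatorially: a fixed mineral-salt
fragment plus one source each of C, N, P and S; one element is varied
over its candidate compounds while the other three stay at the
reference choice; media in which the wild type cannot grow are filtered
out by FBA. Mineral salts are identified by an explicit flag in the
medium file, never inferred chemically. Enrichment opens extra uptake
exchanges at −10 mmol/(gDW·h) by default, skipping (with a warning)
compounds the model cannot take up.

Overconstraining reduces maximal growth to a fraction f of its
reference value in two modes. `mineral_salts`: FVA with biomass pinned
at f·ν\* reads off each salt exchange's maximal uptake (its most
negative feasible flux), which becomes the new lower bound; other
compounds keep reference bounds. `basic_sources`: FVA at maximal growth
gives each element source's uptake limit, which is scaled by f; salts
keep reference bounds. Re-testing across media always re-classifies
with the same FBA mode as the reference screen, so subtype switches
reflect the environment, not solver drift. Cross-environment comparison
first partitions pairs by lethality (conserved / rescued / novel) and
only then inspects subtype switches and, for conserved PSL pairs,
active/backup role swaps among the conserved set.

## Synthetic data: what it emulates and what it does not

The generator assembles toy models from motifs attached to the biomass
reaction through private metabolites, each motif drawing up to
10 mmol/(gDW·h) (the default uptake, matching the conventional exchange
bound) from its own source:

| motif | planted truth | closed form (uptake u) |
|---|---|---|
| `linear_chain` | every step essential | wt = u, KO growth 0 |
| `psl_backup` (yield ratio k > 1) | PSL pair, roles known | active KO: u/k; backup KO: u |
| `rsl_parallel` (capacities c₁, c₂ < u ≤ c₁+c₂) | RSL pair, fitness gain | branch KO: surviving cᵢ |
| `isoenzyme_pair` | PSL pair flagged by the enzyme rule | as psl_backup |
| `dead_branch` | blocked, never a candidate | growth unaffected |
| `medium_dependent_backup` | pair lethal only where the rescue nutrient is absent | as psl_backup |

Biomass consumes one unit of every feeding motif's precursor, so
wild-type growth is the motif-capacity minimum (= u) and knockout
growths compose by a simple minimum; all truths are derivable without
any LP. The constraint c₁, c₂ < u forces parallel use, so planted RSL
pairs always have a fitness gain; the growth-unchanged redundancy case
is exercised at the bookkeeping level because a capacity-slack parallel
pair has no deterministic activity pattern even under parsimonious FBA
(any split of the demand is optimal). Randomisation permutes
identifiers and pathway labels and draws motif parameters inside the
safe ranges — never the topology — so truth remains derivable; one
deliberately entangled variant (two plasticity pairs sharing a single
substrate pool) checks that the screen does not over-count when motifs
interact. A chain's interior step is reversible to exercise
two-direction handling.

What the toys do **not** emulate: genome-scale degree distributions,
currency-metabolite hubs, compartments, cofactor coupling, loops, and
GPRs more complex than one gene, one complex, or one OR-family per
reaction. Passing tests therefore demonstrate correctness of the
screening and classification machinery, not predictive accuracy on any
real reconstruction; real SBML/JSON models are first-class inputs but
their results carry the usual FBA caveats.

## Problem sizes and determinism

The shipped test and acceptance runs use 100 randomized fixtures
(≈ 7–25 reactions each; the brute-force LP oracle covers those with
≤ 12 reactions, distance enumeration the first 30), 200 nested deletion
draws over 20 fixtures, and the canonical 4-reaction toys — sizes at
which the exhaustive oracles remain exact and the whole suite completes
in well under a minute per stage. All randomness flows from explicit
seeds (`numpy.random.default_rng`); fixture generation is byte-stable
for a given seed, and two runs of the pipeline on the same inputs
produce identical tables in `flux_minimized` mode.

## Known limitations

* Quadratic/nonlinear objectives, loopless FBA and flux sampling are
  out of scope; the parsimonious secondary objective is the only
  tie-break offered.
* The isoenzyme/multifunctional flag is structural; curated biology
  should use the explicit list path.
* `raw` mode reproduces single-solver behaviour only in the sense of
  "some optimal vertex": which vertex GLPK or any other solver returns
  is not reproducible in principle.
* Gene-level (GPR-propagated) double knockouts are not screened; genes
  enter through the inconsistency rules and reporting only.
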