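# synlethal

Synthetic-lethality analysis of constraint-based metabolic models:
exhaustive in-silico double-knockout screening by flux balance analysis
(FBA), classification of coessential reaction pairs into **plasticity**
(backup) and **redundancy** (parallel-use) subtypes, inconsistency
flagging against experimental gene essentiality, pathway-entanglement
and network-distance analysis, and media-sensitivity evaluation.

It is aimed at systems biologists who work with genome-scale metabolic
reconstructions (SBML-FBC or BiGG-style JSON) and want reaction-level
synthetic lethal (SL) pairs together with the *mechanism* behind each
pair, and at method developers who need a fully testable pipeline: a
built-in generator of small stoichiometric toy networks with planted
motifs and closed-form ground truth lets every stage run and be verified
without downloading any reconstruction.

## The model and the screen

A metabolic network with stoichiometric matrix **S** is assumed at
steady state, `S·v = 0`, with flux bounds `lb ≤ v ≤ ub` in
mmol/(gDW·h). FBA predicts the growth rate as the biomass flux ν at the
optimum of

```
max ν   subject to   S·v = 0,  lb ≤ v ≤ ub .
```

The screen proceeds in three stages:

1. **Candidate space.** Knockout candidates are reactions that are
   gene-associated (non-empty GPR rule), *active-capable* — able to
   carry flux in the medium under a biomass-unconstrained flux
   variability analysis (only ν ≥ 0 is imposed, so low-growth scenarios
   count) — and not individually essential.
2. **Exhaustive double deletions.** Every unordered candidate pair is
   deleted (both flux directions forced to zero) and FBA re-run; a pair
   is synthetic lethal when the double mutant shows a no-growth
   phenotype (ν below 10⁻⁶ of wild type).
3. **Classification.** Against a deterministic reference optimum
   (parsimonious FBA: total absolute flux minimised at fixed optimal
   biomass), a pair with exactly one zero-flux member is **PSL**
   (plasticity: the idle member is a backup that switches on when its
   active partner is deleted), and a pair with two active members is
   **RSL** (redundancy: parallel use, usually with a fitness gain over
   either branch alone). Pairs contradicted by in-vivo gene
   essentiality — an essential gene that regulates only one member
   reaction, or a PSL pair whose members share isoenzymes or a single
   multifunctional enzyme — are flagged `PSL_I` / `RSL_I`.

Downstream analyses build the bipartite metabolite–reaction network
(distances between pair members), the pathway entanglement graph
(directed backup→active edges for PSL, undirected edges for RSL,
weights = pair counts), and re-test pairs across minimal-media panels,
enriched media, and growth-overconstrained media.

## Worked example

```python
from synlethal import SyntheticLethalityScreen
from synlethal.synthetic_data import kitchen_sink

model, medium, truth = kitchen_sink(seed=0)   # every motif, planted truth
res = SyntheticLethalityScreen(model, medium).fit()
print(res.summary())
```

```
Synthetic lethality screen
==========================
model:               toy_seed0
medium:              reference
FBA mode:            flux_minimized
wild-type growth:    10
candidate reactions: 8
pairs tested:        28
synthetic lethal:    4

class     pairs
RSL           1
RSL_I         0
PSL           3
PSL_I         0

base class  intra  inter (pathway)
RSL             1      0
PSL             0      3

RSL pairs with fitness gain from parallel use: 1
```

The toy network grows at ν = 10 (its uptake bound). Of the 28 candidate
pairs, 4 are synthetic lethal — exactly the planted ones. The pair
table shows the mechanism per pair:

```
    rxn_a     rxn_b subtype    active    backup  growth_wt  growth_ko_a  growth_ko_b
R_iso0_hi R_iso0_lo     PSL R_iso0_hi R_iso0_lo       10.0          5.0         10.0
R_med0_hi R_med0_lo     PSL R_med0_hi R_med0_lo       10.0          5.0         10.0
R_psl0_hi R_psl0_lo     PSL R_psl0_hi R_psl0_lo       10.0          5.0         10.0
R_rsl0_p1 R_rsl0_p2     RSL                           10.0          6.0          6.0
```

Each PSL pair loses half its growth when the *active* member is deleted
(the backup route consumes two substrate units per product, so yield
halves) and nothing when the idle backup is deleted. The RSL pair runs
two capacity-6 branches in parallel to meet a demand of 10: either
single knockout drops growth to 6, so parallel use increases fitness.

The same analysis runs from the shell on any model file:

```bash
synlethal run-all --model model_dir/ --medium medium.tsv --out results/
synlethal fixtures --seed 0 --n 20 --out fixtures/
```

## Layout

- `src/synlethal/` — library: `model`/`gpr`/`io` (data model and
  formats), `fba` (LP core), `screen`, `classify`, `topology`,
  `environments`, `synthetic_data`, `analysis` (Screen/Results
  objects), `cli`.
- `tests/` — unit, property and acceptance tests; `tests/_oracle.py` is
  the independent brute-force checker.
- `docs/methods.md` — modelling assumptions, parameter defaults,
  numerical choices, limitations.
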