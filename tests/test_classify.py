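"""PSL/RSL assignment, backup law, fitness comparison, inconsistency rules."""

from __future__ import annotations

import pytest

from synlethal.classify import (
    ClassificationError,
    SLPair,
    backup_activation_check,
    class_counts,
    classify_pair,
    count_genes_and_complexes,
    fitness_comparison,
    flag_inconsistencies,
)
from synlethal.fba import FluxState, fba
from synlethal.gpr import parse_gpr
from synlethal.model import (
    EssentialityAnnotation,
    Metabolite,
    MetabolicModel,
    Reaction,
    apply_medium,
)
from synlethal.synthetic_data import MotifSpec, make_toy_model


class TestSubtypeAssignment:
    def test_psl_roles(self, psl_fixture):
        model, _, _ = psl_fixture
        wt = fba(model)
        pair = classify_pair(frozenset({"R_psl0_hi", "R_psl0_lo"}), wt, model)
        assert pair.subtype == "PSL"
        assert pair.active_reaction == "R_psl0_hi"
        assert pair.backup_reaction == "R_psl0_lo"
        assert pair.growth_ko_a == pytest.approx(5.0, abs=1e-6)  # KO active
        assert pair.growth_ko_b == pytest.approx(10.0, abs=1e-6)  # KO backup

    def test_rsl_both_active(self, rsl_fixture):
        model, _, _ = rsl_fixture
        wt = fba(model)
        pair = classify_pair(frozenset({"R_rsl0_p1", "R_rsl0_p2"}), wt, model)
        assert pair.subtype == "RSL"
        assert abs(pair.wt_flux_a) > 1e-9 and abs(pair.wt_flux_b) > 1e-9

    def test_threshold_semantics(self, psl_fixture):
        """A 1e-12 flux counts as zero: the pair is plasticity."""
        model, _, _ = psl_fixture
        wt = fba(model)
        doctored = FluxState(
            {**wt.fluxes, "R_psl0_lo": 1e-12}, wt.objective_value, "optimal", wt.mode
        )
        pair = classify_pair(frozenset({"R_psl0_hi", "R_psl0_lo"}), doctored, model)
        assert pair.subtype == "PSL"
        assert pair.backup_reaction == "R_psl0_lo"

    def test_both_zero_rejected(self, psl_fixture):
        model, _, _ = psl_fixture
        wt = fba(model)
        doctored = FluxState(
            {**wt.fluxes, "R_psl0_hi": 0.0}, wt.objective_value, "optimal", wt.mode
        )
        with pytest.raises(ClassificationError):
            classify_pair(frozenset({"R_psl0_hi", "R_psl0_lo"}), doctored, model)


class TestBackupLaw:
    def test_backup_turns_on_and_growth_halves(self, psl_fixture):
        """Yield-ratio-2 motif: active KO lets the backup run at half yield."""
        model, _, _ = psl_fixture
        wt = fba(model)
        pair = classify_pair(frozenset({"R_psl0_hi", "R_psl0_lo"}), wt, model)
        backup_flux, growth = backup_activation_check(pair, model)
        assert backup_flux == pytest.approx(5.0, abs=1e-6)
        assert growth == pytest.approx(5.0, abs=1e-6)

    def test_backup_removal_leaves_growth_untouched(self, psl_fixture):
        model, _, _ = psl_fixture
        state = fba(model.knock_out(["R_psl0_lo"]))
        assert state.objective_value == pytest.approx(10.0, rel=1e-6)

    def test_equal_yield_limit(self):
        """As the backup's yield approaches the active route's, the growth
        penalty of losing the active member vanishes."""
        model, medium, _ = make_toy_model(MotifSpec({"psl_backup": 1}, yield_ratio=1.001))
        conditioned = apply_medium(model, medium)
        state = fba(conditioned.knock_out(["R_psl0_hi"]))
        assert state.objective_value == pytest.approx(10.0 / 1.001, abs=1e-6)


class TestFitness:
    def test_rsl_parallel_use_increases_fitness(self, rsl_fixture):
        model, _, _ = rsl_fixture
        wt = fba(model)
        pair = fitness_comparison(
            classify_pair(frozenset({"R_rsl0_p1", "R_rsl0_p2"}), wt, model)
        )
        assert pair.fitness_increased is True  # 10 > 6

    def test_capacity_slack_means_no_gain(self):
        """If either branch alone covers the demand, growth is unchanged."""
        pair = SLPair(
            "r1", "r2", "RSL", 5.0, 5.0,
            growth_wt=10.0, growth_ko_a=10.0, growth_ko_b=10.0,
        )
        assert fitness_comparison(pair).fitness_increased is False

    def test_not_applicable_for_psl(self, psl_fixture):
        model, _, _ = psl_fixture
        wt = fba(model)
        pair = fitness_comparison(
            classify_pair(frozenset({"R_psl0_hi", "R_psl0_lo"}), wt, model)
        )
        assert pair.fitness_increased is None


# ---------------------------------------------------------------------------
# inconsistency battery
# ---------------------------------------------------------------------------


def _gpr_model(gprs: dict[str, str]) -> MetabolicModel:
    """Structural stand-in model carrying only ids and GPRs (no LP is run)."""
    reactions = [
        Reaction(rid, {"x": -1.0}, 0.0, 1.0, gpr=parse_gpr(rule))
        for rid, rule in gprs.items()
    ]
    reactions.append(Reaction("BM", {"x": -1.0}, 0.0, 1.0, is_biomass=True))
    return MetabolicModel([Metabolite("x")], reactions, id="gpr_only")


def _pair(a, b, subtype, model, active=None, backup=None):
    return SLPair(
        a, b, subtype, 1.0, 1.0 if subtype == "RSL" else 0.0,
        growth_wt=10.0, growth_ko_a=5.0, growth_ko_b=10.0,
        active_reaction=active, backup_reaction=backup,
        genes_a=model.reaction(a).gpr, genes_b=model.reaction(b).gpr,
    )


class TestInconsistencyRules:
    def test_case1_both_nonessential_kept(self):
        model = _gpr_model({"r1": "g1", "r2": "g2"})
        ann = EssentialityAnnotation({"g1": "nonessential", "g2": "nonessential"})
        [out] = flag_inconsistencies([_pair("r1", "r2", "RSL", model)], ann, model)
        assert out.subtype == "RSL"

    def test_case2_single_reaction_essential_gene_flags(self):
        model = _gpr_model({"r1": "g1", "r2": "g2"})
        ann = EssentialityAnnotation({"g1": "essential", "g2": "nonessential"})
        [out] = flag_inconsistencies([_pair("r1", "r2", "PSL", model,
                                            active="r1", backup="r2")], ann, model)
        assert out.subtype == "PSL_I"
        assert out.inconsistency_reason == "single_reaction_essential_gene"

    def test_case2_multi_reaction_essential_gene_excused(self):
        # g1 regulates three reactions: its essentiality may refer to the others
        model = _gpr_model({"r1": "g1", "r2": "g2", "r3": "g1", "r4": "g1"})
        ann = EssentialityAnnotation({"g1": "essential", "g2": "nonessential"})
        [out] = flag_inconsistencies([_pair("r1", "r2", "RSL", model)], ann, model)
        assert out.subtype == "RSL"

    def test_case3_both_essential(self):
        # both multi-reaction -> excused; any single-reaction side -> flagged
        multi = _gpr_model({"r1": "g1", "r2": "g2", "r3": "g1", "r4": "g2"})
        ann = EssentialityAnnotation({"g1": "essential", "g2": "essential"})
        [out] = flag_inconsistencies([_pair("r1", "r2", "RSL", multi)], ann, multi)
        assert out.subtype == "RSL"

        mixed = _gpr_model({"r1": "g1", "r2": "g2", "r3": "g1"})
        [out] = flag_inconsistencies([_pair("r1", "r2", "RSL", mixed)], ann, mixed)
        assert out.subtype == "RSL_I"
        assert out.inconsistency_reason == "both_members_essential_genes"

    def test_isoenzyme_psl_pair_flagged(self):
        model = _gpr_model({"r1": "gx or gy", "r2": "gx or gy"})
        ann = EssentialityAnnotation({"gx": "nonessential", "gy": "nonessential"})
        [out] = flag_inconsistencies([_pair("r1", "r2", "PSL", model,
                                            active="r1", backup="r2")], ann, model)
        assert out.subtype == "PSL_I"
        assert out.inconsistency_reason == "isoenzymes"

    def test_multifunctional_psl_pair_flagged(self):
        model = _gpr_model({"r1": "g1", "r2": "g1"})
        ann = EssentialityAnnotation({"g1": "nonessential"})
        [out] = flag_inconsistencies([_pair("r1", "r2", "PSL", model,
                                            active="r1", backup="r2")], ann, model)
        assert out.subtype == "PSL_I"
        assert out.inconsistency_reason == "multifunctional_enzyme"

    def test_enzyme_rule_spares_rsl_pairs(self):
        """The enzyme-identity rule targets the plasticity subtype only."""
        model = _gpr_model({"r1": "gx or gy", "r2": "gx or gy"})
        ann = EssentialityAnnotation({"gx": "nonessential", "gy": "nonessential"})
        [out] = flag_inconsistencies([_pair("r1", "r2", "RSL", model)], ann, model)
        assert out.subtype == "RSL"

    def test_explicit_curated_list_path(self):
        model = _gpr_model({"r1": "g1", "r2": "g2"})
        ann = EssentialityAnnotation({"g1": "nonessential", "g2": "nonessential"})
        [out] = flag_inconsistencies(
            [_pair("r1", "r2", "PSL", model, active="r1", backup="r2")],
            ann, model, explicit_enzyme_pairs={frozenset({"r1", "r2"})},
        )
        assert out.subtype == "PSL_I"
        assert out.inconsistency_reason == "curated_enzyme_pair"

    def test_unknown_gene_policies(self):
        model = _gpr_model({"r1": "g1", "r2": "gmissing"})
        lax = EssentialityAnnotation({"g1": "nonessential"})
        [out] = flag_inconsistencies([_pair("r1", "r2", "RSL", model)], lax, model)
        assert out.subtype == "RSL"  # unknown defaults to nonessential
        strict = EssentialityAnnotation({"g1": "nonessential"}, unknown_policy="strict")
        with pytest.raises(Exception):
            flag_inconsistencies([_pair("r1", "r2", "RSL", model)], strict, model)


class TestCounting:
    def test_shared_reaction_counted_once(self):
        model = _gpr_model({"r1": "g1", "r2": "g2", "r3": "g3"})
        pairs = [
            _pair("r1", "r2", "RSL", model),
            _pair("r1", "r3", "RSL", model),
        ]
        counts = count_genes_and_complexes(pairs, model)
        assert counts["RSL"] == (3, 3)

    def test_complex_counts_as_one_unit_isoenzymes_as_two(self):
        model = _gpr_model({"r1": "g1 and g2", "r2": "g3 or g4"})
        counts = count_genes_and_complexes(
            [_pair("r1", "r2", "RSL", model)], model
        )
        assert counts["RSL"] == (2, 3)  # {g1,g2} is one unit; g3, g4 two

    def test_partition_into_four_classes(self, kitchen_sink_fixture):
        from synlethal.analysis import SyntheticLethalityScreen

        model, medium, _ = kitchen_sink_fixture
        ann = EssentialityAnnotation({g: "nonessential" for g in model.genes})
        res = SyntheticLethalityScreen(model, medium, annotation=ann).fit()
        counts = class_counts(res.pairs)
        assert sum(counts.values()) == len(res.pairs)
        assert all(p.subtype in counts for p in res.pairs)
        # the shared-OR-rule motif is picked up as an isoenzyme inconsistency
        assert counts["PSL_I"] >= 1
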