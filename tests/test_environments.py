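"""Media panels, enrichment, overconstraining, and cross-environment screens."""

from __future__ import annotations

import pytest

from synlethal.analysis import SyntheticLethalityScreen
from synlethal.environments import (
    MediaPanel,
    build_minimal_media_panel,
    compare_pair_sets,
    enrich_medium,
    media_sensitivity,
    overconstrain_by_growth,
)
from synlethal.fba import fba
from synlethal.gpr import parse_gpr
from synlethal.model import (
    ConfigurationError,
    Medium,
    Metabolite,
    MetabolicModel,
    Reaction,
    apply_medium,
)
from synlethal.screen import essential_reactions
from synlethal.synthetic_data import MotifSpec, make_toy_model


def _two_carbon_model() -> MetabolicModel:
    """Growth on either of two interchangeable carbon sources."""
    mets = [Metabolite(m) for m in ("G", "F", "A")]
    rxns = [
        Reaction("EX_G", {"G": -1.0}, 0.0, 1e6, is_exchange=True),
        Reaction("EX_F", {"F": -1.0}, 0.0, 1e6, is_exchange=True),
        Reaction("R_g", {"G": -1.0, "A": 1.0}, 0.0, 1e6, gpr=parse_gpr("gg")),
        Reaction("R_f", {"F": -1.0, "A": 1.0}, 0.0, 1e6, gpr=parse_gpr("gf")),
        Reaction("BM", {"A": -1.0}, 0.0, 1e6, is_biomass=True),
    ]
    return MetabolicModel(mets, rxns, id="two_carbon")


class TestMediaPanel:
    def test_enumeration_and_filtering(self):
        model = _two_carbon_model()
        panel = build_minimal_media_panel(
            salts=Medium({}, label="salts"),
            sources={"C": ["EX_G", "EX_F", "EX_NOPE"]},
            reference={"C": "EX_G"},
            model=model,
        )
        # reference + fructose are viable; the absent compound is filtered
        assert panel.n_constructed == 3
        assert panel.n_viable == 2
        assert panel.viable_flags["C:EX_NOPE"] is False
        labels = {m.label for m in panel.media}
        assert labels == {"reference", "C:EX_F"}

    def test_every_retained_medium_grows(self):
        model = _two_carbon_model()
        panel = build_minimal_media_panel(
            Medium({}), {"C": ["EX_G", "EX_F"]}, {"C": "EX_G"}, model
        )
        for medium in panel.media:
            state = fba(apply_medium(model, medium), mode="raw")
            assert state.objective_value > 1e-6

    def test_inviable_reference_rejected(self):
        model = _two_carbon_model()
        with pytest.raises(ConfigurationError):
            build_minimal_media_panel(
                Medium({}), {"C": ["EX_G"]}, {"C": "EX_NOPE"}, model
            )


class TestEnrichment:
    def test_adds_uptake_bounds(self):
        model = _two_carbon_model()
        base = Medium({"EX_G": -10.0}, label="min")
        rich = enrich_medium(base, ["EX_F"], model)
        assert rich.uptake_bounds == {"EX_G": -10.0, "EX_F": -10.0}

    def test_empty_list_identity(self):
        model = _two_carbon_model()
        base = Medium({"EX_G": -10.0})
        assert enrich_medium(base, [], model).uptake_bounds == base.uptake_bounds

    def test_unknown_compound_skipped_with_warning(self):
        model = _two_carbon_model()
        base = Medium({"EX_G": -10.0})
        with pytest.warns(UserWarning):
            rich = enrich_medium(base, ["EX_MISSING"], model)
        assert rich.uptake_bounds == base.uptake_bounds

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_enrichment_never_decreases_growth(self, seed):
        """Opening extra uptakes only enlarges the feasible region."""
        from synlethal.synthetic_data import random_motif_spec

        model, medium, _ = make_toy_model(random_motif_spec(seed))
        before = fba(apply_medium(model, medium), mode="raw").objective_value
        all_ex = [r.id for r in model.exchange_reactions]
        rich = enrich_medium(medium, all_ex, model)
        after = fba(apply_medium(model, rich), mode="raw").objective_value
        assert after >= before - 1e-9


class TestOverconstrain:
    def test_mineral_salts_mode_toy(self):
        """Fixing growth at 30% caps the single salt uptake at 3; the
        re-optimised model then grows at exactly 3."""
        from synlethal.synthetic_data import toy_rsl

        model, medium, _ = toy_rsl()
        new = overconstrain_by_growth(
            model, medium, 0.3, "mineral_salts", salt_exchanges=["EX_A_rsl0"]
        )
        assert new.uptake_bounds["EX_A_rsl0"] == pytest.approx(-3.0, abs=1e-6)
        state = fba(apply_medium(model, new), mode="raw")
        assert state.objective_value == pytest.approx(3.0, abs=1e-6)

    def test_basic_sources_mode_toy(self):
        from synlethal.synthetic_data import toy_rsl

        model, medium, _ = toy_rsl()
        new = overconstrain_by_growth(
            model, medium, 0.3, "basic_sources", source_exchanges=["EX_A_rsl0"]
        )
        state = fba(apply_medium(model, new), mode="raw")
        assert state.objective_value == pytest.approx(3.0, abs=1e-6)

    def test_fraction_one_changes_nothing(self):
        from synlethal.synthetic_data import toy_rsl

        model, medium, _ = toy_rsl()
        new = overconstrain_by_growth(
            model, medium, 1.0, "mineral_salts", salt_exchanges=["EX_A_rsl0"]
        )
        state = fba(apply_medium(model, new), mode="raw")
        assert state.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_essentiality_conserved_under_overconstraining(self, kitchen_sink_fixture):
        model, medium, truth = kitchen_sink_fixture
        new = overconstrain_by_growth(
            model, medium, 0.3, "mineral_salts",
            salt_exchanges=sorted(medium.uptake_bounds),
        )
        essential = essential_reactions(apply_medium(model, new))
        assert essential == truth.essential


class TestSensitivity:
    def test_medium_dependent_pair_lethal_in_planted_subset(self):
        model, medium, truth = make_toy_model(
            MotifSpec({"medium_dependent_backup": 1, "psl_backup": 1})
        )
        res = SyntheticLethalityScreen(model, medium).fit()
        panel = MediaPanel(truth.media, [], {m.label: True for m in truth.media})
        profile = res.media_sensitivity(panel)
        by_pair = {frozenset({r["rxn_a"], r["rxn_b"]}): r for r in profile.table()}
        for members, expected_media in truth.media_lethal.items():
            row = by_pair[members]
            assert row["n_media_tested"] == len(truth.media)
            assert row["n_media_lethal"] == len(expected_media)
        # the rescue-dependent pair is lethal in half the panel, the plain one in all
        fractions = sorted(r["fraction_lethal"] for r in profile.table())
        assert fractions == [0.5, 1.0]

    def test_bookkeeping_invariant(self):
        model, medium, truth = make_toy_model(MotifSpec({"psl_backup": 1}))
        res = SyntheticLethalityScreen(model, medium).fit()
        panel = MediaPanel(truth.media, [], {})
        profile = res.media_sensitivity(panel)
        for row in profile.table():
            assert 0 <= row["n_media_psl"] <= row["n_media_lethal"] <= row["n_media_tested"]


class TestComparison:
    def test_identity(self, kitchen_sink_fixture):
        model, medium, _ = kitchen_sink_fixture
        res = SyntheticLethalityScreen(model, medium).fit()
        cmp = res.compare(res)
        assert cmp.n_conserved == len(res.pairs)
        assert not cmp.rescued and not cmp.novel
        assert not cmp.subtype_switches and not cmp.activity_switches

    def test_rescued_pair_in_enriched_environment(self):
        """Opening the rescue nutrient de-lethalises the planted pair."""
        model, medium, truth = make_toy_model(MotifSpec({"medium_dependent_backup": 1}))
        ref = SyntheticLethalityScreen(model, medium).fit()
        alt_medium = truth.media[1]
        alt = SyntheticLethalityScreen(model, alt_medium).fit()
        cmp = ref.compare(alt)
        assert cmp.n_rescued == 1
        assert cmp.n_conserved == 0

    def test_subtype_switch_bookkeeping(self):
        from synlethal.classify import SLPair

        def mk(subtype, active=None):
            return SLPair("r1", "r2", subtype, 1.0, 1.0, 10.0, 5.0, 5.0,
                          active_reaction=active,
                          backup_reaction=None if active is None else
                          ("r2" if active == "r1" else "r1"))

        cmp = compare_pair_sets([mk("PSL", "r1")], [mk("RSL")])
        assert cmp.subtype_switches == [(frozenset({"r1", "r2"}), "PSL", "RSL")]
        cmp2 = compare_pair_sets([mk("PSL", "r1")], [mk("PSL", "r2")])
        assert cmp2.activity_switches == [frozenset({"r1", "r2"})]
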