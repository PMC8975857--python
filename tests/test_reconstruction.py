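"""Role imputation, role->reaction mapping, draft models and gap-filling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cecogem import (
    BIOMASS_MET,
    FBAProblem,
    GapfillError,
    GenusRoleProfile,
    Metabolite,
    Reaction,
    ReactionComplex,
    StoichiometricModel,
    UniversalReactionDB,
    build_draft_model,
    enumerate_gapfill_optimum,
    fit_cooccurrence,
    gapfill,
    impute_roles,
    make_gapfill_instance,
    roles_to_reactions,
)


class TestCooccurrence:
    def test_laplace_marginal(self):
        ref = pd.DataFrame({"a": [1, 1, 1, 1], "b": [0, 1, 0, 1]})
        model = fit_cooccurrence(ref, pseudocount=1.0)
        assert model.marginals["a"] == pytest.approx(5 / 6)

    def test_unsmoothed_absent_role_has_zero_marginal(self):
        ref = pd.DataFrame({"a": [1, 0], "b": [0, 0]})
        model = fit_cooccurrence(ref, pseudocount=0.0)
        assert model.marginals["b"] == 0.0

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError):
            fit_cooccurrence(pd.DataFrame({"a": [1], "b": [0]}))

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.5, 3.0))
    def test_joint_bounded_by_marginals(self, seed, c):
        rng = np.random.default_rng(seed)
        ref = pd.DataFrame(rng.integers(0, 2, size=(5, 4)), columns=list("abcd"))
        model = fit_cooccurrence(ref, pseudocount=c)
        for i in "abcd":
            for j in "abcd":
                assert model.joints.at[i, j] <= min(
                    model.marginals[i], model.marginals[j]
                ) + 1e-12
                cond = model.joints.at[i, j] / model.marginals[i]
                assert 0.0 <= cond <= 1.0


class TestImputeRoles:
    def _model(self):
        # X always co-occurs with A; Y never does
        ref = pd.DataFrame(
            {"A": [1, 1, 1, 1], "X": [1, 1, 1, 1], "Y": [0, 0, 0, 0], "Z": [1, 0, 1, 0]}
        )
        return fit_cooccurrence(ref, pseudocount=1.0)

    def test_no_op_when_target_met(self):
        profile = GenusRoleProfile("g", frozenset({"A"}), target_role_count=1)
        assert impute_roles(profile, self._model()) is profile

    def test_cooccurring_role_wins(self):
        profile = GenusRoleProfile("g", frozenset({"A"}), target_role_count=2)
        out = impute_roles(profile, self._model())
        assert out.roles == frozenset({"A", "X"})

    def test_output_count_capped_by_universe(self):
        profile = GenusRoleProfile("g", frozenset({"A"}), target_role_count=99)
        out = impute_roles(profile, self._model())
        assert out.roles == frozenset({"A", "X", "Y", "Z"})

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_scores_are_probabilities_and_deterministic(self, seed):
        rng = np.random.default_rng(seed)
        ref = pd.DataFrame(rng.integers(0, 2, size=(6, 5)), columns=list("abcde"))
        model = fit_cooccurrence(ref)
        obs = frozenset(rng.choice(list("abcde"), size=2, replace=False))
        for cand in "abcde":
            s = model.score(cand, obs)
            assert 0.0 <= s <= 1.0
        p1 = impute_roles(GenusRoleProfile("g", obs, target_role_count=4), model)
        p2 = impute_roles(GenusRoleProfile("g", obs, target_role_count=4), model)
        assert p1.roles == p2.roles


@pytest.fixture(scope="module")
def mapping_db():
    """5 roles / 4 complexes / 4 reactions exercising the mapping rules."""
    mets = {
        "m1": Metabolite("m1", compartment="c"),
        "m2": Metabolite("m2", compartment="c"),
        BIOMASS_MET: Metabolite(BIOMASS_MET, compartment="c"),
    }
    rxns = {
        f"R{i}": Reaction(f"R{i}", {"m1": -1.0, "m2": 1.0}) for i in range(1, 5)
    }
    complexes = {
        "c1": ReactionComplex("c1", frozenset({"R1"}), frozenset({"a", "b"})),
        "c2": ReactionComplex("c2", frozenset({"R2"}), frozenset({"c"})),
        "c3": ReactionComplex("c3", frozenset({"R2", "R3"}), frozenset({"d"})),
        "c4": ReactionComplex("c4", frozenset({"R4"}), frozenset({"e"})),
    }
    role_map = {
        "a": frozenset({"c1"}), "b": frozenset({"c1"}), "c": frozenset({"c2"}),
        "d": frozenset({"c3"}), "e": frozenset({"c4"}),
    }
    templates = {g: {"m2": -1.0, BIOMASS_MET: 1.0} for g in ("positive", "negative")}
    return UniversalReactionDB(mets, rxns, role_map, complexes, templates)


class TestRolesToReactions:
    def test_partial_complex_mode_dependent(self, mapping_db):
        profile = GenusRoleProfile("g", frozenset({"a"}))
        assert roles_to_reactions(profile, mapping_db, "all_roles") == set()
        assert roles_to_reactions(profile, mapping_db, "any_role") == {"R1"}

    def test_two_complexes_one_reaction(self, mapping_db):
        # R2 reachable through c2 (role c) or c3 (role d); either suffices
        for roles in ({"c"}, {"d"}, {"c", "d"}):
            out = roles_to_reactions(
                GenusRoleProfile("g", frozenset(roles)), mapping_db
            )
            assert "R2" in out

    def test_full_enumeration(self, mapping_db):
        profile = GenusRoleProfile("g", frozenset({"a", "b", "d"}))
        assert roles_to_reactions(profile, mapping_db) == {"R1", "R2", "R3"}

    @settings(max_examples=60, derandomize=True)
    @given(st.sets(st.sampled_from(list("abcde"))))
    def test_all_roles_subset_of_any_role(self, mapping_db, roles):
        profile = GenusRoleProfile("g", frozenset(roles))
        strict = roles_to_reactions(profile, mapping_db, "all_roles")
        loose = roles_to_reactions(profile, mapping_db, "any_role")
        assert strict <= loose


class TestBuildDraftModel:
    def test_transporter_grants_exactly_one_uptake(self, study, toy_db):
        truth = study.genera["g05_specialist"]
        model = truth.model
        assert set(model.uptakes.values()) == {"Csrc05_e", "Nsrc03_e", "Min_e"}

    def test_gram_switches_biomass_template(self, toy_db):
        profile_n = GenusRoleProfile("g", frozenset(), gram="negative")
        profile_p = GenusRoleProfile("g", frozenset(), gram="positive")
        m_n = build_draft_model(set(), profile_n, toy_db)
        m_p = build_draft_model(set(), profile_p, toy_db)
        assert (
            m_n.reactions["bio1"].stoichiometry != m_p.reactions["bio1"].stoichiometry
        )
        with pytest.raises(ValueError, match="gram"):
            build_draft_model(set(), GenusRoleProfile("g", frozenset(), gram="x"), toy_db)

    def test_reaction_columns_match_database(self, toy_db):
        profile = GenusRoleProfile("g", frozenset(), gram="negative")
        model = build_draft_model({"T_Csrc01", "V_Csrc01"}, profile, toy_db)
        for rid in ("T_Csrc01", "V_Csrc01"):
            assert model.reactions[rid].stoichiometry == dict(
                toy_db.reactions[rid].stoichiometry
            )

    def test_serialization_round_trip_is_bit_identical(self, study, tmp_path):
        model = study.genera["g01_generalist"].model
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        model.save(p1)
        StoichiometricModel.load(p1).save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_db_round_trip_is_bit_identical(self, toy_db, tmp_path):
        p1, p2 = tmp_path / "d1.json", tmp_path / "d2.json"
        toy_db.save(p1)
        UniversalReactionDB.load(p1).save(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestGapfill:
    def test_viable_model_adds_nothing(self, study, toy_db):
        model = study.genera["g03_moderate"].model
        filled, added = gapfill(model, toy_db)
        assert added == frozenset()

    def test_two_paths_cheapest_chosen(self):
        # alternative single-reaction paths with penalties 1 and 5
        mets = {
            "S_e": Metabolite("S_e", formula="C2H4O2", compartment="e"),
            "S_c": Metabolite("S_c", formula="C2H4O2", compartment="c"),
            "P_c": Metabolite("P_c", compartment="c"),
            BIOMASS_MET: Metabolite(BIOMASS_MET, compartment="c"),
        }
        rxns = {
            "T_S": Reaction("T_S", {"S_e": -1.0, "S_c": 1.0}, is_transport=True),
            "cheap": Reaction("cheap", {"S_c": -1.0, "P_c": 1.0}, penalty=1.0),
            "dear": Reaction("dear", {"S_c": -1.0, "P_c": 1.0}, penalty=5.0),
        }
        role_map = {"t": frozenset({"cx"})}
        complexes = {"cx": ReactionComplex("cx", frozenset({"T_S"}), frozenset({"t"}))}
        templates = {g: {"P_c": -1.0, BIOMASS_MET: 1.0} for g in ("positive", "negative")}
        db = UniversalReactionDB(mets, rxns, role_map, complexes, templates)
        model = build_draft_model({"T_S"}, GenusRoleProfile("g", frozenset({"t"})), db)
        filled, added = gapfill(model, db)
        assert added == frozenset({"cheap"})
        assert filled.added_by_gapfill == frozenset({"cheap"})

    def test_missing_biomass_reaction_rejected(self, study, toy_db):
        model = study.genera["g03_moderate"].model
        broken = StoichiometricModel(
            genus=model.genus,
            reactions={k: v for k, v in model.reactions.items() if k != "bio1"},
            biomass_reaction="bio1",
            uptakes=dict(model.uptakes),
            gram=model.gram,
            external_atoms=dict(model.external_atoms),
        )
        with pytest.raises(ValueError):
            gapfill(broken, toy_db)

    def test_ungapfillable_raises_named_error(self):
        mets = {
            "P_c": Metabolite("P_c", compartment="c"),
            "Q_c": Metabolite("Q_c", compartment="c"),
            BIOMASS_MET: Metabolite(BIOMASS_MET, compartment="c"),
        }
        # the only reaction cannot make P_c from anything
        rxns = {"R": Reaction("R", {"P_c": -1.0, "Q_c": 1.0})}
        templates = {g: {"P_c": -1.0, BIOMASS_MET: 1.0} for g in ("positive", "negative")}
        db = UniversalReactionDB(mets, rxns, {}, {}, templates)
        model = build_draft_model(set(), GenusRoleProfile("gX", frozenset()), db)
        with pytest.raises(GapfillError, match="gX"):
            gapfill(model, db)

    def test_gapped_genus_regrows_after_gapfill(self, toy_db):
        from cecogem import default_genus_specs, make_genus, roles_to_reactions

        spec = default_genus_specs(toy_db)[0]
        truth = make_genus(toy_db, spec, gap_fraction=0.2, seed=5)
        draft = build_draft_model(
            roles_to_reactions(truth.profile, toy_db), truth.profile, toy_db
        )
        filled, added = gapfill(draft, toy_db)
        prob = FBAProblem(filled)
        assert prob.max_biomass(prob.complete_media(uptake_bound=100.0)) >= 0.001

    def test_matches_enumeration_on_fixed_instance(self):
        model, db = make_gapfill_instance(seed=3)
        filled, added = gapfill(model, db)
        cost = sum(db.reactions[r].penalty for r in added)
        opt, _ = enumerate_gapfill_optimum(model, db)
        assert cost == pytest.approx(opt, abs=1e-9)
        prob = FBAProblem(filled)
        assert prob.max_biomass(prob.complete_media(uptake_bound=100.0)) >= 0.001
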