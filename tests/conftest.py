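"""Shared fixtures: hand-built chain models and the synthetic study."""

import pytest

from cecogem import (
    FBAProblem,
    ModelReaction,
    StoichiometricModel,
    make_community_study,
    make_universal_db,
    phenotype_all,
)

B = 1000.0


def _model(genus, reactions, uptakes, external_atoms, gram="negative"):
    m = StoichiometricModel(
        genus=genus,
        reactions={r.id: r for r in reactions},
        biomass_reaction="bio1",
        uptakes=uptakes,
        gram=gram,
        external_atoms=external_atoms,
    )
    m.validate()
    return m


@pytest.fixture
def chain_model():
    """Linear chain: uptake A <= 10, A -> B, biomass consumes 2 B per unit.

    Analytic optimum: biomass = 5.
    """
    return _model(
        "chain",
        [
            ModelReaction("UP_A_e", {"A_e": 1.0}, 0.0, 10.0),
            ModelReaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, B),
            ModelReaction("CNV", {"A_c": -1.0, "B_c": 1.0}, 0.0, B),
            ModelReaction("bio1", {"B_c": -2.0, "biomass": 1.0}, 0.0, B),
            ModelReaction("SINK_biomass", {"biomass": -1.0}, 0.0, B),
        ],
        {"UP_A_e": "A_e"},
        {"A_e": (1, 0)},
    )


@pytest.fixture
def branch_model():
    """Two substrates converge on B: A -> B (yield 1, uptake <= 10) and
    C -> B (yield 2, uptake <= 3); biomass consumes 1 B.  Optimum 16."""
    return _model(
        "branch",
        [
            ModelReaction("UP_A_e", {"A_e": 1.0}, 0.0, 10.0),
            ModelReaction("UP_C_e", {"C_e": 1.0}, 0.0, 3.0),
            ModelReaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, B),
            ModelReaction("T_C", {"C_e": -1.0, "C_c": 1.0}, 0.0, B),
            ModelReaction("CNV_A", {"A_c": -1.0, "B_c": 1.0}, 0.0, B),
            ModelReaction("CNV_C", {"C_c": -1.0, "B_c": 2.0}, 0.0, B),
            ModelReaction("bio1", {"B_c": -1.0, "biomass": 1.0}, 0.0, B),
            ModelReaction("SINK_biomass", {"biomass": -1.0}, 0.0, B),
        ],
        {"UP_A_e": "A_e", "UP_C_e": "C_e"},
        {"A_e": (1, 0), "C_e": (1, 0)},
    )


@pytest.fixture
def glucose_model():
    """Sole carbon source with 6 C atoms feeding biomass 2:1 via a carbon unit.

    Under a 10-carbon budget the uptake is 10/6, the carbon-unit supply 10 and
    biomass 5; exempted at bound 100 the supply is 600 and biomass 300.
    """
    return _model(
        "glc",
        [
            ModelReaction("UP_glc_e", {"glc_e": 1.0}, 0.0, 100.0),
            ModelReaction("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, B),
            ModelReaction("CNV", {"glc_c": -1.0, "CP_c": 6.0}, 0.0, B),
            ModelReaction("bio1", {"CP_c": -2.0, "biomass": 1.0}, 0.0, B),
            ModelReaction("SINK_biomass", {"biomass": -1.0}, 0.0, B),
        ],
        {"UP_glc_e": "glc_e"},
        {"glc_e": (6, 0)},
    )


@pytest.fixture
def ammonia_model():
    """Sole nitrogen source (1 N) feeding biomass 2:1 via a nitrogen carrier."""
    return _model(
        "nh3",
        [
            ModelReaction("UP_nh3_e", {"nh3_e": 1.0}, 0.0, 100.0),
            ModelReaction("T_nh3", {"nh3_e": -1.0, "nh3_c": 1.0}, 0.0, B),
            ModelReaction("CNV", {"nh3_c": -1.0, "NP_c": 1.0}, 0.0, B),
            ModelReaction("bio1", {"NP_c": -2.0, "biomass": 1.0}, 0.0, B),
            ModelReaction("SINK_biomass", {"biomass": -1.0}, 0.0, B),
        ],
        {"UP_nh3_e": "nh3_e"},
        {"nh3_e": (0, 1)},
    )


@pytest.fixture(scope="session")
def toy_db():
    return make_universal_db(seed=1)


@pytest.fixture(scope="session")
def study(toy_db):
    """Default synthetic community study (un-gapped genera, seed 7)."""
    return make_community_study(seed=7, db=toy_db)


@pytest.fixture(scope="session")
def study_phenotypes(study, toy_db):
    """Phenotype screens over the study genera (shared across tests)."""
    models = [t.model for t in study.genera.values()]
    util, ess, failures = phenotype_all(models, toy_db, n_media=400, seed=11)
    assert not failures
    return util, ess
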