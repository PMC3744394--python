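"""Structural tests: species/reaction enumeration, stoichiometry, moieties,
and thermodynamic consistency of the parameterization."""

import dataclasses

import numpy as np
import pytest

from betaox.config import KEQ_CROTONASE, default_parameters
from betaox.network import (
    CHAINS,
    ConfigurationError,
    MetaboliteSpec,
    ModelVariant,
    NetworkError,
    build_network,
    conserved_moieties,
    stoichiometric_matrix,
    validate_microscopic_reversibility,
)

CARBONS = {"acylCoA": None, "acetylCoA": 2}


def test_standard_counts(network, params):
    assert network.n_species == 45
    assert network.n_reactions == 56
    assert params.n_parameters == 234


def test_boundary_species_have_no_ode_row(network):
    for s in network.boundary:
        assert s.name not in network.index
    # NAD/NADH appear in reactions but are clamped
    names = {s.name for s in network.boundary}
    assert {"NAD_m", "NADH_m", "palmitoylCoA_e", "carnitine_e"} <= names


def test_minimal_single_cycle_network_hand_enumeration():
    # one C4 cycle through the crotonase branch, no shuttle, no CPT1:
    # species acyl/enoyl/hydroxy/keto-C4, acetyl-CoA, CoASH; five reactions
    spec = {"SCAD": (4,), "crotonase": (4,), "MSCHAD": (4,), "MCKAT": (4,)}
    net = build_network(spec)
    assert sorted(net.species_names()) == sorted(
        ["acylCoA_C4_m", "enoylCoA_C4_m", "hydroxyacylCoA_C4_m",
         "ketoacylCoA_C4_m", "acetylCoA_m", "CoASH_m"]
    )
    assert [r.name for r in net.reactions] == [
        "SCAD_C4", "crotonase_C4", "MSCHAD_C4", "MCKAT_C4", "acetylCoA_sink"
    ]
    # C4 thiolysis yields two acetyl-CoA
    mckat = net.reactions[3]
    assert mckat.stoichiometry["acetylCoA_m"] == 2


def test_odd_chain_length_rejected():
    with pytest.raises(ConfigurationError):
        build_network({"SCAD": (5,)})
    with pytest.raises(ConfigurationError):
        build_network({"MCKAT": (18,)})
    with pytest.raises(ConfigurationError, match="CPT1"):
        build_network({"CPT1": (14,)})
    with pytest.raises(ConfigurationError, match="crotonase branch"):
        build_network({"MTP": (6,)})


def test_dead_end_species_flagged_by_name():
    # MTP at C8 produces hexanoyl-CoA, but nothing consumes it
    with pytest.raises(NetworkError, match="acylCoA_C6_m"):
        build_network({"LCAD": (8,), "crotonase": (8,), "MSCHAD": (8,),
                       "MCKAT": (8,), "MTP": (8,)})


def test_chain_indexed_species_validation():
    from betaox.network import Compartment, SpeciesClass

    with pytest.raises(ConfigurationError):
        MetaboliteSpec("CoASH_m", SpeciesClass.CoASH, 4, Compartment.matrix)
    with pytest.raises(ConfigurationError):
        MetaboliteSpec("acylCoA_C5_m", SpeciesClass.acylCoA, 5, Compartment.matrix)


def test_stoichiometric_matrix_columns(network):
    N = stoichiometric_matrix(network)
    assert N.shape == (45, 56)
    assert np.array_equal(N, np.round(N))
    i = network.index["enoylCoA_C14_m"]
    names = [r.name for r in network.reactions]
    # formed by VLCAD and LCAD, consumed by crotonase and MTP
    assert N[i, names.index("VLCAD_C14")] == 1
    assert N[i, names.index("LCAD_C14")] == 1
    assert N[i, names.index("crotonase_C14")] == -1
    assert N[i, names.index("MTP_C14")] == -1
    assert np.count_nonzero(N[i]) == 4


def test_every_reaction_balances_carbon(network):
    carbons = {}
    for s in list(network.species) + list(network.boundary):
        carbons[s.name] = s.carbons
    for r in network.reactions:
        if r.rate_law_kind == "sink":
            continue  # deliberately exports the C2 unit
        total = sum(carbons[name] * c for name, c in r.stoichiometry.items())
        assert total == 0, r.name


def test_rank_deficiency_matches_conserved_moieties(network):
    moieties = [m for m in conserved_moieties(network) if m.get("weights") is not None]
    rank = np.linalg.matrix_rank(network.N)
    assert network.n_species - rank == len(moieties) == 2


def test_moiety_vectors_in_left_null_space(network):
    for m in conserved_moieties(network):
        if m.get("weights") is None:
            continue
        assert np.all(m["weights"] @ network.N == 0)


def test_coa_moiety_membership(network):
    (coa,) = [m for m in conserved_moieties(network) if m["name"] == "CoA"]
    members = set(coa["members"])
    assert "CoASH_m" in members and "acetylCoA_m" in members
    for n in CHAINS:
        assert f"acylCoA_C{n}_m" in members
        assert f"hydroxyacylCoA_C{n}_m" in members
        # carnitine esters carry no CoA
        assert f"acylcarnitine_C{n}_m" not in members
        assert f"acylcarnitine_C{n}_e" not in members


def test_clamped_coash_breaks_coa_moiety():
    net = build_network(variant=ModelVariant(clamped_species={"CoASH_m": 500.0}))
    assert net.n_species == 44
    (coa,) = [m for m in conserved_moieties(net) if m["name"] == "CoA"]
    assert coa["broken"]


def test_no_competition_variant_preserves_species_and_reactions(network, params):
    fractions = {}
    for enzyme in ("VLCAD", "LCAD", "MCAD", "SCAD", "crotonase", "MSCHAD", "MCKAT", "MTP"):
        chains = network.specificity[enzyme]
        for n in chains:
            fractions[(enzyme, n)] = 1.0 / len(chains)
    net = build_network(variant=ModelVariant(competition=False, enzyme_fractions=fractions))
    assert net.n_species == 45
    assert net.n_reactions == 56
    assert net.n_enzyme_pools > network.n_enzyme_pools


def test_dedicated_fractions_must_sum_to_one():
    with pytest.raises(ConfigurationError, match="sum"):
        ModelVariant(competition=False,
                     enzyme_fractions={("SCAD", 4): 0.6, ("SCAD", 6): 0.6})


def test_microscopic_reversibility_of_shipped_set(params):
    report = validate_microscopic_reversibility(params)
    assert report["passed"]
    assert {c["chain"] for c in report["checks"]} == {8, 10, 12, 14, 16}
    for c in report["checks"]:
        assert c["lumped"] == pytest.approx(0.7)
    # the crotonase Keq implied by the printed constants
    assert KEQ_CROTONASE == pytest.approx(0.7 / (2.2e-4 * 1.1e3), rel=1e-12)
    assert params.keq[("crotonase", 8)] == pytest.approx(2.8925619834710743, rel=1e-12)


def test_perturbed_keq_fails_only_affected_chains(params):
    keq = dict(params.keq)
    keq[("MSCHAD", 12)] = keq[("MSCHAD", 12)] * 1.1
    bad = dataclasses.replace(params, keq=keq)
    report = validate_microscopic_reversibility(bad)
    assert not report["passed"]
    failed = {c["chain"] for c in report["checks"] if not c["passed"]}
    assert failed == {12}


def test_missing_keq_names_the_constant(params):
    keq = {k: v for k, v in params.keq.items() if k != ("MCKAT", 10)}
    incomplete = dataclasses.replace(params, keq=keq)
    with pytest.raises(ConfigurationError, match="MCKAT"):
        validate_microscopic_reversibility(incomplete)
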