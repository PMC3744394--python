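"""Rate-law unit tests: closed-form values, equilibrium zeros, competition
and inhibition properties, and parameter validation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from betaox.dynamics import CompiledModel
from betaox.kinetics import (
    DomainError,
    RateContext,
    ester_pair,
    rate_law_registry,
    reaction_rate,
    validate_parameters,
)
from betaox.network import ConfigurationError, build_network


def _zero_conc(network):
    names = [s.name for s in network.species] + [s.name for s in network.boundary]
    return {n: 0.0 for n in names}


def _reaction(network, name):
    return next(r for r in network.reactions if r.name == name)


def _rate(network, params, name, conc):
    base = _zero_conc(network)
    base.update(conc)
    return reaction_rate(RateContext(network, params, _reaction(network, name), base))


def test_all_rates_zero_on_empty_system(network, params):
    conc = _zero_conc(network)
    for r in network.reactions:
        assert reaction_rate(RateContext(network, params, r, conc)) == 0.0


def test_single_substrate_half_saturation_closed_form(network, params):
    # S = Km, P = 0, no competitors: v = Vmax * (S/Km) / (1 + S/Km) = Vmax/2
    km = params.km[("SCAD", 4, "acylCoA_C4_m")]
    v = _rate(network, params, "SCAD_C4", {"acylCoA_C4_m": km})
    assert v == pytest.approx(params.vmax["SCAD"] / 2, rel=1e-12)


def test_two_equal_competing_substrates_third_each(network, params):
    # two substrates at their Km on a shared enzyme: denominator 1+1+1,
    # each route runs at Vmax/3 and the total is 2*Vmax/3
    p = dataclasses.replace(params, km={**params.km,
                                        ("SCAD", 4, "acylCoA_C4_m"): 10.0,
                                        ("SCAD", 6, "acylCoA_C6_m"): 20.0})
    conc = {"acylCoA_C4_m": 10.0, "acylCoA_C6_m": 20.0}
    v4 = _rate(network, p, "SCAD_C4", conc)
    v6 = _rate(network, p, "SCAD_C6", conc)
    assert v4 == pytest.approx(p.vmax["SCAD"] / 3, rel=1e-12)
    assert v6 == pytest.approx(p.vmax["SCAD"] / 3, rel=1e-12)
    assert v4 + v6 == pytest.approx(2 * p.vmax["SCAD"] / 3, rel=1e-12)


@pytest.mark.parametrize("name", ["SCAD_C4", "crotonase_C10", "MSCHAD_C6",
                                  "MCKAT_C8", "MTP_C12", "CPT2_C14", "CACT_C16",
                                  "CPT1_C16"])
def test_rate_zero_exactly_at_equilibrium(network, params, name):
    r = _reaction(network, name)
    e, n = r.enzyme, r.chain_length
    keq = params.keq_of(e, n)
    s_name, p_name = ester_pair(r)
    conc = _zero_conc(network)
    # choose cofactors and set the product so the mass-action ratio equals Keq
    if e == "MSCHAD":
        conc.update({"NAD_m": 100.0, "NADH_m": 50.0, s_name: 7.0,
                     p_name: keq * 7.0 * 100.0 / 50.0})
    elif e == "MCKAT":
        conc.update({"CoASH_m": 40.0, "acetylCoA_m": 5.0, s_name: 3.0,
                     p_name: keq * 3.0 * 40.0 / 5.0})
    elif e == "MTP":
        conc.update({"NAD_m": 100.0, "NADH_m": 50.0, "CoASH_m": 40.0,
                     "acetylCoA_m": 5.0, s_name: 3.0,
                     p_name: keq * 3.0 * 100.0 * 40.0 / (5.0 * 50.0)})
    elif e == "CPT2":
        conc.update({"CoASH_m": 40.0, "carnitine_m": 200.0, s_name: 3.0,
                     p_name: keq * 3.0 * 40.0 / 200.0})
    elif e == "CACT":
        conc.update({"carnitine_m": 200.0, "carnitine_e": 400.0, s_name: 3.0,
                     p_name: keq * 3.0 * 200.0 / 400.0})
    elif e == "CPT1":
        conc.update({"carnitine_e": 400.0, "CoASH_e": 10.0, s_name: 3.0,
                     p_name: keq * 3.0 * 400.0 / 10.0})
    else:
        conc.update({s_name: 5.0, p_name: keq * 5.0})
    assert reaction_rate(RateContext(network, params, r, conc)) == pytest.approx(0.0, abs=1e-14)


def test_cpt1_reduces_to_uninhibited_at_zero_malonyl(network, params):
    conc = _zero_conc(network)
    conc.update({"palmitoylCoA_e": 20.0, "carnitine_e": 300.0,
                 "acylcarnitine_C16_e": 5.0, "CoASH_e": 2.0})
    v0 = _rate(network, params, "CPT1_C16", conc)
    km_s = params.km[("CPT1", 16, "palmitoylCoA_e")]
    km_p = params.km[("CPT1", 16, "acylcarnitine_C16_e")]
    km_c = params.km[("CPT1", None, "carnitine_e")]
    km_a = params.km[("CPT1", None, "CoASH_e")]
    keq = params.keq[("CPT1", 16)]
    s, carn, p, coa = 20.0, 300.0, 5.0, 2.0
    expected = params.vmax["CPT1"] * (s * carn - p * coa / keq) / (
        km_s * km_c * (1 + s / km_s + p / km_p) * (1 + carn / km_c + coa / km_a)
    )
    assert v0 == pytest.approx(expected, rel=1e-12)


def test_cpt1_third_vmax_at_km_with_malonyl_at_ki(network, params):
    # S = Km, P = 0, malonyl = Ki, carnitine saturating: denominator 1+1+1
    km_s = params.km[("CPT1", 16, "palmitoylCoA_e")]
    conc = {"palmitoylCoA_e": km_s, "carnitine_e": 1e9,
            "malonylCoA_e": params.ki_malonyl}
    v = _rate(network, params, "CPT1_C16", conc)
    assert v == pytest.approx(params.vmax["CPT1"] / 3, rel=1e-6)


def test_cpt1_strictly_decreasing_in_malonyl(network, params):
    base = {"palmitoylCoA_e": 25.0, "carnitine_e": 500.0}
    rates = [
        _rate(network, params, "CPT1_C16", {**base, "malonylCoA_e": m})
        for m in (0.0, 1.0, 5.0, 20.0)
    ]
    assert all(a > b > 0 for a, b in zip(rates, rates[1:]))


def test_mtp_forward_drive_and_chain_restriction(network, params):
    conc = {"enoylCoA_C12_m": params.km[("MTP", 12, "enoylCoA_C12_m")],
            "NAD_m": 3000.0, "CoASH_m": 500.0}
    assert _rate(network, params, "MTP_C12", conc) > 0
    from betaox.kinetics import rate_mtp

    r8 = _reaction(network, "MTP_C8")
    bad = dataclasses.replace(r8, chain_length=6)
    with pytest.raises(ConfigurationError):
        rate_mtp(RateContext(network, params, bad, _zero_conc(network)))


def test_sink_linearity(network, params):
    v1 = _rate(network, params, "acetylCoA_sink", {"acetylCoA_m": 10.0})
    v2 = _rate(network, params, "acetylCoA_sink", {"acetylCoA_m": 20.0})
    assert v1 == pytest.approx(params.k1_acesink * 10.0 * params.v_mat, rel=1e-14)
    assert v2 == pytest.approx(2 * v1, rel=1e-14)
    assert _rate(network, params, "acetylCoA_sink", {"acetylCoA_m": 0.0}) == 0.0


def test_negative_concentration_rejected(network, params):
    with pytest.raises(DomainError):
        _rate(network, params, "SCAD_C4", {"acylCoA_C4_m": -1.0})


def test_missing_km_names_the_constant(network, params):
    km = {k: v for k, v in params.km.items() if k != ("SCAD", 4, "acylCoA_C4_m")}
    broken = dataclasses.replace(params, km=km)
    with pytest.raises(ConfigurationError, match="SCAD"):
        _rate(network, broken, "SCAD_C4", {"acylCoA_C4_m": 5.0})


@settings(max_examples=30, deadline=None, derandomize=True)
@given(extra=st.floats(min_value=0.1, max_value=200.0))
def test_competition_property_added_species_slows_other_routes(extra):
    # adding any competing substrate strictly reduces every other rate
    # through the shared enzyme
    net = build_network()
    from betaox.config import default_parameters

    p = default_parameters()
    base = _zero_conc(net)
    base.update({"acylCoA_C8_m": 5.0, "NAD_m": 2812.5, "NADH_m": 187.5})
    v_before = _rate(net, p, "MCAD_C8", base)
    crowded = {**base, "acylCoA_C12_m": extra}
    v_after = _rate(net, p, "MCAD_C12", crowded)  # route is live
    v_c8 = _rate(net, p, "MCAD_C8", crowded)
    assert v_after > 0
    assert 0 < v_c8 < v_before


def test_validate_parameters_aggregates_all_problems(network, params):
    bad = dataclasses.replace(
        params,
        vmax={**params.vmax, "SCAD": -1.0},
        km={**params.km, ("MCAD", 8, "acylCoA_C8_m"): 0.0},
        ki_malonyl=-2.0,
    )
    problems = validate_parameters(bad, network)
    joined = "\n".join(problems)
    assert len(problems) >= 3
    assert "Vmax_SCAD" in joined and "Km_MCAD_C8" in joined and "Ki_malonylCoA" in joined


def test_shipped_set_validates_cleanly(network, params):
    assert validate_parameters(params, network) == []


def test_rate_law_registry_covers_all_kinds(network):
    registry = rate_law_registry()
    kinds = {r.rate_law_kind for r in network.reactions}
    assert kinds <= set(registry)
    assert all(isinstance(v, str) and v for v in registry.values())


def test_compiled_rates_match_reference_path(network, params, rng):
    compiled = CompiledModel(network, params)
    for _ in range(10):
        y = rng.uniform(0.01, 80.0, network.n_species)
        c = compiled.full_concentrations(y.copy())
        c_map = {name: c[compiled.index[name]] for name in compiled.all_names}
        fast = compiled.rates(c)
        slow = compiled.rates_reference(c_map)
        np.testing.assert_allclose(fast, slow, rtol=1e-13, atol=1e-300)
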