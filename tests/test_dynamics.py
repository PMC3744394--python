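"""ODE assembly and integration: RHS contract, conservation along
trajectories, input-profile clamping and solver convergence."""

import dataclasses

import numpy as np
import pytest

from betaox.dynamics import (
    CompiledModel,
    InputProfile,
    build_rhs,
    default_initial_state,
    integrate,
)
from betaox.network import ConfigurationError


def test_all_zero_state_zero_boundaries_is_fixed_point(network, params):
    p = dataclasses.replace(params, boundaries={k: 0.0 for k in params.boundaries})
    rhs = build_rhs(network, p)
    dydt = rhs(0.0, np.zeros(network.n_species))
    assert np.all(dydt == 0.0)


def test_rhs_equals_stoichiometry_times_rates_over_volumes(network, params, rng):
    # independent oracle: N rebuilt from the reaction stoichiometry dicts,
    # volumes from the compartment map
    compiled = CompiledModel(network, params)
    index = network.index
    N = np.zeros((network.n_species, network.n_reactions))
    for j, r in enumerate(network.reactions):
        for name, coeff in r.stoichiometry.items():
            if name in index:
                N[index[name], j] = coeff
    vols = np.array([params.v_mat if s.compartment.value == "m" else 1 - params.v_mat
                     for s in network.species])
    rhs = build_rhs(network, params)
    for _ in range(50):
        y = rng.uniform(0.0, 100.0, network.n_species)
        c = compiled.full_concentrations(y.copy())
        v = compiled.rates(c)
        np.testing.assert_allclose(rhs(0.0, y), (N @ v) / vols, rtol=1e-12, atol=1e-12)


def test_enoyl_c14_rhs_term_pattern(network, params, rng):
    # d[enoyl-C14]/dt = (v_VLCAD14 + v_LCAD14 - v_crotonase14 - v_MTP14)/V_MAT
    compiled = CompiledModel(network, params)
    names = [r.name for r in network.reactions]
    y = rng.uniform(0.1, 50.0, network.n_species)
    v = compiled.rates(compiled.full_concentrations(y.copy()))
    dydt = compiled.rhs(0.0, y)
    i = network.index["enoylCoA_C14_m"]
    expected = (v[names.index("VLCAD_C14")] + v[names.index("LCAD_C14")]
                - v[names.index("crotonase_C14")] - v[names.index("MTP_C14")]) / params.v_mat
    assert dydt[i] == pytest.approx(expected, rel=1e-12)


def test_state_length_mismatch_is_contract_error(network, params):
    rhs = build_rhs(network, params)
    with pytest.raises(ConfigurationError):
        rhs(0.0, np.zeros(3))


def test_trajectory_conserves_moieties(network, params):
    sim = integrate(network, params, t_span=(0.0, 24.0))
    assert sim.moiety_drift("CoA") < 1e-6
    assert sim.moiety_drift("carnitine_matrix") < 1e-6
    assert sim.moieties["CoA"][0] == pytest.approx(params.coa_total)


def test_trajectory_qualitative_phenotype(network, params):
    # C16 acyl-carnitine is exported early and the short-chain (C4/C6)
    # intermediates accumulate over tens of minutes
    sim = integrate(network, params, t_span=(0.0, 24.0))
    c4 = sim.series("hydroxyacylCoA_C4_m")
    assert c4[-1] > c4[0]
    assert sim.series("acylcarnitine_C16_e")[-1] > 0.1
    assert np.min(sim.y) >= 0.0


def test_solver_tolerance_convergence(network, params):
    t_eval = np.linspace(0.0, 10.0, 11)
    lo = integrate(network, params, t_span=(0.0, 10.0), t_eval=t_eval,
                   rtol=1e-8, atol=1e-9)
    hi = integrate(network, params, t_span=(0.0, 10.0), t_eval=t_eval,
                   rtol=5e-9, atol=5e-10)
    scale = np.maximum(np.abs(hi.y), 1.0)
    assert np.max(np.abs(lo.y - hi.y) / scale) < 1e-6


def test_clamped_coash_variant_trajectory(network, params):
    # with CoASH clamped the CoA moiety is no longer conserved and the ester
    # total grows freely; the carnitine moiety is still conserved
    from betaox.scenarios import make_clamped_coash_variant

    net_fix = make_clamped_coash_variant(network, 1200.0)
    sim = integrate(net_fix, params, t_span=(0.0, 24.0))
    assert "CoA" not in sim.moieties  # broken moiety is not tracked as conserved
    assert sim.moiety_drift("carnitine_matrix") < 1e-6
    esters = sum(
        sim.series(s.name)
        for s in net_fix.species
        if s.species_class.value in ("acylCoA", "enoylCoA", "hydroxyacylCoA",
                                     "ketoacylCoA", "acetylCoA")
    )
    assert esters[-1] > esters[0]


class TestInputProfile:
    def test_monotone_interpolation_and_constant_extrapolation(self):
        prof = InputProfile(times=(0.0, 5.0, 10.0), concentrations=(25.0, 10.0, 5.0))
        assert prof(0.0) == 25.0
        assert prof(10.0) == 5.0
        assert prof(50.0) == 5.0  # constant beyond the last sample
        assert prof(-1.0) == 25.0
        mid = prof(2.5)
        assert 10.0 < mid < 25.0

    def test_validation(self):
        with pytest.raises(ConfigurationError):
            InputProfile(times=(0.0, 0.0, 1.0), concentrations=(1.0, 1.0, 1.0))
        with pytest.raises(ConfigurationError):
            InputProfile(times=(0.0, 1.0), concentrations=(1.0, -1.0))

    def test_clamped_substrate_follows_profile(self, network, params):
        prof = InputProfile(times=(0.0, 12.0, 24.0), concentrations=(25.0, 12.0, 8.0))
        sim = integrate(network, params, t_span=(0.0, 24.0), input_profile=prof,
                        t_eval=np.array([0.0, 12.0, 24.0]))
        compiled = CompiledModel(network, params, input_profile=prof)
        for k, t in enumerate(sim.t):
            c = compiled.full_concentrations(sim.y[:, k].copy(), t)
            assert c[compiled.index["palmitoylCoA_e"]] == pytest.approx(float(prof(t)))

    def test_time_span_outside_profile_domain_rejected(self, network, params):
        prof = InputProfile(times=(0.0, 10.0), concentrations=(25.0, 10.0))
        with pytest.raises(ConfigurationError):
            integrate(network, params, t_span=(0.0, 24.0), input_profile=prof)

    def test_input_species_must_be_clamped(self, network, params):
        prof = InputProfile(times=(0.0, 24.0), concentrations=(25.0, 10.0),
                            species="acylCoA_C8_m")
        with pytest.raises(ConfigurationError):
            integrate(network, params, t_span=(0.0, 20.0), input_profile=prof)


def test_default_initial_state(network, params):
    y0 = default_initial_state(network, params)
    assert y0[network.index["CoASH_m"]] == params.coa_total
    assert y0[network.index["carnitine_m"]] == params.initial["carnitine_m"]
    assert np.count_nonzero(y0) == 2
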