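"""Derived read-outs: flux averaging, volume-weighted acyl-carnitines,
carbon balance closure and response coefficients."""

import dataclasses

import numpy as np
import pytest

from betaox.analysis import (
    beta_ox_flux,
    carbon_balance,
    response_coefficient_central,
    response_coefficients,
    weighted_acylcarnitines,
)
from betaox.dynamics import integrate


@pytest.fixture(scope="module")
def sim24(network, params):
    return integrate(network, params, t_span=(0.0, 24.0))


class TestBetaOxFlux:
    def test_flux_components_and_oxygen_equivalence(self, sim24):
        fs = beta_ox_flux(sim24)
        assert fs.j_nadh > 0 and fs.j_fadh2 > 0
        assert fs.oxygen_equivalent == pytest.approx(0.5 * (fs.j_nadh + fs.j_fadh2))
        assert fs.window == (1.5, 8.0)

    def test_seven_reducing_pairs_per_palmitoyl(self, network, params, steady_25):
        # at steady state the averaged flux must equal 7x the C16 uptake:
        # 7 FADH2 + 7 NADH per complete oxidation, halved for O2 equivalence
        sim = integrate(network, params, y0=steady_25.state, t_span=(0.0, 10.0))
        fs = beta_ox_flux(sim, window=(1.5, 8.0))
        assert fs.oxygen_equivalent == pytest.approx(
            7.0 * steady_25.flux_of("CPT1_C16"), rel=1e-6
        )

    def test_zero_flux_trajectory(self, network, params):
        silent = dataclasses.replace(
            params, boundaries={**params.boundaries, "palmitoylCoA_e": 0.0}
        )
        sim = integrate(network, silent, t_span=(0.0, 10.0))
        assert beta_ox_flux(sim).oxygen_equivalent == pytest.approx(0.0, abs=1e-12)

    def test_window_outside_span_rejected(self, sim24):
        with pytest.raises(ValueError):
            beta_ox_flux(sim24, window=(20.0, 30.0))
        with pytest.raises(ValueError):
            beta_ox_flux(sim24, window=(8.0, 1.5))


class TestWeightedAcylcarnitines:
    def test_hand_computed_weighted_average(self, sim24, params):
        df = weighted_acylcarnitines(sim24)
        k = len(sim24.t) // 2
        for n in (4, 16):
            cm = sim24.series(f"acylcarnitine_C{n}_m")[k]
            ce = sim24.series(f"acylcarnitine_C{n}_e")[k]
            expected = params.v_mat * cm + (1 - params.v_mat) * ce
            assert df[f"C{n}"].iloc[k] == pytest.approx(expected, rel=1e-12)

    def test_equal_compartments_give_that_value(self, network, params):
        # degenerate check through the formula: if both compartments held c,
        # the weighted average is c for any volume split
        v_mat = params.v_mat
        c = 7.3
        assert v_mat * c + (1 - v_mat) * c == pytest.approx(c)

    def test_all_chains_reported(self, sim24):
        df = weighted_acylcarnitines(sim24)
        assert list(df.columns) == ["time", "C4", "C6", "C8", "C10", "C12", "C14", "C16"]


class TestCarbonBalance:
    def test_gap_closes_within_integration_tolerance(self, sim24):
        cb = carbon_balance(sim24, 0.0, 24.0)
        assert cb.consumed > 1.0  # substrate was actually consumed
        assert abs(cb.gap) < 1e-4 * cb.consumed

    def test_subinterval_also_closes(self, sim24):
        cb = carbon_balance(sim24, 2.0, 12.0)
        assert abs(cb.gap) < 1e-4 * max(cb.consumed, 1.0)

    def test_bad_interval_rejected(self, sim24):
        with pytest.raises(ValueError):
            carbon_balance(sim24, 10.0, 5.0)
        with pytest.raises(ValueError):
            carbon_balance(sim24, 0.0, 48.0)


class TestResponseCoefficients:
    def test_unreferenced_parameter_has_zero_response(self, toy):
        net, p = toy
        # malonyl-CoA is absent from the toy network: Ki cannot act
        df = response_coefficients(net, p, parameters=["Ki_malonylCoA"],
                                   include_boundaries=False)
        assert df.loc[0, "R"] == 0.0

    def test_vmax_scaling_has_nonzero_response(self, toy):
        net, p = toy
        df = response_coefficients(net, p, parameters=["Vmax_CACT", "CoA_total"])
        assert (df["R"].abs() > 0).all()
        assert set(df.columns) >= {"parameter", "R", "rank", "sign"}
        assert list(df["rank"]) == [1, 2]

    def test_one_sided_agrees_with_central_oracle(self, toy):
        net, p = toy
        one = response_coefficients(net, p, parameters=["Vmax_MCKAT"])["R"].iloc[0]
        central = response_coefficient_central(net, p, "Vmax_MCKAT")
        assert one == pytest.approx(central, rel=0.05)

    def test_richardson_consistency_under_halved_step(self, toy):
        net, p = toy
        r1 = response_coefficients(net, p, parameters=["Vmax_CPT2"],
                                   perturbation=0.01)["R"].iloc[0]
        r2 = response_coefficients(net, p, parameters=["Vmax_CPT2"],
                                   perturbation=0.005)["R"].iloc[0]
        assert r1 == pytest.approx(r2, rel=0.05)
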