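"""Unit tests for the tracer computation chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntracer import (
    LabelingConfig,
    actual_uptake,
    actual_uptake_rate,
    atom_percent_excess,
    atom_percent_to_delta,
    c15n_added,
    delta_to_atom_percent,
    n15_uptake,
    n15_uptake_rate,
    uptake_per_quadrat,
)
from ntracer.isotope import pool_shoot_root


class TestDeltaConversion:
    @pytest.mark.parametrize(
        "delta, expected",
        [
            (0.0, 0.36630),  # air standard by definition
            (1.0, 0.366668),  # direct evaluation of the ratio formula
            (10.0, 0.36995),  # ~1% ratio shift above natural abundance
        ],
    )
    def test_known_values(self, delta, expected):
        assert delta_to_atom_percent(delta) == pytest.approx(expected, abs=5e-6)

    def test_strictly_increasing(self):
        deltas = np.linspace(-900, 5000, 200)
        at = delta_to_atom_percent(deltas)
        assert np.all(np.diff(at) > 0)

    @given(st.floats(min_value=-999.0, max_value=1e5))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip(self, delta):
        assert atom_percent_to_delta(delta_to_atom_percent(delta)) == pytest.approx(
            delta, abs=1e-9
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            delta_to_atom_percent(-1000.0)


class TestAtomPercentExcess:
    def test_subtraction(self):
        assert atom_percent_excess(0.4663, 0.3663) == pytest.approx(0.1, abs=1e-12)

    def test_zero_when_equal(self):
        assert atom_percent_excess(0.3663, 0.3663) == 0.0

    def test_negative_preserved_without_clamp(self):
        assert atom_percent_excess(0.3600, 0.3663) == pytest.approx(-0.0063)

    def test_clamped_to_zero(self):
        assert atom_percent_excess(0.3600, 0.3663, clamp=True) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            atom_percent_excess(0.1, 0.3663)


class TestUptakeChain:
    def test_n15_uptake_hand_value(self):
        # APE 0.1 %, biomass 10 g, N 2 % -> 0.001 * 10 * 0.02 * 1e6 = 200 ug
        assert n15_uptake(0.1, 10.0, 2.0) == pytest.approx(200.0)

    def test_n15_uptake_zero_ape(self):
        assert n15_uptake(0.0, 10.0, 2.0) == 0.0

    def test_rate_hand_value(self):
        assert n15_uptake_rate(200.0, 2.0, 48.0) == pytest.approx(200 / 96)

    def test_rate_domain_errors(self):
        with pytest.raises(ValueError):
            n15_uptake_rate(200.0, 0.0, 48.0)
        with pytest.raises(ValueError):
            n15_uptake_rate(200.0, 2.0, 0.0)

    def test_actual_uptake_hand_value(self):
        assert actual_uptake(200.0, 10.0, 0.24) == pytest.approx(8333.3333, rel=1e-6)

    def test_actual_uptake_linear_in_pool(self):
        base = actual_uptake(200.0, 10.0, 0.24)
        assert actual_uptake(200.0, 30.0, 0.24) == pytest.approx(3 * base)
        assert actual_uptake(200.0, 0.0, 0.24) == 0.0

    def test_actual_rate_hand_value(self):
        assert actual_uptake_rate(200 / 96, 10.0, 0.24) == pytest.approx(86.81, abs=0.01)

    def test_rate_and_amount_paths_agree(self):
        # actual_uptake / (root * time) == actual_uptake_rate for matched inputs
        ape, biomass, ncon, root, t = 0.07, 8.0, 1.4, 2.5, 48.0
        up = n15_uptake(ape, biomass, ncon)
        via_amount = actual_uptake(up, 6.0, 0.24) / (root * t)
        via_rate = actual_uptake_rate(n15_uptake_rate(up, root, t), 6.0, 0.24)
        assert via_amount == pytest.approx(via_rate, rel=1e-12)

    def test_uptake_per_quadrat_hand_value(self):
        assert uptake_per_quadrat(86.81, 100.0, 48.0) == pytest.approx(416688.0, rel=1e-4)

    def test_uptake_per_quadrat_zero_factor(self):
        assert uptake_per_quadrat(0.0, 100.0, 48.0) == 0.0

    @given(
        ape=st.floats(min_value=1e-6, max_value=5.0),
        scale=st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_chain_homogeneous_degree_one_in_ape(self, ape, scale):
        """Every downstream quantity scales linearly with the tracer signal."""
        biomass, ncon, root, t, pool, c15n = 8.0, 1.5, 2.0, 48.0, 6.0, 0.24
        def chain(a):
            up = n15_uptake(a, biomass, ncon)
            rate = n15_uptake_rate(up, root, t)
            act = actual_uptake(up, pool, c15n)
            arate = actual_uptake_rate(rate, pool, c15n)
            return np.array([up, rate, act, arate, uptake_per_quadrat(arate, 120.0, t)])
        assert chain(ape * scale) == pytest.approx(chain(ape) * scale, rel=1e-12)


class TestLabelingConfig:
    def test_c15n_added_default_geometry(self):
        # 360 ug into pi * 25 * 15 * 1.273 ~ 1500 g of soil -> ~0.240 mg/kg
        assert c15n_added(LabelingConfig()) == pytest.approx(0.240, abs=0.001)

    def test_c15n_added_inverse_in_density(self):
        half = LabelingConfig(bulk_density=1.273 / 2)
        assert c15n_added(half) == pytest.approx(2 * c15n_added(LabelingConfig()), rel=1e-12)

    def test_dose_solution_consistency(self):
        # 0.5 mmol 15N/L * 48 mL * 15 g/mol = 360 ug per plant
        assert LabelingConfig().dose_from_solution() == pytest.approx(360.0, rel=1e-12)

    def test_enrichment_bounds(self):
        with pytest.raises(ValueError):
            LabelingConfig(enrichment_nh4=0.3)
        with pytest.raises(ValueError):
            LabelingConfig(dose_15N=0)


def test_pool_shoot_root_mass_weighting():
    assert pool_shoot_root(6.0, 2.0, 2.0, 1.0) == pytest.approx((6 * 2 + 2 * 1) / 8)
    # equal values pool to themselves regardless of the mass split
    assert pool_shoot_root(5.0, 1.4, 3.0, 1.4) == pytest.approx(1.4)
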