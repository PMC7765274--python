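"""Toxic units, mixture toxicity index, classification and enumeration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qsarmix import datasets
from qsarmix.mixture import (
    MixtureComponent,
    MixtureScenario,
    classify_action,
    enumerate_combinations,
    evaluate_scenario,
    mixture_index,
    scenario_report,
    scenarios_from_frame,
    toxic_units,
)


class TestToxicUnits:
    def test_published_farmland_and_garden_values(self):
        tu = toxic_units([MixtureComponent("A", 0.773, 1.069)])
        assert tu["A"] == pytest.approx(0.723, abs=5e-4)
        tu = toxic_units([MixtureComponent("B", 0.110, 0.858)])
        assert tu["B"] == pytest.approx(0.128, abs=5e-4)

    def test_zero_concentration_gives_zero_tu(self):
        assert toxic_units([MixtureComponent("x", 0.0, 1.0)])["x"] == 0.0

    def test_nonpositive_toxicity_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            MixtureComponent("x", 1.0, 0.0)


class TestMixtureIndex:
    def test_published_farmland_binary_mixture(self):
        tu = toxic_units([
            MixtureComponent("A", 0.773, 1.069),
            MixtureComponent("B", 0.773, 0.858),
        ])
        m, m0, mti = mixture_index(tu)
        assert round(m, 3) == 1.624
        assert round(m0, 3) == 1.803
        assert round(mti, 3) == 0.177

    def test_published_woodland_quaternary_mixture(self):
        tu = toxic_units([
            MixtureComponent(k, 0.060, v)
            for k, v in zip("ABCD", (1.069, 0.858, 0.878, 0.873))
        ])
        m, m0, mti = mixture_index(tu)
        assert round(m0, 3) == 3.763
        assert round(mti, 3) == 2.008

    def test_two_unit_toxic_units_force_mti_zero(self):
        m, m0, mti = mixture_index([1.0, 1.0])
        assert (m, m0) == (2.0, 2.0)
        assert mti == pytest.approx(0.0, abs=1e-15)

    def test_zero_tu_components_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-TU"):
            m, m0, mti = mixture_index([1.0, 2.0, 0.0])
        assert m == 3.0

    def test_single_effective_component_is_degenerate(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="at least 2"):
                mixture_index([1.0, 0.0])


class TestClassification:
    @pytest.mark.parametrize("mti,expected", [
        (0.079, "partial additive"), (0.212, "partial additive"),
        (3.486, "synergistic"), (1.550, "synergistic"),
        (1.0, "simple additive"), (0.0, "independent"),
        (-0.5, "antagonism"),
    ])
    def test_rule_table(self, mti, expected):
        assert classify_action(mti) == expected

    def test_tolerance_and_nan(self):
        assert classify_action(1.0 + 1e-12) == "simple additive"
        assert classify_action(1.0 + 1e-12, tol=0.0) == "synergistic"
        with pytest.raises(ValueError, match="NaN"):
            classify_action(float("nan"))


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (4, 11), (5, 26)])
    def test_subset_counts_match_binomial_sums(self, n, count):
        ids = [chr(65 + i) for i in range(n)]
        combos = enumerate_combinations(ids)
        assert len(combos) == count
        assert combos == sorted(combos, key=lambda c: (len(c), c))

    def test_pairs_come_before_triples(self):
        combos = enumerate_combinations(list("ABCD"))
        sizes = [len(c) for c in combos]
        assert sizes == sorted(sizes)


class TestScenarioReport:
    def test_full_three_soil_replay_at_three_decimals(self, soil_scenarios):
        """All 33 published M/M0/MTI values reproduce exactly at 3 dp."""
        detail, summary = scenario_report(scenarios_from_frame(soil_scenarios))
        ref = datasets.load_mixture_reference()
        merged = detail.merge(ref, on=["environment", "combination"])
        assert len(merged) == 33
        pd.testing.assert_series_equal(
            merged["MTI"], merged["mti"], check_names=False
        )
        pd.testing.assert_series_equal(merged["M"], merged["m"], check_names=False)
        pd.testing.assert_series_equal(merged["M0"], merged["m0"], check_names=False)

    def test_environment_summary_matches_published_ranges(self, soil_scenarios):
        _, summary = scenario_report(scenarios_from_frame(soil_scenarios))
        by_env = summary.set_index("environment")
        assert by_env.loc["farmland", ["mti_min", "mti_max"]].tolist() == [0.079, 0.212]
        assert by_env.loc["farmland", "action"] == "partial additive"
        assert by_env.loc["garden", ["mti_min", "mti_max"]].tolist() == [1.550, 3.486]
        assert by_env.loc["garden", "action"] == "synergistic"
        assert by_env.loc["woodland", ["mti_min", "mti_max"]].tolist() == [2.008, 4.515]

    def test_single_pair_scenario_yields_one_row(self):
        comps = (MixtureComponent("A", 1.0, 1.0), MixtureComponent("B", 2.0, 1.0))
        detail, summary = scenario_report(
            [MixtureScenario("lab", comps, ("A", "B"))]
        )
        assert len(detail) == 1 and len(summary) == 1

    def test_component_order_does_not_change_indices(self):
        comps = tuple(
            MixtureComponent(k, c, t)
            for k, c, t in zip("ABC", (0.7, 0.8, 0.9), (1.1, 0.9, 1.0))
        )
        fwd = evaluate_scenario(MixtureScenario("e", comps, ("A", "B", "C")))
        rev = evaluate_scenario(MixtureScenario("e", comps[::-1], ("C", "B", "A")))
        assert fwd.mti == pytest.approx(rev.mti, abs=1e-15)
        assert fwd.m == pytest.approx(rev.m, abs=1e-15)


positive_tus = st.lists(
    st.floats(min_value=0.01, max_value=50.0), min_size=2, max_size=6
).filter(lambda tu: len(set(tu)) > 1)


class TestInvariants:
    @given(tu=positive_tus)
    def test_permutation_invariance(self, tu):
        m1, m01, mti1 = mixture_index(tu)
        m2, m02, mti2 = mixture_index(tu[::-1])
        assert m1 == pytest.approx(m2, rel=1e-12)
        assert mti1 == pytest.approx(mti2, rel=1e-9, abs=1e-12)

    @given(tu=positive_tus, c=st.floats(min_value=0.1, max_value=10.0))
    def test_concentration_scaling_closed_form(self, tu, c):
        """Scaling all concentrations by c shifts MTI by log c / log M0 only."""
        m, m0, mti = mixture_index(tu)
        ms, m0s, mtis = mixture_index([t * c for t in tu])
        assert ms == pytest.approx(c * m, rel=1e-12)
        assert m0s == pytest.approx(m0, rel=1e-12)
        assert mtis == pytest.approx(
            1 - (math.log(m) + math.log(c)) / math.log(m0), rel=1e-9, abs=1e-9
        )

    @given(n=st.integers(min_value=2, max_value=8),
           t=st.floats(min_value=0.05, max_value=20.0))
    def test_equal_tu_closed_form(self, n, t):
        m, m0, mti = mixture_index([t] * n)
        assert m0 == pytest.approx(n, rel=1e-12)
        assert mti == pytest.approx(1 - math.log(n * t) / math.log(n), rel=1e-9, abs=1e-9)
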