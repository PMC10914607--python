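"""Unit tests of the flux primitives, the ODE right-hand side and validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from syntroph import (
    CommunityModel,
    ConfigurationError,
    DomainError,
    InitialCondition,
    MetaboliteSpec,
    StrainSpec,
    UptakeKinetics,
    build_scenario,
    growth_rate,
    leak_flux,
    monod_uptake,
    system_rhs,
    toxicity_factor,
)


class TestMonodUptake:
    @pytest.mark.parametrize(
        "vmax,km,s,expected",
        [
            (10, 10, 10, 5.0),  # half-saturation
            (30, 100, 0, 0.0),  # no substrate
            (30, 1, 1e6, pytest.approx(29.99997, abs=1e-5)),  # saturation
        ],
    )
    def test_values(self, vmax, km, s, expected):
        assert monod_uptake(UptakeKinetics(vmax, km), s) == expected

    def test_negative_substrate_rejected(self):
        with pytest.raises(DomainError, match="substrate"):
            monod_uptake(UptakeKinetics(10, 10), -1.0)

    @given(
        s1=st.floats(0, 1e3),
        s2=st.floats(0, 1e3),
        vmax=st.floats(0.1, 100),
        km=st.floats(0.1, 100),
    )
    @settings(max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, s1, s2, vmax, km):
        kin = UptakeKinetics(vmax, km)
        lo, hi = sorted([s1, s2])
        assert monod_uptake(kin, lo) <= monod_uptake(kin, hi) <= vmax


class TestLeakFlux:
    @pytest.mark.parametrize(
        "phi,delta,jg,expected",
        [(0.5, 1, 8, 4.0), (0.0, 1, 8, 0.0), (0.2, 2, 10, 4.0)],
    )
    def test_values(self, phi, delta, jg, expected):
        assert leak_flux(phi, delta, jg) == pytest.approx(expected)

    def test_phi_out_of_range(self):
        with pytest.raises(ConfigurationError):
            leak_flux(1.0, 1, 8)
        with pytest.raises(ConfigurationError):
            leak_flux(-0.1, 1, 8)


def _strain(phi=0.2, gamma_g=0.5, gamma_j=0.3):
    return StrainSpec(
        id="s",
        auxotrophies=frozenset({"m"}),
        productions={"p": phi},
        glucose_uptake=UptakeKinetics(10, 10),
        metabolite_uptake={"m": UptakeKinetics(5, 50)},
        yield_glucose=gamma_g,
        yield_metabolite={"m": gamma_j},
    )


class TestGrowthRate:
    def test_metabolite_limited(self):
        rate, label = growth_rate(_strain(), 10.0, {"m": 5.0})
        assert rate == pytest.approx(min(0.5 * 0.8 * 10, 0.3 * 5))
        assert label == "m"

    def test_prototroph_glucose_limited(self):
        s = StrainSpec(id="s", glucose_uptake=UptakeKinetics(10, 10), yield_glucose=0.5)
        rate, label = growth_rate(s, 10.0)
        assert rate == pytest.approx(5.0)
        assert label == "glucose"

    def test_full_diversion_kills_growth(self):
        s = StrainSpec(
            id="s",
            productions={"p": 0.999999},
            glucose_uptake=UptakeKinetics(10, 10),
            yield_glucose=0.5,
        )
        rate, _ = growth_rate(s, 10.0)
        assert rate == pytest.approx(0.0, abs=1e-4)

    def test_missing_yield_is_configuration_error(self):
        s = _strain()
        s.yield_metabolite = {}
        with pytest.raises(ConfigurationError, match="yield"):
            growth_rate(s, 10.0, {"m": 1.0})


class TestSystemRhs:
    def test_hand_evaluated_prototroph(self):
        """Single prototroph: dG/dt = −J·y, dy/dt = γ_G·J·y at the stated point."""
        model = CommunityModel(
            metabolites=[],
            strains=[
                StrainSpec(
                    id="y1",
                    glucose_uptake=UptakeKinetics(10, 10),
                    yield_glucose=0.5,
                    death_rate=0.0,
                )
            ],
        )
        d = system_rhs({"glucose": 20.0, "y:y1": 0.1}, model)
        assert d["glucose"] == pytest.approx(-10 * (20 / 30) * 0.1)
        assert d["y:y1"] == pytest.approx(0.5 * 10 * (20 / 30) * 0.1)

    def test_symmetric_pair_equal_derivatives(self, pair):
        model, init = pair
        state = {"glucose": 15.0, "x:em1": 1.0, "x:em2": 1.0, "y:y1": 0.2, "y:y2": 0.2}
        d = system_rhs(state, model)
        assert d["y:y1"] == pytest.approx(d["y:y2"], abs=1e-14)
        assert d["x:em1"] == pytest.approx(d["x:em2"], abs=1e-14)

    def test_washout_fixed_point(self, pair):
        model, _ = pair
        d = system_rhs(
            {"glucose": 20.0, "x:em1": 5.0, "x:em2": 5.0, "y:y1": 0.0, "y:y2": 0.0},
            model,
        )
        assert all(v == 0.0 for v in d.values())

    def test_unknown_component_rejected(self, pair):
        model, _ = pair
        with pytest.raises(ConfigurationError, match="unknown state"):
            system_rhs({"glucose": 20.0, "y:nosuch": 0.1}, model)


class TestToxicity:
    def _model(self, threshold=10.0):
        m, _ = build_scenario("pair_twoway_symmetric")
        m.toxicity_enabled = True
        m.metabolites[0].toxicity_threshold = threshold
        return m

    def test_zero_concentration_identity(self):
        assert toxicity_factor({"em1": 0.0, "em2": 0.0}, self._model()) == 1.0

    def test_half_inhibition_at_threshold(self):
        assert toxicity_factor({"em1": 10.0}, self._model()) == pytest.approx(0.5)

    def test_vanishes_at_high_concentration(self):
        assert toxicity_factor({"em1": 1e9}, self._model()) < 1e-10

    def test_disabled_is_identity(self, pair):
        model, _ = pair
        assert toxicity_factor({"em1": 1e9}, model) == 1.0

    def test_monotone_non_increasing(self):
        m = self._model()
        vals = [toxicity_factor({"em1": x}, m) for x in (0, 1, 5, 10, 50)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestValidation:
    def test_produce_and_require_same_metabolite(self):
        s = StrainSpec(
            id="s",
            auxotrophies=frozenset({"m"}),
            productions={"m": 0.1},
            metabolite_uptake={"m": UptakeKinetics(5, 50)},
            yield_metabolite={"m": 0.3},
        )
        with pytest.raises(ConfigurationError, match="produce and require"):
            s.validate()

    def test_leak_fractions_must_leave_growth_flux(self):
        s = StrainSpec(id="s", productions={"a": 0.6, "b": 0.5})
        with pytest.raises(ConfigurationError, match="< 1"):
            s.validate()

    def test_unknown_metabolite_reference(self):
        model = CommunityModel(
            metabolites=[MetaboliteSpec("em1")],
            strains=[StrainSpec(id="s", productions={"em9": 0.1})],
        )
        with pytest.raises(ConfigurationError, match="em9"):
            model.validate()

    def test_ratios_must_sum_to_one(self, pair):
        model, _ = pair
        init = InitialCondition(ratios_0={"y1": 0.6, "y2": 0.6})
        with pytest.raises(ConfigurationError, match="sum to 1"):
            init.validate(model)

    def test_delta_positive(self):
        with pytest.raises(ConfigurationError, match="delta"):
            MetaboliteSpec("m", delta=0.0).validate()
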