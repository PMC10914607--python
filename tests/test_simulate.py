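"""Simulator, metrics, growth classification, sweeps, and model invariants."""

import numpy as np
import pytest

from syntroph import (
    DomainError,
    SimulationConfig,
    build_scenario,
    classify_growth,
    compute_metrics,
    simulate_batch,
    sweep,
    sweep_grid,
)
from syntroph.model import ConfigurationError
from syntroph.simulate import get_param, set_param


class TestSimulateBatch:
    def test_co_auxotrophs_without_exchange_cannot_grow(self, fast_cfg):
        """Both members ϕ=0, no supplements: nothing to cross-feed, only decay."""
        model, init = build_scenario(
            "pair_twoway_symmetric", phi={"y1": 0.0, "y2": 0.0}
        )
        res = simulate_batch(model, init, fast_cfg)
        assert res.total_biomass[-1] <= init.total_density_0 + 1e-9

    def test_prototroph_glucose_monotone(self, prototroph, fast_cfg):
        model, init = prototroph
        res = simulate_batch(model, init, fast_cfg)
        assert np.all(np.diff(res.glucose) <= 1e-10)

    def test_symmetric_pair_ratio_constant(self, pair, tight_cfg):
        model, init = pair
        res = simulate_batch(model, init, tight_cfg)
        frac = res.biomass("y1") / res.total_biomass
        assert np.allclose(frac, 0.5, atol=1e-9)

    def test_deterministic_repeat(self, pair, fast_cfg):
        model, init = pair
        a = simulate_batch(model, init, fast_cfg)
        b = simulate_batch(model, init, fast_cfg)
        assert np.array_equal(a.states, b.states)


class TestComputeMetrics:
    def test_batch_time_matches_refined_grid_crossing(self, prototroph):
        """Linear interpolation on the output grid vs a 10× finer oracle."""
        model, init = prototroph
        coarse = compute_metrics(
            simulate_batch(model, init, SimulationConfig(dt_out=1.0))
        )
        fine = compute_metrics(
            simulate_batch(model, init, SimulationConfig(dt_out=0.1))
        )
        assert coarse.batch_time < 72.0  # glucose actually exhausted
        assert abs(coarse.batch_time - fine.batch_time) < 1.0

    def test_degenerate_composition_reports_inoculum(self, fast_cfg):
        """Zero population throughout: 0/0 composition falls back to inoculum."""
        model, init = build_scenario("pair_twoway_symmetric", ratio="3:1")
        init.total_density_0 = 0.0
        ms = compute_metrics(simulate_batch(model, init, fast_cfg))
        assert ms.degenerate_composition
        assert ms.final_ratios == pytest.approx({"y1": 0.75, "y2": 0.25})

    def test_productivity_absent_without_pathway(self, pair, fast_cfg):
        model, init = pair
        ms = compute_metrics(simulate_batch(model, init, fast_cfg))
        assert ms.productivity is None and ms.yield_ratio is None
        with pytest.raises(KeyError):
            ms.scalar("productivity")

    def test_pathway_metrics_present(self, fast_cfg):
        model, init = build_scenario("dol_resveratrol")
        ms = compute_metrics(simulate_batch(model, init, fast_cfg))
        assert ms.productivity > 0
        assert ms.yield_ratio > 0

    def test_final_ratios_sum_to_one(self, pair, fast_cfg):
        model, init = pair
        ms = compute_metrics(simulate_batch(model, init, fast_cfg))
        assert sum(ms.final_ratios.values()) == pytest.approx(1.0)


class TestClassifyGrowth:
    @pytest.mark.parametrize(
        "od,label",
        [(0.6, "strong"), (0.5, "strong"), (0.3, "medium"), (0.49, "medium"), (0.1, "weak")],
    )
    def test_thresholds(self, od, label):
        assert classify_growth(od) == label

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            classify_growth(-0.1)


class TestSweep:
    def test_phi_peak_is_unimodal(self, mono, fast_cfg):
        model, init = mono
        phis = np.round(np.arange(0.1, 0.91, 0.1), 2)
        tab = sweep(model, init, fast_cfg, "strains.y1.productions.em1", phis)
        peaks = tab["peak_metabolite:em1"].to_numpy()
        k = int(np.argmax(peaks))
        assert 0 < k < len(peaks) - 1  # interior maximum
        assert np.all(np.diff(peaks[: k + 1]) >= -1e-9)
        assert np.all(np.diff(peaks[k:]) <= 1e-9)

    def test_2d_grid_low_corner_is_poor(self, pair, fast_cfg):
        model, init = pair
        tab = sweep_grid(
            model,
            init,
            fast_cfg,
            [
                ("strains.y1.productions.em1", [0.02, 0.25]),
                ("strains.y2.productions.em2", [0.02, 0.25]),
            ],
        )
        od = tab.set_index(
            ["strains.y1.productions.em1", "strains.y2.productions.em2"]
        )["final_total_od"]
        assert od[(0.25, 0.25)] > od[(0.02, 0.02)]

    def test_empty_values_empty_table(self, mono, fast_cfg):
        model, init = mono
        tab = sweep(model, init, fast_cfg, "strains.y1.productions.em1", [])
        assert len(tab) == 0

    def test_bad_path_lists_valid_forms(self, mono, fast_cfg):
        model, init = mono
        with pytest.raises(ConfigurationError, match="valid forms"):
            sweep(model, init, fast_cfg, "strains.y1.nonsense", [0.1])

    def test_grid_order_preserved(self, mono, fast_cfg):
        model, init = mono
        vals = [0.3, 0.1, 0.2]
        tab = sweep(model, init, fast_cfg, "strains.y1.productions.em1", vals)
        assert list(tab["strains.y1.productions.em1"]) == vals


class TestParamPaths:
    def test_roundtrip(self, pair):
        model, init = pair
        set_param(model, init, "strains.y1.glucose_uptake.v_max", 7.5)
        assert get_param(model, init, "strains.y1.glucose_uptake.v_max") == 7.5
        set_param(model, init, "init.supplements_0.em1", 12.0)
        assert get_param(model, init, "init.supplements_0.em1") == 12.0

    def test_unknown_strain(self, pair):
        model, init = pair
        with pytest.raises(ConfigurationError):
            get_param(model, init, "strains.zz.glucose_uptake.v_max")


class TestInvariants:
    def test_non_negativity(self, pair, tight_cfg):
        model, init = pair
        res = simulate_batch(model, init, tight_cfg)
        assert res.states.min() >= -10 * tight_cfg.atol

    def test_glucose_monotone_while_populated(self, pair, tight_cfg):
        model, init = pair
        res = simulate_batch(model, init, tight_cfg)
        assert np.all(np.diff(res.glucose) <= 1e-10)

    def test_mass_balance_producer(self, mono, tight_cfg):
        """Metabolite made equals ϕ·δ × glucose consumed by its producer."""
        model, init = mono
        phi = model.strains[0].productions["em1"]
        res = simulate_batch(model, init, tight_cfg)
        produced = res.metabolite("em1")[-1]
        consumed = init.glucose_0 - res.glucose[-1]
        assert produced == pytest.approx(phi * 1.0 * consumed, rel=1e-4)

    def test_two_strain_symmetry(self, pair, tight_cfg):
        model, init = pair
        res = simulate_batch(model, init, tight_cfg)
        assert np.max(np.abs(res.biomass("y1") - res.biomass("y2"))) < 1e-8

    def test_prototroph_yield_limit(self, prototroph, tight_cfg):
        """ϕ=0, η=0: all glucose becomes biomass, y(final) = γ_G·G₀ + N₀."""
        model, init = prototroph
        res = simulate_batch(model, init, tight_cfg)
        expected = model.strains[0].yield_glucose * init.glucose_0 + init.total_density_0
        assert res.total_biomass[-1] == pytest.approx(expected, rel=1e-3)

    def test_refinement_stability(self, pair):
        model, init = pair
        a = compute_metrics(simulate_batch(model, init, SimulationConfig(dt_out=0.25)))
        b = compute_metrics(simulate_batch(model, init, SimulationConfig(dt_out=0.125)))
        assert a.final_total_population == pytest.approx(
            b.final_total_population, rel=1e-3
        )
        assert a.max_growth_rate["y1"] == pytest.approx(
            b.max_growth_rate["y1"], rel=1e-3
        )

    def test_batch_time_non_decreasing_in_phi(self, mono, fast_cfg):
        model, init = mono
        tab = sweep(
            model, init, fast_cfg, "strains.y1.productions.em1",
            [0.05, 0.15, 0.25, 0.35, 0.45],
        )
        bt = tab["batch_time"].to_numpy()
        assert np.all(np.diff(bt) >= -1e-9)

    def test_smooth_min_variant_close_to_hard_min(self, pair):
        model, init = pair
        hard = simulate_batch(model, init, SimulationConfig(dt_out=1.0))
        soft = simulate_batch(
            model, init, SimulationConfig(dt_out=1.0, smooth_min=True)
        )
        assert hard.total_biomass[-1] == pytest.approx(
            soft.total_biomass[-1], rel=0.05
        )
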