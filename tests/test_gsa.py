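"""eFAST sampling, spectral index estimation, and significance machinery.

The independent oracles are closed-form variance decompositions: an additive
linear model (uniform inputs) and the Ishigami function, whose partial
variances are

    V1 = (1 + b·π⁴/5)²/2,  V2 = a²/8,  V3 = 0,  V13 = 8·b²·π⁸/225,
    V  = 1/2 + a²/8 + b·π⁴/5 + b²·π⁸/18.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from syntroph.gsa import (
    GsaConfig,
    GsaParameter,
    efast_frequencies,
    efast_indices,
    efast_run_function,
    efast_sample,
)
from syntroph.model import ConfigurationError


def _params(k, dummy=True):
    ps = [GsaParameter(f"z{i}", f"p{i}", 0.0, 1.0) for i in range(k)]
    if dummy:
        ps.append(GsaParameter("dummy", "dummy", 0.0, 1.0))
    return ps


def ishigami(v, a=7.0, b=0.1):
    x = -np.pi + 2 * np.pi * np.asarray(v[:3])
    return float(np.sin(x[0]) + a * np.sin(x[1]) ** 2 + b * x[2] ** 4 * np.sin(x[0]))


def ishigami_closed_form(a=7.0, b=0.1):
    V1 = 0.5 * (1 + b * np.pi**4 / 5) ** 2
    V2 = a**2 / 8
    V13 = 8 * b**2 * np.pi**8 / 225
    V = 0.5 + a**2 / 8 + b * np.pi**4 / 5 + b**2 * np.pi**8 / 18
    return {
        "S1": V1 / V, "S2": V2 / V, "S3": 0.0,
        "ST1": (V1 + V13) / V, "ST2": V2 / V, "ST3": V13 / V,
    }


class TestSampling:
    def test_zero_phase_midpoint(self):
        """At s=0 with φ=0 the search curve sits at the range midpoint."""
        s = 0.0
        x = 0.5 + np.arcsin(np.sin(11 * s + 0.0)) / np.pi
        assert x == pytest.approx(0.5)

    def test_columns_span_range_and_determinism(self):
        cfg = GsaConfig(parameters=_params(4), samples_per_search=257, resamplings=5)
        a = efast_sample(cfg, focus=1, resample_index=3)
        b = efast_sample(cfg, focus=1, resample_index=3)
        assert np.array_equal(a, b)
        assert a.shape == (257, 5)
        assert a.min() >= 0.0 and a.max() <= 1.0
        # the focus column explores nearly the whole range
        assert a[:, 1].max() - a[:, 1].min() > 0.95

    def test_resamples_differ(self):
        cfg = GsaConfig(parameters=_params(4), samples_per_search=257, resamplings=5)
        a = efast_sample(cfg, 0, 0)
        b = efast_sample(cfg, 0, 1)
        assert not np.array_equal(a, b)

    def test_simplex_group_rows_sum_to_one(self):
        ps = [
            GsaParameter("r1", "a", 0.01, 1.0, group="ratio-simplex"),
            GsaParameter("r2", "b", 0.01, 1.0, group="ratio-simplex"),
            GsaParameter("z", "c", 0.0, 1.0),
            GsaParameter("dummy", "dummy", 0.0, 1.0),
        ]
        cfg = GsaConfig(parameters=ps, samples_per_search=257, resamplings=5)
        m = efast_sample(cfg, 0, 0)
        assert np.allclose(m[:, 0] + m[:, 1], 1.0, atol=1e-12)

    def test_nyquist_violation_reports_minimum(self):
        cfg = GsaConfig(parameters=_params(3), samples_per_search=33, resamplings=5)
        with pytest.raises(ConfigurationError, match="at least 65"):
            cfg.validate()

    def test_even_samples_rejected(self):
        cfg = GsaConfig(parameters=_params(3), samples_per_search=256, resamplings=5)
        with pytest.raises(ConfigurationError, match="odd"):
            cfg.validate()

    def test_single_resampling_rejected(self):
        cfg = GsaConfig(parameters=_params(3), samples_per_search=257, resamplings=1)
        with pytest.raises(ConfigurationError, match="resamplings"):
            cfg.validate()

    @given(focus=st.integers(0, 3), r=st.integers(0, 4))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_samples_always_within_bounds(self, focus, r):
        ps = [
            GsaParameter("a", "a", 1.0, 30.0),
            GsaParameter("b", "b", 0.0, 75.0),
            GsaParameter("c", "c", 0.01, 0.5),
            GsaParameter("dummy", "dummy", 0.0, 1.0),
        ]
        cfg = GsaConfig(parameters=ps, samples_per_search=65, resamplings=5)
        m = efast_sample(cfg, focus, r)
        for j, p in enumerate(ps):
            assert m[:, j].min() >= p.low - 1e-12
            assert m[:, j].max() <= p.high + 1e-12

    def test_frequency_assignment_respects_interference(self):
        omega, comp = efast_frequencies(11, 1285, 4)
        assert omega == 160
        assert comp.max() <= omega // (2 * 4)
        assert len(comp) == 10


class TestIndices:
    def test_additive_linear_model(self):
        """y = 2·z1 + z2: analytic shares 4/12 : 1/12 → S = 0.8, 0.2."""
        cfg = GsaConfig(
            parameters=_params(2), samples_per_search=1285, resamplings=3, seed=7
        )
        res = efast_run_function(lambda v: 2 * v[0] + v[1], cfg)
        assert res.indices("z0", "output")["Si_mean"] == pytest.approx(0.8, abs=0.05)
        assert res.indices("z1", "output")["Si_mean"] == pytest.approx(0.2, abs=0.05)

    def test_ishigami_first_order(self):
        cfg = GsaConfig(
            parameters=_params(3), samples_per_search=1285, resamplings=5, seed=11
        )
        res = efast_run_function(ishigami, cfg)
        cf = ishigami_closed_form()
        for name, key in [("z0", "S1"), ("z1", "S2"), ("z2", "S3")]:
            assert res.indices(name, "output")["Si_mean"] == pytest.approx(
                cf[key], abs=0.05
            )
        # interaction-only parameter: ST3 > 0 even though S3 ≈ 0
        assert res.indices("z2", "output")["ST_mean"] > 0.1

    def test_constant_output_flagged_zero(self):
        cfg = GsaConfig(parameters=_params(2), samples_per_search=65, resamplings=2)
        si, s_t, flag = efast_indices(np.ones(65), cfg, 0)
        assert (si, s_t, flag) == (0.0, 0.0, True)

    def test_si_bounded_by_st(self):
        cfg = GsaConfig(
            parameters=_params(3), samples_per_search=513, resamplings=5, seed=3
        )
        res = efast_run_function(ishigami, cfg)
        for _, row in res.table.iterrows():
            assert row.Si_mean <= row.ST_mean + 0.02

    def test_length_mismatch_rejected(self):
        cfg = GsaConfig(parameters=_params(2), samples_per_search=65, resamplings=2)
        with pytest.raises(ConfigurationError, match="length"):
            efast_indices(np.ones(64), cfg, 0)

    def test_resampling_spread_shrinks_with_samples(self):
        """s.d. of the S1 estimate decreases over Ns ∈ {257, 513, 1285}."""
        sds = []
        for ns in (257, 513, 1285):
            cfg = GsaConfig(
                parameters=_params(3), samples_per_search=ns, resamplings=8, seed=5
            )
            res = efast_run_function(ishigami, cfg)
            sds.append(res.indices("z0", "output")["Si_sd"])
        assert sds[2] <= sds[0]


class TestSignificance:
    def test_dummy_never_flagged_and_small(self):
        cfg = GsaConfig(
            parameters=_params(3), samples_per_search=257, resamplings=10, seed=2
        )
        res = efast_run_function(ishigami, cfg)
        row = res.indices("dummy", "output")
        assert not row["significant"]
        assert row["Si_mean"] < 0.05
        # real first-order drivers are flagged against the dummy
        assert res.indices("z0", "output")["significant"]
        assert res.indices("z1", "output")["significant"]

    def test_bonferroni_divisor_is_parameter_count(self):
        cfg = GsaConfig(parameters=_params(3), samples_per_search=257, resamplings=5)
        assert cfg.n_k == 4
        assert cfg.corrected_alpha == pytest.approx(0.01 / 4)

    def test_csv_export_roundtrip(self, tmp_path):
        cfg = GsaConfig(
            parameters=_params(2), samples_per_search=65, resamplings=3, seed=1
        )
        res = efast_run_function(lambda v: v[0], cfg)
        out = tmp_path / "sens.csv"
        res.to_csv(out)
        assert out.exists() and (tmp_path / "sens.csv.json").exists()
        import pandas as pd

        df = pd.read_csv(out)
        assert set(df.columns) >= {
            "parameter", "metric", "Si_mean", "Si_sd", "ST_mean", "ST_sd",
            "p_value", "significant",
        }
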