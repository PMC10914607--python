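"""Extended Fourier amplitude sensitivity test (eFAST) over the simulator.

Variance-based global sensitivity analysis: each parameter is driven along a
sinusoidal search curve through its range,

    x = lower + (upper−lower) · (1/2 + (1/π)·arcsin(sin(ω s + φ))),

the model is evaluated along the curve, and the output's Fourier spectrum is
decomposed.  The focus parameter carries a high driving frequency
ω = (Ns−1)/(2M) (M harmonics retained); the complementary parameters carry
distinct low frequencies ≤ ω/(2M).  The first-order index S_i is the
variance at ω and its first M harmonics divided by the total variance; the
total-order index S_T is one minus the share of variance in the low
(complementary) band, frequencies 1..ω/2.  Random phases φ give independent
resample curves; indices are aggregated as mean ± s.d. over resamplings.

A dummy parameter — varied but absent from the model — provides an empirical
null: each parameter's index distribution over resamplings is compared with
the dummy's by a two-sample t-test (Welch by default) at a
Bonferroni-corrected threshold α/n_k.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CommunityModel, ConfigurationError, InitialCondition
from .simulate import (
    MetricSet,
    SimulationConfig,
    SimulationError,
    compute_metrics,
    set_param,
    simulate_batch,
)


@dataclass
class GsaParameter:
    """One varied parameter: target path, uniform range, optional group.

    ``path == "dummy"`` marks the dummy parameter (varied, never applied).
    Parameters sharing ``group="ratio-simplex"`` are renormalised per sample
    so the initial strain ratios sum to one.
    """

    name: str
    path: str
    low: float
    high: float
    group: Optional[str] = None

    @property
    def is_dummy(self) -> bool:
        return self.path == "dummy"

    def validate(self) -> None:
        if not self.low < self.high:
            raise ConfigurationError(
                f"parameter {self.name!r}: need low < high, got "
                f"[{self.low}, {self.high}]"
            )


@dataclass
class GsaConfig:
    """Sampling sizes, spectral settings and significance threshold."""

    parameters: list
    samples_per_search: int = 1285
    resamplings: int = 100
    harmonics: int = 4
    alpha: float = 0.01
    seed: int = 0
    t_test: str = "welch"  # welch | pooled
    max_failed_fraction: float = 0.01

    def validate(self) -> None:
        if len(self.parameters) < 2:
            raise ConfigurationError("need at least 2 parameters")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate parameter names: {names}")
        for p in self.parameters:
            p.validate()
        if sum(p.is_dummy for p in self.parameters) > 1:
            raise ConfigurationError("at most one dummy parameter per analysis")
        if self.resamplings < 2:
            raise ConfigurationError(
                "resamplings must be >= 2 (the t-test against the dummy needs "
                "a distribution of indices)"
            )
        if self.samples_per_search % 2 == 0:
            raise ConfigurationError("samples_per_search must be odd")
        min_ns = 4 * self.harmonics**2 + 1
        if self.samples_per_search < min_ns:
            raise ConfigurationError(
                f"samples_per_search={self.samples_per_search} violates the "
                f"Nyquist constraint for {self.harmonics} harmonics; need at "
                f"least {min_ns}"
            )
        if self.t_test not in ("welch", "pooled"):
            raise ConfigurationError("t_test must be 'welch' or 'pooled'")

    @property
    def n_k(self) -> int:
        """Number of parameters varied (Bonferroni divisor)."""
        return len(self.parameters)

    @property
    def corrected_alpha(self) -> float:
        return self.alpha / self.n_k

    def dummy_index(self) -> Optional[int]:
        for i, p in enumerate(self.parameters):
            if p.is_dummy:
                return i
        return None


def efast_frequencies(n_params: int, samples_per_search: int, harmonics: int):
    """Frequency assignment for one search: (ω_focus, complementary array).

    The focus parameter gets ω = floor((Ns−1)/(2M)); the k−1 complementary
    parameters get frequencies spread as evenly as possible over
    1..max(1, floor(ω/(2M))), cycling when there are more parameters than
    available frequencies.
    """
    omega = (samples_per_search - 1) // (2 * harmonics)
    if omega < 1:
        raise ConfigurationError(
            f"samples_per_search={samples_per_search} too small for "
            f"{harmonics} harmonics; need at least {2 * harmonics + 1}"
        )
    max_c = max(1, omega // (2 * harmonics))
    k = n_params - 1
    if k <= 0:
        comp = np.array([], dtype=int)
    elif k <= max_c:
        comp = np.unique(np.round(np.linspace(1, max_c, k)).astype(int))
        # rounding can collide for k close to max_c; fall back to 1..k
        if len(comp) < k:
            comp = np.arange(1, k + 1)
    else:
        comp = 1 + (np.arange(k) % max_c)
    return omega, comp


def _search_s(samples_per_search: int) -> np.ndarray:
    j = np.arange(1, samples_per_search + 1)
    return np.pi * (2.0 * j - samples_per_search - 1) / samples_per_search


def efast_sample(
    config: GsaConfig, focus: int, resample_index: int
) -> np.ndarray:
    """Sample matrix (Ns × k) for one focus parameter and one resampling.

    Deterministic given ``(config.seed, focus, resample_index)``.  Columns
    span their [low, high] ranges; ratio-simplex groups are renormalised so
    each row's group entries sum to one.
    """
    config.validate()
    k = len(config.parameters)
    if not 0 <= focus < k:
        raise ConfigurationError(f"focus index {focus} out of range 0..{k - 1}")
    ns = config.samples_per_search
    omega_f, comp = efast_frequencies(k, ns, config.harmonics)
    freqs = np.empty(k)
    freqs[focus] = omega_f
    others = [i for i in range(k) if i != focus]
    for j, i in enumerate(others):
        freqs[i] = comp[j]
    rng = np.random.default_rng(
        [int(config.seed) & 0x7FFFFFFF, int(focus), int(resample_index)]
    )
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    s = _search_s(ns)
    x = 0.5 + np.arcsin(np.sin(freqs[None, :] * s[:, None] + phases[None, :])) / np.pi
    lows = np.array([p.low for p in config.parameters])
    highs = np.array([p.high for p in config.parameters])
    mat = lows[None, :] + (highs - lows)[None, :] * x
    # simplex groups: renormalise each row so the group sums to one
    groups = {}
    for i, p in enumerate(config.parameters):
        if p.group is not None:
            groups.setdefault(p.group, []).append(i)
    for cols in groups.values():
        if len(cols) >= 2:
            sub = mat[:, cols]
            mat[:, cols] = sub / sub.sum(axis=1, keepdims=True)
    return mat


def efast_indices(outputs: np.ndarray, config: GsaConfig, focus: int):
    """First-order and total-order indices from outputs along one curve.

    Returns ``(S_i, S_T, constant_flag)``.  Constant output (zero variance)
    reports (0, 0, True).  Indices are clipped to [0, 1.05] (estimator
    noise can slightly exceed 1).
    """
    y = np.asarray(outputs, dtype=float)
    ns = config.samples_per_search
    if y.shape[0] != ns:
        raise ConfigurationError(
            f"outputs length {y.shape[0]} != samples_per_search {ns}"
        )
    if not np.all(np.isfinite(y)):
        raise ConfigurationError("outputs must be finite")
    omega_f, _ = efast_frequencies(len(config.parameters), ns, config.harmonics)
    yc = y - y.mean()
    spec = np.fft.rfft(yc)
    power = 2.0 * np.abs(spec) ** 2 / ns**2  # variance per positive frequency
    total = power[1:].sum()
    scale = np.mean(yc**2)
    if total <= 0 or scale <= 1e-300:
        return 0.0, 0.0, True
    harm = omega_f * np.arange(1, config.harmonics + 1)
    harm = harm[harm < len(power)]
    v_focus = power[harm].sum()
    v_comp = power[1 : omega_f // 2 + 1].sum()
    s_i = float(np.clip(v_focus / total, 0.0, 1.05))
    s_t = float(np.clip(1.0 - v_comp / total, 0.0, 1.05))
    return s_i, s_t, False


@dataclass
class SensitivityResult:
    """Per-(parameter, metric) indices with resampling statistics.

    ``table`` has one row per (parameter, metric): Si/ST mean and s.d. over
    resamplings, Welch p-values against the dummy parameter for both index
    types, and a significance flag at the Bonferroni-corrected threshold.
    ``si_raw``/``st_raw`` keep the per-resampling index arrays.
    """

    table: pd.DataFrame
    si_raw: dict
    st_raw: dict
    config: GsaConfig
    metrics: list
    n_failed_rows: int = 0

    def indices(self, parameter: str, metric: str) -> dict:
        row = self.table[
            (self.table.parameter == parameter) & (self.table.metric == metric)
        ]
        if row.empty:
            raise KeyError(f"no entry for ({parameter!r}, {metric!r})")
        return row.iloc[0].to_dict()

    def total_order_share(self, metric: str) -> pd.Series:
        """Each parameter's ST mean as a fraction of the summed ST means."""
        sub = self.table[self.table.metric == metric].set_index("parameter")
        st = sub["ST_mean"]
        return st / st.sum()

    def top_parameter(self, metric: str, order: str = "ST", exclude_dummy=True):
        """Name of the parameter with the largest mean index for a metric."""
        sub = self.table[self.table.metric == metric]
        if exclude_dummy:
            dummies = [p.name for p in self.config.parameters if p.is_dummy]
            sub = sub[~sub.parameter.isin(dummies)]
        col = "ST_mean" if order == "ST" else "Si_mean"
        return sub.loc[sub[col].idxmax(), "parameter"]

    def to_csv(self, path, sidecar: bool = True) -> None:
        cols = [
            "parameter", "metric", "Si_mean", "Si_sd", "ST_mean", "ST_sd",
            "p_value", "significant",
        ]
        self.table[cols].to_csv(path, index=False, float_format="%.17g")
        if sidecar:
            side = {
                "seed": self.config.seed,
                "samples_per_search": self.config.samples_per_search,
                "resamplings": self.config.resamplings,
                "harmonics": self.config.harmonics,
                "alpha": self.config.alpha,
                "corrected_alpha": self.config.corrected_alpha,
                "t_test": self.config.t_test,
                "parameters": [
                    {
                        "name": p.name,
                        "path": p.path,
                        "low": p.low,
                        "high": p.high,
                        "group": p.group,
                    }
                    for p in self.config.parameters
                ],
                "metrics": list(self.metrics),
                "n_failed_rows": self.n_failed_rows,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(side, fh, indent=2)


def _aggregate(config, metrics, si_raw, st_raw, n_failed) -> SensitivityResult:
    d_idx = config.dummy_index()
    dummy_name = config.parameters[d_idx].name if d_idx is not None else None
    equal_var = config.t_test == "pooled"
    rows = []
    for metric in metrics:
        for p in config.parameters:
            si = si_raw[(p.name, metric)]
            st = st_raw[(p.name, metric)]
            entry = {
                "parameter": p.name,
                "metric": metric,
                "Si_mean": float(np.mean(si)),
                "Si_sd": float(np.std(si, ddof=1)),
                "ST_mean": float(np.mean(st)),
                "ST_sd": float(np.std(st, ddof=1)),
            }
            if dummy_name is None or p.name == dummy_name:
                entry["p_Si"] = entry["p_ST"] = entry["p_value"] = 1.0
                entry["significant"] = False
            else:
                dsi = si_raw[(dummy_name, metric)]
                dst = st_raw[(dummy_name, metric)]
                p_si = stats.ttest_ind(si, dsi, equal_var=equal_var).pvalue
                p_st = stats.ttest_ind(st, dst, equal_var=equal_var).pvalue
                p_si = 1.0 if math.isnan(p_si) else float(p_si)
                p_st = 1.0 if math.isnan(p_st) else float(p_st)
                entry["p_Si"] = p_si
                entry["p_ST"] = p_st
                entry["p_value"] = min(p_si, p_st)
                # one-sided logic: only indices LARGER than the dummy's count
                larger = (np.mean(si) > np.mean(dsi)) or (
                    np.mean(st) > np.mean(dst)
                )
                entry["significant"] = bool(
                    larger and entry["p_value"] < config.corrected_alpha
                )
            rows.append(entry)
    return SensitivityResult(
        table=pd.DataFrame(rows),
        si_raw=si_raw,
        st_raw=st_raw,
        config=config,
        metrics=list(metrics),
        n_failed_rows=n_failed,
    )


def _run_curves(config, metrics, evaluate_matrix) -> SensitivityResult:
    """Shared driver: sample, evaluate, decompose, aggregate.

    ``evaluate_matrix(mat)`` maps an (Ns × k) sample matrix to a dict
    ``metric -> array of Ns outputs`` plus a count of failed (interpolated)
    rows.
    """
    config.validate()
    si_raw = {}
    st_raw = {}
    n_failed = 0
    for f, p in enumerate(config.parameters):
        si_acc = {m: [] for m in metrics}
        st_acc = {m: [] for m in metrics}
        for r in range(config.resamplings):
            mat = efast_sample(config, f, r)
            outputs, failed = evaluate_matrix(mat)
            n_failed += failed
            for m in metrics:
                s_i, s_t, _flag = efast_indices(outputs[m], config, f)
                si_acc[m].append(s_i)
                st_acc[m].append(s_t)
        for m in metrics:
            si_raw[(p.name, m)] = np.array(si_acc[m])
            st_raw[(p.name, m)] = np.array(st_acc[m])
    return _aggregate(config, metrics, si_raw, st_raw, n_failed)


def efast_run(
    model: CommunityModel,
    init: InitialCondition,
    sim_config: SimulationConfig,
    gsa_config: GsaConfig,
    metrics: Sequence[str],
) -> SensitivityResult:
    """Full eFAST analysis of the batch simulator.

    For every focus parameter and resampling, builds the sample matrix, runs
    one batch simulation per row, extracts the requested metrics (see
    :meth:`MetricSet.scalar` for names) and decomposes their spectra.
    Individual failed simulations are replaced by linear interpolation along
    the search curve and counted; the analysis aborts if more than
    ``max_failed_fraction`` of rows fail.  Fully seeded and reproducible;
    rows are independent, so results do not depend on evaluation order.
    """
    gsa_config.validate()
    # resolve all paths up front (configuration errors precede integration)
    from .simulate import get_param

    for p in gsa_config.parameters:
        if not p.is_dummy:
            get_param(model, init, p.path)
    metrics = list(metrics)
    params = gsa_config.parameters

    def evaluate_matrix(mat):
        ns = mat.shape[0]
        out = {m: np.empty(ns) for m in metrics}
        bad = []
        for row_i in range(ns):
            m2 = model.copy()
            ic = init.copy()
            for p, v in zip(params, mat[row_i]):
                if not p.is_dummy:
                    set_param(m2, ic, p.path, float(v))
            try:
                ms = compute_metrics(simulate_batch(m2, ic, sim_config))
                for m in metrics:
                    out[m][row_i] = ms.scalar(m)
            except SimulationError:
                bad.append(row_i)
                for m in metrics:
                    out[m][row_i] = np.nan
        if bad:
            if len(bad) > gsa_config.max_failed_fraction * ns:
                raise SimulationError(
                    f"{len(bad)}/{ns} simulations failed along one search "
                    f"curve (> {gsa_config.max_failed_fraction:.0%} allowed)"
                )
            good = np.setdiff1d(np.arange(ns), bad)
            for m in metrics:
                out[m][bad] = np.interp(bad, good, out[m][good])
        return out, len(bad)

    return _run_curves(gsa_config, metrics, evaluate_matrix)


def efast_run_function(
    func: Callable[[np.ndarray], float],
    gsa_config: GsaConfig,
    metric_name: str = "output",
) -> SensitivityResult:
    """eFAST analysis of an arbitrary scalar function of a parameter vector.

    Used for benchmark functions with known variance decompositions (and as
    a fast host for dummy-parameter control experiments).  ``func`` receives
    one parameter vector (dummy entries included — it is the function's
    business to ignore them) and returns a scalar.
    """
    gsa_config.validate()

    def evaluate_matrix(mat):
        vals = np.array([func(row) for row in mat], dtype=float)
        return {metric_name: vals}, 0

    return _run_curves(gsa_config, [metric_name], evaluate_matrix)
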