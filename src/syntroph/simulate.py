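"""Batch integration of the community ODE system and performance metrics.

A batch run integrates the stiff system over a fixed window (default 72 h,
the window used to characterise co-culture growth) on a dense output grid,
then summarises the trajectory as the metrics used to describe co-culture
performance: final total population, batch culture time (operationalised as
the glucose-exhaustion crossing), final composition, per-strain maximum
specific growth rate, per-(strain, metabolite) maximum uptake and production
fluxes, and — when a heterologous pathway is configured — productivity and
yield.
"""

from __future__ import annotations

import copy
import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .model import (
    CommunityModel,
    CompiledModel,
    ConfigurationError,
    DomainError,
    InitialCondition,
    rhs_function,
)


@dataclass
class SimulationConfig:
    """Integration window, output grid and solver tolerances.

    ``eps_glucose`` defines batch completion: the batch culture time is the
    first time glucose falls to ``eps_glucose * glucose_0``.  ``smooth_min``
    switches the Liebig min() in the growth law to a soft-min with sharpness
    ``smooth_beta`` (for solver-robustness comparisons only; the hard min is
    the model).
    """

    t_end: float = 72.0
    dt_out: float = 0.25
    rtol: float = 1e-8
    atol: float = 1e-10
    eps_glucose: float = 1e-3
    smooth_min: bool = False
    smooth_beta: float = 200.0

    def validate(self) -> None:
        if not self.t_end > 0:
            raise ConfigurationError(f"t_end must be > 0, got {self.t_end}")
        if not self.dt_out > 0:
            raise ConfigurationError(f"dt_out must be > 0, got {self.dt_out}")
        if not 0.0 < self.eps_glucose < 1.0:
            raise ConfigurationError(
                f"eps_glucose must lie in (0,1), got {self.eps_glucose}"
            )

    def grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt_out))
        return np.linspace(0.0, self.t_end, n + 1)


class SimulationError(RuntimeError):
    """Integration failed; carries the last valid state and time."""

    def __init__(self, message, time=None, last_state=None):
        super().__init__(message)
        self.time = time
        self.last_state = last_state


@dataclass
class SimulationResult:
    """Dense trajectories plus solver metadata."""

    times: np.ndarray
    states: np.ndarray  # (T, D)
    compiled: CompiledModel
    init: InitialCondition
    config: SimulationConfig
    success: bool = True
    message: str = ""
    n_steps: int = 0

    @property
    def layout(self):
        return self.compiled.layout

    def component(self, name: str) -> np.ndarray:
        names = self.layout.component_names()
        try:
            return self.states[:, names.index(name)]
        except ValueError:
            raise KeyError(f"unknown component {name!r}; have {names}") from None

    @property
    def glucose(self) -> np.ndarray:
        return self.states[:, 0]

    def metabolite(self, met_id: str) -> np.ndarray:
        return self.states[:, self.layout.met_index(met_id)]

    def biomass(self, strain_id: str) -> np.ndarray:
        return self.states[:, self.layout.strain_index(strain_id)]

    @property
    def total_biomass(self) -> np.ndarray:
        lo = 1 + self.layout.n_met
        return self.states[:, lo : lo + self.layout.n_strains].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format trajectory table (time, component, value)."""
        names = self.layout.component_names()
        T = len(self.times)
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, len(names)),
                "component": np.tile(names, T),
                "value": self.states.reshape(-1),
            }
        )


def _softmin_patch(compiled: CompiledModel, beta: float):
    """Return rhs callable using a log-sum-exp soft minimum (diagnostic)."""
    args = compiled.rhs_args()
    lay = compiled.layout

    def rhs(t, s):
        M, N = lay.n_met, lay.n_strains
        out = np.zeros_like(s)
        G = max(s[0], 0.0)
        for i in range(N):
            y = max(s[1 + M + i], 0.0)
            j_g = compiled.vmax_g[i] * G / (compiled.km_g[i] + G)
            terms = [compiled.gamma_g[i] * (1 - compiled.phi_tot[i]) * j_g]
            for m in range(M):
                if compiled.aux[i, m]:
                    x = max(s[1 + m], 0.0)
                    j_up = compiled.up_vmax[i, m] * x / (compiled.up_km[i, m] + x)
                    out[1 + m] -= j_up * y
                    terms.append(compiled.gamma_m[i, m] * j_up)
                if compiled.leak[i, m] > 0:
                    out[1 + m] += (
                        compiled.leak[i, m] * compiled.delta[m] * j_g * y
                    )
            t_arr = np.asarray(terms)
            j_grow = -np.log(np.sum(np.exp(-beta * t_arr))) / beta
            out[0] -= j_g * y
            out[1 + M + i] = (j_grow - compiled.eta[i]) * y
        return out

    return rhs


def simulate_batch(
    model: CommunityModel,
    init: InitialCondition,
    config: Optional[SimulationConfig] = None,
) -> SimulationResult:
    """Integrate the batch system and return dense trajectories.

    Deterministic: identical inputs give identical outputs on one platform.
    Uses LSODA (automatic stiff/non-stiff switching), matching the use of a
    stiff solver for the non-smooth Liebig growth law.
    """
    config = config or SimulationConfig()
    config.validate()
    compiled = CompiledModel(model)
    return _simulate_compiled(compiled, init, config)


def _simulate_compiled(
    compiled: CompiledModel,
    init: InitialCondition,
    config: SimulationConfig,
) -> SimulationResult:
    s0 = compiled.initial_state(init)
    t = config.grid()
    if config.smooth_min:
        rhs = _softmin_patch(compiled, config.smooth_beta)
        args = ()
    else:
        rhs = rhs_function()
        args = compiled.rhs_args()
    states, info = odeint(
        rhs,
        s0,
        t,
        args=args,
        rtol=config.rtol,
        atol=config.atol,
        tfirst=True,
        full_output=True,
        mxstep=20000,
    )
    ok = info["message"] == "Integration successful."
    if not ok:
        # locate the last row actually computed
        tcur = float(info["tcur"][-1]) if len(info["tcur"]) else 0.0
        k = int(np.searchsorted(t, tcur, side="right")) - 1
        raise SimulationError(
            f"ODE integration failed at t={tcur:.3f} h: {info['message']}",
            time=tcur,
            last_state=states[max(k, 0)],
        )
    return SimulationResult(
        times=t,
        states=states,
        compiled=compiled,
        init=init,
        config=config,
        success=True,
        message=info["message"],
        n_steps=int(info["nst"][-1]),
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricSet:
    """Performance metrics of one batch run.

    Rates are specific fluxes (per unit biomass): growth in h⁻¹, glucose
    uptake in g h⁻¹ per OD unit, metabolite uptake/production in mg h⁻¹ per
    OD unit.  ``productivity`` (µM h⁻¹) and ``yield_ratio`` (µM product per
    g l⁻¹ glucose consumed) are ``None`` unless a pathway is configured.
    """

    final_total_population: float
    batch_time: float
    final_ratios: dict
    max_growth_rate: dict
    max_uptake_rate: dict  # (strain, metabolite) -> rate
    max_production_rate: dict  # (strain, metabolite) -> rate
    peak_metabolite: dict  # metabolite -> max concentration over the run
    max_total_population: float
    degenerate_composition: bool = False
    productivity: Optional[float] = None
    yield_ratio: Optional[float] = None

    def scalar(self, name: str) -> float:
        """Look up one scalar metric by name.

        Names: ``final_total_od``, ``batch_time``, ``max_total_od``,
        ``final_ratio:<strain>``, ``max_growth_rate:<strain>``,
        ``max_uptake:<strain>:<met>``, ``max_production:<strain>:<met>``,
        ``peak_metabolite:<met>``, ``productivity``, ``yield_ratio``.
        """
        if name == "final_total_od":
            return self.final_total_population
        if name == "batch_time":
            return self.batch_time
        if name == "max_total_od":
            return self.max_total_population
        if name == "productivity":
            if self.productivity is None:
                raise KeyError("productivity is only defined for pathway runs")
            return self.productivity
        if name == "yield_ratio":
            if self.yield_ratio is None:
                raise KeyError("yield_ratio is only defined for pathway runs")
            return self.yield_ratio
        parts = name.split(":")
        try:
            if parts[0] == "final_ratio":
                return self.final_ratios[parts[1]]
            if parts[0] == "max_growth_rate":
                return self.max_growth_rate[parts[1]]
            if parts[0] == "peak_metabolite":
                return self.peak_metabolite[parts[1]]
            if parts[0] == "max_uptake":
                return self.max_uptake_rate[(parts[1], parts[2])]
            if parts[0] == "max_production":
                return self.max_production_rate[(parts[1], parts[2])]
        except (KeyError, IndexError):
            pass
        raise KeyError(f"unknown metric name {name!r}")

    def to_row(self) -> dict:
        """Flatten to a single dict suitable for a one-row-per-run table."""
        row = {
            "final_total_od": self.final_total_population,
            "batch_time": self.batch_time,
            "max_total_od": self.max_total_population,
            "degenerate_composition": self.degenerate_composition,
        }
        for sid, v in self.final_ratios.items():
            row[f"final_ratio:{sid}"] = v
        for sid, v in self.max_growth_rate.items():
            row[f"max_growth_rate:{sid}"] = v
        for (sid, met), v in self.max_uptake_rate.items():
            row[f"max_uptake:{sid}:{met}"] = v
        for (sid, met), v in self.max_production_rate.items():
            row[f"max_production:{sid}:{met}"] = v
        for met, v in self.peak_metabolite.items():
            row[f"peak_metabolite:{met}"] = v
        if self.productivity is not None:
            row["productivity"] = self.productivity
        if self.yield_ratio is not None:
            row["yield_ratio"] = self.yield_ratio
        return row


_DEGENERATE_OD = 1e-9


def compute_metrics(result: SimulationResult) -> MetricSet:
    """Summarise a trajectory as a :class:`MetricSet`.

    Batch time is the linearly interpolated first crossing of
    G(t) ≤ ε_G·G(0) (``t_end`` if glucose is never exhausted).  Maxima are
    taken over the dense output grid.  If the culture never grows (total
    biomass ~0 throughout), the final composition is reported as the
    inoculum ratios with ``degenerate_composition`` set.
    """
    c = result.compiled
    lay = c.layout
    t = result.times
    S = np.clip(result.states, 0.0, None)
    G = S[:, 0]
    X = S[:, 1 : 1 + lay.n_met]  # (T, M)
    Y = S[:, 1 + lay.n_met : 1 + lay.n_met + lay.n_strains]  # (T, N)

    g0 = G[0]
    eps = result.config.eps_glucose
    if g0 <= 0:
        batch_time = 0.0
    else:
        thresh = eps * g0
        below = np.nonzero(G <= thresh)[0]
        if len(below) == 0:
            batch_time = float(t[-1])
        else:
            k = below[0]
            if k == 0:
                batch_time = float(t[0])
            else:
                f = (G[k - 1] - thresh) / (G[k - 1] - G[k])
                batch_time = float(t[k - 1] + f * (t[k] - t[k - 1]))

    j_g = c.vmax_g[None, :] * G[:, None] / (c.km_g[None, :] + G[:, None])  # (T,N)
    grow_g = c.gamma_g[None, :] * (1.0 - c.phi_tot[None, :]) * j_g
    # metabolite-limited terms, (T, N, M)
    up = np.where(
        c.aux[None, :, :] == 1,
        c.up_vmax[None, :, :]
        * X[:, None, :]
        / (c.up_km[None, :, :] + X[:, None, :]),
        0.0,
    )
    grow_m = np.where(c.aux[None, :, :] == 1, c.gamma_m[None, :, :] * up, np.inf)
    grow = np.minimum(grow_g, grow_m.min(axis=2))
    if c.model.toxicity_enabled:
        with np.errstate(divide="ignore"):
            ratio = np.where(
                np.isfinite(c.tox_theta)[None, :], X / c.tox_theta[None, :], 0.0
            )
        tox = np.prod(1.0 / (1.0 + ratio ** c.tox_n), axis=1)
        grow = grow * tox[:, None]
    prod = c.leak[None, :, :] * c.delta[None, None, :] * j_g[:, :, None]

    total = Y.sum(axis=1)
    final_total = float(total[-1])
    degenerate = bool(total.max() <= max(_DEGENERATE_OD, 10 * result.config.atol))
    if final_total > _DEGENERATE_OD and not degenerate:
        ratios = {
            sid: float(Y[-1, i] / final_total)
            for i, sid in enumerate(lay.strain_ids)
        }
    else:
        degenerate = True
        ratios = dict(result.init.ratios_0)

    max_growth = {
        sid: float(grow[:, i].max()) for i, sid in enumerate(lay.strain_ids)
    }
    max_uptake = {}
    max_production = {}
    for i, sid in enumerate(lay.strain_ids):
        for m, met in enumerate(lay.metabolite_ids):
            if c.aux[i, m]:
                max_uptake[(sid, met)] = float(up[:, i, m].max())
            if c.leak[i, m] > 0:
                max_production[(sid, met)] = float(prod[:, i, m].max())
    peaks = {met: float(X[:, m].max()) for m, met in enumerate(lay.metabolite_ids)}

    productivity = None
    yield_ratio = None
    if lay.has_pathway:
        P = float(S[-1, lay.product_index])
        productivity = P / float(t[-1])
        consumed = g0 - float(G[-1])
        yield_ratio = P / consumed if consumed > 1e-12 else 0.0

    return MetricSet(
        final_total_population=final_total,
        batch_time=batch_time,
        final_ratios=ratios,
        max_growth_rate=max_growth,
        max_uptake_rate=max_uptake,
        max_production_rate=max_production,
        peak_metabolite=peaks,
        max_total_population=float(total.max()),
        degenerate_composition=degenerate,
        productivity=productivity,
        yield_ratio=yield_ratio,
    )


def classify_growth(max_od: float) -> str:
    """Growth-strength class of a co-culture from its maximal OD₇₀₀.

    strong: OD ≥ 0.5; medium: 0.3 ≤ OD < 0.5; weak: OD < 0.3.
    """
    if max_od < 0:
        raise DomainError(f"max OD must be >= 0, got {max_od}")
    if max_od >= 0.5:
        return "strong"
    if max_od >= 0.3:
        return "medium"
    return "weak"


# ---------------------------------------------------------------------------
# Parameter paths and sweeps
# ---------------------------------------------------------------------------


def _path_error(path: str) -> ConfigurationError:
    return ConfigurationError(
        f"cannot resolve parameter path {path!r}; valid forms: "
        "init.glucose_0 | init.total_density_0 | init.ratios_0.<strain> | "
        "init.supplements_0.<met> | strains.<id>.productions.<met> | "
        "strains.<id>.glucose_uptake.{v_max,k_m} | "
        "strains.<id>.metabolite_uptake.<met>.{v_max,k_m} | "
        "strains.<id>.yield_glucose | strains.<id>.yield_metabolite.<met> | "
        "strains.<id>.death_rate | metabolites.<id>.delta | "
        "pathway.phi_upstream | pathway.conversion.{v_max,k_m}"
    )


def set_param(
    model: CommunityModel, init: InitialCondition, path: str, value: float
) -> None:
    """Set one scalar parameter addressed by a dotted path, in place."""
    parts = path.split(".")
    try:
        if parts[0] == "init":
            if parts[1] in ("glucose_0", "total_density_0") and len(parts) == 2:
                setattr(init, parts[1], value)
            elif parts[1] == "ratios_0" and len(parts) == 3:
                if parts[2] not in init.ratios_0:
                    raise _path_error(path)
                init.ratios_0[parts[2]] = value
            elif parts[1] == "supplements_0" and len(parts) == 3:
                init.supplements_0[parts[2]] = value
            else:
                raise _path_error(path)
        elif parts[0] == "strains":
            s = model.strain(parts[1])
            if parts[2] == "productions" and len(parts) == 4:
                if parts[3] not in s.productions:
                    raise _path_error(path)
                s.productions[parts[3]] = value
            elif parts[2] == "glucose_uptake" and parts[3] in ("v_max", "k_m"):
                setattr(s.glucose_uptake, parts[3], value)
            elif parts[2] == "metabolite_uptake" and len(parts) == 5:
                setattr(s.metabolite_uptake[parts[3]], parts[4], value)
            elif parts[2] in ("yield_glucose", "death_rate") and len(parts) == 3:
                setattr(s, parts[2], value)
            elif parts[2] == "yield_metabolite" and len(parts) == 4:
                s.yield_metabolite[parts[3]] = value
            else:
                raise _path_error(path)
        elif parts[0] == "metabolites" and parts[2] == "delta":
            model.metabolite(parts[1]).delta = value
        elif parts[0] == "pathway":
            if model.pathway is None:
                raise _path_error(path)
            if parts[1] == "phi_upstream" and len(parts) == 2:
                model.pathway.phi_upstream = value
            elif parts[1] == "conversion" and parts[2] in ("v_max", "k_m"):
                setattr(model.pathway.conversion, parts[2], value)
            else:
                raise _path_error(path)
        else:
            raise _path_error(path)
    except (IndexError, KeyError, ConfigurationError) as e:
        if isinstance(e, ConfigurationError):
            raise
        raise _path_error(path) from None


def get_param(model: CommunityModel, init: InitialCondition, path: str) -> float:
    """Read one scalar parameter addressed by a dotted path."""
    parts = path.split(".")
    try:
        if parts[0] == "init":
            if parts[1] in ("glucose_0", "total_density_0") and len(parts) == 2:
                return getattr(init, parts[1])
            if parts[1] == "ratios_0":
                return init.ratios_0[parts[2]]
            if parts[1] == "supplements_0":
                return init.supplements_0.get(parts[2], 0.0)
        elif parts[0] == "strains":
            s = model.strain(parts[1])
            if parts[2] == "productions":
                return s.productions[parts[3]]
            if parts[2] == "glucose_uptake":
                return getattr(s.glucose_uptake, parts[3])
            if parts[2] == "metabolite_uptake":
                return getattr(s.metabolite_uptake[parts[3]], parts[4])
            if parts[2] in ("yield_glucose", "death_rate"):
                return getattr(s, parts[2])
            if parts[2] == "yield_metabolite":
                return s.yield_metabolite[parts[3]]
        elif parts[0] == "metabolites" and parts[2] == "delta":
            return model.metabolite(parts[1]).delta
        elif parts[0] == "pathway" and model.pathway is not None:
            if parts[1] == "phi_upstream":
                return model.pathway.phi_upstream
            if parts[1] == "conversion":
                return getattr(model.pathway.conversion, parts[2])
    except (IndexError, KeyError, AttributeError):
        pass
    raise _path_error(path)


def _renormalise_ratios(init: InitialCondition) -> None:
    total = sum(init.ratios_0.values())
    if total > 0:
        for k in init.ratios_0:
            init.ratios_0[k] /= total


def sweep(
    model: CommunityModel,
    init: InitialCondition,
    config: SimulationConfig,
    path: str,
    values: Sequence[float],
    renormalise_ratios: bool = True,
) -> pd.DataFrame:
    """Simulate once per value of one parameter; one metrics row per value."""
    return sweep_grid(
        model, init, config, [(path, values)], renormalise_ratios=renormalise_ratios
    )


def sweep_grid(
    model: CommunityModel,
    init: InitialCondition,
    config: SimulationConfig,
    axes: Sequence,
    renormalise_ratios: bool = True,
) -> pd.DataFrame:
    """Cartesian product sweep over several (path, values) axes.

    Grid order is preserved (last axis fastest).  Initial-ratio paths are
    renormalised to sum to one after assignment (disable with
    ``renormalise_ratios=False``).
    """
    # validate paths up front so errors precede any integration
    for path, _ in axes:
        get_param(model, init, path)
    rows = []
    paths = [p for p, _ in axes]
    for combo in itertools.product(*[list(v) for _, v in axes]):
        m = model.copy()
        ic = init.copy()
        for path, value in zip(paths, combo):
            set_param(m, ic, path, float(value))
        if renormalise_ratios and any(p.startswith("init.ratios_0") for p in paths):
            _renormalise_ratios(ic)
        metrics = compute_metrics(simulate_batch(m, ic, config))
        row = dict(zip(paths, combo))
        row.update(metrics.to_row())
        rows.append(row)
    return pd.DataFrame(rows)
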