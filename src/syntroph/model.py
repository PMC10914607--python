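"""Domain types and right-hand side of the batch co-culture ODE system.

The model tracks extracellular glucose G (g l⁻¹), exchanged metabolites
x_i (mg l⁻¹) and strain biomasses y_i (OD₇₀₀ units) in a well-mixed batch
culture.  Each strain takes up glucose by Monod kinetics, diverts a fixed
fraction ϕ of that flux to overproduction of its "donated" metabolite, and
grows at the minimum of its glucose-limited and metabolite-limited growth
fluxes (Liebig-style limitation by whichever substrate is scarcest):

    dG/dt  = −Σ_i  J_upt,G^i · y_i
    dy_i/dt = (J_grow^i − η_i) · y_i
    dx_m/dt = Σ_producers J_leak,m · y  −  Σ_consumers J_upt,m · y

with J_upt = V_max·S/(k_M+S),  J_leak,m = ϕ_m·δ_m·J_upt,G,
J_grow = min( γ_G(1−Σϕ)·J_upt,G,  min_j γ_j·J_upt,j ).

Two optional extensions: Hill-type growth inhibition above a per-metabolite
toxicity threshold, and a two-stage heterologous pathway split across the
community (an upstream strain diverts part of its glucose flux to an
intermediate which a downstream strain converts to an inert product).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np


class ConfigurationError(ValueError):
    """A community/initial-condition specification is internally inconsistent."""


class DomainError(ValueError):
    """A state or argument is outside the model's physical domain."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MetaboliteSpec:
    """One exchanged metabolite.

    Parameters
    ----------
    id : str
        Short name, e.g. ``"ade"`` or ``"lys"``.
    delta : float
        Stoichiometric constant δ (glucose units per metabolite unit) in the
        leak flux J_leak = ϕ·δ·J_upt,G.  Defaults to 1.
    toxicity_threshold : float, optional
        Concentration (mg l⁻¹) at which the Hill inhibition factor reaches
        one half.  ``None`` disables toxicity for this metabolite.
    """

    id: str
    delta: float = 1.0
    toxicity_threshold: Optional[float] = None

    def validate(self) -> None:
        if not self.id:
            raise ConfigurationError("metabolite id must be non-empty")
        if not self.delta > 0:
            raise ConfigurationError(
                f"metabolite {self.id!r}: delta must be > 0, got {self.delta}"
            )
        if self.toxicity_threshold is not None and self.toxicity_threshold < 0:
            raise ConfigurationError(
                f"metabolite {self.id!r}: toxicity_threshold must be >= 0"
            )


@dataclass
class UptakeKinetics:
    """Monod uptake kinetics: J(S) = v_max·S/(k_m+S)."""

    v_max: float
    k_m: float

    def validate(self, context: str = "") -> None:
        where = f" ({context})" if context else ""
        if self.v_max < 0:
            raise ConfigurationError(f"v_max must be >= 0{where}, got {self.v_max}")
        if not self.k_m > 0:
            raise ConfigurationError(f"k_m must be > 0{where}, got {self.k_m}")


@dataclass
class StrainSpec:
    """One community member.

    ``auxotrophies`` lists the metabolites the strain cannot synthesise and
    must take up; ``productions`` maps each donated metabolite to its leak
    fraction ϕ ∈ [0,1).  ``yield_glucose`` (γ_G, biomass per g glucose) and
    ``yield_metabolite`` (γ_j, biomass per mg metabolite) convert uptake
    fluxes to growth fluxes.  ``death_rate`` is the first-order decay η (h⁻¹).
    """

    id: str
    auxotrophies: frozenset = field(default_factory=frozenset)
    productions: dict = field(default_factory=dict)  # metabolite id -> phi
    glucose_uptake: UptakeKinetics = field(
        default_factory=lambda: UptakeKinetics(v_max=1.1, k_m=2.0)
    )
    metabolite_uptake: dict = field(default_factory=dict)  # id -> UptakeKinetics
    yield_glucose: float = 0.05
    yield_metabolite: dict = field(default_factory=dict)  # id -> gamma_j
    death_rate: float = 0.01
    pathway_stage: str = "none"  # none | upstream | downstream
    fluor_channel: Optional[str] = None  # RFP | BFP | GFP

    def __post_init__(self) -> None:
        self.auxotrophies = frozenset(self.auxotrophies)

    @property
    def phi_total(self) -> float:
        """Summed leak fraction over all produced metabolites."""
        return float(sum(self.productions.values()))

    def validate(self, pathway_fraction: float = 0.0) -> None:
        if not self.id:
            raise ConfigurationError("strain id must be non-empty")
        for met, phi in self.productions.items():
            if not 0.0 <= phi < 1.0:
                raise ConfigurationError(
                    f"strain {self.id!r}: leak fraction for {met!r} must lie in "
                    f"[0,1), got {phi}"
                )
        diverted = self.phi_total + pathway_fraction
        if diverted >= 1.0:
            raise ConfigurationError(
                f"strain {self.id!r}: total diverted glucose fraction "
                f"(leaks + pathway) must stay < 1, got {diverted}"
            )
        self.glucose_uptake.validate(f"strain {self.id!r} glucose uptake")
        for met in self.auxotrophies:
            if met not in self.metabolite_uptake:
                raise ConfigurationError(
                    f"strain {self.id!r}: auxotrophic for {met!r} but no "
                    f"metabolite_uptake kinetics given"
                )
            if met not in self.yield_metabolite:
                raise ConfigurationError(
                    f"strain {self.id!r}: auxotrophic for {met!r} but no "
                    f"yield_metabolite entry given"
                )
            self.metabolite_uptake[met].validate(
                f"strain {self.id!r} uptake of {met!r}"
            )
        overlap = self.auxotrophies & set(self.productions)
        if overlap:
            raise ConfigurationError(
                f"strain {self.id!r}: cannot both produce and require "
                f"{sorted(overlap)}"
            )
        if self.death_rate < 0:
            raise ConfigurationError(
                f"strain {self.id!r}: death_rate must be >= 0, got {self.death_rate}"
            )
        if self.yield_glucose < 0:
            raise ConfigurationError(
                f"strain {self.id!r}: yield_glucose must be >= 0"
            )
        if self.pathway_stage not in ("none", "upstream", "downstream"):
            raise ConfigurationError(
                f"strain {self.id!r}: pathway_stage must be none/upstream/"
                f"downstream, got {self.pathway_stage!r}"
            )
        if self.fluor_channel not in (None, "RFP", "BFP", "GFP"):
            raise ConfigurationError(
                f"strain {self.id!r}: fluor_channel must be RFP/BFP/GFP or None"
            )


@dataclass
class PathwaySpec:
    """Two-stage heterologous pathway split across the community.

    The upstream strain diverts ``phi_upstream`` of its glucose uptake flux
    to synthesis of the intermediate (p-coumaric acid in the reference
    application); the downstream strain converts intermediate to product
    (resveratrol) by Monod-type kinetics scaled by its biomass.  The product
    is inert.  ``intermediate_per_glucose`` converts diverted glucose flux
    (g h⁻¹ per OD) to intermediate production (µM h⁻¹ per OD).
    """

    phi_upstream: float = 0.1
    conversion: UptakeKinetics = field(
        default_factory=lambda: UptakeKinetics(v_max=10.0, k_m=50.0)
    )
    intermediate_id: str = "p-coumaric acid"
    product_id: str = "resveratrol"
    intermediate_per_glucose: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.phi_upstream < 1.0:
            raise ConfigurationError(
                f"pathway: phi_upstream must lie in [0,1), got {self.phi_upstream}"
            )
        self.conversion.validate("pathway conversion")
        if self.intermediate_per_glucose <= 0:
            raise ConfigurationError("pathway: intermediate_per_glucose must be > 0")


@dataclass
class CommunityModel:
    """The full community: metabolite catalogue plus strain list."""

    metabolites: list
    strains: list
    pathway: Optional[PathwaySpec] = None
    toxicity_enabled: bool = False
    toxicity_hill: float = 2.0

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ConfigurationError(f"duplicate metabolite ids: {met_ids}")
        strain_ids = [s.id for s in self.strains]
        if len(set(strain_ids)) != len(strain_ids):
            raise ConfigurationError(f"duplicate strain ids: {strain_ids}")
        if not self.strains:
            raise ConfigurationError("community must contain at least one strain")
        known = set(met_ids)
        for m in self.metabolites:
            m.validate()
        for s in self.strains:
            pf = 0.0
            if self.pathway is not None and s.pathway_stage == "upstream":
                pf = self.pathway.phi_upstream
            s.validate(pathway_fraction=pf)
            refs = set(s.auxotrophies) | set(s.productions)
            missing = refs - known
            if missing:
                raise ConfigurationError(
                    f"strain {s.id!r} references unknown metabolite(s) "
                    f"{sorted(missing)}; catalogue has {sorted(known)}"
                )
        if self.pathway is not None:
            self.pathway.validate()
            ups = [s for s in self.strains if s.pathway_stage == "upstream"]
            downs = [s for s in self.strains if s.pathway_stage == "downstream"]
            if not ups or not downs:
                raise ConfigurationError(
                    "pathway enabled but community lacks an upstream or a "
                    "downstream strain"
                )
        if self.toxicity_enabled and self.toxicity_hill <= 0:
            raise ConfigurationError("toxicity_hill must be > 0")

    def strain(self, strain_id: str) -> StrainSpec:
        for s in self.strains:
            if s.id == strain_id:
                return s
        raise ConfigurationError(
            f"unknown strain {strain_id!r}; have {[s.id for s in self.strains]}"
        )

    def metabolite(self, met_id: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise ConfigurationError(
            f"unknown metabolite {met_id!r}; have {[m.id for m in self.metabolites]}"
        )

    def copy(self) -> "CommunityModel":
        return copy.deepcopy(self)


@dataclass
class InitialCondition:
    """Inoculum and medium at t = 0.

    ``ratios_0`` gives the composition r_{0,i} of the total inoculum density
    N_0 (OD₇₀₀), so y_i(0) = r_{0,i}·N_0; the ratios must sum to one.
    ``supplements_0`` gives initial medium concentrations x_{0,i} (mg l⁻¹).
    """

    glucose_0: float = 20.0
    total_density_0: float = 0.1
    ratios_0: dict = field(default_factory=dict)  # strain id -> fraction
    supplements_0: dict = field(default_factory=dict)  # metabolite id -> mg/l

    RATIO_TOL = 1e-12

    def validate(self, model: Optional[CommunityModel] = None) -> None:
        if self.glucose_0 < 0:
            raise ConfigurationError("glucose_0 must be >= 0")
        if self.total_density_0 < 0:
            raise ConfigurationError("total_density_0 must be >= 0")
        for k, v in self.ratios_0.items():
            if v < 0:
                raise ConfigurationError(f"ratio for strain {k!r} must be >= 0")
        for k, v in self.supplements_0.items():
            if v < 0:
                raise ConfigurationError(f"supplement for {k!r} must be >= 0")
        total = sum(self.ratios_0.values())
        if abs(total - 1.0) > self.RATIO_TOL:
            raise ConfigurationError(
                f"initial ratios must sum to 1 (within {self.RATIO_TOL}), "
                f"got {total!r}"
            )
        if model is not None:
            strain_ids = {s.id for s in model.strains}
            unknown = set(self.ratios_0) - strain_ids
            if unknown:
                raise ConfigurationError(
                    f"ratios_0 references unknown strain(s) {sorted(unknown)}"
                )
            if set(self.ratios_0) != strain_ids:
                raise ConfigurationError(
                    f"ratios_0 must cover every strain; missing "
                    f"{sorted(strain_ids - set(self.ratios_0))}"
                )
            met_ids = {m.id for m in model.metabolites}
            unknown = set(self.supplements_0) - met_ids
            if unknown:
                raise ConfigurationError(
                    f"supplements_0 references unknown metabolite(s) "
                    f"{sorted(unknown)}"
                )

    def copy(self) -> "InitialCondition":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Flux primitives
# ---------------------------------------------------------------------------


def monod_uptake(kinetics: UptakeKinetics, substrate: float) -> float:
    """Monod uptake rate per unit biomass: v_max·S/(k_m+S).

    Zero at S = 0, strictly increasing, saturating at v_max.
    """
    if substrate < 0:
        raise DomainError(f"substrate concentration must be >= 0, got {substrate}")
    return kinetics.v_max * substrate / (kinetics.k_m + substrate)


def leak_flux(phi: float, delta: float, j_upt_glucose: float) -> float:
    """Metabolite production rate per unit biomass: ϕ·δ·J_upt,G."""
    if not 0.0 <= phi < 1.0:
        raise ConfigurationError(f"leak fraction phi must lie in [0,1), got {phi}")
    if not delta > 0:
        raise ConfigurationError(f"delta must be > 0, got {delta}")
    if j_upt_glucose < 0:
        raise DomainError(f"glucose uptake flux must be >= 0, got {j_upt_glucose}")
    return phi * delta * j_upt_glucose


def growth_rate(
    strain: StrainSpec,
    j_upt_glucose: float,
    j_upt_metabolites: Optional[Mapping[str, float]] = None,
    pathway_fraction: float = 0.0,
):
    """Liebig growth rate of one strain and the limiting substrate label.

    The glucose-limited term is γ_G·(1−Σϕ)·J_upt,G; each auxotrophic
    metabolite j contributes γ_j·J_upt,j.  Returns ``(rate, label)`` where
    label is ``"glucose"`` or the limiting metabolite id.
    """
    if j_upt_glucose < 0:
        raise DomainError("glucose uptake flux must be >= 0")
    j_upt_metabolites = j_upt_metabolites or {}
    unused = 1.0 - strain.phi_total - pathway_fraction
    best = strain.yield_glucose * unused * j_upt_glucose
    label = "glucose"
    for met in sorted(strain.auxotrophies):
        if met not in strain.yield_metabolite:
            raise ConfigurationError(
                f"strain {strain.id!r}: missing yield for auxotrophic "
                f"metabolite {met!r}"
            )
        j = j_upt_metabolites.get(met, 0.0)
        if j < 0:
            raise DomainError(f"uptake flux of {met!r} must be >= 0")
        term = strain.yield_metabolite[met] * j
        if term < best:
            best = term
            label = met
    return best, label


def toxicity_factor(
    concentrations: Mapping[str, float],
    model: CommunityModel,
) -> float:
    """Multiplicative Hill growth-inhibition factor in (0, 1].

    Each metabolite with a configured threshold θ contributes
    1/(1+(x/θ)^n); metabolites without thresholds contribute 1.  Returns 1
    when toxicity is disabled.
    """
    if not model.toxicity_enabled:
        return 1.0
    fac = 1.0
    n = model.toxicity_hill
    for m in model.metabolites:
        if m.toxicity_threshold is None:
            continue
        x = max(concentrations.get(m.id, 0.0), 0.0)
        if m.toxicity_threshold == 0.0:
            fac *= 0.0 if x > 0 else 1.0
        else:
            fac *= 1.0 / (1.0 + (x / m.toxicity_threshold) ** n)
    return fac


def apply_toxicity(
    growth: float,
    concentrations: Mapping[str, float],
    model: CommunityModel,
) -> float:
    """Attenuate a growth rate by the community's toxicity factor."""
    return growth * toxicity_factor(concentrations, model)


# ---------------------------------------------------------------------------
# State-vector layout and compiled arrays
# ---------------------------------------------------------------------------


@dataclass
class StateLayout:
    """Mapping between the flat ODE state vector and named components.

    Layout: ``[G, x_0..x_{M-1}, y_0..y_{N-1}, (intermediate, product)]``.
    """

    metabolite_ids: tuple
    strain_ids: tuple
    has_pathway: bool

    @property
    def n_met(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def size(self) -> int:
        return 1 + self.n_met + self.n_strains + (2 if self.has_pathway else 0)

    def met_index(self, met_id: str) -> int:
        return 1 + self.metabolite_ids.index(met_id)

    def strain_index(self, strain_id: str) -> int:
        return 1 + self.n_met + self.strain_ids.index(strain_id)

    @property
    def intermediate_index(self) -> int:
        return 1 + self.n_met + self.n_strains

    @property
    def product_index(self) -> int:
        return self.intermediate_index + 1

    def component_names(self) -> list:
        names = ["glucose"]
        names += [f"x:{m}" for m in self.metabolite_ids]
        names += [f"y:{s}" for s in self.strain_ids]
        if self.has_pathway:
            names += ["intermediate", "product"]
        return names


class CompiledModel:
    """Array form of a :class:`CommunityModel` for fast integration.

    All per-strain and per-(strain, metabolite) parameters are packed into
    contiguous float arrays consumed by the jitted right-hand side.
    """

    ARRAY_FIELDS = (
        "delta", "tox_theta", "vmax_g", "km_g", "gamma_g", "eta",
        "phi_tot", "leak", "aux", "up_vmax", "up_km", "gamma_m",
        "path_phi", "conv_vmax", "conv_km",
    )

    def __init__(self, model: CommunityModel):
        model.validate()
        self.model = model
        met_ids = tuple(m.id for m in model.metabolites)
        strain_ids = tuple(s.id for s in model.strains)
        self.layout = StateLayout(met_ids, strain_ids, model.pathway is not None)
        M, N = len(met_ids), len(strain_ids)

        self.delta = np.array([m.delta for m in model.metabolites], dtype=float)
        self.tox_theta = np.full(M, np.inf)
        if model.toxicity_enabled:
            for k, m in enumerate(model.metabolites):
                if m.toxicity_threshold is not None:
                    self.tox_theta[k] = m.toxicity_threshold
        self.tox_n = float(model.toxicity_hill)

        self.vmax_g = np.array([s.glucose_uptake.v_max for s in model.strains])
        self.km_g = np.array([s.glucose_uptake.k_m for s in model.strains])
        self.gamma_g = np.array([s.yield_glucose for s in model.strains])
        self.eta = np.array([s.death_rate for s in model.strains])

        self.leak = np.zeros((N, M))
        self.aux = np.zeros((N, M), dtype=np.int8)
        self.up_vmax = np.zeros((N, M))
        self.up_km = np.ones((N, M))
        self.gamma_m = np.zeros((N, M))
        self.path_phi = np.zeros(N)
        self.conv_vmax = np.zeros(N)
        self.conv_km = np.ones(N)
        for i, s in enumerate(model.strains):
            for met, phi in s.productions.items():
                self.leak[i, met_ids.index(met)] = phi
            for met in s.auxotrophies:
                k = met_ids.index(met)
                self.aux[i, k] = 1
                self.up_vmax[i, k] = s.metabolite_uptake[met].v_max
                self.up_km[i, k] = s.metabolite_uptake[met].k_m
                self.gamma_m[i, k] = s.yield_metabolite[met]
            if model.pathway is not None and s.pathway_stage == "upstream":
                self.path_phi[i] = (
                    model.pathway.phi_upstream * model.pathway.intermediate_per_glucose
                )
            if model.pathway is not None and s.pathway_stage == "downstream":
                self.conv_vmax[i] = model.pathway.conversion.v_max
                self.conv_km[i] = model.pathway.conversion.k_m
        # total diverted fraction (leaks + raw pathway fraction, unscaled)
        self.phi_tot = self.leak.sum(axis=1)
        if model.pathway is not None:
            for i, s in enumerate(model.strains):
                if s.pathway_stage == "upstream":
                    self.phi_tot[i] += model.pathway.phi_upstream

    def rhs_args(self) -> tuple:
        return (
            self.delta, self.tox_theta, self.tox_n,
            self.vmax_g, self.km_g, self.gamma_g, self.eta, self.phi_tot,
            self.leak, self.aux, self.up_vmax, self.up_km, self.gamma_m,
            self.path_phi, self.conv_vmax, self.conv_km,
            1 if self.layout.has_pathway else 0,
        )

    def initial_state(self, init: InitialCondition) -> np.ndarray:
        init.validate(self.model)
        s0 = np.zeros(self.layout.size)
        s0[0] = init.glucose_0
        for met, x0 in init.supplements_0.items():
            s0[self.layout.met_index(met)] = x0
        for sid, r in init.ratios_0.items():
            s0[self.layout.strain_index(sid)] = r * init.total_density_0
        return s0


def _rhs_py(
    t, s, delta, tox_theta, tox_n, vmax_g, km_g, gamma_g, eta, phi_tot,
    leak, aux, up_vmax, up_km, gamma_m, path_phi, conv_vmax, conv_km,
    has_pathway,
):
    """Pure-Python right-hand side (reference; jitted by numba when available).

    Concentrations are clipped at zero for flux evaluation so that small
    negative solver excursions cannot feed back into the dynamics.
    """
    M = delta.shape[0]
    N = vmax_g.shape[0]
    out = np.zeros(s.shape[0])
    G = s[0] if s[0] > 0.0 else 0.0
    # shared toxicity factor (depends on the medium only)
    tox = 1.0
    for m in range(M):
        if tox_theta[m] != np.inf:
            x = s[1 + m]
            if x < 0.0:
                x = 0.0
            if tox_theta[m] == 0.0:
                if x > 0.0:
                    tox = 0.0
            else:
                tox *= 1.0 / (1.0 + (x / tox_theta[m]) ** tox_n)
    for i in range(N):
        y = s[1 + M + i]
        if y < 0.0:
            y = 0.0
        j_g = vmax_g[i] * G / (km_g[i] + G)
        j_grow = gamma_g[i] * (1.0 - phi_tot[i]) * j_g
        for m in range(M):
            if aux[i, m] == 1:
                x = s[1 + m]
                if x < 0.0:
                    x = 0.0
                j_up = up_vmax[i, m] * x / (up_km[i, m] + x)
                out[1 + m] -= j_up * y
                g = gamma_m[i, m] * j_up
                if g < j_grow:
                    j_grow = g
            if leak[i, m] > 0.0:
                out[1 + m] += leak[i, m] * delta[m] * j_g * y
        out[0] -= j_g * y
        out[1 + M + i] = (j_grow * tox - eta[i]) * y
        if has_pathway == 1:
            if path_phi[i] > 0.0:
                out[1 + M + N] += path_phi[i] * j_g * y
            if conv_vmax[i] > 0.0:
                inter = s[1 + M + N]
                if inter < 0.0:
                    inter = 0.0
                c = conv_vmax[i] * inter / (conv_km[i] + inter) * y
                out[1 + M + N] -= c
                out[1 + M + N + 1] += c
    return out


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _rhs_compiled = numba.njit(cache=True)(_rhs_py)
except Exception:  # pragma: no cover
    _rhs_compiled = _rhs_py


def rhs_function():
    """The (jitted when possible) flat-array right-hand side."""
    return _rhs_compiled


def system_rhs(state, model: CommunityModel, init_template=None):
    """Time derivatives of every state component, as a dict.

    ``state`` maps component names (``glucose``, ``x:<met>``, ``y:<strain>``,
    and ``intermediate``/``product`` when a pathway is configured) to values.
    Convenience wrapper over the compiled array right-hand side; unknown
    component names raise :class:`ConfigurationError` before evaluation.
    """
    compiled = CompiledModel(model)
    names = compiled.layout.component_names()
    unknown = set(state) - set(names) - {"time"}
    if unknown:
        raise ConfigurationError(
            f"unknown state component(s) {sorted(unknown)}; expected {names}"
        )
    s = np.array([float(state.get(n, 0.0)) for n in names])
    for n, v in zip(names, s):
        if v < 0:
            raise DomainError(f"state component {n!r} must be >= 0, got {v}")
    ds = _rhs_compiled(0.0, s, *compiled.rhs_args())
    return dict(zip(names, ds))
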