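"""Named community presets, experimental "dials", and OD calibration.

The presets reproduce the community architectures of interest: a monoculture
producer, two-member co-cultures with one-way (commensal) or two-way
(mutualistic) metabolite exchange, three-member communities wired as a
one-way cycle or with double auxotrophies (two-way), and a division-of-labour
bioproduction pair in which a two-stage heterologous pathway is split across
the cross-feeding members.

The nominal parameter set is chosen to reproduce the growth physiology these
engineered slow-growing yeast communities show in plate-reader batch
culture: a prototroph monoculture on 20 g l⁻¹ glucose grows at a maximal
specific rate of ~0.05 h⁻¹ and exhausts its glucose within the 72 h assay
window, reaching a final OD₇₀₀ of order one; metabolite uptake kinetics sit
mid-range of the biologically permissible intervals used for the global
sensitivity analysis.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .gsa import GsaParameter
from .model import (
    CommunityModel,
    ConfigurationError,
    InitialCondition,
    MetaboliteSpec,
    PathwaySpec,
    StrainSpec,
    UptakeKinetics,
)

#: Nominal parameter set (see docs/methods.md for the calibration rationale).
NOMINAL = {
    "glucose_0": 20.0,  # g/l
    "total_density_0": 0.1,  # OD700
    "vmax_g": 1.33,  # g/h per OD unit
    "km_g": 2.0,  # g/l
    "gamma_g": 0.05,  # OD per g/l glucose
    "vmax_m": 60.0,  # mg/h per OD unit
    "km_m": 100.0,  # mg/l
    "gamma_m": 0.5,  # OD per mg/l metabolite
    "eta": 0.01,  # 1/h
    "phi": 0.25,  # leak fraction
    "pathway_phi": 0.1,
    "conv_vmax": 10.0,  # µM/h per OD unit
    "conv_km": 50.0,  # µM
}


@dataclass
class PromoterScale:
    """Promoter rank (1 strongest … 5 weakest, 6 = no expression) → ϕ factor.

    Promoter ranks are ordinal in the source system (pCCW12 > pTEF1 > pRPL18B
    > pPOP6 > pREV1 > none); quantitative strengths default to a geometric
    halving series with level 6 pinned at zero.
    """

    factors: tuple = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.0)

    def __post_init__(self):
        f = self.factors
        if len(f) != 6 or f[5] != 0.0 or any(
            f[i] <= f[i + 1] for i in range(5)
        ):
            raise ConfigurationError(
                "promoter factors must be 6 strictly decreasing values ending at 0"
            )

    def phi(self, level: int, phi_strongest: float) -> float:
        if level not in (1, 2, 3, 4, 5, 6):
            raise ConfigurationError(
                f"promoter level must be one of 1..6, got {level}"
            )
        return self.factors[level - 1] * phi_strongest


_SCENARIOS = (
    "mono_producer",
    "pair_oneway",
    "pair_twoway_symmetric",
    "trio_oneway",
    "trio_twoway",
    "dol_resveratrol",
    "dol_no_crossfeed",
)

_DENSITY_CATALOGUE = (0.067, 0.078, 0.102, 0.148)


def list_scenarios() -> tuple:
    return _SCENARIOS


def _nominal_strain(sid, produces=(), needs=(), p=NOMINAL, channel=None, stage="none"):
    return StrainSpec(
        id=sid,
        auxotrophies=frozenset(needs),
        productions={m: p["phi"] for m in produces},
        glucose_uptake=UptakeKinetics(p["vmax_g"], p["km_g"]),
        metabolite_uptake={m: UptakeKinetics(p["vmax_m"], p["km_m"]) for m in needs},
        yield_glucose=p["gamma_g"],
        yield_metabolite={m: p["gamma_m"] for m in needs},
        death_rate=p["eta"],
        pathway_stage=stage,
        fluor_channel=channel,
    )


def _parse_ratio(ratio, strain_ids):
    if isinstance(ratio, str):
        parts = ratio.split(":")
        try:
            weights = [float(x) for x in parts]
        except ValueError:
            raise ConfigurationError(
                f"cannot parse ratio dial {ratio!r}; use e.g. '10:1' or '1:1:1'"
            ) from None
    else:
        weights = [float(x) for x in ratio]
    if len(weights) != len(strain_ids):
        raise ConfigurationError(
            f"ratio dial has {len(weights)} entries for {len(strain_ids)} strains"
        )
    if any(w < 0 for w in weights) or sum(weights) == 0:
        raise ConfigurationError(f"ratio weights must be >= 0 and not all zero")
    total = sum(weights)
    return {sid: w / total for sid, w in zip(strain_ids, weights)}


def build_scenario(
    name: str,
    promoter_levels: Optional[dict] = None,
    promoter_scale: Optional[PromoterScale] = None,
    phi_strongest: float = 0.3,
    ratio=None,
    supplements: Optional[dict] = None,
    density: Optional[float] = None,
    phi: Optional[dict] = None,
    params: Optional[dict] = None,
):
    """Build a named preset and apply the experimental dials.

    Dials: ``promoter_levels`` maps strain id → promoter rank 1..6, scaling
    that strain's leak fractions through :class:`PromoterScale`; ``ratio``
    sets the inoculum composition (e.g. ``"10:1"``); ``supplements`` sets
    initial metabolite concentrations (mg l⁻¹); ``density`` sets the total
    inoculum density N₀ (the experimental catalogue is OD₇₀₀ 0.067, 0.078,
    0.102, 0.148, but any positive value is accepted); ``phi`` overrides
    per-strain leak fractions directly.  ``params`` overrides entries of the
    nominal parameter set for every strain.

    Returns ``(CommunityModel, InitialCondition)``, validated.
    """
    if name not in _SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {', '.join(_SCENARIOS)}"
        )
    p = dict(NOMINAL)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ConfigurationError(
                f"unknown nominal parameter(s) {sorted(unknown)}; "
                f"have {sorted(p)}"
            )
        p.update(params)

    pathway = None
    if name == "mono_producer":
        mets = [MetaboliteSpec("em1")]
        strains = [_nominal_strain("y1", produces=("em1",), p=p, channel="RFP")]
    elif name == "pair_oneway":
        mets = [MetaboliteSpec("em1")]
        strains = [
            _nominal_strain("y1", produces=("em1",), p=p, channel="BFP"),
            _nominal_strain("y2", needs=("em1",), p=p, channel="RFP"),
        ]
    elif name == "pair_twoway_symmetric":
        mets = [MetaboliteSpec("em1"), MetaboliteSpec("em2")]
        strains = [
            _nominal_strain("y1", produces=("em1",), needs=("em2",), p=p, channel="BFP"),
            _nominal_strain("y2", produces=("em2",), needs=("em1",), p=p, channel="RFP"),
        ]
    elif name == "trio_oneway":
        mets = [MetaboliteSpec(f"em{i}") for i in (1, 2, 3)]
        strains = [
            _nominal_strain("y1", produces=("em1",), needs=("em3",), p=p, channel="RFP"),
            _nominal_strain("y2", produces=("em2",), needs=("em1",), p=p, channel="BFP"),
            _nominal_strain("y3", produces=("em3",), needs=("em2",), p=p, channel="GFP"),
        ]
    elif name == "trio_twoway":
        mets = [MetaboliteSpec(f"em{i}") for i in (1, 2, 3)]
        strains = [
            _nominal_strain("y1", produces=("em1",), needs=("em2", "em3"), p=p, channel="RFP"),
            _nominal_strain("y2", produces=("em2",), needs=("em1", "em3"), p=p, channel="BFP"),
            _nominal_strain("y3", produces=("em3",), needs=("em1", "em2"), p=p, channel="GFP"),
        ]
    elif name == "dol_resveratrol":
        mets = [MetaboliteSpec("em1"), MetaboliteSpec("em2")]
        strains = [
            _nominal_strain(
                "y1", produces=("em1",), needs=("em2",), p=p, channel="BFP",
                stage="upstream",
            ),
            _nominal_strain(
                "y2", produces=("em2",), needs=("em1",), p=p, channel="RFP",
                stage="downstream",
            ),
        ]
        pathway = PathwaySpec(
            phi_upstream=p["pathway_phi"],
            conversion=UptakeKinetics(p["conv_vmax"], p["conv_km"]),
        )
    elif name == "dol_no_crossfeed":
        mets = []
        strains = [
            _nominal_strain("y1", p=p, channel="BFP", stage="upstream"),
            _nominal_strain("y2", p=p, channel="RFP", stage="downstream"),
        ]
        pathway = PathwaySpec(
            phi_upstream=p["pathway_phi"],
            conversion=UptakeKinetics(p["conv_vmax"], p["conv_km"]),
        )

    if phi:
        for sid, value in phi.items():
            matched = [s for s in strains if s.id == sid]
            if not matched:
                raise ConfigurationError(f"phi dial: unknown strain {sid!r}")
            for met in matched[0].productions:
                matched[0].productions[met] = value
    if promoter_levels:
        scale = promoter_scale or PromoterScale()
        for sid, level in promoter_levels.items():
            matched = [s for s in strains if s.id == sid]
            if not matched:
                raise ConfigurationError(
                    f"promoter dial: unknown strain {sid!r}"
                )
            for met in matched[0].productions:
                matched[0].productions[met] = scale.phi(level, phi_strongest)

    model = CommunityModel(metabolites=mets, strains=strains, pathway=pathway)

    strain_ids = [s.id for s in strains]
    if ratio is None:
        ratios = {sid: 1.0 / len(strain_ids) for sid in strain_ids}
    else:
        ratios = _parse_ratio(ratio, strain_ids)
    n0 = p["total_density_0"] if density is None else float(density)
    if n0 <= 0:
        raise ConfigurationError(
            f"density dial must be > 0 (experimental catalogue: "
            f"{_DENSITY_CATALOGUE}), got {n0}"
        )
    init = InitialCondition(
        glucose_0=p["glucose_0"],
        total_density_0=n0,
        ratios_0=ratios,
        supplements_0=dict(supplements or {}),
    )
    model.validate()
    init.validate(model)
    return model, init


# ---------------------------------------------------------------------------
# OD calibration
# ---------------------------------------------------------------------------

#: Spectrophotometer OD600 → microplate-reader OD700 calibration knots.
DEFAULT_OD_PAIRS = (
    (0.2, 0.067),
    (0.4, 0.078),
    (0.8, 0.102),
    (1.2, 0.125),
    (1.6, 0.148),
)


def od_convert(value, direction="od600_to_od700", pairs=DEFAULT_OD_PAIRS):
    """Convert between spectrophotometer OD₆₀₀ and plate-reader OD₇₀₀.

    Monotone (PCHIP) interpolation through the calibration pairs, exact at
    the knots; outside the calibrated range the edge segment is linearly
    extrapolated and a warning is issued.
    """
    pairs = sorted(pairs)
    if len(pairs) < 2:
        raise ConfigurationError("need at least 2 calibration pairs")
    x = np.array([a for a, _ in pairs], dtype=float)
    y = np.array([b for _, b in pairs], dtype=float)
    if np.any(np.diff(x) <= 0) or np.any(np.diff(y) <= 0):
        raise ConfigurationError(
            "calibration pairs must be strictly monotone in both scales"
        )
    if direction == "od600_to_od700":
        xs, ys = x, y
    elif direction == "od700_to_od600":
        xs, ys = y, x
    else:
        raise ConfigurationError(
            f"direction must be od600_to_od700 or od700_to_od600, got "
            f"{direction!r}"
        )
    v = np.asarray(value, dtype=float)
    out_of_range = (v < xs[0]) | (v > xs[-1])
    if np.any(out_of_range):
        warnings.warn(
            "OD value outside the calibrated range; linearly extrapolating",
            stacklevel=2,
        )
    interp = PchipInterpolator(xs, ys, extrapolate=False)
    res = interp(v)
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    res = np.where(v < xs[0], ys[0] + (v - xs[0]) * lo_slope, res)
    res = np.where(v > xs[-1], ys[-1] + (v - xs[-1]) * hi_slope, res)
    return float(res) if np.isscalar(value) or np.ndim(value) == 0 else res


# ---------------------------------------------------------------------------
# Default GSA parameter sets (the parameters varied in the reference analyses)
# ---------------------------------------------------------------------------


def _full_extras(aux_of: dict) -> list:
    """Extra parameters (beyond the headline set) varied in the full variant."""
    ps = [GsaParameter("N0", "init.total_density_0", 0.01, 1.0)]
    for sid, met in aux_of.items():
        ps += [
            GsaParameter(
                f"kmG_{sid}", f"strains.{sid}.glucose_uptake.k_m", 1.0, 100.0
            ),
            GsaParameter(
                f"kmM_{sid}", f"strains.{sid}.metabolite_uptake.{met}.k_m",
                1.0, 1000.0,
            ),
            GsaParameter(
                f"gammaG_{sid}", f"strains.{sid}.yield_glucose", 0.01, 1.0
            ),
            GsaParameter(
                f"gammaM_{sid}", f"strains.{sid}.yield_metabolite.{met}",
                0.01, 1.0,
            ),
        ]
    return ps


def pair_gsa_parameters(variant: str = "headline") -> list:
    """GSA parameters for the two-member mutualistic co-culture.

    ``variant="headline"`` varies the set reported for the two-member
    analysis: leak fractions ϕ₁, ϕ₂, initial medium concentrations x₀,ᵢ,
    inoculum composition r₀,ᵢ (simplex-constrained), each strain's glucose
    V_max and metabolite V_max, plus the dummy parameter δ (K_M and yields
    stay at nominal).  ``variant="full"`` additionally varies N₀, the K_M's
    and the yields over their biological ranges.
    """
    if variant not in ("headline", "full"):
        raise ConfigurationError("variant must be 'headline' or 'full'")
    extras = (
        _full_extras({"y1": "em2", "y2": "em1"}) if variant == "full" else []
    )
    return [
        GsaParameter("phi_1", "strains.y1.productions.em1", 0.01, 0.5),
        GsaParameter("phi_2", "strains.y2.productions.em2", 0.01, 0.5),
        GsaParameter("x0_1", "init.supplements_0.em1", 0.0, 75.0),
        GsaParameter("x0_2", "init.supplements_0.em2", 0.0, 75.0),
        GsaParameter("r0_1", "init.ratios_0.y1", 0.01, 1.0, group="ratio-simplex"),
        GsaParameter("r0_2", "init.ratios_0.y2", 0.01, 1.0, group="ratio-simplex"),
        GsaParameter("vmaxG_y1", "strains.y1.glucose_uptake.v_max", 1.0, 30.0),
        GsaParameter("vmaxG_y2", "strains.y2.glucose_uptake.v_max", 1.0, 30.0),
        GsaParameter("vmaxM_y1", "strains.y1.metabolite_uptake.em2.v_max", 1.0, 120.0),
        GsaParameter("vmaxM_y2", "strains.y2.metabolite_uptake.em1.v_max", 1.0, 120.0),
        *extras,
        GsaParameter("dummy", "dummy", 0.0, 1.0),
    ]


def dol_gsa_parameters() -> list:
    """GSA parameters for the division-of-labour bioproduction pair.

    Same structure as the two-member headline set, on the pathway-carrying
    community: ϕ₁ is the exchange-metabolite leak of the upstream
    (intermediate producer) strain, ϕ₂ that of the downstream
    (product-forming) strain.
    """
    return [
        GsaParameter("phi_1", "strains.y1.productions.em1", 0.01, 0.5),
        GsaParameter("phi_2", "strains.y2.productions.em2", 0.01, 0.5),
        GsaParameter("x0_1", "init.supplements_0.em1", 0.0, 75.0),
        GsaParameter("x0_2", "init.supplements_0.em2", 0.0, 75.0),
        GsaParameter("r0_1", "init.ratios_0.y1", 0.01, 1.0, group="ratio-simplex"),
        GsaParameter("r0_2", "init.ratios_0.y2", 0.01, 1.0, group="ratio-simplex"),
        GsaParameter("vmaxG_y1", "strains.y1.glucose_uptake.v_max", 1.0, 30.0),
        GsaParameter("vmaxG_y2", "strains.y2.glucose_uptake.v_max", 1.0, 30.0),
        GsaParameter("vmaxM_y1", "strains.y1.metabolite_uptake.em2.v_max", 1.0, 120.0),
        GsaParameter("vmaxM_y2", "strains.y2.metabolite_uptake.em1.v_max", 1.0, 120.0),
        GsaParameter("dummy", "dummy", 0.0, 1.0),
    ]
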