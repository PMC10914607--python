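"""Serialization: community/initial-condition schema, tables, run manifests.

The configuration schema (version 1) is a mapping with keys::

    schema: syntroph-community/1
    metabolites: [{id, delta, toxicity_threshold}]
    strains: [{id, auxotrophies, productions, glucose_uptake{v_max,k_m},
               metabolite_uptake{<met>:{v_max,k_m}}, yield_glucose,
               yield_metabolite, death_rate, pathway_stage, fluor_channel}]
    pathway: {phi_upstream, conversion{v_max,k_m}, intermediate_id,
              product_id, intermediate_per_glucose} | null
    toxicity_enabled: bool
    init: {glucose_0, total_density_0, ratios_0, supplements_0}

YAML is the primary format; JSON is accepted (it is a YAML subset).
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Tuple

import pandas as pd
import yaml

from . import __version__ as _version
from .model import (
    CommunityModel,
    ConfigurationError,
    InitialCondition,
    MetaboliteSpec,
    PathwaySpec,
    StrainSpec,
    UptakeKinetics,
)

SCHEMA_ID = "syntroph-community/1"


def model_to_dict(model: CommunityModel, init: Optional[InitialCondition] = None) -> dict:
    d = {
        "schema": SCHEMA_ID,
        "metabolites": [
            {
                "id": m.id,
                "delta": m.delta,
                "toxicity_threshold": m.toxicity_threshold,
            }
            for m in model.metabolites
        ],
        "strains": [
            {
                "id": s.id,
                "auxotrophies": sorted(s.auxotrophies),
                "productions": dict(s.productions),
                "glucose_uptake": asdict(s.glucose_uptake),
                "metabolite_uptake": {
                    k: asdict(v) for k, v in s.metabolite_uptake.items()
                },
                "yield_glucose": s.yield_glucose,
                "yield_metabolite": dict(s.yield_metabolite),
                "death_rate": s.death_rate,
                "pathway_stage": s.pathway_stage,
                "fluor_channel": s.fluor_channel,
            }
            for s in model.strains
        ],
        "pathway": (
            {
                "phi_upstream": model.pathway.phi_upstream,
                "conversion": asdict(model.pathway.conversion),
                "intermediate_id": model.pathway.intermediate_id,
                "product_id": model.pathway.product_id,
                "intermediate_per_glucose": model.pathway.intermediate_per_glucose,
            }
            if model.pathway
            else None
        ),
        "toxicity_enabled": model.toxicity_enabled,
        "toxicity_hill": model.toxicity_hill,
    }
    if init is not None:
        d["init"] = {
            "glucose_0": init.glucose_0,
            "total_density_0": init.total_density_0,
            "ratios_0": dict(init.ratios_0),
            "supplements_0": dict(init.supplements_0),
        }
    return d


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ConfigurationError(f"{where}: missing required key {key!r}")
    return d[key]


def model_from_dict(d: dict) -> Tuple[CommunityModel, Optional[InitialCondition]]:
    if not isinstance(d, dict):
        raise ConfigurationError("configuration root must be a mapping")
    schema = d.get("schema", SCHEMA_ID)
    if schema != SCHEMA_ID:
        raise ConfigurationError(
            f"unsupported schema {schema!r}; this version reads {SCHEMA_ID!r}"
        )
    mets = [
        MetaboliteSpec(
            id=_require(m, "id", "metabolites[]"),
            delta=float(m.get("delta", 1.0)),
            toxicity_threshold=m.get("toxicity_threshold"),
        )
        for m in d.get("metabolites", [])
    ]
    strains = []
    for s in _require(d, "strains", "configuration"):
        sid = _require(s, "id", "strains[]")
        gu = s.get("glucose_uptake", {})
        strains.append(
            StrainSpec(
                id=sid,
                auxotrophies=frozenset(s.get("auxotrophies", [])),
                productions={k: float(v) for k, v in s.get("productions", {}).items()},
                glucose_uptake=UptakeKinetics(
                    float(_require(gu, "v_max", f"strain {sid!r} glucose_uptake")),
                    float(_require(gu, "k_m", f"strain {sid!r} glucose_uptake")),
                ),
                metabolite_uptake={
                    k: UptakeKinetics(float(v["v_max"]), float(v["k_m"]))
                    for k, v in s.get("metabolite_uptake", {}).items()
                },
                yield_glucose=float(
                    _require(s, "yield_glucose", f"strain {sid!r}")
                ),
                yield_metabolite={
                    k: float(v) for k, v in s.get("yield_metabolite", {}).items()
                },
                death_rate=float(s.get("death_rate", 0.0)),
                pathway_stage=s.get("pathway_stage", "none"),
                fluor_channel=s.get("fluor_channel"),
            )
        )
    pathway = None
    if d.get("pathway"):
        p = d["pathway"]
        conv = p.get("conversion", {})
        pathway = PathwaySpec(
            phi_upstream=float(p.get("phi_upstream", 0.0)),
            conversion=UptakeKinetics(
                float(conv.get("v_max", 0.0)), float(conv.get("k_m", 1.0))
            ),
            intermediate_id=p.get("intermediate_id", "intermediate"),
            product_id=p.get("product_id", "product"),
            intermediate_per_glucose=float(p.get("intermediate_per_glucose", 1.0)),
        )
    model = CommunityModel(
        metabolites=mets,
        strains=strains,
        pathway=pathway,
        toxicity_enabled=bool(d.get("toxicity_enabled", False)),
        toxicity_hill=float(d.get("toxicity_hill", 2.0)),
    )
    model.validate()
    init = None
    if "init" in d:
        i = d["init"]
        init = InitialCondition(
            glucose_0=float(i.get("glucose_0", 20.0)),
            total_density_0=float(_require(i, "total_density_0", "init")),
            ratios_0={k: float(v) for k, v in _require(i, "ratios_0", "init").items()},
            supplements_0={
                k: float(v) for k, v in i.get("supplements_0", {}).items()
            },
        )
        init.validate(model)
    return model, init


def save_config(path, model: CommunityModel, init: Optional[InitialCondition] = None):
    path = Path(path)
    d = model_to_dict(model, init)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path) -> Tuple[CommunityModel, Optional[InitialCondition]]:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return model_from_dict(d)


def write_trajectories(path, result) -> None:
    """Tidy CSV (time, component, value), full double precision."""
    result.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_metrics(path, metrics) -> None:
    """One-row-per-run metrics CSV (accepts one MetricSet or a list)."""
    rows = [m.to_row() for m in (metrics if isinstance(metrics, list) else [metrics])]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output set."""

    command: str
    config_hash: str
    seed: Optional[int]
    tool_version: str
    timestamp: str
    outputs: list

    @classmethod
    def create(cls, command: str, config_obj, seed, outputs) -> "RunManifest":
        blob = json.dumps(config_obj, sort_keys=True, default=str).encode()
        return cls(
            command=command,
            config_hash=hashlib.sha256(blob).hexdigest(),
            seed=seed,
            tool_version=_version,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            outputs=[str(o) for o in outputs],
        )

    def write(self, directory) -> Path:
        p = Path(directory) / "manifest.json"
        with open(p, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
        return p
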