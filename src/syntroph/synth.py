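"""Synthetic plate-reader data and parameter recovery.

Emulates a microplate kinetic assay of a (co-)culture: total OD₇₀₀ readings
and one fluorescence channel per tagged strain, each proportional to that
strain's biomass plus a channel background, all corrupted by multiplicative
Gaussian measurement noise.  The generator retains its ground-truth
trajectories so estimation and fitting stages can be tested end to end.

The subpopulation estimator mirrors the channel-estimated OD decomposition
of co-culture growth curves (per-channel linear unmixing, renormalised to
the observed total OD); the fitting stage recovers Monod growth parameters
from total-OD curves by multi-start trust-region least squares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import CommunityModel, ConfigurationError, InitialCondition
from .simulate import SimulationConfig, SimulationResult, simulate_batch, get_param, set_param


@dataclass
class PlateReaderDataset:
    """One synthetic plate-reader run (a single well plus its truth).

    ``od`` is the observed total OD₇₀₀ trace; ``fluorescence`` maps channel
    (RFP/BFP/GFP) to observed intensity; ``gains``/``backgrounds`` are the
    per-channel calibration constants; ``truth`` retains the noise-free
    :class:`SimulationResult`; ``channel_strains`` maps channel → strain id.
    """

    times: np.ndarray
    od: np.ndarray
    fluorescence: dict
    gains: dict
    backgrounds: dict
    noise: float
    seed: int
    channel_strains: dict
    truth: Optional[SimulationResult] = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time, channel, value); channel 'OD' = total."""
        frames = [
            pd.DataFrame({"time": self.times, "channel": "OD", "value": self.od})
        ]
        for ch, vals in self.fluorescence.items():
            frames.append(
                pd.DataFrame({"time": self.times, "channel": ch, "value": vals})
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        if sidecar:
            side = {
                "gains": self.gains,
                "backgrounds": self.backgrounds,
                "noise": self.noise,
                "seed": self.seed,
                "channel_strains": self.channel_strains,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(side, fh, indent=2)

    @classmethod
    def from_csv(cls, path) -> "PlateReaderDataset":
        df = pd.read_csv(path)
        with open(str(path) + ".json") as fh:
            side = json.load(fh)
        od = df[df.channel == "OD"]
        times = od.time.to_numpy()
        fl = {
            ch: df[df.channel == ch].value.to_numpy()
            for ch in df.channel.unique()
            if ch != "OD"
        }
        return cls(
            times=times,
            od=od.value.to_numpy(),
            fluorescence=fl,
            gains=side["gains"],
            backgrounds=side["backgrounds"],
            noise=side["noise"],
            seed=side["seed"],
            channel_strains=side["channel_strains"],
            truth=None,
        )


def generate_platereader(
    model: CommunityModel,
    init: InitialCondition,
    config: Optional[SimulationConfig] = None,
    noise: float = 0.05,
    gains: Optional[dict] = None,
    backgrounds: Optional[dict] = None,
    seed: int = 0,
) -> PlateReaderDataset:
    """Simulate the community and corrupt it into plate-reader observations.

    Total OD reading = Σᵢ yᵢ(t)·(1+ε); channel c reading =
    (gain_c·y_c(t) + background_c)·(1+ε), with ε ~ N(0, noise²) i.i.d. per
    reading.  Reproducible given ``seed``; ground truth is retained.
    """
    if noise < 0:
        raise ConfigurationError(f"noise fraction must be >= 0, got {noise}")
    config = config or SimulationConfig()
    result = simulate_batch(model, init, config)
    channel_strains = {
        s.fluor_channel: s.id for s in model.strains if s.fluor_channel
    }
    gains = dict(gains or {ch: 1000.0 for ch in channel_strains})
    backgrounds = dict(backgrounds or {ch: 50.0 for ch in channel_strains})
    rng = np.random.default_rng(seed)
    total = result.total_biomass
    od = total * (1.0 + rng.normal(0.0, noise, size=total.shape)) if noise else total.copy()
    fl = {}
    for ch, sid in channel_strains.items():
        clean = gains[ch] * result.biomass(sid) + backgrounds[ch]
        eps = rng.normal(0.0, noise, size=clean.shape) if noise else 0.0
        fl[ch] = clean * (1.0 + eps)
    return PlateReaderDataset(
        times=result.times.copy(),
        od=np.asarray(od),
        fluorescence=fl,
        gains=gains,
        backgrounds=backgrounds,
        noise=noise,
        seed=seed,
        channel_strains=channel_strains,
        truth=result,
    )


def estimate_subpopulations(
    dataset: PlateReaderDataset,
    gains: Optional[dict] = None,
    backgrounds: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-strain OD trajectories from fluorescence channels.

    Linear unmixing — ŷ_c = (F_c − background_c)/gain_c, clipped at zero —
    followed by renormalisation so the channel estimates sum to the observed
    total OD at every time point.  Gains/backgrounds default to the
    dataset's own calibration constants (in a wet assay these come from
    monoculture calibration wells); pass them explicitly to override.

    Returns a DataFrame indexed by time with one column per strain.
    """
    gains = gains or dataset.gains
    backgrounds = backgrounds or dataset.backgrounds
    if not dataset.fluorescence:
        raise ConfigurationError("dataset has no fluorescence channels")
    missing = set(dataset.fluorescence) - set(gains)
    if missing:
        raise ConfigurationError(
            f"no gain supplied for channel(s) {sorted(missing)}; supply gains "
            f"or include monoculture calibration constants in the dataset"
        )
    raw = {}
    for ch, trace in dataset.fluorescence.items():
        est = (np.asarray(trace) - backgrounds.get(ch, 0.0)) / gains[ch]
        raw[ch] = np.clip(est, 0.0, None)
    mat = np.vstack([raw[ch] for ch in dataset.fluorescence])  # (C, T)
    total = mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(total > 0, dataset.od / total, 0.0)
    mat = mat * scale[None, :]
    cols = {
        dataset.channel_strains.get(ch, ch): mat[i]
        for i, ch in enumerate(dataset.fluorescence)
    }
    return pd.DataFrame(cols, index=pd.Index(dataset.times, name="time"))


_FIT_PARAM_PATHS = {
    "gamma_g": "strains.{sid}.yield_glucose",
    "vmax_g": "strains.{sid}.glucose_uptake.v_max",
    "km_g": "strains.{sid}.glucose_uptake.k_m",
    "eta": "strains.{sid}.death_rate",
    "phi": None,  # expanded per produced metabolite
}

_FIT_BOUNDS = {
    "gamma_g": (1e-4, 2.0),
    "vmax_g": (1e-3, 50.0),
    "km_g": (1e-3, 200.0),
    "eta": (0.0, 0.5),
    "phi": (0.0, 0.95),
}


@dataclass
class FitResult:
    """Recovered parameters plus diagnostics from the best multi-start."""

    estimates: dict
    residual_norm: float
    converged: bool
    n_starts: int
    start_values: list = field(default_factory=list)

    def __getitem__(self, key):
        return self.estimates[key]


def fit_growth_parameters(
    dataset: PlateReaderDataset,
    model_template: CommunityModel,
    init: InitialCondition,
    free: Sequence[str],
    config: Optional[SimulationConfig] = None,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of simulated total OD to an observed OD trace.

    ``free`` names the parameters estimated jointly for every strain of the
    template (subset of ``gamma_g``, ``vmax_g``, ``km_g``, ``eta``,
    ``phi``).  Trust-region-reflective least squares from ``n_starts``
    seeded random starting points (the Liebig min() kink creates local
    optima); deterministic given ``seed``.
    """
    bad = set(free) - set(_FIT_PARAM_PATHS)
    if bad:
        raise ConfigurationError(
            f"cannot fit {sorted(bad)}; allowed: {sorted(_FIT_PARAM_PATHS)}"
        )
    if len(dataset.times) < 4:
        raise ConfigurationError("dataset too short to fit growth parameters")
    config = config or SimulationConfig(
        t_end=float(dataset.times[-1]),
        dt_out=float(dataset.times[1] - dataset.times[0]),
        rtol=1e-6,
        atol=1e-9,
    )

    # expand free parameter names to concrete paths on the template
    paths = []
    names = []
    for name in free:
        if name == "phi":
            for s in model_template.strains:
                for met in s.productions:
                    paths.append(f"strains.{s.id}.productions.{met}")
                    names.append(f"phi:{s.id}:{met}")
        else:
            for s in model_template.strains:
                paths.append(_FIT_PARAM_PATHS[name].format(sid=s.id))
                names.append(f"{name}:{s.id}")
    if not paths:
        raise ConfigurationError("no free parameters to fit")
    lo = np.array([_FIT_BOUNDS[n.split(":")[0]][0] for n in names])
    hi = np.array([_FIT_BOUNDS[n.split(":")[0]][1] for n in names])

    obs = np.asarray(dataset.od, dtype=float)

    def residuals(theta):
        m = model_template.copy()
        ic = init.copy()
        for path, v in zip(paths, theta):
            set_param(m, ic, path, float(v))
        try:
            res = simulate_batch(m, ic, config)
        except Exception:
            return np.full_like(obs, 1e3)
        sim = np.interp(dataset.times, res.times, res.total_biomass)
        return sim - obs

    rng = np.random.default_rng(seed)
    x0_nominal = np.array(
        [get_param(model_template, init, p) for p in paths], dtype=float
    )
    x0_nominal = np.clip(x0_nominal, lo, hi)
    starts = [x0_nominal]
    for _ in range(max(0, n_starts - 1)):
        starts.append(lo + rng.uniform(0.05, 0.95, size=len(paths)) * (hi - lo))

    best = None
    tried = []
    for x0 in starts:
        sol = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10
        )
        tried.append(list(map(float, x0)))
        if best is None or sol.cost < best.cost:
            best = sol
    return FitResult(
        estimates=dict(zip(names, map(float, best.x))),
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
        n_starts=len(starts),
        start_values=tried,
    )
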