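"""Scenario configuration: schema, validation bounds, presets, seeds.

A scenario file is a JSON document with sections ``landscape``,
``species``, ``pesticide``, ``inoculation``, ``experiment`` and
``numerics`` plus a master ``seed``.  Every omitted field falls back to
the documented default (the midpoint of its sampling range, or the fixed
published value); the loader reports which fields were defaulted and
rejects unknown keys and out-of-range values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dynamics import InoculationConfig, PesticideConfig, SpeciesParams
from .experiment import DesignSpec
from .landscape import GRFConfig

__all__ = [
    "LandscapeSection",
    "NumericsConfig",
    "ScenarioConfig",
    "load_config",
    "save_config",
    "preset",
    "seed_streams",
    "config_hash",
    "PARAM_BOUNDS",
]

#: Validation bounds per parameter (inclusive).  Ranged parameters carry
#: their sampling interval; fixed published values admit any positive
#: override.  Mortalities are bounded by the published lifespan interval
#: [20, 66] d.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "landscape.phi": (0.0, 10 * 5.55),  # 0 = independence limit
    "landscape.rho": (-1.0, 1.0),
    "landscape.p_crop": (0.0, 1.0),
    "landscape.p_hedge": (0.0, 1.0),
    "species.d2v": (0.000625, 0.012),
    "species.m_v": (1.0 / 66.0, 1.0 / 20.0),
    "species.beta": (0.01, 0.10),
    "species.r_v": (0.010, 0.020),
    "species.rho12": (0.0, 0.05),
    "species.d2u": (0.000625, 0.012),
    "species.r_u": (0.010, 0.020),
    "species.m_u": (1.0 / 66.0, 1.0 / 20.0),
    "species.d1v": (0.0, np.inf),
    "species.rho21": (0.0, np.inf),
    "species.k_hedge": (0.0, np.inf),
    "species.k_field": (0.0, np.inf),
}


@dataclass
class LandscapeSection:
    """Tessellation source plus the allocation-model parameters."""

    extent: float = 5.55
    n_polygons: int = 188
    tessellation_seed: int = 0
    geojson: str | None = None  # load a fixed geometry instead of generating
    phi: float = 2.8
    rho: float = 0.5
    p_crop: float = 0.5
    p_hedge: float = 0.5

    def grf(self, seed: int | None = None) -> GRFConfig:
        return GRFConfig(
            phi=self.phi,
            rho=self.rho,
            p_crop=self.p_crop,
            p_hedge=self.p_hedge,
            seed=seed,
        )


@dataclass
class NumericsConfig:
    resolution: float = 0.15  # target cell diameter (km)
    dt_internal: float = 0.1  # internal substep (d)
    season_length: float = 100.0  # reporting horizon (d)

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.dt_internal <= 0 or self.season_length <= 0:
            raise ValueError("numerics parameters must be positive")


@dataclass
class ScenarioConfig:
    landscape: LandscapeSection = field(default_factory=LandscapeSection)
    species: SpeciesParams = field(default_factory=SpeciesParams)
    pesticide: PesticideConfig = field(default_factory=PesticideConfig)
    inoculation: InoculationConfig = field(default_factory=InoculationConfig)
    experiment: DesignSpec = field(default_factory=DesignSpec)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    seed: int = 0
    output_dir: str = "runs"
    defaulted: list[str] = field(default_factory=list, compare=False)

    def to_dict(self) -> dict:
        out = {}
        for sec in ("landscape", "species", "pesticide", "inoculation",
                    "experiment", "numerics"):
            obj = getattr(self, sec)
            d = dataclasses.asdict(obj)
            if sec == "experiment":
                d["factors"] = list(d["factors"])
            out[sec] = d
        out["seed"] = self.seed
        out["output_dir"] = self.output_dir
        return out


_SECTIONS = {
    "landscape": LandscapeSection,
    "species": SpeciesParams,
    "pesticide": PesticideConfig,
    "inoculation": InoculationConfig,
    "experiment": DesignSpec,
    "numerics": NumericsConfig,
}


def _build_section(name: str, cls, data: dict, defaulted: list[str]):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - field_names
    if unknown:
        raise ValueError(
            f"unknown keys in section '{name}': {sorted(unknown)}; "
            f"allowed: {sorted(field_names)}"
        )
    for f in dataclasses.fields(cls):
        if f.name not in data:
            defaulted.append(f"{name}.{f.name}")
    if name == "experiment" and "factors" in data:
        data = {**data, "factors": tuple(data["factors"])}
    return cls(**data)


def _check_bounds(cfg: ScenarioConfig) -> None:
    for path, (lo, hi) in PARAM_BOUNDS.items():
        sec, name = path.split(".")
        value = getattr(getattr(cfg, sec), name)
        if not lo <= value <= hi:
            raise ValueError(
                f"parameter {path} = {value} outside its allowed range "
                f"[{lo:g}, {hi:g}]"
            )


def load_config(path: str | Path | dict) -> ScenarioConfig:
    """Load, validate and default-fill a scenario configuration.

    The returned config's ``defaulted`` attribute lists every field that
    was filled from defaults.  Unknown sections or keys and out-of-range
    parameters raise ``ValueError`` naming the offender and its bound.
    """
    if isinstance(path, dict):
        raw = dict(path)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    defaulted: list[str] = []
    known_top = set(_SECTIONS) | {"seed", "output_dir"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(
            f"unknown top-level keys: {sorted(unknown)}; allowed: "
            f"{sorted(known_top)}"
        )
    kwargs = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build_section(name, cls, raw.get(name, {}), defaulted)
        if name not in raw:
            pass  # every field already recorded as defaulted
    for scalar in ("seed", "output_dir"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
        else:
            defaulted.append(scalar)
    cfg = ScenarioConfig(**kwargs, defaulted=defaulted)
    _check_bounds(cfg)
    return cfg


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)


#: Named pesticide scenarios.  The optimal profile removes 99.5% of the
#: saturation pest density (capacity divided by 200); the realistic one
#: removes 70% (capacity divided by 1/0.3).  The threshold variants halve
#: or double the default spray threshold.
_PRESETS: dict[str, dict] = {
    "optimal-pesticide": {"reduction_factor": 200.0},
    "realistic-pesticide": {"reduction_factor": 1.0 / 0.3},
    "low-threshold": {"threshold": 0.1},
    "high-threshold": {"threshold": 0.4},
}


def preset(name: str) -> dict:
    """Pesticide-scenario fragment to merge into the pesticide section."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {sorted(_PRESETS)}"
        )
    return dict(_PRESETS[name])


def seed_streams(master: int) -> dict[str, int]:
    """Independent substream seeds derived from one master seed."""
    ss = np.random.SeedSequence(master)
    names = ("landscape", "allocation", "inoculation", "design")
    states = ss.generate_state(len(names)) % (2**31)
    return dict(zip(names, (int(s) for s in states)))


def config_hash(cfg: ScenarioConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
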