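"""Run configuration: structured-text (YAML) parsing, validation, units.

A run is described by nested blocks (geometry / spray / flow / transport /
film / output) plus a single global seed that fans out to per-stage child
seeds, so stages rerun in isolation reproduce the full-pipeline results.
Dimensioned entries accept either a bare number in the block's native unit
or a string with an explicit unit ("0.1 mL", "4 mm", "60 um").
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from nasospray.geometry import NasalGeometryParams, HeadPose
from nasospray.spray import SprayConfig, SprayConfigError


class ConfigError(ValueError):
    """Reported with the offending key path."""


_UNIT_TO_NATIVE = {
    # target native unit -> conversion factors from accepted units
    "mL": {"ml": 1.0, "l": 1e3, "ul": 1e-3, "m3": 1e6, "mm3": 1e-3},
    "mm": {"mm": 1.0, "m": 1e3, "cm": 10.0, "um": 1e-3},
    "um": {"um": 1.0, "µm": 1.0, "mm": 1e3, "m": 1e6},
    "m/s": {"m/s": 1.0, "mps": 1.0, "cm/s": 1e-2},
    "deg": {"deg": 1.0, "°": 1.0},
    "s": {"s": 1.0, "ms": 1e-3, "us": 1e-6},
}


def parse_quantity(value, native_unit: str, key: str = "") -> float:
    """Parse ``0.1 mL`` style strings (or bare numbers) into a native unit."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([^\s]+)\s*", str(value))
    if not m:
        raise ConfigError(f"{key}: cannot parse quantity {value!r}")
    num, unit = float(m.group(1)), m.group(2)
    table = _UNIT_TO_NATIVE[native_unit]
    factor = table.get(unit.lower(), table.get(unit))
    if factor is None:
        raise ConfigError(f"{key}: unknown unit {unit!r} (native {native_unit})")
    return num * factor


@dataclass(frozen=True)
class FlowBlock:
    enabled: bool = True
    flow_rate_lpm: float = 1.8
    partition_sm_mm_im: tuple = (0.05, 0.55, 0.40)


@dataclass(frozen=True)
class TransportBlock:
    dt_max: float = 1e-3
    max_flight_time: float = 2.0
    drag_law: str = "schiller_naumann"


@dataclass(frozen=True)
class FilmBlock:
    enabled: bool = True
    dt_min: float = 1e-7
    dt_max: float = 1e-4     # desk-scale bound; adaptive Courant still governs
    courant: float = 0.5
    h_min: float = 1e-8
    h_pin: float = 2e-4
    end_time: float = 0.2
    snapshot_times: tuple = ()
    rho_l: float = 1000.0
    nu_l: float = 1e-6
    sigma: float = 0.072
    airflow_during_film: bool = False


@dataclass(frozen=True)
class RunConfig:
    geometry: NasalGeometryParams = field(default_factory=NasalGeometryParams)
    pose: str = HeadPose.VERTEX_TO_FLOOR
    spray: SprayConfig = field(default_factory=SprayConfig)
    n_simulated: int = 20_000
    flow: FlowBlock = field(default_factory=FlowBlock)
    transport: TransportBlock = field(default_factory=TransportBlock)
    film: FilmBlock = field(default_factory=FilmBlock)
    seed: int = 0
    verbosity: str = "info"

    def digest(self) -> str:
        def enc(o):
            if hasattr(o, "__dataclass_fields__"):
                return {k: enc(v) for k, v in asdict(o).items()}
            if isinstance(o, (tuple, list)):
                return [enc(x) for x in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2**31."""
        stage_ids = {"geometry": 1, "spray": 2, "transport": 3, "film": 4}
        ss = np.random.SeedSequence([int(self.seed), stage_ids[stage]])
        return int(ss.generate_state(1)[0] % (2 ** 31))


_BASELINE_SPRAY = dict(alpha_deg=60.0, plume_deg=45.0)
_OPTIMIZED_SPRAY = dict(alpha_deg=45.0, plume_deg=10.0)


def preset_spray(name: str, **overrides) -> SprayConfig:
    """The study's two delivery systems: conventional baseline (α=60°,
    θ=45°) and the narrow-plume optimized system (α=45°, θ=10°)."""
    base = {"baseline": _BASELINE_SPRAY, "optimized": _OPTIMIZED_SPRAY}[name]
    return SprayConfig(**{**base, **overrides})


def validate_config(raw_text: str | dict) -> RunConfig:
    """Parse + validate a YAML config; empty input yields the baseline run."""
    if isinstance(raw_text, dict):
        data = raw_text
    else:
        data = yaml.safe_load(raw_text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")

    def block(name):
        b = data.get(name, {}) or {}
        if not isinstance(b, dict):
            raise ConfigError(f"{name}: must be a mapping")
        return dict(b)

    sp = block("spray")
    if "dose_ml" in sp:
        sp["dose_ml"] = parse_quantity(sp["dose_ml"], "mL", "spray.dose_ml")
    if "dp_um" in sp:
        sp["dp_um"] = parse_quantity(sp["dp_um"], "um", "spray.dp_um")
    if "insertion_mm" in sp:
        sp["insertion_mm"] = parse_quantity(sp["insertion_mm"], "mm",
                                            "spray.insertion_mm")
    if "speed_mps" in sp:
        sp["speed_mps"] = parse_quantity(sp["speed_mps"], "m/s",
                                         "spray.speed_mps")
    preset = sp.pop("preset", None)
    # range checks up front so violations report their key path
    if "plume_deg" in sp and not (0.0 <= float(sp["plume_deg"]) <= 180.0):
        raise ConfigError("spray.plume_deg: out of range [0, 180]")
    if "alpha_deg" in sp and not (0.0 <= float(sp["alpha_deg"]) <= 90.0):
        raise ConfigError("spray.alpha_deg: out of range [0, 90]")
    if "dose_ml" in sp and float(sp["dose_ml"]) <= 0.0:
        raise ConfigError("spray.dose_ml: must be positive")
    n_simulated = int(data.get("n_simulated", RunConfig.n_simulated))
    if n_simulated < 1:
        raise ConfigError("n_simulated: must be >= 1")
    seed = int(data.get("seed", 0))
    sp.setdefault("seed", seed)
    try:
        spray = preset_spray(preset, **sp) if preset else SprayConfig(**sp)
    except SprayConfigError as err:
        raise ConfigError(f"spray: {err}") from err
    except TypeError as err:
        raise ConfigError(f"spray: {err}") from err
    if not (0.0 <= spray.plume_deg <= 180.0):
        raise ConfigError("spray.plume_deg: out of range [0, 180]")
    if not (0.0 <= spray.alpha_deg <= 90.0):
        raise ConfigError("spray.alpha_deg: out of range [0, 90]")

    geo = block("geometry")
    try:
        geometry = NasalGeometryParams(**geo)
        geometry.validate()
    except (TypeError, ValueError) as err:
        raise ConfigError(f"geometry: {err}") from err

    pose = data.get("pose", RunConfig.pose)
    if pose not in (HeadPose.UPRIGHT, HeadPose.VERTEX_TO_FLOOR):
        raise ConfigError(f"pose: unknown pose {pose!r}")

    try:
        flow = FlowBlock(**block("flow"))
        transport = TransportBlock(**block("transport"))
        film = FilmBlock(**{k: (tuple(v) if k == "snapshot_times" else v)
                            for k, v in block("film").items()})
    except TypeError as err:
        raise ConfigError(str(err)) from err
    if flow.flow_rate_lpm <= 0:
        raise ConfigError("flow.flow_rate_lpm: must be positive")
    if film.end_time <= 0:
        raise ConfigError("film.end_time: must be positive")

    return RunConfig(geometry=geometry, pose=pose, spray=spray,
                     n_simulated=n_simulated, flow=flow, transport=transport,
                     film=film, seed=seed,
                     verbosity=str(data.get("verbosity", "info")))
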