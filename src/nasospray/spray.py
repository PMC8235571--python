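"""Spray release: nozzle placement and seeded droplet initial conditions.

A spray actuation is represented by statistical particles: ``n_simulated``
tracked droplets, each carrying an equal share of the applied liquid volume,
so the physical droplet count (~9e5 for 0.10 mL at 60 µm) is decoupled from
compute cost.  The plume has a centerline-jet structure: initial positions on
the nozzle exit disc follow a truncated normal density peaked on the axis,
droplet directions fan out to half the (full) plume angle in proportion to
their radial position, and speeds follow a Gaussian radial profile normalized
so that the droplet-mean exit speed equals the configured mean speed V, then
multiplied by per-droplet uniform jitter of ±50% by default (the spray-to-
spray variability of real actuations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, stats

from nasospray.geometry import LabeledSurfaceMesh, GeometryError


class SprayConfigError(ValueError):
    """Invalid spray release parameters."""


class NozzlePlacementError(RuntimeError):
    """Nozzle frame would intersect the airway wall (infeasible insertion)."""


NOSTRIL_ANCHORS = ("tip", "middle", "base")


@dataclass(frozen=True)
class SprayConfig:
    """All release parameters of one actuation.

    Angles follow the device-orientation convention: ``alpha_deg`` tilts the
    nozzle axis from vertical within the sagittal (y-z) plane toward
    posterior, ``beta_deg`` then rotates it about the vertical within the
    transverse (x-y) plane.  ``plume_deg`` is the FULL cone opening angle.
    """

    dp_um: float = 60.0              # droplet diameter (monodisperse)
    dp_sd_um: float = 0.0            # >0 switches to a normal size distribution
    speed_mps: float = 10.0          # droplet-mean exit speed V
    plume_deg: float = 45.0          # full cone angle theta
    alpha_deg: float = 60.0          # sagittal device orientation
    beta_deg: float = 0.0            # transverse device orientation
    insertion_mm: float = 4.0        # nozzle depth into the nostril
    anchor: str = "middle"           # tip / middle / base of the nostril plane
    dose_ml: float = 0.10            # applied liquid dose per actuation
    nozzle_radius_mm: float = 1.0
    jitter: float = 0.5              # uniform speed jitter fraction
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.plume_deg <= 180.0):
            raise SprayConfigError("plume angle must lie in [0, 180] degrees")
        if self.dose_ml <= 0:
            raise SprayConfigError("applied dose must be positive")
        if self.dp_um <= 0 or self.dp_sd_um < 0:
            raise SprayConfigError("droplet diameter must be positive")
        if not (0.0 <= self.jitter <= 1.0):
            raise SprayConfigError("jitter fraction must lie in [0, 1]")
        if self.speed_mps <= 0 or self.nozzle_radius_mm <= 0:
            raise SprayConfigError("exit speed and nozzle radius must be positive")
        if self.anchor not in NOSTRIL_ANCHORS:
            raise SprayConfigError(f"anchor must be one of {NOSTRIL_ANCHORS}")

    @property
    def dose_m3(self) -> float:
        return self.dose_ml * 1e-6


# droplet status codes
ACTIVE, DEPOSITED, ESCAPED, EXPIRED = 0, 1, 2, 3
STATUS_NAMES = {ACTIVE: "active", DEPOSITED: "deposited",
                ESCAPED: "escaped", EXPIRED: "expired"}


@dataclass
class DropletSet:
    """Per-droplet state arrays for one actuation."""

    position: np.ndarray       # (N, 3) m
    velocity: np.ndarray       # (N, 3) m/s
    diameter: np.ndarray       # (N,) m
    weight: np.ndarray         # (N,) m³ of liquid represented per particle
    status: np.ndarray = field(default=None)   # (N,) int8
    face_id: np.ndarray = field(default=None)  # (N,) int64, -1 = none

    def __post_init__(self):
        n = len(self.position)
        if self.status is None:
            self.status = np.full(n, ACTIVE, dtype=np.int8)
        if self.face_id is None:
            self.face_id = np.full(n, -1, dtype=np.int64)
        if np.any(self.diameter <= 0):
            raise SprayConfigError("all droplet diameters must be positive")

    def __len__(self) -> int:
        return len(self.position)

    @property
    def mass(self) -> np.ndarray:
        """Physical single-droplet mass (kg) at unit liquid density 1000 kg/m³."""
        return 1000.0 * np.pi / 6.0 * self.diameter ** 3

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "id": np.arange(len(self)),
            "x": self.position[:, 0], "y": self.position[:, 1],
            "z": self.position[:, 2],
            "vx": self.velocity[:, 0], "vy": self.velocity[:, 1],
            "vz": self.velocity[:, 2],
            "d": self.diameter, "weight": self.weight,
            "status": [STATUS_NAMES[int(s)] for s in self.status],
            "face_id": self.face_id,
        })


def droplet_count(dose_ml: float, dp_um: float) -> int:
    """Physical droplet count: applied dose divided by one droplet's volume.

    0.10 mL of 60 µm droplets gives 884,194.
    """
    if dose_ml <= 0 or dp_um <= 0:
        raise SprayConfigError("dose and droplet diameter must be positive")
    v_one = math.pi / 6.0 * (dp_um * 1e-6) ** 3
    return max(1, round(dose_ml * 1e-6 / v_one))


def _mean_radial_profile(sigma_pos: float, s_jet: float, radius: float) -> float:
    """E[exp(-r²/2s²)] under the truncated-normal radial release density."""
    pdf = lambda r: math.exp(-r * r / (2 * sigma_pos ** 2))
    num = integrate.quad(lambda r: math.exp(-r * r / (2 * s_jet ** 2)) * pdf(r),
                         0.0, radius)[0]
    den = integrate.quad(pdf, 0.0, radius)[0]
    return num / den


def sample_droplets(config: SprayConfig, n_simulated: int = 50_000,
                    origin=None, axis=None) -> DropletSet:
    """Draw a seeded set of droplet initial conditions for one actuation.

    ``origin``/``axis`` place the nozzle exit disc (default: origin at 0,
    axis +z); use :func:`place_nozzle` to derive them from a mesh.  The
    output is bit-reproducible for a fixed config (the seed is part of it).
    """
    if n_simulated < 1:
        raise SprayConfigError("n_simulated must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    axis = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)

    R = config.nozzle_radius_mm * 1e-3
    sigma_pos = R / 2.0
    s_jet = R / 2.0

    # orthonormal frame around the nozzle axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u1 = np.cross(axis, helper)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(axis, u1)

    # radial positions: truncated normal peaked on the axis
    tn = stats.truncnorm(a=0.0, b=R / sigma_pos, loc=0.0, scale=sigma_pos)
    r = tn.ppf(rng.random(n_simulated))
    psi = rng.uniform(0.0, 2.0 * np.pi, n_simulated)
    radial = np.outer(np.cos(psi), u1) + np.outer(np.sin(psi), u2)
    positions = origin + r[:, None] * radial

    # directions: off-axis angle grows with radial position, up to theta/2
    half_angle = np.deg2rad(config.plume_deg) / 2.0
    polar = half_angle * (r / R)
    directions = (np.cos(polar)[:, None] * axis[None, :]
                  + np.sin(polar)[:, None] * radial)

    # speeds: normalized centerline-jet profile times jitter
    profile = np.exp(-r ** 2 / (2.0 * s_jet ** 2))
    norm = _mean_radial_profile(sigma_pos, s_jet, R)
    jit = 1.0 + rng.uniform(-config.jitter, config.jitter, n_simulated)
    speeds = config.speed_mps * (profile / norm) * jit
    velocities = speeds[:, None] * directions

    if config.dp_sd_um > 0:
        d = np.empty(n_simulated)
        todo = np.arange(n_simulated)
        while len(todo):                      # resample non-positive draws
            draw = rng.normal(config.dp_um, config.dp_sd_um, len(todo))
            d[todo] = draw
            todo = todo[draw <= 0]
        diameters = d * 1e-6
    else:
        diameters = np.full(n_simulated, config.dp_um * 1e-6)

    weights = np.full(n_simulated, config.dose_m3 / n_simulated)
    return DropletSet(position=positions, velocity=velocities,
                      diameter=diameters, weight=weights)


def nozzle_axis(alpha_deg: float, beta_deg: float) -> np.ndarray:
    """Unit nozzle axis: vertical tilted by alpha in the sagittal plane
    (toward posterior), then rotated by beta about the vertical."""
    a = np.deg2rad(alpha_deg)
    b = np.deg2rad(beta_deg)
    # Rx(alpha) applied to +z: (0, sin a, cos a); then Rz(beta)
    v = np.array([0.0, np.sin(a), np.cos(a)])
    Rz = np.array([[np.cos(b), -np.sin(b), 0.0],
                   [np.sin(b), np.cos(b), 0.0],
                   [0.0, 0.0, 1.0]])
    return Rz @ v


def place_nozzle(config: SprayConfig, mesh: LabeledSurfaceMesh,
                 clearance_m: float = 1e-3):
    """Resolve the nozzle frame (origin, axis) inside a generated airway.

    The origin sits on the cross-section ``insertion_mm`` along the passage
    centerline from the nostril plane, at the anchor point (tip = anterior
    rim side, base = posterior rim side, middle = center).  Raises
    :class:`NozzlePlacementError` when the axis meets the wall within
    ``clearance_m`` of the origin — the infeasible deep-insertion cases.
    """
    stations = mesh.metadata.get("stations")
    if stations is None:
        raise GeometryError("mesh has no centerline stations; "
                            "use a generated airway mesh")
    s_target = config.insertion_mm * 1e-3
    s = stations["s"]
    k = int(np.argmin(np.abs(s - s_target)))
    center = stations["center"][k]
    e2 = stations["e2"][k]
    wz = stations["wz"][k]
    # e2 at the nostril points posterior (+y); "tip" is the anterior rim.
    if config.anchor == "middle":
        origin = center
    elif config.anchor == "tip":
        origin = center - 0.45 * wz * e2
    else:  # base
        origin = center + 0.45 * wz * e2

    axis = nozzle_axis(config.alpha_deg, config.beta_deg)

    from nasospray.transport import detect_wall_hit
    probe_end = origin + 0.2 * axis
    hit = detect_wall_hit(origin, probe_end, mesh)
    if hit is not None:
        _, point = hit
        dist = float(np.linalg.norm(point - origin))
        if dist < clearance_m:
            raise NozzlePlacementError(
                f"nozzle axis meets the wall {dist * 1e3:.2f} mm from the exit "
                f"(anchor={config.anchor}, insertion={config.insertion_mm} mm)")
    return origin, axis
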