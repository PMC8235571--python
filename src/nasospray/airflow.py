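"""Prescribed laminar background airflow.

At a gentle sniff of 1.8 L/min the nasal airflow is predominantly laminar and
spray droplets above ~30 µm are governed by inertia and gravity, so the
droplet phase is one-way coupled to a prescribed analytic field rather than a
CFD solution: air moves along the local centerline tangent with a
parabolic-like lateral profile vanishing at the walls, and the flow through
the turbinate airspace is partitioned among the superior/middle/inferior
meatus bands.  The interface accepts any queryable field, so an externally
computed velocity field can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nasospray.geometry import LabeledSurfaceMesh, GeometryError

#: Air properties at room conditions.
AIR_DENSITY = 1.204          # kg/m³
AIR_VISCOSITY = 1.81e-5      # Pa·s

#: Near-wall sampling distance for air-film shear (the scale of the
#: near-wall mesh resolution the field stands in for).
WALL_SAMPLING_DISTANCE = 3e-4  # m


@dataclass(frozen=True)
class MeatusPartition:
    """Fractions of the turbinate flow through the SM / MM / IM channels."""

    sm: float = 0.05
    mm: float = 0.55
    im: float = 0.40

    def __post_init__(self):
        f = (self.sm, self.mm, self.im)
        if any(x < 0 for x in f):
            raise GeometryError("meatus flow fractions must be non-negative")
        if abs(sum(f) - 1.0) > 1e-9:
            raise GeometryError("meatus flow fractions must sum to 1")


class FlowField:
    """Queryable air velocity field; zero outside the airway."""

    rho_air = AIR_DENSITY
    mu_air = AIR_VISCOSITY

    def velocity(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def kernel_arrays(self):
        """Arrays consumed by the numba droplet-tracking kernel."""
        raise NotImplementedError


class QuiescentField(FlowField):
    """Still air: velocity identically zero (film-only and settling studies)."""

    def velocity(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        return np.zeros_like(points)

    def kernel_arrays(self):
        return dict(
            centers=np.zeros((1, 3)), tangents=np.array([[0.0, 1.0, 0.0]]),
            e1=np.array([[1.0, 0.0, 0.0]]), e2=np.array([[0.0, 0.0, 1.0]]),
            wx=np.ones(1), wz=np.ones(1), u_mean=np.zeros(1),
            is_tr=np.zeros(1), band_coef=np.zeros(3), Q=0.0)


class DuctFlowField(FlowField):
    """Prescribed laminar duct flow along a generated passage's centerline.

    At a query point, the nearest centerline station supplies the local
    tangent, elliptical cross-section semi-axes and mean speed Q/A; the
    velocity is ``tangent * u_mean * 2 (1 - rho²)`` with rho the normalized
    elliptical transverse coordinate (profile mean over the section = 1, so
    the volumetric flux equals Q).  Inside the turbinate, the three vertical
    meatus bands carry their partition fractions of Q with per-band
    parabolic-like profiles normalized by quadrature.
    """

    def __init__(self, mesh: LabeledSurfaceMesh, flow_rate_lpm: float = 1.8,
                 partition: MeatusPartition | None = None):
        if flow_rate_lpm <= 0:
            raise GeometryError("flow rate must be positive")
        stations = mesh.metadata.get("stations")
        if stations is None:
            raise GeometryError("mesh has no centerline stations")
        self.Q = flow_rate_lpm / 60.0 * 1e-3     # m³/s
        self.partition = partition or MeatusPartition()

        s = np.asarray(stations["s"], float)
        self.centers = np.asarray(stations["center"], float)
        self.tangents = np.asarray(stations["tangent"], float)
        self.e1 = np.asarray(stations["e1"], float)
        self.e2 = np.asarray(stations["e2"], float)
        self.wx = np.asarray(stations["wx"], float)
        self.wz = np.asarray(stations["wz"], float)
        self.is_tr = np.array([r == "TR" for r in stations["region"]])
        area = np.pi * self.wx * self.wz
        if np.any(area <= 0):
            raise GeometryError("zero cross-section area along the passage")
        self.u_mean = self.Q / area

        # per-band speed coefficients in the turbinate: band j of the ellipse
        # (z̃ in [-1,-1/3], [-1/3,1/3], [1/3,1]) carries fraction f_j of Q with
        # profile c_j (1 - rho²); c_j from quadrature so the band flux matches.
        zgrid = np.linspace(-1, 1, 201)
        xgrid = np.linspace(-1, 1, 201)
        Z, X = np.meshgrid(zgrid, xgrid, indexing="ij")
        rho2 = X ** 2 + Z ** 2
        inside = rho2 <= 1.0
        shape = np.where(inside, 1.0 - rho2, 0.0)
        bands = [Z < -1 / 3, (Z >= -1 / 3) & (Z <= 1 / 3), Z > 1 / 3]
        cell = (zgrid[1] - zgrid[0]) * (xgrid[1] - xgrid[0])
        fracs = [self.partition.im, self.partition.mm, self.partition.sm]
        self.band_coef = np.zeros(3)
        for j, band in enumerate(bands):
            flux_unit = float((shape * band).sum() * cell)   # per wx*wz
            self.band_coef[j] = fracs[j] / flux_unit if flux_unit > 0 else 0.0

    def _station_of(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(points[:, None, :] - self.centers[None, :, :], axis=2)
        return np.argmin(d, axis=1)

    def velocity(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        k = self._station_of(pts)
        rel = pts - self.centers[k]
        x1 = np.einsum("ij,ij->i", rel, self.e1[k]) / self.wx[k]
        x2 = np.einsum("ij,ij->i", rel, self.e2[k]) / self.wz[k]
        shape = np.clip(1.0 - (x1 ** 2 + x2 ** 2), 0.0, None)
        # meatus bands are anatomical (world-vertical) bands of the section
        zrel = rel[:, 2] / self.wz[k]
        band_c = np.where(zrel < -1 / 3, self.band_coef[0],
                          np.where(zrel > 1 / 3, self.band_coef[2],
                                   self.band_coef[1]))
        # non-TR: u = u_mean·2(1-rho²); TR band j: u = Q/(wx·wz)·c_j·(1-rho²)
        mag = np.where(self.is_tr[k],
                       self.Q / (self.wx[k] * self.wz[k]) * band_c * shape,
                       2.0 * self.u_mean[k] * shape)
        return mag[:, None] * self.tangents[k]

    def kernel_arrays(self):
        return dict(
            centers=self.centers, tangents=self.tangents, e1=self.e1,
            e2=self.e2, wx=self.wx, wz=self.wz, u_mean=self.u_mean,
            is_tr=self.is_tr.astype(float), band_coef=self.band_coef,
            Q=self.Q)

    def mean_speed_at(self, station_index: int) -> float:
        """Section-mean axial speed Q/A at a centerline station."""
        return float(self.u_mean[station_index])


class PointCloudField(FlowField):
    """Externally computed velocity field imported as a point cloud.

    Reads ``x,y,z,ux,uy,uz`` (CSV with that header, or an equivalent
    DataFrame) and evaluates by inverse-distance weighting over the k
    nearest samples — a bridge for fields produced by an external CFD
    solver.  Droplet tracking falls back to the pure-python stepper with
    this field (it has no compiled kernel form).
    """

    def __init__(self, source, k: int = 4):
        import pandas as pd
        from scipy.spatial import cKDTree

        table = source if isinstance(source, pd.DataFrame) else \
            pd.read_csv(source)
        missing = {"x", "y", "z", "ux", "uy", "uz"} - set(table.columns)
        if missing:
            raise GeometryError(
                f"point-cloud field needs columns x,y,z,ux,uy,uz; "
                f"missing {sorted(missing)}")
        self.points = table[["x", "y", "z"]].to_numpy(float)
        self.u = table[["ux", "uy", "uz"]].to_numpy(float)
        self.k = min(k, len(self.points))
        self.tree = cKDTree(self.points)

    def velocity(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        d, idx = self.tree.query(pts, k=self.k)
        d = np.atleast_2d(d)
        idx = np.atleast_2d(idx)
        w = 1.0 / np.maximum(d, 1e-12)
        w /= w.sum(axis=1, keepdims=True)
        exact = d[:, 0] < 1e-12
        out = np.einsum("nk,nkj->nj", w, self.u[idx])
        out[exact] = self.u[idx[exact, 0]]
        return out


def wall_shear_on_film(flow: FlowField, mesh: LabeledSurfaceMesh,
                       faces=None, sampling_distance: float = WALL_SAMPLING_DISTANCE
                       ) -> np.ndarray:
    """Tangential air-film interface traction per face (Pa).

    Samples the air velocity one near-wall distance inward along the inward
    normal, projects out the normal component, and applies a Couette estimate
    tau = mu_air * u_t / y0.  Quiescent air gives zero on every face.
    """
    if faces is None:
        faces = np.arange(mesh.n_faces)
    faces = np.atleast_1d(faces)
    n = mesh.face_normal[faces]
    pts = mesh.face_centroid[faces] - sampling_distance * n   # inward: -outward
    u = flow.velocity(pts)
    u_t = u - np.einsum("ij,ij->i", u, n)[:, None] * n
    return flow.mu_air * u_t / sampling_distance
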