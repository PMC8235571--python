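"""Synthetic nasal-airway surface geometry.

Generates parametric, labeled triangulated surfaces that stand in for a
subject-specific nasal passage: a converging ~90°-bend vestibule, a slit-like
nasal valve, a tall turbinate region whose airspace is banded into inferior /
middle / superior meatus, an olfactory patch on the turbinate roof, and a
nasopharynx bend into a short pharynx.  The mesh is watertight except for the
two designated openings (nostril inlet, pharynx outlet).

Anatomical frame convention: x = subject's left→right, y = anterior→posterior,
z = inferior→superior.  Gravity for an upright head is therefore -z; in the
vertex-to-floor ("Mecca") position the head is inverted and gravity points +z,
from the nasal floor toward the roof and olfactory patch.

All quantities are SI (meters, seconds, kilograms) unless a name says
otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh


class Region(enum.Enum):
    """Surface subregions used for dosimetry accounting."""

    VEST = "VEST"        # nasal vestibule (nostril entrance)
    VALVE = "VALVE"      # nasal valve, the flow-limiting slit
    IM = "IM"            # inferior meatus walls
    MM = "MM"            # middle meatus walls
    SM = "SM"            # superior meatus / upper turbinate walls
    OL = "OL"            # olfactory patch on the turbinate roof
    NP = "NP"            # nasopharynx bend
    PHARYNX = "PHARYNX"  # short pharyngeal outlet segment


ALL_REGIONS = tuple(Region)
_REGION_CODE = {r: i for i, r in enumerate(ALL_REGIONS)}
_CODE_REGION = {i: r for r, i in _REGION_CODE.items()}

#: Meatus labels, inferior to superior.
MEATUS_REGIONS = (Region.IM, Region.MM, Region.SM)
#: Regions downstream of (deeper than) the nasal valve.
BEYOND_VALVE = (Region.IM, Region.MM, Region.SM, Region.OL, Region.NP,
                Region.PHARYNX)


class GeometryError(ValueError):
    """Invalid geometry parameters or malformed mesh input."""


# ---------------------------------------------------------------------------
# mesh resolution helper


def prism_layer_stack_height(first_layer: float, ratio: float, n_layers: int) -> float:
    """Total height of a geometric near-wall prism-layer stack.

    ``first_layer * (1 + ratio + ... + ratio**(n_layers-1))`` — the usual
    boundary-layer inflation arithmetic, exposed for resolution bookkeeping.
    """
    if first_layer <= 0 or ratio <= 0 or n_layers < 1:
        raise GeometryError("prism stack requires positive height, ratio and n>=1")
    return first_layer * sum(ratio ** k for k in range(n_layers))


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class NasalGeometryParams:
    """Dimensions of the idealized single nasal passage.

    Defaults are sized to an adult nose: ~0.10 m passage length and a valve
    cross-section of ~0.7 cm², so that Stokes numbers of 10–120 µm spray
    droplets are realistic.  Semi-axis pairs are (lateral, vertical) ellipse
    half-widths of the local cross-section.
    """

    vestibule_length: float = 0.004          # straight entry below the bend
    vestibule_bend_radius: float = 0.010     # ~90° bend radius
    inlet_semi_axes: tuple[float, float] = (0.0055, 0.0055)
    valve_semi_axes: tuple[float, float] = (0.0025, 0.0090)   # slit: area ~0.7 cm²
    valve_length: float = 0.005
    turbinate_semi_axes: tuple[float, float] = (0.0030, 0.0180)
    turbinate_length: float = 0.040
    olfactory_span: tuple[float, float] = (0.60, 0.92)  # fraction of turbinate length
    olfactory_z_frac: float = 0.72           # roof band |z|/wz above which OL applies
    meatus_lobe_depth: float = 0.22          # lateral pinch amplitude in the turbinate
    np_bend_radius: float = 0.012
    np_semi_axes: tuple[float, float] = (0.0060, 0.0080)
    pharynx_length: float = 0.018
    pharynx_semi_axes: tuple[float, float] = (0.0070, 0.0070)
    target_edge_length: float = 1.5e-3

    def validate(self) -> None:
        lengths = (
            self.vestibule_length, self.vestibule_bend_radius, self.valve_length,
            self.turbinate_length, self.np_bend_radius, self.pharynx_length,
            self.target_edge_length, *self.inlet_semi_axes, *self.valve_semi_axes,
            *self.turbinate_semi_axes, *self.np_semi_axes, *self.pharynx_semi_axes,
        )
        if any(not (v > 0) for v in lengths):
            raise GeometryError("all geometry dimensions must be positive")
        a0, b0 = self.inlet_semi_axes
        av, bv = self.valve_semi_axes
        if av * bv >= a0 * b0:
            raise GeometryError(
                "valve cross-section must be smaller than the vestibule inlet "
                "(converging vestibule)")
        s0, s1 = self.olfactory_span
        if not (0.0 <= s0 < s1 <= 1.0):
            raise GeometryError(
                "olfactory span must be a non-empty sub-interval of [0, 1]; "
                "an olfactory patch is required")
        if not (0.0 < self.olfactory_z_frac < 1.0):
            raise GeometryError("olfactory_z_frac must lie in (0, 1)")
        if not (0.0 <= self.meatus_lobe_depth < 0.9):
            raise GeometryError("meatus_lobe_depth must lie in [0, 0.9)")


# ---------------------------------------------------------------------------
# head pose


@dataclass(frozen=True)
class HeadPose:
    """Head orientation resolved into a mesh-frame gravity vector.

    Either a named pose (``"upright"`` or ``"vertex_to_floor"``) or an explicit
    3×3 rotation applied to the upright gravity direction.
    """

    name: str = "upright"
    rotation: np.ndarray | None = None
    g: float = 9.81

    UPRIGHT = "upright"
    VERTEX_TO_FLOOR = "vertex_to_floor"

    def __post_init__(self):
        if self.rotation is not None:
            R = np.asarray(self.rotation, dtype=float)
            if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
                raise GeometryError("explicit head-pose rotation must be orthonormal 3x3")
            object.__setattr__(self, "rotation", R)
        elif self.name not in (self.UPRIGHT, self.VERTEX_TO_FLOOR):
            raise GeometryError(f"unknown head pose {self.name!r}")


def gravity_in_mesh_frame(pose: HeadPose) -> np.ndarray:
    """Gravity vector in the anatomical mesh frame for a given head pose.

    Upright: (0, 0, -g), roof → floor.  Vertex-to-floor (head inverted):
    (0, 0, +g), floor → roof, aligning gravity with the olfactory patch.
    """
    down = np.array([0.0, 0.0, -pose.g])
    if pose.rotation is not None:
        return pose.rotation @ down
    if pose.name == HeadPose.VERTEX_TO_FLOOR:
        return -down
    return down


# ---------------------------------------------------------------------------
# labeled surface mesh container


@dataclass
class LabeledSurfaceMesh:
    """Triangulated surface with per-face region labels and FV connectivity.

    ``edge_faces`` lists interior edges as (face_a, face_b) pairs together with
    their endpoint vertices; ``boundary_edges`` are edges owned by exactly one
    face (the designated openings, for generated airway meshes).
    """

    vertices: np.ndarray                 # (V, 3) float64
    faces: np.ndarray                    # (F, 3) int64
    region_code: np.ndarray              # (F,) int8, index into ALL_REGIONS
    metadata: dict = field(default_factory=dict)

    face_area: np.ndarray = field(init=False)
    face_normal: np.ndarray = field(init=False)
    face_centroid: np.ndarray = field(init=False)
    edge_vertices: np.ndarray = field(init=False)   # (E, 2) interior edges
    edge_faces: np.ndarray = field(init=False)      # (E, 2)
    boundary_edge_vertices: np.ndarray = field(init=False)  # (B, 2)
    boundary_edge_faces: np.ndarray = field(init=False)     # (B,)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.region_code = np.ascontiguousarray(self.region_code, dtype=np.int8)
        if len(self.region_code) != len(self.faces):
            raise GeometryError("one region label required per face")
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        if np.any(norm <= 0):
            raise GeometryError("degenerate (zero-area) face in mesh")
        self.face_area = 0.5 * norm
        self.face_normal = cross / norm[:, None]
        self.face_centroid = tri.mean(axis=1)
        self._build_adjacency()

    def _build_adjacency(self) -> None:
        f = self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        owner = np.tile(np.arange(len(f)), 3)
        key = np.sort(edges, axis=1)
        order = np.lexsort((key[:, 1], key[:, 0]))
        key, edges, owner = key[order], edges[order], owner[order]
        same = np.all(key[1:] == key[:-1], axis=1)
        # pair up duplicate-keyed consecutive rows
        ev, ef, bv, bf = [], [], [], []
        i = 0
        n = len(key)
        while i < n:
            if i + 1 < n and same[i]:
                if i + 2 < n and same[i + 1]:
                    raise GeometryError("non-manifold edge shared by >2 faces")
                fa, fb = sorted((owner[i], owner[i + 1]))
                ev.append(key[i]); ef.append((fa, fb))
                i += 2
            else:
                bv.append(key[i]); bf.append(owner[i])
                i += 1
        self.edge_vertices = np.asarray(ev, dtype=np.int64).reshape(-1, 2)
        self.edge_faces = np.asarray(ef, dtype=np.int64).reshape(-1, 2)
        self.boundary_edge_vertices = np.asarray(bv, dtype=np.int64).reshape(-1, 2)
        self.boundary_edge_faces = np.asarray(bf, dtype=np.int64)

    # -- convenience ------------------------------------------------------

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def region_of_face(self, face_id: int) -> Region:
        return _CODE_REGION[int(self.region_code[face_id])]

    def faces_in_region(self, region: Region) -> np.ndarray:
        return np.flatnonzero(self.region_code == _REGION_CODE[region])

    def region_labels(self) -> set[Region]:
        return {_CODE_REGION[int(c)] for c in np.unique(self.region_code)}

    def total_area(self) -> float:
        return float(self.face_area.sum())

    def region_area(self, region: Region) -> float:
        return float(self.face_area[self.faces_in_region(region)].sum())

    def min_edge_length(self) -> float:
        all_ev = np.concatenate([self.edge_vertices, self.boundary_edge_vertices])
        d = self.vertices[all_ev[:, 0]] - self.vertices[all_ev[:, 1]]
        return float(np.linalg.norm(d, axis=1).min())

    def mean_edge_length(self) -> float:
        all_ev = np.concatenate([self.edge_vertices, self.boundary_edge_vertices])
        d = self.vertices[all_ev[:, 0]] - self.vertices[all_ev[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())


def mesh_from_regions(vertices, faces, regions, metadata=None) -> LabeledSurfaceMesh:
    """Build a :class:`LabeledSurfaceMesh` from per-face :class:`Region` labels."""
    code = np.array([_REGION_CODE[r] for r in regions], dtype=np.int8)
    return LabeledSurfaceMesh(np.asarray(vertices, float), np.asarray(faces),
                              code, metadata or {})


# ---------------------------------------------------------------------------
# the idealized nasal passage


def _centerline(params: NasalGeometryParams):
    """Piecewise centerline (straight-arc-straight-arc-straight) in the y-z plane.

    Returns a callable s -> (point, unit tangent) plus total length and the
    arclength breakpoints between anatomical segments.
    """
    Lv = params.vestibule_length
    Rb = params.vestibule_bend_radius
    Lc = params.valve_length + params.turbinate_length
    Rn = params.np_bend_radius
    Lp = params.pharynx_length

    s_bends = np.array([
        Lv,                       # end of straight vestibule entry
        Lv + Rb * np.pi / 2,      # end of vestibule bend
        Lv + Rb * np.pi / 2 + Lc,         # end of horizontal run
        Lv + Rb * np.pi / 2 + Lc + Rn * np.pi / 2,  # end of NP bend
        Lv + Rb * np.pi / 2 + Lc + Rn * np.pi / 2 + Lp,
    ])
    total = float(s_bends[-1])

    def eval_s(s: float):
        if s <= s_bends[0]:
            return np.array([0.0, 0.0, s]), np.array([0.0, 0.0, 1.0])
        if s <= s_bends[1]:
            psi = (s - s_bends[0]) / Rb
            p = np.array([0.0, Rb * (1 - np.cos(psi)), Lv + Rb * np.sin(psi)])
            t = np.array([0.0, np.sin(psi), np.cos(psi)])
            return p, t
        if s <= s_bends[2]:
            u = s - s_bends[1]
            return np.array([0.0, Rb + u, Lv + Rb]), np.array([0.0, 1.0, 0.0])
        if s <= s_bends[3]:
            psi = (s - s_bends[2]) / Rn
            p = np.array([0.0, Rb + Lc + Rn * np.sin(psi),
                          Lv + Rb - Rn + Rn * np.cos(psi)])
            t = np.array([0.0, np.cos(psi), -np.sin(psi)])
            return p, t
        u = s - s_bends[3]
        return (np.array([0.0, Rb + Lc + Rn, Lv + Rb - Rn - u]),
                np.array([0.0, 0.0, -1.0]))

    return eval_s, total, s_bends


def _region_span_edges(params: NasalGeometryParams, s_bends):
    """Arclength breakpoints between VEST | VALVE | TR | NP | PHARYNX."""
    vest_end = s_bends[1]
    valve_end = vest_end + params.valve_length
    tr_end = s_bends[2]
    np_end = s_bends[3]
    return vest_end, valve_end, tr_end, np_end


def _semi_axes_of_s(params: NasalGeometryParams, s, s_bends):
    """Smoothly interpolated (lateral, vertical) cross-section semi-axes."""
    vest_end, valve_end, tr_end, np_end = _region_span_edges(params, s_bends)
    total = s_bends[-1]
    tr_ramp = valve_end + 0.25 * (tr_end - valve_end)
    ctrl_s = [0.0, 0.6 * vest_end, vest_end, valve_end, tr_ramp,
              0.95 * tr_end, np_end, total]
    ctrl_a = [params.inlet_semi_axes, params.inlet_semi_axes,
              params.valve_semi_axes, params.valve_semi_axes,
              params.turbinate_semi_axes, params.turbinate_semi_axes,
              params.np_semi_axes, params.pharynx_semi_axes]
    wx = np.interp(s, ctrl_s, [a[0] for a in ctrl_a])
    wz = np.interp(s, ctrl_s, [a[1] for a in ctrl_a])
    return float(wx), float(wz)


def build_idealized_nasal_passage(
        params: NasalGeometryParams | None = None) -> LabeledSurfaceMesh:
    """Generate the labeled synthetic nasal passage surface.

    The passage is a swept tube over the piecewise centerline, with elliptical
    cross-sections interpolated between anatomical control sections, a gentle
    three-lobe lateral pinch in the turbinate (the meatus channels), and open
    rings at the nostril and pharynx ends.  Meatus labels are vertical bands of
    the turbinate wall; the olfactory patch overrides the superior band on the
    roof over ``olfactory_span``.
    """
    params = params or NasalGeometryParams()
    params.validate()
    eval_s, total, s_bends = _centerline(params)
    vest_end, valve_end, tr_end, np_end = _region_span_edges(params, s_bends)

    edge = params.target_edge_length
    n_st = max(8, int(round(total / (0.866 * edge))) + 1)
    s_vals = np.linspace(0.0, total, n_st)

    centers, tangents, e1s, e2s, wxs, wzs = [], [], [], [], [], []
    xhat = np.array([1.0, 0.0, 0.0])
    for s in s_vals:
        c, t = eval_s(s)
        e1 = xhat - np.dot(xhat, t) * t
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        wx, wz = _semi_axes_of_s(params, s, s_bends)
        centers.append(c); tangents.append(t); e1s.append(e1); e2s.append(e2)
        wxs.append(wx); wzs.append(wz)
    centers = np.array(centers); tangents = np.array(tangents)
    e1s = np.array(e1s); e2s = np.array(e2s)
    wxs = np.array(wxs); wzs = np.array(wzs)

    # ring resolution from the mean perimeter (Ramanujan ellipse estimate)
    hmean = ((wxs - wzs) / (wxs + wzs)) ** 2
    perim = np.pi * (wxs + wzs) * (1 + 3 * hmean / (10 + np.sqrt(4 - 3 * hmean)))
    n_theta = max(12, int(round(perim.mean() / edge)))

    lam = params.meatus_lobe_depth
    phi = 2 * np.pi * np.arange(n_theta) / n_theta
    verts = np.empty((n_st, n_theta, 3))
    for i, s in enumerate(s_vals):
        if valve_end <= s <= tr_end:
            ramp_in = np.clip((s - valve_end) / (0.15 * (tr_end - valve_end)), 0, 1)
            ramp_out = np.clip((tr_end - s) / (0.15 * (tr_end - valve_end)), 0, 1)
            lobe = lam * min(ramp_in, ramp_out)
        else:
            lobe = 0.0
        xi1 = wxs[i] * np.cos(phi) * (1.0 - lobe * np.sin(3 * phi) ** 2)
        xi2 = wzs[i] * np.sin(phi)
        verts[i] = centers[i] + np.outer(xi1, e1s[i]) + np.outer(xi2, e2s[i])

    vertices = verts.reshape(-1, 3)
    faces = []
    for i in range(n_st - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append((a, c, b))
            faces.append((b, c, d))
    faces = np.asarray(faces, dtype=np.int64)

    # outward orientation: flip if normals point toward the centerline
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    centroids = tri.mean(axis=1)
    ring = np.minimum((np.arange(len(faces)) // (2 * n_theta)), n_st - 1)
    outward = centroids - centers[ring]
    if np.median(np.einsum("ij,ij->i", cross, outward)) < 0:
        faces = faces[:, [0, 2, 1]]

    # region labels
    tri = vertices[faces]
    centroids = tri.mean(axis=1)
    s_face = 0.5 * (s_vals[ring] + s_vals[np.minimum(ring + 1, n_st - 1)])
    ol0 = valve_end + params.olfactory_span[0] * (tr_end - valve_end)
    ol1 = valve_end + params.olfactory_span[1] * (tr_end - valve_end)

    regions = []
    for k in range(len(faces)):
        s = s_face[k]
        if s < vest_end:
            regions.append(Region.VEST)
        elif s < valve_end:
            regions.append(Region.VALVE)
        elif s < tr_end:
            i = int(ring[k])
            z_rel = np.dot(centroids[k] - centers[i], [0.0, 0.0, 1.0]) / wzs[i]
            if ol0 <= s <= ol1 and z_rel > params.olfactory_z_frac:
                regions.append(Region.OL)
            elif z_rel > 1.0 / 3.0:
                regions.append(Region.SM)
            elif z_rel < -1.0 / 3.0:
                regions.append(Region.IM)
            else:
                regions.append(Region.MM)
        elif s < np_end:
            regions.append(Region.NP)
        else:
            regions.append(Region.PHARYNX)

    # station table reused by nozzle placement and the duct flow field
    region_of_station = []
    for s in s_vals:
        if s < vest_end:
            region_of_station.append(Region.VEST.value)
        elif s < valve_end:
            region_of_station.append(Region.VALVE.value)
        elif s < tr_end:
            region_of_station.append("TR")
        elif s < np_end:
            region_of_station.append(Region.NP.value)
        else:
            region_of_station.append(Region.PHARYNX.value)

    metadata = {
        "kind": "idealized_nasal_passage",
        "params": params,
        "stations": {
            "s": s_vals, "center": centers, "tangent": tangents,
            "e1": e1s, "e2": e2s, "wx": wxs, "wz": wzs,
            "region": region_of_station,
        },
        "span_edges": {"vest_end": vest_end, "valve_end": valve_end,
                       "tr_end": tr_end, "np_end": np_end, "total": total},
        "inlet_plane": {"point": centers[0], "normal": -tangents[0]},
        "outlet_plane": {"point": centers[-1], "normal": tangents[-1]},
        "target_face_count": 2 * (n_st - 1) * n_theta,
    }
    return mesh_from_regions(vertices, faces, regions, metadata)


# ---------------------------------------------------------------------------
# debug geometries (same container machinery, analytic areas)


def unit_cube_mesh(region: Region = Region.VEST) -> LabeledSurfaceMesh:
    """Closed unit cube; total surface area 6.0 m². For solver verification."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return mesh_from_regions(box.vertices, box.faces,
                             [region] * len(box.faces), {"kind": "debug_cube"})


def cylinder_segment_mesh(radius=0.01, height=0.05, sections=48,
                          region: Region = Region.VEST) -> LabeledSurfaceMesh:
    """Capped cylinder; analytic area 2πr(h + r)."""
    cyl = trimesh.creation.cylinder(radius=radius, height=height,
                                    sections=sections)
    return mesh_from_regions(cyl.vertices, cyl.faces,
                             [region] * len(cyl.faces),
                             {"kind": "debug_cylinder"})


def flat_patch_mesh(nx=20, ny=20, lx=1.0, ly=1.0, normal_axis="z",
                    region: Region = Region.VEST,
                    periodic_y: bool = False) -> LabeledSurfaceMesh:
    """Flat rectangular triangulated patch in the x-y plane (normal +z).

    With ``normal_axis='y'`` the patch lies in the x-z plane (a vertical wall
    strip, normal +y).  ``periodic_y`` marks the two edges transverse to the
    second axis as periodic partners in the metadata, so the film solver can
    treat the strip as unbounded along the slope.
    """
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    if normal_axis == "z":
        vertices = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    elif normal_axis == "y":
        vertices = np.column_stack([X.ravel(), np.zeros(X.size), Y.ravel()])
    else:
        raise GeometryError("normal_axis must be 'z' or 'y'")
    faces = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = a + 1
            c = a + (ny + 1)
            d = c + 1
            faces.append((a, c, b))
            faces.append((b, c, d))
    faces = np.asarray(faces, dtype=np.int64)
    if normal_axis == "y":          # keep +y normals
        faces = faces[:, [0, 2, 1]]
    # film side: debug patches carry their liquid on the +normal side
    meta = {"kind": "debug_flat_patch", "nx": nx, "ny": ny, "lx": lx,
            "ly": ly, "film_side": +1.0}
    if periodic_y:
        # pair the j=0 and j=ny-1 rows of cells: (low face, high face) per column
        pairs = []
        for i in range(nx):
            lo = 2 * (i * ny + 0)          # triangle on the y=0 boundary edge
            hi = 2 * (i * ny + (ny - 1)) + 1
            pairs.append((hi, lo))
        meta["periodic_pairs"] = np.asarray(pairs, dtype=np.int64)
        meta["periodic_shift"] = ly
    return mesh_from_regions(vertices, faces, [region] * len(faces), meta)


def straight_tube_mesh(radius=0.005, length=0.05, n_theta=24, n_axial=30,
                       region: Region = Region.VALVE) -> LabeledSurfaceMesh:
    """Open straight tube along +y with circular section (flow-field tests)."""
    s_vals = np.linspace(0.0, length, n_axial)
    phi = 2 * np.pi * np.arange(n_theta) / n_theta
    verts = np.empty((n_axial, n_theta, 3))
    for i, s in enumerate(s_vals):
        verts[i, :, 0] = radius * np.cos(phi)
        verts[i, :, 1] = s
        verts[i, :, 2] = radius * np.sin(phi)
    vertices = verts.reshape(-1, 3)
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append((a, b, c))
            faces.append((b, d, c))
    faces = np.asarray(faces, dtype=np.int64)
    centers = np.column_stack([np.zeros(n_axial), s_vals, np.zeros(n_axial)])
    meta = {
        "kind": "debug_tube",
        "stations": {
            "s": s_vals, "center": centers,
            "tangent": np.tile([0.0, 1.0, 0.0], (n_axial, 1)),
            "e1": np.tile([1.0, 0.0, 0.0], (n_axial, 1)),
            "e2": np.tile([0.0, 0.0, 1.0], (n_axial, 1)),
            "wx": np.full(n_axial, radius), "wz": np.full(n_axial, radius),
            "region": [Region.VALVE.value] * n_axial,
        },
        "inlet_plane": {"point": centers[0], "normal": np.array([0.0, -1.0, 0.0])},
        "outlet_plane": {"point": centers[-1], "normal": np.array([0.0, 1.0, 0.0])},
    }
    mesh = mesh_from_regions(vertices, faces, [region] * len(faces), meta)
    # orient outward
    out = mesh.face_centroid - np.array([0.0, 1.0, 0.0]) * mesh.face_centroid[:, 1:2]
    if np.median(np.einsum("ij,ij->i", mesh.face_normal, out)) < 0:
        return mesh_from_regions(vertices, faces[:, [0, 2, 1]],
                                 [region] * len(faces), meta)
    return mesh


# ---------------------------------------------------------------------------
# mesh I/O with region sidecar


def save_mesh(path, mesh: LabeledSurfaceMesh, sidecar_path=None) -> None:
    """Write the surface (STL/OBJ/PLY by extension) plus a region CSV sidecar.

    The sidecar has header ``face_id,region`` with 0-based face ids in file
    face order.  OBJ round-trips at full double precision; STL and PLY store
    float32 vertices (~1e-8 m at decimeter scale).
    """
    import os

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in (".stl", ".obj", ".ply"):
        raise GeometryError(f"unsupported mesh format {ext!r}; use STL/OBJ/PLY")
    kwargs = {"digits": 17} if ext == ".obj" else {}
    tm.export(str(path), **kwargs)
    if sidecar_path is None:
        sidecar_path = str(path) + ".regions.csv"
    pd.DataFrame({
        "face_id": np.arange(mesh.n_faces),
        "region": [mesh.region_of_face(i).value for i in range(mesh.n_faces)],
    }).to_csv(sidecar_path, index=False)


def load_mesh(path, sidecar_path=None) -> LabeledSurfaceMesh:
    """Read a surface mesh plus its ``face_id,region`` sidecar table."""
    import os

    ext = os.path.splitext(str(path))[1].lower()
    if ext not in (".stl", ".obj", ".ply"):
        raise GeometryError(f"unsupported mesh format {ext!r}; use STL/OBJ/PLY")
    tm = trimesh.load(str(path), process=False, force="mesh")
    if ext == ".stl":
        tm.merge_vertices()     # STL stores soup triangles; restore sharing
    if sidecar_path is None:
        sidecar_path = str(path) + ".regions.csv"
    table = pd.read_csv(sidecar_path)
    if set(table.columns) < {"face_id", "region"}:
        raise GeometryError("region sidecar must have columns face_id,region")
    if len(table) != len(tm.faces):
        raise GeometryError(
            f"region sidecar has {len(table)} rows for {len(tm.faces)} faces")
    valid = {r.value for r in Region}
    bad = set(table["region"].astype(str)) - valid
    if bad:
        raise GeometryError(f"unknown region labels in sidecar: {sorted(bad)}")
    regions = [Region(v) for v in
               table.sort_values("face_id")["region"].astype(str)]
    return mesh_from_regions(tm.vertices, tm.faces, regions,
                             {"kind": "loaded", "source": str(path)})
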