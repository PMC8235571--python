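"""Numba kernels for Lagrangian droplet tracking.

One compiled loop advances each droplet independently to its fate
(deposited / escaped / expired): semi-implicit exponential drag relaxation,
trapezoidal position update, and segment-triangle impaction tests against a
uniform voxel grid of candidate wall faces.  Per-step displacement is capped
at half the smallest mesh edge so a wall crossing can never be stepped over.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DRAG_NONE, DRAG_STOKES, DRAG_SCHILLER_NAUMANN = 0, 1, 2
ACTIVE, DEPOSITED, ESCAPED, EXPIRED = 0, 1, 2, 3


@njit(cache=True)
def _flow_velocity(p, centers, tangents, e1, e2, wx, wz, u_mean, is_tr,
                   band_coef, Q, out):
    """Prescribed duct field at a point (zero for u_mean==0 everywhere)."""
    n = centers.shape[0]
    best = 0
    best_d = 1e300
    for k in range(n):
        dx = p[0] - centers[k, 0]
        dy = p[1] - centers[k, 1]
        dz = p[2] - centers[k, 2]
        d = dx * dx + dy * dy + dz * dz
        if d < best_d:
            best_d = d
            best = k
    k = best
    rx = p[0] - centers[k, 0]
    ry = p[1] - centers[k, 1]
    rz = p[2] - centers[k, 2]
    x1 = (rx * e1[k, 0] + ry * e1[k, 1] + rz * e1[k, 2]) / wx[k]
    x2 = (rx * e2[k, 0] + ry * e2[k, 1] + rz * e2[k, 2]) / wz[k]
    shape = 1.0 - (x1 * x1 + x2 * x2)
    if shape < 0.0:
        shape = 0.0
    if is_tr[k] > 0.5:
        zrel = rz / wz[k]
        if zrel < -1.0 / 3.0:
            c = band_coef[0]
        elif zrel > 1.0 / 3.0:
            c = band_coef[2]
        else:
            c = band_coef[1]
        mag = Q / (wx[k] * wz[k]) * c * shape
    else:
        mag = 2.0 * u_mean[k] * shape
    out[0] = mag * tangents[k, 0]
    out[1] = mag * tangents[k, 1]
    out[2] = mag * tangents[k, 2]


@njit(cache=True)
def _segment_triangle(p0, p1, a, b, c):
    """Möller–Trumbore for segment p0→p1; returns parametric t in [0,1] or -1."""
    e1x = b[0] - a[0]; e1y = b[1] - a[1]; e1z = b[2] - a[2]
    e2x = c[0] - a[0]; e2y = c[1] - a[1]; e2z = c[2] - a[2]
    dx = p1[0] - p0[0]; dy = p1[1] - p0[1]; dz = p1[2] - p0[2]
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    scale = abs(e1x) + abs(e1y) + abs(e1z) + abs(e2x) + abs(e2y) + abs(e2z)
    if abs(det) < 1e-14 * scale * scale * (abs(dx) + abs(dy) + abs(dz) + 1e-300):
        return -1.0
    inv = 1.0 / det
    tx = p0[0] - a[0]; ty = p0[1] - a[1]; tz = p0[2] - a[2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-12 or u > 1.0 + 1e-12:
        return -1.0
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-12 or u + v > 1.0 + 1e-12:
        return -1.0
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t < 0.0 or t > 1.0:
        return -1.0
    return t


@njit(cache=True)
def _voxel_index(p, origin, cell, dims):
    ix = int((p[0] - origin[0]) / cell)
    iy = int((p[1] - origin[1]) / cell)
    iz = int((p[2] - origin[2]) / cell)
    if ix < 0 or iy < 0 or iz < 0 or ix >= dims[0] or iy >= dims[1] or iz >= dims[2]:
        return -1
    return (ix * dims[1] + iy) * dims[2] + iz


@njit(cache=True)
def _hit_in_grid(p0, p1, v0, v1, v2, origin, cell, dims, cell_start, cell_faces):
    """Earliest wall hit on the segment; ties broken toward the lowest face id.

    Candidates come from the 2×2×2 voxel block spanned by the segment AABB
    (per-step displacement <= cell/2 guarantees coverage).
    """
    best_t = 2.0
    best_f = -1
    lox = min(p0[0], p1[0]); hix = max(p0[0], p1[0])
    loy = min(p0[1], p1[1]); hiy = max(p0[1], p1[1])
    loz = min(p0[2], p1[2]); hiz = max(p0[2], p1[2])
    ix0 = int((lox - origin[0]) / cell); ix1 = int((hix - origin[0]) / cell)
    iy0 = int((loy - origin[1]) / cell); iy1 = int((hiy - origin[1]) / cell)
    iz0 = int((loz - origin[2]) / cell); iz1 = int((hiz - origin[2]) / cell)
    for ix in range(max(ix0, 0), min(ix1, dims[0] - 1) + 1):
        for iy in range(max(iy0, 0), min(iy1, dims[1] - 1) + 1):
            for iz in range(max(iz0, 0), min(iz1, dims[2] - 1) + 1):
                v = (ix * dims[1] + iy) * dims[2] + iz
                for q in range(cell_start[v], cell_start[v + 1]):
                    f = cell_faces[q]
                    t = _segment_triangle(p0, p1, v0[f], v1[f], v2[f])
                    if t >= 0.0:
                        if t < best_t - 1e-12:
                            best_t = t
                            best_f = f
                        elif abs(t - best_t) <= 1e-12 and f < best_f:
                            best_f = f
    return best_t, best_f


@njit(cache=True)
def track_droplets(pos, vel, diam, status, face_id, t_dep, imp_pos, imp_vel,
                   v0, v1, v2,
                   origin, cell, dims, cell_start, cell_faces,
                   centers, tangents, e1, e2, wx, wz, u_mean, is_tr,
                   band_coef, Q,
                   g, rho_p, rho_a, mu_a, drag_mode,
                   dt_max, max_time, dl_cap,
                   inlet_p, inlet_n, outlet_p, outlet_n, has_planes,
                   lo, hi, step_cap):
    n = pos.shape[0]
    u = np.zeros(3)
    p_new = np.zeros(3)
    for i in range(n):
        if status[i] != ACTIVE:
            continue
        px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
        vx, vy, vz = vel[i, 0], vel[i, 1], vel[i, 2]
        d = diam[i]
        tau = rho_p * d * d / (18.0 * mu_a)
        t = 0.0
        for _step in range(step_cap):
            pos[i, 0] = px; pos[i, 1] = py; pos[i, 2] = pz
            _flow_velocity(pos[i], centers, tangents, e1, e2, wx, wz,
                           u_mean, is_tr, band_coef, Q, u)
            speed = np.sqrt(vx * vx + vy * vy + vz * vz)
            dt = dt_max
            if speed > 1e-12 and dl_cap / speed < dt:
                dt = dl_cap / speed
            if t + dt > max_time:
                dt = max_time - t
            if dt <= 0.0:
                status[i] = EXPIRED
                break
            if drag_mode == DRAG_NONE:
                nvx = vx + g[0] * dt
                nvy = vy + g[1] * dt
                nvz = vz + g[2] * dt
            else:
                relx = vx - u[0]; rely = vy - u[1]; relz = vz - u[2]
                rel = np.sqrt(relx * relx + rely * rely + relz * relz)
                f = 1.0
                if drag_mode == DRAG_SCHILLER_NAUMANN:
                    Re = rho_a * rel * d / mu_a
                    if Re > 1000.0:
                        Re = 1000.0
                    f = 1.0 + 0.15 * Re ** 0.687
                k = f / tau
                e = np.exp(-k * dt)
                gfac = (1.0 - e) / k
                nvx = u[0] + relx * e + g[0] * gfac
                nvy = u[1] + rely * e + g[1] * gfac
                nvz = u[2] + relz * e + g[2] * gfac
            p_new[0] = px + 0.5 * (vx + nvx) * dt
            p_new[1] = py + 0.5 * (vy + nvy) * dt
            p_new[2] = pz + 0.5 * (vz + nvz) * dt
            best_t, best_f = _hit_in_grid(pos[i], p_new, v0, v1, v2,
                                          origin, cell, dims,
                                          cell_start, cell_faces)
            if best_f >= 0:
                status[i] = DEPOSITED
                face_id[i] = best_f
                t_dep[i] = t + best_t * dt
                imp_pos[i, 0] = px + best_t * (p_new[0] - px)
                imp_pos[i, 1] = py + best_t * (p_new[1] - py)
                imp_pos[i, 2] = pz + best_t * (p_new[2] - pz)
                imp_vel[i, 0] = nvx
                imp_vel[i, 1] = nvy
                imp_vel[i, 2] = nvz
                pos[i] = imp_pos[i]
                vel[i, 0] = nvx; vel[i, 1] = nvy; vel[i, 2] = nvz
                break
            px, py, pz = p_new[0], p_new[1], p_new[2]
            vx, vy, vz = nvx, nvy, nvz
            t += dt
            escaped = False
            if has_planes:
                din = ((px - inlet_p[0]) * inlet_n[0]
                       + (py - inlet_p[1]) * inlet_n[1]
                       + (pz - inlet_p[2]) * inlet_n[2])
                dout = ((px - outlet_p[0]) * outlet_n[0]
                        + (py - outlet_p[1]) * outlet_n[1]
                        + (pz - outlet_p[2]) * outlet_n[2])
                if din > 0.0 or dout > 0.0:
                    escaped = True
            if (px < lo[0] or py < lo[1] or pz < lo[2]
                    or px > hi[0] or py > hi[1] or pz > hi[2]):
                escaped = True
            if escaped:
                status[i] = ESCAPED
                break
            if t >= max_time:
                status[i] = EXPIRED
                break
        else:
            status[i] = EXPIRED
        pos[i, 0] = px; pos[i, 1] = py; pos[i, 2] = pz
        vel[i, 0] = vx; vel[i, 1] = vy; vel[i, 2] = vz
        if status[i] == DEPOSITED:
            pos[i] = imp_pos[i]
            vel[i] = imp_vel[i]
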