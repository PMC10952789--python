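"""Numba kernels for substrate queries and the random-walk engine.

Geometry is passed as flat arrays produced by ``substrate._compile``:

    vx, vy          concatenated polygon vertices (block-local XY, um)
    poly_off        CSR offsets into vx/vy, one entry per polygon + 1
    cp_off, cp_idx  CSR: candidate polygons per uniform-grid cell
    ce_off, ce_poly, ce_vert
                    CSR: candidate edges per grid cell (owning polygon and
                    the vertex index where the edge starts)
    params          [Lx, Ly, Lz, icd_depth, ha_rad_per_um, gdx, gdy]
    iparams         [gnx, gny, half_shift]

Conventions: compartment -1 is extracellular space (ECS); points exactly on
a membrane resolve to ECS (strict inequalities in the crossing test); the
substrate tiles all space, with each Y row of blocks rigidly rotated about
the global Y axis by ha_rate * (row base y) and alternate rows shifted half
a block along Z.
"""

import numpy as np
from numba import njit

ECS = -1
_T_EPS = 1e-12  # parametric lower bound when searching for crossings
_NUDGE = 1e-6  # um: offset applied after crossing/reflection events

# event codes
_EV_NONE = 0
_EV_EDGE = 1
_EV_ZCAP = 2
_EV_XWRAP = 3
_EV_ZWRAP_ECS = 4
_EV_ROW = 5


# ----------------------------------------------------------------------
# counter-based RNG: splitmix64 (public-domain mixing constants)
# ----------------------------------------------------------------------

@njit(inline="always")
def _splitmix64(x):
    x = np.uint64(x) + np.uint64(0x9E3779B97F4A7C15)
    z = x
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(inline="always")
def _to_unit(u):
    # top 53 bits -> double in [0, 1)
    return float(u >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(inline="always")
def rng_uniform(key, ctr):
    return _to_unit(_splitmix64(np.uint64(key) + np.uint64(ctr) * np.uint64(0xD1B54A32D192ED03)))


@njit(inline="always")
def walker_key(seed, walker_id):
    return _splitmix64(np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15) + np.uint64(walker_id))


@njit(inline="always")
def step_key(wkey, step):
    return _splitmix64(np.uint64(wkey) ^ (np.uint64(step) * np.uint64(0x2545F4914F6CDD1D)))


# ----------------------------------------------------------------------
# point location
# ----------------------------------------------------------------------

@njit
def _point_in_poly(x, y, pi, vx, vy, poly_off):
    n0, n1 = poly_off[pi], poly_off[pi + 1]
    inside = False
    j = n1 - 1
    for i in range(n0, n1):
        xi, yi = vx[i], vy[i]
        xj, yj = vx[j], vy[j]
        # points exactly on a membrane belong to the ECS by convention
        cross = (xj - xi) * (y - yi) - (yj - yi) * (x - xi)
        if cross == 0.0 and min(xi, xj) <= x <= max(xi, xj) and min(yi, yj) <= y <= max(yi, yj):
            return False
        if (yi > y) != (yj > y):
            xc = xi + (y - yi) * (xj - xi) / (yj - yi)
            if x < xc:
                inside = not inside
        j = i
    return inside


@njit
def locate_local_xy(x, y, vx, vy, poly_off, cp_off, cp_idx, gnx, gny, gdx, gdy):
    ix = int(x / gdx)
    iy = int(y / gdy)
    if ix < 0:
        ix = 0
    elif ix >= gnx:
        ix = gnx - 1
    if iy < 0:
        iy = 0
    elif iy >= gny:
        iy = gny - 1
    c = iy * gnx + ix
    for k in range(cp_off[c], cp_off[c + 1]):
        pi = cp_idx[k]
        if _point_in_poly(x, y, pi, vx, vy, poly_off):
            return pi
    return ECS


@njit(inline="always")
def _frame(gy, Ly, ha_rad):
    """Row index, rotation angle and its cos/sin for a global y."""
    iy = int(np.floor(gy / Ly))
    theta = ha_rad * (iy * Ly)
    return iy, np.cos(theta), np.sin(theta)


@njit
def locate_point(
    px, py, pz,
    vx, vy, poly_off, cp_off, cp_idx, ce_off, ce_poly, ce_vert, params, iparams,
):
    Lx, Ly, Lz = params[0], params[1], params[2]
    ha_rad = params[4]
    gdx, gdy = params[5], params[6]
    gnx, gny, half_shift = iparams[0], iparams[1], iparams[2]
    if poly_off.shape[0] <= 1:
        return ECS
    iy, c, s = _frame(py, Ly, ha_rad)
    lx = c * px - s * pz
    yloc = py - iy * Ly
    lxw = lx % Lx
    return locate_local_xy(lxw, yloc, vx, vy, poly_off, cp_off, cp_idx, gnx, gny, gdx, gdy)


@njit
def _first_event(
    px, py, pz, dx, dy, dz, comp,
    vx, vy, poly_off, cp_off, cp_idx, ce_off, ce_poly, ce_vert, params, iparams,
):
    """Earliest geometric event on the segment p -> p + d.

    Returns (code, t, nx_local, ny_local, poly_hit, theta_c, theta_s,
             z_local_at_hit) where normals are in block-local coordinates.
    """
    Lx, Ly, Lz = params[0], params[1], params[2]
    ha_rad = params[4]
    gdx, gdy = params[5], params[6]
    gnx, gny, half_shift = iparams[0], iparams[1], iparams[2]

    iy, c, s = _frame(py, Ly, ha_rad)
    # local coordinates of the start point
    lx = c * px - s * pz
    lz = s * px + c * pz
    yloc = py - iy * Ly
    zoff = 0.5 * Lz if (half_shift == 1 and (iy % 2 != 0)) else 0.0
    lxw = lx % Lx
    lzw = (lz - zoff) % Lz
    # local direction
    dlx = c * dx - s * dz
    dlz = s * dx + c * dz

    best_t = 1.0 + 1e-15
    code = _EV_NONE
    nx = 0.0
    ny = 0.0
    poly_hit = -1

    # row boundary in y
    if dy > 0.0:
        t = ((iy + 1) * Ly - py) / dy
        if _T_EPS < t <= best_t:
            best_t = t
            code = _EV_ROW
    elif dy < 0.0:
        t = (iy * Ly - py) / dy
        if _T_EPS < t <= best_t:
            best_t = t
            code = _EV_ROW

    # x wrap planes (never membranes)
    if dlx > 0.0:
        t = (Lx - lxw) / dlx
        if _T_EPS < t <= best_t:
            best_t = t
            code = _EV_XWRAP
    elif dlx < 0.0:
        t = -lxw / dlx
        if _T_EPS < t <= best_t:
            best_t = t
            code = _EV_XWRAP

    # z planes (end caps when inside a cell)
    if dlz > 0.0:
        t = (Lz - lzw) / dlz
        if _T_EPS < t <= best_t:
            best_t = t
            code = _EV_ZCAP if comp >= 0 else _EV_ZWRAP_ECS
    elif dlz < 0.0:
        t = -lzw / dlz
        if _T_EPS < t <= best_t:
            best_t = t
            code = _EV_ZCAP if comp >= 0 else _EV_ZWRAP_ECS

    # polygon side walls up to the earliest plane event
    tmax = best_t if best_t < 1.0 else 1.0
    if poly_off.shape[0] > 1:
        x1 = lxw + tmax * dlx
        y1 = yloc + tmax * dy
        bx0 = lxw if lxw < x1 else x1
        bx1 = lxw if lxw > x1 else x1
        by0 = yloc if yloc < y1 else y1
        by1 = yloc if yloc > y1 else y1
        ix0 = int(bx0 / gdx)
        ix1 = int(bx1 / gdx)
        iy0 = int(by0 / gdy)
        iy1 = int(by1 / gdy)
        if ix0 < 0:
            ix0 = 0
        if iy0 < 0:
            iy0 = 0
        if ix1 >= gnx:
            ix1 = gnx - 1
        if iy1 >= gny:
            iy1 = gny - 1
        for gy_i in range(iy0, iy1 + 1):
            for gx_i in range(ix0, ix1 + 1):
                cidx = gy_i * gnx + gx_i
                for k in range(ce_off[cidx], ce_off[cidx + 1]):
                    pi = ce_poly[k]
                    v0 = ce_vert[k]
                    n0, n1 = poly_off[pi], poly_off[pi + 1]
                    v1 = v0 + 1
                    if v1 >= n1:
                        v1 = n0
                    ex = vx[v1] - vx[v0]
                    ey = vy[v1] - vy[v0]
                    denom = dlx * ey - dy * ex
                    if denom == 0.0:
                        continue
                    rx = vx[v0] - lxw
                    ry = vy[v0] - yloc
                    t = (rx * ey - ry * ex) / denom
                    if t <= _T_EPS or t > best_t:
                        continue
                    u = (rx * dy - ry * dlx) / denom
                    if u < 0.0 or u >= 1.0:
                        continue
                    # outward normal of a CCW polygon edge
                    elen = np.sqrt(ex * ex + ey * ey)
                    best_t = t
                    code = _EV_EDGE
                    nx = ey / elen
                    ny = -ex / elen
                    poly_hit = pi

    if code == _EV_NONE or best_t > 1.0:
        return _EV_NONE, 1.0, 0.0, 0.0, -1, c, s, 0.0

    z_at_hit = (lzw + best_t * dlz) % Lz
    return code, best_t, nx, ny, poly_hit, c, s, z_at_hit


@njit
def first_membrane_hit(
    px, py, pz, dx, dy, dz, comp, out,
    vx, vy, poly_off, cp_off, cp_idx, ce_off, ce_poly, ce_vert, params, iparams,
):
    """First *membrane* crossing on p -> p + d; wrap/row events are skipped.

    out: [t, n_gx, n_gy, n_gz, is_icd, comp_from, comp_to, _, _]
    The normal is global and oriented along the direction of travel.
    Returns True when a membrane is hit.
    """
    Lz = params[2]
    icd = params[3]
    t0 = 0.0
    cx, cy, cz = px, py, pz
    cc = comp
    for _ in range(64):
        rem = 1.0 - t0
        if rem <= 0.0:
            return False
        code, t, nxl, nyl, poly_hit, c, s, zhit = _first_event(
            cx, cy, cz, dx * rem, dy * rem, dz * rem, cc,
            vx, vy, poly_off, cp_off, cp_idx, ce_off, ce_poly, ce_vert, params, iparams,
        )
        if code == _EV_NONE:
            return False
        tg = t0 + t * rem  # global parametric position
        hx = px + tg * dx
        hy = py + tg * dy
        hz = pz + tg * dz
        if code == _EV_EDGE:
            # rotate the local XY normal back to global (y unchanged)
            ngx = c * nxl
            ngy = nyl
            ngz = -s * nxl
            # orient along travel
            if ngx * dx + ngy * dy + ngz * dz < 0.0:
                ngx, ngy, ngz = -ngx, -ngy, -ngz
            is_icd = 1.0 if (zhit < icd or zhit > Lz - icd) else 0.0
            comp_to = ECS if cc >= 0 else poly_hit
            out[0] = tg
            out[1] = ngx
            out[2] = ngy
            out[3] = ngz
            out[4] = is_icd
            out[5] = cc
            out[6] = comp_to
            return True
        if code == _EV_ZCAP:
            # end cap of a cell: membrane between a cell and its periodic copy
            sign = 1.0 if dz * c - dx * s >= 0.0 else -1.0  # local z direction? see below
            # local z axis in global coords is (s_dir) R_y(theta) applied to (0,0,1):
            # global = (sin(theta), 0, cos(theta)) with our rotation convention
            ngx = s * sign
            ngy = 0.0
            ngz = c * sign
            if ngx * dx + ngy * dy + ngz * dz < 0.0:
                ngx, ngy, ngz = -ngx, -ngy, -ngz
            out[0] = tg
            out[1] = ngx
            out[2] = ngy
            out[3] = ngz
            out[4] = 1.0  # caps carry the ICD permeability
            out[5] = cc
            out[6] = cc  # the periodic copy of the same cell
            return True
        if code == _EV_ROW:
            # nudge past the row plane and re-locate
            step = _NUDGE / max(abs(dy), 1e-300)
            tg2 = tg + min(step, 1.0 - tg)
            nx_ = px + tg2 * dx
            ny_ = py + tg2 * dy
            nz_ = pz + tg2 * dz
            newc = locate_point(
                nx_, ny_, nz_,
                vx, vy, poly_off, cp_off, cp_idx, ce_off, ce_poly, ce_vert, params, iparams,
            )
            if (newc >= 0) != (cc >= 0):
                ngy = 1.0 if dy > 0.0 else -1.0
                out[0] = tg
                out[1] = 0.0
                out[2] = ngy
                out[3] = 0.0
                out[4] = 0.0
                out[5] = cc
                out[6] = newc
                return True
            cc = newc
            cx, cy, cz = nx_, ny_, nz_
            t0 = tg2
            continue
        # wrap events: advance slightly past the plane and continue
        adv = _NUDGE / max(np.sqrt(dx * dx + dy * dy + dz * dz), 1e-300)
        tg2 = tg + min(adv, 1.0 - tg)
        cx = px + tg2 * dx
        cy = py + tg2 * dy
        cz = pz + tg2 * dz
        t0 = tg2
    return False
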