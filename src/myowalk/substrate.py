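"""Synthetic periodic cardiomyocyte substrate: generation, morphing, queries.

The tissue model is a block of extruded polygonal cardiomyocyte
cross-sections (XY plane, long axis along Z) tiled periodically over all
space.  Each Y row of blocks is rigidly rotated about the Y axis to emulate
the transmural helix-angle variation, and alternate rows may be shifted half
a block along Z to break up long straight extracellular channels.

Cross-sections are produced as Voronoi cells of a jittered hexagonal point
lattice, made periodic by ghost replication, clipped to the block, and offset
inward so the gaps form a connected extracellular space.  The extracellular
volume fraction (ECV) is then tuned by a uniform polygon offset.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from . import _geometry as geom

#: gap applied to the raw Voronoi partition so the ECS is connected (um)
_RAW_GAP = 0.75


@dataclass(frozen=True)
class CrossSectionSet:
    """Cardiomyocyte cross-section polygons within an Lx-by-Ly block."""

    polygons: tuple[Polygon, ...]
    cell_ids: tuple[int, ...]
    Lx: float
    Ly: float

    def __post_init__(self):
        if len(self.polygons) != len(self.cell_ids):
            raise ValueError("one cell id per polygon required")
        for p in self.polygons:
            if not p.is_valid or p.is_empty:
                raise ValueError("cross-section polygons must be valid and non-empty")

    @property
    def cell_area(self) -> float:
        return float(sum(p.area for p in self.polygons))

    @property
    def ecv(self) -> float:
        """Extracellular volume (area) fraction of the block."""
        return 1.0 - self.cell_area / (self.Lx * self.Ly)


@dataclass(frozen=True)
class TissueBlock:
    """One periodic tissue block: cross-sections extruded along Z."""

    cross_sections: CrossSectionSet
    Lz: float = 127.0
    icd_depth: float = 2.0  # low-permeability end-cap extension (um)

    def __post_init__(self):
        if self.Lz <= 0:
            raise ValueError("Lz must be positive")
        if not 0 <= self.icd_depth < self.Lz / 2:
            raise ValueError("icd_depth must satisfy 0 <= icd_depth < Lz/2")


@dataclass(frozen=True)
class Substrate:
    """Periodic, helix-rotated tiling of a tissue block plus voxel geometry."""

    block: TissueBlock
    ha_rate: float = 10.0  # deg/mm rotation about Y, per block row
    voxel: tuple[float, float, float] = (2800.0, 2800.0, 8000.0)
    buffer: float = 0.0  # seeding margin around the voxel (um)
    half_shift: bool = True

    _compiled: object = field(default=None, compare=False, repr=False)

    def compiled(self):
        """Flat-array geometry tables consumed by the numba kernels."""
        if self._compiled is None:
            object.__setattr__(self, "_compiled", _compile(self))
        return self._compiled


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def generate_cross_sections(
    n_cells: int,
    mean_diameter: float = 18.0,
    jitter: float = 0.35,
    seed: int = 0,
) -> CrossSectionSet:
    """Histology-like packing of convex polygonal cell cross-sections.

    Voronoi cells of a jittered hexagonal lattice, made periodic in the
    block, clipped and offset inward so the gaps form a connected
    extracellular sheet.  Reproducible for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if mean_diameter <= 0:
        raise ValueError("mean_diameter must be positive")
    rng = np.random.default_rng(seed)
    a = mean_diameter  # lattice spacing ~ flat-to-flat hexagon width
    nx = int(np.ceil(np.sqrt(n_cells)))
    ny = int(np.ceil(n_cells / nx))
    Lx, Ly = nx * a, ny * a * np.sqrt(3.0) / 2.0

    pts = []
    for j in range(ny):
        for i in range(nx):
            x = (i + 0.5 * (j % 2)) * a
            y = (j + 0.5) * a * np.sqrt(3.0) / 2.0
            pts.append((x % Lx, y % Ly))
    pts = np.array(pts[: nx * ny])
    pts += rng.uniform(-0.5, 0.5, pts.shape) * (jitter * a)
    pts[:, 0] %= Lx
    pts[:, 1] %= Ly

    # periodic ghosts: replicate the lattice in the 8 neighbouring blocks
    ghosts = [pts]
    for dx in (-Lx, 0.0, Lx):
        for dy in (-Ly, 0.0, Ly):
            if dx == 0.0 and dy == 0.0:
                continue
            ghosts.append(pts + np.array([dx, dy]))
    allpts = np.vstack(ghosts)

    vor = Voronoi(allpts)
    clip = box(0.0, 0.0, Lx, Ly)
    polys, ids = [], []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # unbounded: cannot happen with ghosts
            continue
        cell = Polygon(vor.vertices[region]).intersection(clip)
        cell = cell.buffer(-_RAW_GAP, join_style=2)
        if cell.is_empty:
            continue
        pieces = [cell] if cell.geom_type == "Polygon" else list(cell.geoms)
        for piece in pieces:
            if piece.area > 1e-6:
                polys.append(Polygon(piece.exterior))
                ids.append(len(ids))
    cs = CrossSectionSet(tuple(polys), tuple(ids), Lx, Ly)
    if cs.ecv < 0.02:
        raise ValueError("requested density geometrically infeasible (ECV < 2%)")
    return cs


def morph_ecv(cs: CrossSectionSet, target_ecv: float, tol: float = 1e-3) -> CrossSectionSet:
    """Uniformly offset all cross-sections until the block ECV hits target.

    Binary search on a signed offset distance (negative shrinks the cells,
    raising ECV).  Raises if the target is infeasible: cells vanishing on
    shrink, or neighbouring cells merging on growth.
    """
    if not 0.0 < target_ecv < 1.0:
        raise ValueError("target_ecv must lie in (0, 1)")
    if abs(cs.ecv - target_ecv) <= tol:
        return cs
    area_box = cs.Lx * cs.Ly

    def offset(d: float) -> list[Polygon] | None:
        out = []
        for p in cs.polygons:
            q = p.buffer(d, join_style=2)
            if q.is_empty or q.geom_type != "Polygon" or q.area <= 1e-9:
                return None
            out.append(Polygon(q.exterior))
        return out

    def ecv_of(polys) -> float:
        return 1.0 - sum(p.area for p in polys) / area_box

    # bracket the offset
    grow = target_ecv < cs.ecv
    lo, hi = 0.0, (1.0 if grow else -1.0)
    for _ in range(60):
        polys = offset(hi)
        if polys is None:
            raise ValueError(f"target ECV {target_ecv} infeasible (cells vanish or merge)")
        if (ecv_of(polys) < target_ecv) == grow:
            break
        hi *= 2.0
        if abs(hi) > 0.45 * min(cs.Lx, cs.Ly):
            raise ValueError(f"target ECV {target_ecv} infeasible for this packing")
    else:
        raise AssertionError("unreachable")

    for _ in range(80):
        mid = 0.5 * (lo + hi)
        polys = offset(mid)
        if polys is None:
            hi = mid
            continue
        e = ecv_of(polys)
        if abs(e - target_ecv) <= tol:
            if grow and _overlapping(polys):
                raise ValueError(f"target ECV {target_ecv} would merge cells")
            return replace(cs, polygons=tuple(polys))
        if (e < target_ecv) == grow:
            hi = mid
        else:
            lo = mid
    raise ValueError(f"ECV binary search failed to converge to {target_ecv}")


def _overlapping(polys) -> bool:
    total = sum(p.area for p in polys)
    union = unary_union(polys).area
    amin = min(p.area for p in polys)
    return (total - union) > 1e-6 * amin


def build_substrate(
    block: TissueBlock,
    voxel: tuple[float, float, float] = (2800.0, 2800.0, 8000.0),
    ha_rate: float = 10.0,
    half_shift: bool = True,
    buffer: float = 0.0,
) -> Substrate:
    """Assemble the periodic substrate around a voxel centred at the origin."""
    return Substrate(block=block, ha_rate=ha_rate, voxel=tuple(voxel),
                     half_shift=half_shift, buffer=buffer)


def default_buffer(D_ecs: float, T: float) -> float:
    """Seeding margin 4*sqrt(2*D*T): bounds walker in/out-flux bias."""
    return 4.0 * np.sqrt(2.0 * D_ecs * T)


# ----------------------------------------------------------------------
# plain-text geometry format
# ----------------------------------------------------------------------

def save_block(blk: TissueBlock, path) -> None:
    """Write "Lx Ly Lz icd_depth" header plus one polygon per line."""
    cs = blk.cross_sections
    with open(path, "w") as fh:
        fh.write("# myowalk substrate v1\n")
        fh.write(f"{cs.Lx:.9g} {cs.Ly:.9g} {blk.Lz:.9g} {blk.icd_depth:.9g}\n")
        for pid, poly in zip(cs.cell_ids, cs.polygons):
            xy = np.asarray(poly.exterior.coords)[:-1]  # drop closing vertex
            coords = " ".join(f"{v:.9g}" for v in xy.ravel())
            fh.write(f"{pid} {len(xy)} {coords}\n")


def load_block(path) -> TissueBlock:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    Lx, Ly, Lz, icd = (float(v) for v in lines[0].split())
    polys, ids = [], []
    for ln in lines[1:]:
        parts = ln.split()
        pid, n = int(parts[0]), int(parts[1])
        vals = np.array([float(v) for v in parts[2 : 2 + 2 * n]]).reshape(n, 2)
        polys.append(Polygon(vals))
        ids.append(pid)
    cs = CrossSectionSet(tuple(polys), tuple(ids), Lx, Ly)
    return TissueBlock(cs, Lz=Lz, icd_depth=icd)


# ----------------------------------------------------------------------
# queries (thin wrappers over the numba kernels)
# ----------------------------------------------------------------------

ECS = -1  # compartment code for the extracellular space


@dataclass(frozen=True)
class MembraneHit:
    """First membrane crossing along a step segment."""

    position: np.ndarray  # global coordinates (um)
    normal: np.ndarray  # unit normal, global frame
    kind: str  # "sarcolemma" | "ICD"
    comp_from: int  # ECS (-1) or cell index
    comp_to: int
    t: float  # parametric position along the step in (0, 1]
    delta_x: float  # |(p0 - position) . normal|


def locate(s: Substrate, p) -> int:
    """Compartment at a point: ECS (-1) or the cell (polygon) index.

    Points exactly on a membrane resolve to ECS by convention.
    """
    g = s.compiled()
    p = np.asarray(p, dtype=float)
    return int(geom.locate_point(p[0], p[1], p[2], *g))


def intersect_segment(s: Substrate, p0, p1) -> MembraneHit | None:
    """Earliest membrane crossing on the segment p0 -> p1, if any."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("p0 and p1 must differ")
    g = s.compiled()
    comp = geom.locate_point(p0[0], p0[1], p0[2], *g)
    out = np.empty(9)
    found = geom.first_membrane_hit(
        p0[0], p0[1], p0[2], p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2],
        comp, out, *g,
    )
    if not found:
        return None
    t = out[0]
    pos = p0 + t * (p1 - p0)
    normal = out[1:4].copy()
    kind = "ICD" if out[4] > 0.5 else "sarcolemma"
    comp_from, comp_to = int(out[5]), int(out[6])
    dx = abs(float(np.dot(p0 - pos, normal)))
    return MembraneHit(pos, normal, kind, comp_from, comp_to, float(t), dx)


def ecv_mc_estimate(s: Substrate, n: int = 100_000, seed: int = 0) -> float:
    """Monte Carlo ECS fraction over the voxel (cross-check against areas)."""
    rng = np.random.default_rng(seed)
    v = np.array(s.voxel)
    pts = rng.uniform(-0.5, 0.5, (n, 3)) * v
    g = s.compiled()
    hits = sum(1 for p in pts if geom.locate_point(p[0], p[1], p[2], *g) == ECS)
    return hits / n


# ----------------------------------------------------------------------
# compilation to flat arrays
# ----------------------------------------------------------------------

def _compile(s: Substrate):
    """Pack polygons + a uniform acceleration grid into numba-ready arrays."""
    cs = s.block.cross_sections
    Lx, Ly = cs.Lx, cs.Ly
    vx_list, vy_list, off = [], [], [0]
    for poly in cs.polygons:
        xy = np.asarray(poly.exterior.coords)[:-1]
        # enforce counter-clockwise orientation for consistent outward normals
        if Polygon(xy).exterior.is_ccw is False:
            xy = xy[::-1]
        vx_list.append(xy[:, 0])
        vy_list.append(xy[:, 1])
        off.append(off[-1] + len(xy))
    vx = np.concatenate(vx_list) if vx_list else np.zeros(0)
    vy = np.concatenate(vy_list) if vy_list else np.zeros(0)
    poly_off = np.array(off, dtype=np.int64)
    npoly = len(cs.polygons)

    # uniform grid sized to the typical cell
    target = max(4.0, np.sqrt(Lx * Ly / max(npoly, 1)) / 2.0)
    gnx = max(1, int(round(Lx / target)))
    gny = max(1, int(round(Ly / target)))
    gdx, gdy = Lx / gnx, Ly / gny

    cell_polys = [[] for _ in range(gnx * gny)]
    cell_edges = [[] for _ in range(gnx * gny)]
    for pi, poly in enumerate(cs.polygons):
        xs = vx[poly_off[pi] : poly_off[pi + 1]]
        ys = vy[poly_off[pi] : poly_off[pi + 1]]
        ix0 = max(0, int(np.floor(xs.min() / gdx)))
        ix1 = min(gnx - 1, int(np.floor(xs.max() / gdx)))
        iy0 = max(0, int(np.floor(ys.min() / gdy)))
        iy1 = min(gny - 1, int(np.floor(ys.max() / gdy)))
        for iy in range(iy0, iy1 + 1):
            for ix in range(ix0, ix1 + 1):
                cell_polys[iy * gnx + ix].append(pi)
        n = len(xs)
        for e in range(n):
            x0, y0 = xs[e], ys[e]
            x1, y1 = xs[(e + 1) % n], ys[(e + 1) % n]
            jx0 = max(0, int(np.floor(min(x0, x1) / gdx)))
            jx1 = min(gnx - 1, int(np.floor(max(x0, x1) / gdx)))
            jy0 = max(0, int(np.floor(min(y0, y1) / gdy)))
            jy1 = min(gny - 1, int(np.floor(max(y0, y1) / gdy)))
            for iy in range(jy0, jy1 + 1):
                for ix in range(jx0, jx1 + 1):
                    cell_edges[iy * gnx + ix].append((pi, poly_off[pi] + e))

    def _csr(lists, width):
        offs = np.zeros(len(lists) + 1, dtype=np.int64)
        for i, l in enumerate(lists):
            offs[i + 1] = offs[i] + len(l)
        flat = np.zeros((offs[-1], width), dtype=np.int64)
        k = 0
        for l in lists:
            for item in l:
                flat[k] = item
                k += 1
        return offs, flat

    cp_off, cp_idx = _csr(cell_polys, 1)
    ce_off, ce_flat = _csr(cell_edges, 2)

    params = np.array(
        [
            Lx,
            Ly,
            s.block.Lz,
            s.block.icd_depth,
            np.deg2rad(s.ha_rate) * 1e-3,  # rad per um of depth
            gdx,
            gdy,
        ]
    )
    iparams = np.array([gnx, gny, 1 if s.half_shift else 0], dtype=np.int64)
    return (
        vx,
        vy,
        poly_off,
        cp_off,
        cp_idx[:, 0].copy(),
        ce_off,
        ce_flat[:, 0].copy(),
        ce_flat[:, 1].copy(),
        params,
        iparams,
    )
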