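"""Random-walk diffusion engine with permeable membranes and phase encoding.

Walkers take fixed-size steps whose Cartesian components are +/- sqrt(2 D dt)
with independent fair signs, scaled by the local (intra- or extracellular)
diffusivity.  Membrane encounters are resolved with the hybrid transit model:
the membrane barrier probability

    p_b = 2 kappa dx / (D_ICS + 2 kappa dx)

(dx the start-of-step distance to the membrane along its normal) combined,
for ECS->ICS transits only, with a diffusivity-step factor
p_d = (D_ICS/D_ECS)**pd_exponent.  A failed transit reflects the remaining
displacement specularly; a successful transit rescales the remaining length
by sqrt(D_to/D_from) when the compartment diffusivity changes.

Phase is accumulated per encoding direction with the midpoint rule using a
*normalized* gradient amplitude, so a single trajectory yields signals for
any Gmax (and hence any b-value) of the same waveform shape.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from . import _geometry as geom
from .sequences import GradientWaveform, SequenceSpec, make_waveform, solve_gmax
from .substrate import ECS, Substrate
from .tensorfit import SIX_DIRECTIONS


@dataclass(frozen=True)
class WalkConfig:
    """Particle counts, diffusivities (um^2/ms) and permeabilities (um/ms)."""

    n_walkers: int = 100_000
    n_steps: int = 10_000
    D_ics: float = 1.0
    D_ecs: float = 2.5
    kappa_sarco: float = 0.0
    kappa_icd: float | None = None  # None: same as the sarcolemma
    pd_exponent: float = 1.0  # diffusivity-step factor (D_ICS/D_ECS)**e
    seed: int = 0
    max_substeps: int = 50

    def __post_init__(self):
        if self.n_walkers < 1 or self.n_steps < 1:
            raise ValueError("n_walkers and n_steps must be positive")
        if self.D_ics <= 0 or self.D_ecs <= 0:
            raise ValueError("diffusivities must be positive")
        if self.kappa_sarco < 0 or (self.kappa_icd is not None and self.kappa_icd < 0):
            raise ValueError("permeabilities must be non-negative")

    @property
    def kappa_icd_eff(self) -> float:
        return self.kappa_sarco if self.kappa_icd is None else self.kappa_icd


@dataclass
class WalkerEnsemble:
    """Positions (um), compartment codes (-1 = ECS) and phase accumulators."""

    X: np.ndarray  # (Np, 3)
    comp: np.ndarray  # (Np,) int64
    A: np.ndarray | None = None  # (Np, ndir) normalized phase integrals
    inside: np.ndarray | None = None
    overflow: int = 0


def propose_step(rng: np.random.Generator, D_local: float, dt: float, n: int = 1) -> np.ndarray:
    """Displacement proposals: components are +/- sqrt(2 D dt), fair signs."""
    step = np.sqrt(2.0 * D_local * dt)
    signs = rng.integers(0, 2, size=(n, 3)) * 2 - 1
    out = signs * step
    return out[0] if n == 1 else out


def transit_probability(
    kappa: float,
    delta_x: float,
    D_ics: float,
    D_ecs: float,
    ecs_to_ics: bool,
    pd_exponent: float = 1.0,
) -> float:
    """Hybrid transit probability p_t for one membrane encounter."""
    if delta_x <= 0:
        raise ValueError("delta_x must be positive")
    dx = max(delta_x, 1e-6)
    pb = 2.0 * kappa * dx / (D_ics + 2.0 * kappa * dx)
    if ecs_to_ics:
        pb *= (D_ics / D_ecs) ** pd_exponent
    return pb


def accumulate_phase(positions: np.ndarray, w: GradientWaveform, dt: float,
                     direction=None) -> float:
    """Midpoint-rule phase (rad) for one trajectory sampled every dt.

    positions has shape (Nt + 1, 3); the gradient is evaluated at interval
    midpoints against the mean of the interval's endpoint positions, the
    same quadrature the ensemble kernel uses.
    """
    X = np.asarray(positions, dtype=float)
    e_g = w.direction if direction is None else np.asarray(direction, float)
    e_g = e_g / np.linalg.norm(e_g)
    nt = X.shape[0] - 1
    tmid = (np.arange(nt) + 0.5) * dt
    gmid = w.g(tmid)
    proj = 0.5 * (X[:-1] + X[1:]) @ e_g
    return float(w.gamma * np.sum(proj * gmid) * dt)


def seed_walkers(s: Substrate, cfg: WalkConfig, rng=None) -> WalkerEnsemble:
    """Uniform walker positions over the voxel plus the buffer margin."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ext = np.array(s.voxel) + 2.0 * s.buffer
    X = rng.uniform(-0.5, 0.5, (cfg.n_walkers, 3)) * ext
    comp = np.empty(cfg.n_walkers, dtype=np.int64)
    _locate_batch(X, comp, *s.compiled())
    return WalkerEnsemble(X, comp)


@njit
def _locate_batch(X, out, vx, vy, poly_off, cp_off, cp_idx, ce_off, ce_poly, ce_vert,
                  params, iparams):
    for i in range(X.shape[0]):
        out[i] = geom.locate_point(
            X[i, 0], X[i, 1], X[i, 2],
            vx, vy, poly_off, cp_off, cp_idx, ce_off, ce_poly, ce_vert, params, iparams,
        )


# ----------------------------------------------------------------------
# walker advance with membranes (single step)
# ----------------------------------------------------------------------

@njit
def _advance(
    p, comp, rx, ry, rz,
    D_ics, D_ecs, kappa_s, kappa_i, pd_factor, max_sub,
    skey, ctr0, out_hit,
    vx, vy, poly_off, cp_off, cp_idx, ce_off, ce_poly, ce_vert, params, iparams,
):
    """Advance one walker by the displacement (rx, ry, rz) in place.

    Returns (compartment, substeps used, rng draws used, overflow flag).
    """
    sx, sy, sz = p[0], p[1], p[2]  # step start, defines delta_x
    ctr = ctr0
    nsub = 0
    while nsub < max_sub:
        nsub += 1
        hit = geom.first_membrane_hit(
            p[0], p[1], p[2], rx, ry, rz, comp, out_hit,
            vx, vy, poly_off, cp_off, cp_idx, ce_off, ce_poly, ce_vert, params, iparams,
        )
        if not hit:
            p[0] += rx
            p[1] += ry
            p[2] += rz
            return comp, nsub, ctr - ctr0, 0
        t = out_hit[0]
        nx, ny, nz = out_hit[1], out_hit[2], out_hit[3]
        is_icd = out_hit[4] > 0.5
        comp_to = int(out_hit[6])
        hx = p[0] + t * rx
        hy = p[1] + t * ry
        hz = p[2] + t * rz

        dx_start = abs((sx - hx) * nx + (sy - hy) * ny + (sz - hz) * nz)
        if dx_start < 1e-6:
            dx_start = 1e-6
        kap = kappa_i if is_icd else kappa_s
        pb = 2.0 * kap * dx_start / (D_ics + 2.0 * kap * dx_start)
        if comp < 0 and comp_to >= 0:
            pb *= pd_factor

        u = geom.rng_uniform(skey, ctr)
        ctr += 1
        remx = (1.0 - t) * rx
        remy = (1.0 - t) * ry
        remz = (1.0 - t) * rz
        if u < pb:
            # cross; rescale the remaining length if diffusivity changes
            if (comp >= 0) != (comp_to >= 0):
                D_from = D_ics if comp >= 0 else D_ecs
                D_to = D_ics if comp_to >= 0 else D_ecs
                fct = np.sqrt(D_to / D_from)
                remx *= fct
                remy *= fct
                remz *= fct
            comp = comp_to
            p[0] = hx + 1e-6 * nx
            p[1] = hy + 1e-6 * ny
            p[2] = hz + 1e-6 * nz
        else:
            # specular reflection about the membrane plane
            dot = remx * nx + remy * ny + remz * nz
            remx -= 2.0 * dot * nx
            remy -= 2.0 * dot * ny
            remz -= 2.0 * dot * nz
            p[0] = hx - 1e-6 * nx
            p[1] = hy - 1e-6 * ny
            p[2] = hz - 1e-6 * nz
        rx, ry, rz = remx, remy, remz
        if rx * rx + ry * ry + rz * rz < 1e-18:
            return comp, nsub, ctr - ctr0, 0
    return comp, nsub, ctr - ctr0, 1


def advance_with_membranes(s: Substrate, cfg: WalkConfig, position, comp, displacement,
                           u_stream=None, seed: int = 0):
    """Python-level single-walker advance (unit-test surface).

    Returns (new_position, new_compartment, overflowed).
    """
    p = np.asarray(position, dtype=float).copy()
    d = np.asarray(displacement, dtype=float)
    out_hit = np.empty(9)
    pdf = (cfg.D_ics / cfg.D_ecs) ** cfg.pd_exponent
    skey = geom.walker_key(seed, 0)
    c, _, _, ov = _advance(
        p, int(comp), d[0], d[1], d[2],
        cfg.D_ics, cfg.D_ecs, cfg.kappa_sarco, cfg.kappa_icd_eff, pdf, cfg.max_substeps,
        skey, 0, out_hit, *s.compiled(),
    )
    return p, int(c), bool(ov)


# ----------------------------------------------------------------------
# full ensemble walk
# ----------------------------------------------------------------------

@njit
def _walk_kernel(
    X, comp, A, hmid, dirs, dt,
    D_ics, D_ecs, kappa_s, kappa_i, pd_factor, max_sub, seed,
    vx, vy, poly_off, cp_off, cp_idx, ce_off, ce_poly, ce_vert, params, iparams,
):
    Np = X.shape[0]
    Nt = hmid.shape[0]
    ndir = dirs.shape[0]
    free = poly_off.shape[0] <= 1
    overflow = 0
    p = np.empty(3)
    out_hit = np.empty(9)
    for i in range(Np):
        wkey = geom.walker_key(seed, i)
        p[0] = X[i, 0]
        p[1] = X[i, 1]
        p[2] = X[i, 2]
        c = comp[i]
        for n in range(Nt):
            D = D_ics if c >= 0 else D_ecs
            step = np.sqrt(2.0 * D * dt)
            skey = geom.step_key(wkey, n)
            bits = geom._splitmix64(skey)
            rx = step if (bits & np.uint64(1)) else -step
            ry = step if (bits & np.uint64(2)) else -step
            rz = step if (bits & np.uint64(4)) else -step
            ox, oy, oz = p[0], p[1], p[2]
            if free:
                p[0] += rx
                p[1] += ry
                p[2] += rz
            else:
                c, _, _, ov = _advance(
                    p, c, rx, ry, rz,
                    D_ics, D_ecs, kappa_s, kappa_i, pd_factor, max_sub,
                    skey, 1, out_hit,
                    vx, vy, poly_off, cp_off, cp_idx, ce_off, ce_poly, ce_vert,
                    params, iparams,
                )
                overflow += ov
            h = hmid[n]
            if h != 0.0:
                mx = 0.5 * (ox + p[0])
                my = 0.5 * (oy + p[1])
                mz = 0.5 * (oz + p[2])
                w = h * dt
                for j in range(ndir):
                    A[i, j] += (mx * dirs[j, 0] + my * dirs[j, 1] + mz * dirs[j, 2]) * w
        X[i, 0] = p[0]
        X[i, 1] = p[1]
        X[i, 2] = p[2]
        comp[i] = c
    return overflow


def run_walk(
    s: Substrate,
    cfg: WalkConfig,
    waveform: GradientWaveform,
    directions: np.ndarray | None = None,
) -> WalkerEnsemble:
    """Propagate the ensemble and accumulate normalized phase integrals.

    The accumulators A (um*ms) are per encoding direction and independent of
    Gmax: the physical phase is gamma * Gmax * A, so one trajectory serves
    every b-value of the same waveform shape.
    """
    if directions is None:
        directions = SIX_DIRECTIONS
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)

    ens = seed_walkers(s, cfg)
    Nt = cfg.n_steps
    dt = waveform.T / Nt
    tmid = (np.arange(Nt) + 0.5) * dt
    hmid = waveform.g(tmid) / waveform.gmax
    A = np.zeros((cfg.n_walkers, directions.shape[0]))
    pdf = (cfg.D_ics / cfg.D_ecs) ** cfg.pd_exponent
    overflow = _walk_kernel(
        ens.X, ens.comp, A, hmid, directions, dt,
        cfg.D_ics, cfg.D_ecs, cfg.kappa_sarco, cfg.kappa_icd_eff, pdf,
        cfg.max_substeps, cfg.seed, *s.compiled(),
    )
    half = 0.5 * np.array(s.voxel)
    inside = np.all(np.abs(ens.X) <= half, axis=1)
    return WalkerEnsemble(ens.X, ens.comp, A, inside, int(overflow))


def signals_from_walk(
    ens: WalkerEnsemble,
    waveform: GradientWaveform,
    directions: np.ndarray,
    b_values,
) -> pd.DataFrame:
    """Normalized diffusion signals for each (direction, b) combination."""
    directions = np.atleast_2d(directions)
    rows = []
    A = ens.A[ens.inside]
    n_in = int(ens.inside.sum())
    for b in np.atleast_1d(b_values):
        if b == 0.0:
            for d in directions:
                rows.append((waveform.kind, 0.0, d[0], d[1], d[2], 1.0, n_in))
            continue
        gmax_b = solve_gmax(waveform, float(b))
        phi = waveform.gamma * gmax_b * A
        S = np.abs(np.exp(-1j * phi).mean(axis=0))
        for j, d in enumerate(directions):
            rows.append((waveform.kind, float(b), d[0], d[1], d[2], float(S[j]), n_in))
    return pd.DataFrame(
        rows, columns=["sequence", "b", "gx", "gy", "gz", "S_over_S0", "n_walkers"]
    )


def run_diffusion(
    s: Substrate,
    cfg: WalkConfig,
    spec: SequenceSpec | GradientWaveform,
    directions: np.ndarray | None = None,
    b_values=(0.15, 0.6),
) -> pd.DataFrame:
    """Full diffusion experiment: walk once, read out signals at each b."""
    w = make_waveform(spec) if isinstance(spec, SequenceSpec) else spec
    if directions is None:
        directions = SIX_DIRECTIONS
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    ens = run_walk(s, cfg, w, directions)
    return signals_from_walk(ens, w, directions, b_values)
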