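"""Microvascular perfusion signal from spins on anisotropic capillary paths.

Each perfusing spin travels at a constant (per-spin) speed along a chain of
straight capillary segments.  Segment orientations follow a hemispherical
Dimroth-Watson axial distribution about the local cardiomyocyte long axis
(density proportional to sin(theta) * exp(2K cos^2 theta), K >= 0 the
anisotropy concentration), azimuths are uniform, and segment lengths follow
a Weibull law parameterized by its mean and standard deviation.  Speeds are
drawn once per spin from a truncated Gaussian, so a spin may travel slowly,
quickly, or (slightly) backwards, but never changes speed mid-encoding.

The spin phase for a piecewise-straight path under an effective gradient
G(t) = Gmax * h(t/T) * e_g follows from integrating Eq. phi = gamma *
int X(t).G(t) dt by parts (m0(1) = 0 kills the boundary term):

    phi = -gamma * Gmax * v * T^2 * sum_k (e_g . e_xk) * int_{s_k-1}^{s_k} m0(s) ds

with s_k the normalized times at which the spin completes segment k.  The
integral of the normalized zeroth moment m0 is evaluated exactly on the
piecewise-polynomial waveform, so no time stepping is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gamma as gamma_fn
from scipy.stats import truncnorm

from .sequences import GradientWaveform

#: mm/s -> um/ms (1 mm/s = 1000 um / 1000 ms): numerically identical
MM_S = 1.0


@dataclass(frozen=True)
class PerfusionConfig:
    """Capillary-network and perfusing-spin parameters.

    Velocities are in mm/s (numerically equal to um/ms), lengths in um.
    """

    K: float = 3.25  # Watson anisotropy concentration
    mu_L: float = 60.0  # mean capillary segment length (um)
    sigma_L: float = 40.0  # SD of segment length (um)
    v_mean: float = 0.5  # mean capillary speed (mm/s)
    sigma_v: float = 0.001  # SD of the speed distribution (mm/s)
    v_min: float = -0.1  # truncation bounds (mm/s)
    v_max: float = 1.0
    f: float = 0.10  # perfusion (signal) fraction
    n_spins: int = 100_000
    ha_rate: float = 10.0  # helix-angle rotation, deg/mm about Y
    voxel: tuple[float, float, float] = (2800.0, 2800.0, 8000.0)
    seed: int = 0

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.mu_L <= 0 or self.sigma_L <= 0:
            raise ValueError("segment length moments must be positive")
        if self.v_min >= self.v_max:
            raise ValueError("velocity truncation bounds out of order")
        if not 0 <= self.f <= 1:
            raise ValueError("perfusion fraction must lie in [0, 1]")


# ----------------------------------------------------------------------
# elementary samplers
# ----------------------------------------------------------------------

def sample_zenith(K: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Zenith angles in [0, pi/2] from the hemispherical Watson density.

    Density proportional to sin(theta) exp(2K cos^2 theta).  Rejection
    sampling with the K=0 density (cos theta ~ U[0,1]) as proposal; the
    acceptance ratio exp(2K(x^2 - 1)) is bounded by 1.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    out = np.empty(n)
    filled = 0
    # Laplace estimate of acceptance ~ 1/(4K) for large K
    batch = max(1024, int(1.2 * n * (1 + 4.0 * K)))
    while filled < n:
        x = rng.random(batch)  # cos(theta)
        u = rng.random(batch)
        acc = x[u < np.exp(2.0 * K * (x * x - 1.0))]
        take = min(acc.size, n - filled)
        out[filled : filled + take] = acc[:take]
        filled += take
        batch = max(1024, batch // 2)
    return np.arccos(out)


def weibull_params(mu: float, sigma: float) -> tuple[float, float]:
    """Shape and scale of the Weibull law with the given mean and SD."""
    cv2 = (sigma / mu) ** 2

    def fn(k):
        g1 = gamma_fn(1.0 + 1.0 / k)
        return gamma_fn(1.0 + 2.0 / k) / g1**2 - 1.0 - cv2

    k = brentq(fn, 0.1, 50.0)
    lam = mu / gamma_fn(1.0 + 1.0 / k)
    return k, lam


def sample_lengths(cfg: PerfusionConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    k, lam = weibull_params(cfg.mu_L, cfg.sigma_L)
    return lam * rng.weibull(k, size=n)


def sample_velocity(cfg: PerfusionConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-spin constant speeds (mm/s) from a truncated Gaussian."""
    if cfg.sigma_v <= 0:
        raise ValueError("sigma_v must be positive")
    a = (cfg.v_min - cfg.v_mean) / cfg.sigma_v
    b = (cfg.v_max - cfg.v_mean) / cfg.sigma_v
    return truncnorm.rvs(a, b, loc=cfg.v_mean, scale=cfg.sigma_v, size=n, random_state=rng)


def _local_frame(theta_y: float) -> np.ndarray:
    """Orthonormal frame whose third column is the HA-rotated long axis.

    The long axis (global Z) is rotated about global Y by theta_y.
    """
    c, s = np.cos(theta_y), np.sin(theta_y)
    # columns: x', y', z' (long axis)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def sample_segment(
    cfg: PerfusionConfig, frame: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n capillary segment directions and lengths in one local frame.

    ``frame`` has the local long axis in its third column; directions are
    returned in global coordinates.
    """
    theta = sample_zenith(cfg.K, n, rng)
    alpha = rng.uniform(0.0, 2.0 * np.pi, n)
    st = np.sin(theta)
    local = np.column_stack([st * np.cos(alpha), st * np.sin(alpha), np.cos(theta)])
    return local @ frame.T, sample_lengths(cfg, n, rng)


# ----------------------------------------------------------------------
# capillary paths and phases
# ----------------------------------------------------------------------

@dataclass
class CapillaryPath:
    """Ordered straight segments plus one constant per-spin speed."""

    directions: np.ndarray  # (k, 3) unit vectors
    lengths: np.ndarray  # (k,) um
    speed: float  # mm/s (= um/ms), may be negative
    seed_position: np.ndarray = field(default_factory=lambda: np.zeros(3))


def build_path(
    cfg: PerfusionConfig, speed: float, T: float, frame: np.ndarray, rng: np.random.Generator
) -> CapillaryPath:
    """Chain segments until the path covers |v| * T plus one spare segment."""
    need = abs(speed) * T
    dirs, lens = sample_segment(cfg, frame, max(2, int(need / cfg.mu_L) + 2), rng)
    total = float(np.sum(lens))
    while total < need:
        d2, l2 = sample_segment(cfg, frame, 2, rng)
        dirs = np.vstack([dirs, d2])
        lens = np.concatenate([lens, l2])
        total += float(np.sum(l2))
    return CapillaryPath(dirs, lens, speed)


def normalized_phase(
    path: CapillaryPath, w: GradientWaveform, direction=None
) -> tuple[float | None, float]:
    """(Phi, phi): b-normalized and raw phase (rad) for one path.

    Phi = phi / (v * b * T); for v = 0 the phase is 0 and Phi undefined.
    """
    e_g = w.direction if direction is None else np.asarray(direction, float)
    e_g = e_g / np.linalg.norm(e_g)
    v = path.speed * MM_S  # um/ms
    if v == 0.0:
        return None, 0.0
    T = w.T
    proj = path.directions @ e_g
    t_bounds = np.concatenate([[0.0], np.cumsum(path.lengths)]) / abs(v)
    s_bounds = np.clip(t_bounds / T, 0.0, 1.0)
    phi = 0.0
    for k in range(len(path.lengths)):
        s0, s1 = s_bounds[k], s_bounds[k + 1]
        if s1 <= s0:
            if s0 >= 1.0:
                break
            continue
        phi += proj[k] * w.m0_integral(s0, s1)
    phi *= -w.gamma * w.gmax * v * T * T
    b = w.b_value()
    Phi = phi / (v * b * T)
    return Phi, phi


def _phases(
    cfg: PerfusionConfig, w: GradientWaveform, direction, rng: np.random.Generator
) -> np.ndarray:
    """Raw perfusion phases for n_spins independent spins (vectorized).

    Spins are seeded uniformly on the voxel face at z = 0; each spin's local
    frame is fixed by the helix angle at its seed Y position.
    """
    e_g = np.asarray(direction, float)
    e_g = e_g / np.linalg.norm(e_g)
    n = cfg.n_spins
    T = w.T
    if w.gmax == 0.0:  # b = 0: no encoding, no phase
        return np.zeros(n)

    speeds = sample_velocity(cfg, n, rng) * MM_S
    y_seed = rng.uniform(-0.5 * cfg.voxel[1], 0.5 * cfg.voxel[1], n)
    theta_y = np.deg2rad(cfg.ha_rate * 1e-3) * y_seed  # deg/mm * um

    cs, sn = np.cos(theta_y), np.sin(theta_y)
    need = np.abs(speeds) * T
    # number of segments per spin: generous so running out is essentially
    # impossible (mean need/mu plus a wide Gaussian margin), verified below
    m = float(np.max(need)) / cfg.mu_L
    k_seg = int(np.ceil(m + 5.0 * (cfg.sigma_L / cfg.mu_L) * np.sqrt(m + 1.0))) + 4

    theta = sample_zenith(cfg.K, n * k_seg, rng).reshape(n, k_seg)
    alpha = rng.uniform(0.0, 2.0 * np.pi, (n, k_seg))
    lens = sample_lengths(cfg, n * k_seg, rng).reshape(n, k_seg)
    st = np.sin(theta)
    # local direction components; rotate about global Y into each spin frame:
    # global x = c*lx + s*lz ; global z = -s*lx + c*lz
    lx = st * np.cos(alpha)
    lz = np.cos(theta)
    gx = cs[:, None] * lx + sn[:, None] * lz
    gy = st * np.sin(alpha)
    gz = -sn[:, None] * lx + cs[:, None] * lz
    proj = gx * e_g[0] + gy * e_g[1] + gz * e_g[2]

    # normalized segment-completion times, clipped to the encoding window
    with np.errstate(divide="ignore"):
        tb = np.cumsum(lens, axis=1) / np.abs(speeds)[:, None]
    extra: dict[int, float] = {}
    short = np.flatnonzero((tb[:, -1] < T) & (speeds != 0.0))
    for i in short:  # top up the rare stragglers one by one
        frame = _local_frame(theta_y[i])
        t_last, p_list, t_list = tb[i, -1], [], []
        while t_last < T:
            d2, l2 = sample_segment(cfg, frame, 8, rng)
            for dvec, li in zip(d2, l2):
                t_last += li / abs(speeds[i])
                p_list.append(dvec @ e_g)
                t_list.append(t_last)
        proj_i = np.concatenate([proj[i], p_list])
        sb_i = np.concatenate([[0.0], np.clip(np.concatenate([tb[i], t_list]) / T, 0.0, 1.0)])
        extra[i] = float(np.dot(proj_i, np.diff(w.m0_antiderivative(sb_i))))

    sb = np.concatenate([np.zeros((n, 1)), np.clip(tb / T, 0.0, 1.0)], axis=1)
    dM = np.diff(w.m0_antiderivative(sb), axis=1)
    weighted = np.einsum("ij,ij->i", proj, dM)
    for i, val in extra.items():
        weighted[i] = val
    phis = -w.gamma * w.gmax * speeds * T * T * weighted
    phis[speeds == 0.0] = 0.0
    return phis


def perfusion_phases(
    cfg: PerfusionConfig, w: GradientWaveform, direction=None, rng=None
) -> np.ndarray:
    """Raw phases phi_i (rad) for the whole spin ensemble."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    e_g = w.direction if direction is None else direction
    return _phases(cfg, w, e_g, rng)


def run_perfusion(
    cfg: PerfusionConfig, w: GradientWaveform, direction=None, rng=None
) -> float:
    """Normalized perfusion signal |mean exp(-i phi)| for one encoding."""
    phis = perfusion_phases(cfg, w, direction, rng)
    return float(np.abs(np.mean(np.exp(-1j * phis))))
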