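"""Diffusion-encoding gradient waveforms for STEAM, PGSE and MCSE.

All waveforms are *effective* gradients: the sign flips imposed by refocusing
(or the store/recall pair of a stimulated echo) are folded into G(t), so the
spin phase is the single integral phi = gamma * int X(t).G(t) dt and the
refocusing condition is simply m0(T) = int_0^T G dt = 0.

Unit system: micrometres, milliseconds, milliTesla.  Gradient amplitudes are
stored in mT/um so that b-values come out directly in ms/um^2 with
gamma = 267.522 rad ms^-1 mT^-1 (the proton gyromagnetic ratio).  The public
constructors accept Gmax in the conventional mT/m and convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

#: Proton gyromagnetic ratio, rad ms^-1 mT^-1 (field units); with gradient
#: amplitudes in mT/um this yields b-values in ms um^-2.
GAMMA = 267.52218744

#: mT/m -> mT/um
MT_PER_M = 1e-6

_GAUSS3_X = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GAUSS3_W = np.array([5.0, 8.0, 5.0]) / 9.0


@dataclass(frozen=True)
class SequenceSpec:
    """Timing description of one diffusion-encoding sequence.

    Parameters
    ----------
    kind:
        "STEAM", "PGSE" or "MCSE".
    delta:
        Gradient flat-top duration (ms).  For MCSE this is ignored; the four
        lobe flat-tops are solved numerically from ``T_enc``.
    eps:
        Ramp-up/ramp-down time (ms).
    Delta:
        For STEAM/PGSE: separation between lobe starts (the mixing interval
        of STEAM lives inside this gap).  For MCSE: the gradient-free pause
        around the refocusing pulse, between lobes 2 and 3.
    b:
        Target b-value (ms um^-2) used when solving Gmax.
    direction:
        Unit encoding direction e_g.
    T_enc:
        Total encoding duration for MCSE (ms); ignored otherwise.
    """

    kind: str
    delta: float = 20.0
    eps: float = 1.0
    Delta: float = 30.0
    b: float = 0.6
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    T_enc: float = 70.0

    def __post_init__(self):
        if self.kind not in ("STEAM", "PGSE", "MCSE"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        if min(self.delta, self.eps) <= 0 or self.Delta <= 0:
            raise ValueError("all durations must be positive")
        if self.kind in ("STEAM", "PGSE") and self.Delta < self.delta + 2 * self.eps:
            raise ValueError("lobes overlap: Delta must exceed delta + 2*eps")


def default_spec(kind: str, b: float = 0.6) -> SequenceSpec:
    """Representative clinical timings for each sequence family."""
    if kind == "PGSE":
        return SequenceSpec("PGSE", delta=20.0, eps=1.0, Delta=30.0, b=b)
    if kind == "STEAM":
        # long mixing interval: Delta of order 1000 ms (one cardiac cycle)
        return SequenceSpec("STEAM", delta=6.0, eps=1.0, Delta=1000.0, b=b)
    if kind == "MCSE":
        return SequenceSpec("MCSE", eps=1.0, Delta=6.0, b=b, T_enc=70.0)
    raise ValueError(f"unknown sequence kind {kind!r}")


@dataclass(frozen=True)
class GradientWaveform:
    """Piecewise-linear effective gradient G(t) along a fixed direction.

    ``times`` are breakpoints (ms, starting at 0 and ending at T) and
    ``amps`` the signed amplitudes (mT/um) at those breakpoints; between
    breakpoints the amplitude is linear.
    """

    times: np.ndarray
    amps: np.ndarray
    direction: np.ndarray
    gmax: float  # mT/um
    kind: str = "custom"
    gamma: float = GAMMA

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amps, dtype=float)
        if t.ndim != 1 or t.shape != a.shape or t.size < 2:
            raise ValueError("times/amps must be matching 1-D arrays")
        if np.any(np.diff(t) < 0):
            raise ValueError("breakpoints must be non-decreasing")
        e = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(e)
        if not n > 0:
            raise ValueError("direction must be non-zero")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amps", a)
        object.__setattr__(self, "direction", e / n)

    # ------------------------------------------------------------------
    @property
    def T(self) -> float:
        """Total duration (ms)."""
        return float(self.times[-1])

    def g(self, t) -> np.ndarray:
        """Scalar effective gradient amplitude at time t (mT/um)."""
        return np.interp(t, self.times, self.amps, left=0.0, right=0.0)

    def with_direction(self, e_g) -> "GradientWaveform":
        return replace(self, direction=np.asarray(e_g, dtype=float))

    def with_gmax(self, gmax: float) -> "GradientWaveform":
        """Rescale all amplitudes so the peak equals ``gmax`` (mT/um)."""
        if self.gmax <= 0:
            raise ValueError("cannot rescale a null waveform")
        f = gmax / self.gmax
        return replace(self, amps=self.amps * f, gmax=gmax)

    # -- exact piecewise-polynomial integrals --------------------------
    def moment(self, n: int, upto: float | None = None) -> float:
        """n-th raw gradient moment  int_0^t t'^n G(t') dt'  (exact)."""
        tend = self.T if upto is None else float(upto)
        m = 0.0
        for t0, t1, a0, a1 in self._segments(tend):
            if t1 <= t0:
                continue
            slope = (a1 - a0) / (t1 - t0)
            c0 = a0 - slope * t0
            m += c0 * (t1 ** (n + 1) - t0 ** (n + 1)) / (n + 1)
            m += slope * (t1 ** (n + 2) - t0 ** (n + 2)) / (n + 2)
        return m

    def _segments(self, tend: float):
        t, a = self.times, self.amps
        for i in range(len(t) - 1):
            t0, t1 = t[i], t[i + 1]
            if t0 >= tend:
                break
            if t1 > tend:
                a1 = a[i] + (a[i + 1] - a[i]) * (tend - t0) / (t1 - t0)
                yield t0, tend, a[i], a1
                break
            yield t0, t1, a[i], a[i + 1]

    def q_at_breakpoints(self) -> np.ndarray:
        """Cumulative integral q(t_i) = int_0^{t_i} G dt at each breakpoint."""
        t, a = self.times, self.amps
        dq = 0.5 * (a[:-1] + a[1:]) * np.diff(t)
        return np.concatenate([[0.0], np.cumsum(dq)])

    def b_value(self) -> float:
        """b = gamma^2 int_0^T q(t)^2 dt, exact for piecewise-linear G.

        q is piecewise quadratic, q^2 piecewise quartic: 3-point
        Gauss-Legendre per segment is exact.
        """
        t, a = self.times, self.amps
        q = self.q_at_breakpoints()
        total = 0.0
        for i in range(len(t) - 1):
            dt = t[i + 1] - t[i]
            if dt <= 0:
                continue
            slope = (a[i + 1] - a[i]) / dt
            # local tau in [0, dt]: q(tau) = q_i + a_i tau + slope tau^2/2
            tau = 0.5 * dt * (_GAUSS3_X + 1.0)
            qv = q[i] + a[i] * tau + 0.5 * slope * tau * tau
            total += 0.5 * dt * np.dot(_GAUSS3_W, qv * qv)
        return self.gamma**2 * total

    # -- normalized profile (Eq. for the perfusion phase) ---------------
    def normalized_profile(self, s) -> tuple[np.ndarray, np.ndarray]:
        """Return (h(s), m0(s)) on normalized time s = t/T in [0, 1].

        h(s) = G(sT)/Gmax and m0(s) = int_0^s h(s') ds' = q(sT)/(Gmax*T).
        """
        if self.gmax <= 0:
            raise ValueError("normalized profile undefined for null waveform")
        s = np.asarray(s, dtype=float)
        h = self.g(s * self.T) / self.gmax
        m0 = np.array([self._q(si * self.T) for si in np.atleast_1d(s)])
        m0 = m0.reshape(s.shape) / (self.gmax * self.T)
        return h, m0

    def _q(self, t: float) -> float:
        times, a = self.times, self.amps
        q = self.q_at_breakpoints()
        i = int(np.searchsorted(times, t, side="right") - 1)
        i = max(0, min(i, len(times) - 2))
        dt = times[i + 1] - times[i]
        tau = min(max(t - times[i], 0.0), dt)
        slope = 0.0 if dt <= 0 else (a[i + 1] - a[i]) / dt
        return float(q[i] + a[i] * tau + 0.5 * slope * tau * tau)

    def m0_antiderivative(self, s) -> np.ndarray:
        """Exact M(s) = int_0^s m0(s') ds' on normalized time (vectorized).

        m0 is piecewise quadratic in s, so M is piecewise cubic; the cubic
        coefficients follow directly from the breakpoint values of G and q.
        """
        if self.gmax <= 0:
            raise ValueError("m0 undefined for null waveform")
        T = self.T
        times, a = self.times, self.amps
        q = self.q_at_breakpoints()
        # Q_i = int_0^{t_i} q dt (q quadratic per segment -> exact cubic terms)
        dt = np.diff(times)
        slopes = np.zeros_like(dt)
        np.divide(a[1:] - a[:-1], dt, out=slopes, where=dt > 0)
        dQ = q[:-1] * dt + 0.5 * a[:-1] * dt**2 + slopes * dt**3 / 6.0
        Q = np.concatenate([[0.0], np.cumsum(dQ)])

        s = np.asarray(s, dtype=float)
        t = np.clip(s, 0.0, 1.0) * T
        i = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2)
        tau = np.clip(t - times[i], 0.0, None)
        Qt = Q[i] + q[i] * tau + 0.5 * a[i] * tau**2 + slopes[i] * tau**3 / 6.0
        return Qt / (self.gmax * T * T)

    def m0_integral(self, s0: float, s1: float) -> float:
        """Exact  int_{s0}^{s1} m0(s) ds  on normalized time."""
        M = self.m0_antiderivative([s0, s1])
        return float(M[1] - M[0])


# ----------------------------------------------------------------------
# waveform construction
# ----------------------------------------------------------------------

def _trapezoid(t0: float, sign: float, delta: float, eps: float):
    return (
        [t0, t0 + eps, t0 + eps + delta, t0 + 2 * eps + delta],
        [0.0, sign, sign, 0.0],
    )


def _merge(lobes):
    times, amps = [], []
    for lt, la in lobes:
        if times and abs(lt[0] - times[-1]) < 1e-12:
            times.pop()
            amps.pop()
        times.extend(lt)
        amps.extend(la)
    return np.array(times), np.array(amps)


def _mcse_flat_tops(T_enc: float, eps: float, pause: float) -> np.ndarray:
    """Solve the four MCSE flat-top durations nulling m0, m1 and m2.

    Four trapezoidal lobes with signs (+,-,+,-), equal |G|, a gradient-free
    pause between lobes 2 and 3 (refocusing pulse), and total duration T_enc.
    """
    avail = T_enc - 8 * eps - pause
    if avail <= 0.4:
        raise ValueError("MCSE timings infeasible: no room for gradient lobes")

    def build(d):
        lobes = []
        t = 0.0
        for i, (di, s) in enumerate(zip(d, (1.0, -1.0, 1.0, -1.0))):
            lobes.append(_trapezoid(t, s, di, eps))
            t += 2 * eps + di
            if i == 1:
                t += pause
        return _merge(lobes)

    def resid(d):
        times, amps = build(d)
        w = GradientWaveform(times, amps, (0, 0, 1), gmax=1.0)
        return np.array(
            [
                w.moment(0) / T_enc,
                w.moment(1) / T_enc**2,
                w.moment(2) / T_enc**3,
                (times[-1] - T_enc) / T_enc,
            ]
        )

    x0 = np.array([0.12, 0.38, 0.38, 0.12]) * avail
    sol = least_squares(resid, x0, bounds=(0.05, avail), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-10:
        raise ValueError("MCSE lobe solution infeasible for the given timings")
    return sol.x


def make_waveform(spec: SequenceSpec, gmax: float | None = None) -> GradientWaveform:
    """Build the effective gradient waveform for a sequence spec.

    Parameters
    ----------
    gmax:
        Peak gradient in mT/um.  If None, Gmax is solved so the waveform's
        b-value equals ``spec.b``.
    """
    if spec.kind in ("STEAM", "PGSE"):
        lobes = [
            _trapezoid(0.0, 1.0, spec.delta, spec.eps),
            _trapezoid(spec.Delta, -1.0, spec.delta, spec.eps),
        ]
        times, amps = _merge(lobes)
    else:  # MCSE
        d = _mcse_flat_tops(spec.T_enc, spec.eps, spec.Delta)
        lobes = []
        t = 0.0
        for i, (di, s) in enumerate(zip(d, (1.0, -1.0, 1.0, -1.0))):
            lobes.append(_trapezoid(t, s, di, spec.eps))
            t += 2 * spec.eps + di
            if i == 1:
                t += spec.Delta
        times, amps = _merge(lobes)

    w = GradientWaveform(times, amps, spec.direction, gmax=1.0, kind=spec.kind)
    if gmax is None:
        gmax = solve_gmax(w, spec.b)
    return w.with_gmax(gmax)


def b_value(w: GradientWaveform) -> float:
    return w.b_value()


def solve_gmax(w: GradientWaveform, target_b: float) -> float:
    """Peak gradient (mT/um) giving ``target_b``; uses b proportional to Gmax^2."""
    if target_b < 0:
        raise ValueError("target_b must be non-negative")
    b1 = w.with_gmax(1.0).b_value()
    return float(np.sqrt(target_b / b1))


def gmax_mT_per_m(w: GradientWaveform) -> float:
    """Peak gradient in conventional mT/m."""
    return w.gmax / MT_PER_M
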