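"""Diffusion-tensor estimation from simulated signals.

The mono-exponential model  S(b, e_g)/S0 = exp(-b e_g^T D e_g)  is fitted by
log-linear least squares.  With a non-zero reference b-value, each encoding
direction contributes the signal ratio

    ln S(b) - ln S(bref) = -(b - bref) * e_g^T D e_g,

which absorbs any direction-independent low-b (perfusion) offset; with
bref = 0 the b = 0 sample anchors ln S0.  The design matrix maps the six
unique tensor components; six non-coplanar directions make it full rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: standard dual-gradient six-direction scheme
SIX_DIRECTIONS = np.array(
    [
        [1.0, 1.0, 0.0],
        [1.0, 0.0, 1.0],
        [0.0, 1.0, 1.0],
        [1.0, -1.0, 0.0],
        [1.0, 0.0, -1.0],
        [0.0, 1.0, -1.0],
    ]
) / np.sqrt(2.0)


@dataclass(frozen=True)
class EncodingScheme:
    """Directions plus (b, bref) defining the measurement list."""

    directions: np.ndarray = field(default_factory=lambda: SIX_DIRECTIONS.copy())
    b: float = 0.6
    bref: float = 0.15

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        object.__setattr__(self, "directions", d)
        if not 0.0 <= self.bref < self.b:
            raise ValueError("need 0 <= bref < b")
        if np.linalg.matrix_rank(_design(d)) < 6:
            raise ValueError("directions do not span the six tensor components")

    @property
    def b_values(self) -> tuple[float, ...]:
        """b-values to simulate: (bref, b) or (0, b)."""
        return (self.bref, self.b) if self.bref > 0 else (0.0, self.b)

    @property
    def n_measurements(self) -> int:
        n = len(self.directions)
        return 2 * n if self.bref > 0 else n + 1


def _design(directions: np.ndarray) -> np.ndarray:
    g = np.atleast_2d(directions)
    return np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def _tensor_from_coeffs(c: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [c[0], c[3], c[4]],
            [c[3], c[1], c[5]],
            [c[4], c[5], c[2]],
        ]
    )


@dataclass(frozen=True)
class TensorResult:
    """Symmetric tensor with eigen-metrics (descending eigenvalues)."""

    D: np.ndarray  # um^2/ms
    eigenvalues: np.ndarray  # lambda1 >= lambda2 >= lambda3
    eigenvectors: np.ndarray  # columns E1, E2, E3
    md: float
    fa: float
    residual: float
    b: float
    bref: float

    @property
    def lambda2_over_lambda3(self) -> float:
        l3 = self.eigenvalues[2]
        return float(self.eigenvalues[1] / l3) if l3 != 0 else np.inf


def combine_signals(S_diff, S_perf, f: float):
    """Weighted total signal f*S_perf + (1-f)*S_diff on matching grids."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("perfusion fraction must lie in [0, 1]")
    Sd = np.asarray(S_diff, dtype=float)
    Sp = np.asarray(S_perf, dtype=float)
    if Sd.shape != Sp.shape:
        raise ValueError("signal grids do not match")
    return f * Sp + (1.0 - f) * Sd


def tensor_metrics(eigenvalues: np.ndarray) -> tuple[float, float]:
    """(MD, FA) from eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    md = float(lam.mean())
    num = np.sqrt(((lam - md) ** 2).sum())
    den = np.sqrt((lam**2).sum())
    fa = float(np.sqrt(1.5) * num / den) if den > 0 else 0.0
    return md, fa


def fit_tensor(
    signals_b,
    signals_ref,
    scheme: EncodingScheme,
    axis=(0.0, 0.0, 1.0),
) -> TensorResult:
    """Log-linear LLS tensor fit.

    Parameters
    ----------
    signals_b:
        S/S0 at scheme.b, one per direction.
    signals_ref:
        For bref > 0: S/S0 at bref per direction.  For bref = 0: the b = 0
        signal (scalar or length-1), normally 1 in simulation.
    axis:
        Sign reference: E1 is flipped so E1 . axis >= 0.
    """
    g = scheme.directions
    Sb = np.asarray(signals_b, dtype=float)
    if Sb.shape != (len(g),):
        raise ValueError("need one b-value signal per direction")
    if np.any(Sb <= 0):
        raise ValueError("signals must be positive for a log-linear fit")
    X = _design(g)
    if scheme.bref > 0:
        Sr = np.asarray(signals_ref, dtype=float)
        if Sr.shape != (len(g),) or np.any(Sr <= 0):
            raise ValueError("need one positive reference signal per direction")
        y = -(np.log(Sb) - np.log(Sr)) / (scheme.b - scheme.bref)
    else:
        S0 = float(np.atleast_1d(np.asarray(signals_ref, dtype=float))[0])
        if S0 <= 0:
            raise ValueError("b = 0 signal must be positive")
        y = -(np.log(Sb) - np.log(S0)) / scheme.b
    coeffs, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 6:
        raise ValueError("rank-deficient encoding scheme")
    D = _tensor_from_coeffs(coeffs)
    resid = float(np.sqrt(res[0])) if res.size else float(np.linalg.norm(X @ coeffs - y))

    lam, vec = np.linalg.eigh(D)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    ax = np.asarray(axis, dtype=float)
    if np.dot(vec[:, 0], ax) < 0:
        vec[:, 0] = -vec[:, 0]
    # deterministic signs for E2/E3: first non-zero component positive
    for j in range(1, 3):
        nz = np.flatnonzero(np.abs(vec[:, j]) > 1e-12)
        if nz.size and vec[nz[0], j] < 0:
            vec[:, j] = -vec[:, j]
    md, fa = tensor_metrics(lam)
    return TensorResult(D, lam, vec, md, fa, resid, scheme.b, scheme.bref)


def fit_from_frame(df: pd.DataFrame, scheme: EncodingScheme) -> TensorResult:
    """Fit from a signals table with columns b, gx, gy, gz, S_over_S0."""
    g = scheme.directions

    def pick(b):
        sel = df[np.isclose(df["b"], b)]
        out = np.empty(len(g))
        for j, d in enumerate(g):
            m = sel[
                np.isclose(sel["gx"], d[0])
                & np.isclose(sel["gy"], d[1])
                & np.isclose(sel["gz"], d[2])
            ]
            if len(m) == 0:
                raise ValueError(f"missing measurement b={b} direction={d}")
            out[j] = float(m["S_over_S0"].iloc[0])
        return out

    Sb = pick(scheme.b)
    if scheme.bref > 0:
        Sr = pick(scheme.bref)
    else:
        zero = df[np.isclose(df["b"], 0.0)]
        Sr = np.array([float(zero["S_over_S0"].iloc[0])]) if len(zero) else np.array([1.0])
    return fit_tensor(Sb, Sr, scheme)


def synthesize_signals(D: np.ndarray, scheme: EncodingScheme) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless signals (S_b, S_ref) from a known tensor (inverse problem)."""
    g = scheme.directions
    adc = np.einsum("ij,jk,ik->i", g, np.asarray(D, dtype=float), g)
    Sb = np.exp(-scheme.b * adc)
    Sr = np.exp(-scheme.bref * adc) if scheme.bref > 0 else np.array([1.0])
    return Sb, Sr


def cone_of_uncertainty(results: list[TensorResult], which: int = 0) -> float:
    """95% cone angle (degrees) of one eigenvector across replicates.

    Mean dyadic tensor <E E^T> over replicates (sign-invariant); the cone is
    the 95th percentile of angular deviations from its principal axis.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 replicate tensors")
    vecs = np.array([r.eigenvectors[:, which] for r in results])
    dyadic = np.einsum("ni,nj->ij", vecs, vecs) / len(vecs)
    lam, v = np.linalg.eigh(dyadic)
    mean_axis = v[:, np.argmax(lam)]
    cosang = np.abs(vecs @ mean_axis).clip(0.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    return float(np.percentile(angles, 95))
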