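"""Phase velocity field estimation by variational optical flow on phase.

The phase-constancy assumption states that isophase contours propagate
between consecutive frames, giving the linearised residual

    r(x) = dphi_t(x) + u(x) * dphi/dx + w(x) * dphi/dy

per pixel, where all phase differences are circular (computed through the
argument of products of unit phasors, never by unwrapping).  The field
minimises

    E(u, w) = sum_x m(x) * rho(r(x)) + alpha * sum_edges (du^2 + dw^2)

with ``rho`` either quadratic or Charbonnier ``sqrt(r^2 + eps^2)``, ``m``
the per-pixel reliability mask, and the smoothness sum running over all
horizontal and vertical neighbour pairs.  The Euler-Lagrange equations are
solved by a red-black Gauss-Seidel fixed point with iteratively reweighted
data terms; for the quadratic penalty this converges to the exact solution
of the sparse linear system.  The problem is convex, so the coarse-to-fine
pyramid only accelerates convergence, it never changes the minimiser.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from .datatypes import FlowSettings, PhaseMovie, PhaseVelocityField

__all__ = [
    "estimate_pvf",
    "estimate_pvf_series",
    "pvf_gradient",
    "gradient_series",
    "flow_energy",
]


# ---------------------------------------------------------------------------
# circular phase differences


def _circ_spatial_gradient(P: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Wrap-aware spatial phase gradient from a unit-phasor frame.

    Central differences in the interior, one-sided at the border
    (replicate padding).
    """
    gx = np.empty(P.shape, dtype=float)
    gy = np.empty(P.shape, dtype=float)
    gx[:, 1:-1] = np.angle(P[:, 2:] * np.conj(P[:, :-2])) / 2.0
    gx[:, 0] = np.angle(P[:, 1] * np.conj(P[:, 0]))
    gx[:, -1] = np.angle(P[:, -1] * np.conj(P[:, -2]))
    gy[1:-1, :] = np.angle(P[2:, :] * np.conj(P[:-2, :])) / 2.0
    gy[0, :] = np.angle(P[1, :] * np.conj(P[0, :]))
    gy[-1, :] = np.angle(P[-1, :] * np.conj(P[-2, :]))
    return gx, gy


def _frame_terms(Pt: np.ndarray, Pt1: np.ndarray):
    """Temporal difference and mid-frame spatial gradient of the phase."""
    dt = np.angle(Pt1 * np.conj(Pt))
    Pm = Pt * np.exp(0.5j * dt)  # phasor halfway between the two frames
    gx, gy = _circ_spatial_gradient(Pm)
    return dt, gx, gy


# ---------------------------------------------------------------------------
# energy and solver


def _neighbor_sum(x: np.ndarray) -> np.ndarray:
    s = np.zeros_like(x)
    s[1:, :] += x[:-1, :]
    s[:-1, :] += x[1:, :]
    s[:, 1:] += x[:, :-1]
    s[:, :-1] += x[:, 1:]
    return s


def flow_energy(u: np.ndarray, w: np.ndarray, dt: np.ndarray, gx: np.ndarray,
                gy: np.ndarray, mask: np.ndarray, settings: FlowSettings) -> float:
    """The variational energy of a candidate field (used by the solver and
    exposed for verification)."""
    r = dt + u * gx + w * gy
    if settings.penalty == "quadratic":
        data = r[mask] ** 2
    else:
        data = np.sqrt(r[mask] ** 2 + settings.charbonnier_eps ** 2)
    smooth = 0.0
    for a in (u, w):
        smooth += np.sum((a[:, 1:] - a[:, :-1]) ** 2)
        smooth += np.sum((a[1:, :] - a[:-1, :]) ** 2)
    return float(np.sum(data) + settings.alpha * smooth)


def _solve_level(dt, gx, gy, mask, settings: FlowSettings, u0=None, w0=None):
    H, W = dt.shape
    u = np.zeros((H, W)) if u0 is None else u0.copy()
    w = np.zeros((H, W)) if w0 is None else w0.copy()
    alpha = settings.alpha
    n_nb = _neighbor_sum(np.ones((H, W)))
    rows, cols = np.mgrid[0:H, 0:W]
    colors = [((rows + cols) % 2 == 0), ((rows + cols) % 2 == 1)]
    m = mask.astype(float)
    # Stopping rule: max Euler-Lagrange residual relative to the size of
    # the data forcing term.  Unlike an energy-change rule this does not
    # plateau at sqrt(machine eps) solution error, so tiny tolerances give
    # solutions matching a direct linear solve.
    denom = max(np.abs(m * gx * dt).max(), np.abs(m * gy * dt).max(), 1e-300)

    converged = False
    for _ in range(settings.max_iters):
        # IRLS weight of the data term (fixed for one red-black sweep pair).
        if settings.penalty == "quadratic":
            psi = m
        else:
            r = dt + u * gx + w * gy
            psi = m * 0.5 / np.sqrt(r ** 2 + settings.charbonnier_eps ** 2)
        a11 = psi * gx * gx + alpha * n_nb
        a12 = psi * gx * gy
        a22 = psi * gy * gy + alpha * n_nb
        det = a11 * a22 - a12 * a12
        for color in colors:
            su = _neighbor_sum(u)
            sw = _neighbor_sum(w)
            b1 = -psi * gx * dt + alpha * su
            b2 = -psi * gy * dt + alpha * sw
            u_new = (a22 * b1 - a12 * b2) / det
            w_new = (a11 * b2 - a12 * b1) / det
            om = settings.sor_omega
            u[color] += om * (u_new[color] - u[color])
            w[color] += om * (w_new[color] - w[color])
        r = dt + u * gx + w * gy
        res_u = psi * gx * r + alpha * (n_nb * u - _neighbor_sum(u))
        res_w = psi * gy * r + alpha * (n_nb * w - _neighbor_sum(w))
        res = max(np.abs(res_u).max(), np.abs(res_w).max()) / denom
        if res <= settings.tol:
            converged = True
            break
    return u, w, converged


def _downsample_phasor(P: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    re = resize(P.real, shape, order=1, mode="edge", anti_aliasing=False,
                preserve_range=True)
    im = resize(P.imag, shape, order=1, mode="edge", anti_aliasing=False,
                preserve_range=True)
    c = re + 1j * im
    mag = np.abs(c)
    mag[mag < 1e-12] = 1.0
    return c / mag


def estimate_pvf(phase: PhaseMovie, t: int, settings: Optional[FlowSettings] = None,
                 ) -> PhaseVelocityField:
    """Estimate the phase velocity field between frames ``t`` and ``t+1``.

    The returned vector ``v = u + i*w`` points in the direction of wave
    propagation (a plane wave ``phi = k.x - omega*t`` yields the
    minimal-norm solution ``v = omega * k / |k|^2``), in pixels/frame.
    Pixels whose analytic-signal envelope is negligible are excluded from
    the data term but filled in by the smoothness term; the outermost pixel
    ring is flagged lower-confidence in ``reliability``.
    """
    settings = settings or FlowSettings()
    if t < 0 or t + 1 >= phase.n_frames:
        raise ValueError(f"frame pair ({t}, {t + 1}) out of range")
    if not (phase.valid_mask[t] and phase.valid_mask[t + 1]):
        raise ValueError(f"frame pair ({t}, {t + 1}) is masked as invalid")
    rel = phase.reliability()
    mask = rel[t] & rel[t + 1]
    if not mask.any():
        raise ValueError(f"no reliable pixels in frame pair ({t}, {t + 1})")

    Pt = np.exp(1j * phase.phase[t])
    Pt1 = np.exp(1j * phase.phase[t + 1])
    H, W = Pt.shape

    # Pyramid of shapes, coarsest first; keep every level at least 8 pixels.
    shapes: List[Tuple[int, int]] = [(H, W)]
    for _ in range(settings.n_scales - 1):
        h, w_ = shapes[-1]
        if h // 2 < 8 or w_ // 2 < 8:
            break
        shapes.append((h // 2, w_ // 2))
    shapes = shapes[::-1]

    u = w = None
    for i, shp in enumerate(shapes):
        if shp == (H, W):
            Pa, Pb = Pt, Pt1
            m = mask
        else:
            Pa = _downsample_phasor(Pt, shp)
            Pb = _downsample_phasor(Pt1, shp)
            m = resize(mask.astype(float), shp, order=0, mode="edge",
                       anti_aliasing=False, preserve_range=True) > 0.5
        dt, gx, gy = _frame_terms(Pa, Pb)
        if u is not None:
            scale_r = shp[0] / prev_shape[0]
            scale_c = shp[1] / prev_shape[1]
            u = resize(u, shp, order=1, mode="edge", anti_aliasing=False,
                       preserve_range=True) * scale_c
            w = resize(w, shp, order=1, mode="edge", anti_aliasing=False,
                       preserve_range=True) * scale_r
        u, w, converged = _solve_level(dt, gx, gy, m, settings, u, w)
        prev_shape = shp

    if not converged:
        warnings.warn(f"flow solver did not converge at frame {t} "
                      f"({settings.max_iters} iterations)", stacklevel=2)
    reliability = mask.copy()
    reliability[0, :] = reliability[-1, :] = False
    reliability[:, 0] = reliability[:, -1] = False
    return PhaseVelocityField(v=u + 1j * w, t=t, reliability=reliability,
                              converged=converged)


def estimate_pvf_series(phase: PhaseMovie, settings: Optional[FlowSettings] = None,
                        ) -> List[PhaseVelocityField]:
    """Estimate fields for every consecutive pair of valid frames."""
    settings = settings or FlowSettings()
    out = []
    for t in range(phase.n_frames - 1):
        if phase.valid_mask[t] and phase.valid_mask[t + 1]:
            out.append(estimate_pvf(phase, t, settings))
    return out


def pvf_gradient(field: PhaseVelocityField) -> float:
    """Spatial-average pixel-wise gradient magnitude of the field.

    The pixel-wise gradient stacks the central-difference derivatives of
    both velocity components; its Frobenius norm is averaged over reliable
    pixels.  Small values indicate coherent speed and direction.
    """
    n = int(field.reliability.sum())
    if n == 0:
        raise ValueError("no reliable pixels")
    uy, ux = np.gradient(field.u)
    wy, wx = np.gradient(field.w)
    norm = np.sqrt(ux ** 2 + uy ** 2 + wx ** 2 + wy ** 2)
    return float(norm[field.reliability].mean())


def gradient_series(phase: PhaseMovie, settings: Optional[FlowSettings] = None,
                    ) -> List[Tuple[int, float]]:
    """(frame, gradient-of-PVF) for every valid consecutive frame pair."""
    settings = settings or FlowSettings()
    out = []
    for t in range(phase.n_frames - 1):
        if phase.valid_mask[t] and phase.valid_mask[t + 1]:
            f = estimate_pvf(phase, t, settings)
            out.append((t, pvf_gradient(f)))
    return out
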