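"""Wave-pattern detection and classification on phase velocity fields.

Frame-level classification uses the order parameter

    vbar(t) = |sum_x v(x, t)| / (N * v0(t)),          v0 = mean speed,

which is 1 for perfectly parallel flow: frames are labelled ``standing``
when the mean speed drops 2 SDs below its time-series mean (checked
first), ``plane`` when ``vbar >= 0.85``, else ``other``.

Local complex patterns are organised around critical points of the field,
found as intersections of the bilinearly interpolated nullclines of the
two velocity components, then typed by the trace and determinant of the
Jacobian of the bilinear cell: source (Delta > 0, tau > 0), sink
(Delta > 0, tau < 0), saddle (Delta < 0); subtype node (real eigenvalues)
or focus (complex-conjugate pair).  The Poincare index is +1 for sources
and sinks and -1 for saddles; a winding-number routine verifies index
bookkeeping along arbitrary loops.  Tracking links same-type points over
consecutive frames; a detection threshold (d, r) filters tracks by
lifetime and by the minimum radius over which the local flow keeps the
type's directional signature.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import (CriticalPoint, FrameSummary, PatternTrack,
                        PhaseVelocityField, propagation_angle)

__all__ = [
    "order_parameter",
    "mean_speed",
    "mean_direction",
    "classify_frame",
    "summarize_frames",
    "find_critical_points",
    "classify_jacobian",
    "classify_critical_point",
    "poincare_index",
    "square_loop",
    "pattern_radius",
    "analyze_frame",
    "track_patterns",
    "detection_probability_surface",
    "window_sweep",
    "coexistence_census",
    "index_change_series",
]


# ---------------------------------------------------------------------------
# frame-level statistics


def _reliable_vectors(field: PhaseVelocityField) -> np.ndarray:
    vs = field.v[field.reliability]
    if vs.size == 0:
        raise ValueError("no reliable pixels in field")
    return vs


def mean_speed(field: PhaseVelocityField) -> float:
    """v0: average vector magnitude over reliable pixels."""
    return float(np.abs(_reliable_vectors(field)).mean())


def order_parameter(field: PhaseVelocityField) -> float:
    """Modulus of the mean velocity divided by the mean modulus, in [0, 1]."""
    vs = _reliable_vectors(field)
    v0 = float(np.abs(vs).mean())
    if v0 == 0:
        raise ValueError("zero mean speed: order parameter undefined "
                         "(use the standing-wave criterion)")
    return float(np.abs(vs.mean()) / v0)


def mean_direction(field: PhaseVelocityField) -> float:
    """Angle of the mean velocity vector, counterclockwise from lateral +x
    with anterior = -row, in [0, 2*pi)."""
    vs = _reliable_vectors(field)
    return float(propagation_angle(vs.mean()))


def classify_frame(field: PhaseVelocityField, plane_thresh: float = 0.85,
                   standing_k: float = 2.0,
                   speed_history: Optional[Sequence[float]] = None) -> FrameSummary:
    """Label one frame as standing, plane, or other.

    The standing criterion compares the frame's mean speed against the
    distribution of mean speeds across the analysed period
    (``speed_history``), so that history is required.  Standing is checked
    before the plane criterion.
    """
    if speed_history is None:
        raise ValueError("speed_history is required for the standing criterion")
    hist = np.asarray(speed_history, dtype=float)
    v0 = mean_speed(field)
    standing = v0 < hist.mean() - standing_k * hist.std()
    if v0 > 0:
        op = order_parameter(field)
        theta = mean_direction(field)
    else:
        op, theta = 0.0, 0.0
    if standing:
        label = "standing"
    elif op >= plane_thresh:
        label = "plane"
    else:
        label = "other"
    return FrameSummary(t=field.t, order_parameter=op, mean_speed=v0,
                        mean_direction=theta, label=label)


def summarize_frames(fields: Sequence[PhaseVelocityField],
                     plane_thresh: float = 0.85,
                     standing_k: float = 2.0) -> List[FrameSummary]:
    """Classify every frame using the sequence's own speed history."""
    history = [mean_speed(f) for f in fields]
    return [classify_frame(f, plane_thresh, standing_k, history) for f in fields]


# ---------------------------------------------------------------------------
# critical points


def _bilinear_coeffs(z: np.ndarray, i: int, j: int) -> Tuple[float, float, float, float]:
    """Coefficients of z(xi, eta) = a0 + a1*xi + a2*eta + a3*xi*eta on cell
    (i, j) with xi the column fraction and eta the row fraction."""
    z00, z01 = z[i, j], z[i, j + 1]
    z10, z11 = z[i + 1, j], z[i + 1, j + 1]
    return z00, z01 - z00, z10 - z00, z00 - z01 - z10 + z11


def find_critical_points(field: PhaseVelocityField) -> List[Tuple[float, float]]:
    """Subpixel zeros of the field: intersections of the bilinearly
    interpolated nullclines of u and w, one search per 2x2 pixel cell."""
    u, w = field.u, field.w
    H, W = u.shape
    # A bilinear patch attains its extremes at cell corners, so a cell can
    # contain a zero of a component only if its corners straddle zero.
    u00, u01, u10, u11 = u[:-1, :-1], u[:-1, 1:], u[1:, :-1], u[1:, 1:]
    w00, w01, w10, w11 = w[:-1, :-1], w[:-1, 1:], w[1:, :-1], w[1:, 1:]
    umin = np.minimum(np.minimum(u00, u01), np.minimum(u10, u11))
    umax = np.maximum(np.maximum(u00, u01), np.maximum(u10, u11))
    wmin = np.minimum(np.minimum(w00, w01), np.minimum(w10, w11))
    wmax = np.maximum(np.maximum(w00, w01), np.maximum(w10, w11))
    cand = (umin <= 0) & (umax >= 0) & (wmin <= 0) & (wmax >= 0)

    scale = max(np.abs(u).max(), np.abs(w).max(), 1e-300)
    tol = 1e-9
    points: List[Tuple[float, float]] = []
    for i, j in np.argwhere(cand):
        a0, a1, a2, a3 = _bilinear_coeffs(u, i, j)
        b0, b1, b2, b3 = _bilinear_coeffs(w, i, j)
        # Eliminate xi: (a0 + a2*eta)(b1 + b3*eta) = (b0 + b2*eta)(a1 + a3*eta)
        c2 = a2 * b3 - b2 * a3
        c1 = a0 * b3 + a2 * b1 - b0 * a3 - b2 * a1
        c0 = a0 * b1 - b0 * a1
        if abs(c2) < tol * scale * scale:
            if abs(c1) < tol * scale * scale:
                continue  # degenerate: coincident nullclines
            etas = [-c0 / c1]
        else:
            disc = c1 * c1 - 4.0 * c2 * c0
            if disc < 0:
                continue
            sq = np.sqrt(disc)
            etas = [(-c1 - sq) / (2 * c2), (-c1 + sq) / (2 * c2)]
        for eta in etas:
            if not (-tol <= eta < 1.0 - tol):
                continue
            den_u = a1 + a3 * eta
            den_w = b1 + b3 * eta
            if abs(den_u) >= abs(den_w):
                if abs(den_u) < tol * scale:
                    continue
                xi = -(a0 + a2 * eta) / den_u
            else:
                xi = -(b0 + b2 * eta) / den_w
            if not (-tol <= xi < 1.0 - tol):
                continue
            ru = a0 + a1 * xi + a2 * eta + a3 * xi * eta
            rw = b0 + b1 * xi + b2 * eta + b3 * xi * eta
            if abs(ru) > 1e-6 * scale or abs(rw) > 1e-6 * scale:
                continue
            points.append((float(i + eta), float(j + xi)))
    # Dedupe points reported by adjacent cells at shared edges.
    out: List[Tuple[float, float]] = []
    for p in points:
        if not any(abs(p[0] - q[0]) < 1e-6 and abs(p[1] - q[1]) < 1e-6 for q in out):
            out.append(p)
    return out


def classify_jacobian(J: np.ndarray, eps: float = 0.0):
    """Type, subtype, and Poincare index from a 2x2 Jacobian.

    Returns ``(type, subtype, index, tau, delta, eigenvalues)`` or ``None``
    when both |tau| and |delta| fall below the degeneracy epsilon.
    """
    J = np.asarray(J, dtype=float)
    tau = float(np.trace(J))
    delta = float(np.linalg.det(J))
    if abs(delta) <= eps * eps and abs(tau) <= eps:
        return None
    eig = np.linalg.eigvals(J)
    if delta < 0:
        ptype, subtype, index = "saddle", "none", -1
    elif tau > 0:
        ptype, index = "source", 1
        subtype = "focus" if tau * tau - 4 * delta < 0 else "node"
    elif tau < 0:
        ptype, index = "sink", 1
        subtype = "focus" if tau * tau - 4 * delta < 0 else "node"
    else:
        return None  # centre: delta > 0, tau == 0 exactly
    return ptype, subtype, index, tau, delta, (complex(eig[0]), complex(eig[1]))


def _field_rms_gradient(field: PhaseVelocityField) -> float:
    uy, ux = np.gradient(field.u)
    wy, wx = np.gradient(field.w)
    return float(np.sqrt(np.mean(ux ** 2 + uy ** 2 + wx ** 2 + wy ** 2)))


def classify_critical_point(field: PhaseVelocityField,
                            location: Tuple[float, float],
                            t: Optional[int] = None,
                            degeneracy_eps: Optional[float] = None,
                            ) -> Optional[CriticalPoint]:
    """Classify the singularity at a subpixel location.

    The Jacobian is taken from the bilinear interpolant of the 2x2 pixel
    cell containing the point.  Returns ``None`` for degenerate points
    (both |tau| and |Delta| below epsilon), which are excluded from
    downstream counting.
    """
    row, col = location
    H, W = field.shape
    i = int(np.clip(np.floor(row), 0, H - 2))
    j = int(np.clip(np.floor(col), 0, W - 2))
    eta, xi = row - i, col - j
    a0, a1, a2, a3 = _bilinear_coeffs(field.u, i, j)
    b0, b1, b2, b3 = _bilinear_coeffs(field.w, i, j)
    # d(u,w)/d(x,y) with x = column, y = row.
    J = np.array([[a1 + a3 * eta, a2 + a3 * xi],
                  [b1 + b3 * eta, b2 + b3 * xi]])
    if degeneracy_eps is None:
        degeneracy_eps = 1e-9 * _field_rms_gradient(field)
    res = classify_jacobian(J, degeneracy_eps)
    if res is None:
        return None
    ptype, subtype, index, tau, delta, eig = res
    return CriticalPoint(t=field.t if t is None else t, location=(row, col),
                         jacobian=J, trace=tau, determinant=delta,
                         eigenvalues=eig, type=ptype, subtype=subtype,
                         poincare_index=index)


# ---------------------------------------------------------------------------
# winding number


def square_loop(center: Tuple[float, float], half_width: int) -> np.ndarray:
    """Closed square contour of pixel coordinates, positively oriented in
    the (x = column, y = row) axes used by the winding computation (so a
    source has index +1 and a saddle -1)."""
    r0, c0 = center
    h = half_width
    pts = []
    for c in range(-h, h):
        pts.append((r0 - h, c0 + c))
    for r in range(-h, h):
        pts.append((r0 + r, c0 + h))
    for c in range(h, -h, -1):
        pts.append((r0 + h, c0 + c))
    for r in range(h, -h, -1):
        pts.append((r0 + r, c0 - h))
    return np.array(pts, dtype=float)


def poincare_index(field: PhaseVelocityField, loop: np.ndarray) -> int:
    """Winding number of the vector angle along a closed loop.

    ``loop`` is an (n, 2) array of (row, col) coordinates; the contour is
    closed implicitly.  Raises if the loop touches a near-zero vector.
    """
    loop = np.asarray(loop, dtype=float)
    coords = loop.T  # (2, n): rows then cols, matching array axes
    u = ndimage.map_coordinates(field.u, coords, order=1, mode="nearest")
    w = ndimage.map_coordinates(field.w, coords, order=1, mode="nearest")
    mag = np.hypot(u, w)
    if np.any(mag < 1e-12 * max(mag.max(), 1e-300)) or np.any(mag == 0):
        raise ValueError("loop crosses a near-zero vector: winding undefined")
    ang = np.arctan2(w, u)
    d = np.diff(np.concatenate([ang, ang[:1]]))
    d = np.mod(d + np.pi, 2 * np.pi) - np.pi
    return int(np.rint(d.sum() / (2 * np.pi)))


# ---------------------------------------------------------------------------
# pattern radius and per-frame analysis


def pattern_radius(field: PhaseVelocityField, point: CriticalPoint,
                   ring_agreement: float = 0.8) -> int:
    """Largest radius over which the local flow keeps the type's signature.

    For every ring of pixels at integer radius R (Euclidean distance within
    [R - 0.5, R + 0.5)) the measured radial velocity component is compared
    against the sign predicted by the point's Jacobian quadratic form
    ``d^T J d`` (positive everywhere for a source, negative for a sink,
    quadrant-alternating for a saddle).  R grows while at least
    ``ring_agreement`` of each ring matches and the ring stays in bounds.
    """
    H, W = field.shape
    r0, c0 = point.location
    J = point.jacobian
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    dy = rows - r0
    dx = cols - c0
    dist = np.hypot(dx, dy)
    expected = J[0, 0] * dx * dx + (J[0, 1] + J[1, 0]) * dx * dy + J[1, 1] * dy * dy
    measured = field.u * dx + field.w * dy
    agree = np.sign(measured) == np.sign(expected)

    max_r = int(min(r0, c0, H - 1 - r0, W - 1 - c0) + 0.5)
    radius = 0
    for R in range(1, max(max_r, 0) + 1):
        ring = (dist >= R - 0.5) & (dist < R + 0.5)
        n = int(ring.sum())
        if n == 0:
            break
        if agree[ring].sum() / n < ring_agreement:
            break
        radius = R
    return radius


def analyze_frame(field: PhaseVelocityField, ring_agreement: float = 0.8,
                  ) -> List[CriticalPoint]:
    """Find, classify, and measure all critical points of one field."""
    out = []
    for loc in find_critical_points(field):
        cp = classify_critical_point(field, loc)
        if cp is None:
            continue
        cp.radius = pattern_radius(field, cp, ring_agreement)
        out.append(cp)
    return out


# ---------------------------------------------------------------------------
# tracking and census


def track_patterns(points_by_frame: Sequence[List[CriticalPoint]],
                   link_tol: float = 2.0) -> List[PatternTrack]:
    """Greedy nearest-neighbour linking of same-type points across
    consecutive frames.

    Candidate links are sorted by distance, with ties broken by the lowest
    row then lowest column of the new point; unmatched points open new
    tracks, unmatched tracks close.
    """
    tracks: List[PatternTrack] = []
    active: List[PatternTrack] = []
    for pts in points_by_frame:
        pairs = []
        for ti, tr in enumerate(active):
            last = tr.points[-1]
            for pi, p in enumerate(pts):
                if p.type != last.type:
                    continue
                d = float(np.hypot(p.location[0] - last.location[0],
                                   p.location[1] - last.location[1]))
                if d <= link_tol:
                    pairs.append((d, p.location[0], p.location[1], ti, pi))
        pairs.sort()
        used_tracks, used_pts = set(), set()
        next_active: List[PatternTrack] = []
        for d, _, _, ti, pi in pairs:
            if ti in used_tracks or pi in used_pts:
                continue
            active[ti].points.append(pts[pi])
            used_tracks.add(ti)
            used_pts.add(pi)
            next_active.append(active[ti])
        for pi, p in enumerate(pts):
            if pi not in used_pts:
                tr = PatternTrack(points=[p])
                tracks.append(tr)
                next_active.append(tr)
        active = next_active
    return tracks


def filter_tracks(tracks: Sequence[PatternTrack], d: int = 1, r: int = 1,
                  ) -> List[PatternTrack]:
    """Tracks surviving the detection threshold (d, r)."""
    return [t for t in tracks if t.duration >= d and t.min_radius >= r]


def detection_probability_surface(tracks: Sequence[PatternTrack],
                                  d_range: Sequence[int],
                                  r_range: Sequence[int]) -> np.ndarray:
    """Normalised count of tracks surviving each (d, r) threshold.

    Entry (i, j) is the number of tracks with duration >= d_range[i] and
    minimum radius >= r_range[j], divided by the count at threshold (1, 1);
    the surface is non-increasing along both axes.
    """
    base = len(filter_tracks(tracks, 1, 1))
    if base == 0:
        raise ValueError("no tracks at detection threshold (1, 1)")
    surface = np.empty((len(d_range), len(r_range)))
    for i, d in enumerate(d_range):
        for j, r in enumerate(r_range):
            surface[i, j] = len(filter_tracks(tracks, d, r)) / base
    return surface


_PARTITION_GRIDS = {1: (1, 1), 2: (1, 2), 4: (2, 2), 16: (4, 4)}


def window_sweep(fields: Sequence[PhaseVelocityField],
                 partitions: Sequence[int] = (1, 2, 4, 16),
                 plane_thresh: float = 0.85,
                 standing_k: float = 2.0) -> pd.DataFrame:
    """Plane/standing probabilities when the field of view is subdivided.

    Each partition count splits the frame into that many rectangular
    windows; every window is classified per frame against its own speed
    history.  Returns one row per partition with the fraction of
    (frame, window) pairs labelled plane, standing, and other.
    """
    partitions = list(partitions)
    if not partitions:
        raise ValueError("empty partition specification")
    if not fields:
        raise ValueError("no fields provided")
    H, W = fields[0].shape
    rows = []
    for n in partitions:
        if n not in _PARTITION_GRIDS:
            raise ValueError(f"unsupported partition count {n}; "
                             f"choose from {sorted(_PARTITION_GRIDS)}")
        gh, gw = _PARTITION_GRIDS[n]
        r_edges = np.linspace(0, H, gh + 1).astype(int)
        c_edges = np.linspace(0, W, gw + 1).astype(int)
        labels = []
        for bi in range(gh):
            for bj in range(gw):
                subs = []
                for f in fields:
                    sub = PhaseVelocityField(
                        v=f.v[r_edges[bi]:r_edges[bi + 1], c_edges[bj]:c_edges[bj + 1]],
                        t=f.t,
                        reliability=f.reliability[r_edges[bi]:r_edges[bi + 1],
                                                  c_edges[bj]:c_edges[bj + 1]])
                    subs.append(sub)
                summaries = summarize_frames(subs, plane_thresh, standing_k)
                labels.extend(s.label for s in summaries)
        labels = pd.Series(labels)
        rows.append({
            "n_windows": n,
            "p_plane": float((labels == "plane").mean()),
            "p_standing": float((labels == "standing").mean()),
            "p_other": float((labels == "other").mean()),
        })
    return pd.DataFrame(rows)


_COMBOS = ["source", "sink", "saddle", "source+sink", "source+saddle",
           "sink+saddle", "source+sink+saddle"]


def coexistence_census(tracks: Sequence[PatternTrack],
                       frames: Optional[Sequence[int]] = None):
    """Histogram of the seven type-coexistence combinations per frame.

    Returns ``(histogram, counts)``: the histogram is a Series over the
    seven combinations (counts of frames showing each), and ``counts`` maps
    frame -> number of coexisting patterns.
    """
    present: Dict[int, set] = {}
    counts: Dict[int, int] = {}
    if frames is not None:
        for t in frames:
            present[t] = set()
            counts[t] = 0
    for tr in tracks:
        for p in tr.points:
            present.setdefault(p.t, set()).add(p.type)
            counts[p.t] = counts.get(p.t, 0) + 1
    hist = pd.Series(0, index=_COMBOS, dtype=int)
    for t, types in present.items():
        if not types:
            continue
        key = "+".join(k for k in ("source", "sink", "saddle") if k in types)
        hist[key] += 1
    return hist, counts


def index_change_series(points_by_frame: Sequence[List[CriticalPoint]]):
    """Per-step change of the total Poincare index.

    Returns ``(deltas, distribution)`` where deltas[t] is the total index
    at frame t+1 minus at frame t and the distribution is the empirical
    probability of each delta value.
    """
    totals = np.array([sum(p.poincare_index for p in pts)
                       for pts in points_by_frame], dtype=int)
    deltas = np.diff(totals)
    if deltas.size:
        dist = pd.Series(deltas).value_counts(normalize=True).sort_index()
    else:
        dist = pd.Series(dtype=float)
    return deltas, dist
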