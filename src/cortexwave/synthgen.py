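"""Synthetic voltage movies, analytic vector fields, nulls, and region fixtures.

The generators are kinematic wave templates: each component contributes
``amplitude * cos(phase_field(r, c) - omega * t + phase_offset)`` where the
spatial phase field encodes the pattern geometry (plane, radial, spiral,
standing, saddle).  They exist so that every downstream stage — phase
extraction, optical flow, singularity classification, statistics — can be
tested against planted ground truth.  Two null models mirror the surrogate
controls used for real recordings: per-pixel spectrum-preserving temporal
phase randomisation and a frame-wise spatial pixel permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import PhaseVelocityField, VoltageMovie

__all__ = [
    "WaveComponentSpec",
    "MovieSpec",
    "omega_from_hz",
    "generate_movie",
    "generate_linear_field",
    "shuffle_temporal",
    "shuffle_spatial",
    "generate_region_fixture",
]

_KINDS = ("plane", "standing", "source", "sink", "spiral_in", "spiral_out", "saddle")


def omega_from_hz(freq_hz: float, frame_rate: float) -> float:
    """Angular frequency in radians/frame for a tone of ``freq_hz``."""
    return 2.0 * np.pi * freq_hz / frame_rate


@dataclass
class WaveComponentSpec:
    """One planted wave component.

    kind
        One of plane, standing, source, sink, spiral_in, spiral_out, saddle.
    center
        (row, col) of the pattern centre; defaults to the grid centre.
        Ignored for plane waves.
    wavevector
        (k_row, k_col) in radians/pixel; required for plane and standing.
    radial_wavenumber
        k_r in radians/pixel; required for the radial kinds.
    angular_frequency
        omega in radians/frame.
    """

    kind: str
    angular_frequency: float
    center: Optional[Tuple[float, float]] = None
    wavevector: Optional[Tuple[float, float]] = None
    radial_wavenumber: Optional[float] = None
    amplitude: float = 1.0
    phase_offset: float = 0.0
    envelope_sigma: Optional[float] = None  # Gaussian amplitude envelope, pixels

    def validate(self) -> None:
        if self.envelope_sigma is not None and self.envelope_sigma <= 0:
            raise ValueError("envelope_sigma must be > 0")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.kind in ("plane", "standing") and self.wavevector is None:
            raise ValueError(f"wavevector required for kind {self.kind!r}")
        if self.kind in ("source", "sink", "spiral_in", "spiral_out", "saddle"):
            if self.radial_wavenumber is None:
                raise ValueError(f"radial_wavenumber required for kind {self.kind!r}")
            if self.radial_wavenumber <= 0:
                raise ValueError("radial_wavenumber must be > 0")


@dataclass
class MovieSpec:
    """Full recipe for a synthetic movie; identical seed => identical movie."""

    shape: Tuple[int, int, int]  # (T, H, W)
    frame_rate: float
    components: List[WaveComponentSpec] = dc_field(default_factory=list)
    noise_sd: float = 0.2
    seed: int = 0
    pixel_pitch: float = 58.0  # after 2x coarse graining of a 29 um raster

    def validate(self) -> None:
        T, H, W = self.shape
        if T < 2:
            raise ValueError("shape: T must be >= 2")
        if H < 8 or W < 8:
            raise ValueError("shape: H and W must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        for comp in self.components:
            comp.validate()


def _component_centre(comp: WaveComponentSpec, H: int, W: int) -> Tuple[float, float]:
    if comp.center is not None:
        return comp.center
    return ((H - 1) / 2.0, (W - 1) / 2.0)


def _radial_phase(kind: str, k_r: float, rows: np.ndarray, cols: np.ndarray,
                  center: Tuple[float, float]) -> np.ndarray:
    dr = rows - center[0]
    dc = cols - center[1]
    rho = np.hypot(dr, dc)
    if kind in ("source", "spiral_out"):
        phi = k_r * rho
    else:  # sink, spiral_in
        phi = -k_r * rho
    if kind in ("spiral_out", "spiral_in"):
        phi = phi + np.arctan2(dr, dc)
    return phi


def _expand_saddle(comp: WaveComponentSpec, H: int, W: int) -> List[WaveComponentSpec]:
    """Realise a saddle as two interacting same-sign radial components.

    Two equal sources with localised (Gaussian-envelope) amplitudes are
    placed symmetrically left/right of the requested centre.  Each wave
    dominates near its own centre, so along the connecting axis their
    outward flows collide head-on at the mid-point while the perpendicular
    components add up and flow away from it: the mid-point is a saddle of
    the resulting phase velocity field.
    """
    centre = _component_centre(comp, H, W)
    k_r = comp.radial_wavenumber
    sep = max(4.0, np.pi / (2.0 * k_r))
    sigma = comp.envelope_sigma if comp.envelope_sigma is not None else 1.2 * sep
    left = WaveComponentSpec(
        kind="source", angular_frequency=comp.angular_frequency,
        center=(centre[0], centre[1] - sep), radial_wavenumber=k_r,
        amplitude=comp.amplitude, phase_offset=comp.phase_offset,
        envelope_sigma=sigma)
    right = WaveComponentSpec(
        kind="source", angular_frequency=comp.angular_frequency,
        center=(centre[0], centre[1] + sep), radial_wavenumber=k_r,
        amplitude=comp.amplitude, phase_offset=comp.phase_offset,
        envelope_sigma=sigma)
    return [left, right]


def generate_movie(spec: MovieSpec) -> VoltageMovie:
    """Render a :class:`MovieSpec` into a :class:`VoltageMovie`.

    The movie value at ``(t, r, c)`` is the sum over components of
    ``A * cos(phase_field(r, c) - omega * t + offset)`` plus white Gaussian
    noise of standard deviation ``noise_sd``.  Standing components are
    ``A * cos(k . x) * cos(omega * t - offset)`` instead.
    """
    spec.validate()
    T, H, W = spec.shape
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    t = np.arange(T, dtype=float)[:, None, None]

    data = np.zeros((T, H, W), dtype=float)
    components: List[WaveComponentSpec] = []
    for comp in spec.components:
        if comp.kind == "saddle":
            components.extend(_expand_saddle(comp, H, W))
        else:
            components.append(comp)

    for comp in components:
        omega = comp.angular_frequency
        if comp.kind == "plane":
            k_row, k_col = comp.wavevector
            phi = k_row * rows + k_col * cols
            amp = comp.amplitude
            data += amp * np.cos(phi[None] - omega * t + comp.phase_offset)
        elif comp.kind == "standing":
            k_row, k_col = comp.wavevector
            centre = _component_centre(comp, H, W)
            phi = k_row * (rows - centre[0]) + k_col * (cols - centre[1])
            data += comp.amplitude * np.cos(phi[None]) * np.cos(omega * t - comp.phase_offset)
        else:
            centre = _component_centre(comp, H, W)
            phi = _radial_phase(comp.kind, comp.radial_wavenumber, rows, cols, centre)
            amp = np.full((H, W), comp.amplitude)
            if comp.envelope_sigma is not None:
                rho2 = (rows - centre[0]) ** 2 + (cols - centre[1]) ** 2
                amp = amp * np.exp(-rho2 / (2.0 * comp.envelope_sigma ** 2))
            data += amp[None] * np.cos(phi[None] - omega * t + comp.phase_offset)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, spec.noise_sd, size=(T, H, W))

    return VoltageMovie(data=data, frame_rate=spec.frame_rate, pixel_pitch=spec.pixel_pitch)


def generate_linear_field(A: np.ndarray, center: Tuple[float, float],
                          shape: Tuple[int, int]) -> PhaseVelocityField:
    """Exact linear vector field ``v(x) = A (x - center)``.

    ``A`` acts on the displacement ``(dx, dy) = (col - c0, row - r0)`` and
    returns ``(u, w)``; the Jacobian of the generated field therefore equals
    ``A`` everywhere.  Used as the oracle input for singularity
    classification and winding-number tests.
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (2, 2):
        raise ValueError("A must be a 2x2 matrix")
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("A is singular: degenerate critical point")
    H, W = shape
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    dx = cols - center[1]
    dy = rows - center[0]
    u = A[0, 0] * dx + A[0, 1] * dy
    w = A[1, 0] * dx + A[1, 1] * dy
    return PhaseVelocityField(v=u + 1j * w)


def shuffle_temporal(movie: VoltageMovie, seed: int) -> VoltageMovie:
    """Per-pixel spectrum-preserving temporal phase randomisation.

    Each pixel's time series is Fourier transformed, every positive-frequency
    coefficient is multiplied by an independent unit-modulus random factor
    (the Nyquist bin, present for even T, by a random sign so the output
    stays real), and the series is inverse transformed.  The per-pixel power
    spectrum is preserved to numerical precision.
    """
    T = movie.n_frames
    if T < 4:
        raise ValueError("need at least 4 frames for temporal shuffling")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(movie.data, axis=0)
    n_bins = spec.shape[0]
    factors = np.ones(spec.shape, dtype=complex)
    has_nyquist = T % 2 == 0
    hi = n_bins - 1 if has_nyquist else n_bins
    if hi > 1:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(hi - 1,) + spec.shape[1:])
        factors[1:hi] = np.exp(1j * phases)
    if has_nyquist:
        factors[-1] = rng.choice([-1.0, 1.0], size=spec.shape[1:])
    out = np.fft.irfft(spec * factors, n=T, axis=0)
    return movie.copy_with(data=out)


def shuffle_spatial(movie: VoltageMovie, seed: int) -> VoltageMovie:
    """Apply one random pixel permutation identically to every frame."""
    rng = np.random.default_rng(seed)
    T, H, W = movie.shape
    perm = rng.permutation(H * W)
    flat = movie.data.reshape(T, H * W)
    out = flat[:, perm].reshape(T, H, W)
    return movie.copy_with(data=out)


def generate_region_fixture(shape: Tuple[int, int], n_regions: int,
                            target_corr: float, seed: int,
                            corr_tol: float = 0.02):
    """Contiguous region map, hierarchy table, and a matched probability map.

    The per-pixel probability map is constructed so that its regional
    averages have Pearson correlation ``target_corr`` with the hierarchy
    index (exact by construction, then verified against ``corr_tol``).

    Returns ``(region_map, hierarchy_table, probability_map)`` where
    ``region_map`` is an ``(H, W)`` int label image with labels
    ``0..n_regions-1``, ``hierarchy_table`` a DataFrame with columns
    ``region_id, region_name, hierarchy_index``, and ``probability_map`` an
    ``(H, W)`` float array in [0, 1].
    """
    if n_regions < 4:
        raise ValueError("n_regions must be >= 4")
    if abs(target_corr) > 1:
        raise ValueError("target_corr must lie in [-1, 1]")
    H, W = shape
    if n_regions > H * W:
        raise ValueError("more regions than pixels")
    rng = np.random.default_rng(seed)

    # Voronoi tessellation of random seed points: convex, hence contiguous.
    pts = np.column_stack([rng.uniform(0, H, n_regions), rng.uniform(0, W, n_regions)])
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    d2 = (rows[..., None] - pts[:, 0]) ** 2 + (cols[..., None] - pts[:, 1]) ** 2
    region_map = np.argmin(d2, axis=-1).astype(int)
    # Guarantee every label is populated (redraw degenerate tessellations).
    while len(np.unique(region_map)) < n_regions:
        pts = np.column_stack([rng.uniform(0, H, n_regions), rng.uniform(0, W, n_regions)])
        d2 = (rows[..., None] - pts[:, 0]) ** 2 + (cols[..., None] - pts[:, 1]) ** 2
        region_map = np.argmin(d2, axis=-1).astype(int)

    hierarchy = rng.normal(size=n_regions)
    z_h = (hierarchy - hierarchy.mean()) / hierarchy.std()

    # Regional means with exactly the requested correlation to the hierarchy.
    e = rng.normal(size=n_regions)
    e = e - e.mean()
    e = e - (e @ z_h) / (z_h @ z_h) * z_h
    while np.linalg.norm(e) < 1e-9:
        e = rng.normal(size=n_regions)
        e = e - e.mean()
        e = e - (e @ z_h) / (z_h @ z_h) * z_h
    z_e = e / e.std()
    y = target_corr * z_h + np.sqrt(max(0.0, 1.0 - target_corr ** 2)) * z_e

    prob = y[region_map].astype(float)
    # Within-region texture with exactly zero regional mean, so the regional
    # averages (and hence the correlation) are untouched.
    noise = rng.normal(0.0, 0.3, size=(H, W))
    sums = np.bincount(region_map.ravel(), weights=noise.ravel(), minlength=n_regions)
    counts = np.bincount(region_map.ravel(), minlength=n_regions)
    noise -= (sums / counts)[region_map]
    prob = prob + noise
    prob = (prob - prob.min()) / (prob.max() - prob.min())  # affine: corr preserved

    means = np.bincount(region_map.ravel(), weights=prob.ravel(),
                        minlength=n_regions) / counts
    achieved = np.corrcoef(means, hierarchy)[0, 1]
    if not np.isfinite(achieved) or abs(achieved - target_corr) > corr_tol:
        raise ValueError(
            f"could not realise target_corr={target_corr} with n_regions={n_regions} "
            f"(achieved {achieved:.3f})")

    table = pd.DataFrame({
        "region_id": np.arange(n_regions),
        "region_name": [f"R{i:02d}" for i in range(n_regions)],
        "hierarchy_index": hierarchy,
    })
    return region_map, table, prob
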