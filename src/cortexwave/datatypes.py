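"""Core containers shared across the pipeline.

Conventions used throughout the package
---------------------------------------
* Movies are ``(T, H, W)`` arrays: time, rows, columns.
* Row 0 is anterior (rostral); columns increase laterally to the right.
* Velocity fields are stored as a single complex array ``v = u + i*w``
  where ``u`` is the column (x) velocity and ``w`` the row velocity, in
  pixels/frame.  The physical "anterior" direction is ``-row``, so the
  propagation angle reported to users is ``atan2(-w, u)`` measured
  counterclockwise from the lateral (+x) axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VoltageMovie",
    "PhaseMovie",
    "PhaseVelocityField",
    "FlowSettings",
    "FrameSummary",
    "CriticalPoint",
    "PatternTrack",
    "SVDModeSet",
    "DirectionStateSeries",
    "Episode",
    "propagation_angle",
]


def propagation_angle(v: np.ndarray) -> np.ndarray:
    """Angle of propagation in ``[0, 2*pi)`` with anterior = ``-row``.

    ``v`` is complex ``u + i*w`` (u = column velocity, w = row velocity).
    """
    v = np.asarray(v)
    return np.mod(np.arctan2(-v.imag, v.real), 2.0 * np.pi)


@dataclass
class VoltageMovie:
    """A ``(T, H, W)`` scalar movie of population-voltage values."""

    data: np.ndarray
    frame_rate: float
    pixel_pitch: float = 29.0  # micrometres / pixel, metadata only
    valid_mask: Optional[np.ndarray] = None  # (T,) bool, True = usable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be a (T, H, W) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (self.data.shape[0],):
                raise ValueError("valid_mask must have shape (T,)")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def copy_with(self, **kw) -> "VoltageMovie":
        args = dict(
            data=self.data,
            frame_rate=self.frame_rate,
            pixel_pitch=self.pixel_pitch,
            valid_mask=self.valid_mask.copy(),
        )
        args.update(kw)
        return VoltageMovie(**args)


@dataclass
class PhaseMovie:
    """Instantaneous phase and analytic-signal envelope of a movie."""

    phase: np.ndarray  # (T, H, W) radians in (-pi, pi]
    amplitude: np.ndarray  # (T, H, W) >= 0
    frame_rate: float
    valid_mask: np.ndarray  # (T,) bool

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude shapes differ")

    @property
    def shape(self) -> tuple:
        return self.phase.shape

    @property
    def n_frames(self) -> int:
        return self.phase.shape[0]

    def reliability(self, eps_factor: float = 1e-6) -> np.ndarray:
        """Per-sample reliability: envelope above ``eps_factor * median``."""
        med = np.median(self.amplitude[self.valid_mask]) if self.valid_mask.any() else 0.0
        return self.amplitude > eps_factor * med


@dataclass
class PhaseVelocityField:
    """Per-frame phase velocity field ``v = u + i*w`` in pixels/frame."""

    v: np.ndarray  # (H, W) complex
    t: int = 0
    reliability: Optional[np.ndarray] = None  # (H, W) bool
    converged: bool = True

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=complex)
        if self.v.ndim != 2:
            raise ValueError("v must be a 2-D complex array")
        if self.reliability is None:
            self.reliability = np.ones(self.v.shape, dtype=bool)
        else:
            self.reliability = np.asarray(self.reliability, dtype=bool)

    @property
    def u(self) -> np.ndarray:
        """Column (x) velocity component."""
        return self.v.real

    @property
    def w(self) -> np.ndarray:
        """Row velocity component."""
        return self.v.imag

    @property
    def shape(self) -> tuple:
        return self.v.shape


@dataclass
class FlowSettings:
    """Parameters of the variational phase-flow solver.

    alpha
        Weight of the spatial-smoothness term relative to the phase
        constancy data term.  Larger values give smoother fields.
    penalty
        ``"charbonnier"`` (robust, default) or ``"quadratic"``.
    charbonnier_eps
        Smoothing constant of the Charbonnier penalty sqrt(r^2 + eps^2).
    max_iters, tol
        Stopping rule of the fixed-point Euler-Lagrange iteration: the
        maximum Euler-Lagrange residual, relative to the data forcing
        term, falls below ``tol``, or ``max_iters`` sweeps elapse.
    sor_omega
        Successive over-relaxation factor in (0, 2); 1 is plain
        Gauss-Seidel, values near 2 accelerate convergence markedly.
    n_scales
        Coarse-to-fine pyramid levels used to initialise the solution
        (the problem is convex; extra levels only accelerate convergence).
    """

    alpha: float = 0.5
    penalty: str = "charbonnier"
    charbonnier_eps: float = 1e-3
    max_iters: int = 1000
    tol: float = 1e-6
    sor_omega: float = 1.9
    n_scales: int = 3

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not 0.0 < self.sor_omega < 2.0:
            raise ValueError("sor_omega must be in (0, 2)")
        if self.penalty not in ("quadratic", "charbonnier"):
            raise ValueError("penalty must be 'quadratic' or 'charbonnier'")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")


@dataclass
class FrameSummary:
    """Frame-level wave statistics and plane/standing label."""

    t: int
    order_parameter: float
    mean_speed: float
    mean_direction: float  # radians in [0, 2*pi)
    label: str  # 'standing' | 'plane' | 'other'


@dataclass
class CriticalPoint:
    """A classified singularity of a phase velocity field."""

    t: int
    location: tuple  # (row, col), subpixel
    jacobian: np.ndarray  # 2x2, d(u,w)/d(x,y)
    trace: float
    determinant: float
    eigenvalues: tuple
    type: str  # 'source' | 'sink' | 'saddle'
    subtype: str  # 'node' | 'focus' | 'none'
    poincare_index: int  # +1 source/sink, -1 saddle
    radius: int = 0


@dataclass
class PatternTrack:
    """A time-linked sequence of same-type critical points."""

    points: list = field(default_factory=list)

    @property
    def type(self) -> str:
        return self.points[0].type

    @property
    def duration(self) -> int:
        return len(self.points)

    @property
    def min_radius(self) -> int:
        return min(p.radius for p in self.points)

    @property
    def centroid(self) -> tuple:
        rows = [p.location[0] for p in self.points]
        cols = [p.location[1] for p in self.points]
        return (float(np.mean(rows)), float(np.mean(cols)))

    @property
    def frames(self) -> list:
        return [p.t for p in self.points]


@dataclass
class SVDModeSet:
    """Principal spatial modes of a phase-velocity-field sequence."""

    modes: np.ndarray  # (k, H, W) complex, unit-norm in flattened real form
    singular_values: np.ndarray  # full spectrum, descending
    variance_fractions: np.ndarray  # full spectrum, sums to 1
    projections: np.ndarray  # (L, k) real weights M = w R
    shape: tuple = (0, 0)  # (H, W)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


@dataclass
class Episode:
    state: str
    start: int  # inclusive frame index into the analysed series
    end: int  # exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DirectionStateSeries:
    """Per-frame large-scale direction state and its episode segmentation."""

    frames: np.ndarray  # (L,) frame indices
    states: np.ndarray  # (L,) str in {posteroanterior, anteroposterior, disordered}
    theta: np.ndarray  # (L,)
    order_parameter: np.ndarray  # (L,)
    episodes: list = field(default_factory=list)
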