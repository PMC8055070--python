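"""Raw movie -> masked, band-limited phase movie.

Stages mirror the standard mesoscale voltage-imaging chain: spatial
coarse-graining (bicubic), zero-phase delta-band temporal filtering
(Chebyshev type II, forward-backward), artifact-period masking on the
spatial-mean trace, and per-pixel Hilbert phase extraction.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, signal
from skimage.transform import resize

from .datatypes import PhaseMovie, VoltageMovie

__all__ = ["coarse_grain", "bandpass", "mask_artifacts", "instantaneous_phase"]


def coarse_grain(movie: VoltageMovie, scale: float = 0.5) -> VoltageMovie:
    """Spatially resample every frame by bicubic interpolation.

    ``scale`` is the linear downscaling factor (0.5 halves each dimension).
    Frame count is unchanged; pixel pitch grows by ``1/scale``.
    """
    if not 0 < scale < 1:
        raise ValueError("scale must lie in (0, 1)")
    T, H, W = movie.shape
    out_h = int(round(H * scale))
    out_w = int(round(W * scale))
    if out_h < 4 or out_w < 4:
        raise ValueError(f"scale={scale} would produce a {out_h}x{out_w} frame; "
                         "need at least 4x4")
    out = np.empty((T, out_h, out_w), dtype=float)
    for i in range(T):
        out[i] = resize(movie.data[i], (out_h, out_w), order=3, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    return VoltageMovie(data=out, frame_rate=movie.frame_rate,
                        pixel_pitch=movie.pixel_pitch / scale,
                        valid_mask=movie.valid_mask.copy())


def design_bandpass(frame_rate: float, band: Tuple[float, float] = (0.5, 4.0),
                    attenuation_db: float = 40.0, gpass_db: float = 1.0,
                    stop_factor: float = 2.0) -> np.ndarray:
    """Chebyshev type II band-pass design (second-order sections).

    The order is chosen by the standard order-selection rule for
    ``attenuation_db`` of stopband rejection with stopband edges at
    ``low/stop_factor`` and ``high*stop_factor`` Hz.
    """
    low, high = band
    nyq = frame_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist ({nyq} Hz)")
    ws = [low / stop_factor, min(high * stop_factor, 0.99 * nyq)]
    n, wn = signal.cheb2ord([low, high], ws, gpass_db, attenuation_db, fs=frame_rate)
    return signal.cheby2(n, attenuation_db, wn, btype="bandpass", output="sos",
                         fs=frame_rate)


def bandpass(movie: VoltageMovie, band: Tuple[float, float] = (0.5, 4.0),
             attenuation_db: float = 40.0) -> VoltageMovie:
    """Zero-phase (forward-backward) Chebyshev-II band-pass per pixel."""
    sos = design_bandpass(movie.frame_rate, band, attenuation_db)
    T = movie.n_frames
    # sosfiltfilt needs T > padlen; shrink the pad for short movies.
    default_pad = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                                  (sos[:, 5] == 0).sum()))
    padlen = min(default_pad, T - 2)
    out = signal.sosfiltfilt(sos, movie.data, axis=0, padlen=padlen)
    return movie.copy_with(data=out)


def mask_artifacts(movie: VoltageMovie, k_sd: float = 3.0,
                   guard_s: float = 0.5) -> VoltageMovie:
    """Flag artifact periods on the spatial-mean trace of a filtered movie.

    Frames where the spatially averaged signal deviates from its temporal
    mean by more than ``k_sd`` standard deviations are marked invalid,
    together with a guard margin of ``guard_s`` seconds on each side
    (filter ringing contaminates neighbours).  Data values are untouched.
    """
    trace = movie.data.mean(axis=(1, 2))
    mu = trace.mean()
    sd = trace.std()
    flagged = np.abs(trace - mu) > k_sd * sd
    guard = int(round(guard_s * movie.frame_rate))
    if guard > 0 and flagged.any():
        flagged = ndimage.binary_dilation(flagged, structure=np.ones(2 * guard + 1,
                                                                     dtype=bool))
    new_mask = movie.valid_mask & ~flagged
    if not new_mask.any():
        raise ValueError("every frame flagged as artifact: recording unusable")
    return movie.copy_with(valid_mask=new_mask)


def instantaneous_phase(movie: VoltageMovie, edge_s: float = 2.0) -> PhaseMovie:
    """Per-pixel analytic signal: phase = argument, amplitude = envelope.

    The first and last ``edge_s`` seconds (default one period of the lowest
    passband frequency, 1/0.5 Hz) are flagged invalid because the analytic
    signal has end transients there.
    """
    if not np.isfinite(movie.data).all():
        raise ValueError("movie contains non-finite values; filter/mask first")
    analytic = signal.hilbert(movie.data, axis=0)
    phase = np.angle(analytic)
    amplitude = np.abs(analytic)
    valid = movie.valid_mask.copy()
    edge = int(round(edge_s * movie.frame_rate))
    if edge > 0:
        edge = min(edge, movie.n_frames)
        valid[:edge] = False
        valid[movie.n_frames - edge:] = False
    if not valid.any():
        warnings.warn("no valid frames remain after edge flagging", stacklevel=2)
    return PhaseMovie(phase=phase, amplitude=amplitude,
                      frame_rate=movie.frame_rate, valid_mask=valid)
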