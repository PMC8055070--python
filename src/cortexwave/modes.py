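"""Singular value decomposition of phase-velocity-field sequences.

Each field is embedded as a real row vector (row-major real parts followed
by row-major imaginary parts, length 2*H*W); the stacked L x 2HW matrix w
is factorised as w = T S R* and the k-th column of R, unflattened, is the
k-th spatial mode.  Mode k explains sigma_k^2 / sum_i sigma_i^2 of the
variance, and the projection weights M = w R give each frame's loading on
each mode.
"""

from __future__ import annotations

import warnings
from typing import List, Sequence, Tuple

import numpy as np

from .datatypes import PhaseVelocityField, SVDModeSet

__all__ = ["flatten_pvf", "unflatten_pvf", "svd_modes", "align_modes",
           "direction_split"]


def flatten_pvf(field: PhaseVelocityField, shape=None) -> np.ndarray:
    """Real embedding of a complex field: [real parts, imaginary parts]."""
    if shape is not None and field.shape != tuple(shape):
        raise ValueError(f"field shape {field.shape} does not match {tuple(shape)}")
    return np.concatenate([field.u.ravel(), field.w.ravel()])


def unflatten_pvf(vec: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`flatten_pvf`; returns the complex (H, W) field."""
    H, W = shape
    vec = np.asarray(vec, dtype=float)
    if vec.size != 2 * H * W:
        raise ValueError(f"vector length {vec.size} does not match shape {shape}")
    return vec[:H * W].reshape(H, W) + 1j * vec[H * W:].reshape(H, W)


def svd_modes(fields: Sequence[PhaseVelocityField], k_max: int = 20) -> SVDModeSet:
    """Thin SVD of the stacked field matrix.

    Modes are sign-fixed so each one's largest-magnitude entry is positive
    (deterministic across runs and LAPACK builds).  Variance fractions are
    kept for the full spectrum so they sum to 1; modes and projections are
    truncated to ``k_max``.
    """
    if len(fields) < 2:
        raise ValueError("need at least 2 fields")
    shape = fields[0].shape
    W_mat = np.stack([flatten_pvf(f, shape) for f in fields])
    U, s, Vt = np.linalg.svd(W_mat, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(W_mat.shape) * np.finfo(float).eps)) if s.size else 0
    k = min(k_max, len(s))
    if k_max > rank:
        warnings.warn(f"k_max={k_max} exceeds numerical rank {rank}; "
                      f"returning {k} modes", stacklevel=2)
    R = Vt[:k].T  # (2HW, k)
    # Sign convention: largest-magnitude entry of each mode is positive.
    for m in range(k):
        idx = np.argmax(np.abs(R[:, m]))
        if R[idx, m] < 0:
            R[:, m] = -R[:, m]
    M = W_mat @ R
    total = float(np.sum(s ** 2))
    fractions = s ** 2 / total if total > 0 else np.zeros_like(s)
    modes = np.stack([unflatten_pvf(R[:, m], shape) for m in range(k)])
    return SVDModeSet(modes=modes, singular_values=s, variance_fractions=fractions,
                      projections=M, shape=shape)


def projection_variance(modeset: SVDModeSet) -> np.ndarray:
    """Per-frame share of each mode: M[m, n]^2 / sum_i M[i, n]^2, as an
    (L, k) array of rows summing to 1 over the retained modes."""
    M2 = modeset.projections ** 2
    tot = M2.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return M2 / tot


def align_modes(candidate: SVDModeSet, reference: SVDModeSet, k: int):
    """Greedy one-to-one matching of candidate modes to reference modes.

    Pairs are chosen to maximise the absolute Pearson correlation of the
    flattened modes.  Returns ``(permutation, signed_correlations)`` where
    ``permutation[i]`` is the candidate index matched to reference mode i.
    """
    if k > candidate.n_modes or k > reference.n_modes:
        raise ValueError(f"k={k} exceeds available modes "
                         f"({candidate.n_modes}, {reference.n_modes})")
    if candidate.shape != reference.shape:
        raise ValueError("mode sets have different field shapes")

    def _flat(ms, i):
        return np.concatenate([ms.modes[i].real.ravel(), ms.modes[i].imag.ravel()])

    corr = np.empty((k, k))
    for i in range(k):
        a = _flat(reference, i)
        for j in range(k):
            b = _flat(candidate, j)
            corr[i, j] = np.corrcoef(a, b)[0, 1]
    perm = np.full(k, -1, dtype=int)
    signed = np.zeros(k)
    free_ref = set(range(k))
    free_cand = set(range(k))
    while free_ref:
        best = None
        for i in free_ref:
            for j in free_cand:
                val = abs(corr[i, j])
                if best is None or val > best[0]:
                    best = (val, i, j)
        _, i, j = best
        perm[i] = j
        signed[i] = corr[i, j]
        free_ref.remove(i)
        free_cand.remove(j)
    return perm, signed


def direction_split(modeset: SVDModeSet, mode_index: int) -> Tuple[float, float]:
    """Proportion of frames projecting with dominant vs opposite sign.

    Frames are weighted by squared projection; the labelling convention
    puts the larger share first.
    """
    M = modeset.projections[:, mode_index]
    M2 = M ** 2
    tot = M2.sum()
    if tot == 0:
        return (0.5, 0.5)
    p_pos = float(M2[M > 0].sum() / tot)
    p_neg = float(M2[M < 0].sum() / tot)
    return (p_pos, p_neg) if p_pos >= p_neg else (p_neg, p_pos)
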