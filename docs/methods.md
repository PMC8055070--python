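# Methods

This note records the mathematical model implemented by `cortexwave`, the
parameter conventions, the scope of the synthetic generator, the main
numerical choices, and known limitations. Every quantitative statement
here is exercised by the test suite (`tests/`) or by
`scripts/acceptance.py`.

## Conventions

* Movies are `(T, H, W)` arrays: time, rows, columns. Row 0 is anterior
  (rostral); columns increase laterally.
* Velocity fields are stored as one complex array `v = u + i*w` with `u`
  the column (x) velocity and `w` the row (y) velocity, in pixels/frame.
* The propagation angle reported to users is `atan2(-w, u)` in `[0, 2π)`,
  so "anterior" propagation (towards row 0) is π/2.
* All phase arithmetic is circular: differences are computed through
  arguments of products of unit phasors, never by unwrapping.

## Synthetic generator

`MovieSpec` describes a movie as a sum of components plus white Gaussian
pixel noise (default amplitude 1 per component against `noise_sd = 0.2`,
i.e. SNR 5 before band-limiting; tests use 0.5 for the SNR-2 recovery
checks). Components:

* **plane**: `cos(k·x − ωt + φ0)` for wavevector `k` (rad/pixel).
* **standing**: `cos(k·x) · cos(ωt − φ0)` — zero propagation, fixed nodes.
* **source / sink / spiral_out / spiral_in**: radial phase
  `±k_r·ρ (± θ for spirals)` about a centre, optionally under a Gaussian
  amplitude envelope.
* **saddle**: realised as *two* sources with Gaussian envelopes separated
  by `max(4, π/(2 k_r))` pixels (envelope σ = 1.2× separation). A pure
  equal-amplitude two-source interference field is degenerate — its phase
  reduces to elliptical coordinates and no saddle flow appears — so the
  envelopes are what make the intermediate saddle observable. The
  realisation is therefore a composite: a saddle at the planted centre
  flanked by two sources, and tests assert exactly that.

Null models: `shuffle_temporal` randomises each pixel's Fourier phases
independently (the Nyquist bin receives a random sign for even T), exactly
preserving per-pixel amplitude spectra; `shuffle_spatial` applies one
random pixel permutation identically to every frame, exactly preserving
each frame's value multiset and each pixel's time course.

The region fixture (`generate_region_fixture`) tessellates the grid into
contiguous Voronoi regions and constructs regional probabilities with an
*exact* target correlation to a hierarchy index: the regional vector is
`ρ·z_h + sqrt(1−ρ²)·z_e` with `z_e` orthogonalised against the hierarchy,
within-region noise has zero regional mean, and the final affine rescale
to [0, 1] leaves the Pearson correlation unchanged. Because the target is
realised exactly, permutation-rank uniformity checks must shuffle the map
once to create exchangeability (see `tests/test_acceptance.py`).

Generator scope: the generator plants *stationary* patterns with a single
carrier frequency; it does not model drifting singularities, multiple
simultaneous frequencies, haemodynamic-like confounds, or spatially
correlated noise.

## Preprocessing

* **Coarse graining**: bicubic interpolation (`skimage.transform.resize`,
  order 3, edge padding, anti-aliasing on). Bicubic reproduces linear
  ramps in the interior; spline edge effects are confined to a border a
  few pixels wide, which tests exclude.
* **Band-pass**: Chebyshev type-II band-pass designed with `cheb2ord`
  (stopband edges at `low/2` and `high·2`, 40 dB stopband attenuation,
  1 dB passband ripple), applied forward-backward (`sosfiltfilt`) for zero
  phase. Chebyshev II keeps the *passband* monotone (no ripple where the
  signal lives) while meeting the attenuation spec with a low order.
  Forward-backward filtering is time-reversal symmetric away from the
  ends; with a 0.5 Hz band edge the padding transients take tens of
  seconds to decay, which the symmetry test accounts for.
* **Artifact masking**: frames whose *spatial-mean* trace deviates more
  than `k_sd` SDs from its mean are flagged, with a ±`guard_s` second
  guard dilation. The spatial mean is used because movement and
  illumination artifacts are global, whereas per-pixel statistics would
  flag local signal excursions.
* **Phase**: per-pixel Hilbert transform; the first and last
  `edge_s` seconds (default `1/band_low`, one period of the slowest
  component) are flagged invalid because the analytic signal is unreliable
  near the ends. Pixels with negligible envelope are excluded from the
  flow data term.

## Phase velocity field

The field minimises the convex energy

```
E(u, w) = Σ_x m(x) ρ( φ_t(x) + u φ_x(x) + w φ_y(x) )
        + α Σ_edges (Δu² + Δw²)
```

with `ρ` either quadratic or Charbonnier `sqrt(r² + ε²)` (default,
ε = 1e−3), `m` the per-pixel reliability mask, and α = 0.5. Temporal and
spatial phase differences are circular; the spatial gradient is evaluated
at the mid-frame phasor. The Euler–Lagrange equations are solved by
red-black Gauss–Seidel with a closed-form 2×2 per-pixel solve,
iteratively reweighted for the robust penalty, and accelerated by
successive over-relaxation (ω = 1.9) and a coarse-to-fine pyramid. The
problem is convex, so the pyramid only speeds convergence.

Two numerical choices matter for verification:

* The stopping rule is the maximum **Euler–Lagrange residual** relative to
  the data forcing term (default tol 1e−6). An energy-change rule was
  tried first and plateaus at ~sqrt(machine ε) solution error regardless
  of tolerance; the residual rule lets tiny tolerances drive the iterate
  to agreement with a dense direct solve of the same linear system
  (verified to 1e−8 on 8×8 frames).
* The smoothness term makes the solution the **minimal-norm** explanation
  of the phase data: for a plane wave `φ = k·x − ωt` the recovered
  velocity is `ω k/|k|²` (speed ω/|k| along k), not the unobservable
  full velocity of any particular medium.

The outermost pixel ring is flagged lower-confidence (one-sided gradient
stencils). `pvf_gradient` is the mean Frobenius norm of the pixel-wise
velocity-gradient stack over reliable pixels; low values mean coherent
flow, and shuffled movies separate cleanly from structured ones on this
statistic.

## Wave patterns

* **Order parameter** `vφ̄ = |Σ v| / Σ |v|` over reliable pixels: 1 for
  parallel flow, ~`sqrt(π)/(2 sqrt(N))` for N random directions.
* **Frame labels**: *standing* when the frame's mean speed drops
  `standing_k` (default 2) SDs below the mean of the analysed period's
  speed history (checked first — a speed-collapsed frame can have a
  spuriously high order parameter); *plane* when `vφ̄ ≥ 0.85`; otherwise
  *other*. The standing criterion is inherently relative, so frame
  classification requires a speed history and single-movie pattern
  recovery takes a `reference_speed`.
* **Critical points**: per 2×2 pixel cell, the bilinear interpolants of
  `u` and `w` are intersected analytically (a quadratic in the cell
  coordinate); a corner-sign prefilter is exact because a bilinear patch
  attains its extremes at cell corners. The Jacobian is read off the
  bilinear cell; classification follows the trace–determinant chart
  (Δ < 0 saddle; Δ > 0 with τ > 0 source / τ < 0 sink; node vs focus by
  the discriminant τ² − 4Δ), with degenerate points (|τ| and |Δ| below an
  epsilon scaled to the field's RMS gradient) excluded.
* **Poincaré index**: winding number of the vector angle along a closed
  loop, with wrap-corrected increments. `square_loop` is positively
  oriented in the (x = column, y = row) axes, so sources/sinks score +1
  and saddles −1; the index is additive over enclosed singularities and
  conserved under pairwise creation.
* **Pattern radius**: the largest integer radius R such that every ring
  up to R (Euclidean distance within [R−0.5, R+0.5)) has ≥ 80% of pixels
  whose measured radial velocity component `u·dx + w·dy` matches the sign
  of the Jacobian quadratic form `dᵀJd`. The quadratic form unifies the
  three types: positive everywhere for sources, negative for sinks, and
  quadrant-alternating for saddles, so one rule measures how far each
  type's directional signature extends. The radius is bounded by the
  distance to the field edge.
* **Tracking**: greedy nearest-neighbour linking of same-type points over
  consecutive frames within `link_tol` (default 2 px), ties broken by
  lowest row then column for determinism. The detection threshold keeps
  tracks with lifetime ≥ d frames and minimum radius ≥ r pixels
  (defaults d = 5, r = 3); the survival surface over (d, r) is
  non-increasing by construction.

## Modes

Each field is embedded as a real vector `[Re parts; Im parts]` of length
`2HW` (4576 for 44×52) and the stacked `L × 2HW` matrix is factorised by
thin SVD. Mode k explains `σ_k²/Σσ_i²` of the variance (fractions are kept
for the full spectrum so they sum to 1); projections `M = wR` give frame
loadings. Modes are sign-fixed so each one's largest-magnitude entry is
positive, making results deterministic across runs and LAPACK builds.
`direction_split` reports the squared-projection-weighted share of frames
loading with each sign on a mode; `align_modes` greedily matches two mode
sets by absolute Pearson correlation.

## Statistics

* **Direction states**: a frame is *posteroanterior* when its mean
  direction lies in the open interval (π/4, 3π/4) and *anteroposterior*
  in (5π/4, 7π/4), both requiring order parameter ≥ 0.5 (a relaxed
  threshold — large-scale direction is meaningful below the strict plane
  criterion); otherwise *disordered*. Runs are merged into episodes.
* **Reversal scenarios**: for each coherent → disordered → coherent
  episode triple, source/sink tracks present in the rostral or caudal box
  (default: top/bottom 30% of rows) during the last quarter of the
  disordered episode or the first quarter of the following wave are
  counted, grouped by the following wave's direction. Counts are
  normalised by the number of following waves of that direction and by
  the overall per-type track totals; the two normalisation orders are
  multiplicative and therefore identical, so the `normalization` flag
  documents intent and raw counts are emitted for audit.
* **Emergence maps**: each frame a surviving track occupies a (rounded)
  pixel contributes `1/total_valid_frames`; the denominator is the count
  of artifact-valid analysed frames.
* **Hierarchy correlation**: regional means of the emergence map are
  correlated (Pearson) with a per-region hierarchy index; the null
  shuffles pixel locations of the probability map and recomputes the
  regional correlation (seeded, `n_perm` default 1000), reporting the
  observed rank, an add-one-corrected two-sided p, and central coverage
  bands.

## Limitations

* The generator's planted patterns are stationary and single-frequency;
  recovery rates quoted by the tests apply to that regime.
* The standing/plane decision is relative to a speed history or reference
  speed; there is no absolute speed threshold.
* The flow estimate near the field border uses one-sided stencils and is
  flagged lower-confidence; critical points within ~1 px of the border
  are unreliable.
* The saddle generator kind is a composite realisation (saddle + two
  flanking sources); single-pattern classification of such movies reports
  the dominant track, which may legitimately be a source.
* `reversal_scenarios` requires coherent–disordered–coherent triples; a
  steady synthetic wave yields none (a warning, not an error).
* The permutation null permutes pixels, which destroys spatial
  autocorrelation; for strongly smoothed maps it is anti-conservative
  with respect to region-level exchangeability.
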