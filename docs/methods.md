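# Methods

## Signal model

A volume element's sub-resolution microstructure is an anisotropic 3D
Gaussian density ρ(r) ∝ exp(−½ rᵀ**T** r) with positive-definite precision
tensor **T** = **R** diag(σ₁⁻², σ₂⁻², σ₃⁻²) **R**ᵀ; σᵢ are the standard
deviations along the principal axes, so the *smallest* eigenvalue of **T**
marks the *longest* structural axis. Projecting the density along the
optical axis n̂ and evaluating its autocorrelation along the interferometer
sensitivity axis ê yields the dark-field extinction coefficient, which in
the instrument frame (ê → x, n̂ → z) is

    μ_DF = (T′_xx − T′_xz²/T′_zz) / √T′_zz ,        T′ = BᵀT B,

with B = (ê, n̂×ê, n̂) as columns. The first factor T′_zz^(−1/2) is the
density's standard deviation along the optical axis (leading-order
scattering cross section); the bracket is the precision of the projected
marginal along ê — the Schur complement of the z-block, which is the basis
of the independent test oracle (invert **T** to the covariance, marginalize
z, invert the in-plane block). All factors affecting only the global signal
scale are dropped (proportionality constant 1): the signal is homogeneous of
degree ½ in **T** (μ(c**T**) = √c μ(**T**)), so trace normalization
trace(**T**) = 1 loses no orientation information and the reconstruction
absorbs whatever scale the synthesizer emits. The y-axis sign convention of
the instrument frame is irrelevant to μ (only xx, xz, zz enter) and is fixed
right-handed for reproducibility.

Assumptions inherited from the signal model: isolated volume elements (no
line integrals through extended objects), noiseless signals, Gaussian
single-scale microstructure, no energy or correlation-length dependence.

## Ensemble (synthetic-data generator)

The generator's defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| grid_size | 20 | points per eigenvalue ramp (20×20 = 400 triplets) |
| rotations_per_triplet | 300 | Haar-uniform orientations per triplet |
| n_samples_per_trajectory | 29 | poses per circular trajectory |
| geometry | full | 13 trajectories (377 poses); "orthogonal": 3 (87) |
| λ₀, n_passes | 0.2, 25 | relaxation schedule, τ = 3·k_max/25 |

Eigenvalue triplets: two orthogonal linear ramps on the index grid, 0→1/3
and 0→1/2 (endpoints inclusive on both — the inclusive choice is configured
by `grid_size` and documented here as a convention; any consistent choice
covers the same simplex), third value from the unit-sum constraint, each
triplet sorted ascending. The redundant triangular region of the resulting
coverage is retained. Zero eigenvalues (infinitely extended structures, a
divergent-signal limit) are clamped at 1e-9 and the triplet renormalized to
unit sum, so the forward model stays finite while these physically extreme
cases remain in the ensemble; they carry a `clamped` flag. Triplets whose
two smallest eigenvalues coincide leave the ground-truth principal axis
ill-defined; they carry a `degenerate` flag and ensemble statistics are
reported both with and without them (the mode-based σ estimate is
insensitive to this tail either way).

Rotations are sampled exactly Haar-uniformly via normalized Gaussian
quaternions; each instance draws from a private substream keyed by
(seed, instance_id), so results are independent of chunking and
bit-reproducible. Uniformity is verified by a Kolmogorov–Smirnov test of
the polar cosine of transported unit vectors.

Circular trajectories: for axis â, an in-plane basis u (normalized rejection
of the coordinate axis least aligned with â, ties broken by index) and
v = â×u; poses n̂_j = −(cos θ_j u + sin θ_j v), ê_j = â×n̂_j at θ_j = 2πj/m.
Phases are a free convention (ensemble statistics average over random
orientations); the deterministic choice above makes runs reproducible. With
29 samples over the full circle and no endpoint duplication the 13
trajectories yield 377 pairwise-distinct (n̂, ê) combinations; distinct
trajectories can share an n̂ while differing in ê, which is what
distinguishes the two surrogate parametrizations.

## Reconstruction

Starting from U = 0, the damped back-projection
U ← U + λ_k (r̂ r̂ᵀ)(μ_i − r̂ᵀU r̂) is applied with each of the P projections
visited 25 times (k_max = 25 P) in a deterministic cyclic sweep; an optional
seeded per-pass shuffle exists because the decaying schedule makes the order
immaterial on consistent data (verified to 1e-3). λ_k = λ₀2^(−k/τ) with
λ₀ = 0.2, τ = 3k_max/25; convergence is by schedule exhaustion only, with no
early stopping. The update is implemented on the 6 free components of U
(algebraically identical to symmetric 9-entry updates) and vectorized over
instances sharing one geometry, which is what makes the 120 000-instance
study a minutes-scale computation. On consistent linear data the iteration
agrees with the closed-form least-squares solution (the independent oracle,
solved by `numpy.linalg.lstsq` over the 6 components) to better than 1e-3;
fewer than 6 measurements raise a rank error, and a rank-deficient design
with ≥ 6 measurements returns the minimum-norm solution (per-axis means in
the axis-aligned toy case) unless `require_full_rank=True`.

Surrogate tensors are *not* forced positive definite: the optical-axis model
**N** systematically develops negative eigenvalues, which is part of the
studied behaviour.

## Evaluation

- **NRMSE** (per instance): RMS residual between synthesized signals and the
  fitted quadratic form, divided by the mean signal.
- **Angular error**: Δθ = arccos |v̂_T·v̂_U| ∈ [0°, 90°], sign-invariant.
  v̂_T is the smallest-eigenvalue eigenvector of **T**; v̂_E the
  smallest-eigenvalue eigenvector of **E**; v̂_N the *largest*-eigenvalue
  eigenvector of **N** (anti-correlated spectrum). Eigenvector signs are
  standardized to a non-negative last nonzero component.
- **σ_Δθ**: a normal distribution of inclination angles integrated over
  azimuth has density ∝ sin(Δθ)e^(−Δθ²/2σ²) ≈ Δθ e^(−Δθ²/2σ²), with mode at
  σ in the small-angle regime (the exact sin-weighted mode deviates from σ
  by σ²/6, < 1% for σ ≤ 5°). The printed density mixes σ and σ² between its
  two forms; the dimensionally consistent σ² form is used. σ is estimated as
  the empirical mode: Freedman–Diaconis histogram (bin width 2·IQR·n^(−1/3),
  bins from 0), peak location refined by a quadratic fit over the contiguous
  bins above 75% of the peak count. The refinement matters: the raw peak-bin
  center wanders by up to ~18% at n = 10⁵ (bin-level Poisson noise over a
  flat-topped peak), while the refined estimator stays within ~5% on a
  Rayleigh benchmark; the 75% window is the bias/variance optimum on that
  benchmark (wider windows inherit skew bias, the bare argmax inherits
  noise). As a cross-check the small-angle density is least-squares fitted
  to the histogram up to its maximum; both values are reported, the
  mode-based one is authoritative.
- **Spectra**: eigenvalues of each tensor sorted ascending and normalized by
  their sum; for **N** the surrogate spectrum is paired in descending order
  against the ascending ground truth, matching anti-correlated partners.
  Records where the surrogate trace nearly cancels (|trace| < 1e-6·max|eig|)
  cannot be normalized meaningfully; they are flagged, counted, and excluded
  from the pair-density histograms.
- **Mean signal**: E[r̂ᵀU r̂] over uniform directions is trace(U)/3, so
  trace(U)/3 vs mean(μ) scatter (and its regression slope) measures zeroth-
  order signal reproduction.

## Study scales and what passing shows

The full study is 400 triplets × 300 rotations = 120 000 instances with 377
(or 87) signals each. The desk-scale profile used by the test suite and the
acceptance script is 10×10 × 50 = 5000 instances — chosen so ensemble modes
are stable (the σ estimates move by only a few hundredths of a degree across
seeds) while a complete two-geometry run takes seconds. Both scales share
every code path; `chunk_size` bounds memory and provably does not change
results.

The generator emulates the idealized study conditions: noiseless signals,
perfectly known geometry, isolated volume elements. Passing results
therefore quantify the *intrinsic* approximation error of the linear
surrogate models — they do not speak to detector noise, signal
superposition along rays in real tomography, or model error in the Gaussian
microstructure assumption.

## Numerical choices

- Eigenvalue floor 1e-9 (clamping), orthonormality tolerances 1e-10,
  direction unit-norm tolerance 1e-8, |dot| clamp 1e-9 in arccos.
- Eigen-decompositions via `numpy.linalg.eigh` (ascending order guaranteed).
- Degenerate ground-truth axes: the generating rotation column is used as
  v̂_T (exact, avoids eigh tie-breaking); flagged instances are kept.
- Stored NRMSE histograms are capped at 400 bins for compact summaries; the
  mode estimate always uses the uncapped FD binning.
- Spectra pair-density y-ranges are clipped to the [0.5, 99.5] percentile to
  keep unstable clamped instances from blowing up the binning range.

## Known limitations

- σ_Δθ is a mode-based scale parameter, not a full distribution fit; the
  empirical angular-error distributions match the inclination-angle density
  only up to their maximum, by construction of the estimator.
- The minimum-norm convention for rank-deficient least-squares designs is a
  choice; the iterative scheme applied to such data converges to a
  data-dependent point in the solution set instead.
- The 2D spectra histograms are binned counts, not kernel-density plots.
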