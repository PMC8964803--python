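# Methods

## Model

A ptychography dataset consists of `n` non-negative diffraction frames
`d` (each `S×S`), a known complex probe `p` (`S×S`), and `n` integer scan
positions on an `H×W` object grid. Positions are 0-based `(row, col)`
top-left corners of half-open `S×S` footprints; footprints must lie fully
inside the object (out-of-bounds positions are rejected, never wrapped or
clipped). Sub-pixel positions are not supported.

The forward operator is `G = F Q`: `Q` extracts the object patch under each
footprint and multiplies it elementwise by the probe; `F` applies an
independent 2-D **orthonormal** DFT per patch. The orthonormal (unitary)
convention is a deliberate choice: it makes `Fᴴ` exactly the inverse
transform, so the adjoint identity `⟨Gx, y⟩ = ⟨x, Gᴴy⟩` holds to machine
precision and Parseval's identity ties the far-field and patch energies
together. Any fixed DFT normalization would give an equivalent optimization
problem with rescaled step lengths; outputs of other implementations agree
only up to that convention.

Photon counting is Poisson, so the estimate minimizes the negative
log-likelihood (up to ψ-independent constants)

    F(ψ) = Σⱼ Σ_pixels { |Gψ|² − 2 d log|Gψ| }.

Pixels with `d = 0` contribute only `|Gψ|²`. `|Gψ|` is clamped below at
`eps_guard` (default 1e−32, far below any meaningful signal on unit-scale
data) inside the logarithm and the gradient's division, keeping the phase of
`Gψ`; where `Gψ` is exactly zero the ratio `d/(Gψ)*` is taken as zero.

## Gradient and the Wirtinger convention

F is real-valued in the complex variable ψ. We define the gradient as the
derivative with respect to `conj(ψ)`:

    ∇ψF = Gᴴ ( Gψ − d / (Gψ)* ),

under which the first-order change of F along a perturbation η is
`2·Re⟨∇F, η⟩`. This convention is fixed throughout the package and verified
by central finite differences in the test suite (relative agreement 1e−4
over ≥ 20 random instances).

## Dai–Yuan CG and line search

Iterations: `ψₘ₊₁ = ψₘ + γₘηₘ` with `η₀ = −∇F(ψ₀)` and

    ηₘ = −∇F(ψₘ) + αₘ ηₘ₋₁,
    αₘ = ‖∇F(ψₘ)‖² / Re⟨ηₘ₋₁, ∇F(ψₘ) − ∇F(ψₘ₋₁)⟩.

The inner product is `⟨a,b⟩ = Σ conj(a)·b`; taking the real part of the
denominator is required for a real coefficient on complex grids. If the
denominator's magnitude falls below `eps_guard`, the direction restarts at
steepest descent (standard CG practice for degenerate curvature estimates)
rather than raising.

The step length comes from a backtracking line search: starting at `gamma0`
(default 1.0, reset every iteration — no warm start), γ is multiplied by
`shrink` (default 0.5) until `F(ψ + γη) ≤ F(ψ) + γt`, with `t = 0` by
default, so every accepted step is a non-increase and the recorded cost
sequence is monotone whenever the shrink cap (default 32) is not hit.
Hitting the cap returns the last trial step with a warning — on these data a
descent direction always admits an acceptable step well before 0.5³².

Because G is linear, `G(ψ+γη) = Gψ + γGη`, so the cost along the ray is
evaluated from `|Gψ|²`, `|Gη|²` and `Re(conj(Gψ)·Gη)`: the intensity term
reduces to a scalar quadratic in γ, and only the log term over pixels with
`d > 0` needs elementwise work. Extra line-search trials therefore cost no
Fourier transforms.

Initialization defaults to ψ₀ ≡ 1 (unit transmission); a seeded random
complex perturbation is available. Double precision is the default; single
precision is supported for speed. An optional plateau rule (`stop_tol`)
stops when `‖ψₘ−ψₘ₋₁‖ ≤ stop_tol·‖ψₘ‖`.

A constant-step gradient-descent solver is included as the comparison
baseline; it requires manual step tuning and converges more slowly, which a
paired-run test demonstrates on a small instance.

## Partitioned execution

The object is decomposed into `P` contiguous strips along its longer axis
(1-D decomposition; a 2-D grid would use the identical stage protocol but
more neighbor links, and is left as an extension point). Each strip must be
at least `S` tall. Design choices:

- **Halo width = S** (the full probe side). A footprint touching an owned
  strip starts at most `S−1` rows outside it, so the halo-extended slice
  contains every such footprint entirely. This makes the owned block of the
  locally computed gradient *identical* to the monolithic gradient block —
  same contributing patterns, same per-pixel accumulation order (patterns
  are always accumulated in ascending global index).
- **Ownership by footprint center**, boundary ties to the lower worker id:
  deterministic, total, and every pattern is owned exactly once (this
  single-counting is asserted at run time and in tests).
- **Halo duplicates** are all patterns whose footprint intersects the
  halo-extended slice. Duplicates that do not reach the owned strip can
  overhang the local slice; patch extraction clips them (their contributions
  only land on halo pixels, which are never used as results).
- **DIR on the master** (worker 0): the Dai–Yuan coefficient needs global
  norms, so owned gradient blocks are gathered, each pixel taken from its
  unique owner (block selection, not summation — halo-duplicated patterns
  would double count under summation), the direction is computed exactly as
  in the monolithic solver, and halo-extended slices are scattered back.
  The master retains the gradient/direction history.
- **LS by all-reduce**: per trial step each worker evaluates its partial
  cost over owned patterns only; partials are summed in ascending worker id
  order and the shrink loop runs on the global scalar, so all workers accept
  the same γ.
- **Update + border exchange**: slices update as `ψ + γη`; each worker then
  overwrites its halo strips with the owning neighbor's pixels, making halo
  pixels bitwise equal to their owners.

Equivalence to the monolithic solver is therefore exact except for the
summation order of the cost all-reduce (tested at ≤ 1e−6 relative over 20
iterations; in practice the iterates agree to machine precision, and `P = 1`
reproduces the monolithic run bitwise). Reductions in fixed worker order
were chosen over performance-motivated unordered reductions precisely to
keep runs reproducible.

Backends execute the per-worker stage functions: `serial` (in-process loop,
the default and the reference for determinism tests), `process` (a process
pool that ships worker state per stage — demonstrating the transport-
agnostic contract, worthwhile only for large per-worker workloads), and
`device` (a named extension point for accelerator arrays, requiring cupy;
it raises a configuration error when unavailable). Physical transports
(MPI/NCCL-style) are a performance concern outside the correctness contract
and are not bound here.

## Synthetic data

The generator emulates bench-style synthetic studies so no assets are
downloaded:

- **Star object**: `n_spokes` alternating sectors (`cos(kθ) ≥ 0`) in an
  annulus (outer radius 45% of the side), complex transmission with
  amplitude in `[0.5, 1.0]` and phase in `[0, π/3]` by default — moderate,
  realistic contrast for a transmissive test target. Background exactly
  `1+0j`, matching the solver's default initialization so unilluminated
  margins carry no error.
- **Texture object**: Gaussian-filtered seeded noise mapped to the same
  amplitude/phase ranges (a photographic-object stand-in).
- **Probes**: disk (top-hat, default radius `S/4`) or Gaussian (`σ = S/8`),
  unit peak amplitude, optional quadratic phase.
- **Scans**: jittered raster with step < S (default step 16 for `S = 64`,
  75% linear overlap, the regime in which ptychographic reconstructions are
  well conditioned) and integer jitter (default 2 px) breaking raster
  periodicity; positions clipped to containment. A decimation helper
  subsamples scans by grid stride (default) or seeded random choice.
- **Measurements**: exact `|G ψ|²`, optionally replaced by seeded Poisson
  draws with mean `flux·d/max(d)` (single global flux scale).

What this does *not* emulate: partial coherence, detector point-spread and
background, probe uncertainty (the probe is known exactly), position errors,
and real-detector quantization. Passing tests therefore demonstrate the
correctness of the estimator and of the partitioned execution — not
robustness to the systematic errors of beamline data.

## Metrics

The Poisson cost depends on ψ only through `|Gψ|`, so reconstructions carry
a global phase ambiguity. All comparisons first multiply the estimate by
`e^{−iθ}` with `θ = arg⟨ref, est⟩` (the closed-form minimizer of the
aligned residual norm), then score **amplitude** images: SSIM (canonical
Gaussian-window formulation, σ = 1.5, population covariances, default
stabilization constants; data range = reference amplitude range) and PSNR
with peak = reference amplitude maximum. Whether published curves used
amplitude, phase or complex differences is generally unstated; amplitude is
adopted and documented here. Convergence within a run is tracked by the
iterate 2-norm `‖ψₘ − ψₘ₋₁‖₂`.

## Problem sizes

The test suite runs desk-scale instances chosen to exercise every contract
in seconds: 96²–128² objects with `S = 32` for unit/property tests, a 256²
star (`S = 64`, 169 frames, 20 iterations) for partition-equivalence and
curve-identity checks, and one 512² star (`S = 64`, 841 frames, up to 512
iterations) run to the iterate-norm plateau for the fidelity numbers, which
reaches SSIM ≈ 1.0 and PSNR well above 80 dB on noise-free data. The
memory-planning helper reproduces the reference figure that a 512-pixel
detector with 16K patterns at 4 bytes/value needs exactly 16 GiB, the load
that motivates distributing frames across workers in the first place.

## Known limitations

- Probe retrieval, position refinement, multi-mode probes, near-field
  propagation and regularization are out of scope; the probe is fixed.
- The decomposition is 1-D; very wide aspect ratios aside, this bounds the
  worker count by `floor(L/S)` along the longer axis.
- Poisson-noisy data are generated and accepted by the solver, but the
  headline fidelity figures are defined on noise-free data; no denoising
  claims are made.
- The process backend duplicates worker state per stage call; it is a
  correctness demonstration of the logical-worker contract, not an
  optimized transport.
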