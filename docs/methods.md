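# Methods

## Model

Registration is posed as optimal control of the transport equation. The
unknown is a stationary velocity field v : [0, 2π)^d → R^d, d ∈ {2, 3}; its
flow over t ∈ [0, 1] deforms the template m₀ toward the reference m₁. The
objective is

J(v) = ½ h^d Σ (m(·,1) − m₁)² + (α/2) ⟨A v, v⟩ + (γ/2) h^d Σ (∇·v)²,

subject to ∂ₜm + v·∇m = 0, m(·,0) = m₀, with h^d the cell volume of the
uniform periodic grid. The Sobolev operator A acts componentwise with
spectral symbol |k|² (`h1s`, default), |k|²+1 (`h1`) or |k|⁴ (`h2s`). The
divergence term is a quadratic *penalty relaxation* of an incompressibility
constraint: γ = 0 disables it, large γ approaches volume-preserving flow; a
hard (KKT-enforced) constraint is out of scope. Smoothness of v, not an
explicit constraint, is what keeps the flow diffeomorphic; the package
certifies the result a posteriori through det ∇y > 0.

Assumptions worth stating: intensities are comparable between the two images
(squared-L² distance; no multi-modal similarity measures), the domain is
periodic (images that touch their boundary will wrap; a padding margin is the
caller's responsibility), and grids are square/cubic with even size per axis.

## Discretization

**Spatial derivatives** are spectral: real-to-complex FFTs, multiplication by
ik (Nyquist mode zeroed for odd derivatives — the standard convention on even
grids), inverse transform. Band-limited fields are differentiated to rounding
error. The regularization inverse (αA + shift·I)⁻¹ is an exact per-mode
division; for the seminorm models the zero mode is handled by the shift
alone, with default shift = 10⁻³ α.

**Transport** is semi-Lagrangian and unconditionally stable. Departure
points: RK2 midpoint trace x* = x − dt·v(x − (dt/2)v(x)) with the midpoint
velocity interpolated; because v is stationary the trace is computed once per
solve and reused across all steps. Interpolation is periodic interpolating
cubic B-spline (scipy.ndimage with grid-wrap boundary and prefiltering),
with an order-1 fallback that satisfies a discrete max principle. Cubic
B-spline interpolation is O(h⁴) and exact at the nodes.

**The adjoint** of the transport constraint is the continuity-type equation
−∂ₜλ − ∇·(vλ) = 0 integrated backward from λ(·,1) = m₁ − m(·,1). Along the
reversed characteristics the multiplier grows as exp(∫ ∇·v); each backward
step applies exp((dt/2)∇·v), advects along −v, and applies exp((dt/2)∇·v)
again — a Strang splitting whose exponential factors amount to the
trapezoidal rule for the growth integral. Two details matter: the factors
must be exponential (the linearized form 1 + dt·∇·v loses an O(dt²(∇·v)²)
term per step and degrades the solver to first order), and the advection must
follow −v (pairing the +v departure points with a 1 − dt·∇·v factor looks
plausible but does not conserve the multiplier's integral). The implemented
scheme conserves mass to O(dt²) per step and self-converges at second order.

**Reduced gradient.** g = αAv − γ∇(∇·v) + ∫₀¹ λ∇m dt, with the time integral
by the trapezoidal rule over the nt+1 stored frames and ∇m spectral per
frame. This is the continuous-adjoint gradient evaluated discretely, not the
exact discrete adjoint of the semi-Lagrangian scheme; the finite-difference
verification (relative error ≤ 10⁻³ at the best step size) bounds the
resulting inconsistency. One conditioning point: the verification compares
⟨g, w⟩ with a central difference along w. In a 10⁴-dimensional space a random
w is nearly orthogonal to g, which inflates the *relative* discrepancy
without testing the gradient any harder, so the test direction mixes the
normalized gradient with a random band-limited perturbation.

**Gauss–Newton Hessian.** H w = αAw − γ∇(∇·w) + ∫ λ̃∇m dt, where the
incremental state solves ∂ₜm̃ + v·∇m̃ = −w·∇m (homogeneous part by the reused
departure points, source by trapezoid along the characteristic) and the
incremental adjoint runs the continuity solver backward from λ̃(1) = −m̃(1).
Gauss–Newton drops the second-order constraint terms, keeping H positive
semi-definite, so the Krylov direction is a descent direction whenever
g ≠ 0. Discrete symmetry is approximate (the adjoint is not the exact
transpose); measured relative asymmetry is ~10⁻³ on fields the grid resolves.

**Outer iteration.** Start from v = 0; per iteration solve H p = −g by
preconditioned CG with preconditioner (αA + shift·I)⁻¹, take an Armijo
backtracking step (halvings from 1), and stop when ‖g‖ ≤ outer_tol·‖g₀‖.
Negative curvature detected inside CG truncates the inner solve; if it occurs
on the first pass the preconditioned gradient is used (steepest descent in
the Sobolev metric). Identical inputs are recognized through an absolute
gradient floor of 10⁻¹³(1 + ‖m₁‖) that absorbs interpolation round-off.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `reg_model` | `h1s` | Sobolev model of A |
| `alpha` | 5·10⁻³ | regularization weight; larger → smoother, smaller deformation |
| `div_gamma` | 0 | divergence penalty weight (units of the objective) |
| `nt` | 8 | semi-Lagrangian steps on [0, 1] |
| `interp_order` | 3 | transport interpolation (1 = linear, 3 = cubic) |
| `outer_tol` | 5·10⁻² | relative gradient reduction for convergence |
| `outer_maxit` | 50 | outer iteration cap |
| `krylov_tol`, `krylov_maxit` | 10⁻¹, 50 | inner PCG control (fixed forcing) |
| `ls_c1`, `ls_maxit` | 10⁻⁴, 20 | Armijo constant, max halvings |
| `precond_shift` | 10⁻³ α | identity shift of the preconditioner |

Velocities are in domain lengths per unit flow time, so a magnitude-0.3 field
moves features by up to ~0.3/2π ≈ 5% of the image width. The default α was
chosen so that, on the synthetic benchmark family (64² bump images, smooth
velocities of magnitude ≲ 0.3), the converged solution removes well over 90%
of the squared mismatch while keeping min det ∇y ≈ 0.5 — comfortably
diffeomorphic. α = 10⁻² was measurably too stiff for that regime (the
*converged* optimum retains ~11% of the mismatch); values below ~10⁻³ start
to trade Jacobian margin for fit. No α-continuation or multi-resolution
scheme is used: solves are single-level by design, which is the main
limitation for large deformations.

## Deformation maps and diagnostics

Maps are stored as displacement fields u with y(x) = x + u(x), keeping
periodic wrapping unambiguous. The *forward* map integrates the
characteristics against the flow (pullback convention), so warping the
template through it reproduces the transported template — the package's two
numerical routes to the same object, which the tests require to agree to
5·10⁻³. The inverse map integrates along +v; forward∘inverse returns the
identity to O(h² + dt²). Jacobians are spectral derivatives of the
displacement (consistent with the rest of the code); det ∇y is reported
per-node with its minimum as the headline diagnostic.

## Synthetic data

The generator builds the study conditions for every solver test: a template
that is a seeded sum of 5 periodic Gaussian bumps (widths 0.35–0.9 rad,
normalized to [0, 1]) — smooth, feature-rich, with flat valleys between
features like real images have flat background — and a ground-truth velocity
drawn as a seeded band-limited random field (Fourier modes ≤ 4 per axis)
scaled to a prescribed max |v|, damped by 20% steps if its flow ever folds
(min det ∇y ≤ 0.1). The reference image is the template transported at high
accuracy (nt = 64). The committed benchmark fixture is seed 42, 64²,
magnitude 0.3.

What the generator does *not* emulate: acquisition noise, intensity
inhomogeneity between the two images, occlusion/appearance of structures,
non-periodic boundaries, and anisotropic voxels. Passing tests therefore
demonstrate correctness of the formulation and solver, not robustness to
clinical-image artifacts; on real data the L²-distance assumption (matched
intensities) is the first thing to check.

Recovery of the *velocity* itself is fundamentally limited: stationary
parameterizations of a given map are non-unique, and v is only observable
along ∇m. The recovery test uses a mode-1 ground truth and a 10-bump
template, where the visible, low-frequency part dominates; it asks for
relative L² error ≤ 0.5, which is a statement about the deformation being
captured, not the velocity being identified.

## Numerical choices and edge cases

- All arithmetic is float64; quadratures are the h^d node sum, spectrally
  accurate for periodic integrands.
- Grid sizes must be even and ≥ 4 (real-FFT layout, Nyquist conventions).
- Departure points are wrapped into [0, 2π); displacement fields are left
  unwrapped. A time step carrying points farther than the domain extent only
  warns — the scheme is unconditionally stable but inaccurate there.
- Non-finite inputs are rejected at container construction; mismatched grids
  raise immediately.
- `normalize_intensity` maps constant images to 0 (documented convention).
- I/O accepts NIfTI-1 (.nii/.nii.gz) and a plain .npz container; voxel
  spacing is recorded in headers but the solver always works on the
  normalized periodic domain. Non-square volumes are rejected with a clear
  message. Written files are deterministic (gzip without timestamps), so
  fixed-seed runs are byte-identical.

## Verification problem sizes

The test suite and the acceptance script use 8²–16² grids for operator
algebra and oracle comparisons, 32² for transport accuracy, 64² for gradient
verification and end-to-end registration, and 128² for self-convergence
studies (reference nt = 256); 3D paths are exercised on 8³–16³ volumes. These
sizes keep the whole suite under a minute while leaving every measured
quantity far from its tolerance.
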