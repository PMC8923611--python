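# diffeoreg

Diffeomorphic image registration with a stationary velocity field, at desk
scale: a NumPy/SciPy library plus a thin command-line interface for 2D and
small 3D images.

## The problem

Given a template image m₀(x) and a reference image m₁(x) of the same object,
registration seeks a plausible spatial map y(x) with m₀(x) ≈ m₁(y(x)). For
medical and microscopy images the map should be a **diffeomorphism** —
continuous, one-to-one, with a smooth inverse — so that anatomy is deformed,
never torn or folded. `diffeoreg` parameterizes the map by a smooth stationary
velocity field v(x) and solves the PDE-constrained optimization problem

```
min_v   ½ ‖m(·,1) − m₁‖²_L²  +  (α/2) ⟨A v, v⟩  +  (γ/2) ‖∇·v‖²_L²
s.t.    ∂ₜm + v·∇m = 0,   m(·,0) = m₀
```

on the periodic domain [0, 2π)^d. The first term is the image mismatch after
transporting the template along v for unit time; A is a Sobolev
regularization operator (H¹-seminorm by default, full H¹ or H²-seminorm
optional); the optional divergence penalty pushes the flow toward
incompressibility. A positive Jacobian determinant det ∇y > 0 everywhere is
the reported diffeomorphism certificate.

Numerics: unconditionally stable **semi-Lagrangian** transport (RK2
characteristic tracing + periodic cubic interpolation), **spectral (FFT)**
differentiation and exact spectral inversion of the regularization operator,
an adjoint (continuity-equation) solve for the reduced gradient, and a
reduced-space **Gauss–Newton–Krylov** outer iteration: preconditioned
conjugate gradients on the Gauss–Newton system with the inverse
regularization operator as preconditioner, globalized by an Armijo line
search.

## Worked example

```python
from diffeoreg import register
from diffeoreg.synthetic import generate_synthetic_problem

# template of Gaussian bumps, deformed by a known smooth velocity
prob = generate_synthetic_problem(seed=42, dims=64, magnitude=0.3)
result = register(prob.m0, prob.m1)
print(f"mismatch ratio {result.final_mismatch_ratio:.4f}, "
      f"min det J {result.min_jacobian_det:.4f}")
```

prints

```
mismatch ratio 0.0529, min det J 0.5363
```

i.e. the solver removed ~95% of the squared-L² image mismatch in 4
Gauss–Newton iterations, and the recovered deformation map is a discrete
diffeomorphism (its Jacobian determinant stays above 0.53 everywhere; 1 would
mean volume preservation, ≤ 0 would mean folding). The `examples/` directory
has one short script per capability: spectral operators, transport and
adjoint solves, end-to-end registration, deformation diagnostics, and the
shell pipeline.

The same pipeline from a shell:

```sh
diffeoreg synth --seed 42 --dims 64 --magnitude 0.3 -x problem/
diffeoreg register -mr problem/reference.nii.gz -mt problem/template.nii.gz -x result/
diffeoreg metrics --result result/
```

`register` writes the velocity components, deformation map, Jacobian
determinant, deformed template, and residual as NIfTI volumes, plus a
machine-readable convergence log; repeat runs are byte-identical.

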