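"""End-to-end registration of a synthetic problem with known ground truth.

Generates a template of Gaussian bumps, deforms it with a known smooth
velocity, runs the Gauss-Newton-Krylov solver, and reports how much of the
image mismatch was removed and whether the recovered map is diffeomorphic.
"""

from diffeoreg import register
from diffeoreg.synthetic import generate_synthetic_problem

prob = generate_synthetic_problem(seed=42, dims=64, magnitude=0.3)

result = register(prob.m0, prob.m1)

print("outer iterations:   ", result.iterations)
print("converged:          ", result.converged)
for rec in result.history:
    print(
        f"  it {rec.index}: J={rec.objective:.4e} |g|={rec.gradient_norm:.4e} "
        f"step={rec.step_length:.2f} krylov={rec.krylov_iters}"
    )
print("mismatch ratio:     ", f"{result.final_mismatch_ratio:.4f}")
# final/initial squared-L2 image distance; <= 0.1 means >= 90% removed
print("min det(grad y):    ", f"{result.min_jacobian_det:.4f}")
# strictly positive everywhere: the recovered map is a discrete diffeomorphism
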