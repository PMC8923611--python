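"""The registration objective and its adjoint-based reduced gradient.

The variational problem is

    min_v  J(v) = dist(m(1), m1) + (alpha/2) <A v, v> + (gamma/2) ||div v||^2

subject to the transport of the template m0 along v (solved by the transport
module). The distance is the squared L2 mismatch

    dist(m(1), m1) = (1/2) h^d sum (m(1) - m1)^2 ,

and A is the Sobolev regularization operator selected by the configuration.

Eliminating the state and the Lagrange multiplier gives the reduced gradient

    g(v) = alpha * A v - gamma * grad(div v) + int_0^1 lambda grad(m) dt ,

where lambda solves the continuity-type adjoint equation backward from the
terminal condition lambda(1) = m1 - m(1). The sign convention makes g the
gradient of the minimized objective, so -g is a descent direction. The time
integral uses the trapezoidal rule over the nt+1 stored frames with grad(m)
evaluated spectrally per frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RegistrationConfig
from .grid import ScalarField, VelocityField, inner, same_grid
from .spectral import (
    divergence_gradient,
    regularization_operator_apply,
    spectral_divergence,
    spectral_gradient,
)
from .transport import Trajectory, solve_adjoint, solve_state

__all__ = [
    "ObjectiveReport",
    "l2_distance",
    "regularization_value",
    "divergence_penalty",
    "evaluate_objective",
    "reduced_gradient",
    "reduced_gradient_and_state",
    "body_force",
    "regularization_gradient",
]


@dataclass
class ObjectiveReport:
    """The objective value split into its three terms."""

    total: float
    distance: float
    regularization: float
    div_penalty: float


def l2_distance(m_final: ScalarField, m1: ScalarField) -> float:
    """(1/2) h^d sum (m_final - m1)^2 — the squared-L2 image mismatch."""
    grid = same_grid(m_final, m1)
    diff = m_final.values - m1.values
    return float(0.5 * grid.cell_volume * np.sum(diff * diff))


def regularization_value(v: VelocityField, cfg: RegistrationConfig) -> float:
    """(alpha/2) <A v, v> with A the configured Sobolev operator."""
    av = regularization_operator_apply(v, cfg.reg_model)
    return 0.5 * cfg.alpha * inner(av, v)


def divergence_penalty(v: VelocityField, gamma: float) -> float:
    """(gamma/2) h^d sum (div v)^2 — quadratic relaxation of the
    incompressibility constraint."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if gamma == 0.0:
        return 0.0
    div = spectral_divergence(v)
    return float(0.5 * gamma * v.grid.cell_volume * np.sum(div.values**2))


def evaluate_objective(
    v: VelocityField,
    m0: ScalarField,
    m1: ScalarField,
    cfg: RegistrationConfig,
) -> ObjectiveReport:
    """Transport m0 along v and assemble the three objective terms."""
    same_grid(v, m0, m1)
    state = solve_state(m0, v, cfg.nt, cfg.interp_order)
    dist = l2_distance(state.final, m1)
    reg = regularization_value(v, cfg)
    pen = divergence_penalty(v, cfg.div_gamma)
    return ObjectiveReport(dist + reg + pen, dist, reg, pen)


def regularization_gradient(
    v: VelocityField, cfg: RegistrationConfig
) -> VelocityField:
    """alpha * A v - gamma * grad(div v): the transport-free part of g."""
    g = cfg.alpha * regularization_operator_apply(v, cfg.reg_model).data
    if cfg.div_gamma > 0:
        g = g - cfg.div_gamma * divergence_gradient(v).data
    return VelocityField(v.grid, g)


def body_force(state: Trajectory, adjoint: Trajectory) -> VelocityField:
    """int_0^1 lambda grad(m) dt by trapezoidal quadrature over the frames."""
    grid = state.grid
    nt = len(state.frames) - 1
    dt = 1.0 / nt
    acc = np.zeros((grid.ndim,) + grid.dims)
    for k, (m_k, lam_k) in enumerate(zip(state.frames, adjoint.frames)):
        w = 0.5 * dt if k in (0, nt) else dt
        acc += w * lam_k.values * spectral_gradient(m_k).data
    return VelocityField(grid, acc)


def reduced_gradient_and_state(
    v: VelocityField,
    m0: ScalarField,
    m1: ScalarField,
    cfg: RegistrationConfig,
) -> tuple[VelocityField, Trajectory, ObjectiveReport]:
    """Reduced gradient plus the state trajectory and objective it used."""
    same_grid(v, m0, m1)
    state = solve_state(m0, v, cfg.nt, cfg.interp_order)
    dist = l2_distance(state.final, m1)
    reg = regularization_value(v, cfg)
    pen = divergence_penalty(v, cfg.div_gamma)
    report = ObjectiveReport(dist + reg + pen, dist, reg, pen)

    lam1 = ScalarField(v.grid, m1.values - state.final.values)
    adjoint = solve_adjoint(lam1, v, cfg.nt, cfg.interp_order)
    g = regularization_gradient(v, cfg).data + body_force(state, adjoint).data
    return VelocityField(v.grid, g), state, report


def reduced_gradient(
    v: VelocityField,
    m0: ScalarField,
    m1: ScalarField,
    cfg: RegistrationConfig,
) -> VelocityField:
    """Gradient of the minimized objective with respect to v."""
    g, _, _ = reduced_gradient_and_state(v, m0, m1, cfg)
    return g
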